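"""Bayesian admixture-model ancestry inference and Evanno delta-K selection.

The model is the classic no-linkage admixture model for diploid biallelic
genotypes: each of the two allele copies an individual carries at a locus
originates independently from one of K clusters, cluster k holding alt-allele
frequency P[k, l] at locus l, and individual i holding ancestry proportions
Q[i, :] on the K-simplex with a symmetric Dirichlet(alpha) prior.  Allele
frequencies carry independent Beta(lambda, lambda) priors (the independent-
frequencies variant; no correlated-frequencies prior).

Two inference engines are provided behind one surface:

* ``method="gibbs"`` — the collapsed-state Gibbs sampler: latent allele-copy
  origins, then conjugate Beta/Dirichlet updates for P and Q and a Metropolis
  step for a single shared alpha.  Posterior means over post-burn-in sweeps
  are reported, and the model-evidence estimate follows the
  ``mean(lnL) - var(lnL)/2`` convention so that replicate runs feed the
  Evanno delta-K procedure directly.
* ``method="em"`` — deterministic MAP expectation-maximisation over the same
  likelihood, for fast exact-seed unit testing and quick exploration.

Supervised mode mirrors the use-population-info workflow: cluster frequencies
are learned only from pre-labeled "frequency source" individuals, labeled
individuals are pinned to indicator ancestry (zero migration prior), and only
unlabeled individuals receive admixture estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .snp import MISSING, SnpMatrix

_LN2 = math.log(2.0)
_EPS = 1e-9


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """MCMC run lengths and priors.

    Defaults are the full-scale profile (10,000 burn-in + 50,000 recorded
    sweeps, 3 chains, K = 1..9); :meth:`reduced` gives the test-scale profile
    used throughout the test suite and the pipeline's default.
    """

    burn_in: int = 10_000
    reps: int = 50_000
    n_chains: int = 3
    K_range: tuple[int, ...] = tuple(range(1, 10))
    seed: int = 0
    lambda_: float = 1.0
    infer_alpha: bool = True
    alpha_init: float = 1.0
    alpha_max: float = 10.0
    alpha_proposal_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.burn_in <= 0 or self.reps <= 0:
            raise ValueError("burn_in and reps must be positive")
        if not self.K_range:
            raise ValueError("K_range must be nonempty")

    @classmethod
    def reduced(cls, **kw) -> "RunConfig":
        """Reduced-MCMC profile (1,000 burn-in + 5,000 sweeps)."""
        kw.setdefault("burn_in", 1_000)
        kw.setdefault("reps", 5_000)
        return cls(**kw)


@dataclass(frozen=True)
class PopPrior:
    """Per-individual population labels for supervised runs.

    ``labels[i]`` is the predefined population index of individual i, or -1
    for unlabeled; ``flags[i]`` marks i as an allele-frequency source
    (frequencies-from-flagged-only semantics).  Flagged individuals must be
    labeled.
    """

    labels: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        flags = np.asarray(self.flags, dtype=bool)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "flags", flags)
        if labels.shape != flags.shape:
            raise ValueError("labels and flags must align")
        if (flags & (labels < 0)).any():
            raise ValueError("flagged individuals must be labeled")

    @classmethod
    def from_labels(cls, labels, n_pops: int | None = None) -> "PopPrior":
        labels = np.asarray(labels, dtype=int)
        return cls(labels=labels, flags=labels >= 0)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class AncestryFit:
    """Fitted ancestry model: posterior-mean Q and P, alpha, and evidence."""

    K: int
    Q: np.ndarray  # (n, K) ancestry proportions; rows sum to 1
    P: np.ndarray  # (K, L) cluster alt-allele frequencies in (0, 1)
    alpha: float
    lnP_data: float
    lnL_trace: np.ndarray
    ids: list[str] = field(default_factory=list)
    method: str = "gibbs"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if not np.isfinite(self.lnL_trace).all():
            raise ValueError("non-finite log-likelihood trace")

    def q_frame(self) -> pd.DataFrame:
        cols = [f"cluster{k + 1}" for k in range(self.K)]
        idx = self.ids if self.ids else list(range(self.Q.shape[0]))
        return pd.DataFrame(self.Q, index=idx, columns=cols)

    def summary(self) -> str:
        lines = [
            f"Admixture fit (method={self.method}, K={self.K}, "
            f"n={self.Q.shape[0]}, loci={self.P.shape[1]})",
            f"  alpha        : {self.alpha:.4f}",
            f"  ln P(data)   : {self.lnP_data:.2f}",
            "  mean Q       : "
            + "  ".join(f"{v:.3f}" for v in self.Q.mean(axis=0)),
        ]
        return "\n".join(lines)

    def reorder_clusters(self, perm: np.ndarray) -> "AncestryFit":
        perm = np.asarray(perm, dtype=int)
        return replace(self, Q=self.Q[:, perm].copy(), P=self.P[perm].copy())


@dataclass
class EvannoResult:
    """Evanno delta-K table and the selected optimal K."""

    table: pd.DataFrame  # index K; columns L_mean, L_sd, L1, L2_abs, delta_K
    optimal_K: int

    def summary(self) -> str:
        return (
            f"Evanno delta-K selection: optimal K = {self.optimal_K}\n"
            + self.table.to_string(float_format=lambda v: f"{v:.3f}")
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def loglik(m: SnpMatrix | np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial admixture log-likelihood of the dosage matrix under (Q, P).

    ``sum over non-missing calls of ln C(2,x) + x ln(theta) +
    (2-x) ln(1-theta)`` with ``theta = Q @ P``, frequency-clamped for
    finiteness.
    """
    calls = m.calls if isinstance(m, SnpMatrix) else np.asarray(m)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if Q.shape[0] != calls.shape[0] or P.shape[1] != calls.shape[1] or Q.shape[1] != P.shape[0]:
        raise ValueError(
            f"dimension mismatch: calls {calls.shape}, Q {Q.shape}, P {P.shape}"
        )
    present = calls != MISSING
    x = np.where(present, calls, 0).astype(float)
    theta = _clamp(Q @ _clamp(P))
    ll = x * np.log(theta) + (2.0 - x) * np.log1p(-theta)
    ll += np.where(calls == 1, _LN2, 0.0)
    return float(ll[present].sum())


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class AdmixtureModel:
    """Admixture model bound to a (filtered) SNP matrix.

    ``fit`` runs unsupervised inference at a given K; ``fit_supervised``
    pins labeled individuals and learns frequencies from flagged sources
    only.  ``fit_k_grid`` runs replicate chains over a K grid and returns
    the per-K evidence values that :func:`evanno` consumes.
    """

    def __init__(self, m: SnpMatrix):
        self.m = m
        self._calls = m.calls
        self._present = m.calls != MISSING
        self._altc = np.where(self._present, self._calls, 0).astype(np.int64)
        self._refc = np.where(self._present, 2 - self._calls, 0).astype(np.int64)
        self._lnbinom = np.where(self._calls == 1, _LN2, 0.0) * self._present

    # -- public API -----------------------------------------------------

    def fit(
        self,
        K: int,
        config: RunConfig | None = None,
        method: str = "gibbs",
        seed: int | None = None,
    ) -> AncestryFit:
        """Unsupervised fit at a fixed K."""
        cfg = config or RunConfig.reduced()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        self._check_k(K)
        if method == "gibbs":
            fit = self._gibbs(K, cfg, prior=None)
        elif method == "em":
            fit = self._em(K, cfg, prior=None)
        else:
            raise ValueError(f"unknown method {method!r}")
        return self._canonicalize(fit)

    def fit_supervised(
        self,
        K: int,
        prior: PopPrior,
        config: RunConfig | None = None,
        method: str = "gibbs",
        seed: int | None = None,
    ) -> AncestryFit:
        """Supervised fit: frequencies from flagged individuals only."""
        cfg = config or RunConfig.reduced()
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        self._check_k(K)
        labels = prior.labels
        if labels.shape[0] != self.m.n_individuals:
            raise ValueError("prior length does not match individuals")
        for k in range(K):
            if not ((labels == k) & prior.flags).any():
                raise ValueError(f"predefined population {k} has no flagged source")
        if method == "gibbs":
            return self._gibbs(K, cfg, prior=prior)
        if method == "em":
            return self._em(K, cfg, prior=prior)
        raise ValueError(f"unknown method {method!r}")

    def fit_k_grid(
        self,
        config: RunConfig | None = None,
        method: str = "gibbs",
    ) -> tuple[dict[int, list[float]], dict[int, list[AncestryFit]]]:
        """Replicate chains over ``config.K_range``.

        Returns ``(lnP by K, fits by K)``; chain c at K uses seed
        ``config.seed + 1000*K + c`` so the grid is reproducible from a
        single seed.
        """
        cfg = config or RunConfig.reduced()
        lnp: dict[int, list[float]] = {}
        fits: dict[int, list[AncestryFit]] = {}
        for K in cfg.K_range:
            lnp[K] = []
            fits[K] = []
            for c in range(cfg.n_chains):
                chain_cfg = replace(cfg, seed=cfg.seed + 1000 * K + c)
                f = self.fit(K, config=chain_cfg, method=method)
                lnp[K].append(f.lnP_data)
                fits[K].append(f)
        return lnp, fits

    # -- internals ------------------------------------------------------

    def _check_k(self, K: int) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > self.m.n_individuals:
            raise ValueError(
                f"K={K} exceeds number of individuals ({self.m.n_individuals})"
            )

    def _loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        theta = _clamp(Q @ P)
        ll = self._altc * np.log(theta) + self._refc * np.log1p(-theta)
        return float(ll.sum() + self._lnbinom.sum())

    def _finish(self, K, Q, P, alpha, trace, method, seed) -> AncestryFit:
        trace = np.asarray(trace, dtype=float)
        lnp = float(trace.mean() - trace.var() / 2.0) if trace.size else float("nan")
        Q = Q / Q.sum(axis=1, keepdims=True)
        return AncestryFit(
            K=K,
            Q=Q,
            P=_clamp(P),
            alpha=float(alpha),
            lnP_data=lnp,
            lnL_trace=trace,
            ids=self.m.ids,
            method=method,
            seed=seed,
        )

    def _canonicalize(self, fit: AncestryFit) -> AncestryFit:
        """Stable cluster order: descending total Q mass."""
        order = np.argsort(-fit.Q.sum(axis=0), kind="stable")
        return fit.reorder_clusters(order)

    # .. Gibbs ...........................................................

    def _gibbs(self, K: int, cfg: RunConfig, prior: PopPrior | None) -> AncestryFit:
        rng = np.random.default_rng(cfg.seed)
        n, L = self._calls.shape
        lam = cfg.lambda_
        altc, refc, present = self._altc, self._refc, self._present

        supervised = prior is not None
        if supervised:
            labeled = prior.labels >= 0
            flagged = prior.flags
            # Origins of flagged individuals' alleles are known, so their
            # contribution to the frequency posterior is a fixed Beta count.
            alt_flag = np.zeros((K, L))
            ref_flag = np.zeros((K, L))
            for k in range(K):
                src = flagged & (prior.labels == k)
                alt_flag[k] = altc[src].sum(axis=0)
                ref_flag[k] = refc[src].sum(axis=0)
            free = ~labeled  # individuals whose Q is inferred
        else:
            labeled = np.zeros(n, dtype=bool)
            free = ~labeled

        # init
        Q = rng.dirichlet(np.ones(K), size=n)
        if supervised:
            Q[labeled] = np.eye(K)[prior.labels[labeled]]
        P = rng.beta(1.0, 1.0, size=(K, L))
        alpha = cfg.alpha_init

        total = cfg.burn_in + cfg.reps
        trace = np.empty(cfg.reps)
        Q_sum = np.zeros_like(Q)
        P_sum = np.zeros_like(P)
        alpha_sum = 0.0
        kept = 0

        alt1 = (self._calls >= 1) & present  # first allele copy is alt
        alt2 = (self._calls == 2) & present  # second copy is alt

        for sweep in range(total):
            if K == 1:
                if supervised:
                    a_kl = alt_flag
                    r_kl = ref_flag
                else:
                    a_kl = altc.sum(axis=0, keepdims=True)
                    r_kl = refc.sum(axis=0, keepdims=True)
                P = rng.beta(lam + a_kl, lam + r_kl)
                Q[:] = 1.0
            else:
                # per-copy origin sampling
                W_alt = Q[:, :, None] * P[None, :, :]
                W_ref = Q[:, :, None] * (1.0 - P)[None, :, :]
                z1 = _sample_origins(W_alt, W_ref, alt1, rng)
                z2 = _sample_origins(W_alt, W_ref, alt2, rng)

                n_ik = np.zeros((n, K))
                a_kl = np.zeros((K, L))
                r_kl = np.zeros((K, L))
                for k in range(K):
                    m1 = (z1 == k) & present
                    m2 = (z2 == k) & present
                    n_ik[:, k] = m1.sum(axis=1) + m2.sum(axis=1)
                    a_kl[k] = (m1 & alt1).sum(axis=0) + (m2 & alt2).sum(axis=0)
                    r_kl[k] = (m1 & ~alt1).sum(axis=0) + (m2 & ~alt2).sum(axis=0)

                if supervised:
                    # only flagged individuals inform frequencies, with known origin
                    P = rng.beta(lam + alt_flag, lam + ref_flag)
                else:
                    P = rng.beta(lam + a_kl, lam + r_kl)
                P = _clamp(P)

                g = rng.gamma(alpha + n_ik[free])
                Q[free] = g / g.sum(axis=1, keepdims=True)

                if cfg.infer_alpha and free.any():
                    alpha = self._alpha_step(alpha, Q[free], K, cfg, rng)

            ll = self._loglik(Q, P)
            if sweep >= cfg.burn_in:
                trace[sweep - cfg.burn_in] = ll
                Q_sum += Q
                P_sum += P
                alpha_sum += alpha
                kept += 1

        return self._finish(
            K, Q_sum / kept, P_sum / kept, alpha_sum / kept, trace, "gibbs", cfg.seed
        )

    @staticmethod
    def _alpha_step(alpha, Qf, K, cfg, rng) -> float:
        prop = alpha + rng.normal(0.0, cfg.alpha_proposal_sd)
        if not 0.0 < prop < cfg.alpha_max:
            return alpha
        nf = Qf.shape[0]
        s = np.log(_clamp(Qf)).sum()

        def logp(a: float) -> float:
            return nf * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * s

        if math.log(rng.random()) < logp(prop) - logp(alpha):
            return prop
        return alpha

    # .. EM (MAP) ........................................................

    def _em(
        self,
        K: int,
        cfg: RunConfig,
        prior: PopPrior | None,
        max_iter: int = 500,
        tol: float = 1e-6,
    ) -> AncestryFit:
        rng = np.random.default_rng(cfg.seed)
        n, L = self._calls.shape
        altc = self._altc.astype(float)
        refc = self._refc.astype(float)

        supervised = prior is not None
        if supervised:
            labeled = prior.labels >= 0
            flagged = prior.flags
            alt_flag = np.zeros((K, L))
            ref_flag = np.zeros((K, L))
            for k in range(K):
                src = flagged & (prior.labels == k)
                alt_flag[k] = altc[src].sum(axis=0)
                ref_flag[k] = refc[src].sum(axis=0)
            P = _clamp(alt_flag / np.maximum(alt_flag + ref_flag, 1.0))
        else:
            labeled = np.zeros(n, dtype=bool)
            P = _clamp(rng.beta(2.0, 2.0, size=(K, L)))
        free = ~labeled

        Q = rng.dirichlet(np.ones(K) * 5.0, size=n)
        if supervised:
            Q[labeled] = np.eye(K)[prior.labels[labeled]]

        trace = []
        prev = -np.inf
        for _ in range(max_iter):
            theta = _clamp(Q @ P)
            # E-step: expected per-copy origin fractions
            R_alt = Q[:, :, None] * P[None, :, :] / theta[:, None, :]
            R_ref = Q[:, :, None] * (1.0 - P)[None, :, :] / (1.0 - theta)[:, None, :]
            ea = altc[:, None, :] * R_alt  # (n, K, L) expected alt copies from k
            er = refc[:, None, :] * R_ref
            # M-step
            if not supervised:
                a_kl = ea.sum(axis=0)
                r_kl = er.sum(axis=0)
                P = _clamp(a_kl / np.maximum(a_kl + r_kl, _EPS))
            else:
                P = _clamp(alt_flag / np.maximum(alt_flag + ref_flag, 1.0))
            n_ik = (ea + er).sum(axis=2)
            Q[free] = n_ik[free] / np.maximum(
                n_ik[free].sum(axis=1, keepdims=True), _EPS
            )
            ll = self._loglik(Q, P)
            trace.append(ll)
            if abs(ll - prev) < tol:
                break
            prev = ll

        return self._finish(K, Q, P, cfg.alpha_init, np.array([trace[-1]]), "em", cfg.seed)


def _sample_origins(W_alt, W_ref, is_alt, rng) -> np.ndarray:
    """Sample the cluster of one allele copy per (individual, locus).

    ``W_alt``/``W_ref`` are (n, K, L) unnormalized origin weights for an alt
    or ref copy; ``is_alt`` marks which allele this copy carries.
    """
    probs = np.where(is_alt[:, None, :], W_alt, W_ref)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((probs.shape[0], 1, probs.shape[2])) * cum[:, -1:, :]
    return (cum < u).sum(axis=1)


# ---------------------------------------------------------------------------
# replicate alignment and Evanno delta-K
# ---------------------------------------------------------------------------


def align_clusters(fit: AncestryFit, reference: AncestryFit) -> AncestryFit:
    """Permute clusters of ``fit`` to best match ``reference``.

    Greedy maximum-overlap matching on the Q-mass cross product; resolves
    label switching between replicate runs before averaging or comparing.
    """
    if fit.K != reference.K:
        raise ValueError("fits must share K")
    overlap = reference.Q.T @ fit.Q  # (K_ref, K_fit)
    perm = np.full(fit.K, -1, dtype=int)
    used_ref: set[int] = set()
    used_fit: set[int] = set()
    flat = np.argsort(-overlap, axis=None, kind="stable")
    for idx in flat:
        r, f = divmod(int(idx), fit.K)
        if r in used_ref or f in used_fit:
            continue
        perm[r] = f
        used_ref.add(r)
        used_fit.add(f)
        if len(used_ref) == fit.K:
            break
    return fit.reorder_clusters(perm)


def evanno(runs: dict[int, list[float]]) -> EvannoResult:
    """Evanno delta-K model selection from replicate evidence values.

    ``runs`` maps each K on a contiguous grid to its replicate ``lnP_data``
    values.  ``delta_K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K))`` is defined
    for interior K with positive replicate sd; the optimum is the interior K
    maximising delta_K.
    """
    ks = sorted(runs)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K grid must be contiguous")
    L_mean = np.array([np.mean(runs[k]) for k in ks])
    L_sd = np.array([np.std(runs[k], ddof=1) if len(runs[k]) > 1 else 0.0 for k in ks])

    nK = len(ks)
    L1 = np.full(nK, np.nan)
    L2 = np.full(nK, np.nan)
    dK = np.full(nK, np.nan)
    for i in range(nK):
        if i >= 1:
            L1[i] = L_mean[i] - L_mean[i - 1]
        if 1 <= i <= nK - 2:
            L2[i] = abs(L_mean[i + 1] - 2.0 * L_mean[i] + L_mean[i - 1])
            if L_sd[i] > 0:
                dK[i] = L2[i] / L_sd[i]

    table = pd.DataFrame(
        {"L_mean": L_mean, "L_sd": L_sd, "L1": L1, "L2_abs": L2, "delta_K": dK},
        index=pd.Index(ks, name="K"),
    )
    if np.isnan(dK).all():
        raise ValueError(
            "delta-K undefined at every K (zero replicate variance); "
            "inspect lnP(data) directly instead"
        )
    optimal = ks[int(np.nanargmax(dK))]
    return EvannoResult(table=table, optimal_K=optimal)
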