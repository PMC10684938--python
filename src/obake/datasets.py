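"""Published reference data shipped with the package.

``reference_profiles`` returns the supervised (use-population-info, K = 3)
ancestry estimates for the control interspecific crosses (one F1, two F2, and
14 RILs from an *O. sativa* x *O. longistaminata* controlled cross) and the
19 putative spontaneous hybrids detected in the IRRI *O. longistaminata*
genebank survey this package models.  Q components are (sativa,
longistaminata, barthii-glaberrima), averaged over three replicate runs.

``N_LONGISTAMINATA_SAMPLED`` is the number of individuals carrying
*O. longistaminata* ancestry screened in that survey — the denominator of the
spontaneous-hybrid discovery rate.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .hybrids import AncestryProfile

#: individuals with O. longistaminata ancestry screened in the source survey
N_LONGISTAMINATA_SAMPLED: int = 365

_REFERENCE_TSV = """\
entry	q_sativa	q_longistaminata	q_barthii_glaberrima	origin	kind
Bt136	0.46	0.54	0.00	F2 control	control
Bt135	0.47	0.53	0.00	F1 control	control
Bt137	0.49	0.51	0.00	F2 control	control
RILs15	0.82	0.18	0.00	RIL	control
RILs47	0.84	0.16	0.00	RIL	control
RILs31	0.86	0.14	0.00	RIL	control
RILs24	0.86	0.14	0.00	RIL	control
RILs60	0.88	0.12	0.00	RIL	control
RILs3	0.88	0.12	0.00	RIL	control
RILs43	0.88	0.12	0.00	RIL	control
RILs23	0.89	0.11	0.00	RIL	control
RILs27	0.89	0.11	0.00	RIL	control
RILs78	0.89	0.11	0.00	RIL	control
RILs11	0.89	0.11	0.00	RIL	control
RILs48	0.90	0.10	0.00	RIL	control
RILs42	0.90	0.10	0.00	RIL	control
RILs59	0.95	0.05	0.00	RIL	control
101741.002	0.79	0.18	0.04	Senegal	genebank
101211.001	0.71	0.29	0.00	Cote D'Ivoire	genebank
104300.002	0.46	0.53	0.02	Malawi	genebank
105075.002	0.44	0.55	0.01	Nigeria	genebank
101222.002	0.42	0.58	0.00	Mali	genebank
110404.002	0.42	0.56	0.02	India (Mali)	genebank
92650.002	0.39	0.61	0.01	Mali	genebank
89159.002	0.37	0.62	0.01	Mozambique	genebank
103886.001	0.34	0.66	0.00	Tanzania	genebank
106456.002	0.32	0.67	0.01	Mali	genebank
101211.002	0.32	0.68	0.00	Cote D'Ivoire	genebank
101222.001	0.24	0.76	0.00	Mali	genebank
89155.001	0.24	0.75	0.01	Mozambique	genebank
86480.002	0.20	0.80	0.00	Zambia	genebank
104300.001	0.19	0.81	0.00	Malawi	genebank
103886.002	0.19	0.81	0.00	Tanzania	genebank
86480.001	0.15	0.85	0.00	Zambia	genebank
105183.002	0.08	0.92	0.00	Ghana	genebank
101431.001	0.05	0.95	0.00	Tanzania	genebank
"""


def reference_frame() -> pd.DataFrame:
    """The reference ancestry table as a DataFrame indexed by entry."""
    return pd.read_csv(StringIO(_REFERENCE_TSV), sep="\t", dtype={"entry": str}).set_index(
        "entry"
    )


def reference_profiles() -> list[AncestryProfile]:
    """Reference entries as :class:`AncestryProfile` objects.

    Control crosses carry the ``control_hybrid`` species label and an
    *O. sativa* plastid (the cross used a sativa mother); genebank entries
    are longistaminata-labeled with longistaminata plastid haplotypes, as
    observed for every putative spontaneous hybrid in the source survey.
    """
    out = []
    for entry, row in reference_frame().iterrows():
        control = row["kind"] == "control"
        out.append(
            AncestryProfile(
                entry=str(entry),
                q_sativa=row["q_sativa"],
                q_longistaminata=row["q_longistaminata"],
                q_barthii_glaberrima=row["q_barthii_glaberrima"],
                species_label="control_hybrid" if control else "longistaminata",
                plastid_group="sativa" if control else "longistaminata",
                origin=row["origin"],
            )
        )
    return out
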