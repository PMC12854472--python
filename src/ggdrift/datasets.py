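"""Published hominoid reference inputs.

The branch-divergence table below transcribes the published per-branch
squared Mahalanobis distances (46 craniomandibular traits) and Ne/t
ratios (mean and 95% bounds) for 15 hominoid taxa, together with the
published GGD values and their three-way rate shading
(stabilizing = slow/very-slow tail, neutral, directional = fast/very-fast
tail).  Branches are named ancestor-node -> descendant (internal nodes
1-14, tips by taxon).  These printed columns are inputs for reproducing
the published GGD arithmetic and regime calls; the underlying specimen
data are not redistributed here.
"""

from __future__ import annotations

import io

import pandas as pd

from .io import Phylogeny, parse_newick

__all__ = [
    "hominoid_branch_table",
    "hominoid_tree",
    "HOMINOID_TRAIT_COUNT",
]

HOMINOID_TRAIT_COUNT = 46

# shading: S = stabilizing tail, N = neutral, F = directional tail
_BRANCH_TABLE_TSV = """\
ancestor	descendant	d2	ne_t_mean	ggd_mean	shade_mean	ne_t_lower	ggd_lower	shade_lower	ne_t_upper	ggd_upper	shade_upper
1	Pan_troglodytes_troglodytes	14.47	1.11	16.06	S	0.61	8.83	S	1.62	23.44	S
1	Pan_troglodytes_schweinfurthii	13.88	1.11	15.40	S	0.61	8.47	S	1.62	22.48	S
2	Pan_troglodytes_verus	46.77	0.37	17.31	S	0.23	10.76	S	0.50	23.39	S
2	1	8.73	0.37	3.23	S	0.23	2.01	S	0.50	4.36	S
3	Pan_paniscus	150.91	0.27	40.75	N	0.18	27.16	S	0.35	52.82	N
3	2	13.63	0.27	3.68	S	0.18	2.45	S	0.35	4.77	S
4	Homo_sapiens	669.03	0.18	120.43	F	0.14	93.66	F	0.23	153.88	F
4	3	173.06	0.18	31.15	S	0.14	24.23	S	0.21	36.34	N
5	Gorilla_beringei_beringei	113.07	0.69	78.02	F	0.40	45.23	N	0.99	111.94	F
5	Gorilla_beringei_graueri	23.57	0.69	16.26	S	0.40	9.43	S	0.99	23.33	S
6	Gorilla_gorilla	74.78	0.26	19.44	S	0.18	13.46	S	0.33	24.68	S
6	5	43.71	0.26	11.37	S	0.18	7.87	S	0.33	14.43	S
7	6	164.44	0.15	24.67	S	0.12	19.73	S	0.18	29.60	S
7	4	12.92	0.15	1.94	S	0.12	1.55	S	0.18	2.33	S
8	Pongo_pygmaeus	49.88	0.36	17.96	S	0.23	11.47	S	0.50	24.94	S
8	Pongo_abelii	134.15	0.36	48.29	N	0.23	30.85	S	0.50	67.08	F
9	7	89.87	0.15	13.48	S	0.12	10.78	S	0.18	16.18	S
9	8	208.54	0.15	31.28	S	0.12	25.02	S	0.18	37.54	N
10	Hylobates_muelleri	38.09	0.16	6.09	S	0.13	4.95	S	0.19	7.24	S
10	Hylobates_agilis	35.67	0.16	5.71	S	0.13	4.64	S	0.19	6.78	S
11	Hylobates_lar	34.13	0.14	4.78	S	0.12	4.10	S	0.17	5.80	S
11	10	6.18	0.14	0.87	S	0.12	0.74	S	0.17	1.05	S
12	Symphalangus_syndactylus	65.41	0.23	15.04	S	0.16	10.47	S	0.29	18.97	S
12	11	113.92	0.23	26.20	S	0.16	18.23	S	0.29	33.04	N
13	Hoolock_hoolock	46.40	0.18	8.35	S	0.14	6.50	S	0.23	10.67	S
13	12	0.43	0.18	0.08	S	0.14	0.06	S	0.23	0.10	S
14	9	15.52	0.14	2.17	S	0.12	1.86	S	0.16	2.48	S
14	13	498.49	0.14	69.79	F	0.12	59.82	N	0.16	79.76	F
"""

# Published 15-taxon topology; internal node labels 1-14 follow the branch
# table.  Branch lengths are placeholders (the published ML lengths are not
# transcribed) and must not be used quantitatively.
_HOMINOID_NEWICK = (
    "(((((((Pan_troglodytes_troglodytes:1,Pan_troglodytes_schweinfurthii:1)1:1,"
    "Pan_troglodytes_verus:1)2:1,Pan_paniscus:1)3:1,Homo_sapiens:1)4:1,"
    "((Gorilla_beringei_beringei:1,Gorilla_beringei_graueri:1)5:1,"
    "Gorilla_gorilla:1)6:1)7:1,(Pongo_pygmaeus:1,Pongo_abelii:1)8:1)9:1,"
    "((((Hylobates_muelleri:1,Hylobates_agilis:1)10:1,Hylobates_lar:1)11:1,"
    "Symphalangus_syndactylus:1)12:1,Hoolock_hoolock:1)13:1)14;"
)


def hominoid_branch_table() -> pd.DataFrame:
    """The published 28-branch divergence table (see module docstring)."""
    df = pd.read_csv(io.StringIO(_BRANCH_TABLE_TSV), sep="\t", dtype={"ancestor": str, "descendant": str})
    return df


def hominoid_tree() -> Phylogeny:
    """The published 15-taxon hominoid topology (placeholder branch lengths)."""
    return parse_newick(_HOMINOID_NEWICK)
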