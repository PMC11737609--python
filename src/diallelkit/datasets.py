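"""Published summary tables of the motivating FAW-resistance diallel study.

A 21-parent half-diallel (210 F1 hybrids, two Kenyan environments, two
replicates, alpha-lattice) evaluated under fall-armyworm infestation.  The
study's raw plot data are not public; these printed summary tables are the
study's published surface and serve as inputs for validating the
combining-ability arithmetic (variance-component reconstruction, Baker
ratios, group means, zero-sum checks).

Traits: FD1-FD3 foliar damage 7/14/21 days after infestation (1-9 scale),
ED ear damage (1-9), GY grain yield (t/ha), ER ear rot (%), AD/SD days to
anthesis/silking, PH/EH plant/ear height (cm).
"""

from __future__ import annotations

import io

import pandas as pd

STUDY_P = 21       # parents
STUDY_E = 2        # environments
STUDY_R = 2        # replicates per environment

#: Across-environment ANOVA mean squares (plot-equivalent scale) and df.
_MEAN_SQUARES = """\
source	df	FD1	FD2	FD3	ED	GY	AD	SD	PH	EH
Environment	1	585.14	1226.48	188.82	904.29	517.27	1370.63	1643.60	449354.88	66285.68
Rep(Env)	2	11.15	0.70	0.47	1.91	84.25	86.92	120.55	2363.93	761.11
Hybrids	209	0.84	0.93	1.50	1.04	5.35	12.60	14.23	1339.47	715.07
GCA	20	3.99	4.16	8.40	6.33	26.50	102.27	106.97	8146.64	4740.95
SCA	189	0.53	0.62	0.83	0.48	3.14	3.12	4.42	648.26	299.01
HxE	209	0.69	0.63	0.86	0.47	2.64	1.74	2.86	366.30	159.28
GCAxE	20	1.18	1.97	2.84	1.91	8.48	2.78	5.22	544.96	160.24
SCAxE	189	0.61	0.46	0.67	0.32	2.06	1.63	2.62	324.74	152.39
Error	225	0.30	0.32	0.36	0.23	1.23	1.25	1.42	109.10	47.82
"""

#: Published plot-error variance (separate REML fit; differs slightly from
#: the ANOVA Error mean square above, e.g. 1.29 vs 1.23 for GY).
_SIGMA2_E = {
    "FD1": 0.31, "FD2": 0.33, "FD3": 0.37, "ED": 0.23, "GY": 1.29,
    "AD": 1.30, "SD": 1.50, "PH": 109.31, "EH": 46.66,
}

#: Top 15 hybrids and the four commercial checks: published entry means.
_TOP_TABLE = """\
entry	GY	AD	PH	FD1	FD2	FD3	ED	ER
CKSBL10153/CKDHL0214	8.16	58.71	273.92	3.87	5.46	4.39	1.96	5.33
CKSBL10039/CKSBL10060	7.87	55.60	279.81	4.35	4.93	4.79	1.81	2.04
CKSBL10011/CLRCY039	7.60	57.83	275.11	4.27	4.98	4.76	1.85	-0.43
CKDHL164271/CML338	7.56	54.40	280.50	4.78	5.72	5.10	1.78	3.64
CKDHL0214/CLRCY039	7.52	59.57	263.95	4.29	5.47	5.22	1.99	2.74
CKSBL10039/CKSBL10153	7.51	58.25	289.92	3.87	4.03	3.61	2.00	12.00
CKSBL10043/CKSBL10060	7.47	52.57	245.47	3.69	4.36	4.76	1.79	1.45
CKSBL10008/CML338	7.42	54.30	281.35	2.91	3.59	3.35	2.01	2.04
CML560/CKSBL10008	7.42	54.35	274.88	4.42	5.59	4.93	2.20	3.94
CKDHL0214/CML22	7.41	58.39	263.14	4.63	4.95	4.72	2.38	3.17
CKSBL10008/CLRCY039	7.26	60.58	272.28	4.11	4.53	4.20	1.78	2.17
CKSBL10153/CLRCY039	7.17	61.18	278.15	3.72	4.55	3.81	1.73	-0.10
CKSBL10039/CLRCY039	7.16	59.96	285.15	4.54	5.19	4.59	2.49	5.45
CKDHL0214/CML338	7.14	55.26	275.24	4.36	5.25	4.63	2.01	3.39
CKSBL10039/CML338	7.08	55.60	267.80	3.99	4.83	4.74	1.85	8.12
"""

_CHECK_TABLE = """\
entry	GY	AD	PH	FD1	FD2	FD3	ED	ER
WE1101	5.29	56.56	258.55	4.68	5.45	5.32	2.57	8.59
Duma43	4.40	53.53	266.79	4.41	5.58	5.55	3.85	35.99
DK8031	3.69	55.68	260.68	4.99	6.03	5.75	4.65	50.64
DH04	2.97	58.01	254.36	5.03	6.32	6.07	3.31	40.83
"""

#: Published parental GCA effects for grain yield (t/ha), all 21 parents.
_GCA_GY = {
    "CKSBL10026": -0.63, "CKSPL10158": -0.71, "CKSPL10007": -0.43,
    "CKSBL10011": -0.01, "CKSBL10027": -0.87, "CKSBL10039": 0.68,
    "CKSBL10008": 0.81, "CML560": -0.20, "CKSBL10043": 0.12,
    "CKSBL10060": 0.36, "CKIR04005": 0.06, "CKSBL10153": 1.11,
    "CKDHL0214": 0.26, "CKSBL10020": -1.07, "CKDHL121320": -0.26,
    "CLRCY039": 0.99, "CKDHL166075": -0.06, "CKDHL164271": 0.24,
    "CKSPL10089": 0.13, "CML22": -0.01, "CML71": -0.51,
}


def reference_mean_squares() -> pd.DataFrame:
    """ANOVA mean squares of the study, rows = sources, with a df column."""
    return pd.read_csv(io.StringIO(_MEAN_SQUARES), sep="\t", index_col=0)


def reference_sigma2_e() -> pd.Series:
    """Published plot-error variances (REML), per trait."""
    return pd.Series(_SIGMA2_E, name="sigma2_e")


def reference_top15() -> pd.DataFrame:
    """Published means of the 15 best-yielding experimental hybrids."""
    return pd.read_csv(io.StringIO(_TOP_TABLE), sep="\t", index_col=0)


def reference_checks() -> pd.DataFrame:
    """Published means of the four commercial check hybrids."""
    return pd.read_csv(io.StringIO(_CHECK_TABLE), sep="\t", index_col=0)


def reference_gca_gy() -> pd.Series:
    """Published grain-yield GCA effects of the 21 parents."""
    return pd.Series(_GCA_GY, name="GY")
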