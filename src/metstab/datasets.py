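"""Published summary tables from the horse gram multi-environment trials.

The raw plot-level records of the 30-genotype x 6-environment x
6-replicate horse gram MET are not deposited; what is public are the
printed summaries — per-genotype trait means across environments (with
average YREM), the REML variance components per trait, and the
selection-response table.  These are embedded here as small inline CSV
text so the worked examples and acceptance checks run from the numbers
the trials actually reported.  Trait units: DM days, NC clusters/plant,
NP pods/plant, NPC pods/cluster, NS seeds/pod, YD kg/ha.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "load_genotype_means",
    "load_variance_components",
    "load_selection_response",
]

# Per-genotype means over the six environments, plus each genotype's
# average YREM and the published yield/YREM rank.
_GENOTYPE_MEANS_CSV = """\
GEN,name,DM,NC,NP,NPC,NS,YD,avg_yrem,rank
G1,TNAU-HG-007,123.69,204.61,535.07,4.16,6.28,1335.28,1.00,1
G2,TNAU-HG-031,121.63,122.91,397.31,3.14,5.44,852.79,0.64,20
G3,TNAU-HG-070,122.41,205.19,518.81,3.90,5.89,1245.03,0.93,2
G4,TNAU-HG-034,123.66,186.02,397.68,3.12,5.51,1051.19,0.79,7
G5,TNAU-HG-019,120.37,169.59,444.75,3.61,5.32,864.61,0.65,17
G6,TNAU-HG-027,119.89,131.54,423.53,3.56,5.33,916.89,0.69,12
G7,TNAU-HG-049,124.45,169.68,354.73,3.34,5.96,908.03,0.68,14
G8,TNAU-HG-018,121.53,193.73,521.47,3.75,5.84,1122.83,0.84,6
G9,TNAU-HG-062,120.92,165.18,389.51,3.63,5.02,818.04,0.61,25
G10,TNAU-HG-057,121.96,170.32,448.20,3.29,5.48,886.31,0.66,15
G11,TNAU-HG-073,120.90,124.84,409.58,3.55,5.35,854.22,0.64,19
G12,TNAU-HG-083,120.80,145.97,351.02,3.59,5.44,909.15,0.69,13
G13,TNAU-HG-036,120.48,170.57,325.07,3.26,5.24,863.82,0.65,16
G14,TNAU-HG-030,118.66,126.23,417.03,3.28,4.96,729.49,0.55,30
G15,TNAU-HG-082,121.10,198.09,320.01,3.61,4.86,953.69,0.71,10
G16,TNAU-HG-025,119.56,142.57,428.23,3.16,5.18,804.59,0.63,21
G17,TNAU-HG-053,118.50,115.91,380.95,3.19,5.09,790.24,0.60,27
G18,TNAU-HG-016,118.68,127.36,458.40,3.36,4.96,840.80,0.63,22
G19,TNAU-HG-071,123.53,122.58,349.50,3.49,5.39,825.18,0.62,23
G20,TNAU-HG-075,120.10,118.10,377.86,3.05,4.92,784.59,0.61,26
G21,TNAU-HG-065,122.96,114.76,340.12,2.98,4.84,758.92,0.58,28
G22,TNAU-HG-089,120.63,199.20,521.97,3.93,5.76,1212.73,0.91,4
G23,TNAU-HG-032,123.66,156.34,418.26,3.47,5.55,863.36,0.65,18
G24,TNAU-HG-003,121.51,122.88,357.57,3.09,5.11,810.48,0.61,24
G25,TNAU-HG-081,114.66,194.86,485.29,3.63,6.28,1217.08,0.91,3
G26,TNAU-HG-011,120.59,137.02,391.01,3.23,5.39,768.52,0.58,29
G27,TNAU-HG-039,119.98,199.13,517.42,3.63,5.50,1160.29,0.87,5
G28,TNAU-HG-076,122.71,187.07,309.85,3.48,5.36,1020.50,0.76,9
G29,TNAU-HG-044,125.96,177.73,418.28,3.39,5.67,1048.48,0.79,8
G30,PAIYUR2,126.58,189.86,204.26,3.53,5.20,925.57,0.69,11
"""

# REML variance components per trait (genotype, genotype x environment,
# plot error) from the published mixed-model fits; design 6 environments
# x 6 replicates.
_VARIANCE_COMPONENTS_CSV = """\
trait,sigma2_g,sigma2_gei,sigma2_e
DM,3.13,5.42,37.20
NC,966.70,217.00,69.41
NP,5488.00,841.70,439.90
NPC,0.06,0.11,0.03
NS,0.114,0.175,0.074
YD,25425.00,1663.00,2374.00
"""

# Published selection response at 15% intensity (4 genotypes): overall
# mean Xo, selected mean Xs, selection differential SD% and gain SG%.
_SELECTION_RESPONSE_CSV = """\
trait,Xo,Xs,SD_pct,SG_pct
NC,160.00,201.00,25.70,24.70
NP,407.00,524.00,28.80,28.00
NPC,3.45,3.94,14.20,10.80
NS,5.40,5.94,9.94,7.81
YD,942.00,1229.00,30.40,30.00
DM,122.00,122.00,0.05,0.03
"""

DESIGN_E = 6
DESIGN_R = 6


def load_genotype_means() -> pd.DataFrame:
    """Genotype x trait means across environments (index GEN)."""
    return pd.read_csv(io.StringIO(_GENOTYPE_MEANS_CSV), index_col="GEN")


def load_variance_components() -> pd.DataFrame:
    """Per-trait variance components (index trait)."""
    return pd.read_csv(io.StringIO(_VARIANCE_COMPONENTS_CSV), index_col="trait")


def load_selection_response() -> pd.DataFrame:
    """Per-trait published selection response at 15% intensity."""
    return pd.read_csv(io.StringIO(_SELECTION_RESPONSE_CSV), index_col="trait")
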