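"""Published reference statistics for analytic validation.

Summary numbers reported by the clinical STN-DBS / uric-acid connectivity
study that this pipeline operationalizes: the per-ROI UA-DC correlations
that survived screening, the group-difference edge t statistics, cohort
counts, and UPDRS-III summary means.  They serve as worked examples — the
pipeline's formulas must reproduce the printed p-values and derived counts
from these inputs.
"""

from __future__ import annotations

import pandas as pd

# Screened ROIs: atlas index, region name, reported Pearson r (n = 32 PD).
ROI_SCREEN_ROWS = [
    (3, "Frontal_Sup_2_L", 0.444),
    (4, "Frontal_Sup_2_R", 0.425),
    (5, "Frontal_Mid_2_L", 0.398),
    (20, "Frontal_Sup_Medial_R", 0.394),
    (83, "Heschl_L", -0.350),
    (101, "Cerebellum_4_5_L", -0.364),
    (109, "Cerebellum_9_L", -0.359),
    (110, "Cerebellum_9_R", -0.431),
    (111, "Cerebellum_10_L", -0.365),
    (112, "Cerebellum_10_R", -0.415),
    (119, "Vermis_9", -0.423),
    (120, "Vermis_10", -0.368),
    (123, "Thal_LP_L", -0.369),
    (135, "Thal_MDm_L", -0.405),
    (136, "Thal_MDm_R", -0.380),
]

# Group-difference edges and their reported pooled-t statistics (df = 61).
EDGE_TEST_ROWS = [
    ("Frontal_Sup_2_L", "Heschl_L", -3.402),
    ("Frontal_Sup_2_R", "Heschl_L", -3.745),
    ("Frontal_Sup_Medial_R", "Heschl_L", -3.704),
    ("Cerebellum_9_L", "Cerebellum_10_L", -3.473),
]

# Cohort bookkeeping.
N_PD_ENROLLED = 38
N_PD_DIMENSION_EXCLUDED = 6
N_HC_ENROLLED = 32
N_HC_MOTION_EXCLUDED = 1
N_PD_ANALYSED = N_PD_ENROLLED - N_PD_DIMENSION_EXCLUDED      # 32
N_HC_ANALYSED = N_HC_ENROLLED - N_HC_MOTION_EXCLUDED         # 31

# Atlas bookkeeping: 166 defined regions, two undefined at 3 mm resolution.
ATLAS_N_DEFINED = 166
ATLAS_EXCLUDED_IDS = (133, 134)

# UPDRS-III cohort means (points) and improvement-rate summary.
UPDRS3_PRE_OFF_MEAN = 57.29
UPDRS3_PRE_ON_MEAN = 29.05
UPDRS3_POST_OFF_MEAN = 50.79
UPDRS3_POST_ON_MEAN = 19.34
IMPROVEMENT_RATE_MEAN = 0.66
IMPROVEMENT_RATE_SD = 0.21

# Serum uric acid (umol/L).
UA_PD_MEAN, UA_PD_SD = 288.45, 87.05
UA_HC_MEAN, UA_HC_SD = 327.36, 10.57


def roi_screen_table() -> pd.DataFrame:
    return pd.DataFrame(ROI_SCREEN_ROWS, columns=["index", "roi", "r"])


def edge_test_table() -> pd.DataFrame:
    return pd.DataFrame(EDGE_TEST_ROWS, columns=["roi_a", "roi_b", "t"])
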