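"""Published summary counts from the motivating 75-patient PAS cohort.

The patient-level data of the motivating clinical study are not publicly
available; only aggregate tables were printed.  Those printed counts are
inputs here: they drive the contingency-table analyses exactly and anchor
the marginal distributions of the synthetic cohort generator.

Row/column conventions are documented per table.  All counts are integers
as printed.
"""

from __future__ import annotations

import numpy as np

#: screened / included sample sizes
N_SCREENED = 125
N_INCLUDED = 75

#: exclusion reasons in the published listing order -> count
EXCLUSION_COUNTS = {
    "no_pas_at_surgery": 28,
    "incomplete_records": 14,
    "postpartum_imaging_only": 4,
    "caesarean_scar_pregnancy": 2,
    "stillbirth_induction": 2,
}

#: blood-loss groups, in order: GBL (<1000 ml), MBL (1000-<2000), ex-MBL (>=2000)
GROUP_LABELS = ("GBL", "MBL", "ex-MBL")
GROUP_SIZES = (25, 26, 24)

#: placental attachment by blood-loss group; rows GBL/MBL/ex-MBL,
#: columns LLP, MPP, PPP, CPP (the non-previa column is empty and dropped)
ATTACHMENT_LABELS = ("LLP", "MPP", "PPP", "CPP")
ATTACHMENT_BY_GROUP = np.array([
    [1, 3, 2, 19],
    [5, 2, 1, 18],
    [0, 1, 0, 23],
])

#: haemostasis measures by group; rows balloon occlusion, uterine artery
#: ligation, uterine (sub)total resection; columns GBL, MBL, ex-MBL
HAEMOSTASIS_LABELS = ("balloon_occlusion", "arterial_ligation", "resection")
HAEMOSTASIS_BY_GROUP = np.array([
    [2, 5, 12],
    [17, 17, 10],
    [0, 2, 3],
])

#: prophylactic balloon occlusion, ex-MBL versus the two other groups:
#: rows (ex-MBL, others), columns (balloon, no balloon)
BALLOON_EXMBL_VS_REST = np.array([
    [12, 12],
    [7, 44],
])

#: final myometrial-thickness grades across the cohort (G0, G1, G2)
MT_GRADE_COUNTS = (37, 14, 24)

#: placental attachment margins (non-PP, LLP, MPP, PPP, CPP)
PREVIA_COUNTS = (0, 6, 6, 3, 60)

#: depth of chorionic invasion (accreta, increta, percreta)
PAS_DEPTH_COUNTS = (15, 44, 16)

#: patients in whom no dark band was seen (volume recorded as zero)
N_ZERO_DIB = 19
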