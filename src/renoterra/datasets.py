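"""Bundled example data: a five-patient horseshoe-kidney surgical cohort.

Per-patient volumetry as measured on pre- and postoperative CT angiography:
number of artery ostia, total parenchyma volumes (cm3), endpoint counts on
each scan, and the predicted loss (PKVL) from the preoperative territory
analysis.  These printed measurements drive the worked examples and the
validation statistics; the underlying scans are not distributable.
"""

from __future__ import annotations

import pandas as pd

_COHORT_ROWS = [
    # patient, ostia_n, vol_pre_cm3, vol_post_cm3, endpoints_pre, endpoints_post,
    # pkvl_cm3, pkvl_pct
    (1, 5, 447.2, 412.4, 23, 21, 23.0, 5.1),
    (2, 3, 331.7, 318.1, 28, 26, 36.5, 11.0),
    (3, 5, 271.2, 226.7, 19, 15, 44.5, 16.4),
    (4, 2, 317.2, 209.1, 17, 14, 132.7, 41.8),
    (5, 5, 432.5, 373.8, 25, 23, 34.4, 8.0),
]


def load_cohort() -> pd.DataFrame:
    """Five-patient cohort of paired pre/postoperative kidney volumetry.

    Columns: ``patient``, ``ostia_n``, ``vol_pre_cm3``, ``vol_post_cm3``,
    ``endpoints_pre``, ``endpoints_post``, ``pkvl_cm3``, ``pkvl_pct``.
    KVLS is deliberately not a column: it is derived (``vol_pre - vol_post``)
    and recomputing it is the worked example.
    """
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "patient",
            "ostia_n",
            "vol_pre_cm3",
            "vol_post_cm3",
            "endpoints_pre",
            "endpoints_post",
            "pkvl_cm3",
            "pkvl_pct",
        ],
    )
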