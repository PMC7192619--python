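"""Small built-in reference datasets.

``sqkv1a_assay_summary`` carries the published per-position summary of
the SqKv1A amplicon axoplasm assay: for each naturally edited adenosine
of the substrate, the in vivo editing percentage and the replicate-mean
editing percentage (with SEM) for control and axoplasm reactions
(n = 5 each). Values are percentages, e.g. 0.78 means 0.78%.
"""

from __future__ import annotations

import pandas as pd

from axonedit.model import EditingSite

# position, in_vivo_percent, mean_ctl, sem_ctl, mean_exp, sem_exp
_SQKV1A_ROWS = [
    (44, 27.0, 0.00, 0.00, 0.00, 0.00),
    (48, 8.0, 0.02, 0.00, 0.02, 0.00),
    (63, 20.0, 0.02, 0.00, 0.04, 0.01),
    (103, 5.0, 0.01, 0.00, 0.01, 0.00),
    (107, 48.0, 0.02, 0.00, 0.02, 0.00),
    (110, 4.0, 0.02, 0.00, 0.02, 0.00),
    (127, 52.0, 0.02, 0.00, 0.02, 0.00),
    (133, 9.0, 0.02, 0.00, 0.04, 0.01),
    (134, 69.0, 0.01, 0.00, 0.78, 0.34),
    (138, 2.0, 0.04, 0.00, 0.05, 0.00),
    (139, 15.0, 0.02, 0.00, 0.11, 0.04),
    (175, 4.0, 0.02, 0.00, 0.08, 0.03),
    (190, 2.0, 0.01, 0.00, 0.09, 0.03),
    (257, 16.0, 0.02, 0.00, 0.02, 0.00),
    (259, 60.0, 0.03, 0.00, 0.03, 0.00),
    (262, 2.0, 0.03, 0.00, 0.03, 0.00),
    (361, 2.0, 0.03, 0.00, 0.03, 0.00),
    (394, 59.0, 0.02, 0.00, 0.04, 0.01),
    (395, 21.0, 0.02, 0.01, 0.04, 0.01),
    (396, 2.0, 0.01, 0.00, 0.01, 0.00),
    (418, 94.0, 0.04, 0.01, 10.33, 4.87),
    (429, 2.0, 0.05, 0.00, 0.05, 0.00),
]


def sqkv1a_assay_summary() -> pd.DataFrame:
    """Published SqKv1A amplicon assay summary as a DataFrame."""
    return pd.DataFrame(
        _SQKV1A_ROWS,
        columns=[
            "position",
            "in_vivo_percent",
            "mean_ctl",
            "sem_ctl",
            "mean_exp",
            "sem_exp",
        ],
    )


def sqkv1a_sites() -> list[EditingSite]:
    """The naturally edited SqKv1A adenosines as an :class:`EditingSite` list."""
    return [
        EditingSite("SqKv1A", pos, "A", in_vivo / 100.0)
        for pos, in_vivo, *_ in _SQKV1A_ROWS
    ]
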