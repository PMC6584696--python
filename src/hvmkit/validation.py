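"""Method-agreement statistics: Bland-Altman and ROC/AUC.

Utilities for validating automated readings against a reference method
(e.g., manual analysis): paired-difference bias and limits of agreement
with precision and percentage error, Pearson correlation, and the area
under the ROC curve for binary state prediction from a continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass
class AgreementResult:
    bias: float               # mean(b - a)
    loa_low: float            # bias - 2 SD
    loa_high: float           # bias + 2 SD
    precision: float          # SD of differences
    percentage_error: float
    r: float                  # Pearson correlation (nan if degenerate)
    n: int


def bland_altman(a, b, pe_mode: str = "bias") -> AgreementResult:
    """Bland-Altman agreement of paired readings, differences d = b - a.

    Limits of agreement are bias +- 2 SD. Two percentage-error conventions
    are available, since both are in circulation:

    - ``bias``: 100 * bias / mean of the pairwise means (signed).
    - ``critchley``: 100 * 1.96 * SD / mean of the pairwise means.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired readings must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if pe_mode not in ("bias", "critchley"):
        raise ValueError("pe_mode must be 'bias' or 'critchley'")
    d = b - a
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(((a + b) / 2).mean())
    if grand == 0:
        pe = float("nan")
    elif pe_mode == "bias":
        pe = 100.0 * bias / grand
    else:
        pe = 100.0 * 1.96 * sd / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        if a.std() == 0 or b.std() == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(a, b)[0, 1])
    return AgreementResult(bias=bias, loa_low=bias - 2 * sd, loa_high=bias + 2 * sd,
                           precision=sd, percentage_error=pe, r=r, n=a.size)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties contribute one half.

    Equivalent to the normalized Mann-Whitney U statistic.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))
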