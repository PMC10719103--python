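"""Small shared statistics: one-sided Welch's t and FDR adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def welch_t_one_sided(sample1, sample2) -> tuple[float, float]:
    """Upper-tail Welch's t-test that mean(sample1) > mean(sample2).

    Unequal-variance t statistic with Welch-Satterthwaite degrees of
    freedom.  When both samples are constant with equal means the test is
    uninformative and p = 0.5 by convention.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / a.size + vb / b.size
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return float(t), float(sps.t.sf(t, df))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
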