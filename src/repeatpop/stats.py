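"""Differential abundance between two populations: t-tests + BH correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def two_sample_ttest(
    a, b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled-variance Student by default).

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    with zero pooled variance are an error. Set equal_var=False for Welch.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values, capped at
    1; ranks are stable under ties and the input order is restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_abundance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    equal_var: bool = True,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-column two-sided t-test between the two populations, BH-corrected.

    All columns of the matrix form one BH family (test clusters and
    annotation classes in separate calls). With normalize=True, counts are
    first divided by each individual's row total — off by default because
    the study design fixes the per-individual read count.

    Returns a table indexed by unit with group means/sds, t, p, q and a
    significance flag at q < alpha.
    """
    labels = labels.loc[matrix.index]
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 populations, got {groups}")
    g1, g2 = groups
    if (labels == g1).sum() < 2 or (labels == g2).sum() < 2:
        raise ValueError("each population needs >= 2 individuals")
    data = matrix.astype(float)
    if normalize:
        totals = data.sum(axis=1)
        data = data.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    a = data.loc[labels == g1]
    b = data.loc[labels == g2]
    rows = []
    for col in data.columns:
        t, p = two_sample_ttest(a[col].values, b[col].values, equal_var=equal_var)
        rows.append(
            {
                "unit": col,
                f"mean_{g1}": a[col].mean(),
                f"mean_{g2}": b[col].mean(),
                f"sd_{g1}": a[col].std(ddof=1),
                f"sd_{g2}": b[col].std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("unit")
    out["q"] = bh_adjust(out["p"].values)
    out["significant"] = out["q"] < alpha
    return out
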