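"""Accuracy/precision descriptives: two-way repeated-measures ANOVA with
Greenhouse-Geisser sphericity correction.

Operates on the per-subject condition summaries (one row per subject x
acceleration x duration) with either the mean timing error (accuracy) or
its standard deviation (precision) as the dependent variable. Both factors
are within-subject; the design must be complete and balanced.

The Greenhouse-Geisser epsilon is estimated per effect from the sample
covariance of the orthonormally contrast-transformed subject data:
eps = tr(M)^2 / (q * tr(M @ M)) with M = K S K', K the effect's orthonormal
contrast matrix and q its degrees of freedom, clipped to [1/q, 1]. The
corrected p-value uses F with both degrees of freedom multiplied by eps.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import f as f_dist

__all__ = ["rm_anova", "gg_epsilon"]


def _cell_means(summaries: pd.DataFrame, dv: str, factors: Sequence[str]):
    """Subjects x cells matrix with cells ordered (factor A slow, B fast)."""
    levels = [sorted(summaries[f].unique()) for f in factors]
    pivot = summaries.pivot_table(
        index="subject_id", columns=list(factors), values=dv, aggfunc="mean"
    )
    order = pd.MultiIndex.from_product(levels, names=factors)
    if pivot.isna().any().any() or set(pivot.columns) != set(order):
        raise ValueError("design must be complete and balanced (one value per cell)")
    return pivot[order].to_numpy(), [len(lv) for lv in levels]


def gg_epsilon(y: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for one within-subject effect.

    ``y`` is the subjects x cells matrix; ``contrast`` the effect's q x cells
    contrast matrix (orthogonal rows of equal norm).
    """
    q = contrast.shape[0]
    s = np.cov(y, rowvar=False, ddof=1)
    m = contrast @ s @ contrast.T
    denom = q * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    eps = np.trace(m) ** 2 / denom
    return float(np.clip(eps, 1.0 / q, 1.0))


def rm_anova(
    summaries: pd.DataFrame,
    dv: str,
    factors: Sequence[str] = ("label", "duration_s"),
) -> pd.DataFrame:
    """Two-way within-subject ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    summaries : DataFrame
        Long-format table with ``subject_id``, the factor columns and ``dv``.
    dv : str
        Dependent-variable column (``mean_te`` or ``std_te``).
    factors : sequence of str
        The two within-subject factor columns.

    Returns
    -------
    DataFrame with one row per effect (A, B, A*B): degrees of freedom,
    F, uncorrected p, epsilon and the Greenhouse-Geisser corrected p.
    """
    if len(factors) != 2:
        raise ValueError("exactly two within-subject factors are required")
    y, (a, b) = _cell_means(summaries, dv, factors)
    n = y.shape[0]
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    cells = y.reshape(n, a, b)
    grand = cells.mean()
    m_a = cells.mean(axis=(0, 2))            # per level of A
    m_b = cells.mean(axis=(0, 1))
    m_ab = cells.mean(axis=0)                # a x b
    m_i = cells.mean(axis=(1, 2))            # per subject
    m_ia = cells.mean(axis=2)                # n x a
    m_ib = cells.mean(axis=1)                # n x b

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_ia - m_a[None, :] - m_i[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_ib - m_b[None, :] - m_i[:, None] + grand) ** 2)
    ss_abs = (
        np.sum((cells - m_ab[None] - m_ia[:, :, None] - m_ib[:, None, :]
                + m_a[None, :, None] + m_b[None, None, :] + m_i[:, None, None] - grand) ** 2)
    )

    c_a = helmert(a, full=False)             # orthonormal rows
    c_b = helmert(b, full=False)
    ones_b = np.full((1, b), 1.0 / b)
    ones_a = np.full((1, a), 1.0 / a)
    contrasts = {
        "A": np.kron(c_a, ones_b),
        "B": np.kron(ones_a, c_b),
        "A*B": np.kron(c_a, c_b),
    }

    rows = []
    specs = [
        (factors[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1), contrasts["A"]),
        (factors[1], ss_b, b - 1, ss_bs, (b - 1) * (n - 1), contrasts["B"]),
        (f"{factors[0]}*{factors[1]}", ss_ab, (a - 1) * (b - 1), ss_abs,
         (a - 1) * (b - 1) * (n - 1), contrasts["A*B"]),
    ]
    for source, ss_eff, df1, ss_err, df2, k in specs:
        f_val = (ss_eff / df1) / (ss_err / df2)
        eps = gg_epsilon(y, k)
        rows.append(
            {
                "Source": source,
                "ddof1": df1,
                "ddof2": df2,
                "F": f_val,
                "p_unc": float(f_dist.sf(f_val, df1, df2)),
                "eps": eps,
                "p_GG_corr": float(f_dist.sf(f_val, eps * df1, eps * df2)),
            }
        )
    return pd.DataFrame(rows)
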