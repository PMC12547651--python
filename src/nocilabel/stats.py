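"""Univariate nonparametric comparisons between presumptive subtypes.

Mann–Whitney U contrasts each baseline feature between nociceptor and
non-nociceptor groups (two-sided by default); the exact null distribution
is used for small samples without ties and the tie-corrected normal
approximation with continuity correction otherwise.  Significance stars
follow the usual convention (* < 0.05, ** < 0.01, *** < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "compare_feature_by_label",
    "rank_biserial",
    "holm_correction",
]

EXACT_N_MAX = 8


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str
    method: str
    median_a: float
    median_b: float

    @property
    def larger_group(self) -> str:
        if self.median_a == self.median_b:
            return "tie"
        return "a" if self.median_a > self.median_b else "b"


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_u(
    a, b, alternative: str = "two-sided", feature: str = ""
) -> GroupComparison:
    """Mann–Whitney U test of two independent samples.

    U is the rank-sum statistic of sample ``a`` with midrank ties.  The
    exact p-value is computed when min(n) <= 8 and there are no ties
    across the pooled sample; otherwise the normal approximation with tie
    correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return GroupComparison(
            feature=feature, n_a=a.size, n_b=b.size,
            u_statistic=a.size * b.size / 2.0, p_value=1.0, stars="ns",
            method="degenerate", median_a=float(np.median(a)),
            median_b=float(np.median(b)),
        )
    exact = min(a.size, b.size) <= EXACT_N_MAX and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return GroupComparison(
        feature=feature,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        stars=_stars(float(res.pvalue)),
        method=method,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def rank_biserial(a, b) -> float:
    """Rank-biserial effect size r = 2U/(n1 n2) − 1 (positive: a ranks higher)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    return 2.0 * u / (a.size * b.size) - 1.0


def compare_feature_by_label(
    features: pd.DataFrame,
    feature_columns: list[str] | None = None,
    label_column: str = "label",
    holm: bool = False,
) -> list[GroupComparison]:
    """One Mann–Whitney comparison per feature column, positive-label group
    first (so ``larger_group == "a"`` means nociceptors rank higher).

    No multiple-testing correction is applied by default; ``holm=True``
    applies a Holm step-down adjustment across the features.
    """
    if feature_columns is None:
        feature_columns = ["mfr_hz", "isicv", "sync_median", "sync_skewness"]
    lab = features[label_column].astype(bool)
    if lab.all() or not lab.any():
        raise ValueError("both labels must be present")
    out = []
    for col in feature_columns:
        if col not in features.columns:
            raise ValueError(f"missing feature column {col!r}")
        cmp = mann_whitney_u(
            features.loc[lab, col].to_numpy(),
            features.loc[~lab, col].to_numpy(),
            feature=col,
        )
        out.append(cmp)
    if holm:
        adj = holm_correction([c.p_value for c in out])
        out = [
            GroupComparison(
                feature=c.feature, n_a=c.n_a, n_b=c.n_b,
                u_statistic=c.u_statistic, p_value=p, stars=_stars(p),
                method=c.method + "+holm", median_a=c.median_a,
                median_b=c.median_b,
            )
            for c, p in zip(out, adj)
        ]
    return out


def holm_correction(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()
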