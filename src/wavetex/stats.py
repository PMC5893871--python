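"""Per-feature one-way ANOVA across tissue classes with Holm-Bonferroni control.

Each of the 24 texture features is tested with a fixed-effects one-way F
test across the four tissue grades; the 24 raw p-values are then adjusted
by the Holm-Bonferroni step-down procedure and flagged at a familywise
alpha (default 0.01).  The report keeps both raw and adjusted p-values plus
-log10 transforms for heatmap rendering.

The F statistic is invariant to any per-column affine map, so it does not
matter whether the table is z-scored first; the report is computed on
whatever table it is given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES

__all__ = [
    "StatsReport",
    "anova_oneway",
    "anova_per_feature",
    "holm_bonferroni",
    "significance_report",
]


@dataclass
class StatsReport:
    """Per-feature significance table and test metadata."""

    table: pd.DataFrame  # feature, F, df_between, df_within, p_raw, p_adjusted, significant
    alpha: float
    group_sizes: dict[str, int]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """One-way fixed-effects ANOVA; returns (F, p, df_between, df_within).

    Degenerate case policy: zero within-group variance with distinct group
    means gives p = 0 (F infinite); zero variance everywhere with equal
    means gives F = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 samples")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0, df_b, df_w
        return float("inf"), 0.0, df_b, df_w
    f_stat = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return float(f_stat), p, df_b, df_w


def anova_per_feature(
    table: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> pd.DataFrame:
    """Raw one-way ANOVA p-values for every feature column, grouped by label."""
    labels = table["label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rows = []
    for name in feature_names:
        col = table[name].to_numpy(dtype=float)
        groups = [col[labels == c] for c in classes]
        f_stat, p, df_b, df_w = anova_oneway(groups)
        rows.append(
            {"feature": name, "F": f_stat, "df_between": df_b, "df_within": df_w,
             "p_raw": p}
        )
    return pd.DataFrame(rows)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, p_(i) is multiplied by (m - i), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def significance_report(
    table: pd.DataFrame, alpha: float = 0.01
) -> StatsReport:
    """ANOVA on all 24 features with Holm-Bonferroni correction at ``alpha``."""
    res = anova_per_feature(table)
    res["p_adjusted"] = holm_bonferroni(res["p_raw"].to_numpy())
    res["significant"] = res["p_adjusted"] < alpha
    with np.errstate(divide="ignore"):
        res["neg_log10_p_raw"] = -np.log10(res["p_raw"])
        res["neg_log10_p_adjusted"] = -np.log10(res["p_adjusted"])
    labels = table["label"]
    sizes = labels.value_counts().to_dict()
    return StatsReport(table=res, alpha=alpha, group_sizes=sizes)
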