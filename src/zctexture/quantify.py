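"""Per-cell intensity quantification and normalization schemes.

Covers the measurements that accompany the texture score in a clustering
experiment: mean stain intensity within a cell mask, colocalization-
restricted collagen quantification, anchoring of condition means to a 0–100
arbitrary-unit scale, the fraction of phospho-positive cells, densitometry
fractions of Western-blot band tables, expression-weighted medians from flow
cytometry, and group comparison by ANOVA with the usual post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image import CellMask, ImagePlane

__all__ = [
    "BandTable",
    "mean_intensity",
    "restrict_to_colocalized",
    "anchor_normalize",
    "fraction_positive",
    "positive_threshold",
    "densitometry_fractions",
    "normalize_by_expression",
    "group_compare",
    "GroupComparison",
]


@dataclass
class BandTable:
    """Per-lane band intensities from a blot: (label, phospho, total)."""

    lanes: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, py, total in self.lanes:
            if py < 0 or total < 0:
                raise ValueError(f"lane {label!r}: band intensities must be >= 0")


def mean_intensity(image: ImagePlane, mask: CellMask) -> float:
    """Arithmetic mean of the intensities strictly within the cell mask."""
    if mask.is_empty:
        raise ValueError("cell mask is empty; mean intensity undefined")
    if mask.grid.shape != image.data.shape:
        raise ValueError("mask and image shapes differ")
    return float(image.data[mask.grid].mean())


def restrict_to_colocalized(ddr1_mask: CellMask, crop: np.ndarray) -> CellMask:
    """Intersect the cell mask with a manually chosen crop region.

    Emulates cropping away image areas where ligand stain does not
    colocalize with the receptor stain; quantification then runs on the
    intersection only.  A disjoint crop yields an (explicitly flagged)
    empty mask rather than an error.
    """
    crop = np.asarray(crop, dtype=bool)
    if crop.shape != ddr1_mask.grid.shape:
        raise ValueError("crop region must match the image frame")
    inter = ddr1_mask.grid & crop
    if not inter.any():
        import warnings

        warnings.warn("crop region is disjoint from the cell mask; empty result", stacklevel=2)
    return CellMask(
        grid=inter,
        source_channel=ddr1_mask.source_channel,
        background_level=ddr1_mask.background_level,
    )


def anchor_normalize(
    values: pd.Series | np.ndarray,
    conditions: pd.Series | np.ndarray,
    low_condition,
    high_condition,
) -> np.ndarray:
    """Affinely rescale so two anchor-condition means map to 0 and 100 A.U.

    x ↦ 100·(x − mean(low)) / (mean(high) − mean(low)).  Values outside the
    anchor range map outside [0, 100] (negative values are permitted).
    """
    values = np.asarray(values, dtype=np.float64)
    conditions = np.asarray(conditions)
    low = values[conditions == low_condition]
    high = values[conditions == high_condition]
    if low.size == 0 or high.size == 0:
        raise ValueError("both anchor conditions must be present")
    lo, hi = low.mean(), high.mean()
    if hi == lo:
        raise ValueError("anchor condition means are identical; scale undefined")
    return 100.0 * (values - lo) / (hi - lo)


def fraction_positive(values: np.ndarray, threshold: float) -> tuple[float, float]:
    """Percentage of cells above threshold, with its binomial standard error.

    Returns ``(percent, se_percent)`` where se = 100·sqrt(p(1−p)/n).
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 1:
        raise ValueError("need at least one cell")
    p = float(np.count_nonzero(values > threshold)) / n
    return 100.0 * p, 100.0 * float(np.sqrt(p * (1.0 - p) / n))


def positive_threshold(baseline_values: np.ndarray, k: float = 2.0) -> float:
    """Default positivity threshold: mean + k·SD of the unstimulated condition."""
    v = np.asarray(baseline_values, dtype=np.float64)
    return float(v.mean() + k * v.std(ddof=1 if v.size > 1 else 0))


def densitometry_fractions(bands: BandTable) -> pd.DataFrame:
    """Per-lane phospho/total ratios as percentages of the blot-wide sum.

    r_i = pY_i / total_i; output_i = 100·r_i / Σ r_j, so the outputs sum to
    exactly 100 (within float tolerance).
    """
    for label, _, total in bands.lanes:
        if total <= 0:
            raise ValueError(f"lane {label!r} has non-positive total intensity")
    labels = [l for l, _, _ in bands.lanes]
    ratios = np.array([py / total for _, py, total in bands.lanes])
    if ratios.sum() == 0:
        raise ValueError("all phospho bands are zero; fractions undefined")
    pct = 100.0 * ratios / ratios.sum()
    return pd.DataFrame({"lane": labels, "py_over_total": ratios, "percent_of_blot": pct})


def normalize_by_expression(signal_median: float, expression_median: float) -> float:
    """Weight a stain median by the receptor expression median (ratio convention).

    Implemented as signal/expression, making the result invariant to a
    common rescaling of both stains; the regression-based alternative
    reading is deliberately not implemented.
    """
    if expression_median <= 0:
        raise ValueError("expression median must be > 0")
    return float(signal_median) / float(expression_median)


@dataclass
class GroupComparison:
    """Tidy ANOVA + post-hoc report."""

    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame
    method: str
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool((self.posthoc["p_adj"] < self.alpha).any())


def group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    posthoc: str = "bonferroni",
    control=None,
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA followed by a standard post-hoc test.

    ``posthoc`` is one of ``"bonferroni"`` (all pairwise t-tests,
    Bonferroni-adjusted), ``"tukey"`` (Tukey HSD) or ``"dunnett"``
    (each group vs ``control``).  Returns a tidy table with one row per
    comparison: (comparison, statistic, p, p_adj, significant).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = {g: values[groups == g] for g in labels}
    f, p = stats.f_oneway(*samples.values())
    if np.isnan(p):
        # degenerate case: zero between-group variance (identical groups)
        f, p = 0.0, 1.0

    rows = []
    if posthoc == "bonferroni":
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
        m = len(pairs)
        for a, b in pairs:
            t, praw = stats.ttest_ind(samples[a], samples[b])
            rows.append((f"{a} vs {b}", float(t), float(praw), float(min(1.0, praw * m))))
    elif posthoc == "tukey":
        res = stats.tukey_hsd(*[samples[g] for g in labels])
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if j <= i:
                    continue
                rows.append(
                    (f"{a} vs {b}", float(res.statistic[i, j]), float(res.pvalue[i, j]), float(res.pvalue[i, j]))
                )
    elif posthoc == "dunnett":
        if control is None or control not in samples:
            raise ValueError("dunnett post-hoc requires a valid control group")
        others = [g for g in labels if g != control]
        res = stats.dunnett(*[samples[g] for g in others], control=samples[control])
        for g, t, padj in zip(others, res.statistic, res.pvalue):
            rows.append((f"{g} vs {control}", float(t), float(padj), float(padj)))
    else:
        raise ValueError(f"unknown post-hoc test {posthoc!r}")

    table = pd.DataFrame(rows, columns=["comparison", "statistic", "p", "p_adj"])
    table["significant"] = table["p_adj"] < alpha
    return GroupComparison(anova_f=float(f), anova_p=float(p), posthoc=table, method=posthoc, alpha=alpha)
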