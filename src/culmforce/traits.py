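"""Statistical toolkit for per-plant trait tables and linkage-map summaries.

Group comparisons (Welch, Mann-Whitney), Cohen's D with the threshold
classification small > 0.2 / medium > 0.5 / strong > 0.8, moment-based
normality screening, Pearson correlation, broad-sense heritability from
two-parent + F2 variances, fold changes and map-density arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, ParameterError, ValidationError

RYE_CHROMOSOMES = ("1R", "2R", "3R", "4R", "5R", "6R", "7R")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    group_summary: dict
    stars: str

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class EffectSize:
    d: float

    @property
    def effect_class(self) -> str:
        if self.d > 0.8:
            return "strong"
        if self.d > 0.5:
            return "medium"
        if self.d > 0.2:
            return "small"
        return "negligible"


@dataclass
class MapSummary:
    n_markers: int
    n_chromosomes: int
    total_length_cm: float
    mean_spacing_cm: float
    convention: str

    def report(self) -> dict:
        """Rounded to 2 decimals for printed summaries."""
        return {
            "n_markers": self.n_markers,
            "n_chromosomes": self.n_chromosomes,
            "total_length_cm": round(self.total_length_cm, 2),
            "mean_spacing_cm": round(self.mean_spacing_cm, 2),
        }


def _clean_two(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < min_n or y.size < min_n:
        raise ParameterError(f"each group needs at least {min_n} finite values")
    return x, y


def compare_groups(x, y, test: str = "welch") -> ComparisonResult:
    """Two-sided comparison of two samples.

    Welch's t uses the unequal-variance statistic with Welch-Satterthwaite
    degrees of freedom.  Mann-Whitney enumerates the exact null when both
    samples are small (n1 + n2 <= 20) and tie-free, and otherwise uses the
    normal approximation with tie correction.
    """
    if test == "welch":
        x, y = _clean_two(x, y, 2)
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            if np.mean(x) == np.mean(y):
                # identical constants: no evidence of difference
                stat, p = 0.0, 1.0
            else:
                raise DegenerateError("zero variance in both groups")
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=False)
        summary = {"mean_x": float(np.mean(x)), "mean_y": float(np.mean(y)),
                   "n_x": int(x.size), "n_y": int(y.size)}
    elif test == "mann_whitney":
        x, y = _clean_two(x, y, 1)
        ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
        method = "exact" if (x.size + y.size <= 20 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        summary = {"median_x": float(np.median(x)), "median_y": float(np.median(y)),
                   "n_x": int(x.size), "n_y": int(y.size), "method": method}
    else:
        raise ParameterError(f"unknown test {test!r}; use 'welch' or 'mann_whitney'")
    return ComparisonResult(test, float(stat), float(p), summary, _stars(float(p)))


def cohens_d(x, y) -> EffectSize:
    """Cohen's D with the pooled standard deviation.

    D = |mean(x) - mean(y)| / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2)).
    Symmetric in group order and scale invariant.
    """
    x, y = _clean_two(x, y, 2)
    n1, n2 = x.size, y.size
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0.0:
        raise DegenerateError("pooled standard deviation is zero")
    return EffectSize(float(abs(x.mean() - y.mean()) / pooled))


def normality_check(x, skew_limit: float = 1.0, kurt_limit: float = 2.0):
    """Moment skewness, excess kurtosis and a non-normality flag.

    The flag trips when |skewness| > 1 or |excess kurtosis| > 2 -- a
    documented screening heuristic, not a formal test.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ParameterError("normality check needs at least 4 values")
    if x.var() == 0.0:
        raise DegenerateError("constant input has undefined moments")
    g1 = float(stats.skew(x))
    g2 = float(stats.kurtosis(x, fisher=True))
    return g1, g2, bool(abs(g1) > skew_limit or abs(g2) > kurt_limit)


def pearson_corr(x, y):
    """Pearson's r with a t-distribution p-value; pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ParameterError("correlation needs at least 3 paired values")
    if x.var() == 0.0 or y.var() == 0.0:
        raise DegenerateError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def heritability_h2(table: pd.DataFrame, trait: str,
                    generation_column: str = "generation") -> tuple[float, bool]:
    """Broad-sense heritability from a two-parent + F2 trait table.

    H2 = (V_F2 - sqrt(V_P1 * V_P2)) / V_F2, with the environmental
    variance estimated as the geometric mean of the parental variances.
    The value is clipped to [0, 1]; the second return value flags clipping.
    """
    if trait not in table.columns:
        raise ValidationError(f"trait {trait!r} not in table")
    variances = {}
    for gen in ("P1", "P2", "F2"):
        vals = table.loc[table[generation_column] == gen, trait].dropna().to_numpy(float)
        if vals.size < 3:
            raise ParameterError(f"generation {gen} needs at least 3 plants")
        variances[gen] = vals.var(ddof=1)
    if variances["F2"] == 0.0:
        raise DegenerateError("zero F2 variance")
    v_e = np.sqrt(variances["P1"] * variances["P2"])
    h2 = (variances["F2"] - v_e) / variances["F2"]
    clipped = not (0.0 <= h2 <= 1.0)
    return float(np.clip(h2, 0.0, 1.0)), clipped


def fold_change(mean_a: float, mean_b: float) -> tuple[float, int]:
    """Ratio a/b and its nearest-integer fold."""
    if mean_b == 0:
        raise DegenerateError("division by zero mean")
    ratio = mean_a / mean_b
    return float(ratio), int(round(ratio))


def one_way_anova(*groups):
    """One-way ANOVA F and p (utility; no printed value is claimed for it)."""
    cleaned = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if g.size < 2:
            raise ParameterError("each ANOVA group needs at least 2 values")
        cleaned.append(g)
    f, p = stats.f_oneway(*cleaned)
    return float(f), float(p)


def summarize_linkage_map(map_table: pd.DataFrame,
                          convention: str = "total_over_markers",
                          valid_chromosomes: tuple[str, ...] = RYE_CHROMOSOMES) -> MapSummary:
    """Summarize a marker map: total length and mean inter-marker distance.

    Total length is the sum of per-chromosome spans (max - min position).
    The default spacing convention divides the total length by the marker
    count; ``convention='per_gap'`` divides by the number of inter-marker
    gaps (n_markers - n_chromosomes) instead.  Both are reported to 2
    decimals by :meth:`MapSummary.report`.
    """
    required = {"marker_id", "chromosome", "position_cM"}
    missing = required - set(map_table.columns)
    if missing:
        raise ValidationError(f"map table missing columns: {sorted(missing)}")
    if convention not in ("total_over_markers", "per_gap"):
        raise ParameterError(f"unknown spacing convention {convention!r}")
    unknown = set(map_table["chromosome"]) - set(valid_chromosomes)
    if unknown:
        raise ValidationError(f"unknown chromosome codes: {sorted(unknown)}")
    if (map_table["position_cM"] < 0).any():
        raise ValidationError("marker positions must be nonnegative")

    spans = map_table.groupby("chromosome")["position_cM"].agg(lambda s: s.max() - s.min())
    total = float(spans.sum())
    n_markers = int(len(map_table))
    n_chrom = int(map_table["chromosome"].nunique())
    if convention == "total_over_markers":
        spacing = total / n_markers if n_markers else 0.0
    else:
        gaps = n_markers - n_chrom
        spacing = total / gaps if gaps > 0 else 0.0
    return MapSummary(n_markers, n_chrom, total, float(spacing), convention)
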