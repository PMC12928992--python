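"""Agreement, precision and accuracy statistics for conductance datasets.

Pairwise agreement between devices or laboratories combines four views:
range overlap (Jaccard similarity of [min, max] intervals), distributional
similarity (Bhattacharyya coefficient over 15 shared bins), the share of
pooled measurements inside the range overlap, and a two-sample
Kolmogorov-Smirnov test.  Precision is summarised by the 5th-95th percentile
range, CV and standard error on the trimmed subset; accuracy by inclusion
rates within reference intervals and n-weighted relative deviations from
per-specimen reference values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import ReferenceInterval, range_intersection

DEFAULT_BC_BINS = 15


@dataclass
class AgreementResult:
    """Bundle of pairwise agreement statistics, all percentages except KS."""

    jsi_pct: float
    bc_pct: float
    intersect_pct: float
    mean_diff_pct: float
    ks_stat: float
    ks_p: float


@dataclass
class PrecisionSummary:
    n: int
    range_5_95: float  # kg s^-1 kPa^-1
    stderr: float  # kg s^-1 kPa^-1
    cv_pct: float


@dataclass
class AccuracySummary:
    inclusion_rate_pct: float
    outlier_rate_pct: float
    per_id_relative_deviation_pct: dict
    weighted_bias_pct: float


def _as_array(values, min_n=1, name="values"):
    v = np.asarray(list(values), dtype=float)
    if v.size < min_n:
        raise ValueError(f"{name}: need at least {min_n} values")
    return v


def relative_bias(measurements, k_ref: float) -> float:
    """100 * (mean(K25) - K_ref) / K_ref."""
    v = _as_array(measurements, 1, "measurements")
    if k_ref <= 0:
        raise ValueError("k_ref must be > 0")
    return float(100.0 * (np.mean(v) - k_ref) / k_ref)


def jaccard_range_similarity(a_values, b_values) -> float:
    """Jaccard similarity of the two [min, max] measurement ranges, percent.

    JSI = 100 * |A n B| / |A u B| with |A u B| = |A| + |B| - |A n B|;
    0 for disjoint ranges, 100 for identical ones.
    """
    a = _as_array(a_values, 2, "a_values")
    b = _as_array(b_values, 2, "b_values")
    ra = (float(a.min()), float(a.max()))
    rb = (float(b.min()), float(b.max()))
    inter = range_intersection(ra, rb)
    inter_len = 0.0 if inter is None else inter[1] - inter[0]
    union_len = (ra[1] - ra[0]) + (rb[1] - rb[0]) - inter_len
    if union_len <= 0:
        if ra == rb:  # both degenerate single points, identical
            return 100.0
        raise ValueError("degenerate zero-width union")
    return float(100.0 * inter_len / union_len)


def bhattacharyya_coefficient(a_values, b_values, n_bins: int = DEFAULT_BC_BINS) -> float:
    """BC = 100 * sum_i sqrt(p1_i * p2_i) over shared equal-width bins.

    Bins span the pooled [min, max] of both samples; each sample's bin counts
    are normalized to probabilities.  100 for identical samples, 0 when the
    samples occupy disjoint bins.
    """
    a = _as_array(a_values, 2, "a_values")
    b = _as_array(b_values, 2, "b_values")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        raise ValueError("zero pooled range")
    edges = np.linspace(lo, hi, n_bins + 1)
    p1, _ = np.histogram(a, bins=edges)
    p2, _ = np.histogram(b, bins=edges)
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    return float(100.0 * np.sum(np.sqrt(p1 * p2)))


def intersect_fraction(a_values, b_values) -> float:
    """Percent of pooled measurements lying inside the range intersection."""
    a = _as_array(a_values, 2, "a_values")
    b = _as_array(b_values, 2, "b_values")
    inter = range_intersection(
        (float(a.min()), float(a.max())), (float(b.min()), float(b.max()))
    )
    if inter is None:
        return 0.0
    pooled = np.concatenate([a, b])
    inside = np.count_nonzero((pooled >= inter[0]) & (pooled <= inter[1]))
    return float(100.0 * inside / pooled.size)


def ks_two_sample(a_values, b_values) -> dict:
    """Two-sample Kolmogorov-Smirnov test: {"statistic", "p"}.

    Uses the exact null distribution for small samples (min n <= 25, the
    regime of 15-replicate comparisons) and the asymptotic one otherwise.
    """
    a = _as_array(a_values, 5, "a_values")
    b = _as_array(b_values, 5, "b_values")
    method = "exact" if min(a.size, b.size) <= 25 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


def precision_summary(values) -> PrecisionSummary:
    """Spread statistics on the 5th-95th percentile subset.

    range_5_95 = q95 - q5 with linear-interpolation percentiles; CV and
    standard error are computed on the values inside [q5, q95], excluding
    extremes from the dispersion estimates as well as from the range.
    """
    v = _as_array(values, 3, "values")
    q5, q95 = np.percentile(v, [5, 95])  # linear interpolation
    trimmed = v[(v >= q5) & (v <= q95)]
    mean = float(np.mean(trimmed))
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    sd = float(np.std(trimmed, ddof=1)) if trimmed.size > 1 else 0.0
    return PrecisionSummary(
        n=int(v.size),
        range_5_95=float(q95 - q5),
        stderr=sd / np.sqrt(trimmed.size),
        cv_pct=100.0 * sd / abs(mean),
    )


def accuracy_summary(measurements: pd.DataFrame, interval: ReferenceInterval) -> AccuracySummary:
    """Inclusion rate and reference-anchored bias for one colour/lab group.

    ``measurements`` needs columns ``K25``, ``tubing_sample`` (specimen ID)
    and ``K_ref`` (that specimen's reference conductance).  Per-specimen
    relative deviations 100*(K25 - K_ref)/K_ref are averaged within specimen,
    then combined across specimens weighted by their measurement counts.
    """
    if measurements.empty:
        raise ValueError("no measurements")
    if measurements["K_ref"].isna().any():
        raise ValueError("every measurement must carry its tubing's K_ref")
    k = measurements["K25"].to_numpy(dtype=float)
    inside = interval.contains(k)
    inclusion = 100.0 * np.count_nonzero(inside) / k.size
    dev = 100.0 * (measurements["K25"] - measurements["K_ref"]) / measurements["K_ref"]
    by_id = dev.groupby(measurements["tubing_sample"])
    per_id = by_id.mean()
    weights = by_id.size()
    weighted = float(np.average(per_id.to_numpy(), weights=weights.to_numpy()))
    return AccuracySummary(
        inclusion_rate_pct=float(inclusion),
        outlier_rate_pct=float(100.0 - inclusion),
        per_id_relative_deviation_pct=per_id.to_dict(),
        weighted_bias_pct=weighted,
    )


def mean_difference_pct(a_values, b_values) -> float:
    """Absolute difference of group means as a percent of their average.

    100 * |mean_a - mean_b| / ((mean_a + mean_b) / 2); symmetric in its
    arguments.
    """
    a = _as_array(a_values, 1, "a_values")
    b = _as_array(b_values, 1, "b_values")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    denom = (ma + mb) / 2.0
    if denom == 0:
        raise ValueError("zero pooled mean")
    return float(100.0 * abs(ma - mb) / denom)


def compare_groups(a_values, b_values, n_bins: int = DEFAULT_BC_BINS) -> AgreementResult:
    """All pairwise agreement statistics for two measurement groups."""
    ks = ks_two_sample(a_values, b_values)
    return AgreementResult(
        jsi_pct=jaccard_range_similarity(a_values, b_values),
        bc_pct=bhattacharyya_coefficient(a_values, b_values, n_bins),
        intersect_pct=intersect_fraction(a_values, b_values),
        mean_diff_pct=mean_difference_pct(a_values, b_values),
        ks_stat=ks["statistic"],
        ks_p=ks["p"],
    )
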