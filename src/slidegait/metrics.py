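"""Per-cycle descriptive metrics, bilateral symmetry indices, and paired
left-right comparisons.

The symmetry index normalizes the left-right difference by the bilateral
mean:

    SI% = |L - R| / (|L + R| / 2) * 100

with two special rules: if both values are zero the SI is 0 (perfect
symmetry at zero load), and if the two sides have strictly opposite signs
the ratio is structurally meaningless (the limbs move in opposite
directions, e.g. plantarflexion vs dorsiflexion), so the asymmetry is
reported as the absolute difference in the metric's own units instead.
Timing metrics (T_peak, T_min) enter the symmetry report as
cycle-normalized fractions so cycles of unequal length stay comparable.

Paired comparisons use the Wilcoxon signed-rank test: an exact two-sided
p (dynamic programming over signed-rank sums) for n <= 25 without ties,
the normal approximation with tie and continuity correction otherwise; a
Z statistic is reported in both cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError
from .synthetic import ANGLE_CHANNELS, PRESSURE_CHANNEL, MultimodalRecording

__all__ = [
    "ChannelStats",
    "CycleMetrics",
    "SymmetryEntry",
    "WilcoxonResult",
    "descriptive_stats",
    "cycle_metrics",
    "symmetry_index",
    "bilateral_report",
    "paired_comparison",
    "metrics_frame",
    "symmetry_frame",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass
class ChannelStats:
    """Summary row for one channel over one cycle (Table-2 style)."""

    name: str
    n: int
    minimum: float
    maximum: float
    value_range: float  # maximum - minimum, exactly
    mean: float
    sd: float  # sample SD, n-1 denominator
    cv: float  # SD / |mean|; nan + flag when the mean is 0
    cv_defined: bool
    t_peak: float  # time of the maximum, seconds, cycle-relative
    t_min: float
    t_peak_frac: float  # cycle-normalized times in [0, 1]
    t_min_frac: float


@dataclass
class CycleMetrics:
    side: str
    duration: float  # seconds
    channels: dict[str, ChannelStats] = field(default_factory=dict)


@dataclass
class SymmetryEntry:
    metric_name: str
    left: float
    right: float
    mode: str  # "percent" | "absolute_difference"
    value: float
    defined: bool = True


@dataclass
class WilcoxonResult:
    z: float
    p: float
    test_name: str
    n: int
    degenerate: bool = False


def descriptive_stats(series: np.ndarray, sampling_rate: float = 100.0, name: str = "") -> ChannelStats:
    """n, min, max, range, mean, sample SD (n-1), CV and extremum times."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise DataError("empty series")
    if not np.all(np.isfinite(x)):
        raise DataError("series contains non-finite samples")
    n = int(x.size)
    mn, mx = float(x.min()), float(x.max())
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    cv_defined = mean != 0.0
    cv = sd / abs(mean) if cv_defined else math.nan
    i_peak, i_min = int(np.argmax(x)), int(np.argmin(x))
    duration = (n - 1) / sampling_rate if n > 1 else 0.0
    return ChannelStats(
        name=name,
        n=n,
        minimum=mn,
        maximum=mx,
        value_range=mx - mn,
        mean=mean,
        sd=sd,
        cv=cv,
        cv_defined=cv_defined,
        t_peak=i_peak / sampling_rate,
        t_min=i_min / sampling_rate,
        t_peak_frac=i_peak / (n - 1) if n > 1 else 0.0,
        t_min_frac=i_min / (n - 1) if n > 1 else 0.0,
    )


def cycle_metrics(
    recording: MultimodalRecording, cycle: tuple[int, int] | None = None
) -> CycleMetrics:
    """Descriptive stats for every channel, optionally restricted to a
    detected cycle ``[start, end)``."""
    lo, hi = cycle if cycle is not None else (0, recording.n)
    out = CycleMetrics(side=recording.side, duration=(hi - lo - 1) / recording.sampling_rate)
    for ch in ANGLE_CHANNELS + (PRESSURE_CHANNEL,):
        out.channels[ch] = descriptive_stats(
            recording.channel(ch)[lo:hi], recording.sampling_rate, name=ch
        )
    return out


def symmetry_index(left: float, right: float, metric_name: str = "") -> SymmetryEntry:
    """Bilateral symmetry index with the sign-crossing fallback."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise DataError("symmetry index requires finite inputs")
    if left == 0.0 and right == 0.0:
        return SymmetryEntry(metric_name, left, right, "percent", 0.0)
    if left * right < 0.0:
        return SymmetryEntry(metric_name, left, right, "absolute_difference", abs(left - right))
    denom = abs((left + right) / 2.0)
    if denom == 0.0:
        return SymmetryEntry(metric_name, left, right, "percent", math.nan, defined=False)
    return SymmetryEntry(metric_name, left, right, "percent", abs(left - right) / denom * 100.0)


_PRESSURE_METRICS = ("peak", "min", "mean", "t_peak")
_ANGLE_METRICS = ("peak", "min", "mean", "range", "t_peak", "t_min")


def _stat(stats: ChannelStats, metric: str) -> float:
    return {
        "peak": stats.maximum,
        "min": stats.minimum,
        "mean": stats.mean,
        "range": stats.value_range,
        "t_peak": stats.t_peak_frac,
        "t_min": stats.t_min_frac,
    }[metric]


def bilateral_report(left: CycleMetrics, right: CycleMetrics) -> list[SymmetryEntry]:
    """Symmetry entries for the full bilateral metric list: pressure
    peak/min/mean/T_peak plus, per joint, peak/min/mean/range/T_peak/T_min."""
    if set(left.channels) != set(right.channels):
        raise DataError(
            f"metric-set mismatch: {sorted(left.channels)} vs {sorted(right.channels)}"
        )
    entries: list[SymmetryEntry] = []
    for metric in _PRESSURE_METRICS:
        entries.append(
            symmetry_index(
                _stat(left.channels[PRESSURE_CHANNEL], metric),
                _stat(right.channels[PRESSURE_CHANNEL], metric),
                metric_name=f"pressure_{metric}",
            )
        )
    for ch in ANGLE_CHANNELS:
        for metric in _ANGLE_METRICS:
            entries.append(
                symmetry_index(
                    _stat(left.channels[ch], metric),
                    _stat(right.channels[ch], metric),
                    metric_name=f"{ch.removesuffix('_deg')}_{metric}",
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Exact counts of W+ = r over all 2^m sign assignments (DP)."""
    total = int(round(ranks.sum()))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        r = int(round(r))
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def paired_comparison(left: np.ndarray, right: np.ndarray) -> WilcoxonResult:
    """Wilcoxon signed-rank test on the paired differences right - left.

    Z > 0 when the right side tends to exceed the left. Zero differences
    are discarded (Wilcoxon's rule); if all differences are zero the
    result is the degenerate (Z=0, p=1).
    """
    l = np.asarray(left, dtype=float)
    r = np.asarray(right, dtype=float)
    if l.shape != r.shape or l.ndim != 1:
        raise DataError("paired samples must be 1-D and of equal length")
    if len(l) < 5:
        raise DataError("paired comparison needs n >= 5")
    d = r - l
    d = d[d != 0.0]
    m = len(d)
    if m == 0:
        return WilcoxonResult(z=0.0, p=1.0, test_name="wilcoxon-degenerate", n=0, degenerate=True)

    abs_d = np.abs(d)
    order = np.argsort(abs_d, kind="mergesort")
    ranks = np.empty(m)
    sorted_abs = abs_d[order]
    # average ranks for ties
    i = 0
    pos = np.arange(1, m + 1, dtype=float)
    while i < m:
        j = i
        while j + 1 < m and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = pos[i : j + 1].mean()
        i = j + 1
    has_ties = len(np.unique(abs_d)) < m

    w_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    tie_counts = np.unique(abs_d, return_counts=True)[1]
    sigma2 = m * (m + 1) * (2 * m + 1) / 24.0 - float(((tie_counts**3 - tie_counts).sum())) / 48.0
    sigma = math.sqrt(sigma2)
    delta = w_plus - mu
    z = 0.0 if delta == 0 else (delta - 0.5 * math.copysign(1.0, delta)) / sigma

    if m <= EXACT_WILCOXON_MAX_N and not has_ties:
        counts = _signed_rank_distribution(ranks)
        total = counts.sum()
        w = int(round(w_plus))
        cdf = counts[: w + 1].sum() / total
        sf = counts[w:].sum() / total
        p = min(1.0, 2.0 * min(cdf, sf))
        name = "wilcoxon-exact"
    else:
        p = 2.0 * norm.sf(abs(z))
        name = "wilcoxon-normal"
    return WilcoxonResult(z=z, p=p, test_name=name, n=m)


# ---------------------------------------------------------------------------
# Tabular exports


def metrics_frame(metrics: CycleMetrics) -> pd.DataFrame:
    """Long-format table: one row per channel x statistic."""
    rows = []
    for ch, s in metrics.channels.items():
        for stat in ("n", "minimum", "maximum", "value_range", "mean", "sd", "cv",
                     "t_peak", "t_min", "t_peak_frac", "t_min_frac"):
            rows.append({"side": metrics.side, "channel": ch, "statistic": stat,
                         "value": getattr(s, stat)})
    return pd.DataFrame(rows)


def symmetry_frame(entries: list[SymmetryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": e.metric_name,
                "left": e.left,
                "right": e.right,
                "mode": e.mode,
                "value": e.value,
                "defined": e.defined,
            }
            for e in entries
        ]
    )
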