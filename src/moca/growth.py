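"""Growth statistics from droplet transmission time series.

The per-droplet pipeline mirrors how droplet-array growth records are read
out: normalize each transmission curve to its initial value (so every curve
starts at 1 and droplet-to-droplet illumination differences cancel), find
the threshold growth time — the time at which the normalized transmission
first intersects 0.99 — classify growth versus no-growth with a
sustained-drop guard, flag the post-peak brightening characteristic of
sporulating populations, and summarize threshold times per loading
concentration as Tukey box-plot statistics.

Smoothing (a centered 3-frame moving median) is applied only inside the
growth/rebound classifiers; the threshold time is always read from the raw
normalized curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import DropletTimeSeries

__all__ = [
    "GrowthResult",
    "GroupSummary",
    "NormalizationError",
    "ContractError",
    "normalize_curve",
    "threshold_growth_time",
    "classify_growth",
    "detect_rebound",
    "analyze_droplet",
    "analyze_experiment",
    "results_to_frame",
    "summarize_groups",
    "summaries_to_frame",
    "fit_threshold_vs_log_inoculum",
]

DEFAULT_THRESHOLD = 0.99


class NormalizationError(ValueError):
    """Baseline of a transmission curve is zero or negative."""


class ContractError(ValueError):
    """A curve that should be normalized (first value 1) is not."""


@dataclass
class GrowthResult:
    """Per-droplet growth read-out.

    ``grew`` is true iff ``threshold_time_h`` is present; a threshold
    crossing that fails the sustained-drop guard is discarded as noise.
    """

    droplet_id: int
    group: float
    times_h: np.ndarray
    normalized: np.ndarray
    threshold_time_h: float | None
    grew: bool
    rebound: bool
    rebound_onset_h: float | None


@dataclass
class GroupSummary:
    """Tukey box-plot statistics of threshold times for one loading group."""

    group: float
    n_droplets: int
    n_grew: int
    median_h: float | None = None
    q1_h: float | None = None
    q3_h: float | None = None
    whisker_low_h: float | None = None
    whisker_high_h: float | None = None
    outliers_h: list = field(default_factory=list)


def _values(curve) -> np.ndarray:
    if isinstance(curve, DropletTimeSeries):
        return np.asarray(curve.raw_mean_intensity, dtype=float)
    return np.asarray(curve, dtype=float)


def normalize_curve(curve, baseline_frames: int = 1) -> np.ndarray:
    """Divide a transmission curve by the mean of its first frames.

    With the default single-frame baseline the first normalized value is
    exactly 1, so curves from droplets with different illumination become
    comparable.
    """
    v = _values(curve)
    if v.size == 0:
        raise ValueError("cannot normalize an empty series")
    if not 1 <= baseline_frames <= v.size:
        raise ValueError(f"baseline_frames must be in [1, {v.size}]")
    base = float(v[:baseline_frames].mean())
    if base <= 0:
        raise NormalizationError(f"baseline mean must be > 0, got {base}")
    return v / base


def threshold_growth_time(
    values, times_h, threshold: float = DEFAULT_THRESHOLD
) -> float | None:
    """Time at which a normalized curve first intersects ``threshold``.

    The crossing is located at the first frame pair (i−1, i) with
    value[i−1] ≥ threshold > value[i] and resolved by linear interpolation,
    giving sub-frame resolution.  Returns None if the curve never falls
    below the threshold.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if v.size == 0 or v.size != t.size:
        raise ValueError("values and times must be non-empty and equal length")
    if abs(v[0] - 1.0) > 1e-9:
        raise ContractError(
            f"curve is not normalized: first value {v[0]!r} differs from 1"
        )
    below = v < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:  # possible only for threshold > 1
        return float(t[0])
    return float(t[i - 1] + (v[i - 1] - threshold) / (v[i - 1] - v[i]) * (t[i] - t[i - 1]))


def _moving_median3(v: np.ndarray) -> np.ndarray:
    """Centered 3-frame moving median with replicated edges."""
    if v.size < 3:
        return v.copy()
    padded = np.pad(v, 1, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, 3)
    return np.median(win, axis=1)


def classify_growth(
    values,
    times_h,
    threshold: float = DEFAULT_THRESHOLD,
    min_final_drop: float = 0.05,
) -> bool:
    """Growth/no-growth call for a normalized curve.

    A droplet grew iff its curve crosses the threshold AND its final
    smoothed value sits at least ``min_final_drop`` below 1 — the sustained
    drop guards against single-frame noise dips being called growth.
    """
    v = np.asarray(values, dtype=float)
    crossing = threshold_growth_time(v, times_h, threshold)
    if crossing is None:
        return False
    smoothed = _moving_median3(v)
    return bool(smoothed[-1] <= 1.0 - min_final_drop)


def detect_rebound(
    values,
    times_h,
    min_rise: float = 0.05,
    min_frames: int = 6,
):
    """Post-peak brightening detector for a grown droplet's normalized curve.

    Finds the global minimum of the smoothed curve; the droplet rebounds if
    the curve subsequently rises by at least ``min_rise`` and stays above
    (minimum + min_rise/2) for at least ``min_frames`` consecutive frames.
    Returns ``(flag, onset_h)``; onset (the time of the minimum) is None
    when no rebound is flagged.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_h, dtype=float)
    smoothed = _moving_median3(v)
    i_min = int(np.argmin(smoothed))
    after = smoothed[i_min:]
    if after.size < 2:
        return False, None
    vmin = smoothed[i_min]
    if float(after.max() - vmin) < min_rise:
        return False, None
    above = after > vmin + min_rise / 2.0
    run = best = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    if best < min_frames:
        return False, None
    return True, float(t[i_min])


def analyze_droplet(
    series: DropletTimeSeries,
    group: float,
    *,
    threshold: float = DEFAULT_THRESHOLD,
    baseline_frames: int = 1,
    min_final_drop: float = 0.05,
    rebound_min_rise: float = 0.05,
    rebound_min_frames: int = 6,
) -> GrowthResult:
    """Full per-droplet read-out: normalize, threshold, classify, rebound."""
    norm = normalize_curve(series, baseline_frames)
    t = series.times_h
    grew = classify_growth(norm, t, threshold, min_final_drop)
    crossing = threshold_growth_time(norm, t, threshold) if grew else None
    rebound, onset = (
        detect_rebound(norm, t, rebound_min_rise, rebound_min_frames)
        if grew
        else (False, None)
    )
    return GrowthResult(
        droplet_id=series.droplet_id,
        group=float(group),
        times_h=t,
        normalized=norm,
        threshold_time_h=crossing,
        grew=grew,
        rebound=rebound,
        rebound_onset_h=onset,
    )


def analyze_experiment(series_list, groups, **kwargs) -> list[GrowthResult]:
    """Analyze every droplet; ``groups`` maps droplet_id → nominal cells/droplet."""
    return [analyze_droplet(s, groups[s.droplet_id], **kwargs) for s in series_list]


def results_to_frame(results) -> pd.DataFrame:
    """Results table with absent times encoded as missing values (never
    sentinel numbers)."""
    return pd.DataFrame(
        {
            "droplet_id": [r.droplet_id for r in results],
            "group": [r.group for r in results],
            "grew": [r.grew for r in results],
            "threshold_time_h": [
                r.threshold_time_h if r.threshold_time_h is not None else np.nan
                for r in results
            ],
            "rebound": [r.rebound for r in results],
            "rebound_onset_h": [
                r.rebound_onset_h if r.rebound_onset_h is not None else np.nan
                for r in results
            ],
        }
    )


def summarize_groups(results) -> list[GroupSummary]:
    """Per-group box-plot statistics of threshold growth times.

    Quartiles use the linear-interpolation quantile convention; whiskers are
    Tukey's (most extreme values within 1.5 × IQR of the quartiles), values
    beyond them are listed as outliers.  A group in which nothing grew gets
    counts only — absent statistics, not an error.
    """
    by_group: dict[float, list[GrowthResult]] = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    out = []
    for group in sorted(by_group):
        rs = by_group[group]
        times = np.array(
            [r.threshold_time_h for r in rs if r.grew and r.threshold_time_h is not None]
        )
        summ = GroupSummary(group=group, n_droplets=len(rs), n_grew=len(times))
        if len(times) > 0:
            q1, med, q3 = np.percentile(times, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = times[(times >= lo) & (times <= hi)]
            summ.median_h = float(med)
            summ.q1_h = float(q1)
            summ.q3_h = float(q3)
            summ.whisker_low_h = float(inside.min())
            summ.whisker_high_h = float(inside.max())
            summ.outliers_h = sorted(float(x) for x in times[(times < lo) | (times > hi)])
        out.append(summ)
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "group": s.group,
                "n_droplets": s.n_droplets,
                "n_grew": s.n_grew,
                "median_h": s.median_h if s.median_h is not None else np.nan,
                "q1_h": s.q1_h if s.q1_h is not None else np.nan,
                "q3_h": s.q3_h if s.q3_h is not None else np.nan,
                "whisker_low_h": s.whisker_low_h if s.whisker_low_h is not None else np.nan,
                "whisker_high_h": s.whisker_high_h if s.whisker_high_h is not None else np.nan,
                "outliers_h": ";".join(f"{x:.4g}" for x in s.outliers_h),
            }
        )
    return pd.DataFrame(rows)


def fit_threshold_vs_log_inoculum(results):
    """Least-squares line of threshold time against log10(cells per droplet).

    Under exponential growth to a fixed detection biomass the threshold time
    falls by ln(10)/μ hours per tenfold increase in inoculum, so the slope
    (hours per decade) is a direct read-out of the specific growth rate.
    Uses grown droplets from groups with a positive nominal occupancy;
    requires at least two distinct such groups.
    """
    xs, ys = [], []
    for r in results:
        if r.grew and r.threshold_time_h is not None and r.group > 0:
            xs.append(math.log10(r.group))
            ys.append(r.threshold_time_h)
    if len(set(xs)) < 2:
        raise ValueError(
            "need grown droplets from >= 2 distinct nonzero concentrations"
        )
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)
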