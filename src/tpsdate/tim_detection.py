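"""Time Informative Marker (TIM) detection.

A TIM is a SNP whose allele frequency shows a directed trend over at least
3,000 years in the component-derived time series. The series is built on a
fixed axis of 21 points — 500-year bins from 10,000 to 0 years BP — by
averaging the ancient components' frequencies over the bins their epochs
cover; it is then smoothed with a centered moving average and classified.

Thresholds: the 3,000-year minimum span is the method's defining rule; the
minimum amplitude (default 0.05) and smoothing window (default 3) are this
package's choices, exposed in config — without an amplitude floor,
numerically flat monotone drifts flood the TIM set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .temporal_components import ComponentSet

__all__ = [
    "BIN_CENTERS",
    "N_BINS",
    "TimSeries",
    "TimCall",
    "series_from_components",
    "smooth",
    "classify_trend",
    "detect_tims",
    "sample_non_tims",
]

#: The 21-point time axis, years BP, oldest first.
BIN_CENTERS: np.ndarray = np.arange(10000, -1, -500, dtype=float)
N_BINS: int = len(BIN_CENTERS)  # 21


@dataclass
class TimSeries:
    snp_id: str
    raw: np.ndarray        # 21 values in [0, 1]
    smoothed: np.ndarray
    carried: np.ndarray    # bins filled from the nearest covered bin

    def validate(self) -> None:
        if self.raw.shape != (N_BINS,) or self.smoothed.shape != (N_BINS,):
            raise ValueError("time series must have exactly 21 points")
        for arr in (self.raw, self.smoothed):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("series values outside [0, 1]")


@dataclass
class TimCall:
    snp_id: str
    cls: str                       # global_increasing|global_decreasing|local|none
    interval: tuple[int, int]      # [start_bin, end_bin] point indices
    amplitude: float

    def validate(self) -> None:
        if self.cls != "none" and self.interval[1] - self.interval[0] < 6:
            raise ValueError("qualifying trend must span >= 6 bin steps (3,000 years)")


def series_from_components(
    P_ancient: np.ndarray,
    epochs: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Raw 21-point series per SNP from ancient components and their epochs.

    ``P_ancient`` is (n_components, n_snps) sorted oldest to youngest;
    ``epochs[k] = (old, young)`` in years BP snapped to 500-year edges.
    Each bin's value is the mean frequency of the components whose epoch
    covers the bin center (overlaps average); bins covered by no epoch
    carry the nearest covered bin's value and are flagged.

    Returns ``(series, carried)`` with shapes (n_snps, 21) and (21,).
    """
    P_ancient = np.atleast_2d(np.asarray(P_ancient, dtype=float))
    covers = np.array(
        [[old >= c >= young for c in BIN_CENTERS] for old, young in epochs]
    )
    covered = covers.any(axis=0)
    if not covered.any():
        raise ValueError("no bin is covered by any component epoch")

    counts = covers.sum(axis=0)
    sums = covers.T.astype(float) @ P_ancient  # (21, n_snps)
    with np.errstate(invalid="ignore"):
        series = np.where(counts[:, None] > 0, sums / np.maximum(counts, 1)[:, None], np.nan)

    covered_idx = np.flatnonzero(covered)
    for b in np.flatnonzero(~covered):
        nearest = covered_idx[np.argmin(np.abs(covered_idx - b))]
        series[b] = series[nearest]
    return series.T, ~covered


def smooth(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average along the last axis; edges truncate.

    ``window`` must be odd; 1 is the identity. NaNs are ignored within each
    window (a window of all-NaN stays NaN), which lets gapped curves keep
    their gaps' neighbours informative.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    series = np.asarray(series, dtype=float)
    if window == 1:
        return series.copy()
    x = np.atleast_2d(series)
    vals = np.where(np.isnan(x), 0.0, x)
    ok = (~np.isnan(x)).astype(float)
    kernel = np.ones(window)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, vals)
    den = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, ok)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1.0), np.nan)
    return out if series.ndim > 1 else out[0]


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_step, end_step) inclusive."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def classify_trend(
    smoothed: np.ndarray,
    snp_id: str = "",
    min_span_years: float = 3000.0,
    min_amplitude: float = 0.05,
    tol: float = 1e-3,
    bin_years: float = 500.0,
) -> TimCall:
    """Classify a smoothed 21-point series.

    Finds, per direction, the longest run of consecutive steps that are all
    non-decreasing (or all non-increasing) within ``tol``. A run qualifies
    when it spans at least ``min_span_years / bin_years`` steps and its
    endpoint amplitude is at least ``min_amplitude``; a qualifying run
    covering the whole axis is ``global_*``, otherwise ``local``. A tie
    between qualifying increasing and decreasing runs breaks by larger
    amplitude, then earlier start. Everything else is ``none``.
    """
    s = np.asarray(smoothed, dtype=float)
    if np.isnan(s).any():
        raise ValueError(f"{snp_id or 'series'}: NaN in smoothed series")
    d = np.diff(s)
    min_steps = int(round(min_span_years / bin_years))
    n_steps = len(d)

    best: dict[str, tuple[int, int, float]] = {}
    for direction, ok in (("increasing", d >= -tol), ("decreasing", d <= tol)):
        candidates = []
        for start, end in _runs(ok):
            length = end - start + 1
            amp = abs(s[end + 1] - s[start])
            candidates.append((length, amp, -start, start, end))
        if not candidates:
            continue
        length, amp, _, start, end = max(candidates)
        if length >= min_steps and amp >= min_amplitude:
            best[direction] = (start, end, amp)

    if not best:
        return TimCall(snp_id, "none", (0, 0), 0.0)
    if len(best) == 2:
        direction = max(best, key=lambda k: (best[k][2], -best[k][0]))
    else:
        direction = next(iter(best))
    start, end, amp = best[direction]
    covers_all = start == 0 and end == n_steps - 1
    cls = f"global_{direction}" if covers_all else "local"
    return TimCall(snp_id, cls, (start, end + 1), float(amp))


def detect_tims(
    components: ComponentSet,
    window: int = 3,
    min_span_years: float = 3000.0,
    min_amplitude: float = 0.05,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Run the full TIM pipeline over a curated component set.

    Uses the ancient components in canonical old-to-young order. Returns a
    per-SNP table (snp_id, class, start_bin, end_bin, amplitude, is_tim).
    """
    ordered = components.sorted_old_to_young()
    anc = ordered.ancient_index
    P = ordered.frequencies[anc]
    epochs = [ordered.epochs[i] for i in anc]
    series, _carried = series_from_components(P, epochs)
    sm = smooth(series, window=window)
    snp_ids = ordered.snp_ids or [f"snp{j}" for j in range(P.shape[1])]
    rows = []
    for j, sid in enumerate(snp_ids):
        call = classify_trend(
            sm[j], snp_id=sid, min_span_years=min_span_years,
            min_amplitude=min_amplitude, tol=tol,
        )
        rows.append(
            {
                "snp_id": sid,
                "class": call.cls,
                "start_bin": call.interval[0],
                "end_bin": call.interval[1],
                "amplitude": call.amplitude,
                "is_tim": call.cls != "none",
            }
        )
    return pd.DataFrame(rows).set_index("snp_id")


def sample_non_tims(
    all_snps: Sequence[str],
    tims: Sequence[str],
    size: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Seeded uniform sample of non-TIM SNPs, disjoint from the TIM set.

    Default size matches the TIM set (the null marker panel).
    """
    tim_set = set(tims)
    pool = [s for s in all_snps if s not in tim_set]
    if size is None:
        size = len(tim_set)
    if size > len(pool):
        raise ValueError(f"requested {size} non-TIMs but only {len(pool)} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=size, replace=False)
    return [pool[i] for i in sorted(idx)]
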