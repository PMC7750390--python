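"""Trajectory cleaning for indoor positioning data.

Four stages, applied in fixed order with per-stage removal accounting:

1. region filter -- drop fixes further than a buffer outside the barn
2. stuck-run removal -- drop runs of (near-)identical consecutive fixes
3. moving-average smoothing -- centred unweighted mean, window edge loss
4. stationary-day removal -- drop cow-days that barely move all day

Only smoothing alters coordinates; no stage ever alters a retained
record's animal id or timestamp.  Removal fractions are always reported
against the count the stage received; the pipeline additionally reports
fractions of the original input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import POSITION_COLUMNS
from .geometry import BarnGeometry


@dataclass(frozen=True)
class CleaningParams:
    """Thresholds for the four cleaning stages.

    The stuck-run and stationary-day rules have no published thresholds;
    defaults catch reset artifacts (exact coordinate repeats, jitter well
    under genuine sensor noise) without clipping real lying bouts.
    """

    region_buffer_m: float = 3.0
    stuck_min_run: int = 12  # 2 min at 0.1 Hz
    stuck_eps_m: float = 0.05
    smooth_window: int = 15  # 150 s at 0.1 Hz
    stationary_max_diag_m: float = 5.0
    stationary_min_span_fraction: float = 0.9


@dataclass
class CleanResult:
    cleaned: pd.DataFrame
    #: per-stage fraction of the ORIGINAL record count removed, in stage order
    stage_removed_fraction: dict = field(default_factory=dict)
    stage_removed_count: dict = field(default_factory=dict)
    original_count: int = 0

    @property
    def total_removed_fraction(self) -> float:
        return 1.0 - len(self.cleaned) / self.original_count if self.original_count else 0.0


def _validate(positions: pd.DataFrame) -> None:
    for col in POSITION_COLUMNS:
        if col not in positions.columns:
            raise ValueError(f"position table missing column {col!r}")
    for aid, grp in positions.groupby("animal_id", sort=False):
        t = grp["timestamp"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(
                f"animal {aid!r}: timestamps must be strictly increasing "
                "(unsorted or duplicate timestamps are an input error)"
            )


def filter_to_region(
    positions: pd.DataFrame, geometry: BarnGeometry, buffer_m: float = 3.0
) -> tuple[pd.DataFrame, float]:
    """Drop fixes outside the barn rectangle dilated by ``buffer_m``."""
    if buffer_m < 0:
        raise ValueError("buffer_m must be >= 0")
    if len(positions) == 0:
        return positions.copy(), 0.0
    region = geometry.barn.buffered(buffer_m)
    inside = region.contains(positions["x_m"].to_numpy(), positions["y_m"].to_numpy())
    kept = positions.loc[inside].reset_index(drop=True)
    return kept, 1.0 - len(kept) / len(positions)


def remove_stuck_runs(
    positions: pd.DataFrame, min_run: int = 12, eps_m: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Drop maximal runs of >= min_run consecutive fixes within eps of the run's first fix.

    Runs are scanned per cow per day; the whole run is removed.  Unsorted
    timestamps are rejected, never silently sorted.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if eps_m < 0:
        raise ValueError("eps_m must be >= 0")
    _validate(positions)
    if len(positions) == 0:
        return positions.copy(), 0.0
    drop = np.zeros(len(positions), dtype=bool)
    for _, idx in positions.groupby(["animal_id", "day_index"], sort=False).indices.items():
        x = positions["x_m"].to_numpy()[idx]
        y = positions["y_m"].to_numpy()[idx]
        n = len(idx)
        i = 0
        while i < n:
            # extend run anchored at i while distance to anchor <= eps
            j = i + 1
            while j < n and (x[j] - x[i]) ** 2 + (y[j] - y[i]) ** 2 <= eps_m**2:
                j += 1
            if j - i >= min_run:
                drop[idx[i:j]] = True
                i = j
            else:
                i += 1
    kept = positions.loc[~drop].reset_index(drop=True)
    return kept, drop.mean()


def smooth_trajectory(
    positions: pd.DataFrame, window: int = 15, sample_interval: float = 10.0
) -> tuple[pd.DataFrame, float]:
    """Centred moving average per contiguous same-day segment.

    Each coordinate becomes the unweighted mean of the ``window`` samples
    centred on it; the (window-1)/2 records at each segment end are
    dropped, and segments shorter than the window are dropped whole.
    Gaps larger than one sample interval break segments so absences
    (e.g. milking) do not smear across.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    _validate(positions)
    if len(positions) == 0:
        return positions.copy(), 0.0
    half = (window - 1) // 2
    kernel = np.full(window, 1.0 / window)
    pieces = []
    n_in = len(positions)
    for _, idx in positions.groupby(["animal_id", "day_index"], sort=False).indices.items():
        t = positions["timestamp"].to_numpy()[idx]
        breaks = np.flatnonzero(np.diff(t) > sample_interval + 1e-9) + 1
        for seg in np.split(np.arange(len(idx)), breaks):
            if len(seg) < window:
                continue
            sub = positions.iloc[idx[seg]]
            xs = np.convolve(sub["x_m"].to_numpy(), kernel, mode="valid")
            ys = np.convolve(sub["y_m"].to_numpy(), kernel, mode="valid")
            out = sub.iloc[half:-half].copy()
            out["x_m"] = xs
            out["y_m"] = ys
            pieces.append(out)
    if pieces:
        kept = pd.concat(pieces, ignore_index=True)
        kept.sort_values(["animal_id", "timestamp"], inplace=True, kind="mergesort")
        kept.reset_index(drop=True, inplace=True)
    else:
        kept = positions.iloc[0:0].reset_index(drop=True)
    return kept, 1.0 - len(kept) / n_in


def remove_stationary_days(
    positions: pd.DataFrame,
    max_daily_displacement_m: float = 5.0,
    min_span_fraction: float = 0.9,
) -> tuple[pd.DataFrame, float]:
    """Drop whole cow-days spent essentially in one spot.

    A cow-day is stationary when at least ``min_span_fraction`` of its
    records fall in a box of diagonal ``max_daily_displacement_m`` centred
    on the day's (coordinate-wise) median fix.
    """
    if max_daily_displacement_m <= 0 or not (0 < min_span_fraction <= 1):
        raise ValueError("thresholds must be positive (fraction in (0, 1])")
    if len(positions) == 0:
        return positions.copy(), 0.0
    half_side = max_daily_displacement_m / (2.0 * np.sqrt(2.0))
    drop = np.zeros(len(positions), dtype=bool)
    for _, idx in positions.groupby(["animal_id", "day_index"], sort=False).indices.items():
        x = positions["x_m"].to_numpy()[idx]
        y = positions["y_m"].to_numpy()[idx]
        cx, cy = np.median(x), np.median(y)
        near = (np.abs(x - cx) <= half_side) & (np.abs(y - cy) <= half_side)
        if near.mean() >= min_span_fraction:
            drop[idx] = True
    kept = positions.loc[~drop].reset_index(drop=True)
    return kept, drop.mean()


def clean_pipeline(
    positions: pd.DataFrame,
    geometry: BarnGeometry | None = None,
    params: CleaningParams | None = None,
    sample_interval: float = 10.0,
) -> CleanResult:
    """Apply the four cleaning stages in fixed order with accounting."""
    geometry = geometry or BarnGeometry()
    params = params or CleaningParams()
    _validate(positions)
    n0 = len(positions)
    result = CleanResult(cleaned=positions, original_count=n0)

    def _log(stage: str, before: pd.DataFrame, after: pd.DataFrame) -> None:
        removed = len(before) - len(after)
        result.stage_removed_count[stage] = removed
        result.stage_removed_fraction[stage] = removed / n0 if n0 else 0.0

    cur = positions
    step, _ = filter_to_region(cur, geometry, params.region_buffer_m)
    _log("region_filter", cur, step)
    cur = step
    step, _ = remove_stuck_runs(cur, params.stuck_min_run, params.stuck_eps_m)
    _log("stuck_removal", cur, step)
    cur = step
    step, _ = smooth_trajectory(cur, params.smooth_window, sample_interval)
    _log("smoothing", cur, step)
    cur = step
    step, _ = remove_stationary_days(
        cur, params.stationary_max_diag_m, params.stationary_min_span_fraction
    )
    _log("stationary_day_removal", cur, step)
    result.cleaned = step
    return result
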