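"""Sustained-proximity interaction detection.

An interaction between a dyad is a window of ``window_points`` consecutive
samples (consecutive timestamps exactly one sample interval apart) whose
inter-cow distances all lie within radius ``r`` (strict mode), or of which
a fraction >= ``lenient_fraction`` lie within ``r`` (lenient mode).  The
default protocol is r = 3 m, t = 60 s, i.e. 6 points at 0.1 Hz, strict,
with an inclusive (<= r) threshold.

Two counting conventions are provided: *tumbling* (the default) scans
left to right, counts a qualifying window and advances past it, making
daily counts proportional to sustained contact time; *sliding* counts
every qualifying window.  Which convention underlay the original daily
counts is unknowable from daily totals alone, so both are first-class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import runs_true
from .geometry import ZONES, BarnGeometry

__all__ = [
    "ProximityProtocol",
    "dyad_count",
    "zone_filter",
    "align_dyad",
    "detect_interactions",
    "daily_interaction_matrix",
    "validate_sensitivity",
    "sweep_protocol",
]


@dataclass(frozen=True)
class ProximityProtocol:
    """The (r, t, mode, windowing) contract defining an interaction."""

    r: float = 3.0
    t: float = 60.0
    sample_interval: float = 10.0
    mode: str = "strict"  # strict | lenient
    lenient_fraction: float = 1.0
    windowing: str = "tumbling"  # tumbling | sliding
    inclusive_threshold: bool = True

    def __post_init__(self) -> None:
        if self.r <= 0 or self.t <= 0 or self.sample_interval <= 0:
            raise ValueError("r, t and sample_interval must be positive")
        if self.mode not in ("strict", "lenient"):
            raise ValueError("mode must be 'strict' or 'lenient'")
        if self.windowing not in ("tumbling", "sliding"):
            raise ValueError("windowing must be 'tumbling' or 'sliding'")
        if not (0 < self.lenient_fraction <= 1):
            raise ValueError("lenient_fraction must be in (0, 1]")
        if self.window_points < 2:
            raise ValueError("t must span at least 2 sample points")

    @property
    def window_points(self) -> int:
        """Samples per window: round(t / sample_interval), 6 at the defaults."""
        return int(round(self.t / self.sample_interval))

    @property
    def min_within(self) -> int:
        """Minimum number of in-radius samples for a window to qualify."""
        w = self.window_points
        if self.mode == "strict":
            return w
        return int(np.ceil(self.lenient_fraction * w - 1e-9))


def dyad_count(n: int) -> int:
    """Number of unordered pairs, n(n-1)/2."""
    if n < 2:
        raise ValueError("need at least 2 animals")
    return n * (n - 1) // 2


def zone_filter(
    positions: pd.DataFrame,
    geometry: BarnGeometry,
    zone: str,
    buffer_m: float | None = None,
) -> pd.DataFrame:
    """Retain records inside the zone's region dilated by ``buffer_m``.

    ``full_barn`` uses the barn rectangle (the union of both zones'
    extents) with no dilation.
    """
    if zone not in ZONES:
        raise ValueError(f"unknown zone {zone!r}; expected one of {ZONES}")
    region = geometry.zone_region(zone, buffer_m)
    inside = region.contains(positions["x_m"].to_numpy(), positions["y_m"].to_numpy())
    return positions.loc[inside].reset_index(drop=True)


def align_dyad(
    track_a: pd.DataFrame, track_b: pd.DataFrame, sample_interval: float = 10.0
) -> pd.DataFrame:
    """Pair two single-animal tracks on common timestamps.

    Returns a frame (timestamp, distance) of Euclidean inter-animal
    distances at every timestamp present in both tracks.  Timestamps
    present in only one track simply do not appear, leaving gaps that
    break window contiguity downstream.
    """
    for tr, name in ((track_a, "track_a"), (track_b, "track_b")):
        if tr["animal_id"].nunique() > 1:
            raise ValueError(f"{name} must contain a single animal")
        t = tr["timestamp"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{name} must be sorted by timestamp")
    merged = pd.merge(
        track_a[["timestamp", "x_m", "y_m"]],
        track_b[["timestamp", "x_m", "y_m"]],
        on="timestamp",
        suffixes=("_a", "_b"),
    )
    dist = np.hypot(
        merged["x_m_a"] - merged["x_m_b"], merged["y_m_a"] - merged["y_m_b"]
    )
    return pd.DataFrame({"timestamp": merged["timestamp"], "distance": dist})


def _count_segment(
    within: np.ndarray, protocol: ProximityProtocol
) -> tuple[int, list[int]]:
    """Count qualifying windows in one contiguous segment.

    ``within`` is the boolean in-radius mask of consecutive samples.
    Returns (count, window start offsets).
    """
    w = protocol.window_points
    n = within.size
    if n < w:
        return 0, []
    need = protocol.min_within
    if need == w:
        # strict-equivalent fast path: runs of consecutive in-radius samples
        _, starts, lengths = runs_true(within)
        count = 0
        found: list[int] = []
        for s, ln in zip(starts, lengths):
            if protocol.windowing == "tumbling":
                k = ln // w
                count += k
                found.extend(s + w * j for j in range(k))
            else:
                k = max(ln - w + 1, 0)
                count += k
                found.extend(range(s, s + k))
        return count, found
    # lenient: rolling in-radius counts, then greedy or full scan
    csum = np.concatenate(([0], np.cumsum(within)))
    win_counts = csum[w:] - csum[:-w]  # count of in-radius samples per start
    qualifies = win_counts >= need
    if protocol.windowing == "sliding":
        found = np.flatnonzero(qualifies)
        return int(found.size), found.tolist()
    count = 0
    found = []
    i = 0
    m = qualifies.size
    while i < m:
        if qualifies[i]:
            count += 1
            found.append(i)
            i += w
        else:
            i += 1
    return count, found


def detect_interactions(
    distance_series: pd.DataFrame, protocol: ProximityProtocol
) -> tuple[int, pd.DataFrame]:
    """Count sustained-proximity windows in a dyad's paired distance series.

    Returns the interaction count and a frame of the counted windows
    (start, end timestamps, inclusive).  Windows never span timestamp
    gaps: contiguity requires consecutive samples exactly one sample
    interval apart.
    """
    t = distance_series["timestamp"].to_numpy(dtype=float)
    d = distance_series["distance"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("distance series must be sorted by timestamp")
    w = protocol.window_points
    if t.size < w:
        return 0, pd.DataFrame(columns=["start", "end"])
    within = d <= protocol.r if protocol.inclusive_threshold else d < protocol.r
    breaks = np.flatnonzero(np.abs(np.diff(t) - protocol.sample_interval) > 1e-9) + 1
    total = 0
    rows: list[tuple[float, float]] = []
    for seg in np.split(np.arange(t.size), breaks):
        cnt, starts = _count_segment(within[seg], protocol)
        total += cnt
        for s in starts:
            rows.append((t[seg[s]], t[seg[s] + w - 1]))
    return total, pd.DataFrame(rows, columns=["start", "end"])


def _day_tick_grid(
    positions: pd.DataFrame, day_index: int, sample_interval: float, roster: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pivot one day's records onto the day's uniform tick grid.

    Returns (x, y) arrays of shape (n_cows, ticks) with NaN where an
    animal has no surviving record at that tick, plus the day start time.
    """
    day = positions.loc[positions["day_index"] == day_index]
    ticks_per_day = int(round(86_400 / sample_interval))
    day_t0 = int(day_index) * 86_400
    n = len(roster)
    x = np.full((n, ticks_per_day), np.nan)
    y = np.full((n, ticks_per_day), np.nan)
    if len(day) == 0:
        return x, y, day_t0
    idx_of = {aid: k for k, aid in enumerate(roster)}
    rows = day["animal_id"].map(idx_of)
    if rows.isna().any():
        bad = day.loc[rows.isna(), "animal_id"].unique()
        raise ValueError(f"animals not in roster: {list(bad)[:5]}")
    tick = np.rint((day["timestamp"].to_numpy() - day_t0) / sample_interval).astype(int)
    if (tick < 0).any() or (tick >= ticks_per_day).any():
        raise ValueError("timestamps outside the stated day")
    x[rows.to_numpy(dtype=int), tick] = day["x_m"].to_numpy()
    y[rows.to_numpy(dtype=int), tick] = day["y_m"].to_numpy()
    return x, y, day_t0


def daily_interaction_matrix(
    positions: pd.DataFrame,
    geometry: BarnGeometry,
    zone: str,
    protocol: ProximityProtocol,
    day_index: int,
    roster: list[str] | None = None,
    return_windows: bool = False,
):
    """Symmetric dyadic interaction counts for one day and functional zone.

    Applies the zone filter, then counts qualifying windows for every
    dyad.  A window counts toward a zone only if both animals' samples in
    it survive that zone's buffered filter.  The diagonal is NaN.
    """
    if roster is None:
        roster = sorted(positions["animal_id"].unique())
    if len(roster) < 2:
        raise ValueError("roster must contain at least 2 animals")
    zoned = zone_filter(positions, geometry, zone)
    x, y, day_t0 = _day_tick_grid(zoned, day_index, protocol.sample_interval, roster)
    n = len(roster)
    counts = np.zeros((n, n))
    window_rows: list[tuple] = []
    iu, ju = np.triu_indices(n, 1)
    present = np.isfinite(x)
    w = protocol.window_points
    strictlike = protocol.min_within == w
    for a, b in zip(iu, ju):
        both = present[a] & present[b]
        if both.sum() < w:
            continue
        dx = x[a] - x[b]
        dy = y[a] - y[b]
        dist2 = dx * dx + dy * dy
        r2 = protocol.r**2
        within = np.where(
            both, (dist2 <= r2) if protocol.inclusive_threshold else (dist2 < r2), False
        )
        if strictlike:
            valid = within  # absent samples are already False
            _, starts, lengths = runs_true(valid)
            cnt = 0
            starts_out: list[int] = []
            for s, ln in zip(starts, lengths):
                if protocol.windowing == "tumbling":
                    k = ln // w
                    cnt += k
                    if return_windows:
                        starts_out.extend(s + w * j for j in range(k))
                else:
                    k = max(ln - w + 1, 0)
                    cnt += k
                    if return_windows:
                        starts_out.extend(range(s, s + k))
        else:
            # lenient: windows need all samples present, enough within radius
            run_ok = np.where(both, True, False)
            cnt = 0
            starts_out = []
            _, seg_starts, seg_lens = runs_true(run_ok)
            for s, ln in zip(seg_starts, seg_lens):
                c, offs = _count_segment(within[s : s + ln], protocol)
                cnt += c
                if return_windows:
                    starts_out.extend(s + o for o in offs)
        counts[a, b] = counts[b, a] = cnt
        if return_windows:
            for s in starts_out:
                window_rows.append(
                    (
                        roster[a],
                        roster[b],
                        day_index,
                        day_t0 + s * protocol.sample_interval,
                        day_t0 + (s + w - 1) * protocol.sample_interval,
                    )
                )
    matrix = pd.DataFrame(counts, index=roster, columns=roster)
    np.fill_diagonal(matrix.values, np.nan)
    if return_windows:
        windows = pd.DataFrame(
            window_rows, columns=["id_a", "id_b", "day_index", "start", "end"]
        )
        return matrix, windows
    return matrix


def validate_sensitivity(
    detected_windows: pd.DataFrame, truth_intervals: pd.DataFrame
) -> float:
    """True-positive rate of detection against ground-truth contact intervals.

    sensitivity = (# truth intervals overlapped by >= 1 detected window of
    the same dyad and day) / (# truth intervals).
    """
    if len(truth_intervals) == 0:
        raise ValueError("truth interval set is empty")

    def _key(df: pd.DataFrame) -> pd.Series:
        lo = df[["id_a", "id_b"]].min(axis=1)
        hi = df[["id_a", "id_b"]].max(axis=1)
        return lo + "|" + hi + "|" + df["day_index"].astype(str)

    truth = truth_intervals.assign(dyad_key=_key(truth_intervals))
    hit = 0
    if len(detected_windows):
        det = detected_windows.assign(dyad_key=_key(detected_windows))
        groups = {k: g for k, g in det.groupby("dyad_key")}
        for row in truth.itertuples():
            g = groups.get(row.dyad_key)
            if g is not None and bool(
                ((g["start"] <= row.end) & (g["end"] >= row.start)).any()
            ):
                hit += 1
    return hit / len(truth)


def sweep_protocol(
    positions: pd.DataFrame,
    geometry: BarnGeometry,
    zone: str,
    day_index: int,
    r_values=(1.0, 2.0, 3.0, 4.0, 5.0),
    t_values=(40.0, 60.0, 80.0, 100.0),
    base: ProximityProtocol | None = None,
    roster: list[str] | None = None,
) -> pd.DataFrame:
    """Total daily interactions over a grid of radius and duration values."""
    base = base or ProximityProtocol()
    rows = []
    for r in r_values:
        for t in t_values:
            proto = ProximityProtocol(
                r=r,
                t=t,
                sample_interval=base.sample_interval,
                mode=base.mode,
                lenient_fraction=base.lenient_fraction,
                windowing=base.windowing,
                inclusive_threshold=base.inclusive_threshold,
            )
            m = daily_interaction_matrix(positions, geometry, zone, proto, day_index, roster)
            vals = m.to_numpy()
            total = np.nansum(np.triu(np.nan_to_num(vals), 1))
            rows.append({"r": r, "t": t, "total_interactions": float(total)})
    return pd.DataFrame(rows)
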