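"""Synthetic herd-trajectory generator with known ground truth.

Emulates an indoor positioning system recording a free-stall dairy herd at
0.1 Hz: barn-confined movement alternating between feeding and non-feeding
zone bouts, thrice-daily milking absences, sensor noise at a configurable
CEP50, stuck-sensor and out-of-barn artifacts, and a planted dyadic
preference (affinity) structure optionally coupled to cow attributes.

The movement model is a semi-Markov bout process: each cow alternates
between a personal cubicle station, a feed-face station, loafing, and
"social" bouts spent near a partner's cubicle, with Ornstein--Uhlenbeck
jitter around the current station.  High-affinity dyads receive adjacent
stations (greedy chain ordering of the affinity matrix) and choose each
other as social partners, so planted preferences translate into sustained
co-location that the downstream detector can recover.  Only the statistical
consequences of movement (zone occupancy, dyad-preferential proximity) are
intended to be realistic; the kinematics are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._util import POSITION_COLUMNS, runs_true, subseed
from .geometry import BarnGeometry

SECONDS_PER_DAY = 86_400

#: sigma of a circular bivariate normal whose CEP50 equals 1:  CEP50 = sigma*sqrt(2 ln 2)
CEP50_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))

# movement states
_CUBICLE, _FEED, _LOAF, _SOCIAL = 0, 1, 2, 3


def default_milking_windows() -> tuple[tuple[int, int], ...]:
    """Daily absence intervals (seconds of day), 70 min centred on 05:00, 13:00, 21:00."""
    half = 35 * 60
    return tuple((c - half, c + half) for c in (5 * 3600, 13 * 3600, 21 * 3600))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the recorded system: 0.1 Hz sampling, three daily
    milkings, CEP50 = 1.90 m sensor noise on a moving cow.
    """

    n_cows: int = 92
    n_days: int = 28
    sample_interval: float = 10.0
    milking_windows: tuple[tuple[int, int], ...] = field(
        default_factory=default_milking_windows
    )
    noise_cep50: float = 1.90
    stuck_rate: float = 0.3  # expected stuck runs per cow-day
    stuck_mean_len: int = 30  # mean stuck-run length in samples
    outlier_rate: float = 2e-4  # per-record probability of a far out-of-barn fix
    affinity_spread: float = 0.6
    assortment_effect: float = 0.0
    assort_attr: str = "parity"  # attribute coupled to affinity
    contact_radius: float = 3.0  # radius defining a ground-truth contact
    social_prob: float = 0.35  # probability a rest bout is spent near a partner
    mean_bout_min: dict | None = None  # per-state mean bout length (minutes)
    record_milking_positions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 2:
            raise ValueError("n_cows must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        for name in ("noise_cep50", "stuck_rate", "outlier_rate", "affinity_spread"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if not np.isfinite(self.assortment_effect):
            raise ValueError("assortment_effect must be finite")
        for lo, hi in self.milking_windows:
            if not (0 <= lo < hi <= SECONDS_PER_DAY):
                raise ValueError("milking windows must lie within the day")

    @property
    def ticks_per_day(self) -> int:
        return int(round(SECONDS_PER_DAY / self.sample_interval))

    def bout_minutes(self) -> dict:
        base = {_CUBICLE: 55.0, _FEED: 30.0, _LOAF: 12.0, _SOCIAL: 30.0}
        if self.mean_bout_min:
            base.update(self.mean_bout_min)
        return base


@dataclass
class GroundTruthLog:
    """What the generator actually planted.

    ``true_contact_intervals`` holds one row per maximal interval during
    which a dyad's noise-free distance stayed within ``contact_radius``
    (columns: id_a, id_b, day_index, start, end, inclusive sample times).
    """

    affinity_matrix: pd.DataFrame
    true_contact_intervals: pd.DataFrame
    attributes: pd.DataFrame


def animal_ids(n_cows: int) -> list[str]:
    return [f"cow{i:03d}" for i in range(n_cows)]


def generate_attributes(
    n_cows: int, seed: int, lame_fraction: float = 0.35, ns_rate: float = 0.03
) -> pd.DataFrame:
    """Cow attribute table: parity, days in milk, three mobility scores.

    Parity ~ 1 + Poisson(2) truncated at 7 (herd mean ~3); DIM uniform on
    [10, 262] (mean ~136); mobility scores drawn per cow from a latent
    lameness state so most cows have a consistent L/NL sequence.  The
    derived two-group lameness class follows the dominant-state rules.
    """
    from .permstats import classify_lameness

    rng = subseed(seed, 2)
    parity = np.minimum(1 + rng.poisson(2.0, size=n_cows), 7)
    dim = rng.integers(10, 263, size=n_cows)
    latent_lame = rng.random(n_cows) < lame_fraction
    scores = np.empty((n_cows, 3), dtype=object)
    for i in range(n_cows):
        for s in range(3):
            if rng.random() < ns_rate:
                scores[i, s] = "NS"
            elif latent_lame[i]:
                # lame cows occasionally score 0-1 in one session
                scores[i, s] = int(rng.choice([2, 3])) if rng.random() < 0.85 else int(rng.choice([0, 1]))
            else:
                scores[i, s] = int(rng.choice([0, 1])) if rng.random() < 0.9 else int(rng.choice([2, 3]))
    table = pd.DataFrame(
        {
            "animal_id": animal_ids(n_cows),
            "parity": parity.astype(int),
            "days_in_milk": dim.astype(int),
            "score_1": scores[:, 0],
            "score_2": scores[:, 1],
            "score_3": scores[:, 2],
        }
    )
    table["lameness_class"] = [
        classify_lameness((row.score_1, row.score_2, row.score_3))
        for row in table.itertuples()
    ]
    return table


def plant_affinity(
    n_cows: int,
    affinity_spread: float,
    assortment_effect: float,
    attributes: pd.DataFrame | None = None,
    seed: int = 0,
    attr_field: str = "parity",
) -> np.ndarray:
    """Symmetric positive dyadic preference weights.

    ``w_ij = exp(spread * g_ij - effect * d_ij)`` with ``g_ij`` symmetric
    standard normal and ``d_ij`` the ``attr_field`` difference scaled to
    [0, 1].
    Positive ``assortment_effect`` makes similar cows prefer each other
    (affinity decreasing in attribute difference); a negative effect plants
    the disassortative mirror image.  ``spread = effect = 0`` gives equal
    weights for all dyads.
    """
    if n_cows < 2:
        raise ValueError("n_cows must be >= 2")
    for v, name in ((affinity_spread, "affinity_spread"), (assortment_effect, "assortment_effect")):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if affinity_spread < 0:
        raise ValueError("affinity_spread must be >= 0")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_cows, n_cows))
    g = (g + g.T) / np.sqrt(2.0)
    log_w = affinity_spread * g
    if assortment_effect != 0.0:
        if attributes is None:
            raise ValueError("attributes required when assortment_effect != 0")
        a = attributes[attr_field].to_numpy(dtype=float)
        d = np.abs(a[:, None] - a[None, :])
        dmax = d.max()
        if dmax > 0:
            d = d / dmax
        log_w = log_w - assortment_effect * d
    w = np.exp(log_w)
    np.fill_diagonal(w, 0.0)
    return w


def _chain_order(affinity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Order cows so high-affinity dyads sit at adjacent stations.

    Greedy chain: start from a random cow and repeatedly append the
    unplaced cow with the highest affinity to the current chain end.  With
    an all-equal affinity matrix this degenerates to a uniformly random
    order (ties broken by a random key), keeping the null exchangeable.
    """
    n = affinity.shape[0]
    tiebreak = rng.random((n, n))
    placed = np.zeros(n, dtype=bool)
    order = np.empty(n, dtype=int)
    cur = int(rng.integers(n))
    order[0] = cur
    placed[cur] = True
    for k in range(1, n):
        cand = np.where(~placed)[0]
        a = affinity[cur, cand]
        best = cand[np.lexsort((tiebreak[cur, cand], -a))[0]]
        order[k] = best
        placed[best] = True
        cur = best
    return order


def _stations(
    order: np.ndarray, geometry: BarnGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cubicle, feed-face, and loafing stations per cow (n, 2) arrays."""
    n = len(order)
    barn = geometry.barn
    nf = geometry.non_feeding
    fz = geometry.feeding
    cub = np.empty((n, 2))
    feed = np.empty((n, 2))
    loaf = np.empty((n, 2))
    # serpentine cubicle rows along x (station pitch 2.2 m: immediate chain
    # neighbours sit inside a 3 m radius, second neighbours at 4.4 m, well
    # outside it even through sensor noise), rows 3.2 m apart in y
    pitch = 2.2
    cap = max(2, int((barn.width - 4.0) / pitch))
    row_y = np.array([nf.ymin + 2.0, nf.ymin + 5.2, nf.ymin + 8.4])
    feed_spacing = min(pitch, (barn.width - 4.0) / max(n - 1, 1))
    feed_y = fz.ymax - 1.0
    loaf_y = nf.ymax - 1.0  # passageway below the feed face
    for rank, cow in enumerate(order):
        row, col = divmod(rank, cap)
        cub[cow] = (barn.xmin + 2.0 + pitch * col, row_y[row % len(row_y)])
        feed[cow] = (barn.xmin + 2.0 + feed_spacing * rank, feed_y)
        loaf[cow] = (barn.xmin + 2.0 + (pitch * rank) % (barn.width - 4.0), loaf_y)
    return cub, feed, loaf


def _milking_mask(config: SimConfig) -> np.ndarray:
    """Boolean per-tick mask of samples falling inside a milking window."""
    t = np.arange(config.ticks_per_day) * config.sample_interval
    mask = np.zeros(config.ticks_per_day, dtype=bool)
    for lo, hi in config.milking_windows:
        mask |= (t >= lo) & (t < hi)
    return mask


def _base_day(
    config: SimConfig,
    rng: np.random.Generator,
    cow: int,
    cub: np.ndarray,
    feed: np.ndarray,
    loaf: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Base (asocial) per-tick targets and states for one cow-day.

    The cow alternates cubicle, feed-face and loafing bouts with
    exponential durations; a feeding bout is forced after each milking
    window (feed delivery).  Social behaviour is layered on afterwards.
    """
    T = config.ticks_per_day
    dt_min = config.sample_interval / 60.0
    means = config.bout_minutes()
    targets = np.empty((T, 2))
    states = np.empty(T, dtype=np.int8)
    station = {_CUBICLE: cub[cow], _FEED: feed[cow], _LOAF: loaf[cow]}
    state = _CUBICLE
    t = 0
    while t < T:
        dur = max(3, int(round(rng.exponential(means[state]) / dt_min)))
        end = min(T, t + dur)
        targets[t:end] = station[state]
        states[t:end] = state
        t = end
        if state == _FEED:
            state = _CUBICLE if rng.random() < 0.8 else _LOAF
        elif state == _CUBICLE:
            state = _FEED if rng.random() < 0.5 else _LOAF
        else:
            state = _CUBICLE if rng.random() < 0.6 else _FEED
    # feed is delivered around milking: force a feeding bout after each window
    feed_ticks = int(round(means[_FEED] / dt_min))
    for lo, hi in config.milking_windows:
        start = int(np.ceil(hi / config.sample_interval))
        if start < T:
            stop = min(T, start + feed_ticks)
            targets[start:stop] = feed[cow]
            states[start:stop] = _FEED
    return targets, states


def _ou_jitter(
    T: int, rng: np.random.Generator, sample_interval: float, tau: float = 90.0, sd: float = 0.45
) -> np.ndarray:
    """Stationary OU (AR(1)) jitter, (T, 2)."""
    phi = np.exp(-sample_interval / tau)
    eps = rng.standard_normal((T, 2)) * sd * np.sqrt(1.0 - phi**2)
    eps[0] = rng.standard_normal(2) * sd
    return lfilter([1.0], [1.0, -phi], eps, axis=0)


def simulate_herd(
    config: SimConfig,
    geometry: BarnGeometry | None = None,
    affinity: np.ndarray | None = None,
    attributes: pd.DataFrame | None = None,
    include_truth: bool = True,
) -> tuple[pd.DataFrame, GroundTruthLog]:
    """Simulate noise-free planted trajectories for the whole herd.

    Returns the position table (columns animal_id, day_index, timestamp,
    x_m, y_m; epoch seconds from a day-0 origin; sorted by animal then
    time) and the ground-truth log.  Sensor noise and artifacts are added
    separately by :func:`inject_artifacts`.
    """
    geometry = geometry or BarnGeometry()
    if attributes is None:
        attributes = generate_attributes(config.n_cows, config.seed)
    if affinity is None:
        affinity = plant_affinity(
            config.n_cows,
            config.affinity_spread,
            config.assortment_effect,
            attributes,
            seed=int(subseed(config.seed, 3).integers(2**31)),
            attr_field=config.assort_attr,
        )
    affinity = np.asarray(affinity, dtype=float)
    if affinity.shape != (config.n_cows, config.n_cows):
        raise ValueError("affinity matrix dimension must equal n_cows")

    ids = animal_ids(config.n_cows)
    rng = subseed(config.seed, 0)
    order = _chain_order(affinity, rng)
    cub, feed, loaf = _stations(order, geometry)
    row_sums = affinity.sum(axis=1)
    partner_p = np.where(
        row_sums[:, None] > 0, affinity / np.maximum(row_sums[:, None], 1e-300), 0.0
    )
    # equal-affinity degenerate case: uniform partner choice excluding self
    for i in range(config.n_cows):
        if row_sums[i] <= 0:
            partner_p[i] = 1.0 / (config.n_cows - 1)
            partner_p[i, i] = 0.0

    T = config.ticks_per_day
    milking = _milking_mask(config)
    keep = ~milking
    tick_seconds = np.arange(T) * config.sample_interval
    barn = geometry.barn
    parlor = np.array([barn.xmax + 12.0, barn.ymax + 6.0])

    frames = []
    truth_pos = np.empty((config.n_cows, T, 2)) if include_truth else None
    truth_rows: list[pd.DataFrame] = []
    for day in range(config.n_days):
        day_t0 = day * SECONDS_PER_DAY
        # pass 1: every cow's base (asocial) schedule for the day
        base = np.empty((config.n_cows, T, 2))
        states = np.empty((config.n_cows, T), dtype=np.int8)
        for c in range(config.n_cows):
            base[c], states[c] = _base_day(config, rng, c, cub, feed, loaf)
        # pass 2: social co-location.  Rest bouts become visits that shadow
        # a partner's base track; feed bouts relocate next to a preferred
        # cow that is already feeding.  A host accepts one resting visitor
        # at a time (booking calendar), so a busy first-choice partner makes
        # the visit overflow down the affinity gradient and co-visitors do
        # not pile onto one host as spurious visitor-visitor contacts.
        host_busy = np.zeros((config.n_cows, T), dtype=bool)
        for c in range(config.n_cows):
            targets = base[c].copy()
            st = states[c]
            bnd = np.flatnonzero(np.diff(st)) + 1
            for s, e in zip(np.r_[0, bnd], np.r_[bnd, T]):
                state = st[s]
                if rng.random() >= config.social_prob:
                    continue
                if state in (_CUBICLE, _LOAF):
                    j = -1
                    for _attempt in range(4):
                        cand = int(rng.choice(config.n_cows, p=partner_p[c]))
                        if host_busy[cand, s:e].mean() <= 0.25:
                            j = cand
                            break
                    if j < 0:
                        continue  # everyone preferred is engaged; rest at home
                    host_busy[j, s:e] = True
                    ang = rng.uniform(0, 2 * np.pi)
                    targets[s:e] = base[j, s:e] + 1.8 * np.array(
                        [np.cos(ang), np.sin(ang)]
                    )
                else:  # feeding: stand beside a preferred co-feeding cow
                    co = np.flatnonzero(states[:, s] == _FEED)
                    co = co[co != c]
                    if co.size == 0:
                        continue
                    w = affinity[c, co]
                    tot = w.sum()
                    pvec = w / tot if tot > 0 else np.full(co.size, 1.0 / co.size)
                    j = int(co[rng.choice(co.size, p=pvec)])
                    # track j only while j itself keeps feeding
                    seg = states[j, s:e] == _FEED
                    j_end = e if seg.all() else s + int(np.argmax(~seg))
                    side = 1.7 if rng.random() < 0.5 else -1.7
                    targets[s:j_end] = base[j, s:j_end] + np.array([side, 0.0])
            pos = targets + _ou_jitter(T, rng, config.sample_interval)
            np.clip(pos[:, 0], barn.xmin + 0.05, barn.xmax - 0.05, out=pos[:, 0])
            np.clip(pos[:, 1], barn.ymin + 0.05, barn.ymax - 0.05, out=pos[:, 1])
            if include_truth:
                truth_pos[c] = pos
            if config.record_milking_positions:
                out = pos.copy()
                out[milking] = parlor + 0.5 * rng.standard_normal((milking.sum(), 2))
                sel = slice(None)
            else:
                out = pos[keep]
                sel = keep
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": ids[c],
                        "day_index": day,
                        "timestamp": day_t0 + tick_seconds[sel],
                        "x_m": out[:, 0],
                        "y_m": out[:, 1],
                    }
                )
            )
        if include_truth:
            truth_rows.append(
                _truth_intervals_for_day(
                    truth_pos, keep, ids, day, tick_seconds, config
                )
            )

    positions = pd.concat(frames, ignore_index=True)
    positions.sort_values(["animal_id", "timestamp"], inplace=True, kind="mergesort")
    positions.reset_index(drop=True, inplace=True)

    truth_df = (
        pd.concat(truth_rows, ignore_index=True)
        if truth_rows
        else pd.DataFrame(columns=["id_a", "id_b", "day_index", "start", "end"])
    )
    aff_df = pd.DataFrame(affinity, index=ids, columns=ids)
    return positions[POSITION_COLUMNS], GroundTruthLog(aff_df, truth_df, attributes)


def _truth_intervals_for_day(
    truth_pos: np.ndarray,
    keep: np.ndarray,
    ids: list[str],
    day: int,
    tick_seconds: np.ndarray,
    config: SimConfig,
) -> pd.DataFrame:
    """Maximal co-present intervals with planted distance <= contact_radius."""
    n = truth_pos.shape[0]
    iu, ju = np.triu_indices(n, 1)
    # distances for all dyads at kept ticks only (milking removes everyone)
    p = truth_pos[:, keep, :]
    d = np.linalg.norm(p[iu] - p[ju], axis=2)
    within = d <= config.contact_radius
    # kept ticks are not uniformly spaced across milking gaps: break runs there
    kept_idx = np.flatnonzero(keep)
    contiguous = np.ones(kept_idx.size, dtype=bool)
    contiguous[1:] = np.diff(kept_idx) == 1
    # a run must consist of consecutive ticks: split where contiguity breaks
    within &= True
    boundary = ~contiguous
    # force run breaks at gap starts by inserting False via masking trick:
    # handle by scanning runs on within, then splitting runs crossing a boundary.
    row, start, length = runs_true(within)
    day_t0 = day * SECONDS_PER_DAY
    kept_seconds = tick_seconds[kept_idx]
    recs: list[tuple] = []
    gap_positions = np.flatnonzero(boundary)  # index k means gap between k-1 and k
    for r, s, ln in zip(row, start, length):
        # split the run [s, s+ln) at any gap position inside it
        cuts = gap_positions[(gap_positions > s) & (gap_positions < s + ln)]
        bounds = [s, *cuts.tolist(), s + ln]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            recs.append(
                (
                    ids[iu[r]],
                    ids[ju[r]],
                    day,
                    day_t0 + kept_seconds[b0],
                    day_t0 + kept_seconds[b1 - 1],
                )
            )
    return pd.DataFrame(recs, columns=["id_a", "id_b", "day_index", "start", "end"])


def inject_artifacts(
    positions: pd.DataFrame,
    config: SimConfig,
    geometry: BarnGeometry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add sensor noise, stuck runs, and out-of-barn fixes.

    Returns the corrupted table plus an artifact log (kind, animal_id,
    day_index, start_index, n_records) for cleaning-stage validation.
    Noise is isotropic Gaussian with per-axis sigma = CEP50 / sqrt(2 ln 2);
    stuck runs repeat the run's first (noisy) coordinate exactly; outliers
    are isolated fixes displaced 10--40 m outside the barn.
    """
    geometry = geometry or BarnGeometry()
    rng = subseed(config.seed, 1)
    out = positions.copy(deep=True)
    n = len(out)
    log: list[tuple] = []
    if n == 0:
        return out, pd.DataFrame(columns=["kind", "animal_id", "day_index", "start_index", "n_records"])

    if config.noise_cep50 > 0:
        sigma = config.noise_cep50 * CEP50_TO_SIGMA
        out["x_m"] = out["x_m"].to_numpy() + rng.normal(0.0, sigma, n)
        out["y_m"] = out["y_m"].to_numpy() + rng.normal(0.0, sigma, n)

    x = out["x_m"].to_numpy()
    y = out["y_m"].to_numpy()

    if config.stuck_rate > 0:
        groups = out.groupby(["animal_id", "day_index"], sort=False).indices
        for (aid, day), idx in groups.items():
            for _ in range(rng.poisson(config.stuck_rate)):
                if len(idx) < 2:
                    continue
                start = int(rng.integers(0, len(idx) - 1))
                length = min(
                    int(rng.geometric(1.0 / config.stuck_mean_len)) + 11,
                    len(idx) - start,
                )
                sel = idx[start : start + length]
                x[sel] = x[sel[0]]
                y[sel] = y[sel[0]]
                log.append(("stuck_run", aid, day, int(sel[0]), int(length)))

    if config.outlier_rate > 0:
        hits = np.flatnonzero(rng.random(n) < config.outlier_rate)
        barn = geometry.barn
        for i in hits:
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(10.0, 40.0)
            cx, cy = (barn.xmin + barn.xmax) / 2, (barn.ymin + barn.ymax) / 2
            half_diag = np.hypot(barn.width, barn.height) / 2
            x[i] = cx + (half_diag + dist) * np.cos(ang)
            y[i] = cy + (half_diag + dist) * np.sin(ang)
            log.append(
                ("out_of_barn", out["animal_id"].iat[i], int(out["day_index"].iat[i]), int(i), 1)
            )

    out["x_m"] = x
    out["y_m"] = y
    log_df = pd.DataFrame(
        log, columns=["kind", "animal_id", "day_index", "start_index", "n_records"]
    )
    if config.noise_cep50 == 0 and config.stuck_rate == 0 and config.outlier_rate == 0:
        pass  # strict no-op contract: out is an unchanged copy
    return out, log_df


def generate_herd(
    config: SimConfig, geometry: BarnGeometry | None = None, include_truth: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthLog]:
    """Convenience wrapper: simulate, then corrupt.

    Returns (raw_observed, artifact_log wrapped inside, truth).  The first
    element is what a real deployment would record.
    """
    clean, truth = simulate_herd(config, geometry, include_truth=include_truth)
    observed, artifact_log = inject_artifacts(clean, config, geometry)
    return observed, artifact_log, truth
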