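"""Detection protocol: worked examples, oracle equivalence, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import distance_series, make_track
from herdnet.geometry import BarnGeometry
from herdnet.proximity import (
    ProximityProtocol,
    align_dyad,
    daily_interaction_matrix,
    detect_interactions,
    dyad_count,
    validate_sensitivity,
    zone_filter,
)


def oracle_count(times, dists, protocol: ProximityProtocol) -> int:
    """Naive enumerate-every-window reference detector."""
    w = protocol.window_points
    n = len(times)

    def qualifies(i: int) -> bool:
        for k in range(w - 1):
            if abs((times[i + k + 1] - times[i + k]) - protocol.sample_interval) > 1e-9:
                return False
        within = [
            (d <= protocol.r) if protocol.inclusive_threshold else (d < protocol.r)
            for d in dists[i : i + w]
        ]
        if protocol.mode == "strict":
            return all(within)
        return sum(within) / w >= protocol.lenient_fraction - 1e-12

    if protocol.windowing == "sliding":
        return sum(qualifies(i) for i in range(n - w + 1))
    count = 0
    i = 0
    while i <= n - w:
        if qualifies(i):
            count += 1
            i += w
        else:
            i += 1
    return count


class TestDyadCount:
    @pytest.mark.parametrize("n,expected", [(92, 4186), (48, 1128), (2, 1), (3, 3)])
    def test_values(self, n, expected):
        assert dyad_count(n) == expected

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            dyad_count(1)


class TestZoneFilter:
    def test_feeding_zone_interior(self, geometry):
        t = make_track([10.0], [12.0])
        assert len(zone_filter(t, geometry, "feeding")) == 1

    def test_feeding_zone_buffer_arithmetic(self, geometry):
        # y = 9.0 is outside [10.5, 17.2] but inside the 3 m buffered band
        t = make_track([10.0], [9.0])
        assert len(zone_filter(t, geometry, "feeding", buffer_m=3.0)) == 1

    def test_feeding_zone_outside_buffer_removed(self, geometry):
        t = make_track([10.0], [1.0])
        assert len(zone_filter(t, geometry, "feeding", buffer_m=3.0)) == 0

    def test_unknown_zone_rejected(self, geometry):
        with pytest.raises(ValueError):
            zone_filter(make_track([0.0]), geometry, "parlour")


class TestAlignDyad:
    def test_identical_grids_full_length(self):
        a = make_track(np.zeros(10), np.zeros(10), animal_id="a")
        b = make_track(np.full(10, 3.0), np.full(10, 4.0), animal_id="b")
        paired = align_dyad(a, b)
        assert len(paired) == 10
        assert np.allclose(paired["distance"], 5.0)  # 3-4-5

    def test_disjoint_grids_empty(self):
        a = make_track(np.zeros(5), animal_id="a")
        b = make_track(np.zeros(5), animal_id="b", t0=1000.0)
        assert len(align_dyad(a, b)) == 0

    def test_multi_animal_track_rejected(self):
        a = pd.concat(
            [make_track([0.0], animal_id="a"), make_track([0.0], animal_id="b")]
        )
        with pytest.raises(ValueError):
            align_dyad(a, a)


class TestDetectInteractions:
    def test_twelve_close_samples_tumbling(self):
        count, windows = detect_interactions(
            distance_series([2.0] * 12), ProximityProtocol()
        )
        assert count == 2
        assert len(windows) == 2

    def test_single_breach_strict_vs_lenient(self):
        d = [2.0] * 6
        d[3] = 3.2
        assert detect_interactions(distance_series(d), ProximityProtocol())[0] == 0
        lenient = ProximityProtocol(mode="lenient", lenient_fraction=5 / 6)
        assert detect_interactions(distance_series(d), lenient)[0] == 1

    def test_boundary_distance_inclusive(self):
        assert (
            detect_interactions(distance_series([3.0] * 6), ProximityProtocol())[0] == 1
        )

    def test_timestamp_gap_breaks_window(self):
        s = distance_series([2.0] * 6)
        s.loc[3:, "timestamp"] += 10.0
        assert detect_interactions(s, ProximityProtocol())[0] == 0

    def test_short_series_counts_zero(self):
        assert detect_interactions(distance_series([1.0] * 3), ProximityProtocol())[0] == 0

    @pytest.mark.parametrize("windowing", ["tumbling", "sliding"])
    @pytest.mark.parametrize("mode,f", [("strict", 1.0), ("lenient", 0.5), ("lenient", 5 / 6)])
    def test_matches_oracle_on_random_series(self, windowing, mode, f):
        rng = np.random.default_rng(hash((windowing, mode, f)) % 2**31)
        proto = ProximityProtocol(mode=mode, lenient_fraction=f, windowing=windowing)
        for _ in range(100):
            n = int(rng.integers(1, 120))
            d = rng.uniform(0, 6, n)
            t = np.arange(n) * 10.0
            # knock random holes in the clock
            holes = rng.random(n) < 0.1
            t = t + np.cumsum(holes) * 10.0
            s = pd.DataFrame({"timestamp": t, "distance": d})
            assert detect_interactions(s, proto)[0] == oracle_count(t, d, proto)

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_strict_equals_lenient_f1(self, data):
        d = data.draw(st.lists(st.floats(0, 8), min_size=1, max_size=60))
        windowing = data.draw(st.sampled_from(["tumbling", "sliding"]))
        s = distance_series(d)
        strict = ProximityProtocol(windowing=windowing)
        lenient = ProximityProtocol(mode="lenient", lenient_fraction=1.0, windowing=windowing)
        assert detect_interactions(s, strict)[0] == detect_interactions(s, lenient)[0]

    def test_counts_monotone_in_radius(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.uniform(0, 7, 150)
            s = distance_series(d)
            for windowing in ("tumbling", "sliding"):
                counts = [
                    detect_interactions(
                        s, ProximityProtocol(r=r, windowing=windowing)
                    )[0]
                    for r in (1.0, 2.0, 3.0, 4.0, 5.0)
                ]
                assert counts == sorted(counts)

    def test_sliding_counts_monotone_in_duration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            d = rng.uniform(0, 5, 150)
            s = distance_series(d)
            counts = [
                detect_interactions(
                    s, ProximityProtocol(t=t, windowing="sliding")
                )[0]
                for t in (40.0, 60.0, 80.0, 100.0)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_window_points_derived_from_duration(self):
        assert ProximityProtocol().window_points == 6
        assert ProximityProtocol(t=40).window_points == 4
        assert ProximityProtocol(t=100).window_points == 10


class TestDailyMatrix:
    def test_co_stationed_pair_counts_contact_time(self, geometry):
        # 2 cows 1 m apart for 10 min -> 60 samples -> 10 tumbling windows
        a = make_track(np.full(60, 10.0), np.full(60, 5.0), animal_id="a")
        b = make_track(np.full(60, 11.0), np.full(60, 5.0), animal_id="b")
        pos = pd.concat([a, b], ignore_index=True)
        m = daily_interaction_matrix(pos, geometry, "full_barn", ProximityProtocol(), 0)
        assert m.loc["a", "b"] == 10

    def test_distant_pair_zero_matrix(self, geometry):
        a = make_track(np.full(60, 2.0), np.full(60, 5.0), animal_id="a")
        b = make_track(np.full(60, 50.0), np.full(60, 15.0), animal_id="b")
        pos = pd.concat([a, b], ignore_index=True)
        m = daily_interaction_matrix(pos, geometry, "full_barn", ProximityProtocol(), 0)
        assert np.nansum(m.to_numpy()) == 0

    def test_symmetry_and_nan_diagonal(self, geometry, noisy_herd):
        _, _, noisy, _ = noisy_herd
        m = daily_interaction_matrix(noisy, geometry, "full_barn", ProximityProtocol(), 0)
        v = m.to_numpy()
        assert np.allclose(v, v.T, equal_nan=True)
        assert np.isnan(np.diag(v)).all()

    def test_matches_per_dyad_align_and_detect(self, geometry, noisy_herd):
        """The gridded fast path equals align_dyad + detect_interactions."""
        _, _, noisy, _ = noisy_herd
        proto = ProximityProtocol()
        zoned = zone_filter(noisy, geometry, "non_feeding")
        m = daily_interaction_matrix(noisy, geometry, "non_feeding", proto, 0)
        ids = list(m.index)
        for a, b in [(0, 1), (2, 5), (3, 7), (4, 6)]:
            ta = zoned[zoned["animal_id"] == ids[a]]
            tb = zoned[zoned["animal_id"] == ids[b]]
            series = align_dyad(ta, tb)
            count, _ = detect_interactions(series, proto)
            assert m.loc[ids[a], ids[b]] == count

    def test_zone_counts_bounded_by_full_barn_sliding(self, geometry, noisy_herd):
        # with zero zone buffer and sliding windows, zone windows nest
        _, _, noisy, _ = noisy_herd
        proto = ProximityProtocol(windowing="sliding")
        g0 = BarnGeometry(zone_buffer=0.0)
        full = daily_interaction_matrix(noisy, g0, "full_barn", proto, 0)
        for zone in ("feeding", "non_feeding"):
            mz = daily_interaction_matrix(noisy, g0, zone, proto, 0)
            assert (
                np.nan_to_num(mz.to_numpy()) <= np.nan_to_num(full.to_numpy()) + 1e-9
            ).all()


class TestSensitivity:
    def _truth(self, n):
        return pd.DataFrame(
            {
                "id_a": ["a"] * n,
                "id_b": ["b"] * n,
                "day_index": 0,
                "start": np.arange(n) * 1000.0,
                "end": np.arange(n) * 1000.0 + 200.0,
            }
        )

    def test_all_overlapped_is_one(self):
        truth = self._truth(35)
        det = truth.rename(columns={})  # identical windows overlap themselves
        assert validate_sensitivity(det, truth) == 1.0

    def test_none_overlapped_is_zero(self):
        truth = self._truth(35)
        det = truth.assign(start=truth["start"] + 500.0, end=truth["end"] + 500.0)
        assert validate_sensitivity(det, truth) == 0.0

    def test_29_of_35_rounds_to_083(self):
        truth = self._truth(35)
        det = truth.iloc[:29]
        sens = validate_sensitivity(det, truth)
        assert sens == pytest.approx(29 / 35)
        assert round(sens, 2) == 0.83

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            validate_sensitivity(self._truth(3), self._truth(0))

    def test_planted_contacts_fully_detected_on_noisefree_data(self):
        from herdnet.experiments import planted_contact_sensitivity

        assert planted_contact_sensitivity(n_cows=8, seed=1) == 1.0
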