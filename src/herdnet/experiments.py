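"""Simulation studies of the inference layer: calibration and power.

These harnesses isolate the statistical pipeline (detection -> matrices ->
permutation tests) from the cleaning stages: herds are simulated with
sensor noise but without stuck/out-of-barn artifacts, and detection runs
directly on the noisy positions.  Cleaning has its own test suite; here
the question is whether the tests reject at their nominal rate under the
null and recover planted structure under the alternative.

Power-study effect sizes were fixed once by pilot simulation so the
planted assortment yields a median empirical Mantel R_s of roughly +0.3
against the attribute-difference matrix (the orientation the one-sided
test detects); they are study conditions, not tuning knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import permstats
from .geometry import BarnGeometry
from .preprocess import smooth_trajectory
from .proximity import ProximityProtocol, daily_interaction_matrix
from .synthdata import SimConfig, inject_artifacts, simulate_herd

#: power-study conditions, fixed once by pilot simulation (see module docstring)
POWER_ASSORTMENT_EFFECT = -6.0
POWER_AFFINITY_SPREAD = 0.1
POWER_SOCIAL_PROB = 0.7
POWER_ASSORT_ATTR = "days_in_milk"
#: dyadic preference dispersion used for the differentiation-recovery study
ENRICHMENT_AFFINITY_SPREAD = 1.2


def _herd_matrices(
    config: SimConfig,
    geometry: BarnGeometry,
    protocol: ProximityProtocol,
    smooth: bool = True,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate one herd and return per-day full-barn matrices, attributes, affinity.

    ``smooth`` applies the moving-average stage before detection (the
    normal pipeline path); the differentiation-recovery study turns it
    off to work in the sparse-count regime where per-dyad flags are
    informative.
    """
    clean, truth = simulate_herd(config, geometry, include_truth=False)
    noisy, _ = inject_artifacts(clean, config, geometry)
    if smooth:
        noisy, _ = smooth_trajectory(noisy, sample_interval=config.sample_interval)
    roster = sorted(noisy["animal_id"].unique())
    mats = [
        daily_interaction_matrix(noisy, geometry, "full_barn", protocol, day, roster)
        for day in range(config.n_days)
    ]
    return mats, truth.attributes, truth.affinity_matrix


def _base_config(n_cows: int, n_days: int, seed: int, **overrides) -> SimConfig:
    return SimConfig(
        n_cows=n_cows,
        n_days=n_days,
        stuck_rate=0.0,
        outlier_rate=0.0,
        seed=seed,
        **overrides,
    )


def type1_calibration(
    n_herds: int = 200,
    n_cows: int = 20,
    n_days: int = 2,
    q: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Null rejection rates of the Mantel assortment test and permuted Wilcoxon.

    Herds carry no planted structure (affinity_spread = 0,
    assortment_effect = 0); attributes are independent of movement, and a
    balanced random binary label drives the Wilcoxon.  Both rates should
    sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    geometry = BarnGeometry()
    protocol = ProximityProtocol()
    mantel_rej = wilcox_rej = 0
    for h in range(n_herds):
        cfg = _base_config(
            n_cows,
            n_days,
            seed=int(rng.integers(2**31)),
            affinity_spread=0.0,
            assortment_effect=0.0,
        )
        mats, attributes, _ = _herd_matrices(cfg, geometry, protocol)
        total = sum(np.nan_to_num(m.to_numpy(dtype=float)) for m in mats)
        total_df = pd.DataFrame(total, index=mats[0].index, columns=mats[0].columns)
        dmat = permstats.attribute_difference_matrix(attributes, "parity")
        res = permstats.assortment_test(
            total_df, dmat, q=q, seed=int(rng.integers(2**31))
        )
        if res.p < alpha:
            mantel_rej += 1
        # balanced random two-group label, independent of everything
        labels = np.array(["a"] * (n_cows // 2) + ["b"] * (n_cows - n_cows // 2))
        rng.shuffle(labels)
        per_cow = np.nan_to_num(total).sum(axis=1) / n_days
        w = permstats.group_statistic_tests(
            per_cow, "wilcoxon", q=q, seed=int(rng.integers(2**31)), labels=labels
        )
        if w.p < alpha:
            wilcox_rej += 1
    return {
        "n_herds": n_herds,
        "mantel_rejection_rate": mantel_rej / n_herds,
        "wilcoxon_rejection_rate": wilcox_rej / n_herds,
        "alpha": alpha,
    }


def assortment_power(
    n_herds: int = 100,
    n_cows: int = 20,
    n_days: int = 2,
    q: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    effect: float = POWER_ASSORTMENT_EFFECT,
    spread: float = POWER_AFFINITY_SPREAD,
    social_prob: float = POWER_SOCIAL_PROB,
    attr_field: str = POWER_ASSORT_ATTR,
) -> dict:
    """Recovery of planted attribute-linked preference by the Mantel battery.

    Per herd, per-day assortment tests are Bonferroni-corrected over days;
    a herd counts as rejected when any adjusted p < alpha.  Also reports
    the median per-day empirical R_s.
    """
    rng = np.random.default_rng(seed)
    geometry = BarnGeometry()
    protocol = ProximityProtocol()
    rejected = 0
    r_values: list[float] = []
    for h in range(n_herds):
        cfg = _base_config(
            n_cows,
            n_days,
            seed=int(rng.integers(2**31)),
            affinity_spread=spread,
            assortment_effect=effect,
            social_prob=social_prob,
            assort_attr=attr_field,
        )
        mats, attributes, _ = _herd_matrices(cfg, geometry, protocol)
        dmat = permstats.attribute_difference_matrix(attributes, attr_field)
        adj_ps = []
        for m in mats:
            try:
                res = permstats.assortment_test(
                    m, dmat, q=q, seed=int(rng.integers(2**31))
                )
            except ValueError:  # degenerate attribute draw
                continue
            r_values.append(res.r_s)
            adj_ps.append(permstats.bonferroni(res.p, n_days))
        if adj_ps and min(adj_ps) < alpha:
            rejected += 1
    return {
        "n_herds": n_herds,
        "rejection_rate": rejected / n_herds,
        "median_r_s": float(np.median(r_values)),
        "alpha": alpha,
    }


def differentiation_enrichment(
    n_herds: int = 100,
    n_cows: int = 20,
    n_days: int = 1,
    q: int = 1000,
    seed: int = 0,
    spread: float = ENRICHMENT_AFFINITY_SPREAD,
    top_fraction: float = 0.1,
) -> dict:
    """Do differentiation flags land on the planted high-affinity dyads?

    Enrichment = P(flagged | top-decile affinity) / P(flagged overall),
    averaged over herds; values near 1 mean the flags are noise, >> 1 that
    they recover the planted preference structure.
    """
    rng = np.random.default_rng(seed)
    geometry = BarnGeometry()
    protocol = ProximityProtocol()
    enrichments: list[float] = []
    flagged_fracs: list[float] = []
    for h in range(n_herds):
        cfg = _base_config(
            n_cows,
            n_days,
            seed=int(rng.integers(2**31)),
            affinity_spread=spread,
            assortment_effect=0.0,
        )
        mats, _, affinity = _herd_matrices(cfg, geometry, protocol, smooth=False)
        diff = permstats.social_differentiation(
            mats[0], q=q, seed=int(rng.integers(2**31))
        )
        n = affinity.shape[0]
        iu = np.triu_indices(n, 1)
        aff = affinity.to_numpy()[iu]
        flags = diff.differentiated
        overall = flags.mean()
        if overall == 0:
            continue
        k = max(1, int(round(top_fraction * aff.size)))
        top = np.argsort(aff)[-k:]
        enrichments.append(flags[top].mean() / overall)
        flagged_fracs.append(float(overall))
    return {
        "n_herds": n_herds,
        "mean_enrichment": float(np.mean(enrichments)),
        "mean_flagged_fraction": float(np.mean(flagged_fracs)),
    }


def planted_contact_sensitivity(
    n_cows: int = 10,
    n_days: int = 1,
    seed: int = 0,
    margin: float = 0.5,
    min_duration: float | None = None,
) -> float:
    """Detector sensitivity against planted contacts on noise-free data.

    Truth intervals are recomputed at radius r - margin and restricted to
    length >= the protocol duration, so every interval admits at least one
    qualifying window; on noise-free data sensitivity should be 1.
    """
    protocol = ProximityProtocol()
    geometry = BarnGeometry()
    cfg = SimConfig(
        n_cows=n_cows,
        n_days=n_days,
        noise_cep50=0.0,
        stuck_rate=0.0,
        outlier_rate=0.0,
        contact_radius=protocol.r - margin,
        seed=seed,
    )
    positions, truth = simulate_herd(cfg, geometry, include_truth=True)
    t_min = min_duration if min_duration is not None else protocol.t
    iv = truth.true_contact_intervals
    iv = iv[(iv["end"] - iv["start"]) >= t_min - 1e-9]
    if len(iv) == 0:
        raise ValueError("no truth intervals long enough; enlarge the herd")
    roster = sorted(positions["animal_id"].unique())
    from .proximity import validate_sensitivity

    windows = []
    for day in range(n_days):
        _, w = daily_interaction_matrix(
            positions, geometry, "full_barn", protocol, day, roster, return_windows=True
        )
        windows.append(w)
    det = pd.concat(windows, ignore_index=True)
    return validate_sensitivity(det, iv)
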