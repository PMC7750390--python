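"""End-to-end orchestration: simulate -> clean -> detect -> networks -> stats.

A single :class:`RunConfig` drives every stage; each stochastic stage's
seed derives deterministically from the master seed, and all handoffs are
delimited-text files so any stage can be rerun in isolation from the
manifest.  Reruns with the same config produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, netmetrics, permstats
from .geometry import ZONES, BarnGeometry
from .preprocess import CleaningParams, clean_pipeline
from .proximity import ProximityProtocol, daily_interaction_matrix
from .synthdata import SimConfig, inject_artifacts, simulate_herd

log = logging.getLogger("herdnet")


@dataclass(frozen=True)
class RunConfig:
    sim: SimConfig = field(default_factory=lambda: SimConfig(n_cows=30, n_days=3))
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    protocol: ProximityProtocol = field(default_factory=ProximityProtocol)
    zones: tuple[str, ...] = ZONES
    q: int = 1000
    block_days: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        for z in self.zones:
            if z not in ZONES:
                raise ValueError(f"unknown zone {z!r}")

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["milking_windows"] = [list(w) for w in self.sim.milking_windows]
        d["zones"] = list(self.zones)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.get("sim", {}))
        if "milking_windows" in sim:
            sim["milking_windows"] = tuple(tuple(w) for w in sim["milking_windows"])
        kwargs = {
            "sim": SimConfig(**sim),
            "cleaning": CleaningParams(**d.get("cleaning", {})),
            "protocol": ProximityProtocol(**d.get("protocol", {})),
            "zones": tuple(d.get("zones", ZONES)),
        }
        for k in ("q", "block_days", "seed"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _matrix_path(outdir: Path, day: int, zone: str) -> Path:
    return outdir / "matrices" / f"day{day:02d}_{zone}.csv"


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage, writing artifacts under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "matrices").mkdir(exist_ok=True)
    geometry = BarnGeometry()
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in ("simulate", "stats")},
        "artifacts": [],
    }

    def _art(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(outdir)))

    # --- simulate -----------------------------------------------------
    sim = replace(config.sim, seed=config.stage_seed("simulate"))
    log.info("simulate: %d cows, %d days", sim.n_cows, sim.n_days)
    clean_positions, truth = simulate_herd(sim, geometry, include_truth=False)
    observed, artifact_log = inject_artifacts(clean_positions, sim, geometry)
    io.write_positions(observed, outdir / "positions_raw.csv")
    _art(outdir / "positions_raw.csv")
    io.write_attributes(truth.attributes, outdir / "attributes.csv")
    _art(outdir / "attributes.csv")
    io.write_matrix(truth.affinity_matrix, outdir / "affinity.csv")
    _art(outdir / "affinity.csv")

    # --- clean --------------------------------------------------------
    result = clean_pipeline(observed, geometry, config.cleaning, sim.sample_interval)
    for stage, frac in result.stage_removed_fraction.items():
        log.info(
            "clean: %s removed_count=%d removed_fraction=%.4f",
            stage,
            result.stage_removed_count[stage],
            frac,
        )
    io.write_positions(result.cleaned, outdir / "positions_clean.csv")
    _art(outdir / "positions_clean.csv")
    clean_log = pd.DataFrame(
        {
            "stage": list(result.stage_removed_fraction),
            "removed_count": [
                result.stage_removed_count[s] for s in result.stage_removed_fraction
            ],
            "removed_fraction": [
                result.stage_removed_fraction[s] for s in result.stage_removed_fraction
            ],
        }
    )
    clean_log.to_csv(outdir / "cleaning_log.csv", index=False, float_format="%.6f")
    _art(outdir / "cleaning_log.csv")

    # --- detect -------------------------------------------------------
    roster = sorted(observed["animal_id"].unique())
    matrices: dict[str, list[pd.DataFrame]] = {z: [] for z in config.zones}
    for day in range(sim.n_days):
        for zone in config.zones:
            m = daily_interaction_matrix(
                result.cleaned, geometry, zone, config.protocol, day, roster
            )
            matrices[zone].append(m)
            p = _matrix_path(outdir, day, zone)
            io.write_matrix(m, p)
            _art(p)
    manifest["n_matrices"] = sim.n_days * len(config.zones)

    # --- networks -----------------------------------------------------
    rows = []
    node_rows = []
    for zone in config.zones:
        for day, m in enumerate(matrices[zone]):
            meas = netmetrics.network_measures(m)
            rows.append({"day_index": day, "zone": zone, **meas})
            node = netmetrics.degree_and_clustering(m)
            node.insert(0, "zone", zone)
            node.insert(0, "day_index", day)
            node_rows.append(node)
    pd.DataFrame(rows).to_csv(outdir / "network_measures.csv", index=False, float_format="%.6f")
    _art(outdir / "network_measures.csv")
    pd.concat(node_rows, ignore_index=True).to_csv(
        outdir / "node_measures.csv", index=False, float_format="%.6f"
    )
    _art(outdir / "node_measures.csv")

    # --- stats --------------------------------------------------------
    report = run_stats_battery(
        matrices, truth.attributes, config, seed=config.stage_seed("stats")
    )
    report.to_csv(outdir / "stats_report.csv", index=False, float_format="%.6g")
    _art(outdir / "stats_report.csv")
    summary = {
        zone: {
            "mean_edge_density": float(
                np.mean([netmetrics.edge_density(m) for m in matrices[zone]])
            ),
            "component_counts": [
                len(netmetrics.components(m)) for m in matrices[zone]
            ],
        }
        for zone in config.zones
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _art(outdir / "summary.json")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _daily_totals(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-cow daily interaction totals (cows x days) from daily matrices."""
    cols = {}
    for day, m in enumerate(matrices):
        v = np.nan_to_num(m.to_numpy(dtype=float))
        cols[day] = pd.Series(v.sum(axis=1), index=m.index)
    return pd.DataFrame(cols)


def run_stats_battery(
    matrices: dict[str, list[pd.DataFrame]],
    attributes: pd.DataFrame,
    config: RunConfig,
    seed: int,
) -> pd.DataFrame:
    """The inference battery mirroring the study's result table."""
    rng = np.random.default_rng(seed)
    rows = []
    n_days = len(next(iter(matrices.values())))

    def _row(test, zone, day, stat, p_raw, m_comp, p_adj):
        rows.append(
            {
                "test": test,
                "zone": zone,
                "day_or_block": day,
                "statistic": stat,
                "p_raw": p_raw,
                "m": m_comp,
                "p_adjusted": p_adj,
                "q": config.q,
                "seed": seed,
            }
        )

    for zone, mats in matrices.items():
        totals = _daily_totals(mats)

        if n_days >= 2:
            for design in ("interindividual_kw", "betweenday_kw"):
                res = permstats.group_statistic_tests(
                    totals, design, q=config.q, seed=int(rng.integers(2**31))
                )
                _row(design, zone, "all", res.t_o, res.p, 1, permstats.bonferroni(res.p, 1))

        for day, m in enumerate(mats):
            try:
                diff = permstats.social_differentiation(
                    m, q=config.q, seed=int(rng.integers(2**31))
                )
            except ValueError:
                continue
            _row(
                "social_differentiation",
                zone,
                day,
                diff.S,
                diff.p,
                n_days,
                permstats.bonferroni(diff.p, n_days),
            )

        if n_days >= 2 * config.block_days:
            results = permstats.temporal_block_comparison(
                mats, config.block_days, q=config.q, seed=int(rng.integers(2**31))
            )
            for i, res in enumerate(results):
                _row(
                    "temporal_mantel",
                    zone,
                    f"block{i}-{i + 1}",
                    res.r_s,
                    res.p,
                    len(results),
                    res.p_adjusted,
                )

        for attr in ("parity", "days_in_milk", "lameness"):
            try:
                dmat = permstats.attribute_difference_matrix(attributes, attr)
            except ValueError:
                continue
            for day, m in enumerate(mats):
                try:
                    res = permstats.assortment_test(
                        m, dmat, q=config.q, seed=int(rng.integers(2**31))
                    )
                except ValueError:
                    continue
                _row(
                    f"assortment_{attr}",
                    zone,
                    day,
                    res.r_s,
                    res.p,
                    n_days,
                    permstats.bonferroni(res.p, n_days),
                )

        cls = attributes.set_index("animal_id")["lameness_class"]
        classified = cls[cls.isin(["lame", "non_lame"])]
        if classified.nunique() == 2 and classified.value_counts().min() >= 2:
            ids = [a for a in totals.index if a in classified.index]
            labels = classified.loc[ids].to_numpy()
            mean_daily = totals.loc[ids].mean(axis=1).to_numpy()
            per_day_node = [
                netmetrics.degree_and_clustering(m).set_index("animal_id")
                for m in mats
            ]
            mean_degree = np.mean(
                [nd.loc[ids, "degree"].to_numpy() for nd in per_day_node], axis=0
            )
            mean_clust = np.mean(
                [nd.loc[ids, "clustering"].to_numpy() for nd in per_day_node], axis=0
            )
            for name, vec in (
                ("wilcoxon_mean_daily_interactions", mean_daily),
                ("wilcoxon_mean_degree", mean_degree),
                ("wilcoxon_mean_clustering", mean_clust),
            ):
                if np.ptp(vec) == 0:
                    continue
                res = permstats.group_statistic_tests(
                    vec,
                    "wilcoxon",
                    q=config.q,
                    seed=int(rng.integers(2**31)),
                    labels=labels,
                )
                w = permstats.wilcoxon_w(vec, labels, "non_lame")
                _row(name, zone, "all", w, res.p, 3, permstats.bonferroni(res.p, 3))

    return pd.DataFrame(rows)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
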