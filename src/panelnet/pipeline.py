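"""End-to-end pipeline: configuration, staged execution and artifact manifest.

``run_pipeline`` chains preprocessing -> contemporaneous network estimation
-> communities -> centrality -> two-wave comparison -> cross-lagged panel
network -> stability on a two-wave panel (either simulated from the bundled
generator or loaded from a wide CSV), writing every artifact plus a manifest
with SHA-256 checksums into a run directory.  All randomness derives from a
single global seed through fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import centrality as centrality_mod
from . import communities as communities_mod
from . import comparison as comparison_mod
from . import crosslagged as crosslagged_mod
from . import preprocessing as preprocessing_mod
from . import stability as stability_mod
from .datasets import TwoWavePanel
from .estimation import EstimatorConfig, estimate_network
from .synthetic import SyntheticConfig, generate_truth, simulate_panel

logger = logging.getLogger(__name__)

#: documented per-stage seed offsets (stage seed = global seed + offset)
STAGE_SEED_OFFSETS = {
    "simulate": 1,
    "estimate_t1": 2,
    "estimate_t2": 3,
    "communities": 4,
    "compare": 5,
    "clpn": 6,
    "stability": 7,
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Fully resolved pipeline settings (defaults follow the study design)."""

    output_dir: str = "panelnet_run"
    input_csv: str | None = None  # wide CSV with _T1/_T2 columns; None = simulate
    seed: int = 42
    n_participants: int = 2000
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    cpm_k: int = 4
    cpm_intensity: float = 0.08
    spinglass_n_spins: int = 500
    spinglass_gamma: float = 1.0
    nct_n_perm: int = 1000
    clpn_n_lambda: int = 100
    clpn_cv_folds: int = 10
    stability_n_boot: int = 50
    goldbricker_alpha: float = 0.01
    goldbricker_threshold: float = 0.25
    goldbricker_cor_min: float = 0.50
    run_preprocessing: bool = True
    run_estimate: bool = True
    run_communities: bool = True
    run_centrality: bool = True
    run_nct: bool = True
    run_clpn: bool = True
    run_stability: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            syn = dict(d["synthetic"])
            for key in ("bridge_edges", "cross_lagged"):
                if key in syn:
                    syn[key] = [tuple(e) for e in syn[key]]
            if "community_sizes" in syn:
                syn["community_sizes"] = tuple(syn["community_sizes"])
            d["synthetic"] = SyntheticConfig(**syn)
        if "estimator" in d and isinstance(d["estimator"], dict):
            d["estimator"] = EstimatorConfig(**d["estimator"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls.from_dict(data or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path):
        self.run_dir = run_dir
        self.entries: list[dict] = []

    def add(self, stage: str, path: Path) -> None:
        self.entries.append(
            {
                "stage": stage,
                "path": str(path.relative_to(self.run_dir)),
                "sha256": _sha256(path),
            }
        )

    def write(self, status: str = "complete") -> None:
        payload = {"status": status, "artifacts": self.entries}
        (self.run_dir / "manifest.json").write_text(json.dumps(payload, indent=1))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory.

    A stage failure aborts the run with :class:`PipelineStageError` after
    persisting the partial manifest.
    """
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir)
    seed = config.seed

    cfg_path = run_dir / "config.json"
    cfg_path.write_text(json.dumps(config.to_dict(), indent=1, default=str))
    manifest.add("config", cfg_path)

    stage = "load"
    try:
        t0 = time.perf_counter()
        if config.input_csv is not None:
            stage = "load"
            panel = TwoWavePanel.from_csv(config.input_csv)
            truth = None
        else:
            stage = "simulate"
            syn = dataclasses.replace(config.synthetic, seed=seed)
            truth = generate_truth(syn)
            panel = simulate_panel(
                truth,
                n=config.n_participants,
                seed=seed + STAGE_SEED_OFFSETS["simulate"],
            )
            panel_path = run_dir / "panel.csv"
            panel.to_csv(panel_path)
            manifest.add(stage, panel_path)
            truth_path = run_dir / "truth.json"
            truth.to_json(truth_path)
            manifest.add(stage, truth_path)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "preprocessing"
        t0 = time.perf_counter()
        for wave, data in (
            (("T1", panel.t1), ("T2", panel.t2)) if config.run_preprocessing else ()
        ):
            desc = preprocessing_mod.compute_descriptives(data)
            path = run_dir / f"descriptives_{wave}.csv"
            desc.to_csv(path)
            manifest.add(stage, path)
            gb = preprocessing_mod.goldbricker(
                data,
                alpha=config.goldbricker_alpha,
                prop_threshold=config.goldbricker_threshold,
                cor_min=config.goldbricker_cor_min,
            )
            path = run_dir / f"goldbricker_{wave}.csv"
            gb.to_csv(path, index=False)
            manifest.add(stage, path)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "estimate"
        t0 = time.perf_counter()
        networks = {}
        scores = {}
        needs_networks = (
            config.run_estimate
            or config.run_communities
            or config.run_centrality
            or config.run_nct
        )
        for wave, data, off in (() if not needs_networks else (
            ("T1", panel.t1, STAGE_SEED_OFFSETS["estimate_t1"]),
            ("T2", panel.t2, STAGE_SEED_OFFSETS["estimate_t2"]),
        )):
            est = dataclasses.replace(config.estimator, seed=seed + off)
            scores[wave] = preprocessing_mod.nonparanormal_transform(data)
            net = estimate_network(scores[wave], est)
            networks[wave] = net
            for suffix, writer in (
                ("adjacency.csv", net.to_adjacency_csv),
                ("edges.csv", net.to_edge_csv),
                ("network.graphml", net.to_graphml),
            ):
                path = run_dir / f"{wave}_{suffix}"
                writer(path)
                manifest.add(stage, path)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "communities"
        t0 = time.perf_counter()
        partitions = {}
        needs_partitions = config.run_communities or config.run_centrality
        for wave, net in (networks.items() if needs_partitions else ()):
            part = communities_mod.spinglass_partition(
                net,
                n_spins=config.spinglass_n_spins,
                gamma=config.spinglass_gamma,
                seed=seed + STAGE_SEED_OFFSETS["communities"],
            )
            partitions[wave] = part
            overlap = communities_mod.clique_percolation(
                net, k=config.cpm_k, intensity=config.cpm_intensity
            )
            path = run_dir / f"{wave}_communities.json"
            path.write_text(
                json.dumps(
                    {
                        "spinglass": part.membership,
                        "spinglass_hamiltonian": part.hamiltonian,
                        "clique_percolation": overlap.to_json_payload(),
                    },
                    indent=1,
                )
            )
            manifest.add(stage, path)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "centrality"
        t0 = time.perf_counter()
        for wave, net in (networks.items() if config.run_centrality else ()):
            table = centrality_mod.centrality_table(
                net, partitions[wave], scores[wave]
            )
            path = run_dir / f"{wave}_centrality.csv"
            table.to_csv(path)
            manifest.add(stage, path)
        logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        if config.run_nct:
            stage = "compare"
            t0 = time.perf_counter()
            nct = comparison_mod.network_structure_test(
                panel.t1,
                panel.t2,
                n_perm=config.nct_n_perm,
                seed=seed + STAGE_SEED_OFFSETS["compare"],
                config=config.estimator,
            )
            sim = comparison_mod.adjacency_correlation(
                networks["T1"], networks["T2"]
            )
            path = run_dir / "nct.json"
            path.write_text(
                json.dumps(
                    {**nct.to_json_payload(), "similarity": sim.to_json_payload()},
                    indent=1,
                )
            )
            manifest.add(stage, path)
            path = run_dir / "nct_edges.csv"
            nct.edge_table.to_csv(path, index=False)
            manifest.add(stage, path)
            logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        if config.run_clpn:
            stage = "clpn"
            t0 = time.perf_counter()
            model = crosslagged_mod.fit_clpn(
                panel,
                n_lambda=config.clpn_n_lambda,
                cv_folds=config.clpn_cv_folds,
                seed=seed + STAGE_SEED_OFFSETS["clpn"],
            )
            path = run_dir / "clpn_beta.csv"
            model.to_beta_csv(path)
            manifest.add(stage, path)
            path = run_dir / "clpn_network.graphml"
            model.to_graphml(path)
            manifest.add(stage, path)
            pred = (
                model.in_prediction.to_frame()
                .join(model.out_prediction)
                .rename_axis("item")
            )
            path = run_dir / "clpn_prediction.csv"
            pred.to_csv(path)
            manifest.add(stage, path)
            fit = crosslagged_mod.path_model_fit(panel, model)
            path = run_dir / "clpn_fit.json"
            path.write_text(json.dumps(fit.to_json_payload(), indent=1))
            manifest.add(stage, path)
            logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        if config.run_stability:
            stage = "stability"
            t0 = time.perf_counter()
            results = {}
            for statistic in ("edge", "EI1"):
                cs = stability_mod.case_dropping_cs(
                    panel.t1,
                    statistic=statistic,
                    n_boot=config.stability_n_boot,
                    seed=seed + STAGE_SEED_OFFSETS["stability"],
                    config=config.estimator,
                )
                results[statistic] = cs.to_json_payload()
            path = run_dir / "stability.json"
            path.write_text(json.dumps(results, indent=1))
            manifest.add(stage, path)
            logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except Exception as err:
        manifest.write(status=f"failed at {stage}")
        raise PipelineStageError(stage, err) from err

    manifest.write()
    return run_dir
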