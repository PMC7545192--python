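"""End-to-end orchestration: one config in, a reproducible artifact set out.

Stages run in order data_io -> scaling -> dsam -> association -> network ->
som.  Every random draw derives from the single config seed, all artifacts
are plain text (CSV / Newick / GraphML / JSON) and the run manifest records
the config, derived seeds, package version and a SHA-256 per artifact, so a
rerun with the same config reproduces every file bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .association import hierarchical_cluster, similarity_matrix, similarity_to_distance
from .data_io import compute_density_matrix, read_region_table
from .dsam import compute_dsams
from .network import build_network, detect_communities
from .scaling import fit_all_indicators
from .som import cluster_som_nodes, gap_statistic, train_som
from .synthetic import SyntheticSpec, simulate, spec_from_dict, write_truth

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a full run needs; see module docstring for stage order."""

    out_dir: str = "densiscale_run"
    input_path: str | None = None  # region-table CSV; mutually exclusive with synthetic
    synthetic: dict | None = None  # SyntheticSpec fields
    schema: dict = field(default_factory=dict)
    davies_alpha: float = 0.01
    davies_k: int = 10
    bootstrap_b: int = 2000
    bootstrap_level: float = 0.99
    network_sign: str = "positive"
    similarity: str = "pearson"
    linkage: str = "complete"
    cluster_k: int | None = None
    som_grid: tuple[int, int] = (8, 8)
    som_iterations: int = 350
    som_mode: str = "kohonen"
    som_alpha: tuple[float, float] = (0.05, 0.01)
    gap_b: int = 100
    gap_k_max: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.davies_alpha < 1:
            raise ConfigError(f"davies_alpha must be in (0,1), got {self.davies_alpha}")
        if not 0 < self.bootstrap_level < 1:
            raise ConfigError(f"bootstrap_level must be in (0,1), got {self.bootstrap_level}")
        if self.input_path is None and self.synthetic is None:
            raise ConfigError("config needs either input_path or a synthetic spec")
        self.som_grid = tuple(self.som_grid)
        self.som_alpha = tuple(self.som_alpha)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["som_grid"] = list(self.som_grid)
        d["som_alpha"] = list(self.som_alpha)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        "synthetic": config.seed,
        "network": config.seed + 1,
        "louvain": config.seed + 2,
        "som": config.seed + 3,
        "gap": config.seed + 4,
        "som_kmeans": config.seed + 5,
    }
    artifacts: list[str] = []

    def save(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts.append(name)

    # -- data ---------------------------------------------------------------
    stage = "data_io"
    try:
        if config.input_path is not None:
            table = read_region_table(config.input_path, schema=config.schema or None)
        else:
            spec_dict = dict(config.synthetic or {})
            spec_dict.setdefault("seed", seeds["synthetic"])
            spec: SyntheticSpec = spec_from_dict(spec_dict)
            table = simulate(spec)
            save("regions.csv", table.write_csv)
            save("truth.json", lambda p: write_truth(spec, p))
        dm = compute_density_matrix(table)
        save("densities.csv", dm.write_csv)

        # -- scaling + dsam --------------------------------------------------
        stage = "scaling"
        fits = fit_all_indicators(dm, alpha=config.davies_alpha, davies_k=config.davies_k)
        save("fits.csv", fits.write_csv)

        stage = "dsam"
        zm = compute_dsams(dm, fits)
        save("residuals.csv", zm.write_csv)

        # -- association -----------------------------------------------------
        stage = "association"
        sm = similarity_matrix(zm, measure=config.similarity)
        save(f"similarity_{config.similarity}.csv", sm.write_csv)
        dist = similarity_to_distance(sm)
        save("distance.csv", lambda p: dist.to_csv(p))
        tree = hierarchical_cluster(dist, method=config.linkage)
        save("dendrogram.nwk", lambda p: Path(p).write_text(tree.to_newick() + "\n"))
        if config.cluster_k:
            cut = tree.cut(config.cluster_k)
            save("indicator_clusters.csv", lambda p: cut.to_csv(p))

        # -- network ---------------------------------------------------------
        stage = "network"
        net = build_network(
            zm,
            sign=config.network_sign,
            b=config.bootstrap_b,
            level=config.bootstrap_level,
            seed=seeds["network"],
        )
        save("edges.csv", net.write_edges_csv)
        network_summary: dict = {
            "nodes": net.graph.number_of_nodes(),
            "edges": net.graph.number_of_edges(),
            "pairs_tested": net.n_pairs_tested,
        }
        if net.graph.number_of_edges() > 0:
            partition, q = detect_communities(net, seed=seeds["louvain"])
            network_summary["modularity"] = q
            network_summary["n_communities"] = len(set(partition.values()))
            save(
                "communities.csv",
                lambda p: Path(p).write_text(
                    "indicator,community\n"
                    + "".join(f"{n},{c}\n" for n, c in sorted(partition.items()))
                ),
            )
            save("network.graphml", net.write_graphml)

        # -- som -------------------------------------------------------------
        stage = "som"
        model = train_som(
            zm,
            grid=config.som_grid,
            iterations=config.som_iterations,
            alpha=config.som_alpha,
            neighborhood=config.som_mode,
            seed=seeds["som"],
        )
        gap = gap_statistic(
            model.weights, k_max=config.gap_k_max, b_ref=config.gap_b, seed=seeds["gap"]
        )
        save("gap_curve.csv", lambda p: gap.to_frame().to_csv(p, index=False))
        clusters = cluster_som_nodes(model, gap=gap, zm=zm, seed=seeds["som_kmeans"])
        assign = clusters.region_labels.to_frame()
        assign.insert(0, "node", model.assignments)
        save("som_assignments.csv", lambda p: assign.to_csv(p))
        save("cluster_means.csv", lambda p: clusters.means.to_csv(p))
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} "
            f"(partial artifacts in {out}: {artifacts})"
        ) from exc

    manifest = {
        "package": "densiscale",
        "version": __version__,
        "config": config.to_dict(),
        # hash identifies the analysis, not where it was written
        "config_sha256": hashlib.sha256(
            json.dumps(
                {k: v for k, v in config.to_dict().items() if k != "out_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "seeds": seeds,
        "n_regions": int(table.n_regions),
        "n_indicators": len(table.indicators),
        "n_segmented": fits.n_segmented,
        "median_d_star": None if fits.n_segmented == 0 else fits.median_d_star,
        "network": network_summary,
        "som": {"k_selected": gap.k_selected, "cluster_sizes": clusters.sizes.tolist()},
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
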