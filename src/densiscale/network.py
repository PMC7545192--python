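"""Bootstrap-significant correlation networks over DSAM indicators.

For every unordered pair of indicators the Pearson correlation of their
DSAM vectors is bootstrapped (resampling regions with replacement); an edge
is drawn when the percentile confidence interval at the configured level
(default 99%) excludes zero and the correlation has the requested sign.
Edges are weighted by the point correlation.  Community structure is found
by Louvain modularity maximisation on the weighted graph (best of several
seeded restarts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dsam import DsamMatrix

logger = logging.getLogger(__name__)


@dataclass
class BootstrapEdge:
    i: str
    j: str
    rho: float
    ci_low: float
    ci_high: float
    significant: bool
    sign: str  # "positive" | "negative"
    n_pairs: int
    skipped_reps: int = 0


@dataclass
class Network:
    """Indicator graph with bootstrap-significant edges.

    Isolated indicators (no significant edge of the requested sign) are not
    nodes.  ``partition``/``modularity`` are filled by
    :func:`detect_communities`.
    """

    graph: nx.Graph
    edges: list[BootstrapEdge]
    all_pairs: list[BootstrapEdge]
    b_reps: int
    level: float
    sign: str
    partition: dict[str, int] | None = None
    modularity: float | None = None
    tested_indicators: list[str] = field(default_factory=list)

    @property
    def n_pairs_tested(self) -> int:
        return len(self.all_pairs)

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "i": e.i,
                    "j": e.j,
                    "rho": e.rho,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
                for e in self.edges
            ]
        )

    def write_edges_csv(self, path: str | Path) -> None:
        self.edge_frame().to_csv(path, index=False)

    def write_graphml(self, path: str | Path) -> None:
        g = self.graph.copy()
        if self.partition:
            nx.set_node_attributes(g, self.partition, "community")
        nx.write_graphml(g, path)


def _boot_pearson(x: np.ndarray, y: np.ndarray, b: int, rng: np.random.Generator):
    """Bootstrap distribution of Pearson's r; replicates with a constant
    resample are skipped (their count is returned)."""
    n = len(x)
    idx = rng.integers(0, n, size=(b, n))
    xs = x[idx]
    ys = y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", xs, ys)
    den = np.sqrt(np.einsum("ij,ij->i", xs, xs) * np.einsum("ij,ij->i", ys, ys))
    ok = den > 0
    return num[ok] / den[ok], int(b - ok.sum())


def bootstrap_correlation(
    x,
    y,
    b: int = 2000,
    level: float = 0.99,
    seed: int | np.random.SeedSequence = 0,
    names: tuple[str, str] = ("x", "y"),
) -> BootstrapEdge:
    """Bootstrap the Pearson correlation of two paired vectors.

    Missing cells are dropped pairwise (>= 10 complete pairs required);
    regions are resampled with replacement ``b`` times and the percentile
    interval at ``level`` decides significance (interval excluding zero).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError(f"bootstrap correlation needs >= 10 complete pairs, got {n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rho = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    boot, skipped = _boot_pearson(x, y, b, rng)
    if skipped:
        logger.debug("skipped %d constant resamples for pair %s", skipped, names)
    alpha = 1.0 - level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    significant = bool(lo > 0 or hi < 0)
    return BootstrapEdge(
        i=names[0],
        j=names[1],
        rho=rho,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=significant,
        sign="positive" if rho >= 0 else "negative",
        n_pairs=n,
        skipped_reps=skipped,
    )


def build_network(
    zm: DsamMatrix,
    sign: str = "positive",
    b: int = 2000,
    level: float = 0.99,
    seed: int = 0,
    min_pairs: int = 10,
) -> Network:
    """Test every unordered indicator pair and keep the significant edges.

    Each pair draws from its own seed stream keyed by its position in the
    sorted label order, so the edge set does not depend on column order.
    Indicators left with no significant edge of the requested sign are
    excluded from the node set.
    """
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"sign must be positive|negative|both, not {sign!r}")
    labels = sorted(zm.indicators)
    if len(labels) < 2:
        raise ValueError("need at least 2 indicators")
    z = zm.z
    all_pairs: list[BootstrapEdge] = []
    edges: list[BootstrapEdge] = []
    pair_idx = 0
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            na, nb = labels[a_i], labels[b_i]
            ss = np.random.SeedSequence([seed, pair_idx])
            pair_idx += 1
            xa = z[na].to_numpy(float)
            xb = z[nb].to_numpy(float)
            if (np.isfinite(xa) & np.isfinite(xb)).sum() < min_pairs:
                continue
            edge = bootstrap_correlation(xa, xb, b=b, level=level, seed=ss, names=(na, nb))
            all_pairs.append(edge)
            if edge.significant and (sign == "both" or edge.sign == sign):
                edges.append(edge)
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.i, e.j, weight=e.rho)
    return Network(
        graph=g,
        edges=edges,
        all_pairs=all_pairs,
        b_reps=b,
        level=level,
        sign=sign,
        tested_indicators=labels,
    )


def detect_communities(
    net: Network, seed: int = 0, restarts: int = 20, resolution: float = 1.0
) -> tuple[dict[str, int], float]:
    """Louvain modularity maximisation on the rho-weighted graph.

    Runs ``restarts`` seeded restarts and keeps the partition with the
    highest weighted modularity Q; community ids are relabelled by size
    (largest first) with lexicographic tie-break for determinism.  The
    partition and Q are stored on the network and returned.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("network has no edges; communities undefined")
    best_q, best_comms = -np.inf, None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best_comms = q, comms
    ordered = sorted(best_comms, key=lambda c: (-len(c), min(c)))
    partition = {node: cid for cid, comm in enumerate(ordered) for node in comm}
    net.partition = partition
    net.modularity = float(best_q)
    return partition, float(best_q)


def modularity_of(graph: nx.Graph, partition: dict[str, int], resolution: float = 1.0) -> float:
    """Weighted modularity Q of an arbitrary node partition."""
    k = max(partition.values()) + 1
    comms = [{n for n, c in partition.items() if c == i} for i in range(k)]
    comms = [c for c in comms if c]
    return float(nx.community.modularity(graph, comms, weight="weight", resolution=resolution))
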