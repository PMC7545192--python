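"""Self-organizing map over regional DSAM profiles, with gap-statistic
selection of the number of codebook clusters.

Regions (rows of the DSAM matrix) are mapped onto a fixed 8x8 hexagonal
lattice of nodes by competitive learning: each presented input wins the node
with the smallest Euclidean distance to its weight vector and weights are
pulled toward the input,

    w(t+1) = w(t) + alpha(t) h(t) (x(t) - w(t)),

with a learning rate alpha decaying linearly over training.  Two
neighbourhood modes are provided: ``kohonen`` (Gaussian kernel around the
winner with a linearly shrinking radius — a true topology-preserving map)
and ``winner_only`` (only the winning node moves — a plain vector
quantizer).  Inputs are min-max scaled to [0, 1] per indicator so the
uniform-[0, 1] random weight initialisation is commensurate with the data;
missing DSAM cells are imputed to 0 (the scaling-law expectation) before
scaling.

The trained codebook vectors are then clustered by k-means and the number
of clusters chosen with Tibshirani's standardized gap statistic against a
uniform reference distribution; regions inherit the cluster of their
winning node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dsam import DsamMatrix


def hex_grid(rows: int, cols: int) -> np.ndarray:
    """Coordinates of a rows x cols hexagonal lattice (odd rows offset)."""
    coords = []
    for r in range(rows):
        for c in range(cols):
            coords.append((c + 0.5 * (r % 2), r * np.sqrt(3.0) / 2.0))
    return np.asarray(coords)


@dataclass
class SomModel:
    grid_shape: tuple[int, int]
    coords: np.ndarray  # (m, 2) node positions on the lattice
    weights: np.ndarray  # (m, p) codebook, in scaled input space
    assignments: pd.Series  # region -> winning node index
    qe_history: np.ndarray  # mean quantization error per epoch
    alpha: tuple[float, float]
    radius: tuple[float, float]
    iterations: int
    neighborhood: str
    seed: int
    scale_min: np.ndarray | None  # per-indicator min/max used for scaling
    scale_max: np.ndarray | None
    columns: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def transform(self, z: pd.DataFrame) -> np.ndarray:
        """Apply the training-time imputation and min-max scaling."""
        x = z[self.columns].to_numpy(float)
        x = np.where(np.isfinite(x), x, 0.0)
        if self.scale_min is not None:
            rng = np.where(self.scale_max > self.scale_min, self.scale_max - self.scale_min, 1.0)
            x = (x - self.scale_min) / rng
        return x

    def assign(self, z: pd.DataFrame) -> pd.Series:
        x = self.transform(z)
        d2 = ((x[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return pd.Series(d2.argmin(axis=1), index=z.index, name="node")

    def quantization_error(self, z: pd.DataFrame) -> float:
        x = self.transform(z)
        d2 = ((x[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d2.min(axis=1)).mean())


class MissingCellError(ValueError):
    pass


def train_som(
    zm: DsamMatrix | pd.DataFrame,
    grid: tuple[int, int] = (8, 8),
    iterations: int = 350,
    alpha: tuple[float, float] = (0.05, 0.01),
    neighborhood: str = "kohonen",
    seed: int = 0,
    scale: bool = True,
    impute: bool = True,
) -> SomModel:
    """Train a SOM on the regions x indicators DSAM matrix.

    One *iteration* is a full epoch: every region presented once in a
    seeded shuffled order.  alpha decays linearly from ``alpha[0]`` to
    ``alpha[1]`` over all presentations; in ``kohonen`` mode the Gaussian
    neighbourhood radius decays linearly from the 2/3 quantile of
    inter-node lattice distances to 1.  ``winner_only`` updates only the
    winning node.
    """
    if neighborhood not in ("kohonen", "winner_only"):
        raise ValueError(f"unknown neighborhood mode {neighborhood!r}")
    z = zm.z if isinstance(zm, DsamMatrix) else pd.DataFrame(zm)
    x = z.to_numpy(float)
    if not np.all(np.isfinite(x)):
        if not impute:
            raise MissingCellError("DSAM matrix has missing cells and impute=False")
        x = np.where(np.isfinite(x), x, 0.0)
    n, p = x.shape
    smin = smax = None
    if scale:
        smin, smax = x.min(axis=0), x.max(axis=0)
        rngs = np.where(smax > smin, smax - smin, 1.0)
        x = (x - smin) / rngs
    rows, cols = grid
    m = rows * cols
    if m > 4 * n:
        import warnings

        warnings.warn(f"grid has {m} nodes for only {n} regions", stacklevel=2)
    coords = hex_grid(rows, cols)
    node_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    off_diag = node_d[~np.eye(m, dtype=bool)]
    r0 = float(np.quantile(off_diag, 2.0 / 3.0))
    r1 = 1.0

    rng = np.random.default_rng(seed)
    w = rng.uniform(0.0, 1.0, size=(m, p))
    a0, a1 = alpha
    total = iterations * n
    qe_history = np.empty(iterations)
    step = 0
    for epoch in range(iterations):
        order = rng.permutation(n)
        qe = 0.0
        for i in order:
            frac = step / max(total - 1, 1)
            a_t = a0 + (a1 - a0) * frac
            xi = x[i]
            diff = w - xi
            d2 = np.einsum("ij,ij->i", diff, diff)
            win = int(d2.argmin())
            qe += np.sqrt(d2[win])
            if neighborhood == "winner_only":
                w[win] -= a_t * diff[win]
            else:
                r_t = r0 + (r1 - r0) * frac
                h = np.exp(-(node_d[win] ** 2) / (2.0 * r_t * r_t))
                w -= (a_t * h)[:, None] * diff
            step += 1
        qe_history[epoch] = qe / n

    d2 = ((x[:, None, :] - w[None, :, :]) ** 2).sum(axis=2)
    assignments = pd.Series(d2.argmin(axis=1), index=z.index, name="node")
    return SomModel(
        grid_shape=grid,
        coords=coords,
        weights=w,
        assignments=assignments,
        qe_history=qe_history,
        alpha=alpha,
        radius=(r0, r1),
        iterations=iterations,
        neighborhood=neighborhood,
        seed=seed,
        scale_min=smin,
        scale_max=smax,
        columns=list(z.columns),
    )


@dataclass
class GapResult:
    k_values: np.ndarray
    gap: np.ndarray
    sk: np.ndarray
    wk: np.ndarray  # log(W_k) observed
    ewk: np.ndarray  # E*_n{log(W_k)} under the uniform reference
    b_ref: int
    k_selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "gap": self.gap,
                "sk": self.sk,
                "log_wk": self.wk,
                "ref_log_wk": self.ewk,
            }
        )


def _pooled_wk(x: np.ndarray, k: int, seed: int, n_init: int) -> float:
    """Pooled within-cluster sum of squares around cluster means."""
    if k == 1:
        mu = x.mean(axis=0)
        return float(((x - mu) ** 2).sum())
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(x)
    return float(km.inertia_)


def gap_statistic(
    vectors,
    k_max: int = 8,
    b_ref: int = 100,
    seed: int = 0,
    n_init: int = 20,
) -> GapResult:
    """Standardized gap statistic for choosing the number of clusters.

    Gap(k) = E*{log W_k} - log W_k, with the reference expectation estimated
    from ``b_ref`` uniform samples over the per-dimension range of the data
    and s_k = sd_B sqrt(1 + 1/B).  The selected k is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1} (k_max when no k satisfies the rule).
    """
    x = np.asarray(vectors, float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k_max + 1:
        raise ValueError(f"need at least k_max+1={k_max + 1} distinct points, got {n_distinct}")
    ks = np.arange(1, k_max + 1)
    log_wk = np.array([np.log(_pooled_wk(x, k, seed, n_init)) for k in ks])
    lo, hi = x.min(axis=0), x.max(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    ref = np.empty((b_ref, k_max))
    for b in range(b_ref):
        xb = rng.uniform(lo, hi, size=x.shape)
        ref[b] = [np.log(_pooled_wk(xb, k, seed, n_init)) for k in ks]
    ewk = ref.mean(axis=0)
    sd = ref.std(axis=0)  # population sd over the B reference samples
    sk = sd * np.sqrt(1.0 + 1.0 / b_ref)
    gap = ewk - log_wk
    k_selected = int(ks[-1])
    for i in range(k_max - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            k_selected = int(ks[i])
            break
    return GapResult(
        k_values=ks, gap=gap, sk=sk, wk=log_wk, ewk=ewk, b_ref=b_ref, k_selected=k_selected
    )


@dataclass
class SomClusters:
    k: int
    node_labels: np.ndarray  # node -> cluster id
    region_labels: pd.Series  # region -> cluster id
    means: pd.DataFrame  # cluster x indicator mean DSAM (unscaled)
    normalized: pd.DataFrame  # min-max normalized means for display
    sizes: pd.Series  # regions per cluster


def cluster_som_nodes(
    model: SomModel,
    gap: GapResult | None = None,
    zm: DsamMatrix | pd.DataFrame | None = None,
    k: int | None = None,
    seed: int = 0,
    n_init: int = 20,
) -> SomClusters:
    """Cluster the codebook at the gap-selected k; regions inherit node labels.

    ``zm`` (defaulting to nothing) provides the unscaled DSAMs used for the
    per-cluster mean profiles; when omitted the profiles are computed from
    the codebook weights mapped back to the unscaled space.  Cluster ids are
    ordered by size (largest first).  Empty clusters (nodes with no regions)
    are retained with size 0.
    """
    if k is None:
        if gap is None:
            raise ValueError("provide either a GapResult or an explicit k")
        k = gap.k_selected
    w = model.weights
    if k == 1:
        node_labels = np.zeros(model.n_nodes, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        node_labels = km.fit_predict(w)
    region_labels = model.assignments.map(lambda node: int(node_labels[node]))

    # relabel by region count, largest cluster first (stable tie-break on old id)
    counts = region_labels.value_counts().reindex(range(k), fill_value=0)
    order = sorted(range(k), key=lambda c: (-counts[c], c))
    remap = {old: new for new, old in enumerate(order)}
    node_labels = np.array([remap[c] for c in node_labels])
    region_labels = region_labels.map(remap).rename("cluster")
    sizes = region_labels.value_counts().reindex(range(k), fill_value=0).sort_index()

    if zm is not None:
        z = zm.z if isinstance(zm, DsamMatrix) else pd.DataFrame(zm)
        means = z.groupby(region_labels).mean().reindex(range(k))
    else:
        wdf = pd.DataFrame(w, columns=model.columns)
        if model.scale_min is not None:
            rngs = np.where(
                model.scale_max > model.scale_min, model.scale_max - model.scale_min, 1.0
            )
            wdf = wdf * rngs + model.scale_min
        means = wdf.groupby(pd.Series(node_labels)).mean().reindex(range(k))
    means.index.name = "cluster"
    span = means.max() - means.min()
    normalized = (means - means.min()) / span.where(span > 0, 1.0)
    return SomClusters(
        k=k,
        node_labels=node_labels,
        region_labels=region_labels,
        means=means,
        normalized=normalized,
        sizes=sizes,
    )
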