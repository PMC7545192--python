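import numpy as np
import pandas as pd
import pytest

from densiscale.dsam import DsamMatrix
from densiscale.som import (
    MissingCellError,
    cluster_som_nodes,
    gap_statistic,
    hex_grid,
    train_som,
)


def blob_frame(seed: int, p: int = 3, per_blob: int = 50, sd: float = 0.05):
    """Four well-separated Gaussian blobs of 'regions' in p dimensions."""
    rng0 = np.random.default_rng(7)
    centers = rng0.uniform(0, 1, (4, p))
    while min(
        np.linalg.norm(centers[i] - centers[j]) for i in range(4) for j in range(i + 1, 4)
    ) < 0.4:
        centers = rng0.uniform(0, 1, (4, p))
    rng = np.random.default_rng(seed)
    x = np.vstack([c + rng.normal(0, sd, (per_blob, p)) for c in centers])
    labels = np.repeat(np.arange(4), per_blob)
    z = pd.DataFrame(x, index=[f"r{i}" for i in range(len(x))])
    z.columns = [f"ind{j}" for j in range(p)]
    return z, labels


class TestTrainSom:
    def test_winner_only_fixed_point(self):
        # a single repeated input pulls the winning node's weight onto it
        x = pd.DataFrame(np.tile([0.3, 0.7, 0.2], (5, 1)))
        model = train_som(
            x, grid=(3, 3), iterations=100, alpha=(0.5, 0.5),
            neighborhood="winner_only", seed=0, scale=False,
        )
        win = model.assignments.iloc[0]
        assert np.abs(model.weights[win] - [0.3, 0.7, 0.2]).max() < 1e-6

    def test_zero_learning_rate_leaves_weights_unchanged(self, rng):
        z = pd.DataFrame(rng.uniform(0, 1, (20, 3)))
        model = train_som(z, grid=(3, 3), iterations=5, alpha=(0.0, 0.0), seed=4, scale=False)
        init = np.random.default_rng(4).uniform(0, 1, (9, 3))
        np.testing.assert_allclose(model.weights, init)

    def test_seeded_determinism(self, rng):
        z = pd.DataFrame(rng.normal(size=(40, 4)))
        m1 = train_som(z, grid=(4, 4), iterations=20, seed=3)
        m2 = train_som(z, grid=(4, 4), iterations=20, seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_quantization_error_improves_over_training(self, rng):
        z = pd.DataFrame(rng.normal(size=(100, 5)))
        model = train_som(z, grid=(5, 5), iterations=30, seed=1)
        assert model.qe_history[-1] <= model.qe_history[0]

    def test_scaling_equivariance(self, rng):
        # training on pre-scaled data with scale=False matches scale=True
        z = pd.DataFrame(rng.normal(2.0, 3.0, size=(50, 4)))
        scaled = (z - z.min()) / (z.max() - z.min())
        m1 = train_som(z, grid=(4, 4), iterations=15, seed=8, scale=True)
        m2 = train_som(scaled, grid=(4, 4), iterations=15, seed=8, scale=False)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-12)

    def test_missing_cells_require_imputation(self):
        z = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]] * 5)
        with pytest.raises(MissingCellError):
            train_som(z, grid=(2, 2), iterations=2, impute=False)
        train_som(z, grid=(2, 2), iterations=2, impute=True)  # imputes to 0

    def test_blobs_map_to_disjoint_node_sets(self):
        hits = 0
        for seed in range(10):
            z, labels = blob_frame(1000 + seed, p=6)
            model = train_som(z, grid=(8, 8), iterations=50, seed=seed)
            nodesets = [set(model.assignments[labels == b]) for b in range(4)]
            disjoint = all(
                not (nodesets[i] & nodesets[j]) for i in range(4) for j in range(i + 1, 4)
            )
            hits += disjoint
        assert hits >= 9

    def test_hex_grid_geometry(self):
        coords = hex_grid(8, 8)
        assert coords.shape == (64, 2)
        d = np.linalg.norm(coords[1] - coords[0])
        assert d == pytest.approx(1.0)
        # odd rows offset by half a unit
        assert coords[8, 0] == pytest.approx(0.5)


class TestGapStatistic:
    def test_w1_is_total_sum_of_squares(self, rng):
        x = rng.normal(size=(30, 3))
        g = gap_statistic(x, k_max=3, b_ref=10, seed=0)
        tss = ((x - x.mean(axis=0)) ** 2).sum()
        assert g.wk[0] == pytest.approx(np.log(tss))

    def test_kmax_too_small(self, rng):
        with pytest.raises(ValueError):
            gap_statistic(rng.normal(size=(30, 2)), k_max=1)

    def test_selection_rule_is_first_standardized_crossing(self, rng):
        x = rng.normal(size=(60, 2))
        g = gap_statistic(x, k_max=5, b_ref=30, seed=2)
        k = g.k_selected
        if k < 5:
            i = k - 1
            assert g.gap[i] >= g.gap[i + 1] - g.sk[i + 1]
            for j in range(i):
                assert g.gap[j] < g.gap[j + 1] - g.sk[j + 1]


class TestClusterSomNodes:
    def test_identical_regions_collapse_to_one_cluster(self):
        z = pd.DataFrame(np.tile([0.1, 0.9], (12, 1)))
        model = train_som(z, grid=(3, 3), iterations=10, seed=0, scale=False)
        clusters = cluster_som_nodes(model, k=1, zm=DsamMatrix(z))
        assert clusters.region_labels.nunique() == 1
        assert clusters.sizes.tolist() == [12]

    def test_four_blob_typology_recovered(self):
        hits = 0
        for seed in range(10):
            z, labels = blob_frame(2000 + seed, p=3)
            model = train_som(z, grid=(8, 8), iterations=100, seed=seed)
            gap = gap_statistic(model.weights, k_max=8, b_ref=50, seed=seed)
            clusters = cluster_som_nodes(model, gap=gap, zm=DsamMatrix(z), seed=seed)
            pure = all(
                clusters.region_labels[labels == b].nunique() == 1 for b in range(4)
            )
            hits += gap.k_selected == 4 and pure
        assert hits >= 9

    def test_cluster_means_match_group_means(self, rng):
        z = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        model = train_som(z, grid=(4, 4), iterations=20, seed=5)
        clusters = cluster_som_nodes(model, k=2, zm=DsamMatrix(z), seed=5)
        for cid in range(2):
            members = clusters.region_labels[clusters.region_labels == cid].index
            np.testing.assert_allclose(
                clusters.means.loc[cid], z.loc[members].mean(), atol=1e-12
            )

    def test_normalized_profiles_in_unit_range(self, rng):
        z = pd.DataFrame(rng.normal(size=(40, 3)))
        model = train_som(z, grid=(4, 4), iterations=20, seed=5)
        clusters = cluster_som_nodes(model, k=3, zm=DsamMatrix(z), seed=5)
        vals = clusters.normalized.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
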