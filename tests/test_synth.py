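import numpy as np
import pytest
import scipy.stats

from sctiger.preprocess import normalize
from sctiger.pseudotime import order_cells
from sctiger.synth import (
    BENCHMARK_TOPOLOGIES,
    PlantedSystem,
    generate_case_control,
    generate_lagged_system,
    generate_trajectory_dataset,
    inject_dropout,
    write_benchmark_surrogate,
)


class TestLaggedSystem:
    def test_cross_correlogram_peaks_at_planted_lag(self):
        spec = PlantedSystem(n_genes=4, T=400, edges=[(0, 1, 2, 1, 1.0)],
                             noise_sd=0.1, seed=0)
        X, _ = generate_lagged_system(spec)
        xi, xj = X.X[0], X.X[1]
        cors = [np.corrcoef(xi[: 400 - l], xj[l:])[0, 1] for l in range(6)]
        assert int(np.argmax(np.abs(cors))) == 2

    def test_null_pairwise_correlation_bounded(self):
        hits = 0
        for seed in range(10):
            spec = PlantedSystem(n_genes=8, T=200, edges=[], seed=seed)
            X, truth = generate_lagged_system(spec)
            assert truth == set()
            r = np.corrcoef(X.X)
            np.fill_diagonal(r, 0)
            if np.max(np.abs(r)) <= 0.3:
                hits += 1
        assert hits >= 8

    def test_deterministic(self):
        spec = PlantedSystem(n_genes=5, T=100, edges=[(0, 1, 1, 1, 1.0)], seed=3)
        X1, _ = generate_lagged_system(spec)
        X2, _ = generate_lagged_system(spec)
        np.testing.assert_array_equal(X1.X, X2.X)

    def test_lag_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            PlantedSystem(n_genes=3, T=10, edges=[(0, 1, 10, 1, 1.0)])

    def test_sign_validation(self):
        with pytest.raises(ValueError, match="sign"):
            PlantedSystem(n_genes=3, T=10, edges=[(0, 1, 1, 2, 1.0)])


class TestCaseControl:
    def test_decoy_pairs_correlated_within_not_codiff(self):
        case, control, truth = generate_case_control(seed=0, n_cells=150)
        for a, b in truth["decoys"]:
            ia, ib = case.gene_index(a), case.gene_index(b)
            r_case = np.corrcoef(case.counts[ia], case.counts[ib])[0, 1]
            assert abs(r_case) >= 0.6
            # pair cells by latent position to mimic pseudotime matching
            oc = np.argsort(truth["latent_case"])
            on = np.argsort(truth["latent_control"])
            diff_a = case.counts[ia, oc] - control.counts[control.gene_index(a), on]
            diff_b = case.counts[ib, oc] - control.counts[control.gene_index(b), on]
            assert abs(np.corrcoef(diff_a, diff_b)[0, 1]) <= 0.3

    def test_responders_track_goi_differential(self):
        case, control, truth = generate_case_control(seed=1, n_cells=150)
        oc = np.argsort(truth["latent_case"])
        on = np.argsort(truth["latent_control"])

        def diff(g):
            return case.counts[case.gene_index(g), oc] - control.counts[control.gene_index(g), on]

        d_goi = diff(truth["goi"])
        for _goi, gene, lag, sign in truth["responders"]:
            r = np.corrcoef(d_goi, diff(gene))[0, 1]
            # repression is attenuated by the zero floor of counts
            assert (r > 0.3) if sign == "+" else (r < -0.15)

    def test_latent_positions_recovered_by_pseudotime(self):
        # moderate within-cell coupling: the heavy-coupling regime trades
        # ordering precision for (ordering-invariant) causal signal
        case, _, truth = generate_case_control(seed=2, n_cells=120, n_genes=40,
                                               nb_dispersion=0.05, base_scale=80,
                                               coupling_sd=0.3)
        norm = normalize(case.copy(), 1e4)
        ordering = order_cells(norm, seed=0)
        rho, _ = scipy.stats.spearmanr(ordering.pseudotime, truth["latent_case"])
        assert abs(rho) >= 0.9

    def test_deterministic(self):
        a1, b1, _ = generate_case_control(seed=5)
        a2, b2, _ = generate_case_control(seed=5)
        np.testing.assert_array_equal(a1.counts, a2.counts)
        np.testing.assert_array_equal(b1.counts, b2.counts)


class TestInjectDropout:
    def _mat(self, counts):
        from sctiger.matrix import ExpressionMatrix

        counts = np.asarray(counts, dtype=float)
        return ExpressionMatrix(counts=counts,
                                gene_ids=[f"g{i}" for i in range(counts.shape[0])],
                                cell_ids=[f"c{i}" for i in range(counts.shape[1])])

    def test_noop_at_current_fraction(self):
        m = self._mat([[1.0, 0.0], [2.0, 3.0]])
        out = inject_dropout(m, 0.25, seed=0)
        np.testing.assert_array_equal(out.counts, m.counts)

    def test_exact_counting(self):
        rng = np.random.default_rng(0)
        counts = rng.uniform(1, 5, size=(10, 10))
        counts.ravel()[rng.choice(100, 40, replace=False)] = 0.0
        m = self._mat(counts)
        out = inject_dropout(m, 0.5, seed=1)
        assert int((out.counts == 0).sum()) == 50

    def test_rounding_contract_at_095(self):
        rng = np.random.default_rng(1)
        counts = rng.uniform(1, 5, size=(20, 20))
        counts.ravel()[rng.choice(400, 360, replace=False)] = 0.0  # 0.90
        out = inject_dropout(self._mat(counts), 0.95, seed=0)
        frac = (out.counts == 0).sum() / out.counts.size
        assert 0.95 - 1 / 400 <= frac <= 0.95

    def test_never_revives_zeros_or_alters_survivors(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, size=(15, 15)).astype(float)
        m = self._mat(counts)
        out = inject_dropout(m, 0.8, seed=3)
        assert np.all(out.counts[m.counts == 0] == 0)
        survivors = out.counts != 0
        np.testing.assert_array_equal(out.counts[survivors], m.counts[survivors])

    def test_lowering_target_rejected(self):
        m = self._mat([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="below current"):
            inject_dropout(m, 0.25, seed=0)


class TestTrajectoryDataset:
    def test_shapes_and_reference(self):
        m, ref, latent = generate_trajectory_dataset(
            BENCHMARK_TOPOLOGIES["LI"], n_cells=100, seed=0)
        assert m.n_genes == 7 and m.n_cells == 100
        assert len(ref) == 7
        assert len(latent) == 100

    def test_bundled_topology_sizes(self):
        canon = lambda edges: {frozenset((a, b)) for a, b, _ in edges if a != b}
        assert len(canon(BENCHMARK_TOPOLOGIES["LI"])) == 7
        assert len(canon(BENCHMARK_TOPOLOGIES["CY"])) == 6
        assert len(canon(BENCHMARK_TOPOLOGIES["HSC"])) == 21
        assert len(canon(BENCHMARK_TOPOLOGIES["MCAD"])) == 9

    def test_cascade_propagates_with_lag(self):
        m, _, latent = generate_trajectory_dataset(
            BENCHMARK_TOPOLOGIES["LI"], n_cells=200, lag=3, seed=0,
            shuffle_cells=False)
        x1, x2 = m.counts[0], m.counts[1]
        cors = [np.corrcoef(x1[: 200 - l], x2[l:])[0, 1] for l in range(8)]
        assert int(np.argmax(cors)) == 3

    def test_surrogate_directory_written(self, tmp_path):
        write_benchmark_surrogate("CY", tmp_path, n_cells=50, seed=1)
        assert (tmp_path / "ExpressionData.csv").exists()
        assert (tmp_path / "refNetwork.csv").exists()
        from sctiger.benchmark import load_beeline

        with pytest.warns(UserWarning):
            m, ref = load_beeline(tmp_path)
        assert m.n_genes == 6 and len(ref.edges) == 6
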