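import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import somstab as ss
from somstab.som import _grid_coords


def gaussian_matrix(n, m, seed, loc=0.0):
    rng = np.random.default_rng(seed)
    return rng.normal(loc, 1.0, size=(n, m))


class TestSchedule:
    @pytest.mark.parametrize(
        "rlen,n,expected",
        [
            (10, 10**6, 10_000_000),
            (80, 27_531_842, 2_202_547_360),  # beyond int32, still exact
            (0, 12345, 0),
        ],
    )
    def test_exact_products(self, rlen, n, expected):
        assert ss.schedule_iterations(rlen, n).niter == expected

    def test_guard_on_64bit_overflow(self):
        with pytest.raises(OverflowError):
            ss.schedule_iterations(2**40, 2**24)

    @given(rlen=st.integers(0, 2**31), n=st.integers(1, 2**31))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_big_integer_arithmetic(self, rlen, n):
        product = rlen * n  # Python ints are arbitrary precision
        if product >= 2**63:
            with pytest.raises(OverflowError):
                ss.schedule_iterations(rlen, n)
        else:
            assert ss.schedule_iterations(rlen, n).niter == product

    def test_alpha_and_radius_decay(self):
        sched = ss.schedule_iterations(10, 1000, 0.05, 0.01, radius0=4.0)
        alphas = [sched.alpha_at(t) for t in range(0, 10000, 500)]
        radii = [sched.radius_at(t) for t in range(0, 10000, 500)]
        assert alphas[0] == 0.05
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))
        assert all(r >= s for r, s in zip(radii, radii[1:]))
        assert sched.alpha_at(9999) == pytest.approx(0.01, abs=1e-4)


class TestEmulate32Bit:
    @pytest.mark.parametrize(
        "rlen,n,expected",
        [
            (10, 10**6, 10_000_000),  # below the boundary: unchanged
            (1, 2**31 - 1, 2**31 - 1),  # largest representable value
            (1, 2**31, -(2**31)),  # first wrapped value
            (80, 27_531_842, -2_092_419_936),  # negative => untrained map
            (160, 27_531_842, 110_127_424),  # positive but truncated
        ],
    )
    def test_twos_complement_wraparound(self, rlen, n, expected):
        assert ss.emulate_niter_32bit(rlen, n) == expected

    @given(rlen=st.integers(0, 10**5), n=st.integers(0, 10**5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_agrees_with_true_product_below_boundary(self, rlen, n):
        product = rlen * n
        emulated = ss.emulate_niter_32bit(rlen, n)
        if product <= 2**31 - 1:
            assert emulated == product
        assert -(2**31) <= emulated <= 2**31 - 1


class TestInitCodebook:
    def test_deterministic_given_seed(self, scaled_matrix):
        cfg = ss.SOMConfig(xdim=3, ydim=3, seed=42)
        a = ss.init_codebook(scaled_matrix, cfg)
        b = ss.init_codebook(scaled_matrix, cfg)
        np.testing.assert_array_equal(a.codebook, b.codebook)

    @pytest.mark.parametrize("xdim,ydim,k", [(10, 10, 100), (12, 12, 144)])
    def test_k_is_grid_product(self, xdim, ydim, k):
        x = gaussian_matrix(200, 4, seed=0)
        model = ss.init_codebook(x, ss.SOMConfig(xdim=xdim, ydim=ydim, seed=1))
        assert model.codebook.shape == (k, 4)
        assert model.grid_coords.shape == (k, 2)

    def test_too_few_cells_raises(self):
        with pytest.raises(ValueError, match="k=100"):
            ss.init_codebook(gaussian_matrix(50, 3, 0), ss.SOMConfig(seed=0))

    def test_rows_are_distinct_cells(self):
        x = gaussian_matrix(100, 3, seed=2)
        model = ss.init_codebook(x, ss.SOMConfig(xdim=5, ydim=5, seed=3))
        assert len(np.unique(model.codebook, axis=0)) == 25


class TestTrain:
    def test_rlen_zero_leaves_initialization(self, scaled_matrix):
        cfg = ss.SOMConfig(xdim=3, ydim=3, rlen=0, seed=1)
        model = ss.train_som(scaled_matrix, cfg)
        np.testing.assert_array_equal(model.codebook, model.init_codebook)

    def test_deterministic_bit_identical(self, scaled_matrix):
        cfg = ss.SOMConfig(xdim=3, ydim=3, rlen=3, seed=7)
        a = ss.train_som(scaled_matrix, cfg)
        b = ss.train_som(scaled_matrix, cfg)
        np.testing.assert_array_equal(a.codebook, b.codebook)

    def test_single_node_tracks_mean_vs_scalar_oracle(self):
        # 1x1 grid: the update collapses to w += alpha * (x - w); an
        # independent plain-python loop is the oracle.
        rng = np.random.default_rng(8)
        data = rng.normal(1.5, 1.0, size=(5000, 1))
        cfg = ss.SOMConfig(xdim=1, ydim=1, rlen=100, seed=4)
        model = ss.train_som(data, cfg)
        assert abs(model.codebook[0, 0] - data.mean()) < 0.05

        niter = 100 * 5000
        w = ss.init_codebook(data, cfg).codebook[0, 0]
        for t in range(niter):
            alpha = 0.05 - (0.05 - 0.01) * t / niter
            w += alpha * (data[t % 5000, 0] - w)
        assert model.codebook[0, 0] == pytest.approx(w, abs=1e-10)

    def test_label_recovery_on_separated_gaussians(self):
        # 3 populations >= 10 sd apart, 2x2 grid: majority-vote node
        # labels should recover nearly all true labels.
        rng = np.random.default_rng(9)
        centers = np.array([[0, 0, 0], [12, 0, 0], [0, 12, 0]], dtype=float)
        labels = rng.integers(0, 3, size=3000)
        data = centers[labels] + rng.normal(size=(3000, 3))
        model = ss.train_som(data, ss.SOMConfig(xdim=2, ydim=2, rlen=100, seed=1))
        assign = ss.assign_cells(data, model)
        node_label = {}
        for node in range(4):
            cells = assign.partition[node]
            if len(cells):
                node_label[node] = np.bincount(labels[cells]).argmax()
        predicted = np.array([node_label[i] for i in assign.node_index])
        assert (predicted == labels).mean() >= 0.95

    def test_training_reduces_average_distance(self, scaled_matrix):
        cfg = ss.SOMConfig(xdim=4, ydim=4, rlen=20, seed=2)
        init = ss.init_codebook(scaled_matrix, cfg)
        trained = ss.train_som(scaled_matrix, cfg, init=init)
        ad_init = ss.average_distance(ss.assign_cells(scaled_matrix, init))
        ad_trained = ss.average_distance(ss.assign_cells(scaled_matrix, trained))
        assert ad_trained < ad_init

    def test_non_finite_data_rejected(self):
        bad = np.array([[1.0, np.inf], [0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="non-finite"):
            ss.train_som(bad, ss.SOMConfig(xdim=2, ydim=2, seed=0))


class TestBuggyMode:
    def test_negative_emulated_niter_returns_initialization(self, scaled_matrix):
        # rlen chosen so rlen * n_cells wraps negative in 32 bits
        n = scaled_matrix.n_cells
        rlen = (2**31 + 10**6) // n + 1
        assert ss.emulate_niter_32bit(rlen, n) < 0
        cfg = ss.SOMConfig(xdim=3, ydim=3, rlen=rlen, seed=3)
        with pytest.warns(RuntimeWarning, match="overflow"):
            model = ss.train_som(scaled_matrix, cfg, buggy_mode=True)
        np.testing.assert_array_equal(model.codebook, model.init_codebook)

    def test_below_boundary_buggy_mode_is_identical(self, scaled_matrix):
        cfg = ss.SOMConfig(xdim=3, ydim=3, rlen=2, seed=3)
        clean = ss.train_som(scaled_matrix, cfg, buggy_mode=False)
        buggy = ss.train_som(scaled_matrix, cfg, buggy_mode=True)
        np.testing.assert_array_equal(clean.codebook, buggy.codebook)


class TestAssign:
    def test_cells_equal_to_codebook_rows(self):
        data = np.arange(12.0).reshape(4, 3)
        cfg = ss.SOMConfig(xdim=2, ydim=2, rlen=0, seed=0)
        model = ss.train_som(data, cfg)
        # rlen=0: codebook rows are 4 distinct cells; assigning those
        # exact cells gives distance 0
        assign = ss.assign_cells(model.codebook, model)
        np.testing.assert_allclose(assign.distance, 0, atol=1e-12)
        assert sorted(assign.node_index) == [0, 1, 2, 3]

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(50, 4))
        model = ss.train_som(
            gaussian_matrix(100, 4, 11), ss.SOMConfig(xdim=3, ydim=3, rlen=2, seed=5)
        )
        assign = ss.assign_cells(data, model)
        for i in range(50):
            d = np.linalg.norm(model.codebook - data[i], axis=1)
            assert assign.node_index[i] == np.argmin(d)
            assert assign.distance[i] == pytest.approx(d.min())

    def test_partition_is_disjoint_cover_with_empty_nodes_allowed(self):
        data = np.zeros((5, 2))
        data[:, 0] = [0, 0.1, 0.2, 10, 10.1]
        cfg = ss.SOMConfig(xdim=5, ydim=1, rlen=0, seed=1)
        model = ss.train_som(data, cfg)
        assign = ss.assign_cells(data, model)
        all_cells = np.concatenate(assign.partition)
        assert sorted(all_cells) == list(range(5))
        sizes = assign.node_sizes()
        assert sizes.sum() == 5

    def test_channel_mismatch_raises(self, trained_som):
        with pytest.raises(ValueError, match="channels"):
            ss.assign_cells(np.zeros((3, 2)), trained_som.model)


class TestMetacluster:
    def _model(self, codebook):
        k = codebook.shape[0]
        cfg = ss.SOMConfig(xdim=k, ydim=1, rlen=0, seed=0)
        return ss.SOMModel(codebook, _grid_coords(k, 1), cfg, codebook.copy())

    def test_identity_and_single_cluster(self):
        cb = np.arange(8.0).reshape(4, 2)
        model = self._model(cb)
        np.testing.assert_array_equal(
            ss.metacluster_codebook(model, 4), np.arange(4)
        )
        assert len(set(ss.metacluster_codebook(model, 1))) == 1

    def test_two_blobs_split_exactly(self):
        rng = np.random.default_rng(12)
        blob_a = rng.normal(0, 0.01, size=(5, 3))
        blob_b = rng.normal(50, 0.01, size=(5, 3))
        model = self._model(np.vstack([blob_a, blob_b]))
        labels = ss.metacluster_codebook(model, 2)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_n_meta_out_of_range(self):
        model = self._model(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            ss.metacluster_codebook(model, 5)
        with pytest.raises(ValueError):
            ss.metacluster_codebook(model, 0)


class TestPseudoBulk:
    def test_matches_group_by_mean(self, scaled_matrix, trained_som):
        import pandas as pd

        pb = trained_som.pseudo_bulk()
        df = pd.DataFrame(scaled_matrix.values)
        df["node"] = trained_som.assignment.node_index
        expected = df.groupby("node").mean()
        for node in expected.index:
            np.testing.assert_allclose(pb[node], expected.loc[node].values)

    def test_singleton_and_pair_clusters(self):
        data = np.array([[0.0, 2.0], [2.0, 0.0], [5.0, 5.0]])
        assign = ss.NodeAssignment(
            node_index=[0, 0, 1], distance=[0, 0, 0], k=3
        )
        pb = ss.pseudo_bulk(data, assign)
        np.testing.assert_allclose(pb[0], [1.0, 1.0])  # two-cell mean
        np.testing.assert_allclose(pb[1], [5.0, 5.0])  # singleton
        assert np.isnan(pb[2]).all()  # empty node flagged


class TestModelContainer:
    def test_save_load_round_trip(self, trained_som, tmp_path):
        trained_som.model.save(tmp_path / "model")
        back = ss.SOMModel.load(tmp_path / "model")
        np.testing.assert_array_equal(back.codebook, trained_som.model.codebook)
        np.testing.assert_array_equal(
            back.init_codebook, trained_som.model.init_codebook
        )
        assert back.config == trained_som.model.config

    def test_summary_mentions_grid_and_ad(self, trained_som):
        text = trained_som.summary()
        assert "4 x 4" in text
        assert "average distance" in text
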