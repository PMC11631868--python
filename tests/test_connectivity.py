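"""Temporal preprocessing, connectivity matrices, graph metrics and clustering."""

import numpy as np
import pytest
from scipy import stats

from phmrikit import connectivity as conn
from phmrikit.simulate import NetworkSpec, generate_restingstate
from phmrikit.types import ConnectivityMatrix, NodeTimeSeries


def _series(data, dt=1.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    return NodeTimeSeries(data, list(range(n)), [f"n{i}" for i in range(n)], dt)


def _subject_z(seed, n_nodes=16, within=0.8, between=0.0, length=150):
    series, blocks = generate_restingstate(
        NetworkSpec(n_nodes, within_block_r=within, between_block_r=between,
                    series_length=length, seed=seed)
    )
    return conn.fisher_z_matrix(conn.pearson_matrix(series)), blocks


class TestBandpass:
    def test_constant_series_rejected_as_dc(self):
        out = conn.bandpass(np.full((1, 300), 7.0), 1.0)
        assert np.abs(out).max() < 1e-8

    def test_passband_and_stopband_vs_fft_oracle(self):
        from scipy import signal

        t = np.arange(3000)
        sos = signal.butter(4, [0.01, 0.1], btype="bandpass", fs=1.0, output="sos")
        for freq, keep in ((0.05, True), (0.4, False)):
            out = conn.bandpass(np.sin(2 * np.pi * freq * t)[None], 1.0)[0]
            amp = out[1000:2000].std() * np.sqrt(2)  # mid-series, away from edges
            # oracle: squared magnitude response of the forward-backward filter
            gain = np.abs(signal.sosfreqz(sos, worN=[freq], fs=1.0)[1][0]) ** 2
            assert amp == pytest.approx(gain, rel=0.05)
            assert (amp > 0.95) if keep else (amp < 0.1)

    def test_infeasible_band(self):
        with pytest.raises(ValueError, match="infeasible"):
            conn.bandpass(np.zeros((1, 100)), sampling_interval=6.0, low=0.01, high=0.1)


class TestNuisanceAndScrubbing:
    def test_regressor_identical_to_series(self):
        x = np.random.default_rng(0).normal(size=100)
        resid = conn.nuisance_regress(x[None], x)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_regressor_only_demeans(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        reg = np.sin(np.linspace(0, 8 * np.pi, 200))
        reg -= reg.mean()  # orthogonal to the intercept
        xc = x - x.mean()
        reg -= reg @ xc / (xc @ xc) * xc  # orthogonal to the series
        resid = conn.nuisance_regress(x[None], reg)
        assert np.allclose(resid, (x - x.mean())[None], atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 150))
        reg = rng.normal(size=(150, 4))
        resid = conn.nuisance_regress(x, reg)
        assert np.abs(resid @ reg).max() < 1e-9
        assert np.abs(resid.sum(axis=1)).max() < 1e-9  # intercept projected out

    def test_scrub_identity_when_clean(self):
        x = np.random.default_rng(3).normal(size=(2, 50))
        out, qc = conn.scrub_motion(x, [])
        assert np.array_equal(out, x) and qc["n_censored"] == 0

    def test_spike_zeroed_at_censored_frame(self):
        x = np.random.default_rng(4).normal(size=(1, 60))
        out, _ = conn.scrub_motion(x, [17])
        assert abs(out[0, 17]) < 1e-10

    def test_matches_frame_deletion_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 200))
        x[0] += 0.5 * x[1]  # correlated pair
        spikes = [3, 50, 51, 120]
        scrubbed, _ = conn.scrub_motion(x, spikes)
        r_scrub = np.corrcoef(scrubbed)
        keep = np.setdiff1d(np.arange(200), spikes)
        r_del = np.corrcoef(x[:, keep])
        off = ~np.eye(6, dtype=bool)
        assert np.abs(r_scrub[off] - r_del[off]).max() < 0.02

    def test_excess_censoring_flagged(self):
        x = np.zeros((1, 10)) + np.arange(10)
        with pytest.warns(UserWarning, match="50%"):
            _, qc = conn.scrub_motion(x, list(range(6)))
        assert qc["excess_censoring"]


class TestPearsonAndFisher:
    def test_antithetic_nodes(self):
        x = np.random.default_rng(0).normal(size=100)
        m = conn.pearson_matrix(_series([x, -x]))
        assert m.values[0, 1] == pytest.approx(-1.0)

    def test_pair_count(self):
        rng = np.random.default_rng(1)
        m = conn.pearson_matrix(_series(rng.normal(size=(10, 80))))
        iu = np.triu_indices(10, 1)
        assert iu[0].size == 45 and np.isfinite(m.values[iu]).all()

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(4, 100))
        scaled = data.copy()
        scaled[2] = 3.5 * scaled[2] - 7.0
        a = conn.pearson_matrix(_series(data)).values
        b = conn.pearson_matrix(_series(scaled)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_variance_node_flagged(self):
        data = np.random.default_rng(3).normal(size=(3, 50))
        data[1] = 5.0
        m = conn.pearson_matrix(_series(data))
        assert m.qc_flags["zero_variance_nodes"] == [1]
        assert np.isnan(m.values[1, 0]) and np.isnan(m.values[2, 1])

    def test_fisher_z_values(self):
        assert conn.fisher_z(0.0) == 0.0
        assert conn.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        r = np.linspace(-0.95, 0.95, 21)
        assert np.allclose(conn.fisher_z(-r), -np.asarray(conn.fisher_z(r)))
        assert np.allclose(np.tanh(conn.fisher_z(r)), r, atol=1e-12)

    def test_unit_r_clipped(self):
        z = conn.fisher_z(1.0)
        assert np.isfinite(z) and z == pytest.approx(np.arctanh(1 - 1e-7))


class TestGroupEdgeZ:
    def test_all_zero_edges(self):
        mats = [ConnectivityMatrix(np.zeros((3, 3)), [0, 1, 2], "fisher_z") for _ in range(4)]
        assert np.allclose(conn.group_edge_z(mats).values, 0.0)

    def test_identical_nonzero_values_capped(self):
        v = np.array([[0, 0.7], [0.7, 0]])
        mats = [ConnectivityMatrix(v, [0, 1], "fisher_z") for _ in range(5)]
        out = conn.group_edge_z(mats)
        assert out.values[0, 1] == conn.GROUP_Z_CAP
        assert out.qc_flags["capped_edges"] > 0

    def test_matches_t_cdf_oracle(self):
        rng = np.random.default_rng(9)
        stack = rng.normal(0.2, 0.3, size=(6, 4, 4))
        stack = (stack + stack.transpose(0, 2, 1)) / 2
        for s in stack:
            np.fill_diagonal(s, 0.0)
        mats = [ConnectivityMatrix(s, list(range(4)), "fisher_z") for s in stack]
        z = conn.group_edge_z(mats).values
        for i in range(4):
            for j in range(i + 1, 4):
                t_ref, p_ref = stats.ttest_1samp(stack[:, i, j], 0.0)
                z_ref = np.sign(t_ref) * stats.norm.isf(p_ref / 2)
                assert z[i, j] == pytest.approx(z_ref, abs=1e-8)


class TestGraphMetrics:
    def test_threshold_boundary_inclusive(self):
        v = np.array([[0, 2.3, -1.0], [2.3, 0, -2.31], [-1.0, -2.31, 0]])
        a = conn.threshold_matrix(ConnectivityMatrix(v, [0, 1, 2], "group_z"))
        assert a[0, 1] == 1 and a[1, 2] == 1 and a[0, 2] == 0

    def test_retained_edges_match_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        v = rng.normal(0, 2, (12, 12))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        a = conn.threshold_matrix(ConnectivityMatrix(v, list(range(12)), "group_z"))
        expected = sum(
            1 for i in range(12) for j in range(i + 1, 12) if abs(v[i, j]) >= 2.3
        )
        assert a.sum() // 2 == expected

    def test_degree_known_graphs(self):
        complete = 1 - np.eye(4, dtype=int)
        assert (conn.degree_centrality(complete)["degree"] == 3).all()
        star = np.zeros((5, 5), dtype=int)
        star[0, 1:] = star[1:, 0] = 1
        deg = conn.degree_centrality(star)["degree"].to_numpy()
        assert deg[0] == 4 and (deg[1:] == 1).all()

    def test_degree_matches_networkx_and_handshake(self):
        import networkx as nx

        rng = np.random.default_rng(11)
        a = (rng.random((15, 15)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        deg = conn.degree_centrality(a)["degree"]
        nx_deg = dict(nx.from_numpy_array(a).degree())
        assert [nx_deg[i] for i in range(15)] == deg.tolist()
        assert deg.sum() == 2 * (a.sum() // 2)  # handshake lemma


class TestKnnCluster:
    def test_two_block_network_recovered(self):
        mats = [_subject_z(100 + s)[0] for s in range(6)]
        blocks = _subject_z(100)[1]
        gz = conn.group_edge_z(mats)
        labels = conn.knn_cluster(gz, k=5)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(blocks, labels) == 1.0

    def test_identical_profiles_single_cluster(self):
        v = np.zeros((6, 6))
        labels = conn.knn_cluster(ConnectivityMatrix(v, list(range(6)), "group_z"), k=2)
        assert len(set(labels)) == 1

    def test_node_permutation_permutes_labels(self):
        gz = conn.group_edge_z([_subject_z(300 + s)[0] for s in range(5)])
        labels = conn.knn_cluster(gz, k=4)
        perm = np.random.default_rng(0).permutation(gz.n_nodes)
        permuted = ConnectivityMatrix(
            gz.values[np.ix_(perm, perm)], [gz.node_ids[i] for i in perm], "group_z"
        )
        labels_p = conn.knn_cluster(permuted, k=4)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="k ="):
            conn.knn_cluster(ConnectivityMatrix(np.zeros((4, 4)), list(range(4)), "group_z"), k=4)


class TestCompareDegree:
    def test_identical_vectors(self):
        res = conn.compare_degree(np.arange(10), np.arange(10))
        assert res.test == "no_difference" and res.p_value == 1.0

    def test_normal_shift_uses_paired_t(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 2, 30)
        b = a + rng.normal(1, 0.5, 30)
        res = conn.compare_degree(a, b)
        assert res.test == "paired_t"
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert res.p_value == pytest.approx(p_ref)

    def test_heavy_tailed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(13)
        a = rng.normal(10, 1, 40)
        b = a + rng.standard_cauchy(40) + 0.5  # grossly non-normal differences
        res = conn.compare_degree(a, b)
        assert res.test == "wilcoxon"
        assert res.shapiro_p <= 0.05
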