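"""Voxel scoring, ranked-p filtering, regional counting and composite maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phmrikit import activation as act
from phmrikit.io import load_reference_voa
from phmrikit.simulate import make_atlas
from phmrikit.types import Bold4D, SubjectTransform

from conftest import bold_from_series

BASE_W, RESP_W = (1, 4), (5, 8)


def _bold(baseline_vals, response_vals):
    series = np.concatenate([baseline_vals, response_vals])
    return bold_from_series(series)


class TestPercentChange:
    @pytest.mark.parametrize(
        "base, resp, expected",
        [
            ([100.0] * 4, [100.0] * 4, 0.0),  # constant series
            ([100.0] * 4, [102.0] * 4, 2.0),
            ([100.0] * 4, [99.0] * 4, -1.0),  # negative threshold boundary
        ],
    )
    def test_forced_values(self, base, resp, expected):
        dpct, invalid = act.percent_change_map(_bold(base, resp), BASE_W, RESP_W)
        assert dpct.ravel()[0] == pytest.approx(expected)
        assert not invalid.any()

    def test_zero_baseline_marked_invalid(self):
        dpct, invalid = act.percent_change_map(_bold([0.0] * 4, [5.0] * 4), BASE_W, RESP_W)
        assert invalid.ravel()[0]
        assert dpct.ravel()[0] == 0.0

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            act.percent_change_map(_bold([1.0] * 4, [1.0] * 4), (1, 5), (5, 8))


class TestVoxelTtest:
    def test_permuted_windows_give_p_one(self):
        base = [100.0, 101.0, 99.0, 100.5]
        resp = [99.0, 100.5, 101.0, 100.0]  # a permutation of baseline
        p = act.voxel_ttest(_bold(base, resp), BASE_W, RESP_W)
        assert p.ravel()[0] == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        rng = np.random.default_rng(7)
        base = 100 + rng.normal(0, 0.01, 4)
        resp = 102 + rng.normal(0, 0.01, 4)
        p = act.voxel_ttest(_bold(base, resp), BASE_W, RESP_W).ravel()[0]
        # independent Welch oracle from the textbook formula
        va, vb = base.var(ddof=1) / 4, resp.var(ddof=1) / 4
        t = (resp.mean() - base.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        p_oracle = 2 * stats.t.sf(abs(t), df)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_degenerate_variance_conventions(self):
        assert act.voxel_ttest(_bold([5.0] * 4, [5.0] * 4), BASE_W, RESP_W).ravel()[0] == 1.0
        assert act.voxel_ttest(_bold([5.0] * 4, [6.0] * 4), BASE_W, RESP_W).ravel()[0] == 0.0

    def test_rank_agreement_with_permutation_oracle(self):
        rng = np.random.default_rng(11)
        n_vox = 60
        base = 100 + rng.normal(0, 1, (n_vox, 1, 1, 10))
        shift = np.linspace(0, 2, n_vox)[:, None, None, None]
        resp = 100 + shift + rng.normal(0, 1, (n_vox, 1, 1, 10))
        bold = Bold4D(np.concatenate([base, resp], axis=3), 1.0, "s", "g")
        p = act.voxel_ttest(bold, (1, 10), (11, 20)).ravel()
        pooled = np.concatenate([base, resp], axis=3).reshape(n_vox, 20)
        p_perm = np.empty(n_vox)
        for v in range(n_vox):
            obs = abs(pooled[v, 10:].mean() - pooled[v, :10].mean())
            count = 0
            for _ in range(300):
                perm = rng.permutation(pooled[v])
                count += abs(perm[10:].mean() - perm[:10].mean()) >= obs
            p_perm[v] = (count + 1) / 301
        rho = stats.spearmanr(p, p_perm).statistic
        assert rho > 0.95


class TestRankedPFilter:
    def test_hand_evaluated_step_up(self):
        p = np.array([0.01, 0.05, 0.10, 0.5, 0.9])
        # thresholds (i/5)*0.2: 0.04, 0.08, 0.12, 0.16, 0.20 -> ranks 1-3 pass
        assert act.ranked_p_filter(p, q=0.2, c_v=1.0).sum() == 3

    def test_all_extreme_p(self):
        assert not act.ranked_p_filter(np.ones(8)).any()
        assert act.ranked_p_filter(np.zeros(8)).all()
        assert act.ranked_p_filter(np.array([])).size == 0

    def test_ties_share_the_better_rank(self):
        # only rank 3's threshold is met; all three tied values pass together
        p = np.array([0.10, 0.10, 0.10, 0.9, 0.9])
        passed = act.ranked_p_filter(p, q=0.2, c_v=1.0)
        assert passed.tolist() == [True, True, True, False, False]

    def test_equivalent_to_bh_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(23)
        for _ in range(200):
            v = rng.integers(1, 51)
            p = rng.random(v) ** rng.uniform(0.5, 3)
            ours = act.ranked_p_filter(p, q=0.2, c_v=1.0)
            oracle = multipletests(p, alpha=0.2, method="fdr_bh")[0]
            assert np.array_equal(ours, oracle)

    def test_lowering_q_never_admits_more(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        n_passed = [act.ranked_p_filter(p, q=q).sum() for q in (0.3, 0.2, 0.1, 0.05)]
        assert n_passed == sorted(n_passed, reverse=True)


class TestClassifyAndCount:
    @pytest.mark.parametrize(
        "dpct, passed, expected",
        [
            (0.5, True, 0),  # below magnitude threshold
            (-1.0, True, -1),  # boundary inclusive
            (1.0, True, 1),
            (-5.0, False, 0),  # failed filter dominates
        ],
    )
    def test_sign_rules(self, dpct, passed, expected):
        sign = act.classify_voxels(np.array([dpct]), np.array([passed]))
        assert sign[0] == expected

    def test_raising_threshold_never_adds_voxels(self):
        rng = np.random.default_rng(2)
        dpct = rng.normal(0, 2, 500)
        passed = rng.random(500) < 0.7
        counts = [
            np.count_nonzero(act.classify_voxels(dpct, passed, thr))
            for thr in (0.5, 1.0, 2.0, 3.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_region_counts_constructed_fixture(self, small_atlas):
        sign = np.zeros(small_atlas.labels.shape, dtype=np.int8)
        region_voxels = np.argwhere(small_atlas.labels == 2)
        for x, y, z in region_voxels[:7]:
            sign[x, y, z] = -1
        counts = act.region_voxel_counts(sign, small_atlas)
        row = counts[counts["region_id"] == 2].iloc[0]
        assert row["negative"] == 7 and row["positive"] == 0
        assert (counts.loc[counts["region_id"] != 2, ["negative", "positive"]] == 0).all().all()

    def test_all_null_map(self, small_atlas):
        counts = act.region_voxel_counts(
            np.zeros(small_atlas.labels.shape, dtype=np.int8), small_atlas
        )
        assert (counts[["negative", "positive"]] == 0).all().all()


class TestCompositeMap:
    def test_identity_single_subject(self):
        m = np.random.default_rng(0).normal(size=(4, 5, 3))
        assert np.allclose(act.composite_map([m], [SubjectTransform.identity()]), m)

    def test_trilinear_midpoint(self):
        # neighbours 0 and 2 along x; shifting the grid by half a voxel samples 1.0
        m = np.zeros((2, 1, 1))
        m[1] = 2.0
        shift = np.eye(4)
        shift[0, 3] = 0.5  # composite voxel 0 maps to subject coordinate 0.5
        t = SubjectTransform(np.linalg.inv(shift))
        composite = act.composite_map([m], [t])
        assert composite[0, 0, 0] == pytest.approx(1.0)

    def test_opposite_maps_cancel(self):
        m = np.random.default_rng(1).normal(size=(3, 3, 3))
        out = act.composite_map([m, -m], [SubjectTransform.identity()] * 2)
        assert np.allclose(out, 0.0)

    def test_subject_order_irrelevant_and_idempotent(self):
        rng = np.random.default_rng(4)
        maps = [rng.normal(size=(3, 4, 2)) for _ in range(3)]
        ts = [SubjectTransform.identity() for _ in maps]
        a = act.composite_map(maps, ts)
        b = act.composite_map(maps[::-1], ts)
        assert np.allclose(a, b)
        same = act.composite_map([maps[0]] * 3, ts)
        assert np.allclose(same, maps[0])

    def test_singular_transform_names_subject(self):
        with pytest.raises(ValueError, match="rat_7"):
            SubjectTransform(np.zeros((4, 4)), "rat_7")


class TestKruskalWallisEffectSize:
    def test_hand_computed_fixture(self):
        h, p = act.kruskal_wallis([np.array([1, 2, 3.0]), np.array([4, 5, 6.0]), np.array([7, 8, 9.0])])
        assert h == pytest.approx(7.2)
        assert act.omega_squared(h, 3, 9) == pytest.approx(0.8667, abs=1e-4)

    def test_identical_groups_degenerate(self):
        h, p = act.kruskal_wallis([np.ones(4), np.ones(4)])
        assert h == 0.0 and p == 1.0

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            groups = [rng.normal(size=rng.integers(3, 8)) for _ in range(rng.integers(2, 5))]
            h, p = act.kruskal_wallis(groups)
            h_ref, p_ref = stats.kruskal(*groups)
            assert h == pytest.approx(h_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_omega_conventions(self):
        assert act.omega_squared(2.0, 3, 9) == 0.0  # H at null expectation k-1
        assert act.omega_squared(0.0, 3, 9) == 0.0  # floored
        with pytest.raises(ValueError):
            act.omega_squared(1.0, 3, 3)


class TestRankTable:
    def test_reference_tables_region_counts(self):
        neg, _ = act.rank_table(load_reference_voa("negative"), alpha=0.05)
        pos, _ = act.rank_table(load_reference_voa("positive"), alpha=0.05)
        assert len(neg) == 69
        assert len(pos) == 26

    def test_sorted_ascending_with_stable_ties(self):
        ranked, _ = act.rank_table(load_reference_voa("negative"))
        p = ranked["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()
        ties = ranked[ranked["p_value"] == 0.006]
        assert list(ties["region"]) == sorted(ties["region"])

    def test_empty_table(self):
        out, summary = act.rank_table(pd.DataFrame(columns=["region", "p_value"]))
        assert out.empty and summary["n_discoveries"] == 0
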