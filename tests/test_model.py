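"""Multiblock assembly and decomposition: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from mbplsc import (
    MBPLSC,
    AnalysisConfig,
    FeatureDataset,
    SyntheticConfig,
    assemble_multiblock,
    correlation_block,
    fit_mbplsc,
    generate_dataset,
    participant_scores,
    pattern_strength,
)
from mbplsc.exceptions import AlignmentError, ValidationError, ZeroVarianceError
from mbplsc.model import MultiblockMatrix


def _single_group_ds(n=30, p=8, q=5, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureDataset(
        participant_id=[f"s{i}" for i in range(n)],
        group=np.array(["only"] * n, dtype=object),
        gm=rng.normal(size=(n, p)),
        wm=rng.normal(size=(n, q)),
        covariates=np.empty((n, 0)),
        cognition=np.empty((n, 0)),
        gm_names=[f"g{i}" for i in range(p)],
        wm_names=[f"w{i}" for i in range(q)],
        covariate_names=[],
        cognition_names=[],
        wm_is_fa=False,
    )


class TestCorrelationBlock:
    def test_self_correlation_diagonal_is_one(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        C = correlation_block(X, X)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)

    def test_affine_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 2))
        Y = np.column_stack([2.0 * X[:, 0] + 5.0, rng.normal(size=15)])
        C = correlation_block(X, Y)
        assert C[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_pairwise_loop(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(20, 3)), rng.normal(size=(20, 2))
        C = correlation_block(X, Y)
        for i in range(3):
            for j in range(2):
                expected = np.corrcoef(X[:, i], Y[:, j])[0, 1]
                assert C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_named(self):
        X = np.random.default_rng(3).normal(size=(10, 2))
        Y = np.ones((10, 1))
        with pytest.raises(ZeroVarianceError, match="wcol"):
            correlation_block(X, Y, ynames=["wcol"])

    def test_row_mismatch(self):
        with pytest.raises(ValidationError, match="row mismatch"):
            correlation_block(np.ones((10, 2)), np.ones((8, 2)))


class TestAssembly:
    def test_stacked_shape_and_index_maps(self, toy_ds):
        mb = assemble_multiblock(toy_ds, AnalysisConfig())
        # G=2 groups, p=3 GM, q=2 WM, c=1 covariate
        assert mb.M.shape == (2 * 4, 3)
        rm = mb.row_map()
        assert rm[0] == ("HC", "gm", "gm_a") and rm[3] == ("HC", "cov", "age")
        assert mb.col_map()[0] == ("wm", "wm_a") and mb.col_map()[2] == ("cov", "age")
        assert np.all(np.abs(mb.M) <= 1 + 1e-12)

    def test_no_covariates_reduces_to_stacked_gm_wm(self, toy_ds):
        cfg = AnalysisConfig(covariates_rows=[], covariates_cols=[])
        mb = assemble_multiblock(toy_ds, cfg)
        assert mb.M.shape == (6, 2)  # [A_1; A_2], 2p x q
        for g in ("HC", "ROP"):
            mask = toy_ds.group == g
            A = correlation_block(toy_ds.gm[mask], toy_ds.wm[mask])
            np.testing.assert_allclose(mb.M[mb.row_slice(g, "gm")], A, atol=1e-12)

    def test_participant_order_invariance(self, toy_ds):
        mb1 = assemble_multiblock(toy_ds, AnalysisConfig())
        rng = np.random.default_rng(5)
        perm = np.concatenate([rng.permutation(6), 6 + rng.permutation(6)])
        mb2 = assemble_multiblock(toy_ds.subset(perm), AnalysisConfig())
        np.testing.assert_allclose(mb1.M, mb2.M, atol=1e-12)

    def test_blocks_match_direct_recomputation(self, small_planted):
        ds, _ = small_planted
        mb = assemble_multiblock(ds, AnalysisConfig())
        for g in ds.group_labels:
            mask = ds.group == g
            A = correlation_block(ds.gm[mask], ds.wm[mask])
            np.testing.assert_allclose(
                mb.M[mb.row_slice(g, "gm"), mb.col_slice("wm")], A, atol=1e-12
            )
            B = correlation_block(ds.gm[mask], ds.covariates[mask])
            np.testing.assert_allclose(
                mb.M[mb.row_slice(g, "gm"), mb.col_slice("cov")], B, atol=1e-12
            )


class TestDecomposition:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=6)
        a /= np.linalg.norm(a)
        b = rng.normal(size=4)
        b /= np.linalg.norm(b)
        mb = MultiblockMatrix(
            M=np.outer(a, b), groups=["g"],
            gm_names=[f"g{i}" for i in range(6)],
            wm_names=[f"w{i}" for i in range(4)],
            cov_row_names=[], cov_col_names=[], group_stats={},
        )
        res = fit_mbplsc(mb)
        assert res.singular_values[0] == pytest.approx(1.0, abs=1e-10)
        assert np.all(res.singular_values[1:] < 1e-10)
        # sign rule: max-|entry| of the left vector is positive
        u = res.U[:, 0]
        assert u[np.abs(u).argmax()] > 0
        sign = np.sign(u @ a)
        np.testing.assert_allclose(u, sign * a, atol=1e-10)
        np.testing.assert_allclose(res.V[:, 0], sign * b, atol=1e-10)

    def test_xi_formula(self):
        rng = np.random.default_rng(7)
        Q1, _ = np.linalg.qr(rng.normal(size=(5, 3)))
        Q2, _ = np.linalg.qr(rng.normal(size=(4, 3)))
        M = Q1 @ np.diag([2.0, 1.0, 1.0]) @ Q2.T
        mb = MultiblockMatrix(
            M=M, groups=["g"], gm_names=[f"g{i}" for i in range(5)],
            wm_names=[f"w{i}" for i in range(4)],
            cov_row_names=[], cov_col_names=[], group_stats={},
        )
        res = fit_mbplsc(mb)
        np.testing.assert_allclose(
            res.xi[:3], [400 / 6, 100 / 6, 100 / 6], atol=1e-9
        )

    def test_reduces_to_plain_plsc_single_group(self):
        """With one group and no covariates the decomposition equals the SVD
        of the plain GM-WM correlation matrix."""
        ds = _single_group_ds(seed=8)
        cfg = AnalysisConfig(covariates_rows=[], covariates_cols=[])
        res = MBPLSC(ds, cfg).fit()
        C = correlation_block(ds.gm, ds.wm)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        np.testing.assert_allclose(res.singular_values, s, atol=1e-10)
        for i in range(len(s)):
            sign = np.sign(res.U[:, i] @ U[:, i])
            np.testing.assert_allclose(res.U[:, i], sign * U[:, i], atol=1e-10)
            np.testing.assert_allclose(res.V[:, i], sign * Vt[i], atol=1e-10)

    def test_reconstruction_and_sum_invariants(self, small_planted_results):
        res = small_planted_results
        np.testing.assert_allclose(
            res.reconstruction(), res.multiblock.M, atol=1e-10
        )
        assert res.xi.sum() == pytest.approx(100.0, abs=1e-9)
        sums = res.block_contributions.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums[res.singular_values > 1e-12], 100.0, atol=1e-9)

    def test_scale_invariance_of_raw_features(self, small_planted):
        ds, _ = small_planted
        scaled = ds.subset(np.arange(ds.n))
        scaled.gm[:, 0] *= 37.0
        scaled.wm[:, 1] *= 0.01
        r1 = MBPLSC(ds).fit()
        r2 = MBPLSC(scaled).fit()
        np.testing.assert_allclose(r1.multiblock.M, r2.multiblock.M, atol=1e-12)
        np.testing.assert_allclose(r1.singular_values, r2.singular_values, atol=1e-12)
        # leading (well-separated) saliences agree; trailing components may
        # rotate freely within numerically degenerate subspaces
        np.testing.assert_allclose(r1.U[:, :2], r2.U[:, :2], atol=1e-7)
        np.testing.assert_allclose(r1.V[:, :2], r2.V[:, :2], atol=1e-7)

    def test_summary_renders(self, small_planted_results):
        text = small_planted_results.summary()
        assert "LV1" in text and "xi (%)" in text


class TestScores:
    def test_group_mean_participant_scores_zero(self, small_planted_results):
        res = small_planted_results
        ds = res.dataset
        mb = res.multiblock
        rows_gm, rows_wm, groups = [], [], []
        for g in mb.groups:
            st = mb.group_stats[g]
            rows_gm.append(st["gm_mean"])
            rows_wm.append(st["wm_mean"])
            groups.append(g)
        mean_ds = FeatureDataset(
            participant_id=[f"m{i}" for i in range(2)],
            group=np.array(groups, dtype=object),
            gm=np.vstack(rows_gm),
            wm=np.vstack(rows_wm),
            covariates=np.zeros((2, ds.covariates.shape[1])),
            cognition=np.zeros((2, ds.cognition.shape[1])),
            gm_names=ds.gm_names, wm_names=ds.wm_names,
            covariate_names=ds.covariate_names, cognition_names=ds.cognition_names,
        )
        scores = participant_scores(res, mean_ds)
        vals = scores.drop(columns=["participant_id", "group"]).to_numpy()
        np.testing.assert_allclose(vals, 0.0, atol=1e-10)

    def test_perturbing_gm_changes_only_gm_scores(self, small_planted_results):
        res = small_planted_results
        ds = res.dataset
        bumped = ds.subset(np.arange(ds.n))
        bumped.gm[0, 0] += 1.0
        s0 = participant_scores(res, ds)
        s1 = participant_scores(res, bumped)
        wm_cols = [c for c in s0.columns if c.startswith("wm_lv")]
        gm_cols = [c for c in s0.columns if c.startswith("gm_lv")]
        pd.testing.assert_frame_equal(s0[wm_cols], s1[wm_cols])
        assert not np.allclose(s0[gm_cols].iloc[0], s1[gm_cols].iloc[0])

    def test_in_sample_score_correlation_positive_for_planted(self, default_planted_results):
        res = default_planted_results
        scores = res.scores()
        for g in res.multiblock.groups:
            sub = scores[scores["group"] == g]
            r = np.corrcoef(sub["gm_lv1"], sub["wm_lv1"])[0, 1]
            assert r > 0.5

    def test_variable_name_mismatch(self, small_planted_results, toy_ds):
        with pytest.raises(AlignmentError):
            participant_scores(small_planted_results, toy_ds)


class TestPatternStrength:
    def test_sign_semantics_and_zero_rows(self):
        gm = np.array([0.5, 0.0])
        wm = np.array([-0.4, 0.3])
        P = pattern_strength(gm, wm)
        assert P[0, 0] == pytest.approx(-0.2)  # opposite-direction pairing
        np.testing.assert_array_equal(P[1], 0.0)

    def test_matches_elementwise_product(self):
        rng = np.random.default_rng(9)
        gm, wm = rng.normal(size=5), rng.normal(size=4)
        P = pattern_strength(gm, wm)
        for i in range(5):
            for j in range(4):
                assert P[i, j] == gm[i] * wm[j]
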