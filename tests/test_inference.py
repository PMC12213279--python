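"""Resampling inference: permutation, bootstrap, NSSD, convergence, CV."""

import numpy as np
import pandas as pd
import pytest

from mbplsc import (
    MBPLSC,
    AnalysisConfig,
    SyntheticConfig,
    bootstrap_saliences,
    generate_dataset,
    monte_carlo_cv,
    nssd,
    out_of_sample_projection,
    participant_scores,
    permutation_test,
)
from mbplsc._linalg import procrustes_rotation, rotate_svd
from mbplsc.exceptions import AlignmentError, ConfigError
from mbplsc.inference import convergence_trajectory
from mbplsc.model import MBPLSCResults, MultiblockMatrix


class TestProcrustes:
    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(10, 6))
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        V = Vt.T
        _, s_rot, V_rot = rotate_svd(U, s, V, V)
        np.testing.assert_allclose(s_rot, s, atol=1e-12)
        np.testing.assert_allclose(V_rot, V, atol=1e-12)

    def test_rotation_is_orthogonal(self):
        rng = np.random.default_rng(1)
        V1, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        V2, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        Q = procrustes_rotation(V1, V2)
        np.testing.assert_allclose(Q @ Q.T, np.eye(4), atol=1e-12)


class TestPermutation:
    def test_counting_convention_strong_signal(self, small_planted):
        """A planted coupling stronger than every permutation gives the
        minimum attainable p, (1)/(B+1)."""
        ds, _ = small_planted
        res = MBPLSC(ds, AnalysisConfig(seed=1)).fit()
        perm = permutation_test(ds, AnalysisConfig(seed=1), results=res,
                                n_permutations=99)
        assert perm.omnibus_p == pytest.approx(1 / 100)
        assert perm.component_p[0] == pytest.approx(1 / 100)
        assert perm.n_permutations == 99
        assert np.all(perm.component_p >= 1 / 100)

    def test_reproducible_under_seed(self, small_planted):
        ds, _ = small_planted
        p1 = permutation_test(ds, AnalysisConfig(), n_permutations=50, seed=3)
        p2 = permutation_test(ds, AnalysisConfig(), n_permutations=50, seed=3)
        assert p1.omnibus_p == p2.omnibus_p
        np.testing.assert_array_equal(p1.null_inertia, p2.null_inertia)
        np.testing.assert_array_equal(p1.component_p, p2.component_p)

    def test_invalid_b(self, small_planted):
        ds, _ = small_planted
        with pytest.raises(ConfigError):
            permutation_test(ds, AnalysisConfig(), n_permutations=0)

    def test_scheme_validated(self, small_planted):
        ds, _ = small_planted
        with pytest.raises(ConfigError):
            permutation_test(ds, AnalysisConfig(), n_permutations=10, scheme="bogus")


class TestBootstrap:
    def test_degenerate_two_iterations_flagged_unreliable(self, small_planted):
        ds, _ = small_planted
        boot = bootstrap_saliences(ds, AnalysisConfig(seed=2), n_bootstrap=2,
                                   components=[0])
        assert boot.unreliable
        t = boot.table
        assert (t["ci_lower"] <= t["ci_upper"]).all()

    def test_ci_flags_consistent_with_bounds(self, small_planted):
        ds, _ = small_planted
        boot = bootstrap_saliences(ds, AnalysisConfig(seed=2), n_bootstrap=150,
                                   components=[0, 1])
        t = boot.table
        excludes = (t["ci_lower"] > 0) | (t["ci_upper"] < 0)
        assert (t["significant"] == excludes).all()
        assert not boot.unreliable

    def test_recovers_zero_and_nonzero_loadings(self):
        """Significance flags: specificity >= 90% on planted-zero entries,
        sensitivity >= 80% on strong planted entries.

        A single planted component keeps the zero pattern of the population
        salience identical to the zero pattern of the raw loadings (no
        component mixing), so the flags have an exact ground truth.
        """
        cfg = SyntheticConfig(
            n_per_group=40, p=16, q=12, seed=23, shared_effect=2.5,
            diff_effect=0.0, noise_sd=0.4, sparsity=0.4,
            age_effect=0.0, cognition_link=(0.0, 0.0),
        )
        ds, gt = generate_dataset(cfg)
        res = MBPLSC(ds, AnalysisConfig(seed=23)).fit()
        boot = bootstrap_saliences(ds, AnalysisConfig(seed=23), results=res,
                                   n_bootstrap=300, components=[0])
        spec_n = spec_hit = sens_n = sens_hit = 0
        for margin, block, w_true, names, groups in (
            ("col", "wm", gt.loadings["w_wm_sh"], res.multiblock.wm_names, [None]),
            ("row", "gm", gt.loadings["w_gm_sh"], res.multiblock.gm_names,
             res.multiblock.groups),
        ):
            strong = np.abs(w_true) > 0.5 * np.abs(w_true).max()
            for g in groups:
                mask = boot.significant_mask(margin, 0, group=g, block=block)
                for j, name in enumerate(names):
                    if w_true[j] == 0:
                        spec_n += 1
                        spec_hit += not mask[name]
                    elif strong[j]:
                        sens_n += 1
                        sens_hit += bool(mask[name])
        assert spec_n >= 10 and sens_n >= 10
        assert spec_hit / spec_n >= 0.9
        assert sens_hit / sens_n >= 0.8

    def test_reproducible_under_seed(self, small_planted):
        ds, _ = small_planted
        b1 = bootstrap_saliences(ds, AnalysisConfig(), n_bootstrap=30, seed=5,
                                 components=[0])
        b2 = bootstrap_saliences(ds, AnalysisConfig(), n_bootstrap=30, seed=5,
                                 components=[0])
        pd.testing.assert_frame_equal(b1.table, b2.table)


class TestNSSD:
    @staticmethod
    def _stub_results(gm1, gm2):
        p = len(gm1)
        M = np.zeros((2 * p, 2))
        U = np.zeros((2 * p, 2))
        U[:p, 0] = gm1
        U[p:, 0] = gm2
        mb = MultiblockMatrix(
            M=M, groups=["A", "B"],
            gm_names=[f"g{i}" for i in range(p)], wm_names=["w0", "w1"],
            cov_row_names=[], cov_col_names=[], group_stats={},
        )
        return MBPLSCResults(
            multiblock=mb, U=U, singular_values=np.array([1.0, 0.5]),
            V=np.zeros((2, 2)), xi=np.array([80.0, 20.0]),
            block_contributions=pd.DataFrame(),
        )

    def test_hand_computed_toy_case(self):
        res = self._stub_results([0.6, 0.8], [0.8, 0.6])
        out = nssd(res, 0)
        np.testing.assert_allclose(out.to_numpy(), [-0.2, 0.2], atol=1e-12)

    def test_zero_at_equality(self):
        res = self._stub_results([0.3, 0.4], [0.3, 0.4])
        np.testing.assert_allclose(nssd(res, 0).to_numpy(), 0.0, atol=1e-15)

    def test_antisymmetric_under_group_swap(self):
        res = self._stub_results([0.6, 0.8], [0.1, -0.9])
        fwd = nssd(res, 0, ("A", "B")).to_numpy()
        rev = nssd(res, 0, ("B", "A")).to_numpy()
        np.testing.assert_allclose(fwd, -rev, atol=1e-15)

    def test_unknown_group_label(self):
        res = self._stub_results([0.6, 0.8], [0.8, 0.6])
        with pytest.raises(AlignmentError):
            nssd(res, 0, ("A", "C"))

    def test_fitted_model_antisymmetry(self, small_planted_results):
        fwd = nssd(small_planted_results, 0, ("HC", "ROP"))
        rev = nssd(small_planted_results, 0, ("ROP", "HC"))
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)


class TestConvergence:
    def test_boundary_all_variables_finite(self, small_planted):
        ds, _ = small_planted
        traj = convergence_trajectory(
            ds, AnalysisConfig(), components=[0], n_min=35, n_orderings=2, seed=4
        )
        assert list(traj.n_grid) == [35, 36, 37, 38, 39]
        assert np.isfinite(traj.diffs[0].to_numpy()).all()

    def test_noiseless_trajectory_near_zero(self):
        cfg = SyntheticConfig(
            n_per_group=30, p=6, q=5, seed=13, shared_effect=1.0, diff_effect=0.0,
            noise_sd=1e-8, sparsity=1.0, age_effect=0.0, sex_tiv_effect=0.0,
            cognition_link=(0.0, 0.0),
        )
        ds, _ = generate_dataset(cfg)
        acfg = AnalysisConfig(covariates_rows=[], covariates_cols=[])
        traj = convergence_trajectory(ds, acfg, components=[0], n_min=10,
                                      n_orderings=2, seed=1)
        # deterministic data: the leading salience does not move with n
        assert traj.mean_trajectory(0).max() < 1e-6

    def test_planted_signal_stabilises_with_n(self, small_planted):
        ds, _ = small_planted
        traj = convergence_trajectory(ds, AnalysisConfig(), components=[0],
                                      n_min=8, n_orderings=4, seed=2)
        m = traj.mean_trajectory(0)
        assert m.loc[35] < m.loc[8]

    def test_n_min_too_small_rejected(self, small_planted):
        ds, _ = small_planted
        with pytest.raises(ConfigError):
            convergence_trajectory(ds, AnalysisConfig(), n_min=3)


class TestCrossValidation:
    def test_single_split_summary(self, small_planted):
        ds, _ = small_planted
        cv = monte_carlo_cv(ds, AnalysisConfig(seed=3), component=0, n_splits=1,
                            train_fraction=0.75)
        assert cv.n_splits == 1
        assert np.isnan(cv.summary["sd_r"]).all()
        assert cv.summary["generalisable"].isna().all() or (
            cv.summary["generalisable"] == None  # noqa: E711
        ).all()
        pd.testing.assert_frame_equal(
            cv.summary[["mean_r"]],
            cv.splits.groupby("group")[["r"]].mean().rename(columns={"r": "mean_r"}),
            check_names=False,
        )

    def test_planted_coupling_generalises(self, small_planted):
        ds, _ = small_planted
        cv = monte_carlo_cv(ds, AnalysisConfig(seed=3), component=0, n_splits=20,
                            train_fraction=0.75)
        assert (cv.summary["mean_r"] > 0.5).all()
        assert cv.summary["generalisable"].all()

    def test_infeasible_split_rejected(self, small_planted):
        ds, _ = small_planted
        with pytest.raises(ConfigError):
            monte_carlo_cv(ds, AnalysisConfig(), component=0, n_splits=2,
                           train_fraction=0.95)

    def test_correlations_bounded(self, small_planted):
        ds, _ = small_planted
        cv = monte_carlo_cv(ds, AnalysisConfig(seed=9), component=0, n_splits=5)
        assert cv.splits["r"].between(-1, 1).all()


class TestOutOfSample:
    def test_projecting_training_set_reproduces_scores(self, small_planted_results):
        res = small_planted_results
        ds = res.dataset
        s_in = participant_scores(res)
        s_proj = participant_scores(res, ds)
        num_cols = [c for c in s_in.columns if c.startswith(("gm_", "wm_"))]
        np.testing.assert_allclose(
            s_in[num_cols].to_numpy(), s_proj[num_cols].to_numpy(), atol=1e-12
        )

    def test_heldout_cohort_recovers_planted_sign(self, small_planted_results):
        res = small_planted_results
        cfg = SyntheticConfig(
            n_per_group=40, p=12, q=8, seed=7, age_effect=0.0,
            cognition_link=(0.0, 0.0),
        )
        held, _ = generate_dataset(cfg.replace(participant_seed=99))
        out = out_of_sample_projection(res, held, component=0)
        assert (out["r"] > 0.3).all()

    def test_variable_mismatch_raises(self, small_planted_results, toy_ds):
        with pytest.raises(AlignmentError):
            out_of_sample_projection(small_planted_results, toy_ds)
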