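"""Resampling inference for MB-PLS-C: permutation, bootstrap, NSSD, CV.

Significance of the decomposition is assessed non-parametrically. The
omnibus permutation test shuffles participant rows of the WM block within
each group (breaking GM–WM and covariate–WM coupling while preserving
GM–covariate structure), refits the multiblock matrix, and compares total
inertia ||M||²_F; per-component p-values compare singular values after
orthogonal-Procrustes alignment of the permuted solution to the observed
one. Bootstrap confidence intervals for saliences resample participants with
replacement within group and align each replicate the same way before
accumulating distributions. All p-values follow the (1 + #extreme)/(1 + B)
convention, so p >= 1/(B+1) always.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._linalg import (
    match_components,
    procrustes_rotation,
    standardize,
    tucker_congruence,
)
from .datasets import AnalysisConfig, FeatureDataset
from .exceptions import AlignmentError, ConfigError, ZeroVarianceError
from .model import MBPLSC, MBPLSCResults, participant_scores

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "ConvergenceTrajectory",
    "CVResult",
    "permutation_test",
    "bootstrap_saliences",
    "nssd",
    "convergence_trajectory",
    "monte_carlo_cv",
    "out_of_sample_projection",
]


# ---------------------------------------------------------------------------
# shared internals


def _group_z(ds: FeatureDataset, config: AnalysisConfig):
    """Per-group standardized blocks (rank-transformed first for Spearman)."""
    from .model import _group_arrays, _rank_columns

    cov_rows, cov_cols, ridx, cidx = _group_arrays(ds, config)
    out = {}
    for g in ds.group_labels:
        mask = ds.group == g
        gm, wm = ds.gm[mask], ds.wm[mask]
        zr, zc = ds.covariates[mask][:, ridx], ds.covariates[mask][:, cidx]
        if config.corr_method == "spearman":
            gm, wm = _rank_columns(gm), _rank_columns(wm)
            zr, zc = _rank_columns(zr), _rank_columns(zc)
        n = gm.shape[0]
        Zgm, _, _ = standardize(gm, ds.gm_names, f"gm, group {g!r}")
        Zwm, _, _ = standardize(wm, ds.wm_names, f"wm, group {g!r}")
        Zr = standardize(zr, cov_rows)[0] if len(cov_rows) else np.empty((n, 0))
        Zc = standardize(zc, cov_cols)[0] if len(cov_cols) else np.empty((n, 0))
        out[g] = {"gm": Zgm, "wm": Zwm, "cov_r": Zr, "cov_c": Zc, "n": n}
    return out


def _assemble_from_z(zs: dict, groups: list, include_cov_cov: bool) -> np.ndarray:
    blocks = []
    for g in groups:
        z = zs[g]
        n = z["n"]
        p, q = z["gm"].shape[1], z["wm"].shape[1]
        cr, cc = z["cov_r"].shape[1], z["cov_c"].shape[1]
        A = z["gm"].T @ z["wm"] / (n - 1)
        B = z["gm"].T @ z["cov_c"] / (n - 1) if cc else np.empty((p, 0))
        D = z["cov_r"].T @ z["wm"] / (n - 1) if cr else np.empty((0, q))
        if cr and cc:
            E = (
                z["cov_r"].T @ z["cov_c"] / (n - 1)
                if include_cov_cov
                else np.zeros((cr, cc))
            )
        else:
            E = np.empty((cr, cc))
        blocks.append(np.block([[A, B], [D, E]]))
    return np.vstack(blocks)


def _ensure_results(ds, config, results) -> MBPLSCResults:
    if results is not None:
        return results
    return MBPLSC(ds, config).fit()


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    """Omnibus and per-component permutation p-values with null distributions."""

    omnibus_p: float
    component_p: np.ndarray
    n_permutations: int
    scheme: str
    observed_inertia: float
    observed_singular: np.ndarray
    null_inertia: np.ndarray = field(repr=False)
    null_singular: np.ndarray = field(repr=False)  # B × K, Procrustes-aligned

    def significant_components(self, alpha: float = 0.05) -> list:
        return [i for i, p in enumerate(self.component_p) if p <= alpha]


def permutation_test(
    ds: FeatureDataset,
    config: Optional[AnalysisConfig] = None,
    results: Optional[MBPLSCResults] = None,
    n_permutations: Optional[int] = None,
    seed: Optional[int] = None,
    scheme: Optional[str] = None,
) -> PermutationResult:
    """Permutation significance of the overall pattern and each component.

    Rows of the permuted side are shuffled *within group*; the multiblock
    matrix is refit for every permutation. Omnibus statistic: total inertia
    ||M||²_F (= Σσ²). Per-component statistic: singular values of the
    permuted solution after Procrustes alignment to the observed one.
    """
    config = config or AnalysisConfig()
    B = int(n_permutations if n_permutations is not None else config.n_permutations)
    if B < 1:
        raise ConfigError("n_permutations must be >= 1")
    scheme = scheme or config.permutation_scheme
    if scheme not in ("permute_wm", "permute_gm", "both"):
        raise ConfigError(f"unknown permutation scheme {scheme!r}")
    results = _ensure_results(ds, config, results)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    zs = _group_z(ds, config)
    groups = ds.group_labels
    M_obs = _assemble_from_z(zs, groups, config.include_cov_cov)
    obs_inertia = float((M_obs**2).sum())
    obs_s = results.singular_values
    K = len(obs_s)
    V_ref = results.V

    null_inertia = np.empty(B)
    null_singular = np.empty((B, K))
    for b in range(B):
        perm_zs = {}
        for g in groups:
            z = dict(zs[g])
            if scheme in ("permute_wm", "both"):
                idx = rng.permutation(z["n"])
                z["wm"] = z["wm"][idx]
            if scheme in ("permute_gm", "both"):
                idx = rng.permutation(z["n"])
                z["gm"] = z["gm"][idx]
            perm_zs[g] = z
        M_b = _assemble_from_z(perm_zs, groups, config.include_cov_cov)
        null_inertia[b] = (M_b**2).sum()
        U_b, s_b, Vt_b = np.linalg.svd(M_b, full_matrices=False)
        Q = procrustes_rotation(V_ref, Vt_b.T)
        null_singular[b] = np.linalg.norm((U_b * s_b) @ Q, axis=0)

    omnibus_p = float((1 + (null_inertia >= obs_inertia).sum()) / (B + 1))
    comp_p = (1 + (null_singular >= obs_s).sum(axis=0)) / (B + 1)
    return PermutationResult(
        omnibus_p=omnibus_p,
        component_p=comp_p,
        n_permutations=B,
        scheme=scheme,
        observed_inertia=obs_inertia,
        observed_singular=obs_s.copy(),
        null_inertia=null_inertia,
        null_singular=null_singular,
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Per-salience bootstrap SDs, percentile CIs and significance flags.

    ``table`` has one row per (margin, group, block, variable, component)
    salience entry. A flag is set when the CI excludes zero. ``unreliable``
    marks runs with fewer than 100 retained iterations.
    """

    table: pd.DataFrame
    n_iterations: int
    n_discarded: int
    unreliable: bool
    alpha: float

    @property
    def discard_warning(self) -> bool:
        total = self.n_iterations + self.n_discarded
        return total > 0 and self.n_discarded / total > 0.01

    def significant_mask(
        self, margin: str, component: int, group=None, block=None
    ) -> pd.Series:
        t = self.table
        sel = (t["margin"] == margin) & (t["component"] == component)
        if group is not None:
            sel &= t["group"] == group
        if block is not None:
            sel &= t["block"] == block
        sub = t[sel]
        return pd.Series(sub["significant"].to_numpy(), index=sub["variable"].to_numpy())


def bootstrap_saliences(
    ds: FeatureDataset,
    config: Optional[AnalysisConfig] = None,
    results: Optional[MBPLSCResults] = None,
    n_bootstrap: Optional[int] = None,
    seed: Optional[int] = None,
    components: Optional[list] = None,
) -> BootstrapResult:
    """Bootstrap salience distributions with component alignment.

    Participants are resampled with replacement within group; each replicate
    is refit and aligned to the original solution by maximal-|Tucker
    congruence| component matching with sign flips (a signed-permutation
    orthogonal alignment — an unrestricted Procrustes rotation would absorb
    sampling variability and understate the CIs) before its saliences enter
    the distributions. Replicates containing a zero-variance column are
    discarded and counted. Percentile CIs at level ``1 - config.alpha``.
    """
    config = config or AnalysisConfig()
    B = int(n_bootstrap if n_bootstrap is not None else config.n_bootstrap)
    if B < 1:
        raise ConfigError("n_bootstrap must be >= 1")
    results = _ensure_results(ds, config, results)
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)

    mb = results.multiblock
    K = results.n_components
    comps = np.array(
        list(range(K)) if components is None else list(components), dtype=int
    )
    ref_stacked = results.stacked_saliences()
    masks = {g: np.flatnonzero(ds.group == g) for g in ds.group_labels}

    U_dist = np.empty((B, mb.M.shape[0], len(comps)))
    V_dist = np.empty((B, mb.M.shape[1], len(comps)))
    kept = 0
    discarded = 0
    while kept < B:
        idx = np.concatenate(
            [rng.choice(masks[g], size=len(masks[g]), replace=True)
             for g in ds.group_labels]
        )
        boot = FeatureDataset(  # fresh ids: resampling duplicates participants
            participant_id=[f"b{i}" for i in range(len(idx))],
            group=ds.group[idx],
            gm=ds.gm[idx],
            wm=ds.wm[idx],
            covariates=ds.covariates[idx],
            cognition=ds.cognition[idx],
            gm_names=list(ds.gm_names),
            wm_names=list(ds.wm_names),
            covariate_names=list(ds.covariate_names),
            cognition_names=list(ds.cognition_names),
        )
        try:
            zs = _group_z(boot, config)
        except ZeroVarianceError:
            discarded += 1
            if discarded > 100 * B:
                raise
            continue
        M_b = _assemble_from_z(zs, boot.group_labels, config.include_cov_cov)
        U_b, s_b, Vt_b = np.linalg.svd(M_b, full_matrices=False)
        V_b = Vt_b.T
        # orthogonal alignment restricted to component matching + sign flips
        # (a signed-permutation Procrustes): an unrestricted rotation absorbs
        # genuine sampling variability into the alignment and yields CIs that
        # are too narrow
        st = np.vstack([U_b, V_b])
        index, sign = match_components(ref_stacked, st)
        U_dist[kept] = U_b[:, index[comps]] * sign[comps]
        V_dist[kept] = V_b[:, index[comps]] * sign[comps]
        kept += 1

    lo_q, hi_q = 100 * config.alpha / 2, 100 * (1 - config.alpha / 2)
    rows = []
    row_map, col_map = mb.row_map(), mb.col_map()
    for ci, comp in enumerate(comps):
        for margin, entries, est_mat, dist in (
            ("row", row_map, results.U, U_dist),
            ("col", col_map, results.V, V_dist),
        ):
            est = est_mat[:, comp]
            sd = dist[:, :, ci].std(axis=0, ddof=1) if B > 1 else np.full(len(est), np.nan)
            lo = np.percentile(dist[:, :, ci], lo_q, axis=0)
            hi = np.percentile(dist[:, :, ci], hi_q, axis=0)
            for r, entry in enumerate(entries):
                if margin == "row":
                    group, block, var = entry
                else:
                    group, (block, var) = None, entry
                rows.append(
                    {
                        "margin": margin,
                        "group": group,
                        "block": block,
                        "variable": var,
                        "component": comp,
                        "estimate": est[r],
                        "boot_sd": sd[r],
                        "ci_lower": lo[r],
                        "ci_upper": hi[r],
                        "significant": bool((lo[r] > 0) or (hi[r] < 0)),
                    }
                )
    return BootstrapResult(
        table=pd.DataFrame(rows),
        n_iterations=kept,
        n_discarded=discarded,
        unreliable=kept < 100,
        alpha=config.alpha,
    )


# ---------------------------------------------------------------------------
# NSSD


def nssd(results: MBPLSCResults, component: int, group_pair=None) -> pd.Series:
    """Normalised between-group structural salience difference for one LV.

    Each group's GM salience subvector is L2-normalised, then subtracted
    entrywise (first minus second): positive values mean the salience is
    larger in the first group. Exactly antisymmetric under swapping the
    group order, and zero when the subvectors coincide.
    """
    mb = results.multiblock
    if group_pair is None:
        group_pair = tuple(mb.groups[:2])
    g1, g2 = group_pair
    for g in (g1, g2):
        if g not in mb.groups:
            raise AlignmentError(f"unknown group label {g!r}; groups: {mb.groups}")
    v1 = results.gm_saliences(g1).to_numpy()[:, component].astype(float)
    v2 = results.gm_saliences(g2).to_numpy()[:, component].astype(float)

    def _norm(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    out = pd.Series(_norm(v1) - _norm(v2), index=mb.gm_names, name=f"LV{component + 1}")
    out.attrs["group_pair"] = (g1, g2)
    return out


# ---------------------------------------------------------------------------
# convergence trajectories


@dataclass
class ConvergenceTrajectory:
    """|salience(n+1) − salience(n)| per variable, averaged over orderings.

    ``diffs`` maps component index → DataFrame (rows indexed by n, the
    smaller of the two sample sizes per group; columns labelled
    'group:block:variable' for the GM margin and 'block:variable' for the
    shared margin).
    """

    diffs: dict
    n_grid: np.ndarray
    n_orderings: int

    def mean_trajectory(self, component: int) -> pd.Series:
        return self.diffs[component].mean(axis=1)


def convergence_trajectory(
    ds: FeatureDataset,
    config: Optional[AnalysisConfig] = None,
    results: Optional[MBPLSCResults] = None,
    components: Optional[list] = None,
    n_min: Optional[int] = None,
    n_orderings: Optional[int] = None,
    seed: Optional[int] = None,
) -> ConvergenceTrajectory:
    """Salience stability as the per-group sample size n grows.

    For each of R seeded participant orderings the model is refit on the
    first n participants per group, n = n_min..N; subsample components are
    matched to the full-sample solution by maximal |Tucker congruence| (with
    sign alignment) and the absolute change of every salience between
    consecutive n is recorded, then averaged over orderings.
    """
    config = config or AnalysisConfig()
    n_min = int(n_min if n_min is not None else config.n_min)
    R = int(n_orderings if n_orderings is not None else config.n_orderings)
    if n_min < 5:
        raise ConfigError("n_min must be >= 5 for stable correlations")
    N = min(ds.group_sizes().values())
    if n_min >= N:
        raise ConfigError(f"n_min={n_min} must be < smallest group size {N}")
    results = _ensure_results(ds, config, results)
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)

    mb = results.multiblock
    K = results.n_components
    comps = list(range(K)) if components is None else list(components)
    ref = results.stacked_saliences()
    labels = [f"{g}:{b}:{v}" for g, b, v in mb.row_map()] + [
        f"{b}:{v}" for b, v in mb.col_map()
    ]
    n_grid = np.arange(n_min, N)  # diff between n and n+1
    acc = {c: np.zeros((len(n_grid), len(labels))) for c in comps}
    counts = np.zeros(len(n_grid))

    group_idx = {g: np.flatnonzero(ds.group == g) for g in ds.group_labels}
    for _ in range(R):
        order = {g: rng.permutation(idx) for g, idx in group_idx.items()}
        prev = None
        for n in range(n_min, N + 1):
            take = np.concatenate([order[g][:n] for g in ds.group_labels])
            sub = ds.subset(np.sort(take))
            try:
                sub_res = MBPLSC(sub, config).fit()
            except ZeroVarianceError:
                # e.g. a binary covariate constant in a small subsample;
                # this n is skipped for this ordering
                prev = None
                continue
            stacked = sub_res.stacked_saliences()
            index, sign = match_components(ref, stacked)
            cur = stacked[:, index] * sign
            if prev is not None:
                for c in comps:
                    acc[c][n - n_min - 1] += np.abs(cur[:, c] - prev[:, c])
                counts[n - n_min - 1] += 1
            prev = cur
    with np.errstate(invalid="ignore", divide="ignore"):
        diffs = {
            c: pd.DataFrame(
                np.where(counts[:, None] > 0, acc[c] / counts[:, None], np.nan),
                index=n_grid,
                columns=labels,
            )
            for c in comps
        }
    return ConvergenceTrajectory(diffs=diffs, n_grid=n_grid, n_orderings=R)


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation and out-of-sample projection


@dataclass
class CVResult:
    """Out-of-sample GM–WM score correlations per split and their summary."""

    splits: pd.DataFrame  # columns: split, group, r, p, n_test
    summary: pd.DataFrame  # per group: mean_r, sd_r, generalisable
    component: int
    n_splits: int
    train_fraction: Optional[float] = None


def monte_carlo_cv(
    ds: FeatureDataset,
    config: Optional[AnalysisConfig] = None,
    results: Optional[MBPLSCResults] = None,
    component: int = 0,
    n_splits: Optional[int] = None,
    train_fraction: Optional[float] = None,
    seed: Optional[int] = None,
    match_to_reference: bool = False,
) -> CVResult:
    """Monte Carlo cross-validation of one latent component.

    Each split refits the model on a random train fraction per group,
    projects the held-out participants with the training groups' means/SDs,
    and correlates their GM and WM latent scores per group. ``component``
    indexes the training solution (singular-value order); with
    ``match_to_reference=True`` it instead indexes the full-sample solution
    and each split's components are matched to it by Tucker congruence —
    useful for tracking a labelled component, but mildly optimistic under
    the null because held-out participants contributed to the reference.
    The 'generalisable' flag marks groups whose across-split mean correlation
    has a normal-theory 95 % interval excluding zero.
    """
    config = config or AnalysisConfig()
    S = int(n_splits if n_splits is not None else config.n_splits)
    frac = float(train_fraction if train_fraction is not None else config.train_fraction)
    if not (0 < frac < 1):
        raise ConfigError("train_fraction must lie in (0, 1)")
    results = _ensure_results(ds, config, results)
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)

    sizes = ds.group_sizes()
    for g, n_g in sizes.items():
        n_tr = int(round(frac * n_g))
        if n_tr < 5 or n_g - n_tr < 5:
            raise ConfigError(
                f"split infeasible for group {g!r}: train={n_tr}, test={n_g - n_tr}"
            )
    ref = results.stacked_saliences()
    group_idx = {g: np.flatnonzero(ds.group == g) for g in ds.group_labels}

    rows = []
    for s_i in range(S):
        tr_idx, te_idx = [], []
        for g, idx in group_idx.items():
            perm = rng.permutation(idx)
            n_tr = int(round(frac * len(idx)))
            tr_idx.append(perm[:n_tr])
            te_idx.append(perm[n_tr:])
        train = ds.subset(np.sort(np.concatenate(tr_idx)))
        test = ds.subset(np.sort(np.concatenate(te_idx)))
        tr_res = MBPLSC(train, config).fit()
        if match_to_reference:
            index, _ = match_components(ref, tr_res.stacked_saliences())
            comp = int(index[component])
        else:
            comp = int(component)
        scores = participant_scores(tr_res, test)
        for g in ds.group_labels:
            sub = scores[scores["group"] == g]
            r, p = sstats.pearsonr(sub[f"gm_lv{comp + 1}"], sub[f"wm_lv{comp + 1}"])
            rows.append({"split": s_i, "group": g, "r": float(r), "p": float(p),
                         "n_test": len(sub)})

    splits = pd.DataFrame(rows)
    summ = []
    for g in ds.group_labels:
        rs = splits.loc[splits["group"] == g, "r"].to_numpy()
        mean_r = float(rs.mean())
        sd_r = float(rs.std(ddof=1)) if len(rs) > 1 else np.nan
        if np.isnan(sd_r):
            gen = None
        else:
            half = 1.96 * sd_r / np.sqrt(len(rs))
            gen = bool(abs(mean_r) > half)
        summ.append({"group": g, "mean_r": mean_r, "sd_r": sd_r, "generalisable": gen})
    return CVResult(
        splits=splits,
        summary=pd.DataFrame(summ).set_index("group"),
        component=component,
        n_splits=S,
        train_fraction=frac,
    )


def out_of_sample_projection(
    results: MBPLSCResults,
    new_ds: FeatureDataset,
    component: int = 0,
) -> pd.DataFrame:
    """Project a held-out cohort onto trained saliences and correlate scores.

    New participants are standardized with the *training* groups' means/SDs,
    so projecting the training set itself reproduces in-sample scores
    exactly. Returns per-group r, p and n for the requested component.
    """
    scores = participant_scores(results, new_ds)
    rows = []
    for g in new_ds.group_labels:
        sub = scores[scores["group"] == g]
        r, p = sstats.pearsonr(sub[f"gm_lv{component + 1}"], sub[f"wm_lv{component + 1}"])
        rows.append({"group": g, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows).set_index("group")


def congruence_with_truth(results: MBPLSCResults, ground_truth, component_map=None):
    """Tucker congruences between fitted components and planted ground truth.

    Builds the planted stacked salience vector for each ground-truth
    component (per-group GM polarity included, covariate rows zero), matches
    fitted components by maximal |congruence| and reports, per truth
    component: the matched index, the stacked congruence, per-group GM
    congruences and the WM congruence (all sign-aligned to the match).
    """
    mb = results.multiblock
    names = list(ground_truth.wm_saliences)
    stacked_truth = np.zeros((mb.M.shape[0] + mb.M.shape[1], len(names)))
    for k, comp in enumerate(names):
        for g in mb.groups:
            stacked_truth[mb.row_slice(g, "gm"), k] = ground_truth.gm_saliences[g][comp]
        col0 = mb.M.shape[0]
        wm_sl = mb.col_slice("wm")
        stacked_truth[col0 + wm_sl.start : col0 + wm_sl.stop, k] = (
            ground_truth.wm_saliences[comp]
        )
    fitted = results.stacked_saliences()
    index, sign = match_components(stacked_truth, fitted)
    out = {}
    for k, comp in enumerate(names):
        i = int(index[k])
        rec = {"matched_component": i, "sign": float(sign[k])}
        rec["stacked"] = abs(tucker_congruence(stacked_truth[:, k], fitted[:, i]))
        for g in mb.groups:
            sl = mb.row_slice(g, "gm")
            rec[f"gm_{g}"] = tucker_congruence(
                ground_truth.gm_saliences[g][comp], sign[k] * results.U[sl, i]
            )
        rec["wm"] = tucker_congruence(
            ground_truth.wm_saliences[comp],
            sign[k] * results.V[mb.col_slice("wm"), i],
        )
        g1, g2 = mb.groups[:2]
        sl1, sl2 = mb.row_slice(g1, "gm"), mb.row_slice(g2, "gm")
        rec["cross_group_gm"] = tucker_congruence(results.U[sl1, i], results.U[sl2, i])
        out[comp] = rec
    return out
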