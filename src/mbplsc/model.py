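"""Multiblock PLS correlation: matrix assembly, decomposition, scores.

The method couples a grey-matter morphometry block X (n × p per group) to a
white-matter block Y (n × q) while carrying nuisance covariates Z (age, sex,
TIV) as blocks of their own. Within each group g the data are z-scored and
four Pearson correlation blocks are formed::

    A_g = corr(X_g, Y_g)   (p × q)     B_g = corr(X_g, Z_g)   (p × c)
    D_g = corr(Z_g, Y_g)   (c × q)     E_g = corr(Z_g, Z_g)   (c × c)

arranged as the row block [[A_g, B_g], [D_g, E_g]] and stacked vertically
over groups into M of shape G·(p+c) × (q+c). A singular value decomposition
M = U diag(σ) Vᵀ yields latent components: rows of U carry group-specific GM
saliences (plus covariate saliences), rows of V carry WM saliences shared
across groups. Because the GM margin is group-stacked, same-polarity GM
saliences across groups indicate a shared GM–WM correlation pattern and
opposite polarity a group-differentiating one; the product of a GM and a WM
salience gives the strength and direction of that variable pair's coupling.

Explained covariance per component is ξ_i = 100·σ_i²/Σ_j σ_j², and the signed
percentage of σ_i arising from each cross-block (GM–WM, GM–cov, cov–WM,
cov–cov) is u_iᵀ M_B v_i / σ_i restricted to that block's rows and columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from ._linalg import apply_standardize, fix_svd_signs, standardize
from .datasets import AnalysisConfig, FeatureDataset
from .exceptions import AlignmentError, MbplscError, ValidationError

__all__ = [
    "correlation_block",
    "assemble_multiblock",
    "fit_mbplsc",
    "participant_scores",
    "pattern_strength",
    "MultiblockMatrix",
    "MBPLSC",
    "MBPLSCResults",
]


def correlation_block(
    X: np.ndarray,
    Y: np.ndarray,
    xnames: Optional[Sequence[str]] = None,
    ynames: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Pearson cross-correlation matrix between the columns of X and Y.

    Entry (i, j) is the correlation of column i of X with column j of Y.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"row mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    if X.shape[0] < 4:
        raise ValidationError(f"need >= 4 rows for correlation, got {X.shape[0]}")
    Zx, _, _ = standardize(X, names=xnames, context="X")
    Zy, _, _ = standardize(Y, names=ynames, context="Y")
    return Zx.T @ Zy / (X.shape[0] - 1)


@dataclass
class MultiblockMatrix:
    """Group-stacked multiblock correlation matrix with index bookkeeping."""

    M: np.ndarray
    groups: list
    gm_names: list
    wm_names: list
    cov_row_names: list  # covariates on the row (GM) margin, pairing with WM
    cov_col_names: list  # covariates on the column (WM) margin, pairing with GM
    group_stats: dict  # group -> dict of mean/sd arrays used for z-scoring
    include_cov_cov: bool = True
    corr_method: str = "pearson"

    @property
    def p(self) -> int:
        return len(self.gm_names)

    @property
    def q(self) -> int:
        return len(self.wm_names)

    @property
    def c_rows(self) -> int:
        return len(self.cov_row_names)

    @property
    def c_cols(self) -> int:
        return len(self.cov_col_names)

    @property
    def block_height(self) -> int:
        return self.p + self.c_rows

    def row_slice(self, group, part: str = "gm") -> slice:
        g = self.groups.index(group)
        base = g * self.block_height
        if part == "gm":
            return slice(base, base + self.p)
        if part == "cov":
            return slice(base + self.p, base + self.block_height)
        raise ValueError(part)

    def col_slice(self, part: str = "wm") -> slice:
        if part == "wm":
            return slice(0, self.q)
        if part == "cov":
            return slice(self.q, self.q + self.c_cols)
        raise ValueError(part)

    def row_map(self) -> list:
        """(group, block, variable) per stacked row."""
        out = []
        for g in self.groups:
            out += [(g, "gm", v) for v in self.gm_names]
            out += [(g, "cov", v) for v in self.cov_row_names]
        return out

    def col_map(self) -> list:
        return [("wm", v) for v in self.wm_names] + [
            ("cov", v) for v in self.cov_col_names
        ]


def _group_arrays(ds: FeatureDataset, config: AnalysisConfig):
    """Per-group (GM, WM, cov_rows, cov_cols) raw arrays and name lists."""
    cov_rows = (
        list(config.covariates_rows)
        if config.covariates_rows is not None
        else list(ds.covariate_names)
    )
    cov_cols = (
        list(config.covariates_cols)
        if config.covariates_cols is not None
        else list(ds.covariate_names)
    )
    for name in cov_rows + cov_cols:
        if name not in ds.covariate_names:
            raise AlignmentError(f"covariate {name!r} not in dataset")
    ridx = [ds.covariate_names.index(n) for n in cov_rows]
    cidx = [ds.covariate_names.index(n) for n in cov_cols]
    return cov_rows, cov_cols, ridx, cidx


def _rank_columns(X: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(_sstats.rankdata, 0, X) if X.size else X


def assemble_multiblock(
    ds: FeatureDataset, config: Optional[AnalysisConfig] = None
) -> MultiblockMatrix:
    """Build the group-stacked multiblock correlation matrix from a dataset.

    Data are standardized within group; correlation blocks therefore reflect
    within-group covariation only. With no covariates the matrix reduces to
    the stacked GM–WM correlation blocks [A_1; ...; A_G]. With Spearman
    correlation selected, columns are rank-transformed within group first.
    """
    config = config or AnalysisConfig()
    cov_rows, cov_cols, ridx, cidx = _group_arrays(ds, config)
    p, q = len(ds.gm_names), len(ds.wm_names)
    cr, cc = len(cov_rows), len(cov_cols)

    blocks, stats = [], {}
    for g in ds.group_labels:
        mask = ds.group == g
        if mask.sum() < 4:
            raise ValidationError(f"group {g!r} has n={int(mask.sum())} < 4")
        gm, wm = ds.gm[mask], ds.wm[mask]
        zr, zc = ds.covariates[mask][:, ridx], ds.covariates[mask][:, cidx]
        if config.corr_method == "spearman":
            gm, wm = _rank_columns(gm), _rank_columns(wm)
            zr, zc = _rank_columns(zr), _rank_columns(zc)
        n = gm.shape[0]
        Zgm, m_gm, s_gm = standardize(gm, ds.gm_names, f"gm, group {g!r}")
        Zwm, m_wm, s_wm = standardize(wm, ds.wm_names, f"wm, group {g!r}")
        Zr = Zc = np.empty((n, 0))
        if cr:
            Zr, _, _ = standardize(zr, cov_rows, f"covariates, group {g!r}")
        if cc:
            Zc, _, _ = standardize(zc, cov_cols, f"covariates, group {g!r}")
        stats[g] = {"gm_mean": m_gm, "gm_sd": s_gm, "wm_mean": m_wm, "wm_sd": s_wm, "n": n}

        A = Zgm.T @ Zwm / (n - 1)
        B = Zgm.T @ Zc / (n - 1) if cc else np.empty((p, 0))
        D = Zr.T @ Zwm / (n - 1) if cr else np.empty((0, q))
        if cr and cc:
            E = Zr.T @ Zc / (n - 1) if config.include_cov_cov else np.zeros((cr, cc))
        else:
            E = np.empty((cr, cc))
        blocks.append(np.block([[A, B], [D, E]]))

    return MultiblockMatrix(
        M=np.vstack(blocks),
        groups=ds.group_labels,
        gm_names=list(ds.gm_names),
        wm_names=list(ds.wm_names),
        cov_row_names=cov_rows,
        cov_col_names=cov_cols,
        group_stats=stats,
        include_cov_cov=config.include_cov_cov,
        corr_method=config.corr_method,
    )


def pattern_strength(gm_salience: np.ndarray, wm_salience: np.ndarray) -> np.ndarray:
    """Outer product of GM and WM saliences for one component and group.

    The magnitude of entry (i, j) is the strength of the coupling between GM
    variable i and WM variable j in that component; its sign gives the
    direction of the coupling.
    """
    gm = np.asarray(gm_salience, dtype=float).ravel()
    wm = np.asarray(wm_salience, dtype=float).ravel()
    return np.outer(gm, wm)


def fit_mbplsc(mb: MultiblockMatrix) -> "MBPLSCResults":
    """Decompose a multiblock matrix into ordered latent components."""
    M = mb.M
    if not np.isfinite(M).all():
        raise MbplscError("multiblock matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    U, V = fix_svd_signs(U, V)
    total = float((s**2).sum())
    xi = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    contrib = _block_contributions(mb, U, s, V)
    return MBPLSCResults(
        multiblock=mb, U=U, singular_values=s, V=V, xi=xi, block_contributions=contrib
    )


def _block_contributions(mb: MultiblockMatrix, U, s, V) -> pd.DataFrame:
    """Signed percentage of each σ_i arising from each cross-block type.

    GM–WM, GM–cov and cov–WM are aggregated over groups; rows sum to 100 for
    every component with σ_i > 0.
    """
    K = len(s)
    cols = {"GM-WM": np.zeros(K), "GM-GMcov": np.zeros(K),
            "WM-WMcov": np.zeros(K), "cov-cov": np.zeros(K)}
    wm_c, cov_c = mb.col_slice("wm"), mb.col_slice("cov")
    for g in mb.groups:
        gm_r, cov_r = mb.row_slice(g, "gm"), mb.row_slice(g, "cov")
        cols["GM-WM"] += np.einsum(
            "rk,rc,ck->k", U[gm_r], mb.M[gm_r, wm_c], V[wm_c]
        )
        if mb.c_cols:
            cols["GM-GMcov"] += np.einsum(
                "rk,rc,ck->k", U[gm_r], mb.M[gm_r, cov_c], V[cov_c]
            )
        if mb.c_rows:
            cols["WM-WMcov"] += np.einsum(
                "rk,rc,ck->k", U[cov_r], mb.M[cov_r, wm_c], V[wm_c]
            )
        if mb.c_rows and mb.c_cols:
            cols["cov-cov"] += np.einsum(
                "rk,rc,ck->k", U[cov_r], mb.M[cov_r, cov_c], V[cov_c]
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        data = {k: np.where(s > 0, 100.0 * v / s, np.nan) for k, v in cols.items()}
    return pd.DataFrame(data, index=[f"LV{i + 1}" for i in range(K)])


def participant_scores(
    results: "MBPLSCResults",
    ds: Optional[FeatureDataset] = None,
    use_training_stats: bool = True,
) -> pd.DataFrame:
    """Latent-variable scores: projections of z-scored data onto saliences.

    The GM score of a participant in group g for component i is the dot
    product of the group-standardized GM row with group g's GM salience
    vector; the WM score uses the shared WM saliences. Covariate salience
    entries are excluded. For a new dataset the trained groups' means/SDs are
    reused (``use_training_stats=True``), so held-out participants are scored
    on the training scale.
    """
    mb = results.multiblock
    train = ds is None
    ds = ds if ds is not None else results.dataset
    if ds is None:
        raise MbplscError("no dataset attached to results; pass ds explicitly")
    if list(ds.gm_names) != mb.gm_names or list(ds.wm_names) != mb.wm_names:
        raise AlignmentError("variable names of dataset do not match fitted model")
    K = results.n_components
    wm_sal = results.V[mb.col_slice("wm"), :]
    rows = []
    score_gm = np.zeros((ds.n, K))
    score_wm = np.zeros((ds.n, K))
    for g in ds.group_labels:
        if g not in mb.groups:
            raise AlignmentError(f"group {g!r} was not in the fitted model")
        mask = ds.group == g
        st = mb.group_stats[g]
        if train or use_training_stats:
            Zgm = apply_standardize(ds.gm[mask], st["gm_mean"], st["gm_sd"])
            Zwm = apply_standardize(ds.wm[mask], st["wm_mean"], st["wm_sd"])
        else:
            Zgm, _, _ = standardize(ds.gm[mask], ds.gm_names)
            Zwm, _, _ = standardize(ds.wm[mask], ds.wm_names)
        score_gm[mask] = Zgm @ results.U[mb.row_slice(g, "gm"), :]
        score_wm[mask] = Zwm @ wm_sal
    cols = {"participant_id": ds.participant_id, "group": ds.group}
    for i in range(K):
        cols[f"gm_lv{i + 1}"] = score_gm[:, i]
        cols[f"wm_lv{i + 1}"] = score_wm[:, i]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Model / Results


class MBPLSC:
    """Multiblock PLS correlation model of GM–WM structural coupling.

    Parameters
    ----------
    dataset : FeatureDataset
        Validated participant-level features (two or more groups).
    config : AnalysisConfig, optional
        Analysis settings; defaults are sensible for exploratory use.

    Examples
    --------
    >>> model = MBPLSC(dataset)
    >>> res = model.fit()
    >>> res.summary()           # doctest: +SKIP
    >>> perm = res.permutation_test(n_permutations=1000, seed=7)
    """

    def __init__(self, dataset: FeatureDataset, config: Optional[AnalysisConfig] = None):
        self.dataset = dataset
        self.config = config or AnalysisConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: dict, config=None) -> "MBPLSC":
        """Build a model from an in-memory table plus a column→role schema."""
        from .datasets import dataset_from_frame

        return cls(dataset_from_frame(df, schema), config)

    @classmethod
    def from_files(cls, table_path, schema_path, config=None) -> "MBPLSC":
        from .datasets import load_feature_table

        return cls(load_feature_table(table_path, schema_path), config)

    def fit(self) -> "MBPLSCResults":
        mb = assemble_multiblock(self.dataset, self.config)
        res = fit_mbplsc(mb)
        res.dataset = self.dataset
        res.config = self.config
        res.model = self
        return res


@dataclass
class MBPLSCResults:
    """Fitted MB-PLS-C decomposition with accessors and resampling methods."""

    multiblock: MultiblockMatrix
    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    xi: np.ndarray
    block_contributions: pd.DataFrame
    dataset: Optional[FeatureDataset] = None
    config: Optional[AnalysisConfig] = None
    model: Optional[MBPLSC] = field(default=None, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    @property
    def component_names(self) -> list:
        return [f"LV{i + 1}" for i in range(self.n_components)]

    # -- salience accessors -------------------------------------------------

    def gm_saliences(self, group) -> pd.DataFrame:
        """GM saliences of one group (regions × components)."""
        sl = self.multiblock.row_slice(group, "gm")
        return pd.DataFrame(
            self.U[sl], index=self.multiblock.gm_names, columns=self.component_names
        )

    def cov_row_saliences(self, group) -> pd.DataFrame:
        sl = self.multiblock.row_slice(group, "cov")
        return pd.DataFrame(
            self.U[sl], index=self.multiblock.cov_row_names, columns=self.component_names
        )

    def wm_saliences(self) -> pd.DataFrame:
        """Shared WM saliences (tracts × components)."""
        sl = self.multiblock.col_slice("wm")
        return pd.DataFrame(
            self.V[sl], index=self.multiblock.wm_names, columns=self.component_names
        )

    def cov_col_saliences(self) -> pd.DataFrame:
        sl = self.multiblock.col_slice("cov")
        return pd.DataFrame(
            self.V[sl], index=self.multiblock.cov_col_names, columns=self.component_names
        )

    def stacked_saliences(self) -> np.ndarray:
        """Concatenated [U; V] matrix, used for component matching."""
        return np.vstack([self.U, self.V])

    def pattern_strength(self, component: int, group) -> pd.DataFrame:
        """GM × WM salience outer product for one component (0-based)."""
        gm = self.gm_saliences(group).to_numpy()[:, component]
        wm = self.wm_saliences().to_numpy()[:, component]
        return pd.DataFrame(
            pattern_strength(gm, wm),
            index=self.multiblock.gm_names,
            columns=self.multiblock.wm_names,
        )

    # -- derived quantities ---------------------------------------------

    def scores(self, ds: Optional[FeatureDataset] = None) -> pd.DataFrame:
        return participant_scores(self, ds)

    def reconstruction(self) -> np.ndarray:
        return (self.U * self.singular_values) @ self.V.T

    def summary(self) -> str:
        """Human-readable model summary (statsmodels-style text table)."""
        from statsmodels.iolib.table import SimpleTable

        header = ["", "sigma", "xi (%)", "GM-WM (%)", "GM-GMcov (%)",
                  "WM-WMcov (%)", "cov-cov (%)"]
        rows = []
        bc = self.block_contributions
        for i, name in enumerate(self.component_names):
            rows.append(
                [name, f"{self.singular_values[i]:.4f}", f"{self.xi[i]:.2f}"]
                + [f"{bc.iloc[i][c]:.2f}" for c in ("GM-WM", "GM-GMcov",
                                                    "WM-WMcov", "cov-cov")]
            )
        mb = self.multiblock
        title = (
            f"MB-PLS-C: {len(mb.groups)} groups, p={mb.p} GM, q={mb.q} WM, "
            f"c={mb.c_rows}/{mb.c_cols} covariates ({mb.corr_method})"
        )
        return SimpleTable(rows, header, title=title).as_text()

    # -- inference methods (delegate to mbplsc.inference / .cognition) ------

    def permutation_test(self, **kw):
        from .inference import permutation_test

        return permutation_test(self.dataset, self.config, results=self, **kw)

    def bootstrap_saliences(self, **kw):
        from .inference import bootstrap_saliences

        return bootstrap_saliences(self.dataset, self.config, results=self, **kw)

    def nssd(self, component: int, group_pair=None):
        from .inference import nssd

        return nssd(self, component, group_pair)

    def convergence_trajectory(self, **kw):
        from .inference import convergence_trajectory

        return convergence_trajectory(self.dataset, self.config, results=self, **kw)

    def monte_carlo_cv(self, **kw):
        from .inference import monte_carlo_cv

        return monte_carlo_cv(self.dataset, self.config, results=self, **kw)

    def project(self, new_ds: FeatureDataset, **kw):
        from .inference import out_of_sample_projection

        return out_of_sample_projection(self, new_ds, **kw)

    def correlate_cognition(self, components, **kw):
        from .cognition import correlate_cognition

        return correlate_cognition(self.scores(), self.dataset, components,
                                   self.config, **kw)

    def plot_saliences(self, component: int, ax=None):
        from .plotting import plot_saliences

        return plot_saliences(self, component, ax=ax)
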