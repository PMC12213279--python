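"""Brain–cognition association: correlation, FDR control, group comparison.

Cognitive scores are correlated with participants' latent-variable scores
separately per group. The correlation method follows the data: Pearson when
both variables pass a Shapiro-Wilk normality check, Spearman otherwise.
Benjamini-Hochberg FDR control is applied within the family of
(cognition measures × {GM score, WM score}) tests per group and component.
Group differences in a correlation are tested with Fisher's z.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .datasets import AnalysisConfig, FeatureDataset
from .exceptions import AlignmentError, ConfigError, ValidationError

__all__ = [
    "choose_method",
    "correlate_cognition",
    "bh_adjust",
    "fisher_z_compare",
]


def choose_method(x, y, alpha_norm: float = 0.05) -> str:
    """Pick 'pearson' or 'spearman' from the normality of both variables.

    Shapiro-Wilk is run on each vector; Pearson is chosen iff both pass at
    ``alpha_norm``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 4 or len(y) < 4:
        raise ValidationError("need n >= 4 for the normality gate")
    for name, v in (("x", x), ("y", y)):
        if np.std(v) == 0:
            raise ValidationError(f"constant vector {name}: correlation undefined")
    p_x = sstats.shapiro(x).pvalue
    p_y = sstats.shapiro(y).pvalue
    return "pearson" if (p_x > alpha_norm and p_y > alpha_norm) else "spearman"


def _correlate(x, y, method: str, exact_threshold: int = 20):
    """Correlation coefficient and two-sided p for the chosen method.

    Spearman p uses the large-sample t approximation; below
    ``exact_threshold`` observations an exact permutation p is computed
    instead (the approximation is poor there).
    """
    if method == "pearson":
        r, p = sstats.pearsonr(x, y)
        return float(r), float(p)
    res = sstats.spearmanr(x, y)
    r = float(res.statistic)
    if len(x) < exact_threshold:
        perm = sstats.permutation_test(
            (np.asarray(x),),
            lambda xs: sstats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            alternative="two-sided",
            random_state=0,
        )
        return r, float(perm.pvalue)
    return r, float(res.pvalue)


def bh_adjust(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ConfigError("q must lie in (0, 1)")
    return multipletests(p, alpha=q, method="fdr_bh")[1]


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int):
    """Fisher z-test for the difference of two independent correlations.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided p from
    the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValidationError("|r| must be < 1 (atanh undefined at 1)")
    if n1 < 4 or n2 < 4:
        raise ValidationError("need n >= 4 in both groups")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2 * sstats.norm.sf(abs(z))
    return float(z), float(p)


def correlate_cognition(
    scores: pd.DataFrame,
    ds: FeatureDataset,
    components,
    config: Optional[AnalysisConfig] = None,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Correlate every cognition measure with GM and WM latent scores.

    Runs per group and per selected component (0-based indices); BH
    adjustment is applied within each (group, component) family of
    k_cognition × 2 tests. Returns a tidy table with one row per test:
    method, coefficient, raw p, BH-adjusted p and the significance flag at
    ``config.fdr_q``.
    """
    config = config or AnalysisConfig()
    if not ds.cognition_names:
        raise AlignmentError("dataset has no cognition columns")
    if len(scores) != ds.n:
        raise AlignmentError("scores and dataset have different participant counts")
    components = [int(c) for c in np.atleast_1d(components)]

    rows = []
    for g in ds.group_labels:
        mask = ds.group == g
        sub_scores = scores[scores["group"] == g]
        for comp in components:
            family = []
            for ci, cog_name in enumerate(ds.cognition_names):
                cog = ds.cognition[mask][:, ci]
                for side in ("gm", "wm"):
                    lv = sub_scores[f"{side}_lv{comp + 1}"].to_numpy()
                    ok = ~np.isnan(cog)
                    method = choose_method(cog[ok], lv[ok], alpha_norm)
                    r, p = _correlate(cog[ok], lv[ok], method)
                    family.append(
                        {
                            "group": g,
                            "component": comp,
                            "cognition": cog_name,
                            "score_block": side,
                            "method": method,
                            "coefficient": r,
                            "p_raw": p,
                            "n": int(ok.sum()),
                        }
                    )
            adj = bh_adjust([f["p_raw"] for f in family], config.fdr_q)
            for f, pa in zip(family, adj):
                f["p_adjusted"] = float(pa)
                f["significant"] = bool(pa <= config.fdr_q)
                f["family_size"] = len(family)
            rows += family
    return pd.DataFrame(rows)
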