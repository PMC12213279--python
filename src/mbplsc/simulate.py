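"""Synthetic two-group datasets with planted GM–WM latent couplings.

The generator emulates the statistical structure of a case–control structural
covariance study: two matched groups, a *shared* GM–WM coupling expressed
with the same polarity in both groups, a *differential* coupling whose GM
loadings flip sign between groups (the group-differentiating pattern), age
and sex/TIV covariate effects, and a cognition score driven by the
differential WM latent variable in one group only.

Generative model, per participant j in group g (all on the z scale)::

    t_sh, t_df ~ N(0, 1)                                   latent factors
    gm_j = s·w_gm_sh·t_sh + d·π(g)·w_gm_df·t_df + a·z_age·w_age
           + τ·z_tiv·w_tiv + ε,    ε ~ N(0, noise_sd²·I)
    wm_j = s·w_wm_sh·t_sh + d·w_wm_df·t_df + ε
    cog_1 = λ(g)·(wm_j · w_wm_df) + ε                      linked column

with s = shared_effect, d = diff_effect, π(g) = diff_polarity (+1/−1),
λ(g) = cognition_link. Loading vectors w are drawn once per seed, sparse
(``sparsity`` fraction nonzero) and unit-L2-normalised. Demographics mimic a
young-adult cohort: age ~ U[17, 28] years, sex ~ Bernoulli(0.7) (≈70 % male),
TIV normal and correlated with sex. Outputs are mapped affinely onto natural
scales (thickness in mm or surface area in mm², FA-like WM values, cognition
scores centred at 100) — affine maps leave every correlation, and hence the
fitted model, unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .datasets import FeatureDataset
from .exceptions import ConfigError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_null_dataset",
    "generate_bundle_table",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Default effect sizes plant strong components with well-separated
    strengths (shared > differential), so that component identity is
    unambiguous at n≈71 per group and parameter-recovery tests are
    informative; near-degenerate strengths would make the within-subspace
    rotation of the decomposition arbitrary. Real cohorts show far weaker
    coupling — lower the effects or raise ``noise_sd`` to emulate that.
    """

    n_per_group: int = 71
    p: int = 68  # GM regions
    q: int = 48  # WM tracts
    n_cognition: int = 4
    group_labels: Tuple[str, str] = ("HC", "ROP")
    shared_effect: float = 3.5
    diff_effect: float = 2.0
    diff_polarity: Tuple[float, float] = (1.0, -1.0)  # GM-side sign per group
    age_effect: float = -0.3  # age → thickness, negative
    sex_tiv_effect: float = 0.0  # TIV/sex → surface area, positive when used
    cognition_link: Tuple[float, float] = (0.0, 0.25)  # patient-like group only
    noise_sd: float = 0.3
    sparsity: float = 0.5  # fraction of nonzero loading entries
    gm_measure: str = "thickness"
    seed: int = 0
    participant_seed: Optional[int] = None  # draw new cohorts from one population

    def __post_init__(self):
        for name in ("shared_effect", "diff_effect", "age_effect",
                     "sex_tiv_effect", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.n_per_group < 4:
            raise ConfigError("n_per_group must be >= 4")
        if not (0 < self.sparsity <= 1):
            raise ConfigError("sparsity must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.group_labels) != len(self.diff_polarity) or len(
            self.group_labels
        ) != len(self.cognition_link):
            raise ConfigError("per-group parameter lengths must match group_labels")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, for recovery tests.

    ``gm_saliences``/``wm_saliences`` are the *population* saliences — the
    singular vectors of the population multiblock correlation matrix, which
    is what a correlation-based decomposition estimates (per-variable
    attenuation makes these differ from the raw loading vectors, kept in
    ``loadings``). All salience vectors are unit-L2-norm; GM saliences carry
    the per-group polarity. Components are named 'shared' and 'differential'.
    """

    gm_saliences: dict  # group -> {component -> (p,) vector}
    wm_saliences: dict  # component -> (q,) vector
    factor_scores: dict  # group -> {component -> (n,) vector}
    cognition_slopes: dict  # group -> slope on the linked cognition column
    loadings: dict = field(default_factory=dict)  # raw w vectors

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            return x

        return json.dumps(
            {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)},
            indent=2,
        )


def _sparse_unit(rng: np.random.Generator, size: int, sparsity: float) -> np.ndarray:
    """Unit-norm loading vector with ~`sparsity` fraction nonzero entries."""
    k = max(1, int(round(sparsity * size)))
    w = np.zeros(size)
    idx = rng.choice(size, size=k, replace=False)
    w[idx] = rng.normal(size=k)
    nrm = np.linalg.norm(w)
    if nrm == 0:  # pathological draw; retry deterministically
        w[idx[0]] = 1.0
        nrm = 1.0
    return w / nrm


def _population_saliences(cfg: SyntheticConfig, w: dict) -> tuple:
    """Population (n → ∞) GM/WM saliences implied by the generative model.

    The estimand of a correlation-based PLS is the singular structure of the
    *population correlation* matrix, whose per-variable attenuation
    1/sqrt(var) distorts the raw loading vectors; recovery is therefore
    judged against these population saliences, not the raw loadings. The
    population GM–WM block for group g is::

        A_g = D_g^{-1/2} (s²·w_gm_sh w_wm_shᵀ + d²·π(g)·w_gm_df w_wm_dfᵀ) D_w^{-1/2}

    with D the per-variable population variances. The stacked matrix (zero
    covariate cross-blocks omitted) is decomposed and its components matched
    to the planted ones by congruence with the stacked raw loadings. When an
    effect is zero the raw (normalised) loading is returned, there being no
    population component to recover.
    """
    s2, d2 = cfg.shared_effect**2, cfg.diff_effect**2
    a2, t2 = cfg.age_effect**2, cfg.sex_tiv_effect**2
    var_gm = (
        s2 * w["w_gm_sh"] ** 2 + d2 * w["w_gm_df"] ** 2
        + a2 * w["w_age"] ** 2 + t2 * w["w_tiv"] ** 2 + cfg.noise_sd**2
    )
    var_wm = s2 * w["w_wm_sh"] ** 2 + d2 * w["w_wm_df"] ** 2 + cfg.noise_sd**2
    with np.errstate(divide="ignore", invalid="ignore"):
        dg = np.where(var_gm > 0, 1.0 / np.sqrt(var_gm), 0.0)
        dw = np.where(var_wm > 0, 1.0 / np.sqrt(var_wm), 0.0)
    blocks = []
    for gi in range(len(cfg.group_labels)):
        C = s2 * np.outer(w["w_gm_sh"], w["w_wm_sh"]) + d2 * cfg.diff_polarity[
            gi
        ] * np.outer(w["w_gm_df"], w["w_wm_df"])
        blocks.append((dg[:, None] * C) * dw[None, :])
    M = np.vstack(blocks)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T
    G, p = len(cfg.group_labels), cfg.p

    def norm(v):
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    truth_stacked = {
        "shared": np.concatenate(
            [np.tile(w["w_gm_sh"], G), w["w_wm_sh"]]
        ),
        "differential": np.concatenate(
            [np.concatenate([pi * w["w_gm_df"] for pi in cfg.diff_polarity]),
             w["w_wm_df"]]
        ),
    }
    gm_out = {g: {} for g in cfg.group_labels}
    wm_out = {}
    stacked = np.vstack([U, V])
    used: set = set()
    for comp, effect in (("shared", cfg.shared_effect), ("differential", cfg.diff_effect)):
        if effect == 0:
            for gi, g in enumerate(cfg.group_labels):
                base = w["w_gm_sh"] if comp == "shared" else w["w_gm_df"]
                pol = 1.0 if comp == "shared" else cfg.diff_polarity[gi]
                gm_out[g][comp] = norm(pol * base)
            wm_out[comp] = norm(w["w_wm_sh" if comp == "shared" else "w_wm_df"])
            continue
        tgt = truth_stacked[comp]
        cong = tgt @ stacked / np.maximum(
            np.linalg.norm(tgt) * np.linalg.norm(stacked, axis=0), 1e-300
        )
        order = np.argsort(-np.abs(cong), kind="stable")
        k = int(next(j for j in order if j not in used))
        used.add(k)
        sgn = 1.0 if cong[k] >= 0 else -1.0
        for gi, g in enumerate(cfg.group_labels):
            gm_out[g][comp] = norm(sgn * U[gi * p : (gi + 1) * p, k])
        wm_out[comp] = norm(sgn * V[:, k])
    return gm_out, wm_out


def generate_dataset(config: SyntheticConfig) -> Tuple[FeatureDataset, GroundTruth]:
    """Draw one synthetic cohort and its ground truth.

    Deterministic: the same config (including seed) yields a bit-identical
    dataset. Loading vectors — the population — are drawn from ``seed``
    alone; participants are drawn from ``participant_seed`` (defaulting to
    ``seed``), so held-out cohorts from the same population are obtained by
    varying only ``participant_seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pseed = cfg.participant_seed if cfg.participant_seed is not None else cfg.seed
    prng = np.random.default_rng(np.random.SeedSequence(entropy=(pseed, 0x9E3779B9)))
    p, q, n = cfg.p, cfg.q, cfg.n_per_group

    w_gm_sh = _sparse_unit(rng, p, cfg.sparsity)
    w_gm_df = _sparse_unit(rng, p, cfg.sparsity)
    w_wm_sh = _sparse_unit(rng, q, cfg.sparsity)
    w_wm_df = _sparse_unit(rng, q, cfg.sparsity)
    w_age = _sparse_unit(rng, p, cfg.sparsity)
    w_tiv = _sparse_unit(rng, p, cfg.sparsity)

    ids, groups = [], []
    gm_rows, wm_rows, cov_rows, cog_rows = [], [], [], []
    gt_scores: dict = {}

    for gi, glabel in enumerate(cfg.group_labels):
        t_sh = prng.normal(size=n)
        t_df = prng.normal(size=n)
        age = prng.uniform(17.0, 28.0, size=n)
        sex = (prng.uniform(size=n) < 0.7).astype(float)  # 1 = male-like label
        tiv = 1_400_000 + 120_000 * sex + prng.normal(0, 90_000, size=n)
        z_age = (age - 22.5) / (11.0 / np.sqrt(12.0))  # centred/scaled uniform
        z_tiv = (tiv - 1_484_000) / 110_000

        gm = (
            cfg.shared_effect * np.outer(t_sh, w_gm_sh)
            + cfg.diff_effect * cfg.diff_polarity[gi] * np.outer(t_df, w_gm_df)
            + cfg.age_effect * np.outer(z_age, w_age)
            + cfg.sex_tiv_effect * np.outer(z_tiv, w_tiv)
            + prng.normal(0, cfg.noise_sd, size=(n, p))
        )
        wm = (
            cfg.shared_effect * np.outer(t_sh, w_wm_sh)
            + cfg.diff_effect * np.outer(t_df, w_wm_df)
            + prng.normal(0, cfg.noise_sd, size=(n, q))
        )
        # cognition noise is unit-sd regardless of brain noise, so the link
        # coefficient maps directly onto an expected correlation
        cog = prng.normal(0.0, 1.0, size=(n, cfg.n_cognition))
        wm_lv = wm @ w_wm_df  # differential WM latent score
        cog[:, 0] += cfg.cognition_link[gi] * wm_lv

        ids += [f"{glabel}_{j:03d}" for j in range(n)]
        groups += [glabel] * n
        gm_rows.append(gm)
        wm_rows.append(wm)
        cov_rows.append(np.column_stack([age, sex, tiv]))
        cog_rows.append(cog)
        gt_scores[glabel] = {"shared": t_sh, "differential": t_df}

    gm_z = np.vstack(gm_rows)
    wm_z = np.vstack(wm_rows)

    # affine maps onto natural measurement scales (correlation-preserving)
    if cfg.gm_measure == "thickness":
        gm_nat = 2.5 + 0.15 * gm_z
        gm_names = [f"gm_thk_{i:03d}" for i in range(p)]
    else:
        gm_nat = 3500.0 + 350.0 * gm_z
        gm_names = [f"gm_area_{i:03d}" for i in range(p)]
    wm_nat = 0.5 + 0.04 * wm_z
    cog_nat = 100.0 + 15.0 * np.vstack(cog_rows)

    ds = FeatureDataset(
        participant_id=ids,
        group=np.array(groups, dtype=object),
        gm=gm_nat,
        wm=wm_nat,
        covariates=np.vstack(cov_rows),
        cognition=cog_nat,
        gm_names=gm_names,
        wm_names=[f"wm_fa_{i:03d}" for i in range(q)],
        covariate_names=["age", "sex", "tiv"],
        cognition_names=[f"cog_{i}" for i in range(cfg.n_cognition)],
        provenance={"generator": "mbplsc.simulate", "config": dataclasses.asdict(cfg)},
    )
    loadings = {
        "w_gm_sh": w_gm_sh, "w_gm_df": w_gm_df,
        "w_wm_sh": w_wm_sh, "w_wm_df": w_wm_df,
        "w_age": w_age, "w_tiv": w_tiv,
    }
    gm_truth, wm_truth = _population_saliences(cfg, loadings)
    gt = GroundTruth(
        gm_saliences=gm_truth,
        wm_saliences=wm_truth,
        factor_scores=gt_scores,
        cognition_slopes={
            g: cfg.cognition_link[gi] for gi, g in enumerate(cfg.group_labels)
        },
        loadings=loadings,
    )
    return ds, gt


def generate_null_dataset(config: SyntheticConfig) -> FeatureDataset:
    """A cohort with no planted couplings (all latent effects zero).

    Used for type-I-error calibration: GM, WM and cognition are mutually
    independent noise, while demographics keep their marginal structure.
    """
    cfg = config.replace(
        shared_effect=0.0,
        diff_effect=0.0,
        cognition_link=tuple(0.0 for _ in config.group_labels),
    )
    ds, _ = generate_dataset(cfg)
    return ds


def generate_bundle_table(
    n_regions: int = 68,
    n_tracts: int = 48,
    planted_regions: Optional[Sequence[int]] = None,
    planted_tracts: Optional[Sequence[int]] = None,
    enrichment: float = 1.0,
    n_bundles: int = 2000,
    seed: int = 0,
    max_tracts_per_bundle: int = 4,
    region_labels: Optional[Sequence[str]] = None,
    tract_labels: Optional[Sequence[str]] = None,
):
    """Random streamline-bundle summary table with an optional planted pattern.

    Bundles get uniform random endpoint region pairs, 1..`max_tracts_per_bundle`
    traversed tracts and log-normal weights. Bundles whose endpoints both lie
    in ``planted_regions`` and which traverse at least one planted tract have
    their weight multiplied by ``enrichment`` (=1 leaves the table null).

    Returns ``(BundleTable, (region_labels, tract_labels))`` where the second
    element is the planted pattern expressed in label space.
    """
    from .connectivity import BundleTable

    if n_bundles < 1:
        raise ConfigError("n_bundles must be >= 1 (empty table)")
    if enrichment < 1:
        raise ConfigError("enrichment must be >= 1")
    planted_regions = list(planted_regions or [])
    planted_tracts = list(planted_tracts or [])
    for r in planted_regions:
        if not (0 <= r < n_regions):
            raise ConfigError(f"planted region index {r} out of range")
    for t in planted_tracts:
        if not (0 <= t < n_tracts):
            raise ConfigError(f"planted tract index {t} out of range")

    rng = np.random.default_rng(seed)
    regions = list(region_labels) if region_labels is not None else [
        f"region_{i:03d}" for i in range(n_regions)
    ]
    tracts = list(tract_labels) if tract_labels is not None else [
        f"tract_{i:03d}" for i in range(n_tracts)
    ]
    if len(regions) != n_regions or len(tracts) != n_tracts:
        raise ConfigError("label list lengths must match n_regions/n_tracts")
    a = rng.integers(0, n_regions, size=n_bundles)
    b = rng.integers(0, n_regions, size=n_bundles)
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=n_bundles)
    rows = []
    pr, pt = set(planted_regions), set(planted_tracts)
    k_max = min(max_tracts_per_bundle, n_tracts)
    for i in range(n_bundles):
        k = int(rng.integers(1, k_max + 1))
        tr = rng.choice(n_tracts, size=k, replace=False)
        w = weights[i]
        if pr and pt and a[i] in pr and b[i] in pr and (set(tr) & pt):
            w *= enrichment
        rows.append(
            (regions[a[i]], regions[b[i]], tuple(tracts[t] for t in sorted(tr)), w)
        )
    table = BundleTable.from_records(rows, region_universe=regions, tract_universe=tracts)
    pattern = ([regions[r] for r in sorted(pr)], [tracts[t] for t in sorted(pt)])
    return table, pattern
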