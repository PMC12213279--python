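# Methods

This note documents the statistical model, the numerical conventions, the
synthetic-data generator, and the design decisions taken where the method
left genuine choices open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The multiblock decomposition

**Construction.** Within each group, GM, WM and covariate blocks are
z-scored (ddof = 1) and combined into Pearson correlation blocks
A = corr(GM, WM), B = corr(GM, Cov), D = corr(Cov, WM) and E = corr(Cov,
Cov); the per-group row block `[[A, B], [D, E]]` is stacked vertically over
groups. Consequences of this layout:

- Left singular vectors carry *group-specific* GM (and covariate) saliences;
  right singular vectors carry WM (and covariate) saliences *shared* across
  groups. Same-polarity GM saliences across groups mean a shared coupling
  pattern, opposite polarity a group-differentiating one; the outer product
  of a GM and a WM salience gives per-pair coupling strength and direction.
- Covariates appear on both margins: the row-margin covariates pair with WM
  (block D), the column-margin covariates pair with GM (block B). The two
  sets default to all covariates and are configurable independently
  (`AnalysisConfig.covariates_rows` / `covariates_cols`). The E block is
  included by default and can be zeroed (`include_cov_cov=False`); how the
  original multiblock variant treats E is not settled, so the choice is
  explicit and recorded in run metadata.
- Correlations are Pearson by default; a Spearman variant rank-transforms
  within group first.

**Decomposition outputs.** Full SVD; per component i: σ_i, explained
covariance ξ_i = 100·σ_i²/Σ_jσ_j² (sums to 100 exactly), and signed
block-wise contributions 100·u_iᵀM_B v_i/σ_i per cross-block, aggregated
over groups for GM–WM, GM–cov and cov–WM (they sum to 100 per component).
SVD sign indeterminacy is fixed by making the maximum-|entry| of each left
singular vector positive. Components with tied σ are reported in index
order; all resampling routines match components rather than trusting order.

**Scores.** A participant's GM score on component i is the dot product of
their group-standardized GM row with their group's GM salience vector; the
WM score uses the shared WM saliences. Covariate salience entries are
excluded from scores — scores are meant to express brain-pattern strength,
and this keeps them computable for participants with missing covariates.
Held-out participants are standardized with the *training* group statistics,
so projecting the training set reproduces in-sample scores exactly.

## Resampling inference

**Omnibus permutation test.** Participant rows of the WM block are shuffled
within each group (default scheme; GM-side and both-sides shuffling are
selectable). This breaks GM–WM and covariate–WM coupling while preserving
the GM–covariate structure, so the B and E blocks contribute identically to
the observed and permuted statistics and cancel from the comparison. The
statistic is total inertia ‖M‖²_F; p = (1 + #{perm ≥ obs})/(B + 1), hence
p ≥ 1/(B+1) always. Type-I error at the study's scale is verified by a
200-cohort calibration experiment in the test suite.

**Per-component p-values.** Permuted singular values are aligned to the
observed solution before comparison: with Q the orthogonal Procrustes
rotation of the permuted right singular vectors onto the observed ones, the
aligned values are the column norms of U_p·diag(σ_p)·Q — algebraically the
column norms of M_perm·V_obs, i.e. the permuted matrix projected onto the
observed right subspace. Later components' nulls inherit variance from
earlier ones; this standard construction is mildly anticonservative for
trailing components and is used only alongside the omnibus test.

**Bootstrap salience CIs.** Participants are resampled with replacement
within group; each replicate is refit and aligned to the original solution
by maximal-|Tucker congruence| component matching with sign flips — a
*signed-permutation* orthogonal alignment. An unrestricted Procrustes
rotation was evaluated and rejected: it absorbs genuine sampling variability
into the alignment (and is exactly degenerate whenever the right
singular-vector matrix is square, since any orthonormal basis then rotates
exactly onto the reference), which halved bootstrap SDs relative to the true
sampling SD in a dedicated calibration experiment and inflated the
zero-salience false-flag rate several-fold. With matching-based alignment
the bootstrap SD reproduces the sampling SD. Percentile CIs at 1 − α;
significance flag = CI excludes 0; replicates with a zero-variance column
(e.g. a constant resampled binary covariate) are discarded and counted, with
a warning when more than 1 % are lost; runs with fewer than 100 retained
iterations are flagged unreliable.

**NSSD.** For one component, each group's GM salience subvector is
L2-normalised and subtracted entrywise (first group minus second; positive =
larger salience in the first group). The contrast is exactly antisymmetric
under group swap and zero at equality. The normalisation makes the contrast
scale-free across components; no significance threshold is imposed — the
full vector is reported and thresholding left to the analyst.

**Convergence trajectories.** For R random participant orderings, the model
is refit on the first n per group (n = n_min … N), subsample components are
matched to the full-sample solution (Tucker congruence + sign), and
|salience(n+1) − salience(n)| is recorded per variable and averaged over
orderings. Subsample fits that fail on a zero-variance column (small-n
constant binary covariates) are skipped and the average uses the remaining
orderings. The trajectory's approach to zero indicates the sample size at
which saliences stabilise.

**Monte Carlo cross-validation.** Per split: refit on a random train
fraction per group, project held-out participants with training statistics,
correlate GM and WM scores per group; report per-split r and p, across-split
mean and SD, and a "generalisable" flag (the mean's normal-theory 95 %
interval excludes zero — splits share data, so the interval is approximate).
`component` indexes the *training* solution. Matching each split to the
full-sample solution is available (`match_to_reference=True`) for tracking a
labelled component but is documented as mildly optimistic under the null:
held-out participants contributed to the reference solution, a selection
effect measured at mean r ≈ +0.06 on null data during development of the
null-calibration test. Out-of-sample projection of an independent cohort
uses the trained saliences and training statistics directly.

## Cognition association

Per group and component, every cognition measure is correlated with the GM
and the WM latent score. The method follows the data: Pearson iff both
vectors pass Shapiro-Wilk at α = 0.05, else Spearman (with an exact
permutation p below n = 20, where the t approximation is poor).
Benjamini-Hochberg FDR control is applied within each (group, component)
family of k_cognition × 2 tests (8 by default); family sizes are recorded in
the output. Group differences in a correlation use Fisher's z:
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

## Connectome pattern null

Input is a streamline-bundle summary table (endpoint region pair, traversed
tract labels, non-negative total weight — the schema any tractography
pipeline can export to); raw tractograms are out of scope. The observed
statistic is the total weight of bundles with both endpoints in the
pattern's region set and at least one traversed tract in its tract set; a
bundle traversing several pattern tracts counts once (no double counting).
The null redraws both label sets uniformly without replacement, size-matched
to the observed pattern, jointly per draw; p = (1 + #{null ≥ obs})/(B + 1),
one-sided for enrichment. No degree- or length-preserving null is attempted
— uniform size-matching is the stated comparison. The Monte-Carlo null is
validated against exhaustive enumeration on a small universe in the test
suite.

## Synthetic-data generator

The generator plants: a shared GM–WM coupling (same GM polarity in both
groups), a differential coupling (GM polarity flips between groups, WM
shared), an age→GM effect (negative by default, for thickness), an optional
sex/TIV→GM effect (for surface area), and a cognition column driven by the
differential WM latent score in the patient-like group only. Demographics
mimic a young-adult cohort: age ~ U[17, 28] years, ~70 % of one sex, TIV
correlated with sex. Outputs are mapped affinely onto natural scales
(thickness ≈ 2.5 ± 0.15 mm; FA ≈ 0.5 ± 0.04·z; cognition ≈ 100 ± 15),
which leaves every correlation — and hence the fitted model — unchanged.
Loading vectors are drawn once per `seed` (the "population"); participants
are drawn from `participant_seed`, so independent cohorts from one
population are available for out-of-sample tests. Generation is
bit-reproducible for a fixed config.

**Ground truth is the population salience, not the raw loading.** A
correlation-based decomposition estimates the singular structure of the
*population correlation matrix*; per-variable attenuation 1/√var distorts
the raw loading vectors (at extreme SNR the correlation matrix saturates to
the sign pattern of the loadings, capping congruence with raw Gaussian
loadings near √(2/π) ≈ 0.80). `GroundTruth` therefore stores the population
saliences, computed analytically from the generative model and matched to
the planted components; the raw loading vectors remain available under
`loadings` (their zero patterns coincide with the population zeros, which is
what the bootstrap specificity tests use).

**Default effect sizes.** shared_effect = 3.5, diff_effect = 2.0, noise_sd =
0.3, 50 % nonzero loadings. These were chosen so that (a) the two planted
components have well-separated population singular values — near-degenerate
strengths make the within-subspace rotation of any SVD arbitrary and
component identity meaningless — and (b) at n = 71 per group the sampling
noise of a 2·68 × 48 correlation matrix (whose pure-noise entries fluctuate
at 1/√n regardless of effect size) leaves per-component recovery
informative. The resulting planted couplings are deliberately much stronger
than real GM–WM covariance effects (in-sample latent correlations come out
near 0.97, against roughly 0.25–0.6 in typical cohorts): passing recovery
tests shows the machinery recovers structure that is there, not that such
structure would be detectable at realistic effect sizes. The cognition link
(0.25 on unit-SD cognition noise) corresponds to a planted correlation near
0.45 in the linked group. The null generator zeroes the couplings and the
cognition link while keeping the demographic structure.

**What the generator does not emulate:** spatial autocorrelation between
atlas regions, site/scanner batch effects, non-Gaussian morphometry
distributions, missingness, or any mechanistic link between covariates and
WM. Passing tests therefore demonstrate correctness of the algorithms under
a clean latent-factor model, not robustness to those real-data features.

## Numerical conventions and degenerate inputs

- Standardization ddof = 1 throughout; correlation = ZᵀZ/(n−1).
- Zero-variance columns raise a named error at fit time and are fatal
  validation findings (correlation undefined); groups need n ≥ 4.
- All p-values use the (1 + k)/(1 + B) convention.
- Component matching is greedy on |Tucker congruence| in reference order,
  ties broken by index; sign from the congruence's sign.
- Binary categorical covariates are coded 0/1 in lexicographic label order
  (recorded in provenance so salience signs stay interpretable).
- Missing values: the reader errors on the first missing brain/covariate
  cell by default, naming it; listwise deletion (`on_missing="drop"`) is
  available and logs dropped participants. Missing cognition values drop
  pairs within the affected correlation only.
- Resampling sizes default to 10,000 permutations / 10,000 bootstrap
  iterations; tests and the pipeline's examples scale these down (200–2,000)
  to keep runs interactive, which is a precision trade-off only — p-value
  floors rise to 1/(B+1).

## Known limitations

- Per-LV permutation p-values are anticonservative for trailing components
  (inherited from the aligned-σ construction); rely on the omnibus test for
  existence claims.
- Percentile bootstrap CIs are first-order; no BCa correction.
- The "generalisable" CV flag uses a normal-theory interval over correlated
  splits and is heuristic.
- The connectivity null ignores region degree and tract length; patterns
  involving hub regions will look enriched against a uniform null.
- NSSD has no built-in significance threshold.
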