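# Methods

This note records the models, numerical choices and design decisions
behind `traitnet`, and what the synthetic-data tests do and do not
demonstrate about field data.

## Trait data model

A trait table assigns each taxon scores over trait *modalities*; every
modality carries a category label — `REG` (ecosystem-regulating),
`REC_e`/`REC_i` (recovery-enhancing/-inhibiting) or `RES_e`/`RES_i`
(resistance-enhancing/-inhibiting). Scores may be fuzzy-coded;
`binarize_traits` converts them to presence/absence with a configurable
threshold (default 0: any positive affinity counts as possession, the most
inclusive reading and the only one that never discards information held in
weak affinities). Binarization is idempotent at a fixed threshold.

Community data are long-form `(site, treatment, plot, taxon, count)`
records. One community is formed per site-treatment by unioning the
species present in its replicate plots (summed count > 0). Pooling by
union maximizes the species pool behind each network, consistent with
field protocols that already pool physical cores within plots; abundances
are deliberately not carried further, because every downstream statistic
is presence-based.

## Co-occurrence model and filter

Within a community of `N` species, for modalities borne by `N_i` and `N_j`
species, the overlap count under random placement is hypergeometric with
mean `E = N_i N_j / N`. Probabilities are computed by log-factorial
accumulation (via the log-gamma function), exact in double precision far
beyond realistic community sizes; tail probabilities at the observed
overlap include the probability mass at the observed value, so
`p_lt + p_gt >= 1`.

Edge retention requires `E >= 1` **and** `Q_obs >= 1`. The first condition
removes pairs expected to co-occur in fewer than one species (no
response diversity even in principle); the second is added because a
never-observed pair would produce a zero-weight edge, which carries no
response diversity either. Significance (`p_gt`) is computed and reported
for every pair but not used for retention by default — the retention
contract is the expectation threshold; a `sig_alpha` option enables
p-value-based retention for sensitivity analysis. Pairs of modalities
within the same parent trait are retained by default (an
`exclude_within_trait` option removes them).

## Networks and the complexity proxy

Each retained pair becomes an edge weighted by `Q_obs`; the node set is
exactly the modalities incident to a retained edge, so a modality that
loses all its connections disappears from the network. Metrics per
network: `n_nodes`, `n_connections`, `n_reg_rece`, `n_reg_rese` (category
pairs counted unordered) and mean node eigencentrality.

Eigencentrality is relative, so all site-treatment networks are scored on
one pooled graph in which each network is a disconnected component with
nodes keyed `(site, treatment, modality)` — per-cluster node copies, not
shared trait nodes, so a modality's score can differ between a site's
control and treatment clusters. Two scoring modes exist:

* **fixed** (the scoring-function default): power iteration on the
  identity-shifted adjacency `A + I` with per-iteration
  max-normalization, run for a fixed 100 iterations, final scores rescaled
  to max 1; isolated nodes score 0. The shift is the standard
  regularization for periodic (bipartite) components — it leaves all
  eigenvectors and the ordering of component eigenvalues unchanged while
  guaranteeing convergence toward each component's Perron vector. The
  iteration count is fixed rather than convergence-based on purpose: run
  to convergence, every component except the one with the largest
  eigenvalue is driven to zero.
* **per_component_scaled**: each component's exact dominant eigenvector
  (max-normalized within the component) scaled by the component's dominant
  eigenvalue over the global maximum eigenvalue.

The pipeline defaults to `per_component_scaled` for the stress-response
analysis. The reason is quantitative: dominant eigenvalues of realistic
site networks span roughly 12–24, so after 100 max-normalized iterations
the cross-component factor `((lambda_c + 1)/(lambda_max + 1))^100` leaves
all but the leading component within numerical dust of zero — a valid
relative ordering, but useless as a regression covariate. The
per-component mode preserves the same ordering on a smooth 0–1 scale
(typical control range ≈ 0.28–0.74 under default synthetic conditions)
and is deterministic. The fixed mode remains available
(`eigencentrality_mode: fixed`) and is the contract the eigencentrality
unit tests pin down. Scoring is unweighted by default — complexity here
is a property of the architecture, not of the weights — with a
`weighted` flag for weight-aware iteration.

Force-directed (Fruchterman–Reingold) layouts are computed only for GEXF/
GraphML export, from a seeded embedding; no metric depends on
coordinates.

## Stress-response analysis

Effect sizes are treatment/control ratios per site and metric, joined to
the site's baseline complexity (control mean eigencentrality). Sites
whose control metric is 0 yield an undefined effect, which is excluded
from tests and logged — imputation would manufacture signal. Tests are
two-sided throughout: one-sample t against 1 within each enrichment
level, and a two-sample t between levels (Welch by default, since equal
variances across enrichment levels is not defensible a priori; a
pooled-variance option exists). No multiple-testing correction is applied
by default, matching the convention of reporting raw p-values for a small
planned family; a Benjamini–Hochberg option exists.

Quantile regression at taus 0.1, 0.2, …, 0.9 is solved exactly as a
linear program (HiGHS) minimizing the pinball loss; coefficients are
asserted in tests only through loss-optimality, because with small n and
ties the minimizer need not be unique. Raw fitted lines may cross;
predictions are made non-crossing by monotone rearrangement (sorting
across tau) at reporting time only. The convergence summary evaluates the
rearranged 90th–10th spread at the smallest and largest observed baseline
complexity; a positive spread difference (min-end minus max-end) means
the quantile fan converges as complexity rises.

## Synthetic study generator

The generator emulates a 24-site × 3-treatment × 3-plot enrichment
experiment with per-site richness in 19–48 — the design whose analysis
this package implements. All randomness flows from one seed.

**Trait table.** A 70-species pool draws modalities per category
(category pool sizes 10/8/6/8/6 at default redundancy) with popularity
weights and per-species pick counts controlled by a single `redundancy`
knob in [0, 1]: higher redundancy concentrates popularity and increases
picks, raising the number of species sharing any pair; at redundancy 0
pools are expanded and draws uniform, so the expected sharing of any pair
stays below one species. Every species bears at least one `REG` modality.

**Controls.** Each site carries a latent complexity `u`, evenly spaced in
(0, 1). Control richness rises linearly in `u` across the 19–48 band
(jitter s.d. 1.5), and species selection is tilted toward trait-dense
species as `u` grows (`density_bias` 0.5), so both richness and redundancy
grow along the gradient. Plot counts scatter each species' abundance
(1 + Poisson(5)) over the 3 plots.

**Stress.** For each site and level, one intensity is drawn:
`delta = stress_scale * (mu_L + sigma_L * (1 - decay * u) * z)`,
`z ~ N(0,1)`, clipped to [-0.5, 0.6], with level means `mu` = 0.05
(medium) / 0.30 (high) and s.d. `sigma` = 0.22 / 0.15. The variance-decay
parameter (default 0.85) shrinks the cross-site s.d. with `u` — the
generator's encoding of "complex communities respond predictably". With
the default **calibrated** stress model, `delta` targets a proportional
change of `1 - delta` in the community's four count metrics: species are
removed as a prefix of a RES_i-weighted random order (weight
`1 + res_i_boost` for resistance-inhibited species, boost 0.5), several
candidate orders are tried, and the realization whose metric vector is
closest to the target is kept; a negative `delta` (common at medium
level) instead recruits absent pool species, so medium enrichment
sometimes enhances networks. Calibration on the effect scale is
deliberate: community fragility is strongly size-dependent — species-poor
communities hold most pairs just above the `E >= 1` threshold, so equal
species-loss fractions would produce much larger and much noisier metric
responses at the simple end of the gradient, confounding the variance-
decay knob with an intrinsic size effect. Translating intensities through
each site's own response curve makes decay the sole driver of cross-site
response variance: disabling it yields homoscedastic responses by
construction. A plain `bernoulli` model (delta as per-species loss
probability, RES_i bearers boosted multiplicatively) is available for
mechanism-level experiments.

**Covariates.** Mean PAR decreases and porewater NH4 increases with `u`
(with noise); they are emitted for descriptive biplots only and feed no
analysis stage.

**What the generator does not emulate.** No spatial structure, no
abundance dynamics, no environmental forcing of the trait table, no
taxonomic error, and stress acts through a single scalar intensity per
site-treatment. Passing pattern-recovery tests therefore shows that the
pipeline detects the constructed gradient and variance structure at field
scale — not that real enriched sediments behave this way.

## Problem sizes and runtimes

Default synthetic studies (24 sites, 72 networks, ~38 modalities, 70-taxa
pool) run end to end in ~2 s. Pattern-recovery checks use 20 replicate
studies per condition; the exact-model and eigencentrality oracles sweep
all communities of ≤ 8 species and all connected graphs of ≤ 5 nodes plus
random 6–8-node graphs. These sizes keep the full test suite within a few
minutes while exercising every code path at the design's true dimensions.

## Known limitations

* The fixed-iteration pooled eigencentrality is faithful to its contract
  but numerically degenerate as a cross-site covariate (see above); users
  who need the 100-iteration behaviour for comparability should treat the
  resulting complexity values as ordinal.
* Quantile fits with 24–48 points at tau 0.1/0.9 estimate extreme
  quantiles from few effective observations; the convergence summary is a
  visual-diagnostic analogue, not an inference procedure.
* Effect sizes are undefined where a control metric is 0; such sites are
  excluded, which can bias level comparisons if exclusion correlates with
  treatment severity (it does not under default synthetic conditions).
* The co-occurrence model conditions on per-modality totals within the
  community; it is not a site-by-species null model and provides no
  abundance-weighted or permutation nulls.
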