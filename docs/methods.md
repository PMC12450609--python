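# Methods

`antcomp` implements a complete analysis chain for dominance hierarchies
and dominance–discovery trade-offs in ground-foraging ant communities,
plus a multilevel meta-analysis for pooling published dominance–discovery
correlations. This note documents the models, the conventions chosen
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Individual-level behavioral dominance

One-on-one encounters are scored on the 4-point aggression scale
(1 touch, 2 avoid, 3 brief aggression, 4 prolonged fight). The winner of
a trial is the ant with strictly more aggressive behaviors (scores 3–4);
with equal aggression, the ant with strictly fewer avoidance behaviors;
trials equal on both, including touch-only trials, are ties, and trials
with no interaction at all are excluded. Aggression-first precedence is
a deliberate choice: the scale is ordered by increasing aggression, so
the aggressive-count comparison is the primary signal and avoidance only
breaks its ties. (A weighted summed score would be an alternative
reading; it changes only trials where one ant shows both more aggression
*and* more avoidance.)

Raw dominance is (wins + ties/2) / interactions. Because raw scores are
biased by unequal numbers of trials per pair, the Colley rating solves

    (2 + n_i) r_i − Σ_j n_ij r_j = 1 + (w_i − l_i)/2

where n_ij counts games between i and j. The system matrix is strictly
diagonally dominant, hence always nonsingular; ratings lie in (0, 1) and
sum to T/2. A tie is treated as half a win and half a loss for each side
(the standard extension): it increments the game counts and leaves
w − l unchanged. Taxa never observed in any assay are excluded from the
system (rating NaN) rather than pinned at 0.5, so an unobserved taxon
cannot dilute the ratings of observed ones.

## Colony-level behavioral dominance

At baits, a taxon wins an interaction when it replaces another taxon
occupying the bait at the previous observation; each replacement is a
separate interaction. A pair co-occurring at ≥ 2 consecutive
observations of the same bait scores exactly one tie for that bait
(repeated longer co-occupancy adds nothing — "repeatedly co-occurred" is
taken as a per-bait event, not a per-observation one). Conventions:

- An intervening empty observation breaks the chain: abandonment cannot
  be distinguished from displacement across a gap, so no interaction is
  scored.
- Multi-taxon transitions score one record per (winner present after,
  loser departed) pair; {A,B} → {C} yields C-beats-A and C-beats-B. By
  the same logic {A,B} → {A} scores A-beats-B: the remaining taxon held
  the bait while the other left.

The unit of analysis is the proportion of interactions won per taxon ×
competitor × bait (the pair's two rows sum to 1), fitted on the identity
scale, unweighted by interaction count, with taxon and competitor
identity fixed, and site plus bait-within-site random intercepts. The
taxon estimated marginal means are the colony-level dominance scores.

## Numerical dominance, ecological dominance, discovery

Numerical dominance is presence-at-least-once occupancy: the proportion
of a site's baits (or pitfall traps) where the taxon was ever observed.
Absence yields an explicit zero row — absence is data. Ecological
dominance is baits occupied divided by pitfall traps occupied per
site × taxon; cells with zero pitfall occupancy are excluded (undefined
ratio) and logged, and values above 1 are legal. Discovery ability is
the time of first observation at each bait, right-censored by the
observation schedule — a taxon first seen at the 48-h check may have
arrived any time after the 24-h check. First-observation time (not an
interval midpoint) is used because the relative order of discovery
across taxa is unaffected by shared censoring. Taxa never seen at a bait
yield no row (missing, not zero).

Each of these metrics is compared across taxa via a linear mixed model
with taxon fixed, sampling effort (total deployment hours of the site's
stations; bait + pitfall hours summed for the ratio metric) as a
covariate, and site as a random intercept, fitted by REML. The EMM
reference grid is conventional: equal weight over observed levels of
other fixed factors, covariates at their grand mean, random effects at
zero. Effort enters as the site total by default; per-station effort can
be supplied instead by swapping the `effort_h` column. Boundary
(zero-variance) random effects are retained and logged, never silently
re-specified.

## Trade-off axis and traits

Cross-metric association uses Pearson correlation with the exact t test
on n − 2 df (taxa are the observations; pairwise-complete, n ≥ 3).
Discovery *ability* is the negated discovery-time EMM throughout, so
larger = faster and a dominance–discovery trade-off appears directly as
a negative correlation.

The trade-off axis is PC1 of the standardized (correlation-matrix) PCA
of individual-level behavioral dominance and discovery ability. For two
standardized variables with correlation r, PC1 has eigenvalue 1 + |r|,
so its variance share is (1 + |r|)/2 and loadings are ±1/√2; the sign is
fixed so the dominance loading is positive, making scores fully
deterministic. Only the individual-level behavioral metric enters the
PCA (the colony-level metric is strongly collinear with it). Trait
associations re-use the Pearson test on PC1 versus head width, body
mass, recruitment rate (mean workers per observation where present,
averaged per bait then over baits), and recruit biomass
(body mass × recruitment rate).

## Multilevel meta-analysis

Published dominance–discovery Spearman correlations are pooled on the
Fisher-Z scale, z = atanh(r_s), with effects from fewer than four taxa
excluded as unreliable. Two sampling-variance conventions are supported
as a configuration switch: the Fisher default v = 1/(n − 3) and the
Spearman adjustment v = 1.06/(n − 3); published syntheses rarely state
which they used, so both are evaluated when reproducing one.

The model is z_i = x_i′β + u_study(i) + ε_i with u ~ N(0, σ²_study) and
ε_i ~ N(0, v_i). σ²_study is estimated by REML with the variance on the
log scale, multi-start from {0.001, 0.05, 0.5}, an explicit boundary
check at zero, and tolerance 1e-10; β is the GLS solution at the
optimum. The moderator model fits the three dominance-type means without
intercept plus species number (uncentered), so the type coefficients are
directly the predicted per-type means (back-transformed with tanh); an
omnibus Wald chi-square tests the three type means jointly (df = 3) and
species number alone (df = 1). CIs are Wald-normal on the z scale,
back-transformed. The implementation is cross-checked in the test suite
against `metafor::rma.mv` on a fixed table (agreement to ~1e-5); with a
single contributing study the study intercept is confounded with the
mean and σ²_study sits at the boundary, which is reported, not hidden.

Diagnostics: a modified Egger regression (OLS of the marginal residuals
z_i − x_i′β̂ on √v_i; a nonzero intercept signals funnel asymmetry) and a
multilevel I² = 100·σ²_study/(σ²_study + s²) with typical within-study
variance s² = (k − 1)Σw / ((Σw)² − Σw²), w_i = 1/v_i. Published
multilevel I² routines differ slightly in the typical-variance formula;
values should be compared with a few points of tolerance.

## Synthetic communities

The generator emulates the field campaign: T = 5 taxa, 16 sites, 10
baits and 10 pitfall traps per site, ~200 assays, per-site heterogeneity
in deployment duration (48–120 h baiting; 26–72 h trapping), and an
observation schedule of half-hourly checks for the first 1.5 h then
daily. Latent structure per taxon: aggressiveness α (assay Poisson rates
e^α aggressive, e^−α avoidance; Bradley–Terry takeover probability
e^{α_c}/(e^{α_c}+e^{α_h})), colony density λ (pitfall capture
1 − e^{−cλ·duration}; recruitment 1 + Poisson(2λ)), and discovery
efficiency δ (bait arrival hazard ∝ λδ). (α, log δ) are bivariate normal
with correlation ρ — the dial for the dominance–discovery trade-off —
and body mass increases log-linearly in α with noise, head width
allometrically with mass. Bait state is sampled only at schedule times,
so discovery right-censoring is exercised; a failed challenger
co-occupies with probability 0.25, creating ties; occupancy bouts end by
abandonment after an exponential stay (mean 12 h), creating empty-gap
sequences.

Latent spreads (α sd 1.3, log δ sd 0.9, log λ sd 0.3, mean λ = 2
colonies/site) are calibrated so a five-taxon community is strongly
separated — comparable to a real community whose raw dominance scores
span 0.09–1.0 — and recovery then behaves as designed: with ρ = −0.9 the
estimated trade-off sign is recovered in ≥ 95/100 seeded runs and
Spearman(Colley, α) ≥ 0.8 in ≥ 90/100.

What passing these tests shows: the pipeline recovers ordinal latent
structure and the sign of a built-in trade-off under realistic sampling
noise and censoring. What it does not show: robustness to field features
the generator omits — spatial autocorrelation among stations, diurnal
activity cycles, misidentification, interference between adjacent baits,
or taxa whose assay and bait behavior diverge (a decoupling switch
exists for that last case but is off by default).

## Numerical choices and degenerate inputs

- Colley: direct dense solve (T is small); ratings asserted to sum to
  T/2 within 1e-10 in tests.
- Pearson |r| = 1: t is infinite; p is reported as 0 with a `perfect`
  flag rather than raising.
- EMM standard errors: tiny negative quadratic forms from boundary
  mixed-model fits are clamped to zero before the square root.
- REML σ² below 1e-8 is reported as exactly 0.
- Problem sizes in the test suite (100 pipeline replicates for recovery,
  200 meta replicates for coverage) keep the full run at a few minutes
  on one core while leaving Monte-Carlo error well inside the asserted
  margins.

## Known limitations

- The empirical-study correlations from the original field deposit are
  optional replication: reproducing them requires the deposited raw
  data and the exact model choices of the original analysis.
- The meta-analytic reproduction of published pooled estimates requires
  the curated table of 54 published correlations
  (`data/effects_published.csv`), which is third-party data not
  redistributed here; the corresponding test fails with a clear message
  until the table is supplied.
- The tie definition at baits (one tie per pair per bait) and the
  empty-gap rule are conventions; alternatives (per-episode ties,
  midpoint discovery times) would change metric values but not the
  pipeline structure.
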