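# Methods

`calfnet` analyses the relationship between a calf's social position during
infancy and its survival through the juvenile period in a fission-fusion
society observed by repeated group surveys.  This note records the models,
the synthetic-data generator, the numerical choices, and the limits of what
the test suite demonstrates.

## Data model and filtering

The raw input is a survey table (one row per individual per survey; a survey
*is* a group, membership having been resolved in the field) and an
individual table with sex, birth date, weaning date, mother identity and
last sighting date.  Rows carrying the `UNKNOWN` identity token are removed
before any tallying.  The sampling period is the calendar day: all surveys
on one day form one period.

Subjects are calves with known birth and weaning dates, at least 15 distinct
sighting days inside the half-open infancy window `[birth, weaning)`, and a
resolvable survival outcome.  Survival to age 10 is established by a
sighting at or past age 10 (or an explicit override column); death is
established by the long-gap rule — unsighted for more than 4 years after
weaning, with the last sighting before age 10.  Animals still inside the
grace window are excluded rather than guessed.  The reference date for the
gap is exposed as an argument (`as_of_date`, defaulting to the last survey
date) because the choice between "date of last sighting" and "end of study"
conventions is otherwise invisible.

Design choices worth stating: the infancy window is half-open (the boundary
convention has to be picked; the weaning day itself is excluded); "sighted
on 15 days" counts distinct calendar days, consistent with the day-level
sampling period, with a `count_unit="rows"` flag for the survey-row reading;
unknown-sex individuals stay in networks (structure needs all nodes) but are
excluded from sexed analyses.

## Association and infancy networks

For a dyad (A, B), each day is classified exactly once: toward `X` if they
shared at least one group that day (co-occurrence takes precedence over a
same-day sighting apart), toward `Yab` if both were sighted but never
together, else toward `Ya`/`Yb`.  The half-weight index

    HWI = X / (X + 0.5 (Ya + Yb) + Yab)

is the edge weight.  A calf's infancy network is built from **all** surveys
in its window — not only those containing the calf — over every individual
sighted at least 15 days in-window; any pair with `X >= 1` is connected (no
weight threshold), and networks may be disconnected (no largest-component
restriction).  A dyad never sighted at all has no defined HWI and raises
rather than returning 0.

Internally, dyad counting over the many overlapping subject windows uses
precomputed day-level event arrays (`AssociationData`): together-pair events
and observation events are assembled once per dataset, and any window's
counts reduce to array masking plus one boolean-matrix product.  The slow
per-dyad reference implementation is kept and tested against the fast path.

## Node metrics, normalization, standardization

Five per-subject metrics: binary degree; strength (summed HWI weights);
weighted betweenness with edge length `1/weight` (stronger association =
shorter path; tied geodesics share credit fractionally — Brandes' algorithm
via igraph); eigenvector centrality of the weighted adjacency; and the
binary local clustering coefficient (a geometric-mean weighted variant is
available behind a flag, but neighbour-connectedness is the default
reading).

Eigenvector centrality is computed by power iteration (relative tolerance
1e-10) from an all-ones start — deterministic, no RNG — on the shifted
matrix `A + I`.  The unit shift leaves eigenvectors unchanged and breaks the
±λ symmetry of bipartite graphs, where unshifted power iteration oscillates
for ever.  On disconnected networks the dominant component absorbs the mass
and other components score ≈ 0; this is documented behaviour, not an error.

Normalization divides by the maximum possible for a node in a network of
that size: degree and strength by `n - 1` (strength's maximum assumes every
tie at HWI = 1; normalizing by the observed maximum instead is available as
a flagged alternative), betweenness by `(n-1)(n-2)/2`, eigenvector by the
network's maximum component (the most central node scores exactly 1),
clustering is already in [0, 1].  Across the subject cohort each normalized
metric is z-scored with the sample SD; a zero-variance column raises an
error naming the column.

The maternal-exclusion sensitivity variant removes the subject-mother *edge*
(the mother stays in the network — "excluding the maternal association"
reads as the tie, not the individual) and recomputes the subject's
normalized eigenvector centrality; a subject isolated by the removal scores
0.

## Survival model

Survival to 10 (binary) is modelled by logistic regression with random
intercepts — a binomial GLMM fit by Laplace-approximated maximum likelihood,
the same approximation `lme4::glmer` uses by default (and the test suite
cross-checks one fit against glmer).  The outer optimiser (L-BFGS-B) moves
the fixed effects and the log-SDs of the random terms; for each candidate
the random-effect vector is profiled out at its conditional mode (Newton
with step halving) and the Gaussian curvature correction `-(1/2) log det(I +
D^{1/2} Z'WZ D^{1/2})` applied — a form that stays finite as a variance
goes to 0, so zero-variance random terms settle at the boundary and the fit
then coincides with plain logistic regression instead of failing.  All
Z-matrix algebra goes through per-factor level codes (bincount / indexed
accumulation), never a dense `n x q` product.  Wald SEs come from the
fixed-effect block of the inverse joint penalized Hessian, conditional on
the estimated variances (as in lme4); `aic = -2 loglik + 2k` with k counting
fixed effects plus variance parameters.  Apparent separation (|coefficient|
> 10 on the logit scale) flags the fit rather than failing silently.

Two constructions in the original design cannot be taken literally.  A
per-subject random intercept with one Bernoulli observation per subject is
unidentifiable; the default drops it with a logged warning
(`keep_subject_random=True` retains it for comparison).  "Weaning age as a
random variable" needs a grouping factor, so weaning age is binned to
half-year groups; treating it as a fixed covariate instead is a
one-line model change via `ModelSpec`.

The default reporting model is `eigenvector + strength + sex +
eigenvector:sex` with mother-identity and weaning-group intercepts; AIC
selection over a nested candidate ladder, confirmed by likelihood-ratio
tests (non-nested comparisons are skipped with a warning, ties break to the
earliest candidate), is available behind `select_model`.  Collinearity is
reported as VIFs (`1/(1-R²)` from auxiliary regressions; exact collinearity
reported as infinite with the nearest partner named).

## Permutation tests

Two-sample comparisons (age-sex class strengths and counts between
survivors and non-survivors, run separately per sex) use the absolute
difference in means with a two-sided reading.  When the number of label
splits `C(n, nx)` is at most 20,000 the null distribution is enumerated
exactly (p has no Monte Carlo error and no add-one term); otherwise 10,000
seeded permutations are drawn and `p = (b+1)/(m+1)`, which is valid (never
0) and bounded below by `1/(m+1)`.  Ties in the statistic are counted as
"at least as extreme" with a 1e-12 float guard.  With many exactly-zero
strengths (subjects with no ties to a class) the permutation distribution
is discrete and the test conservative — rejection rates under the null run
below the nominal 5%, which the calibration tests reflect.  Raw p-values
are reported with no multiple-testing correction, matching the analysis
the package reproduces; the full grid is 2 sexes x 6 classes x 2 measures
= 24 tests and users should read it accordingly.

## Age-sex classes

Classes are half-open age intervals — calf [0, 4), juvenile [4, 10), adult
[10, ∞) years, age in days / 365.25 — crossed with sex.  A member observed
in two classes within one subject's window takes the class holding the
majority of its in-window sighting days; an exact tie goes to the older
class (the member spends the rest of the window older), with a
`tie_break="younger"` flag.  The mother counts in the adult-female sums by
default (exclusion is a flag for sensitivity).  Per subject, class counts
sum to binary degree and class strengths to raw strength, with unknown-sex
members tracked in a separate bucket.

## Mark-recapture check

Resighting probability is estimated with a constant-(φ, p)
Cormack-Jolly-Seber model on 4-year occasions anchored at the earliest
survey (partial final bins kept with a warning), restricted by default to
individuals with at least 15 sightings — the well-marked animals the claim
concerns — and conditioned on first detection; individuals first seen in
the final occasion are uninformative and dropped.  The likelihood uses the
closed per-individual form `φ^(l-f) p^d (1-p)^(l-f-d) χ_{l+1}` with the
recursion `χ_t = (1-φ) + φ(1-p) χ_{t+1}`.  Optimization is on the logit
scale (Nelder-Mead from logit 0.5 = 0); SEs come from the observed
information, per-parameter: an estimate pinned at the boundary (e.g. φ̂ = 1
when detection is effectively perfect) gets SE 0 and a boundary flag while
the interior parameter keeps its SE.  Time-varying φ or p is out of scope.

## Synthetic-data generator

The generator emulates a multi-decade boat-survey study of a philopatric
coastal dolphin population, with every random draw flowing from one seed
(identical configs give byte-identical CSVs):

* **Population.** Founder adults (default 60; birth 12-30 y before start)
  plus calves born in-simulation (Poisson with default 0.25 births per
  female-year, mothers drawn from founder females, no births in the final
  6 years so every infancy completes inside the study).  Sex is male with
  probability 28/67 ≈ 0.42, the modest female bias of the cohort being
  emulated.  Weaning age is truncated-normal (3.5 ± 0.5 y on [2.5, 5]).
* **Latent affinity.** `a_ij = exp(-d²/(2 s²)) g_i g_j` clipped to [0, 1]:
  a Gaussian home-range kernel (centers uniform on the unit square,
  bandwidth s = 0.15) times lognormal individual gregariousness (σ = 0.4).
  Mother-calf pairs are boosted 20-fold (clipped) until weaning.
* **Surveys.** Poisson(1.8) surveys per day; each seeds with a uniformly
  drawn alive individual and every other alive animal joins independently
  with probability `min(1, 0.25 a_ij)`; the survey is retained with
  probability 0.9.  Group formation is deliberately a Bernoulli star
  around a seed rather than a spatial chain-rule simulation: it reproduces
  fission-fusion co-occurrence statistics with two tunable parameters and
  no geometry engine.  Dead or unborn animals never appear.
* **Calibration.** The kernel bandwidth and join scale were set so the
  cohort mean total pre-weaning sightings falls near the 67.2 ± 53.0
  regime of the emulated field study, with mean group size ≈ 4; a survey
  scan over (bandwidth, join scale) selected (0.15, 0.25).
* **Planted survival.** Per calf, latent eigenvector centrality (principal
  eigenvector of the affinity submatrix over individuals present during
  its window) and latent juvenile-male tie strength (summed affinity to
  males aged [4, 10) at the window midpoint) are standardized across the
  cohort and fed through `P(survive) = logistic(b0 + b_sex male + b_eig EC
  + b_eig_sex male·EC + b_jm male·JM)`.  Defaults (1.0, -1.5, -0.3, +1.5,
  -1.0) plant the qualitative structure under study: male survival rising
  with centrality, non-surviving males carrying heavier juvenile-male
  ties.  Non-survivors get a uniform death day between weaning and age 10
  (exercising the long-gap rule) and vanish from surveys; latent truth is
  computed ignoring deaths, since death is an outcome, not a cause, in
  this model.  An optional flag replaces a configurable fraction of survey
  identities (default 0.08 when enabled) with the `UNKNOWN` token to test
  the exclusion filter.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatially explicit movement and true chain-rule
group geometry, observation effort that varies seasonally or spatially,
founder mortality and reproductive senescence, calf-to-calf inheritance of
home ranges, misidentification beyond the uniform unknown-ID token, and any
ecological driver of association beyond static affinity.  Recovery results
say the *pipeline* is faithful, not that the biological effect sizes are
realistic.

## Planted-effect recovery conditions

The strong-recovery preset (`planted_effect_config`) uses 80 founders,
birth rate 0.35, 16 years, coefficients (1.0, -1.0, 0.0, +3.0, -3.0), and
subjects restricted to ≥ 40 sighting days, yielding cohorts of roughly
110-160 subjects (~60 male).  The cohort is deliberately larger than the
emulated field study: latent centrality and juvenile-male exposure are
positively correlated (r ≈ 0.3), so the opposite-signed planted effects
partially mask each other in the dichotomized survivor comparison, and the
test's power budget has to absorb that masking plus the latent-to-observed
attenuation (observed HWI metrics correlate ≈ 0.95 with latent truth).
Under these conditions the fitted interaction — strongly attenuated from
its latent value by measurement, collinearity with strength, and the
binary outcome — comes out positive in roughly nine of ten replicates,
the juvenile-male comparison rejects in nearly all of them, and the
planted-neutral female classes stay at or below the nominal rate.  Problem
sizes throughout the suite (cohort sizes, replicate counts, permutation
counts) are chosen to keep the full run fast on a single core while leaving
the statistical conclusions unchanged.

## Reproducibility

Every stage consumes a single integer seed; permutation sub-seeds derive
deterministically from it.  `run-all` writes a manifest (package version,
seed, config echo, SHA-256 of the inputs) and no output embeds a
timestamp, so rerunning with the same inputs and seed reproduces the
output tree byte for byte.  Figures are rendered from the written CSV/JSON
artifacts only, never recomputed inline, and are excluded from the
determinism contract.
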