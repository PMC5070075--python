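# Methods

This note records the model assumptions, the generator's parameterisation
and calibration mathematics, the numerical choices made in the statistics
modules, and the known limitations. It documents what the code computes;
it makes no empirical claims beyond what the package itself can recompute.

## 1. The Decision Process Matrix model

A case is an immutable event log of `n` units with consecutive
`order_index` 1…n. Unit kinds:

- `CUE` — introduces one information unit, with a source tag
  (medical-history taking `MHT`, physical examination `PE`,
  investigations/lab tests `ILT`, literature, other).
- `OPTION` — introduces one suspected diagnosis.
- `CONFIDENCE` — rates one option in the light of one cue on the 9-point
  scale −4…+4 (integer levels; −4 *practically impossible*, +4
  *practically certain*). The flag `is_exclusion` marks the rating that
  rules the option out.
- `FINAL` — exactly one, always last; names the final diagnosis(es).

Validity (checked by `core.validate`) comprises: consecutive 1-based
numbering; exactly one `FINAL` in last position; kind/field discipline
(only `CONFIDENCE` carries `level`, etc.); every reference points to an
already-introduced cue/option (no forward references); registry
consistency (each cue/option introduced exactly once); and outcome
consistency — an option named by `FINAL` must have outcome `FINAL`, an
option whose last rating is an exclusion must have outcome `EXCLUDED`,
and the two must not coincide. Contextual metadata obeys: a similarity
rating (1–6) is only present when the resident reported experience with a
similar case.

### Three-phase segmentation

`segmentation.segment` uses a purely structural boundary rule:

- **Phase 3** is the `FINAL` unit (`phase2_end = index(FINAL) − 1`).
- **Phase 2** begins at the first `CUE` unit whose index exceeds the
  index of the first `OPTION` unit; `phase1_end` is the unit before it.
- **Phase 1** is everything before that.

The rule is total: cases with no option before the final determination,
or with no cue after the first option, are still partitioned but flagged
non-conforming with explanatory notes (`no-option-before-final`,
`empty-phase-2`) rather than rejected. The boundary depends only on the
relative order of CUE and OPTION units, so inserting a `CONFIDENCE` unit
never changes the phase membership of existing units (a property test
asserts this).

## 2. Statistics

- Per-case metrics (`stats.case_summary`): unit/cue/option counts, phase
  composition, initial and terminal confidence per option, whether the
  final option was introduced in phase 1, and terminal levels split by
  outcome.
- Cohort summaries use sample standard deviations (`ddof = 1`); SD is
  reported as undefined (`None`) for `n < 2` rather than 0.
- The mean number of options added in phase 2 is reported under **both**
  denominators — all cases, and only cases with ≥ 1 addition — because
  both conventions occur in practice; the generator's calibration target
  uses the latter by default (configurable).
- **Cohen's d** (`concordance.cohens_d`) uses the pooled sample SD
  `sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2))` with no small-sample (Hedges)
  correction. The 95 % CI uses the standard normal approximation with
  `SE = sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2−2)))`.
- **Pearson/Spearman significance** uses the t transform
  `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of freedom; Spearman is
  computed as Pearson on mid-ranks and its p-value is flagged
  `approximate` (the t transform is an approximation for rank
  correlations). Test-suite oracles compare these p-values against
  exhaustive permutation enumeration at `n ≤ 7`; the observed deviation
  band of the t approximation at those sizes is < 0.05 absolute.
- Rater agreement: perfect / within-one-step / farther shares, maximal
  discrepancy, and the direction of disagreement (expert under- vs
  over-confident relative to the resident).

## 3. Synthetic cohort generator

The generator produces cohorts whose **cohort-level means and
proportions** converge to the configured targets. Scope: it is a
structural/statistical model for pipeline testing, not a cognitive model —
cue and option texts are synthetic tokens, and no diagnosis semantics are
modelled.

### Count marginals

Each count or rating marginal is given as `(mean, sd, lo, hi)` and
realised as a **discretized truncated normal**: integer `k` in `[lo, hi]`
receives the normal mass of `(k−½, k+½]`, with the tails absorbed into
the bounds. Because truncation shifts the mean, the location parameter is
solved with Brent's method (`scipy.optimize.brentq`) so the
post-discretization mean equals the configured mean **exactly** (unit
tests assert agreement to 1e−9). The SD is nominal (pre-truncation);
post-truncation SDs are slightly smaller, which only widens effective
convergence bands.

### Endpoint mixtures

Terminal confidence of final diagnoses must satisfy two constraints at
once: a point mass `P(+4) = 0.67` and a mean of 3.56. The generator
imposes the point mass first and gives the remaining mass a discretized
truncated normal on the remaining support whose mean is solved so the
mixture mean is exact: finals `E[rest] = (3.56 − 0.67·4)/0.33 = 2.667` on
{1..3}; excluded options `P(−4) = 0.54`, `E[rest] = (−2.50 + 2.16)/0.46 =
−0.739` on {−3..2}.

### Structural probabilities

Phase-2 option additions are forced when the sampled option count exceeds
the phase-1 capacity (6) and impossible for single-option cases; the
middle region uses the Bernoulli probability
`p = (0.45 − P(n_opt > 6)) / P(2 ≤ n_opt ≤ 6)` computed from the exact
count pmf, so the overall addition rate is exactly 0.45. Likewise,
`P(final ∈ phase 1 | additions) = (0.87 − 0.55)/0.45`, making the overall
final-in-phase-1 rate exactly 0.87 (cases without additions place the
final option in phase 1 by construction).

### Trajectories

Only the endpoints and the monotone direction of confidence trajectories
are specified, so intermediate ratings interpolate **linearly in scale
steps** between the initial and terminal rating, rounded to integers.
To guarantee monotonicity without disturbing the calibrated *terminal*
marginals (the acceptance-tested quantities), the initial rating is drawn
from its calibrated marginal restricted to the terminal's side
(≤ terminal for finals, ≥ terminal for excluded options). This biases the
initial-confidence mean upward by ≈ 0.01 scale points — a deliberate
trade-off, since terminal calibration has priority. The last rating of an
excluded option carries the exclusion flag.

### Correlations

Two covariate correlations (experience ↔ phase-2 cue count, Pearson
−0.35; similarity ↔ final confidence, Spearman +0.31) are induced by
**rank matching** (Iman–Conover-style reordering of the metadata
covariates against the already-generated structural quantities, using
Blom normal scores with tiny jitter for tie-breaking and an iterative
adjustment of the working correlation). Reordering permutes existing
values, so all marginals remain exactly as calibrated; case *structure*
is untouched — only metadata assignments move between cases.

### Reproducibility

Each case is generated from its own substream
`default_rng(SeedSequence(entropy=seed, spawn_key=(index,)))`; cohort-
level draws (rank matching) use a separate reserved substream. Hence
cohorts are deterministic given the seed and **order-independent**: the
first k cases of an n-case cohort equal the k-case cohort structurally.

### Expert re-rater simulation

For agreement analytics, an expert re-rating is simulated by adding a
discrepancy step (default distribution over −2…+2 with perfect-match mass
1/3 and an under-confidence skew) to the resident's terminal confidence.
A step that would leave the 9-point scale is **reflected** rather than
clipped: clipping would silently inflate the perfect-match share whenever
the resident rating sits at a scale extreme (which is the majority of
final diagnoses).

## 4. Numerical choices

- All probability calibration is done on exact pmfs, not Monte Carlo.
- JSON output is byte-stable (fixed key order, 2-space indent, trailing
  newline); CSV uses a fixed header and `#key=value` metadata lines, so
  `json → csv → json` round trips are byte-identical. The option registry
  is ordered by first appearance in the event log, giving each case a
  single canonical form across dialects.
- Proportion tolerances in tests use Bernoulli standard errors; count
  tolerances use the configured SDs. Cohort-level acceptance bands are
  3 SE at n = 5000.

## 5. Limitations

- The generator reproduces means, proportions, two correlations and the
  endpoint point masses — not full joint distributions of real traces.
  Within-case dynamics (which cue triggers which rating) are scheduled
  uniformly at random.
- Initial-confidence marginals carry the small restriction bias described
  above.
- Spearman p-values use the t approximation (flagged `approximate`);
  exact permutation p-values are only feasible at very small n and are
  used as test oracles, not shipped functionality.
- The Cohen's d confidence interval is a normal approximation; no
  noncentral-t inversion is performed.
- Non-conforming real-world traces are flagged, not modelled: the
  generator only emits conforming three-phase cases.
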