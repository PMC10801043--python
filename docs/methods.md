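# Methods

This note documents the models and procedures implemented in `navassess`,
the assumptions behind the synthetic cohort generator, and the numerical
choices that were genuinely open.

## Spatial-memory metrics

Recall performance is expressed in polar coordinates with the encoding item
location as origin: `r` is the Euclidean distance between the encoding and
recalled (x, z) positions in virtual units, and `θ = atan2(Δz, Δx)` the
displacement angle in degrees on [0°, 360°). Conventions:

- **Zero direction.** The environment +x axis, counter-clockwise positive.
  θ is equivariant under rotations of the coordinate frame, so only internal
  consistency matters; the convention is stated so exported angles are
  interpretable.
- **Angle direction.** The default measures the encoding→recall displacement;
  `direction="recall_to_encoding"` flips it (a 180° shift). Both are exposed
  because the two readings of "the angle from the encoding location relative
  to the recalled location" differ by exactly 180°.
- **r = 0 trials** have no defined angle. They are included in `r`
  aggregates and excluded from angle aggregates only.
- **Angle aggregation.** Cell summaries report the arithmetic mean/SD of the
  degree values by default, matching the layout such studies print (cell
  means near 160–180° with SDs near 80–110° arise naturally from uniform
  angles on [0°, 360°)). A circular mean/SD variant (`angle="circular"`) is
  available, and is the statistically conventional choice when angles
  concentrate near 0°/360°.
- **Correctness.** A recall is correct iff `r ≤ 6` virtual units, boundary
  inclusive — the radius at which the task gives positive feedback.
- SDs are sample SDs (n−1 denominator) throughout, as is standard for
  small-cohort reporting.

## Motion analytics

Pad samples (pitch, yaw) at 100 Hz are reduced to `v_t = √(pitch² + yaw²)`,
a speed-like magnitude in tilt units: 0 means the pad is neutral, larger
values mean greater lower-limb mobility.

The encoding/recall similarity uses a Jaccard index of the two `v_t`
distributions. A literal set intersection is not computable on continuous
series, so the series are histogrammed on shared bins of width 0.05 covering
[0, max v] and compared as distributions. The default is the weighted
(min/max) Jaccard on relative frequencies,

    J = Σ_b min(p_enc(b), p_rec(b)) / Σ_b max(p_enc(b), p_rec(b)),

which is the standard continuous generalization, reproduces the 1/0 anchor
cases (identical series → 1, disjoint supports → 0), and is insensitive to
the encoding phase being longer than recall. Because which normalization the
original analysis used is not decidable from published values alone, two
labeled variants are provided: `counts` (min/max on raw counts, sensitive to
phase length) and `binary` (set Jaccard of occupied bins). The bin width is
configurable (`--jaccard-bin-width`).

Raw-density summaries count (pitch, yaw) samples in square cells of side
0.1 tilt units. Square cells are used instead of the hexagons a plot would
draw; the counts-per-cell content is the same and the total count equals the
sample count for any bin width.

Phase duration is the trace extent `(t_last − t_first)/60000` minutes; it
requires ≥ 2 samples.

## Questionnaire scoring

SUS: 10 Likert items (1–5); odd items contribute `response − 1`, even items
`5 − response`; the sum is scaled by 2.5 to [0, 100]. Scores map onto the
7-level adjective scale. The published bands are integer ranges
(0–25, 26–39, 40–49, 50–69, 70–84, 85–99, 100); fractional scores (SUS
scores are multiples of 2.5) fall between them, so the bands are implemented
as the half-open partition [0, 26), [26, 40), [40, 50), [50, 70), [70, 85),
[85, 100), {100} — no gaps, no overlaps.

ITC-SOPI negative effects: the arithmetic mean of completed items (1–5).
The scorer is length-agnostic because the instrument text is licensed
content and administered subsets vary; blank items are excluded from the
mean, and at least one completed item is required.

## Paired tests

Both the paired Student t and the Wilcoxon signed-rank test are always
reported together, as small-sample usability studies conventionally print
both. Paired t: `t = mean(d)/(sd(d)/√n)`, df = n−1, two-sided; a
zero-variance difference vector raises a typed error rather than returning
±∞. Wilcoxon: W is the **sum of positive-difference ranks** (so W = 0 when
every pair decreases); zero differences are dropped before ranking and their
count surfaced as `tied_pairs`. For ≤ 25 nonzero pairs the two-sided p is
exact — the full 2^n sign-assignment distribution computed by dynamic
programming over doubled midranks, `p = min(1, 2·min(P(W≤w), P(W≥w)))` —
and matches brute-force enumeration bit-for-bit. Beyond 25 pairs a normal
approximation with tie correction and continuity correction is used. (Note
that published small-sample Wilcoxon p-values are often the
continuity-corrected normal approximation; the exact value for W = 0 at
n = 7 is 0.0156, vs 0.0225 for the approximation.)

## Mixed-model ANOVA

Trial-level effects are tested with

    response ~ A * B + (1 | participant),   REML

so trials of participants who completed only one condition are retained
rather than dropped, and the participant intercept absorbs between-subject
level differences. With a single random intercept the marginal covariance is
`V = σ² I + τ² Z Zᵀ`, and the REML criterion profiles to a one-dimensional
optimization over `λ = τ²/σ²` with closed-form per-participant blocks
(`(I + λJ)⁻¹ = I − λ/(1+λm) J`), making fits exact, fast and free of
convergence failures. Details:

- **Contrasts.** Sum-to-zero coding; the Wald F tests are therefore
  Type-III. F-statistics are invariant to level relabeling and row order.
- **Denominator df.** Satterthwaite approximation:
  `df = 2 f² / Var(f)` with `f(θ) = ℓᵀ (Xᵀ V(θ)⁻¹ X)⁻¹ ℓ`, the gradient by
  central finite differences (relative step 1e−5) and the variance-parameter
  covariance from the inverse observed REML information (finite-difference
  Hessian, relative step 1e−4). Multi-df terms combine per-eigenvector df
  the usual way (`2E/(E−q)` with `E = Σ νⱼ/(νⱼ−2)`). Agreement with R's
  `lmerTest` on unbalanced designs is verified in the test suite to ~5
  significant digits.
- **Boundary.** A variance ratio estimated at 0 (singular fit) is reported,
  not an error; the denominator df then fall back to the residual df `n − p`
  of the fixed-effects model, and with `re_variance=0.0` forced the table
  reproduces a classic two-way fixed-effects ANOVA exactly.
- **Optimization.** Bounded scalar minimization of the profiled criterion
  over `log λ ∈ [−30, 15]`, tolerance 1e−10, with the λ = 0 boundary checked
  explicitly.
- **Errors.** A factor with < 2 observed levels or an empty A×B cell raises
  a model error naming the level; rows with missing responses are dropped.
- The v_t analysis aggregates each phase trace to its mean v_t per
  participant × phase × condition before the ANOVA (phase-average response);
  the trial-level error analysis uses every trial.

## Synthetic cohort generator

The generator's defaults are the study conditions; they exist to make every
downstream contract testable, not to be tuned per run.

- **Design.** 7 participants; dropout pattern `both ×5, semi_only, none`
  (11 sessions); per completed session 4 items × 4 repetition blocks = 16
  trials. The landmark cue is assigned per recall block — two allocentric
  and two egocentric blocks in random order, matching random presentation
  while keeping each session balanced. Items sit at 90° spacing on a circle
  of radius 20 virtual units. The generator labels cells abstractly as
  allocentric/egocentric without committing to which physical landmark
  (obelisk vs arcade) maps to which strategy.
- **Recall noise.** `rec = enc + N(0, σ² I)` with σ per landmark × condition
  cell. Isotropic Gaussian displacement is the simplest model with
  closed-form consequences: `r ~ Rayleigh(σ)`, so `E[r] = σ√(π/2)`,
  `SD[r] = σ√((4−π)/2) ≈ 0.655σ`, the correct-recall probability is
  `1 − exp(−6²/(2σ²))`, and θ is uniform. The default cell σ values
  (16.52, 21.12, 16.91, 16.40) are back-solved from published cell means of
  ~20.6–26.5 virtual units via the Rayleigh mean — and the implied Rayleigh
  SDs (10.7–13.8) match the published cell SDs (10.8–12.9), which supports
  the isotropic-Gaussian choice. These laws power the recovery tests: at
  ≥ 10,000 trials the empirical mean error must sit within 2% of `σ√(π/2)`,
  the correct fraction within binomial bounds of the Rayleigh CDF, and θ
  must pass a 36-bin chi-square uniformity test at α = 0.001.
- **Motion traces.** Per phase, an Ornstein–Uhlenbeck tilt process per axis,
  discretized exactly as AR(1) (`φ = exp(−κ·0.01 s)`), started from its
  stationary law, then clipped to [−1, 1]. Defaults κ = 1 s⁻¹,
  volatility 0.35 s^(−1/2): stationary tilt SD ≈ 0.247, hence mean v_t
  ≈ 0.247·√(π/2) ≈ 0.31, inside the 0.29–0.40 range such studies report.
  The clip sits ≈ 4 stationary SDs out, so post-hoc clipping (vectorized)
  is statistically indistinguishable from stepwise clipping. Traces have
  exactly `round(minutes × 6000)` samples at 10 ms spacing, and the stored
  duration is the sample-exact `n/6000`.
- **Durations.** Encoding: mean 10.3 (SD 3.21) min immersive, 8.51 (2.29)
  semi-immersive — the published per-condition encoding times. Recall
  durations are not published; 6.0 (2.0) min is used for both conditions as
  a plausible shorter-than-encoding phase. Draws are floored at 0.05 min.
- **Questionnaires.** A participant-level latent trait shared across
  conditions (correlation ρ = 0.8) plus condition noise gives each
  participant a latent score aimed at the per-condition target mean/SD
  (SUS: 65/22.97 immersive, 69.17/25.52 semi-immersive; ITC-NE: 2.03/0.91,
  1.53/0.56). SUS items are generated polarity-correctly from the latent
  usability level; ITC-NE items (6 by default) from the latent mean. All
  item latents are rounded and clamped into 1–5. Rounding compresses
  extreme scores slightly, so realized cohort means track targets
  approximately (within ~5 SUS points in large cohorts), not exactly. The
  within-participant correlation exists so paired tests see the
  within-subject consistency a real cohort would show.
- **Randomness.** One root seed; substreams via
  `SeedSequence(seed, spawn_key=(participant, condition, stream))`, so
  regenerating any participant never perturbs the others. The frozen
  reference fixture pins seed 20240108 and uses ~0.5 min phases to stay
  test-fast.

**What the generator does not emulate.** Recall displacements are
independent across trials and isotropic — no item-specific bias, no
perseveration, no boundary effects of the arena. Motion traces are
stationary — no guided-path structure in encoding, no stop-and-go search in
recall; consequently encoding and recall magnitude distributions are far
more similar than in real data, and synthetic Jaccard values (~0.9) sit well
above the ~0.3–0.5 a real cohort yields. Questionnaire items are
conditionally independent given the latent trait. Passing recovery tests
therefore validates the pipeline's arithmetic and the generator's stated
laws — it does not certify behavior on real cohorts beyond the format and
invariant checks.

## Problem sizes

The test suite and the acceptance script use: the 11-session reference
cohort with ~0.5 min traces for example-based tests; 313-participant
(10,016-trial) cohorts with 0.05 min traces for the Rayleigh/uniformity
recovery laws; 200 seed-pinned null replicates (7 participants × 224 trials)
for mixed-model type-I calibration; and the full-duration default cohort for
the end-to-end acceptance run. These sizes keep every statistical check
well-powered while the whole suite runs in well under a minute of
computation per heavy test.

## Known limitations

- The exact-p Wilcoxon path is O(n · Σ ranks) dynamic programming — fine for
  the ≤ 25-pair regime it serves; larger samples use the approximation.
- The mixed model supports a single random intercept (the design's grouping
  structure); random slopes or crossed random effects are out of scope.
- The deposit-import adapter recognizes only the package's own log format;
  mapping an external archive requires inspecting its actual layout and is
  deliberately left as an explicit error listing the files found.
- Satterthwaite df rely on finite-difference derivatives; near-singular fits
  fall back to residual df rather than reporting unstable values.
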