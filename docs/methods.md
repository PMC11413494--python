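# Methods

## Ballistic reconstruction

Jumps are modelled as drag-free projectile motion with take-off and landing
at the same height, which is accurate for the low (< 15 cm), short
(< 0.5 s) evasive leaps these rodents make when startled. Given horizontal
displacement *d* and airborne time *t*, the take-off velocity components
are `v_h = d/t` and `v_v = g t / 2` with `g = 9.8 m s^-2` (kept at two
significant figures deliberately, matching how the quantity enters the
field analysis rather than the geodetic standard 9.80665). Take-off speed,
angle and jump height follow algebraically; note that jump height depends
on airborne time alone (`h = g t^2 / 8`). A zero displacement is treated as
the vertical-jump limit (angle = 90°), not an error, via `atan2`. The
forward model `t = 2 v sin θ / g`, `d = v cos θ · t` is the exact inverse;
round-trip error is at machine precision (checked to 1e-9 across a dense
speed × angle grid).

What the model omits: air resistance (negligible at these speeds and
masses), landing-height offsets, and the distinction between toe and
centre-of-mass trajectories. Absolute heights are therefore nominal
toe-path heights; comparisons across species are unaffected because the
same convention applies to every trial.

## Frame timing

Recordings run at 120 fps (ground squirrels, from an earlier study) or
240–250 fps (all other species), so one frame is 8.3 ms or 4.0–4.2 ms.
Event frames (first cork movement, first visible reaction, frame preceding
toe-off, landing) convert to milliseconds through the frame period;
reaction time is cork-to-reaction, take-off time is reaction-to-toe-off,
and overall response time is their sum. Frame digitization error is about
±2 frames, which the simulator reproduces. 500 fps material is
down-sampled by integer factors (index `i -> i // factor`), which preserves
event order and times to within one target-frame period.

## Synthetic trial generator

The generator emulates the study conditions, one row per individual
(animals are tested once):

* **Escape mode** ~ Bernoulli(jump propensity). Default propensities are
  the observed per-species jump fractions (0.625, 0.926, 0.739, 0.909,
  0.071, 0.087 for DIME, DIDE, DISP, CHPE, NEAL, OTBE).
* **Body mass, reaction time, take-off time** ~ truncated normals with the
  per-species field means; only mean ± SE are reported in the field, so the
  per-animal SD is recovered as `se · sqrt(n)` using the per-metric n. The
  distribution family is a modelling choice — truncated normals are the
  simplest family matching the printed moments. Reaction time is truncated
  at 4 ms (faster is physiologically implausible); mass and take-off time
  at zero. Merriam's kangaroo rat gets mode-specific take-off means
  (88 ms jump / 126 ms scramble); its mixture mean reproduces the pooled
  103 ms.
* **Jump performance**: latent take-off speed (truncated > 0) and angle
  (truncated to (0°, 90°)) are drawn and projected through the forward
  ballistic model, so pre-noise displacement and airborne time satisfy the
  reconstruction equations exactly. Woodrats and ground squirrels carry no
  performance moments; their (rare) jumps have null displacement, matching
  the field data.
* **Measurement noise**: displacement rounds to 0.01 m (tape-measure
  precision); every timed quantity snaps to the species frame grid with a
  uniform integer jitter in [−2, +2] frames. Airborne and take-off times
  are clamped to a minimum of one frame — a jump or a take-off that spans
  zero frames cannot be scored.
* **Censoring**: each trial draws hit-by-cork, premature-reaction and
  poor-video flags (defaults 0.11, 0.011, 0.05 — the first two are the
  study-wide observed rates, 20/180 and 2/180); jumps additionally draw an
  off-screen flag (0.05). Flags null exactly the fields the corresponding
  field failure loses (timing for the first three, displacement/airborne
  for off-screen).

Each trial uses an independent RNG substream spawned from the seed, so the
same seed yields the same latent animals whether measurement noise is on
or off, and output is byte-identical across runs.

The generator does **not** emulate: within-site or within-year structure,
ambient-light effects, repeated encounters or learning, correlations
between metrics within an animal beyond those induced by the ballistic
model, or the concentration of hit-by-cork censoring in slow-reacting
species. Passing recovery tests therefore show the pipeline is unbiased
under the stated generative model, not that field data meet that model.

## Size correction

Each performance metric is log-transformed (natural log; the base shifts
only the intercept and leaves residuals unchanged) and regressed on log
body mass by OLS over the pooled species; residuals form the "overall
performance" matrix. Individuals without a mass are dropped. Zero variance
in log mass (a degenerate input) falls back to intercept-only centering
with a warning rather than failing. Take-off angle is strictly positive in
practice, so the log applies without offsets; non-positive values are
rejected. The default metric set is take-off time, take-off angle and jump
height; a velocity-based set (take-off velocity, jump height, angle) is
equally supported through the analysis config because either trio is a
defensible operationalisation of jump performance — the package asserts
neither as canonical.

## Inference

**PERMANOVA** is implemented from first principles on Euclidean distances
of the unit-standardized residuals: `SS_total = Σ_{i<j} d²_ij / n`, within
sums analogously per group, `pseudo-F = (SS_b/df_b)/(SS_w/df_w)`, with the
null built by permuting raw group labels — adequate for a one-factor
design. The p-value uses the `(+1)/(n_perm+1)` convention (the observed
statistic counts as a permutation), so p is never 0 and is bounded below by
`1/(n_perm+1)`. With univariate input the pseudo-F equals the classical
ANOVA F exactly (tested to 1e-9), and the implementation is cross-checked
against scikit-bio's. Degenerate all-coincident input returns F = 0.

**Tukey HSD** uses the studentized-range distribution with the
Tukey–Kramer standard error `sqrt(MSE/2 (1/n_i + 1/n_j))`; samples here are
always unbalanced, so the Kramer correction is applied throughout. Letters
come from the insert-and-absorb algorithm: one letter set over all groups,
split on each significant pair, subsets absorbed, columns ordered by group
mean (descending, ties by label). Groups sharing no letter differ at
α = 0.05; α is fixed at the conventional 0.05 throughout.

**Logistic regression** (jump vs scramble on reaction time) is fit by
maximum likelihood; the odds ratio is per millisecond. Single-class
outcomes and perfect separation raise an explicit error instead of
returning a divergent fit.

## Pipeline rules

* Timing analyses keep both escape modes (jump probability is unrelated to
  reaction time, so pooling is justified) and drop hit-by-cork, premature
  and poor-video trials; performance analyses keep on-screen, well-recorded
  jumps with complete displacement and airborne time, plus a mass and
  strictly positive metrics.
* A species enters the performance branch only with ≥ 3 complete jump
  records (the woodrat and ground squirrel never qualify, mirroring their
  exclusion in the field); the PERMANOVA runs only when ≥ 2 species
  qualify. Within-species mode analyses need ≥ 5 usable trials of each
  mode.
* Jump percentages round half away from zero to the nearest integer
  (30/48 → 63%).
* Every exclusion is counted per rule and logged; excluded + analyzed
  equals input for each branch.
* Reaction- and take-off-time models use raw values, not size-corrected
  ones. Ambient light is deliberately not modelled (field measurements had
  almost no variation above the light meter's sensitivity floor).

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 40–200 simulated trials
per species, 199–999 permutations, and 1,000 replicates for the type-I
error study (n = 20, four groups, 199 permutations each), sizes at which
every check completes in seconds while leaving Monte-Carlo error well
inside the asserted bands. All randomness flows from explicit integer
seeds; rerunning any analysis with the same seed and config reproduces the
serialized report byte for byte.

## Known limitations

Absolute jump heights reflect startle responses, not maximal performance.
Size correction and species identity are partly confounded (the pocket
mouse is half the mass of the smallest kangaroo rat), which lowers power to
detect species signals in corrected performance. Phylogenetic comparative
methods are out of scope (too few species for them to be meaningful). The
letter display can occasionally be non-minimal for pathological
significance graphs; it is always consistent (significant pairs never
share a letter).
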