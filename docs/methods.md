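# Methods

This note records the scientific model the package implements, the
defaults and why they were chosen, what the synthetic cohorts do and do
not emulate, and the numerical and design decisions that were genuinely
open.

## Refraction model

A sphero-cylindrical reading (S, C, α) is stored in negative-cylinder
form (positive-cylinder input is transposed to `(S+C, −C, α+90)` on
ingest) with the axis in the half-open interval [0, 180); axis 180
normalizes to 0, and a zero cylinder stores axis 0 because the axis is
then meaningless. Conversion to power-vector coordinates uses

    SE  = S + C/2,   J0 = −(C/2)·cos 2α,   J45 = −(C/2)·sin 2α.

Because the double angle makes the representation single-valued, replicate
readings are averaged component-wise on (SE, J0, J45). Averaging raw axes
is never done: readings at 10° and 170° have oblique components that
cancel, whereas a naive axis mean of 90° would flip the J0 sign. Whether
the instrument's on-board three-reading average is vector-based is not
something the package can know; vector averaging is what the power-vector
formalism prescribes and is adopted throughout.

The inverse map is `C = −2·√(J0²+J45²)`, `S = SE − C/2`,
`α = ½·atan2(J45, J0)` reduced into [0, 180). With C ≤ 0 the forward map
scales `(cos 2α, sin 2α)` by the positive factor −C/2, so the double
angle is recovered directly from (J0, J45); the round trip is exact to
1e-9 D / 1e-6° and is enforced by property tests.

## Classification criteria

All thresholds live in one `RefractiveCriteria` object; the shipped
default is the profile recommended for the PlusOptix pediatric
autorefractometer:

| quantity | < 6 years | ≥ 6 years |
|---|---|---|
| myopia | SE ≤ −1.00 D | SE ≤ −1.00 D |
| hyperopia | SE ≥ +1.25 D | SE ≥ +1.00 D |
| astigmatism | \|C\| ≥ 1.00 D | \|C\| ≥ 1.25 D |
| anisometropia | IOD ≥ 1.25 D (SE or C) | same |

The emmetrope band is the open interval between the myopia and hyperopia
thresholds, so the per-eye SE partition has no gaps or overlaps by
construction. Ages are completed years; age exactly 6 uses the ≥ 6
column. The anisometropia cutoff is configurable (the 1.00 D literature
convention can be set for cross-study comparisons).

Anisometropia metrics are SA = |SE_RE − SE_LE| and MA = |C_RE − C_LE| on
negative-form cylinders, with MA computed from the cylinder implied by
each eye's mean power vector. Typing of total-anisometropia (TA) cases:
simple meridional (sMA) when MA reaches the cutoff but SA does not;
antimetropic when one eye is myopic and the other hyperopic; myopic when
at least one eye is myopic and the other is myopic or emmetropic;
hyperopic symmetrically. Severity is banded on max(SA, MA): low below
2.00 D, high from 2.00 through 6.00 D (both endpoints high, since "below
2" excludes 2 and "above 6" excludes 6), very high above.

Three rules had to be decided here because the clinical definitions leave
them open:

* **SA with two emmetropic eyes.** The emmetrope band is 2.00–2.25 D wide
  while the cutoff is 1.25 D, so a participant can have SA above the
  cutoff with both eyes labeled emmetropic — a case the standard typing
  rules do not cover. The sign of the more ametropic eye's SE decides
  (negative → myopic, otherwise hyperopic).
* **Person-level SE label.** The person is labeled myopic/hyperopic when
  either eye qualifies; when the eyes conflict (one myopic, one
  hyperopic, outside TA) the larger-|SE| eye decides and an exact tie
  goes to myopia, keeping the rule deterministic and eye-swap symmetric.
  A `right_eye` rule (right eye decides alone) is available as a config
  switch since screening reports often tabulate right-eye data.
* **Precedence.** Person categories are mutually exclusive:
  anisometrope > myope > hyperope > simple astigmat > emmetrope.
  Simple astigmatism is only assigned when the deciding SE is emmetropic;
  an astigmatic eye that is also SE-ametropic sets a separate
  compound-astigmatism flag rather than a category, so the five category
  counts always partition the cohort.

## Statistics

* Proportions use the Wilson score 95% interval by default (Wald and
  Clopper–Pearson switchable). Wilson behaves well at the small
  proportions typical of anisometropia (~6%) and never leaves [0, 1];
  coverage at p = 0.06, n = 749 is verified by simulation to lie in
  93–97%.
* Association tests are uncorrected Pearson chi-squares on the 2×K
  outcome-by-factor table (df = K−1). No Yates continuity correction is
  applied: on 2×2 screening tables of this size the corrected test is
  conservative and does not reproduce standard published values (e.g.
  0.36 instead of 0.29 on the gender×TA counts the tests use); the
  uncorrected statistic is also what the brute-force Σ(O−E)²/E oracle in
  the test suite computes. Expected cells below 1 attach a warning but do
  not suppress the test. No multiple-testing adjustment is applied, and
  the report says so.
* Records with a missing stratifier level are dropped from that test
  only, never imputed.
* The sample-size bound is `n = z²p(1−p)/e²`; both the truncated integer
  (matching the "minimum of N" convention, 384.15 → 384) and the
  conservative ceiling (385) are returned.
* Reported percentages are rounded half-up (1 decimal for prevalences,
  integers for type shares). Note one knock-on effect: a 9/46 share
  prints as 20% under this convention even where 19% is sometimes quoted;
  the convention is applied uniformly rather than special-cased.

## Synthetic cohorts

`simulate_cohort` emulates a school-based screening sample from the
central-Portugal setting the defaults describe: n = 749; school-cycle
shares 13.8/30.8/24.2/31.2% (preschool 3–6 y, cycles 6–10, 10–12,
12–15 y, integer ages uniform within cycle); gender 53.3% male;
residence 42.7% rural / 56.5% urban / 0.8% missing. Each participant gets
a shared two-eye base refraction from a state mixture (emmetrope .758,
hyperope .155, myope .070, simple astigmat .017 — the mixture among
non-anisometropes implied by the category partition the classifier is
validated against), with SE drawn from truncated normals: myopic
−2.67 ± 1.32 D, hyperopic +1.46 ± 0.59 D, emmetropic +0.50 ± 0.50 D
truncated to the age-appropriate band (mild physiological hyperopia being
the documented norm in children). Cylinders are half-normal (SD 0.45 D)
below the astigmatism threshold except for simple astigmats
(−1.50 ± 0.33 D); axes are uniform on [0, 180).

Anisometropia is injected per cycle at rates rising 2.9% → 9.4%
(preschool 2.9, then 5.0 and 7.0 interpolated, 9.4 in the 3rd cycle — the
two intermediate rates are not published and are labeled interpolated),
with type mix myopic 46% / hyperopic 33% / sMA 19% / antimetropic 2% and
IOD magnitudes drawn so about 67% of cases are low severity (< 2.00 D;
high-severity draws are uniform on 2.0–3.5 D, matching the observed IOD
range of screening samples). The worse eye is chosen at random.
Corrective-wear status depends on the truth category (so uncorrected
anisometropes exist), with a small missingness rate.

Replicates are truth plus independent N(0, σ) noise per power-vector
component (default σ = 0.25 D, a realistic test–retest spread for
non-cycloplegic autorefraction; recovery experiments use 0.1 D), then
converted back to (S, C, α) on the CSV grid (0.01 D, integer degrees).
Noise in power-vector space keeps axis noise well-defined near the 0/180
wrap.

Two guarantees are engineered in: (1) truth refractions are snapped to
the CSV grid and kept ≥ 0.02 D away from every classification boundary,
so with σ = 0 the classifier recovers every injected label exactly, even
after a CSV round trip — a zero-noise identity the tests assert; (2)
truth labels attached to the cohort are produced by running the
classifier on the noise-free truth values, so truth and pipeline share
one semantics, and the injected flags are asserted to coincide with them.
Nothing is clamped to the instrument range (−7.00 to +5.00 D), so noisy
draws can exercise the range-exclusion filter.

What the generator does **not** emulate: compound astigmatism in the base
states (non-astigmat cylinders stay below threshold, so compound cases
arise only via the hand-built fixture and noise), within-school
clustering, emmetropization or any longitudinal structure, correlation
between residence and refraction, and very-high (> 6 D) anisometropia
except through extreme antimetropic draws. Passing recovery tests
therefore show that the pipeline is a consistent estimator under
independent Gaussian measurement noise at realistic rates — not that it
is robust to instrument bias, accommodation artifacts or clustered
sampling.

## Pipeline and I/O conventions

Exclusion is participant-level: any replicate with sphere or cylinder
strictly outside the closed instrument range [−7.00, +5.00] D removes the
whole participant (reason `out_of_range`), as do a missing eye or fewer
than three replicates on an eye. Boundary values (exactly −7.00 or +5.00)
are retained, reading "exceeded the limit" as strictly outside. Axis
values outside [0, 180) are reduced modulo 180 with a warning; malformed
rows land in a parse report, never silently dropped. Every run checks the
accounting identity input = analyzed + excluded and writes its resolved
config, seed and package version into `run.json`.

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical (config, seed) produces byte-identical
cohort CSVs.

## Problem sizes used in validation

The shipped checks use cohorts of n = 749 (study-shaped pipeline runs,
pooled over ten draws for per-cycle rates), n = 5,000 for parameter
recovery (200 replicates at 0.1 D noise in the test suite, 50 in the
acceptance script), 2,000 binomial simulations for CI coverage, and a
20,000-participant draw for stratum-shape checks. These sizes put
Monte-Carlo error well below the tolerances being asserted while keeping
the full suite around ten seconds.

## Known limitations

* Non-cycloplegic autorefraction underestimates hyperopia; the
  classification thresholds partly compensate but the package makes no
  correction.
* The typing fallback for both-eyes-emmetropic SA and the worse-eye tie
  rule are package conventions; alternative conventions would reclassify
  a small number of borderline participants.
* The chi-square is asymptotic; small strata trigger a warning rather
  than an exact test.
* Reading real screening exports requires mapping their column layout
  onto the documented schema first; the reader validates but does not
  guess foreign layouts.
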