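# Methods

This note documents the models implemented in `colorcat`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not establish.

## Task and stimuli

The paradigm is a four-alternative forced-choice (4AFC) delayed
match-to-sample color task: a colored cue is shown, then four choice colors
of which exactly one is a direct match; the subject selects one.  Stimuli
are 64 colors evenly sampling CIELUV hue angle (5.625° apart) on an
equiluminant plane: L\* = 76.0693, u\*v\* radius (chroma) 37, around an
adapting field of chromaticity xy = (0.2684, 0.2409) at 38.5 cd/m².
`colorcat.colorspace` stores this geometry and converts stimuli to XYZ with
the CIE 1976 u′v′ formulation against the stored white point — the adapting
chromaticity is not a standard illuminant, so no D-illuminant assumption is
baked in.  Hue index 0 sits at CIELUV hue 0° (positive u\* axis) by
convention; a `phase` argument rotates the ring, and every analysis is
rotation-equivariant, so the origin only affects labeling.

Signed hue differences live in (−180°, +180°] with the antipodal tie broken
to +180° so the arithmetic is deterministic.

## Choice model (TCC-v)

A trial's response is modeled as a race between noisy evidence samples:
each offered choice i draws

    X_i ~ Normal(m_i · δ, 1)

and the argmax is selected.  m_i ∈ [0, 1] is the perceptual similarity of
choice i to the cue and δ is signal-detection sensitivity (d′).  The
similarity function is a bare Gaussian of hue distance,
f(θ) = exp(−θ²/2σ²), evaluated un-normalized on (−180°, 180°] (no circular
wrapping: at the widths relevant here the tails reach a floor well inside
the domain).  Four variants differ in what may vary per color:

| variant | structure | free parameters (reported k) |
|---|---|---|
| null | one f(θ) for all cues | σ, δ (2) |
| cognitive bias | per-cue peak offsets μᵢ (categories pull matches toward attractors) | σ, δ, 64 offsets (66) |
| stimulus nonuniformity | per-neighbor perceptual distances Dᵢ warp the hue circle; f stays peaked at the cue | σ, δ, 64 distances (66) |
| free similarity | every (cue, choice) cell independent; δ fixed | 4,096 cells |

The distances Dᵢ are constrained positive with ΣD = 360°, which pins the
scale degeneracy between D and σ.  Internally they are parameterized as
360·softmax of 64 logits with logit 0 pinned, so the identifiable dimension
is 65 rather than the conventionally reported 66; fit results expose both
(`n_params` and `effective_n_params`).  Offsets are bounded to ±45° to
prevent peak-label swapping.  For the free-similarity variant δ is fixed
(default 1) because it trades off exactly against the range of the matrix;
cells never offered for a cue are uninformed and are reported as NaN with a
mask.

Choice probabilities are

    P(n) = ∫ φ(x) ∏_{i≠n} Φ(x + δ(m_n − m_i)) dx,

evaluated with probabilists' Gauss–Hermite quadrature, 61 nodes by default.
A 31-node evaluation agrees with the 61-node reference to ~1e−8 in a
25,000-trial log likelihood and is used as the fast path in bulk fitting.
The test suite validates the quadrature against adaptive integration
(1,000 random configurations, max |ΔP| < 1e−4 demanded, ~1e−10 achieved),
against a 10⁷-draw Monte-Carlo oracle, and against the 2-choice closed form
Φ(δΔm/√2).

Fitting is maximum likelihood: probabilities floored at 1e−12 before the
log, bounded L-BFGS-B on transformed parameters (log σ, log δ, raw offsets,
distance logits, logistic similarity cells) with analytic gradients
(verified against finite differences), multi-start (default 5 restarts;
bulk experiments use 1 restart with informed starts).  The 66-parameter
variants warm-start from a quick null fit; the nonuniformity variant
additionally seeds its distances from per-cue mixture widths — a wide
selection profile marks a densely sampled region of the underlying space,
so the local warp rate is proportional to the inverse width.  Convergence
is a relative function-decrease tolerance (`ftol`, default 1e−9 ≈ 1e−5
absolute on a 25k-trial NLL).

Model comparison uses AIC = 2k + 2·NLL and BIC = k·ln(n) + 2·NLL with n the
number of completed trials, plus a subject-level bootstrap: each repeat
draws an equal number of trials with replacement from every subject, pools
them, fits both competing variants, and records the BIC pair.

## Mixture-model analysis

The descriptive pipeline tallies, for each cue, how often each choice color
was offered and selected, and fits the selection *frequency* (selected /
offered — normalization removes foil-sampling noise) as a function of
θ = hue(choice) − hue(cue) with a Gaussian plus floor:

    f(θ) = α·exp(−(θ−μ)²/2σ²) + ζ.

Points are weighted by binomial standard errors; parameter covariances are
scaled by reduced χ², which keeps the CIs honest although the Gaussian
shape is only an approximation of the race model's true profile (null-agent
simulations at 50,000 trials show the 95% CI on μ covering zero for ≥60 of
64 cues).  Fits with an unresolved peak (height below twice its standard
error, or width pinned at the 2° lower bound) are flagged and excluded;
their μ values are interpolated circularly before smoothing.  The per-cue
biases are smoothed with a circular 3-point moving average (16.875°).

Zero-crossings of the smoothed bias curve are located by linear
interpolation between adjacent cues; negative slope marks an attractor
(category center), positive slope a repeller.  **Significance rule** (the
one genuinely open design point): a crossing is significant when, within
the same-sign lobe of the curve on each flank, at least one cue's
*simultaneous* 95% band (Šidák-corrected over the 64 cues) excludes zero.
Two alternatives were rejected on statistical grounds: requiring the two
points immediately straddling the crossing to exclude zero essentially
never fires, because those points sit within half a step's slope of zero by
construction; and per-cue pointwise 95% bands certify noise wiggles — on
category-free data they flagged a false category in 28 of 30 replicates of
24,526 trials.  The simultaneous-band rule operates at its nominal level:
5 of 100 category-free replicates show a (weak) significant crossing,
driven by per-cue fits whose width lands in the narrow tail and whose
linearized μ SE is then optimistic, while both true attractors in the
scenario simulations are detected with band z-scores an order of magnitude
above threshold.
Crossing-angle CIs come from a trial-level bootstrap (resample trials with
replacement, re-run the pipeline, percentile interval of the matched
crossing angles).

The psychometric curve is a Weibull in trial difficulty ω (hue distance
from the cue to its nearest foil), y = ζ + (100−ζ−γ)(1−exp(−(ω/λ)^k)),
fitted to percent correct at the grid's exact difficulty levels with two
weighting passes (observed-proportion variances, then variances from the
fitted curve — one-pass weighting biases the asymptote).  The lapse rate is
100 minus the fitted curve averaged over the top decile of ω.

## Synthetic agents

Agents share the similarity/choice machinery of the fitted models, so their
empirical selection frequencies converge to `choice_probability` at the
generating parameters by construction of the code path, and the generator
doubles as the simulation oracle for the fitting code.  Cues are uniform;
three foils are drawn uniformly without replacement from the remaining 63
colors; positions are shuffled; a single seeded generator makes tables
byte-reproducible.  Cue eccentricities, delays, fixation, and reward are
not modeled — they enter no analysis equation; only completed-trial content
exists.

Default generating parameters, chosen once as realistic for this task and
held fixed: similarity width σ = 20°, sensitivity δ = 2 (≈72% accuracy,
comfortably above the 25% floor and below ceiling).

The two matched mechanism scenarios emulate the pivotal simulation design:

* **Cognitive**: two attractors at 17° and 212°.  Per-cue offsets are
  g(d) = 10°·tanh(d/30°) of the signed distance d to the nearest attractor
  — an odd, saturating ramp (bounded well inside the ±22.5° cap), with sign
  flips (repellers) midway between the attractors.  The exact shape of g is
  not prescribed anywhere; tanh is the smoothest saturating choice.
* **Nonuniform**: a category-free agent whose 64 neighbor distances are
  solved by least squares (63 free logits, Levenberg–Marquardt) so that its
  similarity-weighted mean-bias curve matches the cognitive scenario's on
  every cue (agreement < 0.5° everywhere).  The match is enforced on the
  similarity-centroid curve; the mixture-*fitted* bias curves of the two
  scenarios then agree empirically (same significant crossings within one
  stimulus step at ~98k trials).

A third generator, a 2-cycle sinusoidal warp (distances
(360/64)·(1 + 0.45·sin), range 3.1–8.2°), provides a *well-identified*
nonuniformity for parameter-recovery and uniformization experiments: every
step stays well inside σ, so the data inform every distance.  This matters
because identifiability of a neighbor distance collapses once a gap exceeds
~2σ — similarity across it is near zero either way.  The bias-matched
scenario above needs gaps up to ~51° (2.6σ) to mimic a 10° bias amplitude,
and those few extreme steps are recovered only to several degrees even at
10⁵ trials, while σ and δ recover to <1%.  Relatedly, at 10⁵ trials the
per-step ML error for the sinusoidal warp is unbiased sampling noise of RMS
≈1.2° (verified uncorrelated across seeds), so the *maximum* error over 64
steps concentrates near 3°; mean error is ≈1°.  A reader of the recovery
numbers should expect max-type summaries to sit at ~2.5× the RMS.

What the synthetic experiments do **not** show: agents are stationary (no
learning, drift, serial dependence, or lapse dynamics beyond δ), foil
sampling is exactly uniform, and every trial is completed.  Passing tests
therefore validate the inference machinery, not the behavioral assumptions;
on real data the reader contract (`colorcat.pipeline.validate_trials` with
a column mapping) enforces only the structural invariants.

## Uniform color space (MUCS)

The fitted neighbor distances of the nonuniformity model, accumulated
around the circle (anchored so stimulus 0 maps to hue 0 — the rotation is
unidentifiable), define new hue angles under which the subject's matches
are on average unbiased.  Forward and inverse maps interpolate linearly in
hue angle between bracketing stimuli, circularly; they are exact inverses
(round-trip error < 1e−9° is asserted, ~1e−12 observed).  ΣD is normalized
to 360°.  The end-to-end check re-samples 64 stimuli evenly in the derived
space, drives the *original* warped agent with them, refits, and verifies
the structured (2-cycle) Fourier component of the refitted distances
collapses to a small fraction of the original warp amplitude — the
structured component is the sharp readout because sampling noise spreads
over all modes.

## Problem sizes

Simulation scales used by the test suite and `scripts/acceptance.py`,
chosen to match the study's natural scales where one exists: 24,526 trials
(the smallest per-subject count, used for the false-positive control and
bootstrap draws), 98,104 = 4 × 24,526 (the pooled mixture analysis),
25,000 for single-fit recovery and model selection, and 100,000 for
distance recovery.  Model-selection consistency uses 20 replicates per
scenario; the false-positive control uses 100 replicates; bulk fits use the
31-node fast path and single informed starts as described above.

## Known limitations

* The similarity kernel is a bare Gaussian; the original convolution of a
  Gaussian with an exponential is intentionally out of scope.
* No combined cognitive + nonuniformity model; the two are compared, not
  mixed.
* Distances spanning more than ~2σ are weakly identified (see above).
* Mixture-fit CIs are approximate (linearized, χ²-scaled); the category
  detector relies on the simultaneous band plus lobe logic rather than on
  exact pointwise coverage.
* MUCS extends only around the hue circle; lightness and chroma are fixed.
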