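# Methods

## The observer model

The model treats elevation localization as Bayesian inference over a
discrete set of candidate elevations (the hoop grid, −60…+85° in 2.5°
steps).  All spectra live on a log-frequency grid (default 64 bins per
octave over 0.5–20 kHz) in dB, because the compressive cochlea turns the
time-domain convolution of source and pinna filter into a spectral sum:
S(f; ε\*) = H(f; ε\*) + X(f).

**Weighting.** The band-reliability profile is the beta-form bump
w(f) = a (f − f_min)^α₁ (f_max − f)^α₂ on (f_min, f_max), zero outside,
with defaults α₁ = 4.5, α₂ = 1.5, (f_min, f_max) = (3.5, 12) kHz.  Its
analytic maximum is at (α₁ f_max + α₂ f_min)/(α₁ + α₂) = 9.875 kHz.  The
scale a is not identifiable — only relative weights survive the
correlation stage — and is fixed by max w = 1.

**Correlation stage.**  C(ε | ε\*) is the *weighted Pearson correlation*
between the sensory spectrum and the stored template H(f; ε), computed
over the analysis band (default 3–12 kHz) with w(f) as the per-bin
importance entering the means, variances and covariance.  Two properties
drove this choice:

* *Exact veridicality.* For a flat source of any level the sensory
  spectrum is the true template plus a constant, and a (weighted) Pearson
  statistic is invariant to constant offsets, so C peaks at 1 at the true
  elevation; template uniqueness then guarantees a strict maximum.
* *No level leakage.* Correlating the literally weighted spectrum
  w·(H+X) in absolute dB against templates is degenerate: the term
  (stimulus level)·w(f) — e.g. 65 dB times the weighting bump — dominates
  both the shape and the variance of the comparison and carries no
  elevation information.  Mean correction must happen under the weighting
  (i.e., the weighting defines the metric), not after it.

A one-sided literal mode (plain Pearson of w·S against raw templates,
`weight_templates=False`) is retained for comparison.  Correlations with
a zero-variance argument are defined as 0: a flat vector carries no shape
information, and this avoids 0/0.

**Likelihood, prior, decision.** The likelihood is the half-wave
rectified correlation.  The prior over elevations is near-uniform by
default (the regime the simulations use) or Gaussian around straight
ahead with σ_prior (default 25°).  The posterior is the normalized
product; if rectification leaves no mass (all correlations negative) the
posterior falls back to the normalized prior — the Bayesian limit of no
evidence.  The MAP readout breaks exact ties toward the smallest |ε|,
then the smallest ε (a deterministic centrality preference); a
posterior-sampling readout is available as an alternative decision rule.

## The canonical HRTF set

No measured HRTFs ship with the package; `make_canonical_hrtfs` builds a
parametric set carrying the features of real midsagittal pinna spectra
that the model needs, each with explicit parameters (defaults in
parentheses):

* **Ear-canal resonance** — Gaussian bump in log-frequency at 2.5 kHz
  (+15 dB, σ = 0.35 oct), identical at every elevation.
* **Primary notch (N1)** — negative Gaussian (σ = 0.25 oct) whose center
  rises linearly from 5.5 kHz at −60° to 10.5 kHz at +85° (through the
  6–9 kHz band over the central elevations) and whose depth shrinks from
  12 dB at the bottom to 70% of that at the top.
* **Secondary notch (N2)** — at 1.8× the N1 center, 10 dB at the lowest
  elevation fading to zero at the top.  At low elevations N2 falls near
  10 kHz, giving those templates structure inside the heavily weighted
  upper band.
* **Mid-band peak** — Gaussian at 7.5 kHz (σ = 0.35 oct) scaling from
  0 dB at −60° to +5 dB at +85°: high-elevation pinna spectra concentrate
  energy in the former notch region.
* **Low-band ramp** — ±~2 dB monotonic elevation cue confined to
  3.5–6.5 kHz (0.03 dB/deg), the weak but systematic 4–6 kHz cue.
* **High-band ripple** — seeded sinusoid above 11 kHz (1.5 dB, ~4
  cycles/oct, rate and phase drawn per elevation), the erratic
  idiosyncratic structure of the top of the spectrum.

Generated gains stay within the −15…+20 dB display range; the generator
rejects parameterizations whose notch trajectory leaves 5–11 kHz.  The
defaults were set jointly so that the structural invariants hold (notch
frequency monotone in elevation, resonance direction-independent,
template-uniqueness margin positive over 3–12 kHz) **and** the
contrast-dependence of the simulated psychometrics is qualitatively
correct.  Two cross-feature interactions matter and motivated the less
obvious choices:

* If the N1 trajectory topped out at 9 kHz, the top templates would carry
  a notch exactly where a high-contrast notch-band block has maximal
  weighted energy, anti-matching it; with the trajectory ending at
  10.5 kHz the top templates are notch-free through 8.5–9.5 kHz and the
  block correctly recruits them.
* Without N2, low-elevation templates are featureless in the
  high-weight band; the Pearson normalization then amplifies their faint
  ripple into spurious matches.  N2 gives them genuine structure there
  and sets the crossover between veridical and upward interpretations at
  moderate (+9…+15 dB) contrasts — which is where noise-driven up-down
  bistability appears.

## Stimuli

A stimulus is a piecewise-flat dB spectrum: NRI in the closed 6–9 kHz
notch band, ORI in the outer bands (0.5–6, 9–20 kHz), with
linear-in-log-frequency edges of 120 dB/octave extending outward from the
band edges (so the notch band core is exactly flat).  The experiment's
bank crosses NRI × ORI over {29, 38, 47, 56, 65} dB: 25 spectra, flat
noise on the diagonal, spectral contrast NRI − ORI spanning ±36 dB.
Spectra are built directly in the spectral domain; the bin-to-bin
fluctuation of a physical noise token is delegated to the sensory-noise
model.  The outer band's lower edge (0.5 kHz) is configurable.

## Virtual experiment and noise

The design crosses the 25 stimuli with 48 random frontal directions
(azimuth uniform within the double-pole bound |α| + |ε| ≤ 90°, elevation
drawn from the hoop grid), one repeat: 1200 trials shuffled into 8 blocks
of 150.  Azimuth is pass-through metadata — the observer is
elevation-only.

Sensory noise is additive Gaussian dB per frequency bin on the stimulus
spectrum before weighting (σ = 3 dB), followed by the room's background
floor (30 dB SPL) added in the power domain,
L′ = 10 log₁₀(10^(L/10) + 10^(floor/10)) — the physically correct
superposition of uncorrelated power.  The 3 dB default is the smallest
round value that produces clear up-down bistability at +12 dB contrast
while leaving zero-contrast localization unimodal.  Whether real
confusions arise from sensory noise or from decision sampling is not
settled; both mechanisms are available (`NoiseModel` vs.
`decision="sample"`).

## Psychometrics

Per condition the stimulus–response relation is fit as
ε_R = g·ε_T + b by minimizing the mean absolute error — robust to
confusion outliers, and the MLE under Laplace residuals.  The optimizer
is a Nelder-Mead simplex initialized at the least-squares solution with
deterministic perturbed restarts (the convex MAE surface is piecewise
linear and a single simplex run can stall on a kink); an independent
iteratively-refined grid search, run on mean-centered targets so the
(g, b) valley is axis-aligned, serves as the test oracle.  Reported per
fit: g, b, Pearson r, r² (the square of r), residual SD about the fitted
line, MAE, n.  Zero-variance targets make g unidentifiable; such fits are
flagged and return b = median(response).

Profiles aggregate the 25 fits along the stimulus matrix: by contrast
(anti-diagonals; fit parameters averaged across conditions sharing a
contrast, with an optional pool-then-refit mode) and by level (the flat
diagonal).

Coordinates use the double-pole convention (azimuth = angle to the
midsagittal plane, elevation = angle to the horizontal plane;
|α| + |ε| ≤ 90° for any frontal direction) and rear responses unfold as
ε_rear = 180° − ε_front, an involution accepted on the full −90…270°
circle.

## What the synthetic data does and does not show

The generator emulates the *structure* of measured pinna spectra, not any
individual's filters: real HRTFs carry richer idiosyncratic detail,
broader notches, and measurement noise, and real listeners differ in
weighting, priors and decision behavior.  Passing tests therefore
demonstrate that the inference machinery produces the qualitative
behavioral pattern — exact veridicality for flat sounds, asymmetric gain
collapse with positive contrast, steep upward bias, moderate-contrast
bistability — under a realistic cue geometry; they do not calibrate
absolute gains or biases against human data, and no attempt is made to
fit individual subjects.  Simulated magnitudes (e.g. gain ≈ 0.1 at −36 dB
contrast, bias saturating at the +85° grid ceiling) depend on the
canonical parameterization and should be read as orderings, not
measurements.

## Numerical choices and limitations

* Grids: 64 bins/octave (fine enough that a 120 dB/octave edge spans
  ~19 bins); elevation 2.5° steps, 59 points.
* Posterior normalization tolerance 1e-9; correlation clipped to [−1, 1];
  zero-variance correlation ≡ 0.
* Seeds: a single global seed derives per-stage seeds by hashing the
  stage name (CRC32), all below 2³¹; noise-free reruns are bit-identical.
* Simulation sizes used in the shipped analyses and checks: the full
  1200-trial session, 100 noisy repeats per probed elevation for the
  bistability analysis, and the 59-point grid for deterministic profiles.
* Out of scope: binaural/azimuth cue processing (azimuth is regression
  metadata only), time-domain synthesis, reaction times, adaptation of
  the weighting across sessions, and neural implementation beyond
  documentation.
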