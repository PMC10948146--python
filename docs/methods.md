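# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, the numerical decisions that were genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Geometry, units and calibration

Positions are 1D coordinates along the tether in µm, measured from the
trap-1 bead edge; frames are 0-based kymograph line indices with
`time = frame × line_time` (42.4 ms default). The direction sign convention
is positive toward increasing coordinate (trap 2); it is arbitrary but
fixed, which is all push–pull classification needs.

All bp ↔ nm conversions use the worm-like-chain extension per base pair at
the imaging tension, not the 0.34 nm/bp contour rise: the Marko–Siggia
interpolation

  F = (kT/Lp) · [ 1/(4(1−z)²) − 1/4 + z ]

is inverted for the relative extension z by a bracketing root solve
(tolerance 1e-9, valid for forces in (0.1, 80] pN), with Lp = 50 nm,
kT = 4.114 pN·nm. At 5 pN this gives z ≈ 0.9355 and 0.318 nm/bp, which is
the factor that makes 72 nm of localization precision equal 226 bp and a
0.17 µm colocalization radius ≈ 500 bp. A fixed-factor override
(`AcquisitionMeta(rise_nm_per_bp=...)`) is available. Localization
precision follows σ₀ = s/√N from the Gaussian-fit SD and photon count.

## Rolling-window diffusion analysis

Each 20-frame window's time-averaged MSD is computed over all displacement
pairs for lags 1–5, and D is the OLS slope of MSD(kΔt) against kΔt divided
by 2 (one dimension). The fit uses a **free intercept** because static
localization noise adds ≈ 2σ² to every lag — it moves the intercept, not
the slope (asserted in the tests). Negative fitted slopes are clamped to
D = 0 for classification; the *unclamped* slope-mean is carried separately
(`DiffusionProfile.mean_D_raw`) because clamping biases a per-track mean
upward by ~50% at D ≈ 0.005 µm²/s under 72 nm noise, and the unclamped
mean is the statistic that recovers the true D (within a few percent at
D ∈ {0.005, 0.02, 0.08} µm²/s in the test suite).

Class thresholds are 0.01 µm²/s (non-diffusive; the apparent mobility floor
of a truly immobile particle at this noise level) and 0.04 µm²/s (high-
diffusive, inclusive at the boundary). State *durations and fractions* are
computed from a span-5 centred moving-average-smoothed position vector
(shrinking windows at the edges), then connected same-state windows form
segments and segments shorter than 10 windows are discarded (counting
toward `discarded_fraction` and no state). Per-state *mean D* values come
from the raw, unsmoothed windows: the smoother attenuates the short-lag MSD
slope by a factor ≈ 0.81 (computable from the moving-average autocovariance)
and converts white noise into a ≈ +0.005 µm²/s slope bias, so smoothed
windows are used only where the smoothing exists to help — suppressing
state flicker for duration estimates.

Known limitation: a 20-frame, 5-lag estimate has ~40–50% sampling CV and
neighbouring rolling windows share 19 of 20 frames, so misclassification
runs can outlive the 10-window filter. Kept-window label accuracy on a
three-phase ground-truth track is ~73%; segment order and presence are
robust. Windows advance with stride 1 (configurable).

## Dwell kinetics

The single-exponential MLE is closed-form: τ̂ = Σtᵢ / (number of uncensored
events), which is the sample mean without censoring. The two-component
mixture w/τ_f·e^(−t/τ_f) + (1−w)/τ_s·e^(−t/τ_s) is maximised by L-BFGS-B in
(log τ_f, log τ_s, logit w) space from 20 seeded random starts spread over
the decades around the sample mean; components are reported ordered
τ_fast < τ_slow. AIC = 2k − 2 logL with k = 1 or 3; order 2 must beat
order 1 by ΔAIC > 2 to be selected (ties go to the simpler model), and the
mixture is not attempted below 10 uncensored events.

τ is the exponential mean lifetime; τ·ln 2 is the half-life. Published
tables sometimes label τ itself a half-life, so `ExpFit` reports both
(`tau_as_reported_s` carries τ). Censoring defaults to off (events are
taken at face value); when flags are supplied, the likelihood uses the
survival function for censored events and `survival_curve` switches from
the empirical 1 − CDF to the product-limit estimator.

## Two-color colocalization

Two independently diffusing molecules can approach by chance, so the
colocalization threshold is mobility-derived: xᵢ = √(2 μᵢ Δt), the 1D RMS
displacement per exposure at the molecule's mean diffusion coefficient, and
d = x₁ + x₂ (≈ 0.29 µm for two molecules at 0.25 µm²/s and 42.4 ms).
Trajectories are Gaussian-smoothed before thresholding (kernel SD = span/2
frames, truncated at ± span, span 5 exposures); maximal co-visible runs
with |x_A − x_B| < d are colocalized intervals.

Typing: intervals longer than five exposures are long. Sub-threshold
intervals are short (touch-and-recoil) only when the event-local diffusion
coefficient of the separation (event ± 5 frames, same MSD line fit)
exceeds the molecules' average mean D — for independent molecules the
separation diffuses at D_A + D_B, above that average, whereas a transiently
bound pair has near-zero separation diffusion. Bypass: an event is
relabelled when the median separation over the 10 co-visible flanking
frames changes sign across the event *and* both flank medians exceed
max(0.05 µm, 1.2× the separation's high-frequency noise SD) — without the
floor, noise-split gaps in tightly bound pairs produce sign flips with
meaningless sides.

Remodeler–nucleosome colocalization forward-fills nucleosome positions
through pulsed-illumination dark gaps from the last visible signal, excludes
nucleosome signals whose visible-position SD exceeds 0.1 µm (default) as
non-specifically adsorbed material, and uses a fixed 0.17 µm (~500 bp)
radius.

## Translocation analysis

Processive translocation at ~29 bp/s is ~9 nm/s — far below what a
20-frame MSD window can register — so it hides in the non-diffusive class.
Candidate regions are therefore merged runs of non/low-diffusive segments
whose mean window D stays below the 0.01 µm²/s non-diffusive floor; free
Brownian stretches average well above it even when individual windows
flicker low, and motion fast enough to register in the windows is 1D
search, not translocation (each fitted piece is re-checked against the same
floor). Within a region, a recursive changepoint search fits
piecewise-linear segments: a split is accepted when it lowers the cost
n·log(RSS/n + ε²) by more than 10·log n (ε = 1 nm keeps noiseless fits
finite; the penalty is BIC-like — noiseless speed changes always split,
localization noise alone never does; at most 4 changepoints per region).

Each segment is an OLS line of position vs time; speed is the slope, signed
by tether direction, converted to bp/s with the WLC rise. Segments are
reported with the three conjunctive filters — duration ≥ 5 s, span ≥ 300 bp,
R² ≥ 0.5 — and the reasons they fail. Note the R² filter imposes a genuine
detection limit: at 72 nm noise a constant speed below ~20 bp/s needs more
than 40 s of trace to clear R² = 0.5, so short traces truncate the slow
tail of a speed distribution (the recovery tests use 80 s traces for
unbiased cohort means).

Push–pull: the approach sign is the sign of the net displacement over the
diffusive (low/high-state) coverage within 5 s before the segment
(approach scenarios) or after it (release scenarios, sign negated, used
when no approach-side stretch exists); displacements below the 72 nm
localization precision give an indeterminate call. Push means translocation
in the approach direction. When both flanks exist and disagree, the
approach-based call is returned with a conflict flag. On simulated push-mode
encounters ~94% of determinate calls are correct; the residual errors come
from reading a mesoscopic approach direction off a genuinely diffusive
path, which no estimator can fully fix.

## Nucleosome counting

At a ≥ 15 pN force clamp each nucleosome unwraps abruptly, adding ~25 nm of
tether. The counter segments the distance trace into piecewise-constant
plateaus by binary segmentation (split accepted when RSS drops by more than
10·σ̂²·log n, σ̂ from robust first differences), then counts plateau-to-
plateau shifts of 25 ± 10 nm as one nucleosome and shifts near 50 nm as two
unresolved nucleosomes (flagged, not silently merged). Counting below 15 pN
is refused. The detector is exact on 30-step staircases at 3 nm RMS noise
in ≥ 95% of replicates and invariant to offsets and uniform time rescaling.

## Synthetic data

The simulator emulates the acquisition: continuous-time Markov switching
among diffusive states (default symmetric 0.25 s⁻¹ rates over D = 0 / 0.02 /
0.08 µm²/s), Euler–Maruyama increments √(2DΔt)·ξ with reflecting boundaries,
Gaussian localization noise (72 nm default), nucleosome capture within a
radius followed by exponentially distributed sequestration (18 s default,
the no-ATP scale), optional constant-speed translocation (speed ~
N(29, 10²) bp/s, direction push or pull relative to the microscopic
approach side, the nucleosome co-moving), pauses and direction switches as
Poisson events, single-rate photobleaching, and a 1 s-on / 9 s-off green
pulse scheme when pulsing is enabled. Two-color pairs are either one latent
path seen through independent per-channel jitter (bound) or two independent
molecules. Everything is deterministic given the config seed.

What the simulator does *not* emulate: microscopic hopping vs sliding
mechanisms (state diffusivities are phenomenological — the analysis only
ever consumes D values), dye blinking and intensity dimming, force
fluctuations during imaging, and tracking errors other than Gaussian
localization noise. Recovery tests passing on this generator therefore
demonstrate the correctness of the estimators under the stated noise model,
not robustness to every instrument artifact; the naive greedy fixture
tracker exists only to close the render→track loop on synthetic TIFFs and
is no substitute for instrument-grade tracking of real kymographs.

## Problem sizes and tolerances in the test suite

Recovery tests use 100 tracks × 1000 frames per diffusion coefficient,
5000-event mixture samples, 20 pair simulations per colocalization ROC arm,
50 + 100 traces for translocation recovery and null rejection, and 100
staircases for step counting — sizes at which the checked tolerances
(15% on D, 15%/0.1 on mixture parameters, 0.9/0.1 ROC, 1.5 bp/s on speed,
5% null rate, 95% exact counts) are comfortably inside the estimators'
sampling distributions while keeping the whole suite under a minute of
compute for the simulation-heavy parts.
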