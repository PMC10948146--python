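# kymodiff

Kymograph trajectory analysis for one-dimensional protein dynamics on
tethered DNA.

Chromatin remodelers such as RSC and ISW2 find their nucleosome targets by
scanning DNA in 1D. In dual optical-tweezer / confocal experiments, a DNA
molecule (lambda, 48.5 kbp) is stretched to ~5 pN between two beads and
fluorescent proteins moving along it are recorded as kymographs — one scan
line every 42.4 ms. `kymodiff` turns the resulting single-particle tracks
into the quantities such experiments are run for:

- **Diffusion states.** An instantaneous diffusion coefficient is estimated
  in 20-frame (0.85 s) rolling windows from a 5-lag MSD line fit,
  `D = slope / 2d` with `d = 1`, and classified as non-diffusive
  (`D < 0.01 µm²/s`), low (`0.01–0.04`) or high (`≥ 0.04`), with
  connected-component segmentation and a 10-window spurious-segment filter.
- **Dwell kinetics.** Single- and double-exponential maximum-likelihood
  lifetime fits (closed-form `τ̂ = t̄` for one component) with AIC model
  selection and survival curves (`1 − CDF`, product-limit under censoring).
- **Two-color colocalization.** Distance thresholds derived from the
  molecules' own mobility, `d = √(2 μ₁Δt) + √(2 μ₂Δt)`, Gaussian-smoothed
  interval detection, and event typing into short (touch-and-recoil), long
  (co-diffusion) and bypass (side-swapping) encounters; remodeler–nucleosome
  colocalization with dark-gap filling for pulsed illumination.
- **Processive translocation.** Piecewise-linear segmentation of
  constant-speed nucleosome movement (~29 bp/s) hidden inside the
  non-diffusive state, the duration ≥ 5 s / span ≥ 300 bp / R² ≥ 0.5
  filters, direction statistics, and push–pull calls relative to the 1D
  diffusive approach.
- **Physical calibration.** Marko–Siggia worm-like-chain inversion for the
  bp ↔ µm conversion at tension (0.318 nm/bp at 5 pN, so 72 nm of
  localization precision is 226 bp), `σ₀ = s/√N` precision, and nucleosome
  counting from ~25 nm force-induced unwrapping steps at ≥ 15 pN.
- **Synthetic data.** A generative simulator (state-switching Brownian
  motion, sequestration, translocation, photobleaching, pulsed
  illumination, force-curve staircases) that carries full ground truth, so
  every stage of the analysis is testable without instrument data.

The package is a library first: import `kymodiff` and compose the stages, or
run the short narrative scripts in `examples/`. A thin `kymodiff` CLI covers
shell use (`diffusion`, `dwell`, `count-nucs`, `calib`, `simulate`,
`pipeline run/report`).

## Worked example

`examples/04_nucleosome_translocation.py` simulates a remodeler that finds a
nucleosome by 1D search and then pushes it processively, and re-detects the
event from the noisy track:

```
ground truth: translocation at +27.9 bp/s
1 passing segment(s):
    16.3-  90.0 s   +28.0 bp/s   2062 bp  R²=0.87
    direction vs 1D approach: push (scenario approach_to_transloc)
```

The detected segment recovers the simulated speed (28.0 vs 27.9 bp/s), spans
~2 kbp over 74 s, clears all three reporting filters, and is called a *push*
because the translocation continues in the direction of the preceding
diffusive approach. The other examples print diffusion-state fractions,
dwell-time fits, collision typing, and nucleosome counts in the same style.

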