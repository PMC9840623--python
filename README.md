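# smdmap

Single-molecule displacement mapping (SMdM), localization and tracking for
measuring protein diffusion inside rod-shaped bacteria.

Proteins in bacteria move fast relative to the size of the cell: a free
cytoplasmic protein at D ≈ 5 µm²/s crosses a 2 µm cell in milliseconds, far
too fast for conventional single-particle tracking at camera frame rates.
SMdM sidesteps this by pairing two short excitation pulses across the
boundary of consecutive camera frames: each photoconverted molecule yields
one displacement *r* over a fixed, tunable interval Δt (1.5–10 ms), and the
pooled displacements carry the diffusion information. `smdmap` implements
the full analysis, plus a ground-truth synthetic data generator that makes
every stage testable without experimental data. It targets researchers
analyzing single-molecule localization data of small cells — bacteria or
other micron-scale compartments.

## The model

For isotropic 2D Brownian motion the displacement length over Δt follows a
Rayleigh density, `P(r, Δt) = (2r / 4DΔt) · exp(−r² / 4DΔt)`. Pairing all
localization candidates within a search radius r_max = 600 nm admits false
pairs whose probability grows linearly with *r*, adding a background term
*b·r*; truncation at r_max requires renormalization. With *N* diffusive
components of fractions *fᵢ* (Σfᵢ = 1):

```
            Σᵢ fᵢ (2r/4DᵢΔt) exp(−r²/4DᵢΔt) + b·r
P(r, Δt) = ─────────────────────────────────────────,  0 ≤ r ≤ r_max
            1 − Σᵢ fᵢ exp(−r_max²/4DᵢΔt) + (b/2)·r_max²
```

The parameters {Dᵢ, fᵢ, b} are estimated by maximum likelihood (bounded
quasi-Newton on transformed parameters, deterministic multistart). Fitting
the same mixture *without* background or truncation to steps pooled from
linked trajectories gives the single-particle-tracking (SPT) variant for
slow, membrane-bound or clustered molecules.

Around this core the package provides:

- **simkit** — Brownian-dynamics simulation in spherocylindrical cells
  (confined 3D cytoplasmic, surface membrane, immobile clustered
  populations), stroboscopic paired-frame sampling, localization noise,
  uniform false localizations, and camera-frame rendering.
- **locfit** — spot detection (difference-of-Gaussians + noise-scaled
  threshold), elliptical 2D Gaussian fitting, and fiducial-free drift
  correction by redundant cross-correlation.
- **cellseg** — Voronoï-density cell segmentation, covariance-eigenvector
  alignment, pole/middle region assignment (20 % of the length per pole).
- **smdm** — displacement extraction, the mixture MLE, the closed-form
  moment estimator D = ⟨r²⟩/4Δt, and 50 nm per-pixel diffusivity maps.
- **spt** — unambiguous frame-to-frame trajectory linking (5–30 frame
  tracks) and pooled step-size fitting.
- **pipeline** — timing validation, configuration, end-to-end runs and
  reporting; `smdmap` CLI as a thin wrapper.

## Worked example

`examples/01_simulate_and_fit.py` simulates one cell with 60 free
cytoplasmic molecules at D = 5 µm²/s (Δt = 1.5 ms, 20 nm localization
error, sparse photoactivation, uniform background) and fits the pooled
displacements:

```
localizations: 9705, displacements: 4744
fitted D  = 5.01 um^2/s (true 5.0; background slope b = 1.17e-06 /nm^2)
moment D  = 9.18 um^2/s (mean r^2 / 4 dt, no background correction)
```

The naive moment estimator is inflated almost two-fold by false pairs; the
*b·r* term absorbs them and recovers the input D to within the seed-level
scatter. The other examples cover two-component decomposition, cell
segmentation and regions, diffusivity maps, SPT tracking, frame
localization, and the end-to-end pipeline — each prints the numbers it
computes and what they mean.

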