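# Methods

## Displacement model and estimation

The core statistical object is the distribution of single-molecule
displacement lengths *r* over a fixed interval Δt. For isotropic 2D
Brownian motion this is Rayleigh with scale 4DΔt. Two experimental
realities modify it:

1. **Pairing uncertainty.** All candidate matches within r_max (600 nm by
   default) are retained, so unrelated nearby localizations contribute
   false pairs. For a spatially uniform contaminant the probability of a
   false pair at distance *r* grows linearly, giving the additive term
   *b·r* with *b* ≥ 0 in nm⁻². Retaining all candidates rather than the
   nearest is the default because the nearest-only rule biases the
   distribution toward small *r* in exactly the regime where the
   background matters; a `nearest_only` flag exists for sensitivity
   analysis.
2. **Truncation.** Restricting pairs to r ≤ r_max truncates the density;
   the normalizer `1 − Σᵢ fᵢ exp(−r_max²/4DᵢΔt) + (b/2) r_max²` is the
   exact integral of the numerator, so the density integrates to 1 for
   every admissible parameter set (verified by quadrature to 1e-8 in the
   tests).

The multi-component form replaces the single Rayleigh term with a mixture
Σ fᵢ·Rayleigh(4DᵢΔt), Σfᵢ = 1, N ≤ 3. The SPT variant drops both *b* and
the truncation: ambiguous links are discarded during tracking instead of
being modeled.

**Maximum likelihood.** The negative log-likelihood is minimized with
L-BFGS-B on transformed parameters: log Dᵢ, stick-breaking logits for the
fractions, and a dimensionless background weight β = b·r_max²/2 bounded at
zero (β is well-scaled where raw *b* ~ 1e-7 nm⁻² is not). Starts come from
a deterministic grid — the method-of-moments D = ⟨r²⟩/4Δt, quantile-split
estimates for mixtures, and fixed spread factors — so fits are exactly
reproducible without a random seed; ties resolve to the highest
log-likelihood. Components are reported sorted by descending D. Fits with
fewer than 50 displacements are refused rather than returned.

Degenerate checks with closed forms: if all displacements are equal and
truncation/background are off, the MLE is exactly r²/4Δt; displacements
pinned at r_max = 600 nm give D = 60 µm²/s at Δt = 1.5 ms and 9 µm²/s at
10 ms, the sanity bound showing the cutoff comfortably covers biological
mobilities. Units are nm and ms internally; D is reported in µm²/s with
the single conversion 1 µm²/s = 10³ nm²/ms.

**What is not corrected.** The reported D is the apparent in-plane
("quasi") diffusion coefficient. No correction is applied for
localization error (which adds ≈ 2σ_loc² per coordinate to the step
variance, ~ +9 % at σ = 20 nm, D = 3 µm²/s, Δt = 1.5 ms), for motion blur
during the sub-millisecond pulses, for cell confinement (which removes
tail variance; ~ −12 % for D = 5 µm²/s at Δt = 1.5 ms in a 0.32 µm-radius
cell), or for the 2D projection of membrane diffusion (~ −25…30 %, see
below). These offsets partially cancel in practice and are reported as
part of the apparent D, not removed.

## Diffusivity maps

Displacements are binned by starting position into 50 × 50 nm² pixels in
the aligned cell frame. Each pixel with ≥ 20 displacements (`min_count`,
a configuration choice — published maps only say blank pixels lacked
displacements) receives a single-component truncated-model fit. The
background slope is not identifiable per pixel at this size, so *b* is fit
once per cell and held fixed across its pixels. With ~100 displacements
per pixel the per-pixel sampling error is ≈ 10 %, which sets the sampling
depth needed before a map is informative (≥ ~20 000 displacements for a
typical 2 µm cell).

## Cell segmentation, alignment, regions

Local density is the inverse Voronoï polygon area (zero for unbounded hull
polygons). Points above `alpha_density` (default 2.0) times the field
mean density — total points over the occupied bounding-box area, the
convention of Voronoï-based SMLM segmentation — seed clusters, connected
through Voronoï adjacency. Components below `min_points` (300) are noise;
components whose aligned bounding box exceeds 4.0 × 1.5 µm are merged
neighbours; both are reported as rejected with reasons and excluded from
fitting. All thresholds are configuration, not reproductions of any
published values, and are exposed in `RunConfig`.

Alignment rotates each cluster about its centroid so the leading
covariance eigenvector lies along +x, with the applied angle folded into
(−90°, 90°]; cells have no intrinsic left/right, so pole identities are
positional. Region assignment takes the aligned x-extent and labels 20 %
of the length from each end as a pole. The default 0.2 follows from the
average cell geometry: a hemispherical cap extends one radius from the
tip, radius/length = 0.32/2.02 ≈ 0.16, rounded up.

## Spot localization and drift

Detection is a difference-of-Gaussians bandpass at the PSF scale followed
by local maxima above `threshold_sd` (default 4) times a robust MAD noise
estimate. Exact-tie adjacent maxima (an emitter on a pixel boundary in
noiseless data) are merged; distinct candidates closer than 2·σ_PSF are
both rejected rather than risk a midpoint fit. Accepted candidates are fit
with an elliptical 2D Gaussian `B + A·exp(−(x−x₀)²/2σx² − (y−y₀)²/2σy²)`
by trust-region least squares; fits are rejected with reason codes on
non-convergence, a center outside the ROI, a sigma pinned at its bound, or
a fitted sigma outside [0.7, 1.12] × the pixel-integrated PSF width (the
window that rejects blended unresolved doubles). Coordinates use the
pixel-center convention: a localization at the center of pixel *i* is at
(i + 0.5) × pixel size, origin at the field's top-left.

Drift is estimated fiducial-free: 2D histograms (20 nm bins) of temporal
segments (2000 frames) are registered pairwise by subpixel phase
correlation, the redundant pairwise shifts are solved by least squares
anchored at the first segment, and the per-segment drift is interpolated
piecewise-linearly (with linear extrapolation beyond the first/last
segment centers) and subtracted. The correction is exactly invertible.

## Trajectory linking (SPT)

Localizations in consecutive frames are linked only under bidirectional
uniqueness within 800 nm: each end must be the other's sole candidate.
Any multiplicity cuts the affected tracks at that frame; the surviving
segments are re-qualified against the 5–30 frame window. Tracks longer
than 30 frames are dropped, not truncated (both bounds are configurable),
and a missed frame ends a track — no gap closing, consistent with
consecutive-frame matching. The step interval is taken from configuration
as exposure plus camera dead time (30 or 50 ms nominal), not inferred
from the data.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
with full ground truth:

- **Geometry.** Cells are spherocylinders (cylinder plus hemispherical
  caps; default 2.02 µm × 0.32 µm radius) with the axis in the focal
  plane. Cytoplasmic molecules start uniform in the volume, membrane
  molecules uniform on the surface, clustered molecules co-located at
  membrane nucleation sites.
- **Dynamics.** Cytoplasmic diffusion is 3D Euler–Maruyama with radial
  mirror reflection at the wall, 20 substeps per sampled interval.
  Membrane diffusion uses tangent-plane substeps with radial reprojection
  onto the surface — chart-free, exact in the small-step limit, and free
  of coordinate artifacts at the cylinder–cap junctions; at the default
  substep the chord-vs-arc bias is orders of magnitude below the
  localization error. Motion during the sub-millisecond pulses is ignored
  (point sampling at pulse peaks).
- **Acquisition.** Frames are 1-based; pulses sit at the end of odd and
  start of even frames, so pair k = frames (2k−1, 2k) separated by Δt,
  with 2·frame_time − Δt between pairs. Detection is *correlated within a
  pair*: a photoconverted molecule emits at both pulses, so
  `detection_prob` gates whole pairs. This is what reproduces the sparse
  single-molecule regime (≪ 1 active molecule per cell per pair in the
  real acquisitions); independent per-pulse detection cannot, because it
  generates mostly unpaired singles whose cross-pairs swamp the genuine
  signal. Localizations are orthographic 2D projections plus isotropic
  Gaussian error (default σ = 20 nm — a configuration choice for a
  typical setup, not a published value); false localizations are uniform
  over the field at `background_rate` per frame per µm².

**What it does not emulate:** photobleaching kinetics, dipole or
astigmatic PSFs, depth-dependent (HILO) detection (available only as an
optional z-dependent detection probability, default off), sCMOS noise
maps, and within-pulse motion blur. Passing tests therefore validate the
estimators against the stated model of the data, not against every
property of real acquisitions.

**Projection bias.** Simulating lateral diffusion on a 320 nm cylinder
(axis in the focal plane) and fitting the projected steps with the
single-component model underestimates D_true: the axial coordinate is
preserved but the transverse projected variance is halved on average
(E[sin²φ] = ½), giving ⟨r²⟩ ≈ 3DΔt instead of 4DΔt, i.e. ≈ 25 % at
D = 0.2 µm²/s, Δt = 10 ms — the known ~30 % underestimation of projected
membrane diffusion. Membrane-protein D values from 2D fits should be read
with this in mind.

## Pipeline and problem sizes

End-to-end runs validate the acquisition timing (total frame time =
exposure + dead time; Δt must fit inside one frame for the straddling
pulse placement), then segment → align → assign regions → extract
displacements → fit whole cell and regions → map → report. Reports are
versioned JSON; maps are float32 TIFF with NaN masking; per-cell aligned
localization tables are emitted alongside. All randomness flows from the
run seed; reports are byte-identical across re-runs.

Test and example simulations use 10³–10⁴ displacements per condition and
2–5 cells per field — sizes chosen so the parameter-recovery bands
(± 5 % one-component, ± 0.05 on fractions) sit several standard errors
wide of the truth while the whole suite stays desk-scale. The same code
paths scale to full 65 000-frame acquisitions unchanged.

## Known limitations

- Apparent D only: no localization-error, blur, confinement or projection
  corrections (by design, matching how such measurements are reported).
- The Voronoï threshold and minimum cluster size the original analyses
  used are unpublished; the defaults here are sensible practice, not a
  reproduction.
- The background model assumes spatially uniform contaminants; false
  pairs between genuine molecules inside one cell are only approximately
  uniform, leaving a residual percent-level bias at high activation
  density.
- Mixtures with D-ratios below ~3 are weakly identifiable at realistic
  sample sizes; the likelihood surface is flat and the reported split
  should be checked against the N−1 component fit's likelihood.
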