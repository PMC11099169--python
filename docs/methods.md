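# Methods

This note records the models, numerical choices and limitations behind each
module, in the spirit of a package's methods appendix. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and sign conventions

Images are indexed `(row, col) = (y, x)`, 0-based, y increasing downward.
All displacements are reported as `(dy, dx)`: a shift `d` means the *content*
of the image moved by `+d`, i.e. `shifted(y, x) = original(y − dy, x − dx)`.
For axis-labelled summaries, x is the column direction (medio-lateral) and
y the row direction (anterior-posterior). The optics module works in mm
internally, with z pointing up and z = 0 at the top (inner) surface of the
cannula's glass floor; depths and scattering lengths are µm at the API.

## Synthetic scenes (`synth`)

The generator emulates the stated imaging conditions: 600/512 ≈ 1.17 µm/px,
30 Hz, lateral/axial PSF FWHM 1.2/9.1 µm, sparse GCaMP6f-labelled somata.

- **Somata** are 2D Gaussians truncated at 2σ, with σ set so the nominal
  8 µm soma radius equals 2σ. A simple, differentiable footprint; no cell
  model is prescribed by the experiments this emulates.
- **Transients** are Poisson event trains (default 0.1 Hz per cell, a
  conventional sparse-CA1 rate) convolved with a difference-of-exponentials
  kernel, τ_rise = 50 ms, τ_decay = 400 ms — conventional GCaMP6f values;
  the true kinetics in this preparation are not characterised, and both are
  configurable.
- **Axial sensitivity** is a Gaussian in z with FWHM equal to the measured
  axial PSF (9.1 µm): a cell at half-FWHM defocus contributes exactly half
  its in-focus fluorescence. For z-estimation studies each cell can be given
  its own axial offset (`cell_axial_offsets`, uniform ±5 µm by default):
  without this stagger every z-stack plane is a *scaled copy* of the same
  scene and normalized correlation cannot resolve z at all — a property of
  the synthetic world, not of real tissue, where somata are staggered in
  depth.
- **Noise** is Poisson photon noise on scaled intensities followed by
  additive Gaussian read noise, the standard two-photon noise model. Both
  default off so that exactness tests are meaningful.
- **Warping** uses inverse bilinear interpolation with edge clamping,
  matching the correction module so that round trips are consistent.
- **Sessions** re-render each soma under the session's translation and zoom
  (zoom scales distances about the field centre; µm/px divides by the zoom).
  A cell whose footprint falls more than half outside the field of view is
  dropped from that session's mask set and from the true pairings — it is
  not detectable, so counting it would misstate recall.
- **Odor trials**: 0.5 s blank then 1 s odor per trial; every cell responds
  at odor onset with amplitude 0.2 ΔF/F (chosen as a typical single-cell
  odor response; configurable), and a tuned cell's amplitude is multiplied
  by (1 + effect size) on its preferred odor. Injected amplitudes are
  recorded per trial and cell.
- **Bead insertions** render 1 µm beads analytically at subpixel positions,
  so the recorded displacement truth is exact rather than resampled.

What a green test on this world does *not* establish: robustness to neuropil
contamination, blood-vessel occlusion, bleaching, non-rigid tissue
deformation beyond smooth fields, or realistic vignetting — none of which
the generator models.

## Motion correction (`motion`)

Patchwise rigid estimation (default 128 px patches, 64 px stride) against a
template, interpolated to a dense field, then inverse-warped.

- **Shift estimator**: FFT cross-correlation with matrix-multiply DFT
  upsampling (`skimage.registration.phase_cross_correlation`, upsample 10).
  Estimation is two-stage: the integer peak comes from the correlation
  surface of mean-subtracted, **Hann-tapered** patches; the frame patch is
  then re-cropped at that integer offset (pulling real data from the full
  frame) and the sub-pixel residual is refined. The taper matters: cropping
  a patch cuts structures at its border, and with sparse scenes the edge
  terms bias the untapered correlation peak by up to ~0.5 px; the two-stage
  scheme keeps integer shifts exact while removing that bias.
- **Confidence** is the ratio of the correlation peak to the largest local
  maximum outside its 3x3 neighbourhood; patches below 1.1 (and flat
  patches, which report (0,0) with confidence 0) inherit the median shift
  of confident patches.
- **Template**: iterated mean of registered frames (3 iterations over the
  first 100 frames by default); zero iterations give the plain mean. The
  template defines the reference position, so absolute displacement is only
  defined up to the template's own offset.
- **Field interpolation** is bilinear between patch centres with constant
  extrapolation outside their hull; the field at a centre equals that
  patch's shift exactly.
- **Application** is a dense per-pixel inverse bilinear warp — the
  continuum limit of warping small overlapping patches with feathered
  blending — with intensities clipped at zero and edges clamped.
- **Z-estimation** correlates each patch (Pearson) against the same patch
  in every stack plane, refines the peak plane parabolically (skipped when
  the correlation is exactly 1, where the peak *is* the plane), and
  averages over valid patches. Patches with zero variance are excluded; a
  frame with none yields NaN with a warning. Per-frame estimation is the
  default entry point; callers wanting the session-average reading can pass
  the averaged movie as a single frame.
- Defaults: max shift 10 px (~12 µm, comfortably above the ~2 µm RMS brain
  motion the preparation shows); correlation-peak ties break toward the
  smallest shift magnitude.

## ΔF/F (`traces`)

F0(t) is a windowed mode: 3-minute windows, hop of half a window, window
centres interpolated linearly with constant extrapolation (whole-trace mode
for shorter traces). The mode itself is computed from a histogram (numpy's
`auto` rule — Freedman-Diaconis, falling back to Sturges when the IQR
degenerates), taking the median of the samples inside the fullest bin; ties
break toward the lower bin. The median-within-bin step pins the mode exactly
when the baseline repeats a single value, and for continuous data it sits
within a bin width of the bin centre. Non-positive modes are floored at 1e-6
with a warning. ΔF/F = (F − F0)/F0 with the same F0 in both places; no
neuropil subtraction is applied. The activity filter keeps cells with
session-mean ΔF/F strictly above 0.03 ("exceeds" is read as strict; a mean
exactly at threshold, up to accumulation round-off, is excluded).

Whether the 3-minute windows should tile or overlap is not prescribed;
half-overlapping centred windows were chosen because they give a smooth F0.

## Tracking (`tracking`)

Cross-correlations are computed on mean-subtracted images via FFT with zero
padding (no normalization is prescribed; mean subtraction suffices for the
offset). The adjusted correlogram subtracts the cross-correlation of
Gaussian-blurred copies (σ = 4 px, reflective boundaries); at σ = 0 it
degenerates to the plain correlogram. Ties break toward the smallest offset.

Masks are matched as binary pixel sets after translating session B by the
(rounded) alignment offset — no resampling, since the criterion is areal
and masks are pixel sets; the subpixel part of the offset is ignored. Zoom
differences are handled by upsampling the coarser image (bilinear for
intensity, nearest for masks, which approximately preserves areas). The
mutual rule retains a pair iff overlap > 0.5 · area for *both* ROIs. Where
the experimenters resolved conflicts by manual inspection, this package
resolves them greedily by descending min(frac_A, frac_B); on small
ROI-like conflict graphs the greedy choice matches the exhaustive
best-total assignment in ≥ 95% of random instances (tested). The hardware
zeroing procedure (artifact slide, stage re-positioning) is metadata only —
it is not computable offline.

## Decoding (`decoding`)

Features are each cell's mean ΔF/F over the odor window [+0.5 s, +1.5 s)
from fixation start, matching the stimulus timing. The classifier is
multinomial logistic regression with unit L2 regularization, features
z-scored on the training fold only; K = 5 stratified folds. Only "a linear
classifier with K-fold cross-validation" is prescribed; these are the
standard concrete choices and all are configurable. The chance level is the
mean accuracy over label permutations (200 by default) — the construction
of the published chance line is unstated, and permutation is the standard
assumption-free choice.

## Collection optics (`optics`)

The measurement being modelled scans the *cannula* relative to the
microscope, so the source stays on the optical axis while the cannula is
displaced by r; the simulation therefore traces in cannula-centred
coordinates with the source at (r, 0) and references the paraxial
acceptance to the axis through the source. This also makes the no-cannula
reference efficiency radius-independent, matching the normalisation used in
the fluorescein-well measurements (divide by the bare-coverslip value,
scale so the cylindrical profile is 1 at the centre).

- Emission is isotropic over the full sphere; downward rays are lost (no
  tissue backscatter). Refraction is vector Snell at the water→glass and
  glass→air plane interfaces; rays beyond the glass-air critical angle
  terminate as TIR. Fresnel transmittance weighting is available but off by
  default (a pure geometric reading of the original non-sequential
  simulation); the glass is a 0.15 mm parallel plate (#1 coverslip) with
  lateral walk-off included.
- Wall interactions: specular reflection about the frustum normal with
  weight × R per bounce (absorbing 1 − R), or termination for matte walls;
  bounces cap at 10, rays exiting above the rim continue, rays returning to
  the floor or emerging outside the bore are lost. Energy is conserved:
  collected + lost + TIR + wall-absorbed weights sum to the ray count
  (asserted to 1e-9).
- Wall reflectivity defaults to R = 0.6, a representative visible-band
  value for polished steel; the mirror finish of the physical part has no
  published coefficient. The cannula height defaults to 2.6 mm (the
  printed cylindrical height) for both shapes — the conical part's exact
  height is only in an unpublished drawing and is a config parameter.
- Acceptance: each exit ray is extrapolated to the nominal focal plane to
  get apparent position p and slope u; it is collected iff
  |p + f·u| ≤ 10 mm (20 mm stop at the f = 13 mm lens) and |−p| ≤ 1.5 mm
  (image stop of the 4f, −1x relay). The 1.5 mm half-diameter is taken as
  given from the published sequential-mode derivation; the 4f telecentric
  arrangement realises the stated 1x magnification (the lens separation is
  not otherwise prescribed).
- Excitation clipping: the focused excitation cone (air-side NA 0.6) is
  sampled on a deterministic angular grid; the unclipped solid-angle
  fraction f and the two-photon factor f² quantify the fall-off of signal
  near the wall, which affects both cannulas through their common top
  diameter.
- The Monte Carlo error is the standard error of the per-ray collected
  weight; comparisons against the deterministic angular-quadrature oracle
  (bare coverslip, azimuthal symmetry) are made at 3 standard errors.

Limitations: no wave optics or aberrations, no model of the proprietary
objective prescription, no polarization, no spectral integration over the
emission band, and scattering is ballistic-attenuation only (no diffuse
re-injection).

## Mie phantom

The bead phantom (0.974 µm polystyrene, 5.4 × 10⁹ /mL, read at 520 nm) is
evaluated with the Lorenz–Mie series: size parameter x = π·d·n_medium/λ,
relative index m = n_particle/n_medium, logarithmic-derivative downward
recurrence for the internal field and upward Riccati–Bessel recurrence for
the external field; σ_s = Q_sca·π·r² and the mean free path is
1/(ρ·σ_s). Refractive indices default to 1.598 (polystyrene) and 1.336
(dilute aqueous agarose) — literature values, quoted to ±1% at best, which
is why the phantom's scattering length carries a ±15% band. The series is
cross-checked against the Rayleigh closed form in the x ≪ 1 limit. Zero
bead density returns an infinite scattering length as a documented sentinel.

## Test-budget scaling

The Monte Carlo acceptance checks run at 1.5 × 10⁵ rays per point on a
coarse radius grid rather than 10⁶ on a fine one; the Monte Carlo standard
errors are correspondingly larger and are propagated into every comparison,
so the checks are weaker but not biased. The motion-recovery check uses the
known static scene as its template so that displacement is measured in an
absolute frame; template bootstrapping can only add a constant reference
offset and is tested separately.
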