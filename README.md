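# cannulascope

Analysis tools for **lifespan two-photon calcium imaging of hippocampal CA1
through an implanted cannula**, together with a Monte Carlo model of how a
**reflective conical cannula** boosts fluorescence collection.

The experimental setting: rats voluntarily head-fix under a two-photon
microscope (20x/0.6 NA air objective, 13 mm working distance, ~600 x 600 µm
fields of view at 30 Hz) and GCaMP6f-labelled CA1 pyramidal cells are imaged
through a glass-bottomed cannula across sessions spanning months to years.
Analysing such data requires a chain of computations that this package
implements as a tested, reusable library:

- **`synth`** — synthetic movies, reference z-stacks, multi-session fields of
  view, odor-trial sessions and bead-insertion series with complete ground
  truth, so every downstream stage can be validated without raw recordings.
- **`motion`** — piecewise-rigid motion correction: overlapping patches, a
  rigid translation per patch estimated against a template by FFT
  cross-correlation with upsampled-DFT subpixel refinement, bilinear
  interpolation of the patch shifts to a dense motion field, inverse warping.
  Per-frame x/y displacement is the maximum-magnitude patch shift. Axial
  (z) motion is estimated by correlating patches against a 1 µm-spaced
  reference z-stack and averaging the per-patch peak plane.
- **`traces`** — ROI trace extraction and ΔF/F with a **modal baseline**:
  F0(t) is the histogram mode of the fluorescence in 3-minute windows,
  which, unlike a mean, is insensitive to sparse calcium transients. Cells
  whose session-mean ΔF/F does not exceed 0.03 are filtered out before
  population analyses.
- **`tracking`** — cross-session registration from the *adjusted cross
  correlogram* `xcorr(A, B) − xcorr(blur(A), blur(B))` (Gaussian blur,
  σ = 4 px), which suppresses slow illumination structure so the peak is
  driven by high-spatial-frequency anatomy; then cell matching by the
  mutual-overlap rule — a pair is retained only if the overlap area exceeds
  50% of the area of *each* ROI.
- **`decoding`** — odor-identity decoding from trial-aligned population
  activity (0.5 s blank air, then 1 s odor): stratified K-fold
  cross-validated multinomial logistic regression, with the chance level
  estimated by label permutation.
- **`optics`** — non-sequential ray tracing of emission from a point source
  in water through a coverslip and a conical (5.2 mm top / 3.6 mm bottom
  inner diameter) or cylindrical (5.1 mm bore) cannula, with specular or
  matte walls; the objective and collection path are modelled paraxially as
  a 4f lens pair (f = 13 mm, 1x) with a 20 mm aperture stop and a 1.5 mm
  half-diameter image stop encoding the measured spatio-angular acceptance.
  Also: Mie scattering length of the polystyrene-bead tissue phantom, and
  NA utilities (half angular aperture θ = arcsin(NA/n)).

## Worked example

```python
import numpy as np
from cannulascope import synth, decoding, optics

# an 80-trial odor session, 4 odors, 16 tuned cells, effect size 2
spec = synth.SceneSpec(fov_px=(128, 128), n_cells=24, seed=42)
tuned = {i: i % 4 for i in range(16)}
dff, table, gt = synth.make_odor_trials(80, 4, tuned, 2.0, spec, seed=42)
X = decoding.trial_features(dff, table, spec.frame_rate_hz)
res = decoding.kfold_linear_decode(X, table.odor_label.to_numpy(), k=5, seed=0)
print(res.summary())

# collection gain of the reflective conical vs cylindrical cannula
rr = np.array([0.0, 0.8, 1.6])
con, cyl, gains = optics.gain_profile(rr, depth_um=150.0, n_rays=100_000, seed=1)
for r, g in zip(rr, gains):
    print(f"r = {r:.1f} mm  gain = {g:.2f}")
```

prints

```
K-fold linear decoding (5 folds, 4 classes)
  mean accuracy : 1.000
  per fold      : 1.000, 1.000, 1.000, 1.000, 1.000
r = 0.0 mm  gain = 1.00
r = 0.8 mm  gain = 1.13
r = 1.6 mm  gain = 1.63
```

The decoder separates the four odors perfectly at this effect size (its
permutation chance level is ~0.25, as expected for four balanced classes),
and the ray-traced collection gain of the mirror-finish conical cannula
over the conventional cylindrical one is negligible at the cannula centre
but grows toward the edge — reflected photons from central sources re-enter
the objective at positions and angles outside the acceptance of the
collection optics, while near the wall the cone redirects otherwise-lost
light into it.

A thin CLI mirrors the library (`cannulascope simulate|mocorr|zmotion|dff|
register|match|decode|raytrace ...`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the package's deterministic reference quantities:
the half angular apertures of the NA 0.6 air and NA 0.8 water-immersion
objectives from the NA definition, and the Mie scattering mean free path of
the 0.974 µm polystyrene-bead tissue phantom (5.4 x 10⁹ beads/mL, 520 nm),
writing them as JSON.
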