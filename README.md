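# shadecorr

Retrospective background and shading correction for optical microscopy
image collections and time-lapse movies.

Uneven illumination (vignetting) multiplies every image of an
acquisition by a smooth flat-field `S(x)`; camera offset and stray
light add a dark-field `D(x)`; and in time-lapse movies the background
medium photobleaches, so each frame carries a drifting baseline `B_i`:

    I_meas,i(x) = (B_i + foreground_i(x)) · S(x) + D(x)

`shadecorr` estimates `S`, `D` and the `B_i` directly from the images
themselves — no reference slides or closed-shutter frames — and inverts
the model:

    I_corr,i = (I_meas,i − D) / S − B_i + B_norm

It is aimed at anyone quantifying intensities across a field of view or
across time: whole-slide-image stitching, high-content screening wells,
and single-cell fluorescence time courses.

## Method in brief

The (downsampled) images form a pixels × images measurement matrix
whose structured part is rank ≤ 2, `I = S b^T + D 1^T + R`, with `R`
the sparse foreground/artefact residual. The fields are recovered by a
robust, iteratively reweighted block-coordinate fit: per-pixel weighted
regression for `S`, per-column medians for `b`, Tukey-bisquare
rejection of foreground, DCT-domain smoothness for `S` and the
dark-field residual, and the dark mean from a regression of per-image
intercepts on brightnesses. Regularization is set automatically from
the image content. About ten images suffice for an accurate flat-field
at any realistic cell density, and bright spike artefacts land in the
residual instead of the estimates. See `docs/methods.md` for the full
model, solver and study conditions.

## Worked example

```python
import numpy as np
from shadecorr import IlluminationModel, estimation_score
from shadecorr.synthetic import simulate_collection

# 10 synthetic images: vignette strength 0.3, dark-field 10 counts,
# medium cell density, read noise sd 5 — with full ground truth
scene = simulate_collection(10, density_level="medium", seed=7)

res = IlluminationModel(scene.measured_images).fit()
print(res.summary())
```

```
                   Illumination Model Results
================================================================
No. images                   10   Working size               128
Flat-field min           0.7977   Flat-field max          1.1128
Dark-field mean         10.3118   Dark-field max         10.8012
lambda_s                  1.081   lambda_d                0.2161
Iterations                   17   Feasibility gap      0.000e+00
Converged                  True   Time-lapse               False
================================================================
```

The fitted flat-field spans 0.80–1.11 (the generated vignette attenuates
corners to ~0.78 of the mean) and the dark-field is recovered at ~10.3
counts against a ground truth of 10. Scoring the estimate against the
generator's truth — mean absolute error normalized by the error of a
uniform flat-field, so 0 is perfect and 1 is "no better than nothing":

```python
gamma = estimation_score(res.flatfield, scene.truth_flatfield,
                         np.ones_like(res.flatfield))
print(f"flat-field estimation score: {gamma:.4f}")
corrected = res.correct()          # ImageStack of corrected frames
```

```
flat-field estimation score: 0.0199
```

For movies, fit with `timelapse=True` to also estimate the per-frame
baselines, then `res.correct(b_norm="zero")` (fluorescence) or
`b_norm="mean"` (bright-field).

## Command line

```bash
shadecorr simulate fixture/ --n 20 --density medium --seed 1
shadecorr estimate fixture/measured.tif model.tif
shadecorr correct fixture/measured.tif model.tif corrected.tif
shadecorr correct movie.tif model.tif out.tif --timelapse --bnorm zero
shadecorr evaluate --est-flatfield ff.tif --true-flatfield truth.tif --out scores.json
```

Models are stored as a two-page float32 TIFF (flat-field, dark-field)
with a JSON sidecar recording the regularization weights and solver
diagnostics; baselines as a JSON table. A JSON/TOML config file
(`--config`) can supply any option; explicit flags win.

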