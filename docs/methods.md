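# Methods

## The image-formation model

Optical microscopy images are corrupted by two instrument signatures
that are constant across an acquisition session:

* a multiplicative **flat-field** `S(x)` — the spatial profile of the
  effective illumination and detection efficiency (vignetting: bright
  at the optical axis, attenuated towards the edges);
* an additive **dark-field** `D(x)` — camera offset, thermal signal and
  stray light, present even with no light on the sensor.

A measured image relates to the true specimen signal as

    I_meas(x) = I_true(x) · S(x) + D(x).

For a time-lapse movie the true image of frame *i* further decomposes
into a spatially constant background **baseline** `B_i` (culture medium
fluorescence, drifting over time as the medium photobleaches) plus the
foreground of interest:

    I_meas,i(x) = (B_i + fg_i(x)) · S(x) + D(x).

Correction inverts the model: `(I − D)/S` for single images, and
`(I_i − D)/S − B_i + B_norm` for movie frames, where `B_norm` is an
arbitrary reference background — the mean of the `B_i` for bright-field
movies (keeps the output in the input's intensity range) and 0 for
fluorescence (removes the background entirely). `S` is normalized to
mean 1, the convention that fixes the scale ambiguity between `S` and
the per-image brightness.

## Retrospective estimation

Given `n ≥ 2` images sharing one shading profile, each frame is
area-averaged down to a square working resolution (default 128×128;
never upsampled) and vectorized into a column of the measurement matrix
`I` (pixels × images). The structured part of `I` has rank ≤ 2,

    I = S b^T + D 1^T + R,

with `b` the per-image background brightness and `R` a sparse residual
(cells, debris, bright spike particles, noise tails). The estimation
problem is this decomposition under two priors: `R` is sparse in a
robust (reweighted-L1-like) sense, and `S` and the non-constant part of
`D` are smooth, expressed as sparsity of their 2-D orthonormal type-II
DCT (DCT chosen over the DFT because the fields are real and the DCT's
implicit symmetric extension avoids wrap-around boundary artefacts).

### Solver

An iteratively reweighted robust block-coordinate iteration in which
every update solves its subproblem exactly:

1. **S** — per-pixel weighted least-squares slope of the pixel's
   intensity trajectory against `b`, followed by the smoothness
   projection: DCT coefficients outside a low-frequency band
   (`k_y + k_x < band_fraction · working_size`, default 0.2) are
   zeroed, coefficients inside the band are soft-thresholded by
   `0.04 · λ_s`, the DC coefficient passes through, and `S` is
   renormalized to mean 1.
2. **b** — per-column median of `(I − D)/S`. The median is the
   L1-optimal scalar and locks onto the *background* mode of each
   column; this is what confines the method to foreground fractions
   below ~50 % — beyond that the background is no longer the majority
   mode and the baseline can converge to the foreground.
3. **W** — Tukey-bisquare weights of the residuals,
   `w = (1 − (|r|/cσ)²)²` for `|r| < cσ` else 0, with `σ` the scaled
   median absolute residual and `c = 6` by default. Redescending
   weights reject foreground *entirely* instead of merely discounting
   it, which is what keeps the foreground's spatially structured bias
   out of `S`.
4. **D_z** (dark mean) — every column's weighted regression on
   `[S, 1]` has slope `β_j ∝ B_j` and intercept `γ_j = c·B_j + D_z`;
   a robust line fit of `γ` against `β` across columns yields `D_z` as
   its intercept. This step uses the only leverage that exists for
   separating an additive from a multiplicative component: the spatial
   contrast of `S` combined with brightness *diversity* across images.
   If all images shared one background level exactly, `S` and `D`
   would be mathematically unidentifiable (any blend
   `(B·S + D)/(B + D)` fits equally well); if `S` is uniform the
   regression has no leverage and is skipped. The dark-mean regression
   and the rank-1 refit alternate (up to 3 rounds) until the offset
   settles.
5. **D_r** (dark spatial residual) — smoothed (same projection, with
   `0.04 · λ_d`) per-pixel weighted intercept of the remaining
   residual, constrained by the physical bound `0 ≤ D(x) ≤ min_i
   I_i(x)` (true signal and baselines are nonnegative).

Convergence is declared when the relative change of `S` falls below
`feasibility_tol` (default 1e-6); the iteration cap is
`inner_max_iter = 500`, reached only on pathological inputs. All
computations run on the matrix divided by its global mean, so the
estimates are exactly equivariant under intensity rescaling: `S` is
invariant, `D` and `b` scale with the data. Every update is symmetric
in the columns, so permuting the input images leaves `S` and `D`
unchanged.

The package also provides the classical per-pixel **sorted** matrix
(`build_measurement_matrix(..., sort=True)`), in which column *j* holds
every pixel's *j*-th smallest intensity. The estimation pipeline fits
the *unsorted* matrix: sorting makes each column an order statistic of
a sample whose size varies from pixel to pixel (a pixel covered by
foreground in *k* images contributes only `n − k` background values),
which shifts the background order statistics by sub-noise amounts that
correlate spatially with foreground occupancy — a bias no
residual-based robustness can detect. The unsorted model is exact for
background entries and leaves foreground as clean outliers for the
bisquare weights.

### Automatic regularization

`λ_s` is set from the image content:
`λ_s = 20 · ‖dct2(Ī/mean(Ī))‖₁ / n_pixels` with `Ī` the mean image, and
`λ_d = 0.2 λ_s`. Both are invariant to global intensity rescaling. For
time-lapse stacks the automatic values are multiplied by 10: frames of
a movie show the same cells at correlated positions, and persistent
foreground must be *smoothed out* of `S` rather than averaged out —
raising `λ_s` is the standard remedy for correlated movies, at the cost
of a slightly stiffer flat-field. Users can always override both
weights.

### Per-frame baselines

With `S*` and `D*` fixed, the baseline of frame *i* is the background
mode of `(I_i − D*)/S*` at working resolution: a median-initialized,
Tukey-reweighted location estimate (5 sweeps). Every frame is fitted
independently — per-column medians, scales and weights — so `B_i` is
bit-identical whether or not other frames are present, and long movies
can be processed in chunks. No temporal smoothness is imposed on the
`B_i`.

## Evaluation scores

* **Estimation score** `Γ = mean|est − truth| / mean|baseline − truth|`
  with the baseline a uniform flat-field for `S`, a zero dark-field for
  `D`, and the uncorrected images for corrected stacks. 0 is perfect;
  1 is no better than doing nothing.
* **Correction score** `Γ′`: mean absolute difference over pre-aligned
  overlapping image pairs after correction, divided by the same
  statistic before correction; `< 1` means reduced shading. Pixels are
  pooled within a pair first, then pairs averaged unweighted (the
  pooling order is a documented choice; no extra intensity
  normalization is applied to the pairs). Alignment is out of scope —
  the synthetic generator emits exactly overlapping tiles.

## Synthetic study conditions

The generator produces scenes in arbitrary "camera count" units with
full ground truth. Defaults, chosen once as typical of a 10–20×
fluorescence acquisition and calibrated so that the documented
few-image accuracy (median `Γ(S) ≤ 0.1` from 10 images) is reproducible
at desk scale:

| parameter | default | rationale |
| --- | --- | --- |
| image size | 128×128 | matches the default working resolution |
| flat-field | parabolic vignette, strength 0.3 | 30 % corner falloff, mid-range vignetting |
| dark-field | constant 10 counts | camera offset, ~10 % of background |
| background level | 100 counts, ±15 % uniform jitter per image | real collections never share one exact background (medium autofluorescence, source drift); this diversity is also what makes `D` identifiable |
| read noise | Gaussian, sd 5 | ~5 % of background |
| cells | random rotated ellipses, semi-axes 3–9 % of the field, log-normal intensities (median = background, σ = 0.4) | fluorescent-cell-like statistics without biological simulation |
| density bands | low ≈ 5 %, medium ≈ 15 %, high ≈ 30 % foreground pixels | three levels spanning sparse to dense cultures |
| spikes | 1–3 discs, radius 2–4 px, 10–50× background | bright strongly emitting particles |
| movie baseline | `B_i = 100·exp(−i/50) + 10` | exponential medium photobleaching over a floor |
| cell motility | 2 px/frame random walk, 2 % division chance per frame | motile cells traverse several diameters over a movie; near-static foreground is the method's documented failure mode and is exercised in the docs, not used as the default condition |

Spike placement draws from a separate random substream, so a spiked
scene shares its cells and noise bit-for-bit with the clean scene of
the same seed — robustness comparisons are exactly paired. All
randomness flows from one seeded PCG64 generator; scenes are
bit-reproducible across runs and platforms.

What the generator does **not** emulate: PSF blur and partial-volume
cell edges, photon (Poisson) noise, foreground photobleaching,
spatially varying per-image backgrounds, stitching misalignment. Tests
passing on these scenes therefore certify the estimation machinery
under the stated model, not performance on any particular instrument's
data.

## Numerical choices and degenerate inputs

* Working size is clamped to the image size (no upsampling);
  downsampling is area-average, upsampling of the estimated fields back
  to full resolution is bilinear — shading is smooth by construction,
  so low-order interpolation is lossless in practice.
* Corrected output is *not* clipped at zero by default (clipping biases
  downstream quantification); the CLI offers `--clip` for integer
  export. File output defaults to float32; the library computes in
  float64.
* A constant stack returns `S ≡ 1`, `D ≡ min value` with a warning
  rather than an error. All-zero stacks and non-finite pixels raise.
* The estimated flat-field is floored at 1e-6 (with a warning) before
  the mean-1 renormalization, so a returned model is always valid for
  division.
* Fewer than 5 images trigger a warning (accuracy improves with ≥ 5);
  fewer than 2 are an error.

## Known limitations

* Foreground fractions above ~50 % can capture the baseline and, for
  near-static scenes, leak into `S`; inspect the estimated flat-field
  (it should be smooth) and consider raising `λ_s`.
* The dark-field is only as identifiable as the brightness diversity of
  the input allows; with nearly identical backgrounds the dark mean is
  conservatively biased towards 0 and the corrected images absorb the
  difference into a harmless constant offset.
* Foreground photobleaching (fading of the *cells* themselves) is not
  modelled and not corrected.
* Channels are independent: multi-channel data should be corrected one
  channel at a time.
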