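"""Low-rank + sparse decomposition of the measurement matrix.

The estimation problem: stack the (downsampled) images as columns of a
measurement matrix ``I`` (pixels x images).  Because every image shares
one flat-field ``S`` and one dark-field ``D``, the structured part of
``I`` is at most rank 2:

    I = S b^T + D 1^T + R

with ``b`` the per-column background brightness scalars and ``R`` the
sparse residual (foreground objects, spike artefacts, noise tails).  The
fields are found by minimizing a robust (reweighted) error on ``R``
together with Fourier-domain smoothness of ``S`` and of the non-constant
dark-field part ``D_r`` (``D = D_z + D_r``, scalar mean plus zero-mean
residual).

Solver
------
An iteratively reweighted block-coordinate scheme on the raw (unsorted)
matrix:

* ``S``: per-pixel weighted least-squares slope against ``b``, followed
  by a low-frequency DCT projection with soft-thresholding (the
  smoothness prior; threshold scaled by ``lambda_s``);
* ``b``: per-column median of ``(I - D)/S`` — the L1-optimal scalar,
  which locks onto the *background* mode of each column as long as
  foreground covers less than half the image (the method's documented
  validity limit);
* ``W``: Tukey-bisquare weights of the residuals, re-estimated every
  iteration from a robust noise scale, so foreground and artefacts are
  rejected rather than absorbed;
* ``D_z``: each column's fit carries intercept ``gamma_j = c*B_j + D_z``
  and slope ``beta_j = a*B_j``; regressing intercepts on slopes across
  columns yields the dark mean as the line's own intercept.  This
  brightness-diversity leverage is the only information that separates
  an additive offset from the multiplicative field, so the accuracy of
  ``D`` degrades gracefully when all images share one background level;
* ``D_r``: smoothed per-pixel intercept of the residual after the dark
  mean is removed, constrained to ``0 <= D <= min_i I_i`` pixelwise
  (true images and baselines are nonnegative).

Each update solves its subproblem exactly, which makes the iteration
monotone in practice and free of penalty-schedule tuning; convergence is
declared when the relative change of ``S`` drops below
``feasibility_tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.fft import dctn, idctn
from skimage.transform import resize, resize_local_mean

from .core import ImageStack, ShadingModel, as_stack
from .exceptions import (
    ConvergenceError,
    DataError,
    DegenerateInputError,
    DimensionError,
    InputSizeError,
)

__all__ = [
    "MeasurementMatrix",
    "SolverOptions",
    "DecompositionResult",
    "build_measurement_matrix",
    "dct2",
    "idct2",
    "soft_threshold",
    "update_weights",
    "auto_regularization",
    "decompose",
    "estimate_shading",
]

#: proportionality constant of the automatic flat-field smoothness weight:
#: lambda_s = AUTO_LAMBDA_CS * ||dct2(mean image / its mean)||_1 / n_pixels.
#: 20.0 puts lambda_s near 1 for a typical mean-1 vignetted collection at
#: 128x128 working resolution; the solver's DCT threshold is
#: THRESHOLD_UNIT * lambda, so the default smoothing strength is mild and
#: grows linearly when a user raises lambda_s (e.g. for correlated movies).
AUTO_LAMBDA_CS = 20.0
AUTO_LAMBDA_DARK_RATIO = 0.2

#: DCT soft-threshold applied inside the low-pass band, per unit of lambda
THRESHOLD_UNIT = 0.04

#: automatic-lambda multiplier for time-lapse stacks: frames of a movie
#: show the same cells at correlated positions, and persistent foreground
#: must be smoothed out of S rather than averaged out (raising lambda_s
#: for correlated movies is the documented remedy)
TIMELAPSE_LAMBDA_BOOST = 10.0


def dct2(grid: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D type-II DCT."""
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2 or grid.size == 0:
        raise DimensionError(f"dct2 expects a non-empty 2-D grid, got {grid.shape}")
    return dctn(grid, type=2, norm="ortho")


def idct2(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2`."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.ndim != 2 or coeffs.size == 0:
        raise DimensionError(f"idct2 expects a non-empty 2-D grid, got {coeffs.shape}")
    return idctn(coeffs, type=2, norm="ortho")


def soft_threshold(values: np.ndarray, threshold) -> np.ndarray:
    """Proximal operator of the (weighted) L1 norm: sign(v) * max(|v|-t, 0)."""
    threshold = np.asarray(threshold, dtype=np.float64)
    if np.any(threshold < 0):
        raise ValueError("soft_threshold requires a nonnegative threshold")
    values = np.asarray(values, dtype=np.float64)
    return np.sign(values) * np.maximum(np.abs(values) - threshold, 0.0)


def update_weights(residual: np.ndarray, scale: float, epsilon: float) -> np.ndarray:
    """Reweighted-L1 weights: w = 1 / (|r|/scale + eps), mean-normalized.

    Entries with large residual magnitude (confident foreground) get a
    small weight so the penalty stops fighting them — the classic
    reweighting that sharpens an L1 penalty towards the L0 count.
    ``scale`` is the intensity unit (mean of the measurement matrix)
    making the weights dimensionless.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    residual = np.asarray(residual, dtype=np.float64)
    w = 1.0 / (np.abs(residual) / scale + epsilon)
    return w / w.mean()


@dataclass
class MeasurementMatrix:
    """Pixels x images matrix of vectorized (downsampled) frames."""

    data: np.ndarray
    working_height: int
    working_width: int
    sorted_flag: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise DimensionError("measurement matrix must be 2-D")
        if self.data.shape[0] != self.working_height * self.working_width:
            raise DimensionError(
                f"{self.data.shape[0]} rows != "
                f"{self.working_height}x{self.working_width} working pixels"
            )

    @property
    def working_pixels(self) -> int:
        return self.working_height * self.working_width

    @property
    def n_images(self) -> int:
        return self.data.shape[1]


@dataclass
class SolverOptions:
    """Tunables of the decomposition solver.

    lambda_s, lambda_d : float or None
        Smoothness weights for S and D_r; ``None`` selects them
        automatically from the image content
        (:func:`auto_regularization`).  Larger values smooth harder and
        help reject small static objects in correlated movies.
    estimate_darkfield : bool
        If off, D is held at 0 and only the flat-field is estimated.
    working_size : int
        Square estimation resolution (frames are resampled to it).
    max_reweight_rounds : int
        Reweighting sweeps of the per-frame baseline estimator.
    reweight_epsilon : float
        Epsilon of the reweighted-L1 weight formula.
    inner_max_iter, feasibility_tol : int, float
        Iteration cap and the relative-change stopping tolerance of the
        solver.
    band_fraction : float
        Low-pass DCT band kept for S and D_r, as a fraction of the
        working size; shading varies over a large fraction of the field
        of view, so 0.2 retains everything physical.
    tukey_c : float
        Bisquare rejection point in robust-sigma units.
    """

    lambda_s: Optional[float] = None
    lambda_d: Optional[float] = None
    estimate_darkfield: bool = True
    working_size: int = 128
    max_reweight_rounds: int = 5
    reweight_epsilon: float = 0.1
    inner_max_iter: int = 500
    feasibility_tol: float = 1e-6
    band_fraction: float = 0.2
    tukey_c: float = 6.0
    seed: Optional[int] = None  # reserved; the solver is deterministic

    def __post_init__(self):
        if self.working_size < 8:
            raise ValueError("working_size must be >= 8")
        if self.reweight_epsilon <= 0:
            raise ValueError("reweight_epsilon must be > 0")
        if self.feasibility_tol < 0:
            raise ValueError("feasibility_tol must be >= 0")
        if self.max_reweight_rounds < 1 or self.inner_max_iter < 1:
            raise ValueError("iteration counts must be >= 1")
        if not 0.0 < self.band_fraction <= 1.0:
            raise ValueError("band_fraction must be in (0, 1]")
        if self.tukey_c <= 0:
            raise ValueError("tukey_c must be > 0")
        for lam in (self.lambda_s, self.lambda_d):
            if lam is not None and lam < 0:
                raise ValueError("regularization weights must be >= 0")


@dataclass
class DecompositionResult:
    """Output of :func:`decompose`, all in the intensity units of the input."""

    lowrank: np.ndarray          # I_B = S b^T + D 1^T
    residual: np.ndarray         # I_R = data - I_B (exact)
    weights: np.ndarray          # final robustness weights W
    flatfield_vec: np.ndarray    # S, mean 1
    darkfield_vec: np.ndarray    # D = D_z + D_r
    dark_mean: float             # D_z
    dark_residual_vec: np.ndarray  # D_r (zero mean)
    baselines: np.ndarray        # per-column b_i
    n_iterations: int
    final_feasibility_gap: float
    converged: bool
    gap_history: list = field(default_factory=list)  # per-iteration S change
    lambda_s: float = np.nan
    lambda_d: float = np.nan


def _resample_frame(frame: np.ndarray, size: int) -> np.ndarray:
    h, w = frame.shape
    if (h, w) == (size, size):
        return frame.astype(np.float64, copy=False)
    if size <= h and size <= w:
        # downscale: local mean (area average) keeps intensities calibrated
        return resize_local_mean(frame, (size, size))
    return resize(frame, (size, size), order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def build_measurement_matrix(
    stack, working_size: int, sort: bool = True
) -> MeasurementMatrix:
    """Resample each frame to ``working_size`` square, vectorize, stack.

    With ``sort`` on, each pixel's intensity trajectory across images is
    independently sorted ascending, turning the columns into per-pixel
    order statistics.  Downscaling uses area averaging; upscaling is
    bilinear.
    """
    stack = as_stack(stack)
    if sort and stack.n_frames < 2:
        raise InputSizeError("pixel-wise sorting needs at least 2 frames")
    cols = [_resample_frame(f, working_size).ravel() for f in stack.frames]
    data = np.stack(cols, axis=1)
    if sort:
        data = np.sort(data, axis=1)
    return MeasurementMatrix(
        data, working_height=working_size, working_width=working_size,
        sorted_flag=bool(sort),
    )


def auto_regularization(matrix: MeasurementMatrix) -> tuple[float, float]:
    """Content-adaptive smoothness weights (lambda_s, lambda_d).

    lambda_s is proportional to the L1 mass of the DCT of the mean image
    after normalization by its own mean — a measure of how much smooth
    structure the collection carries — divided by the number of working
    pixels; lambda_d is a fixed fraction of lambda_s.  Both are invariant
    to a global rescaling of the input intensities.
    """
    mean_img = matrix.data.mean(axis=1)
    m = float(np.abs(mean_img).mean())
    if m <= 0 or not np.any(mean_img):
        raise DegenerateInputError("all-zero stack: cannot set regularization")
    grid = (mean_img / mean_img.mean()).reshape(
        matrix.working_height, matrix.working_width
    )
    lam_s = AUTO_LAMBDA_CS * float(np.abs(dct2(grid)).sum()) / matrix.working_pixels
    return lam_s, AUTO_LAMBDA_DARK_RATIO * lam_s


def _smooth_field(vec, wh, ww, band, threshold):
    """Low-pass DCT projection + in-band soft threshold; DC passes through."""
    C = dct2(vec.reshape(wh, ww))
    dc = C[0, 0]
    kk = np.add.outer(np.arange(wh), np.arange(ww))
    C = np.where(kk < band, C, 0.0)
    C = soft_threshold(C, threshold)
    C[0, 0] = dc
    return idct2(C).ravel()


def _tukey_weights(abs_resid, c):
    u = np.clip(abs_resid / c, 0.0, 1.0)
    return (1.0 - u * u) ** 2


def _robust_rank1(I, wh, ww, band, t_s, options, D=None, state=None):
    """Robust fit of I - D ~ S b^T; returns (S, b, W, n_iter, history)."""
    p, n = I.shape
    J = I if D is None else I - D[:, None]
    if state is None:
        b = np.maximum(np.median(J, axis=0), 0.0)
        S = np.ones(p)
        W = np.ones((p, n))
    else:
        S, b, W = state
    history = []
    rising = 0
    for _ in range(options.inner_max_iter):
        W2 = W * W
        den = W2 @ (b * b)
        S_new = np.where(den > 1e-10, ((W2 * J) @ b) / np.maximum(den, 1e-12), S)
        S_new = _smooth_field(S_new, wh, ww, band, t_s)
        m = float(S_new.mean())
        if m <= 0:
            raise ConvergenceError(
                "flat-field collapsed to non-positive mean",
                diagnostics={"iterations": len(history)},
            )
        S_new /= m
        delta = float(np.linalg.norm(S_new - S) / max(np.linalg.norm(S), 1e-12))
        history.append(delta)
        rising = rising + 1 if len(history) > 1 and delta > history[-2] else 0
        if rising >= 50:
            raise ConvergenceError(
                "solver diverged: update size grew for 50 consecutive iterations",
                diagnostics={"iterations": len(history), "history": history},
            )
        S = S_new
        b = np.maximum(np.median(J / S[:, None], axis=0), 0.0)
        R = J - S[:, None] * b[None, :]
        abs_r = np.abs(R)
        sigma = 1.4826 * float(np.median(abs_r))
        W = _tukey_weights(abs_r, options.tukey_c * max(sigma, 1e-9)) + 1e-8
        W = W / W.mean()
        if delta < options.feasibility_tol:
            break
    return S, b, W, len(history), history


def _dark_mean_from_columns(I, S, W, lo, hi):
    """Dark mean via the intercept-on-slope regression across columns.

    Each column's robust weighted regression on [S, 1] has slope
    beta_j ~ a*B_j and intercept gamma_j ~ c*B_j + D_z; the intercept of
    the (robust) line gamma = k*beta + D_z across columns is the dark
    mean, clipped into [lo, hi].  The separation leverages the spatial
    contrast of S and the brightness diversity between images; when S is
    (near) uniform the additive and multiplicative parts cannot be told
    apart and the regression is skipped (returns 0).
    """
    p, n = I.shape
    var_s = float(S @ S) / p - float(S.mean()) ** 2
    if var_s < 1e-4:  # sd(S) < 1%: no leverage, D_z unidentifiable
        return 0.0
    W2 = W * W
    sw = W2.sum(axis=0)
    sws = (W2 * S[:, None]).sum(axis=0)
    swss = (W2 * (S * S)[:, None]).sum(axis=0)
    swy = (W2 * I).sum(axis=0)
    swsy = (W2 * I * S[:, None]).sum(axis=0)
    det = np.maximum(swss * sw - sws * sws, 1e-12)
    beta = (swsy * sw - sws * swy) / det
    gamma = (swss * swy - sws * swsy) / det
    A = np.vstack([beta, np.ones(n)]).T
    wl = np.ones(n)
    for _ in range(20):
        Aw = A * wl[:, None]
        coef, *_ = np.linalg.lstsq(Aw, gamma * wl, rcond=None)
        r = gamma - A @ coef
        s_r = 1.4826 * float(np.median(np.abs(r)))
        wl = _tukey_weights(np.abs(r), 6.0 * max(s_r, 1e-9)) + 1e-6
    return float(np.clip(coef[1], lo, hi))


def decompose(matrix: MeasurementMatrix, options: SolverOptions) -> DecompositionResult:
    """Solve the regularized rank-2 + sparse decomposition.

    The matrix is internally normalized by its global mean, making the
    iteration exactly equivariant under rescaling of the input
    intensities; results are reported back in input units.  The returned
    ``residual`` is defined as ``data - lowrank`` exactly, so the
    feasibility identity holds to machine precision.
    """
    data = matrix.data
    if not np.all(np.isfinite(data)):
        raise DataError("measurement matrix contains non-finite values")
    p, n = data.shape
    if n < 2:
        raise InputSizeError("decomposition needs at least 2 images")
    wh, ww = matrix.working_height, matrix.working_width

    scale = float(np.abs(data).mean())
    if scale <= 0:
        raise DegenerateInputError("all-zero measurement matrix")

    if np.ptp(data) <= 1e-12 * scale:
        warnings.warn(
            "constant image stack: returning S=1, D=min value", stacklevel=2
        )
        c = float(data.min())
        return DecompositionResult(
            lowrank=np.full_like(data, c), residual=data - c,
            weights=np.ones_like(data), flatfield_vec=np.ones(p),
            darkfield_vec=np.full(p, c), dark_mean=c,
            dark_residual_vec=np.zeros(p), baselines=np.zeros(n),
            n_iterations=0, final_feasibility_gap=0.0, converged=True,
        )

    lam_s, lam_d = options.lambda_s, options.lambda_d
    if lam_s is None or lam_d is None:
        auto_s, auto_d = auto_regularization(matrix)
        lam_s = auto_s if lam_s is None else lam_s
        lam_d = auto_d if lam_d is None else lam_d

    I = data / scale
    col_min = np.maximum(I.min(axis=1), 0.0)
    band = max(4, round(options.band_fraction * max(wh, ww)))
    t_s = THRESHOLD_UNIT * lam_s
    t_d = THRESHOLD_UNIT * lam_d

    S, b, W, n1, hist = _robust_rank1(I, wh, ww, band, t_s, options)
    dz = 0.0
    Dr = np.zeros(p)
    n_iter = n1
    if options.estimate_darkfield:
        # alternate dark-mean regression and refit until the offset settles
        hi = float(col_min.min())
        for _ in range(3):
            inc = _dark_mean_from_columns(I - dz, S, W, -dz, hi - dz)
            dz = float(np.clip(dz + inc, 0.0, hi))
            S, b, W, n2, hist2 = _robust_rank1(
                I, wh, ww, band, t_s, options,
                D=np.full(p, dz), state=(S, np.maximum(b - inc, 0.0), W),
            )
            n_iter += n2
            hist = hist + hist2
            if abs(inc) < 1e-4:
                break
        W2 = W * W
        d_raw = (W2 * (I - S[:, None] * b[None, :] - dz)).sum(axis=1)
        d_raw /= np.maximum(W2.sum(axis=1), 1e-12)
        Dr = _smooth_field(d_raw, wh, ww, band, t_d)
        Dr -= Dr.mean()
        D = np.clip(dz + Dr, 0.0, col_min)
        dz = float(D.mean())
        Dr = D - dz

    m_s = float(S.mean())
    flat = np.maximum(S / m_s, 1e-6)
    flat /= flat.mean()
    baselines = b * m_s * scale
    dark = (dz + Dr) * scale
    lowrank = flat[:, None] * baselines[None, :] + dark[:, None]
    residual = data - lowrank
    final_delta = hist[-1] if hist else 0.0
    return DecompositionResult(
        lowrank=lowrank,
        residual=residual,
        weights=W,
        flatfield_vec=flat,
        darkfield_vec=dark,
        dark_mean=float(dz * scale),
        dark_residual_vec=Dr * scale,
        baselines=baselines,
        n_iterations=n_iter,
        final_feasibility_gap=float(
            np.linalg.norm(data - lowrank - residual) / np.linalg.norm(data)
        ),
        converged=bool(final_delta < options.feasibility_tol),
        gap_history=hist,
        lambda_s=float(lam_s),
        lambda_d=float(lam_d),
    )


def estimate_shading(stack, options: SolverOptions | None = None) -> ShadingModel:
    """End-to-end flat-field / dark-field estimation from an image stack.

    Builds the measurement matrix at the working resolution, auto-tunes
    the smoothness weights when unset, runs the decomposition, and
    returns the fields upsampled to the full image size (bilinear;
    shading is smooth, so low-order interpolation is lossless in
    practice).
    """
    model, _ = _estimate_shading_full(stack, options)
    return model


def _estimate_shading_full(stack, options=None):
    stack = as_stack(stack)
    options = options or SolverOptions()
    if stack.n_frames < 2:
        raise InputSizeError("shading estimation needs at least 2 images")
    if stack.n_frames < 5:
        warnings.warn(
            f"only {stack.n_frames} images: estimation works but accuracy "
            "improves with 5 or more", stacklevel=2
        )
    ws = min(options.working_size, stack.height, stack.width)
    ws = max(ws, 2)
    matrix = build_measurement_matrix(stack, ws, sort=False)
    if options.lambda_s is None or options.lambda_d is None:
        auto_s, auto_d = auto_regularization(matrix)
        if stack.is_timelapse:
            auto_s *= TIMELAPSE_LAMBDA_BOOST
            auto_d *= TIMELAPSE_LAMBDA_BOOST
        options = replace(
            options,
            lambda_s=options.lambda_s if options.lambda_s is not None else auto_s,
            lambda_d=options.lambda_d if options.lambda_d is not None else auto_d,
        )
    result = decompose(matrix, options)
    flat = result.flatfield_vec.reshape(ws, ws)
    dark = result.darkfield_vec.reshape(ws, ws)
    full_shape = (stack.height, stack.width)
    if full_shape != (ws, ws):
        flat = resize(flat, full_shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
        dark = resize(dark, full_shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    floor = 1e-6
    if np.any(flat < floor):
        warnings.warn(
            "estimated flat-field touched zero; flooring at 1e-6", stacklevel=2
        )
        flat = np.maximum(flat, floor)
    flat = flat / flat.mean()
    if not options.estimate_darkfield:
        dark = np.zeros(full_shape)
    model = ShadingModel(
        flat, dark, working_size=ws,
        metadata={
            "lambda_s": result.lambda_s,
            "lambda_d": result.lambda_d,
            "n_iterations": result.n_iterations,
            "feasibility_gap": result.final_feasibility_gap,
            "converged": result.converged,
            "n_images": stack.n_frames,
            "estimate_darkfield": options.estimate_darkfield,
        },
    )
    return model, result
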