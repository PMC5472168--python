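"""Per-frame baseline estimation for time-lapse movies.

With the flat-field S* and dark-field D* already estimated, the model of
frame ``i`` reduces to

    I_i  =  (B_i + foreground_i) * S* + D* + noise,

so the baseline ``B_i`` is a single scalar per frame: the location of
the *background* mode of the shading-corrected frame
``(I_i - D*) / S*``.  It is estimated independently per frame by a
median-initialized, Tukey-reweighted location fit, the same robust
machinery the decomposition solver uses entrywise: foreground pixels are
rejected as outliers, which keeps the fit on the background while the
foreground fraction stays below one half (the documented validity limit
— beyond ~50 % coverage the estimate can converge to the foreground).

Frames are treated strictly independently — no temporal smoothing is
imposed, and the estimate for frame ``i`` does not change when other
frames are added or removed.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize, resize_local_mean

from .core import BaselineSeries, ShadingModel, as_stack
from .decomposition import SolverOptions, _tukey_weights, build_measurement_matrix
from .exceptions import DimensionError

__all__ = ["estimate_baseline"]


def _model_at_working(model: ShadingModel, ws: int):
    s, d = model.flatfield, model.darkfield
    if s.shape != (ws, ws):
        if ws <= min(s.shape):
            s = resize_local_mean(s, (ws, ws))
            d = resize_local_mean(d, (ws, ws))
        else:
            s = resize(s, (ws, ws), order=1, mode="edge", preserve_range=True,
                       anti_aliasing=False)
            d = resize(d, (ws, ws), order=1, mode="edge", preserve_range=True,
                       anti_aliasing=False)
        s = np.maximum(s, np.finfo(float).tiny)
        s = s / s.mean()
    return s.ravel(), d.ravel()


def estimate_baseline(
    stack, model: ShadingModel, options: SolverOptions | None = None
) -> BaselineSeries:
    """Estimate the per-frame background baselines B_i of a movie.

    ``model`` must have been estimated beforehand (its fields are held
    fixed); the stack is used unsorted, in temporal order.  Returns a
    :class:`BaselineSeries` with ``b_norm = 0`` (the fluorescence
    convention); use :meth:`BaselineSeries.with_b_norm` for bright-field
    movies.
    """
    stack = as_stack(stack, is_timelapse=True)
    options = options or SolverOptions()
    model = model.resampled_to((stack.height, stack.width))
    ws = min(options.working_size, stack.height, stack.width)
    mm = build_measurement_matrix(stack, ws, sort=False)
    S, D = _model_at_working(model, ws)
    flat = (mm.data - D[:, None]) / S[:, None]      # (p, n), per-pixel estimates of B_i

    B = np.median(flat, axis=0)
    # Tukey-reweighted location, each column independent
    for _ in range(options.max_reweight_rounds):
        R = flat - B[None, :]
        abs_r = np.abs(R)
        sigma = 1.4826 * np.median(abs_r, axis=0)
        c = options.tukey_c * np.maximum(sigma, 1e-9)
        W = _tukey_weights(abs_r, c[None, :]) + 1e-12
        B = (W * flat).sum(axis=0) / W.sum(axis=0)
    B = np.maximum(B, 0.0)
    if not np.all(np.isfinite(B)):
        raise DimensionError("baseline estimation produced non-finite values")
    return BaselineSeries(B, b_norm=0.0)
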