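"""Model / Results facade over the estimation pipeline.

`IlluminationModel` bundles an image stack with solver options; `fit()`
runs the measurement-matrix construction, the low-rank + sparse
decomposition and (for movies) the baseline estimation, and returns an
`IlluminationResults` carrying the estimated fields, diagnostics, a
`summary()` table, correction methods and plotting.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .baseline import estimate_baseline
from .core import (
    BaselineSeries,
    ImageStack,
    ShadingModel,
    as_stack,
    correct_image,
    correct_timelapse,
)
from .decomposition import SolverOptions, _estimate_shading_full

__all__ = ["IlluminationModel", "IlluminationResults"]


class IlluminationModel:
    """Retrospective illumination model for an image collection or movie.

    Parameters
    ----------
    stack : ImageStack, 3-D array or list of 2-D arrays
        The measured images (>= 2), all the same shape, sharing one
        shading profile.  Movies should be passed in temporal order with
        ``timelapse=True`` so per-frame baselines are also estimated.
    timelapse : bool, optional
        Defaults to the stack's own flag.
    **options
        Forwarded to :class:`~shadecorr.decomposition.SolverOptions`
        (``lambda_s``, ``lambda_d``, ``estimate_darkfield``,
        ``working_size``, ...).

    Examples
    --------
    >>> model = IlluminationModel(frames)           # doctest: +SKIP
    >>> res = model.fit()                           # doctest: +SKIP
    >>> corrected = res.correct(frames)             # doctest: +SKIP
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(self, stack, timelapse: Optional[bool] = None, **options):
        self.stack = as_stack(stack)
        if timelapse is None:
            timelapse = self.stack.is_timelapse
        self.timelapse = bool(timelapse)
        if self.timelapse and not self.stack.is_timelapse:
            self.stack = ImageStack(self.stack.frames, is_timelapse=True,
                                    pixel_dtype=self.stack.pixel_dtype)
        self.options = SolverOptions(**options)

    @classmethod
    def from_path(cls, path, pattern: str = "*", timelapse: bool = False, **options):
        """Build the model straight from a stack file or image directory."""
        from .io import read_image_stack

        stack = read_image_stack(path, pattern=pattern, is_timelapse=timelapse)
        return cls(stack, timelapse=timelapse, **options)

    def fit(self) -> "IlluminationResults":
        """Estimate S, D (and, for movies, the per-frame baselines B_i)."""
        shading, decomp = _estimate_shading_full(self.stack, self.options)
        baselines = None
        if self.timelapse:
            baselines = estimate_baseline(self.stack, shading, self.options)
        return IlluminationResults(self, shading, decomp, baselines)


class IlluminationResults:
    """Fit results: estimated fields, baselines, diagnostics, correction."""

    def __init__(self, model, shading_model, decomposition, baselines=None):
        self.model = model
        self.shading_model: ShadingModel = shading_model
        self.decomposition = decomposition
        self.baselines: Optional[BaselineSeries] = baselines

    # -- estimates ---------------------------------------------------
    @property
    def flatfield(self) -> np.ndarray:
        return self.shading_model.flatfield

    @property
    def darkfield(self) -> np.ndarray:
        return self.shading_model.darkfield

    @property
    def lambda_s(self) -> float:
        return self.decomposition.lambda_s

    @property
    def lambda_d(self) -> float:
        return self.decomposition.lambda_d

    @property
    def n_iterations(self) -> int:
        return self.decomposition.n_iterations

    @property
    def feasibility_gap(self) -> float:
        return self.decomposition.final_feasibility_gap

    @property
    def converged(self) -> bool:
        return self.decomposition.converged

    # -- correction --------------------------------------------------
    def correct(self, images=None, b_norm=None, baselines=None):
        """Correct images with the fitted model.

        With ``images`` omitted, corrects the stack the model was fitted
        on.  For a time-lapse fit the per-frame baselines are subtracted
        and the frames shifted to ``b_norm`` ("mean" for bright-field,
        "zero"/default for fluorescence, or a number); otherwise each
        frame is corrected independently as ``(I - D) / S``.
        Returns a 2-D array for a single image, else an ImageStack.
        """
        if images is None:
            images = self.model.stack
        single = isinstance(images, np.ndarray) and images.ndim == 2
        if single:
            return correct_image(images, self.shading_model)
        stack = as_stack(images)
        series = baselines if baselines is not None else self.baselines
        if series is not None and len(series) == stack.n_frames:
            return correct_timelapse(stack, self.shading_model, series,
                                     b_norm=b_norm)
        frames = [correct_image(f, self.shading_model) for f in stack.frames]
        return ImageStack(frames, is_timelapse=stack.is_timelapse,
                          pixel_dtype=stack.pixel_dtype)

    # -- reporting ---------------------------------------------------
    def summary(self) -> str:
        d = self.decomposition
        s = self.shading_model
        rows = [
            ("No. images", self.model.stack.n_frames,
             "Working size", s.working_size),
            ("Flat-field min", f"{s.flatfield.min():.4f}",
             "Flat-field max", f"{s.flatfield.max():.4f}"),
            ("Dark-field mean", f"{s.darkfield.mean():.4f}",
             "Dark-field max", f"{s.darkfield.max():.4f}"),
            ("lambda_s", f"{d.lambda_s:.4g}", "lambda_d", f"{d.lambda_d:.4g}"),
            ("Iterations", d.n_iterations,
             "Feasibility gap", f"{d.final_feasibility_gap:.3e}"),
            ("Converged", d.converged, "Time-lapse", self.model.timelapse),
        ]
        if self.baselines is not None:
            v = self.baselines.values
            rows.append(("Baseline first", f"{v[0]:.4g}",
                         "Baseline last", f"{v[-1]:.4g}"))
        title = "Illumination Model Results"
        width = 64
        lines = [title.center(width), "=" * width]
        for a, b, c, e in rows:
            lines.append(f"{a:<18}{str(b):>13}   {c:<18}{str(e):>12}")
        lines.append("=" * width)
        return "\n".join(lines)

    def save(self, path):
        """Write the shading model (TIFF + JSON sidecar) to ``path``."""
        from .io import write_shading_model

        return write_shading_model(self.shading_model, path)

    def plot_fields(self, axes=None):
        """Show estimated flat-field and dark-field side by side."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, field, label in zip(
            axes, (self.flatfield, self.darkfield), ("flat-field S", "dark-field D")
        ):
            im = ax.imshow(field)
            ax.set_title(label)
            ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return axes
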