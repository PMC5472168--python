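"""Domain types and the image-formation model.

A measured microscopy image is modelled as

    I_meas(x) = I_true(x) * S(x) + D(x)

where ``S`` is the multiplicative flat-field (vignetting / uneven effective
illumination, mean-normalized to 1) and ``D`` the additive dark-field
(camera offset, thermal noise, stray light).  For a time-lapse movie the
true image of frame ``i`` further splits into a spatially constant
baseline ``B_i`` (background medium, drifting with photobleaching) plus
the foreground signal.  Correction inverts the model:

    I_corr = (I_meas - D) / S                 (single images)
    I_corr = (I_meas - D) / S - B_i + B_norm  (movie frame i)

``B_norm`` is an arbitrary reference background: the mean of the ``B_i``
for bright-field movies (keeps the corrected movie in the raw intensity
range) and 0 for fluorescence movies (removes the background entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from skimage.transform import resize

from .exceptions import DimensionError, DataError, ModelValidityError

__all__ = [
    "ImageStack",
    "ShadingModel",
    "BaselineSeries",
    "correct_image",
    "correct_timelapse",
]

#: relative tolerance on the mean-1 normalization of the flat-field
FLATFIELD_MEAN_TOL = 1e-6


class ImageStack:
    """An ordered set of same-shape grayscale frames.

    Parameters
    ----------
    frames : array-like
        Shape ``(n_frames, height, width)``, or a sequence of 2-D arrays.
    is_timelapse : bool
        Whether frame order encodes acquisition time.
    pixel_dtype : numpy dtype, optional
        The sample format of the source data (recorded for IO round trips);
        defaults to the dtype of ``frames``.  Pixels are held as float64
        internally regardless.
    """

    def __init__(self, frames, is_timelapse: bool = False, pixel_dtype=None):
        if isinstance(frames, (list, tuple)):
            shapes = {np.asarray(f).shape for f in frames}
            if len(shapes) > 1:
                raise DimensionError(f"frames have mixed shapes: {sorted(shapes)}")
            frames = np.stack([np.asarray(f) for f in frames])
        else:
            frames = np.asarray(frames)
        if frames.ndim != 3:
            raise DimensionError(
                f"expected (n_frames, height, width), got shape {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise DimensionError("a stack needs at least one frame")
        if pixel_dtype is None:
            pixel_dtype = frames.dtype
        data = frames.astype(np.float64, copy=True)
        if not np.all(np.isfinite(data)):
            raise DataError("stack contains non-finite pixel values")
        self.frames = data
        self.is_timelapse = bool(is_timelapse)
        self.pixel_dtype = np.dtype(pixel_dtype)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def shape(self):
        return self.frames.shape

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __getitem__(self, i) -> np.ndarray:
        return self.frames[i]

    def __repr__(self) -> str:
        kind = "timelapse" if self.is_timelapse else "collection"
        return (
            f"ImageStack({self.n_frames} x {self.height}x{self.width}, "
            f"{kind}, source dtype {self.pixel_dtype})"
        )


def as_stack(images, is_timelapse: bool = False) -> ImageStack:
    """Coerce an ImageStack / 3-D array / list of 2-D arrays to ImageStack."""
    if isinstance(images, ImageStack):
        return images
    return ImageStack(images, is_timelapse=is_timelapse)


@dataclass
class ShadingModel:
    """Estimated flat-field S(x) and dark-field D(x).

    ``flatfield`` is unitless multiplicative gain, strictly positive, with
    mean 1 over the image (the convention that resolves the scale ambiguity
    between S and the per-image brightness).  ``darkfield`` is an additive
    offset in the intensity units of the input.  ``working_size`` records
    the (square) resolution the fields were estimated at; the stored fields
    may be an upsampled version.  ``metadata`` carries estimation
    provenance (regularization weights, solver diagnostics).
    """

    flatfield: np.ndarray
    darkfield: np.ndarray
    working_size: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.flatfield = np.asarray(self.flatfield, dtype=np.float64)
        self.darkfield = np.asarray(self.darkfield, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.flatfield.ndim != 2:
            raise ModelValidityError("flat-field must be 2-D")
        if self.darkfield.shape != self.flatfield.shape:
            raise ModelValidityError(
                f"dark-field shape {self.darkfield.shape} != "
                f"flat-field shape {self.flatfield.shape}"
            )
        if not np.all(np.isfinite(self.flatfield)) or not np.all(
            np.isfinite(self.darkfield)
        ):
            raise ModelValidityError("model fields contain non-finite values")
        if np.any(self.flatfield <= 0):
            raise ModelValidityError("flat-field must be strictly positive")
        m = float(self.flatfield.mean())
        if abs(m - 1.0) > FLATFIELD_MEAN_TOL:
            raise ModelValidityError(
                f"flat-field mean must be 1 (got {m:.8g}); renormalize first"
            )

    @property
    def shape(self):
        return self.flatfield.shape

    def resampled_to(self, shape) -> "ShadingModel":
        """Return a copy with fields bilinearly resampled to ``shape``.

        The resampled flat-field is renormalized to mean 1 (bilinear
        interpolation preserves the mean only approximately).
        """
        shape = tuple(shape)
        if shape == self.flatfield.shape:
            return self
        s = resize(self.flatfield, shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        d = resize(self.darkfield, shape, order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        s = np.maximum(s, np.finfo(float).tiny)
        s /= s.mean()
        return ShadingModel(s, d, working_size=self.working_size,
                            metadata=dict(self.metadata))

    @classmethod
    def identity(cls, shape) -> "ShadingModel":
        """The no-op model: S == 1, D == 0."""
        return cls(np.ones(shape), np.zeros(shape))


@dataclass
class BaselineSeries:
    """Per-frame background baselines B_i of a movie plus the reference B_norm."""

    values: np.ndarray
    b_norm: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise DataError("baselines contain non-finite values")
        self.b_norm = float(self.b_norm)

    def __len__(self) -> int:
        return self.values.size

    def with_b_norm(self, rule) -> "BaselineSeries":
        """Return a copy with ``b_norm`` set by rule.

        ``rule`` is ``"mean"`` (bright-field convention: mean of the B_i),
        ``"zero"`` (fluorescence convention) or an explicit number.
        """
        if rule == "mean":
            b = float(self.values.mean())
        elif rule == "zero":
            b = 0.0
        else:
            b = float(rule)
        return BaselineSeries(self.values.copy(), b_norm=b)


def correct_image(image: np.ndarray, model: ShadingModel) -> np.ndarray:
    """Invert the image-formation model: ``(image - D) / S``.

    Model fields estimated at a smaller working size are bilinearly
    resampled to the image shape first.  No clipping is applied — negative
    output values are legitimate (noise around a removed offset) and
    clipping would bias downstream quantification.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {image.shape}")
    model = model.resampled_to(image.shape)
    return (image - model.darkfield) / model.flatfield


def correct_timelapse(
    stack: ImageStack,
    model: ShadingModel,
    baselines: BaselineSeries,
    b_norm=None,
) -> ImageStack:
    """Correct a movie: frame i becomes ``(I_i - D)/S - B_i + B_norm``.

    ``b_norm`` overrides the reference background stored on ``baselines``
    ("mean", "zero" or a number).  Use the mean convention for bright-field
    movies and zero for fluorescence movies.
    """
    stack = as_stack(stack, is_timelapse=True)
    if len(baselines) != stack.n_frames:
        raise DimensionError(
            f"{len(baselines)} baselines for {stack.n_frames} frames"
        )
    if b_norm is not None:
        baselines = baselines.with_b_norm(b_norm)
    model = model.resampled_to((stack.height, stack.width))
    flat = (stack.frames - model.darkfield) / model.flatfield
    shift = baselines.b_norm - baselines.values
    corrected = flat + shift[:, None, None]
    return ImageStack(corrected, is_timelapse=True, pixel_dtype=stack.pixel_dtype)
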