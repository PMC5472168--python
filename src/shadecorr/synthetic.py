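"""Synthetic microscopy scenes with known shading ground truth.

Every stage of the pipeline is testable against these scenes: a smooth
center-bright flat-field (parabolic vignette), a constant dark-field
(camera offset), cell-like elliptical foreground objects at three density
levels, Gaussian read noise, optional bright "spike" particles, and — for
movies — an exponentially decaying per-frame background baseline that
emulates medium photobleaching.

All randomness flows from a single :class:`numpy.random.Generator`
(PCG64) seeded by the caller, so scenes are bit-reproducible.

Default conditions (intensity unit = camera count):
background level 100, dark-field 10, read-noise sd 5, vignette strength
0.3 (30 % corner falloff), foreground density bands low/medium/high of
about 5 / 15 / 30 % of pixels, movie baseline 100*exp(-i/50) + 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ImageStack
from .exceptions import DimensionError

__all__ = [
    "SyntheticScene",
    "OverlapPairs",
    "make_flatfield",
    "simulate_collection",
    "simulate_timelapse",
    "simulate_overlap_pairs",
    "DENSITY_TARGETS",
]

#: target foreground pixel fractions per density level
DENSITY_TARGETS = {"low": 0.05, "medium": 0.15, "high": 0.30}
#: accepted band around each target (overshoot bounded by one cell's area)
DENSITY_BAND_WIDTH = 0.05

DEFAULT_SHAPE = (128, 128)
DEFAULT_BACKGROUND = 100.0
DEFAULT_DARKFIELD = 10.0
DEFAULT_NOISE_SD = 5.0
DEFAULT_FLATFIELD_STRENGTH = 0.3


@dataclass
class SyntheticScene:
    """A generated scene: measured images plus every piece of ground truth."""

    truth_flatfield: np.ndarray
    truth_darkfield: np.ndarray
    true_images: ImageStack
    measured_images: ImageStack
    foreground_masks: np.ndarray          # (n, h, w) bool, cells only
    noise: np.ndarray                     # stored realization, same shape
    density_level: Optional[str]
    seed: int
    params: dict = field(default_factory=dict)
    truth_baselines: Optional[np.ndarray] = None   # movies only
    spike_masks: Optional[np.ndarray] = None       # where artefacts were injected

    @property
    def n_images(self) -> int:
        return self.measured_images.n_frames

    def foreground_fractions(self) -> np.ndarray:
        return self.foreground_masks.reshape(self.n_images, -1).mean(axis=1)


def make_flatfield(
    height: int,
    width: int,
    strength: float = DEFAULT_FLATFIELD_STRENGTH,
    center_offset=(0.0, 0.0),
) -> np.ndarray:
    """Smooth center-bright vignette, renormalized to mean 1.

    Parabolic radial profile ``1 - strength * (d / d_max)**2`` where ``d``
    is the distance from the (optionally offset) optical center and
    ``d_max`` the distance to the farthest corner; ``strength`` in
    [0, 0.9] is the pre-normalization falloff at that corner, so the
    center/corner ratio is ``1 / (1 - strength)``.
    """
    if not 0.0 <= strength <= 0.9:
        raise ValueError(f"strength must be in [0, 0.9], got {strength}")
    if height < 1 or width < 1:
        raise DimensionError("flat-field needs positive dimensions")
    cy = (height - 1) / 2.0 + center_offset[0]
    cx = (width - 1) / 2.0 + center_offset[1]
    yy, xx = np.mgrid[0:height, 0:width]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    corners = [
        (0.0, 0.0), (0.0, width - 1.0), (height - 1.0, 0.0),
        (height - 1.0, width - 1.0),
    ]
    d2max = max((y - cy) ** 2 + (x - cx) ** 2 for y, x in corners)
    field_ = 1.0 - strength * d2 / max(d2max, 1.0)
    return field_ / field_.mean()


def _add_ellipse(canvas, mask, rng, shape, intensity_scale, axes_range):
    """Paint one random rotated ellipse; returns nothing (in-place)."""
    h, w = shape
    cy = rng.uniform(0, h)
    cx = rng.uniform(0, w)
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    theta = rng.uniform(0, np.pi)
    # lognormal cell intensity: median ~ intensity_scale, sigma 0.4
    amp = rng.lognormal(mean=np.log(intensity_scale), sigma=0.4)
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (yy - cy) * ct + (xx - cx) * st
    v = -(yy - cy) * st + (xx - cx) * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[inside] += amp
    mask |= inside


def _cell_layer(rng, shape, target_fraction, intensity_scale, axes_range):
    """Foreground layer of random ellipses reaching the target pixel fraction."""
    canvas = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    n_px = mask.size
    guard = 0
    while mask.sum() / n_px < target_fraction and guard < 10_000:
        _add_ellipse(canvas, mask, rng, shape, intensity_scale, axes_range)
        guard += 1
    return canvas, mask


def _spike_layer(rng, shape, background, amplitude_range=(10.0, 50.0)):
    """1-3 small bright discs, 10-50x the background level."""
    h, w = shape
    canvas = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(2.0, 4.0)
        amp = rng.uniform(*amplitude_range) * background
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        canvas[inside] += amp
        mask |= inside
    return canvas, mask


def _axes_range_for(shape):
    # cell semi-axes ~3-9 % of the image side: realistic for 10x-20x fields
    side = min(shape)
    return (0.03 * side, 0.09 * side)


def simulate_collection(
    n_images: int,
    density_level: str = "medium",
    shape=DEFAULT_SHAPE,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    spike_fraction: float = 0.0,
    spike_amplitude=(10.0, 50.0),
    flatfield_strength: float = DEFAULT_FLATFIELD_STRENGTH,
    darkfield_level: float = DEFAULT_DARKFIELD,
    background_level: float = DEFAULT_BACKGROUND,
    background_jitter: float = 0.15,
) -> SyntheticScene:
    """A collection of independent fields of view sharing one shading profile.

    Each true image is a constant background plus random elliptical
    "cells" (count chosen to reach the density level's foreground
    fraction); the measured image is ``true * S + D + noise``, with bright
    spike particles injected into ``spike_fraction`` of the images.

    The per-image background level is drawn uniformly within
    ``background_level * (1 +/- background_jitter)`` — real collections
    never share one exact background (medium autofluorescence, source
    drift), and it is precisely this brightness diversity that makes the
    additive dark-field identifiable from the multiplicative flat-field.
    The drawn levels are stored in ``truth_baselines``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if density_level not in DENSITY_TARGETS:
        raise ValueError(f"unknown density level {density_level!r}")
    if not 0.0 <= spike_fraction <= 1.0:
        raise ValueError("spike_fraction must be in [0, 1]")
    # spikes draw from their own substream so a spiked scene shares its
    # cells and noise bit-for-bit with the clean scene of the same seed
    main_ss, spike_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(main_ss)
    spike_rng = np.random.default_rng(spike_ss)
    shape = tuple(shape)
    S = make_flatfield(*shape, strength=flatfield_strength)
    D = np.full(shape, float(darkfield_level))
    target = DENSITY_TARGETS[density_level]
    axes_range = _axes_range_for(shape)

    n_spiked = int(round(spike_fraction * n_images))
    spiked = np.zeros(n_images, dtype=bool)
    if n_spiked:
        spiked[spike_rng.choice(n_images, size=n_spiked, replace=False)] = True

    levels = background_level * rng.uniform(
        1.0 - background_jitter, 1.0 + background_jitter, size=n_images
    )
    true_frames = np.empty((n_images, *shape))
    masks = np.zeros((n_images, *shape), dtype=bool)
    spike_masks = np.zeros((n_images, *shape), dtype=bool)
    for i in range(n_images):
        cells, mask = _cell_layer(rng, shape, target, background_level, axes_range)
        frame = levels[i] + cells
        if spiked[i]:
            spikes, smask = _spike_layer(spike_rng, shape, background_level,
                                         spike_amplitude)
            frame = frame + spikes
            spike_masks[i] = smask
        true_frames[i] = frame
        masks[i] = mask

    noise = (rng.normal(0.0, noise_sd, size=true_frames.shape)
             if noise_sd > 0 else np.zeros_like(true_frames))
    measured = true_frames * S + D + noise
    return SyntheticScene(
        truth_flatfield=S,
        truth_darkfield=D,
        true_images=ImageStack(true_frames),
        measured_images=ImageStack(measured),
        foreground_masks=masks,
        noise=noise,
        density_level=density_level,
        seed=seed,
        spike_masks=spike_masks,
        truth_baselines=levels,
        params={
            "n_images": n_images, "shape": shape, "noise_sd": noise_sd,
            "spike_fraction": spike_fraction,
            "flatfield_strength": flatfield_strength,
            "darkfield_level": darkfield_level,
            "background_level": background_level,
            "background_jitter": background_jitter,
        },
    )


def simulate_timelapse(
    n_frames: int = 100,
    shape=DEFAULT_SHAPE,
    decay_scale: float = 50.0,
    baseline_amplitude: float = 100.0,
    baseline_floor: float = 10.0,
    kind: str = "fluorescence",
    density_level: str = "medium",
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    flatfield_strength: float = DEFAULT_FLATFIELD_STRENGTH,
    darkfield_level: float = DEFAULT_DARKFIELD,
    constant_baseline: bool = False,
) -> SyntheticScene:
    """A movie with exponentially decaying background baseline.

    ``B_i = amplitude * exp(-i / decay_scale) + floor`` (all frames equal
    to ``amplitude + floor`` when ``constant_baseline`` is set — the
    no-bleaching limit).  Foreground cells drift by a small random walk
    and occasionally divide, emulating a live-cell movie; bright-field
    movies get absorbing (darker-than-background) cells, fluorescence
    movies emitting ones.
    """
    if n_frames < 2:
        raise ValueError("a movie needs at least 2 frames")
    if kind not in ("fluorescence", "brightfield"):
        raise ValueError(f"unknown movie kind {kind!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    S = make_flatfield(*shape, strength=flatfield_strength)
    D = np.full(shape, float(darkfield_level))
    i = np.arange(n_frames)
    if constant_baseline:
        B = np.full(n_frames, baseline_amplitude + baseline_floor)
    else:
        B = baseline_amplitude * np.exp(-i / decay_scale) + baseline_floor

    # initial cell population sized for the density band
    target = DENSITY_TARGETS[density_level]
    axes_range = _axes_range_for(shape)
    mean_area = np.pi * np.mean(axes_range) ** 2
    n_cells = max(1, int(round(target * shape[0] * shape[1] / mean_area)))
    sign = 1.0 if kind == "fluorescence" else -1.0
    cell_scale = baseline_amplitude if kind == "fluorescence" else 0.3 * baseline_amplitude
    cells = [
        {
            "cy": rng.uniform(0, shape[0]), "cx": rng.uniform(0, shape[1]),
            "a": rng.uniform(*axes_range), "b": rng.uniform(*axes_range),
            "theta": rng.uniform(0, np.pi),
            "amp": rng.lognormal(np.log(cell_scale), 0.4),
        }
        for _ in range(n_cells)
    ]

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    true_frames = np.empty((n_frames, *shape))
    masks = np.zeros((n_frames, *shape), dtype=bool)
    for t in range(n_frames):
        fg = np.zeros(shape)
        mask = np.zeros(shape, dtype=bool)
        for c in cells:
            ct, st = np.cos(c["theta"]), np.sin(c["theta"])
            u = (yy - c["cy"]) * ct + (xx - c["cx"]) * st
            v = -(yy - c["cy"]) * st + (xx - c["cx"]) * ct
            inside = (u / c["a"]) ** 2 + (v / c["b"]) ** 2 <= 1.0
            fg[inside] += sign * c["amp"]
            mask |= inside
        true_frames[t] = B[t] + fg
        masks[t] = mask
        # cell motility (random walk, ~2 px/frame: motile cells traverse
        # several diameters over a movie, decorrelating the foreground)
        # plus rare division, then advance to next frame
        for c in cells:
            c["cy"] = float(np.clip(c["cy"] + rng.normal(0, 2.0), 0, shape[0]))
            c["cx"] = float(np.clip(c["cx"] + rng.normal(0, 2.0), 0, shape[1]))
        if rng.random() < 0.02 and len(cells) < 3 * n_cells:
            parent = cells[rng.integers(len(cells))]
            child = dict(parent)
            child["cy"] = float(np.clip(parent["cy"] + rng.normal(0, 3), 0, shape[0]))
            child["cx"] = float(np.clip(parent["cx"] + rng.normal(0, 3), 0, shape[1]))
            cells.append(child)

    noise = (rng.normal(0.0, noise_sd, size=true_frames.shape)
             if noise_sd > 0 else np.zeros_like(true_frames))
    measured = true_frames * S + D + noise
    return SyntheticScene(
        truth_flatfield=S,
        truth_darkfield=D,
        true_images=ImageStack(true_frames, is_timelapse=True),
        measured_images=ImageStack(measured, is_timelapse=True),
        foreground_masks=masks,
        noise=noise,
        density_level=density_level,
        seed=seed,
        truth_baselines=B,
        params={
            "n_frames": n_frames, "shape": shape, "decay_scale": decay_scale,
            "baseline_amplitude": baseline_amplitude,
            "baseline_floor": baseline_floor, "kind": kind,
            "noise_sd": noise_sd, "flatfield_strength": flatfield_strength,
            "darkfield_level": darkfield_level,
            "constant_baseline": constant_baseline,
        },
    )


@dataclass
class OverlapPairs:
    """Overlapping tile pairs for the correction score.

    ``stack`` holds the measured tiles (two per pair).  ``pair_overlaps``
    maps a corrected (or raw) frame array back to the aligned overlap
    regions: entry ``k`` is ``((i, slice), (j, slice))`` such that
    ``frames[i][:, slice_i]`` and ``frames[j][:, slice_j]`` image the same
    piece of specimen.
    """

    stack: ImageStack
    pair_overlaps: list
    truth_flatfield: np.ndarray
    truth_darkfield: np.ndarray
    seed: int

    def extract_pairs(self, frames) -> list:
        frames = np.asarray(frames)
        out = []
        for (i, sl_i), (j, sl_j) in self.pair_overlaps:
            out.append((frames[i][:, sl_i], frames[j][:, sl_j]))
        return out


def simulate_overlap_pairs(
    n_pairs: int = 6,
    shape=DEFAULT_SHAPE,
    overlap: float = 0.5,
    density_level: str = "medium",
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    flatfield_strength: float = DEFAULT_FLATFIELD_STRENGTH,
    darkfield_level: float = DEFAULT_DARKFIELD,
    background_level: float = DEFAULT_BACKGROUND,
) -> OverlapPairs:
    """Pairs of laterally shifted tiles of one specimen under one shading.

    Each pair views a wide true scene through two windows shifted by
    ``(1 - overlap) * width``; both tiles receive the same flat-field and
    dark-field, so their shared region differs only through shading (and
    noise) — exactly the situation the correction score was designed for.
    """
    if not 0.1 <= overlap <= 0.9:
        raise ValueError("overlap must be in [0.1, 0.9]")
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    h, w = shape
    shift = int(round((1 - overlap) * w))
    shift = max(shift, 1)
    S = make_flatfield(h, w, strength=flatfield_strength)
    D = np.full(shape, float(darkfield_level))
    target = DENSITY_TARGETS[density_level]
    axes_range = _axes_range_for(shape)

    frames = []
    overlaps = []
    for k in range(n_pairs):
        wide = np.zeros((h, w + shift))
        mask = np.zeros_like(wide, dtype=bool)
        n_px = wide.size
        guard = 0
        while mask.sum() / n_px < target and guard < 10_000:
            _add_ellipse(wide, mask, rng, wide.shape, background_level, axes_range)
            guard += 1
        wide += background_level
        t1 = wide[:, :w]
        t2 = wide[:, shift:]
        for t in (t1, t2):
            noise = (rng.normal(0, noise_sd, size=shape)
                     if noise_sd > 0 else 0.0)
            frames.append(t * S + D + noise)
        i = 2 * k
        overlaps.append(
            ((i, slice(shift, w)), (i + 1, slice(0, w - shift)))
        )
    return OverlapPairs(
        stack=ImageStack(np.stack(frames)),
        pair_overlaps=overlaps,
        truth_flatfield=S,
        truth_darkfield=D,
        seed=seed,
    )
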