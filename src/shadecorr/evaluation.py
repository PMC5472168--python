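"""Quantitative quality scores for shading estimation and correction.

Two scores are used throughout:

* the **estimation score** Gamma — mean absolute deviation between an
  estimate and the ground truth, normalized by the deviation of a trivial
  baseline (a uniform flat-field for S, a zero dark-field for D, the
  uncorrected image for I_corr).  0 is perfect, 1 means no better than
  doing nothing, > 1 worse than doing nothing.

* the **correction score** Gamma' — for real data without ground truth:
  mean absolute difference over pre-aligned overlapping image pairs after
  correction, normalized by the same statistic before correction.  Values
  below 1 indicate reduced shading.  No extra intensity normalization is
  applied to the pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

from .exceptions import DegenerateInputError, DimensionError

__all__ = ["ScoreReport", "estimation_score", "correction_score"]


def estimation_score(estimate, truth, baseline) -> float:
    """Gamma = mean|estimate - truth| / mean|baseline - truth|."""
    estimate = np.asarray(estimate, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if not (estimate.shape == truth.shape == baseline.shape):
        raise DimensionError(
            f"shape mismatch: estimate {estimate.shape}, truth {truth.shape}, "
            f"baseline {baseline.shape}"
        )
    denom = float(np.abs(baseline - truth).mean())
    if denom == 0.0:
        raise DegenerateInputError(
            "baseline equals truth everywhere: score undefined"
        )
    return float(np.abs(estimate - truth).mean()) / denom


def _pair_mad(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]) -> float:
    # mean over pixels within each pair, then unweighted mean over pairs
    means = []
    for a, b in pairs:
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.shape != b.shape:
            raise DimensionError(f"pair members differ in shape: {a.shape} vs {b.shape}")
        means.append(float(np.abs(a - b).mean()))
    return float(np.mean(means))


def correction_score(corrected_pairs, uncorrected_pairs) -> float:
    """Gamma' = pooled MAD of corrected overlap pairs / same for uncorrected."""
    corrected_pairs = list(corrected_pairs)
    uncorrected_pairs = list(uncorrected_pairs)
    if len(corrected_pairs) != len(uncorrected_pairs):
        raise DimensionError(
            f"{len(corrected_pairs)} corrected vs "
            f"{len(uncorrected_pairs)} uncorrected pairs"
        )
    if not corrected_pairs:
        raise DegenerateInputError("no pairs supplied")
    denom = _pair_mad(uncorrected_pairs)
    if denom == 0.0:
        raise DegenerateInputError(
            "uncorrected pairs agree exactly: score undefined"
        )
    return _pair_mad(corrected_pairs) / denom


@dataclass
class ScoreReport:
    """Bundle of the scores computed for one run; absent scores are None."""

    gamma_flatfield: Optional[float] = None
    gamma_darkfield: Optional[float] = None
    gamma_corrected: Optional[float] = None
    gamma_prime: Optional[float] = None

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text
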