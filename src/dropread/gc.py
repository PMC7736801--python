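"""Local GC-content profiles by Gaussian smoothing of the G/C indicator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = ["GCProfile", "local_gc", "mean_gc"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GCProfile:
    """Per-position local GC fraction of a sequence.

    ``values[i]`` is the Gaussian-weighted GC fraction centred on position
    ``i`` (sigma in bases, kernel truncated at 4 sigma and renormalized,
    reflecting boundary); ``region_mean`` is the plain unweighted GC fraction
    of the whole region, N excluded.
    """

    sigma: float
    values: np.ndarray
    region_mean: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"invalid symbols in sequence: {sorted(bad)}")


def local_gc(sequence: str, sigma: float = 20.0) -> GCProfile:
    """Local GC profile: Gaussian filter (default sigma = 20 bases).

    The binary G/C indicator is convolved with a discrete Gaussian kernel
    (truncated at 4 sigma, renormalized), reflecting at the ends.  Positions
    holding N contribute to neither the numerator nor the normalizing weight:
    the profile at each position is a weighted fraction over the non-N bases
    in the window.
    """
    _check_sequence(sequence)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C"]).astype(float)
    valid = (arr != b"N").astype(float)
    if not valid.any():
        raise ValueError("sequence contains only N")
    smooth = lambda x: gaussian_filter1d(x, sigma, mode="reflect", truncate=4.0)
    weight = smooth(valid)
    with np.errstate(invalid="ignore"):
        values = np.where(weight > 0, smooth(is_gc * valid) / np.maximum(weight, 1e-300), 0.0)
    values = np.clip(values, 0.0, 1.0)
    return GCProfile(sigma=sigma, values=values, region_mean=mean_gc(sequence))


def mean_gc(sequence: str) -> float:
    """Unweighted GC fraction (#G + #C) / (#A + #C + #G + #T); N excluded."""
    _check_sequence(sequence)
    counts = {b: sequence.count(b) for b in "ACGTN"}
    denom = len(sequence) - counts["N"]
    if denom == 0:
        raise ValueError("sequence contains only N")
    return (counts["G"] + counts["C"]) / denom
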