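"""Signal-domain preprocessing for complexity analysis.

Raw region-by-time matrices are transformed into the three representations
the temporal measures consume: the Hilbert amplitude envelope, a per-row
mean-thresholded binary activation matrix, and a column-stacked flat binary
vector in which each consecutive block of ``n_regions`` bits is one
timepoint's spatial activation pattern.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "EnvelopeSeries",
    "BinaryActivationMatrix",
    "FlatBinaryVector",
    "hilbert_envelope",
    "binarise_rows",
    "stack_flatten",
    "inverse_stack",
    "shuffle_surrogate",
]


@dataclass
class RoiTimeSeries:
    """A parcellated multichannel signal: one row per region, one column per timepoint.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_regions, n_timepoints)``.
    region_ids
        Ordered region labels; defaults to ``ROI_000 ...``.
    sampling_interval
        Seconds between samples (metadata only; 2.0 matches a typical fMRI TR).
    """

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    sampling_interval: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        x, t = self.values.shape
        if x < 1 or t < 2:
            raise ValueError(f"need at least 1 region and 2 timepoints, got {x}x{t}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinite entries")
        if not self.region_ids:
            self.region_ids = [f"ROI_{i:03d}" for i in range(x)]
        if len(self.region_ids) != x:
            raise ValueError("region_ids length does not match number of rows")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class EnvelopeSeries:
    """Nonnegative instantaneous-amplitude series, same shape as its source."""

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("envelope values must be nonnegative")


@dataclass
class BinaryActivationMatrix:
    """Region x time {0,1} matrix; entry 1 where the source was at or above its row mean."""

    values: np.ndarray
    source_means: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")


@dataclass
class FlatBinaryVector:
    """Column-stacked bit sequence; ``segment_length`` bits per timepoint."""

    bits: np.ndarray
    segment_length: int

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be 1-D")
        if self.bits.size % self.segment_length:
            raise ValueError("length must be a multiple of segment_length")


def hilbert_envelope(series: RoiTimeSeries) -> EnvelopeSeries:
    """Per-row modulus of the analytic signal, |x + i*H(x)|.

    Constant rows have a degenerate analytic signal; they are returned as
    their absolute value with a warning.
    """
    vals = series.values
    if vals.shape[1] < 8:
        raise ValueError("need at least 8 timepoints for the analytic signal")
    const = vals.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant row(s): envelope degenerates to |value|",
            RuntimeWarning,
            stacklevel=2,
        )
    env = np.abs(hilbert(vals, axis=1))
    # scipy's analytic signal of an exactly constant row is the constant itself,
    # so no special-casing is needed beyond the warning
    return EnvelopeSeries(values=env, region_ids=list(series.region_ids))


def binarise_rows(env: EnvelopeSeries) -> BinaryActivationMatrix:
    """Threshold each row at its own mean; ties at the mean map to 1."""
    vals = env.values
    means = vals.mean(axis=1, keepdims=True)
    return BinaryActivationMatrix(
        values=(vals >= means).astype(np.uint8), source_means=means.ravel()
    )


def stack_flatten(bin_matrix: BinaryActivationMatrix) -> FlatBinaryVector:
    """Concatenate columns in time order: bits[t*X + i] = M[i, t]."""
    m = bin_matrix.values
    return FlatBinaryVector(bits=m.T.reshape(-1), segment_length=m.shape[0])


def inverse_stack(flat: FlatBinaryVector) -> np.ndarray:
    """Reconstruct the region x time binary matrix from its column stacking."""
    x = flat.segment_length
    return flat.bits.reshape(-1, x).T


def shuffle_surrogate(
    bin_matrix: BinaryActivationMatrix, seed: int
) -> BinaryActivationMatrix:
    """Independently permute each row uniformly at random (bit counts conserved)."""
    rng = np.random.default_rng(seed)
    out = bin_matrix.values.copy()
    for row in out:
        rng.shuffle(row)
    return BinaryActivationMatrix(values=out, source_means=bin_matrix.source_means.copy())
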