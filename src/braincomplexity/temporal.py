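"""Temporal complexity measures.

Five per-scan measures of how compressible / predictable a multichannel
signal is:

* normalised Lempel-Ziv compressibility (LZ76 exhaustive-history parsing of
  the column-stacked binarised envelope, divided by the same quantity on a
  row-shuffled surrogate),
* sample entropy (``-log A/B`` with embedding ``m`` and tolerance
  ``r = r_coef * sd``),
* rescaled-range (R/S) Hurst exponent,
* Higuchi fractal dimension,
* PCA compressibility (number of principal components needed to reach a
  cumulative explained-variance threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .signal_prep import (
    BinaryActivationMatrix,
    FlatBinaryVector,
    RoiTimeSeries,
    binarise_rows,
    hilbert_envelope,
    shuffle_surrogate,
    stack_flatten,
)

__all__ = [
    "LZResult",
    "SampEnResult",
    "HurstFit",
    "HiguchiFit",
    "PcaCompressibility",
    "lz76_dictionary_size",
    "lzc_normalised",
    "sample_entropy",
    "hurst_rs",
    "higuchi_fd",
    "select_kmax",
    "pca_compressibility",
]


# ---------------------------------------------------------------------------
# Lempel-Ziv 76
# ---------------------------------------------------------------------------


@dataclass
class LZResult:
    dictionary_size: int
    surrogate_size: int
    raw_length: int
    normalised: float
    degenerate: bool = False


@njit(cache=True)
def _lz76_count(s):  # pragma: no cover - exercised via lz76_dictionary_size
    n = s.size
    c = 0
    i = 0
    while i < n:
        # longest match of s[i:] against a copy starting at any j < i
        # (overlap into the phrase allowed: exhaustive-history reproduction)
        max_l = 0
        cap = n - i
        for j in range(i):
            if s[j] != s[i]:
                continue
            if max_l > 0 and i + max_l < n and s[j + max_l] != s[i + max_l]:
                continue  # cannot beat the current best
            l = 0
            while i + l < n and s[j + l] == s[i + l]:
                l += 1
            if l > max_l:
                max_l = l
                if max_l >= cap:
                    break
        length = max_l + 1
        if length > cap:
            length = cap
        c += 1
        i += length
    return c


def lz76_dictionary_size(bits: FlatBinaryVector | np.ndarray) -> int:
    """Number of phrases in the LZ76 exhaustive-history parsing of a bit string.

    Scanning left to right, the current phrase is extended while it occurs as
    a substring of everything before its last symbol; each first-novelty
    closes a phrase (a final still-reproducible suffix counts as one phrase).
    """
    arr = bits.bits if isinstance(bits, FlatBinaryVector) else np.asarray(bits)
    arr = np.ascontiguousarray(arr, dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("empty bit sequence")
    return int(_lz76_count(arr))


def lzc_normalised(
    series_matrix: RoiTimeSeries, seed: int, n_surrogates: int = 1
) -> LZResult:
    """Surrogate-normalised Lempel-Ziv compressibility of a whole scan.

    Pipeline: Hilbert envelope -> per-row mean binarisation -> column
    stacking -> LZ76 phrase count, divided by the same count on a
    row-shuffled surrogate (which destroys temporal and spatial structure
    while conserving per-row bit counts). Values approach 1 for
    structureless data; ``n_surrogates > 1`` averages several shuffles.
    """
    env = hilbert_envelope(series_matrix)
    binary = binarise_rows(env)
    flat = stack_flatten(binary)
    d_true = lz76_dictionary_size(flat)

    degenerate = False
    if binary.values.std() == 0:
        warnings.warn("all-constant binarisation: LZC is degenerate", RuntimeWarning,
                      stacklevel=2)
        degenerate = True

    sizes = []
    for k in range(n_surrogates):
        surr = shuffle_surrogate(binary, seed=seed + k)
        sizes.append(lz76_dictionary_size(stack_flatten(surr)))
    d_surr = float(np.mean(sizes))
    return LZResult(
        dictionary_size=d_true,
        surrogate_size=int(round(d_surr)),
        raw_length=flat.bits.size,
        normalised=d_true / d_surr,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------


@dataclass
class SampEnResult:
    value: float
    m: int
    r: float
    match_count_m: int
    match_count_m1: int
    flag: str | None = None


def sample_entropy(series, m: int = 2, r_coef: float = 0.3) -> SampEnResult:
    """Sample entropy ``-log(A/B)`` of a scalar series.

    ``B`` counts ordered pairs (i != j, i, j <= N - m - 1) of m-length
    templates within Chebyshev distance ``r = r_coef * sd`` of each other;
    ``A`` the same for (m+1)-length templates over the same index set, so
    ``A <= B`` always. Self-matches are excluded. A constant series gives 0
    (every template matches at r = 0); ``A = 0`` gives +inf, flagged.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < m + 2:
        raise ValueError(f"series length {n} too short for m={m}")
    r = r_coef * x.std()

    n_templates = n - m  # both an m- and an (m+1)-template exist at each index
    # Chebyshev distance between m-templates via running maximum over lags
    d = np.abs(x[:n_templates, None] - x[None, :n_templates])
    for lag in range(1, m + 1):
        d = np.maximum(d, np.abs(x[lag:lag + n_templates, None]
                                 - x[None, lag:lag + n_templates]))
        if lag == m - 1:
            d_m = d.copy()
    if m == 1:
        d_m = np.abs(x[:n_templates, None] - x[None, :n_templates])

    off = ~np.eye(n_templates, dtype=bool)
    b = int(np.count_nonzero((d_m <= r) & off))
    a = int(np.count_nonzero((d <= r) & off))

    if b == 0:
        return SampEnResult(np.nan, m, r, b, a, flag="undefined: no m-matches")
    if a == 0:
        return SampEnResult(np.inf, m, r, b, a, flag="infinite: no (m+1)-matches")
    return SampEnResult(float(-np.log(a / b)) + 0.0, m, r, b, a)


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)
# ---------------------------------------------------------------------------


@dataclass
class HurstFit:
    exponent: float
    window_sizes: list[int]
    rs_values: list[float]
    fit_r_squared: float


def _default_windows(n: int) -> list[int]:
    sizes = []
    w = 8
    while w <= n // 2:
        sizes.append(w)
        w *= 2
    return sizes


def hurst_rs(series, window_sizes: list[int] | None = None) -> HurstFit:
    """Rescaled-range Hurst exponent.

    For each window size ``n`` the series is cut into ``floor(N/n)``
    non-overlapping segments; per segment the range of the cumulative
    mean-departure profile is divided by the segment standard deviation, and
    the mean R/S over segments is regressed (log-log) against ``n``. The
    slope is reported as H: 0.5 for memoryless noise, toward 1 for
    persistent, predictable signals. Zero-variance segments are skipped.
    """
    x = np.asarray(series, dtype=float).ravel()
    n_total = x.size
    if n_total < 32:
        raise ValueError("series too short for R/S estimation (need >= 32)")
    if window_sizes is None:
        window_sizes = _default_windows(n_total)
    window_sizes = sorted(int(w) for w in window_sizes)

    sizes_used, rs_means = [], []
    for w in window_sizes:
        n_seg = n_total // w
        if n_seg < 1 or w < 4:
            continue
        segs = x[: n_seg * w].reshape(n_seg, w)
        means = segs.mean(axis=1, keepdims=True)
        profile = np.cumsum(segs - means, axis=1)
        rng_ = profile.max(axis=1) - profile.min(axis=1)
        sd = segs.std(axis=1)
        ok = sd > 0
        if not ok.any():
            continue
        sizes_used.append(w)
        rs_means.append(float(np.mean(rng_[ok] / sd[ok])))

    if len(sizes_used) < 3:
        raise ValueError("fewer than 3 usable window sizes for R/S regression")

    logn = np.log(sizes_used)
    logrs = np.log(rs_means)
    slope, intercept = np.polyfit(logn, logrs, 1)
    resid = logrs - (slope * logn + intercept)
    ss_tot = float(np.sum((logrs - logrs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return HurstFit(float(slope), sizes_used, rs_means, r2)


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------


@dataclass
class HiguchiFit:
    dimension: float
    k_max: int
    k_values: list[int]
    mean_lengths: list[float]
    fit_r_squared: float


def higuchi_fd(series, k_max: int) -> HiguchiFit:
    """Higuchi fractal dimension of a scalar series.

    For each subsampling stride ``k`` and offset ``m = 1..k`` the normalised
    curve length ``L_m(k)`` of the decimated series is computed and averaged
    over offsets; the dimension is the negative slope of log<L(k)> against
    log(k). Smooth curves give ~1, white noise ~2, and fractional Gaussian
    noise with Hurst exponent H gives ~2 - H.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n <= 2 * k_max:
        raise ValueError(f"need series length > 2*k_max (N={n}, k_max={k_max})")

    k_values, mean_lengths = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(1, k + 1):
            n_i = (n - m) // k
            if n_i < 1:
                continue
            idx = m - 1 + np.arange(n_i + 1) * k
            diffs = np.abs(np.diff(x[idx]))
            norm = (n - 1) / (n_i * k)
            lengths.append(diffs.sum() * norm / k)
        if not lengths:
            warnings.warn(f"k={k} dropped: no valid offsets", RuntimeWarning,
                          stacklevel=2)
            continue
        k_values.append(k)
        mean_lengths.append(float(np.mean(lengths)))

    logk = np.log(k_values)
    logl = np.log(mean_lengths)
    slope, intercept = np.polyfit(logk, logl, 1)
    resid = logl - (slope * logk + intercept)
    ss_tot = float(np.sum((logl - logl.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return HiguchiFit(-float(slope), k_max, k_values, mean_lengths, r2)


def select_kmax(series_sample, candidates: list[int] | None = None) -> int:
    """Pick ``k_max`` from a stability sweep over candidate values.

    Candidates (powers of two 2..128 by default) that violate ``N > 2k`` for
    any series in the sample are excluded; the mean dimension over the sample
    is computed per remaining candidate, and the smallest candidate in the
    longest contiguous run where successive estimates change by < 0.05 is
    returned.
    """
    if candidates is None:
        candidates = [2, 4, 8, 16, 32, 64, 128]
    series_sample = [np.asarray(s, dtype=float).ravel() for s in series_sample]
    if not series_sample:
        raise ValueError("empty series sample")
    min_n = min(s.size for s in series_sample)
    feasible = [k for k in sorted(candidates) if min_n > 2 * k]
    if not feasible:
        raise ValueError("no feasible k_max candidate for these series lengths")
    if len(feasible) == 1:
        return feasible[0]

    dims = [
        float(np.mean([higuchi_fd(s, k).dimension for s in series_sample]))
        for k in feasible
    ]
    # longest contiguous run of |successive change| < 0.05
    best_start, best_len = 0, 1
    start, run = 0, 1
    for i in range(1, len(feasible)):
        if abs(dims[i] - dims[i - 1]) < 0.05:
            run += 1
        else:
            start, run = i, 1
        if run > best_len:
            best_start, best_len = start, run
    return feasible[best_start]


# ---------------------------------------------------------------------------
# PCA compressibility
# ---------------------------------------------------------------------------


@dataclass
class PcaCompressibility:
    n_components: int
    variance_threshold: float
    explained_curve: np.ndarray = field(repr=False, default=None)


def pca_compressibility(
    series_matrix: RoiTimeSeries, variance_threshold: float = 0.95
) -> PcaCompressibility:
    """Components needed to reach a cumulative explained-variance threshold.

    Timepoints are treated as observations and regions as features; each
    feature is standardised to mean 0 / unit variance first, so the count is
    bounded by the region count. More components for the same variance means
    less compressible, i.e. more complex, data.
    """
    x = series_matrix.values
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 regions and 2 timepoints")
    data = x.T  # observations = timepoints, features = regions
    zero_var = data.std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance region(s): centred only",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        scaled = StandardScaler().fit_transform(data)
    scaled[:, zero_var] = 0.0
    pca = PCA()
    pca.fit(scaled)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cumulative, variance_threshold) + 1)
    n_comp = min(n_comp, cumulative.size)
    return PcaCompressibility(n_comp, variance_threshold, cumulative)
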