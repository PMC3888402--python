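"""Fluctuation analysis of emotional-valence traces.

Hurst rescaled-range (R/S) analysis, shuffle surrogates, power-spectral-
density estimation with log-log tail slopes, the slope <-> Hurst conversions,
and the mean-split dichotomization that turns a continuous valence trace into
crossing intervals comparable to behavioral dwell times.

Conventions: the study pipeline applies R/S to the first differences
(increments) of a trace and the PSD to the raw trace; for a trace whose
increments are uncorrelated (ordinary Brownian motion) this yields H near 0.5
and a tail slope near -2, related by |slope| = 2H + 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .durations import DurationSet
from .errors import DegenerateInputError, ParameterError

PSD_METHODS = ("fft", "periodogram", "welch", "multitaper")
DEFAULT_TAIL_RANGE = (0.01, 0.25)
DICHOTOMIZED_LABEL = "dichotomized"


@dataclass
class HurstResult:
    hurst_H: float
    r_squared: float
    segment_sizes: np.ndarray
    log_points: np.ndarray  # rows (ln segment size, ln mean R/S)


@dataclass
class PsdResult:
    method: str
    frequencies: np.ndarray  # Hz, in (0, 0.5]
    power: np.ndarray
    tail_slope: float
    tail_r_squared: float
    tail_range: tuple[float, float]


@dataclass
class SurrogateComparison:
    original: HurstResult
    shuffled_mean_H: float
    shuffled_mean_r_squared: float
    n_shuffles: int


def default_segment_sizes(n: int, min_size: int = 16) -> list[int]:
    """Powers of two from ``min_size`` up to n/4.

    The smallest segments carry the strongest finite-sample R/S bias, so the
    default floor is 16 samples.
    """
    sizes = []
    s = min_size
    while s <= n // 4:
        sizes.append(s)
        s *= 2
    return sizes


def rescaled_range_hurst(values, segment_sizes=None) -> HurstResult:
    """Hurst exponent by non-overlapping rescaled-range analysis.

    For each segment size n the series is cut into floor(N/n) segments
    (remainder dropped). Within a segment, R is the range of the running sum
    of mean-adjusted values and S the (population) standard deviation; R/S is
    averaged over segments. H is the least-squares slope of ln(mean R/S)
    against ln(n), with the R^2 of that line reported.
    """
    x = np.asarray(values, dtype=float)
    N = len(x)
    if np.all(x == x[0]):
        raise DegenerateInputError("constant series has no rescaled range")
    if segment_sizes is None:
        segment_sizes = default_segment_sizes(N)
    sizes = sorted(int(s) for s in segment_sizes)
    if len(sizes) < 2:
        raise ParameterError("need at least two segment sizes")
    if sizes[0] < 2:
        raise ParameterError("segment sizes must be >= 2")
    if N < 2 * sizes[-1]:
        raise ParameterError(
            f"series length {N} < 2 x max segment size {sizes[-1]}"
        )

    log_pts = []
    kept_sizes = []
    for n in sizes:
        nseg = N // n
        segs = x[: nseg * n].reshape(nseg, n)
        sd = segs.std(axis=1)  # population convention
        ok = sd > 0
        if not ok.any():
            continue
        adj = segs[ok] - segs[ok].mean(axis=1, keepdims=True)
        cum = np.cumsum(adj, axis=1)
        rs = (cum.max(axis=1) - cum.min(axis=1)) / sd[ok]
        log_pts.append((np.log(n), np.log(rs.mean())))
        kept_sizes.append(n)
    if len(log_pts) < 2:
        raise DegenerateInputError("too few segments with nonzero variance")
    pts = np.array(log_pts)
    slope, intercept = np.polyfit(pts[:, 0], pts[:, 1], 1)
    pred = slope * pts[:, 0] + intercept
    sst = np.sum((pts[:, 1] - pts[:, 1].mean()) ** 2)
    r2 = 1.0 - np.sum((pts[:, 1] - pred) ** 2) / sst if sst > 0 else np.nan
    return HurstResult(float(slope), float(r2), np.array(kept_sizes), pts)


def shuffle_surrogate_hurst(values, n_shuffles: int, seed=None,
                            segment_sizes=None) -> SurrogateComparison:
    """Compare R/S of the series against uniformly permuted surrogates.

    Permutation preserves the value distribution but destroys temporal order,
    so surrogate H collapses toward 0.5; curvature or elevated H in the
    original that vanishes under shuffling reflects genuine temporal
    structure.
    """
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    x = np.asarray(values, dtype=float)
    original = rescaled_range_hurst(x, segment_sizes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hs, r2s = [], []
    for _ in range(n_shuffles):
        res = rescaled_range_hurst(rng.permutation(x), segment_sizes)
        hs.append(res.hurst_H)
        r2s.append(res.r_squared)
    return SurrogateComparison(original, float(np.mean(hs)), float(np.mean(r2s)),
                               n_shuffles)


def _multitaper_psd(x: np.ndarray, nw: float = 4.0):
    """Thomson multitaper estimate from DPSS tapers (2*NW - 1 of them)."""
    n = len(x)
    k = int(2 * nw - 1)
    tapers = signal.windows.dpss(n, nw, Kmax=k)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0)  # tapers are unit-norm: per-taper density at fs=1
    freqs = np.fft.rfftfreq(n, d=1.0)
    # one-sided scaling
    psd = 2.0 * psd
    psd[0] /= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    return freqs, psd


def power_spectrum(values, method: str = "periodogram",
                   tail_range: tuple[float, float] = DEFAULT_TAIL_RANGE) -> PsdResult:
    """One-sided PSD of a 1 Hz-sampled series, with its log-log tail slope.

    Methods: raw FFT modulus squared; periodogram (rectangular window, no
    zero-padding, no detrending); Welch (8 segments, 50% overlap, rectangular
    window); Thomson multitaper (time-bandwidth 4). Zero frequency is
    excluded; frequencies run up to the 0.5 Hz Nyquist limit.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 64:
        raise ParameterError(f"series too short for a PSD ({n} < 64 samples)")
    if method == "fft":
        freqs = np.fft.rfftfreq(n, d=1.0)
        psd = np.abs(np.fft.rfft(x)) ** 2 / n
    elif method == "periodogram":
        freqs, psd = signal.periodogram(x, fs=1.0, window="boxcar",
                                        detrend=False)
    elif method == "welch":
        nperseg = max(64, int(2 * n / 9))  # 8 segments at 50% overlap
        freqs, psd = signal.welch(x, fs=1.0, window="boxcar", nperseg=nperseg,
                                  noverlap=nperseg // 2, detrend="constant")
    elif method == "multitaper":
        freqs, psd = _multitaper_psd(x)
    else:
        raise ParameterError(f"unknown PSD method {method!r}; expected {PSD_METHODS}")
    keep = freqs > 0
    freqs, psd = freqs[keep], psd[keep]
    slope, r2 = _tail_fit(freqs, psd, tail_range)
    return PsdResult(method, freqs, psd, slope, r2, tuple(tail_range))


def _tail_fit(freqs, power, f_range):
    lo, hi = f_range
    if not lo < hi:
        raise ParameterError(f"empty frequency range {f_range!r}")
    m = (freqs >= lo) & (freqs <= hi) & (power > 0)
    if m.sum() < 8:
        raise ParameterError(
            f"need >= 8 spectral points in {f_range}, have {int(m.sum())}"
        )
    lx, ly = np.log(freqs[m]), np.log(power[m])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    sst = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum((ly - pred) ** 2) / sst if sst > 0 else np.nan
    return float(slope), float(r2)


def fit_tail_slope(psd: PsdResult,
                   f_range: tuple[float, float] = DEFAULT_TAIL_RANGE):
    """Least-squares line on (log f, log power) restricted to ``f_range``."""
    return _tail_fit(psd.frequencies, psd.power, f_range)


def slope_to_hurst(slope: float, mode: str = "data_slope") -> float:
    """Convert a PSD tail slope to a Hurst exponent.

    mode "data_slope": slope measured on the series itself, H describing its
    increments -> H = (|slope| - 1) / 2 (a Brownian path's -2 gives 0.5).
    mode "increment_slope": both measured on the increments ->
    H = (|slope| + 1) / 2 (white increments' 0 gives 0.5). Results outside
    [0, 1] are clamped with a warning.
    """
    if not np.isfinite(slope):
        raise ParameterError(f"slope must be finite, got {slope!r}")
    if mode == "data_slope":
        h = (abs(slope) - 1.0) / 2.0
    elif mode == "increment_slope":
        h = (abs(slope) + 1.0) / 2.0
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    if not 0.0 <= h <= 1.0:
        warnings.warn(
            f"slope {slope} maps to H={h:.3f} outside [0,1]; clamping",
            stacklevel=2,
        )
        h = min(1.0, max(0.0, h))
    return float(h)


def dichotomize_and_intervals(emotion) -> DurationSet:
    """Mean-split a valence trace and return the crossing intervals.

    Each second is labeled below/above the session-mean valence (exact ties
    count as above); the run lengths of that binary sequence are the
    durations of time between crossings of the mean level.
    """
    x = np.asarray(emotion, dtype=float)
    if x.size == 0:
        raise ParameterError("empty series")
    if np.all(x == x[0]):
        raise DegenerateInputError("constant series cannot be dichotomized")
    binary = (x >= x.mean()).astype(np.int64)
    change = np.nonzero(np.diff(binary))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(binary)]])
    return DurationSet(DICHOTOMIZED_LABEL, ends - starts)
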