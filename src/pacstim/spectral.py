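"""Complex Morlet wavelet scalograms and baseline z-score normalization.

The mother wavelet is

    Psi(t) = (1 / sqrt(pi*fb)) * exp(2j*pi*fc*t) * exp(-t**2 / fb)

with central frequency ``fc`` and bandwidth parameter ``fb`` (defaults
0.8125 Hz and 5, a combination commonly used on EEG).  An analysis
frequency ``f`` is reached by scaling the wavelet with ``a = fc / f``.

Normalization: the transform is computed in the frequency domain with the
wavelet's unit-peak Gaussian response

    H_f(nu) = 2 * exp(-pi**2 * fb * (a*nu - fc)**2),

i.e. L1-normalized in time and doubled like an analytic signal, so a pure
tone ``A*cos(2*pi*f*t)`` yields ``|W| ~= A`` at its own frequency
regardless of ``f``.  This makes amplitudes comparable across frequencies,
which matters downstream when fast-rhythm amplitude is binned by
slow-rhythm phase.

Edges are handled by reflection padding; samples within 3 standard
deviations of the scaled Gaussian envelope from either edge are flagged as
inside the cone of influence and excluded from statistics.

z-scoring follows the pre-stimulation-baseline convention: per analysis
frequency, the mean and standard deviation of ``|W|`` over an unmasked
baseline interval standardize the whole time course.  Samples masked out
(stimulation epochs plus a guard margin) propagate as NaN and never enter
any mean or standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "WaveletParams",
    "Scalogram",
    "BaselineStats",
    "EpochMask",
    "log_grid",
    "morlet_cwt",
    "compute_baseline_stats",
    "zscore_scalogram",
    "band_power",
]


def log_grid(f_min: float, f_max: float, voices_per_octave: int = 8) -> np.ndarray:
    """Logarithmic frequency grid: ``f_min * 2**(k/voices)`` up to ``f_max``."""
    if f_min <= 0 or f_max <= f_min:
        raise ValueError("need 0 < f_min < f_max")
    n = int(np.floor(voices_per_octave * np.log2(f_max / f_min) + 1e-9)) + 1
    return f_min * 2.0 ** (np.arange(n) / voices_per_octave)


def _default_grid() -> np.ndarray:
    return log_grid(0.5, 512.0, 8)


@dataclass(frozen=True)
class WaveletParams:
    """Complex Morlet parameters and the analysis frequency grid."""

    fc: float = 0.8125
    fb: float = 5.0
    frequency_grid: np.ndarray = field(default_factory=_default_grid)

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.fb <= 0:
            raise ValueError("fc and fb must be positive")
        grid = np.asarray(self.frequency_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("frequency_grid is empty")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("frequency_grid must be positive and strictly increasing")
        object.__setattr__(self, "frequency_grid", grid)

    def time_sigma(self, f: float) -> float:
        """Std of the scaled Gaussian envelope at analysis frequency *f*, s."""
        return (self.fc / f) * np.sqrt(self.fb / 2.0)


@dataclass
class Scalogram:
    """Complex wavelet coefficients on a (time x frequency) grid."""

    coefficients: np.ndarray  # (n_times, n_freqs) complex
    times: np.ndarray
    freqs: np.ndarray
    params: WaveletParams
    sample_rate: float
    coi_edge: np.ndarray  # per-frequency edge width, samples

    def freq_index(self, f: float) -> int:
        """Index of frequency *f* in the grid (must be present)."""
        j = int(np.argmin(np.abs(self.freqs - f)))
        if not np.isclose(self.freqs[j], f, rtol=1e-6):
            raise ValueError(f"frequency {f} Hz is not on the scalogram grid")
        return j

    def coi_valid(self) -> np.ndarray:
        """Boolean (n_times, n_freqs): True outside the cone of influence."""
        n = len(self.times)
        idx = np.arange(n)[:, None]
        e = self.coi_edge[None, :]
        return (idx >= e) & (idx < n - e)


@dataclass
class BaselineStats:
    """Per-frequency mean/sd of scalogram magnitude over a baseline interval."""

    freqs: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_samples: np.ndarray


class EpochMask:
    """Per-sample validity flags (False during stimulation plus a guard)."""

    def __init__(self, valid: np.ndarray):
        self.valid = np.asarray(valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.valid)

    def __and__(self, other: "EpochMask") -> "EpochMask":
        return EpochMask(self.valid & other.valid)

    @classmethod
    def all_valid(cls, n_samples: int) -> "EpochMask":
        return cls(np.ones(n_samples, dtype=bool))

    @classmethod
    def from_intervals(
        cls,
        n_samples: int,
        sample_rate: float,
        intervals,
        guard: float = 0.0,
    ) -> "EpochMask":
        """Invalidate half-open ``[start, end)`` intervals (s), +/- *guard* s."""
        valid = np.ones(n_samples, dtype=bool)
        for start, end in intervals:
            i0 = max(0, int(np.floor((start - guard) * sample_rate)))
            i1 = min(n_samples, int(np.ceil((end + guard) * sample_rate)))
            valid[i0:i1] = False
        return cls(valid)


def morlet_cwt(signal, sample_rate: float, params: WaveletParams | None = None) -> Scalogram:
    """Continuous wavelet transform of a 1-D trace.

    FFT-based: the reflected-padded signal spectrum is multiplied by the
    wavelet's Gaussian frequency response at each analysis frequency.
    Frequencies at or above Nyquist raise.
    """
    if params is None:
        params = WaveletParams()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("signal must be a 1-D trace with >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    freqs = params.frequency_grid
    nyquist = sample_rate / 2.0
    if freqs[-1] >= nyquist:
        raise ValueError(
            f"analysis frequency {freqs[-1]} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    n = x.size
    coi_edge = np.minimum(
        np.ceil(3.0 * np.array([params.time_sigma(f) for f in freqs]) * sample_rate),
        n // 2,
    ).astype(int)
    pad = int(min(n - 1, coi_edge.max()))
    padded = np.pad(x, pad, mode="reflect")
    L = next_fast_len(padded.size)
    X = fft(padded, L)
    nu = np.fft.fftfreq(L, d=1.0 / sample_rate)
    coefs = np.empty((n, freqs.size), dtype=complex)
    for j, f in enumerate(freqs):
        a = params.fc / f
        H = 2.0 * np.exp(-(np.pi**2) * params.fb * (a * nu - params.fc) ** 2)
        coefs[:, j] = ifft(X * H)[pad : pad + n]
    times = np.arange(n) / sample_rate
    return Scalogram(coefs, times, freqs, params, sample_rate, coi_edge)


def _magnitude(s: Scalogram, use_power: bool) -> np.ndarray:
    mag = np.abs(s.coefficients)
    return mag**2 if use_power else mag


def compute_baseline_stats(
    s: Scalogram,
    baseline: tuple[float, float],
    mask: EpochMask | None = None,
    use_power: bool = False,
) -> BaselineStats:
    """Per-frequency mean/sd of magnitude over unmasked baseline samples.

    Cone-of-influence samples are excluded along with masked ones.  A
    frequency with no usable samples, or with zero dispersion, raises with
    the frequency named.
    """
    t0, t1 = baseline
    in_base = (s.times >= t0) & (s.times < t1)
    if mask is not None:
        if len(mask) != len(s.times):
            raise ValueError("mask length does not match scalogram")
        in_base = in_base & mask.valid
    mag = _magnitude(s, use_power)
    coi = s.coi_valid()
    means = np.empty(s.freqs.size)
    sds = np.empty(s.freqs.size)
    counts = np.empty(s.freqs.size, dtype=int)
    for j, f in enumerate(s.freqs):
        sel = in_base & coi[:, j]
        counts[j] = int(sel.sum())
        if counts[j] < 1:
            raise ValueError(f"baseline has no unmasked samples at {f:g} Hz")
        means[j] = mag[sel, j].mean()
        sds[j] = mag[sel, j].std()
        if sds[j] == 0:
            raise ValueError(f"baseline standard deviation is zero at {f:g} Hz")
    return BaselineStats(s.freqs.copy(), means, sds, counts)


def zscore_scalogram(
    s: Scalogram,
    baseline: tuple[float, float],
    mask: EpochMask | None = None,
    use_power: bool = False,
) -> np.ndarray:
    """Baseline-normalized magnitude map: ``z = (|W| - mu_f) / sigma_f``.

    Statistics come only from unmasked, in-cone baseline samples; masked
    and in-cone-of-influence samples are NaN in the returned map.
    """
    stats = compute_baseline_stats(s, baseline, mask, use_power)
    z = (_magnitude(s, use_power) - stats.mean[None, :]) / stats.sd[None, :]
    invalid = ~s.coi_valid()
    if mask is not None:
        invalid |= ~mask.valid[:, None]
    z[invalid] = np.nan
    return z


def band_power(
    values: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float],
    interval: tuple[float, float] | None = None,
) -> float:
    """Mean of *values* over in-band frequencies and an optional interval.

    NaN entries (masked samples) are excluded.  Raises if the selection is
    empty or entirely NaN.
    """
    f_lo, f_hi = band
    fsel = (freqs >= f_lo) & (freqs <= f_hi)
    if not fsel.any():
        raise ValueError(f"band [{f_lo}, {f_hi}] Hz selects no grid frequencies")
    tsel = np.ones(len(times), dtype=bool)
    if interval is not None:
        t0, t1 = interval
        tsel = (times >= t0) & (times < t1)
        if not tsel.any():
            raise ValueError(f"interval [{t0}, {t1}) s selects no samples")
    block = values[np.ix_(tsel, fsel)]
    if np.all(np.isnan(block)):
        raise ValueError("selection contains only masked samples")
    return float(np.nanmean(block))
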