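"""Phase-amplitude coupling: modulation index and comodulograms.

Phase of a slow rhythm and amplitude of a fast rhythm are both read off the
same complex Morlet scalogram: phase as the two-argument arctangent of the
coefficient (quadrant-correct angle), amplitude as its modulus.

Coupling strength is the Tort modulation index: phases are sorted into
``n_bins`` equal bins (18 bins of 20 degrees by default), the mean fast
amplitude per bin is normalized into a distribution ``P``, and

    MI = D_KL(P || Uniform) / log(n_bins) = (log(n_bins) - H(P)) / log(n_bins)

so MI is 0 when amplitude ignores phase and 1 when all amplitude mass
concentrates in a single phase bin.  The comodulogram evaluates MI over a
log-spaced (phase-frequency x amplitude-frequency) grid — 1-32 Hz against
32-512 Hz by default — in sliding windows (4 s, giving at least 4 cycles
at the 1 Hz phase floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import EpochMask, Scalogram, log_grid

__all__ = [
    "ComodulogramParams",
    "Comodulogram",
    "extract_phase",
    "extract_amplitude",
    "modulation_index",
    "comodulogram",
    "surrogate_threshold",
]


def _default_phase_freqs() -> np.ndarray:
    return log_grid(1.0, 32.0, 4)


def _default_amp_freqs() -> np.ndarray:
    return log_grid(32.0, 512.0, 4)


@dataclass(frozen=True)
class ComodulogramParams:
    """Grid and windowing for comodulogram computation.

    Defaults: phase 1-32 Hz and amplitude 32-512 Hz at 4 voices per octave,
    18 phase bins (20 degrees), 4-s windows advancing by 1 s.
    """

    phase_freqs: np.ndarray = field(default_factory=_default_phase_freqs)
    amp_freqs: np.ndarray = field(default_factory=_default_amp_freqs)
    n_phase_bins: int = 18
    window: float = 4.0
    stride: float = 1.0

    def __post_init__(self) -> None:
        pf = np.asarray(self.phase_freqs, dtype=float)
        af = np.asarray(self.amp_freqs, dtype=float)
        if pf.size == 0 or af.size == 0:
            raise ValueError("frequency grids must be non-empty")
        if self.n_phase_bins < 4:
            raise ValueError("n_phase_bins must be >= 4")
        if self.stride <= 0:
            raise ValueError("stride must be positive")
        min_cycles = self.window * pf.min()
        if min_cycles < 4.0 - 1e-9:
            raise ValueError(
                f"window of {self.window} s holds only {min_cycles:.2f} cycles at "
                f"{pf.min():g} Hz; at least 4 cycles of the slowest phase frequency "
                "are required"
            )
        object.__setattr__(self, "phase_freqs", pf)
        object.__setattr__(self, "amp_freqs", af)


@dataclass
class Comodulogram:
    """Modulation-index matrices per sliding window.

    ``mi`` has shape (n_windows, n_phase_freqs, n_amp_freqs); fully masked
    windows are omitted rather than NaN-filled, so ``window_starts`` lists
    the surviving windows.
    """

    mi: np.ndarray
    window_starts: np.ndarray
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    params: ComodulogramParams

    def mean(self) -> np.ndarray:
        """Across-window mean MI matrix (NaN cells ignored)."""
        return np.nanmean(self.mi, axis=0)

    def argmax_cell(self) -> tuple[float, float]:
        """(phase_freq, amp_freq) of the global MI maximum."""
        m = self.mean()
        ip, ia = np.unravel_index(np.nanargmax(m), m.shape)
        return float(self.phase_freqs[ip]), float(self.amp_freqs[ia])


def extract_phase(s: Scalogram, f: float) -> np.ndarray:
    """Instantaneous phase (radians, (-pi, pi]) at grid frequency *f*.

    Two-argument arctangent of the complex coefficient; the printed
    ``arctan(Im/Re)`` shorthand is quadrant-ambiguous.
    """
    j = s.freq_index(f)
    return np.angle(s.coefficients[:, j])


def extract_amplitude(s: Scalogram, f: float) -> np.ndarray:
    """Instantaneous amplitude (modulus of the coefficient) at frequency *f*."""
    j = s.freq_index(f)
    return np.abs(s.coefficients[:, j])


def phase_bin_edges(n_bins: int) -> np.ndarray:
    """Equal phase bins covering (-pi, pi]."""
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def modulation_index(phase: np.ndarray, amp: np.ndarray, n_bins: int = 18) -> float:
    """Tort modulation index of *amp* over binned *phase*.

    NaN pairs (masked samples) are dropped first.  Empty phase bins
    contribute zero mean amplitude and the entropy term handles them via
    ``0*log(0) = 0``, so MI stays defined for short windows at low phase
    frequencies.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have the same length")
    keep = ~(np.isnan(phase) | np.isnan(amp))
    phase, amp = phase[keep], amp[keep]
    if phase.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} unmasked samples, got {phase.size}")
    if np.any(amp < 0):
        raise ValueError("amplitude series must be non-negative")
    if not np.any(amp > 0):
        raise ValueError("amplitude series is identically zero")
    idx = _bin_indices(phase, n_bins)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return _mi_from_bins(sums, counts, n_bins)


def _bin_indices(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Map (-pi, pi] onto bins 0..n_bins-1 (closed right edge folds into the last bin)."""
    idx = np.floor((phase + np.pi) / (2 * np.pi) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _mi_from_bins(sums: np.ndarray, counts: np.ndarray, n_bins: int) -> float:
    means = np.zeros(n_bins)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    p = means / means.sum()
    pos = p > 0
    entropy = -np.sum(p[pos] * np.log(p[pos]))
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


def _grid_columns(s: Scalogram, freqs: np.ndarray) -> list[int]:
    return [s.freq_index(f) for f in freqs]


def comodulogram(
    s: Scalogram,
    params: ComodulogramParams | None = None,
    mask: EpochMask | None = None,
) -> Comodulogram:
    """Sliding-window MI over the (phase x amplitude) frequency grid.

    Every frequency in ``params`` must be present on the scalogram grid.
    Within each window only samples that are unmasked and outside the cone
    of influence of both frequencies enter the MI; a window with no valid
    samples is omitted, and a cell with fewer than ``n_phase_bins`` valid
    samples is NaN.
    """
    if params is None:
        params = ComodulogramParams()
    n = len(s.times)
    fs = s.sample_rate
    win = int(round(params.window * fs))
    step = int(round(params.stride * fs))
    if win > n:
        raise ValueError("recording is shorter than one window")
    pj = _grid_columns(s, params.phase_freqs)
    aj = _grid_columns(s, params.amp_freqs)
    phases = np.angle(s.coefficients[:, pj])
    amps = np.abs(s.coefficients[:, aj])
    coi = s.coi_valid()
    valid = mask.valid.copy() if mask is not None else np.ones(n, dtype=bool)

    mats = []
    starts = []
    for i0 in range(0, n - win + 1, step):
        sl = slice(i0, i0 + win)
        v = valid[sl]
        if not v.any():
            continue
        mat = np.full((len(pj), len(aj)), np.nan)
        ph_win = phases[sl]
        am_win = amps[sl]
        nb = params.n_phase_bins
        for ip, jp in enumerate(pj):
            vp = v & coi[sl, jp]
            idx = _bin_indices(ph_win[:, ip], nb)
            for ia, ja in enumerate(aj):
                vv = vp & coi[sl, ja]
                if int(vv.sum()) < nb:
                    continue
                a = am_win[vv, ia]
                if not np.any(a > 0):
                    continue
                iv = idx[vv]
                mat[ip, ia] = _mi_from_bins(
                    np.bincount(iv, weights=a, minlength=nb),
                    np.bincount(iv, minlength=nb),
                    nb,
                )
        if np.all(np.isnan(mat)):
            continue
        mats.append(mat)
        starts.append(s.times[i0])
    if not mats:
        raise ValueError("no window contained valid samples")
    return Comodulogram(
        np.stack(mats), np.array(starts), params.phase_freqs, params.amp_freqs, params
    )


def surrogate_threshold(
    phase: np.ndarray,
    amp: np.ndarray,
    sample_rate: float,
    n_surrogates: int = 200,
    seed: int | None = None,
    n_bins: int = 18,
    min_shift: float = 1.0,
) -> float:
    """95th-percentile MI under circularly time-shifted amplitude surrogates.

    Each surrogate rolls the amplitude series by a uniform random shift of
    at least ``min_shift`` seconds, destroying phase-amplitude alignment
    while preserving both marginals.
    """
    if n_surrogates < 19:
        raise ValueError("need at least 19 surrogates for a 95th percentile")
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    n = phase.size
    if n < 2 * sample_rate:
        raise ValueError("series must be at least 2 s long for circular shifting")
    rng = np.random.default_rng(seed)
    lo = int(round(min_shift * sample_rate))
    hi = n - lo
    if hi <= lo:
        raise ValueError("series too short for the requested minimum shift")
    mis = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = int(rng.integers(lo, hi))
        mis[k] = modulation_index(phase, np.roll(amp, shift), n_bins)
    return float(np.percentile(mis, 95))
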