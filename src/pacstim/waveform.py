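"""Synthesis of pulse-train stimulation waveforms.

Three families of stimulus are generated, all rendered as constant-current
sample trains (microamperes) on a uniform grid, 10 kHz by default:

* **depacer** — biphasic square pulses whose instantaneous rate is drawn
  per pulse from a Gaussian centred on ``f_H`` ("dithering", so the train
  never settles into a fixed period) and whose signed amplitude follows the
  phase of a slow sinusoid: ``A(t) = A0 * sin(2*pi*f_L*t)`` in the default
  signed mode.  This is a phase-amplitude-coupled (PAC) waveform: the slow
  rhythm's phase modulates the fast pulse train's amplitude.
* **lfs / hfs** — mono-rhythmic controls: constant-amplitude biphasic
  pulses at exactly ``f_L`` (low-frequency stimulation) or ``f_H``
  (high-frequency stimulation), no envelope modulation, no dither.
* **kindling** — monophasic 0.5-ms square pulses at 60 Hz for 2 s, the
  classic train used to evoke afterdischarges in kindled animals.

Dither interpretation
---------------------
The per-pulse instantaneous frequency is drawn from
``Normal(f_H, dither_spread**2)``; the inter-pulse interval is its
reciprocal.  ``dither_spread`` is a *standard deviation* in Hz (the common
report "variance of 10 Hz" carries Hz units, which identifies a spread, not
a squared spread).  Set ``spread_is_variance=True`` on the spec to read the
parameter literally as a variance in Hz^2 instead.  Draws below ``f_H/2``
are rejected and redrawn, keeping intervals within one octave of the mean.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EnvelopeMode",
    "WaveformKind",
    "StimulusSpec",
    "PulseEvent",
    "SampledWaveform",
    "envelope_at",
    "sample_pulse_times",
    "render_biphasic_pulse",
    "render_monophasic_pulse",
    "generate_depacer",
    "generate_monorhythmic",
    "generate_kindling_train",
    "generate",
    "export_waveform",
    "read_waveform",
]

#: give up if this many consecutive dither draws fall below the f_H/2 floor
MAX_CONSECUTIVE_REDRAWS = 1000


class EnvelopeMode(str, enum.Enum):
    """How the slow-rhythm phase maps to pulse amplitude."""

    signed_sine = "signed_sine"        # A0*sin(phase): polarity flips on the negative half-cycle
    rectified_sine = "rectified_sine"  # A0*(1+sin(phase))/2: non-negative envelope
    constant = "constant"              # A0 regardless of phase (no modulation)


class WaveformKind(str, enum.Enum):
    depacer = "depacer"
    lfs = "lfs"
    hfs = "hfs"
    kindling = "kindling"


@dataclass(frozen=True)
class StimulusSpec:
    """Complete parameterization of one stimulus waveform.

    Parameters
    ----------
    f_L : float
        Low-frequency rhythm rate in Hz (phase provider of the PAC envelope).
    f_H : float
        Mean rate of the high-frequency pulse train in Hz.
    dither_spread : float
        Gaussian spread of the per-pulse instantaneous frequency, Hz
        (standard deviation unless ``spread_is_variance``).
    A0 : float
        Peak envelope amplitude, microamperes.
    pulse_width : float
        Total duration of one (bi)phasic pulse, ms.  Must span a whole
        number of samples at ``sample_rate``.
    sample_rate : float
        Samples per second.
    duration : float
        Waveform length, s.  Pulse generation is half-open on
        ``[0, duration)``.
    seed : int
        Seed for the dither RNG; identical spec+seed reproduces the
        waveform byte-for-byte.
    """

    f_L: float = 1.0
    f_H: float = 100.0
    dither_spread: float = 10.0
    A0: float = 40.0
    pulse_width: float = 1.0
    sample_rate: float = 10_000.0
    duration: float = 10.0
    seed: int = 0
    envelope_mode: EnvelopeMode = EnvelopeMode.signed_sine
    waveform_kind: WaveformKind = WaveformKind.depacer
    spread_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.f_L <= 0 or self.f_H <= 0:
            raise ValueError("f_L and f_H must be positive")
        if self.dither_spread < 0:
            raise ValueError("dither_spread must be >= 0")
        if self.A0 < 0:
            raise ValueError("A0 must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        n = self.pulse_width * self.sample_rate / 1000.0
        if n < 1 - 1e-9 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"pulse_width ({self.pulse_width} ms) must span a positive whole "
                f"number of samples at {self.sample_rate} Hz"
            )
        if self.f_H * (self.pulse_width / 1000.0) >= 1.0:
            raise ValueError("pulses overlap at the mean rate: f_H * pulse_width >= 1")
        # coerce string enum inputs (convenient for CLI / config files)
        object.__setattr__(self, "envelope_mode", EnvelopeMode(self.envelope_mode))
        object.__setattr__(self, "waveform_kind", WaveformKind(self.waveform_kind))

    @property
    def pulse_samples(self) -> int:
        """Number of samples in one pulse block."""
        return int(round(self.pulse_width * self.sample_rate / 1000.0))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    @property
    def effective_spread(self) -> float:
        """Dither standard deviation in Hz under the configured reading."""
        if self.spread_is_variance:
            return math.sqrt(self.dither_spread)
        return self.dither_spread


@dataclass(frozen=True)
class PulseEvent:
    """One pulse of the train.

    ``instantaneous_frequency`` is the Gaussian draw that produced the
    inter-pulse interval *following* this onset; ``amplitude`` is the signed
    envelope value at the onset.
    """

    onset_time: float
    instantaneous_frequency: float
    amplitude: float


@dataclass
class SampledWaveform:
    """A uniformly sampled current waveform with pulse annotations."""

    samples: np.ndarray
    sample_rate: float
    pulses: list[PulseEvent]
    spec: StimulusSpec

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def pulse_onsets(self) -> np.ndarray:
        return np.array([p.onset_time for p in self.pulses])

    def pulse_frequencies(self) -> np.ndarray:
        return np.array([p.instantaneous_frequency for p in self.pulses])

    def pulse_amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.pulses])


def envelope_at(phase, A0: float, mode: EnvelopeMode | str):
    """Signed envelope amplitude at a slow-rhythm phase (radians).

    Total function: accepts scalars or arrays, result is in ``[-A0, A0]``.
    """
    mode = EnvelopeMode(mode)
    if mode is EnvelopeMode.signed_sine:
        return A0 * np.sin(phase)
    if mode is EnvelopeMode.rectified_sine:
        return A0 * (1.0 + np.sin(phase)) / 2.0
    return A0 * np.ones_like(np.asarray(phase, dtype=float))


def sample_pulse_times(spec: StimulusSpec, rng: np.random.Generator | None = None) -> list[PulseEvent]:
    """Draw the dithered pulse train for *spec*.

    Sequential draws ``g_i ~ Normal(f_H, sd^2)`` truncated to
    ``g_i >= f_H/2`` (redraw on violation); the inter-pulse interval is
    ``1/g_i`` and onsets are cumulative sums starting at the *first*
    interval (the train does not begin with a pulse at t=0).  Generation is
    half-open on ``[0, duration)``.

    Each event's amplitude is the envelope value at its onset.
    """
    if spec.f_H / 2.0 <= 0:
        raise ValueError("f_H/2 must be positive")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sd = spec.effective_spread
    floor = spec.f_H / 2.0
    events: list[PulseEvent] = []
    t = 0.0
    if sd == 0.0:
        # degenerate case: exactly periodic train at f_H
        k = 1
        while True:
            t = k / spec.f_H
            if t >= spec.duration:
                break
            events.append(PulseEvent(t, spec.f_H, float(envelope_at(2 * np.pi * spec.f_L * t, spec.A0, spec.envelope_mode))))
            k += 1
        return events
    rejects = 0
    while True:
        g = rng.normal(spec.f_H, sd)
        if g < floor:
            rejects += 1
            if rejects > MAX_CONSECUTIVE_REDRAWS:
                raise RuntimeError(
                    f"dither truncation rejected {rejects} consecutive draws; "
                    "spread is pathological relative to f_H"
                )
            continue
        rejects = 0
        t += 1.0 / g
        if t >= spec.duration:
            break
        events.append(PulseEvent(t, float(g), float(envelope_at(2 * np.pi * spec.f_L * t, spec.A0, spec.envelope_mode))))
    return events


def render_biphasic_pulse(amplitude: float, pulse_width: float, sample_rate: float) -> np.ndarray:
    """One charge-balanced biphasic square pulse.

    First half of the block at ``+amplitude``, second half at
    ``-amplitude``; the block length equals ``pulse_width`` ms exactly and
    its samples cancel pairwise (net injected charge is zero).
    """
    n = pulse_width * sample_rate / 1000.0
    n_round = int(round(n))
    if abs(n - n_round) > 1e-9 or n_round < 2:
        raise ValueError("pulse_width must span >= 2 whole samples")
    if n_round % 2 != 0:
        raise ValueError(
            f"pulse spans {n_round} samples; an odd count cannot be charge-balanced"
        )
    half = n_round // 2
    block = np.empty(n_round)
    block[:half] = amplitude
    block[half:] = -amplitude
    return block


def render_monophasic_pulse(amplitude: float, pulse_width: float, sample_rate: float) -> np.ndarray:
    """One monophasic square pulse (kindling convention, not charge-balanced)."""
    n = pulse_width * sample_rate / 1000.0
    n_round = int(round(n))
    if abs(n - n_round) > 1e-9 or n_round < 1:
        raise ValueError("pulse_width must span >= 1 whole sample")
    return np.full(n_round, amplitude)


class PulseOverlapError(ValueError):
    """Two pulses were scheduled onto overlapping sample ranges."""


def _place_pulses(
    n_samples: int,
    sample_rate: float,
    events: list[PulseEvent],
    render,
) -> tuple[np.ndarray, list[PulseEvent]]:
    """Render *events* into a zero waveform; pulses must not overlap.

    A pulse whose block would run past the end of the waveform is dropped
    (with its event), keeping every emitted block intact and balanced.
    """
    samples = np.zeros(n_samples)
    placed: list[PulseEvent] = []
    last_end = -1
    for ev in events:
        start = int(round(ev.onset_time * sample_rate))
        block = render(ev.amplitude)
        if start < last_end:
            raise PulseOverlapError(
                f"pulse at t={ev.onset_time:.6f}s overlaps the preceding pulse"
            )
        if start + len(block) > n_samples:
            continue
        samples[start : start + len(block)] = block
        last_end = start + len(block)
        placed.append(ev)
    return samples, placed


def generate_depacer(spec: StimulusSpec) -> SampledWaveform:
    """Dithered, PAC-enveloped biphasic pulse train.

    Each pulse's signed amplitude is the envelope evaluated at its onset
    time, so a regression of pulse amplitudes onto ``sin(2*pi*f_L*t)``
    recovers ``A0`` exactly up to onset-time quantization.
    """
    if spec.waveform_kind is not WaveformKind.depacer:
        raise ValueError("spec.waveform_kind must be 'depacer'")
    events = sample_pulse_times(spec)
    samples, placed = _place_pulses(
        spec.n_samples,
        spec.sample_rate,
        events,
        lambda a: render_biphasic_pulse(a, spec.pulse_width, spec.sample_rate),
    )
    return SampledWaveform(samples, spec.sample_rate, placed, spec)


def generate_monorhythmic(spec: StimulusSpec) -> SampledWaveform:
    """Mono-rhythmic constant-amplitude control train (lfs or hfs).

    Pulses at exactly ``f_L`` (lfs) or ``f_H`` (hfs), amplitude ``A0``,
    no dither.  Onsets at ``k/f`` for ``k = 0 .. floor(duration*f)-1``
    (train starts at t=0; an onset landing exactly at ``duration`` is
    excluded by the half-open convention).
    """
    if spec.waveform_kind not in (WaveformKind.lfs, WaveformKind.hfs):
        raise ValueError("spec.waveform_kind must be 'lfs' or 'hfs'")
    rate = spec.f_L if spec.waveform_kind is WaveformKind.lfs else spec.f_H
    n_pulses = int(math.floor(spec.duration * rate + 1e-9))
    events = [PulseEvent(k / rate, rate, spec.A0) for k in range(n_pulses)]
    samples, placed = _place_pulses(
        spec.n_samples,
        spec.sample_rate,
        events,
        lambda a: render_biphasic_pulse(a, spec.pulse_width, spec.sample_rate),
    )
    return SampledWaveform(samples, spec.sample_rate, placed, spec)


def generate_kindling_train(
    current: float,
    sample_rate: float = 10_000.0,
    frequency: float = 60.0,
    train_duration: float = 2.0,
    pulse_width: float = 0.5,
) -> SampledWaveform:
    """Monophasic kindling train: 0.5-ms square pulses at 60 Hz for 2 s.

    ``current`` outside the conventional 10-150 uA range triggers a warning
    (not an error) so dose-series sweeps can run freely.
    """
    if not (10.0 <= current <= 150.0):
        warnings.warn(
            f"kindling current {current} uA outside the conventional 10-150 uA range",
            stacklevel=2,
        )
    spec = StimulusSpec(
        f_L=frequency,
        f_H=frequency,
        dither_spread=0.0,
        A0=current,
        pulse_width=pulse_width,
        sample_rate=sample_rate,
        duration=train_duration,
        envelope_mode=EnvelopeMode.constant,
        waveform_kind=WaveformKind.kindling,
    )
    n_pulses = int(math.floor(train_duration * frequency + 1e-9))
    events = [PulseEvent(k / frequency, frequency, current) for k in range(n_pulses)]
    samples, placed = _place_pulses(
        spec.n_samples,
        sample_rate,
        events,
        lambda a: render_monophasic_pulse(a, pulse_width, sample_rate),
    )
    return SampledWaveform(samples, sample_rate, placed, spec)


def generate(spec: StimulusSpec) -> SampledWaveform:
    """Dispatch on ``spec.waveform_kind``."""
    if spec.waveform_kind is WaveformKind.depacer:
        return generate_depacer(spec)
    if spec.waveform_kind in (WaveformKind.lfs, WaveformKind.hfs):
        return generate_monorhythmic(spec)
    return generate_kindling_train(
        spec.A0,
        sample_rate=spec.sample_rate,
        frequency=spec.f_H,
        train_duration=spec.duration,
        pulse_width=spec.pulse_width,
    )


# ---------------------------------------------------------------------------
# plain-text export (stimulator front-ends consume one sample per line)

_HEADER_FIELDS = (
    "f_L",
    "f_H",
    "dither_spread",
    "A0",
    "pulse_width",
    "sample_rate",
    "duration",
    "seed",
)


def export_waveform(w: SampledWaveform, path) -> None:
    """Write *w* as UTF-8 text: '#'-prefixed header, one sample per line.

    The header records every spec field (including the seed) so the file is
    self-describing and the waveform regenerable.  Samples are printed with
    17 significant digits, which round-trips float64 exactly.
    """
    path = Path(path)
    lines = ["# pacstim waveform v1"]
    spec = w.spec
    for name in _HEADER_FIELDS:
        lines.append(f"# {name} = {getattr(spec, name)!r}")
    lines.append(f"# envelope_mode = {spec.envelope_mode.value}")
    lines.append(f"# waveform_kind = {spec.waveform_kind.value}")
    lines.append(f"# spread_is_variance = {spec.spread_is_variance!r}")
    lines.append(f"# n_samples = {len(w.samples)}")
    body = "\n".join(f"{v:.17g}" for v in w.samples)
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8", newline="\n")


def read_waveform(path) -> SampledWaveform:
    """Read a waveform written by :func:`export_waveform`.

    Pulse-event annotations are not stored in the text format; they can be
    regenerated from the embedded spec and seed.
    """
    path = Path(path)
    header: dict[str, str] = {}
    body: list[float] = []
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# pacstim waveform"):
            raise ValueError(f"{path}: not a pacstim waveform file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                header[key.strip()] = value.strip()
            else:
                body.append(float(line))
    kwargs = {name: float(header[name]) for name in _HEADER_FIELDS if name != "seed"}
    spec = StimulusSpec(
        seed=int(header["seed"]),
        envelope_mode=EnvelopeMode(header["envelope_mode"]),
        waveform_kind=WaveformKind(header["waveform_kind"]),
        spread_is_variance=header.get("spread_is_variance", "False") == "True",
        **kwargs,
    )
    samples = np.array(body)
    if "n_samples" in header and int(header["n_samples"]) != len(samples):
        raise ValueError(f"{path}: body has {len(samples)} samples, header says {header['n_samples']}")
    return SampledWaveform(samples, spec.sample_rate, [], spec)
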