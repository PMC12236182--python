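"""Synthetic iEEG with known ground truth.

Every analysis stage in this package is validated against recordings whose
generative parameters are known exactly: a 1/f^alpha background with a
high-frequency roll-off (electrode/tissue low-pass), a delta-dominant
interictal rhythm, sporadic interictal spikes, seizure-like events (SLEs)
whose termination carries delta-HFO phase-amplitude coupling, and a
planted sigmoidal dose-response of the delta rhythm to stimulation
amplitude.

Two session builders mirror the experimental protocols:

* :func:`gen_dose_response_session` — ascending-amplitude 30-s interictal
  probes.  At and above the planted threshold the delta rhythm is
  multiplied by the planted gain for ~1 min after the probe.  Stimulation
  epochs are filled with a saturating artifact so that downstream masking
  is actually exercised.
* :func:`gen_evoked_trial` — a pre-stimulation epoch (scaled stand-in for
  the 15-min protocol; the full length is available via ``full_protocol``)
  extending 6 s past an evoked kindling stimulus, followed either by a
  full SLE (no therapy) or by a suppressed, spike-poor trace (therapy on).
  Stimulation epochs are blanked to zero, emulating the gated
  recording/stimulation switch (traces show gaps while a channel is in
  stimulation mode).

Ground truth (event times, planted threshold/gain, injected coupling
parameters) is returned alongside every recording and is independent of
the seed: changing the seed changes the noise, never the plant.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .fileio import RecordingContainer, empty_annotations
from .waveform import EnvelopeMode  # noqa: F401  (re-exported for config files)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_background",
    "inject_spikes",
    "inject_pac",
    "gen_sle",
    "gen_dose_response_session",
    "gen_evoked_trial",
    "session_to_trials",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters of the synthetic iEEG.

    Amplitudes are microvolts.  The delta rhythm is a sum of three tones
    inside 1-4 Hz with slow amplitude jitter — a stable, delta-dominant
    interictal hippocampal rhythm whose planted suppression is what the
    dose-response assessment must recover.
    """

    sample_rate: float = 10_000.0
    # background
    background_alpha: float = 1.0
    background_rms: float = 30.0
    background_corner: float = 150.0  # Hz; roll-off of the electrode/tissue low-pass
    # interictal delta rhythm
    delta_freqs: tuple[float, ...] = (1.1, 1.7, 2.3, 3.0, 3.8)
    delta_amps: tuple[float, ...] = (36.0, 44.0, 48.0, 40.0, 32.0)
    delta_am_jitter: float = 0.1
    # interictal spikes
    spike_rate: float = 4.0  # events/min
    spike_amplitude: float = 250.0
    # SLE morphology
    sle_duration: float = 37.0
    sle_onset_fraction: float = 0.15
    sle_termination_fraction: float = 0.25
    sle_onset_amplitude: float = 500.0
    sle_body_amplitude: float = 1500.0
    sle_onset_sweep: tuple[float, float] = (25.0, 15.0)
    sle_body_sweep: tuple[float, float] = (8.0, 3.0)
    sle_pac_f_L: float = 1.0
    sle_pac_f_H: float = 100.0
    sle_pac_chi: float = 0.9
    sle_pac_gain: float = 1200.0
    # stimulation dose-response
    threshold: float = 40.0
    delta_gain: float = 0.5
    steepness: float = 1.0  # uA; sigmoid slope of the dose-response
    response_duration: float = 62.0
    pre_s: float = 40.0
    stim_s: float = 30.0
    post_s: float = 60.0
    artifact_amplitude: float = 2000.0
    # evoked-trial protocol
    pre_stim_s: float = 60.0  # scaled stand-in for the 15-min pre-stimulation epoch
    full_pre_stim_s: float = 900.0
    extension_s: float = 6.0
    baseline_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_alpha < 0:
            raise ValueError("background_alpha must be >= 0")
        if not (0.0 <= self.sle_pac_chi <= 1.0):
            raise ValueError("sle_pac_chi must lie in [0, 1]")
        if not (0.0 < self.delta_gain <= 1.0):
            raise ValueError("delta_gain must lie in (0, 1]")
        for name in ("sample_rate", "sle_duration", "pre_s", "stim_s", "post_s", "spike_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for round-trip validation."""

    annotations: pd.DataFrame = field(default_factory=empty_annotations)
    planted_threshold: float | None = None
    planted_gain: float | None = None
    pac: dict | None = None
    spike_times: np.ndarray | None = None
    evoked_time: float | None = None
    sle_interval: tuple[float, float] | None = None


def gen_background(
    n_samples: int,
    sample_rate: float,
    alpha: float = 1.0,
    rms: float = 30.0,
    rng: np.random.Generator | None = None,
    corner: float | None = 150.0,
) -> np.ndarray:
    """Gaussian 1/f^alpha noise by spectral shaping, exact-RMS normalized.

    *corner* adds a fourth-order high-frequency roll-off above the given
    frequency (pass ``None`` for a pure power law).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shape = np.ones_like(f)
    nzf = f > 0
    shape[nzf] = f[nzf] ** (-alpha / 2.0)
    shape[0] = 0.0  # no DC
    if corner is not None:
        shape /= np.sqrt(1.0 + (f / corner) ** 4)
    x = np.fft.irfft(spec * shape, n_samples)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


def _slow_modulation(n: int, sample_rate: float, rng: np.random.Generator, step_s: float = 5.0) -> np.ndarray:
    """Unit-variance smooth noise (linear interpolation of ~0.2 Hz draws)."""
    n_knots = max(3, int(np.ceil(n / sample_rate / step_s)) + 2)
    knots = rng.standard_normal(n_knots)
    t = np.arange(n) / sample_rate
    return np.interp(t, np.linspace(0, n / sample_rate, n_knots), knots)


def _delta_rhythm(n: int, sample_rate: float, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for f, a in zip(config.delta_freqs, config.delta_amps):
        am = 1.0 + config.delta_am_jitter * _slow_modulation(n, sample_rate, rng)
        out += a * np.clip(am, 0.2, None) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _spike_kernel(sample_rate: float) -> np.ndarray:
    """Interictal spike-and-wave transient, unit peak, ~0.3 s."""
    t = np.arange(0, 0.3, 1.0 / sample_rate)
    sharp = np.exp(-0.5 * ((t - 0.03) / 0.008) ** 2)
    wave = -0.5 * np.exp(-0.5 * ((t - 0.13) / 0.045) ** 2)
    return sharp + wave


def inject_spikes(
    trace: np.ndarray,
    sample_rate: float,
    rate_per_min: float,
    amplitude: float,
    rng: np.random.Generator,
    interval: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Add Poisson-timed interictal spikes; returns (new trace, spike times)."""
    x = trace.copy()
    n = x.size
    t0, t1 = interval if interval is not None else (0.0, n / sample_rate)
    count = rng.poisson(rate_per_min * (t1 - t0) / 60.0)
    times = np.sort(rng.uniform(t0, t1, count))
    kernel = _spike_kernel(sample_rate) * amplitude
    for t in times:
        i = int(round(t * sample_rate))
        j = min(n, i + kernel.size)
        x[i:j] += kernel[: j - i]
    return x, times


def inject_pac(
    trace: np.ndarray,
    sample_rate: float,
    interval: tuple[float, float],
    f_L: float = 1.0,
    f_H: float = 100.0,
    chi: float = 0.9,
    gain: float = 1.0,
) -> np.ndarray:
    """Add a phase-amplitude-coupled fast rhythm inside *interval*.

    Within ``[t0, t1)`` the trace gains
    ``gain * (1 + chi*sin(2*pi*f_L*t)) / 2 * sin(2*pi*f_H*t)`` plus a
    visible slow component ``gain/2 * sin(2*pi*f_L*t)``; ``chi`` is the
    modulation depth.  Samples outside the interval are untouched.
    """
    if not (0.0 <= chi <= 1.0):
        raise ValueError("chi must lie in [0, 1]")
    if f_H >= sample_rate / 2.0:
        raise ValueError(f"f_H={f_H} Hz is at or above Nyquist")
    n = trace.size
    t0, t1 = interval
    if t0 < 0 or t1 > n / sample_rate + 1e-9 or t1 <= t0:
        raise ValueError("interval must lie within the trace")
    x = trace.copy()
    i0, i1 = int(round(t0 * sample_rate)), min(n, int(round(t1 * sample_rate)))
    t = np.arange(i0, i1) / sample_rate
    slow = np.sin(2 * np.pi * f_L * t)
    x[i0:i1] += gain * (1.0 + chi * slow) / 2.0 * np.sin(2 * np.pi * f_H * t) + 0.5 * gain * slow
    return x


def gen_sle(
    config: SimulationConfig,
    onset: float,
    sample_rate: float | None = None,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """One seizure-like event as an additive segment starting at *onset*.

    Three phases: low-voltage fast onset (frequency sweep down from ~25 Hz
    with an amplitude ramp), a high-amplitude 8->3 Hz body with a sharp
    population-spike transient each cycle, and a termination window (the
    final ``sle_termination_fraction`` of the event) carrying delta-HFO
    phase-amplitude coupling.  Returns the segment (time axis local to the
    event) and an info dict with exact phase boundaries in absolute time.
    """
    fs = sample_rate if sample_rate is not None else config.sample_rate
    dur = duration if duration is not None else config.sle_duration
    if dur <= 0:
        raise ValueError("SLE duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = int(round(dur * fs))
    t = np.arange(m) / fs
    seg = np.zeros(m)
    t_on = config.sle_onset_fraction * dur
    t_term = (1.0 - config.sle_termination_fraction) * dur

    # onset: low-voltage fast activity, ramping up
    sel = t < t_on
    f0, f1 = config.sle_onset_sweep
    freq = f0 + (f1 - f0) * t[sel] / max(t_on, 1e-9)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    ramp = 0.5 + 0.5 * t[sel] / max(t_on, 1e-9)
    seg[sel] += config.sle_onset_amplitude * ramp * np.sin(phase)

    # body: high-amplitude slow sweep with a sharp transient each cycle
    sel = (t >= t_on) & (t < t_term)
    tb = t[sel] - t_on
    f0, f1 = config.sle_body_sweep
    span = max(t_term - t_on, 1e-9)
    freq = f0 + (f1 - f0) * tb / span
    phase = 2 * np.pi * np.cumsum(freq) / fs
    body = np.tanh(2.5 * np.sin(phase)) / np.tanh(2.5)
    # population spikes at each cycle peak (phase crossing of pi/2)
    spikes = np.exp(-0.5 * ((np.mod(phase - np.pi / 2, 2 * np.pi) - np.pi) / 0.12) ** 2)
    seg[sel] += config.sle_body_amplitude * (body + 1.5 * spikes)

    # termination: delta-HFO PAC
    seg = inject_pac(
        seg,
        fs,
        (t_term, dur),
        f_L=config.sle_pac_f_L,
        f_H=config.sle_pac_f_H,
        chi=config.sle_pac_chi,
        gain=config.sle_pac_gain,
    )
    info = {
        "onset": onset,
        "offset": onset + dur,
        "body_start": onset + t_on,
        "termination_start": onset + t_term,
        "pac": {
            "f_L": config.sle_pac_f_L,
            "f_H": config.sle_pac_f_H,
            "chi": config.sle_pac_chi,
        },
    }
    return seg, info


def _dose_gain_factor(amplitude: float, config: SimulationConfig) -> float:
    """Multiplier applied to the delta rhythm after a probe of *amplitude*.

    Sigmoid centred half an amplitude step (5 uA) below the planted
    threshold, so the planted threshold is the smallest 10-uA step showing
    the full planted gain and one step below shows essentially none.
    """
    x = (amplitude - (config.threshold - 5.0)) / config.steepness
    return 1.0 - (1.0 - config.delta_gain) / (1.0 + np.exp(-x))


def _smooth_gate(n: int, sample_rate: float, start: float, end: float, ramp: float = 1.0) -> np.ndarray:
    """0->1->0 envelope over [start, end] with cosine ramps."""
    t = np.arange(n) / sample_rate
    g = np.zeros(n)
    g[(t >= start + ramp) & (t < end - ramp)] = 1.0
    up = (t >= start) & (t < start + ramp)
    g[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - start) / ramp))
    dn = (t >= end - ramp) & (t < end)
    g[dn] = 0.5 * (1 + np.cos(np.pi * (t[dn] - (end - ramp)) / ramp))
    return g


def gen_dose_response_session(
    config: SimulationConfig,
    amplitudes=None,
    seed: int | None = None,
    sample_rate: float | None = None,
) -> tuple[RecordingContainer, GroundTruth]:
    """Ascending-amplitude interictal probe session with a planted threshold.

    Each probe trial is ``pre_s`` baseline + ``stim_s`` stimulation +
    ``post_s`` follow-up.  Probes at or above the planted threshold
    multiply the delta rhythm by the planted gain for
    ``response_duration`` s after stimulation offset.  Stimulation epochs
    are overwritten with a saturating square artifact and annotated
    ``stim`` with the probe amplitude in the payload.
    """
    fs = sample_rate if sample_rate is not None else config.sample_rate
    if amplitudes is None:
        amplitudes = np.arange(10.0, 90.0, 10.0)
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < 2 or np.any(np.diff(amplitudes) <= 0):
        raise ValueError("amplitudes must be >= 2 strictly increasing values")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trial_len = config.pre_s + config.stim_s + config.post_s
    total = trial_len * amplitudes.size
    n = int(round(total * fs))

    bg = gen_background(
        n, fs, config.background_alpha, config.background_rms, rng, config.background_corner
    )
    delta = _delta_rhythm(n, fs, config, rng)
    gate = np.zeros(n)
    rows = []
    for k, amp in enumerate(amplitudes):
        t0 = k * trial_len
        stim_start = t0 + config.pre_s
        stim_end = stim_start + config.stim_s
        depth = 1.0 - _dose_gain_factor(amp, config)
        gate += depth * _smooth_gate(
            n, fs, stim_end, min(stim_end + config.response_duration, total)
        )
        rows.append({"label": "stim", "start": stim_start, "end": stim_end, "payload": {"amplitude": float(amp)}})
    x = bg + delta * (1.0 - np.clip(gate, 0.0, 1.0))
    x, spike_times = inject_spikes(x, fs, config.spike_rate, config.spike_amplitude, rng)

    # saturating stimulation artifact: amplifier rails flipping with the
    # stimulus envelope at f_L, overwriting the gated-out samples
    t = np.arange(n) / fs
    for row in rows:
        i0, i1 = int(round(row["start"] * fs)), int(round(row["end"] * fs))
        x[i0:i1] = config.artifact_amplitude * np.sign(
            np.sin(2 * np.pi * config.sle_pac_f_L * t[i0:i1]) + 1e-12
        )

    annotations = pd.DataFrame(rows, columns=["label", "start", "end", "payload"])
    lag = int(round(0.005 * fs))
    rec = RecordingContainer(
        channels={"hippocampus": x, "thalamus": 0.6 * np.roll(x, lag)},
        sample_rate=fs,
        annotations=annotations,
        metadata={"seed": int(config.seed if seed is None else seed), "config": asdict(config), "kind": "dose_response"},
    )
    truth = GroundTruth(
        annotations=annotations.copy(),
        planted_threshold=config.threshold,
        planted_gain=config.delta_gain,
        spike_times=spike_times,
    )
    return rec, truth


def session_to_trials(rec: RecordingContainer, config: SimulationConfig | None = None):
    """Cut a dose-response session into :class:`~pacstim.biomarker.ProbeTrial`.

    Each ``stim`` annotation yields one trial: the pre-interval spans from
    the previous trial boundary to stimulation onset and the post-interval
    starts 1 s after offset (guard against residual artifact) and runs for
    60 s or to the segment end.
    """
    from .biomarker import ProbeTrial

    if config is None:
        cfg_dict = rec.metadata.get("config", {})
        pre_s = float(cfg_dict.get("pre_s", 40.0))
        post_s = float(cfg_dict.get("post_s", 60.0))
    else:
        pre_s, post_s = config.pre_s, config.post_s
    x = rec.channel("hippocampus")
    fs = rec.sample_rate
    trials = []
    stim_rows = rec.annotations[rec.annotations["label"] == "stim"]
    for _, row in stim_rows.iterrows():
        seg_start = row["start"] - pre_s
        seg_end = min(rec.duration, row["end"] + post_s)
        i0, i1 = int(round(seg_start * fs)), int(round(seg_end * fs))
        trials.append(
            ProbeTrial(
                signal=x[i0:i1],
                sample_rate=fs,
                stim_start=row["start"] - seg_start,
                stim_end=row["end"] - seg_start,
                amplitude=float(row["payload"]["amplitude"]),
                pre_interval=(0.0, row["start"] - seg_start),
                post_interval=(
                    row["end"] - seg_start + 1.0,
                    min(seg_end - seg_start, row["end"] - seg_start + 61.0),
                ),
            )
        )
    return trials


def gen_evoked_trial(
    config: SimulationConfig,
    with_depacer: bool,
    seed: int | None = None,
    sample_rate: float | None = None,
    full_protocol: bool = False,
) -> tuple[RecordingContainer, GroundTruth]:
    """One evoked-seizure trial, with or without therapeutic stimulation.

    Timeline: ``baseline_s`` of untouched recording; if *with_depacer*, a
    therapeutic stimulation epoch running through the evoked kindling
    stimulus and ``extension_s`` beyond it; the 2-s kindling stimulus; then
    either a full SLE (*with_depacer=False*) or a suppressed trace with a
    five-fold reduced spike rate (*with_depacer=True*); then a 30-s tail.
    Stimulation epochs are blanked (gated recording) and annotated, so the
    emitted mask flags them invalid.
    """
    fs = sample_rate if sample_rate is not None else config.sample_rate
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pre_stim = config.full_pre_stim_s if full_protocol else config.pre_stim_s
    t_evoke = config.baseline_s + pre_stim
    kindle_end = t_evoke + 2.0
    total = kindle_end + config.sle_duration + 30.0
    n = int(round(total * fs))

    bg = gen_background(
        n, fs, config.background_alpha, config.background_rms, rng, config.background_corner
    )
    x = bg + _delta_rhythm(n, fs, config, rng)
    rate = config.spike_rate * (0.2 if with_depacer else 1.0)
    x, spike_times = inject_spikes(x, fs, rate, config.spike_amplitude, rng)

    rows = [{"label": "baseline", "start": 0.0, "end": config.baseline_s, "payload": {}}]
    sle_interval = None
    if not with_depacer:
        seg, info = gen_sle(config, kindle_end, sample_rate=fs, rng=rng)
        i0 = int(round(kindle_end * fs))
        x[i0 : i0 + seg.size] += seg
        sle_interval = (info["onset"], info["offset"])
        rows.append({"label": "sle", "start": info["onset"], "end": info["offset"], "payload": info["pac"]})

    stim_epochs = [(t_evoke, kindle_end)]
    rows.append({"label": "kindling", "start": t_evoke, "end": kindle_end, "payload": {}})
    if with_depacer:
        dep = (config.baseline_s, kindle_end + config.extension_s - 2.0)
        stim_epochs.append(dep)
        rows.append({"label": "stim", "start": dep[0], "end": dep[1], "payload": {"kind": "depacer"}})
    # gated recording: channels read zero while switched to stimulation mode
    for s0, s1 in stim_epochs:
        x[int(round(s0 * fs)) : int(round(s1 * fs))] = 0.0

    annotations = pd.DataFrame(rows, columns=["label", "start", "end", "payload"])
    lag = int(round(0.005 * fs))
    rec = RecordingContainer(
        channels={"hippocampus": x, "thalamus": 0.6 * np.roll(x, lag)},
        sample_rate=fs,
        annotations=annotations,
        metadata={
            "seed": int(config.seed if seed is None else seed),
            "config": asdict(config),
            "kind": "evoked",
            "with_depacer": with_depacer,
            "evoked_time": t_evoke,
        },
    )
    truth = GroundTruth(
        annotations=annotations.copy(),
        spike_times=spike_times,
        evoked_time=t_evoke,
        sle_interval=sle_interval,
        pac=None if with_depacer else {"f_L": config.sle_pac_f_L, "f_H": config.sle_pac_f_H, "chi": config.sle_pac_chi},
    )
    return rec, truth
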