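# pacstim

Synthesis and analysis tools for **phase-amplitude-coupled deep-brain
stimulation** in epilepsy research.

Mono-rhythmic thalamic stimulation (fixed 1 Hz or ~100 Hz pulse trains) has
limited efficacy against seizures. A brain-mimetic alternative copies a
feature observed at seizure *termination*: the amplitude of high-frequency
oscillations (~100 Hz) is modulated by the phase of a delta rhythm (~1 Hz).
`pacstim` builds such stimuli and the intracranial-EEG analysis stack needed
to evaluate them, for electrophysiologists working with kindled rodent
models or similar preparations.

## What it implements

**Waveform synthesis** (`pacstim.waveform`). The DEPACER stimulus: biphasic
square pulses (1 ms, charge-balanced) whose instantaneous rate is drawn per
pulse from N(f_H, sigma^2) with f_H = 100 Hz and sigma = 10 Hz (dithering,
to avoid entrainment to a fixed period), and whose signed amplitude follows
the slow rhythm's phase,

    A(t) = A0 * sin(2*pi*f_L*t),      f_L = 1 Hz.

Mono-rhythmic controls (1 Hz LFS / 100 Hz HFS, constant amplitude) and the
classic kindling train (monophasic 0.5-ms pulses, 60 Hz for 2 s) are
generated with the same machinery, and export to stimulator-ready text at
10 kHz.

**Spectral analysis** (`pacstim.spectral`). Complex Morlet continuous
wavelet transform, Psi(t) = (pi*fb)^(-1/2) exp(2*pi*i*fc*t) exp(-t^2/fb)
with fc = 0.8125 Hz, fb = 5, on a log frequency grid; per-frequency
z-scoring of |W(t, f)| against a pre-stimulation baseline, with stimulation
epochs masked out as artifact.

**Phase-amplitude coupling** (`pacstim.pac`). Phase phi(t, f_L) and
amplitude A(t, f_H) read off the same scalogram; coupling strength as the
Tort modulation index — normalized Kullback-Leibler distance of the
phase-binned (18 x 20 degrees) mean-amplitude distribution from uniform —
over a (1-32 Hz) x (32-512 Hz) log grid in 4-s sliding windows, with
circular-shift surrogate significance thresholds.

**Dose-response biomarker** (`pacstim.biomarker`). The interictal
assessment that picks the effective stimulation amplitude: 30-s probes at
ascending 10-uA steps; the post-probe delta-band (1-4 Hz) z summary flags
suppression (z <= -1.96 by default); the threshold is the smallest
suppressing amplitude. Plus the two-sided Wilcoxon signed-rank comparison
(mean +/- SEM reporting) and a line-length afterdischarge-duration
detector.

**Synthetic iEEG** (`pacstim.simulate`). A ground-truth generator — 1/f
background, delta-dominant interictal rhythm, interictal spikes,
seizure-like events with termination-phase delta-HFO coupling, and a
planted sigmoidal dose-response — so every stage is testable without animal
data.

## Worked example

```python
import numpy as np
from pacstim import (StimulusSpec, generate_depacer, SimulationConfig,
                     gen_dose_response_session, session_to_trials, run_dose_series)

spec = StimulusSpec(f_L=1.0, f_H=100.0, dither_spread=10.0, A0=40.0,
                    duration=10.0, seed=1)
w = generate_depacer(spec)
f = w.pulse_frequencies()
print(f"{len(w.pulses)} pulses, mean rate {f.mean():.1f} Hz "
      f"(spread {f.std():.1f} Hz), peak amplitude {abs(w.pulse_amplitudes()).max():.1f} uA")

cfg = SimulationConfig()
rec, truth = gen_dose_response_session(cfg, seed=7, sample_rate=256.0)
res = run_dose_series(session_to_trials(rec))
for a, z in zip(res.amplitudes, res.delta_z):
    print(f"  {a:4.0f} uA   delta z = {z:+.2f}")
print(f"detected threshold: {res.threshold:.0f} uA (planted: {truth.planted_threshold:.0f} uA)")
```

prints

```
984 pulses, mean rate 99.5 Hz (spread 9.9 Hz), peak amplitude 40.0 uA
    10 uA   delta z = -0.14
    20 uA   delta z = -0.12
    30 uA   delta z = +0.17
    40 uA   delta z = -2.23
    50 uA   delta z = -2.37
    60 uA   delta z = -1.94
    70 uA   delta z = -1.94
    80 uA   delta z = -2.41
detected threshold: 40 uA (planted: 40 uA)
```

The 10-s train carries ~10 pulses per slow cycle; the per-pulse rate
statistics recover the configured dither. In the simulated ascending probe
session, sub-threshold probes leave delta power unchanged (z near 0) while
probes at and above the planted 40-uA threshold suppress it by more than
two baseline standard deviations, and the detector reports the first such
amplitude.

The same operations are available from the shell:

```sh
pacstim generate --kind depacer --fl 1 --fh 100 --a0 40 --duration 10 --seed 1 -o wave.txt
pacstim simulate dose-response --seed 7 --rate 256 -o session.h5
pacstim dose-response session.h5 -o dose.csv
pacstim comodulogram session.h5 --window 4 --stride 1 -o comod.csv --plot comod.png
```

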