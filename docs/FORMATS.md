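# File formats

All text files are UTF-8 with LF line endings and `#`-prefixed headers.
Times are seconds (float), intervals half-open [start, end).

## Waveform text (`.txt`)

Stimulator-ready sample train, one current value (uA) per line, preceded
by a self-describing header. Written by `pacstim generate` /
`pacstim.waveform.export_waveform`; read by `read_waveform`.

```
# pacstim waveform v1
# f_L = 1.0
# f_H = 100.0
# dither_spread = 10.0
# A0 = 40.0
# pulse_width = 1.0
# sample_rate = 10000.0
# duration = 10.0
# seed = 1
# envelope_mode = signed_sine
# waveform_kind = depacer
# spread_is_variance = False
# n_samples = 100000
0
0
5.1234567890123456
...
```

Samples are printed with 17 significant digits (exact float64 round trip);
export -> import -> export reproduces a byte-identical body. Pulse-event
annotations are not stored; they are regenerable from the embedded spec
and seed.

## Recording container

Multi-channel recording (uV) with sample rate, annotation table and
metadata. Two dialects, auto-detected by extension.

### Text dialect (`.csv`, `.tsv`, `.txt`)

```
# pacstim recording v1
# sample_rate = 256.0
# channels = hippocampus,thalamus
# meta = {"seed": 7, "config": {...}}
# annotation = {"label": "stim", "start": 40.0, "end": 70.0, "payload": {"amplitude": 10.0}}
...
-12.345678901234567,3.1415926535897931
...
```

One delimited row per sample (comma for `.csv`, tab otherwise), one column
per channel in header order. One JSON object per annotation line. Values
round-trip float64 exactly.

### Binary columnar dialect (`.h5`, `.hdf5`)

HDF5 file with root attributes `format` (`pacstim recording v1`),
`sample_rate`, `meta` (JSON string), `annotations` (JSON array string) and
one float64 dataset per channel under `/channels/<name>`. Bit-exact round
trip.

Errors are distinct: `UnknownFormatError` (extension),
`RecordingFormatError` (malformed header/body),
`ChannelLengthMismatchError` (unequal channel lengths).

## Columnar result tables (CSV)

* `pacstim comodulogram`: columns `window_start, f_phase, f_amp, mi`
  (one row per window and grid cell; NaN for cells with too few valid
  samples).
* `pacstim dose-response`: columns `amplitude_uA, delta_z` (one row per
  probe; the detected threshold is printed to stdout).

## Acceptance output (`results/acceptance.json`)

JSON object mapping target ids to `{"value": <number>, "n": <size>}`,
written by `scripts/acceptance.py`.
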