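# Methods

## Stimulus model

The DEPACER waveform is a point-process pulse train with a deterministic
envelope. Pulse times are generated sequentially: the instantaneous
frequency of pulse *i* is drawn g_i ~ N(f_H, sigma^2), the following
inter-pulse interval is 1/g_i, and onsets accumulate from the first
interval (the train does not begin with a pulse at t = 0). Generation is
half-open on [0, duration). Draws below f_H/2 are rejected and redrawn;
this keeps intervals within one octave of the mean and removes essentially
no probability mass at the default sigma = 10 Hz (the floor sits five
standard deviations below the mean). Whether the original in vivo
generator truncated or redrew non-physical draws is not observable from
the waveform statistics at this spread; redrawing was chosen because it
leaves the distribution of accepted draws exactly truncated-normal.

The dither parameter is quoted in the field as a "variance of 10 Hz". The
Hz unit identifies a spread, so `dither_spread` is interpreted as a
standard deviation; `spread_is_variance=True` gives the literal reading
(sigma = sqrt(10) Hz).

Each pulse is a charge-balanced biphasic square: positive phase first,
equal halves, zero inter-phase gap, total width 1 ms (10 samples at the
10 kHz default). The signed pulse amplitude is the envelope evaluated at
the onset, A0*sin(2*pi*f_L*t) in the default `signed_sine` mode — negative
envelope values flip pulse polarity, which reproduces the both-polarity
swing of the published waveform. `rectified_sine` (non-negative envelope)
and `constant` (no modulation) are alternatives; `constant` also makes the
degenerate case dither = 0 coincide with the HFS control up to a
one-period offset (mono-rhythmic trains start at t = 0 and contain
floor(duration*f) pulses; dithered trains start at the first drawn
interval).

Mono-rhythmic controls are biphasic like the DEPACER stimulus (the
comparison is meant to isolate the rate/envelope structure, not the pulse
shape); the kindling train is monophasic per the standard protocol. Pulses
whose block would cross the end of the waveform are dropped whole, so
every emitted waveform sums exactly to zero; overlapping pulse schedules
raise rather than truncate silently.

## Wavelet analysis

The complex Morlet mother wavelet

    Psi(t) = (pi*fb)^(-1/2) * exp(2*pi*i*fc*t) * exp(-t^2/fb)

is used with fc = 0.8125 Hz and fb = 5, a combination established for EEG.
(Published statements of this formula sometimes write the Gaussian as
exp(-x^2/fb); t is intended.) fb is treated as the dimensionless Gaussian
width appearing in the formula. An analysis frequency f is reached with
scale a = fc/f. The transform is computed in the frequency domain: the
wavelet's unit-peak Gaussian response 2*exp(-pi^2*fb*(a*nu - fc)^2)
multiplies the FFT of the reflection-padded signal. This normalization is
L1 in time and doubled as for an analytic signal, so a tone A*cos(2*pi*f*t)
gives |W| ~= A at its own frequency for every f — a prerequisite for
comparing amplitudes across frequencies in the coupling analysis. Samples
within 3 scaled Gaussian standard deviations (3*a*sqrt(fb/2)) of either
edge are inside the cone of influence and excluded from all statistics.

z-scoring standardizes |W(t, f)| per frequency by the mean and standard
deviation over a pre-stimulation baseline, using only samples that are
unmasked and outside the cone of influence. Amplitude |W| rather than
power |W|^2 is standardized; the two are monotone-equivalent for
sign-of-change claims and a `use_power` flag provides the alternative.
Masked samples propagate as NaN and are excluded from every downstream
mean. A zero baseline standard deviation raises an error naming the
frequency.

## Phase-amplitude coupling

Phase and amplitude both come from the same Morlet scalogram (not from
band-pass + Hilbert): phase as the two-argument arctangent of the complex
coefficient — the printed arctan(Im/Re) shorthand is quadrant-ambiguous —
and amplitude as its modulus. Under this convention the phase of a pure
cosine is 0 at its maxima; a sine reads -pi/2 at its zero upcross.

Coupling strength is the Tort modulation index with n = 18 bins of 20
degrees: P_j is the mean amplitude in phase bin j normalized across bins,
and MI = (log n - H(P)) / log n, which is 0 for phase-indifferent
amplitude and 1 for single-bin concentration. Empty bins contribute zero
mean amplitude and are handled by 0*log 0 = 0, keeping short windows at
low phase frequencies well-defined. The comodulogram evaluates MI over
log-spaced grids, 1-32 Hz (phase) by 32-512 Hz (amplitude) at 4 voices per
octave (21 x 17 cells; the published grids state the ranges and log
spacing but not the density), in 4-s windows — at least 4 cycles of the
1 Hz phase floor — advancing by a configurable 1-s stride. Fully masked
windows are omitted from the output rather than NaN-filled; per-window
matrices are returned with a mean-across-windows reducer, since pooling
behavior is a display choice. Significance floors use circularly
time-shifted amplitude surrogates (shift >= 1 s), which preserve both
marginals while destroying alignment.

## Dose-response biomarker

Each interictal probe trial is z-scored against its own pre-probe baseline
(>= 30 s of unmasked data required), with the stimulation epoch masked.
The mask guard defaults to three wavelet time constants at the lowest band
frequency (~3.9 s at 1 Hz) rather than a fixed 1 s: a saturating artifact
leaks into wavelet coefficients that far outside the epoch, and a narrower
guard measurably biases the delta summary toward zero. The post-probe
summary interval still begins 1 s after stimulation offset; samples inside
the guard are simply excluded from it. The delta band is 1-4 Hz (standard
EEG convention; the band is configurable). The suppression criterion
z <= -1.96 is one defensible operationalization of "sufficient to induce
changes" — the published assessment is qualitative per animal — and is
configurable; threshold detection itself is deterministic given the
recordings.

The Wilcoxon signed-rank comparison uses the exact null distribution for
up to 25 nonzero differences without rank ties, and the tie-corrected
normal approximation otherwise (scipy's implementation); mean +/- SEM per
group accompanies the p-value. The afterdischarge-duration detector is
repository-defined scaffolding, not a published method: line length (mean
absolute first difference) in 1-s windows, hop 0.25 s, against k = 3 times
the median baseline line length; the reported duration spans the
supra-threshold run itself (gaps up to 1 s bridged), so it is insensitive
to the stimulus-to-onset latency, and being baseline-relative it is
invariant to recording gain.

## Synthetic iEEG

The simulator emulates the signal features the analyses target, not
hippocampal biophysics. Background is Gaussian 1/f^alpha noise (alpha = 1,
RMS 30 uV) with a fourth-order roll-off above 150 Hz standing in for the
electrode/amplifier low-pass. The interictal delta rhythm is a sum of five
tones spanning 1-4 Hz (1.1-3.8 Hz, 32-48 uV) with ~10% slow amplitude
jitter: a delta-dominant, quasi-stable rhythm, chosen so that a planted
amplitude change is expressed across the whole analysis band. Interictal
spikes are spike-and-wave transients at 4/min, 250 uV.

Seizure-like events have three phases: a low-voltage-fast onset (25->15 Hz,
ramping from half amplitude), a body sweeping 8->3 Hz at 1.5 mV with a
sharp population-spike transient each cycle, and a termination window —
the final 25% of the event, the published observation being only that
coupling rises "at termination" — carrying injected delta-HFO coupling
(1 Hz phase, 100 Hz amplitude, modulation depth 0.9).

Dose-response sessions concatenate probe trials of 40 s baseline + 30 s
stimulation + 60 s follow-up (the 40-s baseline keeps >= 30 s of usable
data after the mask guard). The planted response multiplies the delta
rhythm by the planted gain (0.5) for ~60 s after probes at or above the
planted 40-uA threshold, via a sigmoid in amplitude centred half a 10-uA
step below threshold so the threshold is the smallest step expressing the
full effect. Stimulation epochs are overwritten with +/-2 mV rails
flipping at the stimulus envelope frequency (1 Hz) — the dominant artifact
of an enveloped pulse train at recording bandwidth — which both exercises
the masking path and makes an unmasked analysis fail loudly.

Evoked trials blank stimulation epochs to zero instead, emulating the
gated recording/stimulation switch of the acquisition chain. The
therapeutic epoch runs from the end of the 30-s baseline to 6 s past the
evoked kindling stimulus. With therapy on, no SLE is added and the spike
rate drops five-fold; with therapy off, a full SLE of the programmed
duration (37 s) follows the 2-s kindling stimulus.

Ground truth (annotations, planted threshold and gain, coupling
parameters) depends only on the configuration, never on the seed.

### What the simulator does not capture

Real iEEG has non-Gaussian, non-stationary background, state transitions,
movement and chewing artifacts, electrode drift, and inter-animal
variability in rhythm structure and artifact morphology. Passing the
round-trip tests therefore shows that the analysis stack correctly
recovers effects of the modeled kind at realistic amplitudes and noise
levels — not that detection thresholds or error rates transfer
quantitatively to animal recordings.

## Problem sizes and numerical choices

Analyses are exact at any sample rate; the test and acceptance runs use
decimated rates chosen per task — 256 Hz for delta-band dose-response
work, 1-2 kHz where 100-512 Hz content matters, 10 kHz for waveform
synthesis and export — and a 60-s stand-in for the 15-min pre-stimulation
epoch (`full_protocol=True` restores it). Dose-response recovery is
assessed over 20 seeded sessions. Intervals are half-open [start, end) in
seconds, sample indices 0-based, throughout. Charge balance is asserted
with compensated summation, since floating partial sums of k*a are not
exactly representable even when the sample multiset cancels. Waveform and
text-recording bodies print 17 significant digits, which round-trips
float64 exactly.
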