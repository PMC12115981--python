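# Methods

## Coded excitation and pulse compression

The excitation codes are binary Golay complementary pairs generated by
the append recursion A′ = A‖B, B′ = A‖(−B) from A = B = (1); every
iterate satisfies the complementarity identity exactly, so the sum of
the two matched-filter outputs is 2N·δ at integer-chip lags with no
sidelobes. Code arithmetic is exact-integer end to end; nothing in the
codes module touches floating point.

Two modulation schemes map chips to drive waveforms. The wide-pulse
scheme holds each chip at ±amplitude for one chip period T (binary
phase keying of a rectangular pulse). The square-carrier scheme
multiplies that chip signal by a ±1 square wave at the carrier
frequency, chip boundaries aligned to carrier zero crossings, each
chip an integer number of cycles starting with the positive half. The
defaults are a 75 kHz carrier (the transducer rating), one cycle per
chip, and 4.8 MHz sampling (64 samples per cycle). Waveforms are
always constructed from the code sequences, never from closed-form
piecewise expressions.

Decoding convolves each received trace with the time-reversed replica
of its transmitted waveform (scipy's convolution, direct for short
inputs so small cases are exact, FFT for long ones) and sums the two
channel outputs. Correlation outputs are divided by the number of
samples per chip so the main lobe reads in code units — 16 for the
length-8 pair — independent of sampling rate. The two shots are
assumed to see the same time-invariant channel; no inter-shot drift
correction is applied. Peak ties break toward the earliest lag.

Peak read-out: for carrier-modulated traces the imaging feature is the
maximum of the analytic-signal envelope (Hilbert magnitude, computed
on a fast-FFT-length padding), which is insensitive to carrier phase;
for baseband wide pulses the raw trace is its own envelope and is used
directly (the Hilbert magnitude of a near-delta has broad 1/t tails
that would corrupt width measurements). `CompressionResult.peak_value`
always reports the raw trace maximum; the envelope feature is what the
scan pipeline images.

## The synthetic channel

Each scan point is an independent vertical ray; the channel is linear
and time-invariant per point. The received signal is

excitation → transmit resonator → delay (two air gaps at 343 m/s plus
the local wood thickness at 1500 m/s) → amplitude gain → receive
resonator → additive white Gaussian sensor noise → DC block → gain →
band-pass.

The amplitude gain is the product of the pressure transmission factors
t = 2Z₂/(Z₂+Z₁) at the entry (air→wood) and exit (wood→air) faces
evaluated with the local impedance, power-law attenuation
α(f) = α₀·(f/75 kHz)^p over the local thickness plus the fixed air
paths, and any knot scattering loss. The identity t = 1 + r holds to
machine precision by construction.

Transducers are two-pole resonant filters (scipy peaking biquads) with
center frequency 75 kHz and Q = 10; the impulse response rings down
with envelope exp(−π f₀ t / Q). The receiver band-pass is designed to
the printed hardware spec — 75 kHz center, 14 kHz −3 dB width — as a
peaking biquad (cascaded sections use a Lorentzian-corrected
per-section width so the composite −3 dB width is preserved). The
hardware's quoted quality factor is inconsistent with its own
center/bandwidth figures, so the bandwidth specification governs. The
DC block is a first-order 1 kHz high-pass.

### Parameters and defaults

| parameter | default | why |
|---|---|---|
| Z_air | 400 Rayls | standard for air |
| Z_wood | 1.6 MRayls | standard for softwood |
| air speed | 343 m/s | room temperature |
| wood speed | 1500 m/s | softwood across grain; sets only the delay |
| wood attenuation α₀ | 500 dB/m at 75 kHz, exponent 1 | calibrated so the reference pit's 4 mm thickness reduction produces the ~+2 dB pit/sound peak contrast observed on real pine (0.85 V vs 0.65 V); a 1 cm board then costs 5 dB |
| air attenuation | 2 dB/m at 75 kHz | atmospheric absorption at this frequency |
| air gap | 10 cm per side | the physical rig geometry |
| knot model | impedance ×2 plus 6 dB scattering loss | the impedance term alone (−6 dB through both faces) understates the observed knot contrast; the scattering term stands in for waveform distortion by irregular grain |
| pit model | local thickness fraction 0.6 | a shallow surface cavity |
| transducer Q | 10 | narrowband air-coupled piezo |
| noise | white Gaussian, sensor-referred, before the receiver filter | seeded per scan point (base seed + row-major index, one stream per shot) so the grid is traversal-order independent |

Noise level is usually specified as a pre-filter SNR: the ratio of the
noiseless sensor-stage peak amplitude at a sound reference point to
the noise sigma. Note that a per-sample sigma at a fixed SNR injects
more in-band noise at lower sampling rates (white noise density is
σ²/fs against a fixed 14 kHz analysis band), so study-condition
results are quoted at the default 4.8 MHz.

### Reference boards

The reference virtual board is 6 cm × 6 cm × 1 cm with a circular knot
(radius 8 mm, centered at (1.8, 1.8) cm) and a circular pit (radius
6 mm, at (4.2, 4.2) cm) — defect shapes are parametric stand-ins for
real, photographed defects, chosen so both classes are present and
well separated. The method-comparison board keeps the same defects but
is 1.5 cm thick with attenuation raised to 700 dB/m: a
penetration-limited regime chosen so that a compressed coded
excitation still images the board while a short uncoded pulse at the
same drive amplitude becomes noise-limited.

## Scanning and classification

Scan grids include both endpoints (a 5 cm span at 1 mm interval is 51
points); point (i, j) sits at (x₀ + j·Δ, y₀ + i·Δ), row-major,
0-based. Traversal is boustrophedon like the physical stage, but
per-point seeding makes the grid independent of traversal order.

Classification thresholds derive from sound-region calibration peaks:
knot_max = mean − k·sd·34 and pit_min = mean + k·sd·15 (k = 1). The
scale factors are anchored to the measured front-face peak-voltage
table: its mean 0.6446 V and sd 0.0072 V place the bands at ≈ 0.40 V
and ≈ 0.75 V, which reproduce the published knot/pit/sound labels of
both tables. With identical calibration values the bands fall back to
±20% of the mean. In simulated scans, calibration uses up to 64
sound-region grid points. These sd-scaled bands are deliberately
faithful to the calibration data but are sensitive to the realized
feature noise: once the sound-feature coefficient of variation exceeds
roughly 2–3%, the knot band collapses and low-SNR methods stop
detecting defects — which is exactly how penetration failure manifests
in the method comparison.

Rendering min–max normalizes the feature grid (constant grids render
mid-gray), upsamples bilinearly ((n−1)·factor+1 pixels per axis), and
maps through grayscale by default (dark = low peak = knot-like) or an
optional blue–red map.

Overlap scoring reports the truth-normalized coincidence
|detected ∩ truth| / |truth| (pooled over defect classes and per
class) and the Dice coefficient 2|∩|/(|detected|+|truth|). The
coincidence denominator is the truth area, so false positives in sound
regions lower Dice but not coincidence.

## Study conditions and problem sizes

The headline simulated result is a full C-scan of the reference board
at 1 mm interval (61×61 points) with 20 dB pre-filter SNR, classified
with thresholds calibrated on its own sound region; the acceptance
script recomputes it from scratch, along with the decoded main-lobe
height and the measured receiver bandwidth. The excitation-method
comparison uses the same noise level with shared per-point seeds at a
2 mm interval (31×31 points), a grid chosen to keep all five scans of
the comparison cheap while leaving dozens of pixels per defect. The
noise-degradation property test averages ten seeds on a coarser
sub-grid for the same reason. The Monte-Carlo compression-gain check
runs 100 seeds of a one-sample-per-chip decode against a single pulse
in white noise and compares the mean gain to the theoretical
10·log₁₀(2N) ≈ 12.04 dB.

## What the simulator does and does not show

The generator emulates the amplitude physics of per-point
through-transmission: interface loss, local attenuation and thickness,
transducer ringing, receiver filtering, and sensor noise. Passing
tests therefore demonstrate that the coding/compression/classification
chain recovers amplitude-contrast defects under realistic loss and
noise — not that it would survive effects the model omits:

* no diffraction, beam spread, or lateral coupling between scan
  points: defect edges are geometrically sharp, so simulated overlap
  scores are optimistic relative to a real beam footprint;
* no structural clutter, stray paths, or narrowband interference —
  only white noise. This matters for method comparisons: with a
  resonant transducer an uncoded in-phase burst builds up the largest
  received amplitude and thus the best per-point feature SNR, so in
  this model it can only tie, never trail, the Barker code in overlap.
  The field-observed inferiority of uncoded bursts comes from ringing
  smear and their lack of anti-interference margin, which a per-point
  white-noise channel cannot express;
* no anisotropy, moisture/temperature dependence, or reflection-mode
  operation; front/back face differences are representable only as an
  optional per-face gain;
* absolute voltages are arbitrary-scale — only orderings, spreads and
  overlap fractions are meaningful.

## Numerical choices

Correlations use scipy's automatic direct/FFT selection, so short
code-domain decodes are exact in float64 (the identity-channel
main lobe is exactly 16.0). Envelope FWHM interpolates the half-max
crossings linearly and floors the width at one sample. The sidelobe
ratio masks ±2 chip periods around the peak and reports +∞ dB when
the residual is below 10⁻¹² of the peak. Sampling-rate, half-period
and samples-per-chip integrality are validated up front with
descriptive errors rather than silently rounded.
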