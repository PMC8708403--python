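# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `ecgdenoise` pipeline, and what its synthetic-data tests
do and do not establish about real recordings.

## Pipeline model and assumptions

The measured segment is modelled additively, `m(n) = d(n) + ŷ(n)`: a
quasi-periodic cardiac signal `d` plus noise `ŷ` composed of baseline
wander (below ~0.5 Hz, from respiration and electrode/torso motion) and
motion artifacts (transient, overlapping the 1–10 Hz ECG band, coupled to
body movement). The pipeline assumes:

* the QRS complex is the most robust landmark in the segment — every
  automatic decision (quality gating, IMF selection, evaluation alignment)
  is anchored on Pan–Tompkins detections;
* 10-s windows are long enough to hold ≥ 8 beats at rest (needed for the
  majority-vote IMF rules) and short enough for the noise to be locally
  stationary;
* the accelerometer observes the motion process that produces the
  artifacts, so an adaptive filter fed with accelerometer-derived reference
  noise can cancel in-band artifacts that no fixed filter can.

## Stage parameters

| Stage | Parameter | Default | Notes |
|---|---|---|---|
| segmentation | window | 10 s | trailing partial window dropped |
| normalization | — | z-score (ECG), min–max (accel) | per segment; population σ |
| resampling | Kaiser β / taps per phase | 5.0 / 10 | cutoff π/max(L,M), gain L, delay-compensated |
| QRS detector | band / integration / refractory / T-window | 5–15 Hz / 150 ms / 200 ms / 360 ms | 2nd-order Butterworth, forward-backward; all thresholds relative (scale-invariant) |
| EMD | sift SD / max sifts / max IMFs | 0.2 / 50 / 12 | Cauchy criterion; mirror boundary; stops when the remainder is below 1e-7 of the input range |
| IMF selection | match tolerance / recursion cap | ±150 ms / 2 | strict inequalities; ties are noisy; residual always noisy |
| LMS | μ / order | 0.01 / 10 | zero initial weights, per-segment reset, |W| > 1e6 aborts |
| VMD | α / τ / tol / iterations | 2000 / 0 / 1e-7 / 500 | uniform ω init, mirror extension |
| VMDR | K | max(10, #EMD IMFs) | see "Design choices" |
| gate | expected HR / rule | 72 bpm / count ≥ 0.6·expected | SVM: Gaussian kernel, γ = 1 on standardized features, C = 1 |
| evaluation | histogram bins | 50 | equal-width over [min D, max D] |

## Design choices

**Correlation target for axis selection.** The activity candidate is chosen
by the largest |ρ| against the *original normalized segment*, not against
the EMD noise estimate `s(n)`. The selection exists to find the axis that
best reflects the interference actually present in the measurement; `s(n)`
cannot serve that role because in-band artifacts ride on the QRS-bearing
IMFs and are routed to the *clean* side of the split, leaving `s(n)` blind
to them. Measured on coupled synthetic corpora, correlating against `s(n)`
identifies the driven axis at chance level, correlating against the segment
at ≈ 95 %.

**LMS reference scaling.** `lms_run` implements the update literally; the
pipeline divides the reference by `√M · std(X)` before filtering so that
the expected tap-vector energy is 1 and the effective adaptation rate is
2μ = 0.02 per sample. LMS is sensitive to input scale: with a unit-power
reference the per-sample cancellation factor `2μ|X(k)|²` is ≈ 0.3 and the
canceller becomes a fast tracker that subtracts the QRS itself (measured
clean-signal gain ≈ 0.35 without scaling, ≈ 0.9 with it). The scaling is
absorbed by the weights and changes nothing about the model.

**VMDR mode count.** K follows the number of EMD IMFs of the same segment
but is floored at 10. With small K the discarded highest-frequency mode
sits inside the QRS band (e.g. centered near 13 Hz at K = 4) and the
smoothing stage erases the very waves the pipeline protects; at K ≥ 10 the
top mode sits above ~40 Hz and removal is nearly lossless.

**Re-decomposition bookkeeping.** An IMF sent back for re-decomposition
contributes its clean sub-modes to the clean sum and the rest (plus its
sub-residual) to the noise sum; its index is assigned to the clean set iff
any sub-mode was clean. At the recursion cap the plain clean/noisy rule
applies, which (since FP ≥ 50 % triggered the recursion) classifies it
noisy.

**Beat morphology.** Synthetic beats are five Gaussian bumps; the P peak
sits 140 ms before R (a normal PR interval) and the T peak 250 ms after.
P-wave timing matters: P-bearing IMFs are kept only because their
detections fall inside the ±150 ms match tolerance.

**Contact loss.** Modeled as a flat rail with one to three broadband
0.2–0.5 s transients (a detached electrode reads a constant level; pops
occur when the loose lead taps the skin). This reproduces both signatures
the gate relies on: a 90 %-power frequency far above the cardiac band, and
a beat count far below 60 % of expected. Stationary broadband noise would
*not* be flagged by the count rule — the detector is scale-invariant and
fires happily on noise peaks — which is itself a documented property of
the rule, not of the noise.

## The synthetic generator

`gen_bundle` emulates a wearable session: jittered beat train (default
72.8 bpm, i.e. mean RR 0.824 s; SD 20 ms), sinusoidal wander mixture
(0.08/0.21/0.37 Hz at amplitudes 0.26/0.17/0.10 of the R peak), Poisson
burst artifacts (10 min⁻¹, 0.5–2 s Hann envelopes, band-passed 1–10 Hz
noise at amplitude 0.8), and a 50 Hz accelerometer whose channels carry a
gravity offset, per-axis postural sway (0.15, frequencies 0.15–0.35 Hz),
sensor noise (0.02), and the artifact process (envelope + in-band waveform)
scaled by per-axis couplings (0.8, 0.1, 0.1). The default mix puts total
noise power near the clean ECG's power (SNR ≈ 0 dB). All draws come from
one seeded generator (PCG64); noisy = clean + wander + artifact holds
exactly before contact-loss replacement.

What the generator does **not** emulate: non-additive electrode phenomena
(impedance changes, saturation during motion), wander that is coherent with
the artifact process, pathological rhythms and ectopy, multi-lead geometry,
and powerline interference. Passing tests therefore demonstrate the
pipeline's mechanics — conservation, gating, selection, cancellation —
under controlled additive conditions, not clinical performance.

## Numerical choices

* EMD envelopes: cubic splines through extrema with two extrema mirrored
  across each end; sifting also stops when the remainder's range falls
  below 1e-7 of the input's (a vanishing remainder is numerical residue,
  not a mode).
* VMD operates on a mirror-extended (2N) signal; modes are recovered as
  twice the real part of the positive-frequency reconstruction and sorted
  by descending converged center frequency; the decomposition remainder is
  defined as input − Σ modes, so reconstruction is exact by construction.
* The QRS detector's candidate peaks exclude integrated-signal values below
  1e-10 of the segment maximum (relative, hence still scale-invariant);
  refined peaks that collide within the refractory period keep the earlier
  event.
* Greedy nearest one-to-one matching of detections is provably optimal in
  match count for interval tolerance matching; the unit tests verify it
  against exhaustive assignment on small sets.
* The rational resampler's DC ripple is bounded by the Kaiser β = 5 image
  rejection (≈ −50 dB, measured 2.4e-3); applications needing flatter
  response can raise `kaiser_beta`/`taps_per_phase` in the config.
* Degenerate inputs fail loudly: constant segments (normalization), silent
  segments reaching the IMF classifier (gate violation), diverging LMS
  weights, K = 1 smoothing requests.

## Problem sizes

The test suite and the acceptance script use 10-s segments at 250 Hz
(2500 samples), 30-segment benchmark corpora (ten 30-s recordings), a
243-segment gate corpus (162 usable / 81 unusable, split 50/50 for
training and held-out testing), 100-segment conservation sweeps, and
10-seed adaptive-filter oracles.

## Known limitations

* **The IMF rules sacrifice P/T fidelity.** Beat-locked low-frequency modes
  (~1.2 Hz) carry T-wave energy but their detections fall 250–430 ms from
  R, outside the ±150 ms tolerance, so they are classified noisy; on a pure
  clean ECG the reconstruction tops out near ρ ≈ 0.90 rather than 1. The
  adaptive filter then subtracts that energy again through `s(n)` in the
  reference. This is inherent to the selection rules, and consistent with
  the known behaviour of QRS-anchored reconstruction: P and T waves are not
  always recovered.
* **Ordering against simple baselines on additive synthetic noise.** On the
  default benchmark the full pipeline clearly beats the unfiltered signal
  and the DWT/EMD/VMD baselines, but zero-phase high-pass (IIR),
  moving-average subtraction (MA) and the accelerometer-only adaptive
  filter (AF) remain slightly ahead in median RR-aligned correlation/MSE:
  when wander is perfectly band-separated and artifacts are strictly
  additive, filters that keep everything else untouched pay no fidelity
  cost, while the QRS-anchored reconstruction pays the P/T penalty above.
  The pipeline's advantage is expected where noise is not neatly
  band-separated — conditions the additive generator deliberately does not
  fabricate.
* **Heart-rate sensitivity.** The IMF verdicts sit near the 50 %-majority
  boundary; at some rates (e.g. exactly 60 bpm, jitter-free) the detector
  yields too few detections on the P-bearing IMF and fidelity drops
  sharply. Real, jittered rhythms behave better than metronomic ones.
* The SVM gate is trained per corpus; a model trained on one device/noise
  profile does not transfer automatically.
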