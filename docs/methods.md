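# Methods

## Pipeline model and assumptions

The package assumes the standard linear instantaneous mixing model of
EEG: the channel data `X` (electrodes × samples, µV) are a mixture
`X = A S` of source activations `S` plus sensor noise.  ICA recovers an
unmixing such that artifact generators (ocular, myogenic, cardiac)
concentrate in single components; removing those columns of `A` and
rebuilding `X` yields artifact-reduced EEG.  Classification operates
entirely on per-IC summaries (the fingerprint), never on raw channels, so
it is agnostic to montage size and decomposition level as long as the
montage's polar coordinates are supplied.

## Pre-processing

Butterworth band-pass 0.3–100 Hz, 4th order, applied forward–backward
(zero phase); optional IIR notch (default 50 Hz, Q = 30).  Filter order
and Q are common EEG practice; both are parameters.  Resampling is
polyphase with anti-aliasing.  Channel vetting replaces visual screening
with three automated screens: flatline (σ < 0.05 µV), saturation (> 5 % of
samples above 500 µV), and excess noise (σ > 8× the median channel σ).  A
dataset is flagged unusable above 20 % bad channels; windows where more
than 50 % of channels saturate are trimmed.  All thresholds live in the
`vet_channels` signature.

## Decomposition

PCA (SVD) reduces to `n_ics` dimensions and whitens; extended-Infomax ICA
(via MNE) unmixes.  The backend is a pluggable contract — any callable
producing an unmixing matrix of matching shape.  ICA's permutation, sign
and scale ambiguities are resolved canonically: sources are scaled to unit
variance (amplitude moves into the mixing weights, so spatial features see
µV-scale maps), components are ordered by descending explained variance,
and each map's largest-|weight| electrode is made positive.  With a fixed
seed the decomposition is reproducible to floating tolerance.

The corpus builder (`make_labeled_corpus`) defaults to a FastICA backend:
on the well-separated synthetic mixtures it recovers planted sources
equivalently (matched |r| ≈ 0.99) at roughly a tenth of the extended-
Infomax runtime, whose block-sequential implementation varies severalfold
in runtime with the data.  `decompose()` itself defaults to extended
Infomax, and the source-recovery and determinism tests exercise both
backends.

## Feature numerics

* **Epochs** — 5 s with 1 s overlap (4 s hop); a trailing remainder
  shorter than one epoch is discarded.  Zero-variance epochs contribute 0,
  never NaN.
* **K** — per-epoch mean-subtracted excess kurtosis, averaged; negative
  averages clamp to 0 before dataset normalization.
* **SAD guards** — set to 0 when var(FA) − var(PA) ≤ 0 (posterior source)
  or when LE/RE mean weights differ in sign (not bilaterally symmetric);
  the remaining |mean FA| − |mean PA| is clamped at 0 so the normalized
  value stays in [0, 1].
* **Regions** — FA: |θ| ≤ 60°, radius ≥ 0.4; PA: |θ| ≤ 120° on the outer
  electrode ring, with "outer ring" = radius within ε = 0.05 of the
  montage maximum (exact equality is brittle on real caps); LE/RE: θ in
  [−60°, −30°] / [30°, 60°].  Angular intervals are closed.  An empty
  region degrades the dependent feature to 0 with a warning.
* **Band powers** — Welch PSD, 2 s Hann windows, 50 % overlap; band edges
  half-open [lo, hi) so 4 Hz belongs to θ; per-band mean PSD normalized
  over the five bands (`band_mode="integral"` switches to integrated
  power).
* **MIF** — integrated PSD 0–20 Hz vs 21–100 Hz taken literally; the
  20–21 Hz bin gap is excluded.
* **CIF** — its PSD uses 8 s Welch windows so candidate beat rates
  resolve to 0.125 Hz; the band peak must exceed 5× the band median PSD
  to count as a peak at all.  Time-course peaks need prominence ≥ 0.5 σ
  and amplitude above half the mean peak amplitude; the inter-beat filter
  drops peaks closer than 0.8× the expected interval to the previously
  kept peak (missed beats are allowed — this is what makes a half-deleted
  beat train score ≈ 0.5).  The score is not clamped; values > 1 are
  possible and documented.
* **Templates** — canonical 4 s zero-mean parametric waveforms: a
  biphasic blink pulse (≈ 150 ms positive lobe with a shallow rebound) and
  a step-and-return saccade with a ≈ 0.5 s hold (gaze returns to fixation
  after each cued movement).  `build_template` averages peak-aligned
  exemplars as an alternative.  Sliding correlation advances one sample at
  a time (FFT-based, verified against a dense per-window scan);
  zero-variance windows are skipped.
* **EF** — amplitude histograms with 100 equal-width bins per 5 s segment
  over that segment's own range, natural-log Shannon entropy,
  zero-probability bins skipped; entropies z-scored across ICs per segment
  index; EF = fraction of |z| ≥ 1.64, floored to 0 at ≤ 0.2.  A single-IC
  dataset yields EF = 0 with a warning.

All thresholds (0.65, 1.64, 0.2, band edges, cardiac band) default to the
method's published values and are fields of `FeatureConfig`.

## Classifier

`sklearn.svm.SVC`, RBF kernel, C = 1, `gamma="scale"`.  Features arrive
already in [0, 1]-ish ranges from the fingerprint normalization, so no
additional standardization is applied by default (exposed via the usual
SVC parameters).  Artifact ICs are rare (a few percent of a corpus), so
inverse-frequency class weighting is on by default.  Exact ties at the
decision boundary resolve to non-artifact — the conservative direction
for data retention.  Models serialize with their subset mask and
hyperparameters and reload to bit-identical predictions.

## Subset search and selection

Subsets are enumerated in ascending (popcount, binary value) order —
deterministic, and it makes "fewest features" ties resolvable by
first-in-order as a last resort.  One random dataset-level split per
iteration is shared by all subsets (the alternative — a split per subset —
would make stage-1 dominance incomparable across subsets).  Splits are by
dataset, never by IC.  The three-stage rule treats the full set as the
benchmark rather than a candidate; if no subset dominates it in every
iteration the full set is returned with a fallback flag.  Remaining ties
trigger additional iterations (default cap: 5 extra rounds, then
first-in-order).  `max_subsets` subsamples the enumeration for smoke
tests; the full search is the default.

## Evaluation

Accuracy (TP+TN)/total, precision TP/(TP+FP), false omission rate
FN/(FN+TN), sensitivity, specificity.  Undefined ratios (e.g. precision
with no positive calls) report as not-applicable rather than NaN.  SNR is
defined on amplitudes: 20 log₁₀(max |v| in the 200 ms window centred on
the event / max |v| in the immediately preceding 200 ms baseline),
averaged over events in a 10 s segment; a power-ratio convention is a
config switch.  Events come from ground truth or a user event file — no
automatic event detection.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of cued-artifact sessions:
stereotyped blink pulses (~300 ms biphasic, delta-dominant, bilateral
frontal topography), alternating step-and-return saccades (left–right
frontal dipole), band-limited > 20 Hz bursts under a contraction envelope
(focal topography), periodic cardiac spikes (48–180 bpm), and 1/f
background sources with smooth random topographies kept out of the
far-frontal strip (cortical sources are not frontopolar-dominant the way
ocular ones are).  Amplitudes default to blink 150 µV, eye movement
100 µV, myogenic 60 µV, background 20 µV, sensor noise 2 µV — chosen so
artifact ICs are visually obvious, as in retained training data.  Scalp
maps are geometric Gaussians on the montage disc, not lead-field
projections; there is no volume conduction model, no non-physiological
artifact (electrode pop, cable sway, sweat drift), and cue timing is
near-deterministic (±50 ms jitter).  Passing tests therefore demonstrate
pipeline correctness and recoverability under the stated mixing model,
not performance on real recordings.

IC labeling replaces expert visual inspection: each ground-truth source is
matched to its best-correlated IC (|r| ≥ 0.9, correlating against sources
passed through the same band-pass as the recording); datasets whose
planted target source finds no match are excluded with a warning — the
analogue of discarding decompositions without clearly identifiable
components.

## Problem sizes

Tests and the acceptance script run the full pipeline at 32 electrodes,
256 Hz, 50 s, 20 ICs, 12 datasets per corpus — the smallest scale at which
every feature stays well defined (γ band under Nyquist, ≥ 9 epochs, ≥ 9
entropy segments) and dataset-level 6-fold splits remain possible; the
generator's protocol-level defaults (1024 Hz, 120 s) are unchanged.  The
reduced search demonstration uses 5 features (31 subsets) × 10 iterations.

## Known limitations

Horizontal eye movements only (no vertical/vergence templates); cardiac
detection is a feature, not a trained classifier; no probability
calibration; the exhaustive 16 383-subset search at full scale is
embarrassingly parallel but implemented sequentially-equivalent; SAD/SED
depend on the montage's polar coordinates being meaningful (no 3-D
digitization support).
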