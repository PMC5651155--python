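# Methods

## Model and assumptions

`spikegp` treats interictal spike detection as window classification. The
unit of analysis is one channel's 100 ms window (N = 100 samples at
1000 Hz, 50% overlap); the unit of decision is the *regional* window, the
same time span across all 26 (occipital: 24) channels of one brain
region. The method assumes that (i) a spike is a regional event — the
magnetic transient is visible, with varying gain, on most channels of the
affected sensor patch, which is what makes strict-majority voting
meaningful; and (ii) spike windows differ from background in simple
distributional statistics (amplitude extremes, dispersion, peakedness),
so a scalar combination of the eight window statistics can separate the
classes in one dimension.

### Window statistics

All eight statistics use 1/(N−1) normalizations: the variance as usual,
but also kurtosis = Σ(x−μ)⁴/((N−1)σ⁴) and skewness = Σ(x−μ)³/((N−1)σ³).
These are *not* the conventional moment estimators (which divide by N);
they are implemented by their defining sums and verified against an
independent direct-summation oracle to 1e−9 relative. Quartiles use the
exclusive-halves rule (median of the lower/upper half of the sorted
window, overall median excluded from both halves at odd N) with no
interpolation. Zero-variance windows get kurtosis = skewness = 0 rather
than NaN so formula evaluation never receives non-finite inputs; the
affected features are meaningless for such windows, but a flat window is
never a spike, so this only needs to be safe, not informative.

### Median smoothing

The smoother is a per-window sliding median of order 5 with edge
replication. Order 5 removes one- and two-sample artifacts without
flattening 20 ms (20-sample) spikes; the boundary policy replicates the
edge sample so output length equals input length.

### Window labels

A window is labeled spike when it overlaps an annotated (start, end)
interval by at least half the window length (50 samples). All coordinates
are 0-based samples, intervals half-open. With 50% window overlap this
rule guarantees that any spike of ≥ 50 ms labels at least one window
positive, and it is symmetric: a window mostly covered by a spike is
positive, one merely grazed is not.

## GP search

Individuals are expression trees over terminals X1..X8 and the function
set {plus, minus, times, sin, cos, log}; there are no numeric constants.
log is protected (ln|x|, and 0 when |x| ≤ 1e−12) and every operation
clamps overflow, so all formulas are total and finite. Choices made where
the procedure design was open:

- **Initialization**: ramped half-and-half over depths 2–6, the community
  default for a diverse initial population.
- **Variation**: subtree crossover (two offspring per pair) and subtree
  mutation (replacement tree up to depth 4), each selecting swap points
  uniformly over all nodes. Offspring exceeding the 25-level depth limit
  are rejected and resampled up to 10 times, after which the parents pass
  through unchanged — this preserves population size and never discards a
  generation slot.
- **Parent selection** is uniform; selection pressure comes entirely from
  elitist μ+λ survival (the best 25 of parents ∪ offspring), which makes
  the best-fitness trace monotone non-increasing by construction.
- **Adaptive probabilities**: crossover/mutation start at 0.90/0.10; each
  generation without improvement of the best fitness adds 0.05 to the
  mutation probability (capped at 0.40, crossover always 1 − p_mut);
  any improvement resets both. This is one admissible schedule — simple,
  monotone under stagnation, and testable.
- **Fitness** is the wrapper error: the candidate formula maps the
  balanced reference group to 1-D reference points and the balanced
  validation group to queries; the KNN error rate on the queries is
  minimized. The neighbor count inside the wrapper defaults to the same
  k = 100 used in the classification stage (clamped to the reference-set
  size); nothing in the procedure requires the two k's to differ, and
  sharing them keeps the wrapper an unbiased rehearsal of deployment.

Evolution is bit-reproducible for a fixed seed: all randomness flows from
one `numpy` generator, survivor sorting is stable, and fitness values are
cached per expression.

## KNN classifier

The evolved formula's scalar output is the only feature, so the
classifier is 1-D with absolute-difference distance (all p-norms
coincide). Classification is exact brute force with fully specified
determinism: distance ties resolve by reference insertion order (stable
sort), and an even-k vote tie resolves by the label of the single nearest
reference — data-driven rather than a fixed class bias, which matters
because the default k = 100 is even. k is clamped to the reference-set
size with a warning so small fixtures run unchanged.

## Regional voting and evaluation

A regional window is a spike iff strictly more than half the channel
votes are positive: > 13 of 26, and by the same strict-majority reading
> 12 of 24 for the occipital regions. Evaluation is per window (matching
the classifier's outputs), pooled over recordings: sensitivity =
100·TP/(TP+FN), specificity = 100·TN/(TN+FP); a zero denominator is
reported as not-applicable, never silently 0. Merging adjacent positive
windows into event intervals is provided for human-readable output only.

## Study layout and groups

Mirroring the clinical design, patients are split at the *patient* level:
4 reference + 4 validation patients feed the GP stage, and a disjoint set
of 20 patients is used only for evaluation, with the reference points
frozen from the GP stage (patient-independence). Within each group the
majority class is undersampled (seeded) to the minority count and both
classes are capped at 200 segments — the wrapper deliberately uses a
small balanced set, which keeps fitness evaluation cheap and the
reference set compact. Every run writes a YAML manifest (config, seeds,
package version) from which it re-executes bit-identically.

## Synthetic data generator

The simulator emulates one region of a gradiometer array: independent
Gaussian noise per channel, band-passed to 1–50 Hz (4th-order Butterworth,
forward-backward) and normalized to unit RMS. Spikes are Mexican-hat
(second-derivative-of-Gaussian) transients — biphasic, zero-mean, peak 1,
main-lobe width 0.2 of the half-duration, giving a window kurtosis near
4.2 versus ≈ 3 for Gaussian background, i.e. visibly "sharper than
background". Events are Poisson-placed (default 10/min, an active
interictal record at desk scale) with non-overlapping uniform placement;
durations are truncated-normal, mean 70 ms, sd 25 ms, bounded to
[20, 150] ms so the 100 ms window covers the bulk of events. Each event
is added coherently to *all* channels, scaled by `snr` (spike peak over
background RMS, default 5) and per-channel gains ~ Normal(1, 0.2)
truncated positive — the coherent insertion is what justifies majority
voting.

What the generator does **not** model: 1/f background spectra,
nonstationarity, ocular/cardiac artifacts, realistic forward-field
topographies (lead fields, dipole orientations), or inter-patient
variability in spike morphology. Passing the synthetic acceptance tests
therefore demonstrates that the pipeline's machinery is correct and that
it detects coherent sharp transients at the stated SNR; it does not
certify clinical-grade performance on real MEG, where artifacts and
morphology variation would lower both metrics.

## Problem sizes and numerical choices

The synthetic study uses 8 training patients × 30 s and 20 evaluation
patients × 15 s (300 s of held-out 26-channel data, ≈ 156k channel
windows), sizes chosen so a full study runs in well under a minute on one
core while leaving ~70 spike windows and ~5900 clean windows in the
evaluation pool. The chance-level control re-runs the identical study
with `snr = 0`: annotations become placebo marks on pure noise. Note that
chance level for the *regional* decision is not exactly 50%: with
independent chance-level channel votes (q ≈ 0.5), the strict > 13-of-26
rule gives a positive rate of P(Binom(26, q) > 13) ≈ 0.42 at q = 0.5
(the central atom at 13 counts as negative), and sampling noise in the
reference set moves q run to run, so sensitivity ≈ decision rate and
specificity ≈ its complement land anywhere in a broad band around 40–60%.
The chance-level tests therefore assert both metrics inside [25%, 75%]
with their sum near 100%, rather than a literal 50% each.

## Known limitations

- The detector is only as good as the 1-D separation the evolved formula
  achieves; classes that differ in ways invisible to the eight window
  statistics cannot be recovered.
- Per-window evaluation counts every overlapping window of a long spike
  separately; event-level scoring would weight long and short spikes
  equally.
- GP bloat is controlled only by the depth cap; evolved formulas can be
  large and redundant (they remain cheap to evaluate).
- The occipital > 12-of-24 threshold extends the strict-majority rule by
  analogy; no 24-channel ground truth was available to test alternatives.
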