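# Methods

This note documents the models and procedures implemented in `ssvepsync`,
the defaults of the synthetic-data generator and what they do and do not
emulate, the numerical choices, and the decisions taken where the
methodology was genuinely open.

## Signal model and synchronization index

An SSVEP epoch is a channels-by-samples matrix `X ∈ R^{N1×M}` sampled at
`Fs`; the reference for candidate frequency `f` stacks
`sin(2π h f t), cos(2π h f t)` for harmonics `h = 1..Nh` on the grid
`t = 1/Fs, 2/Fs, …, M/Fs`. The time axis deliberately starts at `1/Fs`,
not 0; this shifts absolute phases by one sample and is applied identically
in the generator and the references, so phase bookkeeping stays consistent.

Both signal sets are normalized per channel to zero mean and unit
*population* variance (1/M), matching the 1/M covariance convention
`C_ab = (1/M) A Bᵀ` so that auto-covariance diagonals are exactly 1.
Per-channel (rather than global matrix) normalization is used; the
alternative only rescales whitened quantities and left classification
unchanged in sensitivity checks.

The synchronization index is the normalized eigenvalue entropy of the
block-whitened joint correlation matrix:

    R = U C Uᵀ,  U = diag(C11^{-1/2}, C22^{-1/2}),
    S = 1 + Σ λ'_i log λ'_i / log P,  λ' = λ / tr(R),  P = N1 + N2,

with `0·log 0 = 0` and natural logarithms internally (the base cancels).
Closed-form anchors used as tests: `S = 1` for identical single-channel
signals; `S = 0` when the whitened correlation matrix is the identity;
`S = 1 − log 2 / log 4 = 0.5` for the two-channel self-synchrony case.

Numerical choices:

- Inverse square roots are computed by symmetric eigendecomposition with an
  eigenvalue floor `1e−10 · trace/dim` (shrinkage toward identity). Short
  windows with 8+ channels can be rank-deficient; flooring keeps the method
  defined and is logged when it triggers.
- `R` is symmetrized as `(R + Rᵀ)/2` before eigendecomposition to guard
  against floating-point asymmetry; tiny negative eigenvalues are clipped
  to zero before the entropy.
- Ties in any argmax classification break toward the lowest class index
  (deterministic and testable).

## Contrast methods

- **CCA**: largest canonical correlation via singular values of the
  whitened cross-covariance `C11^{-1/2} C12 C22^{-1/2}`, same
  regularization as above.
- **Multi-set CCA**: per class, the stacked generalized eigenproblem
  `(R − S) w = ρ S w` over all pairwise trial cross-products, top
  eigenvector only (one filter per training trial), rescaled to the exact
  mean-power constraint `(1/n) Σ w_hᵀ χ_h χ_hᵀ w_h = 1`; the optimized
  reference stacks the filtered trials. `S` receives a ridge of
  `1e−8 · trace/dim` before inversion. Trial cross-products are used
  unscaled; a 1/M factor would cancel between the two sides.
  A single training trial falls back to the raw trial as reference, with a
  warning.
- **IT-CCA**: largest canonical correlation against the trial-averaged
  individual template; only the first canonical coefficient is used.

## Template transfer

The intra-subject template is the element-wise mean of the training trials;
templates are stored raw and normalized after window slicing, so each
analysis window sees exact per-window statistics.

Donor screening: a labeled donor trial's confidence is its synchronization
index at the label divided by the mean index over all K frequencies
(scale-invariant by construction), evaluated on full-length trials against
sine–cosine references with Nh = 3. The cut-off is `1 + ln(T_w)` with `T_w`
the window length in **seconds** (≈2.386 for 4 s trials). A sample-count ×
rate product reading of the cut-off argument is also implemented
(`mode="product"`) but is inoperable at realistic sample counts — it exceeds
any attainable confidence — so the seconds reading is the default and the
switch is logged.

The inter-subject template is a two-stage average: per-donor mean of
selected trials first, then the mean across donors, so donors with many
selected trials do not outweigh donors with few. Donors contributing zero
selected trials for a class are dropped from that class's denominator
rather than contributing a zero matrix (which would bias the template
toward silence). If every donor is empty the class has no inter template
and scoring degenerates to intra-only, which ranks classes identically to
the intra-template synchronization index. Donors are ranked by their own
full-length MSI accuracy (sine–cosine references), test subject excluded,
ties toward the lower subject index; the default pool size is 4.

Combined score: `γ_i = S_i² + (S*_i)² ∈ [0, 2]`.

## Dynamic-window adaptive threshold

Cumulative windows start at 0.5 s and grow in 0.5 s increments to the trial
end. "New data segment" is read as the cumulative prefix (previous segment
with the increment appended); an increment-only mode exists for sensitivity
analysis. Templates are sliced to the prefix length, never rebuilt, so one
template provenance covers all windows.

Per window, scores become probability ratios `r_i = γ_i / mean_k γ_k`
(per-window mean exactly 1), multiplied into the joint probability
`J_i ← J_i · r_{m,i}` with `J` initialized to the first window's ratios.
The trial stops at the first window where `max_i J_i ≥ T_c(d)` and outputs
`argmax_i J_i`; exhausting the data below the cut-off marks the trial
invalid. Because `max_i r_i ≥ mean_i r_i = 1`, a cut-off of 1 stops every
trial at the first window, and an arbitrarily large cut-off invalidates
every trial; decision times are monotone in the cut-off.

Cut-off tuning uses a per-duration-bucket candidate grid
(d ≤ 1 s: 1–2 step 0.05; 1–2 s: 1–4 step 0.1; 2–3 s: 3–8 step 0.2;
3–4 s: 3–16 step 0.4 — the last bucket's arithmetic grid tops out at 15.8).
Candidates whose invalid-trial proportion is strictly above 20% are
discarded; invalid trials are excluded from the accuracy denominator.
Survivors are ranked by training accuracy, then shorter mean decision time,
then smaller cut-off. The default search is greedy over buckets in order of
increasing duration; **later, still-unset buckets are held at their grid
maximum** during evaluation, so trials that have not yet stopped keep
accumulating evidence instead of being forced to decide at the next
bucket's first window (a grid-minimum completion collapses training
accuracy). A full Cartesian-product search is available for small grids.
If every candidate in a bucket is discarded the largest cut-off is taken
with a loud warning. One cut-off per bucket is the default schedule shape;
a constant-threshold mode is also provided.

## Evaluation

- Accuracy: unweighted mean of fold-wise percentages over *valid* trials
  (not pooled counts — the two differ once invalid-trial filtering
  unbalances folds). Three folds, per-class partitions (15 trials → 5 per
  fold), seeded.
- ITR: Wolpaw bit rate with `0·log 0 = 0`; below-chance accuracy clamps the
  bit rate at zero with a warning. Base-2 logarithms are the default
  (bits/min). The natural-log convention (`paper_nat`) exists because some
  published per-subject ITR tables evaluate the formula with natural logs;
  with N = 12 and T = 5 s it reproduces such tables from their printed
  accuracies to two decimals, and the exact identity
  `bits = nat / ln 2` is asserted in tests.
- Selection time: window length + 1 s gaze shift. For the adaptive decoder,
  T uses the mean decision time of *valid* trials plus the gaze shift; this
  convention is a package choice (reasonable alternatives exist) and is
  therefore kept out of any regression against published numbers.
- Preprocessing for continuous recordings: 4th-order Butterworth band-pass
  6–80 Hz applied forward–backward (zero phase, doubled attenuation), then
  an epoch crop of [0.15, 4.15) s to skip stimulus-onset latency. Filter
  order/type and the phase handling are configurable; sampling rates below
  160 Hz are rejected because the upper band edge would sit at or above
  Nyquist.

## Synthetic cohort: what it emulates, and what it does not

The generator mirrors the geometry of public 12-class joint
frequency–phase-modulated recordings: 10 subjects, 15 trials per class,
8 occipital channels, 4 s epochs, frequencies 9.25–14.75 Hz in 0.5 Hz steps
with phases advancing 0.5π per keypad row. The sampling rate is not fixed
by that geometry and defaults to 256 Hz, configurable everywhere.

Each non-lapse trial is a harmonic series at the stimulus frequency
(amplitudes 1/h through the 5th harmonic) with phase `h·(φ_i + δ_p + δ_t)`,
where `δ_p ~ N(0, 0.2 rad)` is a subject-level latency-like offset shared
by all of a subject's trials and `δ_t ~ N(0, 0.05 rad)` is trial jitter.
The source projects to channels through a fixed occipital-gradient profile
(gains 1.0 → 0.6) and is buried in pink (1/f) noise — EEG background is not
white — scaled per trial to the subject's broadband SNR. 5% of trials are
attention lapses containing noise only (flagged), which caps fixed-window
accuracy near 95% and gives the adaptive decoder's invalid-trial rule
something real to reject.

Two defaults were calibrated against the difficulty profile of the real
recordings the generator emulates, and then frozen:

- **Source harmonics beyond the references.** With a purely sinusoidal
  source truncated at the reference harmonic count, the sine–cosine
  references are *exact* templates and no learned-template method can beat
  them — the opposite of real data, where individual templates carry
  waveform content the references lack. The source therefore spans five
  harmonics while the protocol's references keep Nh = 3.
- **Subject SNRs −12…−4 dB** (evenly spread), putting the weakest subject's
  template methods in the 70–90% range at 4 s and leaving 0.5 s windows
  hard for everyone, like the published per-subject spread.

What passing tests on this cohort do **not** show: the generator has no
alpha rhythm or ocular/muscular artifacts, no non-stationarity within
trials, no electrode-level correlated noise, and its inter-subject
variability is a pure phase offset — real transfer learning faces waveform
and topography differences too. Synthetic results validate the machinery
and the qualitative method orderings, not absolute real-data accuracy.
(One test constructs in-band alpha interference explicitly to exercise the
regime where learned references beat sine–cosine references.)

## Problem sizes

The benchmark used by the tests and by `scripts/acceptance.py` runs the
full emulated cohort — 10 subjects × 12 classes × 15 trials, three-fold CV,
eight window lengths, all seven methods including the adaptive decoder's
grid search — about 1,800 trials decoded per method, a few minutes on one
core. All randomness descends from a single seed; repeated runs are
bit-identical.

## Known limitations

- The Multi-set CCA reference keeps one filter per training trial (top
  eigenvector only); multi-component variants are out of scope.
- Donor confidence is evaluated on full-length trials only; screening at
  the decoding window length is a plausible alternative that is not
  implemented.
- The greedy bucket search is not guaranteed to find the joint optimum of
  the full product grid (the product mode exists but is expensive at the
  default grid sizes).
- No session-to-session transfer, donor weighting by similarity, filter
  banks, or temporally local / time-delay-embedded synchronization
  variants.
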