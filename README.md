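# ssvepsync

Frequency decoding for SSVEP brain–computer interfaces built around the
multivariate synchronization index (MSI), its inter- and intra-subject
template-transfer extension, and a dynamic-window adaptive-threshold
sequential decoder — together with the classical contrast methods (CCA,
Multi-set CCA, individual-template CCA), a cross-validated accuracy/ITR
benchmark harness, and a synthetic multi-subject SSVEP generator so that
every component is testable without any recordings.

## Who this is for

Researchers building or evaluating SSVEP spellers: a subject gazes at one of
K stimuli flickering at distinct frequencies `f_1..f_K`; the occipital EEG
then oscillates at the attended frequency and its harmonics, and the decoder
must identify which frequency — quickly, because the selection time bounds
the information transfer rate (ITR) of the interface.

## The methods, briefly

**MSI.** For an epoch `X ∈ R^{N1×M}` and a reference set `Y ∈ R^{N2×M}`
(sine/cosine pairs at harmonics `1..Nh` of a candidate frequency), form the
joint covariance `C` of the normalized signals, whiten it block-wise with
`U = diag(C11^{-1/2}, C22^{-1/2})`, and score the eigenvalue spectrum
`λ'_i = λ_i / tr(R)` of `R = U C Uᵀ` by its normalized entropy:

    S = 1 + Σ_i λ'_i log λ'_i / log(P),   P = N1 + N2.

`S = 1` for perfect synchrony, `S = 0` for empirically uncorrelated sets.
The decoded class is `argmax_i S_i`.

**Template transfer (IIST-MSI).** The sine–cosine references are replaced by
(1) the subject's own trial-averaged template `Y_i` and (2) an inter-subject
template `Y*_i` averaging *high-confidence* trials donated by other
subjects. A donor trial's confidence is `C = S_label / mean_k S_k`, and only
trials with `C > 1 + ln(window seconds)` are transferred; per-donor means
are averaged across donors so prolific donors do not dominate. The combined
score is `γ_i = S_i² + (S*_i)²`.

**Adaptive threshold (IIST-MSI-AT).** The epoch is examined on growing
windows (0.5 s initial, 0.5 s increments). Each window's scores become
probability ratios `r_i = γ_i / mean_k γ_k`, multiplied across windows into
a joint probability `J_i`. The decoder stops as soon as `max_i J_i` reaches
a duration-dependent cut-off `T_c(d)` tuned on training folds (candidates
with more than 20% invalid trials are discarded); trials that never reach
the cut-off are *invalid* and yield no command.

**Evaluation.** Three-fold cross-validated accuracy is the unweighted mean
of fold percentages over valid trials, and the Wolpaw ITR is
`B = log N + P log P + (1−P) log[(1−P)/(N−1)]`, `ITR = 60·B/T` with
T = window + 1 s gaze shift (base-2 by default; a natural-log convention is
provided for regression against published per-subject tables).

## Worked example

```python
from ssvepsync import (SyntheticSpec, simulate_dataset, twelve_class_keypad,
                       CVPlan, run_benchmark)

ds = simulate_dataset(SyntheticSpec(seed=42), twelve_class_keypad())
res = run_benchmark(ds, methods=("msi", "itmsi", "iist", "iist_at"),
                    cv=CVPlan(n_folds=3, seed=1), n_donors=4,
                    subjects=[0, 5, 9])
t = res.table
print(t[t.window_s == 4.0][["method", "subject", "accuracy"]])
print(t[t.method == "iist_at"][["subject", "accuracy",
                                "mean_decision_time_s"]])
```

prints (subject 0 is the weakest of the emulated cohort, subject 9 the
strongest):

```
method  subject  accuracy
   msi        0 93.888889
 itmsi        0 88.888889
  iist        0 93.888889
   msi        5 95.000000
 itmsi        5 95.000000
  iist        5 94.444444
   msi        9 95.555556
 itmsi        9 96.666667
  iist        9 96.666667
 subject  accuracy  mean_decision_time_s
       0 90.087078              1.384393
       5 94.971751              0.682584
       9 96.111111              0.547222
```

Fixed 4 s windows and the adaptive decoder reach comparable accuracy (the
generator plants attention-lapse trials in ~5% of epochs, which caps
fixed-window accuracy near 95%), but the adaptive decoder commits after
~0.5–1.4 s on average — that time saving is exactly what multiplies the ITR.

A command-line interface mirrors the library
(`ssvepsync simulate|decode|gridsearch|benchmark|report`); datasets
round-trip through HDF5/NPZ, and a MAT loader ingests public epoch archives
with a declared axis order.

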