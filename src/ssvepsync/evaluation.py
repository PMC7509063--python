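"""Cross-validated benchmark harness: accuracy, ITR and method comparison.

Accuracy follows the three-fold convention: the unweighted mean of the
fold-wise percentages ``acc = (1/3) Σ P_i/N_i · 100`` where ``N_i`` counts
*valid* trials in fold i — not the pooled ratio (the two differ when the
adaptive decoder unbalances folds by rejecting trials).

The information transfer rate uses the Wolpaw bit rate

    B = log N + P log P + (1-P) log[(1-P)/(N-1)],   ITR = 60 B / T

with base-2 logarithms by default (bits/min).  A natural-log convention
(``convention='paper_nat'``) is also provided: some published per-subject
ITR tables evaluate the formula with natural logs, and regression tests
against such tables need the same convention.  T is the analysis window
plus a fixed gaze-shift overhead (1 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from . import adaptive_decoder as ad
from .cca_family import fit_mset_cca
from .iist_transfer import (
    inter_template,
    intra_template,
    select_donors,
    select_high_confidence,
)
from .msi_core import EpochScorer, prepare_target
from .signal_models import Dataset, build_reference_bank

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "BenchmarkResult",
    "cv_accuracy",
    "itr",
    "preprocess",
    "msi_self_accuracy",
    "run_benchmark",
    "ALL_METHODS",
]

ALL_METHODS = ("cca", "msi", "mset", "itcca", "itmsi", "iist", "iist_at")


# ---------------------------------------------------------------------------
# cross-validation plan


@dataclass(frozen=True)
class CVPlan:
    """Per-class trial partition into disjoint, exhaustive folds."""

    n_folds: int = 3
    seed: int = 0

    def assignments(self, n_classes: int, n_trials: int) -> np.ndarray:
        """Fold id per (class, trial); each class is permuted independently."""
        rng = np.random.default_rng(self.seed)
        base = np.arange(n_trials) % self.n_folds
        out = np.empty((n_classes, n_trials), dtype=int)
        for i in range(n_classes):
            out[i] = base[rng.permutation(n_trials)]
        return out


def cv_accuracy(correct_counts, valid_counts) -> float:
    """Unweighted mean of fold-wise percentages (not pooled counts).

    Folds with zero valid trials are skipped with a warning; if every fold
    is empty a ValueError is raised.
    """
    P = np.asarray(correct_counts, dtype=float)
    N = np.asarray(valid_counts, dtype=float)
    if P.shape != N.shape:
        raise ValueError("correct and valid counts must align")
    keep = N >= 1
    if not keep.any():
        raise ValueError("no fold contains a valid trial")
    if not keep.all():
        logger.warning("%d fold(s) without valid trials skipped",
                       int((~keep).sum()))
    return float(np.mean(P[keep] / N[keep]) * 100.0)


# ---------------------------------------------------------------------------
# information transfer rate


def itr(P: float, N: int, T: float, convention: str = "bits") -> float:
    """Information transfer rate per minute for accuracy ``P`` over ``N``
    choices at ``T`` seconds per selection.

    ``convention='bits'`` is the textbook base-2 rate (bits/min);
    ``'paper_nat'`` evaluates the same formula with natural logarithms
    (nat-based units, used by some published per-subject tables).
    Below-chance accuracy clamps the bit rate at 0 with a warning.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy fraction must lie in [0, 1]")
    if N < 2:
        raise ValueError("need at least two classes")
    if T <= 0:
        raise ValueError("selection time must be positive")
    if convention == "bits":
        log = np.log2
    elif convention == "paper_nat":
        log = np.log
    else:
        raise ValueError(f"unknown ITR convention {convention!r}")
    if P < 1.0 / N:
        logger.warning("below-chance accuracy %.3f < 1/%d: bit rate clamped at 0",
                       P, N)
        B = 0.0
    elif P >= 1.0:
        B = float(log(N))
    else:
        # 0·log 0 = 0 at the P ∈ {0, 1} limits
        B = float(log(N) + P * log(P) + (1.0 - P) * log((1.0 - P) / (N - 1)))
        B = max(B, 0.0)
    return B * 60.0 / T


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(raw, fs: float, band=(6.0, 80.0), order: int = 4,
               span=(0.15, 4.15)):
    """Zero-phase Butterworth band-pass then epoch crop.

    ``raw`` is any array whose last axis is time.  The band-pass (default
    6–80 Hz, 4th-order Butterworth, forward–backward so the effective
    attenuation doubles and the phase is zero) is applied before cropping
    to ``[span[0], span[1])`` seconds, which skips the stimulus-onset
    latency and leaves an integral number of seconds of data.
    """
    if band[1] >= fs / 2.0:
        raise ValueError(
            f"band edge {band[1]} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = scipy.signal.butter(order, band, btype="bandpass", fs=fs,
                              output="sos")
    filt = scipy.signal.sosfiltfilt(sos, np.asarray(raw, dtype=float), axis=-1)
    i0 = int(round(span[0] * fs))
    n = int(round((span[1] - span[0]) * fs))
    if i0 + n > filt.shape[-1]:
        raise ValueError("epoch span exceeds the recorded data")
    logger.debug("preprocess: order-%d Butterworth %s Hz, crop [%s, %s) s",
                 order, band, span[0], span[1])
    return filt[..., i0:i0 + n]


# ---------------------------------------------------------------------------
# donor utilities


def msi_self_accuracy(dataset: Dataset, subject: int, ref_bank) -> float:
    """Fraction of a subject's own trials classified correctly by the
    standard synchronization index at full length (used to rank donors)."""
    M = dataset.n_samples
    preps = [prepare_target(ref_bank.reference(i, M))
             for i in range(ref_bank.n_classes)]
    correct = total = 0
    for i in range(dataset.n_classes):
        for h in range(dataset.n_trials):
            scorer = EpochScorer(dataset.data[subject, i, h])
            scores = [scorer.msi(p) for p in preps]
            correct += int(np.argmax(scores) == i)
            total += 1
    return correct / total


def _donor_confidences(dataset: Dataset, ref_bank) -> np.ndarray:
    """Confidence of every trial vs the sine–cosine bank (full length)."""
    S, K, N = dataset.n_subjects, dataset.n_classes, dataset.n_trials
    M = dataset.n_samples
    preps = [prepare_target(ref_bank.reference(i, M)) for i in range(K)]
    conf = np.empty((S, K, N))
    for p in range(S):
        for i in range(K):
            for h in range(N):
                scorer = EpochScorer(dataset.data[p, i, h])
                scores = np.array([scorer.msi(t) for t in preps])
                conf[p, i, h] = scores[i] / scores.mean()
    return conf


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkResult:
    """Long-format benchmark table plus run metadata.

    ``table`` columns: method, subject, window_s, accuracy (percent,
    valid-trial based), itr, invalid_proportion, mean_decision_time_s.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def accuracy(self, method: str, window_s: float | None = None):
        t = self.table[self.table.method == method]
        if window_s is not None:
            t = t[np.isclose(t.window_s, window_s)]
        return t

    def mean_accuracy(self, method: str, window_s: float) -> float:
        return float(self.accuracy(method, window_s).accuracy.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby(["method", "window_s"], dropna=False)
                [["accuracy", "itr"]].mean().reset_index())


def _fold_indices(assign_row: np.ndarray, fold: int):
    return np.flatnonzero(assign_row != fold), np.flatnonzero(assign_row == fold)


def run_benchmark(dataset: Dataset, methods=ALL_METHODS, window_lengths=None,
                  cv: CVPlan = CVPlan(), n_donors: int = 4,
                  n_harmonics: int = 3, gaze_shift_s: float = 1.0,
                  itr_convention: str = "bits", tc_grid=None,
                  threshold_mode: str = "seconds",
                  segment_mode: str = "cumulative",
                  grid_mode: str = "greedy",
                  subjects=None) -> BenchmarkResult:
    """Cross-validated comparison of all decoding methods on one dataset.

    Fixed-window methods are scored at every window length; the adaptive
    decoder tunes its cut-off schedule on the training folds and is scored
    once per subject with its own decision times.  Deterministic given the
    dataset and the CV seed.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(
            f"unknown method(s) {sorted(unknown)}; valid: {list(ALL_METHODS)}")
    fs, K, M = dataset.fs, dataset.n_classes, dataset.n_samples
    if window_lengths is None:
        window_lengths = ad.WindowSchedule(max_s=M / fs).lengths()
    window_lengths = [float(d) for d in window_lengths]
    win_samples = [int(round(d * fs)) for d in window_lengths]
    ref_bank = build_reference_bank(dataset.stim, fs, M, n_harmonics)
    subjects = list(range(dataset.n_subjects)) if subjects is None else list(subjects)

    need_transfer = bool({"iist", "iist_at"} & set(methods))
    if need_transfer and dataset.n_subjects < 2:
        raise ValueError("transfer methods need at least two subjects")

    # reference preparations shared across subjects
    prep_ref = {n: [prepare_target(ref_bank.reference(i, n)) for i in range(K)]
                for n in set(win_samples)}

    # donor-side quantities are independent of the test subject's folds
    if need_transfer:
        msi_acc = {p: msi_self_accuracy(dataset, p, ref_bank)
                   for p in range(dataset.n_subjects)}
        confidences = _donor_confidences(dataset, ref_bank)
        selected = {}  # (p, i) -> trial indices above the confidence cut-off
        for p in range(dataset.n_subjects):
            for i in range(K):
                idx, _ = select_high_confidence(
                    dataset.data[p, i], i, ref_bank, fs, mode=threshold_mode,
                    confidences=confidences[p, i])
                selected[(p, i)] = idx

    fixed_methods = [m for m in methods if m != "iist_at"]
    rows = []
    meta = {"n_donors": n_donors, "n_harmonics": n_harmonics,
            "itr_convention": itr_convention, "threshold_mode": threshold_mode,
            "segment_mode": segment_mode, "grid_mode": grid_mode,
            "cv_seed": cv.seed, "window_lengths": window_lengths}

    for s in subjects:
        assign = cv.assignments(K, dataset.n_trials)
        # inter-subject templates: donors ranked by their own MSI accuracy
        inter = [None] * K
        if need_transfer and n_donors > 0:
            policy = select_donors(
                [p for p in range(dataset.n_subjects) if p != s],
                n_donors, msi_acc)
            for i in range(K):
                sel = {p: dataset.data[p, i][selected[(p, i)]]
                       for p in policy.P_set}
                inter[i], _ = inter_template(sel)

        # per-fold counters: stats[m][w][fold] = (correct, valid)
        stats = {m: {w: [[0, 0] for _ in range(cv.n_folds)]
                     for w in range(len(window_lengths))}
                 for m in fixed_methods}
        at_stats = [[0, 0] for _ in range(cv.n_folds)]  # correct, valid
        at_times, at_total = [], 0

        for f in range(cv.n_folds):
            train_by_class = [
                _fold_indices(assign[i], f)[0] for i in range(K)]
            test_by_class = [
                _fold_indices(assign[i], f)[1] for i in range(K)]
            intra = [intra_template(dataset.data[s, i][train_by_class[i]])
                     for i in range(K)]
            prep_intra = {n: [prepare_target(intra[i][:, :n]) for i in range(K)]
                          for n in set(win_samples)} \
                if {"itcca", "itmsi", "iist", "iist_at"} & set(methods) else None
            prep_inter = {n: [prepare_target(inter[i][:, :n])
                              if inter[i] is not None else None
                              for i in range(K)]
                          for n in set(win_samples)} \
                if {"iist", "iist_at"} & set(methods) else None
            if "mset" in methods:
                msets = [fit_mset_cca(
                    list(dataset.data[s, i][train_by_class[i]]))
                    for i in range(K)]
                prep_mset = {n: [prepare_target(m.reference_window(n))
                                 for m in msets] for n in set(win_samples)}

            def gamma_vector(scorer, n):
                S_in = np.array([scorer.msi(t) for t in prep_intra[n]])
                if prep_inter is not None and all(
                        t is not None for t in prep_inter[n]):
                    S_st = np.array([scorer.msi(t) for t in prep_inter[n]])
                    return S_in, S_in ** 2 + S_st ** 2
                return S_in, S_in ** 2

            def trial_trace(trial):
                gam = []
                for n in win_samples:
                    scorer = EpochScorer(trial[:, :n])
                    _, g = gamma_vector(scorer, n)
                    gam.append(g)
                gam = np.asarray(gam)
                ratios = gam / gam.mean(axis=1, keepdims=True)
                return ad.ScoreTrace(window_s=np.asarray(window_lengths),
                                     gamma=gam, ratios=ratios,
                                     joint=np.cumprod(ratios, axis=0))

            test_traces, test_labels = [], []
            for i in range(K):
                for h in test_by_class[i]:
                    trial = dataset.data[s, i, h]
                    for w, n in enumerate(win_samples):
                        scorer = EpochScorer(trial[:, :n])
                        if "msi" in methods:
                            sc = [scorer.msi(t) for t in prep_ref[n]]
                            stats["msi"][w][f][0] += int(np.argmax(sc) == i)
                            stats["msi"][w][f][1] += 1
                        if "cca" in methods:
                            sc = [scorer.cca(t) for t in prep_ref[n]]
                            stats["cca"][w][f][0] += int(np.argmax(sc) == i)
                            stats["cca"][w][f][1] += 1
                        if "itcca" in methods:
                            sc = [scorer.cca(t) for t in prep_intra[n]]
                            stats["itcca"][w][f][0] += int(np.argmax(sc) == i)
                            stats["itcca"][w][f][1] += 1
                        if "mset" in methods:
                            sc = [scorer.cca(t) for t in prep_mset[n]]
                            stats["mset"][w][f][0] += int(np.argmax(sc) == i)
                            stats["mset"][w][f][1] += 1
                        if {"itmsi", "iist", "iist_at"} & set(methods):
                            S_in, gam = gamma_vector(scorer, n)
                            if "itmsi" in methods:
                                stats["itmsi"][w][f][0] += int(np.argmax(S_in) == i)
                                stats["itmsi"][w][f][1] += 1
                            if "iist" in methods:
                                stats["iist"][w][f][0] += int(np.argmax(gam) == i)
                                stats["iist"][w][f][1] += 1
                    if "iist_at" in methods:
                        test_traces.append(trial_trace(trial))
                        test_labels.append(i)

            if "iist_at" in methods:
                train_traces, train_labels = [], []
                for i in range(K):
                    for h in train_by_class[i]:
                        train_traces.append(trial_trace(dataset.data[s, i, h]))
                        train_labels.append(i)
                sched, _ = ad.grid_search_threshold(
                    train_traces, train_labels, grid=tc_grid, mode=grid_mode)
                for trace, label in zip(test_traces, test_labels):
                    dec = ad.apply_threshold(trace, sched, keep_trace=False)
                    at_total += 1
                    if dec.valid:
                        at_stats[f][1] += 1
                        at_stats[f][0] += int(dec.predicted_class == label)
                        at_times.append(dec.decision_time_s)

        for m in fixed_methods:
            for w, d in enumerate(window_lengths):
                corr = [stats[m][w][f][0] for f in range(cv.n_folds)]
                val = [stats[m][w][f][1] for f in range(cv.n_folds)]
                acc = cv_accuracy(corr, val)
                rows.append({
                    "method": m, "subject": s, "window_s": d,
                    "accuracy": acc,
                    "itr": itr(acc / 100.0, K, d + gaze_shift_s,
                               convention=itr_convention),
                    "invalid_proportion": 0.0,
                    "mean_decision_time_s": d,
                })
        if "iist_at" in methods:
            corr = [at_stats[f][0] for f in range(cv.n_folds)]
            val = [at_stats[f][1] for f in range(cv.n_folds)]
            acc = cv_accuracy(corr, val)
            mean_time = float(np.mean(at_times)) if at_times else float(window_lengths[-1])
            rows.append({
                "method": "iist_at", "subject": s, "window_s": np.nan,
                "accuracy": acc,
                "itr": itr(acc / 100.0, K, mean_time + gaze_shift_s,
                           convention=itr_convention),
                "invalid_proportion": 1.0 - sum(val) / at_total,
                "mean_decision_time_s": mean_time,
            })

    return BenchmarkResult(table=pd.DataFrame(rows), meta=meta)
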