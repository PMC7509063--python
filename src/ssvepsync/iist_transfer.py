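"""Inter- and intra-subject template transfer for the synchronization index.

The intra-subject template for class ``i`` is the element-wise mean of the
subject's own training trials.  The inter-subject template averages
high-confidence trials donated by other subjects: a donor trial's confidence
is its synchronization index at the labeled frequency divided by its mean
index over all K frequencies, and only trials whose confidence exceeds a
window-length-dependent cut-off are transferred.  Per-donor means are
averaged across donors (two-stage average), so donors with many selected
trials do not outweigh donors with few.

Scoring a test window combines both templates through the sum of squares
``γ_i = S_i² + (S*_i)²``; with no inter-subject template available the score
degenerates to intra-only (``γ_i = S_i²``), which ranks classes identically
to the intra-template-only synchronization index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .msi_core import (
    DegenerateScoreError,
    EpochArray,
    EpochScorer,
    ScoreVector,
    _as_array,
    prepare_target,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateBank",
    "TransferPolicy",
    "intra_template",
    "trial_confidence",
    "confidence_threshold",
    "select_high_confidence",
    "inter_template",
    "classify_iist",
    "select_donors",
]


# ---------------------------------------------------------------------------
# templates


def intra_template(trials) -> np.ndarray:
    """Element-wise mean of one subject's training trials for one class.

    The returned template is *not* normalized here; it is normalized when it
    enters the synchronization index (slicing a window first, then
    normalizing, keeps per-window statistics exact).
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim == 2:
        trials = trials[None]
    if trials.shape[0] == 0:
        raise ValueError("cannot average an empty trial set")
    return trials.mean(axis=0)


def trial_confidence(trial, label: int, bank, n_samples: int | None = None) -> float:
    """Confidence of a labeled trial against the sine–cosine reference bank.

    ``C = S_label / mean_k(S_k)``; a value well above 1 means the labeled
    frequency clearly dominates the trial's synchronization spectrum.
    """
    Xa = _as_array(trial)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    scorer = EpochScorer(Xa[:, :M])
    scores = np.array([
        scorer.msi(prepare_target(bank.reference(i, M)))
        for i in range(bank.n_classes)
    ])
    mean = float(scores.mean())
    if not np.isfinite(mean) or mean <= 0:
        raise DegenerateScoreError("mean synchronization score is zero")
    return float(scores[label] / mean)


def confidence_threshold(n_samples: int, fs: float, mode: str = "seconds") -> float:
    """Confidence cut-off as a function of the trial window.

    ``mode='seconds'`` (default): ``1 + ln(n_samples / fs)`` — the cut-off
    grows with the window length in seconds (≈2.386 for 4 s windows).
    ``mode='product'``: ``1 + ln(n_samples · fs)``, the literal product
    reading, provided for sensitivity analysis (it exceeds any attainable
    confidence at realistic sample counts).
    """
    if mode == "seconds":
        return 1.0 + np.log(n_samples / fs)
    if mode == "product":
        return 1.0 + np.log(n_samples * fs)
    raise ValueError(f"unknown threshold mode {mode!r}")


def select_high_confidence(trials, label: int, bank, fs: float,
                           mode: str = "seconds", confidences=None):
    """Select the donor trials whose confidence exceeds the cut-off.

    Returns ``(indices, confidences)`` where ``indices`` are trial indices in
    iteration order (set semantics: each trial appears at most once).
    Confidence is evaluated on full-length trials.  An empty selection is
    allowed and logged.
    """
    trials = np.asarray(trials, dtype=float)
    n_t = trials.shape[-1]
    cut = confidence_threshold(n_t, fs, mode=mode)
    if confidences is None:
        confidences = np.array([
            trial_confidence(trials[h], label, bank) for h in range(len(trials))
        ])
    else:
        confidences = np.asarray(confidences, dtype=float)
    indices = [h for h in range(len(trials)) if confidences[h] > cut]
    if not indices:
        logger.info("no high-confidence trials for class %d (cut-off %.3f)",
                    label, cut)
    return indices, confidences


def inter_template(selections: dict):
    """Two-stage average of the selected donor trials for one class.

    ``selections`` maps donor id → array of selected trials (possibly empty).
    Donors with an empty selection are skipped and do not enter the
    denominator (a zero matrix would bias the template toward silence).
    Returns ``(template or None, contributing_donors)``.
    """
    donor_means, contributing = [], []
    for donor, trials in selections.items():
        trials = np.asarray(trials, dtype=float)
        if trials.size == 0:
            logger.info("donor %s contributes no trials; dropped from average",
                        donor)
            continue
        if trials.ndim == 2:
            trials = trials[None]
        donor_means.append(trials.mean(axis=0))
        contributing.append(donor)
    if not donor_means:
        return None, []
    return np.mean(donor_means, axis=0), contributing


# ---------------------------------------------------------------------------
# bank and policy


@dataclass
class TemplateBank:
    """Per-class intra- and inter-subject templates plus their provenance."""

    intra: list  # K templates, each N_c x N_t
    inter: list  # K entries, each N_c x N_t or None
    fs: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.intra)

    def has_inter(self, i: int) -> bool:
        return self.inter[i] is not None


@dataclass
class TransferPolicy:
    """Donor selection: candidates ranked by their own MSI accuracy."""

    donor_pool: list
    P_set: list
    ranking_scores: dict

    @property
    def size(self) -> int:
        return len(self.P_set)


def select_donors(candidates, n_donors: int, accuracies: dict) -> TransferPolicy:
    """Top-``n_donors`` candidates in descending order of their MSI accuracy
    (computed on each candidate's own data with sine–cosine references);
    ties break toward the lower subject index.  ``n_donors`` larger than the
    pool is capped with a warning; ``n_donors = 0`` yields the intra-only
    (IT-MSI) mode."""
    candidates = list(candidates)
    if n_donors > len(candidates):
        logger.warning("requested %d donors but only %d candidates; capping",
                       n_donors, len(candidates))
        n_donors = len(candidates)
    ranked = sorted(candidates, key=lambda p: (-accuracies[p], p))
    return TransferPolicy(donor_pool=candidates, P_set=ranked[:n_donors],
                          ranking_scores=dict(accuracies))


# ---------------------------------------------------------------------------
# scoring


def iist_scores(epoch, bank: TemplateBank, n_samples: int | None = None):
    """Per-class intra index S, inter index S*, and combined γ = S² + S*²."""
    Xa = _as_array(epoch)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    scorer = EpochScorer(Xa[:, :M])
    K = bank.n_classes
    S = np.empty(K)
    S_star = np.full(K, np.nan)
    for i in range(K):
        S[i] = scorer.msi(prepare_target(np.asarray(bank.intra[i])[:, :M]))
        if bank.has_inter(i):
            S_star[i] = scorer.msi(prepare_target(np.asarray(bank.inter[i])[:, :M]))
    gamma = np.where(np.isnan(S_star), S ** 2, S ** 2 + np.nan_to_num(S_star) ** 2)
    return S, S_star, gamma


def classify_iist(epoch, bank: TemplateBank, n_samples: int | None = None):
    """Classify by the combined template score ``γ_i = S_i² + (S*_i)²``.

    Classes lacking an inter-subject template fall back to ``γ_i = S_i²``
    (warned once per call when the whole bank lacks inter templates, which
    is the intra-only IT-MSI mode).  Ties break toward the lowest index.
    """
    if all(not bank.has_inter(i) for i in range(bank.n_classes)):
        logger.debug("no inter-subject templates: scoring intra-only (IT-MSI)")
    _, _, gamma = iist_scores(epoch, bank, n_samples=n_samples)
    fs = bank.fs or (epoch.fs if isinstance(epoch, EpochArray) else None)
    M = (_as_array(epoch).shape[1] if n_samples is None else int(n_samples))
    sv = ScoreVector(gamma, kind="gamma",
                     window_length_s=M / fs if fs else None)
    return sv.argmax(), sv
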