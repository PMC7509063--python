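"""Canonical-correlation contrast methods: CCA, Multi-set CCA, IT-CCA.

Standard CCA scores an epoch by the largest canonical correlation against a
sine–cosine reference bank.  Multi-set CCA jointly spatially filters the
training trials of one class (one filter per trial, maximizing the summed
pairwise inter-trial correlation under a mean-power constraint) and stacks
the filtered trials into an optimized reference.  IT-CCA replaces the
reference with the trial-averaged individual template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .msi_core import (
    EpochArray,
    EpochScorer,
    ScoreVector,
    _as_array,
    _channel_normalize,
    _inv_sqrt_psd,
    prepare_target,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CanonicalResult",
    "MsetFilters",
    "cca_max_correlation",
    "classify_cca",
    "fit_mset_cca",
    "classify_mset",
    "classify_itcca",
]


@dataclass
class CanonicalResult:
    """Largest canonical correlation and its projection vectors."""

    rho_max: float
    w: np.ndarray  # spatial weights on X (length N1)
    v: np.ndarray  # weights on the reference Y (length N2)


def cca_max_correlation(X, Y, *, normalize_inputs: bool = True) -> CanonicalResult:
    """Maximum canonical correlation between two multivariate signals.

    Solved through the singular values of the whitened cross-covariance
    ``C11^{-1/2} C12 C22^{-1/2}``; the returned ``rho_max`` is clipped to
    [0, 1] against floating-point overshoot.
    """
    Xa, Ya = _as_array(X), _as_array(Y)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    if Ya.ndim == 1:
        Ya = Ya[None, :]
    if Xa.shape[1] != Ya.shape[1]:
        raise ValueError("sample-count mismatch between X and Y")
    if normalize_inputs:
        Xa, Ya = _channel_normalize(Xa), _channel_normalize(Ya)
    M = Xa.shape[1]
    C11 = Xa @ Xa.T / M
    C22 = Ya @ Ya.T / M
    C12 = Xa @ Ya.T / M
    U11, _ = _inv_sqrt_psd(C11)
    U22, _ = _inv_sqrt_psd(C22)
    K = U11 @ C12 @ U22
    u, s, vt = np.linalg.svd(K)
    rho = float(min(max(s[0], 0.0), 1.0))
    return CanonicalResult(rho_max=rho, w=U11 @ u[:, 0], v=U22 @ vt[0])


def _classify_by_cca(epoch, targets, fs, n_samples=None):
    Xa = _as_array(epoch)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    scorer = EpochScorer(Xa[:, :M])
    scores = np.array([scorer.cca(t) for t in targets])
    sv = ScoreVector(scores, kind="rho",
                     window_length_s=M / fs if fs else None)
    return sv.argmax(), sv


def classify_cca(epoch, bank, n_samples: int | None = None):
    """Argmax-of-ρ classification against a sine–cosine reference bank.

    Ties break toward the lowest class index, matching the MSI classifier.
    """
    Xa = _as_array(epoch)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    targets = [prepare_target(bank.reference(i, M)) for i in range(bank.n_classes)]
    fs = getattr(bank, "fs", None)
    return _classify_by_cca(Xa, targets, fs, n_samples=M)


# ---------------------------------------------------------------------------
# Multi-set CCA


@dataclass
class MsetFilters:
    """Per-trial spatial filters and the stacked optimized reference."""

    filters: list  # n vectors of length N_c (None for the single-trial fallback)
    reference: np.ndarray  # Z_n: n x N_t (or N_c x N_t fallback)
    objective: float = float("nan")

    def reference_window(self, n_samples: int) -> np.ndarray:
        return self.reference[:, : int(n_samples)]


def fit_mset_cca(trials, ridge_scale: float = 1e-8) -> MsetFilters:
    """Fit joint spatial filters over the training trials of one class.

    Solves the generalized eigenproblem ``(R - S) w = ρ S w`` where ``R``
    holds all pairwise trial cross-products and ``S`` its block diagonal,
    keeping only the top eigenvector; the stacked weight vector is rescaled
    to satisfy the mean-power constraint ``(1/n) Σ w_hᵀ χ_h χ_hᵀ w_h = 1``
    and split into one filter per trial.  ``S`` receives a small ridge
    before inversion because block-diagonal trial covariances are often
    ill-conditioned for short windows.
    """
    trials = [np.asarray(x, dtype=float) for x in trials]
    if len(trials) == 0:
        raise ValueError("need at least one training trial")
    shapes = {x.shape for x in trials}
    if len(shapes) != 1:
        raise ValueError("all trials must share the same (channels, samples) shape")
    n = len(trials)
    if n == 1:
        logger.warning("single training trial: falling back to the trial itself "
                       "as the optimized reference")
        return MsetFilters(filters=[None], reference=trials[0].copy())

    n_c, n_t = trials[0].shape
    D = np.vstack(trials)  # (n*N_c) x N_t
    R = D @ D.T
    S = np.zeros_like(R)
    for h in range(n):
        sl = slice(h * n_c, (h + 1) * n_c)
        S[sl, sl] = R[sl, sl]
    ridge = ridge_scale * np.trace(S) / S.shape[0]
    A = (R - S)
    B = S + ridge * np.eye(S.shape[0])
    vals, vecs = scipy.linalg.eigh((A + A.T) / 2.0, (B + B.T) / 2.0)
    w = vecs[:, -1]
    # rescale to the exact (ridge-free) constraint (1/n) Σ w_hᵀχχᵀw_h = 1
    c = float(w @ S @ w)
    if c <= 0:
        raise ValueError("degenerate trial covariances in Multi-set CCA fit")
    w = w * np.sqrt(n / c)
    filters = [w[h * n_c:(h + 1) * n_c].copy() for h in range(n)]
    Z = np.vstack([filters[h] @ trials[h] for h in range(n)])
    obj = float(w @ (R - S) @ w)
    return MsetFilters(filters=filters, reference=Z, objective=obj)


def mset_objective(filters, trials) -> float:
    """Eq-style objective: summed pairwise cross-correlation of filtered trials."""
    z = [np.asarray(w) @ np.asarray(x, float) for w, x in zip(filters, trials)]
    total = 0.0
    for a in range(len(z)):
        for b in range(len(z)):
            if a != b:
                total += float(z[a] @ z[b])
    return total


def classify_mset(epoch, mset_by_class, n_samples: int | None = None, fs=None):
    """Classify via the maximum canonical correlation against each class's
    Multi-set-CCA optimized reference (fitted on training folds only)."""
    Xa = _as_array(epoch)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    targets = [prepare_target(m.reference_window(M)) for m in mset_by_class]
    if fs is None and isinstance(epoch, EpochArray):
        fs = epoch.fs
    return _classify_by_cca(Xa, targets, fs, n_samples=M)


def classify_itcca(epoch, templates, n_samples: int | None = None, fs=None):
    """Individual-template CCA: ρ against each class's trial-averaged template.

    ``templates`` is a sequence of ``N_c x N_t`` class templates built from
    training folds only; the score is the first canonical correlation.
    """
    Xa = _as_array(epoch)
    M = Xa.shape[1] if n_samples is None else int(n_samples)
    targets = [prepare_target(np.asarray(T, float)[:, :M]) for T in templates]
    if fs is None and isinstance(epoch, EpochArray):
        fs = epoch.fs
    return _classify_by_cca(Xa, targets, fs, n_samples=M)
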