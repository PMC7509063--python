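"""Dynamic-window decoding with an adaptive stopping threshold.

A trial is examined on a growing sequence of cumulative windows (initial
window ITW, increments TWI).  Each window yields combined template scores
γ, converted to probability ratios ``r_i = γ_i / mean_k γ_k`` (mean exactly
1 per window); ratios are multiplied window-by-window into a joint
probability ``J_i``.  The decoder stops at the first window where
``max_i J_i`` reaches the duration-dependent cut-off ``T_c(d)`` and outputs
``argmax_i J_i``; a trial whose joint probability never reaches the cut-off
before the data run out is an *invalid trial* (attention lapse / weak
signal) and yields no decision.

The cut-off schedule is tuned on training trials over a per-duration
candidate grid; candidates whose invalid-trial proportion exceeds 20% are
discarded, and among survivors the schedule with maximum training accuracy
wins (ties: shorter mean decision time, then smaller cut-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iist_transfer import TemplateBank, iist_scores
from .msi_core import DegenerateScoreError, _as_array

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSchedule",
    "ThresholdSchedule",
    "ScoreTrace",
    "Decision",
    "DEFAULT_TC_GRID",
    "probability_ratio",
    "score_trace",
    "apply_threshold",
    "decode_trial",
    "grid_search_threshold",
]


@dataclass(frozen=True)
class WindowSchedule:
    """Cumulative analysis windows: [0, itw + m·twi], clamped to max_s."""

    itw_s: float = 0.5
    twi_s: float = 0.5
    max_s: float = 4.0

    def __post_init__(self):
        if not (0 < self.itw_s <= self.max_s):
            raise ValueError("need 0 < itw_s <= max_s")
        if self.twi_s <= 0:
            raise ValueError("twi_s must be positive")

    def lengths(self) -> list:
        """Window end times in seconds; the last window is the full trial."""
        out, d = [], self.itw_s
        while d < self.max_s - 1e-9:
            out.append(round(d, 9))
            d += self.twi_s
        out.append(self.max_s)
        return out


# grid of cut-off candidates per decision-duration bucket
DEFAULT_TC_GRID = {
    (0.0, 1.0): np.round(np.arange(1.0, 2.0 + 1e-9, 0.05), 10),
    (1.0, 2.0): np.round(np.arange(1.0, 4.0 + 1e-9, 0.1), 10),
    (2.0, 3.0): np.round(np.arange(3.0, 8.0 + 1e-9, 0.2), 10),
    (3.0, 4.0): np.round(np.arange(3.0, 16.0 + 1e-9, 0.4), 10),
}


@dataclass(frozen=True)
class ThresholdSchedule:
    """Mapping from current window length d to the cut-off T_c(d).

    Either bucketed (one value per duration bucket, the default shape the
    candidate grid implies) or constant.
    """

    buckets: tuple  # ((lo, hi), ...) half-open (lo, hi]
    values: tuple

    def __post_init__(self):
        if len(self.buckets) != len(self.values):
            raise ValueError("one value per bucket required")
        if any(v < 1.0 for v in self.values):
            raise ValueError("cut-off values must be >= 1")

    @classmethod
    def bucketed(cls, values, edges=(0.0, 1.0, 2.0, 3.0, 4.0)) -> "ThresholdSchedule":
        buckets = tuple((edges[i], edges[i + 1]) for i in range(len(edges) - 1))
        return cls(buckets=buckets, values=tuple(float(v) for v in values))

    @classmethod
    def constant(cls, tc: float, max_s: float = 4.0) -> "ThresholdSchedule":
        return cls(buckets=((0.0, max_s),), values=(float(tc),))

    def threshold_for(self, d: float) -> float:
        for (lo, hi), v in zip(self.buckets, self.values):
            if lo < d <= hi + 1e-9:
                return v
        raise KeyError(f"no threshold configured for window length {d} s")


@dataclass
class ScoreTrace:
    """Per-window γ, probability ratios and running joint probability."""

    window_s: np.ndarray        # (W,)
    gamma: np.ndarray           # (W, K)
    ratios: np.ndarray          # (W, K)
    joint: np.ndarray           # (W, K) cumulative products of ratios


@dataclass
class Decision:
    """Outcome of decoding one trial.

    ``valid=False`` iff the data were exhausted with ``max J < T_c`` — then
    ``predicted_class`` is None.
    """

    predicted_class: int | None
    valid: bool
    decision_time_s: float
    n_windows_used: int
    trace: ScoreTrace | None = None


def probability_ratio(gamma) -> np.ndarray:
    """``r_i = γ_i / mean_k γ_k``; the per-class mean of r is exactly 1."""
    gamma = np.asarray(gamma, dtype=float)
    mean = gamma.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise DegenerateScoreError("all-zero (or non-finite) score vector")
    return gamma / mean


def score_trace(trial, bank: TemplateBank, fs: float,
                schedule: WindowSchedule = WindowSchedule(),
                segment_mode: str = "cumulative") -> ScoreTrace:
    """Score every dynamic window of a trial (threshold-independent).

    ``segment_mode='cumulative'`` (default) scores the cumulative prefix at
    each step — the previous segment with the increment appended;
    ``'increment'`` scores only the newly appended segment, provided for
    sensitivity analysis.  Templates are built at full length and sliced to
    the window.
    """
    if segment_mode not in ("cumulative", "increment"):
        raise ValueError("segment_mode must be 'cumulative' or 'increment'")
    Xa = _as_array(trial)
    n_total = Xa.shape[1]
    lengths = [d for d in schedule.lengths() if round(d * fs) <= n_total]
    if not lengths:
        raise ValueError("trial shorter than the initial window")
    gammas, ratios = [], []
    prev = 0
    for d in lengths:
        n = int(round(d * fs))
        if segment_mode == "cumulative":
            seg = Xa[:, :n]
        else:
            seg = Xa[:, prev:n]
        prev = n
        _, _, gamma = iist_scores(seg, bank)
        gammas.append(gamma)
        ratios.append(probability_ratio(gamma))
    ratios = np.asarray(ratios)
    return ScoreTrace(window_s=np.asarray(lengths), gamma=np.asarray(gammas),
                      ratios=ratios, joint=np.cumprod(ratios, axis=0))


def apply_threshold(trace: ScoreTrace, thresholds: ThresholdSchedule,
                    keep_trace: bool = True) -> Decision:
    """Run the stopping rule over a pre-computed score trace."""
    for m, d in enumerate(trace.window_s):
        tc = thresholds.threshold_for(float(d))
        J = trace.joint[m]
        if J.max() >= tc:
            return Decision(predicted_class=int(np.argmax(J)), valid=True,
                            decision_time_s=float(d), n_windows_used=m + 1,
                            trace=trace if keep_trace else None)
    return Decision(predicted_class=None, valid=False,
                    decision_time_s=float(trace.window_s[-1]),
                    n_windows_used=len(trace.window_s),
                    trace=trace if keep_trace else None)


def decode_trial(trial, bank: TemplateBank, fs: float,
                 windows: WindowSchedule = WindowSchedule(),
                 thresholds: ThresholdSchedule = ThresholdSchedule.bucketed((1.5, 1.5, 3.0, 3.0)),
                 segment_mode: str = "cumulative") -> Decision:
    """Decode one trial with the dynamic-window adaptive-threshold rule."""
    trace = score_trace(trial, bank, fs, schedule=windows,
                        segment_mode=segment_mode)
    return apply_threshold(trace, thresholds)


# ---------------------------------------------------------------------------
# threshold tuning


def _bucket_index(buckets, d: float) -> int:
    for b, (lo, hi) in enumerate(buckets):
        if lo < d <= hi + 1e-9:
            return b
    raise KeyError(f"window length {d} outside all buckets")


def _evaluate_schedule(max_joint, arg_joint, labels, tc_per_window, window_s):
    """Vectorized stop/decide over precomputed per-window max/argmax."""
    stop = max_joint >= tc_per_window[None, :]
    any_stop = stop.any(axis=1)
    first = np.where(any_stop, stop.argmax(axis=1), max_joint.shape[1] - 1)
    pred = arg_joint[np.arange(len(labels)), first]
    valid = any_stop
    correct = valid & (pred == labels)
    n_valid = int(valid.sum())
    acc = float(correct.sum() / n_valid) if n_valid else 0.0
    invalid_prop = 1.0 - n_valid / len(labels)
    times = np.where(valid, window_s[first], window_s[-1])
    mean_time = float(times[valid].mean()) if n_valid else float(window_s[-1])
    return acc, invalid_prop, mean_time


def grid_search_threshold(traces, labels, grid=None, mode: str = "greedy",
                          max_invalid: float = 0.2):
    """Tune the cut-off schedule on training-trial score traces.

    Candidates whose invalid-trial proportion is *strictly above*
    ``max_invalid`` are discarded; invalid trials are excluded from the
    accuracy denominator.  ``mode='greedy'`` searches one bucket at a time
    in order of increasing duration, holding later (still-unset) buckets at
    their grid maximum so that trials not yet stopped keep accumulating
    evidence instead of being forced to decide early; ``mode='product'``
    scores the full Cartesian grid.  Returns ``(ThresholdSchedule, log)``
    where ``log`` is a DataFrame of every evaluated candidate.
    """
    if grid is None:
        grid = DEFAULT_TC_GRID
    buckets = tuple(sorted(grid.keys()))
    labels = np.asarray(labels, dtype=int)
    window_s = traces[0].window_s
    max_joint = np.stack([t.joint.max(axis=1) for t in traces])
    arg_joint = np.stack([t.joint.argmax(axis=1) for t in traces])
    w_bucket = np.array([_bucket_index(buckets, float(d)) for d in window_s])

    def tc_vector(values) -> np.ndarray:
        return np.array([values[b] for b in w_bucket], dtype=float)

    rows = []

    def score_candidate(values, stage):
        acc, inv, mt = _evaluate_schedule(max_joint, arg_joint, labels,
                                          tc_vector(values), window_s)
        rows.append({"stage": stage, **{f"tc_{b}": values[b] for b in range(len(buckets))},
                     "accuracy": acc, "invalid_proportion": inv,
                     "mean_decision_time_s": mt,
                     "discarded": inv > max_invalid})
        return acc, inv, mt

    maxes = [float(grid[b][-1]) for b in buckets]

    if mode == "greedy":
        chosen = list(maxes)
        for b, bucket in enumerate(buckets):
            best = None
            for tc in grid[bucket]:
                cand = list(chosen)
                cand[b] = float(tc)
                acc, inv, mt = score_candidate(cand, stage=f"bucket{b}")
                if inv > max_invalid:
                    continue
                key = (-acc, mt, tc)
                if best is None or key < best[0]:
                    best = (key, float(tc))
            if best is None:
                fallback = float(grid[bucket][-1])
                logger.warning(
                    "all cut-off candidates for bucket %s exceed the %.0f%% "
                    "invalid limit; falling back to the largest value %.2f",
                    bucket, 100 * max_invalid, fallback)
                chosen[b] = fallback
            else:
                chosen[b] = best[1]
        values = chosen
    elif mode == "product":
        import itertools

        best = None
        fallback_best = None
        for combo in itertools.product(*(grid[b] for b in buckets)):
            cand = [float(c) for c in combo]
            acc, inv, mt = score_candidate(cand, stage="product")
            fb_key = (-min(c for c in cand),)
            if fallback_best is None or fb_key < fallback_best[0]:
                fallback_best = (fb_key, cand)
            if inv > max_invalid:
                continue
            key = (-acc, mt, tuple(cand))
            if best is None or key < best[0]:
                best = (key, cand)
        if best is None:
            logger.warning("every candidate schedule exceeds the invalid limit; "
                           "falling back to the largest-threshold candidate")
            values = [float(grid[b][-1]) for b in buckets]
        else:
            values = best[1]
    else:
        raise ValueError("mode must be 'greedy' or 'product'")

    sched = ThresholdSchedule(buckets=buckets,
                              values=tuple(float(v) for v in values))
    log = pd.DataFrame(rows)
    return sched, log
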