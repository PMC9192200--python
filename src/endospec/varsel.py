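"""Forward interval-PLS (iPLS) variable selection.

Variables are grouped into contiguous windows (width 1 for biochemical
parameters, 10 for spectra — matching the effective spectral resolution)
and a greedy forward loop grows the selected set one window at a time.

At each step every unaccepted window is scored by leave-one-out CV of a
PLS-DA model on (accepted + candidate) columns, yielding the pair
(LOO RMSE of the indicator predictions, misclassification count).
Candidates are ranked by RMSE (then miss count, then interval index) —
the continuous criterion; an integer error count is too coarse to rank
candidates at n ~ 71 and can trap the greedy loop on a plateau where no
single window lowers the count even though one clearly improves the
fit.  The ranked-best candidate is accepted when it strictly lowers the
misclassification count, or lowers the cross-validated RMSE by at least
a relative margin (``min_improvement``, default 1%).  The margin is
essential because the acceptance test is a minimum over up to ~150
candidates, and the minimum of that many near-zero chance fluctuations
is almost surely a small spurious improvement (~0.1%) — without a
margin, forward selection over many windows keeps absorbing noise.  The
loop stops as soon as the best candidate improves neither term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .plsda import DEFAULT_CLASS_ORDER, LOOFoldCache, encode_classes, loo_scores


@dataclass(frozen=True)
class IPLSResult:
    width: int
    accepted: tuple[int, ...]          # interval indices, acceptance order
    retained: tuple[int, ...]          # sorted retained column indices
    trace: tuple[tuple[int, float], ...]  # (misclass, rmsecv) after each acceptance
    stopped: str                       # 'no_improvement' | 'max_intervals' | 'all_accepted'


def make_intervals(m: int, w: int) -> list[np.ndarray]:
    """Contiguous half-open windows [0,w), [w,2w), ...; last may be shorter."""
    if w < 1:
        raise ValueError(f"interval width must be >= 1, got {w}")
    if w > m:
        raise ValueError(f"interval width {w} exceeds variable count {m}")
    return [np.arange(s, min(s + w, m)) for s in range(0, m, w)]


def _score(X, Y, cols, A, scaler_kind, true_idx):
    """(misclassifications, RMSE) of LOO indicator predictions on columns."""
    Xsub = X[:, cols]
    a_eff = max(1, min(A, Xsub.shape[1], Xsub.shape[0] - 2))
    scores = loo_scores(Xsub, Y, a_eff, scaler_kind)
    miss = int(np.sum(np.argmax(scores, axis=1) != true_idx))
    rmse = float(np.sqrt(np.mean((scores - Y) ** 2)))
    return miss, rmse


def ipls_forward(
    X: np.ndarray,
    labels: Sequence[str],
    w: int,
    A: int,
    scaler_kind: str = "autoscale",
    max_intervals: int | None = None,
    min_improvement: float = 0.01,
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> IPLSResult:
    """Greedy forward interval selection.

    ``A`` is the LV count of the final model; during selection it is capped
    by the current column count (and the LOO training-set rank).
    ``min_improvement`` is the relative LOO-RMSE margin a candidate must
    beat when the misclassification count is unchanged.
    """
    X = np.asarray(X, dtype=float)
    enc = encode_classes(labels, class_order)
    true_idx = np.argmax(enc.Y, axis=1)
    intervals = make_intervals(X.shape[1], w)
    cache = LOOFoldCache(X, enc.Y, scaler_kind)
    remaining = list(range(len(intervals)))
    accepted: list[int] = []
    trace: list[tuple[int, float]] = []
    best_miss, best_rmse = np.inf, np.inf
    stopped = "all_accepted"
    while remaining:
        if max_intervals is not None and len(accepted) >= max_intervals:
            stopped = "max_intervals"
            break
        acc_cols = (
            np.concatenate([intervals[i] for i in accepted]) if accepted else
            np.empty(0, dtype=int)
        )
        col_sets = [np.concatenate([acc_cols, intervals[i]]) for i in remaining]
        scores = cache.scores_for_columns(col_sets, A)
        candidates = []
        for k, idx in enumerate(remaining):
            miss = int(np.sum(np.argmax(scores[k], axis=1) != true_idx))
            rmse = float(np.sqrt(np.mean((scores[k] - enc.Y) ** 2)))
            candidates.append((rmse, miss, idx))
        rmse, miss, idx = min(candidates)
        improves = miss < best_miss or rmse < best_rmse * (1.0 - min_improvement)
        if not improves:
            stopped = "no_improvement"
            break
        accepted.append(idx)
        remaining.remove(idx)
        best_miss = min(best_miss, miss)
        best_rmse = rmse
        trace.append((miss, rmse))
    retained = (
        np.sort(np.concatenate([intervals[i] for i in accepted]))
        if accepted else np.empty(0, dtype=int)
    )
    return IPLSResult(
        width=w,
        accepted=tuple(accepted),
        retained=tuple(int(c) for c in retained),
        trace=tuple(trace),
        stopped=stopped,
    )
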