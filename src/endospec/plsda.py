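"""PLS-DA: SIMPLS fitting, prediction, VIP scores, leave-one-out CV.

The classifier regresses a one-hot class-indicator matrix Y (columns in
the fixed order E, NE, C) on the data block X via partial least squares,
which maximizes covariance between X and Y in a small number of latent
variables (LVs).  Class assignment is the argmax over predicted indicator
columns, ties broken toward the lowest-index class in the declared order.

The SIMPLS algorithm (de Jong 1993) is used throughout; it is
deterministic and, at full rank, its predictions coincide with the
multivariate least-squares fit.  A NIPALS implementation is provided as an
independent cross-check (identical to SIMPLS for a single response column
and at full rank).

All leave-one-out machinery is vectorised over folds: the n deflated
training sets are stacked into a (n, n-1, m) tensor and SIMPLS runs on all
folds at once, with centering/autoscaling refit inside each fold so no
held-out information leaks into the pretreatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .preprocess import ScalerState, apply_scaler, fit_scaler

DEFAULT_CLASS_ORDER = ("E", "NE", "C")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class ClassEncoding:
    classes: tuple[str, ...]
    Y: np.ndarray  # n x g one-hot

    @property
    def labels(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[np.argmax(self.Y, axis=1)]


def encode_classes(
    labels: Sequence[str], class_order: Sequence[str] = DEFAULT_CLASS_ORDER
) -> ClassEncoding:
    """One-hot indicator matrix with column order fixed by declaration."""
    labels = list(labels)
    if not labels:
        raise EncodingError("no labels supplied")
    order = tuple(class_order)
    index = {c: i for i, c in enumerate(order)}
    unknown = sorted({l for l in labels if l not in index})
    if unknown:
        raise EncodingError(f"labels not in class order {order}: {unknown}")
    Y = np.zeros((len(labels), len(order)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return ClassEncoding(order, Y)


# ---------------------------------------------------------------------------
# SIMPLS core (batched over leading axis)
# ---------------------------------------------------------------------------


def _simpls_batch(X: np.ndarray, Y: np.ndarray, A: int):
    """SIMPLS on pre-centred/scaled stacks X (B,n,m), Y (B,n,g).

    Returns weights R (B,m,A), Y-loadings Q (B,g,A), X-loadings P (B,m,A)
    and orthonormal scores T (B,n,A).  Regression coefficients for a model
    with ``a`` LVs are R[:, :, :a] @ Q[:, :, :a]^T; equivalently the
    prediction of a row x is sum_a (x . r_a) q_a.  Components beyond the
    rank of X come out as zero vectors and contribute nothing.
    """
    B, n, m = X.shape
    g = Y.shape[2]
    Xt = X.transpose(0, 2, 1)
    S = np.matmul(Xt, Y)                                # (B, m, g)
    dtype = S.dtype
    tol = float(np.finfo(dtype).eps) ** 0.75
    R = np.zeros((B, m, A), dtype=dtype)
    P = np.zeros((B, m, A), dtype=dtype)
    Q = np.zeros((B, g, A), dtype=dtype)
    T = np.zeros((B, n, A), dtype=dtype)
    V = np.zeros((B, m, A), dtype=dtype)
    for a in range(A):
        StS = np.matmul(S.transpose(0, 2, 1), S)        # (B, g, g)
        _, evecs = np.linalg.eigh(StS)
        q = evecs[..., -1:]                             # dominant right sv of S
        r = np.matmul(S, q)                             # (B, m, 1)
        t = np.matmul(X, r)                             # (B, n, 1)
        t = t - t.mean(axis=1, keepdims=True)
        normt = np.linalg.norm(t, axis=1, keepdims=True)
        dead = normt < tol
        safe = np.where(dead, 1.0, normt)
        t = np.where(dead, 0.0, t / safe)
        r = np.where(dead, 0.0, r / safe)
        p = np.matmul(Xt, t)                            # (B, m, 1)
        qa = np.matmul(Y.transpose(0, 2, 1), t)         # (B, g, 1)
        v = p.copy()
        if a > 0:
            Vp = V[:, :, :a]
            v = v - np.matmul(Vp, np.matmul(Vp.transpose(0, 2, 1), p))
        nv = np.linalg.norm(v, axis=1, keepdims=True)
        v = v / np.where(nv < tol, 1.0, nv)
        S = S - np.matmul(v, np.matmul(v.transpose(0, 2, 1), S))
        R[:, :, a] = r[..., 0]
        P[:, :, a] = p[..., 0]
        Q[:, :, a] = qa[..., 0]
        T[:, :, a] = t[..., 0]
        V[:, :, a] = v[..., 0]
    return R, P, Q, T


@dataclass
class PLSDAModel:
    encoding: ClassEncoding
    scaler: ScalerState
    A: int
    weights: np.ndarray         # R, m x A (X-weights in scaled space)
    x_loadings: np.ndarray      # P, m x A
    y_loadings: np.ndarray      # Q, g x A
    coef: np.ndarray            # B = R Q^T, m x g
    y_mean: np.ndarray          # intercept in indicator space
    explained_x: np.ndarray     # per-LV fraction of (scaled) X variance
    explained_y: np.ndarray     # per-LV fraction of centred-Y variance
    scores: np.ndarray = field(repr=False, default=None)  # training T, n x A


def plsda_fit(
    X: np.ndarray,
    encoding: ClassEncoding | Sequence[str],
    A: int,
    scaler_kind: str = "autoscale",
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> PLSDAModel:
    """Fit a PLS-DA model with ``A`` latent variables.

    ``encoding`` may be a :class:`ClassEncoding` or raw labels.  X is
    scaled according to ``scaler_kind`` (refit here), Y is centred.
    """
    if not isinstance(encoding, ClassEncoding):
        encoding = encode_classes(encoding, class_order)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not 1 <= A <= min(n - 1, m):
        raise ValueError(f"A must be in [1, {min(n - 1, m)}], got {A}")
    scaler = fit_scaler(X, scaler_kind)
    Xs = apply_scaler(scaler, X)
    y_mean = encoding.Y.mean(axis=0)
    Yc = encoding.Y - y_mean
    R, P, Q, T = _simpls_batch(Xs[None], Yc[None], A)
    R, P, Q, T = R[0], P[0], Q[0], T[0]
    ssx_total = float(np.sum((Xs - Xs.mean(axis=0)) ** 2))
    ssy_total = float(np.sum(Yc**2))
    explained_x = np.sum(P**2, axis=0) / ssx_total if ssx_total else np.zeros(A)
    explained_y = np.sum(Q**2, axis=0) / ssy_total if ssy_total else np.zeros(A)
    return PLSDAModel(
        encoding=encoding, scaler=scaler, A=A,
        weights=R, x_loadings=P, y_loadings=Q,
        coef=R @ Q.T, y_mean=y_mean,
        explained_x=explained_x, explained_y=explained_y, scores=T,
    )


def plsda_predict(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous indicator scores and argmax class per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise ValueError(
            f"expected {model.coef.shape[0]} variables, got {X.shape[1]}"
        )
    scores = apply_scaler(model.scaler, X) @ model.coef + model.y_mean
    classes = np.asarray(model.encoding.classes, dtype=object)[np.argmax(scores, axis=1)]
    return scores, classes


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( m * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a the Y-variance captured by LV a; satisfies sum_j VIP_j^2 = m.
    """
    W = model.weights
    m = W.shape[0]
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2 = np.where(wnorm2 == 0, 1.0, wnorm2)
    ssy = np.sum(model.y_loadings**2, axis=0)
    denom = ssy.sum()
    if denom == 0:
        return np.zeros(m)
    return np.sqrt(m * (W**2 / wnorm2) @ ssy / denom)


# ---------------------------------------------------------------------------
# NIPALS cross-check
# ---------------------------------------------------------------------------


def nipals_pls(
    X: np.ndarray, Y: np.ndarray, A: int, tol: float = 1e-12, max_iter: int = 1000
) -> np.ndarray:
    """NIPALS PLS2 regression coefficients on pre-centred X, Y.

    Independent of the SIMPLS path; used as a cross-check oracle.  Returns
    the m x g coefficient matrix.
    """
    X = np.array(X, dtype=float)
    Y = np.array(Y, dtype=float)
    n, m = X.shape
    g = Y.shape[1]
    Wmat = np.zeros((m, A))
    Pmat = np.zeros((m, A))
    Qmat = np.zeros((g, A))
    for a in range(A):
        u = Y[:, np.argmax(np.sum(Y**2, axis=0))].copy()
        w = np.zeros(m)
        for _ in range(max_iter):
            w_new = X.T @ u
            norm = np.linalg.norm(w_new)
            if norm < 1e-14:
                break
            w_new /= norm
            t = X @ w_new
            q = Y.T @ t / (t @ t)
            u_new = Y @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w, u = w_new, u_new
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = X.T @ t / tt
        q = Y.T @ t / tt
        X = X - np.outer(t, p)
        Y = Y - np.outer(t, q)
        Wmat[:, a], Pmat[:, a], Qmat[:, a] = w, p, q
    Rmat = Wmat @ np.linalg.pinv(Pmat.T @ Wmat)
    return Rmat @ Qmat.T


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    classes: tuple[str, ...]
    scores: np.ndarray            # n x g continuous predictions (held-out)
    predicted: np.ndarray         # n class labels
    true_labels: np.ndarray
    misclassified: int
    flagged_folds: tuple[int, ...] = ()

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predicted == self.true_labels))

    @property
    def rmse(self) -> float:
        enc = encode_classes(self.true_labels, self.classes)
        return float(np.sqrt(np.mean((self.scores - enc.Y) ** 2)))


def _loo_fold_tensors(X: np.ndarray, Y: np.ndarray, scaler_kind: str):
    """Stacked per-fold scaled training sets and scaled held-out rows."""
    n, m = X.shape
    mask = ~np.eye(n, dtype=bool)
    folds = np.tile(np.arange(n), (n, 1))[mask].reshape(n, n - 1)
    Xb = X[folds]                                    # (n, n-1, m)
    Yb = Y[folds]
    if scaler_kind in ("center", "autoscale"):
        mean = Xb.mean(axis=1, keepdims=True)
        if scaler_kind == "autoscale":
            sd = Xb.std(axis=1, ddof=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
        else:
            sd = np.ones_like(mean)
        Xs = (Xb - mean) / sd
        xh = (X - mean[:, 0, :]) / sd[:, 0, :]
    elif scaler_kind == "range01":
        lo = Xb.min(axis=1, keepdims=True)
        hi = Xb.max(axis=1, keepdims=True)
        span = np.where(hi == lo, 1.0, hi - lo)
        Xs = (Xb - lo) / span
        xh = np.clip((X - lo[:, 0, :]) / span[:, 0, :], 0.0, 1.0)
        # PLS still needs centred X inside the fold
        mean = Xs.mean(axis=1, keepdims=True)
        xh = xh - mean[:, 0, :]
        Xs = Xs - mean
    else:
        raise ValueError(f"unknown scaler kind {scaler_kind!r}")
    ymean = Yb.mean(axis=1, keepdims=True)
    Yc = Yb - ymean
    return Xs, Yc, xh, ymean[:, 0, :]


def loo_scores(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    scaler_kind: str,
    per_component: bool = False,
) -> np.ndarray:
    """Held-out continuous predictions for every sample.

    Returns (n, g), or (A, n, g) cumulative-per-LV predictions when
    ``per_component`` is true (used for LV selection without refitting).
    """
    n, m = X.shape
    A = min(A, n - 2, m)
    A = max(A, 1)
    Xs, Yc, xh, ymean = _loo_fold_tensors(np.asarray(X, float), np.asarray(Y, float), scaler_kind)
    R, _, Q, _ = _simpls_batch(Xs, Yc, A)
    tcomp = np.einsum("nm,nma->na", xh, R)           # projections per LV
    contrib = tcomp[:, None, :] * Q                  # (n, g, A)
    if per_component:
        cum = np.cumsum(contrib, axis=2)             # (n, g, A)
        return np.moveaxis(cum, 2, 0) + ymean[None]
    return contrib.sum(axis=2) + ymean


class LOOFoldCache:
    """Precomputed scaled LOO fold tensors for one data block.

    Column scaling statistics are independent across columns, so the
    scaled (n, n-1, m) training tensor and the scaled held-out rows can be
    built once for the full block; any column subset of a fold is then a
    cheap gather.  Used by interval selection, where thousands of column
    subsets are scored against the same block.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray, scaler_kind: str):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        self.n, self.m = X.shape
        self.g = Y.shape[1]
        Xs, Yc, xh, ymean = _loo_fold_tensors(X, Y, scaler_kind)
        # PLS predictions are invariant to a common rescale of X (weights
        # absorb it); normalising to unit RMS keeps blocks that live at
        # tiny absolute scales (second-derivative spectra ~1e-4) clear of
        # the rank tolerances.
        scale = float(np.sqrt(np.mean(Xs**2)))
        if scale > 0:
            Xs = Xs / scale
            xh = xh / scale
        # Column-major fold tensor: gathers of column subsets are contiguous.
        # Kept in double precision: spectral blocks combine a few dominant
        # directions with weak ones ~300x smaller, and the SIMPLS deflation
        # cancellations on such data exceed single-precision headroom.
        self.XsT = np.ascontiguousarray(np.moveaxis(Xs, 2, 0))
        self.Yc = Yc
        self.xh = xh
        self.ymean = ymean

    def scores_for_columns(
        self, col_sets: Sequence[np.ndarray], A: int, chunk_elems: float = 4e7
    ) -> np.ndarray:
        """Held-out predictions (C, n, g) for each candidate column subset.

        Subsets are zero-padded to a common width (harmless for SIMPLS on
        centred data: a zero column gets zero weight) and chunks of
        candidates are stacked into one batched SIMPLS call.
        """
        n, g = self.n, self.g
        C = len(col_sets)
        wmax = max(len(c) for c in col_sets)
        a_eff = max(1, min(A, n - 2, min(len(c) for c in col_sets)))
        cols_pad = np.zeros((C, wmax), dtype=int)
        mask = np.zeros((C, wmax))
        for i, cols in enumerate(col_sets):
            cols_pad[i, : len(cols)] = cols
            mask[i, : len(cols)] = 1.0
        out = np.empty((C, n, g))
        step = max(1, int(chunk_elems / (n * (n - 1) * wmax)))
        for s in range(0, C, step):
            e = min(s + step, C)
            idx = cols_pad[s:e]
            msk = mask[s:e]
            cc = e - s
            G = self.XsT[idx]                       # (cc, wmax, n, n-1) contiguous
            G *= msk[:, :, None, None]
            XT = np.ascontiguousarray(G.transpose(0, 2, 1, 3)).reshape(cc * n, wmax, n - 1)
            Yb = np.ascontiguousarray(
                np.broadcast_to(self.Yc, (cc,) + self.Yc.shape)
            ).reshape(cc * n, n - 1, g)
            R, _, Q, _ = _simpls_batch(XT.transpose(0, 2, 1), Yb, a_eff)
            xh_c = (np.moveaxis(self.xh[:, idx], 1, 0) * msk[:, None, :]).reshape(cc * n, wmax)
            tcomp = np.matmul(xh_c[:, None, :], R)[:, 0, :]       # (cc*n, A)
            yhat = (tcomp[:, None, :] * Q).sum(axis=2).reshape(cc, n, g)
            out[s:e] = yhat + self.ymean[None]
        return out


def loo_cv(
    X: np.ndarray,
    labels: Sequence[str],
    A: int,
    scaler_kind: str = "autoscale",
    pretreatment: Callable[[np.ndarray], np.ndarray] | None = None,
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> CVResult:
    """Leave-one-out CV: each sample predicted by a model fit without it.

    ``pretreatment`` is an optional row-local transform (e.g. an SG
    derivative) applied once up front — being row-local it cannot leak
    held-out information.  Scalers and the PLS model are refit per fold.
    Folds whose training set misses a class entirely are still run but
    flagged.
    """
    enc = encode_classes(labels, class_order)
    X = np.asarray(X, dtype=float)
    if pretreatment is not None:
        X = np.asarray(pretreatment(X), dtype=float)
    n = X.shape[0]
    if n < len(enc.classes) + 1:
        raise ValueError("need at least one more sample than classes for LOO")
    scores = loo_scores(X, enc.Y, A, scaler_kind)
    pred = np.asarray(enc.classes, dtype=object)[np.argmax(scores, axis=1)]
    true = np.asarray(list(labels), dtype=object)
    counts = enc.Y.sum(axis=0)
    flagged = tuple(
        int(i) for i in range(n)
        if counts[np.argmax(enc.Y[i])] == 1  # held-out sample was its class's only one
    )
    return CVResult(
        classes=enc.classes, scores=scores, predicted=pred, true_labels=true,
        misclassified=int(np.sum(pred != true)), flagged_folds=flagged,
    )


def select_n_lv(
    X: np.ndarray,
    labels: Sequence[str],
    A_max: int,
    scaler_kind: str = "autoscale",
    class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
) -> tuple[int, np.ndarray]:
    """Pick the LV count minimizing LOO misclassifications.

    Ties break toward the smaller A.  Returns (A, misclassification trace
    for A = 1..A_max).
    """
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    enc = encode_classes(labels, class_order)
    X = np.asarray(X, dtype=float)
    A_eff = max(1, min(A_max, X.shape[0] - 2, X.shape[1]))
    all_scores = loo_scores(X, enc.Y, A_eff, scaler_kind, per_component=True)
    true_idx = np.argmax(enc.Y, axis=1)
    trace = np.array([
        int(np.sum(np.argmax(all_scores[a], axis=1) != true_idx))
        for a in range(A_eff)
    ])
    best = int(np.argmin(trace)) + 1  # argmin returns first minimum -> smallest A
    return best, trace
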