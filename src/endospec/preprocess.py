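"""Data pretreatments: Savitzky-Golay second derivative, scalers, GLSW.

The spectral models work on second derivatives (third-degree polynomial,
15-point windows), which suppress polynomial baselines and sharpen the
overlapping bands of serum spectra.  Biochemical panels are autoscaled,
spectra mean-centred, fused blocks range-scaled to [0, 1].  Generalized
least squares weighting (GLSW) down-weights within-class ("clutter")
variance directions via a regularized inverse-square-root covariance
filter and is used ahead of exploratory PCA on the panel data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .grid import WavenumberGrid


class ConfigError(ValueError):
    pass


class StateError(RuntimeError):
    """Raised when applying an unfitted transform."""


class RegionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Savitzky-Golay derivative
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay derivative settings: odd window, poly order, derivative."""

    window: int = 15
    polyorder: int = 3
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ConfigError(f"SG window must be odd, got {self.window}")
        if self.polyorder >= self.window:
            raise ConfigError("SG polyorder must be smaller than the window")
        if self.deriv > self.polyorder:
            raise ConfigError("SG derivative order cannot exceed polyorder")

    @property
    def half_window(self) -> int:
        return self.window // 2


def sg_second_derivative(
    X: np.ndarray, spacing: float | WavenumberGrid, cfg: SGConfig | None = None
) -> np.ndarray:
    """Row-wise SG derivative on a uniform grid.

    Exact for polynomials up to ``cfg.polyorder``.  The ``cfg.half_window``
    points at each edge come from the filter's polynomial extrapolation and
    should be treated as invalid; :func:`sg_valid_slice` marks the interior.
    Computed on the full grid — callers extract spectral regions afterwards,
    so no valid points are lost inside an interior region.
    """
    cfg = cfg or SGConfig()
    delta = spacing.spacing if isinstance(spacing, WavenumberGrid) else float(spacing)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if cfg.window > X.shape[1]:
        raise ConfigError("SG window exceeds the number of grid points")
    return savgol_filter(
        X, window_length=cfg.window, polyorder=cfg.polyorder,
        deriv=cfg.deriv, delta=delta, axis=1, mode="interp",
    )


def sg_valid_slice(cfg: SGConfig | None = None) -> slice:
    """Column slice of fully supported (non-edge) derivative points."""
    cfg = cfg or SGConfig()
    return slice(cfg.half_window, -cfg.half_window)


# ---------------------------------------------------------------------------
# Column scalers
# ---------------------------------------------------------------------------


@dataclass
class ScalerState:
    """Fitted per-variable statistics for center / autoscale / range01."""

    kind: str
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    min: np.ndarray | None = None
    max: np.ndarray | None = None
    zero_variance: np.ndarray | None = field(default=None, repr=False)

    @property
    def fitted(self) -> bool:
        return self.mean is not None or self.min is not None


KINDS = ("center", "autoscale", "range01")


def fit_scaler(X: np.ndarray, kind: str) -> ScalerState:
    """Fit column statistics.  Zero-variance columns are flagged and their
    scale set to 1 (autoscale) or mapped to 0 (range01)."""
    if kind not in KINDS:
        raise ConfigError(f"unknown scaler kind {kind!r}; choose from {KINDS}")
    X = np.asarray(X, dtype=float)
    state = ScalerState(kind=kind)
    if kind in ("center", "autoscale"):
        state.mean = X.mean(axis=0)
    if kind == "autoscale":
        sd = X.std(axis=0, ddof=1)
        state.zero_variance = sd == 0
        state.sd = np.where(state.zero_variance, 1.0, sd)
    if kind == "range01":
        state.min = X.min(axis=0)
        state.max = X.max(axis=0)
        state.zero_variance = state.max == state.min
    return state


def apply_scaler(state: ScalerState, X: np.ndarray) -> np.ndarray:
    """Apply a fitted scaler; range01 clips new data into [0, 1]."""
    if not state.fitted:
        raise StateError("scaler has not been fitted")
    X = np.asarray(X, dtype=float)
    if state.kind == "center":
        return X - state.mean
    if state.kind == "autoscale":
        return (X - state.mean) / state.sd
    span = np.where(state.zero_variance, 1.0, state.max - state.min)
    out = (X - state.min) / span
    out[:, state.zero_variance] = 0.0
    return np.clip(out, 0.0, 1.0)


def invert_scaler(state: ScalerState, X: np.ndarray) -> np.ndarray:
    """Inverse transform (exact on training data for center/autoscale)."""
    if not state.fitted:
        raise StateError("scaler has not been fitted")
    if state.kind == "center":
        return X + state.mean
    if state.kind == "autoscale":
        return X * state.sd + state.mean
    span = np.where(state.zero_variance, 1.0, state.max - state.min)
    return X * span + state.min


# ---------------------------------------------------------------------------
# GLSW
# ---------------------------------------------------------------------------


@dataclass
class GLSWTransform:
    """Clutter filter W = V diag(1/sqrt(1 + s/alpha)) V^T.

    V, s are the eigenvectors/eigenvalues of the pooled within-class
    covariance of the training data.  As alpha -> infinity, W -> identity;
    small alpha filters clutter aggressively (default 0.02, a customary
    choice in chemometric practice).
    """

    weights: np.ndarray
    alpha: float
    eigvecs: np.ndarray = field(repr=False)
    eigvals: np.ndarray = field(repr=False)


def glsw_fit(X: np.ndarray, labels: np.ndarray, alpha: float = 0.02) -> GLSWTransform:
    if alpha <= 0:
        raise ConfigError("GLSW alpha must be positive")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("GLSW needs at least two classes")
    D = np.empty_like(X)
    for c in classes:
        mask = labels == c
        if mask.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        D[mask] = X[mask] - X[mask].mean(axis=0)
    C = D.T @ D / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    eigvals = np.clip(eigvals, 0.0, None)  # numerical negatives
    scale = 1.0 / np.sqrt(1.0 + eigvals / alpha)
    W = (eigvecs * scale) @ eigvecs.T
    return GLSWTransform(weights=W, alpha=float(alpha), eigvecs=eigvecs, eigvals=eigvals)


def glsw_apply(transform: GLSWTransform, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ transform.weights


# ---------------------------------------------------------------------------
# Spectral region extraction
# ---------------------------------------------------------------------------


def extract_region(
    X: np.ndarray, grid: WavenumberGrid, lo: float = 700.0, hi: float = 1450.0
) -> tuple[np.ndarray, WavenumberGrid]:
    """Columns with lo <= wavenumber <= hi, order preserved, plus subgrid."""
    if not lo < hi:
        raise RegionError(f"invalid region bounds [{lo}, {hi}]")
    mask = (grid.values >= lo) & (grid.values <= hi)
    if not mask.any():
        raise RegionError(f"region [{lo}, {hi}] selects no grid points")
    values = grid.values[mask]
    if values.size < 2:
        raise RegionError(f"region [{lo}, {hi}] selects fewer than 2 grid points")
    sub = WavenumberGrid(float(values[0]), float(values[-1]), int(values.size), values)
    X = np.atleast_2d(np.asarray(X))
    return X[:, mask], sub
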