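"""Low-level data fusion of the biochemical and spectral blocks.

Spectra carry orders of magnitude more variables than the 29-parameter
panel and their second-derivative intensities live on a very different
scale, so fusing the raw blocks would let the spectral block swamp the
panel.  Two steps fix this:

1. *Quadrant reduction* (x10): PCA is run on the transposed
   second-derivative block (variables as observations), every variable
   gets a (PC1, PC2) score, the variables are partitioned into the four
   quadrants of the score plane and, within each quadrant, picks are taken
   at evenly spaced ranks of the angular ordering — spreading the retained
   variables around the scores cloud rather than clustering them.
2. *Range scaling*: every column of both blocks is linearly mapped to
   [0, 1] on the training rows; the blocks are then concatenated,
   biochemistry first.

The reduction is a deterministic function of the block (no randomness).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decomposition import pca_fit
from .preprocess import ScalerState, apply_scaler, fit_scaler

logger = logging.getLogger(__name__)


@dataclass
class FusedDataset:
    X: np.ndarray
    provenance: tuple[tuple[str, object], ...]   # ('biochem', name) | ('spectral', wavenumber)
    biochem_scaler: ScalerState
    spectral_scaler: ScalerState
    constant_columns: tuple[int, ...] = ()

    @property
    def n_biochem(self) -> int:
        return sum(1 for block, _ in self.provenance if block == "biochem")


def reduce_variables_quadrant(X2nd: np.ndarray, factor: int = 10) -> np.ndarray:
    """Retained column indices of the second-derivative block.

    The total retained count is round(m / factor); per-quadrant quotas are
    apportioned by largest remainder on the quadrant sizes (an empty
    quadrant's quota is thereby redistributed proportionally), and within
    a quadrant picks sit at evenly spaced ranks of the atan2(PC2, PC1)
    ordering.  Variables with zero PC1 and PC2 scores land in quadrant I
    by the >= 0 sign convention.
    """
    X2nd = np.asarray(X2nd, dtype=float)
    m = X2nd.shape[1]
    if factor < 2:
        raise ValueError(f"reduction factor must be >= 2, got {factor}")
    if m < 4 * factor:
        raise ValueError(f"need at least {4 * factor} variables, got {m}")
    model = pca_fit(X2nd.T, k=2)
    pc1, pc2 = model.scores[:, 0], model.scores[:, 1]
    quadrant = np.where(
        (pc1 >= 0) & (pc2 >= 0), 0,
        np.where((pc1 < 0) & (pc2 >= 0), 1, np.where((pc1 < 0) & (pc2 < 0), 2, 3)),
    )
    target = int(round(m / factor))
    sizes = np.array([(quadrant == q).sum() for q in range(4)])
    # largest-remainder apportionment, quotas capped at quadrant size
    exact = sizes * target / m
    quota = np.minimum(np.floor(exact).astype(int), sizes)
    while quota.sum() < target:
        remainder = np.where(quota < sizes, exact - quota, -np.inf)
        quota[int(np.argmax(remainder))] += 1
    retained: list[int] = []
    angles = np.arctan2(pc2, pc1)
    for q in range(4):
        members = np.where(quadrant == q)[0]
        k = quota[q]
        if k == 0 or members.size == 0:
            continue
        order = members[np.argsort(angles[members], kind="stable")]
        ranks = np.floor(members.size * (np.arange(k) + 0.5) / k).astype(int)
        retained.extend(order[ranks])
    return np.sort(np.asarray(retained, dtype=int))


def fuse(
    biochem: np.ndarray,
    spectra_reduced: np.ndarray,
    biochem_names: Sequence[str] | None = None,
    wavenumbers: Sequence[float] | None = None,
) -> FusedDataset:
    """Range-scale each block to [0, 1] and concatenate, biochemistry first.

    Constant columns are scaled to 0 and flagged.  Held-out data pushed
    through :func:`fuse_apply` is clipped into [0, 1].
    """
    biochem = np.asarray(biochem, dtype=float)
    spectra_reduced = np.asarray(spectra_reduced, dtype=float)
    if biochem.shape[0] != spectra_reduced.shape[0]:
        raise ValueError(
            f"row mismatch: biochem {biochem.shape[0]} vs "
            f"spectral {spectra_reduced.shape[0]}"
        )
    bsc = fit_scaler(biochem, "range01")
    ssc = fit_scaler(spectra_reduced, "range01")
    X = np.hstack([apply_scaler(bsc, biochem), apply_scaler(ssc, spectra_reduced)])
    if biochem_names is None:
        biochem_names = [f"param_{j}" for j in range(biochem.shape[1])]
    if wavenumbers is None:
        wavenumbers = [float(j) for j in range(spectra_reduced.shape[1])]
    provenance = tuple(
        [("biochem", n) for n in biochem_names]
        + [("spectral", float(w)) for w in wavenumbers]
    )
    constant = tuple(
        int(j) for j, flag in enumerate(
            np.concatenate([bsc.zero_variance, ssc.zero_variance])
        ) if flag
    )
    if constant:
        logger.info("fusion: %d constant column(s) scaled to 0: %s", len(constant), constant)
    return FusedDataset(
        X=X, provenance=provenance,
        biochem_scaler=bsc, spectral_scaler=ssc,
        constant_columns=constant,
    )


def fuse_apply(
    fused: FusedDataset, biochem: np.ndarray, spectra_reduced: np.ndarray
) -> np.ndarray:
    """Scale new rows with the training min/max (clipped to [0, 1])."""
    return np.hstack([
        apply_scaler(fused.biochem_scaler, np.atleast_2d(biochem)),
        apply_scaler(fused.spectral_scaler, np.atleast_2d(spectra_reduced)),
    ])
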