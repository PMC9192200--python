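"""End-to-end model runners for the three serum classifiers.

Three published model families are orchestrated on a generated or loaded
cohort:

* **biochem** — autoscale the 29-parameter panel, forward iPLS with
  singleton windows, PLS-DA with 4 LVs;
* **spectral** — SG second derivative on the full grid, extract the
  700-1450 cm^-1 fingerprint region, mean-centre, forward iPLS with
  10-variable windows, PLS-DA with 5 LVs;
* **fused** — quadrant-reduce the second-derivative region block by a
  factor of 10, range-scale both blocks to [0, 1], concatenate, forward
  iPLS with singleton windows, PLS-DA with 2 LVs.

Each runner reports calibration (training-set) and leave-one-out
cross-validation confusion statistics, VIP scores and the selected
variables, and optionally writes all artifacts as CSV plus a run
manifest.  Variable selection is performed once on the full dataset and
LOO-CV then evaluates the fixed selection; this mirrors common
chemometric practice and carries an optimistic bias, which is noted in
the run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CLASS_ORDER, SyntheticCohort, default_config, generate_cohort
from .evaluation import ConfusionStats, confusion
from .fusion import fuse, reduce_variables_quadrant
from .grid import WavenumberGrid, build_grid
from .plsda import CVResult, loo_cv, plsda_fit, plsda_predict, vip_scores
from .preprocess import SGConfig, extract_region, sg_second_derivative
from .varsel import IPLSResult, ipls_forward

logger = logging.getLogger(__name__)

SELECTION_BIAS_NOTE = (
    "variable selection fitted on the full dataset; LOO-CV evaluates the "
    "fixed selection and is therefore optimistically biased"
)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the three model families, with study defaults."""

    lv_biochem: int = 4
    lv_spectral: int = 5
    lv_fused: int = 2
    scaler_biochem: str = "autoscale"
    scaler_spectral: str = "center"
    scaler_fused: str = "center"      # fused block is already range-scaled
    ipls_width_biochem: int = 1
    ipls_width_spectral: int = 10
    ipls_width_fused: int = 1
    region_lo: float = 700.0
    region_hi: float = 1450.0
    fusion_factor: int = 10
    ipls_min_improvement: float = 0.01
    sg_window: int = 15
    sg_polyorder: int = 3
    glsw_alpha: float = 0.02
    max_intervals: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ModelReport:
    name: str
    selection: IPLSResult
    selected_names: tuple[object, ...]
    cv: CVResult
    metrics_cal: ConfusionStats
    metrics_cv: ConfusionStats
    vip: np.ndarray
    n_lv: int


def _evaluate(
    name: str,
    X: np.ndarray,
    labels: np.ndarray,
    selection: IPLSResult,
    selected_names,
    A: int,
    scaler_kind: str,
) -> ModelReport:
    cols = np.asarray(selection.retained, dtype=int)
    if cols.size == 0:
        raise PipelineError(f"{name}: variable selection retained no columns")
    Xsel = X[:, cols]
    A_eff = max(1, min(A, Xsel.shape[1], Xsel.shape[0] - 2))
    if A_eff != A:
        logger.info("%s: LV count capped from %d to %d by selected columns", name, A, A_eff)
    model = plsda_fit(Xsel, labels, A_eff, scaler_kind, class_order=CLASS_ORDER)
    _, cal_pred = plsda_predict(model, Xsel)
    cv = loo_cv(Xsel, labels, A_eff, scaler_kind, class_order=CLASS_ORDER)
    return ModelReport(
        name=name,
        selection=selection,
        selected_names=tuple(selected_names),
        cv=cv,
        metrics_cal=confusion(labels, cal_pred, CLASS_ORDER),
        metrics_cv=confusion(labels, cv.predicted, CLASS_ORDER),
        vip=vip_scores(model),
        n_lv=A_eff,
    )


def run_biochem_model(
    cohort: SyntheticCohort, config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> ModelReport:
    """Panel-only classifier: autoscale -> iPLS(w=1) -> PLS-DA(4 LVs)."""
    sel = ipls_forward(
        cohort.biochem, cohort.labels, config.ipls_width_biochem,
        config.lv_biochem, config.scaler_biochem,
        max_intervals=config.max_intervals,
        min_improvement=config.ipls_min_improvement, class_order=CLASS_ORDER,
    )
    names = [cohort.param_names[j] for j in sel.retained]
    report = _evaluate(
        "biochem", cohort.biochem, cohort.labels, sel, names,
        config.lv_biochem, config.scaler_biochem,
    )
    if outdir:
        _write_report(report, cohort, config, Path(outdir))
    return report


def _spectral_block(cohort: SyntheticCohort, config: PipelineConfig):
    """Second-derivative fingerprint-region block and its subgrid."""
    spacing = cohort.grid.spacing
    expected = np.arange(cohort.grid.n_points) * spacing + cohort.grid.lo
    if not np.allclose(cohort.grid.values, expected, atol=1e-6 * max(1.0, spacing)):
        raise PipelineError("spectral model requires a uniform wavenumber grid")
    cfg = SGConfig(window=config.sg_window, polyorder=config.sg_polyorder, deriv=2)
    deriv = sg_second_derivative(cohort.spectra, cohort.grid, cfg)
    return extract_region(deriv, cohort.grid, config.region_lo, config.region_hi)


def run_spectral_model(
    cohort: SyntheticCohort, config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> ModelReport:
    """Spectra-only classifier: SG 2nd derivative -> 700-1450 cm^-1 ->
    mean-centre -> iPLS(w=10) -> PLS-DA(5 LVs)."""
    block, subgrid = _spectral_block(cohort, config)
    sel = ipls_forward(
        block, cohort.labels, config.ipls_width_spectral,
        config.lv_spectral, config.scaler_spectral,
        max_intervals=config.max_intervals,
        min_improvement=config.ipls_min_improvement, class_order=CLASS_ORDER,
    )
    names = [round(float(subgrid.values[j]), 2) for j in sel.retained]
    report = _evaluate(
        "spectral", block, cohort.labels, sel, names,
        config.lv_spectral, config.scaler_spectral,
    )
    if outdir:
        _write_report(report, cohort, config, Path(outdir))
    return report


def run_fused_model(
    cohort: SyntheticCohort, config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> ModelReport:
    """Fused classifier: quadrant reduction(x10) -> range-[0,1] fusion ->
    iPLS(w=1) -> PLS-DA(2 LVs)."""
    if cohort.biochem.shape[0] != cohort.spectra.shape[0]:
        raise PipelineError("biochemical and spectral blocks are row-misaligned")
    block, subgrid = _spectral_block(cohort, config)
    keep = reduce_variables_quadrant(block, config.fusion_factor)
    fused = fuse(
        cohort.biochem, block[:, keep],
        biochem_names=cohort.param_names,
        wavenumbers=subgrid.values[keep],
    )
    sel = ipls_forward(
        fused.X, cohort.labels, config.ipls_width_fused,
        config.lv_fused, config.scaler_fused,
        max_intervals=config.max_intervals,
        min_improvement=config.ipls_min_improvement, class_order=CLASS_ORDER,
    )
    names = []
    for j in sel.retained:
        block_name, origin = fused.provenance[j]
        names.append(origin if block_name == "biochem" else round(float(origin), 2))
    report = _evaluate(
        "fused", fused.X, cohort.labels, sel, names,
        config.lv_fused, config.scaler_fused,
    )
    if outdir:
        _write_report(report, cohort, config, Path(outdir))
    return report


RUNNERS = {
    "biochem": run_biochem_model,
    "spectral": run_spectral_model,
    "fused": run_fused_model,
}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_cohort(
    biochem_csv: str | Path,
    spectra_csv: str | Path,
    labels_column: str = "label",
) -> SyntheticCohort:
    """Load an externally stored cohort; rows realigned by sample ID.

    The spectra header must be a strictly increasing, uniformly spaced
    wavenumber axis.
    """
    bio = pd.read_csv(biochem_csv)
    spec = pd.read_csv(spectra_csv)
    for df, path in ((bio, biochem_csv), (spec, spectra_csv)):
        if "sample_id" not in df.columns:
            raise PipelineError(f"{path}: missing 'sample_id' column")
    if labels_column not in bio.columns:
        raise PipelineError(f"{biochem_csv}: missing label column {labels_column!r}")
    missing = bio[bio[labels_column].isna()]["sample_id"].tolist()
    if missing:
        raise PipelineError(f"missing label value for sample(s): {missing}")
    if set(bio["sample_id"]) != set(spec["sample_id"]):
        raise PipelineError("sample IDs differ between biochemical and spectral files")
    bio = bio.set_index("sample_id")
    spec = spec.set_index("sample_id").loc[bio.index]  # realign by ID
    try:
        wavenumbers = np.array([float(c) for c in spec.columns])
    except ValueError as exc:
        raise PipelineError(f"non-numeric wavenumber header in {spectra_csv}") from exc
    if np.any(np.diff(wavenumbers) <= 0):
        raise PipelineError("wavenumber header is not strictly increasing")
    spacing = np.diff(wavenumbers)
    if not np.allclose(spacing, spacing[0], rtol=1e-4):
        raise PipelineError("wavenumber header is not uniformly spaced")
    grid = build_grid(float(wavenumbers[0]), float(wavenumbers[-1]), wavenumbers.size)
    labels = bio[labels_column].to_numpy(dtype=object)
    params = [c for c in bio.columns if c != labels_column]
    biochem = bio[params].to_numpy(dtype=float)
    spectra = spec.to_numpy(dtype=float)
    if np.isnan(biochem).any() or np.isnan(spectra).any():
        raise PipelineError("non-numeric or missing data cells")
    return SyntheticCohort(
        biochem=biochem, param_names=tuple(params), spectra=spectra,
        labels=labels, grid=grid, seed=-1, sample_ids=tuple(bio.index),
    )


def generate_default_cohort(seed: int, grid: WavenumberGrid | None = None) -> SyntheticCohort:
    """Convenience wrapper: the standard 71-sample study cohort."""
    return generate_cohort(default_config(seed=seed, grid=grid))


def _write_report(
    report: ModelReport,
    cohort: SyntheticCohort,
    config: PipelineConfig,
    outdir: Path,
) -> None:
    outdir = outdir / report.name
    outdir.mkdir(parents=True, exist_ok=True)
    report.metrics_cal.as_percent_table().to_csv(outdir / "metrics_calibration.csv")
    report.metrics_cv.as_percent_table().to_csv(outdir / "metrics_cv.csv")
    pd.DataFrame({
        "variable": list(report.selected_names),
        "column": list(report.selection.retained),
    }).to_csv(outdir / "selected_variables.csv", index=False)
    pd.DataFrame({
        "step": np.arange(1, len(report.selection.trace) + 1),
        "misclassified": [t[0] for t in report.selection.trace],
        "rmsecv": [t[1] for t in report.selection.trace],
    }).to_csv(outdir / "criterion_trace.csv", index=False)
    pd.DataFrame({
        "variable": list(report.selected_names),
        "vip": report.vip,
    }).to_csv(outdir / "vip.csv", index=False)
    cv_df = pd.DataFrame(report.cv.scores, columns=[f"score_{c}" for c in report.cv.classes])
    cv_df.insert(0, "predicted", report.cv.predicted)
    cv_df.insert(0, "true", report.cv.true_labels)
    cv_df.insert(0, "sample_id", list(cohort.sample_ids))
    cv_df.to_csv(outdir / "cv_predictions.csv", index=False)
    manifest: dict[str, object] = {
        "model": report.name,
        "package_version": __version__,
        "cohort_seed": cohort.seed,
        "n_lv": report.n_lv,
        "stopping": report.selection.stopped,
        "note": SELECTION_BIAS_NOTE,
    }
    manifest.update({f"config.{k}": v for k, v in config.to_dict().items()})
    (outdir / "manifest.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in manifest.items())
    )
    logger.info("%s: artifacts written to %s", report.name, outdir)
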