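"""Synthetic serum cohorts: biochemical panels plus ATR-FTIR spectra.

The study population this package targets — women with advanced
endometriosis (E, n=29), women with other benign gynecological disorders
(NE, n=24) and healthy controls (C, n=18) — is not publicly deposited, so
analyses run against cohorts generated here.  The generator reproduces the
statistical structure the downstream models assume:

* a 29-parameter biochemical panel whose 12 group-discriminating markers
  (CA 125, prolactin, IgG, hsCRP, albumin, calcium, magnesium, hsIL-1beta,
  IL-6, FRAP, AOPP, YKL-40) follow published group mean/SD values, drawn
  from moment-matched lognormal distributions (several markers have
  SD > mean, so a normal model would produce impossible negative
  concentrations);
* serum-like absorbance spectra built as sums of Gaussian bands (amide,
  CH-stretch, OH/NH and fingerprint-region bands), with class-dependent
  multiplicative band effects: an inflammation effect shared by E and NE
  (nucleic-acid / phosphate bands 1056, 1080, 1213, 1241 cm^-1) and a
  subtler E-vs-NE effect on the fingerprint bands the spectral models end
  up selecting (731-1243 cm^-1);
* instrument artefacts: per-sample multiplicative gain (film-thickness
  scatter), a random low-order polynomial baseline, and white noise.

Every cohort is a deterministic function of its configuration, including
the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .grid import WavenumberGrid, build_grid, default_grid

CLASS_ORDER = ("E", "NE", "C")


class ParameterError(ValueError):
    """Raised for invalid biochemical distribution parameters."""


class BandConfigError(ValueError):
    """Raised when a group effect references a band not in the library."""


# ---------------------------------------------------------------------------
# Biochemical panel
# ---------------------------------------------------------------------------

#: Group-specific reference distributions (mean, SD) per class (E, NE, C)
#: for the 12 panel markers with known group differences in advanced
#: endometriosis.  Units are embedded in the parameter names.
GROUP_PANEL_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "PRL (ng/mL)": {"E": (29.01, 18.71), "NE": (27.02, 18.62), "C": (12.84, 4.86)},
    "CA 125 (U/mL)": {"E": (113.41, 129.42), "NE": (23.64, 17.39), "C": (14.28, 7.40)},
    "IgG (mg/dL)": {"E": (1065.46, 286.73), "NE": (1078.22, 298.25), "C": (1237.28, 215.91)},
    "hsCRP (mg/L)": {"E": (14.29, 19.45), "NE": (13.88, 19.96), "C": (0.96, 1.19)},
    "Albumin (g/dL)": {"E": (4.36, 0.64), "NE": (4.13, 0.32), "C": (4.26, 0.19)},
    "Calcium (mg/dL)": {"E": (9.62, 1.15), "NE": (9.35, 0.49), "C": (9.29, 0.25)},
    "Magnesium (mg/dL)": {"E": (2.44, 0.37), "NE": (2.47, 0.18), "C": (2.22, 0.14)},
    "hsIL-1b (pg/mL)": {"E": (0.57, 0.39), "NE": (0.56, 0.46), "C": (0.27, 0.26)},
    "IL-6 (pg/mL)": {"E": (19.33, 43.69), "NE": (18.05, 34.09), "C": (1.47, 1.48)},
    "FRAP (mmol/L)": {"E": (1.11, 0.26), "NE": (1.18, 0.30), "C": (0.95, 0.22)},
    "AOPP (umol/L)": {"E": (235.16, 150.41), "NE": (181.78, 156.00), "C": (105.16, 49.24)},
    "YKL-40 (ng/mL)": {"E": (685.22, 1246.58), "NE": (403.29, 934.76), "C": (104.12, 154.07)},
}

#: The remaining 17 panel parameters (full assay list not public); they get
#: clinically plausible means/SDs identical across groups, so they act as
#: nuisance variables for the variable-selection machinery.
SHARED_PANEL_STATS: dict[str, tuple[float, float]] = {
    "SIRT3 (ng/mL)": (5.0, 2.0),
    "SIRT5 (ng/mL)": (4.0, 1.5),
    "SIRT6 (ng/mL)": (6.0, 2.0),
    "Telomerase (ng/mL)": (1.2, 0.5),
    "TAS (mmol/L)": (1.5, 0.2),
    "Glucose (mg/dL)": (90.0, 10.0),
    "Total protein (g/dL)": (7.2, 0.5),
    "Total bilirubin (mg/dL)": (0.6, 0.25),
    "Uric acid (mg/dL)": (4.5, 1.0),
    "Iron (ug/dL)": (90.0, 30.0),
    "Total cholesterol (mg/dL)": (190.0, 35.0),
    "Triglycerides (mg/dL)": (100.0, 45.0),
    "HDL (mg/dL)": (60.0, 14.0),
    "LDL (mg/dL)": (110.0, 30.0),
    "Estradiol (pg/mL)": (80.0, 60.0),
    "Phosphorus (mg/dL)": (3.5, 0.5),
    "Globulin (g/dL)": (2.9, 0.4),
}

PARAM_NAMES: tuple[str, ...] = tuple(GROUP_PANEL_STATS) + tuple(SHARED_PANEL_STATS)


def lognormal_moment_matched(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw lognormal samples whose population mean and SD equal (mean, sd).

    Moment matching: sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2.
    ``sd == 0`` degenerates to the constant ``mean``.  Strictly positive
    output for any mean > 0.
    """
    m = float(mean)
    s = float(sd)
    if m <= 0:
        raise ParameterError(f"lognormal mean must be positive, got {m}")
    if s < 0:
        raise ParameterError(f"SD must be non-negative, got {s}")
    if s == 0:
        return np.full(size, m)
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# Spectral model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """Gaussian absorption band: centre (cm^-1), width sigma (cm^-1), amplitude."""

    center: float
    width: float
    amplitude: float


#: Serum-like band library.  Amide I/II dominate; OH/NH and CH stretches sit
#: above 2900 cm^-1; the fingerprint region carries the weaker nucleic-acid,
#: carbohydrate and phospholipid bands the discriminant models select from.
DEFAULT_BAND_LIBRARY: tuple[Band, ...] = (
    Band(3290.0, 60.0, 0.150),   # amide A / nu(OH)
    Band(2960.0, 12.0, 0.035),   # nu_as(CH3)
    Band(2930.0, 12.0, 0.045),   # nu_as(CH2)
    Band(1645.0, 25.0, 0.300),   # amide I
    Band(1545.0, 22.0, 0.200),   # amide II
    Band(1454.0, 12.0, 0.060),   # delta(CH2/CH3)
    Band(1400.0, 12.0, 0.055),   # nu_s(COO-)
    Band(1306.0, 10.0, 0.020),   # amide III region
    Band(1243.0, 9.0, 0.025),    # nu_as(PO2-), immunoglobulins
    Band(1241.0, 9.0, 0.020),    # nucleic acids
    Band(1213.0, 9.0, 0.018),    # A-DNA / RNA
    Band(1186.0, 9.0, 0.012),    # nu_as(C-O-C) esters
    Band(1137.0, 9.0, 0.012),    # nu_as(CO-O-C) glycan
    Band(1125.0, 9.0, 0.010),    # carbohydrate C-O
    Band(1100.0, 9.0, 0.015),    # C-C / C-O carbohydrates
    Band(1094.0, 9.0, 0.015),    # nu_s(PO2-)
    Band(1080.0, 9.0, 0.018),    # nucleic acids / phospholipids
    Band(1060.0, 9.0, 0.016),    # nu(C-O) ribose
    Band(1056.0, 9.0, 0.016),    # nucleic acids
    Band(834.0, 8.0, 0.008),
    Band(796.0, 8.0, 0.007),
    Band(747.0, 8.0, 0.006),
    Band(731.0, 8.0, 0.006),
)

#: Inflammation effect shared by the two patient groups (E and NE vs C).
INFLAMMATION_EFFECT: dict[float, float] = {1056.0: 1.10, 1080.0: 1.10, 1213.0: 1.12, 1241.0: 1.08}

#: Bands carrying the subtler endometriosis-vs-other-disorder contrast.
ENDO_CONTRAST_BANDS: tuple[float, ...] = (
    731.0, 747.0, 796.0, 834.0, 1094.0, 1100.0, 1125.0, 1137.0, 1186.0, 1243.0,
)

DEFAULT_GROUP_EFFECTS: dict[str, dict[float, float]] = {
    "E": {**INFLAMMATION_EFFECT, **{c: 1.08 for c in ENDO_CONTRAST_BANDS}},
    "NE": {**INFLAMMATION_EFFECT, **{c: 0.92 for c in ENDO_CONTRAST_BANDS}},
    "C": {},
}


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """One class of the cohort.

    ``biochem_mean``/``biochem_sd`` map parameter name -> value; all 29
    panel parameters must be covered.  ``band_effects`` maps band centre
    (cm^-1) -> multiplicative amplitude factor applied before summation.
    """

    name: str
    n: int
    biochem_mean: Mapping[str, float]
    biochem_sd: Mapping[str, float]
    band_effects: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name}: n must be >= 1, got {self.n}")
        for p, s in self.biochem_sd.items():
            if s < 0:
                raise ParameterError(f"group {self.name}: SD of {p!r} is negative")
        for c, f in self.band_effects.items():
            if f < 0:
                raise ValueError(f"group {self.name}: band factor at {c} cm^-1 is negative")


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    grid: WavenumberGrid
    band_library: tuple[Band, ...] = DEFAULT_BAND_LIBRARY
    noise_sd: float = 1e-4
    baseline_order: int = 2
    baseline_scale: float = 4e-3
    gain_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.gain_sd < 0 or self.baseline_scale < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be non-negative")


@dataclass(frozen=True)
class SyntheticCohort:
    """Aligned biochemical matrix, spectral matrix and class labels."""

    biochem: np.ndarray
    param_names: tuple[str, ...]
    spectra: np.ndarray
    labels: np.ndarray
    grid: WavenumberGrid
    seed: int
    sample_ids: tuple[str, ...]

    @property
    def n_samples(self) -> int:
        return self.biochem.shape[0]

    # -- plain-text writers -------------------------------------------------

    def write_biochem_csv(self, path: str | Path) -> None:
        """Sample-ID, class label, then one column per panel parameter."""
        import pandas as pd

        df = pd.DataFrame(self.biochem, columns=list(self.param_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", list(self.sample_ids))
        df.to_csv(path, index=False)

    def write_spectra_csv(self, path: str | Path) -> None:
        """Header = wavenumbers to 5 decimals; first column sample-ID."""
        import pandas as pd

        cols = [f"{w:.5f}" for w in self.grid.values]
        df = pd.DataFrame(self.spectra, columns=cols)
        df.insert(0, "sample_id", list(self.sample_ids))
        df.to_csv(path, index=False)

    def write_manifest(self, path: str | Path, extra: Mapping[str, object] | None = None) -> None:
        lines = {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "n_params": len(self.param_names),
            "grid_lo": self.grid.lo,
            "grid_hi": self.grid.hi,
            "grid_points": self.grid.n_points,
            "groups": ",".join(f"{c}:{int((self.labels == c).sum())}" for c in CLASS_ORDER),
        }
        if extra:
            lines.update(extra)
        Path(path).write_text("".join(f"{k} = {v}\n" for k, v in lines.items()))


# ---------------------------------------------------------------------------
# Generation operations
# ---------------------------------------------------------------------------


def sample_biochem(
    groups: Sequence[GroupSpec],
    rng: np.random.Generator,
    param_names: Sequence[str] = PARAM_NAMES,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Draw the biochemical matrix, one lognormal per (group, parameter)."""
    blocks = []
    for g in groups:
        cols = []
        for p in param_names:
            try:
                m, s = g.biochem_mean[p], g.biochem_sd[p]
            except KeyError as exc:
                raise ParameterError(f"group {g.name} lacks parameter {p!r}") from exc
            cols.append(lognormal_moment_matched(m, s, g.n, rng))
        blocks.append(np.column_stack(cols))
    return np.vstack(blocks), tuple(param_names)


def generate_base_spectrum(
    grid: WavenumberGrid, band_library: Sequence[Band]
) -> np.ndarray:
    """Sum of Gaussian band profiles on the grid; bands outside it are skipped."""
    spectrum = np.zeros(grid.n_points)
    for band in band_library:
        if not (grid.lo <= band.center <= grid.hi):
            warnings.warn(
                f"band at {band.center} cm^-1 outside grid "
                f"[{grid.lo}, {grid.hi}] — skipped",
                stacklevel=2,
            )
            continue
        spectrum += band.amplitude * np.exp(
            -0.5 * ((grid.values - band.center) / band.width) ** 2
        )
    return spectrum


def apply_group_effects(
    grid: WavenumberGrid,
    band_library: Sequence[Band],
    band_effects: Mapping[float, float],
) -> np.ndarray:
    """Group spectrum: named bands' amplitudes scaled before summation."""
    centers = {b.center for b in band_library}
    unknown = set(band_effects) - centers
    if unknown:
        raise BandConfigError(
            f"band effects reference unknown centres: {sorted(unknown)}"
        )
    scaled = tuple(
        replace(b, amplitude=b.amplitude * band_effects.get(b.center, 1.0))
        for b in band_library
    )
    return generate_base_spectrum(grid, scaled)


def add_instrument_noise(
    spectrum: np.ndarray,
    baseline_order: int,
    baseline_scale: float,
    gain_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """gain*spectrum + random polynomial baseline + white noise.

    gain ~ Normal(1, gain_sd^2) truncated to > 0; baseline coefficients
    ~ Normal(0, baseline_scale^2) on a Chebyshev-friendly [-1, 1] axis.
    """
    gain = 1.0
    if gain_sd > 0:
        gain = rng.normal(1.0, gain_sd)
        while gain <= 0:  # truncation; practically never loops at sane gain_sd
            gain = rng.normal(1.0, gain_sd)
    out = gain * spectrum
    if baseline_scale > 0:
        coeffs = rng.normal(0.0, baseline_scale, size=baseline_order + 1)
        x = np.linspace(-1.0, 1.0, spectrum.shape[-1])
        out = out + np.polynomial.polynomial.polyval(x, coeffs)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=spectrum.shape)
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Deterministically generate the full cohort from its configuration."""
    rng = np.random.default_rng(config.seed)
    biochem, names = sample_biochem(config.groups, rng)
    labels = np.concatenate([np.full(g.n, g.name, dtype=object) for g in config.groups])
    spectra = np.empty((len(labels), config.grid.n_points))
    row = 0
    for g in config.groups:
        group_spectrum = apply_group_effects(config.grid, config.band_library, g.band_effects)
        for _ in range(g.n):
            spectra[row] = add_instrument_noise(
                group_spectrum,
                config.baseline_order,
                config.baseline_scale,
                config.gain_sd,
                config.noise_sd,
                rng,
            )
            row += 1
    ids = tuple(f"S{i:03d}" for i in range(len(labels)))
    return SyntheticCohort(
        biochem=biochem,
        param_names=names,
        spectra=spectra,
        labels=np.asarray(labels, dtype=object),
        grid=config.grid,
        seed=config.seed,
        sample_ids=ids,
    )


# ---------------------------------------------------------------------------
# Standard study configurations
# ---------------------------------------------------------------------------


def default_groups(
    group_effects: Mapping[str, Mapping[float, float]] | None = None,
    sizes: Mapping[str, int] | None = None,
) -> tuple[GroupSpec, ...]:
    """E/NE/C groups (29/24/18) with the reference panel distributions."""
    effects = DEFAULT_GROUP_EFFECTS if group_effects is None else group_effects
    n = {"E": 29, "NE": 24, "C": 18}
    if sizes:
        n.update(sizes)
    groups = []
    for cls in CLASS_ORDER:
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for p, stats in GROUP_PANEL_STATS.items():
            means[p], sds[p] = stats[cls]
        for p, (m, s) in SHARED_PANEL_STATS.items():
            means[p], sds[p] = m, s
        groups.append(
            GroupSpec(cls, n[cls], means, sds, dict(effects.get(cls, {})))
        )
    return tuple(groups)


def default_config(seed: int = 0, grid: WavenumberGrid | None = None) -> CohortConfig:
    """The standard study conditions: 71 samples, 400-4000 cm^-1 / 7,469 pts."""
    return CohortConfig(
        groups=default_groups(),
        grid=grid if grid is not None else default_grid(),
        seed=seed,
    )


def implanted_window_config(
    seed: int,
    interval_indices: Sequence[int],
    *,
    region: tuple[float, float] = (700.0, 1450.0),
    window_width: int = 10,
    grid: WavenumberGrid | None = None,
    band_sigma: float = 1.0,
    band_amplitude: float = 0.02,
    class_factors: Sequence[Mapping[str, float]] | None = None,
    noise_sd: float = 2e-5,
    gain_sd: float = 0.0,
    baseline_scale: float = 0.0,
) -> CohortConfig:
    """Cohort whose spectral class signal sits in chosen 10-point windows.

    A known-support recovery design: one narrow Gaussian band is placed at
    the centre of each requested interval of the ``region`` block, with
    per-class amplitude factors that differ strongly between groups, and
    instrument noise kept low.  Gain scatter and baseline drift are off by
    default: they contaminate *every* column with a shared per-sample
    latent, which turns band-free windows into genuinely useful clutter
    references for the PLS model and defeats the purpose of a
    known-support design.  Everything outside the chosen windows is then
    class-uninformative white noise, so forward interval selection should
    recover the implanted windows (up to one-window smearing by the SG
    derivative filter).

    ``class_factors[k]`` maps class name -> amplitude factor for window k;
    by default windows cycle through three patterns so each window carries
    a different pairwise contrast.
    """
    g = grid if grid is not None else default_grid()
    region_idx = np.where((g.values >= region[0]) & (g.values <= region[1]))[0]
    if class_factors is None:
        patterns = (
            {"E": 1.6, "NE": 1.0, "C": 0.6},
            {"E": 0.6, "NE": 1.6, "C": 1.0},
            {"E": 1.0, "NE": 0.6, "C": 1.6},
        )
        class_factors = [patterns[k % 3] for k in range(len(interval_indices))]
    bands = []
    effects: dict[str, dict[float, float]] = {c: {} for c in CLASS_ORDER}
    for k, iv in enumerate(interval_indices):
        start = iv * window_width
        stop = min(start + window_width, len(region_idx))
        cols = region_idx[start:stop]
        center = float(g.values[cols].mean())
        bands.append(Band(center, band_sigma, band_amplitude))
        for cls in CLASS_ORDER:
            effects[cls][center] = float(class_factors[k].get(cls, 1.0))
    groups = default_groups(group_effects=effects)
    return CohortConfig(
        groups=groups,
        grid=g,
        band_library=tuple(bands),
        noise_sd=noise_sd,
        baseline_order=2,
        baseline_scale=baseline_scale,
        gain_sd=gain_sd,
        seed=seed,
    )


def implanted_biochem_groups(
    informative: Sequence[str] = (
        "CA 125 (U/mL)",
        "IgG (mg/dL)",
        "hsCRP (mg/L)",
        "Albumin (g/dL)",
        "Magnesium (mg/dL)",
        "YKL-40 (ng/mL)",
    ),
    shift_sd: float = 1.5,
    sizes: Mapping[str, int] | None = None,
) -> tuple[GroupSpec, ...]:
    """Groups where only ``informative`` parameters differ between classes.

    Each informative parameter keeps the shared reference (mean, SD) as its
    base; the group means are shifted by multiples of the SD in a distinct
    class-contrast pattern per parameter (one class up, one class up vs a
    pair, opposed pairs, ...), guaranteeing >= ``shift_sd`` standard
    deviations between at least two groups for every parameter and making
    each parameter individually informative about a different contrast.
    All other parameters are identical across groups (pure nuisance).
    """
    base: dict[str, tuple[float, float]] = dict(SHARED_PANEL_STATS)
    for p, stats in GROUP_PANEL_STATS.items():
        # class-neutral base: the control-group distribution
        base[p] = stats["C"]
    n = {"E": 29, "NE": 24, "C": 18}
    if sizes:
        n.update(sizes)
    # per-parameter (E, NE, C) shift multipliers: six distinct contrasts
    patterns = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
        (0.5, -0.5, 0.0),
        (0.0, 0.5, -0.5),
        (0.5, 0.0, -0.5),
    )
    groups = []
    for ci, cls in enumerate(CLASS_ORDER):
        means: dict[str, float] = {}
        sds: dict[str, float] = {}
        for p, (m, s) in base.items():
            shift = 0.0
            if p in informative:
                k = list(informative).index(p)
                shift = patterns[k % len(patterns)][ci] * shift_sd * s
            means[p] = max(m + shift, 0.05 * m)  # keep strictly positive
            sds[p] = s
        groups.append(GroupSpec(cls, n[cls], means, sds, {}))
    return tuple(groups)
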