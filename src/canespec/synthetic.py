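"""Synthetic multispectral field-trial generator.

Emulates a factorial sugarcane irrigation x fertilization experiment:
12 plots (8 treated, 4 blank), 3 sampling areas per plot, 9 grids per
area, giving 324 grid-level spectral samples.  Each sample carries
5-band canopy reflectance (B/G/R/RE/NIR) and a canopy nitrogen
concentration (CNC, % of dry mass).

The generative model is a single latent "vigor" score, linear in the
irrigation and fertilizer rates, that drives both CNC and the band
responses: visible bands (B, G, R) darken with vigor while red-edge
and NIR brighten, reproducing the correlation-sign structure of a
healthy green canopy.

Also houses the Kjeldahl total-nitrogen titration formula used to turn
wet-chemistry measurements into CNC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

BANDS = ("B", "G", "R", "RE", "NIR")
#: Band centre wavelengths, nm (metadata only; computation keys on names).
BAND_WAVELENGTHS_NM = {"B": 475, "G": 560, "R": 668, "RE": 717, "NIR": 840}

IRRIGATION_LEVELS = (0, 180, 300)  # m3/ha
FERTILIZER_LEVELS = (0.0, 0.9, 1.0, 1.1, 1.2)  # relative to standard rate


@dataclass(frozen=True)
class PlotSpec:
    plot_id: str
    irrigation_level: float  # m3/ha
    fertilizer_level: float  # relative rate


@dataclass(frozen=True)
class TreatmentDesign:
    """Plot layout of the trial: which plot gets which water/fertilizer."""

    plots: tuple[PlotSpec, ...]
    areas_per_plot: int = 3
    grids_per_area: int = 9

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.plots]
        if len(set(ids)) != len(ids):
            raise ValueError("plot_ids must be unique")
        if not self.plots:
            raise ValueError("design needs at least one plot")
        if self.areas_per_plot < 1 or self.grids_per_area < 1:
            raise ValueError("areas_per_plot and grids_per_area must be >= 1")

    @property
    def n_samples(self) -> int:
        return len(self.plots) * self.areas_per_plot * self.grids_per_area

    @classmethod
    def default(cls, areas_per_plot: int = 3, grids_per_area: int = 9) -> "TreatmentDesign":
        """The 12-plot layout: 2 irrigation x 4 fertilizer treatments plus
        4 blank plots with neither water nor fertilizer."""
        plots = []
        for w, wtag in ((180, "W0.6"), (300, "W1.0")):
            for f in (0.9, 1.0, 1.1, 1.2):
                plots.append(PlotSpec(f"{wtag}F{f:.1f}", w, f))
        for i in range(1, 5):
            plots.append(PlotSpec(f"BL{i}", 0, 0.0))
        return cls(tuple(plots), areas_per_plot, grids_per_area)


@dataclass(frozen=True)
class GeneratorConfig:
    """Coefficients of the latent-vigor generative model.

    vigor  = intercept + b_irrigation*W + b_fertilizer*F
             + b_interaction*W*F + N(0, vigor_sd)      (per grid)
    cnc    = cnc_mean + cnc_slope*vigor + N(0, cnc_sd)          [%]
    band_b = baseline_b + slope_b*vigor + N(0, band_sd_b), clipped

    Default band slopes are negative for B/G/R and positive for RE/NIR
    so that better-watered, better-fed canopies look darker in the
    visible and brighter in the red edge and NIR.
    """

    seed: int = 0
    vigor_intercept: float = 0.0
    b_irrigation: float = 1.0 / 300.0  # per m3/ha; full irrigation adds 1.0
    b_fertilizer: float = 0.5  # per unit relative rate
    b_interaction: float = 0.0
    vigor_sd: float = 0.2
    cnc_mean: float = 1.7  # % at zero vigor
    cnc_slope: float = 0.35  # % per unit vigor
    cnc_sd: float = 0.05  # %
    band_baseline: dict[str, float] = field(
        default_factory=lambda: {"B": 0.05, "G": 0.08, "R": 0.07, "RE": 0.25, "NIR": 0.45}
    )
    band_slope: dict[str, float] = field(
        default_factory=lambda: {"B": -0.015, "G": -0.010, "R": -0.030, "RE": 0.040, "NIR": 0.100}
    )
    band_sd: dict[str, float] = field(
        default_factory=lambda: {b: 0.01 for b in BANDS}
    )
    clip_lo: float = 0.001
    clip_hi: float = 0.999

    def __post_init__(self) -> None:
        if not 0 < self.clip_lo < self.clip_hi < 1:
            raise ValueError("clip bounds must satisfy 0 < lo < hi < 1")
        for b in BANDS:
            if not 0 < self.band_baseline[b] < 1:
                raise ValueError(f"baseline reflectance for {b} must lie in (0,1)")
            if self.band_sd[b] < 0:
                raise ValueError(f"band noise sd for {b} must be >= 0")
        if self.vigor_sd < 0 or self.cnc_sd < 0:
            raise ValueError("noise sds must be >= 0")

    def scaled_noise(self, factor: float) -> "GeneratorConfig":
        """Same signal, all noise standard deviations scaled by `factor`."""
        return replace(
            self,
            vigor_sd=self.vigor_sd * factor,
            cnc_sd=self.cnc_sd * factor,
            band_sd={b: s * factor for b, s in self.band_sd.items()},
        )

    def to_yaml(self) -> str:
        d = {
            "seed": self.seed,
            "vigor_intercept": self.vigor_intercept,
            "b_irrigation": self.b_irrigation,
            "b_fertilizer": self.b_fertilizer,
            "b_interaction": self.b_interaction,
            "vigor_sd": self.vigor_sd,
            "cnc_mean": self.cnc_mean,
            "cnc_slope": self.cnc_slope,
            "cnc_sd": self.cnc_sd,
            "band_baseline": dict(self.band_baseline),
            "band_slope": dict(self.band_slope),
            "band_sd": dict(self.band_sd),
            "clip_lo": self.clip_lo,
            "clip_hi": self.clip_hi,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls(**yaml.safe_load(text))


@dataclass(frozen=True)
class SpectralSample:
    """One grid cell: identifiers, treatment, 5-band reflectance, CNC."""

    plot_id: str
    area_index: int
    grid_index: int
    irrigation_level: float
    fertilizer_level: float
    reflectance: dict[str, float]
    cnc: float | None = None

    def __post_init__(self) -> None:
        for b, v in self.reflectance.items():
            if not 0 < v < 1:
                raise ValueError(f"reflectance[{b}]={v} outside (0,1)")
        if self.cnc is not None and self.cnc < 0:
            raise ValueError("cnc must be >= 0 when present")


def generate_dataset(
    design: TreatmentDesign | None = None,
    config: GeneratorConfig | None = None,
) -> list[SpectralSample]:
    """Draw one synthetic grid-level dataset.

    Deterministic for a fixed config: a single seed sequence spawns one
    child stream per plot (in plot order), so regenerating a subset of
    plots reproduces the same samples.
    """
    design = design or TreatmentDesign.default()
    config = config or GeneratorConfig()
    root = np.random.SeedSequence(config.seed)
    plot_seeds = root.spawn(len(design.plots))

    samples: list[SpectralSample] = []
    for plot, seq in zip(design.plots, plot_seeds):
        rng = np.random.default_rng(seq)
        n = design.areas_per_plot * design.grids_per_area
        vigor = (
            config.vigor_intercept
            + config.b_irrigation * plot.irrigation_level
            + config.b_fertilizer * plot.fertilizer_level
            + config.b_interaction * plot.irrigation_level * plot.fertilizer_level
            + rng.normal(0.0, config.vigor_sd, size=n)
        )
        cnc = config.cnc_mean + config.cnc_slope * vigor + rng.normal(0.0, config.cnc_sd, size=n)
        cnc = np.clip(cnc, 0.0, None)
        refl = {}
        for b in BANDS:
            r = (
                config.band_baseline[b]
                + config.band_slope[b] * vigor
                + rng.normal(0.0, config.band_sd[b], size=n)
            )
            refl[b] = np.clip(r, config.clip_lo, config.clip_hi)
        k = 0
        for area in range(design.areas_per_plot):
            for grid in range(design.grids_per_area):
                samples.append(
                    SpectralSample(
                        plot_id=plot.plot_id,
                        area_index=area,
                        grid_index=grid,
                        irrigation_level=plot.irrigation_level,
                        fertilizer_level=plot.fertilizer_level,
                        reflectance={b: float(refl[b][k]) for b in BANDS},
                        cnc=float(cnc[k]),
                    )
                )
                k += 1
    return samples


def samples_to_frame(samples: list[SpectralSample]) -> pd.DataFrame:
    """Tabulate samples with the canonical CSV column layout."""
    rows = []
    for s in samples:
        row = {
            "plot_id": s.plot_id,
            "area": s.area_index,
            "grid": s.grid_index,
            "irrigation": s.irrigation_level,
            "fertilizer": s.fertilizer_level,
        }
        row.update({f"refl_{b}": s.reflectance[b] for b in BANDS})
        row["cnc"] = np.nan if s.cnc is None else s.cnc
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_samples(df: pd.DataFrame) -> list[SpectralSample]:
    out = []
    for _, r in df.iterrows():
        cnc = r.get("cnc", np.nan)
        out.append(
            SpectralSample(
                plot_id=str(r["plot_id"]),
                area_index=int(r["area"]),
                grid_index=int(r["grid"]),
                irrigation_level=float(r["irrigation"]),
                fertilizer_level=float(r["fertilizer"]),
                reflectance={b: float(r[f"refl_{b}"]) for b in BANDS},
                cnc=None if pd.isna(cnc) else float(cnc),
            )
        )
    return out


@dataclass(frozen=True)
class KjeldahlInput:
    """Acid-titration measurement for one dried, ground leaf sample."""

    v1: float  # acid consumed, mL
    v0: float  # blank titration volume, mL
    c: float  # acid concentration, mol/L
    m: float  # sample mass, g

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("sample mass must be > 0")
        if self.c <= 0:
            raise ValueError("acid concentration must be > 0")
        if self.v1 < self.v0:
            raise ValueError("titration volume v1 must be >= blank v0")


def kjeldahl_tn(inp: KjeldahlInput) -> float:
    """Total nitrogen (%) from a Kjeldahl titration.

    TN% = (V1 - V0) * C * 0.014 / m * 100, where 0.014 g is the mass of
    nitrogen equivalent to 1 mmol of standard acid.
    """
    return (inp.v1 - inp.v0) * inp.c * 0.014 / inp.m * 100.0
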