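"""End-to-end pipeline: measurements + weather + metadata + harvest -> analyses.

``run_pipeline`` orchestrates the stages in order — curve fitting, trait
derivation, harvest traits, heritability, correlations, species ANOVA,
duration-binned correlations, species-adjusted extremes and geographic
regression — writing each stage's CSV plus a JSON run manifest (settings,
seed, row counts, exclusions).  Given the same inputs, config and seed the
outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitConfig, fit_stem_table
from .io import write_csv
from .quantgen import (
    NonEstimableError,
    estimate_dry_weight,
    pearson_correlation_matrix,
    species_anova_tukey,
    VarianceComponents,
)
from .seasonal import (
    bin_by_duration,
    composite_traits,
    extremes_table,
    geographic_regression,
    within_bin_correlation,
)

__all__ = ["AnalysisConfig", "PipelineConfig", "run_pipeline"]

GROWTH_TRAITS = ["max_gr", "day_max_gr", "start_logg", "end_logg", "duration", "auc"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for the downstream statistical stages."""

    bin_width: float = 10.0
    min_count: int = 10
    extremes_fraction: float = 0.05
    alpha: float = 0.05
    auc_window: tuple[float, float] = (0.0, 365.0)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and settings for a full run."""

    measurements: str
    metadata: str
    harvest: str | None = None
    weather: str | None = None
    outdir: str = "results"
    fit: FitConfig = field(default_factory=FitConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys mirror the dataclass fields; ``fit:`` and ``analysis:``
    are nested mappings of the respective settings.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fit = FitConfig(**raw.pop("fit", {}))
    analysis = raw.pop("analysis", {})
    if "auc_window" in analysis:
        analysis["auc_window"] = tuple(analysis["auc_window"])
    return PipelineConfig(fit=fit, analysis=AnalysisConfig(**analysis), **raw)


def build_trait_table(traits_df: pd.DataFrame, metadata: pd.DataFrame,
                      harvest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join derived traits with plant metadata and harvest-derived DW/MC."""
    table = traits_df.merge(metadata, on="plant_id", how="left")
    if harvest is not None and len(harvest):
        hh = harvest.copy()
        mc, dw = zip(*(estimate_dry_weight(r.wet_g, r.sub_wet_g, r.sub_dry_g)
                       for r in hh.itertuples()))
        hh["mc"], hh["dw"] = mc, dw
        table = table.merge(hh[["plant_id", "year", "dw", "mc"]],
                            on=["plant_id", "year"], how="left")
    return table


def heritability_table(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """REML variance components and H² per trait; non-estimable traits noted."""
    rows = []
    for trait in traits:
        if trait not in table.columns:
            continue
        try:
            res = VarianceComponents(table[trait], table["genotype"], table["block"]).fit()
            rows.append({"trait": trait, "vg": res.v_g, "vblock": res.v_block,
                         "ve": res.v_e, "h2": res.h2, "note": ""})
        except NonEstimableError as err:
            rows.append({"trait": trait, "vg": np.nan, "vblock": np.nan, "ve": np.nan,
                         "h2": np.nan, "note": str(err)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.outdir``."""
    from .io import (measurements_to_series, read_harvest, read_measurements,
                     read_metadata, read_weather)
    from .thermal import accumulate_thermal_time

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stemgrowth_version": __version__,
        "seed": config.seed,
        "fit": dataclasses.asdict(config.fit),
        "analysis": dataclasses.asdict(config.analysis),
        "counts": {},
        "stages": [],
    }

    meas = read_measurements(config.measurements)
    metadata = read_metadata(config.metadata)
    harvest = read_harvest(config.harvest) if config.harvest else None
    manifest["counts"]["measurement_rows"] = int(len(meas))
    manifest["counts"]["plants"] = int(metadata["plant_id"].nunique())

    if config.weather:
        weather = read_weather(config.weather)
        thermal = accumulate_thermal_time(weather)
        write_csv(thermal, outdir / "thermal.csv")
        manifest["stages"].append("thermal")

    series = measurements_to_series(meas)
    fit_cfg = dataclasses.replace(config.fit, seed=config.seed)
    fits, traits, exclusions = fit_stem_table(series, fit_cfg,
                                              window=config.analysis.auc_window)
    write_csv(fits, outdir / "fits.csv")
    write_csv(traits, outdir / "traits.csv")
    write_csv(pd.DataFrame(exclusions, columns=["plant_id", "year", "reason", "detail"]),
              outdir / "exclusions.csv")
    manifest["counts"]["fits"] = int(len(fits))
    manifest["counts"]["accepted_traits"] = int(len(traits))
    manifest["counts"]["excluded"] = int(len(exclusions))
    manifest["stages"] += ["fit", "traits"]

    table = build_trait_table(traits, metadata, harvest)
    table = composite_traits(table)
    write_csv(table, outdir / "trait_table.csv")

    stat_traits = [t for t in GROWTH_TRAITS + ["dw", "mc", "day_at_15cm"]
                   if t in table.columns]

    herit = heritability_table(table, stat_traits)
    write_csv(herit, outdir / "heritability.csv")
    manifest["stages"].append("heritability")

    corr = pearson_correlation_matrix(table, stat_traits)
    write_csv(corr, outdir / "correlations.csv")
    manifest["stages"].append("correlations")

    anova_rows = []
    letters_rows = []
    for trait in stat_traits:
        try:
            res = species_anova_tukey(table, trait, alpha=config.analysis.alpha)
        except NonEstimableError:
            continue
        term = "C(species, Sum)"
        anova_rows.append({"trait": trait,
                           "F": float(res["anova"].loc[term, "F"]),
                           "p": float(res["anova"].loc[term, "PR(>F)"])})
        for sp, letter in res["letters"].items():
            letters_rows.append({"trait": trait, "species_group": sp, "letters": letter})
    write_csv(pd.DataFrame(anova_rows), outdir / "anova.csv")
    write_csv(pd.DataFrame(letters_rows), outdir / "tukey_letters.csv")
    manifest["stages"].append("anova")

    bins = bin_by_duration(table, config.analysis.bin_width, config.analysis.min_count)
    binned_frames = []
    for y_trait in [t for t in ("dw", "max_gr") if t in table.columns]:
        binned_frames.append(within_bin_correlation(
            bins, table, x_trait="start_logg", y_trait=y_trait,
            alpha=config.analysis.alpha))
    binned = (pd.concat(binned_frames, ignore_index=True) if binned_frames
              else pd.DataFrame())
    write_csv(binned, outdir / "binned_correlations.csv")
    manifest["counts"]["retained_bins"] = int(len(bins))
    manifest["stages"].append("binned")

    ext_traits = stat_traits + ["maxgr_duration_ratio", "rank_sum"]
    extremes = extremes_table(table, [t for t in ext_traits if t in table.columns],
                              fraction=config.analysis.extremes_fraction)
    write_csv(extremes, outdir / "extremes.csv")
    manifest["stages"].append("extremes")

    geo_frames = []
    if "day_at_15cm" in table.columns and table["lat"].notna().any():
        geo = geographic_regression(table.dropna(subset=["lat"]), "day_at_15cm",
                                    alpha=config.analysis.alpha)
        gt = geo["table"]
        geo_frames.append(gt)
        manifest["geo_selected"] = geo["selected"]
    write_csv(pd.concat(geo_frames, ignore_index=True) if geo_frames else pd.DataFrame(),
              outdir / "geo_regression.csv")
    manifest["stages"].append("geo")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"outdir": outdir, "manifest": manifest, "table": table, "fits": fits,
            "heritability": herit, "binned": binned, "extremes": extremes}
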