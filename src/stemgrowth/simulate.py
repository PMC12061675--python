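"""Synthetic diversity-trial generator with known ground truth.

Emulates the structure of a large perennial-grass diversity trial: ~900
genotypes in 3 fully randomised blocks, several species groups with
distinct growth-trait distributions, noisy stem-elongation visits through
the season, a sinusoidal temperate weather year, and harvest wet/dry
weights whose moisture content tracks late growth.

Ground truth is constructed trait-first: per-genotype targets for MaxGR,
DayMaxGR and Duration are drawn from species-specific distributions and the
four Richards parameters are solved from them exactly —

    c = ln(u_hi/u_lo) / Duration        (u_hi, u_lo the curvature roots of d)
    a = MaxGR · Duration · (1+d)^((d+1)/d) / ln(u_hi/u_lo)
    b = d · exp(c · DayMaxGR)

so the species means/SDs of the *derived traits* are controlled directly
(field studies report traits, not parameters).  Genotype effects are shared
across blocks and block/residual effects are added per plant, so the planted
broad-sense heritability of each trait is recoverable by REML.  A timing
shift proportional to collection-site latitude gives early growth a planted
geographic signal.

The species trait means/SDs and group sizes default to values representative
of a real *Miscanthus* diversity trial (2016 season scale: population MaxGR
mean ~2.1 cm/d, Duration mean ~74 d); these are calibration targets for the
generator, not a reproduction of any field dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .fitting import StemSeries
from .richards import Domain, RichardsParams, _curvature_roots_u, auc, day_at_height, richards_value

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "SPECIES_DEFAULTS",
    "params_from_traits",
    "generate_population",
    "generate_measurements",
    "generate_weather",
    "generate_harvest",
    "simulate_trial",
    "simulate_balanced_trait",
    "simulate_binned_population",
    "simulate_geographic_timing",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Trait distribution and site-of-origin distribution of one species group.

    ``maxgr``, ``day_max_gr`` and ``duration`` are (mean, sd) pairs of the
    within-group phenotypic distribution; ``lat``/``lon``/``alt_m`` are
    (mean, sd) of collection-site coordinates.
    """

    name: str
    n: int
    maxgr: tuple[float, float]
    day_max_gr: tuple[float, float]
    duration: tuple[float, float]
    lat: tuple[float, float] = (35.0, 3.0)
    lon: tuple[float, float] = (130.0, 8.0)
    alt_m: tuple[float, float] = (300.0, 200.0)


# Group sizes and 2016-season trait means/SDs representative of a large
# Miscanthus diversity trial; coordinates sketch the species' native ranges
# (M. floridulus southerly; M. lutarioriparius central China; M. sinensis
# groups across Japan/Korea; M. sacchariflorus northerly).
SPECIES_DEFAULTS: tuple[SpeciesSpec, ...] = (
    SpeciesSpec("M_floridulus", 47, (1.0, 0.4), (211.1, 19.2), (96.2, 33.3),
                lat=(24.0, 2.0), lon=(121.0, 3.0), alt_m=(250.0, 150.0)),
    SpeciesSpec("M_lutarioriparius", 79, (2.8, 0.8), (175.1, 10.6), (76.7, 11.3),
                lat=(29.5, 1.0), lon=(113.0, 3.0), alt_m=(50.0, 30.0)),
    SpeciesSpec("M_sacchariflorus", 245, (2.5, 0.7), (174.6, 10.0), (63.8, 10.1),
                lat=(41.0, 3.0), lon=(127.0, 6.0), alt_m=(200.0, 150.0)),
    SpeciesSpec("M_sinensis_A", 127, (1.5, 0.5), (184.6, 15.2), (87.4, 20.1),
                lat=(33.0, 1.5), lon=(132.0, 3.5), alt_m=(300.0, 250.0)),
    SpeciesSpec("M_sinensis_B", 55, (2.3, 0.4), (180.6, 9.9), (59.3, 10.0),
                lat=(36.0, 2.0), lon=(138.0, 3.0), alt_m=(400.0, 300.0)),
    SpeciesSpec("M_sinensis_C", 245, (1.9, 0.6), (182.0, 14.4), (78.0, 22.3),
                lat=(38.0, 2.0), lon=(139.5, 2.0), alt_m=(350.0, 300.0)),
    SpeciesSpec("M_sinensis_D", 56, (2.0, 0.4), (184.2, 17.3), (76.8, 14.4),
                lat=(36.0, 2.0), lon=(137.0, 3.0), alt_m=(400.0, 300.0)),
    SpeciesSpec("Hybrid1", 3, (2.1, 0.4), (178.0, 7.5), (71.4, 13.1)),
    SpeciesSpec("Hybrid2", 6, (2.2, 0.5), (179.2, 14.2), (66.4, 5.4)),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic trial.

    ``h2`` is the planted broad-sense heritability per trait (error variance
    is set from the realized genotype-target variance so the planted
    Vg/(Vg+Ve) hits these values); ``block_var_frac`` scales the block
    variance relative to the error variance.  ``noise_sd`` is the stem-length
    measurement noise in cm; ``schedule`` the visit days of year (roughly
    fortnightly, May–October).  ``lat_timing_slope`` shifts a genotype's
    whole seasonal trajectory (days per degree latitude from its species'
    centre).  Harvest: dry weight is proportional to AUC with multiplicative
    noise; moisture content is a logistic function of late growth
    (standardized EndLogG minus standardized MaxGR).  ``dw_start_corr``, when
    set, replaces the AUC-proportional dry weight with a construction that
    plants a chosen within-Duration-band correlation between StartLogG and
    dry weight ((lo, hi, rho) bands).
    """

    n_genotypes: int = 900
    n_blocks: int = 3
    species: tuple[SpeciesSpec, ...] = SPECIES_DEFAULTS
    h2: dict = field(default_factory=lambda: {"max_gr": 0.77, "day_max_gr": 0.66,
                                              "duration": 0.65})
    block_var_frac: float = 0.2
    d_sigma: float = 0.25
    noise_sd: float = 5.0
    max_stem_bias: float = 0.0
    schedule: tuple = (121, 137, 154, 170, 187, 204, 220, 237, 254, 270, 287, 304)
    auc_window: tuple[float, float] = (0.0, 365.0)
    lat_timing_slope: float = 1.0
    # weather
    tmean_c: float = 9.5
    tamp_c: float = 5.5
    tphase_day: float = 110.0
    tspread_c: float = 7.0
    tnoise_c: float = 2.0
    # harvest
    dw_kappa: float = 0.05       # g per cm·d of AUC
    dw_cv: float = 0.3
    mc_lo: float = 0.2
    mc_hi: float = 0.7
    mc_noise: float = 0.5
    sub_wet_g: float = 200.0
    dw_start_corr: tuple | None = None
    seed: int = 0


_TRAITS = ("max_gr", "day_max_gr", "duration")


def params_from_traits(max_gr: float, day_max_gr: float, duration: float, d: float,
                       domain: Domain = Domain.julian_day) -> RichardsParams:
    """Solve (a, b, c) exactly from target MaxGR, DayMaxGR, Duration and shape d."""
    if duration <= 0 or max_gr <= 0 or d <= 0:
        raise ValueError("targets must be positive")
    u_hi, u_lo = _curvature_roots_u(d)
    log_ratio = math.log(u_hi / u_lo)
    c = log_ratio / duration
    a = max_gr * duration * (1.0 + d) ** ((d + 1.0) / d) / log_ratio
    b = d * math.exp(c * day_max_gr)
    return RichardsParams(a=a, b=b, c=c, d=d, domain=domain)


def generate_population(config: SimConfig | None = None,
                        seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the trial population; returns (metadata, truth).

    ``metadata`` is one row per plant (plant_id, genotype, block,
    species_group, lat, lon, alt_m).  ``truth`` additionally carries the true
    Richards parameters and the true derived traits per plant plus the
    genotype-level trait targets (columns ``*_geno``).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    specs = cfg.species
    fracs = np.array([s.n for s in specs], float)
    fracs /= fracs.sum()
    sp_idx = rng.choice(len(specs), size=cfg.n_genotypes, p=fracs)

    # genotype-level draws -------------------------------------------------
    geno_rows = []
    for g in range(cfg.n_genotypes):
        sp = specs[sp_idx[g]]
        lat = rng.normal(*sp.lat)
        row = {
            "genotype": f"G{g:04d}", "species_group": sp.name,
            "lat": lat, "lon": rng.normal(*sp.lon),
            "alt_m": max(rng.normal(*sp.alt_m), 0.0),
            "d_shape": float(np.clip(rng.lognormal(0.0, cfg.d_sigma), 0.2, 5.0)),
        }
        for trait in _TRAITS:
            mean, sd = getattr(sp, "maxgr" if trait == "max_gr" else trait)
            row[f"{trait}_geno"] = mean + math.sqrt(cfg.h2[trait]) * sd * rng.standard_normal()
        # latitude shifts the whole trajectory (earlier at lower latitude)
        row["day_max_gr_geno"] += cfg.lat_timing_slope * (lat - sp.lat[0])
        geno_rows.append(row)
    geno = pd.DataFrame(geno_rows)

    # environmental variances from the realized genotype-target variances --
    v_e, v_block = {}, {}
    for trait in _TRAITS:
        vg_hat = float(np.var(geno[f"{trait}_geno"], ddof=1))
        v_e[trait] = vg_hat * (1.0 - cfg.h2[trait]) / cfg.h2[trait]
        v_block[trait] = cfg.block_var_frac * v_e[trait]
    # block effects are centred so the block lottery cannot shift the
    # population mean away from the species calibration targets
    block_eff = {}
    for trait in _TRAITS:
        eff = rng.normal(0.0, math.sqrt(v_block[trait]), cfg.n_blocks)
        block_eff[trait] = eff - eff.mean()

    # plant-level realization ----------------------------------------------
    rows = []
    for g in range(cfg.n_genotypes):
        grow = geno.iloc[g]
        for j in range(cfg.n_blocks):
            for attempt in range(60):
                vals = {}
                ok = True
                for trait in _TRAITS:
                    vals[trait] = (grow[f"{trait}_geno"] + block_eff[trait][j]
                                   + rng.normal(0.0, math.sqrt(v_e[trait])))
                if vals["duration"] < 8.0 or vals["max_gr"] <= 0.05:
                    ok = False
                if ok:
                    try:
                        params = params_from_traits(vals["max_gr"], vals["day_max_gr"],
                                                    vals["duration"], grow["d_shape"])
                    except ValueError:
                        ok = False
                    else:
                        ok = params.a > 16.0 and 1e-4 < params.c <= 1.0
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"could not realize feasible traits for genotype {grow['genotype']}"
                )
            u_hi, u_lo = _curvature_roots_u(params.d)
            start = math.log(params.b / u_hi) / params.c
            end = math.log(params.b / u_lo) / params.c
            rows.append({
                "plant_id": f"{grow['genotype']}_B{j + 1}",
                "genotype": grow["genotype"], "block": j + 1,
                "species_group": grow["species_group"],
                "lat": grow["lat"], "lon": grow["lon"], "alt_m": grow["alt_m"],
                "a": params.a, "b": params.b, "c": params.c, "d": params.d,
                "max_gr": vals["max_gr"], "day_max_gr": vals["day_max_gr"],
                "duration": vals["duration"],
                "start_logg": start, "end_logg": end,
                "auc": auc(params, cfg.auc_window),
                "day_at_15cm": day_at_height(params, 15.0) if params.a > 15 else np.nan,
                "max_gr_geno": grow["max_gr_geno"],
                "day_max_gr_geno": grow["day_max_gr_geno"],
                "duration_geno": grow["duration_geno"],
            })
    truth = pd.DataFrame(rows)
    meta_cols = ["plant_id", "genotype", "block", "species_group", "lat", "lon", "alt_m"]
    return truth[meta_cols].copy(), truth


def generate_measurements(truth: pd.DataFrame, config: SimConfig | None = None,
                          seed: int | None = None) -> list[StemSeries]:
    """Noisy stem-elongation series for every plant in ``truth``.

    Lengths are the true curve at the scheduled days plus i.i.d. Gaussian
    noise (SD ``config.noise_sd``), plus an optional small positive bias
    emulating recording the longest of three stems, truncated at 0.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng((cfg.seed + 1) if seed is None else seed)
    days = np.asarray(cfg.schedule, float)
    series = []
    for row in truth.itertuples():
        params = RichardsParams(row.a, row.b, row.c, row.d)
        y = richards_value(params, days)
        y = y + cfg.max_stem_bias + rng.normal(0.0, cfg.noise_sd, len(days))
        series.append(StemSeries(row.plant_id, 2016, days, np.maximum(y, 0.0)))
    return series


def generate_weather(config: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """A sinusoidal temperate weather year (day, tmax_c, tmin_c), days 1–365."""
    cfg = config or SimConfig()
    rng = np.random.default_rng((cfg.seed + 2) if seed is None else seed)
    days = np.arange(1, 366)
    tmean = (cfg.tmean_c + cfg.tamp_c * np.sin(2 * np.pi * (days - cfg.tphase_day) / 365.0)
             + rng.normal(0.0, cfg.tnoise_c, len(days)))
    spread = cfg.tspread_c * rng.uniform(0.6, 1.4, len(days))
    return pd.DataFrame({"day": days, "tmax_c": tmean + spread / 2,
                         "tmin_c": tmean - spread / 2})


def _banded_dw(truth: pd.DataFrame, cfg: SimConfig, rng) -> np.ndarray:
    """Dry weight with a planted within-Duration-band StartLogG correlation."""
    mean_dw = cfg.dw_kappa * float(np.nanmean(truth["auc"]))
    z = rng.standard_normal(len(truth))
    dw = mean_dw * (1.0 + cfg.dw_cv * z)  # default: uncorrelated
    dur = truth["duration"].to_numpy(float)
    start = truth["start_logg"].to_numpy(float)
    for lo, hi, rho in cfg.dw_start_corr:
        m = (dur >= lo) & (dur < hi)
        if m.sum() < 3:
            continue
        zs = (start[m] - start[m].mean()) / max(start[m].std(), 1e-12)
        mix = rho * zs + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(m.sum())
        dw[m] = mean_dw * (1.0 + cfg.dw_cv * mix)
    return np.maximum(dw, 0.02 * mean_dw)


def generate_harvest(truth: pd.DataFrame, config: SimConfig | None = None,
                     seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harvest records; returns (harvest table, truth with dw/mc columns).

    Dry weight is κ·AUC·(1+noise); moisture content is a logistic function of
    standardized EndLogG minus standardized MaxGR (late-growing, slow plants
    carry the wettest biomass).  Subsample wet/dry weights are back-computed
    so the moisture-content arithmetic round-trips the planted values exactly.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng((cfg.seed + 3) if seed is None else seed)
    t = truth.copy()
    if cfg.dw_start_corr is not None:
        dw = _banded_dw(t, cfg, rng)
    else:
        dw = cfg.dw_kappa * t["auc"].to_numpy(float) * (1.0 + rng.normal(0.0, cfg.dw_cv, len(t)))
        dw = np.maximum(dw, 0.02 * cfg.dw_kappa * float(np.nanmean(t["auc"])))

    def _z(col):
        v = t[col].to_numpy(float)
        return (v - np.nanmean(v)) / max(np.nanstd(v), 1e-12)

    logit_arg = _z("end_logg") - _z("max_gr") + rng.normal(0.0, cfg.mc_noise, len(t))
    mc = cfg.mc_lo + (cfg.mc_hi - cfg.mc_lo) * expit(logit_arg)
    t["dw"], t["mc"] = dw, mc

    plant_wet = dw / (1.0 - mc)
    sub_wet = np.minimum(cfg.sub_wet_g, 0.5 * plant_wet)
    harvest = pd.DataFrame({
        "plant_id": t["plant_id"], "year": 2016,
        "wet_g": plant_wet, "sub_wet_g": sub_wet, "sub_dry_g": sub_wet * (1.0 - mc),
    })
    return harvest, t


def simulate_trial(config: SimConfig | None = None) -> dict:
    """Generate a full synthetic trial: metadata, truth, measurements, weather, harvest."""
    cfg = config or SimConfig()
    metadata, truth = generate_population(cfg)
    harvest, truth = generate_harvest(truth, cfg)
    series = generate_measurements(truth, cfg)
    weather = generate_weather(cfg)
    return {"metadata": metadata, "truth": truth, "series": series,
            "weather": weather, "harvest": harvest, "config": cfg}


# ---------------------------------------------------------------------------
# focused generators for single-stage studies


def simulate_balanced_trait(n_genotypes: int, n_blocks: int, v_g: float, v_block: float,
                            v_e: float, mean: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Balanced genotype × block table of one trait with known variance split."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, math.sqrt(v_g), n_genotypes)
    b = rng.normal(0.0, math.sqrt(v_block), n_blocks)
    e = rng.normal(0.0, math.sqrt(v_e), (n_genotypes, n_blocks))
    y = mean + g[:, None] + b[None, :] + e
    return pd.DataFrame({
        "genotype": np.repeat([f"G{i:04d}" for i in range(n_genotypes)], n_blocks),
        "block": np.tile(np.arange(1, n_blocks + 1), n_genotypes),
        "value": y.ravel(),
    })


def simulate_binned_population(
    n: int = 600,
    bands: tuple = ((40.0, 110.0, -0.5), (110.0, 140.0, 0.0)),
    duration_range: tuple[float, float] = (40.0, 140.0),
    mean_dw: float = 1500.0,
    dw_cv: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Trait table with a planted within-Duration-band r(StartLogG, DW).

    Durations are uniform over ``duration_range``; StartLogG is seasonal
    (mean day 145); within each (lo, hi, rho) band dry weight is built from
    the band-standardized StartLogG at the requested correlation.  MaxGR is a
    decreasing function of Duration only (the rate–duration tradeoff) and is
    independent of StartLogG, so within-band r(StartLogG, MaxGR) is centred
    on zero — useful for checking that binning controls the confound.
    """
    rng = np.random.default_rng(seed)
    duration = rng.uniform(*duration_range, n)
    start = rng.normal(145.0, 15.0, n)
    dw = mean_dw * (1.0 + dw_cv * rng.standard_normal(n))
    for lo, hi, rho in bands:
        m = (duration >= lo) & (duration < hi)
        if m.sum() < 3:
            continue
        zs = (start[m] - start[m].mean()) / max(start[m].std(), 1e-12)
        mix = rho * zs + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(m.sum())
        dw[m] = mean_dw * (1.0 + dw_cv * mix)
    max_gr = 150.0 / duration * (1.0 + 0.1 * rng.standard_normal(n))
    return pd.DataFrame({
        "plant_id": [f"P{i:05d}" for i in range(n)],
        "duration": duration, "start_logg": start,
        "dw": np.maximum(dw, 0.02 * mean_dw), "max_gr": max_gr,
    })


def simulate_geographic_timing(
    n: int = 200,
    intercept: float = 110.0,
    lat_slope: float = 1.2,
    lat_ref: float = 30.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plants whose day-to-15-cm depends linearly on collection latitude only."""
    rng = np.random.default_rng(seed)
    lat = rng.uniform(25.0, 45.0, n)
    lon = rng.uniform(100.0, 145.0, n)
    alt = rng.uniform(0.0, 1500.0, n)
    day15 = intercept + lat_slope * (lat - lat_ref) + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({
        "plant_id": [f"P{i:05d}" for i in range(n)],
        "lat": lat, "lon": lon, "alt_m": alt, "day_at_15cm": day15,
    })
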