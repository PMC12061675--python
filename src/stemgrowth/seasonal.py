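"""Seasonal procedures: duration binning, species-adjusted extremes,
composite traits and regression of early-growth timing on site of origin.

The duration-binning analysis addresses a confound: plants with high maximum
growth rates tend to have short logarithmic growth phases, so a raw
correlation between growth onset and yield mixes the rate–duration tradeoff
with the effect of timing.  Grouping plants into bins of similar Duration
(3–10 d wide, bins with fewer than 10 plants discarded) and correlating
within bins isolates the effect of when growth starts from how long it lasts.

The extremes table asks which species are over-represented in the population
tails: for each trait the highest and lowest 5% of plants are taken
population-wide and each species' share of the tail is expressed as a
percentage of that species' own membership, adjusting for unequal species
sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DurationBin",
    "bin_by_duration",
    "within_bin_correlation",
    "composite_traits",
    "extremes_table",
    "geographic_regression",
]


@dataclass(frozen=True)
class DurationBin:
    """A half-open Duration interval [lo, hi) and its member plants."""

    lo: float
    hi: float
    plant_ids: tuple
    n: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n", len(self.plant_ids))


def bin_by_duration(
    table: pd.DataFrame,
    bin_width: float = 10.0,
    min_count: int = 10,
    duration_col: str = "duration",
    id_col: str = "plant_id",
) -> list[DurationBin]:
    """Partition plants into Duration bins aligned to multiples of the width.

    Bins are [k*w, (k+1)*w); bins with fewer than ``min_count`` plants are
    discarded.  Every plant with a finite Duration lands in exactly one bin
    before the count filter.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sub = table[[id_col, duration_col]].dropna()
    if sub.empty:
        return []
    idx = np.floor(sub[duration_col].to_numpy(float) / bin_width).astype(int)
    bins = []
    for k in sorted(set(idx)):
        ids = tuple(sub.loc[idx == k, id_col])
        if len(ids) >= min_count:
            bins.append(DurationBin(lo=k * bin_width, hi=(k + 1) * bin_width, plant_ids=ids))
    return bins


def within_bin_correlation(
    bins: list[DurationBin],
    table: pd.DataFrame,
    x_trait: str = "start_logg",
    y_trait: str = "dw",
    alpha: float = 0.05,
    id_col: str = "plant_id",
) -> pd.DataFrame:
    """Pearson correlation of two traits within each retained Duration bin.

    Returns one row per bin: bin_lo, bin_hi, n, r, p, significant (p < alpha),
    note ("zero variance" when the correlation is undefined in a bin).
    """
    indexed = table.set_index(id_col)
    rows = []
    for b in bins:
        sub = indexed.loc[list(b.plant_ids), [x_trait, y_trait]].dropna()
        x = sub[x_trait].to_numpy(float)
        y = sub[y_trait].to_numpy(float)
        r = p = np.nan
        note = ""
        if len(x) < 3:
            note = "fewer than 3 complete pairs"
        elif np.std(x) == 0 or np.std(y) == 0:
            note = "zero variance"
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({
            "bin_lo": b.lo, "bin_hi": b.hi, "n": len(x),
            "x_trait": x_trait, "y_trait": y_trait,
            "r": r, "p": p,
            "significant": bool(np.isfinite(p) and p < alpha),
            "note": note,
        })
    return pd.DataFrame(rows)


def composite_traits(
    table: pd.DataFrame,
    maxgr_col: str = "max_gr",
    duration_col: str = "duration",
) -> pd.DataFrame:
    """Add the two rate-vs-duration composite traits.

    ``maxgr_duration_ratio`` = MaxGR/Duration, and ``rank_sum`` = rank(MaxGR)
    + rank(Duration) with ascending average ranks, so a high rank sum marks
    the desirable fast-and-long combination.  Rows with non-positive Duration
    are excluded (returned table omits them).
    """
    out = table.copy()
    bad = out[duration_col] <= 0
    if bad.any():
        out = out[~bad].copy()
    out["maxgr_duration_ratio"] = out[maxgr_col] / out[duration_col]
    out["rank_sum"] = (
        out[maxgr_col].rank(method="average") + out[duration_col].rank(method="average")
    )
    return out


def _tail_size(n: int, fraction: float) -> int:
    # round-half-up of fraction*N, at least 1
    import math

    return max(int(math.floor(fraction * n + 0.5)), 1)


def extremes_table(
    table: pd.DataFrame,
    traits: list[str],
    fraction: float = 0.05,
    species_col: str = "species_group",
) -> pd.DataFrame:
    """Species composition of the population-level trait tails.

    For each trait the top and bottom k = round(fraction*N) plants are taken
    over the whole population (stable sort, so boundary ties resolve in row
    order) and, for each species, the members falling in the tail are
    expressed as a percentage of that species' total membership.

    Returns a long frame (species_group, trait, tail, count, percent).
    """
    if not (0 < fraction < 0.5):
        raise ValueError(f"fraction must be in (0, 0.5), got {fraction!r}")
    rows = []
    species_sizes = table[species_col].value_counts()
    for trait in traits:
        sub = table[[species_col, trait]].dropna().reset_index(drop=True)
        n = len(sub)
        k = _tail_size(n, fraction)
        order = np.argsort(sub[trait].to_numpy(float), kind="stable")
        low_idx, high_idx = order[:k], order[-k:]
        for tail, idx in (("high", high_idx), ("low", low_idx)):
            tail_species = sub.loc[idx, species_col].value_counts()
            for sp in species_sizes.index:
                cnt = int(tail_species.get(sp, 0))
                rows.append({
                    "species_group": sp, "trait": trait, "tail": tail,
                    "count": cnt,
                    "percent": 100.0 * cnt / species_sizes[sp],
                })
    return pd.DataFrame(rows)


def geographic_regression(
    table: pd.DataFrame,
    response: str,
    predictors: tuple[str, ...] = ("lat", "lon", "alt_m"),
    include_lat_alt2: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Simple regressions of early-growth timing on collection-site coordinates.

    One OLS per predictor (plus, optionally, the two-term latitude +
    altitude² model labelled ``lat_alt2``); rows without coordinates are
    excluded.  The best predictor is the smallest p, ties broken by larger
    adjusted R²; ``selected`` is "none" when no model reaches ``alpha``.

    Returns ``{"table": DataFrame, "selected": str}`` where the table has
    one row per model with slope, adj_r2 and p of the (first) slope term.
    """
    import statsmodels.api as sm

    rows = []
    for pred in predictors:
        sub = table[[response, pred]].dropna()
        if sub[pred].nunique() < 3:
            rows.append({"response": response, "predictor": pred, "slope": np.nan,
                         "adj_r2": np.nan, "p": np.nan, "note": "non-estimable"})
            continue
        X = sm.add_constant(sub[[pred]].to_numpy(float))
        fit = sm.OLS(sub[response].to_numpy(float), X).fit()
        rows.append({"response": response, "predictor": pred,
                     "slope": fit.params[1], "adj_r2": fit.rsquared_adj,
                     "p": fit.pvalues[1], "note": ""})
    if include_lat_alt2 and {"lat", "alt_m"} <= set(table.columns):
        sub = table[[response, "lat", "alt_m"]].dropna()
        if len(sub) >= 4 and sub["lat"].nunique() >= 3:
            X = np.column_stack([sub["lat"], sub["alt_m"] ** 2])
            fit = sm.OLS(sub[response].to_numpy(float), sm.add_constant(X)).fit()
            rows.append({"response": response, "predictor": "lat_alt2",
                         "slope": fit.params[1], "adj_r2": fit.rsquared_adj,
                         "p": fit.f_pvalue, "note": "lat + alt^2 two-term model"})
    out = pd.DataFrame(rows)
    valid = out.dropna(subset=["p"]).sort_values(["p", "adj_r2"], ascending=[True, False])
    selected = "none"
    if len(valid) and valid.iloc[0]["p"] < alpha:
        selected = str(valid.iloc[0]["predictor"])
    out["selected"] = out["predictor"] == selected
    return {"table": out, "selected": selected}
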