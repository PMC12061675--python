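"""Population-level statistics on derived growth traits.

Covers the harvest-trait arithmetic (moisture content and whole-plant dry
weight), REML variance components for the genotype + block random model and
broad-sense heritability H² = Vg/(Vg + Ve), pairwise-complete Pearson
correlation matrices, and a type-III species ANOVA with Tukey HSD compact
letter groups.

The variance-component model is

    y_ijk = mu + g_i + b_j + e_ijk,   g ~ N(0, Vg), b ~ N(0, Vb), e ~ N(0, Ve)

with genotype and block crossed.  REML is computed directly: the error
variance is profiled out and the restricted likelihood maximized over the two
variance ratios on the log scale, which on balanced data reproduces the
classical expected-mean-squares estimators to optimizer precision and clamps
negative components at zero.  The printed heritability excludes the block
variance from the denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .exceptions import NonEstimableError

__all__ = [
    "estimate_dry_weight",
    "VarianceComponents",
    "VarianceComponentsResults",
    "estimate_variance_components",
    "broad_sense_heritability",
    "pearson_correlation_matrix",
    "species_anova_tukey",
    "compact_letter_display",
]


# ---------------------------------------------------------------------------
# harvest traits


def estimate_dry_weight(plant_wet: float, sub_wet: float, sub_dry: float) -> tuple[float, float]:
    """Moisture content and whole-plant dry weight from a dried subsample.

    mc = (sub_wet - sub_dry)/sub_wet; dw = plant_wet * (1 - mc).
    """
    if sub_wet <= 0:
        raise ValueError(f"subsample wet weight must be > 0, got {sub_wet!r}")
    if sub_dry > sub_wet:
        raise ValueError(
            f"subsample dry weight ({sub_dry}) exceeds its wet weight ({sub_wet})"
        )
    if sub_dry < 0 or plant_wet < 0:
        raise ValueError("weights must be non-negative")
    mc = (sub_wet - sub_dry) / sub_wet
    return mc, plant_wet * (1.0 - mc)


# ---------------------------------------------------------------------------
# variance components / heritability


class VarianceComponents:
    """REML for the two-random-factor model y = mu + genotype + block + error."""

    def __init__(self, values, genotype, block):
        self.y = np.asarray(values, float)
        self.genotype = np.asarray(genotype)
        self.block = np.asarray(block)
        if not (len(self.y) == len(self.genotype) == len(self.block)):
            raise ValueError("values, genotype and block must have equal length")
        mask = np.isfinite(self.y)
        self.y, self.genotype, self.block = self.y[mask], self.genotype[mask], self.block[mask]
        _, self._gi = np.unique(self.genotype, return_inverse=True)
        _, self._bi = np.unique(self.block, return_inverse=True)
        self.n_genotypes = self._gi.max() + 1 if len(self._gi) else 0
        self.n_blocks = self._bi.max() + 1 if len(self._bi) else 0
        counts = np.bincount(self._gi, minlength=self.n_genotypes)
        if self.n_genotypes < 2 or (counts >= 2).sum() < 2:
            raise NonEstimableError(
                "need >= 2 genotypes with >= 2 replicates each to separate Vg from Ve"
            )
        n = len(self.y)
        Zg = np.zeros((n, self.n_genotypes))
        Zg[np.arange(n), self._gi] = 1.0
        Zb = np.zeros((n, self.n_blocks))
        Zb[np.arange(n), self._bi] = 1.0
        self._Gg = Zg @ Zg.T
        self._Gb = Zb @ Zb.T
        self._I = np.eye(n)

    def _neg_reml(self, log_ratios, return_scale=False):
        gg, gb = np.exp(np.clip(log_ratios, -30, 30))
        n = len(self.y)
        M = self._I + gg * self._Gg + gb * self._Gb
        cf = cho_factor(M, lower=True)
        X = np.ones((n, 1))
        Mi_y = cho_solve(cf, self.y)
        Mi_X = cho_solve(cf, X)
        xtmx = float((X.T @ Mi_X).item())
        beta = float(X[:, 0] @ Mi_y) / xtmx
        r = self.y - beta
        se2 = float(r @ cho_solve(cf, r)) / (n - 1)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        nll = 0.5 * (logdet_m + (n - 1) * np.log(se2) + np.log(xtmx) + (n - 1))
        if return_scale:
            return nll, se2
        return nll

    def _mom_start(self) -> list[float]:
        # crude expected-mean-squares start (exact on balanced data)
        y = self.y
        g_means = np.bincount(self._gi, weights=y) / np.bincount(self._gi)
        b_means = np.bincount(self._bi, weights=y) / np.bincount(self._bi)
        resid = y - g_means[self._gi] - b_means[self._bi] + y.mean()
        dfe = max(len(y) - self.n_genotypes - self.n_blocks + 1, 1)
        mse = float(resid @ resid) / dfe
        reps_g = len(y) / self.n_genotypes
        reps_b = len(y) / self.n_blocks
        msg = reps_g * float(np.var(g_means, ddof=1)) if self.n_genotypes > 1 else mse
        msb = reps_b * float(np.var(b_means, ddof=1)) if self.n_blocks > 1 else mse
        vg = max((msg - mse) / reps_g, 1e-6 * mse + 1e-12)
        vb = max((msb - mse) / reps_b, 1e-6 * mse + 1e-12)
        mse = max(mse, 1e-12)
        return [float(np.log(vg / mse)), float(np.log(vb / mse))]

    def fit(self) -> "VarianceComponentsResults":
        opts = {"xatol": 1e-11, "fatol": 1e-13, "maxiter": 2000}
        best = minimize(self._neg_reml, self._mom_start(), method="Nelder-Mead",
                        options=opts)
        if not best.success:
            # fall back to a neutral start when the moment start misleads
            res = minimize(self._neg_reml, [0.0, 0.0], method="Nelder-Mead", options=opts)
            if res.fun < best.fun - 1e-12:
                best = res
        _, se2 = self._neg_reml(best.x, return_scale=True)
        gg, gb = np.exp(np.clip(best.x, -30, 30))
        v_g, v_b, v_e = gg * se2, gb * se2, se2
        # boundary clamp: ratios driven to the floor are genuinely zero
        if gg < 1e-8:
            v_g = 0.0
        if gb < 1e-8:
            v_b = 0.0
        return VarianceComponentsResults(self, v_g, v_b, v_e)


@dataclass
class VarianceComponentsResults:
    """REML variance components and broad-sense heritability."""

    model: VarianceComponents
    v_g: float
    v_block: float
    v_e: float

    @property
    def h2(self) -> float:
        return broad_sense_heritability(self.v_g, self.v_e)

    def summary(self) -> str:
        return (
            "Variance components (REML)\n"
            "--------------------------\n"
            f"genotypes: {self.model.n_genotypes}   blocks: {self.model.n_blocks}   "
            f"n: {len(self.model.y)}\n"
            f"Vg = {self.v_g:.5g}\nVblock = {self.v_block:.5g}\nVe = {self.v_e:.5g}\n"
            f"H2 = Vg/(Vg+Ve) = {self.h2:.4f}"
        )


def estimate_variance_components(values, genotype, block) -> tuple[float, float, float]:
    """Functional wrapper: (Vg, Vblock, Ve) by REML."""
    res = VarianceComponents(values, genotype, block).fit()
    return res.v_g, res.v_block, res.v_e


def broad_sense_heritability(v_g: float, v_e: float) -> float:
    """H² = Vg / (Vg + Ve); block variance deliberately excluded."""
    if v_g < 0 or v_e < 0:
        raise ValueError("variance components must be >= 0")
    if v_g == 0 and v_e == 0:
        raise ValueError("H2 undefined when Vg and Ve are both zero")
    return v_g / (v_g + v_e)


# ---------------------------------------------------------------------------
# correlations


def pearson_correlation_matrix(table: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    Returns a long-format frame (trait_i, trait_j, r, p, n, note) covering
    every unordered pair; cells with fewer than 3 complete pairs or a
    zero-variance trait are reported as missing with the reason in ``note``.
    """
    rows = []
    for ti, tj in itertools.combinations_with_replacement(traits, 2):
        xi = table[ti].to_numpy(float)
        xj = table[tj].to_numpy(float)
        mask = np.isfinite(xi) & np.isfinite(xj)
        n = int(mask.sum())
        r = p = np.nan
        note = ""
        if ti == tj:
            r, p = 1.0, 0.0
        elif n < 3:
            note = "fewer than 3 complete pairs"
        elif np.std(xi[mask]) == 0 or np.std(xj[mask]) == 0:
            note = "zero variance"
        else:
            r, p = stats.pearsonr(xi[mask], xj[mask])
        rows.append({"trait_i": ti, "trait_j": tj, "r": r, "p": p, "n": n, "note": note})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# species ANOVA + Tukey letters


def compact_letter_display(
    groups: list[str],
    significant_pairs: set[tuple[str, str]],
    order_stat: dict[str, float] | None = None,
    tiebreak: dict[str, float] | None = None,
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different.  Letters are
    assigned to columns in descending order of the group statistic
    (``order_stat``, e.g. the group mean); ties broken by ``tiebreak``
    (e.g. sample size, larger first) then by name.
    """
    sig = {tuple(sorted(p)) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(sig):
        g1, g2 = pair
        for col in list(columns):
            if g1 in col and g2 in col:
                columns.remove(col)
                columns.extend([col - {g1}, col - {g2}])
        # absorb: drop columns that are subsets of another
        columns = [c for c in columns if c and not any(c < other for other in columns)]
        # dedupe
        seen, uniq = set(), []
        for c in columns:
            key = frozenset(c)
            if key not in seen:
                seen.add(key)
                uniq.append(c)
        columns = uniq

    def colkey(col: set[str]) -> tuple:
        stat = max(order_stat.get(g, 0.0) for g in col) if order_stat else 0.0
        tb = max(tiebreak.get(g, 0.0) for g in col) if tiebreak else 0.0
        return (-stat, -tb, min(col))

    columns.sort(key=colkey)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, str] = {g: "" for g in groups}
    for i, col in enumerate(columns):
        for g in col:
            letters[g] += alphabet[i % len(alphabet)]
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def species_anova_tukey(
    table: pd.DataFrame,
    trait: str,
    group_col: str = "species_group",
    alpha: float = 0.05,
) -> dict:
    """Type-III ANOVA of a trait across species plus Tukey HSD letter groups.

    Species with fewer than 2 observations are dropped with a warning entry.
    Returns a dict with keys ``anova`` (DataFrame of F and p per term),
    ``tukey`` (pairwise comparisons), ``letters`` (species -> letter group)
    and ``dropped``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = table[[group_col, trait]].dropna().copy()
    counts = sub[group_col].value_counts()
    dropped = sorted(counts[counts < 2].index.tolist())
    sub = sub[~sub[group_col].isin(dropped)]
    if sub[group_col].nunique() < 2:
        raise NonEstimableError("need >= 2 species groups with >= 2 observations")
    sub = sub.rename(columns={group_col: "species", trait: "value"})

    ols_fit = smf.ols("value ~ C(species, Sum)", data=sub).fit()
    anova = sm.stats.anova_lm(ols_fit, typ=3)

    tk = pairwise_tukeyhsd(sub["value"], sub["species"], alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    sig_pairs = {
        (str(r["group1"]), str(r["group2"])) for _, r in tukey.iterrows() if bool(r["reject"])
    }
    means = sub.groupby("species")["value"].mean().to_dict()
    sizes = sub.groupby("species")["value"].size().astype(float).to_dict()
    letters = compact_letter_display(
        sorted(sub["species"].unique()), sig_pairs, order_stat=means, tiebreak=sizes
    )
    return {"anova": anova, "tukey": tukey, "letters": letters, "dropped": dropped}
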