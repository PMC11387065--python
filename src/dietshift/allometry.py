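"""Balanced resampling, diet-seasonality indicators and allometric tests.

The seasonal comparison draws, for every (species, season) cell, the
minimum available number of herd samples (4 by default) and repeats the
draw 100 times, so unequal sampling effort across species and seasons
cannot drive the results. Each replicate yields five indicators:

* ``turnover_BC`` — mean Bray-Curtis dissimilarity over all summer x winter
  sample pairs within a species (seasonal diet switching);
* ``herd_richness`` — mean number of plant taxa per herd sample;
* ``TNW_at_8`` — total niche width: incidence-based expected taxon richness
  standardized to 8 sampling units;
* ``herd_dprime`` — mean Bluethgen d' of a species' samples within the
  season's herd x taxon network;
* ``species_dprime`` — d' of the species' mean seasonal profile within the
  species x taxon network.

Allometric hypothesis tests regress the replicate means against log body
mass (grams): simple linear regression for turnover, and Type III ANCOVA
(mass x season) with likelihood-ratio model simplification for the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from . import community
from .diet_table import DietTable, DietTableError

RESPONSES = ("herd_richness", "TNW_at_8", "herd_dprime", "species_dprime")


@dataclass(frozen=True)
class SubsampleDesign:
    """Balanced subsampling design over (species, season) cells."""

    n_per_cell: int = 4
    n_reps: int = 100
    seasons: tuple = ("summer", "winter")
    seed: int | None = None


def draw_subsamples(table: DietTable, design: SubsampleDesign) -> list[pd.Index]:
    """Draw ``n_reps`` balanced replicates of sample ids.

    Each replicate holds exactly ``n_per_cell`` ids from every
    (species, season) cell, drawn without replacement within the replicate.
    """
    meta = table.sample_meta
    cells = {}
    for (sp, se), grp in meta.groupby(["species", "season"]):
        if se in design.seasons:
            cells[(sp, se)] = grp.index.to_numpy()
    species = sorted({sp for sp, _ in cells})
    for sp in species:
        for se in design.seasons:
            ids = cells.get((sp, se), np.array([]))
            if len(ids) < design.n_per_cell:
                raise DietTableError(
                    f"cell ({sp}, {se}) has {len(ids)} samples; "
                    f"needs {design.n_per_cell}"
                )
    rng = np.random.default_rng(design.seed)
    reps = []
    for _ in range(design.n_reps):
        chosen = []
        for sp in species:
            for se in design.seasons:
                ids = cells[(sp, se)]
                chosen.extend(rng.choice(ids, size=design.n_per_cell, replace=False))
        reps.append(pd.Index(chosen))
    return reps


@dataclass
class IndicatorTable:
    """Per-replicate indicator values.

    ``seasonal`` is indexed by (species, season, replicate); ``turnover``
    by (species, replicate) since switching spans both seasons.
    """

    seasonal: pd.DataFrame
    turnover: pd.DataFrame

    def replicate_means(self) -> pd.DataFrame:
        """Mean of each indicator per (species, season) over replicates."""
        return self.seasonal.groupby(["species", "season"]).mean()

    def turnover_means(self) -> pd.Series:
        return self.turnover.groupby("species")["turnover_BC"].mean()

    def to_tsv(self, path) -> None:
        tidy = self.seasonal.reset_index().melt(
            id_vars=["species", "season", "replicate"], var_name="metric"
        )
        turn = self.turnover.reset_index().rename(columns={"turnover_BC": "value"})
        turn["season"] = "both"
        turn["metric"] = "turnover_BC"
        pd.concat([tidy, turn], ignore_index=True).to_csv(path, sep="\t", index=False)


def compute_indicators(
    table: DietTable,
    replicate_ids: pd.Index,
    replicate: int = 0,
    seasons: tuple = ("summer", "winter"),
) -> IndicatorTable:
    """Compute the five diet-seasonality indicators on one replicate."""
    sub = table.subset(replicate_ids)
    meta = sub.sample_meta
    if (sub.counts.sum(axis=1) == 0).any():
        raise DietTableError("replicate contains an all-zero sample")

    seas_rows = []
    sp_d = {se: community.species_dprime(sub, se) for se in seasons}
    herd_d = {se: community.herd_dprime(sub, se) for se in seasons}
    for (sp, se), grp in meta.groupby(["species", "season"]):
        if se not in seasons:
            continue
        cell = sub.counts.loc[grp.index]
        rich = float(np.mean(community.richness(cell)))
        inc = community.incidence_from_samples(cell)
        tnw = community.estimate_richness_at(inc, 8)
        seas_rows.append(
            {
                "species": sp,
                "season": se,
                "replicate": replicate,
                "herd_richness": rich,
                "TNW_at_8": tnw,
                "herd_dprime": float(herd_d[se].loc[sp]),
                "species_dprime": float(sp_d[se].loc[sp]),
            }
        )
    seasonal = pd.DataFrame(seas_rows).set_index(["species", "season", "replicate"])

    turn_rows = []
    for sp, grp in meta.groupby("species"):
        su = sub.counts.loc[grp.index[grp["season"] == seasons[0]]].values
        wi = sub.counts.loc[grp.index[grp["season"] == seasons[1]]].values
        vals = [
            community.bray_curtis_pair(a, b) for a in su for b in wi
        ]
        turn_rows.append(
            {"species": sp, "replicate": replicate, "turnover_BC": float(np.mean(vals))}
        )
    turnover = pd.DataFrame(turn_rows).set_index(["species", "replicate"])
    return IndicatorTable(seasonal=seasonal, turnover=turnover)


def run_indicators(table: DietTable, design: SubsampleDesign) -> IndicatorTable:
    """Draw all replicates and stack their indicator tables."""
    reps = draw_subsamples(table, design)
    seasonal, turnover = [], []
    for r, ids in enumerate(reps):
        part = compute_indicators(table, ids, replicate=r, seasons=design.seasons)
        seasonal.append(part.seasonal)
        turnover.append(part.turnover)
    return IndicatorTable(pd.concat(seasonal), pd.concat(turnover))


# ---------------------------------------------------------------------------
# allometric fits


@dataclass
class AllometryFit:
    """Fit of an indicator against log body mass (grams)."""

    slope: float
    intercept: float
    r2: float
    p: float
    response: str
    log_base: float
    per_replicate: pd.DataFrame | None = None
    terms: pd.DataFrame | None = None        # Type III table of the final model
    chain: list = field(default_factory=list)
    final_model: str | None = None
    model: object | None = None


def _log_mass(masses_kg: dict, species, log_base: float) -> np.ndarray:
    m = np.array([masses_kg[sp] * 1000.0 for sp in species], dtype=float)
    return np.log(m) / np.log(log_base)


def turnover_allometry(
    indicators: IndicatorTable, masses_kg: dict, log_base: float = 10.0
) -> AllometryFit:
    """OLS of per-species mean seasonal turnover on log body mass.

    The reported fit uses per-species means over replicates (thick line);
    per-replicate fits are retained for the uncertainty envelope.
    """
    means = indicators.turnover_means()
    if len(means) < 3:
        raise ValueError("need >= 3 species for an allometric regression")
    x = _log_mass(masses_kg, means.index, log_base)
    fit = sm.OLS(means.values, sm.add_constant(x)).fit()
    degenerate = np.allclose(means.values, means.values[0])
    per_rep = []
    for r, grp in indicators.turnover.groupby("replicate"):
        g = grp.droplevel("replicate")["turnover_BC"]
        xr = _log_mass(masses_kg, g.index, log_base)
        b, a = np.polyfit(xr, g.values, 1)
        per_rep.append({"replicate": r, "slope": b, "intercept": a})
    return AllometryFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float("nan") if degenerate else float(fit.rsquared),
        p=float(fit.pvalues[1]),
        response="turnover_BC",
        log_base=log_base,
        per_replicate=pd.DataFrame(per_rep).set_index("replicate"),
    )


def _fit_formula(df: pd.DataFrame, formula: str):
    return smf.ols(formula, data=df).fit()


def _lrt(big, small) -> tuple[float, int, float]:
    """Nested-model comparison via the exact F form of the likelihood ratio.

    For Gaussian linear models the likelihood ratio is a monotone function
    of the extra-sum-of-squares F statistic, whose null distribution is
    exact at any sample size (the chi-square approximation is
    anticonservative on the handful of species-season means used here).
    """
    df_num = int(big.df_model - small.df_model)
    if df_num <= 0:
        return 0.0, 0, 1.0
    df_den = int(big.df_resid)
    F = ((small.ssr - big.ssr) / df_num) / (big.ssr / df_den)
    p = float(scipy.stats.f.sf(max(F, 0.0), df_num, df_den))
    return float(F), df_num, p


def ancova_type3(
    indicators: IndicatorTable,
    response: str,
    masses_kg: dict,
    alpha: float = 0.05,
    log_base: float = 10.0,
    on_means: bool = True,
) -> AllometryFit:
    """Type III ANCOVA of an indicator on log mass x season with LRT pruning.

    The full model ``response ~ log_mass * season`` (sum-to-zero factor
    coding, Type III sums of squares) is simplified by likelihood-ratio
    tests: the interaction is dropped if regression slopes are homogeneous
    (LRT p > alpha), then each main effect is dropped if its removal does
    not significantly worsen the model. Observations are per-(species,
    season) replicate means by default (``on_means``), or every replicate.
    """
    if response not in RESPONSES:
        raise ValueError(f"response must be one of {RESPONSES}")
    data = indicators.replicate_means() if on_means else indicators.seasonal
    df = data.reset_index()[["species", "season", response]].rename(
        columns={response: "y"}
    )
    if df["season"].nunique() < 2:
        raise ValueError("both seasons required")
    if df["species"].nunique() < 3:
        raise ValueError("need >= 3 species")
    lm = _log_mass(masses_kg, df["species"], log_base)
    # centring the covariate makes the sum-coded design orthogonal on the
    # balanced species x season grid, so Type III main effects are
    # interpretable at the mean mass (slopes are unaffected)
    df["logmass"] = lm - lm.mean()

    full_f = "y ~ logmass * C(season, Sum)"
    add_f = "y ~ logmass + C(season, Sum)"
    full = _fit_formula(df, full_f)
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")
    chain = []
    additive = _fit_formula(df, add_f)
    lr, dfree, p = _lrt(full, additive)
    chain.append({"test": "drop interaction", "stat": lr, "df": dfree, "p": p, "dropped": p > alpha})
    if p > alpha:
        model, formula = additive, add_f
        # try dropping each main effect, least harmful first
        while True:
            candidates = []
            terms_now = [t for t in ("logmass", "C(season, Sum)") if t in formula]
            if not terms_now:
                break
            for term in terms_now:
                rest = [t for t in terms_now if t != term]
                sub_f = "y ~ " + (" + ".join(rest) if rest else "1")
                sub = _fit_formula(df, sub_f)
                lr, dfree, p = _lrt(model, sub)
                candidates.append((p, term, sub_f, sub, lr, dfree))
            p, term, sub_f, sub, lr, dfree = max(candidates, key=lambda c: c[0])
            dropped = p > alpha
            chain.append({"test": f"drop {term}", "stat": lr, "df": dfree, "p": p, "dropped": dropped})
            if not dropped:
                break
            model, formula = sub, sub_f
    else:
        model, formula = full, full_f

    if model.df_model > 0:
        terms = anova_lm(model, typ=3)
    else:
        terms = None
    slope = float(model.params.get("logmass", np.nan))
    return AllometryFit(
        slope=slope,
        intercept=float(model.params.get("Intercept", np.nan)),
        r2=float(model.rsquared) if model.df_model > 0 else float("nan"),
        p=float(model.f_pvalue) if model.df_model > 0 else float("nan"),
        response=response,
        log_base=log_base,
        terms=terms,
        chain=chain,
        final_model=formula,
        model=model,
    )


def log_response_ratio(summer_means: pd.Series, winter_means: pd.Series) -> pd.Series:
    """ln(summer mean / winter mean) per species: the seasonal effect size."""
    s = pd.Series(summer_means, dtype=float)
    w = pd.Series(winter_means, dtype=float).reindex(s.index)
    if (w <= 0).any() or (s <= 0).any() or w.isna().any():
        raise ValueError("log-response ratios need positive seasonal means for all species")
    out = np.log(s / w)
    out.name = "LRR"
    return out
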