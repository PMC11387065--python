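import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.anova import anova_lm

import statsmodels.formula.api as smf

from dietshift import (
    DEFAULT_MASSES_KG,
    SubsampleDesign,
    ancova_type3,
    compute_indicators,
    draw_subsamples,
    log_response_ratio,
    run_indicators,
    turnover_allometry,
)
from dietshift.allometry import IndicatorTable, RESPONSES
from dietshift.diet_table import DietTableError

from conftest import make_table
from oracles import oracle_indicators


class TestDrawSubsamples:
    def test_replicates_hold_forty_ids(self, small_dataset, design):
        table, _, _ = small_dataset
        reps = draw_subsamples(table, design)
        assert len(reps) == design.n_reps
        for rep in reps:
            assert len(rep) == 5 * 2 * 4
            assert len(set(rep)) == 40

    def test_forced_draw_when_cell_is_minimum(self, small_dataset, design):
        # every cell has exactly 4 samples, so all replicates coincide
        table, _, _ = small_dataset
        reps = draw_subsamples(table, design)
        assert all(set(rep) == set(reps[0]) for rep in reps)

    def test_seed_reproducible(self, paper_scale_dataset):
        table, _, _ = paper_scale_dataset
        d = SubsampleDesign(n_reps=3, seed=42)
        a = draw_subsamples(table, d)
        b = draw_subsamples(table, d)
        assert all(list(x) == list(y) for x, y in zip(a, b))

    def test_short_cell_error_names_cell(self, paper_scale_dataset):
        table, _, _ = paper_scale_dataset
        with pytest.raises(DietTableError, match="bighorn_sheep.*winter"):
            draw_subsamples(table, SubsampleDesign(n_per_cell=5, n_reps=1, seed=0))


class TestComputeIndicators:
    def test_disjoint_seasonal_profiles_give_full_turnover(self):
        counts, species, seasons = [], [], []
        for sp in ["elk", "bison", "mule_deer"]:
            for se, vec in [("summer", [7, 3, 0, 0]), ("winter", [0, 0, 5, 5])]:
                for _ in range(2):
                    counts.append(vec)
                    species.append(sp)
                    seasons.append(se)
        t = make_table(counts, species=species, season=seasons)
        ind = compute_indicators(t, t.sample_ids)
        assert np.allclose(ind.turnover["turnover_BC"].values, 1.0)

    def test_shared_profile_gives_zero_species_dprime(self):
        counts, species, seasons = [], [], []
        for sp in ["elk", "bison", "mule_deer"]:
            for se in ["summer", "winter"]:
                for _ in range(2):
                    counts.append([4, 4, 2])
                    species.append(sp)
                    seasons.append(se)
        t = make_table(counts, species=species, season=seasons)
        ind = compute_indicators(t, t.sample_ids)
        assert np.allclose(ind.seasonal["species_dprime"].values, 0.0)
        assert np.allclose(ind.seasonal["herd_dprime"].values, 0.0)

    def test_matches_straight_line_oracle(self, small_dataset, design):
        """Every indicator equals an independent re-implementation."""
        table, _, _ = small_dataset
        rep = draw_subsamples(table, design)[0]
        ind = compute_indicators(table, rep)
        oracle = oracle_indicators(table, rep)
        for key in ["herd_richness", "TNW_at_8", "herd_dprime", "species_dprime"]:
            got = ind.seasonal[key]
            for idx in got.index:
                sp, se, _ = idx
                assert got[idx] == pytest.approx(oracle[(sp, se, key)], abs=1e-9), key
        for (sp, _r), val in ind.turnover["turnover_BC"].items():
            assert val == pytest.approx(oracle[(sp, "turnover")], abs=1e-9)


def _synthetic_indicator_table(values, turnovers=None):
    """IndicatorTable built directly from per-cell means (unit testing)."""
    rows = []
    for (sp, se, rep), v in values.items():
        rows.append(
            dict(species=sp, season=se, replicate=rep, **v)
        )
    seasonal = pd.DataFrame(rows).set_index(["species", "season", "replicate"])
    if turnovers is None:
        turnovers = {(sp, 0): 0.5 for sp in seasonal.index.get_level_values(0).unique()}
    t_rows = [
        {"species": sp, "replicate": r, "turnover_BC": v}
        for (sp, r), v in turnovers.items()
    ]
    turnover = pd.DataFrame(t_rows).set_index(["species", "replicate"])
    return IndicatorTable(seasonal=seasonal, turnover=turnover)


SPECIES5 = list(DEFAULT_MASSES_KG)


def _table_from_response(fun, rng, n_reps=1, noise=0.0):
    vals, turns = {}, {}
    for sp in SPECIES5:
        lm = np.log10(DEFAULT_MASSES_KG[sp] * 1000.0)
        for rep in range(n_reps):
            for se in ("summer", "winter"):
                y = fun(lm, se) + (rng.normal(0, noise) if noise else 0.0)
                vals[(sp, se, rep)] = {k: y for k in RESPONSES}
            turns[(sp, rep)] = 0.9 - 0.05 * lm + (rng.normal(0, noise) if noise else 0)
    return _synthetic_indicator_table(vals, turns)


class TestTurnoverAllometry:
    def test_recovers_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        ind = _table_from_response(lambda lm, se: 0.0, rng)
        fit = turnover_allometry(ind, DEFAULT_MASSES_KG)
        assert fit.slope == pytest.approx(-0.05, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_turnover_flags_degenerate_r2(self):
        vals = {
            (sp, se, 0): {k: 1.0 for k in RESPONSES}
            for sp in SPECIES5
            for se in ("summer", "winter")
        }
        turns = {(sp, 0): 0.8 for sp in SPECIES5}
        ind = _synthetic_indicator_table(vals, turns)
        fit = turnover_allometry(ind, DEFAULT_MASSES_KG)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(fit.r2)

    def test_per_replicate_envelope_returned(self):
        rng = np.random.default_rng(1)
        ind = _table_from_response(lambda lm, se: 0.0, rng, n_reps=7, noise=0.01)
        fit = turnover_allometry(ind, DEFAULT_MASSES_KG)
        assert len(fit.per_replicate) == 7

    def test_too_few_species_rejected(self):
        vals = {
            (sp, se, 0): {k: 1.0 for k in RESPONSES}
            for sp in ["elk", "bison"]
            for se in ("summer", "winter")
        }
        turns = {(sp, 0): 0.8 for sp in ["elk", "bison"]}
        with pytest.raises(ValueError):
            turnover_allometry(
                _synthetic_indicator_table(vals, turns), DEFAULT_MASSES_KG
            )


class TestAncovaChain:
    def test_additive_data_selects_additive_model(self):
        """Strong additive effects, no interaction: the chain should drop the
        interaction and keep both main effects nearly always."""
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            ind = _table_from_response(
                lambda lm, se: 2.0 * lm + (1.5 if se == "summer" else 0.0),
                rng,
                noise=0.3,
            )
            fit = ancova_type3(ind, "herd_richness", DEFAULT_MASSES_KG)
            if fit.final_model == "y ~ logmass + C(season, Sum)":
                hits += 1
        assert hits / n_sim >= 0.95

    def test_pure_interaction_retained(self):
        rng = np.random.default_rng(3)
        kept = 0
        for _ in range(50):
            ind = _table_from_response(
                lambda lm, se: (2.0 if se == "summer" else -2.0) * lm,
                rng,
                noise=0.1,
            )
            fit = ancova_type3(ind, "TNW_at_8", DEFAULT_MASSES_KG)
            if "*" in fit.final_model:
                kept += 1
        assert kept >= 48

    def test_interaction_type1_error_at_alpha(self):
        """Noise-only responses: the interaction LRT rejects at ~alpha."""
        rng = np.random.default_rng(4)
        n_sim = 500
        rejects = 0
        for _ in range(n_sim):
            ind = _table_from_response(lambda lm, se: 0.0, rng, noise=1.0)
            fit = ancova_type3(ind, "herd_dprime", DEFAULT_MASSES_KG)
            if not fit.chain[0]["dropped"]:
                rejects += 1
        assert 0.03 <= rejects / n_sim <= 0.07

    def test_type3_equals_type1_on_balanced_design(self):
        rng = np.random.default_rng(5)
        ind = _table_from_response(
            lambda lm, se: lm + (1.0 if se == "summer" else 0.0), rng, noise=0.5
        )
        df = ind.replicate_means()["herd_richness"].reset_index()
        lm = np.array(
            [np.log10(DEFAULT_MASSES_KG[sp] * 1000.0) for sp in df["species"]]
        )
        df["logmass"] = lm - lm.mean()  # centred covariate, as in the ANCOVA
        df = df.rename(columns={"herd_richness": "y"})
        m = smf.ols("y ~ logmass * C(season, Sum)", df).fit()
        t1 = anova_lm(m, typ=1)
        t3 = anova_lm(m, typ=3)
        for term in ["logmass", "C(season, Sum)"]:
            assert t1.loc[term, "sum_sq"] == pytest.approx(
                t3.loc[term, "sum_sq"], rel=1e-8
            )

    def test_full_pipeline_ancova_runs(self, small_dataset, design):
        table, _, cfg = small_dataset
        ind = run_indicators(table, design)
        fit = ancova_type3(ind, "herd_richness", cfg.species_masses)
        assert fit.final_model is not None
        assert fit.chain


class TestLogResponseRatio:
    def test_hand_value(self):
        s = pd.Series({"elk": 20.0})
        w = pd.Series({"elk": 10.0})
        assert log_response_ratio(s, w)["elk"] == pytest.approx(np.log(2), abs=1e-12)

    def test_equal_means_zero(self):
        s = pd.Series({"elk": 5.0})
        assert log_response_ratio(s, s)["elk"] == 0.0

    def test_antisymmetry(self):
        s = pd.Series({"elk": 8.0, "bison": 3.0})
        w = pd.Series({"elk": 2.0, "bison": 9.0})
        assert np.allclose(
            log_response_ratio(s, w).values, -log_response_ratio(w, s).values
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            log_response_ratio(pd.Series({"elk": 1.0}), pd.Series({"elk": 0.0}))


def test_indicator_means_stable_under_more_replicates(paper_scale_dataset):
    """Doubling replicates shifts species-season means by less than twice the
    replicate-mean standard error."""
    table, _, _ = paper_scale_dataset
    ind100 = run_indicators(table, SubsampleDesign(n_reps=60, seed=1))
    ind200 = run_indicators(table, SubsampleDesign(n_reps=120, seed=2))
    m1 = ind100.replicate_means()
    m2 = ind200.replicate_means()
    se1 = ind100.seasonal.groupby(["species", "season"]).sem()
    se2 = ind200.seasonal.groupby(["species", "season"]).sem()
    for col in m1.columns:
        diff = (m1[col] - m2[col]).abs()
        # combined standard error of the two independent estimates; a small
        # absolute floor covers cells where almost every subsample coincides
        tol = 2 * np.sqrt(se1[col] ** 2 + se2[col] ** 2) + 0.02
        assert (diff <= tol).all(), col
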