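"""Mixed-model fitting, df/AICc conventions, ranking and all-subsets selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from planktte.errors import ConfigurationError, ValidationError
from planktte.inference import (
    ModelSpec,
    aicc,
    dredge_all_subsets,
    enumerate_admissible_subsets,
    fit_lmm,
    pearson_with_p,
    rank_univariate,
    within_group_df,
)
from planktte.synthetic_data import LmmSimConfig, simulate_lmm_dataset


class TestWithinGroupDf:
    @pytest.mark.parametrize(
        "n,g,p,expected", [(106, 40, 1, 65), (106, 1, 0, 105), (10, 2, 3, 5)]
    )
    def test_containment_rule(self, n, g, p, expected):
        assert within_group_df(n, g, p) == expected

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValidationError):
            within_group_df(10, 8, 2)


class TestAicc:
    def test_closed_form(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7, rel=1e-12)

    def test_exceeds_aic_and_shrinks_with_n(self):
        k, ll = 4, -12.3
        aic = -2 * ll + 2 * k
        gaps = [aicc(ll, k, n) - aic for n in (10, 30, 100, 1000)]
        assert all(g > 0 for g in gaps)
        assert gaps == sorted(gaps, reverse=True)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            aicc(0.0, 5, 6)


class TestModelSpec:
    def test_formula_roundtrip_with_interaction(self):
        spec = ModelSpec.from_formula("y ~ A + B + A×B | station")
        assert spec.fixed_terms == ("A", "B", "A:B")
        assert spec.grouping == "station"
        assert spec.formula == "y ~ A + B + A:B"

    def test_marginality_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("y", ("A", "A:B"), "station")

    def test_malformed_formula_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec.from_formula("y ~ A + B")


class TestFitLmm:
    def test_noise_free_exact_recovery(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=50, n_groups=5, fixed_effects={"A": 2.0},
                         intercept=0.0, random_intercept_sd=0.0,
                         residual_sd=0.0, seed=4)
        )
        fit = fit_lmm(ModelSpec("y", ("A",), "station"), data)
        p = fit.params.set_index("term")
        assert p.loc["A", "estimate"] == pytest.approx(2.0, abs=1e-8)
        assert p.loc["Intercept", "estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_reports_containment_df_and_k(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=106, n_groups=40, fixed_effects={"A": 1.0}, seed=0)
        )
        fit = fit_lmm(ModelSpec("y", ("A",), "station"), data)
        assert (fit.params["df"] == 65).all()
        assert fit.k == 2 + 2  # intercept + slope + two variance components
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, 106), rel=1e-12)

    def test_parameter_recovery_within_three_se(self):
        hits = 0
        for seed in range(20):
            data, truth = simulate_lmm_dataset(
                LmmSimConfig(n_obs=106, n_groups=40,
                             fixed_effects={"A": -1.655}, intercept=0.8, seed=seed)
            )
            p = fit_lmm(ModelSpec("y", ("A",), "station"), data).params.set_index("term")
            if abs(p.loc["A", "estimate"] + 1.655) <= 3 * p.loc["A", "se"]:
                hits += 1
        assert hits >= 19

    def test_zero_variance_boundary_matches_ols(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=80, n_groups=1, fixed_effects={"A": 1.2, "B": -0.7},
                         intercept=0.5, random_intercept_sd=0.0,
                         residual_sd=0.6, seed=11)
        )
        fit = fit_lmm(ModelSpec("y", ("A", "B"), "station"), data)
        ols = smf.ols("y ~ A + B", data).fit()
        p = fit.params.set_index("term")
        # slopes are identified; the intercept is confounded with the single
        # group's random effect and not compared
        for term in ("A", "B"):
            assert p.loc[term, "t"] == pytest.approx(ols.tvalues[term], abs=1e-6)
            assert p.loc[term, "estimate"] == pytest.approx(ols.params[term], abs=1e-9)
        assert (p["df"] == 80 - 1 - 2).all()

    def test_collinear_design_rejected_with_names(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=40, n_groups=4, fixed_effects={"A": 1.0}, seed=0)
        )
        data["A2"] = 2.0 * data["A"]
        with pytest.raises(ValidationError, match="A2"):
            fit_lmm(ModelSpec("y", ("A", "A2"), "station"), data)

    def test_missing_column_rejected(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=40, n_groups=4, fixed_effects={"A": 1.0}, seed=0)
        )
        with pytest.raises(ValidationError, match="missing"):
            fit_lmm(ModelSpec("y", ("Z",), "station"), data)


class TestRankUnivariate:
    def test_single_candidate_single_row(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=60, n_groups=10, fixed_effects={"A": 1.0}, seed=2)
        )
        table, fits = rank_univariate("y", ["A"], "station", data)
        assert len(table) == 1 and len(fits) == 1
        assert list(table.columns) == ["term", "aicc", "estimate", "se", "t", "p", "df"]

    def test_true_effect_ranks_first(self):
        wins = 0
        for seed in range(10):
            cfg = LmmSimConfig(
                n_obs=106, n_groups=40,
                fixed_effects={"A": 1.5, "B": 0.0, "C": 0.0}, seed=seed,
            )
            data, _ = simulate_lmm_dataset(cfg)
            table, _ = rank_univariate("y", ["A", "B", "C"], "station", data)
            wins += table["term"].iloc[0] == "A"
        assert wins >= 9

    def test_duplicate_columns_tie_in_input_order(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=60, n_groups=10, fixed_effects={"A": 1.0}, seed=5)
        )
        data["A_copy"] = data["A"]
        table, _ = rank_univariate("y", ["A", "A_copy"], "station", data)
        assert table["aicc"].iloc[0] == pytest.approx(table["aicc"].iloc[1], abs=1e-8)
        assert list(table["term"]) == ["A", "A_copy"]


class TestDredge:
    def test_admissible_subsets_match_enumeration_oracle(self):
        # oracle: brute-force all subsets, keep those whose interactions
        # have both parents present
        terms = ["A", "B", "A:B"]
        brute = set()
        for r in range(4):
            for combo in itertools.combinations(terms, r):
                ok = all(
                    set(t.split(":")) <= set(combo) for t in combo if ":" in t
                )
                if ok:
                    brute.add(frozenset(combo))
        got = {frozenset(s) for s in enumerate_admissible_subsets(["A", "B", "A×B"])}
        assert got == brute
        assert len(got) == 5

    def test_selects_generating_interaction_model(self):
        wins = 0
        for seed in range(10):
            data, _ = simulate_lmm_dataset(
                LmmSimConfig(n_obs=106, n_groups=40,
                             fixed_effects={"A": 0.5, "B": 0.3, "A:B": 1.0},
                             seed=seed)
            )
            _, best, _ = dredge_all_subsets("y", ["A", "B", "A:B"], "station", data)
            wins += "A:B" in best.spec.fixed_terms
        assert wins >= 9

    def test_ranked_ascending_by_aicc(self):
        data, _ = simulate_lmm_dataset(
            LmmSimConfig(n_obs=106, n_groups=40,
                         fixed_effects={"A": 0.5, "B": 0.3, "A:B": 1.0}, seed=1)
        )
        table, best, fits = dredge_all_subsets("y", ["A", "B", "A:B"], "station", data)
        assert list(table["aicc"]) == sorted(table["aicc"])
        assert best.aicc == table["aicc"].iloc[0]
        assert table["delta_aicc"].iloc[0] == 0.0

    def test_combinatorial_guard(self):
        data = pd.DataFrame({"y": [1.0], "station": ["a"]})
        with pytest.raises(ConfigurationError):
            dredge_all_subsets("y", [f"x{i}" for i in range(21)], "station", data)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, x)[0] == pytest.approx(1.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_small_sample(self):
        x = np.array([1.0, 2.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 6.0])
        # direct textbook formula
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
        r, p, n = pearson_with_p(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert n == 4
        assert 0 < p <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
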