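"""Biomass/production ratios, PPMR, and bootstrap uncertainty propagation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from planktte.errors import ValidationError
from planktte.morphometry import (
    BiomassConversionTable,
    SampleCommunity,
    derive_biomass,
)
from planktte.transfer_metrics import (
    CohortPair,
    bootstrap_proxy_uncertainty,
    build_sample_summaries,
    cohort_growth_rate,
    diversity_ratio,
    log10_ppbr,
    log10_pppr,
    ppmr_log10,
    pppr_table,
    production,
)

from conftest import make_particles

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestLog10Ppbr:
    def test_equal_biomasses_give_zero(self):
        assert log10_ppbr(3.2, 3.2) == 0.0

    def test_tenfold_gives_one(self):
        assert log10_ppbr(10.0, 1.0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert log10_ppbr(2.5, 50.0) == pytest.approx(math.log10(0.05), rel=1e-12)

    @given(positive, positive)
    def test_antisymmetric(self, a, b):
        assert log10_ppbr(a, b) == pytest.approx(-log10_ppbr(b, a), abs=1e-12)

    def test_error_names_offending_sample(self):
        with pytest.raises(ValidationError, match="S99"):
            log10_ppbr(0.0, 1.0, sample_id="S99")


class TestCohortGrowth:
    def test_no_mass_change_is_zero_rate(self):
        assert cohort_growth_rate(CohortPair(2.0, 2.0, 3.0, 1.0)) == 0.0

    def test_e_fold_in_one_day(self):
        assert cohort_growth_rate(CohortPair(1.0, math.e, 1.0, 1.0)) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        g = cohort_growth_rate(CohortPair(2.0, 3.0, 2.0, 1.0))
        assert g == pytest.approx(math.log(1.5) / 2.0, rel=1e-12)

    def test_mass_rescaling_invariance(self):
        g1 = cohort_growth_rate(CohortPair(2.0, 3.0, 2.0, 1.0))
        g2 = cohort_growth_rate(CohortPair(2000.0, 3000.0, 2.0, 1.0))
        assert g1 == pytest.approx(g2, rel=1e-12)

    def test_negative_rate_kept_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = cohort_growth_rate(CohortPair(3.0, 2.0, 1.0, 1.0))
        assert g < 0
        assert "negative" in caplog.text

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValidationError):
            CohortPair(0.0, 1.0, 1.0, 1.0)


class TestProductionRatio:
    def test_production_is_rate_times_biomass(self):
        pair = CohortPair(1.0, math.e**0.2, 1.0, 10.0)
        assert production(pair) == pytest.approx(2.0, rel=1e-12)

    def test_equal_productions_give_zero(self):
        assert log10_pppr(4.4, 4.4) == 0.0

    def test_common_scaling_cancels(self):
        assert log10_pppr(6.0, 2.0) == pytest.approx(log10_pppr(3.0, 1.0))


class TestPpmrAndDiversityRatio:
    def _community(self, seed=0):
        df = derive_biomass(make_particles(seed=seed), BiomassConversionTable())
        return SampleCommunity("S01", "ST001", "CR01", df)

    def test_identical_mean_masses_give_zero(self):
        df = make_particles(n_prey=3, n_predator=3)
        # force identical axes across groups -> identical biomass
        df.loc[:, "major_um"] = 50.0
        df.loc[:, "minor_um"] = 50.0
        df.loc[:, "weight_per_m3"] = 1.0
        com = SampleCommunity(
            "S01", "ST001", "CR01", derive_biomass(df, BiomassConversionTable())
        )
        assert ppmr_log10(com) == pytest.approx(0.0, abs=1e-12)

    def test_thousandfold_geometric_mean_gives_three(self):
        df = make_particles(n_prey=2, n_predator=2)
        df["weight_per_m3"] = 1.0
        df.loc[df["group"] == "prey", ["major_um", "minor_um"]] = 10.0
        df.loc[df["group"] == "predator", ["major_um", "minor_um"]] = 100.0
        com = SampleCommunity(
            "S01", "ST001", "CR01", derive_biomass(df, BiomassConversionTable())
        )
        assert ppmr_log10(com) == pytest.approx(3.0, rel=1e-12)

    def test_equal_diversities_give_unit_ratio(self):
        assert diversity_ratio(1.7, 1.7) == 1.0

    def test_zero_prey_diversity_rejected(self):
        with pytest.raises(ValidationError):
            diversity_ratio(1.0, 0.0)


class TestBootstrap:
    def test_perfect_line_has_unit_r_and_zero_width(self):
        x = np.arange(10.0)
        pairs = np.column_stack([x, 2.0 * x + 1.0])
        res = bootstrap_proxy_uncertainty(pairs, n_boot=200, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(res.boot_r, 1.0, atol=1e-9)
        assert res.ci_high - res.ci_low < 1e-9

    def test_recovers_generating_correlation(self):
        # bivariate normal with the proxy-validation correlation and size
        rng = np.random.default_rng(42)
        cov = [[1.0, 0.84], [0.84, 1.0]]
        pairs = rng.multivariate_normal([0, 0], cov, size=29)
        res = bootstrap_proxy_uncertainty(pairs, n_boot=1000, seed=1)
        assert res.ci_low <= 0.84 <= res.ci_high
        assert res.ci_low <= np.mean(res.boot_r) <= res.ci_high

    def test_fixed_seed_reproducible(self, rng):
        pairs = rng.normal(size=(20, 2))
        r1 = bootstrap_proxy_uncertainty(pairs, n_boot=300, seed=7)
        r2 = bootstrap_proxy_uncertainty(pairs, n_boot=300, seed=7)
        assert np.array_equal(r1.boot_r, r2.boot_r)
        r3 = bootstrap_proxy_uncertainty(pairs, n_boot=300, seed=8)
        assert not np.array_equal(r1.boot_r, r3.boot_r)

    def test_refit_hook_reports_sign_stability(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(scale=0.1, size=40)
        pairs = np.column_stack([x, y])

        def hook(idx):
            xs, ys = x[idx], y[idx]
            slope = np.polyfit(xs, ys, 1)[0]
            return {"slope": slope}

        res = bootstrap_proxy_uncertainty(pairs, n_boot=100, seed=3, refit_hook=hook)
        assert res.sign_stability == {"slope": 1.0}

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_proxy_uncertainty(np.ones((2, 2)), n_boot=100, seed=0)


def test_sample_summary_table():
    from planktte.morphometry import process_sample
    from planktte.size_diversity import size_diversity_table

    table = BiomassConversionTable()
    coms = [
        SampleCommunity(f"S{i:02d}", f"ST{i:03d}", "CR01",
                        make_particles(sample_id=f"S{i:02d}", station_id=f"ST{i:03d}",
                                       n_prey=40, n_predator=30, seed=i))
        for i in range(3)
    ]
    processed = [process_sample(c, table) for c in coms]
    from planktte.morphometry import communities_to_frame

    diversity = size_diversity_table(communities_to_frame(processed))
    summary = build_sample_summaries(processed, diversity)
    assert len(summary) == 3
    assert (summary["prey_biomass"] > 0).all()
    expected = np.log10(summary["predator_biomass"] / summary["prey_biomass"])
    assert np.allclose(summary["log10_ppbr"], expected)


def test_pppr_table_pairs_groups():
    cohorts = pd.DataFrame(
        dict(
            sample_id=["S01", "S01", "S02"],
            group=["prey", "predator", "prey"],
            w0_ugc=[1.0, 2.0, 1.0],
            wt_ugc=[1.5, 2.5, 1.2],
            dt_days=[1.0, 1.0, 1.0],
            biomass_mgc_m3=[10.0, 5.0, 8.0],
        )
    )
    out = pppr_table(cohorts)
    assert list(out["sample_id"]) == ["S01"]  # S02 lacks a predator cohort
    g_prey = math.log(1.5)
    g_pred = math.log(1.25)
    expected = math.log10((g_pred * 5.0) / (g_prey * 10.0))
    assert out["log10_pppr"].iloc[0] == pytest.approx(expected, rel=1e-12)
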