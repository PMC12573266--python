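"""Unit and property tests for the endpoint carbon budget."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leachflux as lf
from leachflux.budget import FG_TO_UG, BudgetDomainError

from conftest import biomass_ug_ml


class TestElementaryOperations:
    @pytest.mark.parametrize(
        "c_i, c_f, t, expected",
        [
            (2000, 2000, 3, 0.0),
            (1000, 2000, 1, math.log(2)),
            (2000, 4919.2, 3, 0.300),  # the BCP plateau reconstruction
        ],
    )
    def test_growth_rate(self, c_i, c_f, t, expected):
        assert lf.growth_rate(c_i, c_f, t) == pytest.approx(expected, abs=1e-4)

    def test_growth_rate_may_be_negative(self):
        assert lf.growth_rate(2000, 1000, 1) == pytest.approx(-math.log(2))

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(c_initial=0, c_final=1, duration=1), "c_initial"),
            (dict(c_initial=1, c_final=0, duration=1), "c_final"),
            (dict(c_initial=1, c_final=1, duration=0), "duration"),
        ],
    )
    def test_growth_rate_domain_errors_name_field(self, kwargs, field):
        with pytest.raises(BudgetDomainError, match=field):
            lf.growth_rate(**kwargs)

    @pytest.mark.parametrize(
        "esd, expected",
        [(0, 0.0), (2, 4.18879), (13.8, 1376.0555)],
    )
    def test_esd_to_volume(self, esd, expected):
        assert lf.esd_to_volume(esd) == pytest.approx(expected, rel=1e-5)

    def test_esd_to_volume_rejects_negative(self):
        with pytest.raises(BudgetDomainError, match="esd"):
            lf.esd_to_volume(-1)

    @pytest.mark.parametrize(
        "volume, factor, expected",
        [(0, 0.123, 0.0), (1000, 0.123, 123.0), (1376.0555, 0.123, 169.255)],
    )
    def test_cell_carbon(self, volume, factor, expected):
        assert lf.cell_carbon(volume, factor) == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize(
        "b_i, b_f, expected", [(1, 1, 1.0), (0.338, 1.122, 0.730), (0, 2, 1.0)]
    )
    def test_mean_biomass(self, b_i, b_f, expected):
        assert lf.mean_biomass(b_i, b_f) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "r, c_mean, t, expected",
        [(0.355, 0, 3, 0.0), (0.5, 1, 2, 1.0), (0.355, 0.730, 3, 0.77745)],
    )
    def test_respiration(self, r, c_mean, t, expected):
        assert lf.respiration(r, c_mean, t) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "growth, resp, c_mean, t, expected",
        [
            # budget reconstructions of the printed 100 % assimilation values
            (0.7845, 0.7775, 0.730, 3, 0.713),
            (0.4937, 0.6231, 0.585, 3, 0.636),
        ],
    )
    def test_assimilation_reconstructions(self, growth, resp, c_mean, t, expected):
        assert lf.assimilation(growth, resp, c_mean, t) == pytest.approx(
            expected, abs=5e-4
        )

    @given(
        b=st.floats(1e-6, 1e3),
        t=st.floats(1e-3, 30),
        r=st.floats(0, 2),
    )
    @settings(max_examples=100, derandomize=True)
    def test_assimilation_zero_growth_returns_r(self, b, t, r):
        assert lf.assimilation(0.0, r * b * t, b, t) == pytest.approx(r, rel=1e-12)

    @pytest.mark.parametrize(
        "growth, resp, doc, expected",
        [(0, 0, 1, 0.0), (0, 0.360, 1.0, 36.0), (0.7845, 0.7775, 34.0, 4.594)],
    )
    def test_pcu(self, growth, resp, doc, expected):
        assert lf.pcu(growth, resp, doc) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "t_from, t_to, expected",
        [(20, 20, 1.0), (25, 20, 2**-0.5), (10, 20, 2.0)],
    )
    def test_q10_adjust(self, t_from, t_to, expected):
        assert lf.q10_adjust(1.0, t_from, t_to, 2.0) == pytest.approx(expected)

    def test_max_bacterivory_printed_constants(self, constants):
        cell_ug = lf.cell_carbon(lf.esd_to_volume(13.8)) * 1e-6
        unadjusted = lf.max_bacterivory(1.0, cell_ug, constants, temperature=25.0)
        assert unadjusted == pytest.approx(0.2022, abs=2e-4)
        adjusted = lf.max_bacterivory(1.0, cell_ug, constants, temperature=20.0)
        assert adjusted == pytest.approx(0.2022 * 2**-0.5, abs=2e-4)
        assert lf.max_bacterivory(0.0, 0.730, constants, 20.0) == 0.0

    @pytest.mark.parametrize(
        "assim, imax, expected",
        [(0.5, 0, 1.0), (0.5, 0.7, 0.0), (0.713, 0.2022, 0.7164)],
    )
    def test_osmotrophy_fraction(self, assim, imax, expected):
        assert lf.osmotrophy_fraction(assim, imax) == pytest.approx(
            expected, abs=5e-4
        )

    @pytest.mark.parametrize(
        "n_i, n_f, doc, expected",
        [
            (1e6, 1e6, 5.0, 0.0),
            (4.75e5, 1.29e7, 1.0, 24.85),
            (1e6, 2e6, 2.0, 1.0),
            (2e6, 1e6, 1.0, 0.0),  # net decline floors at zero
        ],
    )
    def test_bacterial_carbon_use(self, n_i, n_f, doc, expected):
        ep = lf.BacterialEndpoint(n_i, n_f, doc)
        assert lf.bacterial_carbon_use(ep, 20.0) == pytest.approx(expected, abs=1e-2)


class TestFullBudget:
    def test_biop_100_chain(self, constants):
        pop = lf.ProtistPopulation(2000, 2000 * math.e**1.2, 13.8, 3.0, 20.0)
        result = lf.full_budget(pop, doc=34.0, constants=constants)
        assert result.growth_rate == pytest.approx(0.4, rel=1e-12)
        assert result.c_assimilation == pytest.approx(0.713, abs=5e-4)
        assert result.pcu == pytest.approx(4.59, abs=2e-2)
        assert result.i_max == pytest.approx(0.143, abs=5e-4)
        assert result.osmotrophy_fraction == pytest.approx(0.80, abs=5e-3)

    def test_zero_growth_limit(self, constants):
        pop = lf.ProtistPopulation(2000, 2000, 13.8, 3.0, 20.0)
        result = lf.full_budget(pop, doc=1.0, constants=constants)
        assert result.growth_rate == 0.0
        assert result.c_assimilation == pytest.approx(constants.resp_rate_r, rel=1e-14)

    @pytest.mark.parametrize("esd", [5.0, 13.8, 30.0])
    def test_cell_carbon_scale_invariance(self, esd, constants):
        """Assimilation cannot depend on cell size; I_max scales inversely.

        Per-cell carbon multiplies every biomass term, so it cancels from
        C_assimilation; I_max divides a cell count by a biomass, so the
        specific bacterivory ceiling scales as 1/per-cell carbon (a fixed
        per-cell ingestion ceiling is a smaller specific flux for a bigger
        cell).
        """
        ref = lf.full_budget(
            lf.ProtistPopulation(2000, 6000, 13.8, 3.0, 20.0), 10.0, constants
        )
        other = lf.full_budget(
            lf.ProtistPopulation(2000, 6000, esd, 3.0, 20.0), 10.0, constants
        )
        assert other.c_assimilation == pytest.approx(ref.c_assimilation, rel=1e-12)
        carbon_ratio = ref.cell_carbon / other.cell_carbon
        assert other.i_max == pytest.approx(ref.i_max * carbon_ratio, rel=1e-12)

    @given(g=st.floats(-0.5, 1.0), t=st.floats(0.5, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_closed_form_equivalence(self, g, t):
        """For exponential growth, C_assim = 2(e^{gt}−1)/((1+e^{gt})t) + R."""
        constants = lf.BudgetConstants()
        pop = lf.ProtistPopulation(2000, 2000 * math.exp(g * t), 13.8, t, 20.0)
        result = lf.full_budget(pop, 1.0, constants)
        expected = (
            2.0 * (math.exp(g * t) - 1.0) / ((1.0 + math.exp(g * t)) * t)
            + constants.resp_rate_r
        )
        assert result.c_assimilation == pytest.approx(expected, rel=1e-9)

    @given(
        g1=st.floats(-0.5, 1.0),
        g2=st.floats(-0.5, 1.0),
        t1=st.floats(0.1, 5.0),
        t2=st.floats(0.1, 5.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_growth_rate_time_additivity(self, g1, g2, t1, t2):
        """GR over [0, t1+t2] is the duration-weighted mean of subintervals."""
        c0 = 1000.0
        c_mid = c0 * math.exp(g1 * t1)
        c_end = c_mid * math.exp(g2 * t2)
        total = lf.growth_rate(c0, c_end, t1 + t2)
        weighted = (g1 * t1 + g2 * t2) / (t1 + t2)
        assert total == pytest.approx(weighted, rel=1e-9, abs=1e-12)

    def test_pcu_strictly_decreasing_in_doc(self):
        values = [lf.pcu(0.5, 0.5, doc) for doc in (1.0, 2.0, 5.0, 34.0)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_assimilation_strictly_increasing_in_growth_rate(self, constants):
        assims = []
        for g in (0.0, 0.1, 0.2, 0.3, 0.4):
            pop = lf.ProtistPopulation(2000, 2000 * math.exp(3 * g), 13.8, 3.0)
            assims.append(lf.full_budget(pop, 1.0, constants).c_assimilation)
        assert all(a < b for a, b in zip(assims, assims[1:]))

    def test_imax_dilution_independent(self, constants):
        """With constant ESD, C_avg/C_mean reduces to 1/cell-carbon."""
        imaxes = []
        for g in (0.0, 0.2, 0.4):
            pop = lf.ProtistPopulation(2000, 2000 * math.exp(3 * g), 13.8, 3.0)
            imaxes.append(lf.full_budget(pop, 1.0, constants).i_max)
        assert imaxes[0] == pytest.approx(imaxes[1], rel=1e-12)
        assert imaxes[0] == pytest.approx(imaxes[2], rel=1e-12)

    def test_unit_audit_against_fg_tracking_oracle(self, constants):
        """Eq.-5 unit bookkeeping: redo the ratio entirely in femtograms."""
        pop = lf.ProtistPopulation(2000, 6640.2, 13.8, 3.0, 25.0)
        result = lf.full_budget(pop, 1.0, constants)
        c_avg = 0.5 * (pop.c_initial + pop.c_final)
        c_mean_fg = lf.mean_biomass(
            biomass_ug_ml(pop.c_initial, 13.8), biomass_ug_ml(pop.c_final, 13.8)
        ) / FG_TO_UG  # µg -> fg
        numerator_fg = 71.3 * 24.0 * 20.0 * c_avg  # fg C ml⁻¹ d⁻¹ ingested
        assert result.i_max == pytest.approx(numerator_fg / c_mean_fg, rel=1e-12)

    def test_negative_growth_reported_unclamped(self, constants):
        pop = lf.ProtistPopulation(2000, 1500, 13.8, 3.0)
        result = lf.full_budget(pop, 1.0, constants)
        assert result.c_growth < 0
        assert result.c_assimilation < constants.resp_rate_r
        assert 0.0 <= result.osmotrophy_fraction <= 1.0

    def test_steep_decline_leaves_osmotrophy_undefined(self, constants):
        # respiration cannot offset the biomass loss: assimilation < 0 and
        # the osmotrophy split has no meaning
        pop = lf.ProtistPopulation(2000, 500, 13.8, 3.0)
        result = lf.full_budget(pop, 1.0, constants)
        assert result.c_assimilation < 0
        assert math.isnan(result.osmotrophy_fraction)


class TestTableInterface:
    def test_summary_is_replicate_first(self, constants):
        import pandas as pd

        rows = []
        for rep, c_final in enumerate([5000.0, 6000.0, 7000.0], start=1):
            rows.append(
                dict(
                    experiment_id="x",
                    treatment="BioP",
                    dilution_pct=100.0,
                    replicate=rep,
                    c_initial_cells_ml=2000.0,
                    c_final_cells_ml=c_final,
                    esd_um=13.8,
                    duration_h=72.0,
                    temperature_c=20.0,
                    doc_ug_ml=34.0,
                )
            )
        budgets = lf.budget_table(pd.DataFrame(rows), constants)
        summary = lf.summarize_budgets(budgets)
        assert summary.loc[0, "c_assimilation_mean"] == pytest.approx(
            budgets["c_assimilation"].mean(), rel=1e-14
        )
        assert summary.loc[0, "n"] == 3

    def test_missing_bacterial_columns_omit_bacterial_output(self, constants):
        import pandas as pd

        row = dict(
            experiment_id="x",
            treatment="control",
            dilution_pct=0.0,
            replicate=1,
            c_initial_cells_ml=2000.0,
            c_final_cells_ml=2100.0,
            esd_um=13.8,
            duration_h=72.0,
            temperature_c=20.0,
            doc_ug_ml=1.0,
        )
        budgets = lf.budget_table(pd.DataFrame([row]), constants)
        assert "bacterial_pcu" not in budgets.columns
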