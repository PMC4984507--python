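"""Joint MLE, per-microcosm inversion and the (e, mu) sensitivity scan."""

import math

import numpy as np
import pandas as pd
import pytest

from hvhfit import (
    FixedParams,
    HVHParams,
    InterferenceScenario,
    DEFAULT_SCENARIO,
    build_design,
    consumer_growth,
    derive_growth_table,
    fit_joint,
    invert_m,
    manufacture_consistent_census,
    nll,
    per_microcosm_m,
    sensitivity_scan,
    true_m_for,
)
from hvhfit.dynamics import GrowthRecord, records_from_table
from hvhfit.errors import (
    DomainError,
    InsufficientDataError,
    SingularInversionError,
)


def make_record(Ni, R, p, fx, T=72.0, mid="m1"):
    """Model-consistent record: dC/dt set exactly by the consumer equation."""
    dcdt = consumer_growth(Ni, R, p, fx)
    r = dcdt / Ni
    return GrowthRecord(
        microcosm_id=mid, treatment_id="T01", replicate=1, resource_mg=R,
        initial_density=Ni, final_density=Ni * math.exp(r * T), duration_h=T,
        per_capita_growth=math.exp(r * T) - 1.0, r=r, dCdt=dcdt, valid=True,
    )


class TestNll:
    def test_zero_residuals_unit_sigma(self, fx, true_params):
        recs = [make_record(Ni, 3.0, HVHParams(a=true_params.a, h=true_params.h, m=-0.5), fx,
                            mid=f"m{i}")
                for i, Ni in enumerate([26.0, 77.0, 132.0])]
        val = nll(true_params.a, true_params.h, -0.5, 1.0, recs, fx)
        assert val == pytest.approx(len(recs) * 0.5 * math.log(2 * math.pi), rel=1e-12)

    def test_unit_standardized_residual(self, fx):
        p = HVHParams(a=0.3, h=5.0, m=-0.5)
        rec = make_record(50.0, 3.0, p, fx)
        sigma = 0.7
        shifted = rec.__class__(**{**rec.__dict__, "dCdt": rec.dCdt + sigma})
        val = nll(p.a, p.h, p.m, sigma, [shifted], fx)
        assert val == pytest.approx(math.log(sigma) + 0.5 * math.log(2 * math.pi) + 0.5,
                                    rel=1e-12)

    def test_matches_term_by_term_oracle(self, fx, rng):
        p = HVHParams(a=0.4, h=2.0, m=-0.3)
        recs = []
        for i in range(6):
            rec = make_record(float(rng.uniform(10, 300)), float(rng.choice([3.0, 12.0])),
                              p, fx, mid=f"m{i}")
            recs.append(rec.__class__(**{**rec.__dict__, "dCdt": rec.dCdt + rng.normal(0, 0.5)}))
        a, h, m, sigma = 0.35, 2.5, -0.4, 0.8
        expected = 0.0
        for rec in recs:
            pred = consumer_growth(rec.initial_density, rec.resource_mg,
                                   HVHParams(a=a, h=h, m=m), fx)
            expected += (math.log(sigma) + 0.5 * math.log(2 * math.pi)
                         + (rec.dCdt - pred) ** 2 / (2 * sigma**2))
        assert nll(a, h, m, sigma, recs, fx) == pytest.approx(expected, rel=1e-12)

    def test_rejects_invalid_records(self, fx):
        bad = GrowthRecord("x", "T01", 1, 3.0, 0.0, 0.0, 72.0,
                           float("nan"), float("nan"), float("nan"), False)
        with pytest.raises(DomainError):
            nll(0.3, 5.0, 0.0, 1.0, [bad], fx)

    def test_likelihood_minimal_at_truth_on_consistent_data(self, fx):
        """Coarse-grid global-minimum check: no perturbed parameter beats the
        generating parameters on noise-free, model-consistent data."""
        growth = derive_growth_table(manufacture_consistent_census(
            build_design((26, 77, 132, 263), (3, 12), 2, 72.0),
            HVHParams(a=0.3, h=5.0, m=-0.5), fx,
            InterferenceScenario(mode="constant", m_constant=-0.5)))
        recs = records_from_table(growth[growth["valid"]])
        base = nll(0.3, 5.0, -0.5, 0.1, recs, fx)
        for da, dh, dm in [(0.05, 0, 0), (-0.05, 0, 0), (0, 0.5, 0), (0, -0.5, 0),
                           (0, 0, 0.1), (0, 0, -0.1), (0.02, 0.3, -0.05)]:
            assert nll(0.3 + da, 5.0 + dh, -0.5 + dm, 0.1, recs, fx) >= base


class TestInvertM:
    @pytest.mark.parametrize("m_true", [-0.5, -1.0, 0.3])
    def test_round_trip_machine_precision(self, fx, m_true):
        p = HVHParams(a=0.3, h=5.0, m=m_true)
        rec = make_record(77.0, 3.0, p, fx)
        pm = invert_m(rec, p.a, p.h, fx)
        assert pm.feasible
        assert pm.m_hat == pytest.approx(m_true, rel=1e-9, abs=1e-12)
        # reconstituted dC/dt reproduces the record
        pred = consumer_growth(77.0, 3.0, HVHParams(a=p.a, h=p.h, m=pm.m_hat), fx)
        assert pred == pytest.approx(rec.dCdt, rel=1e-9)

    def test_mortality_floor_infeasible(self, fx):
        # dCdt/C < -mu requires a negative foraging rate
        rec = GrowthRecord("x", "T01", 1, 3.0, 100.0, 1e-9, 72.0,
                           -1.0, -0.2, -20.0, True)
        pm = invert_m(rec, 0.3, 5.0, fx)
        assert not pm.feasible and math.isnan(pm.m_hat)

    def test_saturation_ceiling_infeasible(self, fx):
        # required f >= 1/h cannot be produced by the trophic function
        h = 5.0
        r_too_fast = (fx.e / h - fx.mu) * 1.01
        rec = GrowthRecord("x", "T01", 1, 3.0, 100.0, 100.0 * math.exp(r_too_fast * 72), 72.0,
                           0.0, r_too_fast, r_too_fast * 100.0, True)
        pm = invert_m(rec, 0.3, h, fx)
        assert not pm.feasible

    def test_unit_density_singular(self, fx):
        rec = GrowthRecord("x", "T01", 1, 3.0, 1.0, 2.0, 72.0, 1.0,
                           math.log(2) / 72, math.log(2) / 72, True)
        with pytest.raises(SingularInversionError):
            invert_m(rec, 0.3, 5.0, fx)

    def test_invalid_record_rejected(self, fx):
        bad = GrowthRecord("x", "T01", 1, 3.0, 0.0, 0.0, 72.0,
                           float("nan"), float("nan"), float("nan"), False)
        with pytest.raises(DomainError):
            invert_m(bad, 0.3, 5.0, fx)


class TestPerMicrocosmM:
    def test_recovers_generating_interpolation_line(self, fx, true_params, design,
                                                    consistent_census_shifting):
        """On model-consistent data with the true (a, h), the per-microcosm
        estimates lie exactly on the generator's density-m line."""
        growth = derive_growth_table(consistent_census_shifting)
        m_table = per_microcosm_m(growth[growth["valid"]], true_params.a, true_params.h, fx)
        assert m_table["feasible"].all()
        for row in m_table.itertuples():
            expected = true_m_for(row.initial_density, DEFAULT_SCENARIO, design)
            assert row.m_hat == pytest.approx(expected, abs=1e-9)

    def test_all_infeasible_yields_empty_feasible_set(self, fx):
        recs = [GrowthRecord(f"x{i}", "T01", 1, 3.0, 100.0, 1e-9, 72.0,
                             -1.0, -0.2, -20.0, True) for i in range(3)]
        tab = per_microcosm_m(recs, 0.3, 5.0, fx)
        assert len(tab) == 3 and not tab["feasible"].any()


class TestFitJoint:
    def test_exact_recovery_on_consistent_constant_m_data(self, fx):
        """Noise-free model-consistent records: (a, h, m) recovered to 1e-3."""
        design = build_design((26, 77, 132, 263), (3, 12), 2, 72.0)
        sc = InterferenceScenario(mode="constant", m_constant=-0.5)
        p = HVHParams(a=0.3, h=5.0, m=-0.5)
        census = manufacture_consistent_census(design, p, fx, sc)
        growth = derive_growth_table(census)
        fit = fit_joint(growth[growth["valid"]], fx, seed=0)
        assert fit.converged and fit.valid
        assert abs(fit.a_hat - 0.3) / 0.3 < 1e-3
        assert abs(fit.h_hat - 5.0) / 5.0 < 1e-3
        assert abs(fit.m_hat + 0.5) / 0.5 < 1e-3

    def test_exploitative_limit_has_near_zero_m(self, fx, noiseless_growth_m0):
        fit = fit_joint(noiseless_growth_m0[noiseless_growth_m0["valid"]], fx, seed=0)
        assert abs(fit.m_hat) < 0.05

    def test_record_order_irrelevant(self, fx, noiseless_growth_m0, rng):
        valid = noiseless_growth_m0[noiseless_growth_m0["valid"]]
        fit1 = fit_joint(valid, fx, seed=3)
        shuffled = valid.sample(frac=1.0, random_state=42)
        fit2 = fit_joint(shuffled, fx, seed=3)
        assert fit1.a_hat == pytest.approx(fit2.a_hat, rel=1e-6)
        assert fit1.m_hat == pytest.approx(fit2.m_hat, abs=1e-6)

    def test_aic_consistent_with_nll(self, fx, noiseless_growth_m0):
        fit = fit_joint(noiseless_growth_m0[noiseless_growth_m0["valid"]], fx, seed=0)
        assert fit.aic == pytest.approx(8.0 + 2.0 * fit.nll)

    def test_insufficient_data_rejected(self, fx):
        p = HVHParams(a=0.3, h=5.0, m=-0.5)
        recs = [make_record(26.0, 3.0, p, fx, mid=f"m{i}") for i in range(10)]
        with pytest.raises(InsufficientDataError):
            fit_joint(recs, fx)  # one density, one resource level


@pytest.fixture(scope="module")
def valid_growth(fx):
    design = build_design((26, 77, 132, 263), (3, 12), 3, 72.0)
    sc = InterferenceScenario(mode="constant", m_constant=-0.5)
    p = HVHParams(a=0.3, h=5.0, m=-0.5)
    growth = derive_growth_table(manufacture_consistent_census(design, p, fx, sc))
    return growth[growth["valid"]]


class TestSensitivityScan:
    def test_grid_cell_reproduces_single_fit(self, fx, valid_growth):
        scan = sensitivity_scan(valid_growth, [0.8], [0.1], seed=1)
        single = fit_joint(valid_growth, fx, seed=1)
        row = scan.iloc[0]
        assert row["a_hat"] == pytest.approx(single.a_hat, rel=1e-9)
        assert row["m_hat"] == pytest.approx(single.m_hat, abs=1e-9)

    def test_empty_grid_rejected(self, valid_growth):
        with pytest.raises(DomainError):
            sensitivity_scan(valid_growth, [], [0.1])
        with pytest.raises(DomainError):
            sensitivity_scan(valid_growth, [1.5], [0.1])

    def test_misspecified_mortality_triggers_handling_time_rejection(self, fx, true_params):
        """Fitting with an implausibly low assumed mortality drives the
        handling time against its zero bound, and the scan flags such
        fits invalid (the constrained analogue of a negative
        handling-time estimate)."""
        from hvhfit import DEFAULT_DESIGN, DEFAULT_OBSERVATION, generate_dataset

        census = generate_dataset(DEFAULT_DESIGN, true_params, fx, DEFAULT_SCENARIO,
                                  DEFAULT_OBSERVATION, seed=21)
        growth = derive_growth_table(census)
        valid = growth[growth["valid"]]
        scan = sensitivity_scan(valid, [0.8], [0.01, 0.1], seed=2).set_index("mu")
        assert scan.loc[0.01, "h_hat"] == pytest.approx(0.0, abs=1e-6)
        assert not scan.loc[0.01, "valid"]
        assert scan.loc[0.1, "valid"]
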