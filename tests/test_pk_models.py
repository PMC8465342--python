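"""Model-structure tests: derived parameters, steady states, and the
forward simulator against independent closed-form and matrix-exponential
oracles."""

from __future__ import annotations


import numpy as np
import pytest
from scipy.linalg import expm

from ipinsulin import (
    AbsorptionParams,
    AbsorptionVariant,
    DegenerateParametersError,
    GlucoseProfile,
    HEVariant,
    InfusionProfile,
    KineticsParams,
    ModelSpec,
    basal_steady_state,
    derive_m3_basal,
    derive_m4,
    hepatic_extraction,
    simulate,
)
from ipinsulin.pk_models import params_from_json, params_to_json


def _absorption_for(variant: str) -> AbsorptionParams:
    return {
        "1": AbsorptionParams(ka1=0.015),
        "2": AbsorptionParams(ka2=0.028, kd=0.05),
        "3": AbsorptionParams(ka1=0.012, ka2=0.026),
    }[variant]


def _glucose_flat(Gb=120.0):
    return GlucoseProfile(Gb=Gb)


def _kin_for(he: str, **over):
    base = dict(VI=3.4, m1=0.15, CL=1.16, HEb=0.59)
    if he == "B":
        base.update(aG=5e-4, Gb=120.0)
    elif he == "C":
        base.update(aI=16e-5)
    base.update(over)
    return KineticsParams(**base)


# ---------------------------------------------------------------------------
# Derived parameters
# ---------------------------------------------------------------------------


class TestDerivedParameters:
    def test_m4_from_median_estimates(self, median_kinetics):
        m4 = derive_m4(median_kinetics)
        assert m4 == pytest.approx(0.1830564706, rel=1e-9)
        # plugging back recovers the clearance decomposition
        assert (0.59 * 0.268 + m4) * 3.4 == pytest.approx(1.16, rel=1e-12)

    def test_m4_zero_extraction_limit(self):
        kin = KineticsParams(VI=3.4, m1=0.15, CL=1.16, HEb=1e-12)
        assert derive_m4(kin) == pytest.approx(1.16 / 3.4, rel=1e-9)

    def test_m4_infeasible_clearance_rejected(self):
        with pytest.raises(DegenerateParametersError):
            KineticsParams(VI=3.4, m1=0.15, CL=0.1, HEb=0.59)

    @pytest.mark.parametrize(
        "heb,m1,expected",
        [(0.5, 0.15, 0.15), (0.59, 0.15, 0.2158536585), (1e-9, 0.15, 1.5e-10)],
    )
    def test_m3_basal(self, heb, m1, expected):
        kin = KineticsParams(VI=3.4, m1=m1, CL=2.0, HEb=heb)
        assert derive_m3_basal(kin) == pytest.approx(expected, rel=1e-6)
        # solving HE back from m3 = HE/(1-HE)*m1 recovers HEb
        m3 = derive_m3_basal(kin)
        assert m3 / (m3 + m1) == pytest.approx(heb, rel=1e-6)


class TestHepaticExtraction:
    def test_constant_variant_returns_basal(self):
        kin = _kin_for("A")
        assert hepatic_extraction(HEVariant.A, kin, Ql=123.0) == 0.59

    def test_insulin_controlled_at_basal_equals_heb(self):
        kin = _kin_for("C")
        assert hepatic_extraction(HEVariant.C, kin, Ql=56.4, Qlb=56.4) == pytest.approx(0.59)

    def test_insulin_controlled_decreases_with_liver_insulin(self):
        kin = _kin_for("C")
        he = hepatic_extraction(HEVariant.C, kin, Ql=556.4, Qlb=56.4)
        assert he == pytest.approx(0.51, abs=1e-12)
        assert he < kin.HEb

    def test_glucose_controlled_needs_glucose(self):
        kin = KineticsParams(VI=3.4, m1=0.15, CL=1.16, HEb=0.59, aG=5e-4)
        with pytest.raises(ValueError):
            hepatic_extraction(HEVariant.B, kin, G=None)

    def test_clamped_to_interval(self):
        kin = _kin_for("C", aI=1.0)
        assert hepatic_extraction(HEVariant.C, kin, Ql=1e4, Qlb=0.0) == 0.0
        assert hepatic_extraction(HEVariant.C, kin, Ql=-1e4, Qlb=0.0) == 0.95


# ---------------------------------------------------------------------------
# Basal steady state
# ---------------------------------------------------------------------------


class TestBasalSteadyState:
    def test_no_input_gives_zero_state(self, model_3c, median_kinetics):
        ss = basal_steady_state(model_3c, _absorption_for("3"), median_kinetics, 0.0)
        assert np.all(ss == 0)

    def test_plasma_liver_balance_matches_linear_solve(self, median_kinetics):
        # independent oracle: solve the 2x2 basal balance numerically
        inf_b = 15.6
        m4 = 1.16 / 3.4 - 0.59 * 0.268
        m3b = 0.59 / 0.41 * 0.15
        a = np.array([[0.268 + m4, -0.15], [-0.268, 0.15 + m3b]])
        qpb, qlb = np.linalg.solve(a, [0.0, inf_b])
        assert qlb == pytest.approx(56.37, abs=0.01)
        assert qpb == pytest.approx(18.75, abs=0.01)
        spec = ModelSpec.from_string("3C")
        ss = basal_steady_state(spec, _absorption_for("3"), median_kinetics, inf_b)
        assert ss[2] == pytest.approx(qpb, rel=1e-12)
        assert ss[3] == pytest.approx(qlb, rel=1e-12)
        assert ss[2] / 3.4 == pytest.approx(5.51, abs=0.01)  # basal Ip

    def test_m3_ip_compartments_split_infusion(self, median_kinetics):
        spec = ModelSpec.from_string("3A")
        ss = basal_steady_state(
            spec, AbsorptionParams(ka1=0.010, ka2=0.028), median_kinetics, 15.6
        )
        assert ss[0] == pytest.approx(15.6 / 0.038, rel=1e-12)
        assert ss[1] == pytest.approx(ss[0])
        assert ss[0] == pytest.approx(410.5, abs=0.1)

    @pytest.mark.parametrize("spec_str", [str(s) for s in ModelSpec.all_nine()])
    def test_fixed_point_has_zero_derivatives(self, spec_str):
        """The steady state must be a fixed point of the assembled ODEs,
        checked with an independently written right-hand side."""
        spec = ModelSpec.from_string(spec_str)
        kin = _kin_for(spec_str[1])
        p = _absorption_for(spec_str[0])
        inf_b = 15.6
        y = basal_steady_state(spec, p, kin, inf_b)
        q1, q2, qp, ql = y
        # independent RHS straight from the model definition
        if spec.absorption is AbsorptionVariant.M1:
            dq1, dq2, ra = -p.ka1 * q1 + inf_b, 0.0, p.ka1 * q1
        elif spec.absorption is AbsorptionVariant.M2:
            dq1 = -p.kd * q1 + inf_b
            dq2 = p.kd * q1 - p.ka2 * q2
            ra = p.ka2 * q2
        else:
            dq1 = -(p.ka1 + p.ka2) * q1 + inf_b
            dq2 = p.ka2 * (q1 - q2)
            ra = p.ka1 * q1 + p.ka2 * q2
        he = kin.HEb  # all laws evaluate to HEb at their own basal point
        m3 = he / (1 - he) * kin.m1
        m4 = kin.CL / kin.VI - kin.HEb * kin.m2
        dqp = -(kin.m2 + m4) * qp + kin.m1 * ql
        dql = -(kin.m1 + m3) * ql + kin.m2 * qp + ra
        assert ra == pytest.approx(inf_b, rel=1e-12)
        assert max(abs(d) for d in (dq1, dq2, dqp, dql)) < 1e-9

    def test_no_absorption_route_rejected(self, median_kinetics):
        spec = ModelSpec.from_string("3A")
        with pytest.raises(DegenerateParametersError):
            basal_steady_state(spec, AbsorptionParams(ka1=0.0, ka2=0.0), median_kinetics, 15.6)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


class TestSimulate:
    @pytest.mark.parametrize("spec_str", [str(s) for s in ModelSpec.all_nine()])
    def test_basal_steady_state_invariance(self, spec_str):
        """Started at the basal steady state with basal-only infusion, the
        plasma insulin trace stays flat over 24 h."""
        spec = ModelSpec.from_string(spec_str)
        kin = _kin_for(spec_str[1])
        res = simulate(
            spec,
            _absorption_for(spec_str[0]),
            kin,
            InfusionProfile.constant(15.6),
            glucose=_glucose_flat() if spec.hepatic is HEVariant.B else None,
            horizon=1440.0,
            t_eval=np.linspace(0, 1440, 49),
        )
        assert np.abs(res.Ip / res.Ip[0] - 1).max() < 1e-3
        assert np.allclose(res.Ip, res.states[:, 2] / kin.VI)
        assert np.allclose(res.RaI, 15.6, rtol=1e-6)

    def test_single_bolus_matches_closed_form(self):
        """M1 with one bolus into an empty IP space: RaI = ka1*D*exp(-ka1*t)."""
        spec = ModelSpec.from_string("1A")
        ka1, dose = 0.015, 5000.0
        kin = _kin_for("A")
        res = simulate(
            spec,
            AbsorptionParams(ka1=ka1),
            kin,
            InfusionProfile.constant(0.0, boluses=[(0.0, dose)]),
            horizon=360.0,
            t_eval=np.linspace(0, 360, 73),
            initial_state=np.zeros(4),
        )
        expected = ka1 * dose * np.exp(-ka1 * res.times)
        np.testing.assert_allclose(res.RaI, expected, rtol=1e-6)

    def test_matrix_exponential_oracle(self):
        """Variant A is linear time-invariant between boluses: the states
        must match an affine matrix-exponential solution."""
        spec = ModelSpec.from_string("1A")
        kin = _kin_for("A")
        ka1, inf_b, dose = 0.015, 15.6, 7500.0
        p = AbsorptionParams(ka1=ka1)
        y0 = basal_steady_state(spec, p, kin, inf_b)
        y0[0] += dose  # off steady state: just after a bolus
        grid = np.linspace(0.0, 360.0, 25)
        res = simulate(
            spec, p, kin, InfusionProfile.constant(inf_b),
            horizon=360.0, t_eval=grid, initial_state=y0,
        )
        m3b = kin.HEb / (1 - kin.HEb) * kin.m1
        m4 = kin.CL / kin.VI - kin.HEb * kin.m2
        A = np.array(
            [
                [-ka1, 0.0, 0.0],
                [0.0, -(kin.m2 + m4), kin.m1],
                [ka1, kin.m2, -(kin.m1 + m3b)],
            ]
        )
        b = np.array([inf_b, 0.0, 0.0])
        x0 = y0[[0, 2, 3]]
        xinf = -np.linalg.solve(A, b)
        for k, t in enumerate(grid):
            x = expm(A * t) @ (x0 - xinf) + xinf
            np.testing.assert_allclose(res.states[k, [0, 2, 3]], x, rtol=1e-6)

    def test_m3_without_first_route_equals_m2_with_equal_rates(self, median_kinetics):
        """M3 with ka1=0 reduces exactly to M2 with kd=ka2."""
        inf = InfusionProfile.constant(15.6, boluses=[(120.0, 6000.0)])
        grid = np.linspace(0, 720, 73)
        kw = dict(kin=median_kinetics, infusion=inf, horizon=720.0, t_eval=grid)
        r3 = simulate(ModelSpec.from_string("3C"), AbsorptionParams(ka1=0.0, ka2=0.028), **kw)
        r2 = simulate(ModelSpec.from_string("2C"), AbsorptionParams(ka2=0.028, kd=0.028), **kw)
        np.testing.assert_allclose(r3.Ip, r2.Ip, rtol=1e-7)

    def test_m2_with_fast_distribution_approaches_m1(self, median_kinetics):
        """As kd >> ka2 the first M2 compartment becomes transparent and M2
        approaches M1 with ka1=ka2 (asymptotic, 2% band)."""
        ka = 0.02
        inf = InfusionProfile.constant(15.6, boluses=[(120.0, 6000.0)])
        grid = np.linspace(60, 720, 34)
        kw = dict(kin=median_kinetics, infusion=inf, horizon=720.0, t_eval=grid)
        r2 = simulate(ModelSpec.from_string("2C"), AbsorptionParams(ka2=ka, kd=100 * ka), **kw)
        r1 = simulate(ModelSpec.from_string("1C"), AbsorptionParams(ka1=ka), **kw)
        assert np.abs(r2.Ip / r1.Ip - 1).max() < 0.02

    def test_ip_mass_balance_with_impulsive_boluses(self, model_3c, median_kinetics):
        """Cumulative infused dose = IP mass gain + integrated absorption
        flux, to 1e-6 relative, on a full basal-bolus day."""
        inf = InfusionProfile.constant(
            15.625, boluses=[(60.0, 7500.0), (360.0, 7500.0), (720.0, 7500.0)]
        )
        # dense grid with segment ends just before each bolus so the
        # trapezoid never straddles a flux discontinuity
        edges = [0.0, 60.0, 360.0, 720.0, 1440.0]
        parts = []
        for a, b in zip(edges[:-1], edges[1:]):
            stop = b - 1e-7 if b != edges[-1] else b
            parts.append(np.linspace(a, stop, int((b - a) * 4) + 1))
        grid = np.unique(np.concatenate(parts))
        res = simulate(
            model_3c, AbsorptionParams(ka1=0.012, ka2=0.026), median_kinetics,
            inf, horizon=1440.0, t_eval=grid,
        )
        infused = inf.total_delivered(1440.0)
        ip_mass = res.states[:, 0] + res.states[:, 1]
        absorbed = np.trapezoid(res.RaI, res.times)
        balance = (ip_mass[-1] - ip_mass[0]) + absorbed
        assert balance == pytest.approx(infused, rel=1e-6)

    def test_ip_mass_balance_square_wave_boluses(self, model_3c, median_kinetics):
        inf = InfusionProfile.constant(15.625, boluses=[(60.0, 7500.0), (720.0, 7500.0)])
        grid = np.arange(0.0, 1440.0 + 1e-9, 0.25)
        res = simulate(
            model_3c, AbsorptionParams(ka1=0.012, ka2=0.026), median_kinetics,
            inf, horizon=1440.0, t_eval=grid, bolus_duration=10.0,
        )
        infused = inf.total_delivered(1440.0)
        ip_mass = res.states[:, 0] + res.states[:, 1]
        balance = (ip_mass[-1] - ip_mass[0]) + np.trapezoid(res.RaI, res.times)
        assert balance == pytest.approx(infused, rel=1e-6)

    def test_he_trace_stays_in_clamp_interval(self, median_subject, open_loop_design):
        kin = KineticsParams(VI=3.4, m1=0.15, CL=1.16, HEb=0.59, aI=5e-3)  # extreme control
        res = simulate(
            ModelSpec.from_string("3C"),
            AbsorptionParams(ka1=0.012, ka2=0.026),
            kin,
            open_loop_design,
            horizon=1440.0,
            t_eval=np.linspace(0, 1440, 145),
        )
        assert res.clamp_active
        assert res.HE.min() >= 0.0 and res.HE.max() <= 0.95
        m3 = res.HE / (1 - res.HE) * kin.m1
        assert np.all(m3 >= 0)

    def test_states_nonnegative(self, noise_free_day):
        assert noise_free_day.insulin.min() >= 0

    def test_glucose_required_for_variant_b(self, median_kinetics):
        with pytest.raises(ValueError, match="glucose"):
            simulate(
                ModelSpec.from_string("1B"),
                AbsorptionParams(ka1=0.015),
                median_kinetics,
                InfusionProfile.constant(15.6),
                horizon=60.0,
                t_eval=np.array([0.0, 60.0]),
            )


# ---------------------------------------------------------------------------
# Spec round-trips and validation
# ---------------------------------------------------------------------------


class TestSpecAndSerialization:
    @pytest.mark.parametrize("s", ["1A", "2B", "3C"])
    def test_model_spec_string_roundtrip(self, s):
        assert str(ModelSpec.from_string(s)) == s

    def test_nine_distinct_variants(self):
        assert len({str(s) for s in ModelSpec.all_nine()}) == 9

    def test_kd_must_dominate_ka2(self):
        with pytest.raises(DegenerateParametersError):
            AbsorptionParams(ka2=0.05, kd=0.02).validate(AbsorptionVariant.M2)

    def test_params_json_roundtrip(self, median_kinetics, median_absorption, model_3c):
        s = params_to_json(model_3c, median_absorption, median_kinetics)
        spec, plist, kin = params_from_json(s)
        assert str(spec) == "3C"
        assert [p.ka1 for p in plist] == [0.018, 0.004, 0.012]
        assert kin == median_kinetics

    def test_simulation_frame_header(self, model_3c, median_kinetics):
        res = simulate(
            model_3c, AbsorptionParams(ka1=0.012, ka2=0.026), median_kinetics,
            InfusionProfile.constant(15.6), horizon=60.0, t_eval=np.array([0.0, 30.0, 60.0]),
        )
        assert list(res.to_frame().columns) == [
            "time_min", "Qip1", "Qip2", "Qp", "Ql",
            "Ip_mU_per_L", "RaI_mU_per_min", "HE",
        ]
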