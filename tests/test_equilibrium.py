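import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glagov as gl

import oracles


@pytest.fixture(scope="module")
def geom():
    return gl.build_reference_geometry(12.0)


class TestPressureResidual:
    def test_reference_state_is_equilibrium(self, geom, materials):
        assert gl.pressure_residual(geom.A, 1.0, 0.0, geom, materials) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_residual_is_minus_P_at_unit_stretch(self, geom, materials):
        # With a=A and g=1 the stretch field is identically 1, so every
        # integrand vanishes and the imbalance is exactly the pressure.
        P80 = 80.0 * gl.MMHG_TO_KPA
        assert gl.pressure_residual(geom.A, 1.0, P80, geom, materials) == pytest.approx(
            -10.665792, rel=1e-10
        )

    def test_pinned_by_dense_trapezoid_oracle(self, geom, materials):
        val = gl.pressure_residual(1.05 * geom.A, 1.0, 0.0, geom, materials)
        # Frozen from the 1e4-point trapezoid evaluation.
        assert val == pytest.approx(0.57385109, abs=5e-7)
        assert val == pytest.approx(
            oracles.trapezoid_residual(1.05 * geom.A, 1.0, 0.0, geom.A), abs=5e-7
        )

    def test_rejects_nonpositive_radius(self, geom, materials):
        with pytest.raises(ValueError):
            gl.pressure_residual(0.0, 1.0, 0.0, geom, materials)


class TestFrameEquivalence:
    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(
        alpha_B=st.floats(0.9, 1.25),
        g=st.floats(1.0, 2.0),
        P_mmHg=st.floats(0.0, 110.0),
    )
    def test_reference_and_deformed_residuals_agree(self, alpha_B, g, P_mmHg, materials):
        # Trial states parameterized by the IEL stretch keep the collagen
        # exponentials in their physical range, where kPa-scale tolerances
        # are meaningful.
        geom = gl.build_reference_geometry(12.0)
        a = np.sqrt((alpha_B * geom.B) ** 2 - g**2 * (geom.B**2 - geom.A**2))
        P = P_mmHg * gl.MMHG_TO_KPA
        r_ref = gl.pressure_residual(a, g, P, geom, materials)
        r_def = gl.residual_deformed_frame(a, g, P, geom, materials)
        assert r_def == pytest.approx(r_ref, abs=1e-6)


class TestSolveConfiguration:
    def test_reference_state_solution(self, geom, materials):
        cfg = gl.solve_configuration(1.0, 0.0, geom, materials)
        assert cfg.a == pytest.approx(geom.A, abs=1e-9)
        assert (cfg.b, cfg.c, cfg.d) == pytest.approx((geom.B, geom.C, geom.D), abs=1e-9)

    def test_pressurized_solution_pinned_by_bisection_oracle(self, geom, materials):
        cfg = gl.solve_configuration(1.0, 110.0 * gl.MMHG_TO_KPA, geom, materials)
        # Frozen from bisection on the dense trapezoid residual.
        assert cfg.a == pytest.approx(2.58823444, abs=1e-6)

    def test_grown_unpressurized_solution(self, geom, materials):
        cfg = gl.solve_configuration(1.5, 0.0, geom, materials)
        assert cfg.a == pytest.approx(1.97576114, abs=1e-6)
        # the stiff outer layers hold the grown intima back
        assert cfg.a < 1.5 * geom.A

    def test_self_consistency(self, geom, materials):
        for g, P_mmHg in ((1.2, 0.0), (1.0, 80.0), (1.7, 110.0)):
            cfg = gl.solve_configuration(g, P_mmHg * gl.MMHG_TO_KPA, geom, materials)
            res = gl.pressure_residual(cfg.a, g, cfg.P, geom, materials)
            assert abs(res) < 1e-6

    def test_lumen_dilates_with_pressure(self, geom, materials):
        radii = [
            gl.solve_configuration(1.4, P * gl.MMHG_TO_KPA, geom, materials).a
            for P in np.linspace(0.0, 110.0, 6)
        ]
        assert np.all(np.diff(radii) > 0)

    def test_invalid_inputs(self, geom, materials):
        with pytest.raises(ValueError):
            gl.solve_configuration(0.9, 0.0, geom, materials)
        with pytest.raises(ValueError):
            gl.solve_configuration(1.0, -1.0, geom, materials)

    def test_runaway_growth_raises_diagnostic(self, geom, materials):
        with pytest.raises(gl.EquilibriumError):
            gl.solve_configuration(40.0, 0.0, geom, materials)


@pytest.fixture(scope="module")
def solved(geom, materials):
    cfg = gl.solve_configuration(1.3, 80.0 * gl.MMHG_TO_KPA, geom, materials)
    return cfg, gl.stress_profile(cfg, materials, n_points=200)


class TestStressProfile:
    def test_boundary_conditions(self, solved):
        cfg, prof = solved
        assert prof.Trr[0] == pytest.approx(-cfg.P, abs=1e-6)
        assert prof.Trr[-1] == pytest.approx(0.0, abs=1e-6)

    def test_continuity_at_interfaces(self, solved):
        cfg, prof = solved
        for interface in (cfg.b, cfg.c):
            i = np.searchsorted(prof.r, interface)
            gaps = np.abs(np.diff(prof.Trr[max(i - 2, 0) : i + 2]))
            assert np.all(gaps < 0.5)  # kPa; no jump beyond local variation

    def test_radial_equilibrium_ode(self, solved):
        # dTrr/dr must equal (Ttheta - Trr)/r at interior points of each layer.
        cfg, prof = solved
        r, Trr, Tth = prof.r, prof.Trr, prof.Ttheta
        inside = []
        for i in range(1, len(r) - 1):
            same_layer = (
                (r[i - 1] < cfg.b and r[i + 1] < cfg.b)
                or (cfg.b < r[i - 1] and r[i + 1] < cfg.c)
                or (cfg.c < r[i - 1])
            )
            if same_layer:
                inside.append(i)
        inside = np.array(inside)
        num = (Trr[inside + 1] - Trr[inside - 1]) / (r[inside + 1] - r[inside - 1])
        rhs = (Tth[inside] - Trr[inside]) / r[inside]
        scale = np.max(np.abs(rhs))
        np.testing.assert_allclose(num, rhs, atol=1e-4 * scale, rtol=1e-3)

    def test_reference_state_is_stress_free(self, geom, materials):
        cfg = gl.solve_configuration(1.0, 0.0, geom, materials)
        prof = gl.stress_profile(cfg, materials, n_points=60)
        np.testing.assert_allclose(prof.Trr, 0.0, atol=1e-9)
        np.testing.assert_allclose(prof.Ttheta, 0.0, atol=1e-9)

    def test_rejects_unsolved_configuration(self, geom, materials):
        b, c, d = gl.radii_from_lumen(1.4 * geom.A, 1.0, geom)
        bad = gl.Configuration(a=1.4 * geom.A, b=b, c=c, d=d, g=1.0, P=0.0, geometry=geom)
        with pytest.raises(ValueError):
            gl.stress_profile(bad, materials)
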