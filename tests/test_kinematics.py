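import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glagov as gl

GEOM = gl.ReferenceGeometry(A=1.0, B=1.01, C=1.33, D=1.67)


def make_config(a, g, geometry=GEOM, P=0.0):
    b, c, d = gl.radii_from_lumen(a, g, geometry)
    return gl.Configuration(a=a, b=b, c=c, d=d, g=g, P=P, geometry=geometry)


class TestReferenceGeometry:
    @pytest.mark.parametrize(
        "area,expected_A",
        [(math.pi, 1.0), (12.0, math.sqrt(12.0 / math.pi)), (5.0, math.sqrt(5.0 / math.pi))],
    )
    def test_lumen_radius_from_area(self, area, expected_A):
        geom = gl.build_reference_geometry(area)
        assert geom.A == pytest.approx(expected_A, rel=1e-14)
        assert geom.B == pytest.approx(expected_A + 0.01, rel=1e-14)
        assert geom.C == pytest.approx(expected_A + 0.33, rel=1e-14)
        assert geom.D == pytest.approx(expected_A + 0.67, rel=1e-14)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            gl.build_reference_geometry(-1.0)
        with pytest.raises(ValueError):
            gl.build_reference_geometry(12.0, intima_thickness=0.0)
        with pytest.raises(ValueError):
            gl.ReferenceGeometry(A=1.0, B=0.9, C=1.3, D=1.7)


class TestGrowthLaw:
    def test_closed_form_values(self):
        assert gl.growth_factor(0.0, 0.5) == 1.0
        assert gl.growth_factor(2.0, 0.5) == pytest.approx(math.e**0.5, rel=1e-14)
        assert gl.growth_factor(4.0, 0.5) == pytest.approx(math.e, rel=1e-14)

    def test_rate_identity(self):
        # trace(F_g^{-1} dF_g/dt) = 2 g'/g must equal the production rate.
        Gamma, t, h = 0.5, 3.0, 1e-6
        gdot = (gl.growth_factor(t + h, Gamma) - gl.growth_factor(t - h, Gamma)) / (2 * h)
        assert 2.0 * gdot / gl.growth_factor(t, Gamma) == pytest.approx(Gamma, rel=1e-8)

    def test_inverse(self):
        t = gl.time_from_growth(gl.growth_factor(3.7, 0.25), 0.25)
        assert t == pytest.approx(3.7, rel=1e-12)

    def test_rejects_negative_time(self):
        with pytest.raises(ValueError):
            gl.growth_factor(-0.1, 0.5)

    def test_growth_state_consistency(self):
        state = gl.GrowthState.at(2.0, 0.5)
        assert state.g == pytest.approx(math.e**0.5, rel=1e-12)
        with pytest.raises(ValueError):
            gl.GrowthState(g=2.0, t=1.0, Gamma=0.5)


class TestDeformationMap:
    def test_identity_at_reference(self):
        b, c, d = gl.radii_from_lumen(GEOM.A, 1.0, GEOM)
        assert (b, c, d) == pytest.approx((GEOM.B, GEOM.C, GEOM.D), rel=1e-14)

    def test_closed_form_example(self):
        b, _, _ = gl.radii_from_lumen(1.0, 2.0, GEOM)
        assert b == pytest.approx(math.sqrt(1.0804), rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.3, 4.0), g=st.floats(1.0, 5.0))
    def test_layer_area_conservation(self, a, g):
        # Elastic incompressibility: each layer keeps its (grown) area under
        # any deformation.
        b, c, d = gl.radii_from_lumen(a, g, GEOM)
        assert b**2 - a**2 == pytest.approx(g**2 * (GEOM.B**2 - GEOM.A**2), rel=1e-12)
        assert c**2 - b**2 == pytest.approx(GEOM.C**2 - GEOM.B**2, rel=1e-12)
        assert d**2 - c**2 == pytest.approx(GEOM.D**2 - GEOM.C**2, rel=1e-12)

    def test_map_strictly_increasing_with_matching_gradient(self):
        a, g = 0.9, 1.5
        R = np.linspace(GEOM.A, GEOM.D, 400)
        r = gl.deformation_map(R, a, g, GEOM)
        assert np.all(np.diff(r) > 0)
        # dr/dR = g^2 R / r in the intima, R / r outside.
        h = 1e-7
        for Rp in (1.004, 1.2, 1.5):
            num = (
                gl.deformation_map(Rp + h, a, g, GEOM) - gl.deformation_map(Rp - h, a, g, GEOM)
            ) / (2 * h)
            rp = gl.deformation_map(Rp, a, g, GEOM)
            expected = g**2 * Rp / rp if Rp <= GEOM.B else Rp / rp
            assert num == pytest.approx(expected, rel=1e-6)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 3.0), g=st.floats(1.0, 4.0))
    def test_total_stretch_continuous_elastic_stretch_jumps_at_iel(self, a, g):
        # The deformation (and total stretch r/R) is continuous at R=B; the
        # elastic stretch jumps by the growth factor because the growth
        # tensor switches off across the interface.
        cfg = make_config(a, g)
        eps = 1e-9
        r_left = gl.deformation_map(GEOM.B - eps, a, g, GEOM)
        r_right = gl.deformation_map(GEOM.B + eps, a, g, GEOM)
        assert r_left == pytest.approx(r_right, rel=1e-7)
        al_left = gl.stretch_field(GEOM.B - eps, cfg)
        al_right = gl.stretch_field(GEOM.B + eps, cfg)
        assert g * al_left == pytest.approx(al_right, rel=1e-6)

    def test_stretch_field_reference_state_and_lumen_value(self):
        cfg = make_config(GEOM.A, 1.0)
        R = np.linspace(GEOM.A, GEOM.D, 50)
        np.testing.assert_allclose(gl.stretch_field(R, cfg), 1.0, atol=1e-14)
        cfg2 = make_config(1.2, 1.7)
        assert gl.stretch_field(GEOM.A, cfg2) == pytest.approx(1.2 / (1.7 * GEOM.A), rel=1e-14)

    def test_domain_errors(self):
        cfg = make_config(1.0, 1.2)
        with pytest.raises(ValueError):
            gl.stretch_field(GEOM.A - 0.1, cfg)
        with pytest.raises(ValueError):
            gl.deformation_map(GEOM.D + 0.1, 1.0, 1.2, GEOM)


class TestMorphometrics:
    def test_plaque_identity_and_growth_invariance(self):
        cfg = make_config(1.1, 2.0)
        m = gl.morphometrics(cfg)
        assert m.plaque_area == pytest.approx(m.iel_area - m.lumen_area, rel=1e-14)
        assert m.stenosis == pytest.approx(m.plaque_area / m.iel_area, rel=1e-14)
        # plaque area depends only on g (incompressibility)
        assert m.plaque_area == pytest.approx(4.0 * math.pi * 0.0201, rel=1e-12)

    def test_disease_free_limit(self):
        m = gl.morphometrics(make_config(GEOM.A, 1.0))
        assert m.stenosis == pytest.approx((GEOM.B**2 - GEOM.A**2) / GEOM.B**2, rel=1e-12)

    def test_occlusion_limit(self):
        m = gl.morphometrics(make_config(1e-6, 2.0))
        assert m.stenosis == pytest.approx(1.0, abs=1e-10)

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.2, 5.0), a=st.floats(0.5, 2.0), g=st.floats(1.0, 3.0))
    def test_stenosis_scale_invariant(self, scale, a, g):
        m1 = gl.morphometrics(make_config(a, g))
        scaled = gl.ReferenceGeometry(
            A=scale * GEOM.A, B=scale * GEOM.B, C=scale * GEOM.C, D=scale * GEOM.D
        )
        m2 = gl.morphometrics(make_config(scale * a, g, geometry=scaled))
        assert m1.stenosis == pytest.approx(m2.stenosis, rel=1e-12)
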