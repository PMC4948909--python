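import pytest

import glagov as gl

#: Reference lumen areas (mm^2) used for the ex-vivo curve family.
EXVIVO_AREAS = (5.0, 8.0, 12.0, 15.0)
#: Physiological luminal pressures (mmHg) for the in-vivo family.
INVIVO_PRESSURES = (50.0, 80.0, 110.0)

# Trajectory resolutions: fine enough to place the interior maximum to a few
# 1e-3 in stenosis while keeping the whole suite to a few minutes.
EXVIVO_STEPS = 150
INVIVO_STEPS = 100


@pytest.fixture(scope="session")
def materials():
    return gl.table1_materials()


@pytest.fixture(scope="session")
def geom12():
    return gl.build_reference_geometry(12.0)


@pytest.fixture(scope="session")
def exvivo_curves(materials):
    """Unpressurized remodeling curves for the four reference lumen areas."""
    return {
        area: gl.simulate_remodeling(
            gl.build_reference_geometry(area), materials, P_mmHg=0.0, n_steps=EXVIVO_STEPS
        )
        for area in EXVIVO_AREAS
    }


@pytest.fixture(scope="session")
def invivo_curves(materials, geom12):
    """Pressurized remodeling curves of the 12 mm^2 vessel."""
    return {
        P: gl.simulate_remodeling(geom12, materials, P_mmHg=P, n_steps=INVIVO_STEPS)
        for P in INVIVO_PRESSURES
    }


@pytest.fixture(scope="session")
def exvivo_cohort():
    """Default synthetic ex-vivo cohort (150 vessels, 1 mm^2 noise)."""
    spec = gl.CohortSpec(seed=0)
    samples, truth = gl.generate_cohort(spec)
    return spec, samples, truth
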