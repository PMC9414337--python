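import pytest
from hypothesis import HealthCheck, settings

from pbpkdgi import engine, physiology, scaling

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Printed reference table: activity score -> (rel % interpolated, PAR, ATO,
#: RIS->9-OH, RIS->other k_cat in 1/min).  Inputs are integer-rounded, hence
#: the 2% reproduction tolerance used in the tests.
PRINTED_KCAT_TABLE = {
    0.0: (0, 0.00, 0.00, 0.0, 0.00),
    0.25: (8, 0.30, 7.63, 0.23, 0.14),
    0.5: (17, 0.66, 16.79, 0.52, 0.31),
    0.75: (27, 1.08, 27.48, 0.84, 0.51),
    1.0: (39, 1.56, 39.70, 1.22, 0.74),
    1.25: (53, 2.11, 53.44, 1.64, 1.00),
    1.5: (68, 2.71, 68.70, 2.11, 1.29),
    2.0: (102, 4.09, 103.82, 3.19, 1.94),
    3.0: (189, 7.58, 192.37, 5.91, 3.60),
}


@pytest.fixture(scope="session")
def curve():
    """Scaling curve fitted to the pooled packaged reference points."""
    return scaling.fit_kcat_rel_polynomial(scaling.load_reference_points())


@pytest.fixture(scope="session")
def printed_table():
    return PRINTED_KCAT_TABLE


def make_one_compartment_linear(volume=40.0, cl=5.0, fu=1.0):
    """One-compartment model with a single first-order hepatic clearance."""
    phys = physiology.one_compartment(volume=volume)
    cpd = engine.CompoundProperties("drug", molecular_weight=300.0, fraction_unbound=fu)
    proc = engine.ClearanceProcess(
        kind="first_order_hepatic", compound="drug", name="CL", cl_linear=cl / fu
    )
    return engine.build_model(phys, [cpd], [proc])


@pytest.fixture()
def one_comp_linear():
    return make_one_compartment_linear()
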