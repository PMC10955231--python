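"""Shared fixtures.

The expensive whole-model simulations (microdose, therapeutic dose and the
clarithromycin DDI pairs) are session-scoped so the engine, DDI and
acceptance tests share one run each instead of re-integrating the ODE
system per test.
"""

import pytest

import dabepbpk as d
from dabepbpk.compounds import CompoundSpec
from dabepbpk.disposition import DistributionParams
from dabepbpk.ivive import BindingParams
from dabepbpk.physiology import default_physiology


def tracer_compound(ka_duodenum=1.5, ke=0.1, vc_l=50.0):
    """One-compartment tracer: no metabolism, no efflux, no conversion."""
    r_duod = 1.53
    peff = ka_duodenum * r_duod / 0.72
    return CompoundSpec(
        id="tracer", mw_g_mol=500.0,
        binding=BindingParams(fu_plasma=1.0, bp_ratio=1.0),
        distribution=DistributionParams(vss_l_kg=vc_l / 70.0,
                                        central_fraction=1.0, q_l_h=0.0),
        peff_1e4_cm_s=peff, cl_renal_l_h=ke * vc_l,
        kbl_h=1e4,   # enterocyte pass-through is effectively instantaneous
    )


def degenerate_physiology():
    """Stomach empties instantly, duodenum never transits onward, and the
    portal/liver pass-through volumes are tiny: the system degenerates to
    first-order absorption into one well-mixed compartment."""
    phys = default_physiology()
    phys.segments[0].transit_time_h = 1e-4
    phys.segments[1].transit_time_h = 1e9
    return phys.with_overrides(portal_volume_l=2e-3, liver_volume_l=2e-3)


@pytest.fixture(scope="session")
def compounds():
    return d.load_compounds()


@pytest.fixture(scope="session")
def perp_library():
    return d.load_perpetrators()


@pytest.fixture(scope="session")
def res_micro(compounds):
    """Microdose (375 ug) oral solution, mean individual."""
    return d.run_scenario(compounds, d.substrate_scenario(0.375))


@pytest.fixture(scope="session")
def res_therapeutic(compounds):
    """Therapeutic 300 mg solid immediate-release dose."""
    return d.run_scenario(compounds, d.substrate_scenario(300, form="solid_IR"))


@pytest.fixture(scope="session")
def ctc_micro_pair(compounds, perp_library):
    ctrl = d.run_scenario(compounds, d.ddi_scenario(
        0.375, "ctc", library=perp_library, with_perpetrator=False))
    inh = d.run_scenario(compounds, d.ddi_scenario(
        0.375, "ctc", library=perp_library))
    return ctrl, inh


@pytest.fixture(scope="session")
def ctc_therapeutic_pair(compounds, perp_library):
    ctrl = d.run_scenario(compounds, d.ddi_scenario(
        300, "ctc", form="solid_IR", library=perp_library,
        with_perpetrator=False))
    inh = d.run_scenario(compounds, d.ddi_scenario(
        300, "ctc", form="solid_IR", library=perp_library))
    return ctrl, inh
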