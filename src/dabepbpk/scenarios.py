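"""Canonical simulation scenarios and the printed evaluation tables.

The clinical study designs used for model training and qualification are
encoded here: single-dose substrate PK at micro- and therapeutic doses,
and the DDI designs (clarithromycin 500 mg BID x 5 days with the substrate
on day 5; itraconazole 200 mg QD x 5 days; rifampicin 600 mg single dose;
verapamil 120 mg single dose, concomitant or 1 h before the substrate).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ddi import Regimen, load_perpetrators, make_perpetrator
from .engine import ScenarioSpec
from .errors import ConfigurationError
from .gut import FormulationSpec

__all__ = ["substrate_scenario", "ddi_scenario", "load_observed_pk",
           "load_observed_ddi"]

MICRODOSE_MG = 0.375
THERAPEUTIC_MG = 300.0


def formulation_for(form: str) -> FormulationSpec:
    """Micro/solution doses use the solution-with-precipitation form;
    therapeutic tablets are solid immediate release.  CSR/PRC apply to
    both (printed estimates 17.9 and 2.88 1/h)."""
    return FormulationSpec(form=form)


def substrate_scenario(dose_mg: float, form: str = "solution_with_precipitation",
                       horizon_h: float = 48.0, start_h: float = 0.0,
                       **kwargs) -> ScenarioSpec:
    return ScenarioSpec(
        substrate="dabe", dose_mg=dose_mg, formulation=formulation_for(form),
        substrate_start_h=start_h, horizon_h=horizon_h, **kwargs)


_DDI_DESIGNS = {
    # perpetrator id -> (library key, regimen args, substrate start h)
    "ctc": ("ctc", dict(dose_mg=500.0, n_doses=10, interval_h=12.0), 96.0),
    "itz": ("itz", dict(dose_mg=200.0, n_doses=5, interval_h=24.0), 96.0),
    "rf": ("rf", dict(dose_mg=600.0, n_doses=1), 0.0),
    "vp": ("vp", dict(dose_mg=120.0, n_doses=1), 0.0),
    "vp_1h": ("vp", dict(dose_mg=120.0, n_doses=1), 1.0),
}


def ddi_scenario(dose_mg: float, perpetrator: str,
                 form: str = "solution_with_precipitation",
                 library=None, with_perpetrator: bool = True,
                 tail_h: float = 48.0, **kwargs) -> ScenarioSpec:
    """Substrate + perpetrator scenario per the clinical DDI designs.

    ``with_perpetrator=False`` returns the matching control arm: identical
    substrate timing and horizon, no perpetrator — so control and
    inhibited runs differ only in the interaction terms.
    """
    if perpetrator not in _DDI_DESIGNS:
        raise ConfigurationError(f"unknown DDI design {perpetrator!r}")
    key, regimen_args, sub_start = _DDI_DESIGNS[perpetrator]
    perps = []
    if with_perpetrator:
        if library is None:
            library = load_perpetrators()
        perps = [make_perpetrator(library, key, Regimen(**regimen_args))]
    return ScenarioSpec(
        substrate="dabe", dose_mg=dose_mg, formulation=formulation_for(form),
        substrate_start_h=sub_start, horizon_h=sub_start + tail_h,
        perpetrators=perps, **kwargs)


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("dabepbpk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_observed_pk() -> pd.DataFrame:
    """Printed observed/simulated PK parameter pairs with their acceptance
    windows (training + qualification datasets)."""
    return _read_csv("observed_pk.csv")


def load_observed_ddi() -> pd.DataFrame:
    """Printed observed/simulated DDI ratio pairs with their Guest
    acceptance windows."""
    return _read_csv("observed_ddi.csv")
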