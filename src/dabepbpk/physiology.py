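"""Physiology: gut segment geometry/transit and hepatic/systemic constants.

A nine-segment serial gut (stomach, duodenum, two jejunal, four ileal
segments, colon) in the style of compartmental absorption-transit models,
plus standard hepatic scaling constants.  All values are population means
for a healthy adult; the gut CYP3A abundance and P-gp expression are
distributed over the absorptive small-intestinal segments by fixed weight
vectors (proximal-heavy for CYP3A, distal-heavy for P-gp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["GutSegmentSpec", "PhysiologySpec", "default_physiology",
            "transit_rate"]

SEGMENT_NAMES = (
    "stomach", "duodenum", "jejunum_1", "jejunum_2",
    "ileum_1", "ileum_2", "ileum_3", "ileum_4", "colon",
)


@dataclass
class GutSegmentSpec:
    """One luminal segment.

    ``cyp3a_abundance_fraction`` and ``pgp_weight`` are that segment's
    share of the whole-gut enzyme/transporter pool (zero in the stomach,
    which has no absorption or metabolism).
    """

    name: str
    radius_cm: float
    fluid_volume_ml: float
    transit_time_h: float
    ph: float
    enterocyte_volume_ml: float
    villous_flow_l_h: float
    cyp3a_abundance_fraction: float
    pgp_weight: float

    def __post_init__(self):
        if self.transit_time_h <= 0:
            raise ConfigurationError(f"{self.name}: transit_time must be > 0")
        if self.name == "stomach" and (
            self.cyp3a_abundance_fraction or self.pgp_weight
        ):
            raise ConfigurationError("stomach carries no enzymes/transporters")


def transit_rate(segment: GutSegmentSpec) -> float:
    """First-order serial transit rate constant, kt = 1/transit_time (1/h)."""
    return 1.0 / segment.transit_time_h


@dataclass
class PhysiologySpec:
    """Whole-body physiological constants plus the gut segmentation."""

    segments: list[GutSegmentSpec]
    # hepatic scaling
    mppgl_mg_g: float = 40.0            # microsomal protein per g liver
    hepatocellularity_1e6_g: float = 120.0
    liver_mass_g: float = 1650.0
    liver_cyp3a4_pmol_mg: float = 137.0
    gut_cyp3a4_nmol: float = 66.0
    # flows and volumes
    qh_l_h: float = 97.0                # total hepatic blood flow
    q_portal_l_h: float = 73.0          # portal-venous fraction of Qh
    portal_volume_l: float = 1.0
    liver_volume_l: float = 1.65
    villous_flow_total_l_h: float = 18.0
    body_weight_kg: float = 70.0
    # enterocyte basolateral geometry: effective monolayer thickness and a
    # surface amplification for the villous basolateral membrane, used to
    # turn a transcellular Peff into a first-order basolateral escape rate
    enterocyte_thickness_cm: float = 2.5e-3
    basolateral_area_amplification: float = 1.0
    # enzyme turnover (natural degradation) for mechanism-based inhibition
    kdeg_cyp3a_liver_h: float = 0.019
    kdeg_cyp3a_gut_h: float = 0.03

    def __post_init__(self):
        names = [s.name for s in self.segments]
        if tuple(names) != SEGMENT_NAMES:
            raise ConfigurationError(
                f"expected segments {SEGMENT_NAMES}, got {tuple(names)}"
            )
        for attr in ("cyp3a_abundance_fraction", "pgp_weight"):
            total = sum(getattr(s, attr) for s in self.segments)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{attr} must sum to 1 (got {total})")

    # -- convenience array views used by the ODE builder -------------------
    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(s, attr) for s in self.segments], dtype=float)

    def with_overrides(self, **kwargs) -> "PhysiologySpec":
        return replace(self, **kwargs)


def default_physiology() -> PhysiologySpec:
    """Literature-default physiology for a 70 kg healthy adult.

    Small-intestinal transit times sum to 3.5 h; the colon is a long,
    poorly absorbing terminal segment.  CYP3A is proximal-weighted and
    P-gp distal-weighted along the small intestine.
    """
    rows = [
        # name        r_cm  V_ml  tt_h   pH   Vent_ml Qvil  cyp3a  pgp
        ("stomach",   9.8,  47.0, 0.25,  1.5,  0.0,   0.0,  0.00,  0.00),
        ("duodenum",  1.53, 42.0, 0.26,  6.4,  9.0,   2.4,  0.22,  0.06),
        ("jejunum_1", 1.45, 80.0, 0.95,  6.5, 24.0,   5.2,  0.30,  0.13),
        ("jejunum_2", 1.30, 70.0, 0.75,  6.7, 20.0,   4.0,  0.20,  0.15),
        ("ileum_1",   1.20, 50.0, 0.60,  7.0, 12.0,   2.6,  0.12,  0.16),
        ("ileum_2",   1.10, 45.0, 0.40,  7.2, 10.0,   1.8,  0.08,  0.16),
        ("ileum_3",   1.00, 40.0, 0.30,  7.4,  8.0,   1.2,  0.05,  0.17),
        ("ileum_4",   0.95, 35.0, 0.24,  7.5,  6.0,   0.8,  0.03,  0.17),
        ("colon",     2.50, 50.0, 12.0,  6.8, 15.0,   0.0,  0.00,  0.00),
    ]
    segments = [
        GutSegmentSpec(name, r, v, tt, ph, vent, qv, cyp, pgp)
        for name, r, v, tt, ph, vent, qv, cyp, pgp in rows
    ]
    return PhysiologySpec(segments=segments)
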