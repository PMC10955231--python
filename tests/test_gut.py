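"""Gut mechanics: transit, dissolution, precipitation, uptake, efflux."""

import numpy as np
import pytest

from dabepbpk import errors, gut
from dabepbpk.physiology import default_physiology, transit_rate


class TestTransit:
    def test_reciprocal(self):
        seg = default_physiology().segments[1]
        seg.transit_time_h = 0.5
        assert transit_rate(seg) == pytest.approx(2.0)

    def test_small_intestine_transit_sums_to_3_5_h(self):
        phys = default_physiology()
        si = [s for s in phys.segments
              if s.name not in ("stomach", "colon")]
        assert sum(s.transit_time_h for s in si) == pytest.approx(3.5)

    def test_long_transit_time_freezes_compartment(self):
        seg = default_physiology().segments[1]
        seg.transit_time_h = 1e12
        assert transit_rate(seg) == pytest.approx(0.0, abs=1e-11)


class TestDissolution:
    def dlm(self, radius_um=10.0, dose_umol=478.0):
        return gut.dissolution_coefficient(5e-6, 1.2, radius_um, dose_umol,
                                           mw=627.7)

    def test_zero_at_equilibrium(self):
        assert gut.dissolution_flux(100.0, 4.78, 4.78, self.dlm()) == 0.0

    def test_zero_without_solid(self):
        assert gut.dissolution_flux(0.0, 0.0, 4.78, self.dlm()) == 0.0

    def test_finer_particles_dissolve_faster(self):
        assert self.dlm(radius_um=5.0).kd > self.dlm(radius_um=10.0).kd

    def test_supersaturation_limit_drives_flux_above_solubility(self):
        # below the supersaturation ceiling the flux stays positive even
        # though the bulk is already above the equilibrium solubility
        flux = gut.dissolution_flux(100.0, 10.0, 4.78, self.dlm(),
                                    supersaturation_limit=17.9 * 4.78)
        assert flux > 0

    def test_negative_solid_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            gut.dissolution_flux(-1.0, 0.0, 4.78, self.dlm())


class TestPrecipitation:
    form = gut.FormulationSpec(csr=17.9, prc=2.88)

    def test_below_threshold_silent(self):
        # ratio 10 < CSR 17.9 and no prior trigger
        assert gut.precipitation_flux(47.8, 4.78, self.form, 0.1, False) == 0.0

    def test_triggered_flux_value(self):
        # ratio 20: flux = 2.88 * (95.6 - 4.78) * 0.1 L
        flux = gut.precipitation_flux(95.6, 4.78, self.form, 0.1, True)
        assert flux == pytest.approx(2.88 * (95.6 - 4.78) * 0.1, rel=1e-9)

    def test_relaxed_to_solubility(self):
        assert gut.precipitation_flux(4.78, 4.78, self.form, 0.1, True) == 0.0

    def test_csr_below_one_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            gut.FormulationSpec(csr=0.5)


class TestAbsorptionAndEfflux:
    def test_ka_value(self):
        assert gut.absorption_rate_constant(1.0, 1.0) == pytest.approx(0.72)

    def test_radius_inverse_proportionality(self):
        assert gut.absorption_rate_constant(1.0, 2.0) \
            == pytest.approx(gut.absorption_rate_constant(1.0, 1.0) / 2)

    def test_zero_peff(self):
        assert gut.absorption_rate_constant(0.0, 1.0) == 0.0

    def test_pgp_zero_half_saturation_and_plateau(self):
        jmax, km = 5.0, 2.6
        assert gut.pgp_efflux(0.0, jmax, km) == 0.0
        assert gut.pgp_efflux(km, jmax, km) == pytest.approx(jmax / 2)
        # saturation plateau is inhibitor-independent
        assert gut.pgp_efflux(1e6, jmax, km, inhibition_factor=50.0) \
            == pytest.approx(jmax, rel=1e-3)

    def test_inhibition_factor_below_one_rejected(self):
        with pytest.raises(errors.InvalidParameterError):
            gut.pgp_efflux(1.0, 5.0, 2.6, inhibition_factor=0.5)


class TestMichaelisRate:
    def test_linear_limit_slope(self):
        vmax, km = 10.0, 2.0
        c = 1e-6
        assert gut.michaelis_rate(c, vmax, km) \
            == pytest.approx(vmax / km * c, rel=1e-5)

    def test_half_saturation(self):
        assert gut.michaelis_rate(2.0, 10.0, 2.0) == pytest.approx(5.0)

    def test_mbi_knockdown_scales_activity(self):
        full = gut.michaelis_rate(2.0, 10.0, 2.0, activity=1.0)
        assert gut.michaelis_rate(2.0, 10.0, 2.0, activity=0.25) \
            == pytest.approx(full / 4)


class TestFirstPassSummary:
    def test_clean_absorption_gives_unity(self):
        ledger = {"apical_in": 10.0, "efflux": 0.0,
                  "basolateral": {"dabe": 10.0}, "gut_formed": {}}
        out = gut.first_pass_summary(ledger, 10.0, "dabe", ["dabe"])
        assert out["dabe"]["fa"] == pytest.approx(1.0)
        assert out["dabe"]["fg"] == pytest.approx(1.0)

    def test_metabolite_fg_over_formed(self):
        ledger = {"apical_in": 10.0, "efflux": 2.0,
                  "basolateral": {"dabe": 2.0, "m1": 3.0},
                  "gut_formed": {"m1": 6.0}}
        out = gut.first_pass_summary(ledger, 10.0, "dabe", ["dabe", "m1"])
        assert out["dabe"]["fa"] == pytest.approx(0.8)
        assert out["m1"]["fa"] == 1.0
        assert out["m1"]["fg"] == pytest.approx(0.5)

    def test_zero_dose_undefined(self):
        with pytest.raises(errors.UndefinedMetricError):
            gut.first_pass_summary({"apical_in": 0, "efflux": 0,
                                    "basolateral": {}, "gut_formed": {}},
                                   0.0, "dabe", ["dabe"])


class TestPhysiologyValidation:
    def test_weights_must_sum_to_one(self):
        phys = default_physiology()
        phys.segments[1].pgp_weight += 0.1
        from dabepbpk.physiology import PhysiologySpec
        with pytest.raises(errors.ConfigurationError):
            PhysiologySpec(segments=phys.segments)

    def test_stomach_carries_no_enzymes(self):
        from dabepbpk.physiology import GutSegmentSpec
        with pytest.raises(errors.ConfigurationError):
            GutSegmentSpec("stomach", 9.8, 47.0, 0.25, 1.5, 0.0, 0.0,
                           cyp3a_abundance_fraction=0.1, pgp_weight=0.0)
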