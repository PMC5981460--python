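"""Layer absorption/scattering derivations for diastole and systole."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppgsim.chromophores import absorption_at, dermal_baseline, load_default_table
from ppgsim.layer_optics import (
    blood_fractions_diastole,
    mu_a_diastole,
    mu_a_epidermis,
    mu_a_nonblood,
    scattering,
    self_shield,
    systolic_state,
    systolic_state_wd,
)
from ppgsim.skin_models import build_optical_stack, reference_model


@pytest.fixture(scope="module")
def table():
    return load_default_table()


@pytest.fixture(scope="module")
def ref_layers():
    return {layer.name: layer for layer in reference_model().layers}


class TestSelfShield:
    def test_no_shielding_for_zero_product(self):
        assert self_shield(0.0, 40.0) == 1.0
        assert self_shield(250.0, 0.0) == 1.0

    def test_band_representative_values(self):
        """Green-band whole-blood absorption at the two vessel scales."""
        assert self_shield(250.0, 40.0) == pytest.approx(0.70, abs=0.05)
        assert self_shield(250.0, 20.0) == pytest.approx(0.85, abs=0.05)

    @given(st.floats(min_value=0.01, max_value=500.0))
    def test_strictly_decreasing_in_product(self, mua):
        assert self_shield(mua, 40.0) < self_shield(mua, 20.0) < 1.0

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            self_shield(-1.0, 10.0)
        with pytest.raises(ValueError):
            self_shield(10.0, -1.0)


class TestAbsorptionComposition:
    def test_epidermis_limits(self, table):
        lam = 560.0
        from ppgsim.chromophores import epidermal_baseline

        assert mu_a_epidermis(lam, 0.0) == pytest.approx(epidermal_baseline(lam, 0.5))
        assert mu_a_epidermis(lam, 1.0) == pytest.approx(
            absorption_at(table, "water", lam)
        )

    def test_epidermis_reference_water_fraction(self, table):
        """Hand-composed value at the reference epidermal settings."""
        lam, cw = 560.0, 0.20
        from ppgsim.chromophores import epidermal_baseline

        expected = cw * absorption_at(table, "water", lam) + (1 - cw) * epidermal_baseline(lam, 0.5)
        assert mu_a_epidermis(lam, cw) == pytest.approx(expected, rel=1e-12)

    def test_nonblood_limits(self, table):
        lam = 700.0
        assert mu_a_nonblood(lam, 0.65, 1.0, 0.5) == pytest.approx(
            absorption_at(table, "fat", lam)
        )
        expected = 0.65 * absorption_at(table, "water", lam) + 0.35 * dermal_baseline(
            lam, 0.5, 0.65
        )
        assert mu_a_nonblood(lam, 0.65, 0.0, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_nonblood_subcutis_composition(self, table):
        lam, cw, cf, gamma = 900.0, 0.05, 0.40, 0.25
        expected = (
            cf * absorption_at(table, "fat", lam)
            + (1 - cf) * cw * absorption_at(table, "water", lam)
            + (1 - cf) * (1 - cw) * dermal_baseline(lam, gamma, cw)
        )
        assert mu_a_nonblood(lam, cw, cf, gamma) == pytest.approx(expected, rel=1e-12)

    def test_blood_fractions_bloodless_layer(self, ref_layers):
        assert blood_fractions_diastole(ref_layers["EPI"], 550.0) == (0.0, 0.0, 0.0)

    def test_blood_fractions_no_shield_limit(self, ref_layers, table):
        """Red-IR blood absorption is so low the shielding factor is ~1."""
        layer = ref_layers["UP"]
        fa, fv, cb = blood_fractions_diastole(layer, 800.0)
        assert fa == pytest.approx(layer.ra * layer.Cb, rel=0.01)
        assert cb <= layer.Cb

    def test_blood_fractions_deep_plexus_composition(self, ref_layers, table):
        """Brute-force chain of the shielding and saturation-mixing forms."""
        layer = ref_layers["DP"]
        lam = 550.0
        mua_art = 0.03 * absorption_at(table, "Hb", lam) + 0.97 * absorption_at(
            table, "HbO2", lam
        )
        mua_ven = 0.33 * absorption_at(table, "Hb", lam) + 0.67 * absorption_at(
            table, "HbO2", lam
        )
        fa_exp = 0.5 * 0.04 * self_shield(mua_art, 40.0)
        fv_exp = 0.5 * 0.04 * self_shield(mua_ven, 40.0)
        fa, fv, cb = blood_fractions_diastole(layer, lam)
        assert fa == pytest.approx(fa_exp, rel=1e-12)
        assert fv == pytest.approx(fv_exp, rel=1e-12)
        assert cb == pytest.approx(fa_exp + fv_exp, rel=1e-12)

    def test_diastolic_bloodless_equals_nonblood(self, ref_layers):
        layer = ref_layers["RD"]
        bloodless = type(layer)(**{**layer.__dict__, "Cb": 0.0, "pulsatile": False})
        assert mu_a_diastole(bloodless, 550.0) == pytest.approx(
            mu_a_nonblood(550.0, layer.Cw, layer.Cf, layer.gamma)
        )

    def test_diastolic_monotone_in_blood_at_green(self, ref_layers):
        layer = ref_layers["RD"]
        vals = []
        for cb in (0.002, 0.004, 0.01, 0.03):
            mod = type(layer)(**{**layer.__dict__, "Cb": cb})
            vals.append(mu_a_diastole(mod, 550.0))
        assert np.all(np.diff(vals) > 0)

    def test_diastolic_reticular_dermis_red_composition(self, ref_layers, table):
        layer = ref_layers["RD"]
        lam = 660.0
        mua_art = 0.03 * absorption_at(table, "Hb", lam) + 0.97 * absorption_at(
            table, "HbO2", lam
        )
        mua_ven = 0.33 * absorption_at(table, "Hb", lam) + 0.67 * absorption_at(
            table, "HbO2", lam
        )
        fa = 0.5 * layer.Cb * self_shield(mua_art, layer.vd)
        fv = 0.5 * layer.Cb * self_shield(mua_ven, layer.vd)
        expected = (
            fa * mua_art
            + fv * mua_ven
            + (fa + fv) * absorption_at(table, "water", lam)
            + (1 - layer.Cb) * mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma)
        )
        assert mu_a_diastole(layer, lam) == pytest.approx(expected, rel=1e-12)


class TestSystole:
    def test_no_pulse_is_identity(self, ref_layers):
        layer = ref_layers["UP"]
        st_ = systolic_state(layer, 550.0, 0.0)
        assert st_.mua_s == pytest.approx(mu_a_diastole(layer, 550.0), rel=1e-12)
        assert st_.d_s == layer.d and st_.E == 1.0
        assert systolic_state_wd(layer, 550.0, 0.0) == pytest.approx(
            mu_a_diastole(layer, 550.0), rel=1e-12
        )

    def test_green_absorption_increases_with_pulse(self, ref_layers):
        layer = ref_layers["UP"]
        assert systolic_state(layer, 550.0, 0.05).mua_s > mu_a_diastole(layer, 550.0)

    @pytest.mark.parametrize("lam", [500.0, 550.0, 600.0])
    def test_pulsating_layers_absorb_more_in_green(self, lam):
        for layer in reference_model().layers:
            if layer.pulsatile:
                assert systolic_state(layer, lam, 0.05).mua_s > mu_a_diastole(layer, lam)

    def test_deep_plexus_brute_force_chain(self, ref_layers, table):
        """Recompute the full systolic chain independently at 530 nm."""
        layer = ref_layers["DP"]
        lam, p = 530.0, 0.05
        mua_art = 0.03 * absorption_at(table, "Hb", lam) + 0.97 * absorption_at(
            table, "HbO2", lam
        )
        mua_ven = 0.33 * absorption_at(table, "Hb", lam) + 0.67 * absorption_at(
            table, "HbO2", lam
        )
        fa = 0.5 * 0.04 * self_shield(mua_art, 40.0)
        fv = 0.5 * 0.04 * self_shield(mua_ven, 40.0)
        fa_s = fa * (1 + p)
        cb_s = fa + fv + p * fa
        d_s = layer.d * (1 + cb_s * p)
        E = layer.d / d_s
        mua_nb = mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma)
        expected = E * (
            fa_s * mua_art
            + fv * mua_ven
            + cb_s * absorption_at(table, "water", lam)
            + (1 - (0.04 + p * fa)) * mua_nb
        )
        got = systolic_state(layer, lam, p)
        assert got.mua_s == pytest.approx(expected, rel=1e-12)
        assert got.d_s == pytest.approx(d_s, rel=1e-12)

    def test_water_displacement_brute_force(self, ref_layers, table):
        layer = ref_layers["RD"]
        lam, p = 577.0, 0.05
        fa, fv, cb = blood_fractions_diastole(layer, lam)
        mua_art = 0.03 * absorption_at(table, "Hb", lam) + 0.97 * absorption_at(
            table, "HbO2", lam
        )
        mua_ven = 0.33 * absorption_at(table, "Hb", lam) + 0.67 * absorption_at(
            table, "HbO2", lam
        )
        expected = (
            fa * (1 + p) * mua_art
            + fv * mua_ven
            + cb * absorption_at(table, "water", lam)
            + (1 - (layer.Cb + p * fa))
            * mu_a_nonblood(lam, layer.Cw, layer.Cf, layer.gamma)
        )
        assert systolic_state_wd(layer, lam, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_pulse_raises(self, ref_layers):
        with pytest.raises(ValueError):
            systolic_state(ref_layers["UP"], 550.0, -0.01)

    def test_le_and_wd_absorption_agree_closely(self):
        """The two systole mechanisms perturb the optical thickness alike.

        Their difference is the plasma-water term of the added blood, which
        is under 10% of the perturbation even at the 975 nm water peak.
        """
        model = reference_model()
        lams = np.arange(450.0, 1001.0, 25.0)
        for layer in model.layers:
            if not layer.pulsatile:
                continue
            for lam in lams:
                le = systolic_state(layer, lam, 0.05)
                wd = systolic_state_wd(layer, lam, 0.05)
                base = mu_a_diastole(layer, lam) * layer.d
                d_le = le.mua_s * le.d_s - base
                d_wd = wd * layer.d - base
                assert d_le == pytest.approx(d_wd, rel=0.10, abs=1e-6 * base)


class TestScattering:
    def test_dermal_normalization_point(self):
        mus, g = scattering(580.0, "dermal")
        assert g == 0.9
        assert mus * (1 - g) == pytest.approx(20.0, rel=1e-12)
        assert mus == pytest.approx(200.0, rel=1e-12)

    def test_subcutis_and_epidermis_targets(self):
        assert scattering(580.0, "SC")[0] * 0.1 == pytest.approx(10.0, rel=1e-12)
        assert scattering(580.0, "EPI")[0] * 0.1 == pytest.approx(15.0, rel=1e-12)

    def test_continuity_at_exponent_break(self):
        left = scattering(580.0 - 1e-9, "dermal")[0]
        right = scattering(580.0, "dermal")[0]
        assert left == pytest.approx(right, rel=1e-9)

    def test_out_of_range_and_unknown_class(self):
        with pytest.raises(ValueError):
            scattering(400.0, "dermal")
        with pytest.raises(ValueError):
            scattering(600.0, "bone")


class TestStackInvariants:
    def test_all_optics_finite_positive_over_grid(self):
        from ppgsim.skin_models import compressed_model

        for model in (reference_model(), compressed_model()):
            for lam in np.arange(450.0, 1001.0, 50.0):
                for state in ("diastole", "systole"):
                    for lay in build_optical_stack(model, lam, state):
                        assert np.isfinite(lay.mua) and lay.mua >= 0
                        assert np.isfinite(lay.mus) and lay.mus > 0
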