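"""Perturbed-state forward model: charge, velocity and signal components."""

import dataclasses
import math

import numpy as np
import pytest

import poresig as ps
from poresig.errors import DegenerateStateError, InvalidInputError

import oracle


@pytest.fixture(scope="module")
def ref():
    return oracle.naf_baseline()


class TestDeltaNVolume:
    def test_vanishes_with_analyte_volume(self, baseline_naf, pore23):
        tiny = ps.Analyte(name="t", r_analyte=1e-12, z_analyte=0, water_layer=0.0)
        dn = ps.delta_n_volume(tiny, baseline_naf, pore23)
        # displaced fraction of the pore volume is ~5e-12 at this radius
        assert abs(dn) < 1e-11 * abs(baseline_naf.n_bs)

    def test_proportional_to_volume(self, baseline_naf, pore23):
        a1 = ps.Analyte(name="a", r_analyte=0.5e-9, z_analyte=0, water_layer=0.0)
        a2 = ps.Analyte(
            name="b", r_analyte=0.5e-9 * 2 ** (1 / 3), z_analyte=0, water_layer=0.0
        )
        d1 = ps.delta_n_volume(a1, baseline_naf, pore23)
        d2 = ps.delta_n_volume(a2, baseline_naf, pore23)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_opposite_sign_to_baseline_density(self, baseline_naf, pore23):
        a = ps.Analyte(name="a", r_analyte=1e-9, z_analyte=0)
        dn = ps.delta_n_volume(a, baseline_naf, pore23)
        assert np.sign(dn) == -np.sign(baseline_naf.n_bs)

    def test_stokes_radius_value_matches_transcription(self, baseline_naf, pore23, ref):
        ana = ps.Analyte(name="p", r_analyte=1.27e-9, z_analyte=0, water_layer=0.0)
        v_an = 4 / 3 * math.pi * 1.27e-9**3
        expected = oracle.dn_volume(ref["n_bs"], v_an, ref["V_total"])
        assert ps.delta_n_volume(ana, baseline_naf, pore23) == pytest.approx(
            expected, rel=1e-9
        )

    def test_oversized_analyte_rejected(self, baseline_naf, pore23):
        big = ps.Analyte(name="big", r_analyte=20e-9, z_analyte=0)
        with pytest.raises(InvalidInputError):
            ps.delta_n_volume(big, baseline_naf, pore23)


class TestDeltaNElectric:
    def test_neutral_analyte_no_effect(self, baseline_naf, pore23):
        a = ps.Analyte(name="n", r_analyte=1e-9, z_analyte=0)
        assert ps.delta_n_electric(a, baseline_naf, pore23) == 0.0

    def test_monotone_in_charge_magnitude(self, baseline_naf, pore23):
        mags = [
            abs(
                ps.delta_n_electric(
                    ps.Analyte(name="a", r_analyte=1e-9, z_analyte=z),
                    baseline_naf,
                    pore23,
                )
            )
            for z in range(1, 121)
        ]
        assert all(b >= a for a, b in zip(mags, mags[1:]))

    def test_antisymmetric_in_charge(self, baseline_naf, pore23, ref):
        plus = ps.Analyte(name="p", r_analyte=1e-9, z_analyte=28)
        minus = ps.Analyte(name="m", r_analyte=1e-9, z_analyte=-28)
        d_plus = ps.delta_n_electric(plus, baseline_naf, pore23)
        d_minus = ps.delta_n_electric(minus, baseline_naf, pore23)
        assert d_plus == pytest.approx(-d_minus, rel=1e-12)
        assert d_plus == pytest.approx(
            oracle.dn_electric(ref["P_bs"], 28, ref["V_total"]), rel=1e-9
        )


class TestDeltaVelocity:
    def test_zero_perturbation(self, baseline_naf, pore23):
        assert ps.delta_velocity(0.0, baseline_naf, pore23) == 0.0

    def test_scales_with_baseline_velocity(self, baseline_naf, pore23):
        dn = 1e5
        dv1 = ps.delta_velocity(dn, baseline_naf, pore23)
        doubled = dataclasses.replace(baseline_naf, v_bs=2 * baseline_naf.v_bs)
        dv2 = ps.delta_velocity(dn, doubled, pore23)
        assert dv2 == pytest.approx(2 * dv1, rel=1e-12)

    def test_value_matches_transcription(self, baseline_naf, pore23, ref):
        dn = -1.4e6
        expected = oracle.dv(ref["v_bs"], dn, ref["n_bs"])
        assert ps.delta_velocity(dn, baseline_naf, pore23) == pytest.approx(
            expected, rel=1e-9
        )

    def test_degenerate_perturbed_density(self, baseline_naf, pore23):
        with pytest.raises(DegenerateStateError):
            ps.delta_velocity(-baseline_naf.n_bs, baseline_naf, pore23)


class TestDeltaCurrent:
    def test_null_perturbation(self, baseline_naf, pore23):
        assert ps.delta_current(0.0, 0.0, baseline_naf, pore23) == 0.0

    def test_sign_flips_with_perturbation(self, baseline_naf, pore23):
        dn = 2e5
        dv = ps.delta_velocity(dn, baseline_naf, pore23)
        di_pos = ps.delta_current(dn, dv, baseline_naf, pore23)
        dv_m = ps.delta_velocity(-dn, baseline_naf, pore23)
        di_neg = ps.delta_current(-dn, dv_m, baseline_naf, pore23)
        assert np.sign(di_pos) == -np.sign(di_neg)

    def test_ceria_like_chain_matches_transcription(self, baseline_naf, pore23, ref):
        ana = ps.Analyte(name="c", r_analyte=1.27e-9, z_analyte=112)
        dn_v = ps.delta_n_volume(ana, baseline_naf, pore23)
        dn_e = ps.delta_n_electric(ana, baseline_naf, pore23)
        dn = dn_v + dn_e
        dv = ps.delta_velocity(dn, baseline_naf, pore23)
        got = ps.delta_current(dn, dv, baseline_naf, pore23)

        v_an = 4 / 3 * math.pi * (1.27e-9 + 0.14e-9) ** 3
        o_dn = oracle.dn_volume(ref["n_bs"], v_an, ref["V_total"]) + oracle.dn_electric(
            ref["P_bs"], 112, ref["V_total"]
        )
        o_dv = oracle.dv(ref["v_bs"], o_dn, ref["n_bs"])
        expected = oracle.delta_current(ref["area"], o_dn, o_dv, ref["n_bs"], ref["v_bs"])
        assert got == pytest.approx(expected, rel=1e-9)


class TestAnalyteContribution:
    def test_charge_density_linear_in_valence(self, pore23):
        vals = [
            ps.analyte_charge_density(
                ps.Analyte(name="a", r_analyte=1e-9, z_analyte=z), pore23
            )
            for z in (0, 1, 7, 112)
        ]
        assert vals[0] == 0.0
        assert vals[3] == pytest.approx(112 * vals[1], rel=1e-12)

    def test_charge_density_value(self):
        pore4 = ps.NanoporeGeometry(r_np=4e-9)
        ana = ps.Analyte(name="c", r_analyte=1.27e-9, z_analyte=112)
        expected = oracle.n_analyte(112, math.pi * (4e-9) ** 2 * 55e-9)
        assert ps.analyte_charge_density(ana, pore4) == pytest.approx(expected, rel=1e-9)

    def test_velocity_is_length_over_time(self, pore23):
        assert ps.analyte_velocity(1e-3, pore23) == pytest.approx(5.5e-5, rel=1e-12)
        assert ps.analyte_velocity(0.5e-3, pore23) == pytest.approx(
            2 * ps.analyte_velocity(1e-3, pore23), rel=1e-12
        )
        assert ps.analyte_velocity(1e3, pore23) < 1e-10
        with pytest.raises(InvalidInputError):
            ps.analyte_velocity(0.0, pore23)

    def test_current_value_and_neutral_zero(self, pore23):
        ana = ps.Analyte(name="c", r_analyte=1.27e-9, z_analyte=112)
        got = ps.analyte_current(ana, 1e-3, pore23)
        n_an = oracle.n_analyte(112, pore23.area * 55e-9)
        expected = oracle.i_analyte(n_an, pore23.area, oracle.v_analyte(55e-9, 1e-3))
        assert got == pytest.approx(expected, rel=1e-9)
        neutral = ps.Analyte(name="n", r_analyte=1e-9, z_analyte=0)
        assert ps.analyte_current(neutral, 1e-3, pore23) == 0.0

    def test_direct_current_negligible(
        self, naf_1mM, pore23, validation_analytes, ceria_oxidized
    ):
        for ana in list(validation_analytes.values()) + [ceria_oxidized]:
            state = ps.predict_signals(naf_1mM, pore23, ana, 1e-3)
            assert abs(state.I_analyte) / abs(state.I_ps) < 1e-2


class TestPotentialSignal:
    def test_null_inputs_zero_signal(self, baseline_naf, pore23):
        assert ps.potential_signal(0.0, 0.0, baseline_naf.C_EDL, pore23) == 0.0

    def test_zero_capacitance_degenerate(self, pore23):
        with pytest.raises(DegenerateStateError):
            ps.potential_signal(1.0, 0.0, 0.0, pore23)

    def test_validation_analytes_within_millivolt_band(
        self, naf_1mM, pore23, validation_analytes
    ):
        for ana in validation_analytes.values():
            v_ps = ps.predict_signals(naf_1mM, pore23, ana).V_ps
            assert -1e-3 < v_ps < 1e-3

    def test_value_matches_transcription(self, baseline_naf, pore23, ref):
        dn, n_an = -1.4e6, 2e4
        expected = oracle.vps(ref["V_total"], dn, n_an, ref["C_EDL"])
        got = ps.potential_signal(dn, n_an, baseline_naf.C_EDL, pore23)
        assert got == pytest.approx(expected, rel=1e-9)


class TestPredictSignals:
    def test_null_analyte_zero_signals(self, naf_1mM, pore23):
        state = ps.predict_signals(naf_1mM, pore23, None)
        assert state.I_ps == 0.0 and state.V_ps == 0.0
        assert state.dn_total == 0.0 and state.dv == 0.0

    def test_additivity_and_composition_identities(self, naf_1mM, pore23, ceria_small):
        st = ps.predict_signals(naf_1mM, pore23, ceria_small)
        assert st.dn_total == st.dn_volume + st.dn_electric
        assert st.I_ps == st.dI_bs + st.I_analyte

    def test_potential_signal_monotone_in_charge(self, naf_1mM, pore23):
        vps = [
            ps.predict_signals(
                naf_1mM, pore23, ps.Analyte(name="a", r_analyte=1e-9, z_analyte=z)
            ).V_ps
            for z in range(0, 121, 10)
        ]
        assert all(b > a for a, b in zip(vps, vps[1:]))

    def test_validation_analyte_signal_ordering(self, naf_1mM, pore23, validation_analytes):
        """Hydroquinone gives the most positive potential signal and citric
        acid the most negative; across the charge series the current signals
        order opposite to the potential signals."""
        v = {n: ps.predict_signals(naf_1mM, pore23, a).V_ps for n, a in validation_analytes.items()}
        i = {n: ps.predict_signals(naf_1mM, pore23, a).I_ps for n, a in validation_analytes.items()}
        assert v["hydroquinone"] == max(v.values())
        assert v["citric_acid"] == min(v.values())
        # distinct-valence analytes: z = -1 (HQ), -2 (AA), -3 (CA)
        assert v["hydroquinone"] > v["ascorbic_acid"] > v["citric_acid"]
        assert i["hydroquinone"] < i["ascorbic_acid"] < i["citric_acid"]

    def test_baseline_modulates_signal_magnitude(self, pore23, ceria_small):
        """The same analyte produces different signal magnitudes on different
        baseline states (concentration changes the baseline charge density)."""
        s1 = ps.predict_signals(ps.default_solution(1e-4), pore23, ceria_small)
        s2 = ps.predict_signals(ps.default_solution(1e-2), pore23, ceria_small)
        assert abs(abs(s1.I_ps) - abs(s2.I_ps)) / abs(s2.I_ps) > 0.01

    def test_forward_model_continuous_in_parameters(self, naf_1mM, pore23):
        base = ps.baseline_state(naf_1mM, pore23)
        radii = np.linspace(0.3e-9, 2.0e-9, 60)
        i_vals, v_vals = [], []
        for r in radii:
            st = ps.predict_signals(
                naf_1mM, pore23, ps.Analyte(name="a", r_analyte=float(r), z_analyte=30),
                baseline=base,
            )
            i_vals.append(st.I_ps)
            v_vals.append(st.V_ps)
        for series in (np.array(i_vals), np.array(v_vals)):
            jumps = np.abs(np.diff(series))
            scale = np.abs(series).max()
            assert jumps.max() < 0.1 * scale
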