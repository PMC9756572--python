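import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dermvbe.formulation import (
    Component,
    Formulation,
    FormulationState,
    continuous_phase_fractions,
    derive_tertiary,
    evaporation_step,
    initial_state,
    load_formulation,
    mass_fractions_from_volume,
    mixture_density,
    sprays_to_dose,
    vehicle_diffusivity,
    volume_fractions,
    write_composition_report,
)
from dermvbe.presets import TOPICORT_COMPONENTS, topicort_spray


# ---------------------------------------------------------------------------
# composition arithmetic


class TestVolumeFractions:
    def test_reference_spray_ipa(self, spray):
        vf = volume_fractions(spray.components)
        assert round(vf["isopropyl alcohol"], 2) == 25.17

    def test_single_component_is_100(self):
        comps = [Component("x", 1.0, 0.7)]
        assert volume_fractions(comps)["x"] == pytest.approx(100.0)

    def test_equal_masses_densities_1_and_2(self):
        # hand arithmetic: (1/1) / (1/1 + 1/2) = 2/3
        comps = [Component("a", 0.5, 1.0), Component("b", 0.5, 2.0)]
        vf = volume_fractions(comps)
        assert vf["a"] == pytest.approx(200 / 3, abs=1e-9)
        assert vf["b"] == pytest.approx(100 / 3, abs=1e-9)

    def test_fractions_sum_to_100(self, spray):
        assert sum(volume_fractions(spray.components).values()) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_zero_density_error_names_component(self):
        with pytest.raises(ValueError, match="oddball"):
            Component("oddball", 0.5, 0.0)

    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 1.0),  # raw mass weight
                st.floats(0.1, 3.0),  # density
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_with_mass_fractions(self, raw):
        total = sum(w for w, _ in raw)
        comps = [
            Component(f"c{i}", w / total, rho) for i, (w, rho) in enumerate(raw)
        ]
        vf = volume_fractions(comps)
        back = mass_fractions_from_volume(vf, {c.name: c.density for c in comps})
        for c in comps:
            assert back[c.name] == pytest.approx(c.mass_fraction, abs=1e-9)


class TestMixtureDensity:
    def test_primary_density(self, spray):
        assert round(mixture_density(spray.components), 2) == 0.83

    def test_tertiary_density(self, spray):
        tert = derive_tertiary(spray)
        nonzero = [c for c in tert.components if c.mass_fraction > 0]
        assert round(mixture_density(nonzero), 2) == 0.85

    def test_uniform_density_is_exact(self):
        comps = [Component("a", 0.3, 1.2), Component("b", 0.7, 1.2)]
        assert mixture_density(comps) == pytest.approx(1.2, abs=1e-12)

    def test_empty_list_error(self):
        with pytest.raises(ValueError):
            mixture_density([])

    def test_tertiary_at_least_primary_when_volatiles_light(self, spray):
        # IPA is the least dense component of the reference spray
        tert = derive_tertiary(spray)
        nonzero = [c for c in tert.components if c.mass_fraction > 0]
        assert mixture_density(nonzero) >= mixture_density(spray.components)


class TestDeriveTertiary:
    def test_api_fraction(self, spray):
        tert = derive_tertiary(spray)
        assert round(100 * tert.component("desoximetasone").mass_fraction, 2) == 0.33

    def test_ipm_fraction(self, spray):
        tert = derive_tertiary(spray)
        assert (
            round(100 * tert.component("isopropyl myristate").mass_fraction, 2)
            == 40.96
        )

    def test_mineral_oil_fraction(self, spray):
        tert = derive_tertiary(spray)
        assert round(100 * tert.component("mineral oil").mass_fraction, 2) == 57.47

    def test_volatiles_present_at_zero(self, spray):
        tert = derive_tertiary(spray)
        assert tert.component("isopropyl alcohol").mass_fraction == 0.0
        assert sum(c.mass_fraction for c in tert.components) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_no_volatiles_is_identity(self):
        f = Formulation(
            components=(Component("a", 0.4, 1.0), Component("b", 0.6, 0.9)),
        )
        tert = derive_tertiary(f)
        assert [c.mass_fraction for c in tert.components] == [0.4, 0.6]

    def test_all_volatile_error(self):
        f = Formulation(
            components=(Component("a", 1.0, 0.8, is_volatile=True),),
        )
        with pytest.raises(ValueError):
            derive_tertiary(f)


class TestContinuousPhase:
    def test_printed_normalised_fractions(self, spray):
        tert = derive_tertiary(spray)
        cp = continuous_phase_fractions(
            tert, ["mineral oil", "isopropyl myristate"]
        )
        assert round(cp["mineral oil"], 2) == 58.39
        assert round(cp["isopropyl myristate"], 2) == 41.61

    def test_single_member(self, spray):
        cp = continuous_phase_fractions(spray, ["mineral oil"])
        assert cp["mineral oil"] == pytest.approx(100.0)

    def test_three_member_hand_arithmetic(self, spray):
        # independent oracle: renormalise the tertiary volumes by hand from
        # the raw label composition
        raw = {
            d["name"]: d["w_w_percent"] / d["density_g_ml"]
            for d in TOPICORT_COMPONENTS
            if not d["volatile"]
        }
        members = ["mineral oil", "isopropyl myristate", "glyceryl oleate"]
        total = sum(raw[m] for m in members)
        expected = {m: 100.0 * raw[m] / total for m in members}
        got = continuous_phase_fractions(derive_tertiary(spray), members)
        for m in members:
            assert got[m] == pytest.approx(expected[m], abs=1e-9)

    def test_empty_members_error(self, spray):
        with pytest.raises(ValueError):
            continuous_phase_fractions(spray, [])

    def test_unknown_member_error(self, spray):
        with pytest.raises(KeyError):
            continuous_phase_fractions(spray, ["water"])


# ---------------------------------------------------------------------------
# vehicle physics


class TestVehicleDiffusivity:
    def test_inverse_proportionality(self):
        for eta in (1.0, 37.5, 12000.0):
            assert vehicle_diffusivity(10 * eta, 289.6, 305.0) == pytest.approx(
                vehicle_diffusivity(eta, 289.6, 305.0) / 10.0
            )

    def test_ratio_100_vs_1(self):
        d100 = vehicle_diffusivity(100.0, 289.6, 305.0)
        d1 = vehicle_diffusivity(1.0, 289.6, 305.0)
        assert d100 / d1 == pytest.approx(0.01)

    def test_stokes_einstein_hand_value(self):
        # independent evaluation of D = kB*T/(6*pi*eta*r), solute radius from
        # molar volume MW/rho = 376.46/1.3 cm3/mol
        kb, na = 1.380649e-23, 6.02214076e23
        vm = 376.46 / 1.3  # cm3/mol
        r_m = (3 * (vm / na) * 1e-6 / (4 * math.pi)) ** (1 / 3)
        expected = kb * 305.0 / (6 * math.pi * 0.1 * r_m) * 1e4 * 3600  # cm2/h
        got = vehicle_diffusivity(100.0, vm, 305.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_non_positive_inputs_error(self):
        for args in [(-1, 300, 300), (100, 0, 300), (100, 300, -5)]:
            with pytest.raises(ValueError):
                vehicle_diffusivity(*args)


class TestEvaporation:
    def make_formulation(self, max_frac=0.2517, rate=5.0):
        return topicort_spray(
            max_evaporated_fraction=max_frac, evaporation_rate=rate
        )

    def test_zero_rate_unchanged(self):
        f = self.make_formulation(rate=None or 0.0)
        s0 = initial_state(f, 0.005)
        s1 = evaporation_step(s0, f, 1.0)
        assert s1.volume == s0.volume
        assert s1.evaporated_volume == 0.0

    def test_time_to_cap_closed_form(self):
        f = self.make_formulation(max_frac=0.3, rate=2.0)
        v0 = 0.01
        t_star = 0.3 * v0 / 2.0
        s = initial_state(f, v0)
        s = evaporation_step(s, f, t_star)
        assert s.evaporated_volume == pytest.approx(0.3 * v0, rel=1e-12)
        # further evaporation saturates
        s2 = evaporation_step(s, f, 10.0)
        assert s2.evaporated_volume == pytest.approx(0.3 * v0, rel=1e-12)

    def test_reference_dose_concentration_factor(self):
        # 5 µL with 25.17 %v/v volatiles -> 3.74 µL residual film
        f = topicort_spray()
        s = initial_state(f, 0.005)
        s = evaporation_step(s, f, 10.0)
        assert s.volume * 1000 == pytest.approx(3.74, abs=0.005)
        factor = s.api_concentration / (s.api_amount_dissolved / 0.005)
        assert factor == pytest.approx(5.0 / 3.74, abs=0.005)

    def test_api_mass_conserved(self):
        f = self.make_formulation()
        s = initial_state(f, 0.005)
        for _ in range(5):
            s = evaporation_step(s, f, 0.001)
        assert s.api_amount_dissolved == initial_state(f, 0.005).api_amount_dissolved

    @given(
        dt=st.floats(0, 10),
        rate=st.floats(0, 20),
        max_frac=st.floats(0, 1),
    )
    @settings(max_examples=80, deadline=None)
    def test_evaporated_volume_capped_and_monotone(self, dt, rate, max_frac):
        f = topicort_spray(
            max_evaporated_fraction=max_frac, evaporation_rate=rate
        )
        s0 = initial_state(f, 0.005)
        s1 = evaporation_step(s0, f, dt)
        s2 = evaporation_step(s1, f, dt)
        assert 0 <= s1.evaporated_volume <= s2.evaporated_volume
        assert s2.evaporated_volume <= max_frac * 0.005 + 1e-15
        assert s2.api_amount_dissolved == s0.api_amount_dissolved

    def test_negative_dt_error(self, spray):
        with pytest.raises(ValueError):
            evaporation_step(initial_state(spray, 0.005), spray, -0.1)


class TestSpraysToDose:
    def test_one_spray(self, spray):
        mass, volume = sprays_to_dose(1, spray)
        assert mass == pytest.approx(2.4)
        # label composition sums to 100.01%; normalisation shifts the API
        # fraction from 0.25% by one part in 10^4
        assert mass * spray.api_mass_fraction == pytest.approx(0.006, rel=2e-4)
        assert volume == pytest.approx(0.0024 / mixture_density(spray.components))

    def test_zero_sprays(self, spray):
        assert sprays_to_dose(0, spray) == (0.0, 0.0)

    def test_ivpt_dose_is_about_3_5_sprays_per_cm2(self, spray):
        # 5 µL on 0.5 cm² at the primary density, 2.4 mg per spray
        mass_mg = 5e-3 * mixture_density(spray.components) * 1000
        sprays_per_cm2 = mass_mg / 0.5 / 2.4
        assert round(sprays_per_cm2, 1) == 3.5

    def test_negative_error(self, spray):
        with pytest.raises(ValueError):
            sprays_to_dose(-1, spray)


# ---------------------------------------------------------------------------
# state & I/O


def test_formulation_state_concentration():
    s = FormulationState(volume=0.004, api_amount_dissolved=0.01)
    assert s.api_concentration == pytest.approx(2.5)
    assert FormulationState(0.0, 0.0).api_concentration == 0.0


def test_supersaturation_flagged():
    f = topicort_spray(api_solubility_cont_phase=3.0)
    s = initial_state(f, 0.005)
    assert not s.supersaturated
    f2 = topicort_spray(api_solubility_cont_phase=0.001)
    assert initial_state(f2, 0.005).supersaturated


def test_mass_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        Formulation(components=(Component("a", 0.5, 1.0),))


def test_yaml_round_trip(tmp_path, spray):
    from dermvbe.synthdata import make_fixture_suite

    written = make_fixture_suite(tmp_path)
    loaded = load_formulation(written["topicort.yaml"])
    assert loaded.api_mass_fraction == pytest.approx(
        spray.api_mass_fraction, rel=1e-3
    )
    assert loaded.viscosity == spray.viscosity
    assert loaded.max_evaporated_fraction == pytest.approx(
        spray.max_evaporated_fraction, abs=5e-5
    )


def test_composition_report(tmp_path, spray):
    import csv

    path = tmp_path / "report.csv"
    write_composition_report(spray, path)
    with open(path) as fh:
        rows = {r["component"]: r for r in csv.DictReader(fh)}
    assert float(rows["desoximetasone"]["tertiary_w_w_pct"]) == 0.33
    assert float(rows["isopropyl alcohol"]["primary_v_v_pct"]) == 25.17
    assert float(rows["mixture_density_g_ml"]["primary_w_w_pct"]) == 0.83
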