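from dataclasses import replace

import numpy as np
import pytest

from dermvbe.formulation import Component, Formulation
from dermvbe.presets import desoximetasone, topicort_spray
from dermvbe.skin import (
    CompartmentSystem,
    SkinPhysiology,
    build_skin,
    partition_from_solubility,
    rhs,
    simulate,
)


def make_system(physiology=None, formulation=None, dose=4.15, area=0.5,
                mode="ivpt", **kwargs):
    return build_skin(
        physiology or SkinPhysiology(),
        formulation or topicort_spray(),
        dose,
        area,
        mode,
        compound=desoximetasone(),
        **kwargs,
    )


def series_membrane_system(layer_perms, donor_conc=1.0, area=1.0):
    """Hand-built constant-donor stack for the analytic flux oracle.

    ``layer_perms`` are the per-layer permeabilities of every diffusive layer
    in the chain (SC layers + viable epidermis + dermis).  The donor is a
    huge, non-evaporating reservoir so its concentration is effectively
    constant, and its boundary-layer resistance is made negligible.
    """
    n_sc = len(layer_perms) - 2
    names = ["vehicle"] + [f"sc_{i+1}" for i in range(n_sc)]
    names += ["viable_epidermis", "dermis", "receptor"]
    dim = len(names)
    volumes = np.full(dim, 1e-4)
    v_donor = 1e6
    volumes[0] = v_donor
    formulation = Formulation(
        components=(Component("solvent", 1.0, 1.0),),
        evaporation_rate=0.0,
        max_evaporated_fraction=0.0,
    )
    x0 = np.zeros(dim)
    x0[0] = donor_conc * v_donor
    return CompartmentSystem(
        names=names,
        mode="ivpt",
        area=area,
        volumes=volumes,
        partition=np.ones(dim),
        layer_perm=np.asarray(layer_perms, dtype=float),
        vehicle_diff=1e12,  # no donor-side resistance
        formulation=formulation,
        x0=x0,
        dose_api=float(x0[0]),
        film_volume0=v_donor,
    )


class TestBuildSkin:
    def test_layer_count(self):
        sys10 = make_system(replace(SkinPhysiology(), n_sc_layers=10))
        assert sum(n.startswith("sc_") for n in sys10.names) == 10
        sys20 = make_system()
        assert sum(n.startswith("sc_") for n in sys20.names) == 20

    def test_single_layer_degenerate(self):
        phys = replace(SkinPhysiology(), n_sc_layers=1)
        system = make_system(phys)
        perms = system.interface_permeabilities(system.film_volume0)
        # SC block resistance (vehicle interface minus film part) equals the
        # single layer's parallel-path value
        k_sc = system.partition[1]
        p_layer = (
            k_sc * phys.lipid_diffusivity / (phys.sc_layer_thickness * 1e-4)
            + phys.P_cell
        )
        film_res = system.film_volume0 / system.area / system.vehicle_diff
        assert 1.0 / perms[0] - film_res == pytest.approx(
            1.0 / (2 * p_layer), rel=1e-12
        )

    def test_doubling_layer_permeability_halves_sc_resistance(self):
        phys = SkinPhysiology()
        fast = replace(
            phys,
            lipid_diffusivity=2 * phys.lipid_diffusivity,
            P_cell=2 * phys.P_cell,
        )
        r_slow = sum(1.0 / make_system(phys).layer_perm[:-2])
        r_fast = sum(1.0 / make_system(fast).layer_perm[:-2])
        assert r_fast == pytest.approx(r_slow / 2, rel=1e-12)

    def test_unknown_mode_error(self):
        with pytest.raises(ValueError, match="mode"):
            make_system(mode="ex_vivo")

    def test_in_vivo_has_systemic_compartments(self, systemic):
        system = make_system(mode="in_vivo", systemic=systemic)
        assert {"central", "peripheral", "eliminated"} <= set(system.names)


class TestRhs:
    def test_zero_state_zero_derivatives(self):
        system = make_system()
        dx = rhs(np.zeros(len(system.names)), system)
        assert np.all(dx == 0)

    def test_partition_equilibrium_has_no_net_flux(self):
        system = make_system()
        nc = system.n_chain
        x = np.zeros(len(system.names))
        psi = 0.37  # common vehicle-referenced activity
        x[0] = psi * system.film_volume0 * system.partition[0]
        for i in range(1, nc):
            x[i] = psi * system.volumes[i] * system.partition[i]
        dx = rhs(x, system)
        # interior chain is at equilibrium; only the terminal sink drains
        assert np.allclose(dx[: nc - 1], 0.0, atol=1e-12 * system.dose_api)

    def test_empty_vehicle_no_flux_into_sc(self):
        system = make_system()
        x = np.zeros(len(system.names))
        dx = rhs(x, system)
        assert dx[1] == 0.0

    def test_mass_closed(self):
        system = make_system()
        x = np.abs(np.sin(np.arange(len(system.names)))) * 1e-3
        assert rhs(x, system).sum() == pytest.approx(0.0, abs=1e-18)

    def test_nan_state_error(self):
        system = make_system()
        x = np.zeros(len(system.names))
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            rhs(x, system)


class TestSimulate:
    def test_zero_dose_all_zero(self):
        system = make_system(dose=0.0)
        res = simulate(system, 24.0)
        assert np.all(res.amounts == 0)

    def test_negligible_partition_traps_drug_in_vehicle(self):
        phys = replace(SkinPhysiology(), K_sclip_vehicle=1e-12, P_cell=1e-15)
        res = simulate(make_system(phys), 24.0)
        assert res.amount("receptor")[-1] <= 1e-6 * res.dose_api

    def test_mass_balance(self):
        res = simulate(make_system(), 24.0)
        assert res.mass_balance_error < 1e-6

    def test_receptor_monotone(self):
        res = simulate(make_system(), 24.0)
        assert np.all(np.diff(res.amount("receptor")) >= -1e-12)

    def test_everything_reaches_sink_eventually(self):
        res = simulate(make_system(), 2000.0)
        assert res.amount("receptor")[-1] == pytest.approx(
            res.dose_api, rel=1e-3
        )

    def test_expm_matches_ode_solver(self):
        system = make_system()
        r1 = simulate(system, 24.0, method="expm")
        r2 = simulate(system, 24.0, method="ivp")
        assert np.max(np.abs(r1.amounts - r2.amounts)) < 1e-6 * system.dose_api

    def test_invalid_t_end(self):
        with pytest.raises(ValueError):
            simulate(make_system(), -1.0)


class TestSeriesResistanceOracle:
    @pytest.mark.parametrize("n_layers", [1, 2, 5])
    def test_steady_state_flux_matches_analytic(self, n_layers):
        rng = np.random.default_rng(n_layers)
        perms = 10.0 ** rng.uniform(-2.5, -1.0, n_layers + 2)
        system = series_membrane_system(perms, donor_conc=2.0)
        p_tot = 1.0 / np.sum(1.0 / perms)
        res = simulate(system, 2000.0, t_eval=np.linspace(0, 2000, 51))
        receptor = res.amount("receptor")
        flux = (receptor[-1] - receptor[-2]) / (res.t[-1] - res.t[-2])
        donor_conc = res.amount("vehicle")[-1] / system.film_volume0
        expected = p_tot * system.area * donor_conc
        assert flux == pytest.approx(expected, rel=0.01)


class TestPartitionFromSolubility:
    def test_identity(self):
        assert partition_from_solubility(0.5, 2.0, 0.5) == 2.0

    def test_doubling_solubility_halves_K(self):
        assert partition_from_solubility(1.0, 2.0, 0.5) == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            partition_from_solubility(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            partition_from_solubility(1.0, -1.0, 1.0)


class TestMonotonicity:
    def cumulative_at_24h(self, physiology=None, formulation=None):
        res = simulate(make_system(physiology, formulation), 24.0)
        return res.amount("receptor")[-1]

    def test_non_increasing_in_viscosity(self):
        values = [
            self.cumulative_at_24h(formulation=topicort_spray(viscosity=v))
            for v in [1.0, 100.0, 1e4, 1e5, 1e6]
        ]
        assert np.all(np.diff(values) <= 1e-12)

    def test_non_increasing_in_vehicle_solubility(self):
        values = [
            self.cumulative_at_24h(
                formulation=topicort_spray(api_solubility_cont_phase=s)
            )
            for s in [0.1, 0.25, 0.5, 0.75, 1.0]
        ]
        assert np.all(np.diff(values) < 0)

    def test_non_decreasing_in_partition_coefficient(self):
        values = [
            self.cumulative_at_24h(replace(SkinPhysiology(), K_sclip_vehicle=k))
            for k in [0.05, 0.15, 0.35, 0.8, 2.0]
        ]
        assert np.all(np.diff(values) > 0)

    def test_halving_layers_increases_flux(self):
        v20 = self.cumulative_at_24h(replace(SkinPhysiology(), n_sc_layers=20))
        v10 = self.cumulative_at_24h(replace(SkinPhysiology(), n_sc_layers=10))
        assert v10 > v20


class TestPhysiologyValidation:
    def test_layer_count_required(self):
        with pytest.raises(ValueError):
            SkinPhysiology(n_sc_layers=0)

    def test_positive_thickness(self):
        with pytest.raises(ValueError):
            SkinPhysiology(sc_layer_thickness=-1)

    def test_perfused_fraction_range(self):
        with pytest.raises(ValueError):
            SkinPhysiology(fraction_capillaries_perfused=1.5)

    def test_yaml_round_trip(self, tmp_path):
        from dermvbe.skin import load_physiology, write_physiology

        phys = replace(SkinPhysiology(), n_sc_layers=10, body_site="forearm")
        path = tmp_path / "phys.yaml"
        write_physiology(phys, path)
        assert load_physiology(path) == phys


def test_result_csv(tmp_path):
    import pandas as pd

    from dermvbe.skin import write_result_csv

    res = simulate(make_system(), 4.0, t_eval=np.linspace(0, 4, 5))
    path = tmp_path / "trace.csv"
    write_result_csv(res, path)
    df = pd.read_csv(path)
    assert set(df.columns) == {
        "time_h", "compartment", "amount_mg", "concentration_mg_ml"
    }
    assert df["compartment"].nunique() == len(res.names)
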