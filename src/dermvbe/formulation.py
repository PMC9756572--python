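"""Formulation composition (Q2), attributes (Q3) and vehicle-side physics.

A topical product is represented by its quantitative composition — a list of
components with mass fractions, densities and volatility flags — plus the
physical attributes that drive absorption: viscosity, drug solubility in the
continuous phase, and the evaporation behaviour of the volatile fraction.

The module supports the life cycle of a sprayed solution formulation:

* *primary* composition (in-container, as listed on the label / patent),
* *tertiary* composition (after the volatile components have evaporated),
* the continuous-phase sub-mixture that actually solvates the drug.

All mass fractions are stored as dimensionless fractions (not percent);
densities are g/ml, volumes ml, amounts mg, times hours.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Component",
    "Formulation",
    "FormulationState",
    "volume_fractions",
    "mass_fractions_from_volume",
    "mixture_density",
    "derive_tertiary",
    "continuous_phase_fractions",
    "volatile_volume_fraction",
    "vehicle_diffusivity",
    "evaporation_step",
    "sprays_to_dose",
    "initial_state",
    "load_formulation",
    "write_composition_report",
]

#: Boltzmann constant, J/K
_KB = 1.380649e-23
#: Avogadro constant, 1/mol
_NA = 6.02214076e23


@dataclass(frozen=True)
class Component:
    """One formulation ingredient.

    ``mass_fraction`` is the fraction of total formulation mass (0..1).
    """

    name: str
    mass_fraction: float
    density: float  # g/ml
    is_volatile: bool = False
    is_api: bool = False

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(
                f"component {self.name!r} has non-positive density {self.density}"
            )
        if not 0.0 <= self.mass_fraction <= 1.0:
            raise ValueError(
                f"component {self.name!r} mass fraction {self.mass_fraction} "
                "outside [0, 1]"
            )


@dataclass(frozen=True)
class Formulation:
    """Quantitative composition plus the critical quality attributes.

    ``max_evaporated_fraction`` is the %v/v of the *initial applied volume*
    that can be lost to evaporation (stored as a fraction), and
    ``evaporation_rate`` is a zero-order volume loss rate in ml/h.
    """

    components: tuple[Component, ...]
    viscosity: float = 100.0  # cP
    api_solubility_cont_phase: float = 0.5  # mg/ml
    max_evaporated_fraction: float = 0.0  # fraction v/v of initial volume
    evaporation_rate: float = 0.0  # ml/h
    molar_volume_cont_phase: float = 415.8  # cm3/mol, supplied not derived

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not self.components:
            raise ValueError("formulation needs at least one component")
        total = sum(c.mass_fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, expected 1")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.api_solubility_cont_phase <= 0:
            raise ValueError("api solubility must be positive")
        if not 0.0 <= self.max_evaporated_fraction <= 1.0:
            raise ValueError("max_evaporated_fraction outside [0, 1]")
        if self.evaporation_rate < 0:
            raise ValueError("evaporation_rate must be non-negative")

    # -- composition helpers -------------------------------------------------

    @property
    def api_mass_fraction(self) -> float:
        return sum(c.mass_fraction for c in self.components if c.is_api)

    @property
    def density(self) -> float:
        return mixture_density(self.components)

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @classmethod
    def from_percent(
        cls,
        components: Iterable[Mapping],
        *,
        normalise: bool = True,
        **q3,
    ) -> "Formulation":
        """Build from per-component dicts with ``w_w_percent`` entries.

        Printed compositions often sum to 100 only within rounding error;
        with ``normalise`` the fractions are rescaled exactly to 1 (input
        must still be within 0.5% of 100).
        """
        comps = [
            Component(
                name=d["name"],
                mass_fraction=float(d["w_w_percent"]) / 100.0,
                density=float(d["density_g_ml"]),
                is_volatile=bool(d.get("volatile", False)),
                is_api=bool(d.get("api", False)),
            )
            for d in components
        ]
        total = sum(c.mass_fraction for c in comps)
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"component percentages sum to {100 * total:.3f}%")
        if normalise and total != 1.0:
            comps = [replace(c, mass_fraction=c.mass_fraction / total) for c in comps]
        return cls(components=tuple(comps), **q3)


@dataclass(frozen=True)
class FormulationState:
    """Instantaneous state of an applied dose undergoing metamorphosis."""

    volume: float  # ml
    api_amount_dissolved: float  # mg
    evaporated_volume: float = 0.0  # ml
    supersaturated: bool = False

    @property
    def initial_volume(self) -> float:
        # Only evaporation changes volume, so the applied volume is recoverable.
        return self.volume + self.evaporated_volume

    @property
    def api_concentration(self) -> float:
        """mg/ml; zero for an empty film."""
        if self.volume <= 0:
            return 0.0
        return self.api_amount_dissolved / self.volume


# ---------------------------------------------------------------------------
# composition arithmetic


def volume_fractions(components: Sequence[Component]) -> dict[str, float]:
    """Per-component volume fractions in percent (%v/v).

    v_i = (w_i / rho_i) / sum_j (w_j / rho_j).
    """
    if not components:
        raise ValueError("empty component list")
    for c in components:
        if c.density <= 0:
            raise ValueError(f"component {c.name!r} has zero density")
    specific = [c.mass_fraction / c.density for c in components]
    total = sum(specific)
    if total <= 0:
        raise ValueError("total volume is zero")
    return {c.name: 100.0 * s / total for c, s in zip(components, specific)}


def mass_fractions_from_volume(
    volume_percent: Mapping[str, float], densities: Mapping[str, float]
) -> dict[str, float]:
    """Inverse of :func:`volume_fractions`: w_i = v_i rho_i / sum v_j rho_j."""
    masses = {n: volume_percent[n] * densities[n] for n in volume_percent}
    total = sum(masses.values())
    return {n: m / total for n, m in masses.items()}


def mixture_density(components: Sequence[Component]) -> float:
    """Volume-weighted mixture density, g/ml: total mass over total volume."""
    if not components:
        raise ValueError("empty component list")
    mass = sum(c.mass_fraction for c in components)
    volume = sum(c.mass_fraction / c.density for c in components)
    if volume <= 0:
        raise ValueError("total volume is zero")
    return mass / volume


def derive_tertiary(primary: Formulation) -> Formulation:
    """Composition left after complete loss of the volatile components.

    Non-volatile components keep their relative proportions; volatile ones
    remain in the list with mass fraction 0 so reports can show both columns.
    The tertiary formulation has nothing left to evaporate.
    """
    residual = sum(
        c.mass_fraction for c in primary.components if not c.is_volatile
    )
    if residual <= 0:
        raise ValueError("all components are volatile; no tertiary formulation")
    comps = tuple(
        replace(c, mass_fraction=0.0 if c.is_volatile else c.mass_fraction / residual)
        for c in primary.components
    )
    return replace(
        primary,
        components=comps,
        max_evaporated_fraction=0.0,
    )


def continuous_phase_fractions(
    formulation: Formulation | Sequence[Component], phase_members: Iterable[str]
) -> dict[str, float]:
    """Volume fractions (%v/v) of ``phase_members`` renormalised to 100%."""
    members = set(phase_members)
    if not members:
        raise ValueError("empty continuous-phase member set")
    comps = (
        formulation.components
        if isinstance(formulation, Formulation)
        else tuple(formulation)
    )
    names = {c.name for c in comps}
    unknown = members - names
    if unknown:
        raise KeyError(f"unknown phase members: {sorted(unknown)}")
    vf = volume_fractions(comps)
    total = sum(vf[n] for n in members)
    if total <= 0:
        raise ValueError("continuous phase has zero volume")
    return {n: 100.0 * vf[n] / total for n in sorted(members)}


def volatile_volume_fraction(components: Sequence[Component]) -> float:
    """Total %v/v of the volatile components, as a fraction (0..1)."""
    vf = volume_fractions(components)
    return sum(vf[c.name] for c in components if c.is_volatile) / 100.0


# ---------------------------------------------------------------------------
# vehicle physics


def solute_radius_cm(molar_volume: float) -> float:
    """Equivalent-sphere solute radius (cm) from molar volume in cm³/mol."""
    if molar_volume <= 0:
        raise ValueError("molar volume must be positive")
    v_molecule = molar_volume / _NA  # cm3
    return (3.0 * v_molecule / (4.0 * math.pi)) ** (1.0 / 3.0)


def vehicle_diffusivity(
    viscosity: float, molar_volume: float, temperature: float
) -> float:
    """Stokes–Einstein diffusivity of the drug in the vehicle, cm²/h.

    ``viscosity`` in cP, ``molar_volume`` of the solute in cm³/mol,
    ``temperature`` in K.  D = k_B T / (6 pi eta r).
    """
    if viscosity <= 0 or molar_volume <= 0 or temperature <= 0:
        raise ValueError("viscosity, molar volume and temperature must be positive")
    r_m = solute_radius_cm(molar_volume) * 1e-2
    eta = viscosity * 1e-3  # Pa s
    d_m2_s = _KB * temperature / (6.0 * math.pi * eta * r_m)
    return d_m2_s * 1e4 * 3600.0  # cm2/h


def evaporation_step(
    state: FormulationState, formulation: Formulation, dt: float
) -> FormulationState:
    """Advance the film by ``dt`` hours of zero-order evaporation.

    Volume is lost at ``evaporation_rate`` until the evaporated volume
    reaches ``max_evaporated_fraction`` of the initially applied volume.
    The API is non-volatile: its dissolved amount is conserved and the
    concentration rises as the film shrinks.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    v0 = state.initial_volume
    cap = formulation.max_evaporated_fraction * v0
    headroom = max(cap - state.evaporated_volume, 0.0)
    dv = min(formulation.evaporation_rate * dt, headroom)
    new = replace(
        state,
        volume=state.volume - dv,
        evaporated_volume=state.evaporated_volume + dv,
    )
    supersat = new.api_concentration > formulation.api_solubility_cont_phase * (
        1.0 + 1e-12
    )
    return replace(new, supersaturated=supersat or state.supersaturated)


def evaporation_end_time(formulation: Formulation, initial_volume: float) -> float:
    """Time (h) at which the volatile fraction is fully lost; 0 if nothing to lose."""
    loss = formulation.max_evaporated_fraction * initial_volume
    if loss <= 0 or formulation.evaporation_rate <= 0:
        return 0.0
    return loss / formulation.evaporation_rate


def film_volume_at(
    formulation: Formulation, initial_volume: float, t: float
) -> float:
    """Film volume (ml) at time ``t`` hours after application."""
    loss = min(
        formulation.evaporation_rate * max(t, 0.0),
        formulation.max_evaporated_fraction * initial_volume,
    )
    return initial_volume - loss


def sprays_to_dose(
    n_sprays: float, formulation: Formulation, per_spray_mass_mg: float = 2.4
) -> tuple[float, float]:
    """Applied formulation mass (mg) and volume (ml) for ``n_sprays`` sprays."""
    if n_sprays < 0:
        raise ValueError("n_sprays must be non-negative")
    mass_mg = per_spray_mass_mg * n_sprays
    volume_ml = mass_mg / 1000.0 / mixture_density(formulation.components)
    return mass_mg, volume_ml


def initial_state(formulation: Formulation, volume_ml: float) -> FormulationState:
    """Freshly applied dose: dissolved API amount from volume and composition."""
    if volume_ml < 0:
        raise ValueError("volume must be non-negative")
    mass_mg = volume_ml * mixture_density(formulation.components) * 1000.0
    api_mg = mass_mg * formulation.api_mass_fraction
    state = FormulationState(volume=volume_ml, api_amount_dissolved=api_mg)
    if state.api_concentration > formulation.api_solubility_cont_phase:
        state = replace(state, supersaturated=True)
    return state


# ---------------------------------------------------------------------------
# I/O


def load_formulation(path: str | Path) -> Formulation:
    """Read a formulation definition YAML file.

    Layout::

        components:
          - {name: ..., w_w_percent: ..., density_g_ml: ..., volatile: ..., api: ...}
        q3:
          viscosity_cP: 100
          solubility_mg_ml: 0.5
          max_evaporated_pct_vv: 25.17
          evaporation_rate_ml_h: 5.0
          molar_volume_cont_phase: 415.8
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    q3 = doc.get("q3", {})
    return Formulation.from_percent(
        doc["components"],
        viscosity=float(q3.get("viscosity_cP", 100.0)),
        api_solubility_cont_phase=float(q3.get("solubility_mg_ml", 0.5)),
        max_evaporated_fraction=float(q3.get("max_evaporated_pct_vv", 0.0)) / 100.0,
        evaporation_rate=float(q3.get("evaporation_rate_ml_h", 0.0)),
        molar_volume_cont_phase=float(q3.get("molar_volume_cont_phase", 415.8)),
    )


def write_composition_report(formulation: Formulation, path: str | Path) -> None:
    """Write the primary/tertiary %w/w and %v/v table as CSV."""
    tertiary = derive_tertiary(formulation)
    vf_primary = volume_fractions(formulation.components)
    nonvol = [c for c in tertiary.components if c.mass_fraction > 0]
    vf_tertiary = volume_fractions(nonvol)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "component",
                "primary_w_w_pct",
                "tertiary_w_w_pct",
                "density_g_ml",
                "primary_v_v_pct",
                "tertiary_v_v_pct",
            ]
        )
        tert = {c.name: c for c in tertiary.components}
        for c in formulation.components:
            writer.writerow(
                [
                    c.name,
                    round(100.0 * c.mass_fraction, 2),
                    round(100.0 * tert[c.name].mass_fraction, 2),
                    c.density,
                    round(vf_primary[c.name], 2),
                    round(vf_tertiary.get(c.name, 0.0), 2),
                ]
            )
        writer.writerow(
            [
                "mixture_density_g_ml",
                round(mixture_density(formulation.components), 2),
                round(mixture_density(nonvol), 2),
                "",
                "",
                "",
            ]
        )
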