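"""Packaged reference configurations: compound, formulation, physiology, designs.

These are the defaults for the worked example — a 0.25% desoximetasone (DSM)
spray — and for the study designs used throughout the trials module.  All of
them can equally be loaded from YAML files written by
:func:`dermvbe.synthdata.make_fixture_suite`.
"""

from __future__ import annotations

from .formulation import Formulation, volatile_volume_fraction
from .ivpt import IVPTDesign
from .skin import SkinPhysiology
from .systemic import Compound, DosingEvent, SystemicModel

__all__ = [
    "desoximetasone",
    "topicort_spray",
    "default_systemic",
    "physiology_scenario",
    "ivpt_design",
    "dose_scenario",
    "default_dosing",
    "TOPICORT_COMPONENTS",
    "DOSE_SCENARIOS",
]

#: per-component {name, %w/w, density g/ml, volatile, api} of the spray
TOPICORT_COMPONENTS = (
    {"name": "desoximetasone", "w_w_percent": 0.25, "density_g_ml": 1.3,
     "volatile": False, "api": True},
    {"name": "glyceryl oleate", "w_w_percent": 0.9, "density_g_ml": 1.0,
     "volatile": False, "api": False},
    {"name": "isopropyl alcohol", "w_w_percent": 23.4, "density_g_ml": 0.774,
     "volatile": True, "api": False},
    {"name": "isopropyl myristate", "w_w_percent": 31.38, "density_g_ml": 0.85,
     "volatile": False, "api": False},
    {"name": "l-menthol", "w_w_percent": 0.05, "density_g_ml": 0.89,
     "volatile": False, "api": False},
    {"name": "mineral oil", "w_w_percent": 44.03, "density_g_ml": 0.85,
     "volatile": False, "api": False},
)

#: sprays per application and treated area for the four dose scenarios
DOSE_SCENARIOS = {
    1: {"sprays_per_cm2": 0.1, "label": "low (1 spray / 10 cm2)"},
    2: {"sprays_per_cm2": 0.5, "label": "middle (1 spray / 2 cm2)"},
    3: {"sprays_per_cm2": 1.0, "label": "default (1 spray / cm2)"},
    4: {"sprays_per_cm2": 3.5, "label": "IVPT-equivalent (3.5 sprays / cm2)"},
}


def desoximetasone() -> Compound:
    return Compound()


def topicort_spray(
    *,
    viscosity: float = 100.0,
    api_solubility_cont_phase: float = 0.5,
    evaporation_rate: float = 5.0,
    max_evaporated_fraction: float | None = None,
    molar_volume_cont_phase: float = 415.8,
) -> Formulation:
    """The reference spray formulation with its assumed Q3 attributes.

    By default the evaporable volume fraction is the computed volatile %v/v
    of the composition; pass ``max_evaporated_fraction`` to override it when
    sweeping the volatile fraction.
    """
    f = Formulation.from_percent(
        TOPICORT_COMPONENTS,
        viscosity=viscosity,
        api_solubility_cont_phase=api_solubility_cont_phase,
        evaporation_rate=evaporation_rate,
        molar_volume_cont_phase=molar_volume_cont_phase,
    )
    if max_evaporated_fraction is None:
        max_evaporated_fraction = volatile_volume_fraction(f.components)
    return Formulation(
        components=f.components,
        viscosity=viscosity,
        api_solubility_cont_phase=api_solubility_cont_phase,
        max_evaporated_fraction=max_evaporated_fraction,
        evaporation_rate=evaporation_rate,
        molar_volume_cont_phase=molar_volume_cont_phase,
    )


def default_systemic() -> SystemicModel:
    return SystemicModel()


def physiology_scenario(scenario: str = "A") -> SkinPhysiology:
    """Physiology presets.

    A: healthy volunteer with steroid vasoconstriction (capillary radius and
    perfused fraction both halved); B: without vasoconstriction; C/D: as A/B
    with the SC reduced to 10 layers (impaired barrier).
    """
    scenario = scenario.upper()
    base = SkinPhysiology()
    vc = {"capillary_radius_scale": 0.5, "fraction_capillaries_perfused": 0.5}
    thin = {"n_sc_layers": 10}
    if scenario == "A":
        kwargs = vc
    elif scenario == "B":
        kwargs = {}
    elif scenario == "C":
        kwargs = {**vc, **thin}
    elif scenario == "D":
        kwargs = thin
    else:
        raise ValueError(f"unknown physiology scenario {scenario!r}")
    from dataclasses import replace

    return replace(base, **kwargs)


def ivpt_design() -> IVPTDesign:
    return IVPTDesign()


def dose_scenario(
    scenario: int,
    *,
    area_cm2: float = 50.0,
    n_applications: int = 2,
    wear_h: float = 12.0,
) -> list[DosingEvent]:
    """Twice-daily dosing schedule for one of the four dose scenarios."""
    if scenario not in DOSE_SCENARIOS:
        raise ValueError(f"unknown dose scenario {scenario}")
    sprays = DOSE_SCENARIOS[scenario]["sprays_per_cm2"] * area_cm2
    return [
        DosingEvent(
            start_h=i * wear_h,
            duration_h=wear_h,
            n_sprays=sprays,
            area_cm2=area_cm2,
        )
        for i in range(n_applications)
    ]


def default_dosing() -> list[DosingEvent]:
    """Default in vivo design: 1 spray/cm² on 50 cm², two 12-h applications."""
    return dose_scenario(3)
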