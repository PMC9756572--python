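"""In vitro–in vivo extrapolation: dermis perfusion uptake and systemic PK.

The calibrated skin model is reused with in vivo physiology restored: dermal
blood flow clears unbound drug from the dermis into a minimal two-compartment
systemic disposition model with first-order elimination from the central
compartment.  Vasoconstriction is represented as static scaling of the
capillary radius (flow scales with radius squared) and of the fraction of
perfused capillaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .formulation import Formulation, sprays_to_dose
from .skin import SkinPhysiology, SimulationResult, build_skin, simulate

__all__ = [
    "Compound",
    "SystemicModel",
    "DosingEvent",
    "InVivoResult",
    "apply_vasoconstriction",
    "run_in_vivo",
    "fraction_remaining",
    "load_compound",
    "load_dosing",
]


@dataclass(frozen=True)
class Compound:
    """Physicochemical and disposition parameters of the drug."""

    name: str = "desoximetasone"
    molecular_weight: float = 376.46  # g/mol
    log_p: float = 2.35
    water_solubility: float = 0.0421  # mg/ml
    blood_plasma_ratio: float = 0.76
    fu_plasma: float = 0.145
    clearance_iv: float = 16.95  # L/h
    density: float = 1.3  # g/ml, for the solute-radius estimate
    compound_type: str = "neutral"

    def __post_init__(self) -> None:
        for name in (
            "molecular_weight",
            "water_solubility",
            "blood_plasma_ratio",
            "fu_plasma",
            "clearance_iv",
            "density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fu_plasma > 1 or self.blood_plasma_ratio > 10:
            raise ValueError("implausible binding parameters")

    @property
    def molar_volume(self) -> float:
        """Solute molar volume, cm³/mol."""
        return self.molecular_weight / self.density


@dataclass(frozen=True)
class SystemicModel:
    """Two-compartment disposition; stands in for whole-body distribution."""

    central_volume: float = 120.0  # L
    peripheral_volume: float = 250.0  # L
    intercompartment_clearance: float = 20.0  # L/h
    clearance: float = 16.95  # L/h

    def __post_init__(self) -> None:
        for name in (
            "central_volume",
            "peripheral_volume",
            "intercompartment_clearance",
            "clearance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DosingEvent:
    """One application of formulation: wear from ``start_h`` for ``duration_h``."""

    start_h: float
    duration_h: float
    n_sprays: float
    area_cm2: float

    def __post_init__(self) -> None:
        if self.start_h < 0 or self.duration_h <= 0:
            raise ValueError("event times must be non-negative with duration > 0")
        if self.n_sprays < 0 or self.area_cm2 <= 0:
            raise ValueError("invalid dose")

    @property
    def end_h(self) -> float:
        return self.start_h + self.duration_h


def apply_vasoconstriction(
    physiology: SkinPhysiology, radius_scale: float, perfused_scale: float
) -> SkinPhysiology:
    """Scale capillary radius and perfused fraction (flow goes with radius²)."""
    if radius_scale <= 0 or perfused_scale <= 0:
        raise ValueError("scales must be positive")
    return replace(
        physiology,
        capillary_radius_scale=physiology.capillary_radius_scale * radius_scale,
        fraction_capillaries_perfused=(
            physiology.fraction_capillaries_perfused * perfused_scale
        ),
    )


@dataclass
class InVivoResult:
    """Amount and concentration traces for one simulated subject."""

    t: np.ndarray  # h
    amounts: np.ndarray  # mg, (n_compartments, n_times)
    names: list[str]
    removed: np.ndarray  # mg wiped off at end-of-wear, cumulative over time
    dose_api_total: float  # mg
    central_volume: float  # ml
    dermis_volume: float  # ml
    area: float  # cm²
    mass_balance_error: float

    def amount(self, name: str) -> np.ndarray:
        return self.amounts[self.names.index(name)]

    @property
    def plasma_concentration(self) -> np.ndarray:
        """mg/ml in the central compartment."""
        return self.amount("central") / self.central_volume

    @property
    def dermis_concentration(self) -> np.ndarray:
        """mg/ml in the dermis of the treated site."""
        return self.amount("dermis") / self.dermis_volume

    def to_frame(self, subject: str | int = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": subject,
                "time_h": np.concatenate([self.t, self.t]),
                "matrix": ["plasma"] * len(self.t) + ["dermis"] * len(self.t),
                "concentration_mg_ml": np.concatenate(
                    [self.plasma_concentration, self.dermis_concentration]
                ),
            }
        )


def run_in_vivo(
    physiology: SkinPhysiology,
    formulation: Formulation,
    dosing: Sequence[DosingEvent],
    systemic: SystemicModel,
    *,
    compound: Compound | None = None,
    t_end: float = 72.0,
    t_eval: Sequence[float] | None = None,
    per_spray_mass_mg: float = 2.4,
    method: str = "expm",
) -> InVivoResult:
    """Simulate plasma and dermis kinetics for a dosing schedule.

    Each event applies a fresh film over the same treated site; at the end of
    its wear period the residual formulation is wiped off (tracked in
    ``removed``) while drug already in the skin continues to absorb.
    Overlapping wear periods are rejected.
    """
    if compound is None:
        from .presets import desoximetasone

        compound = desoximetasone()
    if not dosing:
        raise ValueError("dosing schedule is empty")
    events = sorted(dosing, key=lambda e: e.start_h)
    for prev, nxt in zip(events[:-1], events[1:]):
        if nxt.start_h < prev.end_h - 1e-12:
            raise ValueError("overlapping application events")
    area = events[0].area_cm2
    if any(abs(e.area_cm2 - area) > 1e-12 for e in events):
        raise ValueError("all events must share the treated area")

    if t_eval is None:
        t_eval = np.arange(0.0, t_end + 1e-9, 0.25)
    t_eval = np.asarray(t_eval, dtype=float)

    # template system (defines ordering/volumes); dose fills in per event
    mass_mg, _ = sprays_to_dose(events[0].n_sprays, formulation, per_spray_mass_mg)
    base = build_skin(
        physiology,
        formulation,
        max(mass_mg, 1e-12),
        area,
        "in_vivo",
        compound=compound,
        systemic=systemic,
    )
    dim = len(base.names)
    x = np.zeros(dim)
    amounts = np.zeros((dim, len(t_eval)))
    removed_trace = np.zeros(len(t_eval))
    removed = 0.0
    dose_total = 0.0

    # breakpoints: event starts and ends, plus horizon
    marks = sorted({0.0, t_end} | {e.start_h for e in events} | {e.end_h for e in events})
    marks = [m for m in marks if m <= t_end + 1e-12]
    i_veh = 0

    def record(seg_result: SimulationResult, lo: float) -> None:
        sel = (t_eval >= lo - 1e-12) & (t_eval <= lo + seg_result.t[-1] + 1e-12)
        if not np.any(sel):
            return
        interp_t = t_eval[sel] - lo
        for i in range(dim):
            amounts[i, sel] = np.interp(interp_t, seg_result.t, seg_result.amounts[i])
        removed_trace[sel] = removed

    for lo, hi in zip(marks[:-1], marks[1:]):
        if hi - lo <= 1e-12:
            continue
        active = next(
            (e for e in events if e.start_h - 1e-12 <= lo < e.end_h - 1e-12), None
        )
        if active is not None and abs(lo - active.start_h) < 1e-12:
            mass_mg, _ = sprays_to_dose(
                active.n_sprays, formulation, per_spray_mass_mg
            )
            fresh = build_skin(
                physiology,
                formulation,
                mass_mg,
                area,
                "in_vivo",
                compound=compound,
                systemic=systemic,
            )
            x[i_veh] += fresh.dose_api
            dose_total += fresh.dose_api
            seg_system = fresh
        elif active is not None:
            seg_system = base  # wear continues (no mid-wear breakpoints by design)
        else:
            seg_system = base.wiped()
        seg_system = replace(seg_system, x0=x.copy())
        seg_system.names = list(base.names)
        local_eval = np.unique(
            np.concatenate(
                [[0.0], t_eval[(t_eval > lo) & (t_eval < hi)] - lo, [hi - lo]]
            )
        )
        res = simulate(seg_system, hi - lo, t_eval=local_eval, method=method)
        record(res, lo)
        x = res.amounts[:, -1].copy()
        ends_here = any(abs(hi - e.end_h) < 1e-12 for e in events)
        if ends_here:
            removed += x[i_veh]
            x[i_veh] = 0.0
        # write the state at the breakpoint itself
        at_hi = np.isclose(t_eval, hi)
        if np.any(at_hi):
            amounts[:, at_hi] = x[:, None]
            removed_trace[at_hi] = removed

    total = amounts.sum(axis=0) + removed_trace
    mbe = float(np.max(np.abs(total - _applied_by(t_eval, events, formulation,
                                                  per_spray_mass_mg))) /
                max(dose_total, 1e-300))
    return InVivoResult(
        t=t_eval,
        amounts=amounts,
        names=list(base.names),
        removed=removed_trace,
        dose_api_total=dose_total,
        central_volume=base.central_volume,
        dermis_volume=float(base.volumes[base.i_dermis]),
        area=area,
        mass_balance_error=mbe,
    )


def _applied_by(
    t_eval: np.ndarray,
    events: Sequence[DosingEvent],
    formulation: Formulation,
    per_spray_mass_mg: float,
) -> np.ndarray:
    """Cumulative dissolved API applied by each output time, mg."""
    out = np.zeros(len(t_eval))
    for e in events:
        mass_mg, _ = sprays_to_dose(e.n_sprays, formulation, per_spray_mass_mg)
        api = mass_mg * formulation.api_mass_fraction
        out[t_eval >= e.start_h - 1e-12] += api
    return out


def fraction_remaining(result: InVivoResult, t: float) -> float:
    """Fraction of the API applied so far that is still in the film at ``t``."""
    if t < result.t[0] - 1e-9 or t > result.t[-1] + 1e-9:
        raise ValueError(f"t={t} outside simulated range")
    vehicle = np.interp(t, result.t, result.amount("vehicle"))
    applied = np.interp(t, result.t, _cumulative_applied(result))
    if applied <= 0:
        return 1.0
    return float(min(max(vehicle / applied, 0.0), 1.0))


def _cumulative_applied(result: InVivoResult) -> np.ndarray:
    # reconstruct from totals: applied = in-system + removed
    return result.amounts.sum(axis=0) + result.removed


# ---------------------------------------------------------------------------
# I/O


def load_compound(path: str | Path) -> Compound:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Compound(**doc)


def load_dosing(path: str | Path) -> list[DosingEvent]:
    """Read a dosing schedule YAML: a list of event mappings."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    events = doc["events"] if isinstance(doc, dict) else doc
    return [DosingEvent(**e) for e in events]
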