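"""Franz-diffusion-cell (IVPT) simulation and two-stage calibration.

The measured quantities of an IVPT study are the cumulative amount of drug in
the receptor chamber per unit area over time and, at end of study, the drug
amounts recovered from the epidermis and dermis.  The first few
stratum-corneum layers are removed by tape stripping and discarded; the
remaining SC layers are counted together with the viable epidermis as "the
epidermis".

Calibration replaces the manual optimisation of the two unknown transport
parameters with a reproducible two-stage bounded search:

* stage 1 fits the SC-lipid:vehicle partition coefficient to the cumulative
  receptor profile (least squares on amounts);
* stage 2 fits the corneocyte permeability to the end-of-study epidermis and
  dermis amounts (least squares on log amounts), holding stage 1 fixed.

The stages are alternated a few times because both endpoints respond to both
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize_scalar

from .formulation import Formulation
from .skin import SkinPhysiology, SimulationResult, build_skin, simulate
from .systemic import Compound

__all__ = [
    "IVPTDesign",
    "IVPTResult",
    "CalibrationResult",
    "run_ivpt",
    "tape_strip_partition",
    "calibrate",
    "load_design",
    "read_observations",
]


@dataclass(frozen=True)
class IVPTDesign:
    """Franz-cell study design."""

    dose_volume: float = 5.0  # µL
    area: float = 0.5  # cm²
    receptor_volume: float = 8.0  # ml (bookkeeping only; receptor is a sink)
    duration: float = 24.0  # h
    sampling_times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
    n_discarded_tape_strips: int = 3
    temperature: float = 32.0  # °C

    def __post_init__(self) -> None:
        if self.dose_volume <= 0 or self.area <= 0 or self.duration <= 0:
            raise ValueError("dose volume, area and duration must be positive")
        times = tuple(float(t) for t in self.sampling_times)
        if list(times) != sorted(times):
            raise ValueError("sampling times must be sorted")
        if times and times[-1] > self.duration + 1e-9:
            raise ValueError("sampling times exceed study duration")
        if self.n_discarded_tape_strips < 0:
            raise ValueError("n_discarded_tape_strips must be >= 0")
        object.__setattr__(self, "sampling_times", times)


@dataclass
class IVPTResult:
    """Simulated IVPT endpoints."""

    times: np.ndarray  # h
    cumulative_receptor: np.ndarray  # µg/cm²
    epidermis_amount: float  # µg (post-strip SC remainder + viable epidermis)
    dermis_amount: float  # µg
    discarded_strip_amount: float  # µg
    dose_api: float  # µg applied (dissolved)
    trace: SimulationResult = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "cumulative_ug_cm2": self.cumulative_receptor}
        )


def run_ivpt(
    compound: Compound,
    formulation: Formulation,
    physiology: SkinPhysiology,
    design: IVPTDesign,
    *,
    method: str = "expm",
) -> IVPTResult:
    """Simulate one Franz cell and apply end-of-study tape-strip accounting."""
    dose_mass_mg = (
        design.dose_volume * 1e-3 * formulation.density * 1000.0
    )  # µL -> ml -> g -> mg
    system = build_skin(
        physiology,
        formulation,
        dose_mass_mg,
        design.area,
        "ivpt",
        compound=compound,
        temperature=design.temperature + 273.15,
    )
    t_eval = np.unique(
        np.concatenate(
            [np.asarray(design.sampling_times), np.linspace(0, design.duration, 97)]
        )
    )
    res = simulate(system, design.duration, t_eval=t_eval, method=method)
    sample_idx = np.searchsorted(res.t, design.sampling_times)
    receptor_ug = res.amount("receptor") * 1000.0
    cumulative = receptor_ug[sample_idx] / design.area
    discarded, epidermis = tape_strip_partition(res, design.n_discarded_tape_strips)
    dermis = res.amount("dermis")[-1] * 1000.0
    return IVPTResult(
        times=np.asarray(design.sampling_times, dtype=float),
        cumulative_receptor=cumulative,
        epidermis_amount=epidermis,
        dermis_amount=dermis,
        discarded_strip_amount=discarded,
        dose_api=system.dose_api * 1000.0,
        trace=res,
    )


def tape_strip_partition(
    trace: SimulationResult, n_strips: int
) -> tuple[float, float]:
    """Split end-of-study skin amounts by the tape-strip protocol.

    Returns ``(discarded, epidermis)`` in µg: the top ``n_strips`` SC layers
    are discarded; the remaining SC layers plus the viable epidermis make up
    the reported epidermis amount.
    """
    sc_names = [n for n in trace.names if n.startswith("sc_")]
    if n_strips > len(sc_names):
        raise ValueError(
            f"cannot discard {n_strips} strips from {len(sc_names)} SC layers"
        )
    discarded = sum(trace.amount(n)[-1] for n in sc_names[:n_strips])
    remaining = sum(trace.amount(n)[-1] for n in sc_names[n_strips:])
    epidermis = remaining + trace.amount("viable_epidermis")[-1]
    return discarded * 1000.0, epidermis * 1000.0


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    physiology: SkinPhysiology
    K_sclip_vehicle: float
    P_cell: float
    receptor_sse: float
    local_sse: float
    mean_abs_fold_error: float
    warnings: list[str] = field(default_factory=list)


def _mean_observed(
    receptor: pd.DataFrame, weights: Mapping[int, float] | None
) -> pd.DataFrame:
    df = receptor.copy()
    df["w"] = 1.0
    if weights:
        df["w"] = df["replicate"].map(lambda r: weights.get(r, 1.0))
    df = df[df["w"] > 0]
    grouped = df.groupby("time_h").apply(
        lambda g: np.average(g["cumulative_ug_cm2"], weights=g["w"]),
        include_groups=False,
    )
    return grouped.reset_index(name="cumulative_ug_cm2")


def calibrate(
    observed_receptor: pd.DataFrame,
    observed_local: pd.DataFrame,
    compound: Compound,
    formulation: Formulation,
    physiology: SkinPhysiology,
    design: IVPTDesign,
    *,
    bounds_K: tuple[float, float] = (1e-3, 1e2),
    bounds_P: tuple[float, float] = (1e-6, 1e1),
    replicate_weights: Mapping[int, float] | None = None,
    mask_times: Sequence[float] = (),
    n_cycles: int = 3,
    n_grid: int = 17,
) -> CalibrationResult:
    """Fit (K_sclip_vehicle, P_cell) to an observed IVPT dataset.

    ``observed_receptor`` has columns {replicate, time_h, cumulative_ug_cm2};
    ``observed_local`` has {replicate, compartment, amount_ug} with
    compartments ``epidermis`` and ``dermis``.  ``replicate_weights`` allows
    down-weighting or dropping (weight 0) divergent replicates, and
    ``mask_times`` excludes individual time points from the receptor
    objective.
    """
    if observed_receptor["time_h"].nunique() < 3:
        raise ValueError("need at least 3 receptor time points")
    mean_rec = _mean_observed(observed_receptor, replicate_weights)
    if mask_times:
        mask = ~mean_rec["time_h"].isin(list(mask_times))
        mean_rec = mean_rec[mask]
    obs_times = mean_rec["time_h"].to_numpy()
    obs_cum = mean_rec["cumulative_ug_cm2"].to_numpy()

    loc = observed_local.copy()
    if replicate_weights:
        loc["w"] = loc["replicate"].map(lambda r: replicate_weights.get(r, 1.0))
        loc = loc[loc["w"] > 0]
    obs_local = loc.groupby("compartment")["amount_ug"].mean()
    obs_epi = float(obs_local.get("epidermis", np.nan))
    obs_der = float(obs_local.get("dermis", np.nan))
    if not np.isfinite(obs_epi) or not np.isfinite(obs_der):
        raise ValueError("observed local amounts need epidermis and dermis rows")

    sim_design = replace(design, sampling_times=tuple(obs_times))

    def endpoints(k: float, p: float) -> tuple[np.ndarray, float, float]:
        phys = replace(physiology, K_sclip_vehicle=k, P_cell=p)
        res = run_ivpt(compound, formulation, phys, sim_design)
        return res.cumulative_receptor, res.epidermis_amount, res.dermis_amount

    def receptor_obj(log10_k: float, p: float) -> float:
        cum, _, _ = endpoints(10.0**log10_k, p)
        return float(np.sum((cum - obs_cum) ** 2))

    def local_obj(log10_p: float, k: float) -> float:
        _, epi, der = endpoints(k, 10.0**log10_p)
        eps = 1e-12
        return float(
            (np.log(epi + eps) - np.log(obs_epi + eps)) ** 2
            + (np.log(der + eps) - np.log(obs_der + eps)) ** 2
        )

    def fit_scalar(obj, bounds_log, center, half_width) -> tuple[float, float, bool]:
        # bounded refinement in a window around the current estimate; the
        # window keeps the alternating stages from running away when the
        # other parameter is off, the joint grid below sets the start point
        lo = max(bounds_log[0], center - half_width)
        hi = min(bounds_log[1], center + half_width)
        grid = np.linspace(lo, hi, n_grid)
        vals = [obj(g) for g in grid]
        i = int(np.argmin(vals))
        res = minimize_scalar(
            obj,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]),
            method="bounded",
            options={"xatol": 1e-6},
        )
        best, fun = (res.x, res.fun) if res.fun <= vals[i] else (grid[i], vals[i])
        at_bound = (
            abs(best - bounds_log[0]) < 1e-3 or abs(best - bounds_log[1]) < 1e-3
        )
        return float(best), float(fun), at_bound

    log_bk = (np.log10(bounds_K[0]), np.log10(bounds_K[1]))
    log_bp = (np.log10(bounds_P[0]), np.log10(bounds_P[1]))

    # joint coarse grid to initialise both parameters (cheap, avoids the
    # K/P compensation valley trapping the alternating stages)
    rec_scale = float(np.sum(obs_cum**2)) + 1e-300
    kk = np.linspace(*log_bk, 9)
    pp = np.linspace(*log_bp, 7)
    best_joint = (np.inf, kk[0], pp[0])
    for gk in kk:
        for gp in pp:
            j = receptor_obj(gk, 10.0**gp) / rec_scale + local_obj(gp, 10.0**gk)
            if j < best_joint[0]:
                best_joint = (j, gk, gp)
    log_k, log_p = best_joint[1], best_joint[2]
    k, p = 10.0**log_k, 10.0**log_p

    notes: list[str] = []
    sse_rec = sse_loc = np.inf
    half_width = 1.0  # decades around the current estimate
    for cycle in range(n_cycles):
        log_k, sse_rec, k_bound = fit_scalar(
            lambda g: receptor_obj(g, p), log_bk, log_k, half_width
        )
        k = 10.0**log_k
        log_p, sse_loc, p_bound = fit_scalar(
            lambda g: local_obj(g, k), log_bp, log_p, half_width
        )
        p = 10.0**log_p
        if k_bound:
            notes.append(f"cycle {cycle}: K_sclip_vehicle pinned at bound ({k:.3g})")
        if p_bound:
            notes.append(f"cycle {cycle}: P_cell pinned at bound ({p:.3g})")
        half_width = 0.5
    for note in notes:
        warnings.warn(note, stacklevel=2)

    fitted = replace(physiology, K_sclip_vehicle=k, P_cell=p)
    cum, epi, der = endpoints(k, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        positive = (obs_cum > 0) & (cum > 0)
        fold = np.exp(
            np.mean(np.abs(np.log(cum[positive] / obs_cum[positive])))
        ) if np.any(positive) else np.inf
    return CalibrationResult(
        physiology=fitted,
        K_sclip_vehicle=k,
        P_cell=p,
        receptor_sse=sse_rec,
        local_sse=sse_loc,
        mean_abs_fold_error=float(fold),
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# I/O


def load_design(path: str | Path) -> IVPTDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "sampling_times" in doc:
        doc["sampling_times"] = tuple(doc["sampling_times"])
    return IVPTDesign(**doc)


def read_observations(
    receptor_csv: str | Path, local_csv: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the observed-data CSV pair used by :func:`calibrate`."""
    receptor = pd.read_csv(receptor_csv)
    local = pd.read_csv(local_csv)
    need_r = {"replicate", "time_h", "cumulative_ug_cm2"}
    need_l = {"replicate", "compartment", "amount_ug"}
    if not need_r.issubset(receptor.columns):
        raise ValueError(f"receptor CSV needs columns {sorted(need_r)}")
    if not need_l.issubset(local.columns):
        raise ValueError(f"local CSV needs columns {sorted(need_l)}")
    return receptor, local
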