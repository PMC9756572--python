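"""Synthetic "observed" IVPT datasets and packaged configuration fixtures.

No redistributable IVPT observations exist for the worked example, so this
module generates replicate-level datasets with the statistical structure the
calibration assumes: a truth simulation from known transport parameters,
multiplicative lognormal noise applied to the *per-interval* receptor
increments (keeping every replicate's cumulative curve monotone), lognormal
noise on the end-of-study local amounts, and optionally one biased replicate
mimicking a divergent study that an analyst would exclude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .formulation import Formulation
from .ivpt import IVPTDesign, run_ivpt
from .skin import SkinPhysiology
from .systemic import Compound

__all__ = ["SynthSpec", "generate_ivpt_observations", "make_fixture_suite"]


@dataclass(frozen=True)
class SynthSpec:
    """Ground truth and noise model for a synthetic IVPT dataset."""

    K_sclip_vehicle: float = 0.35
    P_cell: float = 1.2e-3
    n_replicates: int = 5
    noise_cv_receptor: float = 0.25
    noise_cv_local: float = 0.40
    outlier_replicate: int | None = None
    outlier_bias: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv_receptor < 0 or self.noise_cv_local < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.outlier_replicate is not None and not (
            0 <= self.outlier_replicate < self.n_replicates
        ):
            raise ValueError("outlier_replicate out of range")


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def generate_ivpt_observations(
    spec: SynthSpec,
    design: IVPTDesign,
    formulation: Formulation,
    physiology: SkinPhysiology,
    compound: Compound | None = None,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate truth and emit noisy replicate-level observation tables.

    Returns ``(receptor, local)`` data frames in the dialect the calibration
    reads; if ``outdir`` is given they are also written as
    ``ivpt_receptor.csv`` and ``ivpt_local.csv``.
    """
    if compound is None:
        from .presets import desoximetasone

        compound = desoximetasone()
    truth_phys = replace(
        physiology, K_sclip_vehicle=spec.K_sclip_vehicle, P_cell=spec.P_cell
    )
    truth = run_ivpt(compound, formulation, truth_phys, design)
    rng = np.random.default_rng(spec.seed)

    increments = np.diff(np.concatenate([[0.0], truth.cumulative_receptor]))
    rec_rows = []
    loc_rows = []
    for rep in range(spec.n_replicates):
        bias = (
            spec.outlier_bias if rep == spec.outlier_replicate else 1.0
        )
        noisy_inc = increments * bias
        if spec.noise_cv_receptor > 0:
            noisy_inc = noisy_inc * rng.lognormal(
                0.0, _sigma(spec.noise_cv_receptor), len(increments)
            )
        cumulative = np.cumsum(noisy_inc)
        for t, v in zip(truth.times, cumulative):
            rec_rows.append(
                {"replicate": rep, "time_h": t, "cumulative_ug_cm2": v}
            )
        for compartment, amount in (
            ("epidermis", truth.epidermis_amount),
            ("dermis", truth.dermis_amount),
        ):
            v = amount * bias
            if spec.noise_cv_local > 0:
                v *= rng.lognormal(0.0, _sigma(spec.noise_cv_local))
            loc_rows.append(
                {"replicate": rep, "compartment": compartment, "amount_ug": v}
            )
    receptor = pd.DataFrame(rec_rows)
    local = pd.DataFrame(loc_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        receptor.to_csv(outdir / "ivpt_receptor.csv", index=False)
        local.to_csv(outdir / "ivpt_local.csv", index=False)
    return receptor, local


def make_fixture_suite(outdir: str | Path) -> dict[str, Path]:
    """Write the full set of YAML configs the pipeline consumes.

    Emits the compound file, the reference spray formulation with its Q3
    assumptions, the four physiology scenario presets, the four dosing
    scenarios, the default dosing schedule and the IVPT design.
    """
    from dataclasses import asdict

    from .presets import (
        DOSE_SCENARIOS,
        TOPICORT_COMPONENTS,
        desoximetasone,
        dose_scenario,
        ivpt_design,
        physiology_scenario,
        topicort_spray,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def dump(name: str, doc) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        written[name] = path

    dump("compound.yaml", asdict(desoximetasone()))

    ref = topicort_spray()
    dump(
        "topicort.yaml",
        {
            "components": [dict(d) for d in TOPICORT_COMPONENTS],
            "q3": {
                "viscosity_cP": ref.viscosity,
                "solubility_mg_ml": ref.api_solubility_cont_phase,
                "max_evaporated_pct_vv": round(
                    100.0 * ref.max_evaporated_fraction, 2
                ),
                "evaporation_rate_ml_h": ref.evaporation_rate,
                "molar_volume_cont_phase": ref.molar_volume_cont_phase,
            },
        },
    )

    for scen in "ABCD":
        dump(f"physiology_{scen.lower()}.yaml", asdict(physiology_scenario(scen)))

    design = ivpt_design()
    doc = asdict(design)
    doc["sampling_times"] = list(design.sampling_times)
    dump("ivpt_design.yaml", doc)

    for dose_id in DOSE_SCENARIOS:
        dump(
            f"dosing_scenario_{dose_id}.yaml",
            {"events": [asdict(e) for e in dose_scenario(dose_id)]},
        )
    dump("dosing_default.yaml", {"events": [asdict(e) for e in dose_scenario(3)]})
    return written
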