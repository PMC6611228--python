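"""Synthetic clonogenic-assay data with the structure the fitter assumes.

Each simulated well draws a Poisson colony count around

    E[colonies] = cells_plated * PE * exp(-(alpha D + beta D^2 + b_i)),

with a shared normal random intercept ``b_i`` per biological repeat
(replicate set) on the log-survival scale — exactly the data-generating
process of the mixed-effects fit, which makes parameter recovery a
well-posed end-to-end check.  Protracted exposures are built on top of the
dosimetry module: the dose ladder of a real stack experiment is the set of
cumulated doses over (activity, dish position) pairs.

Defaults mirror the laboratory design: triplicate wells in three biological
repeats, acute doses 0-10 Gy, 6-day Y-90 exposures at 10/15/20 MBq, several
thousand cells plated per well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .dosimetry import dish_dose_table

__all__ = ["SimulationSpec", "simulate_clonogenic", "simulate_y90_experiment"]


@dataclass(frozen=True)
class SimulationSpec:
    """Generating parameters of one synthetic clonogenic experiment."""

    alpha: float = 0.273  # Gy^-1
    beta: float = 0.0189  # Gy^-2
    plating_efficiency: float = 0.6
    doses: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)  # Gy
    wells_per_dose: int = 3
    replicate_sets: int = 3
    sigma_b: float = 0.1  # SD of the repeat-level log-survival intercept
    cells_plated: int = 4000
    seed: int = 0
    cell_line: str = "SIM"
    modality: str = "LINAC"

    def __post_init__(self) -> None:
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating efficiency must lie in (0, 1]")
        if self.wells_per_dose < 1 or self.replicate_sets < 1 or self.cells_plated < 1:
            raise ValueError("counts must be at least 1")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be non-negative")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")


def simulate_clonogenic(spec: SimulationSpec) -> pd.DataFrame:
    """Draw one synthetic experiment; fully reproducible from ``spec.seed``.

    Returns a survival-record frame (one row per well) including the 0 Gy
    control wells.  A control dose is prepended if the dose list lacks one,
    since the analysis normalises to controls.
    """
    rng = np.random.default_rng(spec.seed)
    doses = list(spec.doses)
    if 0.0 not in doses:
        doses = [0.0] + doses
    rows = []
    clipped = 0
    for i in range(spec.replicate_sets):
        b_i = rng.normal(0.0, spec.sigma_b) if spec.sigma_b > 0 else 0.0
        for dose in doses:
            log_kill = spec.alpha * dose + spec.beta * dose * dose + b_i
            expected = spec.cells_plated * spec.plating_efficiency * np.exp(-log_kill)
            if expected > spec.cells_plated:
                expected = float(spec.cells_plated)
                clipped += 1
            for j in range(spec.wells_per_dose):
                rows.append(
                    {
                        "cell_line": spec.cell_line,
                        "modality": spec.modality,
                        "dose_Gy": float(dose),
                        "colonies": int(rng.poisson(expected)),
                        "plated": int(spec.cells_plated),
                        "replicate_set": f"R{i + 1}",
                        "well": f"R{i + 1}-D{dose:g}-W{j + 1}",
                    }
                )
    if clipped:
        warnings.warn(
            f"{clipped} condition(s) had expected colonies above cells plated "
            "and were clipped; the generating spec is unphysical",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def simulate_y90_experiment(
    A0_list: Sequence[float],
    formulation: str,
    T: float = constants.EXPOSURE_6D_H,
    spec: SimulationSpec | None = None,
    evaporation_factor: float = constants.DEFAULT_EVAPORATION_FACTOR,
) -> pd.DataFrame:
    """Simulate a protracted stack experiment over activities x dish positions.

    The dose ladder is computed by the evaporation-corrected dosimetry for
    every (initial activity, dish position) pair; colony counts are then
    generated by :func:`simulate_clonogenic` at those cumulated doses, with
    one 0 Gy control arm.
    """
    spec = spec or SimulationSpec(modality="Y90")
    doses = {0.0}
    for a0 in A0_list:
        table = dish_dose_table(a0, formulation, T=T, evaporation_factor=evaporation_factor)
        doses.update(table.values())
    return simulate_clonogenic(
        replace(spec, doses=tuple(sorted(doses)), modality="Y90")
    )
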