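"""Cumulated dose and dose rate for cells irradiated by a decaying Y-90 source.

The source activity decays as ``A(t) = A0 * exp(-lambda * t)`` while the
S-value (absorbed dose rate per unit activity, MIRD formalism) drifts
linearly from ``S_initial`` to ``S_final`` over the exposure because medium
evaporation concentrates the source.  The cumulated dose is the closed form
of ``integral_0^T A0 exp(-lambda t) S(t) dt``:

    D(T) = (A0 / lambda) * [ (S_final - S_initial) / (lambda T)
                             * (1 - (1 + lambda T) exp(-lambda T))
                             + S_initial * (1 - exp(-lambda T)) ]

Internal canonical units are hours, MBq and Gy.  S-values are accepted in
the conventional cGy MBq^-1 d^-1 of monolayer dosimetry tables and converted
at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants

__all__ = [
    "DecayParams",
    "SValuePair",
    "ExposureConfig",
    "s_value_at",
    "cumulated_dose",
    "dose_rate",
    "dish_dose_table",
]

#: cGy MBq^-1 d^-1  ->  Gy MBq^-1 h^-1
_S_UNIT = 1.0 / (100.0 * 24.0)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class DecayParams:
    """Physical decay of the radionuclide.

    The decay constant is always derived from the half-life, never stored
    separately, so the two cannot drift apart.
    """

    T_phys: float = constants.T_PHYS_Y90_H  # hours

    def __post_init__(self) -> None:
        if not self.T_phys > 0:
            raise ValueError(f"T_phys must be positive, got {self.T_phys}")

    @property
    def lambda_phys(self) -> float:
        """Decay constant, per hour."""
        return LN2 / self.T_phys


@dataclass(frozen=True)
class SValuePair:
    """S-values at the start and end of the exposure, cGy MBq^-1 d^-1."""

    S_initial: float
    S_final: float
    dish_position: str = ""
    formulation: str = ""

    def __post_init__(self) -> None:
        if self.S_initial < 0 or self.S_final < 0:
            raise ValueError("S-values must be non-negative")


@dataclass(frozen=True)
class ExposureConfig:
    """One protracted irradiation scenario."""

    A0: float  # initial activity, MBq
    svalues: SValuePair
    T: float  # exposure duration, hours
    decay: DecayParams = field(default_factory=DecayParams)

    def __post_init__(self) -> None:
        if self.A0 < 0:
            raise ValueError("initial activity must be non-negative")
        if self.T < 0:
            raise ValueError("exposure duration must be non-negative")


def s_value_at(svalues: SValuePair, t: float, T: float) -> float:
    """Linearly interpolated S-value at time ``t`` of a ``T``-hour exposure.

    Returns cGy MBq^-1 d^-1.  ``T == 0`` returns ``S_initial``.
    """
    if T == 0:
        return svalues.S_initial
    if not 0 <= t <= T:
        raise ValueError(f"t={t} outside exposure window [0, {T}]")
    return svalues.S_initial + (svalues.S_final - svalues.S_initial) * t / T


def _protraction_shape(x: float) -> float:
    # (1 - (1 + x) e^{-x}) / x, series for small x to avoid cancellation
    if x < 1e-6:
        return x / 2.0 - x * x / 3.0 + x ** 3 / 8.0
    return (1.0 - (1.0 + x) * math.exp(-x)) / x


def cumulated_dose(cfg: ExposureConfig) -> float:
    """Dose in Gy absorbed over the full exposure, evaporation-corrected.

    Equals ``integral_0^T A0 exp(-lambda t) S(t) dt`` with the linearly
    interpolated S-value; with ``S_final == S_initial`` it reduces exactly to
    the constant-S MIRD formula ``(A0 S / lambda)(1 - exp(-lambda T))``.
    """
    if cfg.T == 0:
        return 0.0
    lam = cfg.decay.lambda_phys
    x = lam * cfg.T
    s_i = cfg.svalues.S_initial * _S_UNIT
    s_f = cfg.svalues.S_final * _S_UNIT
    return (cfg.A0 / lam) * ((s_f - s_i) * _protraction_shape(x) - s_i * math.expm1(-x))


def dose_rate(cfg: ExposureConfig, t: float) -> float:
    """Instantaneous dose rate at time ``t`` (hours), in Gy min^-1."""
    if not 0 <= t <= cfg.T:
        raise ValueError(f"t={t} outside exposure window [0, {cfg.T}]")
    s_t = s_value_at(cfg.svalues, t, cfg.T) * _S_UNIT  # Gy/MBq/h
    lam = cfg.decay.lambda_phys
    return cfg.A0 * math.exp(-lam * t) * s_t / 60.0


def dish_dose_table(
    A0: float,
    formulation: str,
    T: float = constants.EXPOSURE_6D_H,
    evaporation_factor: float = constants.DEFAULT_EVAPORATION_FACTOR,
    decay: DecayParams | None = None,
) -> dict[str, float]:
    """Cumulated dose (Gy) at every dish position of the irradiation stack.

    ``S_final`` is modelled as ``evaporation_factor * S_initial`` because
    end-of-exposure S-values are dish-specific measurements that are not
    tabulated; the factor is configurable per run.
    """
    if formulation not in constants.S_INITIAL_CGY_PER_MBQ_DAY:
        raise KeyError(
            f"unknown formulation {formulation!r}; expected one of "
            f"{constants.FORMULATIONS}"
        )
    if evaporation_factor < 0:
        raise ValueError("evaporation_factor must be non-negative")
    decay = decay or DecayParams()
    table: dict[str, float] = {}
    for position, s_init in constants.S_INITIAL_CGY_PER_MBQ_DAY[formulation].items():
        pair = SValuePair(
            S_initial=s_init,
            S_final=evaporation_factor * s_init,
            dish_position=position,
            formulation=formulation,
        )
        table[position] = cumulated_dose(ExposureConfig(A0=A0, svalues=pair, T=T, decay=decay))
    return table
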