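"""Packaged physical and experimental constants.

Physics of the radionuclide, Monte-Carlo derived monolayer S-values for the
dish-stack irradiation geometry, and published linear-quadratic fit parameters
for the two colorectal cancer cell lines (DLD-1, HT-29) studied with this
apparatus.  These constants are inputs to the equivalence calculators; they
are not recomputed by this package.
"""

from __future__ import annotations

#: Physical half-life of Y-90, hours.
T_PHYS_Y90_H: float = 64.1

#: Duration of the standard protracted exposure (6 days), hours.
EXPOSURE_6D_H: float = 144.0

#: Dish positions in the irradiation stack, relative to the source dish.
DISH_POSITIONS: tuple[str, ...] = ("+2", "+1", "-1", "-2")

#: Supported Y-90 formulations.
FORMULATIONS: tuple[str, ...] = ("YCl3", "DOTATATE")

#: S-values at the start of exposure, cGy MBq^-1 d^-1, for a 15 um cell
#: monolayer at each dish position.  The source non-uniformity of each
#: formulation (free ion vs chelated) is already folded into these numbers.
S_INITIAL_CGY_PER_MBQ_DAY: dict[str, dict[str, float]] = {
    "YCl3": {"+2": 6.26, "+1": 37.9, "-1": 31.4, "-2": 3.01},
    "DOTATATE": {"+2": 8.40, "+1": 47.3, "-1": 24.3, "-2": 2.06},
}

#: Default ratio S_final / S_initial.  Medium evaporation over the 6 d
#: exposure (up to a third of the volume) concentrates the source and raises
#: the S-value; 1.2 is a representative mid-range correction.
DEFAULT_EVAPORATION_FACTOR: float = 1.2

#: Fitted linear-quadratic parameters (alpha in Gy^-1, beta in Gy^-2) per
#: (cell line, modality), from the clonogenic survival fits.
LQ_FITTED: dict[tuple[str, str], tuple[float, float]] = {
    ("DLD-1", "LINAC"): (0.273, 0.0189),
    ("DLD-1", "Cs137"): (0.264, 0.0153),
    ("DLD-1", "Y90"): (0.106, 0.00109),
    ("HT-29", "LINAC"): (0.050, 0.0276),
    ("HT-29", "Cs137"): (0.056, 0.0367),
    ("HT-29", "Y90"): (0.090, 0.000141),
}

#: Linear-only refits of the Y-90 curves (beta fixed at zero), alpha in Gy^-1.
LQ_FITTED_ALPHA_ONLY: dict[tuple[str, str], float] = {
    ("DLD-1", "Y90"): 0.129,
    ("HT-29", "Y90"): 0.0897,
}

#: Published protraction-modelling parameters per cell line, for comparison
#: reports: RBE_max, G over the 6 d exposure, repair half-time (h), G for a
#: fully decayed source.
PUBLISHED_MODELLING: dict[str, dict[str, float]] = {
    "DLD-1": {"rbe_max": 0.388, "g6": 0.0577, "t_rep_h": 2.51, "g_inf": 0.0377},
    "HT-29": {"rbe_max": 1.800, "g6": 0.0051, "t_rep_h": 0.21, "g_inf": 0.0033},
}

#: Published equivalent EBRT doses at a 60 Gy Y-90 absorbed dose.  The EQD10
#: values are stored as an unordered pair: the published per-line assignment
#: is inconsistent with direct evaluation of the equivalence formula, so only
#: the pair itself is comparable.
PUBLISHED_EQD2_60GY: dict[str, float] = {"DLD-1": 28.7, "HT-29": 54.5}
PUBLISHED_EQD10_60GY_PAIR: tuple[float, float] = (17.6, 19.3)
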