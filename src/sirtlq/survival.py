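"""Clonogenic survival and mixed-effects linear-quadratic fitting.

Colony counts are converted to surviving fractions (SF) by normalising to
the plating efficiency of the unirradiated control wells of the same
biological repeat, and the linear-quadratic model

    -ln(SF) = alpha * D + beta * D^2 + b_i + eps,    b_i ~ N(0, sigma_b^2)

is fitted by restricted maximum likelihood (REML) with a random intercept
``b_i`` per replicate set and no fixed intercept (SF(0) = 1 for the
population curve).  The REML criterion is profiled analytically down to a
one-dimensional search over the variance ratio ``gamma = sigma_b^2 /
sigma_e^2``, which is deterministic and cheap; the grouped structure lets
every quantity be computed from per-group sums (Woodbury identity).

Inference on the fitted coefficients uses Wald statistics, and the
alpha/beta ratio gets a delta-method standard error:

    SE(a/b)^2 = var(a)/b^2 - 2 a cov(a,b)/b^3 + a^2 var(b)/b^4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "SurvivalRecord",
    "LQFit",
    "RatioEstimate",
    "surviving_fraction",
    "survival_table",
    "fit_lqm",
    "alpha_beta_ratio",
    "wald_test",
]

#: Canonical column order of the tabular survival-record interchange format.
RECORD_COLUMNS = [
    "cell_line",
    "modality",
    "dose_Gy",
    "colonies",
    "plated",
    "replicate_set",
    "well",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One well of a clonogenic assay."""

    cell_line: str
    modality: str
    dose: float  # Gy
    colonies: float
    plated: float
    replicate_set: str
    well: str

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError("colony count must be non-negative")
        if self.plated <= 0:
            raise ValueError("plated cell count must be positive")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class LQFit:
    """Fitted linear-quadratic parameters with covariance and variance parts."""

    alpha: float  # Gy^-1
    beta: float  # Gy^-2
    var_alpha: float
    var_beta: float
    cov_alpha_beta: float
    sigma_b: float  # SD of the replicate-set random intercept
    sigma_e: float  # residual SD on the -ln(SF) scale
    n_obs: int
    alpha_only: bool = False
    n_excluded: int = 0
    excluded: tuple = field(default=())

    @property
    def se_alpha(self) -> float:
        return math.sqrt(self.var_alpha)

    @property
    def se_beta(self) -> float:
        return math.sqrt(self.var_beta)

    def predict_sf(self, dose) -> np.ndarray:
        """Population surviving fraction at the given dose(s)."""
        d = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d * d))

    def to_dict(self) -> dict:
        out = {
            "alpha": self.alpha,
            "beta": self.beta,
            "var_alpha": self.var_alpha,
            "var_beta": self.var_beta,
            "cov_alpha_beta": self.cov_alpha_beta,
            "se_alpha": self.se_alpha,
            "se_beta": self.se_beta,
            "sigma_b": self.sigma_b,
            "sigma_e": self.sigma_e,
            "n_obs": self.n_obs,
            "alpha_only": self.alpha_only,
            "n_excluded": self.n_excluded,
            "wald_p_alpha": wald_test(self.alpha, self.se_alpha),
        }
        out["wald_p_beta"] = (
            None if self.alpha_only else wald_test(self.beta, self.se_beta)
        )
        return out


@dataclass(frozen=True)
class RatioEstimate:
    """alpha/beta with delta-method standard error and normal 95% CI."""

    value: float  # Gy
    se: float
    ci_low: float
    ci_high: float


def surviving_fraction(
    record: SurvivalRecord, plating_efficiency: float
) -> tuple[float, bool]:
    """Surviving fraction of one well: (colonies/plated)/PE.

    Returns ``(sf, flagged)``; a zero-colony well yields SF 0 and is flagged
    because it cannot enter a log-scale fit.
    """
    if not 0 < plating_efficiency <= 1:
        raise ValueError("plating efficiency must lie in (0, 1]")
    if record.colonies == 0:
        return 0.0, True
    return (record.colonies / record.plated) / plating_efficiency, False


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "cell_line": r.cell_line,
                    "modality": r.modality,
                    "dose_Gy": r.dose,
                    "colonies": r.colonies,
                    "plated": r.plated,
                    "replicate_set": r.replicate_set,
                    "well": r.well,
                }
                for r in records
            ]
        )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival records lack columns: {sorted(missing)}")
    return df


def survival_table(
    records: Iterable[SurvivalRecord] | pd.DataFrame,
    plating_efficiency: float | None = None,
) -> pd.DataFrame:
    """Attach plating efficiency and surviving fraction to every record.

    By default the plating efficiency of each replicate set is estimated
    from its own 0 Gy control wells (pooled colonies / pooled plated), so
    control SF averages to one by construction; a fixed global efficiency
    may be supplied instead.
    """
    df = _as_frame(records)
    if plating_efficiency is not None:
        if not 0 < plating_efficiency <= 1:
            raise ValueError("plating efficiency must lie in (0, 1]")
        df["plating_efficiency"] = plating_efficiency
    else:
        controls = df[df["dose_Gy"] == 0]
        if controls.empty:
            raise ValueError(
                "no 0 Gy control wells; supply plating_efficiency explicitly"
            )
        pe = (
            controls.groupby("replicate_set")
            .apply(
                lambda g: g["colonies"].sum() / g["plated"].sum(),
                include_groups=False,
            )
            .rename("plating_efficiency")
        )
        df = df.merge(pe, on="replicate_set", how="left")
        if df["plating_efficiency"].isna().any():
            bad = df.loc[df["plating_efficiency"].isna(), "replicate_set"].unique()
            raise ValueError(f"replicate sets without control wells: {list(bad)}")
    df["sf"] = (df["colonies"] / df["plated"]) / df["plating_efficiency"]
    df["flagged"] = df["colonies"] == 0
    return df


def _profiled_reml(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray):
    """REML fit of y = X b + Z u + e with one random intercept per group.

    Profiles coefficients and sigma_e^2 out analytically and searches the
    variance ratio gamma = sigma_b^2/sigma_e^2 on a log grid plus bounded
    scalar minimisation; flat likelihoods resolve toward gamma = 0.
    Returns (coef, cov, sigma_b, sigma_e).
    """
    n, p = X.shape
    groups = np.unique(group_idx)
    n_i = np.array([(group_idx == g).sum() for g in groups], dtype=float)
    # per-group sums of X columns and y
    Sx = np.vstack([X[group_idx == g].sum(axis=0) for g in groups])  # (q, p)
    Sy = np.array([y[group_idx == g].sum() for g in groups])
    XtX = X.T @ X
    Xty = X.T @ y

    def crit_and_fit(gamma: float):
        c = gamma / (1.0 + gamma * n_i)  # per-group Woodbury weight
        A = XtX - (Sx.T * c) @ Sx  # X' V0^-1 X
        b = Xty - Sx.T @ (c * Sy)  # X' V0^-1 y
        coef = np.linalg.solve(A, b)
        r = y - X @ coef
        Sr = np.array([r[group_idx == g].sum() for g in groups])
        quad = r @ r - (c * Sr) @ Sr  # r' V0^-1 r
        sigma2 = quad / (n - p)
        crit = (
            (n - p) * math.log(sigma2)
            + np.log1p(gamma * n_i).sum()
            + math.log(abs(np.linalg.det(A)))
        )
        return crit, coef, A, sigma2

    # coarse log-grid bracket, then refine; include the gamma = 0 boundary
    grid = np.concatenate([[0.0], np.logspace(-6, 6, 49)])
    crits = np.array([crit_and_fit(g)[0] for g in grid])
    k = int(np.argmin(crits))
    if k == 0:
        gamma_hat = 0.0
    else:
        lo = grid[max(k - 1, 1)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda lg: crit_and_fit(math.exp(lg))[0],
            bounds=(math.log(lo), math.log(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        gamma_hat = math.exp(res.x)
        # prefer the no-heterogeneity boundary on effective ties
        if crits[0] <= crit_and_fit(gamma_hat)[0] + 1e-9:
            gamma_hat = 0.0
    _, coef, A, sigma2 = crit_and_fit(gamma_hat)
    cov = sigma2 * np.linalg.inv(A)
    return coef, cov, math.sqrt(gamma_hat * sigma2), math.sqrt(sigma2)


def fit_lqm(
    records: Iterable[SurvivalRecord] | pd.DataFrame,
    alpha_only: bool = False,
    plating_efficiency: float | None = None,
) -> LQFit:
    """Fit -ln(SF) = alpha D + beta D^2 with a replicate-set random intercept.

    Control (0 Gy) wells define the plating efficiency of their replicate
    set; irradiated wells carry the fit.  Wells with non-positive SF are
    excluded with a warning (the log transform is undefined there).  With a
    single replicate set the random intercept is inestimable and the fit
    degrades to fixed-effects least squares through the origin.
    """
    df = survival_table(records, plating_efficiency=plating_efficiency)
    fit_df = df[df["dose_Gy"] > 0]
    if fit_df.empty:
        raise ValueError("all doses are zero: linear-quadratic design is singular")
    bad = fit_df[(fit_df["sf"] <= 0) | ~np.isfinite(fit_df["sf"])]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} well(s) with non-positive surviving fraction "
            "from the log-scale fit",
            stacklevel=2,
        )
        fit_df = fit_df.drop(bad.index)
    n_distinct = fit_df["dose_Gy"].nunique()
    if n_distinct < (1 if alpha_only else 2):
        raise ValueError(
            f"{n_distinct} distinct positive dose(s): design is singular"
        )

    d = fit_df["dose_Gy"].to_numpy(dtype=float)
    y = -np.log(fit_df["sf"].to_numpy(dtype=float))
    X = d[:, None] if alpha_only else np.column_stack([d, d * d])
    groups, group_idx = np.unique(fit_df["replicate_set"], return_inverse=True)

    if len(groups) < 2:
        warnings.warn(
            "single replicate set: random intercept inestimable, "
            "falling back to fixed-effects least squares",
            stacklevel=2,
        )
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        sigma_b, sigma_e = 0.0, math.sqrt(sigma2)
    else:
        coef, cov, sigma_b, sigma_e = _profiled_reml(y, X, group_idx)

    alpha = float(coef[0])
    beta = 0.0 if alpha_only else float(coef[1])
    var_alpha = float(cov[0, 0])
    var_beta = 0.0 if alpha_only else float(cov[1, 1])
    cov_ab = 0.0 if alpha_only else float(cov[0, 1])
    return LQFit(
        alpha=alpha,
        beta=beta,
        var_alpha=var_alpha,
        var_beta=var_beta,
        cov_alpha_beta=cov_ab,
        sigma_b=sigma_b,
        sigma_e=sigma_e,
        n_obs=len(y),
        alpha_only=alpha_only,
        n_excluded=len(bad),
        excluded=tuple(bad["well"].astype(str)),
    )


def alpha_beta_ratio(fit: LQFit, z: float = 1.96) -> RatioEstimate:
    """alpha/beta in Gy with delta-method SE and normal-approximation CI."""
    if fit.alpha_only or fit.beta == 0:
        raise ValueError("alpha/beta undefined: beta is zero (alpha-only fit)")
    a, b = fit.alpha, fit.beta
    value = a / b
    var = (
        fit.var_alpha / b ** 2
        - 2.0 * a * fit.cov_alpha_beta / b ** 3
        + a ** 2 * fit.var_beta / b ** 4
    )
    se = math.sqrt(max(var, 0.0))
    return RatioEstimate(value=value, se=se, ci_low=value - z * se, ci_high=value + z * se)


def wald_test(estimate: float, se: float) -> float:
    """Two-sided p-value for H0: parameter = 0, normal reference."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        return 1.0 if estimate == 0 else 0.0
    return 2.0 * float(norm.sf(abs(estimate) / se))
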