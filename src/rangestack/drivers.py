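"""Quasi-Poisson GLM driver attribution and collinearity screening.

Richness counts per grid cell are related to the predictor stack with a
log-link Poisson GLM whose dispersion is estimated freely (quasi-Poisson):
the point estimates are the Poisson maximum-likelihood estimates, and the
standard errors are inflated by the square root of the Pearson dispersion
phi = X^2/(n-p), so overdispersed counts do not overstate significance.

Model quality is summarised by explained deviance D2 = 1 - residual/null
deviance (the GLM analogue of R^2) and its adjusted form
D2_adj = 1 - ((n-1)/(n-p)) (1-D2).  AIC under quasi-likelihood is formally
undefined; the AIC reported here is that of the Poisson likelihood at the
(identical) parameter estimates, which is what applied tables alongside
quasi-Poisson fits conventionally show.

Collinearity among predictors is screened with variance inflation factors
(VIF) and an iterative procedure that drops the worst offender until all
VIFs fall below a threshold (default 10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geodata import DRIVER_TABLE_COLUMNS
from .predictors import PREDICTOR_NAMES, PredictorStack
from .richness import RichnessMap

logger = logging.getLogger("rangestack")

FORMS = ("linear", "quadratic")


class RankDeficiencyError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class DriverConfig:
    """Knobs of the driver analysis."""

    standardize: bool = True
    vif_threshold: float = 10.0
    subsample_fraction: float = 1.0
    seed: int = 0


@dataclass
class GLMFit:
    """One fitted quasi-Poisson GLM."""

    coefficients: np.ndarray  # intercept first
    se: np.ndarray  # quasi-Poisson (dispersion-inflated) standard errors
    z_values: np.ndarray
    dispersion: float
    null_deviance: float
    residual_deviance: float
    n: int
    p: int
    aic: float

    @property
    def d2(self) -> float:
        if abs(self.null_deviance) < 1e-10:
            raise ValueError("degenerate response: null deviance is zero")
        return 1.0 - self.residual_deviance / self.null_deviance

    @property
    def d2_adjusted(self) -> float:
        return 1.0 - ((self.n - 1) / (self.n - self.p)) * (1.0 - self.d2)


def p_stars(z: float) -> str:
    """Two-sided normal-tail significance stars (0.05 / 0.01 / 0.001)."""
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _check_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be 1-D")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("response must be non-negative integer counts")
    return y


def _design(x: np.ndarray, form: str) -> np.ndarray:
    """Intercept + x (linear) or intercept + x + x^2 per column (quadratic)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if form == "linear":
        cols = [x]
    elif form == "quadratic":
        cols = [np.column_stack([x[:, j], x[:, j] ** 2]) for j in range(x.shape[1])]
    else:
        raise ValueError(f"unknown form {form!r}")
    return np.column_stack([np.ones(len(x))] + cols)


def fit_glm(y: np.ndarray, X: np.ndarray, maxiter: int = 100, tol: float = 1e-8) -> GLMFit:
    """Fit a quasi-Poisson GLM (log link) on an explicit design matrix.

    Estimation is iteratively reweighted least squares on the Poisson
    likelihood; the quasi-Poisson part enters only through the Pearson
    dispersion that scales the standard errors.
    """
    y = _check_response(y)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol, scale=1.0)
    if not getattr(res, "converged", True):
        # statsmodels stops on absolute deviance change; judge convergence
        # on parameter stability (max |delta beta| < tol) instead
        step = model.fit(start_params=res.params, maxiter=1, tol=0.0, scale=1.0)
        dbeta = float(np.max(np.abs(step.params - res.params)))
        if dbeta >= tol:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations "
                f"(max |delta beta| = {dbeta:.3g}, deviance trace tail: "
                f"{res.fit_history['deviance'][-3:]})"
            )
        res = step
    phi = float(res.pearson_chi2) / (n - p)
    se = np.asarray(res.bse) * math.sqrt(phi)
    return GLMFit(
        coefficients=np.asarray(res.params),
        se=se,
        z_values=np.asarray(res.params) / se,
        dispersion=phi,
        null_deviance=float(res.null_deviance),
        residual_deviance=float(res.deviance),
        n=n,
        p=p,
        aic=float(res.aic),
    )


def fit_quasipoisson(
    y: np.ndarray,
    x: np.ndarray,
    form: str = "linear",
    standardize: bool = False,
) -> GLMFit:
    """Fit richness counts against one predictor (or a predictor matrix).

    ``form="quadratic"`` adds a squared term for every predictor column.
    With ``standardize`` the predictors are z-scored before the design is
    built (squares are of the standardized variable).
    """
    x = np.asarray(x, dtype=float)
    if standardize:
        x = zscore_columns(x)
    return fit_glm(y, _design(x, form))


def zscore_columns(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant column")
    out = (x - x.mean(axis=0)) / sd
    return out[:, 0] if one_d else out


def explained_deviance(fit: GLMFit) -> tuple[float, float]:
    """(D2, adjusted D2) of a converged fit."""
    return fit.d2, fit.d2_adjusted


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

def vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column of ``X``.

    VIF_j = 1/(1-R^2_j) from the OLS regression of column j on all other
    columns plus an intercept.  Perfectly collinear columns get inf.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns for VIF")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("VIF undefined for constant columns")
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class VIFReport:
    """Outcome of iterative VIF screening."""

    vifs: dict[str, float]  # final VIFs of retained predictors
    removal_sequence: list[str]
    retained: list[str]
    threshold: float

    def write_csv(self, path: str | Path) -> None:
        rows = [
            {"predictor": name, "vif": v, "status": "retained"}
            for name, v in self.vifs.items()
        ] + [
            {"predictor": name, "vif": np.nan, "status": f"removed (step {i+1})"}
            for i, name in enumerate(self.removal_sequence)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def vifstep(
    X: np.ndarray,
    threshold: float = 10.0,
    names: Sequence[str] | None = None,
) -> VIFReport:
    """Iteratively drop the predictor with the largest VIF above threshold.

    Mirrors the usual stepwise screen: recompute VIFs after each removal
    until all remaining values are at or below the threshold.
    """
    X = np.asarray(X, dtype=float)
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("names length must match number of columns")
    keep = list(range(X.shape[1]))
    removed: list[str] = []
    while len(keep) > 1:
        vals = vif(X[:, keep])
        worst = int(np.argmax(vals))
        if vals[worst] <= threshold:
            break
        removed.append(names[keep[worst]])
        logger.info("vifstep: removing %s (VIF=%.3g)", removed[-1], vals[worst])
        keep.pop(worst)
    final = vif(X[:, keep]) if len(keep) > 1 else np.array([1.0] * len(keep))
    return VIFReport(
        vifs={names[k]: float(v) for k, v in zip(keep, final)},
        removal_sequence=removed,
        retained=[names[k] for k in keep],
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Driver table
# ---------------------------------------------------------------------------

@dataclass
class DriverTable:
    """Per-predictor and full-model GLM results for each activity group."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=DRIVER_TABLE_COLUMNS)

    def top_predictor(self, group: str, form: str) -> str | None:
        """Single predictor with the highest D2 for a group/form."""
        best, best_d2 = None, -np.inf
        for row in self.rows:
            if (
                row["group"] == group
                and row["form"] == form
                and row["predictor"] != "full"
                and not row["failed"]
                and row["D2"] > best_d2
            ):
                best, best_d2 = row["predictor"], row["D2"]
        return best


def _fit_row(group: str, predictor: str, form: str, y, x) -> dict:
    row = {
        "group": group, "predictor": predictor, "form": form,
        "slope": np.nan, "slope_linear_term": np.nan, "z_value": np.nan,
        "p_stars": "", "AIC": np.nan, "D2": np.nan, "D2_adjusted": np.nan,
        "top_d2": False, "failed": False,
    }
    try:
        fit = fit_glm(y, _design(x, form))
    except (RankDeficiencyError, ConvergenceError, ValueError) as exc:
        logger.warning("fit failed for %s/%s/%s: %s", group, predictor, form, exc)
        row["failed"] = True
        return row
    d2, d2a = explained_deviance(fit)
    row.update(AIC=fit.aic, D2=d2, D2_adjusted=d2a)
    if predictor != "full" and np.ndim(x) == 1:
        if form == "linear":
            slope, se = fit.coefficients[1], fit.se[1]
            row.update(slope=slope, z_value=fit.z_values[1])
        else:  # quadratic: report the x^2 coefficient, emit the x one too
            slope = fit.coefficients[2]
            row.update(
                slope=slope,
                slope_linear_term=fit.coefficients[1],
                z_value=fit.z_values[2],
            )
        row["p_stars"] = p_stars(row["z_value"])
    return row


def build_driver_table(
    richness: Mapping[str, RichnessMap],
    stack: PredictorStack,
    config: DriverConfig | None = None,
) -> DriverTable:
    """Fit every (group, predictor, form) model plus the full models.

    The sampling unit is the raster cell: cells valid in every predictor
    layer and inside the richness mask enter the fits.  Per group and
    form, the single-predictor row with the highest explained deviance is
    flagged ``top_d2`` (the headline "most important variable").
    """
    config = config or DriverConfig()
    mask = stack.validity_mask()
    table = DriverTable()
    for group, rmap in richness.items():
        if not rmap.raster.aligned_with(stack.grid):
            raise ValueError(f"richness map '{group}' not aligned with stack")
        cells = mask & rmap.raster.valid_mask()
        n = int(cells.sum())
        if n < 2:
            raise ValueError(f"group '{group}': fewer than 2 valid cells")
        y = rmap.raster.values[cells].astype(float)
        X = stack.to_matrix(cells)
        if config.subsample_fraction < 1.0:
            rng = np.random.default_rng(config.seed)
            take = rng.random(n) < config.subsample_fraction
            y, X = y[take], X[take]
        if config.standardize:
            X = zscore_columns(X)
        logger.info("driver fits for group '%s' on %d cells", group, len(y))
        for form in FORMS:
            for j, name in enumerate(PREDICTOR_NAMES):
                table.rows.append(_fit_row(group, name, form, y, X[:, j]))
            table.rows.append(_fit_row(group, "full", form, y, X))
            top = None
            best = -np.inf
            for row in table.rows:
                if (
                    row["group"] == group and row["form"] == form
                    and row["predictor"] != "full" and not row["failed"]
                    and row["D2"] > best
                ):
                    top, best = row, row["D2"]
            if top is not None:
                top["top_d2"] = True
    return table
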