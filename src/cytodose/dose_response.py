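"""Dose-response model families and maximum-likelihood fitting.

Aberration yields in the 0–1 Gy range are modelled per endpoint:

* ``LINEAR``          Y(D) = c + alpha*D
* ``LQ``              Y(D) = c + alpha*D + beta*D^2  (the standard
  linear-quadratic yield curve of radiation cytogenetics)
* ``EXP_SATURATION``  F(D) = f_max - (f_max - c)*exp(-k*D), a saturating
  fraction anchored at the background c with asymptote f_max
* ``HRS_LQ``          an induced-repair modification of the LQ curve in which
  the linear coefficient relaxes from a low-dose value alpha_s to the
  high-dose value alpha_r with dose constant d_c:
  Y(D) = c + [alpha_r + (alpha_s - alpha_r)*exp(-D/d_c)]*D + beta*D^2.
  With alpha_s = alpha_r it reduces exactly to LQ.

Count endpoints (breaks, exchanges, total aberrations) are fitted by Poisson
maximum likelihood on per-dose totals, counts ~ Poisson(n * Y(D)); the
aberrant-cell fraction by binomial likelihood, aberrant ~ Binomial(n, F(D)).
A weighted-least-squares mode on per-cell frequencies (weights = cells
scored) is provided as an alternative fitting criterion.  Covariances come
from the inverse observed information (finite-difference Hessian of the
negative log-likelihood at the optimum).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .scoring import ScoringTable

__all__ = [
    "ModelFamily",
    "EndpointKind",
    "DoseResponseFit",
    "PARAM_NAMES",
    "DEFAULT_FAMILY_MAP",
    "endpoint_kind",
    "predict",
    "fit",
    "compare_models",
]


class ModelFamily(str, enum.Enum):
    LINEAR = "linear"
    LQ = "lq"
    EXP_SATURATION = "exp_saturation"
    HRS_LQ = "hrs_lq"


class EndpointKind(str, enum.Enum):
    COUNT_PER_CELL = "count_per_cell"
    CELL_FRACTION = "cell_fraction"


PARAM_NAMES: dict[ModelFamily, tuple[str, ...]] = {
    ModelFamily.LINEAR: ("c", "alpha"),
    ModelFamily.LQ: ("c", "alpha", "beta"),
    ModelFamily.EXP_SATURATION: ("c", "f_max", "k"),
    ModelFamily.HRS_LQ: ("c", "alpha_r", "alpha_s", "d_c", "beta"),
}

#: endpoint -> model family used for the calibration curves
DEFAULT_FAMILY_MAP: dict[str, ModelFamily] = {
    "breaks": ModelFamily.LQ,
    "aberrant_cells": ModelFamily.EXP_SATURATION,
    "stable_exchanges": ModelFamily.LQ,
    "unstable_exchanges": ModelFamily.LQ,
    "total_aberrations": ModelFamily.LINEAR,
}

_NESTED_PAIRS = {
    (ModelFamily.LINEAR, ModelFamily.LQ),
    (ModelFamily.LQ, ModelFamily.HRS_LQ),
    (ModelFamily.LINEAR, ModelFamily.HRS_LQ),
}


def endpoint_kind(endpoint: str) -> EndpointKind:
    """Aberrant-cell counts are a per-cell fraction; everything else a rate."""
    return (
        EndpointKind.CELL_FRACTION
        if endpoint == "aberrant_cells"
        else EndpointKind.COUNT_PER_CELL
    )


def _check_params(family: ModelFamily, params: np.ndarray) -> None:
    p = np.asarray(params, dtype=float)
    if p.shape != (len(PARAM_NAMES[family]),):
        raise ValueError(
            f"{family.value} expects {len(PARAM_NAMES[family])} parameters "
            f"{PARAM_NAMES[family]}, got shape {p.shape}"
        )
    if family is ModelFamily.LINEAR:
        c, alpha = p
        ok = c >= 0 and alpha >= 0
    elif family is ModelFamily.LQ:
        c, alpha, beta = p
        ok = c >= 0 and alpha >= 0 and beta >= 0
    elif family is ModelFamily.EXP_SATURATION:
        c, f_max, k = p
        ok = 0 <= c <= f_max <= 1 and k > 0
    else:
        c, alpha_r, alpha_s, d_c, beta = p
        ok = c >= 0 and 0 <= alpha_r <= alpha_s and d_c > 0 and beta >= 0
    if not ok:
        raise ValueError(
            f"parameters {p.tolist()} violate the {family.value} constraints"
        )


def _mean(family: ModelFamily, params: np.ndarray, dose: np.ndarray) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    p = np.asarray(params, dtype=float)
    if family is ModelFamily.LINEAR:
        return p[0] + p[1] * d
    if family is ModelFamily.LQ:
        return p[0] + p[1] * d + p[2] * d * d
    if family is ModelFamily.EXP_SATURATION:
        c, f_max, k = p
        return f_max - (f_max - c) * np.exp(-k * d)
    c, alpha_r, alpha_s, d_c, beta = p
    alpha_eff = alpha_r + (alpha_s - alpha_r) * np.exp(-d / d_c)
    return c + alpha_eff * d + beta * d * d


def predict(
    family: ModelFamily, params: np.ndarray, dose: float | np.ndarray
) -> float | np.ndarray:
    """Evaluate the family's mean yield at the given dose(s) in Gy."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0 Gy")
    _check_params(family, params)
    out = _mean(family, np.asarray(params, dtype=float), d)
    return float(out) if np.isscalar(dose) else out


@dataclass
class DoseResponseFit:
    """Result of fitting one model family to one endpoint's per-dose data."""

    family: ModelFamily
    endpoint: str
    kind: EndpointKind
    params: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    deviance: float
    doses: np.ndarray
    counts: np.ndarray
    cells_scored: np.ndarray
    method: str = "ml"
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def predict(self, dose: float | np.ndarray) -> float | np.ndarray:
        return _mean(self.family, self.params, np.asarray(dose, dtype=float))

    def same_data(self, other: "DoseResponseFit") -> bool:
        return (
            np.array_equal(self.doses, other.doses)
            and np.array_equal(self.counts, other.counts)
            and np.array_equal(self.cells_scored, other.cells_scored)
        )

    def report(self) -> dict:
        """JSON-serializable fit report with observed-vs-predicted table."""
        pred = _mean(self.family, self.params, self.doses)
        return {
            "endpoint": self.endpoint,
            "family": self.family.value,
            "method": self.method,
            "param_names": list(self.param_names),
            "estimates": self.params.tolist(),
            "se": self.se.tolist(),
            "covariance": self.cov.tolist(),
            "log_likelihood": self.log_likelihood,
            "deviance": self.deviance,
            "converged": self.converged,
            "warnings": list(self.warnings),
            "per_dose": [
                {
                    "dose_gy": float(d),
                    "cells_scored": int(n),
                    "observed": int(k),
                    "observed_rate": float(k / n),
                    "predicted_rate": float(y),
                }
                for d, n, k, y in zip(
                    self.doses, self.cells_scored, self.counts, pred
                )
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=2))


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

_BIG = 1e12


def _nll_factory(
    family: ModelFamily,
    kind: EndpointKind,
    method: str,
    d: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
):
    if method == "wls":
        f_obs = k / n

        def nll(p: np.ndarray) -> float:
            mu = _mean(family, p, d)
            if not np.all(np.isfinite(mu)):
                return _BIG
            return float(np.sum(n * (f_obs - mu) ** 2))

        return nll

    if kind is EndpointKind.CELL_FRACTION:

        def nll(p: np.ndarray) -> float:
            f = _mean(family, p, d)
            if np.any(f <= 0) or np.any(f >= 1) or not np.all(np.isfinite(f)):
                return _BIG
            return float(-np.sum(k * np.log(f) + (n - k) * np.log1p(-f)))

    else:

        def nll(p: np.ndarray) -> float:
            mu = n * _mean(family, p, d)
            if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
                return _BIG
            return float(np.sum(mu - k * np.log(mu)))

    return nll


def _log_likelihood(
    kind: EndpointKind, d: np.ndarray, k: np.ndarray, n: np.ndarray,
    family: ModelFamily, p: np.ndarray,
) -> float:
    if kind is EndpointKind.CELL_FRACTION:
        f = np.clip(_mean(family, p, d), 1e-12, 1 - 1e-12)
        return float(stats.binom.logpmf(k, n, f).sum())
    mu = np.clip(n * _mean(family, p, d), 1e-12, None)
    return float(stats.poisson.logpmf(k, mu).sum())


def _deviance(
    kind: EndpointKind, d: np.ndarray, k: np.ndarray, n: np.ndarray,
    family: ModelFamily, p: np.ndarray,
) -> float:
    if kind is EndpointKind.CELL_FRACTION:
        f = np.clip(_mean(family, p, d), 1e-12, 1 - 1e-12)
        f_sat = np.clip(k / n, 1e-12, 1 - 1e-12)
        ll_sat = np.sum(k * np.log(f_sat) + (n - k) * np.log1p(-f_sat))
        ll_mod = np.sum(k * np.log(f) + (n - k) * np.log1p(-f))
        return float(2.0 * (ll_sat - ll_mod))
    mu = np.clip(n * _mean(family, p, d), 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(k > 0, k * np.log(k / mu), 0.0)
    return float(2.0 * np.sum(term - (k - mu)))


def _hessian(fun, p: np.ndarray) -> np.ndarray:
    """Central finite-difference Hessian with parameter-scaled steps."""
    m = len(p)
    h = 1e-4 * np.maximum(np.abs(p), 1e-2)
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(p + ei + ej) - fun(p + ei - ej)
                - fun(p - ei + ej) + fun(p - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return 0.5 * (H + H.T)


def _bounds(family: ModelFamily, kind: EndpointKind) -> list[tuple[float, float]]:
    rate_hi = 1.0 if kind is EndpointKind.CELL_FRACTION else 10.0
    if family is ModelFamily.LINEAR:
        return [(1e-9, rate_hi), (0.0, 10.0)]
    if family is ModelFamily.LQ:
        return [(1e-9, rate_hi), (0.0, 10.0), (0.0, 10.0)]
    if family is ModelFamily.EXP_SATURATION:
        return [(1e-9, 1.0), (1e-6, 1.0), (1e-6, 50.0)]
    return [(1e-9, rate_hi), (0.0, 10.0), (0.0, 10.0), (1e-3, 5.0), (0.0, 10.0)]


def _starts(
    family: ModelFamily, d: np.ndarray, k: np.ndarray, n: np.ndarray
) -> list[np.ndarray]:
    """Moment-based deterministic starting points."""
    f = k / n
    c0 = max(f[0], 1e-4)
    pos = d > 0
    # low-dose secant slope and high-dose residual curvature
    d_lo, f_lo = d[pos][0], f[pos][0]
    d_hi, f_hi = d[-1], f[-1]
    alpha0 = max((f_lo - c0) / d_lo, 1e-3)
    beta0 = max((f_hi - c0 - alpha0 * d_hi) / d_hi**2, 1e-3)
    slope0 = max((f_hi - c0) / d_hi, 1e-3)
    if family is ModelFamily.LINEAR:
        base = [np.array([c0, slope0])]
        base.append(np.array([c0, alpha0]))
    elif family is ModelFamily.LQ:
        base = [np.array([c0, alpha0, beta0])]
        base.append(np.array([c0, slope0, 1e-3]))
        base.append(np.array([c0, 1e-3, slope0]))
    elif family is ModelFamily.EXP_SATURATION:
        f_max0 = min(max(f_hi * 1.1, c0 + 1e-3), 0.999)
        base = [np.array([c0, f_max0, 1.0])]
        base.append(np.array([c0, f_max0, 3.0]))
        base.append(np.array([c0, min(2 * f_max0, 0.999), 0.5]))
    else:
        base = [np.array([c0, alpha0, 2 * alpha0, 0.2, beta0])]
        base.append(np.array([c0, alpha0, alpha0, 0.2, beta0]))
        base.append(np.array([c0, slope0, 4 * slope0, 0.1, 1e-3]))
    return base


def fit(
    table: ScoringTable,
    endpoint: str,
    family: ModelFamily,
    method: str = "ml",
) -> DoseResponseFit:
    """Fit one model family to one endpoint of a per-dose scoring table.

    ``method="ml"`` (default) maximizes the Poisson likelihood for count
    endpoints and the binomial likelihood for the aberrant-cell fraction;
    ``method="wls"`` minimizes cells-weighted squared error on frequencies.
    """
    if method not in ("ml", "wls"):
        raise ValueError(f"method must be 'ml' or 'wls', got {method!r}")
    d = table.doses.astype(float)
    k = table.endpoint_counts(endpoint).astype(float)
    n = table.cells_scored.astype(float)
    kind = endpoint_kind(endpoint)
    n_par = len(PARAM_NAMES[family])
    if len(d) < n_par:
        raise ValueError(
            f"{family.value} has {n_par} free parameters but only "
            f"{len(d)} dose levels are available"
        )
    if np.any(n <= 0):
        raise ValueError("cells_scored must be positive at every dose")

    warnings: list[str] = []
    if len(d) == n_par:
        warnings.append(
            f"saturated model: {family.value} has as many parameters as dose "
            "levels; goodness of fit is not assessable"
        )

    nll = _nll_factory(family, kind, method, d, k, n)
    bounds = _bounds(family, kind)
    lo_b = np.array([b[0] for b in bounds])
    hi_b = np.array([b[1] for b in bounds])

    def nll_constrained(p: np.ndarray) -> float:
        # box bounds plus the cross-parameter constraints of the family
        if np.any(p < lo_b) or np.any(p > hi_b):
            return _BIG
        if family is ModelFamily.EXP_SATURATION and p[0] > p[1]:
            return _BIG
        if family is ModelFamily.HRS_LQ and p[1] > p[2]:
            return _BIG
        return nll(p)

    best = None
    for x0 in _starts(family, d, k, n):
        x0 = np.clip(x0, lo_b, hi_b)
        res = optimize.minimize(
            nll_constrained, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish, robust near active bounds
    polish = optimize.minimize(
        nll_constrained, best.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    if polish.fun < best.fun:
        best = polish
    if not np.isfinite(best.fun) or best.fun >= _BIG:
        raise RuntimeError(
            f"fit of {family.value} to {endpoint} did not converge: {best.message}"
        )
    p_hat = np.clip(best.x, lo_b, hi_b)

    H = _hessian(nll, p_hat)
    if method == "wls":
        # Gauss-Markov: sigma^2 * (0.5 H)^{-1} with sigma^2 from weighted RSS
        dof = max(len(d) - n_par, 1)
        sigma2 = best.fun / dof
        H_eff = H / (2.0 * sigma2)
    else:
        H_eff = H
    try:
        cov = np.linalg.inv(H_eff)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H_eff)
        warnings.append("observed information singular; pseudo-inverse covariance")
    cov = 0.5 * (cov + cov.T)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        # project onto the PSD cone
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        warnings.append("covariance projected to positive semidefinite")

    return DoseResponseFit(
        family=family,
        endpoint=endpoint,
        kind=kind,
        params=p_hat,
        cov=cov,
        log_likelihood=_log_likelihood(kind, d, k, n, family, p_hat),
        deviance=_deviance(kind, d, k, n, family, p_hat),
        doses=d,
        counts=k.astype(int),
        cells_scored=n.astype(int),
        method=method,
        converged=bool(best.success or polish.success),
        warnings=warnings,
    )


def compare_models(
    fit_reduced: DoseResponseFit, fit_full: DoseResponseFit
) -> tuple[float, float]:
    """Extra-deviance F-test of a nested model pair fitted to the same data.

    F = (D_reduced - D_full)/df1 / (D_full/df2) with df1 the number of extra
    parameters and df2 = n_doses - n_params_full.  A full model with as many
    parameters as dose levels leaves no residual degrees of freedom and is
    rejected ("no uncertainty in the regression").
    """
    if (fit_reduced.family, fit_full.family) not in _NESTED_PAIRS:
        raise ValueError(
            f"{fit_reduced.family.value} is not nested in {fit_full.family.value}"
        )
    if not fit_reduced.same_data(fit_full):
        raise ValueError("model comparison requires fits to the same data")
    df1 = fit_full.n_params - fit_reduced.n_params
    df2 = fit_full.n_doses - fit_full.n_params
    if df2 <= 0:
        raise ValueError(
            "no uncertainty in the regression (as many parameters as dose "
            "levels); p is not calculated"
        )
    dev_r, dev_f = fit_reduced.deviance, fit_full.deviance
    num = max(dev_r - dev_f, 0.0)
    if dev_f <= 0:
        return (0.0, 1.0) if num == 0 else (np.inf, 0.0)
    f_stat = (num / df1) / (dev_f / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p
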