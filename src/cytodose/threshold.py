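"""Detection-threshold doses with conservative 95% upper confidence limits.

The detection-threshold dose of an endpoint is the smallest dose at which the
fitted yield becomes statistically distinguishable from the unirradiated
background at a stated scoring effort.  Concretely the detectability
criterion asks: in a sample of ``n_cells`` cells, what is the smallest count
``k*`` that a one-sided Fisher exact test against the observed control row
flags at level ``alpha``?  The implied minimal detectable yield is
``y_detect = k*/n_cells``, and the threshold dose D* solves
``Y(D*) = y_detect`` on the fitted calibration curve.

The conservative 95% upper confidence limit on D* propagates the regression
uncertainty by parametric Monte Carlo: parameter vectors are drawn from the
asymptotic normal of the estimates, truncated to the family's constraint
set, the threshold is recomputed per draw, and the 95th percentile reported.
Draws whose curve never reaches the detectable yield inside the search
bracket count as an infinite threshold (they can only enlarge the upper
limit, keeping it conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .dose_response import (
    DEFAULT_FAMILY_MAP,
    DoseResponseFit,
    ModelFamily,
    _bounds,
    _mean,
    fit as fit_model,
)
from .scoring import ENDPOINTS, ScoringTable, fisher_exact

__all__ = [
    "DetectabilityCriterion",
    "ThresholdEstimate",
    "minimal_detectable_yield",
    "threshold_dose",
    "threshold_upper_cl",
    "threshold_table",
    "empirical_threshold",
]

#: search bracket for the threshold dose; values above EXTRAPOLATION_LIMIT Gy
#: are flagged as extrapolation beyond the calibrated range
D_MAX = 2.0
EXTRAPOLATION_LIMIT = 1.0
DEFAULT_SEED = 20130729


@dataclass(frozen=True)
class DetectabilityCriterion:
    """What counts as a detectable increase over the control sample."""

    control: tuple[int, int]  # (count, cells scored) in the control sample
    alpha: float = 0.05
    n_cells: int = 200
    sided: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        c, n = self.control
        if n < 1 or c < 0:
            raise ValueError(f"invalid control row {self.control}")
        if self.sided not in ("one", "two"):
            raise ValueError(f"sided must be 'one' or 'two', got {self.sided!r}")


@dataclass(frozen=True)
class ThresholdEstimate:
    """Detection-threshold dose of one endpoint, with its 95% upper CL."""

    endpoint: str
    family: ModelFamily
    d_star: float
    upper_cl95: float
    y_detect: float
    criterion: DetectabilityCriterion
    n_draws: int
    seed: int
    empirical: float | None = None
    extrapolated: bool = False
    attained: bool = True
    error: str | None = None
    warnings: tuple[str, ...] = ()


def minimal_detectable_yield(criterion: DetectabilityCriterion) -> float:
    """Smallest per-cell yield detectable against the control sample.

    Scans counts k above the control rate in a sample of ``n_cells`` cells
    and returns k*/n_cells for the smallest k whose Fisher exact test
    against the control table rejects at level alpha.
    """
    c, n_c = criterion.control
    control_rate = c / n_c
    sided = "greater" if criterion.sided == "one" else "two"
    for k in range(criterion.n_cells + 1):
        if k / criterion.n_cells <= control_rate:
            continue
        p = fisher_exact(
            k, criterion.n_cells - k, c, n_c - c, sided=sided
        )
        if p <= criterion.alpha:
            return k / criterion.n_cells
    raise ValueError(
        f"no count up to n_cells={criterion.n_cells} is detectable against "
        f"control {criterion.control} at alpha={criterion.alpha}"
    )


def _invert_curve(
    family: ModelFamily, params: np.ndarray, y_detect: float, d_max: float = D_MAX
) -> float:
    """Solve Y(D) = y_detect by bisection on [0, d_max]; 0 if already above,
    +inf if the curve never reaches the target inside the bracket."""
    y0 = float(_mean(family, params, np.array(0.0)))
    if y_detect <= y0:
        return 0.0
    y_hi = float(_mean(family, params, np.array(d_max)))
    if y_hi < y_detect:
        return np.inf
    return float(
        optimize.brentq(
            lambda d: float(_mean(family, params, np.array(d))) - y_detect,
            0.0,
            d_max,
            xtol=1e-6,
        )
    )


def threshold_dose(
    fit: DoseResponseFit, y_detect: float, d_max: float = D_MAX
) -> float:
    """Dose at which the fitted curve reaches the minimal detectable yield."""
    d = _invert_curve(fit.family, fit.params, y_detect, d_max)
    if np.isinf(d):
        y0 = fit.predict(0.0)
        y_hi = fit.predict(d_max)
        raise ValueError(
            f"detectable yield {y_detect:.4g} is above the fitted curve's "
            f"attainable range [{y0:.4g}, {y_hi:.4g}] on [0, {d_max}] Gy"
        )
    return d


def _invert_many(
    family: ModelFamily, params: np.ndarray, y_detect: float, d_max: float = D_MAX
) -> np.ndarray:
    """Vectorized bisection of Y(D) = y_detect across rows of ``params``."""
    P = np.asarray(params, dtype=float)

    def mean_at(d: np.ndarray) -> np.ndarray:
        if family is ModelFamily.LINEAR:
            return P[:, 0] + P[:, 1] * d
        if family is ModelFamily.LQ:
            return P[:, 0] + P[:, 1] * d + P[:, 2] * d * d
        if family is ModelFamily.EXP_SATURATION:
            return P[:, 1] - (P[:, 1] - P[:, 0]) * np.exp(-P[:, 2] * d)
        a_eff = P[:, 1] + (P[:, 2] - P[:, 1]) * np.exp(-d / P[:, 3])
        return P[:, 0] + a_eff * d + P[:, 4] * d * d

    out = np.full(len(P), np.inf)
    at_zero = mean_at(np.zeros(len(P)))
    done_zero = y_detect <= at_zero
    out[done_zero] = 0.0
    reachable = mean_at(np.full(len(P), d_max)) >= y_detect
    active = ~done_zero & reachable
    lo = np.zeros(len(P))
    hi = np.full(len(P), float(d_max))
    for _ in range(60):  # 2 / 2^60 << 1e-6 Gy
        mid = 0.5 * (lo + hi)
        above = mean_at(mid) >= y_detect
        hi = np.where(active & above, mid, hi)
        lo = np.where(active & ~above, mid, lo)
    out[active] = 0.5 * (lo + hi)[active]
    return out


def threshold_upper_cl(
    fit: DoseResponseFit,
    criterion: DetectabilityCriterion,
    n_draws: int = 100_000,
    seed: int = DEFAULT_SEED,
    y_detect: float | None = None,
) -> float:
    """95% upper confidence limit of the threshold dose by parametric
    Monte Carlo propagation of the fit covariance (deterministic per seed)."""
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable 95th percentile")
    eig = np.linalg.eigvalsh(0.5 * (fit.cov + fit.cov.T))
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError("fit covariance is not positive semidefinite")
    if y_detect is None:
        y_detect = minimal_detectable_yield(criterion)

    bounds = _bounds(fit.family, fit.kind)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    n_kept = 0
    n_sampled = 0
    max_sample = 50 * n_draws
    while n_kept < n_draws and n_sampled < max_sample:
        batch = rng.multivariate_normal(
            fit.params, fit.cov, size=n_draws, method="svd"
        )
        n_sampled += len(batch)
        ok = np.all((batch >= lo) & (batch <= hi), axis=1)
        if fit.family is ModelFamily.EXP_SATURATION:
            ok &= batch[:, 0] <= batch[:, 1]
        elif fit.family is ModelFamily.HRS_LQ:
            ok &= batch[:, 1] <= batch[:, 2]
        good = batch[ok]
        kept.append(good)
        n_kept += len(good)
    if n_kept < n_draws:
        raise ValueError(
            f"more than 50% of parameter draws violate the {fit.family.value} "
            f"constraints ({n_kept}/{n_sampled} feasible); the normal "
            "approximation to the fit is unusable"
        )
    P = np.concatenate(kept)[:n_draws]
    d_draws = _invert_many(fit.family, P, y_detect)
    n_inf = int(np.isinf(d_draws).sum())
    if n_inf > 0.5 * n_draws:
        raise ValueError(
            f"{n_inf}/{n_draws} draws never reach the detectable yield "
            f"{y_detect:.4g} within [0, {D_MAX}] Gy"
        )
    ucl = float(np.percentile(d_draws, 95.0))
    if np.isinf(ucl):
        raise ValueError(
            "95th percentile of the threshold distribution is unbounded "
            f"({n_inf}/{n_draws} draws do not attain the detectable yield)"
        )
    return ucl


def empirical_threshold(
    table: ScoringTable, endpoint: str, alpha: float = 0.05, sided: str = "one"
) -> float | None:
    """Lowest scored dose whose exact test against control rejects, or None."""
    c, n_c = table.control_row(endpoint)
    dose0 = float(table.doses.min())
    alternative = "greater" if sided == "one" else "two"
    for dose in table.doses:
        if dose == dose0:
            continue
        row = table.counts.loc[dose]
        k, n = int(row[endpoint]), int(row["cells_scored"])
        p = fisher_exact(k, max(n - k, 0), c, n_c - c, sided=alternative)
        if p <= alpha:
            return float(dose)
    return None


def threshold_table(
    table: ScoringTable,
    family_map: dict[str, ModelFamily] | None = None,
    alpha: float = 0.05,
    n_cells: int = 200,
    sided: str = "one",
    n_draws: int = 100_000,
    seed: int = DEFAULT_SEED,
    method: str = "ml",
) -> list[ThresholdEstimate]:
    """Detection-threshold doses for all five endpoints of a scoring table.

    Each endpoint is fitted with its calibration family (breaks, stable and
    unstable exchanges: LQ; aberrant cells: exponential saturation; total
    aberrations: linear), the minimal detectable yield is derived from that
    endpoint's control row, and the fitted curve inverted.  A failing
    endpoint yields an estimate carrying an error message, not an abort.
    """
    if len(table.doses) < 4 or table.doses.min() != 0.0:
        raise ValueError("need >= 4 dose levels including 0 Gy")
    family_map = dict(DEFAULT_FAMILY_MAP if family_map is None else family_map)
    results: list[ThresholdEstimate] = []
    for i, endpoint in enumerate(ENDPOINTS):
        family = family_map[endpoint]
        criterion = DetectabilityCriterion(
            control=table.control_row(endpoint),
            alpha=alpha,
            n_cells=n_cells,
            sided=sided,
        )
        emp = empirical_threshold(table, endpoint, alpha=alpha, sided=sided)
        try:
            y_detect = minimal_detectable_yield(criterion)
            fit_res = fit_model(table, endpoint, family, method=method)
            d_star = threshold_dose(fit_res, y_detect)
            ucl = threshold_upper_cl(
                fit_res, criterion, n_draws=n_draws, seed=seed + i,
                y_detect=y_detect,
            )
        except (ValueError, RuntimeError) as exc:
            results.append(
                ThresholdEstimate(
                    endpoint=endpoint,
                    family=family,
                    d_star=np.nan,
                    upper_cl95=np.nan,
                    y_detect=np.nan,
                    criterion=criterion,
                    n_draws=n_draws,
                    seed=seed + i,
                    empirical=emp,
                    attained=False,
                    error=str(exc),
                )
            )
            continue
        results.append(
            ThresholdEstimate(
                endpoint=endpoint,
                family=family,
                d_star=d_star,
                upper_cl95=ucl,
                y_detect=y_detect,
                criterion=criterion,
                n_draws=n_draws,
                seed=seed + i,
                empirical=emp,
                extrapolated=d_star > EXTRAPOLATION_LIMIT
                or ucl > EXTRAPOLATION_LIMIT,
                warnings=tuple(fit_res.warnings),
            )
        )
    return results
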