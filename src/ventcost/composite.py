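"""The six-predictor composite model of the oxygen cost of ventilation.

The model predicts peak V̇O2VENT (L·min⁻¹) from peak expired ventilation
(cubic), body weight (cubic), height (exponential), age, V̇O2 peak and
maximal heart rate (each linear)::

    V̇O2VENT = c + ve1·VE + ve2·VE² + ve3·VE³
             + w1·W + w2·W² + w3·W³
             + h_scale·exp(h_rate·H)
             + age1·Age + vp1·V̇O2peak + hr1·HRMax

The published coefficient set (:func:`published_composite`) spreads the
intercept ``c`` over five additive constants, an artefact of how the model
was assembled from the single-predictor equations; only their sum is
identifiable, and predictions are invariant to how mass is distributed
among them.

Refitting (:func:`fit_composite`) exploits the structure of the model: it
is linear in every parameter except the height rate ``h_rate``, so the fit
is solved as a one-dimensional profile over ``h_rate`` with an exact linear
least-squares solve of the 11 remaining identifiable coefficients at each
candidate — far more stable than a 16-parameter black-box optimiser on a
problem with a five-way non-identifiable constant split.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .dataset import CohortTable, ParticipantRecord
from .exceptions import (
    InsufficientDataError,
    SingularFitError,
    UndefinedR2Error,
)

__all__ = [
    "CompositeCoefficients",
    "FitOptions",
    "FitResult",
    "GoodnessOfFit",
    "COEFFICIENT_NAMES",
    "N_PREDICTORS",
    "N_IDENTIFIABLE_PARAMS",
    "published_composite",
    "evaluate_composite",
    "predict_record",
    "predict_cohort",
    "fit_composite",
    "goodness_of_fit",
]

N_PREDICTORS = 6
#: intercept + 3 VE terms + 3 weight terms + h_scale + h_rate + age + vo2peak + hr
N_IDENTIFIABLE_PARAMS = 12

#: identifiable coefficients in design order (h_rate profiled, hence last)
COEFFICIENT_NAMES = (
    "intercept", "ve1", "ve2", "ve3", "w1", "w2", "w3",
    "h_scale", "age1", "vp1", "hr1", "h_rate",
)


@dataclasses.dataclass(frozen=True)
class CompositeCoefficients:
    """The 16 named constants of the composite model.

    ``c0_list`` carries the five additive constants of the published
    expression; refits return a single effective intercept in the first
    slot. ``provenance`` is ``"published"`` or ``"refit"``.
    """

    c0_list: tuple
    ve1: float
    ve2: float
    ve3: float
    w1: float
    w2: float
    w3: float
    h_scale: float
    h_rate: float
    age1: float
    vp1: float
    hr1: float
    provenance: str = "refit"

    def __post_init__(self) -> None:
        if len(self.c0_list) != 5:
            raise ValueError("c0_list must hold exactly five additive constants")
        vals = list(self.c0_list) + [
            self.ve1, self.ve2, self.ve3, self.w1, self.w2, self.w3,
            self.h_scale, self.h_rate, self.age1, self.vp1, self.hr1,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all coefficients must be finite")

    @property
    def effective_intercept(self) -> float:
        """Sum of the five additive constants — the identifiable intercept."""
        return float(sum(self.c0_list))

    def identifiable(self) -> dict:
        """The 12 identifiable parameters, keyed by :data:`COEFFICIENT_NAMES`."""
        return {
            "intercept": self.effective_intercept,
            "ve1": self.ve1, "ve2": self.ve2, "ve3": self.ve3,
            "w1": self.w1, "w2": self.w2, "w3": self.w3,
            "h_scale": self.h_scale, "age1": self.age1,
            "vp1": self.vp1, "hr1": self.hr1, "h_rate": self.h_rate,
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c0_list"] = list(self.c0_list)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeCoefficients":
        d = dict(d)
        d["c0_list"] = tuple(d["c0_list"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CompositeCoefficients":
        return cls.from_dict(json.loads(text))


def published_composite() -> CompositeCoefficients:
    """The exact published coefficient set (immutable, provenance ``"published"``)."""
    text = resources.files("ventcost.data").joinpath("published_composite.json").read_text()
    return CompositeCoefficients.from_json(text)


def evaluate_composite(
    coeffs: CompositeCoefficients,
    ve,
    age,
    weight,
    height,
    vo2peak,
    hr_max,
    *,
    clip_negative: bool = True,
    warn_negative: bool = True,
):
    """Predicted V̇O2VENT (L·min⁻¹) for the given predictor values.

    Vectorised over any broadcastable combination of inputs. Physiologically
    V̇O2VENT ≥ 0, so negative raw predictions are clamped to zero (with a
    warning); pass ``clip_negative=False`` to retain the raw value for
    diagnostics.
    """
    ve = np.asarray(ve, dtype=float)
    w = np.asarray(weight, dtype=float)
    out = (
        coeffs.effective_intercept
        + coeffs.ve1 * ve + coeffs.ve2 * ve**2 + coeffs.ve3 * ve**3
        + coeffs.w1 * w + coeffs.w2 * w**2 + coeffs.w3 * w**3
        + coeffs.h_scale * np.exp(coeffs.h_rate * np.asarray(height, dtype=float))
        + coeffs.age1 * np.asarray(age, dtype=float)
        + coeffs.vp1 * np.asarray(vo2peak, dtype=float)
        + coeffs.hr1 * np.asarray(hr_max, dtype=float)
    )
    if clip_negative and np.any(out < 0):
        if warn_negative:
            warnings.warn(
                "negative V̇O2VENT prediction clamped to 0", stacklevel=2
            )
        out = np.clip(out, 0.0, None)
    return float(out) if np.ndim(out) == 0 else out


def predict_record(coeffs: CompositeCoefficients, rec: ParticipantRecord, **kw) -> float:
    return evaluate_composite(
        coeffs, rec.ve_peak, rec.age, rec.weight, rec.height, rec.vo2peak, rec.hr_max, **kw
    )


def predict_cohort(coeffs: CompositeCoefficients, cohort: CohortTable, **kw) -> np.ndarray:
    ve, age, w, h, vp, hr = cohort.predictors().T
    return np.atleast_1d(evaluate_composite(coeffs, ve, age, w, h, vp, hr, **kw))


# ---------------------------------------------------------------------------
# refitting


@dataclasses.dataclass(frozen=True)
class FitOptions:
    """Convergence settings for the profiled least-squares fit.

    ``h_rate_bounds`` bracket the profiled exponential rate; over heights of
    150–200 cm a |rate| of 0.06 already spans e^9–e^12 of curvature, beyond
    which the exponential column is numerically indistinguishable from a
    step. ``rel_tol`` is the relative RSS-reduction convergence criterion.
    """

    h_rate_bounds: tuple = (-0.06, 0.06)
    coarse_grid: int = 61
    rel_tol: float = 1e-8
    h_rate_fixed: float | None = None


@dataclasses.dataclass
class FitResult:
    coefficients: CompositeCoefficients
    rss: float
    r2: float
    adjusted_r2: float
    n: int
    k_predictors: int
    n_params: int
    converged: bool
    iterations: int
    fitted: np.ndarray | None = None
    message: str = ""


def _design(P: np.ndarray, h_rate: float) -> np.ndarray:
    ve, age, w, h, vp, hr = P.T
    return np.column_stack(
        [np.ones(len(P)), ve, ve**2, ve**3, w, w**2, w**3,
         np.exp(h_rate * h), age, vp, hr]
    )


def _solve(P: np.ndarray, y: np.ndarray, h_rate: float):
    """Exact linear LS of the 11 identifiable coefficients at fixed h_rate."""
    X = _design(P, h_rate)
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    Xs = X / scale
    beta, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
    rss = float(np.sum((y - Xs @ beta) ** 2))
    return rss, beta / scale, rank


def fit_composite(
    cohort: CohortTable,
    init: CompositeCoefficients | str = "from_submodels",
    options: FitOptions | None = None,
) -> FitResult:
    """Least-squares refit of the composite form to a cohort with measured V̇O2VENT.

    The height rate is profiled over a coarse grid (plus any rates suggested
    by `init`) and refined by bounded scalar minimisation; at each candidate
    the remaining 11 coefficients are solved exactly. The five-way constant
    split of the published expression is not identifiable, so refits return
    a single effective intercept as ``c0_list = (intercept, 0, 0, 0, 0)``.

    Raises :class:`InsufficientDataError` for n < 13 and
    :class:`SingularFitError` on a rank-deficient design.
    """
    opts = options or FitOptions()
    cohort.require_stpd()
    y = cohort.measured()
    if np.any(~np.isfinite(y)):
        raise InsufficientDataError("fit_composite requires measured V̇O2VENT for every row")
    P = cohort.predictors()
    n = len(y)
    if n < N_IDENTIFIABLE_PARAMS + 1:
        raise InsufficientDataError(
            f"fit_composite needs n >= {N_IDENTIFIABLE_PARAMS + 1}, got {n}"
        )

    lo, hi = opts.h_rate_bounds
    extras: list[float] = []
    if isinstance(init, CompositeCoefficients):
        extras.append(init.h_rate)
    elif init == "from_submodels":
        extras.append(published_composite().h_rate)
        extras.append(0.01293)  # stand-alone height-curve rate
    elif init is not None and init != "none":
        raise ValueError(f"unknown init {init!r}")
    extras = [r for r in extras if lo <= r <= hi]

    # rank check once, away from r = 0 degeneracies
    _, _, rank = _solve(P, y, 0.01)
    if rank < 11:
        raise SingularFitError(f"design matrix rank {rank} < 11")

    n_solves = 0

    def profile(r: float) -> float:
        nonlocal n_solves
        n_solves += 1
        return _solve(P, y, float(r))[0]

    candidates = np.concatenate([np.linspace(lo, hi, opts.coarse_grid), extras])
    if opts.h_rate_fixed is not None:
        best_r = float(opts.h_rate_fixed)
        converged, message = True, "h_rate held fixed"
    else:
        vals = np.array([profile(r) for r in candidates])
        i = int(np.argmin(vals))
        step = (hi - lo) / (opts.coarse_grid - 1)
        blo = max(lo, candidates[i] - step)
        bhi = min(hi, candidates[i] + step)
        res = minimize_scalar(
            profile, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-9}
        )
        best_r = float(res.x) if res.fun <= vals[i] else float(candidates[i])
        # declare convergence when refinement no longer reduces RSS materially
        rel_gain = (vals[i] - min(res.fun, vals[i])) / max(vals[i], np.finfo(float).tiny)
        converged = bool(res.success) and np.isfinite(res.fun)
        message = f"profile refinement relative RSS reduction {rel_gain:.2e}"

    rss, beta, _ = _solve(P, y, best_r)
    coeffs = CompositeCoefficients(
        c0_list=(float(beta[0]), 0.0, 0.0, 0.0, 0.0),
        ve1=float(beta[1]), ve2=float(beta[2]), ve3=float(beta[3]),
        w1=float(beta[4]), w2=float(beta[5]), w3=float(beta[6]),
        h_scale=float(beta[7]), h_rate=best_r,
        age1=float(beta[8]), vp1=float(beta[9]), hr1=float(beta[10]),
        provenance="refit",
    )
    fitted = _design(P, best_r) @ beta
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        # no variance to explain; rss is ~0 and R² is 0 by convention
        r2 = 0.0
    else:
        r2 = 1.0 - rss / sstot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - N_PREDICTORS - 1)
    return FitResult(
        coefficients=coeffs,
        rss=rss,
        r2=r2,
        adjusted_r2=adj,
        n=n,
        k_predictors=N_PREDICTORS,
        n_params=N_IDENTIFIABLE_PARAMS,
        converged=converged,
        iterations=n_solves,
        fitted=fitted,
        message=message,
    )


# ---------------------------------------------------------------------------
# goodness of fit


@dataclasses.dataclass(frozen=True)
class GoodnessOfFit:
    rss: float
    r2: float
    adjusted_r2: float
    #: F with df1 = k_predictors, df2 = n − k_predictors − 1
    f_by_predictors: tuple
    #: F with df1 = n_params, df2 = n − n_params (second df convention), or None
    f_by_parameters: tuple | None


def goodness_of_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    k_predictors: int = N_PREDICTORS,
    n_params: int | None = N_IDENTIFIABLE_PARAMS,
) -> GoodnessOfFit:
    """RSS, R², adjusted R² and the model F-statistic under both df conventions.

    The F numerator is the explained sum of squares over df1 and the
    denominator RSS over df2, with (df1, df2) either
    ``(k_predictors, n − k_predictors − 1)`` or ``(n_params, n − n_params)``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    n = len(obs)
    if n < k_predictors + 2:
        raise InsufficientDataError(f"need at least {k_predictors + 2} pairs, got {n}")
    rss = float(np.sum((obs - pred) ** 2))
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    if sstot == 0.0:
        raise UndefinedR2Error("observed values are constant; R² undefined")
    r2 = 1.0 - rss / sstot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k_predictors - 1)

    def f_stat(df1: int, df2: int):
        if df2 <= 0:
            return None
        num = (sstot - rss) / df1
        den = rss / df2 if rss > 0 else np.nan
        return (float(num / den) if den and np.isfinite(den) else float("inf"), df1, df2)

    f_pred = f_stat(k_predictors, n - k_predictors - 1)
    f_par = f_stat(n_params, n - n_params) if n_params else None
    return GoodnessOfFit(rss=rss, r2=r2, adjusted_r2=adj,
                         f_by_predictors=f_pred, f_by_parameters=f_par)
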