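"""Single-predictor relationships against peak V̇O2VENT.

Each of the six predictors relates to the peak oxygen cost of ventilation
through its own fixed functional form, chosen in the source analysis by
lowest standard error of estimate: a cubic polynomial for V̇E and weight,
simple linear regressions for age, V̇O2 peak and maximal heart rate, and an
exponential-growth curve ``a·exp(k·height)`` for height. The published
coefficient sets ship with the package (:func:`published_submodels`) and the
same forms can be refit to any cohort (:func:`fit_submodel`).

Cubic fits are performed on a scaled/centred basis (``numpy.polynomial``)
and reported in the raw power basis, because raw cubics on predictors
spanning 50–190 L·min⁻¹ are badly conditioned.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from importlib import resources

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import curve_fit

from .dataset import TABLE1_PREDICTOR_RANGES
from .exceptions import InsufficientDataError, SingularFitError

__all__ = [
    "SubmodelForm",
    "SubmodelFit",
    "FORMS",
    "get_form",
    "fit_submodel",
    "evaluate_submodel",
    "published_submodels",
    "submodels_to_json",
    "submodels_from_json",
]

_KIND_NPARAMS = {"linear": 2, "cubic": 4, "expgrowth": 2}


@dataclasses.dataclass(frozen=True)
class SubmodelForm:
    """A named functional form tying one predictor to peak V̇O2VENT."""

    name: str
    kind: str  # linear | cubic | expgrowth
    predictor: str  # canonical predictor column name

    @property
    def n_params(self) -> int:
        return _KIND_NPARAMS[self.kind]


#: the six fixed forms, keyed by name
FORMS = {
    f.name: f
    for f in (
        SubmodelForm("ve_cubic", "cubic", "ve_peak"),
        SubmodelForm("age_linear", "linear", "age"),
        SubmodelForm("height_expgrowth", "expgrowth", "height"),
        SubmodelForm("weight_cubic", "cubic", "weight"),
        SubmodelForm("vo2peak_linear", "linear", "vo2peak"),
        SubmodelForm("hrmax_linear", "linear", "hr_max"),
    )
}


def get_form(name: str) -> SubmodelForm:
    try:
        return FORMS[name]
    except KeyError:
        raise KeyError(f"unknown sub-model form {name!r}; one of {sorted(FORMS)}") from None


@dataclasses.dataclass(frozen=True)
class SubmodelFit:
    """Fitted (or published) coefficients for one form.

    ``coefficients`` are in ascending order for polynomial kinds
    (intercept first) and ``(scale, rate)`` for the exponential-growth kind.
    """

    form: SubmodelForm
    coefficients: tuple
    rss: float | None = None
    see: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.form.n_params:
            raise ValueError(
                f"{self.form.name} expects {self.form.n_params} coefficients, "
                f"got {len(self.coefficients)}"
            )
        if self.rss is not None and self.rss < -1e-12:
            raise ValueError("residual sum of squares must be non-negative")

    def predict(self, x):
        return evaluate_submodel(self, x, warn_extrapolation=False)


def _eval_raw(kind: str, coef, x):
    x = np.asarray(x, dtype=float)
    if kind == "expgrowth":
        a, k = coef
        return a * np.exp(k * x)
    return sum(c * x**i for i, c in enumerate(coef))


def evaluate_submodel(fit: SubmodelFit, x, *, warn_extrapolation: bool = True,
                      bounds: tuple | None = None):
    """Evaluate a fitted form at predictor value(s) `x`.

    Values outside the guard interval (default: the observed range of the
    packaged derivation cohort for that predictor) trigger a warning, never
    an error.
    """
    x = np.asarray(x, dtype=float)
    if warn_extrapolation:
        lo, hi = bounds or TABLE1_PREDICTOR_RANGES[fit.form.predictor]
        if np.any(x < lo) or np.any(x > hi):
            warnings.warn(
                f"{fit.form.name}: evaluating outside observed range [{lo:g}, {hi:g}]",
                stacklevel=2,
            )
    out = _eval_raw(fit.form.kind, fit.coefficients, x)
    return float(out) if np.ndim(out) == 0 else out


def fit_submodel(x, y, form: SubmodelForm | str) -> SubmodelFit:
    """Least-squares fit of one form to (predictor, peak V̇O2VENT) data.

    Linear and cubic forms are exact linear least squares (solved on a
    scaled/centred basis, reported in the raw basis). The exponential-growth
    form is optimised from multiple starts — a log-linear initialisation
    (when all y > 0) and the published height coefficients — keeping the
    best residual sum of squares.
    """
    if isinstance(form, str):
        form = get_form(form)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n, p = len(x), form.n_params
    if n < p + 1:
        raise InsufficientDataError(f"{form.name} needs at least {p + 1} points, got {n}")

    if form.kind in ("linear", "cubic"):
        deg = 1 if form.kind == "linear" else 3
        if len(np.unique(x)) <= deg:
            raise SingularFitError(
                f"{form.name}: only {len(np.unique(x))} distinct x values for degree {deg}"
            )
        # domain-mapped fit for conditioning, then convert to raw powers
        poly = Polynomial.fit(x, y, deg=deg).convert()
        coef = np.zeros(deg + 1)
        coef[: len(poly.coef)] = poly.coef
        coefficients = tuple(float(c) for c in coef)
    elif form.kind == "expgrowth":
        coefficients = _fit_expgrowth(x, y)
    else:  # pragma: no cover - forms are closed
        raise ValueError(f"unknown kind {form.kind!r}")

    resid = y - _eval_raw(form.kind, coefficients, x)
    rss = float(np.sum(resid**2))
    see = float(np.sqrt(rss / (n - p))) if n > p else float("nan")
    return SubmodelFit(form=form, coefficients=coefficients, rss=rss, see=see, n=n)


def _fit_expgrowth(x, y) -> tuple:
    starts = []
    if np.all(y > 0):
        k0, loga0 = np.polyfit(x, np.log(y), 1)
        starts.append((float(np.exp(loga0)), float(k0)))
    starts.append(tuple(published_submodels()["height_expgrowth"].coefficients))

    best: tuple | None = None
    best_rss = np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    lambda t, a, k: a * np.exp(k * t), x, y, p0=p0, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - popt[0] * np.exp(popt[1] * x)) ** 2))
        if np.isfinite(rss) and rss < best_rss:
            best, best_rss = (float(popt[0]), float(popt[1])), rss
    if best is None:
        raise SingularFitError("exponential-growth fit failed from all starts")
    return best


def submodels_to_json(fits: dict) -> str:
    """Serialize a name→:class:`SubmodelFit` mapping to a JSON document."""
    doc = {
        name: {
            "kind": f.form.kind,
            "predictor": f.form.predictor,
            "coefficients": list(f.coefficients),
            **({"rss": f.rss} if f.rss is not None else {}),
            **({"see": f.see} if f.see is not None else {}),
            **({"n": f.n} if f.n is not None else {}),
        }
        for name, f in fits.items()
    }
    return json.dumps(doc, indent=1)


def submodels_from_json(text: str) -> dict:
    doc = json.loads(text)
    out = {}
    for name, d in doc.items():
        form = SubmodelForm(name=name, kind=d["kind"], predictor=d["predictor"])
        out[name] = SubmodelFit(
            form=form,
            coefficients=tuple(d["coefficients"]),
            rss=d.get("rss"),
            see=d.get("see"),
            n=d.get("n"),
        )
    return out


def published_submodels() -> dict:
    """The six published coefficient sets, keyed by form name.

    Note the published stand-alone height curve uses a different exponential
    rate (0.01293 per cm) from the height term inside the composite model
    (0.00006302 per cm); each set is kept in its own container.
    """
    text = resources.files("ventcost.data").joinpath("published_submodels.json").read_text()
    return submodels_from_json(text)
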