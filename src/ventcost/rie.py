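"""Applying a coefficient set to breath-by-breath ramp-incremental tests.

Given a subject's anthropometrics and a ramp-test recording (time, power,
V̇O2, V̇E per breath), the composite model is slid along the V̇E channel to
produce a predicted V̇O2VENT trajectory; subtracting it from V̇O2 yields the
ventilation-corrected uptake V̇O2VCORR. The module also provides the
down-stream analyses: block averaging over breaths, interpolation of the
channels at fractions of peak power, final-window slopes, a paired t-test
on slopes, and one-/two-way within-subject repeated-measures ANOVA with the
Greenhouse–Geisser sphericity correction and Bonferroni pairwise follow-ups.

Only V̇E varies within a test; the other five predictors are fixed at the
subject's values. How the original analysis produced submaximal V̇O2VENT is
not documented, so this instantaneous-V̇E convention is the default and a
peak-anchored alternative (peak prediction scaled by V̇E(t)/V̇E_peak) is
available behind a flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import null_space

from .composite import CompositeCoefficients, evaluate_composite
from .dataset import ParticipantRecord, percent_of_max
from .exceptions import (
    DegenerateTestError,
    ExtrapolationError,
    IncompleteDesignError,
    InsufficientDataError,
    ShapeError,
    UnitsError,
)
from .gas_volume import VolumeConversionParams, btps_to_stpd

__all__ = [
    "RIETimeSeries",
    "CorrectionResult",
    "AnovaResult",
    "PairedTestResult",
    "average_breaths",
    "predict_vent_series",
    "correct_series",
    "intensity_table",
    "final_slope",
    "paired_slope_test",
    "rm_anova",
    "apply_correction",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.35, 0.55, 0.75, 0.85, 0.95, 1.00)


@dataclasses.dataclass
class RIETimeSeries:
    """Breath-wise channels of one ramp-incremental test.

    ``time`` is seconds (strictly increasing), ``power`` watts, ``vo2`` and
    ``ve`` L·min⁻¹; breathing frequency ``fr`` (min⁻¹) and tidal volume
    ``vt`` (L) are optional but, when present, must satisfy ve ≈ fr·vt
    within 10% per breath. ``averaging_width`` is the number of raw breaths
    behind each sample (1 = raw).
    """

    time: np.ndarray
    power: np.ndarray
    vo2: np.ndarray
    ve: np.ndarray
    fr: np.ndarray | None = None
    vt: np.ndarray | None = None
    ve_condition: str = "STPD"
    averaging_width: int = 1

    def __post_init__(self) -> None:
        for name in ("time", "power", "vo2", "ve"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("fr", "vt"):
            if getattr(self, name) is not None:
                setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        for name in ("power", "vo2", "ve", "fr", "vt"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ShapeError(f"channel {name!r} has length {len(ch)} != {n}")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ShapeError("time must be strictly increasing")
        if np.any(self.power < 0):
            raise ShapeError("power must be non-negative")
        if self.fr is not None and self.vt is not None:
            prod = self.fr * self.vt
            ok = prod > 0
            if np.any(np.abs(self.ve[ok] - prod[ok]) > 0.10 * prod[ok]):
                raise ShapeError("ve deviates from fr·vt by more than 10%")

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "time_s": self.time,
            "power_w": self.power,
            "vo2_lmin": self.vo2,
            "ve_lmin": self.ve,
        }
        if self.fr is not None:
            d["fr_bpm"] = self.fr
        if self.vt is not None:
            d["vt_l"] = self.vt
        return pd.DataFrame(d)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "RIETimeSeries":
        return cls(
            time=df["time_s"].to_numpy(),
            power=df["power_w"].to_numpy(),
            vo2=df["vo2_lmin"].to_numpy(),
            ve=df["ve_lmin"].to_numpy(),
            fr=df["fr_bpm"].to_numpy() if "fr_bpm" in df else None,
            vt=df["vt_l"].to_numpy() if "vt_l" in df else None,
            **kw,
        )

    @classmethod
    def read(cls, path, **kw) -> "RIETimeSeries":
        return cls.from_dataframe(pd.read_csv(path, sep=None, engine="python"), **kw)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclasses.dataclass
class CorrectionResult:
    """Predicted V̇O2VENT and V̇O2VCORR trajectories with summary analyses.

    Invariant: ``vo2vcorr_series = vo2 − vo2vent_series`` samplewise, so the
    two corrected channels always reconstruct the measured V̇O2 exactly.
    """

    time: np.ndarray
    power: np.ndarray
    vo2: np.ndarray
    vo2vent_series: np.ndarray
    vo2vcorr_series: np.ndarray
    wpeak: float | None = None
    intensity_table: pd.DataFrame | None = None
    slope_vo2: float | None = None
    slope_vo2vcorr: float | None = None
    percent_vent_at_max: float | None = None
    has_negative_vcorr: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "power_w": self.power,
                "vo2_lmin": self.vo2,
                "vo2vent_lmin": self.vo2vent_series,
                "vo2vcorr_lmin": self.vo2vcorr_series,
            }
        )


def average_breaths(raw: RIETimeSeries, width: int = 7) -> RIETimeSeries:
    """Non-overlapping `width`-breath block means of every channel.

    Block time is the mean breath time in the block; a trailing partial
    block is dropped. ``width=1`` is the identity.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    n = len(raw)
    if n < width:
        raise InsufficientDataError(f"need at least {width} breaths, got {n}")
    if width == 1:
        return dataclasses.replace(raw)
    m = n // width

    def block(ch):
        return None if ch is None else ch[: m * width].reshape(m, width).mean(axis=1)

    return RIETimeSeries(
        time=block(raw.time),
        power=block(raw.power),
        vo2=block(raw.vo2),
        ve=block(raw.ve),
        fr=block(raw.fr),
        vt=block(raw.vt),
        ve_condition=raw.ve_condition,
        averaging_width=raw.averaging_width * width,
    )


def predict_vent_series(
    coeffs: CompositeCoefficients,
    series: RIETimeSeries,
    subject: ParticipantRecord,
    *,
    rest_offset: bool = False,
    peak_anchored: bool = False,
    conversion: VolumeConversionParams | None = None,
) -> np.ndarray:
    """Predicted V̇O2VENT (L·min⁻¹) at each breath sample.

    The composite model is evaluated with V̇E equal to the instantaneous
    expired ventilation and every other predictor fixed at the subject's
    values; predictions are clamped at 0. ``rest_offset=True`` subtracts the
    prediction at the pre-ramp baseline V̇E (first sample), re-clamping at 0.
    ``peak_anchored=True`` switches to the alternative convention: the peak
    prediction scaled by V̇E(t)/V̇E_peak.

    A BTPS-tagged series requires `conversion` parameters, else
    :class:`UnitsError`.
    """
    ve = series.ve
    if series.ve_condition == "BTPS":
        if conversion is None:
            raise UnitsError(
                "series V̇E is BTPS; pass VolumeConversionParams to convert to STPD"
            )
        ve = btps_to_stpd(ve, conversion)

    if peak_anchored:
        peak = evaluate_composite(
            coeffs, subject.ve_peak, subject.age, subject.weight,
            subject.height, subject.vo2peak, subject.hr_max, warn_negative=False,
        )
        vent = peak * ve / subject.ve_peak
    else:
        vent = evaluate_composite(
            coeffs, ve, subject.age, subject.weight, subject.height,
            subject.vo2peak, subject.hr_max, warn_negative=False,
        )
    vent = np.atleast_1d(np.asarray(vent, dtype=float))
    if rest_offset:
        vent = np.clip(vent - vent[0], 0.0, None)
    return vent


def correct_series(series: RIETimeSeries, vent: np.ndarray) -> CorrectionResult:
    """Subtract a V̇O2VENT trajectory from V̇O2: V̇O2VCORR = V̇O2 − V̇O2VENT.

    Negative corrected values are permitted but flagged via
    ``has_negative_vcorr``.
    """
    vent = np.asarray(vent, dtype=float)
    if vent.shape != series.vo2.shape:
        raise ShapeError(
            f"vent trajectory length {len(vent)} != series length {len(series)}"
        )
    vcorr = series.vo2 - vent
    # store the rounded complement (≤ 1 ulp from the raw prediction) so that
    # vo2vent_series + vo2vcorr_series reconstructs vo2 exactly, samplewise
    vent_stored = series.vo2 - vcorr
    return CorrectionResult(
        time=series.time.copy(),
        power=series.power.copy(),
        vo2=series.vo2.copy(),
        vo2vent_series=vent_stored,
        vo2vcorr_series=vcorr,
        has_negative_vcorr=bool(np.any(vcorr < 0)),
    )


def intensity_table(
    result: CorrectionResult, fractions=DEFAULT_FRACTIONS
) -> pd.DataFrame:
    """Channels interpolated in power at each fraction of peak power (Wpeak).

    Wpeak is the maximum recorded power; each channel is linearly
    interpolated at fraction·Wpeak, using the *last* crossing of that power
    level when the power channel is non-monotone. Fraction 1.0 returns the
    peak-power sample itself. A fraction below the first sample's power
    raises :class:`ExtrapolationError`.
    """
    fractions = tuple(fractions)
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    p = result.power
    wpeak = float(p.max())
    ipeak = int(np.argmax(p))
    channels = {
        "vo2": result.vo2,
        "vo2vcorr": result.vo2vcorr_series,
        "vo2vent": result.vo2vent_series,
    }
    rows = []
    for f in fractions:
        target = f * wpeak
        if target < p[0] - 1e-12:
            raise ExtrapolationError(
                f"{f:.0%} of Wpeak ({target:g} W) precedes the first sample ({p[0]:g} W)"
            )
        if target >= wpeak:
            rows.append({k: float(v[ipeak]) for k, v in channels.items()})
            continue
        # last crossing of the level `target`
        d = p - target
        cross = np.flatnonzero(d[:-1] * d[1:] <= 0)
        i = int(cross[-1]) if len(cross) else int(np.flatnonzero(p <= target)[-1])
        if p[i + 1] == p[i]:
            frac = 0.0
        else:
            frac = (target - p[i]) / (p[i + 1] - p[i])
        rows.append(
            {k: float(v[i] + frac * (v[i + 1] - v[i])) for k, v in channels.items()}
        )
    out = pd.DataFrame(rows, index=pd.Index(fractions, name="fraction_of_wpeak"))
    return out


def final_slope(values, time, window: float = 30.0) -> float:
    """OLS slope of a channel over the final `window` seconds, per minute.

    Window membership is by time stamp, inclusive of both endpoints:
    samples with t in [t_end − window, t_end].
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    mask = time >= time[-1] - window
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"final_slope needs >= 3 samples in the last {window:g} s, got {int(mask.sum())}"
        )
    t, v = time[mask], values[mask]
    if np.ptp(v) == 0:
        return 0.0
    res = stats.linregress(t, v)
    return float(res.slope * 60.0)


@dataclasses.dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float


def paired_slope_test(slopes_a, slopes_b) -> PairedTestResult:
    """Paired t-test between per-subject slopes, with Cohen's d = mean(d)/sd(d)."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("slope vectors must be equal-length 1-D arrays")
    n = len(a)
    if n < 3:
        raise InsufficientDataError("paired test needs n >= 3")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, cohen_d=0.0, mean_diff=0.0)
        raise DegenerateTestError("zero-variance non-zero differences")
    res = stats.ttest_rel(a, b)
    d = float(diff.mean() / sd)
    return PairedTestResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue),
        cohen_d=d, mean_diff=float(diff.mean()),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclasses.dataclass
class AnovaResult:
    """Effect table (with Greenhouse–Geisser-corrected df/p) and pairwise follow-ups."""

    effects: pd.DataFrame
    pairwise: pd.DataFrame


def _contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal contrasts orthogonal to the constant vector."""
    return null_space(np.ones((1, k))).T


def _gg_epsilon_from_cov(S: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon for the contrast space C of covariance S."""
    M = C @ S @ C.T
    d = M.shape[0]
    if d == 0:
        return 1.0
    denom = d * float(np.sum(M * M))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(M)) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _snap(ss: float, ss_tot: float) -> float:
    """Zero-clip an SS term that is only float noise away from zero."""
    return 0.0 if ss <= 1e-12 * max(ss_tot, 1.0) else ss


def _effect_row(ss_eff, df_eff, ss_err, df_err, eps):
    if ss_eff <= 0:
        f = 0.0
    elif ss_err <= 0:
        f = float("inf")
    else:
        f = (ss_eff / df_eff) / (ss_err / df_err)
    if np.isfinite(f):
        p = float(stats.f.sf(f, df_eff, df_err)) if ss_err > 0 or f == 0.0 else 0.0
        p_gg = float(stats.f.sf(f, df_eff * eps, df_err * eps))
    else:
        p = p_gg = 0.0
    return {
        "ss": float(ss_eff), "df1": float(df_eff), "df2": float(df_err),
        "F": f, "eps": float(eps),
        "p_uncorrected": p,
        "df1_gg": float(df_eff * eps), "df2_gg": float(df_err * eps),
        "p_gg": p_gg,
    }


def _pairwise_paired(data: np.ndarray, labels, context: str) -> list[dict]:
    """All paired comparisons between columns of (n, k) data."""
    k = data.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        diff = data[:, i] - data[:, j]
        if diff.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if np.allclose(diff, 0) else (float("inf"), 0.0)
        else:
            res = stats.ttest_rel(data[:, i], data[:, j])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {"context": context, "level_1": labels[i], "level_2": labels[j],
             "t": t, "df": data.shape[0] - 1, "p_uncorrected": p,
             "p_bonferroni": min(1.0, p * len(pairs))}
        )
    return rows


def rm_anova(values, second_factor=None) -> AnovaResult:
    """Within-subject repeated-measures ANOVA with Greenhouse–Geisser correction.

    Parameters
    ----------
    values
        ``(n_subjects, k)`` matrix for a one-way design, or
        ``(n_subjects, a, b)`` for a two-way fully-within design.
    second_factor
        Alternative two-way entry point: a second ``(n_subjects, k)`` matrix
        measured under the same k conditions (e.g. corrected vs uncorrected
        V̇O2), stacked with `values` into an ``(n, k, 2)`` design.

    Returns an :class:`AnovaResult` whose ``effects`` table carries, per
    effect, the sums of squares, F, GG epsilon (estimated from the sample
    covariance of the repeated measures) and both uncorrected and
    GG-corrected p-values; ``pairwise`` holds Bonferroni-adjusted paired
    t follow-ups.
    """
    X = np.asarray(values, dtype=float)
    if second_factor is not None:
        B = np.asarray(second_factor, dtype=float)
        if B.shape != X.shape or X.ndim != 2:
            raise ShapeError("values and second_factor must be matching (n, k) matrices")
        X = np.stack([X, B], axis=2)
    if np.any(~np.isfinite(X)):
        raise IncompleteDesignError("design contains missing cells")
    if X.shape[0] < 3:
        raise InsufficientDataError("rm_anova needs >= 3 subjects")
    if X.ndim == 2:
        return _rm_anova_oneway(X)
    if X.ndim == 3:
        return _rm_anova_twoway(X)
    raise ShapeError("values must be 2-D (one-way) or 3-D (two-way)")


def _rm_anova_oneway(X: np.ndarray) -> AnovaResult:
    n, k = X.shape
    if k < 2:
        raise ShapeError("need at least 2 conditions")
    grand = X.mean()
    ss_tot = float(np.sum((X - grand) ** 2))
    ss_cond = n * float(np.sum((X.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((X.mean(axis=1) - grand) ** 2))
    ss_err = _snap(ss_tot - ss_cond - ss_subj, ss_tot)
    eps = _gg_epsilon_from_cov(np.cov(X, rowvar=False), _contrasts(k))
    row = _effect_row(_snap(ss_cond, ss_tot), k - 1, ss_err, (n - 1) * (k - 1), eps)
    effects = pd.DataFrame([row], index=pd.Index(["condition"], name="effect"))
    pairwise = pd.DataFrame(
        _pairwise_paired(X, [f"c{j}" for j in range(k)], "condition")
    )
    return AnovaResult(effects=effects, pairwise=pairwise)


def _rm_anova_twoway(X: np.ndarray) -> AnovaResult:
    n, a, b = X.shape
    if a < 2 or b < 2:
        raise ShapeError("each within factor needs at least 2 levels")
    grand = X.mean()
    mA = X.mean(axis=(0, 2))            # (a,)
    mB = X.mean(axis=(0, 1))            # (b,)
    mAB = X.mean(axis=0)                # (a, b)
    mS = X.mean(axis=(1, 2))            # (n,)
    mSA = X.mean(axis=2)                # (n, a)
    mSB = X.mean(axis=1)                # (n, b)

    ss_a = n * b * float(np.sum((mA - grand) ** 2))
    ss_b = n * a * float(np.sum((mB - grand) ** 2))
    ss_ab = n * float(np.sum((mAB - mA[:, None] - mB[None, :] + grand) ** 2))
    ss_s = a * b * float(np.sum((mS - grand) ** 2))
    ss_as = b * float(np.sum((mSA - mA[None, :] - mS[:, None] + grand) ** 2))
    ss_bs = a * float(np.sum((mSB - mB[None, :] - mS[:, None] + grand) ** 2))
    ss_tot = float(np.sum((X - grand) ** 2))
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    Ca, Cb = _contrasts(a), _contrasts(b)
    ones_a = np.ones((1, a)) / a
    ones_b = np.ones((1, b)) / b
    S = np.cov(X.reshape(n, a * b), rowvar=False)  # row-major: index = j*b + l
    eps_a = _gg_epsilon_from_cov(S, np.kron(Ca, ones_b))
    eps_b = _gg_epsilon_from_cov(S, np.kron(ones_a, Cb))
    eps_ab = _gg_epsilon_from_cov(S, np.kron(Ca, Cb))

    rows = {
        "factor_a": _effect_row(
            _snap(ss_a, ss_tot), a - 1, _snap(ss_as, ss_tot), (a - 1) * (n - 1), eps_a
        ),
        "factor_b": _effect_row(
            _snap(ss_b, ss_tot), b - 1, _snap(ss_bs, ss_tot), (b - 1) * (n - 1), eps_b
        ),
        "interaction": _effect_row(
            _snap(ss_ab, ss_tot), (a - 1) * (b - 1),
            _snap(ss_abs, ss_tot), (a - 1) * (b - 1) * (n - 1), eps_ab
        ),
    }
    effects = pd.DataFrame.from_dict(rows, orient="index")
    effects.index.name = "effect"

    pw: list[dict] = []
    # factor_b levels compared at each level of factor_a (e.g. measure at intensity)
    for j in range(a):
        pw.extend(_pairwise_paired(X[:, j, :], [f"b{l}" for l in range(b)], f"a{j}"))
    # factor_a levels compared within each level of factor_b
    for l in range(b):
        pw.extend(_pairwise_paired(X[:, :, l], [f"a{j}" for j in range(a)], f"b{l}"))
    return AnovaResult(effects=effects, pairwise=pd.DataFrame(pw))


# ---------------------------------------------------------------------------
# orchestration


def apply_correction(
    coeffs: CompositeCoefficients,
    series: RIETimeSeries,
    subject: ParticipantRecord,
    *,
    fractions=DEFAULT_FRACTIONS,
    window: float = 30.0,
    rest_offset: bool = False,
    peak_anchored: bool = False,
    conversion: VolumeConversionParams | None = None,
) -> CorrectionResult:
    """Full pipeline for one subject: trajectory, correction, %Wpeak table, slopes."""
    vent = predict_vent_series(
        coeffs, series, subject,
        rest_offset=rest_offset, peak_anchored=peak_anchored, conversion=conversion,
    )
    result = correct_series(series, vent)
    result.wpeak = float(series.power.max())
    result.intensity_table = intensity_table(result, fractions)
    result.slope_vo2 = final_slope(result.vo2, result.time, window)
    result.slope_vo2vcorr = final_slope(result.vo2vcorr_series, result.time, window)
    ipeak = int(np.argmax(series.power))
    result.percent_vent_at_max = percent_of_max(
        result.vo2vent_series[ipeak], result.vo2[ipeak]
    )
    return result
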