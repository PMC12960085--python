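"""Seeded synthetic ramp-test and cohort generator.

No raw breath-by-breath ramp data ship with the model, so this module
produces series with the statistical structure the application stage
assumes: power rises linearly at the ramp rate (36 W·min⁻¹ by default),
V̇O2 follows the steady-state demand through first-order (mono-exponential)
kinetics, and V̇E is linear in V̇O2 up to a gas-exchange threshold (GET)
after which an exponential excess term drives the disproportionate rise
seen near exhaustion. Tidal volume saturates while breathing frequency
climbs to supply V̇E (ve = fr·vt holds exactly by construction), the
inter-breath interval shortens accordingly, and multiplicative Gaussian
noise is applied per breath to V̇O2 and V̇E.

Cohorts are model-true by design: "measured" V̇O2VENT is drawn from the
composite family plus Gaussian noise, so validation-stage properties have
known ground truth. Anthropometrics are sampled uniformly within the
observed ranges of the packaged derivation cohort — simplicity over
realism; see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .composite import CompositeCoefficients, evaluate_composite
from .dataset import (
    CohortTable,
    ParticipantRecord,
    TABLE1_PREDICTOR_RANGES,
)
from .exceptions import InsufficientDataError
from .rie import RIETimeSeries

__all__ = ["SimParams", "generate_subject", "generate_cohort", "vo2_ramp_response"]


@dataclasses.dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate a ~10-min ramp to exhaustion.

    ``ramp_rate`` W·min⁻¹; ``vo2_gain`` L·min⁻¹ per W; ``tau`` s (V̇O2
    kinetics time constant); ``get_fraction`` the fraction of end-test V̇O2
    at which V̇E departs linearity; ``ve_slope_below`` L V̇E per L V̇O2;
    ``ve_excess_rate`` per L·min⁻¹ V̇O2 above the GET; ``breath_noise_sd``
    is the fractional (multiplicative) per-breath noise.
    """

    ramp_rate: float = 36.0
    baseline_power: float = 30.0
    test_duration: float = 600.0
    vo2_baseline: float = 0.9
    vo2_gain: float = 0.010
    tau: float = 35.0
    get_fraction: float = 0.6
    ve_slope_below: float = 24.0
    ve_excess_rate: float = 2.0
    vt_max: float = 2.6
    fr_base: float = 16.0
    breath_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.ramp_rate, self.test_duration, self.vo2_baseline, self.vo2_gain,
            self.tau, self.ve_slope_below, self.ve_excess_rate, self.vt_max,
            self.fr_base,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("rate/duration/gain parameters must be positive")
        if self.baseline_power < 0 or self.breath_noise_sd < 0:
            raise ValueError("baseline_power and breath_noise_sd must be >= 0")
        if not (0 < self.get_fraction < 1):
            raise ValueError("get_fraction must lie in (0, 1)")


def vo2_ramp_response(t, params: SimParams):
    """Noise-free V̇O2 at time `t` (s) of the ramp.

    Exact first-order response to a linearly increasing demand: with
    G = vo2_gain·ramp_rate/60 (L·min⁻¹ per s),

        V̇O2(t) = V̇O2_base + gain·P_base + G·(t − τ + τ·e^(−t/τ))

    starting from steady state at the baseline power.
    """
    t = np.asarray(t, dtype=float)
    g_per_s = params.vo2_gain * params.ramp_rate / 60.0
    out = (
        params.vo2_baseline
        + params.vo2_gain * params.baseline_power
        + g_per_s * (t - params.tau + params.tau * np.exp(-t / params.tau))
    )
    return float(out) if out.ndim == 0 else out


def _ve_demand(vo2, vo2_get: float, params: SimParams):
    vo2 = np.asarray(vo2, dtype=float)
    ve = params.ve_slope_below * vo2
    excess = np.where(
        vo2 > vo2_get,
        np.exp(params.ve_excess_rate * np.clip(vo2 - vo2_get, 0, None)) - 1.0,
        0.0,
    )
    out = ve + excess
    return float(out) if out.ndim == 0 else out


def generate_subject(
    params: SimParams,
    anthropometrics: Mapping | None = None,
) -> tuple[ParticipantRecord, RIETimeSeries]:
    """One synthetic subject: a participant record and their ramp-test series.

    `anthropometrics` may supply ``subject_id``, ``age``, ``weight``,
    ``height``, ``hr_max`` and ``sex``; missing entries fall back to a
    mid-range adult (30 y, 72 kg, 176 cm, hr_max 220 − age). ``ve_peak`` and
    ``vo2peak`` are written back from the generated series. Fully
    reproducible for a given ``params.seed``.
    """
    skel = dict(anthropometrics or {})
    age = float(skel.get("age", 30.0))
    weight = float(skel.get("weight", 72.0))
    height = float(skel.get("height", 176.0))
    hr_max = float(skel.get("hr_max", 220.0 - age))
    rng = np.random.default_rng(params.seed)

    vo2_end = vo2_ramp_response(params.test_duration, params)
    vo2_get = params.get_fraction * vo2_end

    times, powers, vo2s, ves = [], [], [], []
    t = 0.0
    while t <= params.test_duration:
        v_nf = vo2_ramp_response(t, params)
        ve_nf = _ve_demand(v_nf, vo2_get, params)
        times.append(t)
        powers.append(params.baseline_power + params.ramp_rate * t / 60.0)
        vo2s.append(v_nf * (1.0 + params.breath_noise_sd * rng.standard_normal()))
        ves.append(ve_nf * (1.0 + params.breath_noise_sd * rng.standard_normal()))
        # breath interval from the current ventilatory demand
        vt_nf = params.vt_max * np.tanh(ve_nf / (params.fr_base * params.vt_max))
        fr_nf = ve_nf / vt_nf
        t += 60.0 / fr_nf

    time = np.array(times)
    ve = np.clip(np.array(ves), 1e-6, None)
    vo2 = np.clip(np.array(vo2s), 1e-6, None)
    # tidal volume saturates; frequency supplies the rest (ve = fr·vt exactly)
    vt = params.vt_max * np.tanh(ve / (params.fr_base * params.vt_max))
    fr = ve / vt

    series = RIETimeSeries(
        time=time, power=np.array(powers), vo2=vo2, ve=ve, fr=fr, vt=vt,
        ve_condition="STPD", averaging_width=1,
    )
    record = ParticipantRecord(
        subject_id=str(skel.get("subject_id", f"sim-{params.seed}")),
        ve_peak=float(ve.max()),
        age=age,
        weight=weight,
        height=height,
        vo2peak=float(vo2.max()),
        hr_max=hr_max,
        vo2vent_measured=None,
        sex=str(skel.get("sex", "unknown")),
    )
    return record, series


def generate_cohort(
    n: int,
    params: SimParams | None = None,
    coeffs: CompositeCoefficients | None = None,
    noise_sd: float = 0.13,
    seed: int = 0,
) -> CohortTable:
    """A model-true cohort with "measured" V̇O2VENT.

    Anthropometrics are drawn uniformly within the observed ranges of the
    packaged derivation cohort; measured V̇O2VENT is the composite-model
    prediction plus Gaussian(0, `noise_sd`) noise, redrawn in the rare case
    a draw leaves the physiological band (0, vo2peak).
    """
    if n < 14:
        raise InsufficientDataError(f"generate_cohort needs n >= 14, got {n}")
    if coeffs is None:
        from .composite import published_composite

        coeffs = published_composite()
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in TABLE1_PREDICTOR_RANGES.items():
        cols[name] = rng.uniform(lo, hi, n)
    pred = evaluate_composite(
        coeffs, cols["ve_peak"], cols["age"], cols["weight"], cols["height"],
        cols["vo2peak"], cols["hr_max"], clip_negative=False,
    )
    measured = pred + noise_sd * rng.standard_normal(n)
    for _ in range(100):
        bad = (measured <= 0) | (measured >= cols["vo2peak"])
        if not np.any(bad):
            break
        measured[bad] = pred[bad] + noise_sd * rng.standard_normal(int(bad.sum()))
    measured = np.clip(measured, 1e-3, cols["vo2peak"] * 0.999)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            **{k: cols[k] for k in ("ve_peak", "age", "weight", "height", "vo2peak", "hr_max")},
            "vo2vent_measured": measured,
            "sex": "unknown",
        }
    )
    return CohortTable(df=df, volume_condition="STPD")
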