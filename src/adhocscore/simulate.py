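"""Synthetic trauma-registry cohorts with configurable, registry-like structure.

The generator emulates the marginal structure of a large European trauma
registry cohort of adults with major fractures: an age distribution
(truncated normal, mean 49.9 y, SD 21.4), published marginal prevalences of
the dichotomized trauma-bay risk parameters (GCS < 12 in 24.1%, SBP <= 90
mmHg in 15.5%, INR > 1.4 in 15.6%, Hb < 7 in 3.8%, hemothorax in 10.0%,
base excess <= -6 mmol/L in 22.3%, Horowitz ratio <= 200 in 52.5% of
intubated patients, 66.5% male, 97.5% blunt trauma), and outcomes driven
either by aspect-level log-odds (adjusted odds ratios 4.9 / 5.1 / 2.6 / 4.1
for the Age / Head / Oxygenation / Circulation aspects, intercept calibrated
to an overall mortality of 11.9%) or by a per-score outcome table
(mortality 0.3 / 5.3 / 15.6 / 42.5 / 62.6% for scores 0-4).

Dependence between risk parameters is a one-factor Gaussian-copula
threshold model: each binary indicator is the event that a latent standard
normal — a mixture of a shared "severity" factor and idiosyncratic noise —
exceeds the quantile matching its configured prevalence.  Continuous values
are then drawn from sub- or supra-threshold intervals consistent with their
own indicator, so marginal prevalences are exact by construction.

Randomness: every variable owns a dedicated, named substream derived from
the root seed, and each substream is consumed in record order; growing the
cohort size therefore extends the cohort without reshuffling earlier
records.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.special import expit

from .records import PatientRecord

ASPECTS = ("age", "head", "oxygenation", "circulation")


class AgeModel(BaseModel):
    """Truncated-normal admission age, years."""

    mean: float = 49.9
    sd: float = Field(21.4, gt=0)
    lower: float = 16.0
    upper: float = 100.0


class Marginals(BaseModel):
    """Marginal prevalences of the dichotomized risk parameters.

    ``pf_le_200`` is conditional on intubation; everything else is a plain
    marginal.  Intubation and pRBC transfusion prevalences are not published
    for the reference cohort and default to modeling choices (a high
    intubation rate is characteristic of the registry's population).
    """

    male: float = Field(0.665, ge=0, le=1)
    blunt: float = Field(0.975, ge=0, le=1)
    gcs_lt_12: float = Field(0.241, ge=0, le=1)
    ecs_motor_abnormal: float = Field(0.12, ge=0, le=1)
    ecs_pupil_size_abnormal: float = Field(0.12, ge=0, le=1)
    ecs_pupil_reactivity_abnormal: float = Field(0.12, ge=0, le=1)
    hemothorax: float = Field(0.100, ge=0, le=1)
    be_le_minus6: float = Field(0.223, ge=0, le=1)
    intubated: float = Field(0.40, ge=0, le=1)
    pf_le_200: float = Field(0.525, ge=0, le=1)
    sbp_le_90: float = Field(0.155, ge=0, le=1)
    prbc_transfused: float = Field(0.15, ge=0, le=1)
    inr_gt_1_4: float = Field(0.156, ge=0, le=1)
    hb_lt_7: float = Field(0.038, ge=0, le=1)
    fracture_femur: float = Field(0.43, ge=0, le=1)
    fracture_tibia: float = Field(0.34, ge=0, le=1)
    fracture_pelvis: float = Field(0.49, ge=0, le=1)


#: indicators coupled through the latent severity factor by default
_RISK_INDICATORS = (
    "gcs_lt_12", "ecs_motor_abnormal", "ecs_pupil_size_abnormal",
    "ecs_pupil_reactivity_abnormal", "hemothorax", "be_le_minus6",
    "intubated", "pf_le_200", "sbp_le_90", "prbc_transfused",
    "inr_gt_1_4", "hb_lt_7",
)
_INDEPENDENT_INDICATORS = (
    "male", "blunt", "fracture_femur", "fracture_tibia", "fracture_pelvis",
)


class Interval(BaseModel):
    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "Interval":
        if self.low > self.high:
            raise ValueError("interval bounds out of order")
        return self


class ConditionalRanges(BaseModel):
    """Uniform intervals for continuous values, conditional on the value's
    own threshold indicator (``pos`` = threshold crossed).  Defaults are
    clinically plausible trauma-bay ranges chosen to be strictly consistent
    with the score thresholds."""

    sbp_pos: Interval = Interval(low=50.0, high=90.0)
    sbp_neg: Interval = Interval(low=92.0, high=160.0)
    be_pos: Interval = Interval(low=-16.0, high=-6.0)
    be_neg: Interval = Interval(low=-5.8, high=4.0)
    inr_pos: Interval = Interval(low=1.5, high=4.5)
    inr_neg: Interval = Interval(low=0.85, high=1.4)
    hb_pos: Interval = Interval(low=3.0, high=6.9)
    hb_neg: Interval = Interval(low=7.0, high=17.0)
    pf_pos: Interval = Interval(low=60.0, high=200.0)
    pf_neg: Interval = Interval(low=205.0, high=480.0)


class AspectLogisticModel(BaseModel):
    """Outcome as Bernoulli(expit(intercept + sum of aspect log-odds))."""

    or_age: float = Field(4.9, gt=0)
    or_head: float = Field(5.1, gt=0)
    or_oxygenation: float = Field(2.6, gt=0)
    or_circulation: float = Field(4.1, gt=0)
    intercept: Optional[float] = None  # None -> calibrate to target_rate
    target_rate: float = Field(0.119, gt=0, lt=1)

    @property
    def log_ors(self) -> np.ndarray:
        return np.log([self.or_age, self.or_head, self.or_oxygenation, self.or_circulation])


class ScoreTableModel(BaseModel):
    """Outcome probability looked up by total score 0..4."""

    probs: list[float] = Field(default_factory=lambda: [0.003, 0.053, 0.156, 0.425, 0.626])
    monotone: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ScoreTableModel":
        if len(self.probs) != 5:
            raise ValueError("score table needs exactly 5 entries (scores 0..4)")
        if any(not (0 <= p <= 1) for p in self.probs):
            raise ValueError("score-table probabilities must lie in [0, 1]")
        if self.monotone and any(b < a for a, b in zip(self.probs, self.probs[1:])):
            raise ValueError("score table must be monotone non-decreasing")
        return self


class OutcomeModel(BaseModel):
    mode: Literal["aspect_logistic", "score_table"] = "aspect_logistic"
    aspect_logistic: AspectLogisticModel = AspectLogisticModel()
    score_table: ScoreTableModel = ScoreTableModel()


class LosModel(BaseModel):
    """Lognormal length of stay, mean (days) indexed by score value."""

    icu_means: list[float] = Field(default_factory=lambda: [4.1, 7.2, 13.2, 14.3, 12.1])
    hosp_means: list[float] = Field(default_factory=lambda: [21.2, 24.8, 29.6, 25.6, 18.1])
    sigma: float = Field(0.8, gt=0)


class SimulationConfig(BaseModel):
    n: int = Field(1000, ge=0)
    seed: int = 0
    age_model: AgeModel = AgeModel()
    marginals: Marginals = Marginals()
    default_loading: float = Field(0.3, ge=0, lt=1)
    loadings: dict[str, float] = Field(default_factory=dict)
    ranges: ConditionalRanges = ConditionalRanges()
    mortality: OutcomeModel = OutcomeModel()
    mof: OutcomeModel = OutcomeModel(
        mode="score_table",
        score_table=ScoreTableModel(probs=[0.055, 0.189, 0.377, 0.624, 0.763]),
    )
    los: LosModel = LosModel()
    missingness: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name, lam in self.loadings.items():
            if name not in _RISK_INDICATORS + _INDEPENDENT_INDICATORS:
                raise ValueError(f"loadings: unknown indicator {name!r}")
            if not (0 <= lam < 1):
                raise ValueError(f"loadings[{name!r}] must lie in [0, 1)")
        for name, p in self.missingness.items():
            if name not in PatientRecord.__dataclass_fields__:
                raise ValueError(f"missingness: unknown field {name!r}")
            if not (0 <= p <= 1):
                raise ValueError(f"missingness[{name!r}] must lie in [0, 1]")
        return self

    def loading_of(self, name: str) -> float:
        if name in self.loadings:
            return self.loadings[name]
        return self.default_loading if name in _RISK_INDICATORS else 0.0


# ---------------------------------------------------------------------------
# named, ordered substreams: one per variable, consumed in record order


_STREAM_NAMES = (
    ("factor",)
    + _RISK_INDICATORS
    + _INDEPENDENT_INDICATORS
    + (
        "age", "gcs_value", "ecs_motor_kind", "sbp_value", "be_value",
        "inr_value", "hb_value", "pf_value", "fracture_combo",
        "death", "mof", "icu_los", "hosp_los", "calibration",
    )
    + tuple(f"miss_{f}" for f in PatientRecord.__dataclass_fields__)
)
_STREAM_IDS = {name: i for i, name in enumerate(_STREAM_NAMES)}


def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_IDS[name],)))


def _draw_indicators(config: SimulationConfig, n: int) -> dict[str, np.ndarray]:
    """Latent-threshold draw of every binary indicator (boolean arrays)."""
    factor = _rng(config.seed, "factor").standard_normal(n)
    out: dict[str, np.ndarray] = {}
    for name in _RISK_INDICATORS + _INDEPENDENT_INDICATORS:
        p = getattr(config.marginals, name)
        lam = config.loading_of(name)
        eps = _rng(config.seed, name).standard_normal(n)
        z = lam * factor + math.sqrt(1.0 - lam * lam) * eps
        out[name] = z > stats.norm.ppf(1.0 - p) if p > 0 else np.zeros(n, dtype=bool)
    return out


def _draw_ages(config: SimulationConfig, n: int) -> np.ndarray:
    am = config.age_model
    a = (am.lower - am.mean) / am.sd
    b = (am.upper - am.mean) / am.sd
    u = _rng(config.seed, "age").random(n)
    ages = stats.truncnorm.ppf(u, a, b, loc=am.mean, scale=am.sd)
    return np.floor(ages).astype(int)


def _conditional_uniform(
    config: SimulationConfig, stream: str, indicator: np.ndarray,
    pos: Interval, neg: Interval,
) -> np.ndarray:
    u = _rng(config.seed, stream).random(indicator.shape[0])
    lo = np.where(indicator, pos.low, neg.low)
    hi = np.where(indicator, pos.high, neg.high)
    return lo + u * (hi - lo)


def _aspect_matrix(ind: dict[str, np.ndarray], ages: np.ndarray) -> np.ndarray:
    """n x 4 boolean matrix of the true aspect indicators, in aspect order."""
    head = (
        ind["gcs_lt_12"] | ind["ecs_motor_abnormal"]
        | ind["ecs_pupil_size_abnormal"] | ind["ecs_pupil_reactivity_abnormal"]
    )
    oxy = ind["hemothorax"] | ind["be_le_minus6"] | (ind["intubated"] & ind["pf_le_200"])
    circ = ind["sbp_le_90"] | ind["prbc_transfused"] | ind["inr_gt_1_4"] | ind["hb_lt_7"]
    return np.column_stack([ages > 65, head, oxy, circ])


def calibrate_intercept(
    config: SimulationConfig,
    target_mortality: Optional[float] = None,
    n_calibration: int = 100_000,
    tol: float = 1e-3,
) -> float:
    """Intercept (log-odds) making mean simulated mortality hit the target.

    Bisection on a fixed-seed calibration cohort of aspect indicators; the
    mean of expit(c + X @ beta) is strictly increasing in c, so the root is
    unique.  Tolerance is 0.1 percentage points on the mortality scale.
    Raises ``ValueError`` when the target is unattainable within the
    intercept bounds [-15, 5] (e.g. a target of exactly 0).
    """
    if config.mortality.mode != "aspect_logistic":
        raise ValueError("intercept calibration applies to aspect_logistic mode only")
    model = config.mortality.aspect_logistic
    if target_mortality is None:
        target_mortality = model.target_rate
    calib = config.model_copy(update={"seed": _calibration_seed(config.seed)})
    ind = _draw_indicators(calib, n_calibration)
    ages = _draw_ages(calib, n_calibration)
    eta_aspects = _aspect_matrix(ind, ages).astype(float) @ model.log_ors

    def mean_mortality(c: float) -> float:
        return float(np.mean(expit(c + eta_aspects)))

    lo, hi = -15.0, 5.0
    if not (mean_mortality(lo) <= target_mortality <= mean_mortality(hi)):
        raise ValueError(
            f"target mortality {target_mortality} unattainable for intercept in [{lo}, {hi}]")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = mean_mortality(mid)
        if abs(m - target_mortality) <= tol:
            return mid
        if m < target_mortality:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _calibration_seed(seed: int) -> int:
    # deterministic companion seed for the calibration cohort, kept < 2^31
    return (seed * 2654435761 + 97) % (2**31)


def _outcome_probs(
    model: OutcomeModel, aspects: np.ndarray, scores: np.ndarray, intercept: Optional[float],
) -> np.ndarray:
    if model.mode == "score_table":
        return np.asarray(model.score_table.probs)[scores]
    assert intercept is not None
    return expit(intercept + aspects.astype(float) @ model.aspect_logistic.log_ors)


def generate_cohort_with_truth(
    config: SimulationConfig,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate the cohort plus a per-patient truth table.

    The truth table records, for every patient, the latent aspect indicators
    (evaluated before any missingness is applied), the resulting true score,
    and the linear predictor / probability used to draw death — the oracle
    against which scoring and model-recovery code can be tested.
    """
    n = config.n
    m = config.marginals
    r = config.ranges
    ind = _draw_indicators(config, n)
    ages = _draw_ages(config, n)

    gcs_u = _rng(config.seed, "gcs_value").random(n)
    gcs = np.where(
        ind["gcs_lt_12"],
        3 + np.floor(gcs_u * 9),     # 3..11
        12 + np.floor(gcs_u * 4),    # 12..15
    ).astype(int)
    motor_u = _rng(config.seed, "ecs_motor_kind").random(n)
    ecs_motor = np.where(
        ind["ecs_motor_abnormal"],
        np.where(motor_u < 0.5, "non_specific", "none"),
        "normal",
    )
    sbp = _conditional_uniform(config, "sbp_value", ind["sbp_le_90"], r.sbp_pos, r.sbp_neg)
    be = _conditional_uniform(config, "be_value", ind["be_le_minus6"], r.be_pos, r.be_neg)
    inr = _conditional_uniform(config, "inr_value", ind["inr_gt_1_4"], r.inr_pos, r.inr_neg)
    hb = _conditional_uniform(config, "hb_value", ind["hb_lt_7"], r.hb_pos, r.hb_neg)
    pf = _conditional_uniform(config, "pf_value", ind["pf_le_200"], r.pf_pos, r.pf_neg)

    # fracture pattern: joint distribution of the three flags conditioned on
    # at least one fracture (the cohort is defined by major fractures), drawn
    # with a single uniform per record for stream stability
    combos = [(p, f, t) for p in (0, 1) for f in (0, 1) for t in (0, 1)][1:]
    probs = np.array([
        (m.fracture_pelvis if p else 1 - m.fracture_pelvis)
        * (m.fracture_femur if f else 1 - m.fracture_femur)
        * (m.fracture_tibia if t else 1 - m.fracture_tibia)
        for p, f, t in combos
    ])
    probs /= probs.sum()
    combo_idx = np.searchsorted(np.cumsum(probs), _rng(config.seed, "fracture_combo").random(n))
    combo_arr = np.array(combos)[combo_idx]

    aspects = _aspect_matrix(ind, ages)
    scores = aspects.sum(axis=1)

    intercept = None
    if config.mortality.mode == "aspect_logistic":
        intercept = config.mortality.aspect_logistic.intercept
        if intercept is None:
            intercept = calibrate_intercept(config)
    p_death = _outcome_probs(config.mortality, aspects, scores, intercept)
    died = _rng(config.seed, "death").random(n) < p_death

    mof_intercept = None
    if config.mof.mode == "aspect_logistic":
        mof_intercept = config.mof.aspect_logistic.intercept
        if mof_intercept is None:
            mof_cfg = config.model_copy(update={"mortality": config.mof})
            mof_intercept = calibrate_intercept(mof_cfg)
    p_mof = _outcome_probs(config.mof, aspects, scores, mof_intercept)
    mof = _rng(config.seed, "mof").random(n) < p_mof

    sig = config.los.sigma
    icu_mu = np.log(np.asarray(config.los.icu_means))[scores] - 0.5 * sig**2
    hosp_mu = np.log(np.asarray(config.los.hosp_means))[scores] - 0.5 * sig**2
    icu_los = np.exp(icu_mu + sig * _rng(config.seed, "icu_los").standard_normal(n))
    hosp_los = np.exp(hosp_mu + sig * _rng(config.seed, "hosp_los").standard_normal(n))

    miss_draws = {
        f: _rng(config.seed, f"miss_{f}").random(n) < p
        for f, p in config.missingness.items() if p > 0
    }

    width = max(6, len(str(max(n, 1))))
    records: list[PatientRecord] = []
    for i in range(n):
        rec = PatientRecord(
            id=f"sim-{i + 1:0{width}d}",
            age=int(ages[i]),
            sex="male" if ind["male"][i] else "female",
            mechanism="blunt" if ind["blunt"][i] else "penetrating",
            gcs=int(gcs[i]),
            ecs_motor=str(ecs_motor[i]),
            ecs_pupil_size="not_normal" if ind["ecs_pupil_size_abnormal"][i] else "normal",
            ecs_pupil_reactivity="not_normal" if ind["ecs_pupil_reactivity_abnormal"][i] else "normal",
            base_excess=round(float(be[i]), 2),
            intubated=bool(ind["intubated"][i]),
            pao2_fio2=round(float(pf[i]), 1) if ind["intubated"][i] else None,
            hemothorax=bool(ind["hemothorax"][i]),
            sbp=round(float(sbp[i]), 1),
            hb=round(float(hb[i]), 2),
            inr=round(float(inr[i]), 2),
            prbc_transfused=bool(ind["prbc_transfused"][i]),
            fracture_pelvis=bool(combo_arr[i, 0]),
            fracture_femur=bool(combo_arr[i, 1]),
            fracture_tibia=bool(combo_arr[i, 2]),
            secondary_admission=False,
            transferred_out_within_48h=False,
            died=bool(died[i]),
            mof=bool(mof[i]),
            icu_los=round(float(icu_los[i]), 1),
            hosp_los=round(float(hosp_los[i]), 1),
        )
        for f, mask in miss_draws.items():
            if mask[i]:
                setattr(rec, f, None)
        records.append(rec)

    eta = (
        (intercept if intercept is not None else np.nan)
        + aspects.astype(float) @ config.mortality.aspect_logistic.log_ors
        if config.mortality.mode == "aspect_logistic"
        else np.full(n, np.nan)
    )
    truth = pd.DataFrame({
        "id": [rec.id for rec in records],
        "aspect_age": aspects[:, 0],
        "aspect_head": aspects[:, 1],
        "aspect_oxygenation": aspects[:, 2],
        "aspect_circulation": aspects[:, 3],
        "true_score": scores,
        "linear_predictor": np.round(eta, 6) if np.ndim(eta) else eta,
        "p_death": np.round(p_death, 6),
        "p_mof": np.round(p_mof, 6),
    })
    return records, truth


def generate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate ``config.n`` synthetic patient records (see module docstring).

    Identical (config, seed) always yields the identical cohort, and the
    first ``k`` records do not change when ``n`` is increased.
    """
    records, _ = generate_cohort_with_truth(config)
    return records


__all__ = [
    "AgeModel",
    "Marginals",
    "Interval",
    "ConditionalRanges",
    "AspectLogisticModel",
    "ScoreTableModel",
    "OutcomeModel",
    "LosModel",
    "SimulationConfig",
    "generate_cohort",
    "generate_cohort_with_truth",
    "calibrate_intercept",
]
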