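"""Synthetic ischemic-stroke cohort generator.

Each case carries a latent etiological subtype, baseline covariates drawn from
subtype-specific marginals, diagnostic findings emitted from the subtype, an
investigation profile that masks findings to "unknown" when the corresponding
test was not done, and competing-risks follow-up outcomes (subsequent stroke,
death, censoring) with constant hazards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import (
    EVENT_CENSORED,
    EVENT_DEATH,
    EVENT_STROKE,
    STROKE_BLANKING_YEARS,
    SUBTYPES,
    ConfigError,
    GeneratorConfig,
    Hazards,
    region_subtype_weights,
)

AGE_BOUNDS = (30.0, 79.0)
SBP_BOUNDS = (60.0, 260.0)
DBP_BOUNDS = (30.0, 160.0)
BMI_BOUNDS = (12.0, 60.0)

COHORT_COLUMNS = [
    "case_id", "region_id", "urban", "true_subtype",
    "age", "sex", "diabetes", "chd", "hypertension", "bp_meds",
    "smoker", "drinker", "family_history_stroke", "health_insurance",
    "sbp", "dbp", "bmi",
    "brain_imaging_done", "cardiac_test_done", "vascular_imaging_done",
    "cardioaortic_source", "ipsilateral_stenosis_ge50", "infarct_pattern", "laci_syndrome",
    "silent_infarct",
    "t_stroke", "t_death", "t_censor", "time", "event",
]

_BOOL_COLUMNS = [
    "urban", "diabetes", "chd", "hypertension", "bp_meds", "smoker", "drinker",
    "family_history_stroke", "health_insurance",
    "brain_imaging_done", "cardiac_test_done", "vascular_imaging_done", "silent_infarct",
]
_TIME_COLUMNS = ["t_stroke", "t_death", "t_censor", "time"]


@dataclass
class EventOutcome:
    """Follow-up outcome of one case; +inf marks an event that never occurs."""

    t_stroke: float
    t_death: float
    t_censor: float

    @property
    def first_event(self) -> tuple[float, str]:
        t = min(self.t_stroke, self.t_death, self.t_censor)
        if t == self.t_stroke:
            return t, EVENT_STROKE
        if t == self.t_death:
            return t, EVENT_DEATH
        return t, EVENT_CENSORED


def _exp_times(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def simulate_competing_exponentials(
    n: int,
    lam_stroke: float,
    lam_death: float,
    *,
    censor_rate: float = 0.0,
    admin_years: float = np.inf,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """First-event data (``time``, ``event``) under competing constant hazards.

    Latent stroke, death and loss-to-follow-up times are independent
    exponentials; follow-up is administratively cut at ``admin_years``.
    """
    if lam_stroke < 0 or lam_death < 0 or censor_rate < 0:
        raise ValueError("hazard rates must be >= 0")
    t_s = _exp_times(rng, lam_stroke, n)
    t_d = _exp_times(rng, lam_death, n)
    t_c = np.minimum(_exp_times(rng, censor_rate, n), admin_years)
    time = np.minimum.reduce([t_s, t_d, t_c])
    event = np.where(t_s == time, EVENT_STROKE, np.where(t_d == time, EVENT_DEATH, EVENT_CENSORED))
    return pd.DataFrame({"time": time, "event": event, "t_stroke": t_s, "t_death": t_d, "t_censor": t_c})


def sample_outcome(
    subtype: str,
    hazards: dict[str, Hazards],
    followup_years: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> EventOutcome:
    """Draw one case's follow-up outcome.

    Subsequent-stroke times are left-truncated at 28 days (memorylessness makes
    this a shift) and only recorded when the stroke precedes death; death is
    observed regardless of a prior non-fatal stroke.
    """
    if followup_years <= 0:
        raise ConfigError("followup_years must be > 0")
    h = hazards[subtype]
    if h.stroke < 0 or h.death < 0 or censor_rate < 0:
        raise ConfigError("hazard rates must be >= 0")
    t_s, t_d, t_c = _sample_outcome_arrays(1, h.stroke, h.death, followup_years, censor_rate, rng)
    return EventOutcome(t_stroke=float(t_s[0]), t_death=float(t_d[0]), t_censor=float(t_c[0]))


def _sample_outcome_arrays(n, lam_s, lam_d, followup_years, censor_rate, rng):
    lat_s = STROKE_BLANKING_YEARS + _exp_times(rng, lam_s, n)
    t_d = _exp_times(rng, lam_d, n)
    t_s = np.where(lat_s < t_d, lat_s, np.inf)
    t_c = np.minimum(_exp_times(rng, censor_rate, n), followup_years)
    return t_s, t_d, t_c


def _truncnorm(rng, mean, sd, bounds, n):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: GeneratorConfig, n: int, seed: int | None = None) -> pd.DataFrame:
    """Generate ``n`` case records; identical (config, n, seed) gives identical output."""
    config.validate()
    if n < 1:
        raise ValueError("cannot generate an empty cohort (n must be >= 1)")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # region and latent subtype
    if config.region_table is not None:
        region_ids = np.array([r.region_id for r in config.region_table])
        urban_by_region = {r.region_id: r.urban for r in config.region_table}
        region = rng.choice(region_ids, size=n)
        weights = region_subtype_weights(config)
        probs = np.array([[weights[r][s] for s in SUBTYPES] for r in region_ids])
        cum = probs.cumsum(axis=1)
        row = np.searchsorted(region_ids, region)
        u = rng.random(n)
        sub_idx = (u[:, None] > cum[row]).sum(axis=1)
        urban = np.array([urban_by_region[r] for r in region])
    else:
        region = np.zeros(n, dtype=int)
        w = np.array([config.subtype_weights[s] for s in SUBTYPES])
        sub_idx = rng.choice(len(SUBTYPES), size=n, p=w)
        urban = np.zeros(n, dtype=bool)  # filled from covariate params below
    subtype = np.array(SUBTYPES)[sub_idx]

    def per_subtype(attr):
        vals = np.array([getattr(config.covariate_params[s], attr) for s in SUBTYPES])
        return vals[sub_idx]

    female = rng.random(n) < per_subtype("female_frac")
    if config.region_table is None:
        urban = rng.random(n) < per_subtype("urban_frac")

    df = pd.DataFrame({
        "case_id": [f"case_{i:06d}" for i in range(n)],
        "region_id": region,
        "urban": urban,
        "true_subtype": subtype,
        "sex": np.where(female, "female", "male"),
    })
    # continuous covariates, truncated normals per subtype
    for col, mean_attr, sd_attr, bounds in (
        ("age", "age_mean", "age_sd", AGE_BOUNDS),
        ("sbp", "sbp_mean", "sbp_sd", SBP_BOUNDS),
        ("dbp", "dbp_mean", "dbp_sd", DBP_BOUNDS),
        ("bmi", "bmi_mean", "bmi_sd", BMI_BOUNDS),
    ):
        x = np.empty(n)
        for k, s in enumerate(SUBTYPES):
            mask = sub_idx == k
            if mask.any():
                p = config.covariate_params[s]
                x[mask] = _truncnorm(rng, getattr(p, mean_attr), getattr(p, sd_attr), bounds, int(mask.sum()))
        df[col] = x
    for col, attr in (
        ("diabetes", "diabetes"), ("chd", "chd"), ("hypertension", "hypertension"),
        ("bp_meds", "bp_meds"), ("family_history_stroke", "family_history_stroke"),
        ("health_insurance", "health_insurance"),
    ):
        df[col] = rng.random(n) < per_subtype(attr)
    smoke_p = np.where(female, per_subtype("smoking_female"), per_subtype("smoking_male"))
    drink_p = np.where(female, per_subtype("drinking_female"), per_subtype("drinking_male"))
    df["smoker"] = rng.random(n) < smoke_p
    df["drinker"] = rng.random(n) < drink_p

    # true findings emitted from the latent subtype
    def emission(attr):
        vals = np.array([getattr(config.emission_probs[s], attr) for s in SUBTYPES])
        return vals[sub_idx]

    u = rng.random(n)
    p_none, p_low = emission("source_none"), emission("source_low")
    source = np.where(u < p_none, "none", np.where(u < p_none + p_low, "low_risk", "high_risk"))
    stenosis = np.where(rng.random(n) < emission("stenosis_yes"), "yes", "no")
    u = rng.random(n)
    p_lac, p_ter, p_mul = emission("pattern_lacunar"), emission("pattern_territorial"), emission("pattern_multi")
    pattern = np.select(
        [u < p_lac, u < p_lac + p_ter, u < p_lac + p_ter + p_mul],
        ["lacunar_lt20mm", "territorial", "multi_territory"],
        default="none_visible",
    )
    laci = np.where(rng.random(n) < emission("laci_yes"), "yes", "no")

    # investigation availability, independent per test
    p_brain, p_cardiac, p_vascular = config.availability_probs
    brain = rng.random(n) < p_brain
    cardiac = rng.random(n) < p_cardiac
    vascular = rng.random(n) < p_vascular
    record_review = rng.random(n) < config.record_review_source_prob

    df["brain_imaging_done"] = brain
    df["cardiac_test_done"] = cardiac
    df["vascular_imaging_done"] = vascular
    # masking: findings requiring an investigation are unknown when it was not done;
    # a cardioaortic source may still be recorded from stroke-record review.
    df["cardioaortic_source"] = np.where(cardiac | record_review, source, "unknown")
    df["ipsilateral_stenosis_ge50"] = np.where(vascular, stenosis, "unknown")
    df["infarct_pattern"] = np.where(brain, pattern, "unknown")
    df["laci_syndrome"] = laci  # clinical, always observed
    df["silent_infarct"] = rng.random(n) < config.silent_infarct_rate

    # outcomes
    t_s = np.empty(n)
    t_d = np.empty(n)
    t_c = np.empty(n)
    for k, s in enumerate(SUBTYPES):
        mask = sub_idx == k
        if mask.any():
            h = config.hazards[s]
            a, b, c = _sample_outcome_arrays(
                int(mask.sum()), h.stroke, h.death, config.followup_years, config.censor_rate, rng
            )
            t_s[mask], t_d[mask], t_c[mask] = a, b, c
    df["t_stroke"], df["t_death"], df["t_censor"] = t_s, t_d, t_c
    time = np.minimum.reduce([t_s, t_d, t_c])
    df["time"] = time
    df["event"] = np.where(t_s == time, EVENT_STROKE, np.where(t_d == time, EVENT_DEATH, EVENT_CENSORED))
    return df[COHORT_COLUMNS]


# ---- CSV round trip ----------------------------------------------------

def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """One row per case; "unknown"/+inf encoded as empty fields, times to 6 decimals."""
    out = df.copy()
    for col in ("cardioaortic_source", "ipsilateral_stenosis_ge50", "infarct_pattern"):
        out[col] = out[col].replace("unknown", "")
    for col in _TIME_COLUMNS:
        out[col] = out[col].map(lambda v: "" if np.isinf(v) else f"{v:.6f}")
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=False, na_values=[])
    for col in ("cardioaortic_source", "ipsilateral_stenosis_ge50", "infarct_pattern"):
        df[col] = df[col].replace("", "unknown")
    for col in _TIME_COLUMNS:
        df[col] = pd.to_numeric(df[col].replace("", np.inf))
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    df["region_id"] = df["region_id"].astype(int)
    for col in ("age", "sbp", "dbp", "bmi"):
        df[col] = pd.to_numeric(df[col])
    return df[COHORT_COLUMNS]
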