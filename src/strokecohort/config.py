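"""Generator configuration: subtype mixture, covariate and finding distributions, hazards.

The default configuration encodes the study conditions the rest of the package is
exercised under: a three-subtype etiological mixture (cardioaortic embolism CE,
large-artery atherosclerosis LAA, small-artery occlusion SAO) with subtype-specific
baseline covariates, per-test investigation availability, diagnostic-finding emission
probabilities, and constant (exponential) hazards for subsequent stroke and death
calibrated so the 5-year readouts of the prognosis estimators land on the cohort
values the generator emulates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml
from scipy.optimize import brentq

SUBTYPES = ("CE", "LAA", "SAO")

# findings vocabulary
SOURCE_LEVELS = ("none", "low_risk", "high_risk", "unknown")
STENOSIS_LEVELS = ("yes", "no", "unknown")
PATTERN_LEVELS = ("lacunar_lt20mm", "territorial", "multi_territory", "none_visible", "unknown")

EVENT_STROKE = "subsequent_stroke"
EVENT_DEATH = "death"
EVENT_CENSORED = "censored"

#: subsequent strokes within 28 days of the index event are not counted
STROKE_BLANKING_YEARS = 28.0 / 365.25


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass
class CovariateParams:
    """Per-subtype baseline covariate distribution (marginals).

    Continuous covariates are truncated normals; binary covariates are Bernoulli.
    Smoking/drinking prevalences are sex-specific.
    """

    age_mean: float
    age_sd: float
    female_frac: float
    urban_frac: float
    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float
    bmi_mean: float
    bmi_sd: float
    diabetes: float
    chd: float
    hypertension: float
    bp_meds: float
    smoking_male: float
    smoking_female: float
    drinking_male: float
    drinking_female: float
    family_history_stroke: float
    health_insurance: float


@dataclass
class EmissionParams:
    """Per-subtype probabilities of diagnostic findings (before masking)."""

    source_none: float
    source_low: float
    source_high: float
    stenosis_yes: float
    pattern_lacunar: float
    pattern_territorial: float
    pattern_multi: float
    pattern_none_visible: float
    laci_yes: float

    @property
    def any_source(self) -> float:
        return self.source_low + self.source_high


@dataclass
class RegionSpec:
    region_id: int
    urban: bool
    sao_laa_ratio: float


@dataclass
class Hazards:
    """Constant event rates, per person-year."""

    stroke: float
    death: float


@dataclass
class GeneratorConfig:
    subtype_weights: dict[str, float]
    region_table: list[RegionSpec] | None
    covariate_params: dict[str, CovariateParams]
    availability_probs: tuple[float, float, float]  # brain, cardiac, vascular
    emission_probs: dict[str, EmissionParams]
    hazards: dict[str, Hazards]
    followup_years: float = 9.0
    censor_rate: float = 0.0002
    record_review_source_prob: float = 0.5
    silent_infarct_rate: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        w = self.subtype_weights
        if set(w) != set(SUBTYPES):
            raise ConfigError(f"subtype_weights must have keys {SUBTYPES}")
        if abs(sum(w.values()) - 1.0) > 1e-12:
            raise ConfigError("subtype_weights must sum to 1")
        if any(v < 0 or v > 1 for v in w.values()):
            raise ConfigError("subtype_weights must lie in [0, 1]")
        if self.region_table is not None:
            if len(self.region_table) != 10:
                raise ConfigError("region_table must have exactly 10 entries")
            for r in self.region_table:
                if r.sao_laa_ratio <= 0:
                    raise ConfigError(f"region_table[{r.region_id}].sao_laa_ratio must be > 0")
        for name, p in (
            ("availability_probs.brain", self.availability_probs[0]),
            ("availability_probs.cardiac", self.availability_probs[1]),
            ("availability_probs.vascular", self.availability_probs[2]),
            ("record_review_source_prob", self.record_review_source_prob),
            ("silent_infarct_rate", self.silent_infarct_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for s in SUBTYPES:
            e = self.emission_probs[s]
            for fname in ("source_none", "source_low", "source_high", "stenosis_yes",
                          "pattern_lacunar", "pattern_territorial", "pattern_multi",
                          "pattern_none_visible", "laci_yes"):
                v = getattr(e, fname)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"emission_probs[{s}].{fname} must lie in [0, 1]")
            if abs(e.source_none + e.source_low + e.source_high - 1.0) > 1e-9:
                raise ConfigError(f"emission_probs[{s}] source probabilities must sum to 1")
            pat = e.pattern_lacunar + e.pattern_territorial + e.pattern_multi + e.pattern_none_visible
            if abs(pat - 1.0) > 1e-9:
                raise ConfigError(f"emission_probs[{s}] pattern probabilities must sum to 1")
            h = self.hazards[s]
            if h.stroke < 0 or h.death < 0:
                raise ConfigError(f"hazards[{s}] must be >= 0")
            c = self.covariate_params[s]
            for fname in ("female_frac", "urban_frac", "diabetes", "chd", "hypertension",
                          "bp_meds", "smoking_male", "smoking_female", "drinking_male",
                          "drinking_female", "family_history_stroke", "health_insurance"):
                v = getattr(c, fname)
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"covariate_params[{s}].{fname} must lie in [0, 1]")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["availability_probs"] = list(self.availability_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        d["covariate_params"] = {k: CovariateParams(**v) for k, v in d["covariate_params"].items()}
        d["emission_probs"] = {k: EmissionParams(**v) for k, v in d["emission_probs"].items()}
        d["hazards"] = {k: Hazards(**v) for k, v in d["hazards"].items()}
        if d.get("region_table") is not None:
            d["region_table"] = [RegionSpec(**r) for r in d["region_table"]]
        d["availability_probs"] = tuple(d["availability_probs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json_str(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def closed_form_cif(lam_cause: float, lam_total: float, t: float) -> float:
    """Cumulative incidence of one cause at time t under competing exponentials.

    F_k(t) = (lam_k / lam_total) * (1 - exp(-lam_total * t)).
    """
    if lam_total == 0:
        return 0.0
    return lam_cause / lam_total * (1.0 - np.exp(-lam_total * t))


def calibrate_hazards(stroke_cif: float, mortality: float, horizon: float = 5.0) -> Hazards:
    """Invert 5-year readouts into constant hazards.

    ``mortality`` is the marginal cumulative death probability at the horizon
    (death is observed regardless of an intervening non-fatal stroke), so
    lam_death = -log(1 - mortality) / horizon.  ``stroke_cif`` is the cumulative
    incidence of subsequent stroke with death as a competing risk, so lam_stroke
    solves the competing-exponentials closed form given lam_death.
    """
    if not 0.0 <= mortality < 1.0 or not 0.0 <= stroke_cif < 1.0:
        raise ConfigError("5-year rates must lie in [0, 1)")
    lam_d = -np.log1p(-mortality) / horizon
    if stroke_cif == 0.0:
        return Hazards(stroke=0.0, death=float(lam_d))

    def gap(lam_s: float) -> float:
        return closed_form_cif(lam_s, lam_s + lam_d, horizon) - stroke_cif

    lam_s = brentq(gap, 1e-12, 10.0, xtol=1e-12)
    return Hazards(stroke=float(lam_s), death=float(lam_d))


def _default_region_table() -> list[RegionSpec]:
    """Ten regions whose SAO:LAA ratios span ~4-fold, scaled to the overall mixture.

    The five higher-ratio regions are flagged urban (SAO is the more urban subtype);
    the scale factor is solved so the uniform-over-regions mixture of the non-CE mass
    reproduces the overall SAO share.
    """
    spread = np.logspace(0.0, np.log10(4.0), 10)
    target_share = 0.66 / 0.98  # SAO share of the non-CE mass

    def gap(c: float) -> float:
        rho = c * spread
        return float(np.mean(rho / (1.0 + rho))) - target_share

    c = brentq(gap, 1e-3, 1e3, xtol=1e-12)
    ratios = c * spread
    order = np.argsort(ratios)
    urban_ids = set(int(i) for i in order[5:])  # top half by SAO:LAA ratio
    return [
        RegionSpec(region_id=i + 1, urban=(i in urban_ids), sao_laa_ratio=float(ratios[i]))
        for i in range(10)
    ]


def region_subtype_weights(config: GeneratorConfig) -> dict[int, dict[str, float]]:
    """Per-region subtype weights; each region's weights sum to 1.

    The CE share is held at its overall value; the remaining mass is split
    between LAA and SAO by the region's SAO:LAA ratio.
    """
    if config.region_table is None:
        return {0: dict(config.subtype_weights)}
    ce = config.subtype_weights["CE"]
    rest = 1.0 - ce
    out = {}
    for r in config.region_table:
        sao = rest * r.sao_laa_ratio / (1.0 + r.sao_laa_ratio)
        out[r.region_id] = {"CE": ce, "LAA": rest - sao, "SAO": sao}
    return out


def default_config(seed: int = 0) -> GeneratorConfig:
    """Configuration pre-filled with the cohort the generator emulates.

    Subtype mixture 2% CE / 32% LAA / 66% SAO among evident+probable cases;
    covariate marginals per subtype (age, sex, urban residence, blood pressure,
    BMI, medical history, lifestyle); investigation availability 91% brain
    imaging / 87% cardiac testing / 51% vascular imaging; cardioaortic-source
    prevalence 100.0% (CE), 4.1% (LAA), 0.3% (SAO); hazards inverted from the
    5-year readouts (subsequent-stroke CIF 43.5/43.2/38.1%, mortality
    40.7/17.4/11.1% for CE/LAA/SAO).
    """
    covariates = {
        "CE": CovariateParams(61.9, 9.4, 0.469, 0.594, 141.9, 25.6, 80.8, 13.5, 24.8, 3.8,
                              0.106, 0.144, 0.594, 0.294, 0.718, 0.027, 0.388, 0.027,
                              0.17, 0.97),
        "LAA": CovariateParams(59.9, 8.9, 0.463, 0.514, 144.7, 23.8, 82.2, 12.6, 24.2, 3.3,
                               0.145, 0.078, 0.619, 0.240, 0.749, 0.049, 0.421, 0.022,
                               0.20, 0.95),
        "SAO": CovariateParams(58.7, 9.5, 0.591, 0.644, 139.9, 23.1, 81.1, 12.2, 24.6, 3.5,
                               0.125, 0.074, 0.546, 0.215, 0.716, 0.057, 0.443, 0.029,
                               0.16, 0.98),
    }
    emissions = {
        "CE": EmissionParams(source_none=0.0, source_low=0.04, source_high=0.96,
                             stenosis_yes=0.05, pattern_lacunar=0.0, pattern_territorial=0.72,
                             pattern_multi=0.25, pattern_none_visible=0.03, laci_yes=0.02),
        "LAA": EmissionParams(source_none=0.959, source_low=0.0205, source_high=0.0205,
                              stenosis_yes=0.95, pattern_lacunar=0.01, pattern_territorial=0.96,
                              pattern_multi=0.02, pattern_none_visible=0.01, laci_yes=0.05),
        "SAO": EmissionParams(source_none=0.997, source_low=0.0025, source_high=0.0005,
                              stenosis_yes=0.02, pattern_lacunar=0.94, pattern_territorial=0.02,
                              pattern_multi=0.0, pattern_none_visible=0.04, laci_yes=0.85),
    }
    hazards = {
        "CE": calibrate_hazards(stroke_cif=0.435, mortality=0.407),
        "LAA": calibrate_hazards(stroke_cif=0.432, mortality=0.174),
        "SAO": calibrate_hazards(stroke_cif=0.381, mortality=0.111),
    }
    cfg = GeneratorConfig(
        subtype_weights={"CE": 0.02, "LAA": 0.32, "SAO": 0.66},
        region_table=_default_region_table(),
        covariate_params=covariates,
        availability_probs=(0.91, 0.87, 0.51),
        emission_probs=emissions,
        hazards=hazards,
        seed=seed,
    )
    cfg.validate()
    return cfg
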