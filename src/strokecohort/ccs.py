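"""Rule-based etiological subtyping (modified Causative Classification System).

A fixed, ordered decision table maps diagnostic findings and investigation
completeness to a subtype (CE / LAA / SAO / UNDETERMINED) with a confidence
tier (EVIDENT / PROBABLE / POSSIBLE / NONE).  The hierarchy follows published
CCS logic: a high-risk cardioaortic source dominates; ipsilateral >=50%
stenosis defines LAA; a lacunar infarct (<20 mm) or lacunar syndrome defines
SAO; confidence reflects how completely competing mechanisms were excluded.
Conflicting positive evidence (e.g. a high-risk source together with >=50%
stenosis) resolves to UNDETERMINED (cryptogenic) rather than a forced choice.

The table is declarative (``DECISION_TABLE``) so alternative rule sets can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PATTERN_LEVELS, SOURCE_LEVELS, STENOSIS_LEVELS

SUBTYPE_UNDETERMINED = "UNDETERMINED"
CONFIDENCE_ORDER = {"EVIDENT": 3, "PROBABLE": 2, "POSSIBLE": 1, "NONE": 0}

FINDING_FIELDS = ("cardioaortic_source", "ipsilateral_stenosis_ge50", "infarct_pattern", "laci_syndrome")


class InconsistentFindingsError(ValueError):
    """Findings incompatible with the investigation profile."""


@dataclass(frozen=True)
class SubtypeAssignment:
    subtype: str  # CE | LAA | SAO | UNDETERMINED
    confidence: str  # EVIDENT | PROBABLE | POSSIBLE | NONE
    reason: str  # code of the fired rule
    undetermined_kind: str  # incomplete_investigation | cryptogenic | not_applicable


@dataclass(frozen=True)
class Rule:
    """One row of the decision table.

    ``clauses`` is a disjunction of conjunctive conditions; each condition maps
    a finding field to the set of admissible levels.
    """

    code: str
    subtype: str
    confidence: str
    clauses: tuple[dict[str, frozenset], ...]


def _c(**kw) -> dict[str, frozenset]:
    return {k: frozenset(v) for k, v in kw.items()}


_NEUTRAL_PATTERNS_CE = ("territorial", "multi_territory", "none_visible", "unknown")
_NEUTRAL_PATTERNS_LAA = ("territorial", "multi_territory", "none_visible")

#: Fixed evaluation order; the first matching rule fires.
DECISION_TABLE: tuple[Rule, ...] = (
    Rule("CE-1", "CE", "EVIDENT", (
        _c(cardioaortic_source=["high_risk"], ipsilateral_stenosis_ge50=["no"],
           infarct_pattern=["territorial", "multi_territory"]),
    )),
    # high-risk source with no contradicting positive finding (stenosis not
    # demonstrated, no lacunar infarct) but incomplete/negative corroboration
    Rule("CE-2", "CE", "PROBABLE", (
        _c(cardioaortic_source=["high_risk"], ipsilateral_stenosis_ge50=["no", "unknown"],
           infarct_pattern=_NEUTRAL_PATTERNS_CE),
    )),
    Rule("LAA-1", "LAA", "EVIDENT", (
        _c(ipsilateral_stenosis_ge50=["yes"], cardioaortic_source=["none"],
           infarct_pattern=["territorial"]),
    )),
    # stenosis demonstrated, no high-risk source, no lacunar infarct, with at
    # most one corroborating item missing (both missing drops to LAA-3)
    Rule("LAA-2", "LAA", "PROBABLE", (
        _c(ipsilateral_stenosis_ge50=["yes"], cardioaortic_source=["none", "low_risk", "unknown"],
           infarct_pattern=_NEUTRAL_PATTERNS_LAA),
        _c(ipsilateral_stenosis_ge50=["yes"], cardioaortic_source=["none", "low_risk"],
           infarct_pattern=["unknown"]),
    )),
    Rule("SAO-1", "SAO", "EVIDENT", (
        _c(infarct_pattern=["lacunar_lt20mm"], ipsilateral_stenosis_ge50=["no"],
           cardioaortic_source=["none"]),
    )),
    Rule("SAO-2", "SAO", "PROBABLE", (
        _c(infarct_pattern=["lacunar_lt20mm"], laci_syndrome=["yes"],
           ipsilateral_stenosis_ge50=["unknown"], cardioaortic_source=["none", "unknown"]),
        _c(infarct_pattern=["lacunar_lt20mm"], laci_syndrome=["yes"],
           ipsilateral_stenosis_ge50=["no"], cardioaortic_source=["unknown"]),
    )),
    Rule("CE-3", "CE", "POSSIBLE", (
        _c(cardioaortic_source=["low_risk"]),
    )),
    Rule("LAA-3", "LAA", "POSSIBLE", (
        _c(ipsilateral_stenosis_ge50=["yes"], cardioaortic_source=["unknown"],
           infarct_pattern=["unknown"]),
    )),
    Rule("SAO-3", "SAO", "POSSIBLE", (
        _c(laci_syndrome=["yes"], infarct_pattern=["unknown", "none_visible"]),
    )),
)


def is_completely_investigated(brain_imaging_done, cardiac_test_done, vascular_imaging_done) -> bool:
    """True iff brain imaging, a cardiac test (Echo or ECG) and vascular imaging were all done."""
    return bool(brain_imaging_done) and bool(cardiac_test_done) and bool(vascular_imaging_done)


def _validate_case(findings: dict, profile: dict) -> None:
    src = findings["cardioaortic_source"]
    sten = findings["ipsilateral_stenosis_ge50"]
    pat = findings["infarct_pattern"]
    if src not in SOURCE_LEVELS:
        raise InconsistentFindingsError(f"invalid cardioaortic_source {src!r}")
    if sten not in STENOSIS_LEVELS:
        raise InconsistentFindingsError(f"invalid ipsilateral_stenosis_ge50 {sten!r}")
    if pat not in PATTERN_LEVELS:
        raise InconsistentFindingsError(f"invalid infarct_pattern {pat!r}")
    if findings["laci_syndrome"] not in ("yes", "no"):
        raise InconsistentFindingsError("laci_syndrome must be yes/no (clinical, always observed)")
    if (sten == "unknown") != (not profile["vascular_imaging_done"]):
        raise InconsistentFindingsError(
            "ipsilateral_stenosis_ge50 must be unknown iff vascular imaging was not done"
        )
    if (pat == "unknown") != (not profile["brain_imaging_done"]):
        raise InconsistentFindingsError(
            "infarct_pattern must be unknown iff brain imaging was not done"
        )
    if profile["cardiac_test_done"] and src == "unknown":
        raise InconsistentFindingsError(
            "cardioaortic_source cannot be unknown when a cardiac test was done"
        )


def classify_case(findings: dict, profile: dict) -> SubtypeAssignment:
    """Assign one case; total and deterministic over the finite findings domain."""
    _validate_case(findings, profile)
    for rule in DECISION_TABLE:
        for clause in rule.clauses:
            if all(findings[f] in levels for f, levels in clause.items()):
                return SubtypeAssignment(rule.subtype, rule.confidence, rule.code, "not_applicable")
    complete = is_completely_investigated(
        profile["brain_imaging_done"], profile["cardiac_test_done"], profile["vascular_imaging_done"]
    )
    kind = "cryptogenic" if complete else "incomplete_investigation"
    return SubtypeAssignment(SUBTYPE_UNDETERMINED, "NONE", "UND", kind)


def classify_cohort(cohort: pd.DataFrame, decision_table: tuple[Rule, ...] = DECISION_TABLE) -> tuple[pd.DataFrame, dict]:
    """Vectorized classification of a cohort plus a flowchart-style summary.

    Returns per-case assignments (case_id, subtype, confidence, reason,
    undetermined_kind) and a summary counting cases by subtype x confidence and
    undetermined cases by investigation completeness; counts sum to the cohort size.
    """
    if len(cohort) == 0:
        raise ValueError("cannot classify an empty cohort")
    n = len(cohort)
    bad = (cohort["ipsilateral_stenosis_ge50"].eq("unknown") != ~cohort["vascular_imaging_done"]) \
        | (cohort["infarct_pattern"].eq("unknown") != ~cohort["brain_imaging_done"]) \
        | (cohort["cardiac_test_done"] & cohort["cardioaortic_source"].eq("unknown"))
    if bad.any():
        idx = cohort.index[bad][0]
        raise InconsistentFindingsError(
            f"findings inconsistent with investigation profile at row {idx}"
        )
    subtype = np.full(n, SUBTYPE_UNDETERMINED, dtype=object)
    confidence = np.full(n, "NONE", dtype=object)
    reason = np.full(n, "UND", dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for rule in decision_table:
        fired = np.zeros(n, dtype=bool)
        for clause in rule.clauses:
            m = np.ones(n, dtype=bool)
            for f, levels in clause.items():
                m &= cohort[f].isin(levels).to_numpy()
            fired |= m
        fired &= unassigned
        subtype[fired] = rule.subtype
        confidence[fired] = rule.confidence
        reason[fired] = rule.code
        unassigned &= ~fired

    complete = (
        cohort["brain_imaging_done"] & cohort["cardiac_test_done"] & cohort["vascular_imaging_done"]
    ).to_numpy()
    kind = np.where(
        subtype == SUBTYPE_UNDETERMINED,
        np.where(complete, "cryptogenic", "incomplete_investigation"),
        "not_applicable",
    )
    assignments = pd.DataFrame({
        "case_id": cohort["case_id"].to_numpy(),
        "subtype": subtype,
        "confidence": confidence,
        "reason": reason,
        "undetermined_kind": kind,
    })
    by_cell = (
        assignments.groupby(["subtype", "confidence"]).size().rename("count").reset_index()
    )
    ep = assignments["confidence"].isin(["EVIDENT", "PROBABLE"])
    summary = {
        "n": int(n),
        "by_subtype_confidence": {
            f"{r.subtype}/{r.confidence}": int(r.count) for r in by_cell.itertuples()
        },
        "evident_or_probable": int(ep.sum()),
        "evident_or_probable_by_subtype": {
            s: int((ep & (assignments["subtype"] == s)).sum()) for s in ("CE", "LAA", "SAO")
        },
        "possible": int((assignments["confidence"] == "POSSIBLE").sum()),
        "undetermined": {
            "total": int((subtype == SUBTYPE_UNDETERMINED).sum()),
            "incomplete_investigation": int((kind == "incomplete_investigation").sum()),
            "cryptogenic": int((kind == "cryptogenic").sum()),
        },
        "incompletely_investigated": int((~complete).sum()),
    }
    return assignments, summary


class CCSRuleClassifier:
    """sklearn-style wrapper over the decision table.

    Stateless: ``fit`` only records the rule table in use; ``predict`` returns
    the assigned subtype per case and ``predict_assignments`` the full
    assignment frame.
    """

    def __init__(self, decision_table: tuple[Rule, ...] = DECISION_TABLE):
        self.decision_table = decision_table

    def get_params(self, deep: bool = True) -> dict:
        return {"decision_table": self.decision_table}

    def set_params(self, **params) -> "CCSRuleClassifier":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "CCSRuleClassifier":
        self.rules_ = self.decision_table
        return self

    def predict_assignments(self, X: pd.DataFrame) -> pd.DataFrame:
        assignments, self.summary_ = classify_cohort(X, self.decision_table)
        return assignments

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_assignments(X)["subtype"].to_numpy()
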