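"""Adjuvant-treatment guideline engine and grade-substitution impact analysis.

A guideline is an ordered list of rules with first-match semantics; each
rule has a predicate over patient fields (ER/PR/HER2, grade, tumour size,
age, LVI, Ki67) and a treatment in {NONE, AHT, ACT, AHT_ACT}.  Running
the same guideline twice — once with the histological grade, once with
the genomic grade substituted for it (equivocal calls count as grade 2)
— quantifies how many patients would be spared chemotherapy or hormonal
therapy.

The shipped default ruleset is a documented *reconstruction* of a
2010-era hormone-receptor-driven guideline (hormone-receptor-negative
tumours receive chemotherapy alone; receptor-positive grade 3 adds
chemotherapy to hormonal therapy; grade 2 adds it on a secondary risk
trigger; very low-risk grade 1 tumours receive no adjuvant treatment).
It is NOT an authoritative transcription of any institution's rules;
impact figures on published assignment counts do not depend on it.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import yaml

from .cohort import PatientRecord
from .errors import DecisionError
from .grading import GenomicGrade

__all__ = [
    "Treatment",
    "Rule",
    "GuidelineRuleset",
    "effective_grade",
    "assign",
    "assign_cohort",
    "impact",
    "ImpactSummary",
    "default_reconstruction_ruleset",
]


class Treatment(str, enum.Enum):
    NONE = "NONE"
    AHT = "AHT"
    AHT_ACT = "AHT_ACT"
    ACT = "ACT"


_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "in": lambda a, b: a in b,
}


@dataclass(frozen=True)
class Rule:
    """``when`` maps a field name to a condition: a scalar (equality), a list
    (membership) or a single-op dict like ``{"gt": 20}``."""

    rule_id: str
    when: dict
    then: Treatment

    def matches(self, ctx: Mapping) -> bool:
        for fname, cond in self.when.items():
            if fname not in ctx or ctx[fname] is None:
                raise DecisionError(
                    f"rule {self.rule_id!r} needs field {fname!r}, absent from patient"
                )
            val = ctx[fname]
            if isinstance(cond, dict):
                if len(cond) != 1:
                    raise DecisionError(
                        f"rule {self.rule_id!r}: condition must have exactly one operator"
                    )
                (op, ref), = cond.items()
                if op not in _OPS:
                    raise DecisionError(f"rule {self.rule_id!r}: unknown operator {op!r}")
                if not _OPS[op](val, ref):
                    return False
            elif isinstance(cond, (list, tuple, set)):
                if val not in cond:
                    return False
            elif val != cond:
                return False
        return True


@dataclass
class GuidelineRuleset:
    """Ordered first-match rules; the last rule must be a catch-all."""

    name: str
    rules: tuple
    version: str = ""

    def __post_init__(self):
        self.rules = tuple(self.rules)
        if not self.rules:
            raise DecisionError("ruleset must contain at least one rule")
        if self.rules[-1].when:
            raise DecisionError("the final rule must be a catch-all (empty predicate)")

    @classmethod
    def from_yaml(cls, path) -> "GuidelineRuleset":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = tuple(
            Rule(rule_id=r.get("id", f"rule{i}"), when=r.get("when", {}) or {},
                 then=Treatment(r["then"]))
            for i, r in enumerate(payload["rules"], start=1)
        )
        return cls(name=payload.get("name", str(path)),
                   version=str(payload.get("version", "")), rules=rules)

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "version": self.version,
            "rules": [
                {"id": r.rule_id, "when": dict(r.when), "then": r.then.value}
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def effective_grade(hg: int, gg_call: Optional[GenomicGrade], source: str = "HG") -> int:
    """Grade fed to the guideline: the histological grade, or the genomic
    grade with equivocal calls counted as grade 2."""
    if source == "HG":
        return int(hg)
    if source == "GG":
        if gg_call is None:
            raise DecisionError("source GG requires a genomic-grade call")
        grade = getattr(gg_call, "grade", gg_call)
        return {GenomicGrade.GG1: 1, GenomicGrade.EQ: 2, GenomicGrade.GG3: 3}[grade]
    raise DecisionError(f"unknown grade source {source!r}")


def _context(patient, grade: int) -> dict:
    if isinstance(patient, PatientRecord):
        ctx = {
            "er": patient.er, "pr": patient.pr, "her2": patient.her2,
            "tumor_size": patient.tumor_size, "age": patient.age,
            "lvi": patient.lvi, "ki67": patient.ki67,
        }
    else:
        ctx = dict(patient)
    ctx["grade"] = int(grade)
    return ctx


def assign(patient, grade: int, ruleset: GuidelineRuleset):
    """Treatment of the first matching rule; returns ``(treatment, rule_id)``."""
    ctx = _context(patient, grade)
    for rule in ruleset.rules:
        if rule.matches(ctx):
            return rule.then, rule.rule_id
    raise DecisionError("no rule matched (catch-all invariant violated)")


def assign_cohort(patients, grades, ruleset: GuidelineRuleset) -> list:
    """Vectorized :func:`assign`; ``grades`` is one effective grade per patient."""
    return [assign(p, g, ruleset)[0] for p, g in zip(patients, grades)]


_ACT_CONTAINING = {Treatment.ACT, Treatment.AHT_ACT}
_AHT_CONTAINING = {Treatment.AHT, Treatment.AHT_ACT}


@dataclass
class ImpactSummary:
    """Per-arm treatment counts and relative reductions (arm2 vs arm1).

    ``act_reduction`` is 1 - (ACT-containing in arm 2)/(ACT-containing in
    arm 1) where ACT-containing means ACT or AHT+ACT; ``aht_reduction`` is
    the analogue over {AHT, AHT+ACT}.  ``None`` marks an undefined ratio
    (zero denominator).
    """

    counts_arm1: dict
    counts_arm2: dict
    act_reduction: Optional[float]
    aht_reduction: Optional[float]
    n: int


def _counts(assignments) -> dict:
    c = Counter(Treatment(a) for a in assignments)
    return {t: int(c.get(t, 0)) for t in Treatment}


def impact(assignments_arm1: Sequence, assignments_arm2: Sequence) -> ImpactSummary:
    """Compare two treatment-assignment arms over the same patients."""
    if len(assignments_arm1) != len(assignments_arm2):
        raise DecisionError("the two arms must cover the same patients")
    c1, c2 = _counts(assignments_arm1), _counts(assignments_arm2)

    def reduction(containing):
        d1 = sum(c1[t] for t in containing)
        d2 = sum(c2[t] for t in containing)
        if d1 == 0:
            return None
        return 1.0 - d2 / d1

    return ImpactSummary(
        counts_arm1=c1,
        counts_arm2=c2,
        act_reduction=reduction(_ACT_CONTAINING),
        aht_reduction=reduction(_AHT_CONTAINING),
        n=len(assignments_arm1),
    )


def impact_from_counts(counts_arm1: Mapping, counts_arm2: Mapping) -> ImpactSummary:
    """Impact summary from per-treatment counts (e.g. a published table)."""
    def expand(counts):
        out = []
        for t, n in counts.items():
            out.extend([Treatment(t)] * int(n))
        return out

    return impact(expand(counts_arm1), expand(counts_arm2))


def default_reconstruction_ruleset() -> GuidelineRuleset:
    """Non-authoritative reconstruction of a 2010-era adjuvant guideline.

    Constraints honoured: hormone-receptor-negative (ER-/PR-) tumours get
    chemotherapy alone; receptor-positive grade 3 gets hormonal therapy
    plus chemotherapy; grade 2 adds chemotherapy when a secondary risk
    trigger fires (tumour > 20 mm or lymphovascular invasion); very
    low-risk grade 1 tumours (<= 10 mm, LVI-negative, low Ki67) receive
    no adjuvant treatment; every other receptor-positive tumour gets
    hormonal therapy alone.
    """
    return GuidelineRuleset(
        name="reconstructed-2010-guideline",
        version="synthetic-1",
        rules=(
            Rule("hr-negative", {"er": False, "pr": False}, Treatment.ACT),
            Rule("grade3", {"grade": 3}, Treatment.AHT_ACT),
            Rule("grade2-size", {"grade": 2, "tumor_size": {"gt": 20}}, Treatment.AHT_ACT),
            Rule("grade2-lvi", {"grade": 2, "lvi": True}, Treatment.AHT_ACT),
            Rule(
                "grade1-lowrisk",
                {"grade": 1, "tumor_size": {"le": 10}, "lvi": False,
                 "ki67": {"le": 20}},
                Treatment.NONE,
            ),
            Rule("default-aht", {}, Treatment.AHT),
        ),
    )
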