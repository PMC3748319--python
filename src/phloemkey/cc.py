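"""Companion-cell subtype classification.

The key assigns a companion-cell trait profile to one of eleven subtypes
(grouped into four major types: ordinary cells, transfer cells, intermediary
and IC-like cells, and cells with plasmodesmal fields / many single
plasmodesmata).  Semantics are those of a deterministic identification key
over categorical traits with three-valued logic:

* a profile is *compatible* with a subtype row iff every KNOWN trait value
  lies in the row's allowed set — UNKNOWN traits constrain nothing;
* the compatible set is then narrowed by two documented tie-breaks
  (IC vs ICL on RFO evidence when starch is unscored; MIC-a vs MIC-b by
  grade band);
* the result is UNIQUE, AMBIGUOUS (several subtypes remain) or UNCLASSIFIED
  (the trait combination matches no row), never a forced guess.

The rule table ships as ``data/cc_rules.yaml`` and may be overridden with a
user YAML of the same shape.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .records import CCProfile
from .vocab import (
    Branching,
    CWIMorphology,
    Evidence,
    Grade,
    Plastid,
    Tristate,
)

__all__ = [
    "CCLabel",
    "CCMajorType",
    "CC_MAJOR_TYPE",
    "CCClassification",
    "Status",
    "CCRuleSet",
    "load_cc_rules",
    "classify_cc",
    "canonical_profile",
    "enumerate_rule_space",
    "RuleSpace",
]


class CCLabel(enum.Enum):
    """The eleven companion-cell subtypes."""

    OC_A = "OC-a"
    OC_B = "OC-b"
    TC_A = "TC-a"
    TC_B = "TC-b"
    TC_C = "TC-c"
    IC = "IC"
    ICL = "ICL"
    CC_A = "CC-a"
    CC_B = "CC-b"
    MIC_A = "MIC-a"
    MIC_B = "MIC-b"

    def __str__(self) -> str:
        return self.value


class CCMajorType(enum.Enum):
    ORDINARY = "ordinary"
    TRANSFER = "transfer"
    INTERMEDIARY = "intermediary"   # intermediary cells and IC-like cells
    PF_CC = "pf_cc"                 # CC with PF and/or many single PD

    def __str__(self) -> str:
        return self.value


class Status(enum.Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    UNCLASSIFIED = "unclassified"


# trait-field -> parser, used when reading the YAML rule table
_FIELD_PARSERS = {
    "pf_grade": Grade.parse,
    "pd_branching": Branching.parse,
    "cwi_grade": Grade.parse,
    "cwi_morphology": CWIMorphology.parse,
    "plastid": Plastid.parse,
    "starch_in_leucoplasts": Tristate.parse,
    "rfo_evidence": Evidence.parse,
}

_UNKNOWNS = {
    "pf_grade": Grade.UNKNOWN,
    "pd_branching": Branching.UNKNOWN,
    "cwi_grade": Grade.UNKNOWN,
    "cwi_morphology": CWIMorphology.UNKNOWN,
    "plastid": Plastid.UNKNOWN,
    "starch_in_leucoplasts": Tristate.UNKNOWN,
    "rfo_evidence": Evidence.UNKNOWN,
}


@dataclass(frozen=True)
class CCRule:
    label: CCLabel
    major: CCMajorType
    canonical: CCProfile
    match: Mapping[str, frozenset]


@dataclass(frozen=True)
class CCRuleSet:
    rules: tuple[CCRule, ...]

    def __iter__(self):
        return iter(self.rules)

    def __getitem__(self, label: CCLabel) -> CCRule:
        for rule in self.rules:
            if rule.label is label:
                return rule
        raise KeyError(label)

    @property
    def labels(self) -> tuple[CCLabel, ...]:
        return tuple(r.label for r in self.rules)


def load_cc_rules(path: str | Path | None = None) -> CCRuleSet:
    """Load the subtype decision table (packaged default or user override)."""
    if path is None:
        text = (resources.files("phloemkey.data") / "cc_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rules = []
    for name, entry in raw.items():
        label = CCLabel[name]
        canonical_kwargs = {
            f: _FIELD_PARSERS[f](tok) for f, tok in entry["canonical"].items()
        }
        match = {
            f: frozenset(_FIELD_PARSERS[f](t) for t in toks)
            for f, toks in entry["match"].items()
        }
        rules.append(CCRule(
            label=label,
            major=CCMajorType[entry["major"]],
            canonical=CCProfile(**canonical_kwargs),
            match=match,
        ))
    if len(rules) != len({r.label for r in rules}):
        raise ValueError("duplicate subtype in rule table")
    return CCRuleSet(tuple(rules))


_DEFAULT_RULES: CCRuleSet | None = None


def default_rules() -> CCRuleSet:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_cc_rules()
    return _DEFAULT_RULES


CC_MAJOR_TYPE: dict[CCLabel, CCMajorType] = {
    CCLabel.OC_A: CCMajorType.ORDINARY,
    CCLabel.OC_B: CCMajorType.ORDINARY,
    CCLabel.TC_A: CCMajorType.TRANSFER,
    CCLabel.TC_B: CCMajorType.TRANSFER,
    CCLabel.TC_C: CCMajorType.TRANSFER,
    CCLabel.IC: CCMajorType.INTERMEDIARY,
    CCLabel.ICL: CCMajorType.INTERMEDIARY,
    CCLabel.CC_A: CCMajorType.PF_CC,
    CCLabel.CC_B: CCMajorType.PF_CC,
    CCLabel.MIC_A: CCMajorType.PF_CC,
    CCLabel.MIC_B: CCMajorType.PF_CC,
}


@dataclass(frozen=True)
class CCClassification:
    labels: frozenset[CCLabel]
    status: Status
    rationale: tuple[tuple[str, str, str], ...]  # (feature, observed, consequence)

    @property
    def unique_label(self) -> CCLabel | None:
        if self.status is Status.UNIQUE:
            return next(iter(self.labels))
        return None


def _hard_violations(profile: CCProfile) -> list[str]:
    out = []
    g, m = profile.cwi_grade, profile.cwi_morphology
    if m is CWIMorphology.NONE and g.is_known and g is not Grade.ABSENT:
        out.append("cwi_morphology NONE with cwi_grade present")
    if g is Grade.ABSENT and m not in (CWIMorphology.NONE, CWIMorphology.UNKNOWN):
        out.append("cwi_grade ABSENT with a cwi morphology recorded")
    if (profile.plastid is Plastid.CHLOROPLAST
            and profile.starch_in_leucoplasts is Tristate.YES):
        out.append("starch in leucoplasts with chloroplasts")
    return out


def _is_known(field: str, value) -> bool:
    return value is not _UNKNOWNS[field]


def raw_compatible(
    profile: CCProfile, rules: CCRuleSet | None = None
) -> frozenset[CCLabel]:
    """Subtypes compatible with every KNOWN trait, before tie-breaks."""
    rules = rules or default_rules()
    out = set()
    for rule in rules:
        ok = True
        for field, allowed in rule.match.items():
            value = getattr(profile, field)
            if _is_known(field, value) and value not in allowed:
                ok = False
                break
        if ok:
            out.add(rule.label)
    return frozenset(out)


def _apply_tiebreaks(
    labels: set[CCLabel], profile: CCProfile
) -> tuple[set[CCLabel], list[tuple[str, str, str]]]:
    notes: list[tuple[str, str, str]] = []
    if CCLabel.IC in labels and CCLabel.ICL in labels:
        # starch settles the pair outright (encoded in the match sets); with
        # starch unscored, detected RFO synthesis settles it in favour of IC.
        if (profile.starch_in_leucoplasts is Tristate.UNKNOWN
                and profile.rfo_evidence is Evidence.DETECTED):
            labels.discard(CCLabel.ICL)
            notes.append((
                "rfo_evidence", "detected",
                "RFO synthesis with starch unscored resolves IC/ICL to IC"))
    if CCLabel.MIC_A in labels and CCLabel.MIC_B in labels:
        pf, cwi = profile.pf_grade, profile.cwi_grade
        if pf.is_known and cwi.is_known:
            if pf <= Grade.SPARSE and cwi <= Grade.SPARSE:
                labels.discard(CCLabel.MIC_B)
                notes.append((
                    "pf_grade/cwi_grade", f"{pf.token}/{cwi.token}",
                    "both at most sparse: MIC-a grade band"))
            elif pf >= Grade.ABUNDANT and cwi >= Grade.ABUNDANT:
                labels.discard(CCLabel.MIC_A)
                notes.append((
                    "pf_grade/cwi_grade", f"{pf.token}/{cwi.token}",
                    "both abundant: MIC-b grade band"))
            else:
                notes.append((
                    "pf_grade/cwi_grade", f"{pf.token}/{cwi.token}",
                    "intermediate grades: MIC-a/MIC-b left ambiguous"))
    return labels, notes


def classify_cc(
    profile: CCProfile,
    vein_context: Iterable[CCLabel] | None = None,
    rules: CCRuleSet | None = None,
) -> CCClassification:
    """Assign a companion-cell profile to its subtype(s).

    ``vein_context`` — subtypes known to co-occur in the same vein — may add
    a rationale note for the TC-b row (a transfer cell with leucoplasts found
    together with IC/MIC), but never flips a label.
    """
    violations = _hard_violations(profile)
    if violations:
        raise ValueError(
            "profile fails hard validation: " + "; ".join(violations))
    rules = rules or default_rules()

    rationale: list[tuple[str, str, str]] = []
    candidates = set(rules.labels)
    for field in _UNKNOWNS:
        value = getattr(profile, field)
        if not _is_known(field, value):
            continue
        excluded = {
            rule.label for rule in rules
            if rule.label in candidates
            and field in rule.match and value not in rule.match[field]
        }
        token = getattr(value, "token", str(value))
        if excluded:
            candidates -= excluded
            rationale.append((
                field, token,
                "excludes " + ", ".join(sorted(l.value for l in excluded))))
        else:
            rationale.append((field, token, "consistent with all candidates"))

    labels, notes = _apply_tiebreaks(set(candidates), profile)
    rationale.extend(notes)

    if vein_context is not None and CCLabel.TC_B in labels:
        context = set(vein_context)
        if context & {CCLabel.IC, CCLabel.ICL, CCLabel.MIC_A, CCLabel.MIC_B}:
            rationale.append((
                "vein_context",
                ", ".join(sorted(l.value for l in context)),
                "co-occurring IC/MIC supports TC-b (note only, no flip)"))

    if not labels:
        status = Status.UNCLASSIFIED
    elif len(labels) == 1:
        status = Status.UNIQUE
    else:
        status = Status.AMBIGUOUS
    return CCClassification(frozenset(labels), status, tuple(rationale))


def canonical_profile(label: CCLabel, rules: CCRuleSet | None = None) -> CCProfile:
    """The archetypal trait vector of a subtype (classifies uniquely back)."""
    rules = rules or default_rules()
    return rules[label].canonical


# ---------------------------------------------------------------------------
# exhaustive rule-space enumeration (consistency oracle)

_ENUM_DOMAINS = {
    "pf_grade": [Grade.ABSENT, Grade.SPARSE, Grade.MODERATE, Grade.ABUNDANT],
    "pd_branching": [Branching.ASYMMETRIC_CC_SIDE, Branching.SYMMETRIC,
                     Branching.SINGLE_UNBRANCHED],
    "cwi_grade": [Grade.ABSENT, Grade.SPARSE, Grade.MODERATE, Grade.ABUNDANT],
    "cwi_morphology": [CWIMorphology.RETICULATE, CWIMorphology.FLANGE,
                       CWIMorphology.NONE],
    "plastid": [Plastid.LEUCOPLAST, Plastid.CHLOROPLAST],
    "starch_in_leucoplasts": [Tristate.YES, Tristate.NO],
    "rfo_evidence": [Evidence.DETECTED, Evidence.NOT_DETECTED],
}

_MIC_BAND = frozenset({CCLabel.MIC_A, CCLabel.MIC_B})


@dataclass(frozen=True)
class RuleSpace:
    """Result of exhaustively classifying every complete trait vector."""

    table: pd.DataFrame        # one row per vector: traits, labels, status
    total: int                 # product of vocabulary sizes
    n_valid: int               # vectors passing hard validation
    n_unclassified: int
    collisions: tuple[tuple, ...]  # complete vectors claimed by >=2 subtypes
                                   # outside the documented MIC grade band


def enumerate_rule_space(rules: CCRuleSet | None = None) -> RuleSpace:
    """Classify every complete (no-UNKNOWN) trait vector over the vocabulary.

    Proves by construction that no two subtype rows claim the same complete
    vector: the only multi-label outcomes are the documented MIC-a/MIC-b
    intermediate grade band, recorded separately from true collisions.
    """
    rules = rules or default_rules()
    fields = list(_ENUM_DOMAINS)
    rows = []
    collisions = []
    n_valid = n_unclassified = 0
    for combo in itertools.product(*_ENUM_DOMAINS.values()):
        profile = CCProfile(**dict(zip(fields, combo)))
        tokens = tuple(v.token for v in combo)
        if _hard_violations(profile):
            rows.append(tokens + ("", "invalid"))
            continue
        n_valid += 1
        result = classify_cc(profile, rules=rules)
        label_str = ";".join(sorted(l.value for l in result.labels))
        rows.append(tokens + (label_str, result.status.value))
        if result.status is Status.UNCLASSIFIED:
            n_unclassified += 1
        elif len(result.labels) >= 2 and result.labels != _MIC_BAND:
            collisions.append(tokens)
    table = pd.DataFrame(rows, columns=fields + ["labels", "status"])
    total = 1
    for domain in _ENUM_DOMAINS.values():
        total *= len(domain)
    return RuleSpace(
        table=table,
        total=total,
        n_valid=n_valid,
        n_unclassified=n_unclassified,
        collisions=tuple(collisions),
    )
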