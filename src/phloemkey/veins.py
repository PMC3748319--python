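"""Minor-vein phloem classification.

A vein observation is first assigned its ontogenetic major type (0, 1 or 2)
from three criteria consulted in order of precedence — the orientation of the
first division of the phloem initial, the aggregate CC:SE ratio (an exact
rational), and the parenchyma layout — with disagreements decided by majority
and flagged.  The eleven Table-style subtype rows are then matched on the
companion-cell composition (via :mod:`phloemkey.cc`), phloem-parenchyma
presence, wall ingrowths in phloem parenchyma, and the vein's spatial
symmetry.  Veins matching no row are UNCLASSIFIED with nearest-row
diagnostics; veins matching several rows (typically because of heavily
missing trait data) are AMBIGUOUS.

The module also maps subtype labels onto the two legacy typologies: the
four-type plasmodesmal-density scheme (1 / 1-2a / 2a / 2b) and the five-type
ontogeny-plus-specialization consensus scheme (0 / 1A / 1B / 2A / 2B).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .cc import CCClassification, CCLabel, CCRuleSet, Status, classify_cc
from .records import SpeciesRecord, VeinObservation
from .vocab import (
    Branching,
    DivisionPlane,
    Grade,
    SlotPosition,
    Symmetry,
    Tristate,
)

__all__ = [
    "VeinLabel",
    "VEIN_MAJOR_TYPE",
    "Gamalei",
    "VanBelHafke",
    "LegacyLabel",
    "TypeInference",
    "VeinClassification",
    "infer_type",
    "classify_vein",
    "classify_record",
    "to_legacy",
    "density_type",
    "structure_symplasm_audit",
    "load_vanbel_map",
]


class VeinLabel(enum.Enum):
    """The eleven assignable minor-vein phloem subtypes."""

    T1_I = "1-I"
    T1_II = "1-II"
    T1_III = "1-III"
    T1_IV = "1-IV"
    T0 = "0"
    T2_I = "2-I"
    T2_II = "2-II"
    T2_III = "2-III"
    T2_IV = "2-IV"
    T2_V = "2-V"
    T2_VI = "2-VI"

    def __str__(self) -> str:
        return self.value


VEIN_MAJOR_TYPE: dict[VeinLabel, int] = {
    VeinLabel.T1_I: 1, VeinLabel.T1_II: 1, VeinLabel.T1_III: 1,
    VeinLabel.T1_IV: 1, VeinLabel.T0: 0,
    VeinLabel.T2_I: 2, VeinLabel.T2_II: 2, VeinLabel.T2_III: 2,
    VeinLabel.T2_IV: 2, VeinLabel.T2_V: 2, VeinLabel.T2_VI: 2,
}


class Gamalei(enum.Enum):
    """Four-type plasmodesmal-density typology (open/closed spectrum)."""

    G1 = "1"
    G1_2A = "1-2a"
    G2A = "2a"
    G2B = "2b"

    def __str__(self) -> str:
        return self.value


class VanBelHafke(enum.Enum):
    """Five-type consensus scheme: ontogeny digit + specialization letter."""

    VH0 = "0"
    VH1A = "1A"
    VH1B = "1B"
    VH2A = "2A"
    VH2B = "2B"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class LegacyLabel:
    gamalei: Gamalei
    vanbel_hafke: VanBelHafke


# Types 1 and 2 keep their positions in the four-type scheme; the former
# intermediate 1-2a group is divided between type 0 and subtype 2-I.  The
# closed subtypes split on companion-cell wall ingrowths (2b keys on CWI):
# PP-level ingrowths in 2-II do not promote, while every CWI-bearing CC
# subtype (the TCs and MIC-b) does.
GAMALEI_MAP: dict[VeinLabel, Gamalei] = {
    VeinLabel.T1_I: Gamalei.G1,
    VeinLabel.T1_II: Gamalei.G1,
    VeinLabel.T1_III: Gamalei.G1,
    VeinLabel.T1_IV: Gamalei.G1,
    VeinLabel.T0: Gamalei.G1_2A,
    VeinLabel.T2_I: Gamalei.G1_2A,
    VeinLabel.T2_II: Gamalei.G2A,
    VeinLabel.T2_III: Gamalei.G2B,
    VeinLabel.T2_IV: Gamalei.G2B,
    VeinLabel.T2_V: Gamalei.G2B,
    VeinLabel.T2_VI: Gamalei.G2B,
}

# Default consensus-scheme mapping (configurable; the letter grades "less vs
# more advanced structural specialization").
VANBEL_DEFAULT: dict[VeinLabel, VanBelHafke] = {
    VeinLabel.T0: VanBelHafke.VH0,
    VeinLabel.T1_I: VanBelHafke.VH1B,
    VeinLabel.T1_IV: VanBelHafke.VH1B,
    VeinLabel.T1_II: VanBelHafke.VH1A,
    VeinLabel.T1_III: VanBelHafke.VH1A,
    VeinLabel.T2_I: VanBelHafke.VH2A,
    VeinLabel.T2_II: VanBelHafke.VH2A,
    VeinLabel.T2_III: VanBelHafke.VH2B,
    VeinLabel.T2_IV: VanBelHafke.VH2B,
    VeinLabel.T2_V: VanBelHafke.VH2B,
    VeinLabel.T2_VI: VanBelHafke.VH2B,
}


def load_vanbel_map(path: str | Path) -> dict[VeinLabel, VanBelHafke]:
    """Load a user override of the consensus-scheme mapping from YAML
    (``{"1-I": "1B", ...}``); unlisted subtypes keep the default."""
    raw = yaml.safe_load(Path(path).read_text())
    out = dict(VANBEL_DEFAULT)
    by_value_v = {m.value: m for m in VeinLabel}
    by_value_h = {m.value: m for m in VanBelHafke}
    for k, v in raw.items():
        out[by_value_v[str(k)]] = by_value_h[str(v)]
    return out


def to_legacy(
    label: VeinLabel,
    vanbel_map: Mapping[VeinLabel, VanBelHafke] | None = None,
) -> LegacyLabel:
    """Map a subtype to both legacy typologies (total on all 11 labels)."""
    if not isinstance(label, VeinLabel):
        raise ValueError("cannot map an unclassified vein to legacy typologies")
    vb = (vanbel_map or VANBEL_DEFAULT)[label]
    return LegacyLabel(gamalei=GAMALEI_MAP[label], vanbel_hafke=vb)


def density_type(pd_density_per_um2: float, cwi_present: Tristate) -> Gamalei:
    """Classify from plasmodesmal density alone (counts per μm² of CC wall
    facing the bundle sheath).

    Bands, closed on the left: [10, 100] open type 1; [1, 10) intermediate
    1-2a; [0, 1) closed, split into 2b (wall ingrowths present) and 2a.
    Densities above 100 still fall in type 1 (flagged out of printed range
    by callers if needed).
    """
    if pd_density_per_um2 < 0:
        raise ValueError("plasmodesmal density must be non-negative")
    if pd_density_per_um2 >= 10:
        return Gamalei.G1
    if pd_density_per_um2 >= 1:
        return Gamalei.G1_2A
    return Gamalei.G2B if cwi_present is Tristate.YES else Gamalei.G2A


# ---------------------------------------------------------------------------
# major-type inference

_TYPE2_RATIOS = (Fraction(3, 2), Fraction(2, 1))


@dataclass(frozen=True)
class TypeInference:
    major: int
    conflict: bool
    votes: tuple[tuple[str, int], ...]   # (criterion, voted type)
    rationale: tuple[str, ...]


def infer_type(vein: VeinObservation) -> TypeInference:
    """Infer the ontogenetic major type (0/1/2) of a vein.

    Criteria in order of precedence: first division plane (anticlinal → 1,
    periclinal → 2, unordered → 0); spatial organization (both ordered types
    are defined with well-organized veins, so an explicitly not-well-defined
    organization votes for type 0); aggregate CC:SE ratio (1 → 1; 3/2 or
    2 → 2; anything else → 0); parenchyma layout (phloem parenchyma → 2;
    a vascular-parenchyma row with no phloem parenchyma → 1).  Majority
    decides under conflict, precedence breaks ties, and a CONFLICT flag is
    raised whenever the criteria disagree.
    """
    votes: list[tuple[str, int]] = []
    notes: list[str] = []

    plane = vein.first_division_plane
    if plane is DivisionPlane.ANTICLINAL:
        votes.append(("division_plane", 1))
    elif plane is DivisionPlane.PERICLINAL:
        votes.append(("division_plane", 2))
    elif plane is DivisionPlane.UNORDERED:
        votes.append(("division_plane", 0))

    if vein.spatial_symmetry is Symmetry.NOT_WELL_DEFINED:
        votes.append(("spatial_organization", 0))

    ratio = vein.cc_se_ratio
    if ratio == 1:
        votes.append(("cc_se_ratio", 1))
    elif ratio in _TYPE2_RATIOS:
        votes.append(("cc_se_ratio", 2))
    else:
        votes.append(("cc_se_ratio", 0))
    notes.append(f"CC:SE = {ratio}")

    pp = vein.phloem_parenchyma_present
    vp = vein.vascular_parenchyma_row_present
    if pp is Tristate.YES:
        votes.append(("parenchyma_layout", 2))
    elif pp is Tristate.NO and vp is Tristate.YES:
        votes.append(("parenchyma_layout", 1))

    tally: dict[int, int] = {}
    for _, t in votes:
        tally[t] = tally.get(t, 0) + 1
    best = max(tally.values())
    leaders = [t for t, n in tally.items() if n == best]
    if len(leaders) == 1:
        major = leaders[0]
    else:
        # tie: highest-precedence criterion voting for a leading type decides
        major = next(t for _, t in votes if t in leaders)
    conflict = len(tally) > 1
    if conflict:
        notes.append("criteria disagree: "
                     + ", ".join(f"{c}→{t}" for c, t in votes))
    return TypeInference(major, conflict, tuple(votes), tuple(notes))


# ---------------------------------------------------------------------------
# subtype rules

@dataclass(frozen=True)
class VeinRule:
    label: VeinLabel
    major: int
    symmetry_allowed: frozenset[Symmetry]
    cc_all: tuple[CCLabel, ...] | None
    cc_adaxial: tuple[CCLabel, ...] | None
    cc_abaxial: tuple[CCLabel, ...] | None
    phloem_parenchyma: str   # "yes" | "no" | "any"
    pp_cwi: str


_CC_BY_VALUE = {m.value: m for m in CCLabel}
_VEIN_BY_VALUE = {m.value: m for m in VeinLabel}


def _load_vein_rules() -> tuple[VeinRule, ...]:
    text = (resources.files("phloemkey.data") / "vein_rules.yaml").read_text()
    raw = yaml.safe_load(text)
    rules = []
    for key, entry in raw.items():
        cc = entry["cc"]
        rules.append(VeinRule(
            label=_VEIN_BY_VALUE[str(key)],
            major=int(entry["major"]),
            symmetry_allowed=frozenset(
                Symmetry.parse(s) for s in entry["symmetry"]),
            cc_all=tuple(_CC_BY_VALUE[c] for c in cc["all"])
            if "all" in cc else None,
            cc_adaxial=tuple(_CC_BY_VALUE[c] for c in cc["adaxial"])
            if "adaxial" in cc else None,
            cc_abaxial=tuple(_CC_BY_VALUE[c] for c in cc["abaxial"])
            if "abaxial" in cc else None,
            phloem_parenchyma=str(entry["phloem_parenchyma"]),
            pp_cwi=str(entry["pp_cwi"]),
        ))
    return tuple(rules)


_VEIN_RULES: tuple[VeinRule, ...] | None = None


def vein_rules() -> tuple[VeinRule, ...]:
    global _VEIN_RULES
    if _VEIN_RULES is None:
        _VEIN_RULES = _load_vein_rules()
    return _VEIN_RULES


@dataclass(frozen=True)
class VeinClassification:
    labels: frozenset[VeinLabel]
    status: Status
    inferred_type: TypeInference
    flags: tuple[str, ...]                       # CONFLICT, ATYPICAL
    rationale: tuple[str, ...]
    slot_classifications: tuple[tuple[CCClassification, ...], ...]

    @property
    def label(self) -> VeinLabel | None:
        if self.status is Status.UNIQUE:
            return next(iter(self.labels))
        return None

    @property
    def cc_labels_present(self) -> frozenset[CCLabel]:
        """Union of unique CC calls across slots."""
        out = set()
        for slot in self.slot_classifications:
            for res in slot:
                if res.status is Status.UNIQUE:
                    out.add(res.unique_label)
        return frozenset(out)


def _slot_assignable(slot_results: Sequence[CCClassification],
                     label: CCLabel) -> bool:
    """True if every CC of the slot could be the given subtype."""
    return all(label in res.labels for res in slot_results)


def _tristate_ok(value: Tristate, requirement: str) -> bool:
    if requirement == "any":
        return True
    if requirement == "yes":
        return value is Tristate.YES
    # "no": UNKNOWN is treated as not-observed and passes
    return value is not Tristate.YES


def _match_rule(
    rule: VeinRule,
    vein: VeinObservation,
    slot_results: Sequence[Sequence[CCClassification]],
) -> str | None:
    """Return None on match, else the name of the first failed predicate."""
    if (vein.spatial_symmetry is not Symmetry.UNKNOWN
            and vein.spatial_symmetry not in rule.symmetry_allowed):
        return "vein_symmetry"
    if not _tristate_ok(vein.phloem_parenchyma_present, rule.phloem_parenchyma):
        return "phloem_parenchyma"
    if not _tristate_ok(vein.pp_cwi_present, rule.pp_cwi):
        return "pp_cwi"
    slots = list(zip(vein.slots, slot_results))
    if rule.cc_all is not None:
        if not any(
            all(_slot_assignable(res, lab) for _, res in slots)
            for lab in rule.cc_all
        ):
            return "cc_composition"
        return None
    # two-subtype arrangement: deviant SE-CCC at the abaxial pole
    abaxial = [(s, r) for s, r in slots if s.position is SlotPosition.ABAXIAL]
    if abaxial:
        adaxial = [(s, r) for s, r in slots
                   if s.position is not SlotPosition.ABAXIAL]
        if not adaxial:
            return "cc_composition"
        ab_ok = any(all(_slot_assignable(r, lab) for _, r in abaxial)
                    for lab in rule.cc_abaxial)
        ad_ok = any(all(_slot_assignable(r, lab) for _, r in adaxial)
                    for lab in rule.cc_adaxial)
        return None if (ab_ok and ad_ok) else "cc_composition"
    # positions unspecified: look for a two-group assignment
    if len(slots) < 2:
        return "cc_composition"
    for lab_ab in rule.cc_abaxial:
        for lab_ad in rule.cc_adaxial:
            groups_ab = [x for x in slots if _slot_assignable(x[1], lab_ab)]
            groups_ad = [x for x in slots if _slot_assignable(x[1], lab_ad)]
            if not groups_ab or not groups_ad:
                continue
            # every slot must belong to at least one group
            if all(_slot_assignable(r, lab_ab) or _slot_assignable(r, lab_ad)
                   for _, r in slots):
                return None
    return "cc_composition"


def _asarina_like(
    vein: VeinObservation,
    slot_results: Sequence[Sequence[CCClassification]],
) -> bool:
    """Veins combining adaxial MIC-a complexes with abaxial transfer cells
    (two per sieve element) and no phloem parenchyma: kept in type 1 next to
    1-III despite their unstable CC:SE ratio."""
    if vein.phloem_parenchyma_present is Tristate.YES:
        return False
    has_mic_a = any(
        _slot_assignable(res, CCLabel.MIC_A) for res in slot_results
    )
    has_tc_b = any(
        _slot_assignable(res, CCLabel.TC_B) for res in slot_results
    )
    # require MIC-a to be a positive call somewhere, not just "possible"
    mic_called = any(
        res.status is Status.UNIQUE and res.unique_label is CCLabel.MIC_A
        for slot in slot_results for res in slot
    )
    return has_mic_a and has_tc_b and mic_called


def classify_vein(
    vein: VeinObservation,
    cc_rules: CCRuleSet | None = None,
) -> VeinClassification:
    """Assign a vein observation to one of the eleven subtypes.

    Companion cells are classified internally; the subtype row must agree
    with the inferred major type, the CC composition, the parenchyma traits
    and the vein symmetry.
    """
    slot_results: list[tuple[CCClassification, ...]] = []
    context: set[CCLabel] = set()
    for slot in vein.slots:
        results = tuple(classify_cc(p, rules=cc_rules) for p in slot.cc_profiles)
        slot_results.append(results)
        for res in results:
            if res.status is Status.UNIQUE:
                context.add(res.unique_label)
    inferred = infer_type(vein)
    flags: list[str] = []
    notes: list[str] = list(inferred.rationale)
    if inferred.conflict:
        flags.append("CONFLICT")

    matches: list[VeinLabel] = []
    diagnostics: list[str] = []
    for rule in vein_rules():
        if rule.major != inferred.major:
            continue
        failed = _match_rule(rule, vein, slot_results)
        if failed is None:
            matches.append(rule.label)
        else:
            diagnostics.append(f"{rule.label.value}: failed {failed}")

    if len(matches) == 1:
        label = matches[0]
        notes.append(f"matched row {label.value} (major type {inferred.major})")
        return VeinClassification(
            frozenset({label}), Status.UNIQUE, inferred, tuple(flags),
            tuple(notes), tuple(slot_results))
    if len(matches) > 1:
        notes.append("several rows compatible: "
                     + ", ".join(m.value for m in matches))
        return VeinClassification(
            frozenset(matches), Status.AMBIGUOUS, inferred, tuple(flags),
            tuple(notes), tuple(slot_results))

    if _asarina_like(vein, slot_results):
        flags.append("ATYPICAL")
        notes.append(
            "adaxial MIC-a with abaxial transfer cells and no phloem "
            "parenchyma: placed in type 1 next to 1-III")
        return VeinClassification(
            frozenset({VeinLabel.T1_III}), Status.UNIQUE, inferred,
            tuple(flags), tuple(notes), tuple(slot_results))

    notes.append("no subtype row matched; nearest rows: "
                 + ("; ".join(diagnostics) if diagnostics else "none in type"))
    return VeinClassification(
        frozenset(), Status.UNCLASSIFIED, inferred, tuple(flags),
        tuple(notes), tuple(slot_results))


def classify_record(
    record: SpeciesRecord,
    cc_rules: CCRuleSet | None = None,
) -> list[VeinClassification]:
    """Classify every vein of a species record."""
    return [classify_vein(v, cc_rules=cc_rules) for v in record.veins]


def species_labels(
    record: SpeciesRecord,
    cc_rules: CCRuleSet | None = None,
) -> frozenset[VeinLabel]:
    """The species-level label set: unique calls over its veins (a species
    may legitimately carry several subtypes; the set is never collapsed)."""
    out = set()
    for res in classify_record(record, cc_rules=cc_rules):
        if res.label is not None:
            out.add(res.label)
    return frozenset(out)


# ---------------------------------------------------------------------------
# structure--symplasm correlation audit

def _has_true_fields(vein: VeinObservation) -> bool | None:
    """Whether any CC shows genuine plasmodesmal fields (aggregated, not just
    many single plasmodesmata).  None if nothing is known."""
    any_known = False
    for slot in vein.slots:
        for prof in slot.cc_profiles:
            if not prof.pf_grade.is_known:
                continue
            any_known = True
            if (prof.pf_grade >= Grade.SPARSE
                    and prof.pd_branching is not Branching.SINGLE_UNBRANCHED):
                return True
    return False if any_known else None


def structure_symplasm_audit(
    records: Sequence[SpeciesRecord],
    cc_rules: CCRuleSet | None = None,
) -> dict:
    """Fraction of classified veins where vein ontogeny and symplasmic
    continuity disagree.

    The expectation — anticlinal/type-1 veins carry plasmodesmal fields,
    periclinal/type-2 veins lack them — holds in the overwhelming majority of
    species; the audit surfaces the exceptions (hemiparasite 2-VI veins with
    fields, type-1 layouts connected only by many single plasmodesmata).
    """
    n_audited = 0
    disagreements: list[tuple[str, str, str]] = []
    for record in records:
        for vein, res in zip(record.veins, classify_record(record, cc_rules)):
            if res.label is None or VEIN_MAJOR_TYPE[res.label] == 0:
                continue
            fields = _has_true_fields(vein)
            if fields is None:
                continue
            n_audited += 1
            major = VEIN_MAJOR_TYPE[res.label]
            if major == 1 and not fields:
                disagreements.append(
                    (record.taxon, res.label.value,
                     "type-1 ontogeny without plasmodesmal fields"))
            elif major == 2 and fields:
                disagreements.append(
                    (record.taxon, res.label.value,
                     "type-2 ontogeny with plasmodesmal fields"))
    fraction = len(disagreements) / n_audited if n_audited else 0.0
    return {
        "n_audited": n_audited,
        "n_disagreements": len(disagreements),
        "fraction": fraction,
        "disagreements": disagreements,
    }
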