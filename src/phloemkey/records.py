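"""Core record types: companion-cell profiles, vein observations, species records.

The containers are deliberately permissive: a profile that violates a
cytological invariant (say, abundant wall ingrowths with morphology "none")
can be constructed and round-tripped, and :func:`validate_record` reports the
contradiction instead of refusing to represent it.  Only type-level
preconditions (positive cell counts, non-negative plasmodesmal density) raise
at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

from .vocab import (
    Branching,
    CWIMorphology,
    DivisionPlane,
    Evidence,
    Grade,
    GrowthForm,
    Plastid,
    SlotPosition,
    Symmetry,
    Tristate,
)

__all__ = [
    "CCProfile",
    "SECCCSlot",
    "VeinObservation",
    "SpeciesRecord",
    "Violation",
    "ValidationReport",
    "validate_record",
    "UNKNOWN_PROFILE",
]


@dataclass(frozen=True)
class CCProfile:
    """Cytological trait vector of one companion cell.

    ``pf_grade`` grades the plasmodesmal fields facing the bundle sheath,
    ``cwi_grade``/``cwi_morphology`` the cell-wall ingrowths,
    ``starch_in_leucoplasts`` and ``rfo_evidence`` the two subordinate
    metabolic traits, and ``pd_density_per_um2`` an optional quantitative
    plasmodesmal count per square micrometre at the bundle-sheath wall.
    """

    pf_grade: Grade = Grade.UNKNOWN
    pd_branching: Branching = Branching.UNKNOWN
    cwi_grade: Grade = Grade.UNKNOWN
    cwi_morphology: CWIMorphology = CWIMorphology.UNKNOWN
    plastid: Plastid = Plastid.UNKNOWN
    starch_in_leucoplasts: Tristate = Tristate.UNKNOWN
    rfo_evidence: Evidence = Evidence.UNKNOWN
    pd_density_per_um2: float | None = None
    xylem_facing_cwi: Tristate = Tristate.UNKNOWN

    def __post_init__(self) -> None:
        if self.pd_density_per_um2 is not None and self.pd_density_per_um2 < 0:
            raise ValueError("pd_density_per_um2 must be non-negative")

    def replace(self, **kwargs) -> "CCProfile":
        return replace(self, **kwargs)


UNKNOWN_PROFILE = CCProfile()


@dataclass(frozen=True)
class SECCCSlot:
    """One sieve-element / companion-cell complex within a vein.

    A slot with two companion cells per sieve element carries two profiles;
    the CC count is always ``len(cc_profiles)`` and is never stored.
    """

    cc_profiles: tuple[CCProfile, ...]
    se_count: int = 1
    position: SlotPosition = SlotPosition.UNSPECIFIED

    def __post_init__(self) -> None:
        if not self.cc_profiles:
            raise ValueError("a SE-CCC slot needs at least one CC profile")
        if self.se_count < 1:
            raise ValueError("se_count must be a positive integer")
        object.__setattr__(self, "cc_profiles", tuple(self.cc_profiles))

    @property
    def cc_count(self) -> int:
        return len(self.cc_profiles)


@dataclass(frozen=True)
class VeinObservation:
    """One minor vein: ordered SE-CCC slots plus vein-level traits."""

    slots: tuple[SECCCSlot, ...]
    spatial_symmetry: Symmetry = Symmetry.UNKNOWN
    phloem_parenchyma_present: Tristate = Tristate.UNKNOWN
    pp_cwi_present: Tristate = Tristate.UNKNOWN
    vascular_parenchyma_row_present: Tristate = Tristate.UNKNOWN
    first_division_plane: DivisionPlane = DivisionPlane.UNKNOWN

    def __post_init__(self) -> None:
        if not self.slots:
            raise ValueError("a vein observation needs at least one slot")
        object.__setattr__(self, "slots", tuple(self.slots))

    @property
    def cc_count(self) -> int:
        return sum(s.cc_count for s in self.slots)

    @property
    def se_count(self) -> int:
        return sum(s.se_count for s in self.slots)

    @property
    def cc_se_ratio(self) -> Fraction:
        """Aggregate CC:SE ratio as an exact rational (always recomputed)."""
        return Fraction(self.cc_count, self.se_count)


@dataclass(frozen=True)
class SpeciesRecord:
    """Taxon metadata plus one or more vein observations."""

    taxon: str
    genus: str = ""
    family: str = ""
    growth_form: GrowthForm = GrowthForm.UNKNOWN
    hemiparasite: Tristate = Tristate.UNKNOWN
    veins: tuple[VeinObservation, ...] = ()
    leaf_sugars: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "veins", tuple(self.veins))
        object.__setattr__(self, "leaf_sugars", frozenset(self.leaf_sugars))


@dataclass(frozen=True)
class Violation:
    rule_id: str
    severity: str  # "ERROR" | "WARN"
    message: str
    path: str      # e.g. "veins[0].slots[2].cc_profiles[1]"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...]

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def errors(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "ERROR")

    @property
    def warnings(self) -> tuple[Violation, ...]:
        return tuple(v for v in self.violations if v.severity == "WARN")


def _check_profile(profile: CCProfile, path: str) -> Iterable[Violation]:
    g, m = profile.cwi_grade, profile.cwi_morphology
    if m is CWIMorphology.NONE and g.is_known and g is not Grade.ABSENT:
        yield Violation(
            "cwi-morphology-grade", "ERROR",
            f"cwi_morphology NONE contradicts cwi_grade {g.token}", path)
    if g is Grade.ABSENT and m not in (CWIMorphology.NONE, CWIMorphology.UNKNOWN):
        yield Violation(
            "cwi-morphology-grade", "ERROR",
            f"cwi_grade ABSENT contradicts cwi_morphology {m.token}", path)
    if (profile.plastid is Plastid.CHLOROPLAST
            and profile.starch_in_leucoplasts is Tristate.YES):
        yield Violation(
            "starch-plastid", "ERROR",
            "starch_in_leucoplasts YES is impossible with chloroplasts", path)
    if profile.pd_density_per_um2 is not None and profile.pf_grade is Grade.ABSENT:
        yield Violation(
            "density-without-fields", "WARN",
            "pd_density_per_um2 recorded but plasmodesmal fields graded absent",
            path)


def validate_record(record: SpeciesRecord) -> ValidationReport:
    """Report every violated invariant of a species record, exactly once each.

    Deterministic and report-only: ERROR for hard cytological contradictions,
    WARN for soft ones.  A fully UNKNOWN profile is legal.
    """
    out: list[Violation] = []
    if not record.family.strip():
        out.append(Violation("family-empty", "ERROR", "family must be non-empty",
                             "family"))
    if not record.veins:
        out.append(Violation("no-veins", "WARN",
                             "record has no vein observations; not classifiable",
                             "veins"))
    for vi, vein in enumerate(record.veins):
        vpath = f"veins[{vi}]"
        if vein.pp_cwi_present is Tristate.YES:
            if vein.phloem_parenchyma_present is Tristate.NO:
                out.append(Violation(
                    "pp-cwi-without-pp", "ERROR",
                    "wall ingrowths in phloem parenchyma but phloem parenchyma "
                    "marked absent", vpath))
            elif vein.phloem_parenchyma_present is Tristate.UNKNOWN:
                out.append(Violation(
                    "pp-cwi-without-pp", "WARN",
                    "wall ingrowths in phloem parenchyma but phloem parenchyma "
                    "presence unknown", vpath))
        for si, slot in enumerate(vein.slots):
            for ci, prof in enumerate(slot.cc_profiles):
                out.extend(_check_profile(
                    prof, f"{vpath}.slots[{si}].cc_profiles[{ci}]"))
    return ValidationReport(tuple(out))


def validate_records(records: Sequence[SpeciesRecord]) -> dict[str, ValidationReport]:
    """Validate a collection; order-independent per-record reports."""
    return {r.taxon: validate_record(r) for r in records}
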