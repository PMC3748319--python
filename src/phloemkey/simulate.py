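"""Synthetic species records and a minor-vein ontogeny simulator.

The generator emulates the structure of a cytological survey: species
records whose trait vectors follow the canonical subtype definitions, with
configurable missingness (fields replaced by UNKNOWN), ordinal noise on the
abundance grades, family assignment constrained by a family × subtype
incidence profile, growth forms biased by ontogenetic type (type 1 leans
woody, types 0/2 lean herbaceous), and injection of the two documented
exception archetypes.  At zero noise and zero missingness the generated
veins classify back to their source subtype exactly.

Default subtype weights follow the printed aggregate distribution of the
survey: the five dominant subtypes (1-I, 1-II, 2-I, 2-III, 2-IV) jointly
carry >80% of species and subtypes 1-I + 1-IV about 31%, with the remaining
six subtypes rare.

The division-program simulator reproduces the two vein ontogenies at the
level of lineage counts: anticlinal first divisions produce an arc of 2–3
SE-CCCs with one companion cell per sieve element (CC:SE = 1); periclinal
first divisions produce tiers alternating with phloem parenchyma and
CC:SE of 3/2 or 2; unordered divisions yield unstable CC excess.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cc import CCLabel, canonical_profile
from .records import CCProfile, SECCCSlot, SpeciesRecord, VeinObservation
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
from .veins import VeinLabel

__all__ = [
    "DEFAULT_SUBTYPE_WEIGHTS",
    "GeneratorConfig",
    "DivisionProgramKind",
    "DivisionProgram",
    "generate_species",
    "generate_survey",
    "simulate_vein_development",
    "inject_exceptions",
]

DEFAULT_SUBTYPE_WEIGHTS: dict[VeinLabel, float] = {
    VeinLabel.T1_I: 0.25,
    VeinLabel.T1_II: 0.18,
    VeinLabel.T1_III: 0.03,
    VeinLabel.T1_IV: 0.06,
    VeinLabel.T0: 0.03,
    VeinLabel.T2_I: 0.15,
    VeinLabel.T2_II: 0.02,
    VeinLabel.T2_III: 0.15,
    VeinLabel.T2_IV: 0.10,
    VeinLabel.T2_V: 0.02,
    VeinLabel.T2_VI: 0.01,
}

# growth-form sampling biased by ontogenetic type (woody type 1 vs
# herbaceous types 0/2); magnitudes are configurable defaults
_GROWTH_WOODY = ([GrowthForm.TREE, GrowthForm.SHRUB,
                  GrowthForm.PERENNIAL_HERB, GrowthForm.ANNUAL_HERB],
                 [0.40, 0.40, 0.15, 0.05])
_GROWTH_HERB = ([GrowthForm.TREE, GrowthForm.SHRUB,
                 GrowthForm.PERENNIAL_HERB, GrowthForm.ANNUAL_HERB],
                [0.05, 0.15, 0.50, 0.30])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic survey."""

    n_species: int = 320
    subtype_weights: Mapping[VeinLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_WEIGHTS))
    missing_rate: float = 0.0
    noise_rate: float = 0.0
    exception_rate: float = 0.0
    cooccurrence_rate: float = 0.0   # chance of an extra 1-II vein in 1-I species
    veins_per_species: int = 1
    seed: int = 0
    family_profile: pd.DataFrame | None = None   # bool family × subtype frame

    def __post_init__(self) -> None:
        for name in ("missing_rate", "noise_rate", "exception_rate",
                     "cooccurrence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_species < 0:
            raise ValueError("n_species must be non-negative")
        total = sum(self.subtype_weights.values())
        if total <= 0 or any(w < 0 for w in self.subtype_weights.values()):
            raise ValueError("subtype weights must be non-negative, sum > 0")


def _default_family_profile() -> pd.DataFrame:
    from .fixtures import FixtureName, load_fixture
    return load_fixture(FixtureName.TABLE3)


def _slot(label: CCLabel, n_cc: int = 1, se: int = 1,
          pos: SlotPosition = SlotPosition.UNSPECIFIED) -> SECCCSlot:
    prof = canonical_profile(label)
    return SECCCSlot(cc_profiles=(prof,) * n_cc, se_count=se, position=pos)


def _canonical_vein(label: VeinLabel, rng: np.random.Generator) -> VeinObservation:
    """A vein exactly matching the subtype's canonical layout."""
    t1 = dict(spatial_symmetry=Symmetry.WELL_DEFINED,
              phloem_parenchyma_present=Tristate.NO,
              pp_cwi_present=Tristate.NO,
              vascular_parenchyma_row_present=Tristate.YES,
              first_division_plane=DivisionPlane.ANTICLINAL)
    if label is VeinLabel.T1_I:
        cc = [CCLabel.IC, CCLabel.ICL, CCLabel.CC_A][
            rng.choice(3, p=[0.6, 0.2, 0.2])]
        slots = (_slot(cc, pos=SlotPosition.ADAXIAL),
                 _slot(cc, pos=SlotPosition.LATERAL),
                 _slot(cc, pos=SlotPosition.ABAXIAL))
        return VeinObservation(slots=slots, **t1)
    if label is VeinLabel.T1_II:
        slots = (_slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
                 _slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
                 _slot(CCLabel.OC_A, pos=SlotPosition.ABAXIAL))
        return VeinObservation(slots=slots, **t1)
    if label is VeinLabel.T1_III:
        slots = (_slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
                 _slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
                 _slot(CCLabel.TC_B, pos=SlotPosition.ABAXIAL))
        return VeinObservation(slots=slots, **t1)
    if label is VeinLabel.T1_IV:
        slots = tuple(_slot(CCLabel.CC_B, pos=p) for p in
                      (SlotPosition.ADAXIAL, SlotPosition.LATERAL,
                       SlotPosition.ABAXIAL))
        return VeinObservation(slots=slots, **t1)
    if label is VeinLabel.T0:
        cc = CCLabel.OC_A if rng.random() < 0.5 else CCLabel.OC_B
        slots = (_slot(cc), _slot(cc), _slot(cc, n_cc=2))  # CC:SE = 4/3
        return VeinObservation(
            slots=slots,
            spatial_symmetry=Symmetry.NOT_WELL_DEFINED,
            phloem_parenchyma_present=Tristate.NO,
            pp_cwi_present=Tristate.NO,
            vascular_parenchyma_row_present=Tristate.NO,
            first_division_plane=DivisionPlane.UNORDERED)
    # type 2 rows: tiers with phloem parenchyma, aggregate CC:SE 3/2 or 2
    by_cc = {
        VeinLabel.T2_I: CCLabel.OC_B if rng.random() < 0.8 else CCLabel.OC_A,
        VeinLabel.T2_II: CCLabel.OC_B,
        VeinLabel.T2_III: CCLabel.TC_A,
        VeinLabel.T2_IV: CCLabel.TC_A,
        VeinLabel.T2_V: CCLabel.TC_C,
        VeinLabel.T2_VI: CCLabel.MIC_B,
    }
    cc = by_cc[label]
    first_n = 1 if rng.random() < 0.5 else 2    # aggregate 3/2 or 2
    slots = (_slot(cc, n_cc=first_n), _slot(cc, n_cc=2))
    ppcwi = Tristate.YES if label in (VeinLabel.T2_II, VeinLabel.T2_IV) \
        else Tristate.NO
    if label is VeinLabel.T2_VI:
        sym = Symmetry.NOT_WELL_DEFINED if rng.random() < 0.5 \
            else Symmetry.WELL_DEFINED
        plane = DivisionPlane.UNKNOWN   # development undescribed for 2-VI
    else:
        sym = Symmetry.WELL_DEFINED
        plane = DivisionPlane.PERICLINAL
    return VeinObservation(
        slots=slots, spatial_symmetry=sym,
        phloem_parenchyma_present=Tristate.YES, pp_cwi_present=ppcwi,
        vascular_parenchyma_row_present=Tristate.NO,
        first_division_plane=plane)


# ordinal noise: move a grade one step up or down, reflecting at the ends
def _perturb_grade(grade: Grade, rng: np.random.Generator) -> Grade:
    if not grade.is_known:
        return grade
    ladder = [Grade.ABSENT, Grade.SPARSE, Grade.MODERATE, Grade.ABUNDANT]
    i = grade.rank
    step = 1 if rng.random() < 0.5 else -1
    j = i + step
    if j < 0 or j >= len(ladder):
        j = i - step
    return ladder[j]


def _apply_profile_noise(prof: CCProfile, noise_rate: float,
                         rng: np.random.Generator) -> CCProfile:
    if noise_rate <= 0:
        return prof
    pf, cwi, morph = prof.pf_grade, prof.cwi_grade, prof.cwi_morphology
    if rng.random() < noise_rate:
        pf = _perturb_grade(pf, rng)
    if rng.random() < noise_rate:
        cwi = _perturb_grade(cwi, rng)
        # keep the grade/morphology pairing coherent after perturbation
        if cwi is Grade.ABSENT:
            morph = CWIMorphology.NONE
        elif morph is CWIMorphology.NONE:
            morph = CWIMorphology.UNKNOWN
    return prof.replace(pf_grade=pf, cwi_grade=cwi, cwi_morphology=morph)


_PROFILE_UNKNOWNS = dict(
    pf_grade=Grade.UNKNOWN, pd_branching=Branching.UNKNOWN,
    cwi_grade=Grade.UNKNOWN, cwi_morphology=CWIMorphology.UNKNOWN,
    plastid=Plastid.UNKNOWN, starch_in_leucoplasts=Tristate.UNKNOWN,
    rfo_evidence=Evidence.UNKNOWN, xylem_facing_cwi=Tristate.UNKNOWN,
)


def _apply_profile_missing(prof: CCProfile, rate: float,
                           rng: np.random.Generator) -> CCProfile:
    if rate <= 0:
        return prof
    updates = {f: unk for f, unk in _PROFILE_UNKNOWNS.items()
               if rng.random() < rate}
    return prof.replace(**updates) if updates else prof


def _apply_vein_missing(vein: VeinObservation, rate: float,
                        rng: np.random.Generator) -> VeinObservation:
    if rate <= 0:
        return vein
    kwargs = {}
    if rng.random() < rate:
        kwargs["spatial_symmetry"] = Symmetry.UNKNOWN
    if rng.random() < rate:
        kwargs["phloem_parenchyma_present"] = Tristate.UNKNOWN
    if rng.random() < rate:
        kwargs["pp_cwi_present"] = Tristate.UNKNOWN
    if rng.random() < rate:
        kwargs["vascular_parenchyma_row_present"] = Tristate.UNKNOWN
    if rng.random() < rate:
        kwargs["first_division_plane"] = DivisionPlane.UNKNOWN
    return replace(vein, **kwargs) if kwargs else vein


def _degrade_vein(vein: VeinObservation, config: GeneratorConfig,
                  rng: np.random.Generator) -> VeinObservation:
    slots = []
    for slot in vein.slots:
        profs = tuple(
            _apply_profile_missing(
                _apply_profile_noise(p, config.noise_rate, rng),
                config.missing_rate, rng)
            for p in slot.cc_profiles)
        slots.append(replace(slot, cc_profiles=profs))
    return _apply_vein_missing(replace(vein, slots=tuple(slots)),
                               config.missing_rate, rng)


def _sample_growth_form(label: VeinLabel,
                        rng: np.random.Generator) -> GrowthForm:
    from .veins import VEIN_MAJOR_TYPE
    forms, probs = _GROWTH_WOODY if VEIN_MAJOR_TYPE[label] == 1 \
        else _GROWTH_HERB
    return forms[rng.choice(len(forms), p=probs)]


def generate_species(
    label: VeinLabel,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    taxon: str | None = None,
    family: str | None = None,
) -> SpeciesRecord:
    """Generate one species record of the given vein subtype.

    At zero noise and zero missingness every generated vein classifies back
    to exactly ``label``.  Hemiparasitism is forced for the hemiparasite
    subtype 2-VI; growth form is sampled with the type-conditional bias.
    """
    if not isinstance(label, VeinLabel):
        raise ValueError("label must be an assignable vein subtype")
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    veins = []
    for _ in range(max(1, config.veins_per_species)):
        veins.append(_degrade_vein(_canonical_vein(label, rng), config, rng))
    if (label is VeinLabel.T1_I
            and rng.random() < config.cooccurrence_rate):
        veins.append(_degrade_vein(
            _canonical_vein(VeinLabel.T1_II, rng), config, rng))
    hemi = Tristate.YES if label is VeinLabel.T2_VI else Tristate.NO
    family = family or "Simulaceae"
    name = taxon or f"{family} sp. {label.value}"
    return SpeciesRecord(
        taxon=name,
        genus=name.split()[0],
        family=family,
        growth_form=_sample_growth_form(label, rng),
        hemiparasite=hemi,
        veins=tuple(veins),
        leaf_sugars=frozenset(),
    )


def generate_survey(config: GeneratorConfig | None = None) -> list[SpeciesRecord]:
    """Generate a survey of species records.

    Subtype frequencies are multinomial in the configured weights; each
    species' family is drawn uniformly from the families marked for its
    subtype in the family profile (the packaged incidence table by default).
    Deterministic per seed.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    profile = config.family_profile
    if profile is None:
        profile = _default_family_profile()
    labels = [lab for lab in VeinLabel
              if config.subtype_weights.get(lab, 0.0) > 0]
    weights = np.array([config.subtype_weights[lab] for lab in labels],
                       dtype=float)
    weights /= weights.sum()
    family_pool: dict[VeinLabel, list[str]] = {}
    for lab in labels:
        if lab.value not in profile.columns:
            raise ValueError(f"family profile lacks a column for {lab.value}")
        fams = list(profile.index[profile[lab.value].astype(bool)])
        if not fams:
            raise ValueError(
                f"family profile marks no family for weighted subtype "
                f"{lab.value}")
        family_pool[lab] = fams
    records = []
    for i in range(config.n_species):
        lab = labels[rng.choice(len(labels), p=weights)]
        fams = family_pool[lab]
        family = fams[rng.choice(len(fams))]
        records.append(generate_species(
            lab, config, rng,
            taxon=f"{family} sp. {i:04d}", family=family))
    return inject_exceptions(records, config, rng)[0]


# ---------------------------------------------------------------------------
# documented exception archetypes

def _exception_hemiparasite(taxon: str) -> SpeciesRecord:
    """Hemiparasite with MIC-b veins, ingrowths facing the xylem and
    undefined symmetry (classifies 2-VI; flags the structure audit)."""
    prof = canonical_profile(CCLabel.MIC_B).replace(
        xylem_facing_cwi=Tristate.YES)
    slots = (SECCCSlot(cc_profiles=(prof,), se_count=1),
             SECCCSlot(cc_profiles=(prof, prof), se_count=1))
    vein = VeinObservation(
        slots=slots, spatial_symmetry=Symmetry.UNKNOWN,
        phloem_parenchyma_present=Tristate.YES,
        pp_cwi_present=Tristate.NO,
        vascular_parenchyma_row_present=Tristate.NO,
        first_division_plane=DivisionPlane.UNKNOWN)
    return SpeciesRecord(
        taxon=taxon, genus=taxon.split()[0], family="Orobanchaceae",
        growth_form=GrowthForm.ANNUAL_HERB, hemiparasite=Tristate.YES,
        veins=(vein,), leaf_sugars=frozenset({"sucrose", "galactitol"}))


def _exception_single_pd(taxon: str) -> SpeciesRecord:
    """Type-1 layout whose companion cells connect to the bundle sheath by
    many single plasmodesmata instead of true fields (Campanulaceae-like
    1-IV; flags the structure audit)."""
    prof = canonical_profile(CCLabel.CC_B).replace(
        pd_branching=Branching.SINGLE_UNBRANCHED)
    slots = tuple(SECCCSlot(cc_profiles=(prof,), se_count=1, position=p)
                  for p in (SlotPosition.ADAXIAL, SlotPosition.LATERAL,
                            SlotPosition.ABAXIAL))
    vein = VeinObservation(
        slots=slots, spatial_symmetry=Symmetry.WELL_DEFINED,
        phloem_parenchyma_present=Tristate.NO, pp_cwi_present=Tristate.NO,
        vascular_parenchyma_row_present=Tristate.YES,
        first_division_plane=DivisionPlane.ANTICLINAL)
    return SpeciesRecord(
        taxon=taxon, genus=taxon.split()[0], family="Campanulaceae",
        growth_form=GrowthForm.PERENNIAL_HERB, hemiparasite=Tristate.NO,
        veins=(vein,), leaf_sugars=frozenset())


def inject_exceptions(
    records: Sequence[SpeciesRecord],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpeciesRecord], dict[str, int]]:
    """Replace records with documented exception archetypes at the
    configured rate; returns (records, injection counts)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    counts = {"hemiparasite_2vi": 0, "single_pd_1iv": 0}
    for record in records:
        if config.exception_rate > 0 and rng.random() < config.exception_rate:
            if rng.random() < 0.5:
                out.append(_exception_hemiparasite(record.taxon))
                counts["hemiparasite_2vi"] += 1
            else:
                out.append(_exception_single_pd(record.taxon))
                counts["single_pd_1iv"] += 1
        else:
            out.append(record)
    return out, counts


# ---------------------------------------------------------------------------
# division-program (ontogeny) simulator

class DivisionProgramKind(enum.Enum):
    ANTICLINAL_T1 = "anticlinal_t1"
    PERICLINAL_T2 = "periclinal_t2"
    UNORDERED_T0 = "unordered_t0"


@dataclass(frozen=True)
class DivisionProgram:
    """A minor-vein division program at lineage-count resolution."""

    kind: DivisionProgramKind
    n_seccc: int = 3
    parenchyma_layers: int = 0

    def __post_init__(self) -> None:
        if self.n_seccc not in (2, 3):
            raise ValueError("n_seccc must be 2 or 3")
        if self.parenchyma_layers < 0:
            raise ValueError("parenchyma_layers must be non-negative")
        if (self.kind is DivisionProgramKind.ANTICLINAL_T1
                and self.parenchyma_layers != 0):
            # the parenchyma row of type-1 veins is vascular parenchyma,
            # not a product of the phloem initial
            raise ValueError(
                "anticlinal programs produce no phloem parenchyma layers")


def simulate_vein_development(
    program: DivisionProgram, seed: int = 0
) -> VeinObservation:
    """Run a division program and return the resulting vein observation.

    Anticlinal: the initial splits into 2–3 cells at once, each then divides
    unequally into a sieve element and its companion cell, giving an arc
    with CC:SE = 1 and a separate vascular-parenchyma row.  Periclinal:
    tiers of SE-CCCs alternate with phloem-parenchyma layers, per-slot
    CC:SE in {1, 2} and aggregate 3/2 or 2.  Unordered: unstable counts with
    more companion cells than sieve elements.  Companion-cell cytology is
    outside the simulator's scope: profiles are emitted fully UNKNOWN.
    """
    rng = np.random.default_rng(seed)
    unknown = CCProfile()
    if program.kind is DivisionProgramKind.ANTICLINAL_T1:
        positions = [SlotPosition.ADAXIAL, SlotPosition.LATERAL,
                     SlotPosition.ABAXIAL][:program.n_seccc]
        slots = tuple(SECCCSlot(cc_profiles=(unknown,), se_count=1, position=p)
                      for p in positions)
        return VeinObservation(
            slots=slots, spatial_symmetry=Symmetry.WELL_DEFINED,
            phloem_parenchyma_present=Tristate.NO,
            pp_cwi_present=Tristate.NO,
            vascular_parenchyma_row_present=Tristate.YES,
            first_division_plane=DivisionPlane.ANTICLINAL)
    if program.kind is DivisionProgramKind.PERICLINAL_T2:
        if program.n_seccc == 2:
            first_n = 1 if rng.random() < 0.5 else 2   # aggregate 3/2 or 2
            cc_counts = [first_n, 2]
        else:
            cc_counts = [2, 2, 2]                      # aggregate 2
        slots = tuple(SECCCSlot(cc_profiles=(unknown,) * n, se_count=1)
                      for n in cc_counts)
        return VeinObservation(
            slots=slots, spatial_symmetry=Symmetry.WELL_DEFINED,
            phloem_parenchyma_present=Tristate.YES,
            pp_cwi_present=Tristate.UNKNOWN,
            vascular_parenchyma_row_present=Tristate.NO,
            first_division_plane=DivisionPlane.PERICLINAL)
    # unordered: companion cells exceed sieve elements, unstable ratio
    n = program.n_seccc
    extra = int(rng.integers(1, 3))   # 1 or 2 surplus CCs
    cc_counts = [1] * n
    for _ in range(extra):
        cc_counts[int(rng.integers(0, n))] += 1
    # avoid landing on the type-2 signature ratios 3/2 and 2
    from fractions import Fraction
    while Fraction(sum(cc_counts), n) in (Fraction(3, 2), Fraction(2, 1)):
        cc_counts[int(rng.integers(0, n))] += 1
    slots = tuple(SECCCSlot(cc_profiles=(unknown,) * c, se_count=1)
                  for c in cc_counts)
    return VeinObservation(
        slots=slots, spatial_symmetry=Symmetry.NOT_WELL_DEFINED,
        phloem_parenchyma_present=Tristate.NO,
        pp_cwi_present=Tristate.NO,
        vascular_parenchyma_row_present=Tristate.NO,
        first_division_plane=DivisionPlane.UNORDERED)
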