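from fractions import Fraction

import pytest

from phloemkey import (
    Branching,
    CCLabel,
    CCProfile,
    DivisionPlane,
    GAMALEI_MAP,
    Gamalei,
    SECCCSlot,
    SlotPosition,
    SpeciesRecord,
    Status,
    Symmetry,
    Tristate,
    VEIN_MAJOR_TYPE,
    VanBelHafke,
    VeinLabel,
    VeinObservation,
    canonical_profile,
    classify_vein,
    density_type,
    infer_type,
    structure_symplasm_audit,
    to_legacy,
)
from phloemkey.veins import VANBEL_DEFAULT

from conftest import make_slot, type1_vein, type2_vein


# -- major-type inference ---------------------------------------------------

def test_equal_cc_se_counts_give_type_1():
    vein = type1_vein(make_slot(CCLabel.IC), make_slot(CCLabel.IC),
                      make_slot(CCLabel.IC))
    result = infer_type(vein)
    assert result.major == 1
    assert not result.conflict


def test_ratio_three_halves_with_parenchyma_gives_type_2():
    vein = type2_vein(make_slot(CCLabel.TC_A),
                      make_slot(CCLabel.TC_A, n_cc=2))
    assert vein.cc_se_ratio == Fraction(3, 2)
    assert infer_type(vein).major == 2


def test_unstable_cc_excess_gives_type_0():
    vein = VeinObservation(
        slots=(SECCCSlot(cc_profiles=(CCProfile(),) * 4, se_count=2),),
        spatial_symmetry=Symmetry.NOT_WELL_DEFINED,
        phloem_parenchyma_present=Tristate.NO)
    assert infer_type(vein).major == 0


def test_conflicting_criteria_flagged_with_majority_decision():
    # periclinal plane but CC:SE = 1 and phloem parenchyma present:
    # votes 2, 1, 2 -> majority 2, conflict flagged
    vein = VeinObservation(
        slots=(make_slot(CCLabel.OC_B), make_slot(CCLabel.OC_B)),
        spatial_symmetry=Symmetry.WELL_DEFINED,
        phloem_parenchyma_present=Tristate.YES,
        pp_cwi_present=Tristate.NO,
        first_division_plane=DivisionPlane.PERICLINAL)
    result = infer_type(vein)
    assert result.major == 2
    assert result.conflict


def test_division_plane_takes_precedence_on_ties():
    # anticlinal plane vs ratio 2 with no parenchyma evidence: 1-1 tie,
    # the plane criterion decides
    vein = VeinObservation(
        slots=(SECCCSlot(cc_profiles=(CCProfile(), CCProfile())),),
        spatial_symmetry=Symmetry.UNKNOWN,
        first_division_plane=DivisionPlane.ANTICLINAL)
    result = infer_type(vein)
    assert result.major == 1
    assert result.conflict


# -- subtype classification -------------------------------------------------

def test_pure_ic_vein_is_1_i():
    result = classify_vein(type1_vein(
        make_slot(CCLabel.IC), make_slot(CCLabel.IC), make_slot(CCLabel.IC)))
    assert result.label is VeinLabel.T1_I


def test_cc_a_only_vein_is_also_1_i():
    result = classify_vein(type1_vein(
        make_slot(CCLabel.CC_A), make_slot(CCLabel.CC_A),
        make_slot(CCLabel.CC_A)))
    assert result.label is VeinLabel.T1_I


def test_adaxial_ic_abaxial_oc_is_1_ii():
    result = classify_vein(type1_vein(
        make_slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
        make_slot(CCLabel.IC, pos=SlotPosition.ADAXIAL),
        make_slot(CCLabel.OC_A, pos=SlotPosition.ABAXIAL)))
    assert result.label is VeinLabel.T1_II


def test_tc_a_with_pp_cwi_is_2_iv():
    result = classify_vein(type2_vein(
        make_slot(CCLabel.TC_A), make_slot(CCLabel.TC_A, n_cc=2),
        pp_cwi=Tristate.YES))
    assert result.label is VeinLabel.T2_IV


def test_mic_b_with_unknown_symmetry_is_2_vi():
    vein = VeinObservation(
        slots=(make_slot(CCLabel.MIC_B), make_slot(CCLabel.MIC_B, n_cc=2)),
        spatial_symmetry=Symmetry.UNKNOWN,
        phloem_parenchyma_present=Tristate.YES,
        pp_cwi_present=Tristate.NO)
    assert classify_vein(vein).label is VeinLabel.T2_VI


def test_unmatched_vein_reports_nearest_rows():
    # transfer cells with chloroplasts inside a type-1 layout match no row
    result = classify_vein(type1_vein(
        make_slot(CCLabel.TC_A), make_slot(CCLabel.TC_A),
        make_slot(CCLabel.TC_A)))
    assert result.status is Status.UNCLASSIFIED
    assert any("failed" in note for note in result.rationale)


def test_heavily_unknown_vein_is_ambiguous():
    vein = VeinObservation(
        slots=tuple(SECCCSlot(cc_profiles=(CCProfile(),)) for _ in range(3)))
    result = classify_vein(vein)
    assert result.status in (Status.AMBIGUOUS, Status.UNCLASSIFIED)
    assert result.label is None


def test_asarina_layout_is_atypical_1_iii():
    vein = VeinObservation(
        slots=(make_slot(CCLabel.MIC_A, pos=SlotPosition.ADAXIAL),
               make_slot(CCLabel.MIC_A, pos=SlotPosition.ADAXIAL),
               SECCCSlot(cc_profiles=(canonical_profile(CCLabel.TC_B),) * 2,
                         se_count=1, position=SlotPosition.ABAXIAL)),
        spatial_symmetry=Symmetry.WELL_DEFINED,
        phloem_parenchyma_present=Tristate.NO,
        pp_cwi_present=Tristate.NO,
        vascular_parenchyma_row_present=Tristate.NO)
    result = classify_vein(vein)
    assert result.label is VeinLabel.T1_III
    assert "ATYPICAL" in result.flags


# -- legacy typologies ------------------------------------------------------

def test_legacy_mapping_is_total_and_surjective_checks():
    for label in VeinLabel:
        legacy = to_legacy(label)
        assert legacy.gamalei in Gamalei
        assert legacy.vanbel_hafke in VanBelHafke
        assert label in VEIN_MAJOR_TYPE
    assert set(GAMALEI_MAP) == set(VeinLabel)
    assert set(VANBEL_DEFAULT) == set(VeinLabel)


@pytest.mark.parametrize("label,expected", [
    (VeinLabel.T0, Gamalei.G1_2A),       # old intermediate group, part 1
    (VeinLabel.T2_I, Gamalei.G1_2A),     # old intermediate group, part 2
    (VeinLabel.T1_II, Gamalei.G1),       # type 1 keeps its position
    (VeinLabel.T2_IV, Gamalei.G2B),      # wall-ingrowth TCs key the 2b box
])
def test_gamalei_mapping_examples(label, expected):
    assert to_legacy(label).gamalei is expected


def test_unclassified_cannot_be_mapped():
    with pytest.raises(ValueError):
        to_legacy(None)


# -- density-only classification --------------------------------------------

@pytest.mark.parametrize("density,cwi,expected", [
    (60.0, Tristate.NO, Gamalei.G1),       # ash-type abundant fields
    (10.0, Tristate.NO, Gamalei.G1),       # closed-left band edge
    (9.99, Tristate.NO, Gamalei.G1_2A),
    (1.0, Tristate.NO, Gamalei.G1_2A),     # closed-left band edge
    (0.99, Tristate.NO, Gamalei.G2A),
    (0.1, Tristate.YES, Gamalei.G2B),      # transfer-cell density
    (0.1, Tristate.UNKNOWN, Gamalei.G2A),
    (140.0, Tristate.NO, Gamalei.G1),      # above the printed range
])
def test_density_bands(density, cwi, expected):
    assert density_type(density, cwi) is expected


def test_negative_density_rejected():
    with pytest.raises(ValueError):
        density_type(-0.5, Tristate.NO)


# -- structure--symplasm audit ----------------------------------------------

def _species(name, family, vein):
    return SpeciesRecord(taxon=name, family=family, veins=(vein,))


def test_audit_zero_on_canonical_non_exception_data():
    records = [
        _species("A a", "Lamiaceae", type1_vein(
            make_slot(CCLabel.IC), make_slot(CCLabel.IC),
            make_slot(CCLabel.IC))),
        _species("B b", "Asteraceae", type2_vein(
            make_slot(CCLabel.TC_A), make_slot(CCLabel.TC_A, n_cc=2))),
    ]
    audit = structure_symplasm_audit(records)
    assert audit["n_audited"] == 2
    assert audit["fraction"] == 0.0


def test_audit_flags_documented_exceptions():
    mic_b_vein = VeinObservation(
        slots=(make_slot(CCLabel.MIC_B), make_slot(CCLabel.MIC_B, n_cc=2)),
        spatial_symmetry=Symmetry.UNKNOWN,
        phloem_parenchyma_present=Tristate.YES,
        pp_cwi_present=Tristate.NO)
    single_pd = canonical_profile(CCLabel.CC_B).replace(
        pd_branching=Branching.SINGLE_UNBRANCHED)
    single_pd_vein = type1_vein(
        SECCCSlot(cc_profiles=(single_pd,)),
        SECCCSlot(cc_profiles=(single_pd,)),
        SECCCSlot(cc_profiles=(single_pd,)))
    records = [
        _species("Hemi hemi", "Orobanchaceae", mic_b_vein),
        _species("Campa campa", "Campanulaceae", single_pd_vein),
    ]
    audit = structure_symplasm_audit(records)
    assert audit["n_audited"] == 2
    assert audit["n_disagreements"] == 2
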