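from fractions import Fraction

import numpy as np
import pytest

from phloemkey import (
    DEFAULT_SUBTYPE_WEIGHTS,
    DivisionProgram,
    DivisionProgramKind,
    GeneratorConfig,
    Status,
    Tristate,
    VeinLabel,
    classify_vein,
    generate_species,
    generate_survey,
    infer_type,
    inject_exceptions,
    simulate_vein_development,
    species_labels,
    structure_symplasm_audit,
)


def _recovery(missing_rate: float, noise_rate: float = 0.0,
              replicates: int = 20, seed: int = 11) -> float:
    config = GeneratorConfig(missing_rate=missing_rate,
                             noise_rate=noise_rate, seed=seed)
    rng = np.random.default_rng(seed)
    hits = total = 0
    for label in VeinLabel:
        for _ in range(replicates):
            record = generate_species(label, config, rng)
            hits += species_labels(record) == frozenset({label})
            total += 1
    return hits / total


def test_zero_noise_round_trip_recovery_is_perfect():
    assert _recovery(0.0) == 1.0


def test_recovery_degrades_monotonically_with_missingness():
    rates = [0.0, 0.2, 0.5, 0.9]
    accs = [_recovery(r) for r in rates]
    assert all(a >= b for a, b in zip(accs, accs[1:]))
    assert accs[-1] < accs[0]


def test_full_missingness_gives_no_unique_vein_calls():
    config = GeneratorConfig(missing_rate=1.0, seed=3)
    rng = np.random.default_rng(3)
    record = generate_species(VeinLabel.T2_V, config, rng)
    for vein in record.veins:
        result = classify_vein(vein)
        assert result.status in (Status.AMBIGUOUS, Status.UNCLASSIFIED)


def test_seed_determinism():
    config = GeneratorConfig(n_species=60, seed=17, missing_rate=0.3,
                             noise_rate=0.2, exception_rate=0.1)
    assert generate_survey(config) == generate_survey(config)


def test_different_seeds_differ():
    a = generate_survey(GeneratorConfig(n_species=60, seed=1,
                                        missing_rate=0.3))
    b = generate_survey(GeneratorConfig(n_species=60, seed=2,
                                        missing_rate=0.3))
    assert a != b


def test_hemiparasitism_forced_for_2_vi():
    rng = np.random.default_rng(0)
    rec = generate_species(VeinLabel.T2_VI, GeneratorConfig(), rng)
    assert rec.hemiparasite is Tristate.YES
    rec2 = generate_species(VeinLabel.T1_I, GeneratorConfig(), rng)
    assert rec2.hemiparasite is Tristate.NO


def test_growth_form_bias_by_ontogenetic_type():
    rng = np.random.default_rng(5)
    config = GeneratorConfig()
    woody = {"tree", "shrub"}
    t1 = [generate_species(VeinLabel.T1_I, config, rng).growth_form.token
          for _ in range(200)]
    t2 = [generate_species(VeinLabel.T2_III, config, rng).growth_form.token
          for _ in range(200)]
    woody1 = sum(g in woody for g in t1) / len(t1)
    woody2 = sum(g in woody for g in t2) / len(t2)
    assert woody1 > 0.6
    assert woody2 < 0.4


def test_survey_counts_multinomial_within_tail_bound():
    """Uniform weights, n = 1100: every label count within 4 sigma of 100."""
    weights = {lab: 1.0 for lab in VeinLabel}
    survey = generate_survey(GeneratorConfig(
        n_species=1100, seed=23, subtype_weights=weights))
    counts = {lab: 0 for lab in VeinLabel}
    for record in survey:
        labs = species_labels(record)
        assert len(labs) == 1
        counts[next(iter(labs))] += 1
    p = 1 / 11
    sigma = (1100 * p * (1 - p)) ** 0.5
    for lab, n in counts.items():
        assert abs(n - 100) <= 4 * sigma, (lab, n)


def test_survey_respects_family_profile():
    from phloemkey import FixtureName, load_fixture
    printed = load_fixture(FixtureName.TABLE3)
    survey = generate_survey(GeneratorConfig(n_species=80, seed=6))
    for record in survey:
        for label in species_labels(record):
            assert printed.loc[record.family, label.value], (
                record.family, label.value)


def test_survey_errors_on_unmarkable_subtype():
    import pandas as pd
    profile = pd.DataFrame(
        False, index=["Xaceae"], columns=[m.value for m in VeinLabel])
    profile.loc["Xaceae", "1-I"] = True
    config = GeneratorConfig(
        n_species=5, seed=0,
        subtype_weights={VeinLabel.T1_I: 1.0, VeinLabel.T2_V: 1.0},
        family_profile=profile)
    with pytest.raises(ValueError, match="2-V"):
        generate_survey(config)


def test_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(missing_rate=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(subtype_weights={VeinLabel.T1_I: 0.0})
    with pytest.raises(ValueError):
        generate_species("1-I", GeneratorConfig())


def test_default_weights_cover_all_labels_and_sum_to_one():
    assert set(DEFAULT_SUBTYPE_WEIGHTS) == set(VeinLabel)
    assert sum(DEFAULT_SUBTYPE_WEIGHTS.values()) == pytest.approx(1.0)


# -- exception injection ----------------------------------------------------

def test_injection_rate_zero_is_identity():
    survey = generate_survey(GeneratorConfig(n_species=30, seed=8))
    out, counts = inject_exceptions(
        survey, GeneratorConfig(exception_rate=0.0, seed=8))
    assert out == list(survey)
    assert sum(counts.values()) == 0


def test_injection_rate_one_replaces_everything():
    survey = generate_survey(GeneratorConfig(n_species=30, seed=8))
    out, counts = inject_exceptions(
        survey, GeneratorConfig(exception_rate=1.0, seed=8))
    assert sum(counts.values()) == 30
    labels = {next(iter(species_labels(r))) for r in out}
    assert labels == {VeinLabel.T2_VI, VeinLabel.T1_IV}


def test_exception_archetypes_classify_and_flag_audit():
    survey = generate_survey(GeneratorConfig(n_species=20, seed=12))
    out, counts = inject_exceptions(
        survey, GeneratorConfig(exception_rate=1.0, seed=12))
    audit = structure_symplasm_audit(out)
    assert audit["n_disagreements"] == audit["n_audited"] == 20
    hemi = [r for r in out if r.hemiparasite is Tristate.YES]
    assert len(hemi) == counts["hemiparasite_2vi"]
    for record in hemi:
        prof = record.veins[0].slots[0].cc_profiles[0]
        assert prof.xylem_facing_cwi is Tristate.YES


def test_audit_clean_when_exception_subtypes_absent():
    weights = {lab: w for lab, w in DEFAULT_SUBTYPE_WEIGHTS.items()
               if lab is not VeinLabel.T2_VI}
    survey = generate_survey(GeneratorConfig(
        n_species=100, seed=14, subtype_weights=weights))
    audit = structure_symplasm_audit(survey)
    assert audit["fraction"] == 0.0


# -- division-program simulator ---------------------------------------------

def test_anticlinal_program_always_gives_unit_ratio():
    for seed in range(100):
        program = DivisionProgram(DivisionProgramKind.ANTICLINAL_T1,
                                  n_seccc=2 + seed % 2)
        vein = simulate_vein_development(program, seed=seed)
        assert vein.cc_se_ratio == 1
        assert len(vein.slots) == program.n_seccc
        assert infer_type(vein).major == 1


def test_periclinal_program_gives_type_2_ratios():
    allowed = {Fraction(3, 2), Fraction(2, 1)}
    for seed in range(100):
        program = DivisionProgram(DivisionProgramKind.PERICLINAL_T2,
                                  n_seccc=2, parenchyma_layers=1)
        vein = simulate_vein_development(program, seed=seed)
        assert vein.cc_se_ratio in allowed
        assert all(s.cc_count in (1, 2) for s in vein.slots)
        assert infer_type(vein).major == 2


def test_unordered_program_gives_type_0():
    for seed in range(100):
        program = DivisionProgram(DivisionProgramKind.UNORDERED_T0)
        vein = simulate_vein_development(program, seed=seed)
        assert vein.cc_count > vein.se_count
        assert infer_type(vein).major == 0


def test_simulator_is_deterministic_per_seed():
    program = DivisionProgram(DivisionProgramKind.PERICLINAL_T2, n_seccc=2)
    assert (simulate_vein_development(program, seed=5)
            == simulate_vein_development(program, seed=5))


def test_anticlinal_program_forbids_parenchyma_layers():
    with pytest.raises(ValueError):
        DivisionProgram(DivisionProgramKind.ANTICLINAL_T1,
                        parenchyma_layers=1)
    with pytest.raises(ValueError):
        DivisionProgram(DivisionProgramKind.PERICLINAL_T2, n_seccc=5)
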