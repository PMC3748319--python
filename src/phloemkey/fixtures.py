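"""Packaged reference fixtures: the printed rule tables and worked examples.

The package ships hand-transcribed versions of the four printed tables —
the companion-cell decision table, the vein-subtype decision table, the
family × subtype incidence matrix, and the hemiparasite cross-tabulation —
plus a canonical trait table of the figure exemplars with their published
subtype labels.  These are the oracle data for the classifiers: classifying
every exemplar must reproduce its published label.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .cc import CCLabel, CCRuleSet, load_cc_rules
from .io import read_trait_table
from .records import SpeciesRecord
from .veins import VeinLabel, VeinRule, vein_rules
from .vocab import GrowthForm

__all__ = [
    "FixtureName",
    "WorkedExpectation",
    "load_fixture",
    "worked_example_records",
    "worked_example_expectations",
    "fixture_checksums",
]

_DATA_FILES = [
    "cc_rules.yaml",
    "vein_rules.yaml",
    "table3_incidence.tsv",
    "table4_hemiparasites.tsv",
    "worked_examples.tsv",
    "worked_examples_expected.tsv",
]


class FixtureName(enum.Enum):
    TABLE1 = "table1"
    TABLE2 = "table2"
    TABLE3 = "table3"
    TABLE4 = "table4"
    WORKED_EXAMPLES = "worked_examples"


@dataclass(frozen=True)
class WorkedExpectation:
    """Published labels of one figure exemplar."""

    taxon: str
    cc_labels: frozenset[CCLabel]       # subtypes expected as unique calls
    cc_ambiguous: frozenset[CCLabel]    # an expected ambiguity set (or empty)
    vein_label: VeinLabel | None        # published vein subtype, if printed


def _data_text(name: str) -> str:
    return (resources.files("phloemkey.data") / name).read_text()


def _load_table3() -> pd.DataFrame:
    with resources.as_file(
        resources.files("phloemkey.data") / "table3_incidence.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.set_index("family")
    # validate columns against the assignable vein labels
    valid = {m.value for m in VeinLabel}
    bad = [c for c in df.columns if c not in valid]
    if bad:
        raise ValueError(f"incidence fixture has unknown subtype columns {bad}")
    return df.map(lambda cell: cell.strip() == "+")


def _load_table4() -> dict[str, tuple[GrowthForm, VeinLabel]]:
    with resources.as_file(
        resources.files("phloemkey.data") / "table4_hemiparasites.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    by_value = {m.value: m for m in VeinLabel}
    return {
        row["genus"]: (GrowthForm.parse(row["life_form"]),
                       by_value[row["vein_subtype"]])
        for _, row in df.iterrows()
    }


def worked_example_expectations() -> dict[str, WorkedExpectation]:
    with resources.as_file(
        resources.files("phloemkey.data") / "worked_examples_expected.tsv"
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cc_by_value = {m.value: m for m in CCLabel}
    vein_by_value = {m.value: m for m in VeinLabel}

    def split(cell: str) -> frozenset[CCLabel]:
        return frozenset(cc_by_value[t] for t in cell.split(";") if t)

    out = {}
    for _, row in df.iterrows():
        vein = row["vein_label"].strip()
        out[row["taxon"]] = WorkedExpectation(
            taxon=row["taxon"],
            cc_labels=split(row["cc_labels"]),
            cc_ambiguous=split(row["cc_ambiguous"]),
            vein_label=vein_by_value[vein] if vein else None,
        )
    return out


def load_fixture(name: FixtureName):
    """Load one packaged fixture (deterministic, immutable content).

    TABLE1 → the companion-cell rule set; TABLE2 → the vein-subtype rules;
    TABLE3 → family × subtype boolean incidence frame; TABLE4 → hemiparasite
    genus → (life form, vein subtype); WORKED_EXAMPLES → published labels
    per figure exemplar.
    """
    if name is FixtureName.TABLE1:
        return load_cc_rules()
    if name is FixtureName.TABLE2:
        return vein_rules()
    if name is FixtureName.TABLE3:
        return _load_table3()
    if name is FixtureName.TABLE4:
        return _load_table4()
    if name is FixtureName.WORKED_EXAMPLES:
        return worked_example_expectations()
    raise ValueError(f"unknown fixture {name!r}")


def worked_example_records() -> list[SpeciesRecord]:
    """The figure exemplars as species records (canonical trait table)."""
    with resources.as_file(
        resources.files("phloemkey.data") / "worked_examples.tsv"
    ) as path:
        return read_trait_table(path)


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of every packaged data file (provenance pinning)."""
    out = {}
    for name in _DATA_FILES:
        data = (resources.files("phloemkey.data") / name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out
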