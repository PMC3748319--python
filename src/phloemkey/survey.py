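"""Survey-level summaries: incidence, richness, dominance, NEXUS export.

The central object is the family × vein-subtype incidence matrix (presence
only, matching how the printed family table records distribution: a blank
cell means "not observed", not "tested absent"); per-cell species counts are
computed on request but are not part of the printed-table shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .cc import CCLabel, Status
from .records import SpeciesRecord
from .vocab import GrowthForm, Tristate
from .veins import VeinLabel, classify_record, species_labels

__all__ = [
    "IncidenceTable",
    "incidence_matrix",
    "subtype_richness",
    "dominant_subtypes",
    "export_nexus",
    "NEXUS_CHARACTER_COUNT",
]

_LABEL_ORDER = list(VeinLabel)

# Family synonyms normalized at ingest (the survey follows APG III).
FAMILY_SYNONYMS = {
    "Veronicaceae": "Plantaginaceae",
}


def normalize_family(family: str) -> str:
    return FAMILY_SYNONYMS.get(family, family)


@dataclass(frozen=True)
class IncidenceTable:
    """Family × vein-subtype presence matrix with per-cell provenance."""

    frame: pd.DataFrame       # bool, families (sorted) × 11 subtype columns
    provenance: str           # "observed" | "fixture"

    @property
    def families(self) -> list[str]:
        return list(self.frame.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.frame.columns)


def incidence_matrix(records: Sequence[SpeciesRecord]) -> IncidenceTable:
    """Presence matrix over a classified survey.

    Cell (family, subtype) is set iff at least one species of the family has
    at least one vein classified to the subtype.  Rows sorted
    lexicographically; monotone in the record collection.
    """
    columns = [lab.value for lab in _LABEL_ORDER]
    cells: dict[str, set[str]] = {}
    for record in records:
        family = normalize_family(record.family)
        marked = cells.setdefault(family, set())
        for label in species_labels(record):
            marked.add(label.value)
    families = sorted(cells)
    data = [[col in cells[f] for col in columns] for f in families]
    frame = pd.DataFrame(data, index=pd.Index(families, name="family"),
                         columns=columns, dtype=bool)
    return IncidenceTable(frame=frame, provenance="observed")


def fixture_incidence(frame: pd.DataFrame) -> IncidenceTable:
    """Wrap the packaged printed-table frame as an IncidenceTable."""
    return IncidenceTable(frame=frame.astype(bool), provenance="fixture")


def subtype_richness(table: IncidenceTable, family: str) -> int:
    """Number of subtypes recorded for a family (its row sum)."""
    family = normalize_family(family)
    if family not in table.frame.index:
        raise KeyError(f"family {family!r} not present in the table")
    return int(table.frame.loc[family].sum())


def dominant_subtypes(
    records: Sequence[SpeciesRecord],
    threshold_fraction: float,
) -> set[VeinLabel]:
    """Smallest set of subtypes covering ≥ the given fraction of species.

    Subtypes are taken in order of decreasing species count (ties broken by
    label order) until the species covered — a species counts as covered if
    any of its subtypes is selected — reach the threshold.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold must be in (0, 1]")
    per_species = {
        r.taxon: species_labels(r) for r in records
    }
    classified = {t: labs for t, labs in per_species.items() if labs}
    if not classified:
        return set()
    counts = {lab: 0 for lab in _LABEL_ORDER}
    for labs in classified.values():
        for lab in labs:
            counts[lab] += 1
    order = sorted(
        (lab for lab in _LABEL_ORDER if counts[lab] > 0),
        key=lambda lab: (-counts[lab], _LABEL_ORDER.index(lab)),
    )
    chosen: set[VeinLabel] = set()
    covered: set[str] = set()
    total = len(classified)
    for lab in order:
        if len(covered) / total >= threshold_fraction:
            break
        chosen.add(lab)
        covered |= {t for t, labs in classified.items() if lab in labs}
    return chosen


# ---------------------------------------------------------------------------
# NEXUS character-matrix export

_GROWTH_STATES = [GrowthForm.TREE, GrowthForm.SHRUB,
                  GrowthForm.PERENNIAL_HERB, GrowthForm.ANNUAL_HERB]

#: 11 vein-subtype presence + 11 CC-subtype presence + growth form + hemiparasite
NEXUS_CHARACTER_COUNT = len(_LABEL_ORDER) + len(CCLabel) + 2


def _char_labels() -> list[str]:
    labels = [f"vein_{lab.value}" for lab in _LABEL_ORDER]
    labels += [f"cc_{lab.value}" for lab in CCLabel]
    labels += ["growth_form", "hemiparasite"]
    return [lab.replace("-", "_") for lab in labels]


def _species_states(record: SpeciesRecord) -> str:
    vein_set = species_labels(record)
    cc_set: set[CCLabel] = set()
    any_cc_call = False
    for res in classify_record(record):
        for slot in res.slot_classifications:
            for c in slot:
                if c.status is Status.UNIQUE:
                    cc_set.add(c.unique_label)
                    any_cc_call = True
    chars = []
    if vein_set:
        chars += ["1" if lab in vein_set else "0" for lab in _LABEL_ORDER]
    else:
        chars += ["?"] * len(_LABEL_ORDER)
    if any_cc_call:
        chars += ["1" if lab in cc_set else "0" for lab in CCLabel]
    else:
        chars += ["?"] * len(CCLabel)
    if record.growth_form in _GROWTH_STATES:
        chars.append(str(_GROWTH_STATES.index(record.growth_form)))
    else:
        chars.append("?")
    if record.hemiparasite is Tristate.YES:
        chars.append("1")
    elif record.hemiparasite is Tristate.NO:
        chars.append("0")
    else:
        chars.append("?")
    return "".join(chars)


def export_nexus(
    records: Sequence[SpeciesRecord],
    sink: str | Path | IO[str] | None = None,
) -> str:
    """Export classified records as a NEXUS standard character matrix.

    One taxon per species; unordered multistate characters encode the vein
    subtypes present (as presence characters), the CC subtypes present, the
    growth form (0 tree, 1 shrub, 2 perennial herb, 3 annual herb) and the
    hemiparasite flag; missing data is "?".  The document parses with
    standard NEXUS consumers.
    """
    taxa = [r.taxon for r in records]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon names: {dupes}")

    def quote(name: str) -> str:
        return "'" + name.replace("'", "''") + "'"

    lines = ["#NEXUS", "", "BEGIN TAXA;",
             f"    DIMENSIONS NTAX={len(taxa)};"]
    if taxa:
        lines.append("    TAXLABELS")
        for t in taxa:
            lines.append(f"        {quote(t)}")
        lines.append("    ;")
    lines += ["END;", "", "BEGIN CHARACTERS;",
              f"    DIMENSIONS NCHAR={NEXUS_CHARACTER_COUNT};",
              '    FORMAT DATATYPE=STANDARD SYMBOLS="0123" MISSING=? GAP=-;']
    charlabels = _char_labels()
    lines.append("    CHARSTATELABELS")
    lines.append("        "
                 + ", ".join(f"{i + 1} {lab}"
                             for i, lab in enumerate(charlabels))
                 + ";")
    if records:   # NEXUS forbids a MATRIX command with zero taxa
        lines.append("    MATRIX")
        for record in records:
            lines.append(f"        {quote(record.taxon)}  "
                         f"{_species_states(record)}")
        lines.append("    ;")
    lines += ["END;", ""]
    text = "\n".join(lines)
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(text)
        else:
            sink.write(text)
    return text
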