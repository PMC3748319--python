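"""Reading and writing the canonical trait table.

Dialect: UTF-8, tab-delimited, one row per companion-cell profile.  Rows are
grouped into SE-CCC slots by ``slot_id`` (a slot holding two companion cells
per sieve element spans two rows), into veins by ``vein_id`` and into species
by ``taxon``.  Unknown cells are written ``?`` (empty cells are accepted on
input).  Vein-level and species-level columns are repeated on every row and
must be consistent within their group.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from .records import (
    CCProfile,
    SECCCSlot,
    SpeciesRecord,
    VeinObservation,
    validate_record,
)
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
    VocabularyError,
)

__all__ = ["COLUMNS", "TraitTableError", "read_trait_table", "write_trait_table"]

COLUMNS = [
    "taxon", "genus", "family", "growth_form", "hemiparasite", "leaf_sugars",
    "vein_id", "slot_id", "slot_position", "se_count",
    "pf_grade", "pd_branching", "cwi_grade", "cwi_morphology", "plastid",
    "starch_in_leucoplasts", "rfo_evidence", "pd_density_per_um2",
    "xylem_facing_cwi",
    "spatial_symmetry", "phloem_parenchyma_present", "pp_cwi_present",
    "vascular_parenchyma_row_present", "first_division_plane",
]

_SPECIES_COLS = ["genus", "family", "growth_form", "hemiparasite", "leaf_sugars"]
_VEIN_COLS = [
    "spatial_symmetry", "phloem_parenchyma_present", "pp_cwi_present",
    "vascular_parenchyma_row_present", "first_division_plane",
]
_SLOT_COLS = ["slot_position", "se_count"]

_PROFILE_PARSERS = {
    "pf_grade": Grade.parse,
    "pd_branching": Branching.parse,
    "cwi_grade": Grade.parse,
    "cwi_morphology": CWIMorphology.parse,
    "plastid": Plastid.parse,
    "starch_in_leucoplasts": Tristate.parse,
    "rfo_evidence": Evidence.parse,
    "xylem_facing_cwi": Tristate.parse,
}


class TraitTableError(ValueError):
    """Malformed trait table: names the row, column and offending token."""


def _cell(row, col: str) -> str:
    v = str(row[col]).strip()
    return "?" if v == "" else v


def _parse_profile(row, rownum: int, aliases) -> CCProfile:
    kwargs = {}
    for col, parser in _PROFILE_PARSERS.items():
        tok = _cell(row, col)
        try:
            kwargs[col] = parser(tok, aliases)
        except VocabularyError as exc:
            raise TraitTableError(f"row {rownum}, column {col!r}: {exc}") from exc
    dens = _cell(row, "pd_density_per_um2")
    if dens != "?":
        try:
            value = float(dens)
        except ValueError as exc:
            raise TraitTableError(
                f"row {rownum}, column 'pd_density_per_um2': "
                f"not a number: {dens!r}") from exc
        if value < 0:
            raise TraitTableError(
                f"row {rownum}, column 'pd_density_per_um2': negative density")
        kwargs["pd_density_per_um2"] = value
    return CCProfile(**kwargs)


def read_trait_table(
    source: str | Path | IO[str],
    aliases: Mapping[str, str] | None = None,
) -> list[SpeciesRecord]:
    """Read a canonical trait table into species records.

    Every row is consumed or reported; grouping by (taxon, vein_id, slot_id)
    reconstructs slots and veins in file order.  Unknown vocabulary tokens and
    conflicting group-level values raise :class:`TraitTableError`.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"missing columns: {missing}")

    # taxon -> species fields; taxon -> vein_id -> vein fields;
    # (taxon, vein_id) -> slot_id -> slot fields + profiles
    species_meta: dict[str, dict] = {}
    vein_meta: dict[tuple[str, str], dict] = {}
    slot_meta: dict[tuple[str, str, str], dict] = {}
    order_species: list[str] = []
    order_veins: dict[str, list[str]] = {}
    order_slots: dict[tuple[str, str], list[str]] = {}

    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based, counting the header line
        rowmap = dict(zip(df.columns, row))
        taxon = str(rowmap["taxon"]).strip()
        if not taxon:
            raise TraitTableError(f"row {rownum}: empty taxon")
        vein_id = _cell(rowmap, "vein_id")
        slot_id = _cell(rowmap, "slot_id")

        sp_fields = {c: _cell(rowmap, c) for c in _SPECIES_COLS}
        if taxon not in species_meta:
            species_meta[taxon] = sp_fields
            order_species.append(taxon)
            order_veins[taxon] = []
        elif species_meta[taxon] != sp_fields:
            raise TraitTableError(
                f"row {rownum}: species-level columns conflict with earlier "
                f"rows of taxon {taxon!r}")

        vkey = (taxon, vein_id)
        v_fields = {c: _cell(rowmap, c) for c in _VEIN_COLS}
        if vkey not in vein_meta:
            vein_meta[vkey] = v_fields
            order_veins[taxon].append(vein_id)
            order_slots[vkey] = []
        elif vein_meta[vkey] != v_fields:
            raise TraitTableError(
                f"row {rownum}: vein-level columns conflict within vein "
                f"{vein_id!r} of taxon {taxon!r}")

        skey = (taxon, vein_id, slot_id)
        s_fields = {c: _cell(rowmap, c) for c in _SLOT_COLS}
        profile = _parse_profile(rowmap, rownum, aliases)
        if skey not in slot_meta:
            slot_meta[skey] = {"fields": s_fields, "profiles": [profile]}
            order_slots[vkey].append(slot_id)
        else:
            if slot_meta[skey]["fields"] != s_fields:
                raise TraitTableError(
                    f"row {rownum}: duplicate slot {slot_id!r} in vein "
                    f"{vein_id!r} of taxon {taxon!r} with conflicting "
                    f"slot-level values")
            slot_meta[skey]["profiles"].append(profile)

    records: list[SpeciesRecord] = []
    for taxon in order_species:
        veins = []
        for vein_id in order_veins[taxon]:
            vkey = (taxon, vein_id)
            slots = []
            for slot_id in order_slots[vkey]:
                meta = slot_meta[(taxon, vein_id, slot_id)]
                f = meta["fields"]
                try:
                    se = int(f["se_count"])
                except ValueError as exc:
                    raise TraitTableError(
                        f"taxon {taxon!r}, vein {vein_id!r}, slot {slot_id!r}: "
                        f"se_count not an integer: {f['se_count']!r}") from exc
                pos = f["slot_position"]
                slots.append(SECCCSlot(
                    cc_profiles=tuple(meta["profiles"]),
                    se_count=se,
                    position=SlotPosition.UNSPECIFIED if pos == "?"
                    else SlotPosition.parse(pos, aliases),
                ))
            vm = vein_meta[vkey]
            veins.append(VeinObservation(
                slots=tuple(slots),
                spatial_symmetry=Symmetry.parse(vm["spatial_symmetry"], aliases),
                phloem_parenchyma_present=Tristate.parse(
                    vm["phloem_parenchyma_present"], aliases),
                pp_cwi_present=Tristate.parse(vm["pp_cwi_present"], aliases),
                vascular_parenchyma_row_present=Tristate.parse(
                    vm["vascular_parenchyma_row_present"], aliases),
                first_division_plane=DivisionPlane.parse(
                    vm["first_division_plane"], aliases),
            ))
        sp = species_meta[taxon]
        sugars = sp["leaf_sugars"]
        records.append(SpeciesRecord(
            taxon=taxon,
            genus=sp["genus"] if sp["genus"] != "?" else "",
            family=sp["family"] if sp["family"] != "?" else "",
            growth_form=GrowthForm.parse(sp["growth_form"], aliases),
            hemiparasite=Tristate.parse(sp["hemiparasite"], aliases),
            veins=tuple(veins),
            leaf_sugars=frozenset() if sugars == "?"
            else frozenset(s for s in sugars.split(";") if s),
        ))
    return records


def _fmt_density(value: float | None) -> str:
    return "?" if value is None else repr(value)


def write_trait_table(
    records: Sequence[SpeciesRecord],
    sink: str | Path | IO[str],
) -> int:
    """Write records in the canonical dialect; returns the number of data rows.

    Refuses a record whose validation report carries ERROR-severity
    violations.  Output is deterministic and re-readable by
    :func:`read_trait_table` with identical content.
    """
    rows = []
    for record in records:
        report = validate_record(record)
        if report.errors:
            msgs = "; ".join(v.message for v in report.errors)
            raise ValueError(
                f"refusing to write record {record.taxon!r} with hard "
                f"violations: {msgs}")
        sugars = ";".join(sorted(record.leaf_sugars)) or "?"
        for vi, vein in enumerate(record.veins, start=1):
            for si, slot in enumerate(vein.slots, start=1):
                for prof in slot.cc_profiles:
                    rows.append({
                        "taxon": record.taxon,
                        "genus": record.genus or "?",
                        "family": record.family or "?",
                        "growth_form": record.growth_form.token,
                        "hemiparasite": record.hemiparasite.token,
                        "leaf_sugars": sugars,
                        "vein_id": f"v{vi}",
                        "slot_id": f"s{si}",
                        "slot_position": slot.position.token,
                        "se_count": str(slot.se_count),
                        "pf_grade": prof.pf_grade.token,
                        "pd_branching": prof.pd_branching.token,
                        "cwi_grade": prof.cwi_grade.token,
                        "cwi_morphology": prof.cwi_morphology.token,
                        "plastid": prof.plastid.token,
                        "starch_in_leucoplasts":
                            prof.starch_in_leucoplasts.token,
                        "rfo_evidence": prof.rfo_evidence.token,
                        "pd_density_per_um2":
                            _fmt_density(prof.pd_density_per_um2),
                        "xylem_facing_cwi": prof.xylem_facing_cwi.token,
                        "spatial_symmetry": vein.spatial_symmetry.token,
                        "phloem_parenchyma_present":
                            vein.phloem_parenchyma_present.token,
                        "pp_cwi_present": vein.pp_cwi_present.token,
                        "vascular_parenchyma_row_present":
                            vein.vascular_parenchyma_row_present.token,
                        "first_division_plane":
                            vein.first_division_plane.token,
                    })
    df = pd.DataFrame(rows, columns=COLUMNS)
    if isinstance(sink, (str, Path)):
        df.to_csv(sink, sep="\t", index=False, lineterminator="\n")
    else:
        df.to_csv(sink, sep="\t", index=False, lineterminator="\n")
    return len(df)


def records_to_string(records: Sequence[SpeciesRecord]) -> str:
    """Render records as a canonical trait-table string."""
    buf = _io.StringIO()
    write_trait_table(records, buf)
    return buf.getvalue()
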