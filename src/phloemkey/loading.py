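"""Predicted phloem-loading modes from vein-subtype structure.

Each minor-vein subtype implies a set of plausible loading pathways for the
species: subtypes whose SE-CCCs all carry plasmodesmal fields load through
the symplast, subtypes built from ordinary or transfer cells load from the
apoplast, and the mixed arrangements (an apoplasmically specialized abaxial
SE-CCC inside an otherwise "open" vein) support both at once.  The calls are
structural predictions, not flux measurements; the confidence note records
whether functional evidence exists for the subtype or the mechanism is
explicitly open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .records import SpeciesRecord
from .veins import VeinLabel, species_labels

__all__ = [
    "LoadingMode",
    "Confidence",
    "LoadingCall",
    "loading_modes",
    "SpeciesLoadingSummary",
    "species_loading_summary",
]


class LoadingMode(enum.Enum):
    SYMPLASMIC = "symplasmic"
    APOPLASMIC = "apoplasmic"

    def __str__(self) -> str:
        return self.value


class Confidence(enum.Enum):
    STRUCTURAL_ONLY = "structural_only"
    FUNCTIONALLY_SUPPORTED = "functionally_supported"
    OPEN = "open"


@dataclass(frozen=True)
class LoadingCall:
    modes: frozenset[LoadingMode]
    confidence_note: Confidence
    basis: VeinLabel


_S = LoadingMode.SYMPLASMIC
_A = LoadingMode.APOPLASMIC

# subtype -> (modes, confidence).  1-I and 1-IV read as purely symplasmic on
# structure, with the mechanism explicitly open; 1-II carries functional
# support (stachyose synthase in the adaxial ICs, a sucrose transporter in
# the abaxial OC of the same vein); the hemiparasite subtype 2-VI combines
# well-developed fields and wall ingrowths and is left open.
_LOADING_MAP: dict[VeinLabel, tuple[frozenset[LoadingMode], Confidence]] = {
    VeinLabel.T1_I: (frozenset({_S}), Confidence.OPEN),
    VeinLabel.T1_II: (frozenset({_S, _A}), Confidence.FUNCTIONALLY_SUPPORTED),
    VeinLabel.T1_III: (frozenset({_S, _A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T1_IV: (frozenset({_S}), Confidence.OPEN),
    VeinLabel.T0: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_I: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_II: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_III: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_IV: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_V: (frozenset({_A}), Confidence.STRUCTURAL_ONLY),
    VeinLabel.T2_VI: (frozenset({_S, _A}), Confidence.OPEN),
}

_OPEN_CYTOLOGY = frozenset({
    VeinLabel.T1_I, VeinLabel.T1_II, VeinLabel.T1_III, VeinLabel.T1_IV,
})
_MIXED = frozenset({VeinLabel.T1_II, VeinLabel.T1_III})


def loading_modes(label: VeinLabel) -> LoadingCall:
    """The loading-mode call implied by a vein subtype (total mapping)."""
    if not isinstance(label, VeinLabel):
        raise ValueError("cannot derive loading modes for an unclassified vein")
    modes, conf = _LOADING_MAP[label]
    return LoadingCall(modes=modes, confidence_note=conf, basis=label)


@dataclass(frozen=True)
class SpeciesLoadingSummary:
    """Survey-level loading summary.

    Among species with "open" minor-vein cytology (any type-1 subtype), the
    mixed bin counts species that also carry an apoplasmically specialized
    SE-CCC (a 1-II or 1-III vein anywhere in the leaf); the pure bin counts
    species with 1-I/1-IV veins only.
    """

    n_species: int
    n_excluded: int          # species with no classifiable vein
    n_open: int              # open cytology: label set meets the type-1 group
    n_mixed: int
    n_pure: int
    mixed_fraction: float    # of open-cytology species
    pure_fraction: float
    mode_counts: dict[str, int]   # distribution over per-species mode sets
    per_species: dict[str, frozenset[VeinLabel]]


def species_loading_summary(
    records: Sequence[SpeciesRecord],
) -> SpeciesLoadingSummary:
    """Aggregate loading calls over a classified survey.

    Species whose veins are all unclassified are excluded and counted
    separately.  Deterministic given the input.
    """
    per_species: dict[str, frozenset[VeinLabel]] = {}
    n_excluded = 0
    n_open = n_mixed = n_pure = 0
    mode_counts: dict[str, int] = {}
    for record in records:
        labels = species_labels(record)
        per_species[record.taxon] = labels
        if not labels:
            n_excluded += 1
            continue
        modes: set[LoadingMode] = set()
        for label in labels:
            modes |= loading_modes(label).modes
        key = "+".join(sorted(m.value for m in modes))
        mode_counts[key] = mode_counts.get(key, 0) + 1
        if labels & _OPEN_CYTOLOGY:
            n_open += 1
            if labels & _MIXED:
                n_mixed += 1
            else:
                n_pure += 1
    return SpeciesLoadingSummary(
        n_species=len(per_species),
        n_excluded=n_excluded,
        n_open=n_open,
        n_mixed=n_mixed,
        n_pure=n_pure,
        mixed_fraction=n_mixed / n_open if n_open else 0.0,
        pure_fraction=n_pure / n_open if n_open else 0.0,
        mode_counts=mode_counts,
        per_species=per_species,
    )
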