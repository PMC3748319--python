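# phloemkey

Trait-based classification of minor-vein phloem and companion cells in the
Asteridae.

Leaf minor veins are where photoassimilates are loaded into the phloem.
Whether a species loads sugars through plasmodesmata (symplasmically) or
across the cell-wall space via membrane transporters (apoplasmically) is
written into the cytology of its companion cells: intermediary cells (ICs)
carry abundant, asymmetrically branched plasmodesmal fields toward the
bundle sheath; transfer cells (TCs) carry cell-wall ingrowths that amplify
the apoplasmic exchange surface; ordinary cells (OCs) carry neither.  The
spatial organization of the vein — whether the phloem initial first divides
anticlinally (type 1, an arc of SE-CCCs with CC:SE = 1), periclinally
(type 2, tiers alternating with phloem parenchyma, CC:SE = 3/2 or 2), or
without order (type 0, unstable CC excess) — records the vein's ontogeny.

`phloemkey` implements the two formal classifications built on these
observations as a deterministic identification key with explicit
three-valued logic:

* **Companion cells** are assigned to eleven subtypes (OC-a, OC-b, TC-a,
  TC-b, TC-c, IC, ICL, CC-a, CC-b, MIC-a, MIC-b) grouped in four major
  types.  A profile matches a subtype row iff every *known* trait lies in
  the row's allowed set; unknown traits ("?") constrain nothing.  The result
  is unique, an explicit ambiguity set (e.g. {IC, ICL} when starch and RFO
  assays are missing), or unclassified — never a forced guess.
* **Minor veins** are assigned to eleven subtypes (1-I…1-IV, 0, 2-I…2-VI)
  from the inferred ontogenetic type (division plane ≻ spatial organization
  ≻ exact CC:SE ratio ≻ parenchyma layout, majority under conflict), the
  companion-cell composition, phloem-parenchyma traits and vein symmetry.
* Subtype labels map onto the two legacy typologies — the plasmodesmal-
  density scheme 1 / 1-2a / 2a / 2b (with direct classification from
  densities: ≥10 per μm² → 1, [1, 10) → 1-2a, <1 → 2a or 2b by wall
  ingrowths) and the consensus scheme 0/1A/1B/2A/2B — and onto predicted
  phloem-loading mode sets.
* Survey tools compute family × subtype incidence, subtype richness,
  dominant subtypes, and a NEXUS character matrix for downstream
  phylogenetic work.
* A synthetic-survey generator and a division-program simulator make every
  stage testable without any external data.

The package ships hand-transcribed fixtures of the published rule tables
and of seventeen figure exemplars with their published labels; classifying
the exemplars reproduces all seventeen.

## Worked example

```python
from phloemkey import (
    CCProfile, Grade, Branching, Plastid, classify_cc,
    worked_example_records, classify_vein, to_legacy, loading_modes,
)

# a companion cell with abundant asymmetrically branched plasmodesmal
# fields, no wall ingrowths, leucoplasts; starch and RFO assays not done
profile = CCProfile(
    pf_grade=Grade.ABUNDANT,
    pd_branching=Branching.ASYMMETRIC_CC_SIDE,
    cwi_grade=Grade.ABSENT,
    plastid=Plastid.LEUCOPLAST,
)
result = classify_cc(profile)
print("labels:", sorted(l.value for l in result.labels))
print("status:", result.status.value)

# classify a published exemplar vein
record = [r for r in worked_example_records()
          if r.taxon == "Mimulus guttatus"][0]
vein_result = classify_vein(record.veins[0])
print("vein subtype:", vein_result.label.value)
legacy = to_legacy(vein_result.label)
print("legacy:", legacy.gamalei.value, "/", legacy.vanbel_hafke.value)
call = loading_modes(vein_result.label)
print("loading modes:", sorted(m.value for m in call.modes))
```

prints

```
labels: ['IC', 'ICL']
status: ambiguous
vein subtype: 1-II
legacy: 1 / 1A
loading modes: ['apoplasmic', 'symplasmic']
```

The cell is an intermediary cell or its starch-storing look-alike — without
a starch or sugar assay the key reports the ambiguity instead of guessing.
The *Mimulus* vein combines adaxial ICs with an abaxial ordinary cell
(subtype 1-II): an "open", type-1 vein that nevertheless carries an SE-CCC
specialized for apoplasmic loading, so both loading modes are predicted.

## Command line

```sh
phloemkey simulate -o survey.tsv -n 320 --seed 1 --missing-rate 0.2
phloemkey classify-vein survey.tsv -o veins.tsv --species-out species.tsv
phloemkey summarize-loading survey.tsv -o loading.tsv
phloemkey summarize survey.tsv -o incidence.tsv --threshold 0.8
phloemkey export-nexus survey.tsv -o survey.nex
phloemkey pipeline survey.tsv -O results/
```

Input is a tab-separated trait table, one row per companion cell, grouped by
`taxon` / `vein_id` / `slot_id`, with `?` for unknown cells (see
`phloemkey.io.COLUMNS`); `phloemkey simulate` writes the same dialect.

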