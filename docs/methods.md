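# Methods

## The classification model

`phloemkey` treats the published companion-cell and minor-vein typologies as
decision tables over closed categorical vocabularies, evaluated with
three-valued logic.  The central modelling commitment is that *absence of
evidence is not evidence of absence*: every trait has an UNKNOWN state that
is distinct from its negative state (ABSENT, NO, NOT_DETECTED), never
silently coerced, and never allowed to constrain a rule.  A trait record
therefore denotes the set of all complete trait vectors compatible with
what was actually observed, and a classification is the set of subtype rows
that intersect it.

### Companion cells

Each of the eleven companion-cell subtypes is a row of allowed values over
seven discriminating traits: plasmodesmal-field grade, plasmodesmata
branching, wall-ingrowth grade, ingrowth morphology, plastid type, starch
in leucoplasts, and RFO (raffinose-family oligosaccharide) evidence.
Abundance grades are the expert ordinal scale −, +, ++, +++; they are never
inferred from quantitative plasmodesmal densities, which the printed table
does not define cut-offs for.  A profile matches a row iff every *known*
trait lies in the row's allowed set.  Two documented tie-breaks narrow the
raw compatible set:

* **IC vs ICL.**  The pair differs by starch in leucoplasts.  Starch
  observed → ICL; starch absent → IC.  With starch unscored, detected RFO
  synthesis resolves to IC (RFO synthesis and ICs co-occur strictly in the
  surveyed material); with neither assay, the ambiguity set {IC, ICL} is
  reported as such.
* **MIC-a vs MIC-b.**  The printed rows contrast "small" against
  "well-developed" fields and ingrowths (+ vs +++).  Both grades at most
  sparse → MIC-a; both abundant → MIC-b; mixed intermediate grades are
  deliberately left as the ambiguity set {MIC-a, MIC-b}, because the
  printed table gives no rule for them.  This band is the only way a
  complete (fully scored) vector can receive two labels; the exhaustive
  enumeration over all 1152 complete vectors verifies that no other pair of
  subtypes shares a vector.

Grade sets were transcribed pragmatically: all transfer-cell rows accept
{++, +++} ingrowths and the field-bearing rows (IC, ICL, CC-a, CC-b) accept
{++, +++} fields, so that the printed discriminators — morphology, plastid
type, branching symmetry — and not the ordinal step between ++ and +++
decide between subtypes.  Combinations outside the table (e.g. chloroplasts
with flange ingrowths, or symmetric branching with chloroplasts) return
UNCLASSIFIED and are surfaced for curation rather than forced into the
nearest row.

Vein context (other subtypes present in the same vein) may annotate a TC-b
call — a transfer cell with leucoplasts is described as co-occurring with
IC/MIC — but by design it never flips a label.

### Minor veins

A vein observation is an ordered collection of SE-CCC slots (each with a
sieve-element count and one or more companion-cell profiles) plus vein-level
traits.  Classification proceeds in two stages.

**Ontogenetic type (0/1/2).**  Four criteria vote, in order of precedence:

1. first division plane of the phloem initial (anticlinal → 1, periclinal
   → 2, unordered → 0);
2. spatial organization (both ordered types are defined by a well-organized
   vein, so an explicitly not-well-defined organization votes 0);
3. the aggregate CC:SE ratio, computed as an exact rational and never
   stored (1 → 1; 3/2 or 2 → 2; anything else → 0);
4. parenchyma layout (phloem parenchyma → 2; a vascular-parenchyma row with
   none from the phloem initial → 1).

Unknown criteria abstain; the majority decides; precedence breaks ties; any
disagreement raises a CONFLICT flag while still returning a type.  The
second criterion is an extension over a plain three-criterion reading: a
disorganized vein with a coincidental aggregate ratio of 2 would otherwise
be typed 2, although type 2 is defined by its ordered tiers.

**Subtype row matching.**  Rows of the inferred type are matched on the
companion-cell composition (single-subtype rows need one label compatible
with every cell; two-subtype rows place the deviant SE-CCC at the abaxial
pole, with a composition fallback when positions are unrecorded), phloem
parenchyma, wall ingrowths in phloem parenchyma, and symmetry allowances
("rarely −" rows accept both states).  An unknown parenchyma-ingrowth flag
is treated as not-observed, i.e. it matches the ingrowth-free rows.  Veins
matching no row are UNCLASSIFIED with per-row diagnostics of the first
failed predicate; veins matching several rows (typically under heavy
missingness) are reported AMBIGUOUS with the candidate set, never collapsed
to one label.  One special case is handled before giving up: veins that
combine adaxial MIC-a complexes with doubled abaxial transfer cells and no
phloem parenchyma (the *Asarina* layout, whose development is undescribed)
are placed in type 1 next to subtype 1-III and flagged ATYPICAL.

Species-level labels are the *set* of per-vein calls; a species may
legitimately carry 1-I and 1-II veins simultaneously and the set is never
collapsed.

### Legacy typologies and plasmodesmal densities

The subtypes map totally onto the four-type scheme (types 1 and 2 keep
their positions; the former intermediate group 1-2a is divided between
type 0 and subtype 2-I; the closed subtypes split on companion-cell wall
ingrowths, so 2-II with ingrowths only in the phloem parenchyma maps to 2a
while 2-III…2-VI map to 2b).  The five-type consensus mapping
(0/1A/1B/2A/2B) is not printed anywhere authoritative; the default —
0 → 0, {1-I, 1-IV} → 1B, {1-II, 1-III} → 1A, {2-I, 2-II} → 2A,
{2-III…2-VI} → 2B — is a documented choice, overridable from YAML.

Density-only classification uses the printed bands with closed-left
boundaries: counts per μm² in [10, 100] → type 1, [1, 10) → 1-2a, [0, 1) →
2b when wall ingrowths are present, else 2a.  "Between 100 and 10" versus
"below 1" leaves [1, 10) for the middle band only under this convention;
densities above 100 remain type 1.

### Loading-mode inference

Each subtype implies a mode set: {symplasmic} for 1-I and 1-IV (with the
mechanism explicitly open — how such veins prevent sucrose leakage is an
unresolved question), {symplasmic, apoplasmic} for 1-II (functionally
supported by transporter localization in the abaxial ordinary cell of a
stachyose-translocating model species), 1-III (structural only) and the
hemiparasite subtype 2-VI (open), and {apoplasmic} for type 0 and the
remaining type-2 subtypes.  The survey summary counts, among species with
"open" type-1 cytology, those that also carry an apoplasmically specialized
SE-CCC (any 1-II or 1-III vein — a species with both 1-I and 1-II veins is
mixed) against those with 1-I/1-IV veins only; species whose veins are all
unclassifiable are excluded and counted separately, so mixed + pure = open
always holds.

## Synthetic surveys

The generator emulates the *structure* of a cytological TEM survey, not its
optics: species records whose veins are built from the canonical subtype
layouts (profiles taken from the rule table's archetypal vectors, slot
arrangements from the vein rows), with

* **subtype weights** — defaults follow the printed aggregate distribution:
  the five dominant subtypes 1-I (0.25), 1-II (0.18), 2-I (0.15), 2-III
  (0.15) and 2-IV (0.10) jointly 0.83, subtypes 1-I + 1-IV jointly 0.31,
  and the six rare subtypes sharing the rest;
* **family assignment** constrained to the cells of the packaged incidence
  table (a configurable profile; an error if a weighted subtype has no
  permitted family);
* **missingness** — each trait independently replaced by UNKNOWN at the
  configured rate, emulating unscorable micrographs;
* **ordinal noise** — each abundance grade moved one step up or down with
  the configured probability, reflecting at the scale ends; the simplest
  perturbation respecting ordinality, since no error model for TEM trait
  scoring exists.  After perturbation the grade/morphology pairing is kept
  coherent (an ingrowth grade raised from absent leaves morphology
  unknown);
* **growth-form bias** — type-1 species drawn 0.8 woody, types 0/2 drawn
  0.8 herbaceous; magnitudes are defaults for a correlation the literature
  states only qualitatively;
* **exception injection** — two documented archetypes replace records at a
  configured rate: a hemiparasite with MIC-b veins and ingrowths facing the
  xylem (classifies 2-VI), and a type-1 layout connected to the bundle
  sheath only by many single unbranched plasmodesmata (classifies 1-IV);
  both are the designed counterexamples for the structure–symplasm audit;
* a **co-occurrence rate** for an extra 1-II vein in 1-I species (default
  0, since no frequency is published).

At zero noise and zero missingness every generated record classifies back
to exactly its source subtype; this round-trip identity, its monotone
degradation under missingness, and bit-identical reproduction under a fixed
seed are tested invariants.  All randomness flows through one explicit
NumPy generator; there is no hidden global state.

What the generator does **not** emulate: correlated missingness (a poor
fixation run affects all traits of a section together), observer bias
between grades, within-species heterogeneity beyond the co-occurrence
parameter, and real family-level abundances (families are drawn uniformly
among those permitted).  Passing recovery tests therefore demonstrate the
key's logical soundness, not robustness to the failure modes of real
micrograph scoring.

The division-program simulator reproduces vein ontogeny at lineage-count
resolution only: anticlinal programs yield an arc of 2–3 slots with one
companion cell per sieve element (CC:SE = 1 by construction), periclinal
programs yield tiers with per-slot CC:SE in {1, 2} and aggregate 3/2 or 2,
unordered programs yield a companion-cell excess that avoids the type-2
signature ratios.  No cell geometry or mechanics is modelled; companion-cell
cytology is emitted UNKNOWN, since it is no product of the division
pattern.

## Numerical and representational choices

* CC:SE ratios are exact `Fraction`s throughout; 3/2 is never a float.
* The trait table dialect is UTF-8 TSV, one row per companion cell, grouped
  by `taxon`/`vein_id`/`slot_id`, `?` for unknown (empty accepted on read),
  vein- and species-level columns repeated per row and required consistent
  within their group; plasmodesmal densities are serialized with `repr` so
  the canonical form round-trips bit-identically.
* Validation is report-only (ERROR for hard cytological contradictions,
  WARN for soft ones); only type-level preconditions (positive counts,
  non-negative density) raise at construction.  The writer refuses records
  with hard violations; the classifier raises on them.
* Fixture content is pinned by SHA-256 in the test suite and echoed into
  every pipeline provenance record.
* The NEXUS export writes a standard character matrix (11 vein-presence +
  11 CC-presence + growth form + hemiparasite = 24 characters, `?` for
  missing); documents are verified in tests by re-parsing with dendropy, an
  independent implementation.  An empty survey yields a valid document with
  zero taxa and no MATRIX command.

## Known limitations

* The key is deterministic and rule-faithful by design: it cannot rate the
  *plausibility* of competing labels under partial data, only enumerate
  them.
* Subtype rows for type 0 are deliberately coarse; the group is
  heterogeneous and underdescribed, and veins of ordinary cells with
  phloem-parenchyma ingrowths (described in passing for some taxa) match no
  row and surface as UNCLASSIFIED.
* The consensus-scheme (0/1A/1B/2A/2B) mapping and the 2-VI legacy
  assignment are documented interpretations, flagged as such in rationale
  output and overridable.
* Whether subtype 2-VI belongs developmentally to type 2 is an open
  question in the source material; the label is retained with that caveat,
  and the generator leaves its division plane unknown.
* The species-level aggregation policy (how many veins justify a
  species-level call) is not prescribed anywhere; the package reports label
  sets per species and leaves thresholds to the user.
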