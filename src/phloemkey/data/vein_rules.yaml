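# Decision table for the eleven minor-vein phloem subtypes.
#
# Per row:
#   major               - ontogenetic major type (0, 1 or 2)
#   symmetry            - allowed spatial-organization states; an UNKNOWN
#                         observation always passes ("rarely -" rows allow both)
#   cc                  - companion-cell composition: either
#                           all:     every CC assignable to ONE subtype drawn
#                                    from this list
#                         or adaxial/abaxial: two-subtype arrangement with the
#                                    deviant SE-CCC at the abaxial pole
#   phloem_parenchyma   - "yes" required present, "no" required not-present,
#                         "any" no constraint
#   pp_cwi              - wall ingrowths in phloem parenchyma, same convention

"1-I":
  major: 1
  symmetry: ["well_defined"]
  cc: {all: ["IC", "ICL", "CC-a"]}
  phloem_parenchyma: "no"
  pp_cwi: "no"

"1-II":
  major: 1
  symmetry: ["well_defined"]
  cc: {adaxial: ["IC"], abaxial: ["OC-a"]}
  phloem_parenchyma: "no"
  pp_cwi: "no"

"1-III":
  major: 1
  symmetry: ["well_defined", "not_well_defined"]   # "+ (rarely -)"
  cc: {adaxial: ["IC", "MIC-a"], abaxial: ["TC-b"]}
  phloem_parenchyma: "no"
  pp_cwi: "no"

"1-IV":
  major: 1
  symmetry: ["well_defined"]
  cc: {all: ["CC-b"]}
  phloem_parenchyma: "no"
  pp_cwi: "no"

"0":
  major: 0
  symmetry: ["not_well_defined"]
  cc: {all: ["OC-a", "OC-b"]}
  phloem_parenchyma: "any"                          # "- (rarely +)"
  pp_cwi: "no"

"2-I":
  major: 2
  symmetry: ["well_defined"]
  cc: {all: ["OC-a", "OC-b"]}
  phloem_parenchyma: "yes"
  pp_cwi: "no"

"2-II":
  major: 2
  symmetry: ["well_defined", "not_well_defined"]   # "+ (rarely -)"
  cc: {all: ["OC-a", "OC-b"]}
  phloem_parenchyma: "yes"
  pp_cwi: "yes"

"2-III":
  major: 2
  symmetry: ["well_defined"]
  cc: {all: ["TC-a"]}
  phloem_parenchyma: "yes"
  pp_cwi: "no"

"2-IV":
  major: 2
  symmetry: ["well_defined"]
  cc: {all: ["TC-a"]}
  phloem_parenchyma: "yes"
  pp_cwi: "yes"

"2-V":
  major: 2
  symmetry: ["well_defined"]
  cc: {all: ["TC-c"]}
  phloem_parenchyma: "yes"
  pp_cwi: "no"

"2-VI":
  major: 2
  symmetry: ["well_defined", "not_well_defined"]   # "+/-"
  cc: {all: ["MIC-b"]}
  phloem_parenchyma: "yes"
  pp_cwi: "no"
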