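{
  "family": "CON2",
  "reference_id": "CON2_reference",
  "length": 538,
  "comment": "CON2 alteration-state fixture: zygosity structure is as described in the source study; base identities and column positions are synthetic conventions (positions evenly spaced; per column one reference allele r and one shared alternative a, r < a alphabetically).",
  "columns": [
    {"index": 1, "position": 59,  "ref_allele": "A", "alt_allele": "G", "reference_state": "het"},
    {"index": 2, "position": 119, "ref_allele": "C", "alt_allele": "T", "reference_state": "hom_ref"},
    {"index": 3, "position": 179, "ref_allele": "A", "alt_allele": "C", "reference_state": "het"},
    {"index": 4, "position": 239, "ref_allele": "G", "alt_allele": "T", "reference_state": "het"},
    {"index": 5, "position": 299, "ref_allele": "A", "alt_allele": "T", "reference_state": "het"},
    {"index": 6, "position": 358, "ref_allele": "C", "alt_allele": "G", "reference_state": "hom_ref"},
    {"index": 7, "position": 418, "ref_allele": "A", "alt_allele": "G", "reference_state": "hom_ref"},
    {"index": 8, "position": 478, "ref_allele": "C", "alt_allele": "T", "reference_state": "het"}
  ],
  "groups": [
    {
      "id": 1,
      "members": [
        "D. antarctica KEW-0522816",
        "D. antarctica KEW-0661919",
        "D. antarctica KEW-0521613",
        "D. parvula"
      ],
      "states": {"2": "het"}
    },
    {
      "id": 2,
      "members": [
        "D. sukatschewii",
        "D. cespitosa PI-562652",
        "D. cespitosa PI-577069",
        "D. cespitosa PI-371724",
        "D. elongata",
        "D. flexuosa"
      ],
      "states": {"1": "hom_alt", "3": "hom_alt", "4": "hom_alt", "5": "hom_alt", "8": "hom_alt", "6": "het", "7": "het"}
    },
    {
      "id": 3,
      "members": ["H. pubescens", "K. macrantha"],
      "states": {"1": "hom_alt", "3": "hom_alt", "4": "hom_alt", "5": "hom_alt", "8": "hom_alt"}
    },
    {
      "id": 4,
      "members": ["D. danthonioides"],
      "states": {"1": "hom_alt", "3": "hom_alt", "4": "hom_alt", "5": "hom_alt", "8": "hom_alt", "6": "het"}
    }
  ]
}
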