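{
  "mtdna": {
    "root_label": "mt-root",
    "markers": [
      {"name": "M", "position": 10400, "defining_allele": "T", "ancestral_allele": "C",
       "assay": "APLP", "band_lengths": {"T": 149, "C": 142}, "implies": "M", "parent": null},
      {"name": "R", "position": 12705, "defining_allele": "C", "ancestral_allele": "T",
       "assay": "sequencing", "implies": "R", "parent": null},
      {"name": "C", "position": 14318, "defining_allele": "C", "ancestral_allele": "T",
       "assay": "APLP", "band_lengths": {"T": 110, "C": 115}, "implies": "C", "parent": "M"},
      {"name": "C4", "position": 11969, "defining_allele": "A", "ancestral_allele": "G",
       "assay": "sequencing", "implies": "C4", "parent": "C",
       "expected_motif": [16298, 16327]},
      {"name": "UK", "position": 12308, "defining_allele": "G", "ancestral_allele": "A",
       "assay": "sequencing", "implies": "UK", "parent": "R",
       "motif_refine": {"label": "K", "requires": [16224, 16311]}},
      {"name": "HV", "position": 14766, "defining_allele": "T", "ancestral_allele": "C",
       "assay": "sequencing", "implies": "HV", "parent": "R"},
      {"name": "H", "position": 7028, "defining_allele": "C", "ancestral_allele": "T",
       "assay": "sequencing", "implies": "H", "parent": "HV"},
      {"name": "R1", "position": 4917, "defining_allele": "G", "ancestral_allele": "A",
       "assay": "sequencing", "implies": "R1", "parent": "R"},
      {"name": "R11", "position": 10031, "defining_allele": "C", "ancestral_allele": "T",
       "assay": "sequencing", "implies": "R11", "parent": "R"},
      {"name": "B", "position": 8280, "defining_allele": "del9", "ancestral_allele": "nodel",
       "assay": "deletion-length", "band_lengths": {"nodel": 121, "del9": 112},
       "implies": "B", "parent": "R"},
      {"name": "F", "position": 3970, "defining_allele": "T", "ancestral_allele": "C",
       "assay": "APLP", "band_lengths": {"T": 70, "C": 66}, "implies": "F", "parent": "R"}
    ],
    "motif_advisories": [
      {"label": "TJ", "parent": "R", "requires": [16126]}
    ]
  },
  "y": {
    "root_label": "pre-F",
    "markers": [
      {"name": "M89", "position": null, "defining_allele": "T", "ancestral_allele": "C",
       "assay": "sequencing", "implies": "F", "parent": null},
      {"name": "M9", "position": null, "defining_allele": "G", "ancestral_allele": "C",
       "assay": "sequencing", "implies": "K", "parent": "F"},
      {"name": "M45", "position": null, "defining_allele": "A", "ancestral_allele": "G",
       "assay": "sequencing", "implies": "P", "parent": "K"},
      {"name": "M173", "position": null, "defining_allele": "A", "ancestral_allele": "C",
       "assay": "sequencing", "implies": "R1", "parent": "P"},
      {"name": "M198", "position": null, "defining_allele": "A", "ancestral_allele": "G",
       "assay": "sequencing", "implies": "R1a1a", "parent": "R1"}
    ]
  },
  "amg": {
    "band_lengths": {"115": "X", "121": "Y"}
  }
}
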