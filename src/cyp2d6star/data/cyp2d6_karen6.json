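{
  "activity_scores": {
    "normal": 1.0,
    "decreased": 0.5,
    "none": 0.0
  },
  "informative_loci": ["C100T", "G1846A", "C2850T", "G4180C"],
  "variants": [
    {"id": "C100T", "position": 100, "ref_base": "C", "alt_base": "T", "rsid": "rs1065852", "region": "exon1", "effect": "P34S"},
    {"id": "C1039T", "position": 1039, "ref_base": "C", "alt_base": "T", "rsid": "", "region": "exon2", "effect": "synonymous"},
    {"id": "G1661C", "position": 1661, "ref_base": "G", "alt_base": "C", "rsid": "", "region": "exon3", "effect": "synonymous"},
    {"id": "G1846A", "position": 1846, "ref_base": "G", "alt_base": "A", "rsid": "rs3892097", "region": "intron3/exon4 junction", "effect": "splicing defect"},
    {"id": "C2850T", "position": 2850, "ref_base": "C", "alt_base": "T", "rsid": "rs16947", "region": "exon6", "effect": "R296C"},
    {"id": "G4180C", "position": 4180, "ref_base": "G", "alt_base": "C", "rsid": "rs1135840", "region": "exon9", "effect": "S486T"}
  ],
  "alleles": [
    {"name": "*1", "key_variants": [], "all_variants": [], "structural": [], "function_class": "normal"},
    {"name": "*2", "key_variants": ["C2850T"], "all_variants": ["C2850T", "G4180C"], "structural": [], "function_class": "normal"},
    {"name": "*4", "key_variants": ["G1846A"], "all_variants": ["C100T", "G1846A", "G4180C"], "structural": [], "function_class": "none"},
    {"name": "*5", "key_variants": [], "all_variants": [], "structural": ["whole_gene_deletion"], "function_class": "none"},
    {"name": "*10", "key_variants": ["C100T"], "all_variants": ["C100T", "G4180C"], "structural": [], "function_class": "decreased"},
    {"name": "*36", "key_variants": ["C100T"], "all_variants": ["C100T", "G4180C"], "structural": ["exon9_conversion"], "function_class": "decreased"}
  ]
}
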