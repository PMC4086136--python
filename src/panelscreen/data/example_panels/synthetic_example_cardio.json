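{
  "schema_version": "1",
  "name": "example-cardio (synthetic)",
  "created": "2026-01-01",
  "notes": "Shipped example panel. Entirely synthetic coordinates and phenotype names; for demonstration only.",
  "thresholds": {"sift_max": null, "polyphen_min": null},
  "diseases": [
    {"name": "Synthetic cardiomyopathy", "source": "CLINVAR"}
  ],
  "regions": [
    {"chrom": "1", "start": 100000, "end": 105000, "label": "DEMOA", "origin": "DISEASE_AUTO"},
    {"chrom": "2", "start": 200000, "end": 204000, "label": "DEMOB", "origin": "DISEASE_AUTO"}
  ],
  "mutations": [
    {"chrom": "1", "pos": 100500, "ref": "A", "alt": "T", "gene": "DEMOA",
     "phenotype": "Synthetic cardiomyopathy", "source": "CLINVAR",
     "snp_id": "rs0000001", "sift": 0.01, "polyphen": 0.98, "phastcons": 0.9},
    {"chrom": "2", "pos": 200750, "ref": "GA", "alt": "G", "gene": "DEMOB",
     "phenotype": "Synthetic cardiomyopathy", "source": "CLINVAR",
     "snp_id": null, "sift": null, "polyphen": null, "phastcons": 0.7}
  ],
  "disease_contributions": [
    {"name": "Synthetic cardiomyopathy", "source": "CLINVAR",
     "region_labels": ["DEMOA", "DEMOB"],
     "mutation_keys": [
       {"chrom": "1", "pos": 100500, "ref": "A", "alt": "T"},
       {"chrom": "2", "pos": 200750, "ref": "GA", "alt": "G"}
     ]}
  ]
}
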