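{
  "schema_version": "1",
  "name": "example-neuro (synthetic)",
  "created": "2026-01-01",
  "notes": "Shipped example panel. Entirely synthetic coordinates and phenotype names; for demonstration only.",
  "thresholds": {"sift_max": 0.05, "polyphen_min": 0.85},
  "diseases": [
    {"name": "Synthetic neuropathy", "source": "HGMD_PUBLIC"}
  ],
  "regions": [
    {"chrom": "3", "start": 50000, "end": 56000, "label": "DEMOC", "origin": "DISEASE_AUTO"}
  ],
  "mutations": [
    {"chrom": "3", "pos": 51200, "ref": "C", "alt": "G", "gene": "DEMOC",
     "phenotype": "Synthetic neuropathy", "source": "HGMD_PUBLIC",
     "snp_id": null, "sift": 0.02, "polyphen": 0.99, "phastcons": null}
  ],
  "disease_contributions": [
    {"name": "Synthetic neuropathy", "source": "HGMD_PUBLIC",
     "region_labels": ["DEMOC"],
     "mutation_keys": [
       {"chrom": "3", "pos": 51200, "ref": "C", "alt": "G"}
     ]}
  ]
}
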