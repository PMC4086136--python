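{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "panelscreen panel document, schema_version 1",
  "type": "object",
  "required": ["schema_version", "name", "created", "notes", "thresholds",
               "diseases", "regions", "mutations", "disease_contributions"],
  "properties": {
    "schema_version": {"const": "1"},
    "name": {"type": "string", "minLength": 1},
    "created": {"type": "string", "description": "ISO-8601 date or empty"},
    "notes": {"type": "string"},
    "thresholds": {
      "type": "object",
      "properties": {
        "sift_max": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
        "polyphen_min": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
      }
    },
    "diseases": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "source"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "source": {"enum": ["HGMD_PUBLIC", "HUMSAVAR", "CLINVAR", "COSMIC", "CUSTOM"]}
        }
      }
    },
    "regions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["chrom", "start", "end", "label", "origin"],
        "properties": {
          "chrom": {"type": "string", "minLength": 1},
          "start": {"type": "integer", "minimum": 1},
          "end": {"type": "integer", "minimum": 1},
          "label": {"type": "string", "minLength": 1},
          "origin": {"enum": ["DISEASE_AUTO", "USER_GENE", "USER_BED"]}
        }
      }
    },
    "mutations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["chrom", "pos", "ref", "alt", "gene", "phenotype", "source"],
        "properties": {
          "chrom": {"type": "string"},
          "pos": {"type": "integer", "minimum": 1},
          "ref": {"type": "string", "pattern": "^[ACGT]+$"},
          "alt": {"type": "string", "pattern": "^[ACGT]+$"},
          "gene": {"type": "string"},
          "phenotype": {"type": "string"},
          "source": {"enum": ["HGMD_PUBLIC", "HUMSAVAR", "CLINVAR", "COSMIC", "CUSTOM"]},
          "snp_id": {"type": ["string", "null"]},
          "sift": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "polyphen": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
          "phastcons": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
        }
      }
    },
    "disease_contributions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "source", "region_labels", "mutation_keys"],
        "properties": {
          "name": {"type": "string"},
          "source": {"type": "string"},
          "region_labels": {"type": "array", "items": {"type": "string"}},
          "mutation_keys": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["chrom", "pos", "ref", "alt"]
            }
          }
        }
      }
    }
  }
}
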