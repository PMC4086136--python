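{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "panelscreen report document (json rendering)",
  "type": "object",
  "required": ["meta", "columns", "primary_findings", "secondary_findings", "panel"],
  "properties": {
    "meta": {
      "type": "object",
      "required": ["title", "date"],
      "properties": {
        "title": {"type": "string", "minLength": 1},
        "date": {"type": "string"},
        "reporter": {"type": "string"},
        "analysis_info": {"type": "string"},
        "comments": {"type": "string"}
      }
    },
    "columns": {
      "type": "array",
      "items": {
        "enum": ["chrom", "position", "snp_id", "ref", "alt", "gene",
                 "consequence", "phenotype", "source", "sift", "polyphen",
                 "phastcons", "qual", "filter"]
      }
    },
    "primary_findings": {
      "type": "array",
      "items": {"type": "object", "additionalProperties": {"type": "string"}}
    },
    "secondary_findings": {
      "type": "array",
      "items": {"type": "object", "additionalProperties": {"type": "string"}}
    },
    "panel": {
      "type": "object",
      "required": ["name", "genes", "mutations", "thresholds"],
      "properties": {
        "name": {"type": "string"},
        "genes": {"type": "array", "items": {"type": "string"}},
        "mutations": {"type": "array", "items": {"type": "string"}},
        "thresholds": {"type": "object"}
      }
    }
  }
}
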