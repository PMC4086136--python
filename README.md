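# panelscreen

Gene-panel diagnostics for targeted-enrichment (and virtual-panel
exome/genome) sequencing: define and manage diagnostic panels, screen a
patient's VCF against a panel's known disease mutations, and produce a
clinical-style report of primary diagnostic hits and secondary findings.

## Who this is for

Targeted disease testing captures and sequences a *panel* — a named set
of genomic regions (usually genes), the known diagnostic mutations found
in them, and the disease terms those mutations belong to. After mapping
and variant calling, the clinician is left with a VCF of thousands of
variants and one question: *is a known diagnostic mutation among them,
and if not, what else in the panel could explain the phenotype?*
`panelscreen` answers that question locally — patient data never leaves
the machine — using a flat-file knowledge base of disease variants in
the role that databases such as HGMD-public, HUMSAVAR, ClinVar and
COSMIC play in clinical practice (licensed content is not bundled; a
seeded synthetic generator produces structurally identical stand-ins
for development and testing).

## The method

1. **Normalization.** Every variant spelling — from the VCF and from the
   knowledge base — is reduced to a canonical key
   `(chrom, pos, ref, alt)` by iteratively trimming shared flanking
   bases (longest common suffix first, then prefix, keeping ≥ 1 base per
   allele; `pos` advances by the prefix bases removed). This collapses
   padded spellings such as `CA>CT` vs `A>T`. Multiallelic records are
   split per ALT allele; symbolic ALTs are skipped and counted.
2. **Region filter.** The panel's regions are merged into a canonical
   per-chromosome interval union; a variant is *in panel* when its
   normalized anchor position lies inside a merged region (boundaries
   inclusive). Applying a panel to whole-exome/genome calls this way is
   a *virtual panel*.
3. **Primary diagnostic.** An in-panel variant whose key exactly matches
   a mutation of the panel (catalogue mutations of its disease terms
   plus custom additions) is a primary hit, reported once per matching
   annotation (phenotype × source database).
4. **Secondary findings.** Every remaining in-panel variant of uncertain
   effect: all indels, and every SNV passing the pathogenicity
   thresholds `SIFT ≤ sift_max` and `PolyPhen ≥ polyphen_min` (each
   applied only when the threshold is set and the score is present; no
   thresholds are set by default, so every SNV is reported). Secondary
   findings are always computed, even when a primary hit exists.
5. **Report.** Results render to JSON / HTML / Markdown / TSV with the
   standard diagnostic columns (chromosome, position, SNP id, ref, alt,
   gene, consequence, phenotype, source, SIFT, PolyPhen, phastCons) plus
   optional qual/filter, the panel description and analysis metadata.

## Worked example

Generate a fully synthetic study (catalogue, knowledge base, panel,
patient VCF with known ground truth), then screen the patient:

```sh
$ panelscreen fixtures --seed 42 --out fx
$ panelscreen --store store panel import fx/panel.json
imported panel 'synthetic-panel'
$ panelscreen --store store panel show synthetic-panel
panel: synthetic-panel (created 2026-09-24)
thresholds: sift_max=None polyphen_min=None
diseases (3):
  - Synthetic syndrome 01 [HGMD_PUBLIC]
  - Synthetic syndrome 02 [HUMSAVAR]
  - Synthetic syndrome 03 [CLINVAR]
regions (6):
  - GENE001 1:10214-13832 [DISEASE_AUTO]
  ...
$ panelscreen --store store diagnose --vcf fx/patient.vcf \
    --panel synthetic-panel --kb fx/kb.tsv --format markdown --out report
variants read:      317
in panel regions:   17
primary diagnostic: 2
secondary findings: 15
wrote report.md
```

Reading the numbers: of 317 variants called in the patient, 17 fall in
the panel's six genes; 2 exactly match known diagnostic mutations of the
panel's diseases (the primary diagnostic, listed with phenotype and
source database), and the other 15 are in-panel variants of uncertain
effect reported as secondary findings (no thresholds were set, so every
SNV passes). `report.md` contains both tables, the panel description
and the analysis metadata. Panels themselves are managed with
`panelscreen panel new|add-disease|add-genes|remove-gene|add-mutation|
add-bed|export|import|reset`.

The same workflow is available as a library:

```python
from panelscreen import load_catalogue, load_kb, import_panel, run_diagnosis

panel = import_panel(open("fx/panel.json").read())
kb = load_kb(open("fx/kb.tsv").read())
result = run_diagnosis("fx/patient.vcf", panel, kb)
print(result.counts)   # {'n_read': 317, 'n_in_panel': 17, 'n_primary': 2, ...}
```

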