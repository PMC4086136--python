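# Methods

## The diagnostic model

A diagnostic panel is the triple (disease terms, genomic regions, known
mutations). Screening a patient VCF against a panel proceeds in three
fixed stages: normalize every allele to a canonical key, restrict to the
panel's merged regions, then partition the in-panel variants into
**primary diagnostic hits** (exact key match against the panel's own
mutation set) and **secondary findings** (everything else of uncertain
effect that survives the pathogenicity thresholds). The partition is a
true partition: primary and secondary key sets are disjoint, both are
subsets of the in-panel set, and out-of-panel variants never appear.

Primary matching is deliberately scoped to the panel's mutation set, not
the whole knowledge base: a panel encodes the clinical question being
asked. A knowledge-base variant outside the panel's diseases that shows
up in a panel gene is still surfaced — as a secondary finding.

Both result tabs are always populated. Reporting secondary findings only
on a negative primary result is a display policy, not an analysis one;
computing both costs nothing and hides nothing.

## Variant normalization

Matching identity is the normalized `(chrom, pos, ref, alt)` tuple.
Normalization iteratively strips the longest shared allele suffix, then
the longest shared prefix, keeping at least one base in each allele;
the position advances by the number of prefix bases removed; the loop
runs to a fixed point and is idempotent. Chromosome names are
normalized by stripping a case-insensitive `chr` prefix and mapping
`M` to `MT`.

Trimming suffix-before-prefix matches common practice (vt, bcftools
right-trim/left-trim) and is frozen; an exhaustive test (all minimal
events with alleles ≤ 3 bp, all shared-flank paddings ≤ 3 bp with padded
alleles ≤ 6 bp, ~239 000 spellings) checks it against an independent
brute-force oracle that enumerates every valid trim.

**Known limitation — repeat tracts.** Without a reference genome,
trimming cannot left-align. A padded indel spelling whose flank extends
a repeat across the event boundary (`A>AA` left-padded with `A` gives
`AA>AAA`) is consistent with the same event at two positions, and *no*
reference-free normalizer can collapse all such spellings to one key: a
normalizer constant across all padding relations would have to give an
insertion the same key at every position. Likewise a pure insertion
spelled with left context (`G>GA` for an `A` insertion) reduces to the
shifted anchor form, not to the context-free spelling. Substitutions
are never ambiguous and collapse under every padding; for indels the
test proves every non-collapsing padding is genuinely ambiguous
(multiple minimal-length trims exist, the true event among them).
Databases and callers that disagree on indel anchoring in repeat
regions therefore require reference-based left-alignment upstream.

## Coordinates and regions

Internal coordinates are 1-based inclusive (VCF convention). BED input
and output convert at the boundary (`start = bedStart + 1`,
`end = bedEnd`). Region containment uses the variant's normalized
anchor position only, not the full REF span — simpler and deterministic
at region edges; a long deletion anchored on the last base of a region
is counted in, one anchored just outside is not. `merged_regions`
merges overlapping and directly adjacent (gap 0) intervals per
chromosome; the interval filter is a binary search over the merged set
and is tested against per-variant linear scan and per-base union
coverage.

## Thresholds

SIFT is deleterious near 0, PolyPhen near 1, so the secondary-finding
rule for SNVs is `sift <= sift_max` and `polyphen >= polyphen_min`.
Both thresholds are **unset by default** (every SNV reported). Two
deliberate choices:

* an absent score passes a set threshold — secondary findings are
  variants of *uncertain* effect, and silently dropping unscored
  variants would hide candidates;
* indels are always reported regardless of scores or thresholds, since
  the predictors are substitution-oriented.

Equal-length multi-nucleotide substitutions are classed with SNVs for
threshold purposes. Tightening either threshold can only shrink the
secondary SNV set; the indel count is threshold-invariant (tested).
Thresholds given at diagnose time override the panel's stored ones.
The VCF FILTER column is passed through, never used to exclude, unless
`--pass-only` is set (default off).

## Panel semantics

* Adding a disease term pulls its catalogue genes (origin
  `DISEASE_AUTO`) and mutations into the panel, deduplicated by region
  label and by normalized mutation key; the operation is idempotent.
* What each term contributed is recorded on the panel at add time, so
  removing a term removes only what it alone contributed; genes and
  mutations shared with remaining terms, and all user additions
  (`USER_GENE`/`USER_BED` regions, `CUSTOM` mutations), are kept.
* Removing a gene keeps mutations it covered but flags them
  out-of-region; the screening engine ignores flagged mutations. Genes
  and mutations are edited independently, so deletion would destroy
  user work on a temporarily narrowed capture design.
* A custom mutation with a disease name matching an existing panel term
  (case-insensitive) attaches to it; an unknown name creates a `CUSTOM`
  disease term rather than failing.
* Panels serialize to a versioned JSON dialect (`schema_version: "1"`,
  schema shipped in `data/panel.schema.json`); import∘export is the
  identity on canonical (order-insensitive) form. The CLI stores panels
  as one JSON file per panel, written atomically; `panel reset` deletes
  user panels and restores the shipped (synthetic) example panels.

## Synthetic data generator

The generator emulates the *shape* of clinical panel data: disease terms
with non-overlapping gene intervals (default 3 diseases × 2 genes of
1–5 kb on chromosomes 1–3), five known mutations per disease (~20%
indels) with SIFT/PolyPhen/phastCons drawn uniform on [0, 1] at 30%
missingness, a patient VCF with 1–3 planted diagnostic mutations, 10
in-panel SNVs and 5 in-panel indels of uncertain effect, 300 background
variants outside the panel, and a symbolic-ALT record. These sizes keep
a full screen under 10 ms while exercising every branch of the
classification rule; the defaults are the study conditions used by the
tests and the acceptance script.

The generator is a true oracle: expected primary/secondary sets are
computed with its own naive linear-scan containment and threshold code
and with planted keys tracked by construction — never by calling the
engine. About half the planted variants are re-spelled with shared
flanking bases to exercise normalization; pads are resampled with the
generator's own brute-force trimmer until recoverable, mirroring a real
caller whose padded spellings are reference-consistent (insertions get
right-side pads only, see the repeat-tract limitation above).

What it does *not* emulate: realistic mutation spectra, genotype
likelihoods, coverage/quality structure, multi-sample VCFs, or reference
consistency across records. Passing tests therefore demonstrate the
correctness of panel logic, matching and classification — not robustness
to caller-specific VCF quirks beyond those modelled.

## Numerical and degenerate-input choices

* Knowledge-base and catalogue TSVs use `.` for absent values; scores
  must lie in [0, 1]; malformed rows are rejected with line numbers;
  a disease term with zero mutations (or an empty catalogue) is a
  validation error.
* INFO floats arrive in single precision from htslib and are rounded to
  6 decimals on read.
* Annotation order is deterministic: source database order
  (HGMD-public, HUMSAVAR, ClinVar, COSMIC, custom), then phenotype.
  Result ordering is (chromosome, position, alt) with numeric
  chromosomes before X, Y, MT.
* Duplicate patient spellings of one normalized key are reported once
  (first occurrence).
* An empty VCF yields an empty result with zero counts; a panel with no
  regions yields no in-panel variants.

## Known limitations

* No reference-genome awareness: REF alleles are not checked and indels
  are not left-aligned (see above).
* Pathogenicity and consequence annotations are passthrough inputs; the
  tool never computes them.
* The gene column of a secondary finding is the label of the first
  enclosing panel region in sort order, which is arbitrary when regions
  overlap.
* PDF output is out of scope; the HTML rendering is print-ready.
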