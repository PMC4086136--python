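"""Ground-truth-known synthetic fixtures.

Generates a disease catalogue, a variant knowledge base, panels and
patient VCFs whose expected diagnostic outcome is known by construction,
so the whole pipeline is testable without downloading any licensed
database content.  Everything is driven by a seed: identical seeds give
byte-identical outputs.

The generator is a true oracle: expected primary/secondary sets are
computed with its own naive linear-scan containment and threshold logic,
and planted variants are tracked by the minimal spelling they were
constructed from — never by calling the screening engine or its
normalizer.  What it emulates is the *shape* of clinical panel data
(genes as intervals, known mutations with pathogenicity annotations, a
caller's VCF with padded indel spellings); it does not attempt realistic
mutation spectra, genotype likelihoods or read-level noise.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

from .errors import GenerationError
from .knowledgebase import Source, VariantKey
from .panel_model import (
    DiseaseCatalogue, DiseaseTerm, Panel, add_disease, new_panel,
)

_BASES = "ACGT"
_REAL_SOURCES = (Source.HGMD_PUBLIC, Source.HUMSAVAR, Source.CLINVAR, Source.COSMIC)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a small targeted panel screen: three diseases of two
    genes each with five known mutations per disease, a couple of planted
    diagnostic hits, and 300 background variants outside the panel —
    enough to exercise every decision branch while running in well under a
    second."""

    seed: int = 0
    n_diseases: int = 3
    genes_per_disease: int = 2
    mutations_per_disease: int = 5
    n_background_variants: int = 300
    n_planted_primary: int = 2
    n_in_panel_snv: int = 10
    n_in_panel_indel: int = 5
    chrom_set: tuple[str, ...] = ("1", "2", "3")
    gene_length_range: tuple[int, int] = (1000, 5000)
    chrom_length: int = 1_000_000
    score_missingness: float = 0.3
    indel_fraction_kb: float = 0.2
    n_symbolic: int = 1

    def __post_init__(self):
        for name in ("n_diseases", "genes_per_disease", "mutations_per_disease",
                     "n_background_variants", "n_planted_primary",
                     "n_in_panel_snv", "n_in_panel_indel", "n_symbolic"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")


@dataclass
class FixtureTruth:
    """Everything the generator created, recorded for verification."""

    diseases: list[dict] = field(default_factory=list)

    def all_mutations(self) -> list[dict]:
        return [m for d in self.diseases for m in d["mutations"]]

    def all_genes(self) -> list[dict]:
        return [g for d in self.diseases for g in d["genes"]]

    def to_json(self) -> str:
        return json.dumps({"diseases": self.diseases}, indent=2, sort_keys=True)


@dataclass
class ExpectedDiagnosis:
    """Ground-truth outcome of screening a generated VCF against a panel."""

    primary_keys: set[VariantKey] = field(default_factory=set)
    secondary_keys: set[VariantKey] = field(default_factory=set)
    n_records: int = 0
    n_symbolic: int = 0


# -- naive oracle helpers (deliberately simple, independent of the engine) --


def _naive_in_regions(regions: list[dict], chrom: str, pos: int) -> bool:
    for r in regions:
        if r["chrom"] == chrom and r["start"] <= pos <= r["end"]:
            return True
    return False


def _naive_passes(
    is_indel: bool, sift, polyphen, sift_max, polyphen_min
) -> bool:
    if is_indel:
        return True
    if sift_max is not None and sift is not None and sift > sift_max:
        return False
    if polyphen_min is not None and polyphen is not None and polyphen < polyphen_min:
        return False
    return True


# -- catalogue / kb generation ----------------------------------------------


def _other_base(rng: random.Random, base: str) -> str:
    return rng.choice([b for b in _BASES if b != base])


def _make_mutation(rng: random.Random, gene: dict, spec: FixtureSpec) -> dict:
    """One mutation inside ``gene``, in minimal spelling."""
    pos = rng.randint(gene["start"], gene["end"] - 4)
    ref_base = rng.choice(_BASES)
    if rng.random() < spec.indel_fraction_kb:
        if rng.random() < 0.5:  # deletion: anchored multi-base ref
            extra = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 2)))
            ref, alt = ref_base + extra, ref_base
        else:  # insertion
            extra = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 2)))
            ref, alt = ref_base, ref_base + extra
    else:
        ref, alt = ref_base, _other_base(rng, ref_base)
    return {"chrom": gene["chrom"], "pos": pos, "ref": ref, "alt": alt,
            "gene": gene["label"]}


def _maybe_score(rng: random.Random, spec: FixtureSpec) -> float | None:
    if rng.random() < spec.score_missingness:
        return None
    return round(rng.random(), 4)


def make_catalogue_and_kb(spec: FixtureSpec) -> tuple[str, str, FixtureTruth]:
    """Generate catalogue TSV, knowledge-base TSV and the truth record.

    Gene intervals never overlap within a chromosome, and every disease
    term receives at least one mutation inside one of its genes (provided
    ``mutations_per_disease >= 1``)."""
    rng = random.Random(spec.seed)
    truth = FixtureTruth()
    next_free = {c: 10_000 for c in spec.chrom_set}
    gene_no = 0

    for d in range(spec.n_diseases):
        source = _REAL_SOURCES[d % len(_REAL_SOURCES)]
        disease = {
            "name": f"Synthetic syndrome {d + 1:02d}",
            "source": source.value,
            "genes": [],
            "mutations": [],
        }
        for _ in range(spec.genes_per_disease):
            gene_no += 1
            chrom = spec.chrom_set[(gene_no - 1) % len(spec.chrom_set)]
            length = rng.randint(*spec.gene_length_range)
            start = next_free[chrom] + rng.randint(100, 1000)
            end = start + length - 1
            if end > spec.chrom_length:
                raise GenerationError(
                    f"gene GENE{gene_no:03d} does not fit on chromosome {chrom} "
                    f"(needs [{start}, {end}], length limit {spec.chrom_length})"
                )
            next_free[chrom] = end
            disease["genes"].append(
                {"chrom": chrom, "start": start, "end": end,
                 "label": f"GENE{gene_no:03d}"}
            )
        used_pos: set[tuple[str, int]] = set()
        for m in range(spec.mutations_per_disease):
            gene = disease["genes"][m % len(disease["genes"])]
            while True:
                mut = _make_mutation(rng, gene, spec)
                if (mut["chrom"], mut["pos"]) not in used_pos:
                    break
            used_pos.add((mut["chrom"], mut["pos"]))
            mut.update(
                phenotype=disease["name"], source=source.value,
                snp_id=f"rs{rng.randint(10**6, 10**8)}" if rng.random() < 0.5 else None,
                sift=_maybe_score(rng, spec),
                polyphen=_maybe_score(rng, spec),
                phastcons=_maybe_score(rng, spec),
            )
            disease["mutations"].append(mut)
        truth.diseases.append(disease)

    catalogue_tsv = _catalogue_tsv(truth)
    kb_tsv = _kb_tsv(truth, rng)
    return catalogue_tsv, kb_tsv, truth


def _dot(value) -> str:
    return "." if value is None else str(value)


def _catalogue_tsv(truth: FixtureTruth) -> str:
    lines = ["\t".join([
        "PHENOTYPE", "SOURCE", "GENE", "CHROM", "GENE_START", "GENE_END",
        "MUT_POS", "MUT_REF", "MUT_ALT",
    ])]
    for disease in truth.diseases:
        gene_by_label = {g["label"]: g for g in disease["genes"]}
        for mut in disease["mutations"]:
            gene = gene_by_label[mut["gene"]]
            lines.append("\t".join([
                disease["name"], disease["source"], gene["label"], gene["chrom"],
                str(gene["start"]), str(gene["end"]),
                str(mut["pos"]), mut["ref"], mut["alt"],
            ]))
        # gene-only rows for genes without a mutation of their own
        mutated = {m["gene"] for m in disease["mutations"]}
        for gene in disease["genes"]:
            if gene["label"] not in mutated:
                lines.append("\t".join([
                    disease["name"], disease["source"], gene["label"], gene["chrom"],
                    str(gene["start"]), str(gene["end"]), ".", ".", ".",
                ]))
    return "\n".join(lines) + "\n"


def _kb_tsv(truth: FixtureTruth, rng: random.Random) -> str:
    header = "\t".join([
        "CHROM", "POS", "REF", "ALT", "GENE", "PHENOTYPE",
        "SOURCE", "SNP_ID", "SIFT", "POLYPHEN", "PHASTCONS",
    ])
    lines = [header]
    for mut in truth.all_mutations():
        row = [
            mut["chrom"], str(mut["pos"]), mut["ref"], mut["alt"],
            mut["gene"], mut["phenotype"], mut["source"], _dot(mut["snp_id"]),
            _dot(mut["sift"]), _dot(mut["polyphen"]), _dot(mut["phastcons"]),
        ]
        lines.append("\t".join(row))
        if rng.random() < 0.2:  # a second annotation of the same event
            other = rng.choice(
                [s.value for s in _REAL_SOURCES if s.value != mut["source"]]
            )
            row2 = list(row)
            row2[6] = other
            lines.append("\t".join(row2))
    return "\n".join(lines) + "\n"


def build_full_panel(catalogue: DiseaseCatalogue, name: str = "synthetic-panel") -> Panel:
    """Panel containing every catalogue disease (convenience for fixtures)."""
    panel = new_panel(name)
    for term in catalogue.terms():
        add_disease(panel, term, catalogue)
    return panel


# -- patient VCF generation --------------------------------------------------


_VCF_HEADER = """\
##fileformat=VCFv4.2
{contigs}##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score (passthrough)">
##INFO=<ID=POLYPHEN,Number=1,Type=Float,Description="PolyPhen score (passthrough)">
##INFO=<ID=PHASTCONS,Number=1,Type=Float,Description="phastCons score (passthrough)">
##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotation">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _naive_minimal(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Brute-force canonical spelling: enumerate every valid shared
    prefix/suffix trim (each allele keeps >= 1 base), pick the shortest,
    preferring the larger suffix trim on ties.  Deliberately independent
    of the library's iterative trimmer."""
    best = None
    for i in range(min(len(ref), len(alt))):
        if ref[:i] != alt[:i]:
            break
        for j in range(min(len(ref), len(alt)) - i):
            if ref[len(ref) - j:] != alt[len(alt) - j:]:
                break
            r = ref[i:len(ref) - j] if j else ref[i:]
            a = alt[i:len(alt) - j] if j else alt[i:]
            if not r or not a:
                continue
            rank = (len(r) + len(a), -j, -i)
            if best is None or rank < best[0]:
                best = (rank, (pos + i, r, a))
    assert best is not None
    return best[1]


def _pad_spelling(rng: random.Random, mut: dict) -> tuple[int, str, str]:
    """Re-spell a variant with shared flanking bases.

    A real caller pads with the actual reference flanks, so its padded
    spelling is always recoverable; mimic that by resampling any pad that
    would extend a repeat across the event boundary (which would make the
    spelling positionally ambiguous without a reference genome)."""
    while True:
        left = "".join(rng.choice(_BASES) for _ in range(rng.randint(0, 3)))
        right = "".join(rng.choice(_BASES) for _ in range(rng.randint(0, 2)))
        if not left and not right:
            continue
        padded = (mut["pos"] - len(left), left + mut["ref"] + right,
                  left + mut["alt"] + right)
        if _naive_minimal(*padded) == (mut["pos"], mut["ref"], mut["alt"]):
            return padded


def make_patient_vcf(
    spec: FixtureSpec, truth: FixtureTruth, panel: Panel
) -> tuple[str, ExpectedDiagnosis]:
    """Generate a patient VCF with known expected outcome.

    Plants ``n_planted_primary`` panel mutations (about half re-spelled
    with shared flanking bases to exercise normalization), adds in-panel
    SNVs and indels with random scores, background variants outside the
    panel, and a symbolic-ALT record or two.  The expected primary and
    secondary key sets are derived from ground truth with the naive
    oracle, not from the screening engine."""
    rng = random.Random(spec.seed * 1_000_003 + 7)
    regions = [
        {"chrom": r.chrom, "start": r.start, "end": r.end} for r in panel.regions
    ]
    panel_keys = {(m.chrom, m.pos, m.ref, m.alt) for m in panel.mutations}
    in_region_panel_muts = [
        m for m in panel.mutations
        if _naive_in_regions(regions, m.chrom, m.pos)
    ]
    if spec.n_planted_primary > len(in_region_panel_muts):
        raise GenerationError(
            f"cannot plant {spec.n_planted_primary} primaries: panel has only "
            f"{len(in_region_panel_muts)} in-region mutations"
        )

    expected = ExpectedDiagnosis()
    rows: list[tuple[str, int, str, str, str, str, str, str]] = []
    occupied = {(m.chrom, m.pos) for m in panel.mutations}

    def info_str(sift, polyphen, phastcons, consequence) -> str:
        parts = []
        if sift is not None:
            parts.append(f"SIFT={sift}")
        if polyphen is not None:
            parts.append(f"POLYPHEN={polyphen}")
        if phastcons is not None:
            parts.append(f"PHASTCONS={phastcons}")
        if consequence:
            parts.append(f"CSQ={consequence}")
        return ";".join(parts) if parts else "."

    # planted primary hits
    planted = rng.sample(sorted(in_region_panel_muts, key=lambda m: str(m.key)),
                         spec.n_planted_primary)
    for i, mut in enumerate(planted):
        if i % 2 == 1:
            pos, ref, alt = _pad_spelling(
                rng, {"pos": mut.pos, "ref": mut.ref, "alt": mut.alt}
            )
        else:
            pos, ref, alt = mut.pos, mut.ref, mut.alt
        rows.append((
            mut.chrom, pos, mut.snp_id or ".", ref, alt,
            f"{rng.uniform(30, 99):.1f}", "PASS",
            info_str(_maybe_score(rng, spec), _maybe_score(rng, spec),
                     _maybe_score(rng, spec), "missense_variant"),
        ))
        expected.primary_keys.add(VariantKey(mut.chrom, mut.pos, mut.ref, mut.alt))

    def fresh_position(region: dict) -> int:
        while True:
            pos = rng.randint(region["start"], region["end"] - 4)
            if (region["chrom"], pos) not in occupied:
                occupied.add((region["chrom"], pos))
                return pos

    # in-panel variants of uncertain effect (secondary candidates)
    sift_max = panel.thresholds.sift_max
    polyphen_min = panel.thresholds.polyphen_min
    if regions:
        for i in range(spec.n_in_panel_snv + spec.n_in_panel_indel):
            is_indel = i >= spec.n_in_panel_snv
            region = regions[rng.randrange(len(regions))]
            pos = fresh_position(region)
            ref_base = rng.choice(_BASES)
            if is_indel:
                extra = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 2)))
                ref, alt = (ref_base + extra, ref_base) if rng.random() < 0.5 \
                    else (ref_base, ref_base + extra)
            else:
                ref, alt = ref_base, _other_base(rng, ref_base)
            if (region["chrom"], pos, ref, alt) in panel_keys:
                continue
            sift = _maybe_score(rng, spec)
            polyphen = _maybe_score(rng, spec)
            rows.append((
                region["chrom"], pos, ".", ref, alt,
                f"{rng.uniform(30, 99):.1f}", "PASS",
                info_str(sift, polyphen, _maybe_score(rng, spec),
                         "intron_variant" if rng.random() < 0.3 else "missense_variant"),
            ))
            if _naive_passes(is_indel, sift, polyphen, sift_max, polyphen_min):
                expected.secondary_keys.add(VariantKey(region["chrom"], pos, ref, alt))

    # background variants outside every panel region
    chroms = list(spec.chrom_set)
    for _ in range(spec.n_background_variants):
        while True:
            chrom = rng.choice(chroms)
            pos = rng.randint(1, spec.chrom_length)
            if not _naive_in_regions(regions, chrom, pos) and (chrom, pos) not in occupied:
                occupied.add((chrom, pos))
                break
        ref = rng.choice(_BASES)
        rows.append((
            chrom, pos, ".", ref, _other_base(rng, ref),
            f"{rng.uniform(30, 99):.1f}", "PASS",
            info_str(_maybe_score(rng, spec), _maybe_score(rng, spec), None, None),
        ))

    # symbolic ALTs the reader must skip
    for _ in range(spec.n_symbolic):
        chrom = rng.choice(chroms)
        pos = rng.randint(1, spec.chrom_length)
        rows.append((chrom, pos, ".", rng.choice(_BASES), "<DEL>",
                     ".", "PASS", "SVTYPE=DEL"))
        expected.n_symbolic += 1

    rows.sort(key=lambda r: (r[0], r[1]))
    expected.n_records = len(rows)
    contigs = "".join(
        f"##contig=<ID={c},length={spec.chrom_length + 10_000}>\n"
        for c in sorted(spec.chrom_set)
    )
    body = "".join(
        f"{c}\t{p}\t{i}\t{r}\t{a}\t{q}\t{f}\t{info}\n"
        for c, p, i, r, a, q, f, info in rows
    )
    return _VCF_HEADER.format(contigs=contigs) + body, expected


def write_fixture_dir(spec: FixtureSpec, outdir) -> dict:
    """Emit a complete fixture directory: catalogue.tsv, kb.tsv,
    panel.json, patient.vcf and truth.json.  Returns the file map."""
    import os
    from .knowledgebase import load_catalogue
    from .panel_model import export_panel

    os.makedirs(outdir, exist_ok=True)
    catalogue_tsv, kb_tsv, truth = make_catalogue_and_kb(spec)
    catalogue = load_catalogue(catalogue_tsv)
    panel = build_full_panel(catalogue)
    vcf_text, expected = make_patient_vcf(spec, truth, panel)
    files = {
        "catalogue.tsv": catalogue_tsv,
        "kb.tsv": kb_tsv,
        "panel.json": export_panel(panel),
        "patient.vcf": vcf_text,
        "truth.json": json.dumps(
            {
                "spec": asdict(spec),
                "truth": {"diseases": truth.diseases},
                "expected": {
                    "primary_keys": sorted(map(str, expected.primary_keys)),
                    "secondary_keys": sorted(map(str, expected.secondary_keys)),
                    "n_records": expected.n_records,
                    "n_symbolic": expected.n_symbolic,
                },
            },
            indent=2, sort_keys=True,
        ),
    }
    paths = {}
    for name, text in files.items():
        path = os.path.join(outdir, name)
        with open(path, "w") as handle:
            handle.write(text)
        paths[name] = path
    return paths
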