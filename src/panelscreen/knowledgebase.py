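"""Local knowledge base of known disease variants.

This module stands in for the disease-variant databases a clinical panel
tool queries (HGMD-public, HUMSAVAR, ClinVar, COSMIC): a flat TSV file of
annotated variants is loaded, every record is reduced to a canonical
(minimal) allele representation, and two indexes are built — by variant
key, for exact diagnostic matching, and by genomic region, for panel
construction and reporting.

Matching identity
-----------------
Two variant spellings denote the same event iff they normalize to the same
``(chrom, pos, ref, alt)`` key.  Normalization trims shared flanking bases
(suffix first, then prefix, iterated to a fixed point) while always keeping
at least one base in each allele; the position advances by the number of
prefix bases removed.  This collapses the padded spellings that different
callers emit (``CA>CT`` vs ``A>T``) without requiring a reference genome.
True left-alignment across repeat tracts is out of scope and documented as
a limitation.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, TextIO

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

_VALID_BASES = frozenset("ACGT")


class Source(str, Enum):
    """Origin database of a disease-variant annotation."""

    HGMD_PUBLIC = "HGMD_PUBLIC"
    HUMSAVAR = "HUMSAVAR"
    CLINVAR = "CLINVAR"
    COSMIC = "COSMIC"
    CUSTOM = "CUSTOM"


#: Deterministic ordering of annotation sources in query results and reports.
SOURCE_ORDER = {s: i for i, s in enumerate(Source)}


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name: strip a case-insensitive ``chr`` prefix
    and map the mitochondrial aliases ``M``/``m`` to ``MT``."""
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in {"X", "Y", "MT"}:
        return name.upper()
    if name.upper() == "M":
        return "MT"
    if not name:
        raise ValidationError("empty chromosome name")
    return name


def chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Sort key placing numeric chromosomes first, then X, Y, MT, others."""
    if chrom.isdigit():
        return (0, int(chrom))
    special = {"X": 0, "Y": 1, "MT": 2}
    if chrom in special:
        return (1, special[chrom])
    return (2, chrom)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a variant after allele normalization."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _check_alleles(ref: str, alt: str) -> None:
    for name, allele in (("ref", ref), ("alt", alt)):
        if not allele:
            raise ValidationError(f"{name} allele is empty")
        bad = set(allele) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"{name} allele {allele!r} contains invalid characters {sorted(bad)}"
            )


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Reduce a variant spelling to its canonical key.

    Shared flanking bases are trimmed iteratively — longest common suffix
    first, then longest common prefix — keeping at least one base in each
    allele; ``pos`` advances by the number of prefix bases removed.  The
    operation is idempotent.

    Raises
    ------
    ValidationError
        If an allele is empty or non-ACGT, or if ref equals alt (the
        spelling does not describe a variant).
    """
    ref = ref.upper()
    alt = alt.upper()
    _check_alleles(ref, alt)
    if ref == alt:
        raise ValidationError(f"ref and alt are identical ({ref!r}): not a variant")
    chrom = normalize_chrom(chrom)
    if pos < 1:
        raise ValidationError(f"position must be >= 1, got {pos}")

    changed = True
    while changed:
        changed = False
        # suffix trim: cap so each allele keeps >= 1 base
        k = 0
        cap = min(len(ref), len(alt)) - 1
        while k < cap and ref[-1 - k] == alt[-1 - k]:
            k += 1
        if k:
            ref, alt = ref[:-k], alt[:-k]
            changed = True
        # prefix trim, same cap rule; position advances
        k = 0
        cap = min(len(ref), len(alt)) - 1
        while k < cap and ref[k] == alt[k]:
            k += 1
        if k:
            ref, alt = ref[k:], alt[k:]
            pos += k
            changed = True
    if ref == alt:
        raise ValidationError("alleles identical after trimming: not a variant")
    return VariantKey(chrom, pos, ref, alt)


@dataclass(frozen=True)
class KnownVariant:
    """One disease-mutation annotation from a variant database.

    The same genomic event may carry several annotations (one per
    phenotype/source pair); each is a separate record sharing a key.
    Records are stored in normalized form: ``normalize_variant`` is the
    identity on them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    phenotype: str
    source: Source
    snp_id: str | None = None
    sift: float | None = None
    polyphen: float | None = None
    phastcons: float | None = None

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @staticmethod
    def create(
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        gene: str,
        phenotype: str,
        source: Source,
        snp_id: str | None = None,
        sift: float | None = None,
        polyphen: float | None = None,
        phastcons: float | None = None,
    ) -> "KnownVariant":
        """Build a record, normalizing the allele spelling first."""
        key = normalize_variant(chrom, pos, ref, alt)
        for name, score in (("sift", sift), ("polyphen", polyphen), ("phastcons", phastcons)):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValidationError(f"{name} score {score} outside [0, 1]")
        return KnownVariant(
            key.chrom, key.pos, key.ref, key.alt, gene, phenotype, source,
            snp_id, sift, polyphen, phastcons,
        )

    def annotation_sort_key(self):
        return (SOURCE_ORDER[self.source], self.phenotype, self.gene)


_KB_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "GENE", "PHENOTYPE",
    "SOURCE", "SNP_ID", "SIFT", "POLYPHEN", "PHASTCONS",
]


def _parse_score(field: str, name: str, line: int) -> float | None:
    if field == "." or field == "":
        return None
    try:
        value = float(field)
    except ValueError:
        raise ParseError(f"{name} value {field!r} is not a number", line) from None
    if not (0.0 <= value <= 1.0):
        raise ParseError(f"{name} value {value} outside [0, 1]", line)
    return value


class KnowledgeBase:
    """Indexed collection of :class:`KnownVariant` records.

    ``by_key`` maps a canonical :class:`VariantKey` to every annotation of
    that event; ``query_by_region`` answers positional queries through a
    per-chromosome interval tree.
    """

    def __init__(self, records: Iterable[KnownVariant] = ()):
        self.records: list[KnownVariant] = []
        self.by_key: dict[VariantKey, list[KnownVariant]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for rec in records:
            self.add(rec)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, rec: KnownVariant) -> None:
        self.records.append(rec)
        self.by_key.setdefault(rec.key, []).append(rec)
        self.by_key[rec.key].sort(key=KnownVariant.annotation_sort_key)
        tree = self._trees.setdefault(rec.chrom, IntervalTree())
        tree.addi(rec.pos, rec.pos + 1, rec)

    def query_by_key(self, key: VariantKey) -> list[KnownVariant]:
        """All annotations whose normalized key equals ``key`` (allele-exact,
        never position-only), in deterministic source/phenotype order."""
        return list(self.by_key.get(key, []))

    def query(self, chrom: str, pos: int, ref: str, alt: str) -> list[KnownVariant]:
        """Convenience wrapper accepting an un-normalized spelling."""
        return self.query_by_key(normalize_variant(chrom, pos, ref, alt))

    def query_by_region(self, region) -> list[KnownVariant]:
        """All records on ``region.chrom`` with position in [start, end]."""
        tree = self._trees.get(normalize_chrom(region.chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(region.start, region.end + 1)]
        hits.sort(key=lambda r: (r.pos, r.ref, r.alt, r.annotation_sort_key()))
        return hits

    def keys(self) -> set[VariantKey]:
        return set(self.by_key)


def _open_rows(stream: TextIO | str):
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return csv.reader(stream, delimiter="\t")


def load_kb(stream: TextIO | str) -> KnowledgeBase:
    """Load a knowledge-base TSV into an indexed :class:`KnowledgeBase`.

    The file must carry a header row with the columns CHROM POS REF ALT
    GENE PHENOTYPE SOURCE SNP_ID SIFT POLYPHEN PHASTCONS; ``.`` marks an
    absent value.  Row count is preserved (annotations, not unique keys).
    Malformed rows are rejected with their line number.
    """
    reader = _open_rows(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ParseError("empty knowledge-base file", 1) from None
    header = [h.strip() for h in header]
    missing = [c for c in _KB_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"missing mandatory column(s): {', '.join(missing)}", 1)
    idx = {c: header.index(c) for c in _KB_COLUMNS}

    kb = KnowledgeBase()
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < len(header):
            raise ParseError(f"expected {len(header)} columns, got {len(row)}", lineno)
        field = lambda c: row[idx[c]].strip()
        try:
            source = Source(field("SOURCE"))
        except ValueError:
            raise ParseError(
                f"unknown SOURCE {field('SOURCE')!r} "
                f"(expected one of {[s.value for s in Source]})", lineno
            ) from None
        try:
            pos = int(field("POS"))
        except ValueError:
            raise ParseError(f"POS {field('POS')!r} is not an integer", lineno) from None
        snp = field("SNP_ID")
        try:
            rec = KnownVariant.create(
                chrom=field("CHROM"), pos=pos,
                ref=field("REF"), alt=field("ALT"),
                gene=field("GENE"), phenotype=field("PHENOTYPE"),
                source=source,
                snp_id=None if snp in (".", "") else snp,
                sift=_parse_score(field("SIFT"), "SIFT", lineno),
                polyphen=_parse_score(field("POLYPHEN"), "POLYPHEN", lineno),
                phastcons=_parse_score(field("PHASTCONS"), "PHASTCONS", lineno),
            )
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from None
        kb.add(rec)
    return kb


_CAT_COLUMNS = [
    "PHENOTYPE", "SOURCE", "GENE", "CHROM", "GENE_START", "GENE_END",
    "MUT_POS", "MUT_REF", "MUT_ALT",
]


def load_catalogue(stream: TextIO | str):
    """Load the disease catalogue TSV.

    Rows are grouped by (PHENOTYPE, SOURCE); every group contributes gene
    regions and, on rows where the mutation columns are filled, known
    mutations.  Every disease term must end up with at least one mutation
    — a term is only meaningful for diagnosis if it names a variant.

    Returns a :class:`panelscreen.panel_model.DiseaseCatalogue`.
    """
    from .panel_model import (
        DiseaseCatalogue, CatalogueEntry, DiseaseTerm, GenomicRegion, RegionOrigin,
    )

    reader = _open_rows(stream)
    try:
        header = [h.strip() for h in next(reader)]
    except StopIteration:
        raise ParseError("empty catalogue file", 1) from None
    missing = [c for c in _CAT_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"missing mandatory column(s): {', '.join(missing)}", 1)
    idx = {c: header.index(c) for c in _CAT_COLUMNS}

    entries: dict[DiseaseTerm, CatalogueEntry] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < len(header):
            raise ParseError(f"expected {len(header)} columns, got {len(row)}", lineno)
        field = lambda c: row[idx[c]].strip()
        try:
            source = Source(field("SOURCE"))
        except ValueError:
            raise ParseError(f"unknown SOURCE {field('SOURCE')!r}", lineno) from None
        name = field("PHENOTYPE")
        if not name:
            raise ParseError("empty PHENOTYPE", lineno)
        term = DiseaseTerm(name=name, source=source)
        entry = entries.setdefault(term, CatalogueEntry(term=term))
        gene = field("GENE")
        if not gene:
            raise ParseError("empty GENE", lineno)
        try:
            chrom = normalize_chrom(field("CHROM"))
            start, end = int(field("GENE_START")), int(field("GENE_END"))
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"bad gene coordinates: {exc}", lineno) from None
        try:
            region = GenomicRegion(chrom, start, end, gene, RegionOrigin.DISEASE_AUTO)
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from None
        if all(r.label != gene for r in entry.genes):
            entry.genes.append(region)
        mut_pos = field("MUT_POS")
        if mut_pos not in (".", ""):
            try:
                rec = KnownVariant.create(
                    chrom=chrom, pos=int(mut_pos),
                    ref=field("MUT_REF"), alt=field("MUT_ALT"),
                    gene=gene, phenotype=name, source=source,
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"bad mutation columns: {exc}", lineno) from None
            if all(m.key != rec.key for m in entry.mutations):
                entry.mutations.append(rec)

    if not entries:
        raise ValidationError("catalogue defines no disease terms")
    for term, entry in entries.items():
        if not entry.mutations:
            raise ValidationError(
                f"disease term {term.name!r} ({term.source.value}) has no "
                "associated mutation; every disease term must have at least one"
            )
    return DiseaseCatalogue(entries=entries)
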