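"""Diagnostic panel model: construction, customization, (de)serialization.

A panel is built from three concepts — disease terms, genomic regions to
capture (usually genes), and known diagnostic mutations.  The natural
workflow is disease-driven: adding a disease term pulls its genes and
catalogued mutations into the panel, which can then be customized by
adding/removing genes, importing BED regions, and adding custom mutations.

Panels serialize to a versioned JSON dialect and their region sets to BED;
``merged_regions`` yields the canonical per-chromosome interval union used
by the screening engine.
"""

from __future__ import annotations

import datetime as _dt
import io
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, TextIO

from .errors import (
    DuplicateError, LookupFailure, ParseError, SchemaError, ValidationError,
)
from .knowledgebase import (
    KnownVariant, Source, VariantKey, chrom_sort_key, normalize_chrom,
    normalize_variant,
)

SCHEMA_VERSION = "1"


class RegionOrigin(str, Enum):
    DISEASE_AUTO = "DISEASE_AUTO"   # pulled in automatically by a disease term
    USER_GENE = "USER_GENE"         # added by name through the gene index
    USER_BED = "USER_BED"           # imported from a BED file


@dataclass(frozen=True)
class GenomicRegion:
    """A labelled interval on a chromosome (gene or captured region).

    Coordinates are 1-based inclusive (VCF convention); BED input/output
    converts at the boundary.
    """

    chrom: str
    start: int
    end: int
    label: str
    origin: RegionOrigin = RegionOrigin.USER_GENE

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("region chromosome is empty")
        if not self.label:
            raise ValidationError("region label is empty")
        if self.start < 1:
            raise ValidationError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"region end {self.end} precedes start {self.start}"
            )
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.start, self.end, self.label)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DiseaseTerm:
    """A phenotype/disease definition, qualified by its source database."""

    name: str
    source: Source

    def __post_init__(self):
        if not self.name:
            raise ValidationError("disease term name is empty")


@dataclass
class CatalogueEntry:
    """Genes and known mutations associated with one disease term."""

    term: DiseaseTerm
    genes: list[GenomicRegion] = field(default_factory=list)
    mutations: list[KnownVariant] = field(default_factory=list)


@dataclass
class DiseaseCatalogue:
    """Mapping from disease terms to their genes and known mutations.

    Invariant (enforced at load time): every term has >= 1 mutation.
    """

    entries: dict[DiseaseTerm, CatalogueEntry] = field(default_factory=dict)

    def __contains__(self, term: DiseaseTerm) -> bool:
        return term in self.entries

    def __getitem__(self, term: DiseaseTerm) -> CatalogueEntry:
        try:
            return self.entries[term]
        except KeyError:
            raise LookupFailure(
                f"disease term {term.name!r} ({term.source.value}) not in catalogue"
            ) from None

    def terms(self) -> list[DiseaseTerm]:
        return sorted(self.entries, key=lambda t: (t.name, t.source.value))


@dataclass
class ScoreThresholds:
    """Pathogenicity cut-offs for secondary findings.

    SIFT is deleterious near 0, PolyPhen near 1, so an SNV passes when
    ``sift <= sift_max`` and ``polyphen >= polyphen_min`` (each applied
    only when the threshold is set and the score is present).  Both are
    unset by default: with no threshold every SNV is reported.
    """

    sift_max: float | None = None
    polyphen_min: float | None = None

    def __post_init__(self):
        for name, v in (("sift_max", self.sift_max), ("polyphen_min", self.polyphen_min)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class _Contribution:
    """What one disease term brought into a panel (recorded at add time)."""

    region_labels: set[str] = field(default_factory=set)
    mutation_keys: set[VariantKey] = field(default_factory=set)


@dataclass
class Panel:
    """A named diagnostic panel: diseases, regions, mutations, thresholds."""

    name: str
    diseases: list[DiseaseTerm] = field(default_factory=list)
    regions: list[GenomicRegion] = field(default_factory=list)
    mutations: list[KnownVariant] = field(default_factory=list)
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    created: str = ""
    notes: str = ""
    contributions: dict[DiseaseTerm, _Contribution] = field(default_factory=dict)

    # -- derived views ----------------------------------------------------

    def mutation_keys(self) -> set[VariantKey]:
        return {m.key for m in self.mutations}

    def region_labels(self) -> set[str]:
        return {r.label for r in self.regions}

    def is_out_of_region(self, mutation: KnownVariant) -> bool:
        return not any(r.contains(mutation.chrom, mutation.pos) for r in self.regions)

    @property
    def out_of_region_mutations(self) -> list[KnownVariant]:
        """Panel mutations not covered by any panel region.  These are kept
        (genes and mutations are edited independently) but flagged, and the
        screening engine ignores them."""
        return [m for m in self.mutations if self.is_out_of_region(m)]

    def canonical(self):
        """Order-insensitive canonical form, used for equality."""
        return (
            self.name,
            tuple(sorted((d.name, d.source.value) for d in self.diseases)),
            tuple(sorted(
                (r.chrom, r.start, r.end, r.label, r.origin.value) for r in self.regions
            )),
            tuple(sorted(
                (m.chrom, m.pos, m.ref, m.alt, m.gene, m.phenotype, m.source.value,
                 m.snp_id or "", m.sift, m.polyphen, m.phastcons)
                for m in self.mutations
            )),
            (self.thresholds.sift_max, self.thresholds.polyphen_min),
            self.created,
            self.notes,
            tuple(sorted(
                ((t.name, t.source.value),
                 tuple(sorted(c.region_labels)),
                 tuple(sorted(map(str, c.mutation_keys))))
                for t, c in self.contributions.items()
            )),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self.canonical() == other.canonical()


class PanelCollection:
    """In-memory set of panels keyed by unique name."""

    def __init__(self):
        self._panels: dict[str, Panel] = {}

    def add(self, panel: Panel) -> None:
        if panel.name in self._panels:
            raise DuplicateError(f"a panel named {panel.name!r} already exists")
        self._panels[panel.name] = panel

    def __getitem__(self, name: str) -> Panel:
        try:
            return self._panels[name]
        except KeyError:
            raise LookupFailure(f"no panel named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._panels

    def names(self) -> list[str]:
        return sorted(self._panels)


# -- panel-manager operations ---------------------------------------------


def new_panel(name: str) -> Panel:
    """Create an empty panel with default (absent) thresholds."""
    if not name or not name.strip():
        raise ValidationError("panel name must be non-empty")
    return Panel(name=name.strip(), created=_dt.date.today().isoformat())


def add_disease(panel: Panel, term: DiseaseTerm, catalogue: DiseaseCatalogue) -> Panel:
    """Add a disease term: its catalogue genes join the panel regions (as
    DISEASE_AUTO) and its catalogue mutations join the primary-diagnostic
    set, both deduplicated.  Idempotent for an already-present term."""
    entry = catalogue[term]
    if term not in panel.diseases:
        panel.diseases.append(term)
    contribution = panel.contributions.setdefault(term, _Contribution())
    existing_labels = panel.region_labels()
    for gene in entry.genes:
        contribution.region_labels.add(gene.label)
        if gene.label not in existing_labels:
            panel.regions.append(gene)
            existing_labels.add(gene.label)
    existing_keys = panel.mutation_keys()
    for mut in entry.mutations:
        contribution.mutation_keys.add(mut.key)
        if mut.key not in existing_keys:
            panel.mutations.append(mut)
            existing_keys.add(mut.key)
    return panel


def remove_disease(panel: Panel, term: DiseaseTerm) -> Panel:
    """Remove a disease term and everything it alone contributed.

    Regions and mutations also contributed by a remaining term, and all
    user additions (USER_GENE/USER_BED regions, CUSTOM mutations), are
    kept.  Membership is recomputed from the recorded contributions."""
    if term not in panel.diseases:
        raise LookupFailure(f"disease term {term.name!r} is not in panel {panel.name!r}")
    panel.diseases.remove(term)
    panel.contributions.pop(term, None)
    kept_labels: set[str] = set()
    kept_keys: set[VariantKey] = set()
    for contribution in panel.contributions.values():
        kept_labels |= contribution.region_labels
        kept_keys |= contribution.mutation_keys
    panel.regions = [
        r for r in panel.regions
        if r.origin is not RegionOrigin.DISEASE_AUTO or r.label in kept_labels
    ]
    panel.mutations = [
        m for m in panel.mutations
        if m.source is Source.CUSTOM or m.key in kept_keys
    ]
    return panel


def add_genes(
    panel: Panel, gene_names: Iterable[str], gene_index: dict[str, GenomicRegion]
) -> Panel:
    """Add genes by name, resolving coordinates through ``gene_index``.

    Atomic: if any name is unresolvable, all unknown names are reported
    together and the panel is left unchanged."""
    names = list(gene_names)
    unknown = [n for n in names if n not in gene_index]
    if unknown:
        raise LookupFailure(f"unknown gene name(s): {', '.join(sorted(unknown))}")
    existing = panel.region_labels()
    for name in names:
        region = gene_index[name]
        if region.label in existing:
            continue
        panel.regions.append(
            GenomicRegion(region.chrom, region.start, region.end, region.label,
                          RegionOrigin.USER_GENE)
        )
        existing.add(region.label)
    return panel


def remove_gene(panel: Panel, label: str) -> Panel:
    """Remove every region with the given label.

    Mutations left uncovered are retained but become flagged out-of-region
    (see ``Panel.out_of_region_mutations``); the screening engine ignores
    them."""
    if label not in panel.region_labels():
        raise LookupFailure(f"no region labelled {label!r} in panel {panel.name!r}")
    panel.regions = [r for r in panel.regions if r.label != label]
    return panel


def add_regions_bed(panel: Panel, bed_stream: TextIO | str) -> Panel:
    """Import regions from 3+-column BED text (0-based, half-open).

    Each line becomes a 1-based inclusive region with origin USER_BED;
    column 4, when present, supplies the label, otherwise
    ``chrom:start-end`` is used.  Malformed lines abort with their line
    number and leave the panel unchanged."""
    if isinstance(bed_stream, str):
        bed_stream = io.StringIO(bed_stream)
    parsed: list[GenomicRegion] = []
    for lineno, raw in enumerate(bed_stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ParseError(f"expected >= 3 tab-separated columns, got {len(cols)}", lineno)
        try:
            bed_start, bed_end = int(cols[1]), int(cols[2])
        except ValueError:
            raise ParseError(f"non-integer coordinates {cols[1]!r}, {cols[2]!r}", lineno) from None
        if bed_end <= bed_start:
            raise ParseError(
                f"empty or inverted interval [{bed_start}, {bed_end})", lineno
            )
        try:
            chrom = normalize_chrom(cols[0])
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from None
        start, end = bed_start + 1, bed_end
        label = cols[3].strip() if len(cols) >= 4 and cols[3].strip() else f"{chrom}:{start}-{end}"
        parsed.append(GenomicRegion(chrom, start, end, label, RegionOrigin.USER_BED))
    existing = panel.region_labels()
    for region in parsed:
        if region.label in existing:
            continue
        panel.regions.append(region)
        existing.add(region.label)
    return panel


def export_regions_bed(panel: Panel) -> str:
    """Render the panel's regions as BED text (0-based, half-open)."""
    lines = [
        f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}"
        for r in sorted(panel.regions, key=GenomicRegion.sort_key)
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def add_custom_mutation(
    panel: Panel, chrom: str, pos: int, ref: str, alt: str, disease_name: str
) -> Panel:
    """Add a user-supplied diagnostic mutation (source CUSTOM).

    The spelling is normalized first and deduplicated by key.  If
    ``disease_name`` matches an existing panel disease term (exact,
    case-insensitive) the mutation is attached to it; otherwise a new
    CUSTOM disease term with that name is created and added."""
    key = normalize_variant(chrom, pos, ref, alt)
    if key in panel.mutation_keys():
        raise DuplicateError(f"mutation {key} already in panel {panel.name!r}")
    if not disease_name or not disease_name.strip():
        raise ValidationError("disease name must be non-empty")
    disease_name = disease_name.strip()
    matched = next(
        (d for d in panel.diseases if d.name.lower() == disease_name.lower()), None
    )
    if matched is None:
        matched = DiseaseTerm(name=disease_name, source=Source.CUSTOM)
        panel.diseases.append(matched)
    gene = next(
        (r.label for r in sorted(panel.regions, key=GenomicRegion.sort_key)
         if r.contains(key.chrom, key.pos)),
        ".",
    )
    panel.mutations.append(
        KnownVariant(
            key.chrom, key.pos, key.ref, key.alt,
            gene=gene, phenotype=matched.name, source=Source.CUSTOM,
        )
    )
    return panel


def merged_regions(panel_or_regions) -> list[GenomicRegion]:
    """Canonical interval set: per-chromosome sorted union of the regions,
    merging overlapping and directly adjacent (gap 0) intervals."""
    regions = (
        panel_or_regions.regions
        if isinstance(panel_or_regions, Panel)
        else list(panel_or_regions)
    )
    merged: list[GenomicRegion] = []
    for region in sorted(regions, key=GenomicRegion.sort_key):
        if (
            merged
            and merged[-1].chrom == region.chrom
            and region.start <= merged[-1].end + 1
        ):
            last = merged[-1]
            if region.end > last.end:
                merged[-1] = GenomicRegion(
                    last.chrom, last.start, region.end, last.label, last.origin
                )
        else:
            merged.append(region)
    return merged


# -- JSON (de)serialization -------------------------------------------------


def _mutation_to_json(m: KnownVariant) -> dict:
    return {
        "chrom": m.chrom, "pos": m.pos, "ref": m.ref, "alt": m.alt,
        "gene": m.gene, "phenotype": m.phenotype, "source": m.source.value,
        "snp_id": m.snp_id, "sift": m.sift, "polyphen": m.polyphen,
        "phastcons": m.phastcons,
    }


def export_panel(panel: Panel) -> str:
    """Serialize a panel to its versioned JSON dialect (schema_version 1)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": panel.name,
        "created": panel.created,
        "notes": panel.notes,
        "thresholds": {
            "sift_max": panel.thresholds.sift_max,
            "polyphen_min": panel.thresholds.polyphen_min,
        },
        "diseases": [
            {"name": d.name, "source": d.source.value} for d in panel.diseases
        ],
        "regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "label": r.label, "origin": r.origin.value}
            for r in panel.regions
        ],
        "mutations": [_mutation_to_json(m) for m in panel.mutations],
        "disease_contributions": [
            {
                "name": t.name, "source": t.source.value,
                "region_labels": sorted(c.region_labels),
                "mutation_keys": [
                    {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt}
                    for k in sorted(c.mutation_keys)
                ],
            }
            for t, c in sorted(
                panel.contributions.items(), key=lambda tc: (tc[0].name, tc[0].source.value)
            )
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def _expect(obj, key, types, path):
    if key not in obj:
        raise SchemaError("required field is missing", f"{path}.{key}")
    value = obj[key]
    if not isinstance(value, types):
        names = types.__name__ if isinstance(types, type) else "/".join(t.__name__ for t in types)
        raise SchemaError(
            f"expected {names}, got {type(value).__name__}", f"{path}.{key}"
        )
    return value


def _expect_optional_score(obj, key, path):
    value = obj.get(key)
    if value is None:
        return None
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise SchemaError("expected number or null", f"{path}.{key}")
    return float(value)


def _source_of(value, path) -> Source:
    try:
        return Source(value)
    except ValueError:
        raise SchemaError(
            f"unknown source {value!r} (expected one of {[s.value for s in Source]})", path
        ) from None


def import_panel(json_text: str) -> Panel:
    """Parse and validate a panel JSON document.

    ``import_panel(export_panel(p))`` reproduces ``p`` field-for-field
    (order-insensitive on the set-valued fields).  Schema violations raise
    :class:`SchemaError` carrying the JSON path of the offending element."""
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}", "$") from None
    if not isinstance(doc, dict):
        raise SchemaError("top-level value must be an object", "$")
    version = _expect(doc, "schema_version", str, "$")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})",
            "$.schema_version",
        )
    name = _expect(doc, "name", str, "$")
    if not name:
        raise SchemaError("panel name must be non-empty", "$.name")
    created = _expect(doc, "created", str, "$")
    if created:
        try:
            _dt.date.fromisoformat(created)
        except ValueError:
            raise SchemaError(f"not an ISO-8601 date: {created!r}", "$.created") from None
    notes = _expect(doc, "notes", str, "$")

    thr_obj = _expect(doc, "thresholds", dict, "$")
    try:
        thresholds = ScoreThresholds(
            sift_max=_expect_optional_score(thr_obj, "sift_max", "$.thresholds"),
            polyphen_min=_expect_optional_score(thr_obj, "polyphen_min", "$.thresholds"),
        )
    except ValidationError as exc:
        raise SchemaError(str(exc), "$.thresholds") from None

    diseases: list[DiseaseTerm] = []
    for i, d in enumerate(_expect(doc, "diseases", list, "$")):
        path = f"$.diseases[{i}]"
        if not isinstance(d, dict):
            raise SchemaError("expected object", path)
        term = DiseaseTerm(
            name=_expect(d, "name", str, path),
            source=_source_of(_expect(d, "source", str, path), f"{path}.source"),
        )
        if term in diseases:
            raise SchemaError(f"duplicate disease term {term.name!r}", path)
        diseases.append(term)

    regions: list[GenomicRegion] = []
    for i, r in enumerate(_expect(doc, "regions", list, "$")):
        path = f"$.regions[{i}]"
        if not isinstance(r, dict):
            raise SchemaError("expected object", path)
        try:
            origin = RegionOrigin(_expect(r, "origin", str, path))
        except ValueError:
            raise SchemaError(f"unknown origin {r.get('origin')!r}", f"{path}.origin") from None
        try:
            regions.append(GenomicRegion(
                chrom=_expect(r, "chrom", str, path),
                start=_expect(r, "start", int, path),
                end=_expect(r, "end", int, path),
                label=_expect(r, "label", str, path),
                origin=origin,
            ))
        except ValidationError as exc:
            raise SchemaError(str(exc), path) from None

    mutations: list[KnownVariant] = []
    seen_keys: set[VariantKey] = set()
    for i, m in enumerate(_expect(doc, "mutations", list, "$")):
        path = f"$.mutations[{i}]"
        if not isinstance(m, dict):
            raise SchemaError("expected object", path)
        snp = m.get("snp_id")
        if snp is not None and not isinstance(snp, str):
            raise SchemaError("expected string or null", f"{path}.snp_id")
        try:
            rec = KnownVariant.create(
                chrom=_expect(m, "chrom", str, path),
                pos=_expect(m, "pos", int, path),
                ref=_expect(m, "ref", str, path),
                alt=_expect(m, "alt", str, path),
                gene=_expect(m, "gene", str, path),
                phenotype=_expect(m, "phenotype", str, path),
                source=_source_of(_expect(m, "source", str, path), f"{path}.source"),
                snp_id=snp,
                sift=_expect_optional_score(m, "sift", path),
                polyphen=_expect_optional_score(m, "polyphen", path),
                phastcons=_expect_optional_score(m, "phastcons", path),
            )
        except ValidationError as exc:
            raise SchemaError(str(exc), path) from None
        if rec.key in seen_keys:
            raise SchemaError(f"duplicate normalized mutation key {rec.key}", path)
        seen_keys.add(rec.key)
        mutations.append(rec)

    contributions: dict[DiseaseTerm, _Contribution] = {}
    for i, c in enumerate(_expect(doc, "disease_contributions", list, "$")):
        path = f"$.disease_contributions[{i}]"
        if not isinstance(c, dict):
            raise SchemaError("expected object", path)
        term = DiseaseTerm(
            name=_expect(c, "name", str, path),
            source=_source_of(_expect(c, "source", str, path), f"{path}.source"),
        )
        labels = _expect(c, "region_labels", list, path)
        keys_raw = _expect(c, "mutation_keys", list, path)
        keys: set[VariantKey] = set()
        for j, k in enumerate(keys_raw):
            kpath = f"{path}.mutation_keys[{j}]"
            if not isinstance(k, dict):
                raise SchemaError("expected object", kpath)
            keys.add(VariantKey(
                chrom=_expect(k, "chrom", str, kpath),
                pos=_expect(k, "pos", int, kpath),
                ref=_expect(k, "ref", str, kpath),
                alt=_expect(k, "alt", str, kpath),
            ))
        contributions[term] = _Contribution(
            region_labels=set(labels), mutation_keys=keys
        )

    return Panel(
        name=name, diseases=diseases, regions=regions, mutations=mutations,
        thresholds=thresholds, created=created, notes=notes,
        contributions=contributions,
    )
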