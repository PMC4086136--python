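"""Patient-VCF screening engine.

Reads patient variants from a VCF (v4.x), normalizes each ALT allele to
its canonical key, restricts variants to the panel's merged regions, and
partitions the in-panel set into

* **primary diagnostic hits** — variants whose normalized key exactly
  matches a known diagnostic mutation of the panel, reported with every
  matching knowledge-base annotation, and
* **secondary findings** — the remaining in-panel variants of uncertain
  effect: every indel, and every SNV passing the panel's pathogenicity
  thresholds (SIFT low, PolyPhen high; with no thresholds set — the
  default — every SNV passes).

Secondary findings are always computed, even when a primary hit exists:
both result sets are part of every diagnosis.  Applying a panel to a
whole-exome or whole-genome VCF turns it into a *virtual panel* — the same
region/mutation filter, no physical capture required.
"""

from __future__ import annotations

import bisect
import logging
import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from cyvcf2 import VCF

from .errors import ParseError
from .knowledgebase import (
    KnowledgeBase, KnownVariant, Source, VariantKey, chrom_sort_key,
    normalize_variant,
)
from .panel_model import GenomicRegion, Panel, ScoreThresholds, merged_regions

logger = logging.getLogger("panelscreen")

#: VCF INFO keys carrying passthrough annotations (computed upstream).
INFO_SIFT = "SIFT"
INFO_POLYPHEN = "POLYPHEN"
INFO_PHASTCONS = "PHASTCONS"
INFO_CONSEQUENCE = ("CSQ", "ANN")


class VariantClass(str, Enum):
    SNV = "SNV"      # equal allele lengths after normalization (incl. MNVs)
    INDEL = "INDEL"  # length-changing variant


@dataclass(frozen=True)
class PatientVariant:
    """One normalized alternate allele observed in the patient VCF.

    Multiallelic records are split into one object per ALT allele.  SIFT,
    PolyPhen and phastCons are passthrough annotations read from INFO
    when present; the engine never computes them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    snp_id: str | None = None
    qual: float | None = None
    filter: str = "PASS"
    sift: float | None = None
    polyphen: float | None = None
    phastcons: float | None = None
    consequence: str = "unknown"

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> VariantClass:
        return VariantClass.SNV if len(self.ref) == len(self.alt) else VariantClass.INDEL

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass
class DiagnosisResult:
    """Outcome of screening one VCF against one panel."""

    panel_name: str
    thresholds: ScoreThresholds
    primary: list[tuple[PatientVariant, list[KnownVariant]]] = field(default_factory=list)
    secondary: list[PatientVariant] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def primary_keys(self) -> set[VariantKey]:
        return {v.key for v, _ in self.primary}

    def secondary_keys(self) -> set[VariantKey]:
        return {v.key for v in self.secondary}


@dataclass
class DiagnoseConfig:
    """Run-time options for a diagnosis.

    Threshold overrides, when set, take precedence over the panel's own
    thresholds.  ``pass_only`` restricts screening to records whose FILTER
    is PASS; by default the FILTER column is passed through, never used to
    exclude."""

    sift_max: float | None = None
    polyphen_min: float | None = None
    pass_only: bool = False


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in ("*", ".")


def _info_scalar(value, allele_index: int):
    """Pick the per-allele entry from an INFO value when it is a list."""
    if isinstance(value, (tuple, list)):
        if allele_index < len(value):
            return value[allele_index]
        return value[0] if value else None
    if isinstance(value, str) and "," in value:
        parts = value.split(",")
        return parts[allele_index] if allele_index < len(parts) else parts[0]
    return value


def _as_score(value) -> float | None:
    if value is None:
        return None
    try:
        # htslib stores INFO floats in single precision; round away the
        # representation noise (0.03 -> 0.029999999329...)
        score = round(float(value), 6)
    except (TypeError, ValueError):
        return None
    return score if 0.0 <= score <= 1.0 else None


def read_vcf(source) -> Iterator[PatientVariant]:
    """Yield one normalized :class:`PatientVariant` per ALT allele.

    ``source`` is a path to a plain or bgzipped VCF, or a file-like object
    of VCF text.  Symbolic ALTs (``<DEL>``, ``<NON_REF>``, breakends, ``*``)
    are skipped with a logged count.  Malformed input raises
    :class:`ParseError`."""
    tmp_path = None
    if hasattr(source, "read"):
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as handle:
            handle.write(source.read())
        path = tmp_path
    else:
        path = os.fspath(source)
    try:
        try:
            vcf = VCF(path)
        except Exception as exc:
            raise ParseError(f"cannot parse VCF {path!r}: {exc}") from None
        n_symbolic = 0
        try:
            for record in vcf:
                for allele_index, alt in enumerate(record.ALT):
                    if _is_symbolic(alt):
                        n_symbolic += 1
                        continue
                    try:
                        key = normalize_variant(record.CHROM, record.POS, record.REF, alt)
                    except Exception as exc:
                        raise ParseError(
                            f"bad record {record.CHROM}:{record.POS} "
                            f"{record.REF}>{alt}: {exc}"
                        ) from None
                    consequence = "unknown"
                    for info_key in INFO_CONSEQUENCE:
                        raw = record.INFO.get(info_key)
                        if raw:
                            consequence = str(raw).split(",")[0].split("|")[0] or "unknown"
                            break
                    yield PatientVariant(
                        chrom=key.chrom, pos=key.pos, ref=key.ref, alt=key.alt,
                        snp_id=record.ID or None,
                        qual=record.QUAL,
                        filter=record.FILTER or "PASS",
                        sift=_as_score(_info_scalar(record.INFO.get(INFO_SIFT), allele_index)),
                        polyphen=_as_score(
                            _info_scalar(record.INFO.get(INFO_POLYPHEN), allele_index)
                        ),
                        phastcons=_as_score(
                            _info_scalar(record.INFO.get(INFO_PHASTCONS), allele_index)
                        ),
                        consequence=consequence,
                    )
        finally:
            vcf.close()
        if n_symbolic:
            logger.info("skipped %d symbolic ALT allele(s)", n_symbolic)
        read_vcf.last_symbolic_count = n_symbolic
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


read_vcf.last_symbolic_count = 0


class _RegionIndex:
    """Binary-search index over merged (disjoint, sorted) regions."""

    def __init__(self, merged: Sequence[GenomicRegion]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._labels: dict[str, list[str]] = {}
        for region in merged:
            self._starts.setdefault(region.chrom, []).append(region.start)
            self._ends.setdefault(region.chrom, []).append(region.end)
            self._labels.setdefault(region.chrom, []).append(region.label)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos <= self._ends[chrom][i]


def in_panel(variant: PatientVariant, merged: Sequence[GenomicRegion]) -> bool:
    """True iff the variant's anchor position falls inside a merged panel
    region on the same chromosome (boundaries inclusive)."""
    return _RegionIndex(merged).contains(variant.chrom, variant.pos)


def passes_thresholds(variant: PatientVariant, thresholds: ScoreThresholds) -> bool:
    """Secondary-finding rule for one variant.

    Indels always pass.  An SNV passes when every *set* threshold is met
    by every *present* score: ``sift <= sift_max`` and
    ``polyphen >= polyphen_min``; an absent score passes (variants of
    uncertain effect are reported, not silently dropped), and an unset
    threshold passes everything."""
    if variant.variant_class is VariantClass.INDEL:
        return True
    if thresholds.sift_max is not None and variant.sift is not None:
        if variant.sift > thresholds.sift_max:
            return False
    if thresholds.polyphen_min is not None and variant.polyphen is not None:
        if variant.polyphen < thresholds.polyphen_min:
            return False
    return True


def classify(
    variants: Iterable[PatientVariant],
    panel: Panel,
    kb: KnowledgeBase,
    config: DiagnoseConfig | None = None,
) -> DiagnosisResult:
    """Partition patient variants into primary hits and secondary findings.

    Only variants inside the panel's merged regions are considered.
    Primary matching is allele-exact against the panel's own mutation set
    (catalogue mutations of its diseases plus custom additions, ignoring
    mutations flagged out-of-region) — not against the whole knowledge
    base; a kb variant outside the panel's diseases surfaces as an
    ordinary secondary finding.  Primary hits carry every matching kb
    annotation plus any CUSTOM panel annotation."""
    config = config or DiagnoseConfig()
    thresholds = ScoreThresholds(
        sift_max=config.sift_max if config.sift_max is not None else panel.thresholds.sift_max,
        polyphen_min=(
            config.polyphen_min if config.polyphen_min is not None
            else panel.thresholds.polyphen_min
        ),
    )
    merged = merged_regions(panel)
    index = _RegionIndex(merged)
    panel_keys = {
        m.key: m for m in panel.mutations if not panel.is_out_of_region(m)
    }

    result = DiagnosisResult(panel_name=panel.name, thresholds=thresholds)
    n_read = n_in_panel = 0
    seen_keys: set[VariantKey] = set()
    for variant in variants:
        n_read += 1
        if config.pass_only and variant.filter not in ("PASS", "."):
            continue
        if not index.contains(variant.chrom, variant.pos):
            continue
        n_in_panel += 1
        if variant.key in seen_keys:
            continue
        seen_keys.add(variant.key)
        if variant.key in panel_keys:
            annotations = kb.query_by_key(variant.key)
            panel_mut = panel_keys[variant.key]
            if panel_mut.source is Source.CUSTOM and panel_mut not in annotations:
                annotations = sorted(
                    annotations + [panel_mut], key=KnownVariant.annotation_sort_key
                )
            if not annotations:
                # panel mutation absent from the kb file: fall back to the
                # panel's own record so the hit still carries its phenotype
                annotations = [panel_mut]
            result.primary.append((variant, annotations))
        elif passes_thresholds(variant, thresholds):
            result.secondary.append(variant)

    result.primary.sort(key=lambda pair: pair[0].sort_key())
    result.secondary.sort(key=PatientVariant.sort_key)
    result.counts = {
        "n_read": n_read,
        "n_in_panel": n_in_panel,
        "n_primary": len(result.primary),
        "n_secondary": len(result.secondary),
    }
    return result


def run_diagnosis(
    vcf_source,
    panel: Panel,
    kb: KnowledgeBase,
    config: DiagnoseConfig | None = None,
) -> DiagnosisResult:
    """Full diagnostic run: read VCF, filter to panel, classify.

    Output ordering is deterministic (chromosome, position, alt allele);
    summary counts, including skipped symbolic alleles, are logged and
    recorded on the result."""
    variants = list(read_vcf(vcf_source))
    result = classify(variants, panel, kb, config)
    result.counts["n_symbolic_skipped"] = read_vcf.last_symbolic_count
    logger.info(
        "diagnosis %s: read=%d in_panel=%d primary=%d secondary=%d",
        panel.name, result.counts["n_read"], result.counts["n_in_panel"],
        result.counts["n_primary"], result.counts["n_secondary"],
    )
    return result
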