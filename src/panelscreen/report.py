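"""Clinical-style reporting of a diagnosis.

A report packages the analysis metadata (title, date, reporter), the
primary diagnostic table, the secondary-findings table, a description of
the panel used (its genes and mutations) and free-text comments, and
renders to machine-readable (json, tsv) or human-readable (html,
markdown) form.  Rendering is deterministic: the same report yields
byte-identical output, and the JSON form parses back losslessly.
"""

from __future__ import annotations

import datetime as _dt
import html as _html
import json
from dataclasses import dataclass, field

from .errors import ValidationError
from .panel_model import GenomicRegion, Panel
from .vcf_engine import DiagnosisResult, PatientVariant

#: Column identifiers accepted in a report configuration.
ALLOWED_COLUMNS = (
    "chrom", "position", "snp_id", "ref", "alt", "gene", "consequence",
    "phenotype", "source", "sift", "polyphen", "phastcons", "qual", "filter",
)

#: Default layout: the classic diagnostic-table columns, chromosome
#: through conservation score.
DEFAULT_COLUMNS = ALLOWED_COLUMNS[:12]

MISSING = "."


@dataclass(frozen=True)
class ReportMeta:
    title: str
    date: str = ""
    reporter: str = ""
    analysis_info: str = ""
    comments: str = ""

    def __post_init__(self):
        if not self.title:
            raise ValidationError("report title must be non-empty")
        date = self.date or _dt.date.today().isoformat()
        try:
            _dt.date.fromisoformat(date)
        except ValueError:
            raise ValidationError(f"not an ISO-8601 date: {self.date!r}") from None
        object.__setattr__(self, "date", date)


@dataclass
class Report:
    meta: ReportMeta
    columns: list[str]
    primary_findings: list[dict[str, str]]
    secondary_findings: list[dict[str, str]]
    panel_name: str
    panel_genes: list[str]
    panel_mutations: list[str]
    thresholds: dict[str, float | None] = field(default_factory=dict)


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return format(value, ".6g")
    text = str(value)
    return text if text else MISSING


def _variant_row(
    variant: PatientVariant,
    columns: list[str],
    gene: str,
    phenotype: str,
    source: str,
    annotation=None,
) -> dict[str, str]:
    values = {
        "chrom": variant.chrom,
        "position": variant.pos,
        "snp_id": variant.snp_id or (annotation.snp_id if annotation else None),
        "ref": variant.ref,
        "alt": variant.alt,
        "gene": gene,
        "consequence": variant.consequence,
        "phenotype": phenotype,
        "source": source,
        "sift": variant.sift if variant.sift is not None else (annotation.sift if annotation else None),
        "polyphen": variant.polyphen if variant.polyphen is not None else (annotation.polyphen if annotation else None),
        "phastcons": variant.phastcons if variant.phastcons is not None else (annotation.phastcons if annotation else None),
        "qual": variant.qual,
        "filter": variant.filter,
    }
    return {c: _fmt(values[c]) for c in columns}


def build_report(
    result: DiagnosisResult,
    meta: ReportMeta,
    panel: Panel,
    columns: list[str] | None = None,
) -> Report:
    """Assemble a report from a diagnosis.

    ``columns`` selects and orders the table columns (default: the
    standard twelve, chromosome through phastCons).  Primary hits emit one
    row per annotation (phenotype/source pair); secondary findings one row
    per variant, with the gene column set to the label of the enclosing
    panel region (first in sort order when several cover the position).
    Absent values render as ``"."``."""
    columns = list(columns) if columns is not None else list(DEFAULT_COLUMNS)
    unknown = [c for c in columns if c not in ALLOWED_COLUMNS]
    if unknown:
        raise ValidationError(
            f"unknown column name(s): {', '.join(unknown)}; "
            f"allowed: {', '.join(ALLOWED_COLUMNS)}"
        )

    sorted_regions = sorted(panel.regions, key=GenomicRegion.sort_key)

    def enclosing_label(variant: PatientVariant) -> str:
        return next(
            (r.label for r in sorted_regions if r.contains(variant.chrom, variant.pos)),
            MISSING,
        )

    primary_rows = [
        _variant_row(
            variant, columns,
            gene=annotation.gene, phenotype=annotation.phenotype,
            source=annotation.source.value, annotation=annotation,
        )
        for variant, annotations in result.primary
        for annotation in annotations
    ]
    secondary_rows = [
        _variant_row(variant, columns, gene=enclosing_label(variant),
                     phenotype=MISSING, source=MISSING)
        for variant in result.secondary
    ]
    return Report(
        meta=meta,
        columns=columns,
        primary_findings=primary_rows,
        secondary_findings=secondary_rows,
        panel_name=panel.name,
        panel_genes=sorted(panel.region_labels()),
        panel_mutations=[
            f"{m.key} {m.gene} {m.phenotype} [{m.source.value}]"
            for m in sorted(panel.mutations, key=lambda m: (m.key, m.source.value))
        ],
        thresholds={
            "sift_max": result.thresholds.sift_max,
            "polyphen_min": result.thresholds.polyphen_min,
        },
    )


FORMATS = ("json", "html", "markdown", "tsv")

SECTION_TITLES = (
    "Meta", "Primary Diagnostic", "Secondary Findings", "Panel", "Comments",
)


def render(report: Report, format: str) -> str:
    """Render a report to one of: json, html, markdown, tsv."""
    if format not in FORMATS:
        raise ValidationError(f"unknown format {format!r}; expected one of {FORMATS}")
    return {
        "json": _render_json,
        "html": _render_html,
        "markdown": _render_markdown,
        "tsv": _render_tsv,
    }[format](report)


def _render_json(report: Report) -> str:
    doc = {
        "meta": {
            "title": report.meta.title,
            "date": report.meta.date,
            "reporter": report.meta.reporter,
            "analysis_info": report.meta.analysis_info,
            "comments": report.meta.comments,
        },
        "columns": report.columns,
        "primary_findings": report.primary_findings,
        "secondary_findings": report.secondary_findings,
        "panel": {
            "name": report.panel_name,
            "genes": report.panel_genes,
            "mutations": report.panel_mutations,
            "thresholds": report.thresholds,
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def parse_report(json_text: str) -> Report:
    """Inverse of the json rendering: parse back into an equal Report."""
    doc = json.loads(json_text)
    return Report(
        meta=ReportMeta(**doc["meta"]),
        columns=list(doc["columns"]),
        primary_findings=[dict(r) for r in doc["primary_findings"]],
        secondary_findings=[dict(r) for r in doc["secondary_findings"]],
        panel_name=doc["panel"]["name"],
        panel_genes=list(doc["panel"]["genes"]),
        panel_mutations=list(doc["panel"]["mutations"]),
        thresholds=dict(doc["panel"]["thresholds"]),
    )


def _table_markdown(columns: list[str], rows: list[dict[str, str]]) -> list[str]:
    if not rows:
        return ["*(no findings)*"]
    out = ["| " + " | ".join(columns) + " |",
           "| " + " | ".join("---" for _ in columns) + " |"]
    out += ["| " + " | ".join(row[c] for c in columns) + " |" for row in rows]
    return out


def _render_markdown(report: Report) -> str:
    thr = report.thresholds
    lines = [
        f"# {report.meta.title}",
        "",
        "## Meta",
        "",
        f"- Date: {report.meta.date}",
        f"- Reporter: {_fmt(report.meta.reporter)}",
        f"- Analysis: {_fmt(report.meta.analysis_info)}",
        "",
        "## Primary Diagnostic",
        "",
        *_table_markdown(report.columns, report.primary_findings),
        "",
        "## Secondary Findings",
        "",
        *_table_markdown(report.columns, report.secondary_findings),
        "",
        "## Panel",
        "",
        f"- Name: {report.panel_name}",
        f"- Thresholds: sift_max={_fmt(thr.get('sift_max'))}, "
        f"polyphen_min={_fmt(thr.get('polyphen_min'))}",
        f"- Genes: {', '.join(report.panel_genes) if report.panel_genes else MISSING}",
        "- Mutations:",
        *[f"  - {m}" for m in report.panel_mutations],
        "",
        "## Comments",
        "",
        report.meta.comments or "(none)",
        "",
    ]
    return "\n".join(lines)


def _table_html(columns: list[str], rows: list[dict[str, str]]) -> str:
    head = "".join(f"<th>{_html.escape(c)}</th>" for c in columns)
    body = "".join(
        "<tr>" + "".join(f"<td>{_html.escape(row[c])}</td>" for c in columns) + "</tr>"
        for row in rows
    )
    return f"<table><thead><tr>{head}</tr></thead><tbody>{body}</tbody></table>"


def _render_html(report: Report) -> str:
    esc = _html.escape
    thr = report.thresholds
    mutations = "".join(f"<li>{esc(m)}</li>" for m in report.panel_mutations)
    return (
        "<!DOCTYPE html>\n"
        '<html><head><meta charset="utf-8">'
        f"<title>{esc(report.meta.title)}</title>"
        "<style>body{font-family:sans-serif;margin:2em}"
        "table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:0.3em 0.6em}"
        "@media print{body{margin:0}}</style>"
        "</head><body>\n"
        f"<h1>{esc(report.meta.title)}</h1>\n"
        "<h2>Meta</h2>\n"
        f"<p>Date: {esc(report.meta.date)}<br>"
        f"Reporter: {esc(_fmt(report.meta.reporter))}<br>"
        f"Analysis: {esc(_fmt(report.meta.analysis_info))}</p>\n"
        "<h2>Primary Diagnostic</h2>\n"
        f"{_table_html(report.columns, report.primary_findings)}\n"
        "<h2>Secondary Findings</h2>\n"
        f"{_table_html(report.columns, report.secondary_findings)}\n"
        "<h2>Panel</h2>\n"
        f"<p>Name: {esc(report.panel_name)}<br>"
        f"Thresholds: sift_max={esc(_fmt(thr.get('sift_max')))}, "
        f"polyphen_min={esc(_fmt(thr.get('polyphen_min')))}<br>"
        f"Genes: {esc(', '.join(report.panel_genes) if report.panel_genes else MISSING)}</p>\n"
        f"<ul>{mutations}</ul>\n"
        "<h2>Comments</h2>\n"
        f"<p>{esc(report.meta.comments or '(none)')}</p>\n"
        "</body></html>\n"
    )


def _render_tsv(report: Report) -> str:
    lines = ["#section\tprimary_findings", "\t".join(report.columns)]
    lines += ["\t".join(row[c] for c in report.columns) for row in report.primary_findings]
    lines += ["#section\tsecondary_findings", "\t".join(report.columns)]
    lines += ["\t".join(row[c] for c in report.columns) for row in report.secondary_findings]
    return "\n".join(lines) + "\n"
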