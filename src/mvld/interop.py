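"""Reading, writing and exporting MVLD records.

Three interchange surfaces live here:

* the **MVLD table** — UTF-8, tab-separated, one header row of canonical
  column names in the standard's field order, ``;`` as the in-cell list
  delimiter, empty cells for absent optionals.  Unknown columns are preserved
  into each record's ``extensions`` map and survive a read→write cycle
  byte-identically.  The sub-level evidence block is structured, so its cell
  holds a compact JSON array.
* the **MVLD JSON** document — ``{"mvld_version": "1.0", "records": [...]}``,
  mirroring the type model one-to-one.
* the **ClinVar-style export** — one flat row per record in the spirit of a
  ClinVar submission table: HGVS expressions, gene, condition
  (``source:code (label)``), a clinical-significance analog, the level of
  evidence rendered into the assertion-method field, and citations.  The
  layout is a documented approximation of a submission sheet, not a bit-exact
  copy of any dated template; it is lossless for the required MVLD fields and
  :func:`from_clinvar_row` reconstructs them.

Readers report problems as findings (and skip rows that cannot be structured
at all); only an unusable header is a hard :class:`MvldReadError`.  The
packaged cancer-ontology fixture (an ~50-term, hand-curated Oncotree/NCIt
subset for desk-scale testing — not a substitute for the live services) is
consulted by :func:`lookup_cancer_term`.
"""

from __future__ import annotations

import csv
import difflib
import io
import json
import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .model import (
    MVLD_VERSION,
    AlleleDescriptor,
    AlleleInterpretation,
    CancerInterpretation,
    Effect,
    EvidenceAssertion,
    ExpertOpinion,
    LevelOfEvidence,
    MVLDRecord,
    OntologyTerm,
)
from .tiering import TIER_SENTENCES
from .validation import (
    ValidationFinding,
    ValidationReport,
    validate_record,
)
from .vocab import UnknownTermError, normalize_term

__all__ = [
    "MVLD_COLUMNS",
    "TableDialect",
    "MvldReadError",
    "ConversionError",
    "UnknownCancerTermError",
    "ClinVarRow",
    "CLINVAR_COLUMNS",
    "read_mvld_table",
    "write_mvld_table",
    "read_mvld_json",
    "write_mvld_json",
    "to_clinvar_row",
    "from_clinvar_row",
    "write_clinvar_table",
    "lookup_cancer_term",
    "oncotree_entries",
]

#: Canonical MVLD column names, in the standard's field order
#: (descriptive block, interpretive block, cancer-interpretive block).
MVLD_COLUMNS: tuple[str, ...] = (
    "genome_build",
    "gene_name",
    "chromosome",
    "dna_position",
    "refseq_transcript",
    "refseq_protein",
    "somatic_classification",
    "dna_hgvs",
    "protein_hgvs",
    "variant_type",
    "variant_consequence",
    "pmids",
    "cancer_type",
    "biomarker_class",
    "therapeutic_context",
    "effect",
    "level_of_evidence",
    "sub_level_of_evidence",
)


@dataclass(frozen=True)
class TableDialect:
    """MVLD table conventions: tab-separated, ``;`` inside list cells, empty
    cell for an absent optional, exact canonical header names."""

    delimiter: str = "\t"
    list_sep: str = ";"
    columns: tuple[str, ...] = MVLD_COLUMNS


class MvldReadError(ValueError):
    """The input cannot be read at all (bad header, undecodable text)."""


class ConversionError(ValueError):
    """A record was refused for export; carries the blocking findings."""

    def __init__(self, findings: Sequence[ValidationFinding]):
        self.findings = tuple(findings)
        ids = ", ".join(f.rule_id for f in self.findings)
        super().__init__(f"record fails submission-profile validation: {ids}")


# ---------------------------------------------------------------------------
# packaged fixture tables


def _data_text(name: str) -> str:
    return (resources.files("mvld") / "data" / name).read_text(encoding="utf-8")


_ONCOTREE: list[dict[str, str]] | None = None
_GENES: list[dict[str, str]] | None = None


def oncotree_entries() -> list[dict[str, str]]:
    """Rows of the packaged Oncotree/NCIt subset
    (``oncotree_code``, ``label``, ``ncit_code``)."""
    global _ONCOTREE
    if _ONCOTREE is None:
        reader = csv.DictReader(io.StringIO(_data_text("oncotree_subset.tsv")), delimiter="\t")
        _ONCOTREE = list(reader)
    return _ONCOTREE


def _load_gene_table() -> list[str]:
    global _GENES
    if _GENES is None:
        reader = csv.DictReader(io.StringIO(_data_text("hugo_symbols.tsv")), delimiter="\t")
        _GENES = list(reader)
    return [row["symbol"] for row in _GENES]


def gene_entries() -> list[dict[str, str]]:
    """Rows of the packaged gene table (symbol, chromosome, RefSeq ids)."""
    _load_gene_table()
    assert _GENES is not None
    return _GENES


class UnknownCancerTermError(KeyError):
    """No fixture entry matches; carries nearest-label suggestions."""

    def __init__(self, query: str, source: str, suggestions: tuple[str, ...]):
        self.query = query
        self.source = source
        self.suggestions = suggestions
        hint = f"; nearest: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"unknown cancer term for {source}: {query!r}{hint}")


def lookup_cancer_term(query: str, source: str = "Oncotree") -> OntologyTerm:
    """Resolve a cancer-type query against the packaged ontology subset.

    Matches the code exactly (case-insensitively) or the label
    case-insensitively.  Oncotree entries carry their paired NCI Thesaurus
    code, so an ``NCIt`` lookup accepts either the ``C``-code or the label.
    """
    if source not in ("NCIt", "Oncotree"):
        raise ValueError(f"source must be NCIt or Oncotree, got {source!r}")
    q = query.strip()
    qf = q.casefold()
    for row in oncotree_entries():
        code = row["oncotree_code"] if source == "Oncotree" else row["ncit_code"]
        if qf == code.casefold() or qf == row["label"].casefold():
            return OntologyTerm(source=source, code=code, label=row["label"])
    pool = [row["label"] for row in oncotree_entries()] + [
        (row["oncotree_code"] if source == "Oncotree" else row["ncit_code"])
        for row in oncotree_entries()
    ]
    near = tuple(difflib.get_close_matches(q, pool, n=3, cutoff=0.5))
    raise UnknownCancerTermError(query, source, near)


def ncit_code_for(oncotree_code: str) -> str:
    """The NCI Thesaurus code paired with an Oncotree code in the fixture."""
    for row in oncotree_entries():
        if row["oncotree_code"] == oncotree_code:
            return row["ncit_code"]
    raise UnknownCancerTermError(oncotree_code, "Oncotree", ())


# ---------------------------------------------------------------------------
# cell codecs

_ONTOLOGY_CELL_RE = re.compile(r"^(NCIt|Oncotree|local):(\S+?)(?: \((.*)\))?$")


def _render_ontology(term: OntologyTerm | None) -> str:
    if term is None:
        return ""
    if term.label:
        return f"{term.source}:{term.code} ({term.label})"
    return f"{term.source}:{term.code}"


def _parse_ontology(cell: str) -> OntologyTerm | None:
    if not cell:
        return None
    m = _ONTOLOGY_CELL_RE.match(cell)
    if not m:
        raise ValueError(f"cancer_type cell must be 'source:code (label)', got {cell!r}")
    return OntologyTerm.build_unchecked(
        source=m.group(1), code=m.group(2), label=m.group(3) or ""
    )


def _render_effect(effect: Effect | None) -> str:
    if effect is None:
        return ""
    if effect.term == "other":
        return f"other: {effect.free_text}"
    return effect.term or ""


def _parse_effect(cell: str) -> Effect | None:
    if not cell:
        return None
    if cell.startswith("other:"):
        return Effect.build_unchecked(term="other", free_text=cell[len("other:"):].strip())
    term = cell.strip()
    try:
        term = normalize_term("effect", term)
    except UnknownTermError:
        pass  # keep raw; the validator reports VOC.EFFECT
    return Effect.build_unchecked(term=term, free_text="")


def _render_level(level: LevelOfEvidence | None) -> str:
    if level is None:
        return ""
    return f"{level.schema_name}: {level.level_label}"


def _parse_level(cell: str) -> LevelOfEvidence | None:
    if not cell:
        return None
    schema, _, label = cell.partition(": ")
    if not _:
        raise ValueError(f"level_of_evidence cell must be 'schema: label', got {cell!r}")
    return LevelOfEvidence.build_unchecked(schema_name=schema.strip(), level_label=label.strip())


def _assertion_to_obj(a: EvidenceAssertion) -> dict:
    obj: dict = {"category": a.category}
    if a.trial_ids:
        obj["trial_ids"] = list(a.trial_ids)
    if a.pmids:
        obj["pmids"] = list(a.pmids)
    if a.expert is not None:
        obj["expert"] = {
            "name": a.expert.name,
            "date": a.expert.date,
            "affiliation": a.expert.affiliation,
        }
    if a.tools:
        obj["tools"] = list(a.tools)
    if a.note:
        obj["note"] = a.note
    return obj


def _assertion_from_obj(obj: dict) -> EvidenceAssertion:
    expert = None
    if obj.get("expert"):
        e = obj["expert"]
        expert = ExpertOpinion.build_unchecked(
            name=str(e.get("name", "")),
            date=str(e.get("date", "")),
            affiliation=str(e.get("affiliation", "")),
        )
    return EvidenceAssertion.build_unchecked(
        category=int(obj["category"]),
        trial_ids=tuple(str(t) for t in obj.get("trial_ids", [])),
        pmids=tuple(int(p) for p in obj.get("pmids", [])),
        expert=expert,
        tools=tuple(str(t) for t in obj.get("tools", [])),
        note=str(obj.get("note", "")),
    )


def _render_sublevel(assertions: tuple[EvidenceAssertion, ...]) -> str:
    if not assertions:
        return ""
    return json.dumps([_assertion_to_obj(a) for a in assertions], separators=(",", ":"))


def _parse_sublevel(cell: str) -> tuple[EvidenceAssertion, ...]:
    if not cell:
        return ()
    data = json.loads(cell)
    if not isinstance(data, list):
        raise ValueError("sub_level_of_evidence cell must hold a JSON array")
    return tuple(_assertion_from_obj(obj) for obj in data)


def _join(values: Iterable, sep: str) -> str:
    return sep.join(str(v) for v in values)


def _split(cell: str, sep: str) -> tuple[str, ...]:
    if not cell:
        return ()
    return tuple(part.strip() for part in cell.split(sep) if part.strip())


def _normalize_or_raw(field_name: str, cell: str) -> str | None:
    """Canonicalize a vocabulary cell; keep the raw spelling when unknown so
    the validator can report it as a VOC.* finding."""
    if not cell:
        return None
    try:
        return normalize_term(field_name, cell)
    except UnknownTermError:
        return cell.strip()


# ---------------------------------------------------------------------------
# MVLD table


def record_to_row(record: MVLDRecord, dialect: TableDialect = TableDialect()) -> dict[str, str]:
    """Flatten one record into canonical-column cells plus its extensions."""
    d, i, c = record.descriptor, record.interpretation, record.cancer
    sep = dialect.list_sep
    row = {
        "genome_build": d.genome_build or "",
        "gene_name": d.gene_symbol or "",
        "chromosome": d.chromosome or "",
        "dna_position": "" if d.genomic_position is None else str(d.genomic_position),
        "refseq_transcript": _join(d.transcripts, sep),
        "refseq_protein": d.protein_id or "",
        "somatic_classification": i.somatic_classification or "",
        "dna_hgvs": i.dna_hgvs or "",
        "protein_hgvs": i.protein_hgvs or "",
        "variant_type": i.variant_type or "",
        "variant_consequence": i.variant_consequence or "",
        "pmids": _join(i.pmids, sep),
        "cancer_type": _render_ontology(c.cancer_type),
        "biomarker_class": c.biomarker_class or "",
        "therapeutic_context": _join(c.therapeutic_context, sep),
        "effect": _render_effect(c.effect),
        "level_of_evidence": _render_level(c.level_of_evidence),
        "sub_level_of_evidence": _render_sublevel(c.sub_level),
    }
    row.update(record.extensions)
    return row


def _record_from_cells(cells: dict[str, str], dialect: TableDialect) -> MVLDRecord:
    sep = dialect.list_sep
    pos_cell = cells.get("dna_position", "")
    descriptor = AlleleDescriptor.build_unchecked(
        genome_build=cells.get("genome_build") or None,
        gene_symbol=cells.get("gene_name") or None,
        chromosome=cells.get("chromosome") or None,
        genomic_position=int(pos_cell) if pos_cell else None,
        transcripts=_split(cells.get("refseq_transcript", ""), sep),
        protein_id=cells.get("refseq_protein") or None,
    )
    interpretation = AlleleInterpretation.build_unchecked(
        somatic_classification=_normalize_or_raw(
            "somatic_classification", cells.get("somatic_classification", "")
        ),
        dna_hgvs=cells.get("dna_hgvs") or None,
        protein_hgvs=cells.get("protein_hgvs") or None,
        variant_type=_normalize_or_raw("variant_type", cells.get("variant_type", "")),
        variant_consequence=_normalize_or_raw(
            "variant_consequence", cells.get("variant_consequence", "")
        ),
        pmids=tuple(int(p) for p in _split(cells.get("pmids", ""), sep)),
    )
    cancer = CancerInterpretation.build_unchecked(
        cancer_type=_parse_ontology(cells.get("cancer_type", "")),
        biomarker_class=_normalize_or_raw("biomarker_class", cells.get("biomarker_class", "")),
        therapeutic_context=_split(cells.get("therapeutic_context", ""), sep),
        effect=_parse_effect(cells.get("effect", "")),
        level_of_evidence=_parse_level(cells.get("level_of_evidence", "")),
        sub_level=_parse_sublevel(cells.get("sub_level_of_evidence", "")),
    )
    extensions = {k: v for k, v in cells.items() if k not in dialect.columns}
    return MVLDRecord.build_unchecked(
        descriptor=descriptor, interpretation=interpretation, cancer=cancer,
        extensions=extensions,
    )


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_mvld_table(
    source: str | Path | TextIO,
    dialect: TableDialect = TableDialect(),
    profile: str = "submission",
) -> tuple[list[MVLDRecord], ValidationReport]:
    """Read an MVLD TSV into records plus an aggregated validation report.

    Every data row becomes one record (vocabulary cells are canonicalized on
    the way in); per-row findings carry the record index.  Rows that cannot
    be structured at all are skipped with an ``IO.ROW_SKIPPED`` error naming
    the row.  A missing or duplicated canonical header is a hard
    :class:`MvldReadError`.
    """
    stream, should_close = _open_text(source)
    try:
        try:
            reader = csv.reader(stream, delimiter=dialect.delimiter)
            try:
                header = next(reader)
            except StopIteration:
                raise MvldReadError("missing header row") from None
            rows = [row for row in reader]
        except (UnicodeDecodeError, csv.Error) as exc:
            raise MvldReadError(f"unreadable input: {exc}") from exc
    finally:
        if should_close:
            stream.close()

    seen = [c for c in header if header.count(c) > 1]
    if seen:
        raise MvldReadError(f"duplicate columns in header: {sorted(set(seen))}")
    missing = [c for c in dialect.columns if c not in header]
    if missing:
        raise MvldReadError(f"missing canonical columns: {missing}")

    findings: list[ValidationFinding] = []
    unknown_cols = [c for c in header if c not in dialect.columns]
    for col in unknown_cols:
        findings.append(
            ValidationFinding(
                "warning", "IO.UNKNOWN_COLUMN", f"extensions.{col}",
                f"unknown column {col!r} preserved into extensions",
            )
        )

    records: list[MVLDRecord] = []
    for row_no, row in enumerate(rows, start=2):  # 1-based, after header
        cells = {name: (row[k] if k < len(row) else "") for k, name in enumerate(header)}
        try:
            record = _record_from_cells(cells, dialect)
        except (ValueError, KeyError, json.JSONDecodeError) as exc:
            findings.append(
                ValidationFinding(
                    "error", "IO.ROW_SKIPPED", f"row[{row_no}]",
                    f"row {row_no} could not be structured: {exc}",
                )
            )
            continue
        idx = len(records)
        records.append(record)
        for f in validate_record(record, profile).findings:
            findings.append(
                ValidationFinding(f.severity, f.rule_id, f.field_path, f.message, idx)
            )
    return records, ValidationReport(tuple(findings))


def write_mvld_table(
    records: Sequence[MVLDRecord],
    target: str | Path | TextIO,
    dialect: TableDialect = TableDialect(),
) -> None:
    """Write records as an MVLD TSV: canonical column order, then any
    extension columns in first-seen order.  Byte-stable for identical input."""
    extension_cols: list[str] = []
    rows = []
    for record in records:
        row = record_to_row(record, dialect)
        for key in record.extensions:
            if key not in extension_cols:
                extension_cols.append(key)
        rows.append(row)
    columns = list(dialect.columns) + extension_cols

    stream, should_close = _open_text(target, "w")
    try:
        writer = csv.writer(stream, delimiter=dialect.delimiter, lineterminator="\n")
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row.get(col, "") for col in columns])
    finally:
        if should_close:
            stream.close()


def mvld_table_str(records: Sequence[MVLDRecord], dialect: TableDialect = TableDialect()) -> str:
    buf = io.StringIO()
    write_mvld_table(records, buf, dialect)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# MVLD JSON


def record_to_obj(record: MVLDRecord) -> dict:
    """One record as a JSON-ready mapping mirroring the type model."""
    d, i, c = record.descriptor, record.interpretation, record.cancer
    obj: dict = {
        "descriptor": {
            "genome_build": d.genome_build,
            "gene_symbol": d.gene_symbol,
            "chromosome": d.chromosome,
            "genomic_position": d.genomic_position,
            "transcripts": list(d.transcripts),
            "protein_id": d.protein_id,
        },
        "interpretation": {
            "somatic_classification": i.somatic_classification,
            "dna_hgvs": i.dna_hgvs,
            "protein_hgvs": i.protein_hgvs,
            "variant_type": i.variant_type,
            "variant_consequence": i.variant_consequence,
            "pmids": list(i.pmids),
        },
        "cancer": {
            "cancer_type": (
                None
                if c.cancer_type is None
                else {
                    "source": c.cancer_type.source,
                    "code": c.cancer_type.code,
                    "label": c.cancer_type.label,
                }
            ),
            "biomarker_class": c.biomarker_class,
            "therapeutic_context": list(c.therapeutic_context),
            "effect": (
                None
                if c.effect is None
                else {"term": c.effect.term, "free_text": c.effect.free_text}
            ),
            "level_of_evidence": (
                None
                if c.level_of_evidence is None
                else {
                    "schema_name": c.level_of_evidence.schema_name,
                    "level_label": c.level_of_evidence.level_label,
                }
            ),
            "sub_level": [_assertion_to_obj(a) for a in c.sub_level],
        },
        "extensions": dict(record.extensions),
    }
    return obj


def record_from_obj(obj: dict) -> MVLDRecord:
    """Rebuild a record from its JSON mapping (unchecked: the validator, not
    the parser, is the arbiter of conformance)."""
    d = obj.get("descriptor", {})
    i = obj.get("interpretation", {})
    c = obj.get("cancer", {})
    ct = c.get("cancer_type")
    eff = c.get("effect")
    loe = c.get("level_of_evidence")
    return MVLDRecord.build_unchecked(
        descriptor=AlleleDescriptor.build_unchecked(
            genome_build=d.get("genome_build"),
            gene_symbol=d.get("gene_symbol"),
            chromosome=d.get("chromosome"),
            genomic_position=d.get("genomic_position"),
            transcripts=tuple(d.get("transcripts", [])),
            protein_id=d.get("protein_id"),
        ),
        interpretation=AlleleInterpretation.build_unchecked(
            somatic_classification=i.get("somatic_classification"),
            dna_hgvs=i.get("dna_hgvs"),
            protein_hgvs=i.get("protein_hgvs"),
            variant_type=i.get("variant_type"),
            variant_consequence=i.get("variant_consequence"),
            pmids=tuple(int(p) for p in i.get("pmids", [])),
        ),
        cancer=CancerInterpretation.build_unchecked(
            cancer_type=(
                None
                if ct is None
                else OntologyTerm.build_unchecked(
                    source=ct.get("source"), code=ct.get("code"), label=ct.get("label", "")
                )
            ),
            biomarker_class=c.get("biomarker_class"),
            therapeutic_context=tuple(c.get("therapeutic_context", [])),
            effect=(
                None
                if eff is None
                else Effect.build_unchecked(
                    term=eff.get("term"), free_text=eff.get("free_text", "")
                )
            ),
            level_of_evidence=(
                None
                if loe is None
                else LevelOfEvidence.build_unchecked(
                    schema_name=loe.get("schema_name"), level_label=loe.get("level_label")
                )
            ),
            sub_level=tuple(_assertion_from_obj(a) for a in c.get("sub_level", [])),
        ),
        extensions={str(k): str(v) for k, v in obj.get("extensions", {}).items()},
    )


def write_mvld_json(records: Sequence[MVLDRecord], target: str | Path | TextIO) -> None:
    doc = {"mvld_version": MVLD_VERSION, "records": [record_to_obj(r) for r in records]}
    stream, should_close = _open_text(target, "w")
    try:
        json.dump(doc, stream, indent=2)
        stream.write("\n")
    finally:
        if should_close:
            stream.close()


def read_mvld_json(
    source: str | Path | TextIO, profile: str = "submission"
) -> tuple[list[MVLDRecord], ValidationReport]:
    stream, should_close = _open_text(source)
    try:
        try:
            doc = json.load(stream)
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise MvldReadError(f"unreadable JSON input: {exc}") from exc
    finally:
        if should_close:
            stream.close()
    if not isinstance(doc, dict) or "records" not in doc:
        raise MvldReadError('MVLD JSON must be an object with a "records" array')

    findings: list[ValidationFinding] = []
    records: list[MVLDRecord] = []
    for k, obj in enumerate(doc["records"]):
        try:
            record = record_from_obj(obj)
        except (ValueError, KeyError, TypeError) as exc:
            findings.append(
                ValidationFinding(
                    "error", "IO.ROW_SKIPPED", f"records[{k}]",
                    f"record {k} could not be structured: {exc}",
                )
            )
            continue
        idx = len(records)
        records.append(record)
        for f in validate_record(record, profile).findings:
            findings.append(
                ValidationFinding(f.severity, f.rule_id, f.field_path, f.message, idx)
            )
    return records, ValidationReport(tuple(findings))


# ---------------------------------------------------------------------------
# ClinVar-style export

CLINVAR_COLUMNS: tuple[str, ...] = (
    "gene_symbol",
    "genome_build",
    "chromosome",
    "genomic_position",
    "refseq_transcripts",
    "refseq_protein",
    "dna_hgvs",
    "protein_hgvs",
    "somatic_classification",
    "variant_type",
    "variant_consequence",
    "condition",
    "clinical_significance",
    "assertion_method",
    "citations",
)


@dataclass(frozen=True)
class ClinVarRow:
    """One flat ClinVar-submission-style row; ``values`` is keyed by
    :data:`CLINVAR_COLUMNS`."""

    values: dict[str, str] = dc_field(default_factory=dict)

    def __getitem__(self, key: str) -> str:
        return self.values[key]


def _render_significance(record: MVLDRecord) -> str:
    c = record.cancer
    parts = [c.biomarker_class or ""]
    if c.effect is not None:
        parts.append(f"effect: {_render_effect(c.effect)}")
    if c.therapeutic_context:
        parts.append("therapeutic context: " + "; ".join(c.therapeutic_context))
    return " | ".join(p for p in parts if p)


def to_clinvar_row(record: MVLDRecord) -> ClinVarRow:
    """Flatten a conformant record into a ClinVar-submission-style row.

    The record must carry zero errors under the ``submission`` profile;
    otherwise :class:`ConversionError` lists the blocking findings.  The
    level of evidence is rendered into the assertion-method field (for the
    built-in CanDL scheme the structured tier sentence is appended), and the
    cancer type renders as ``source:code (label)``.
    """
    report = validate_record(record, "submission")
    if not report.ok:
        raise ConversionError(report.errors())
    d, i, c = record.descriptor, record.interpretation, record.cancer

    loe = c.level_of_evidence
    assertion_method = f"{loe.schema_name}: {loe.level_label}"
    if loe.schema_name == "CanDL":
        tier = int(loe.level_label.split()[-1])
        assertion_method += f" - {TIER_SENTENCES[tier]}"

    citations = [f"PMID:{p}" for p in i.pmids]
    for a in c.sub_level:
        citations.extend(a.trial_ids)

    values = {
        "gene_symbol": d.gene_symbol or "",
        "genome_build": d.genome_build or "",
        "chromosome": d.chromosome or "",
        "genomic_position": "" if d.genomic_position is None else str(d.genomic_position),
        "refseq_transcripts": ";".join(d.transcripts),
        "refseq_protein": d.protein_id or "",
        "dna_hgvs": i.dna_hgvs or "",
        "protein_hgvs": i.protein_hgvs or "",
        "somatic_classification": i.somatic_classification or "",
        "variant_type": i.variant_type or "",
        "variant_consequence": i.variant_consequence or "",
        "condition": _render_ontology(c.cancer_type),
        "clinical_significance": _render_significance(record),
        "assertion_method": assertion_method,
        "citations": ";".join(citations),
    }
    return ClinVarRow(values)


def from_clinvar_row(row: ClinVarRow) -> MVLDRecord:
    """Reconstruct the required MVLD fields from an exported row."""
    v = row.values
    descriptor = AlleleDescriptor(
        genome_build=v.get("genome_build") or None,
        gene_symbol=v.get("gene_symbol") or None,
        chromosome=v.get("chromosome") or None,
        genomic_position=int(v["genomic_position"]) if v.get("genomic_position") else None,
        transcripts=tuple(t for t in v.get("refseq_transcripts", "").split(";") if t),
        protein_id=v.get("refseq_protein") or None,
    )
    pmids = tuple(
        int(tok.split(":", 1)[1])
        for tok in v.get("citations", "").split(";")
        if tok.startswith("PMID:")
    )
    interpretation = AlleleInterpretation(
        somatic_classification=v.get("somatic_classification") or None,
        dna_hgvs=v.get("dna_hgvs") or None,
        protein_hgvs=v.get("protein_hgvs") or None,
        variant_type=v.get("variant_type") or None,
        variant_consequence=v.get("variant_consequence") or None,
        pmids=pmids,
    )
    method = v.get("assertion_method", "")
    level = None
    if method:
        head = method.split(" - ", 1)[0]
        schema, _, label = head.partition(": ")
        level = LevelOfEvidence(schema_name=schema.strip(), level_label=label.strip())
    significance = v.get("clinical_significance", "")
    biomarker = significance.split(" | ", 1)[0].strip() or None
    cancer = CancerInterpretation(
        cancer_type=_parse_ontology(v.get("condition", "")),
        biomarker_class=biomarker,
        level_of_evidence=level,
    )
    return MVLDRecord(descriptor=descriptor, interpretation=interpretation, cancer=cancer)


def write_clinvar_table(records: Sequence[MVLDRecord], target: str | Path | TextIO) -> None:
    """Export a corpus as a tab-separated ClinVar-style table; refuses (and
    writes nothing) if any record fails submission-profile validation."""
    rows = [to_clinvar_row(r) for r in records]  # may raise ConversionError
    stream, should_close = _open_text(target, "w")
    try:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(CLINVAR_COLUMNS)
        for row in rows:
            writer.writerow([row.values.get(col, "") for col in CLINVAR_COLUMNS])
    finally:
        if should_close:
            stream.close()
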