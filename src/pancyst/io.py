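"""Readers and writers for case tables, variant tables and diagnosis reports.

Case and variant tables are plain TSV/CSV; missing cells map to the explicit
missing/unknown states of the domain model and are never imputed, so that
classifier steps with absent inputs can be skipped rather than guessed.
Reports are versioned JSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from .types import (
    Assay,
    Cytology,
    CystCase,
    Diagnosis,
    DxLabel,
    DysplasiaGrade,
    EusImpression,
    GradeFlag,
    PathologyDx,
    RuleRecord,
    SomaticStatus,
    Tristate,
    VariantCall,
    Viscosity,
)

REPORT_SCHEMA_VERSION = 1

#: Synonyms accepted in input tables, mapped onto canonical enum values.
#: Abbreviations follow common cytopathology report usage ("A/S" for
#: atypical/suspicious, "PDA" for ductal adenocarcinoma, "CP" for chronic
#: pancreatitis pseudocysts).
CYTOLOGY_SYNONYMS = {
    "ND": Cytology.ND,
    "NON-DIAGNOSTIC": Cytology.ND,
    "NONDIAGNOSTIC": Cytology.ND,
    "NEG": Cytology.NEG,
    "NEGATIVE": Cytology.NEG,
    "A/S": Cytology.ATY_SUS,
    "ATY/SUS": Cytology.ATY_SUS,
    "ATY_SUS": Cytology.ATY_SUS,
    "ATYPICAL": Cytology.ATY_SUS,
    "SUSPICIOUS": Cytology.ATY_SUS,
    "POS": Cytology.POS,
    "POSITIVE": Cytology.POS,
    "MISSING": Cytology.MISSING,
}

PATHOLOGY_SYNONYMS = {
    "IPMN": PathologyDx.IPMN,
    "MCN": PathologyDx.MCN,
    "PDA": PathologyDx.PDAC,
    "PDAC": PathologyDx.PDAC,
    "SCA": PathologyDx.SCA,
    "PNET": PathologyDx.PNET,
    "PSEUDOCYST": PathologyDx.PSEUDOCYST,
    "PSEUDOCYST/CP": PathologyDx.PSEUDOCYST,
    "UNKNOWN": PathologyDx.UNKNOWN,
}

_CASE_COLUMNS = (
    "case_id", "pathology_dx", "grade", "cytology", "cea_ng_ml", "amylase_u_l",
    "cyst_size_mm", "mural_nodule", "viscosity", "eus_impression",
    "genes_tested", "algorithm_label", "molecular_label",
)


class TableFormatError(ValueError):
    """Raised when an input table has a malformed cell or structure."""


def _is_missing(cell: str | None) -> bool:
    return cell is None or cell.strip() in ("", "NA", ".")


def _parse_enum(cell: str, synonyms: dict, what: str, row: int):
    key = cell.strip().upper()
    if key not in synonyms:
        raise TableFormatError(f"row {row}: unrecognized {what} value {cell!r}")
    return synonyms[key]


def _parse_float(cell: str, what: str, row: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"row {row}: {what} is not numeric: {cell!r}") from None


def read_case_table(path: str | Path, dialect: str = "tsv") -> list[CystCase]:
    """Read one ``CystCase`` per row from a TSV/CSV case table.

    The header must contain at least ``case_id``; recognized columns populate
    the domain model, unrecognized columns are preserved verbatim in
    ``case.metadata``. Missing cells become explicit missing/unknown states.
    Row order is preserved. Duplicate case ids and malformed enum values are
    rejected with the offending row number.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    path = Path(path)
    cases: list[CystCase] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None or "case_id" not in reader.fieldnames:
            raise TableFormatError(f"{path}: header must contain a case_id column")
        extra_cols = [c for c in reader.fieldnames if c not in _CASE_COLUMNS]
        for i, row in enumerate(reader, start=2):  # 1-based, header is line 1
            cid = (row.get("case_id") or "").strip()
            if not cid:
                raise TableFormatError(f"row {i}: empty case_id")
            if cid in seen:
                raise TableFormatError(f"row {i}: duplicate case_id {cid!r}")
            seen.add(cid)
            kw: dict = {"case_id": cid}
            cell = row.get("pathology_dx")
            if not _is_missing(cell):
                kw["pathology_dx"] = _parse_enum(cell, PATHOLOGY_SYNONYMS, "pathology_dx", i)
            cell = row.get("grade")
            if not _is_missing(cell):
                kw["dysplasia_grade"] = _parse_enum(
                    cell, {g.value: g for g in DysplasiaGrade}, "grade", i)
            cell = row.get("cytology")
            if not _is_missing(cell):
                kw["cytology"] = _parse_enum(cell, CYTOLOGY_SYNONYMS, "cytology", i)
            for col, name in (("cea_ng_ml", "cea_ng_ml"),
                              ("amylase_u_l", "amylase_u_l"),
                              ("cyst_size_mm", "cyst_size_mm")):
                cell = row.get(col)
                if not _is_missing(cell):
                    kw[name] = _parse_float(cell, name, i)
            cell = row.get("mural_nodule")
            if not _is_missing(cell):
                kw["mural_nodule"] = _parse_enum(
                    cell, {t.value.upper(): t for t in Tristate}, "mural_nodule", i)
            cell = row.get("viscosity")
            if not _is_missing(cell):
                kw["viscosity"] = _parse_enum(
                    cell, {v.value.upper(): v for v in Viscosity}, "viscosity", i)
            cell = row.get("eus_impression")
            if not _is_missing(cell):
                kw["eus_impression"] = _parse_enum(
                    cell, {e.value.upper(): e for e in EusImpression}, "eus_impression", i)
            cell = row.get("genes_tested")
            if not _is_missing(cell):
                kw["genes_tested"] = frozenset(
                    g.strip().upper() for g in cell.split(";") if g.strip())
            for col, attr in (("algorithm_label", "algorithm_label"),
                              ("molecular_label", "molecular_label")):
                cell = row.get(col)
                if not _is_missing(cell):
                    kw[attr] = _parse_enum(
                        cell, {l.value.upper(): l for l in DxLabel}, col, i)
            kw["metadata"] = {c: row[c] for c in extra_cols if not _is_missing(row.get(c))}
            cases.append(CystCase(**kw))
    return cases


def write_case_table(cases: Iterable[CystCase], path: str | Path,
                     dialect: str = "tsv") -> None:
    """Write cases back to a table; inverse of :func:`read_case_table`."""
    sep = {"tsv": "\t", "csv": ","}[dialect]

    def fmt(val) -> str:
        if val is None:
            return ""
        if hasattr(val, "value"):
            return val.value
        return str(val)

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(_CASE_COLUMNS)
        for c in cases:
            grade = "" if c.dysplasia_grade == DysplasiaGrade.NA else c.dysplasia_grade.value
            cyt = "" if c.cytology == Cytology.MISSING else c.cytology.value
            writer.writerow([
                c.case_id,
                "" if c.pathology_dx == PathologyDx.UNKNOWN else c.pathology_dx.value,
                grade, cyt, fmt(c.cea_ng_ml), fmt(c.amylase_u_l), fmt(c.cyst_size_mm),
                "" if c.mural_nodule == Tristate.UNKNOWN else c.mural_nodule.value,
                "" if c.viscosity == Viscosity.UNKNOWN else c.viscosity.value,
                "" if c.eus_impression == EusImpression.UNKNOWN else c.eus_impression.value,
                ";".join(sorted(c.genes_tested)),
                fmt(c.algorithm_label), fmt(c.molecular_label),
            ])


def read_variant_table(path: str | Path, dialect: str = "tsv") -> dict[str, list[VariantCall]]:
    """Read a variant table into ``{case_id: [VariantCall, ...]}``.

    Columns: case_id, gene, protein_change, maf_percent, read_depth, assay,
    and optionally somatic_status.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    out: dict[str, list[VariantCall]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None or not {"case_id", "gene"} <= set(reader.fieldnames):
            raise TableFormatError(f"{path}: header must contain case_id and gene")
        for i, row in enumerate(reader, start=2):
            cid = (row.get("case_id") or "").strip()
            if not cid:
                raise TableFormatError(f"row {i}: empty case_id")
            kw: dict = {"gene": row["gene"].strip()}
            if not _is_missing(row.get("protein_change")):
                kw["protein_change"] = row["protein_change"].strip()
            if not _is_missing(row.get("maf_percent")):
                kw["maf_percent"] = _parse_float(row["maf_percent"], "maf_percent", i)
            if not _is_missing(row.get("read_depth")):
                kw["read_depth"] = int(_parse_float(row["read_depth"], "read_depth", i))
            if not _is_missing(row.get("assay")):
                kw["assay"] = _parse_enum(row["assay"], {a.value: a for a in Assay}, "assay", i)
            if not _is_missing(row.get("somatic_status")):
                kw["somatic_status"] = _parse_enum(
                    row["somatic_status"],
                    {s.value.upper(): s for s in SomaticStatus}, "somatic_status", i)
            out.setdefault(cid, []).append(VariantCall(**kw))
    return out


def read_vcf_variants(path: str | Path, case_id: str) -> dict[str, list[VariantCall]]:
    """Read variant calls for one case from a minimal annotated VCF.

    Gene and protein change are taken from the INFO field (``GENE``/``HGVSP``
    keys, or the first ANN entry), allele fraction from ``AF`` (scaled to
    percent), depth from ``DP``.
    """
    from cyvcf2 import VCF

    calls: list[VariantCall] = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        gene = info.get("GENE")
        hgvsp = info.get("HGVSP")
        if gene is None and "ANN" in info:
            ann = str(info["ANN"]).split("|")
            gene = ann[3] if len(ann) > 3 else None
            hgvsp = ann[10] if len(ann) > 10 else None
        if gene is None:
            continue
        af = info.get("AF")
        dp = info.get("DP")
        calls.append(VariantCall(
            gene=str(gene),
            protein_change=str(hgvsp) if hgvsp else "p.?",
            maf_percent=float(af) * 100.0 if af is not None else None,
            read_depth=int(dp) if dp is not None else None,
            assay=Assay.NGS,
            somatic_status=SomaticStatus.UNREVIEWED,
        ))
    return {case_id: calls}


def attach_variants(cases: Iterable[CystCase],
                    variants: dict[str, list[VariantCall]]) -> list[CystCase]:
    """Attach variant calls to their cases (matching on case_id), in place."""
    cases = list(cases)
    by_id = {c.case_id: c for c in cases}
    for cid, calls in variants.items():
        if cid not in by_id:
            raise TableFormatError(f"variant table references unknown case_id {cid!r}")
        case = by_id[cid]
        case.variants = case.variants + calls
        for v in calls:
            if v.gene not in case.genes_tested:
                raise ValueError(
                    f"case {cid}: variant in {v.gene} but gene not in genes_tested")
    return cases


def write_report(diagnoses: Iterable[Diagnosis], path: str | Path) -> dict:
    """Write a machine-readable diagnosis report (versioned JSON)."""
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "cases": [
            {
                "case_id": d.case_id,
                "label": d.label.value,
                "grade_flag": d.grade_flag.value,
                "rationale": [
                    {"rule": r.rule, "fired": r.fired, "evidence": r.evidence}
                    for r in d.rationale
                ],
            }
            for d in diagnoses
        ],
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return doc


def read_report(path: str | Path) -> list[Diagnosis]:
    """Inverse of :func:`write_report`."""
    with Path(path).open() as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise TableFormatError(f"unsupported report schema: {doc.get('schema_version')}")
    return [
        Diagnosis(
            case_id=entry["case_id"],
            label=DxLabel(entry["label"]),
            grade_flag=GradeFlag(entry["grade_flag"]),
            rationale=[RuleRecord(r["rule"], r["fired"], r["evidence"])
                       for r in entry["rationale"]],
        )
        for entry in doc["cases"]
    ]
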