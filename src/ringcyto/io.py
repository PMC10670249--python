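"""Tabular input/output: patient karyotype TSVs, variant tables, FISH columns.

The on-disk formats are deliberately plain: UTF-8 delimited text with one
patient or one variant per row, readable by any spreadsheet. Boolean flag
columns accept 1/0, true/false, yes/no (case-insensitive).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .iscn_core import Karyotype, parse_karyotype
from .variant_integration import PatientRecord, VariantCall

__all__ = [
    "read_patient_table",
    "read_variant_table",
    "assemble_cohort",
    "cohort_to_tables",
    "write_cohort",
    "read_cohort",
]

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}

VARIANT_COLUMNS = [
    "patient_id",
    "gene",
    "genomic_change",
    "protein_change",
    "vaf",
    "alt_reads_fwd",
    "alt_reads_rev",
    "mean_qscore",
    "known_cancer_flag",
    "damaging_flag",
    "effect_hint",
]


def _parse_flag(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (bool,)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return None if s == "" else False
    raise ValueError(f"unrecognized boolean flag value: {value!r}")


def read_patient_table(path: Union[str, Path], sep: str = "\t") -> pd.DataFrame:
    """Read a patient TSV: patient_id, diagnosis, karyotype[, fish_patterns].

    The karyotype column is parsed; a ``parsed`` column of Karyotype objects is
    added. ``fish_patterns`` is an optional comma-separated column.
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"patient_id", "karyotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patient table missing columns: {sorted(missing)}")
    df["parsed"] = [parse_karyotype(s) for s in df["karyotype"]]
    return df


def read_variant_table(path: Union[str, Path], sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    required = {"patient_id", "gene", "genomic_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return df


def _row_to_variant(row: Dict[str, str]) -> VariantCall:
    def num(key, cast):
        v = row.get(key, "")
        if v is None or str(v).strip() == "":
            return None
        return cast(float(v)) if cast is int else cast(v)

    return VariantCall(
        gene=row["gene"],
        genomic_change=row["genomic_change"],
        protein_change=row.get("protein_change") or None,
        vaf=num("vaf", float),
        alt_reads_fwd=num("alt_reads_fwd", int),
        alt_reads_rev=num("alt_reads_rev", int),
        mean_qscore=num("mean_qscore", float),
        known_cancer_flag=_parse_flag(row.get("known_cancer_flag")),
        damaging_flag=_parse_flag(row.get("damaging_flag")),
        effect_hint=row.get("effect_hint") or None,
    )


def assemble_cohort(
    patients: pd.DataFrame, variants: Optional[pd.DataFrame] = None
) -> List[PatientRecord]:
    """Join a parsed patient table with a variant table on patient_id.

    Patients absent from the variant table are treated as lacking NGS data;
    to mark a sequenced patient with zero variants, include a row whose gene
    field is empty.
    """
    var_by_patient: Dict[str, List[VariantCall]] = {}
    if variants is not None:
        for _, row in variants.iterrows():
            pid = row["patient_id"]
            bucket = var_by_patient.setdefault(pid, [])
            if str(row.get("gene", "")).strip():
                bucket.append(_row_to_variant(dict(row)))
    records: List[PatientRecord] = []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        fish = None
        raw_fish = str(row.get("fish_patterns", "") or "").strip()
        if raw_fish:
            fish = tuple(s for s in raw_fish.split(",") if s)
        vlist = var_by_patient.get(pid)
        records.append(
            PatientRecord(
                patient_id=pid,
                diagnosis=str(row.get("diagnosis", "") or ""),
                karyotype=row["parsed"],
                variants=tuple(vlist) if vlist is not None else None,
                fish_patterns=fish,
            )
        )
    return records


def cohort_to_tables(records: Sequence[PatientRecord]) -> Dict[str, pd.DataFrame]:
    """Flatten PatientRecords to patient and variant DataFrames."""
    prows = []
    vrows = []
    for r in records:
        prows.append(
            {
                "patient_id": r.patient_id,
                "diagnosis": r.diagnosis,
                "karyotype": str(r.karyotype) if r.karyotype is not None else "",
                "fish_patterns": ",".join(r.fish_patterns or ()),
            }
        )
        for v in r.variants or ():
            vrows.append(
                {
                    "patient_id": r.patient_id,
                    "gene": v.gene,
                    "genomic_change": v.genomic_change,
                    "protein_change": v.protein_change or "",
                    "vaf": v.vaf,
                    "alt_reads_fwd": v.alt_reads_fwd,
                    "alt_reads_rev": v.alt_reads_rev,
                    "mean_qscore": v.mean_qscore,
                    "known_cancer_flag": v.known_cancer_flag,
                    "damaging_flag": v.damaging_flag,
                    "effect_hint": v.effect_hint or "",
                }
            )
        if r.has_ngs and not (r.variants or ()):
            vrows.append({"patient_id": r.patient_id, "gene": "", "genomic_change": ""})
    return {
        "patients": pd.DataFrame(prows),
        "variants": pd.DataFrame(vrows, columns=VARIANT_COLUMNS),
    }


def write_cohort(
    records: Sequence[PatientRecord],
    outdir: Union[str, Path],
    ledger: Optional[Sequence[dict]] = None,
) -> Dict[str, Path]:
    """Write patient TSV, variant TSV, and optional ledger JSON to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = cohort_to_tables(records)
    paths = {
        "patients": outdir / "patients.tsv",
        "variants": outdir / "variants.tsv",
    }
    tables["patients"].to_csv(paths["patients"], sep="\t", index=False)
    tables["variants"].to_csv(paths["variants"], sep="\t", index=False)
    if ledger is not None:
        paths["ledger"] = outdir / "ledger.json"
        paths["ledger"].write_text(json.dumps(list(ledger), indent=1))
    return paths


def read_cohort(
    patients_path: Union[str, Path], variants_path: Optional[Union[str, Path]] = None
) -> List[PatientRecord]:
    patients = read_patient_table(patients_path)
    variants = read_variant_table(variants_path) if variants_path else None
    return assemble_cohort(patients, variants)
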