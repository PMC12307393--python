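"""Readers, writers and cohort alignment for the delimited formats the tool uses.

All tables are plain TSV/CSV (sniffed from the header line). Gene and sample
IDs are opaque strings. Grade and stage strings from the common source-dataset
dialects are normalized through explicit dictionaries documented below.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, Platform

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "align_cohort",
    "read_mutations",
    "read_segments",
    "read_cytobands",
    "GRADE_DIALECTS",
    "STAGE_DIALECTS",
]

#: Source-dataset grade dialects -> canonical grade. Anything not listed maps
#: to "missing" with a logged warning (e.g. "GX", "GB").
GRADE_DIALECTS = {
    "g1": "G1", "1": "G1", "i": "G1", "i/1": "G1", "grade 1": "G1", "low": "G1",
    "g2": "G2", "2": "G2", "ii": "G2", "ii/2": "G2", "grade 2": "G2", "intermediate": "G2",
    "g3": "G3", "3": "G3", "iii": "G3", "iii/3": "G3", "grade 3": "G3", "high": "G3",
    "g4": "G4", "4": "G4", "iv": "G4", "iv/4": "G4", "grade 4": "G4",
}

#: Stage dialects -> canonical stage (sub-stages collapse to their main stage).
STAGE_DIALECTS = {
    "i": "I", "1": "I", "ia": "I", "ib": "I", "stage i": "I", "i/1": "I",
    "ii": "II", "2": "II", "iia": "II", "iib": "II", "stage ii": "II", "ii/2": "II",
    "iii": "III", "3": "III", "iiia": "III", "iiib": "III", "iiic": "III",
    "stage iii": "III", "iii/3": "III",
    "iv": "IV", "4": "IV", "iva": "IV", "ivb": "IV", "stage iv": "IV", "iv/4": "IV",
}

_NODE_DIALECTS = {
    "n0": "negative", "negative": "negative", "0": "negative",
    "n1": "positive", "n2": "positive", "n3": "positive",
    "positive": "positive", "1": "positive",
}


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_expression(path, platform: Platform | str = Platform.MICROARRAY) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    First column holds gene IDs, the header row sample IDs. Blank and NA
    cells become NaN (kept as missing, never imputed). Duplicate IDs and
    non-numeric cells are hard errors.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene ID {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    values = df.apply(pd.to_numeric, errors="coerce")
    # anything that coerced to NaN but was not blank/NA to begin with is bad input
    na_tokens = df.isna() | df.apply(lambda c: c.str.strip().str.upper().isin(["", "NA", "NAN", "NULL"]))
    bad = values.isna() & ~na_tokens
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[gi, si]!r} at gene "
            f"{df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    values = values.astype(float)
    values.index.name = None
    values.columns.name = None
    return ExpressionMatrix(values, Platform(platform))


def write_expression(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, na_rep="NA")


def _normalize_grade(raw) -> str:
    if pd.isna(raw) or str(raw).strip() == "":
        return "missing"
    key = str(raw).strip().lower()
    if key in GRADE_DIALECTS:
        return GRADE_DIALECTS[key]
    logger.warning("unrecognized grade %r mapped to missing", raw)
    return "missing"


def _normalize_stage(raw) -> str:
    if pd.isna(raw) or str(raw).strip() == "":
        return "missing"
    key = str(raw).strip().lower()
    return STAGE_DIALECTS.get(key, "missing")


def _normalize_node(raw):
    if pd.isna(raw) or str(raw).strip() == "":
        return "missing"
    return _NODE_DIALECTS.get(str(raw).strip().lower(), "missing")


def read_clinical(path) -> ClinicalTable:
    """Read a per-sample clinical table.

    Required columns: ``sample_id``, ``os_time``, ``os_event``. Optional:
    ``grade``, ``stage``, ``cohort``, ``lymph_node_status`` (absent columns
    fill with "missing"). Grade/stage dialects are normalized; unknown grades
    become "missing" with a warning. Negative survival times are rejected.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame(index=df["sample_id"].astype(str))
    out.index.name = "sample_id"
    out["grade"] = [_normalize_grade(g) for g in df.get("grade", pd.Series(index=df.index, dtype=object))]
    out["os_time"] = pd.to_numeric(df["os_time"], errors="coerce").to_numpy()
    out["os_event"] = pd.to_numeric(df["os_event"], errors="coerce").to_numpy()
    out["stage"] = [_normalize_stage(s) for s in df.get("stage", pd.Series(index=df.index, dtype=object))]
    out["cohort"] = df.get("cohort", pd.Series("cohort0", index=df.index)).astype(str).values
    out["lymph_node_status"] = [
        _normalize_node(v) for v in df.get("lymph_node_status", pd.Series(index=df.index, dtype=object))
    ]
    return ClinicalTable(out)


def write_clinical(clin: ClinicalTable, path, sep: str = "\t") -> None:
    clin.data.to_csv(path, sep=sep, na_rep="NA")


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict expression and clinical tables to their common samples.

    Order follows the expression matrix. Idempotent; empty intersection is a
    hard error.
    """
    clin_set = set(clin.sample_ids)
    shared = [s for s in expr.sample_ids if s in clin_set]
    if not shared:
        raise ValueError("no samples shared between expression and clinical tables")
    n_drop_expr = expr.n_samples - len(shared)
    n_drop_clin = len(clin.sample_ids) - len(shared)
    if n_drop_expr or n_drop_clin:
        logger.info(
            "align_cohort: dropped %d expression-only and %d clinical-only samples",
            n_drop_expr, n_drop_clin,
        )
    return expr.subset_samples(shared), clin.subset(shared)


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-like somatic mutation table.

    Required columns (case-insensitive aliases accepted): sample_id
    (Tumor_Sample_Barcode), gene (Hugo_Symbol), variant_classification, vaf.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    rename = {}
    for col in df.columns:
        lc = col.lower()
        if lc in ("tumor_sample_barcode", "sample", "sample_id"):
            rename[col] = "sample_id"
        elif lc in ("hugo_symbol", "gene", "gene_symbol"):
            rename[col] = "gene"
        elif lc in ("variant_classification", "classification"):
            rename[col] = "variant_classification"
        elif lc in ("vaf", "tumor_vaf", "t_vaf", "allele_frequency"):
            rename[col] = "vaf"
    df = df.rename(columns=rename)
    for col in ("sample_id", "gene", "variant_classification", "vaf"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mutation column {col!r}")
    df["vaf"] = df["vaf"].astype(float)
    if ((df["vaf"] < 0) | (df["vaf"] > 1)).any():
        raise ValueError(f"{path}: VAF outside [0, 1]")
    return df[["sample_id", "gene", "variant_classification", "vaf"]]


def read_segments(path, one_based: bool = False) -> pd.DataFrame:
    """Read a SEG-like copy-number segment table.

    Columns: sample_id, chrom, start, end, total_cn, ploidy. Coordinates are
    stored 0-based half-open; pass ``one_based=True`` for SEG-style 1-based
    closed input (start is shifted down by one).
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    for col in ("sample_id", "chrom", "start", "end", "total_cn", "ploidy"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing segment column {col!r}")
    df = df.copy()
    if one_based:
        df["start"] = df["start"].astype(int) - 1
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: segment with end <= start (coordinate convention mismatch?)")
    return df


def read_cytobands(path) -> pd.DataFrame:
    """Read a BED-like cytoband annotation (0-based half-open): chrom, start, end, name."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: cytoband BED needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "name"]
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: cytoband with end <= start")
    return df
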