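"""Core data types and readers/writers for methylation-array data.

In-memory containers are pandas DataFrames:

* **beta matrix** — probes x samples, ``float`` beta values in ``[0, 1]``
  (methylated signal fraction), index named ``probe_id``, ``NaN`` for
  missing measurements.
* **M-value matrix** — same shape/ordering, unbounded log2-ratio scale.
* **probe annotation** — indexed by ``probe_id`` with columns
  ``gene_symbol``, ``region_category`` (TSS1500/Promoter/Body/UTR3),
  ``cpg_class`` (island/shore/poor), ``prc2_target``, ``known_snp``.
* **sample sheet** — one row per sample with tissue type, the four IHC
  markers used by the St Gallen 2013 surrogate rules (ER, PgR %, Ki-67 %,
  HER2) and optional clinicopathologic fields (size, grade, node, relapse).

Validation is strict: out-of-range beta values and unknown category labels
raise :class:`ValidationError` naming the offending entries rather than
being silently coerced.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

REGION_CATEGORIES = ("TSS1500", "Promoter", "Body", "UTR3")
CPG_CLASSES = ("island", "shore", "poor")
SUBTYPES = ("LumA", "LumB", "LumB_HER2")

SAMPLE_SHEET_COLUMNS = [
    "sample_id", "tissue", "er", "pgr_percent", "ki67_percent", "her2",
    "size_cm", "grade", "node", "relapse",
]
ANNOTATION_COLUMNS = [
    "probe_id", "gene_symbol", "region_category", "cpg_class",
    "prc2_target", "known_snp",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant."""


class NotLuminalError(ValueError):
    """St Gallen surrogate subtyping requested outside the ER+ context."""


# ---------------------------------------------------------------------------
# beta matrix


def validate_beta_matrix(beta: pd.DataFrame) -> pd.DataFrame:
    """Check beta-matrix invariants, returning the validated frame.

    Raises :class:`ValidationError` listing (probe, sample) cells outside
    [0, 1], or on duplicated probe/sample identifiers. NaN is allowed
    (missing measurement).
    """
    if beta.index.duplicated().any():
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated probe_ids: {dups[:10]}")
    if beta.columns.duplicated().any():
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated sample_ids: {dups[:10]}")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0.0) | (vals > 1.0)
    if bad.any():
        rows, cols = np.nonzero(bad)
        cells = [
            f"({beta.index[r]}, {beta.columns[c]})={vals[r, c]:g}"
            for r, c in list(zip(rows, cols))[:10]
        ]
        raise ValidationError(
            f"{bad.sum()} beta value(s) outside [0, 1]: " + ", ".join(cells)
        )
    beta.index.name = "probe_id"
    return beta


def read_beta_matrix(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a probes-x-samples beta matrix.

    Parameters
    ----------
    path
        File path.
    dialect
        ``"tsv"`` — plain tab-separated table, first column ``probe_id``;
        ``"series_matrix"`` — GEO series-matrix export: metadata lines
        starting with ``!`` are skipped and the probe table is taken from
        between the ``!series_matrix_table_begin`` / ``_end`` markers,
        accepting quoted probe identifiers.
    """
    if dialect == "tsv":
        try:
            beta = pd.read_csv(path, sep="\t", index_col=0,
                               na_values=["NA"], keep_default_na=True)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"cannot parse beta TSV {path}: {exc}") from exc
    elif dialect == "series_matrix":
        beta = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    non_numeric = [c for c in beta.columns
                   if not pd.api.types.is_numeric_dtype(beta[c])]
    if non_numeric:
        raise ParseError(
            f"non-numeric sample column(s) in {path}: {non_numeric}")
    beta.index = beta.index.astype(str)
    beta.columns = beta.columns.astype(str)
    return validate_beta_matrix(beta)


def _read_series_matrix(path) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.readlines()
    begin = end = None
    for i, line in enumerate(lines):
        key = line.strip().lower()
        if key.startswith("!series_matrix_table_begin"):
            begin = i
        elif key.startswith("!series_matrix_table_end"):
            end = i
    if begin is None or end is None or end <= begin + 1:
        raise ParseError(
            f"{path}: series-matrix table_begin/table_end markers not found")
    table = [l for l in lines[begin + 1:end] if not l.startswith("!")]
    from io import StringIO

    df = pd.read_csv(StringIO("".join(table)), sep="\t", index_col=0,
                     na_values=["NA", "null"], quotechar='"')
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return df


def write_beta_matrix(beta: pd.DataFrame, path) -> None:
    """Write the plain-TSV dialect (``NA`` for missing)."""
    out = beta.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# probe annotation


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann.index.duplicated().any():
        raise ValidationError("duplicated probe_ids in annotation")
    bad_region = set(ann["region_category"]) - set(REGION_CATEGORIES)
    if bad_region:
        raise ValidationError(f"unknown region_category values: {bad_region}")
    bad_class = set(ann["cpg_class"]) - set(CPG_CLASSES)
    if bad_class:
        raise ValidationError(f"unknown cpg_class values: {bad_class}")
    ann = ann.copy()
    ann["prc2_target"] = ann["prc2_target"].astype(bool)
    ann["known_snp"] = ann["known_snp"].astype(bool)
    ann.index.name = "probe_id"
    return ann


def read_annotation(path) -> pd.DataFrame:
    """Read a 27K-style flat annotation CSV (see :data:`ANNOTATION_COLUMNS`)."""
    ann = pd.read_csv(path, index_col="probe_id")
    missing = set(ANNOTATION_COLUMNS[1:]) - set(ann.columns)
    if missing:
        raise ParseError(f"annotation {path} missing columns: {sorted(missing)}")
    ann.index = ann.index.astype(str)
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, index=True)


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet CSV; booleans encoded as True/False or 1/0."""
    sheet = pd.read_csv(path)
    missing = set(SAMPLE_SHEET_COLUMNS[:6]) - set(sheet.columns)
    if missing:
        raise ParseError(f"sample sheet {path} missing columns: {sorted(missing)}")
    for col in ("er", "her2"):
        sheet[col] = sheet[col].astype(bool)
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample_ids in sample sheet")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index=False)


def match_identifiers(beta: pd.DataFrame, annotation: pd.DataFrame | None,
                      sheet: pd.DataFrame | None) -> dict:
    """Report identifier mismatches between matrix, annotation and sheet.

    Matching is strict string equality; nothing is dropped here — the
    report lets callers decide.
    """
    report: dict[str, list[str]] = {}
    if annotation is not None:
        report["probes_without_annotation"] = sorted(
            set(beta.index) - set(annotation.index))
        report["annotation_without_probe"] = sorted(
            set(annotation.index) - set(beta.index))
    if sheet is not None:
        report["samples_without_record"] = sorted(
            set(beta.columns) - set(sheet["sample_id"]))
        report["records_without_sample"] = sorted(
            set(sheet["sample_id"]) - set(beta.columns))
    return report


# ---------------------------------------------------------------------------
# St Gallen 2013 surrogate subtyping


def assign_st_gallen_subtype(er: bool, pgr_percent: float,
                             ki67_percent: float, her2: bool) -> str:
    """Assign the St Gallen 2013 IHC surrogate subtype of an ER+ tumor.

    Rules (luminal context only):

    * HER2-positive, any PgR, any Ki-67 → ``LumB_HER2``
    * HER2-negative, PgR >= 20 % and Ki-67 < 20 % → ``LumA``
    * HER2-negative, Ki-67 >= 20 % or PgR < 20 % → ``LumB``

    Both thresholds are inclusive on the high side exactly as printed:
    Ki-67 of 20 % is high (LumB), PgR of 20 % is high (compatible with LumA).
    """
    if er is None or her2 is None or pgr_percent is None or ki67_percent is None:
        raise ValidationError("missing IHC marker for subtype assignment")
    if isinstance(pgr_percent, float) and math.isnan(pgr_percent):
        raise ValidationError("missing PgR value")
    if isinstance(ki67_percent, float) and math.isnan(ki67_percent):
        raise ValidationError("missing Ki-67 value")
    if not er:
        raise NotLuminalError("sample is ER-negative: not a luminal tumor")
    if not (0 <= pgr_percent <= 100 and 0 <= ki67_percent <= 100):
        raise ValidationError("PgR/Ki-67 percentages must be in [0, 100]")
    if her2:
        return "LumB_HER2"
    if pgr_percent >= 20 and ki67_percent < 20:
        return "LumA"
    return "LumB"


def assign_subtypes(sheet: pd.DataFrame) -> pd.Series:
    """Vectorized subtype assignment for tumor rows; normals get ``"NA"``."""
    out = []
    for _, row in sheet.iterrows():
        if row["tissue"] != "tumor":
            out.append("NA")
        else:
            out.append(assign_st_gallen_subtype(
                row["er"], row["pgr_percent"], row["ki67_percent"], row["her2"]))
    return pd.Series(out, index=sheet.index, name="subtype")
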