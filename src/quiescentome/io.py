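"""TSV/GMT readers and writers for every pipeline artefact.

All tables are tab-separated with a header row; gene symbols are the join key
across files and matching is case-sensitive unless ``case_fold`` is requested
at load. Writers can prepend a ``# config_hash=...`` comment declaring the
generating configuration; readers skip ``#`` comment lines.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .synthdata import validate_annotations
from .types import ExpressionMatrix, GeneSetCollection, ValidationError, validate_edges


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, index: bool, comment: str | None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --- expression -------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, expr_path, samples_path,
                     comment: str | None = None) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    _write_tsv(out, expr_path, index=True, comment=comment)
    sheet = matrix.samples.copy()
    sheet.index.name = "sample"
    _write_tsv(sheet, samples_path, index=True, comment=comment)


def read_expression(expr_path, samples_path, case_fold: bool = False) -> ExpressionMatrix:
    raw = _read_tsv(expr_path, dtype={0: str})
    if raw.columns[0] != "gene":
        raise ValidationError(f"{expr_path}: first column must be 'gene', "
                              f"got {raw.columns[0]!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{expr_path}: duplicated sample column {dup!r}")
    values = raw.set_index("gene")
    if case_fold:
        values.index = values.index.str.upper()
    for col in values.columns:
        bad = pd.to_numeric(values[col], errors="coerce").isna() & values[col].notna()
        if bad.any():
            gene = values.index[bad][0]
            raise ValidationError(
                f"{expr_path}: non-numeric value at gene {gene!r}, sample {col!r}")
        values[col] = pd.to_numeric(values[col])
    samples = _read_tsv(samples_path).set_index("sample")
    return ExpressionMatrix(values, samples)


# --- gene sets (GMT) --------------------------------------------------------

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "na")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields (< 3)")
            name, desc, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} "
                                      f"(line {lineno})")
            sets[name] = set(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# --- edges / annotations / cell profiles ------------------------------------

def write_edges(edges: pd.DataFrame, path, comment: str | None = None) -> None:
    _write_tsv(edges, path, index=False, comment=comment)


def read_edges(path) -> pd.DataFrame:
    return validate_edges(_read_tsv(path))


def write_annotations(ann: pd.DataFrame, path, comment: str | None = None) -> None:
    _write_tsv(ann, path, index=False, comment=comment)


def read_annotations(path, genes=None) -> pd.DataFrame:
    ann = _read_tsv(path)
    for col in ("gene", "class"):
        if col not in ann.columns:
            raise ValidationError(f"{path}: annotation table lacks {col!r}")
    if genes is not None:
        validate_annotations(ann, genes)
    return ann


def write_cell_profiles(profiles: pd.DataFrame, path, comment: str | None = None) -> None:
    out = profiles.copy()
    out.index.name = "gene"
    _write_tsv(out, path, index=True, comment=comment)


def read_cell_profiles(path) -> pd.DataFrame:
    raw = _read_tsv(path)
    if raw.columns[0] != "gene":
        raise ValidationError(f"{path}: first column must be 'gene'")
    prof = raw.set_index("gene")
    if prof.index.duplicated().any():
        dup = prof.index[prof.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate gene {dup!r}")
    if prof.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate cell-type column")
    return prof.astype(float)


# --- misc tables ------------------------------------------------------------

def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    _write_tsv(df, path, index=False, comment=comment)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_truth(truth_table: pd.DataFrame, path, comment: str | None = None) -> None:
    _write_tsv(truth_table, path, index=False, comment=comment)
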