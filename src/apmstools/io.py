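"""Readers and writers for the tabular formats the pipeline touches.

The quantification input is a FragPipe-style combined-protein TSV: one row
per protein, an accession column, optionally a gene column, and one MaxLFQ
intensity column per sample identified by a configurable suffix. A zero or
blank intensity cell means "not detected" — the standard LFQ convention —
and becomes a masked (missing) entry, never a measured zero.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    Condition,
    DesignError,
    FormatError,
    ProteinQuantTable,
    SampleInfo,
    StudyDesign,
)

__all__ = [
    "read_combined_protein_tsv",
    "write_combined_protein_tsv",
    "read_design",
    "write_design",
    "write_results_tsv",
    "read_results_tsv",
]

DEFAULT_INTENSITY_SUFFIX = "MaxLFQ Intensity"
_ID_COLUMNS = ("Protein ID", "Protein", "Protein.ID")
_GENE_COLUMNS = ("Gene", "Gene Symbol", "Gene Names")

#: serialisation precision for floats in results tables
_FLOAT_FORMAT = "%.6g"


def read_combined_protein_tsv(
    path: "str | Path",
    intensity_suffix: str = DEFAULT_INTENSITY_SUFFIX,
) -> ProteinQuantTable:
    """Read a combined-protein quantification TSV into a :class:`ProteinQuantTable`.

    Intensity columns are those whose header ends with *intensity_suffix*;
    the sample id is the header with the suffix (and separating whitespace)
    stripped. Zero and empty cells become missing entries. Column order of
    the file is preserved in ``sample_ids``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    id_col = next((c for c in _ID_COLUMNS if c in df.columns), None)
    if id_col is None:
        raise FormatError(
            f"{path}: no protein-identifier column; expected one of {_ID_COLUMNS} "
            f"in the header"
        )
    intensity_cols = [c for c in df.columns if c.endswith(intensity_suffix) and c != intensity_suffix]
    if not intensity_cols:
        raise FormatError(
            f"{path}: no per-sample column matching suffix {intensity_suffix!r}"
        )
    protein_ids = df[id_col].astype(str).tolist()
    dup = sorted({p for p in protein_ids if protein_ids.count(p) > 1})
    if dup:
        raise FormatError(f"{path}: duplicate protein ids: {dup}")
    gene_col = next((c for c in _GENE_COLUMNS if c in df.columns), None)
    genes = df[gene_col].astype(str).tolist() if gene_col else [""] * len(protein_ids)

    sample_ids = [c[: -len(intensity_suffix)].rstrip(" _") for c in intensity_cols]
    raw = df[intensity_cols].replace("", "0")
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise FormatError(f"{path}: negative intensity values found")
    mask = values == 0.0
    return ProteinQuantTable(
        protein_ids=protein_ids,
        intensities=values,
        sample_ids=sample_ids,
        missing_mask=mask,
        gene_symbols=genes,
        scale_tag="linear",
    )


def write_combined_protein_tsv(
    table: ProteinQuantTable,
    path: "str | Path",
    intensity_suffix: str = DEFAULT_INTENSITY_SUFFIX,
) -> None:
    """Write a linear-scale table back in combined-protein layout (0 = missing)."""
    if table.scale_tag != "linear":
        raise ValueError("combined-protein files store linear-scale intensities")
    values = table.intensities.copy()
    values[table.missing_mask] = 0.0
    df = pd.DataFrame({"Protein ID": table.protein_ids, "Gene": table.gene_symbols})
    for j, s in enumerate(table.sample_ids):
        df[f"{s} {intensity_suffix}"] = values[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_design(path: "str | Path") -> StudyDesign:
    """Read a sample design table (CSV or TSV; sniffed from the header line).

    Required columns: ``sample_id``, ``condition``, ``replicate``; optional
    ``pair_id`` (blank = unpaired). Unknown condition strings, duplicate
    samples and incomplete GTPγS/GDPβS pairs are rejected.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"sample_id", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: design needs columns {sorted(required)}, got {list(df.columns)}"
        )
    samples = []
    for _, row in df.iterrows():
        try:
            replicate = int(row["replicate"])
        except ValueError:
            raise FormatError(
                f"{path}: replicate {row['replicate']!r} for sample "
                f"{row['sample_id']!r} is not an integer"
            ) from None
        pair = row.get("pair_id", "")
        samples.append(
            SampleInfo(
                sample_id=str(row["sample_id"]),
                condition=Condition.parse(row["condition"]),
                replicate=replicate,
                pair_id=str(pair) if str(pair) else None,
            )
        )
    return StudyDesign(samples)


def write_design(design: StudyDesign, path: "str | Path") -> None:
    design.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_results_tsv(table: pd.DataFrame, path: "str | Path") -> None:
    """Write a results table deterministically (fixed column order and precision)."""
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=_FLOAT_FORMAT,
        lineterminator="\n",
    )


def read_results_tsv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
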