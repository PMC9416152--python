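"""TSV / JSON readers and writers.

TSV is the interchange format: samples in rows, first column
``sample_id``. Missing metabolite values are written as empty cells and
read back from empty cells or "NA". OTU tables can also be exchanged as
BIOM-style sparse triplets (otu_id, sample_id, count). All writers
produce files their paired readers parse back to equal in-memory values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ConfigError,
    MetaboliteMatrix,
    OtuCountTable,
    ParseError,
    SampleMetadata,
    TREATMENTS,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_metabolite_matrix",
    "write_metabolite_matrix",
    "read_metadata",
    "write_metadata",
    "write_truth",
    "read_truth",
    "write_manifest",
]

_NA_VALUES = ["", "NA"]


def read_metadata(path, label_map: dict | None = None) -> SampleMetadata:
    """Read per-sample metadata (columns: treatment, core, replicate)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    frame = frame.set_index("sample_id")
    missing = {"treatment", "core", "replicate"} - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if label_map:
        frame["treatment"] = frame["treatment"].map(lambda t: label_map.get(t, t))
    unknown = set(frame["treatment"]) - set(TREATMENTS)
    if unknown:
        raise ParseError(
            f"{path}: unknown treatment labels {sorted(unknown)}; expected {TREATMENTS} "
            "(supply a label map to translate)"
        )
    frame["replicate"] = frame["replicate"].astype(int)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def _parse_count_frame(frame: pd.DataFrame, path) -> pd.DataFrame:
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values))
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: non-integer count at sample {row!r}, OTU {col!r}")
        if (values < 0).any():
            row = frame.index[(values < 0).to_numpy().argmax()]
            raise ParseError(f"{path}: negative count at sample {row!r}, OTU {col!r}")
        frame[col] = values.astype(np.int64)
    return frame


def read_otu_table(path, format: str = "wide", taxonomy_path=None) -> OtuCountTable:
    """Read an OTU count table from wide TSV or sparse-triplet TSV."""
    if format == "wide":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "sample_id" not in frame.columns:
            raise ParseError(f"{path}: missing 'sample_id' column")
        if frame["sample_id"].duplicated().any():
            raise ParseError(f"{path}: duplicate sample IDs")
        frame = frame.set_index("sample_id")
        if frame.columns.duplicated().any():
            raise ParseError(f"{path}: duplicate OTU IDs")
        counts = _parse_count_frame(frame, path)
    elif format == "sparse":
        trip = pd.read_csv(
            path, sep="\t", dtype={"otu_id": str, "sample_id": str}, keep_default_na=False
        )
        needed = {"otu_id", "sample_id", "count"}
        if not needed.issubset(trip.columns):
            raise ParseError(f"{path}: sparse triplets need columns {sorted(needed)}")
        values = pd.to_numeric(trip["count"], errors="coerce")
        if values.isna().any() or (values != np.floor(values)).any():
            raise ParseError(f"{path}: non-integer count in triplets")
        if (values < 0).any():
            raise ParseError(f"{path}: negative count in triplets")
        trip["count"] = values.astype(np.int64)
        if trip.duplicated(subset=["otu_id", "sample_id"]).any():
            raise ParseError(f"{path}: duplicate (otu_id, sample_id) triplets")
        counts = (
            trip.pivot(index="sample_id", columns="otu_id", values="count")
            .fillna(0)
            .astype(np.int64)
        )
        counts.index.name = None
        counts.columns.name = None
    else:
        raise ConfigError(f"unknown OTU table format {format!r}")

    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
        if not {"otu_id", "lineage"}.issubset(tax.columns):
            raise ParseError(f"{taxonomy_path}: needs columns otu_id, lineage")
        taxonomy = tax.set_index("otu_id")["lineage"]
    return OtuCountTable(counts, taxonomy)


def write_otu_table(table: OtuCountTable, path, format: str = "wide", taxonomy_path=None) -> None:
    if format == "wide":
        table.counts.to_csv(path, sep="\t", index_label="sample_id")
    elif format == "sparse":
        stacked = table.counts.stack()
        stacked = stacked[stacked > 0]
        trip = stacked.rename("count").reset_index()
        trip.columns = ["sample_id", "otu_id", "count"]
        trip[["otu_id", "sample_id", "count"]].to_csv(path, sep="\t", index=False)
    else:
        raise ConfigError(f"unknown OTU table format {format!r}")
    if taxonomy_path is not None:
        table.taxonomy.rename("lineage").to_csv(taxonomy_path, sep="\t", index_label="otu_id")


def read_metabolite_matrix(path, scale: str = "raw") -> MetaboliteMatrix:
    frame = pd.read_csv(
        path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, dtype={"sample_id": str}
    )
    if "sample_id" not in frame.columns:
        raise ParseError(f"{path}: missing 'sample_id' column")
    if frame["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs")
    frame = frame.set_index("sample_id")
    frame.index.name = None
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric abundance value ({exc})") from exc
    return MetaboliteMatrix(frame, scale=scale)


def write_metabolite_matrix(matrix: MetaboliteMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(manifest: dict, path) -> None:
    """Write the run manifest as deterministic JSON (sorted keys)."""
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
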