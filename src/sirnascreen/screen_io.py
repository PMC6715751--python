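"""Readers and writers for every table the pipeline touches.

All tabular formats are tab-separated UTF-8 with a one-line header; gene sets
use the standard GMT dialect (name, description, members...). Gene labels are
opaque case-sensitive strings, except the control labels siNC/siPLK1 which are
recognized case-insensitively on input and canonicalized.
"""

from __future__ import annotations

from os import PathLike

import pandas as pd

from .errors import ParseError, SchemaError
from .simulate import NEGATIVE_CONTROL, POSITIVE_CONTROL, READOUTS, TruthTable

__all__ = [
    "read_raw_screen",
    "write_raw_screen",
    "validate_raw_screen",
    "read_normalized_screen",
    "write_normalized_screen",
    "read_gmt",
    "write_gmt",
    "read_result_table",
    "write_result_table",
    "read_edge_list",
    "write_edge_list",
    "read_truth_table",
    "write_truth_table",
]

RAW_COLUMNS = ["cell_line", "readout", "plate", "well", "gene_id", "replicate", "raw_value"]
NORM_COLUMNS = ["cell_line", "readout", "plate", "well", "gene_id", "replicate", "log2fc"]
RESULT_COLUMNS = [
    "cell_line", "readout", "gene_id", "log2fc_mean", "log2fc_sd",
    "n_replicates", "p_value", "hit_flag",
]
EDGE_COLUMNS = ["gene_a", "gene_b", "tanimoto_score"]

_CONTROL_CANON = {NEGATIVE_CONTROL.lower(): NEGATIVE_CONTROL, POSITIVE_CONTROL.lower(): POSITIVE_CONTROL}


def canonicalize_controls(labels: pd.Series) -> pd.Series:
    lowered = labels.str.lower()
    out = labels.copy()
    for low, canon in _CONTROL_CANON.items():
        out[lowered == low] = canon
    return out


def _require_columns(frame: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def validate_raw_screen(screen: pd.DataFrame, source: str = "raw screen") -> pd.DataFrame:
    _require_columns(screen, RAW_COLUMNS, source)
    screen = screen[RAW_COLUMNS].copy()
    bad_readout = ~screen["readout"].isin(READOUTS)
    if bad_readout.any():
        row = screen.index[bad_readout][0]
        raise SchemaError(
            f"{source}: unknown readout {screen.loc[row, 'readout']!r} at row {row}"
        )
    values = pd.to_numeric(screen["raw_value"], errors="coerce")
    if values.isna().any():
        row = screen.index[values.isna()][0]
        raise SchemaError(f"{source}: non-numeric raw_value at row {row}")
    if (values < 0).any():
        row = screen.index[values < 0][0]
        raise SchemaError(f"{source}: negative raw_value {values[row]} at row {row}")
    screen["raw_value"] = values.astype(float)
    screen["replicate"] = screen["replicate"].astype(int)
    screen["gene_id"] = canonicalize_controls(screen["gene_id"].astype(str))
    return screen


def read_raw_screen(path: str | PathLike) -> pd.DataFrame:
    """Read a per-well raw readout table, validating schema and values."""
    frame = pd.read_csv(path, sep="\t", dtype={"plate": str, "well": str}, float_precision="round_trip")
    return validate_raw_screen(frame, source=str(path))


def write_raw_screen(screen: pd.DataFrame, path: str | PathLike) -> None:
    _require_columns(screen, RAW_COLUMNS, "raw screen")
    screen[RAW_COLUMNS].to_csv(path, sep="\t", index=False)


def read_normalized_screen(path: str | PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"plate": str, "well": str}, float_precision="round_trip")
    _require_columns(frame, NORM_COLUMNS, path)
    frame["gene_id"] = canonicalize_controls(frame["gene_id"].astype(str))
    return frame[NORM_COLUMNS]


def write_normalized_screen(norm: pd.DataFrame, path: str | PathLike) -> None:
    _require_columns(norm, NORM_COLUMNS, "normalized screen")
    norm[NORM_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path: str | PathLike) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Parse a GMT gene-set file into ``{set_name: (description, members)}``.

    Duplicate members within a set are collapsed (first occurrence kept);
    a duplicated set name or a line with fewer than 3 fields is an error.
    """
    collection: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, description, *members = fields
            if name in collection:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in members if m))
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            collection[name] = (description, members)
    return collection


def write_gmt(collection: dict[str, tuple[str, tuple[str, ...]]], path: str | PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name, (description, members) in collection.items():
            handle.write("\t".join([name, description, *members]) + "\n")


def invert_gene_sets(collection: dict[str, tuple[str, tuple[str, ...]]]) -> dict[str, frozenset]:
    """Invert a set collection to gene -> annotation-term set."""
    gene_terms: dict[str, set] = {}
    for name, (_desc, members) in collection.items():
        for gene in members:
            gene_terms.setdefault(gene, set()).add(name)
    return {g: frozenset(t) for g, t in gene_terms.items()}


def read_result_table(path: str | PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(frame, RESULT_COLUMNS, path)
    bad_p = frame["p_value"].dropna()
    if ((bad_p < 0) | (bad_p > 1)).any():
        raise SchemaError(f"{path}: p_value outside [0, 1]")
    frame["hit_flag"] = frame["hit_flag"].astype(bool)
    return frame[list(frame.columns)]


def write_result_table(table: pd.DataFrame, path: str | PathLike) -> None:
    _require_columns(table, RESULT_COLUMNS, "result table")
    table.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(frame, EDGE_COLUMNS, path)
    scores = frame["tanimoto_score"]
    if ((scores < 0) | (scores > 1)).any():
        raise SchemaError(f"{path}: tanimoto_score outside [0, 1]")
    return frame[EDGE_COLUMNS]


def write_edge_list(edges: pd.DataFrame, path: str | PathLike) -> None:
    """Write a similarity edge list; scores printed with 4 decimals."""
    _require_columns(edges, EDGE_COLUMNS, "edge list")
    out = edges[EDGE_COLUMNS].copy()
    out["tanimoto_score"] = out["tanimoto_score"].map(lambda s: f"{s:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | PathLike) -> TruthTable:
    return TruthTable.from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_truth_table(truth: TruthTable, path: str | PathLike) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)
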