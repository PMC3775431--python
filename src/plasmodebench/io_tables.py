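"""Readers and writers for every on-disk artifact.

TSV is the canonical interchange format (tab-separated, documented headers);
MatrixMarket coordinate format is supported for sparse interoperability.
All writers are deterministic: row order follows the source object and
floating-point values are serialized with 12 significant digits.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .data_model import CountMatrix, DesignTable, ResultTable, StructuralError, TruthTable

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_truth",
    "write_truth",
    "read_results",
    "write_results",
    "read_config",
    "write_config",
    "RunConfig",
    "SchemaError",
    "ParseError",
]

FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class SchemaError(ValueError):
    """A table or config file violates its documented schema."""


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | os.PathLike, format: str = "tsv") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: first row sample ids, first column gene ids, integer cells.
    ``mtx``: MatrixMarket coordinate integer file with sidecar id files
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "mtx":
        return _read_counts_mtx(path)
    raise ValueError(f"unknown counts format {format!r}; use 'tsv' or 'mtx'")


def _read_counts_tsv(path: Path) -> CountMatrix:
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise ParseError(f"{path}: no data rows")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            bad = vals[pd.to_numeric(vals, errors="coerce") != np.floor(
                pd.to_numeric(vals, errors="coerce")
            )]
            line = df.index.get_loc(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(
                f"{path}: non-integer cell in column {col!r} (line {line})"
            )
    return CountMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy()
    )


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.genes.txt"), Path(f"{stem}.samples.txt")


def _read_counts_mtx(path: Path) -> CountMatrix:
    genes_path, samples_path = _sidecars(path)
    for p in (path, genes_path, samples_path):
        if not p.exists():
            raise ParseError(f"{p}: missing (mtx requires sidecar id files)")
    mat = scipy.io.mmread(path)
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.issubdtype(counts.dtype, np.integer):
        if np.any(counts != np.floor(counts)):
            raise ParseError(f"{path}: non-integer entries in MatrixMarket file")
        counts = counts.astype(np.int64)
    gene_ids = genes_path.read_text().splitlines()
    sample_ids = samples_path.read_text().splitlines()
    return CountMatrix(gene_ids, sample_ids, counts)


def write_counts(cm: CountMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts)
        scipy.io.mmwrite(str(path), sparse, field="integer")
        genes_path, samples_path = _sidecars(path)
        genes_path.write_text("\n".join(cm.gene_ids) + "\n")
        samples_path.write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}; use 'tsv' or 'mtx'")


# ---------------------------------------------------------------------------
# design / truth / results tables


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def read_design(path: str | os.PathLike) -> DesignTable:
    """Read a design TSV (``sample_id``, ``treatment``; optional ``block``,
    ``bio_rep``, ``tech_rep``).  A missing block column yields one implicit
    common block."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "treatment"], path)
    return DesignTable(df)


def write_design(design: DesignTable, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    design.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> TruthTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "is_de", "true_log_effect"], path)
    is_de = df["is_de"].map({"True": True, "False": False, True: True, False: False})
    if is_de.isna().any():
        raise SchemaError(f"{path}: is_de must be True/False")
    return TruthTable(
        [str(g) for g in df["gene_id"]],
        is_de.to_numpy(dtype=bool),
        df["true_log_effect"].to_numpy(dtype=float),
    )


def write_truth(tt: TruthTable, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tt.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path: str | os.PathLike) -> ResultTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["gene_id", "statistic", "p_value", "method"], path)
    methods = df["method"].unique()
    if len(methods) != 1:
        raise SchemaError(f"{path}: expected a single method tag, found {methods}")
    return ResultTable(
        [str(g) for g in df["gene_id"]],
        df["statistic"].to_numpy(dtype=float),
        df["p_value"].to_numpy(dtype=float),
        str(methods[0]),
    )


def write_results(rt: ResultTable, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rt.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# run configuration

#: Allowed keys and defaults, by section.  Unknown keys are rejected so a
#: typo ("fo" for "p0") fails loudly instead of silently using a default.
CONFIG_SCHEMA: dict[str, dict[str, Any]] = {
    "": {"seed": 1, "out": "runs", "methods": [
        "nb-lrt-tagwise", "nb-lrt-trend",
        "gauss-F1-tab", "gauss-F1-perm", "gauss-Fs-tab", "gauss-Fs-perm",
    ], "n_perm": 100, "format": "tsv"},
    "scenario": {
        "T": 5000, "K": 1000, "n_levels": [3, 5, 10], "r_levels": [1, 3, 5],
        "p0": 0.1, "offset_kind": "lognormal", "offset_cv": 0.2,
        "offset_depth": 2.0e7,
    },
    "plasmode": {
        "p": 10, "t": 2, "r": 10, "pi": 0.2, "q_threshold": 0.01,
        "effect_mode": "sampled_from_G",
    },
}


@dataclass
class RunConfig:
    """Fully resolved run configuration (flat key-value tree).

    Every run writes the resolved config next to its outputs so results are
    reproducible from the manifest alone.
    """

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        resolved: dict[str, Any] = {}
        values = dict(self.values)
        for key, default in CONFIG_SCHEMA[""].items():
            resolved[key] = values.pop(key, default)
        for section in ("scenario", "plasmode"):
            sub = values.pop(section, {}) or {}
            if not isinstance(sub, dict):
                raise SchemaError(f"config section {section!r} must be a mapping")
            out = {}
            for key, default in CONFIG_SCHEMA[section].items():
                out[key] = sub.pop(key, default)
            if sub:
                raise SchemaError(
                    f"unknown config key(s) in {section!r}: {sorted(sub)}"
                )
            resolved[section] = out
        if values:
            raise SchemaError(f"unknown config key(s): {sorted(values)}")
        self.values = resolved

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


def read_config(path: str | os.PathLike) -> RunConfig:
    """Read a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    return RunConfig(data)


def write_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.values, fh, sort_keys=True)
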