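"""Core validated containers shared by every pipeline stage.

A benchmark run moves a gene x sample count matrix, its experimental design,
and (when ground truth exists) a per-gene truth table through preprocessing,
testing and evaluation.  These containers enforce the structural invariants
once, at the boundary, so downstream numerical code can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "DesignTable",
    "TruthTable",
    "ResultTable",
    "StructuralError",
    "validate_dataset",
]

#: Label used when a design carries no explicit blocking factor.  A single
#: common block makes unblocked analyses (e.g. exchangeable-sample null
#: plasmodes) a degenerate case of the blocked code path.
DEFAULT_BLOCK = "block1"


class StructuralError(ValueError):
    """Identifiers or table shapes of companion objects do not line up."""


def _check_unique(ids, what: str) -> list:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise StructuralError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class CountMatrix:
    """Gene x sample matrix of nonnegative integer read counts.

    Parameters
    ----------
    gene_ids, sample_ids
        Unique row / column identifiers.
    counts
        Integer array of shape ``(len(gene_ids), len(sample_ids))``.
        Fractional or negative values are rejected, never rounded: any
        thinning or spiking decision must be explicit upstream.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise StructuralError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise StructuralError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if np.any(frac):
                g, s = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integral count {counts[g, s]!r} at "
                    f"({self.gene_ids[g]}, {self.sample_ids[s]})"
                )
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count {counts[g, s]} at "
                f"({self.gene_ids[g]}, {self.sample_ids[s]})"
            )
        self.counts = counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.gene_ids[i] for i in keep], list(self.sample_ids), self.counts[keep]
        )

    def subset_samples(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            list(self.gene_ids), [self.sample_ids[i] for i in keep], self.counts[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DesignTable:
    """Per-sample experimental factors.

    ``table`` has one row per sample with columns ``sample_id``,
    ``treatment``, ``block``, ``bio_rep``, ``tech_rep``.  A missing block is
    interpreted as one common block; missing replicate columns default to one
    biological replicate per sample / one technical replicate.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns:
            raise StructuralError("design table lacks required column 'sample_id'")
        if "treatment" not in df.columns:
            raise StructuralError("design table lacks required column 'treatment'")
        if "block" not in df.columns:
            df["block"] = DEFAULT_BLOCK
        if "bio_rep" not in df.columns:
            df["bio_rep"] = df["sample_id"]
        if "tech_rep" not in df.columns:
            df["tech_rep"] = "t1"
        df = df[["sample_id", "treatment", "block", "bio_rep", "tech_rep"]]
        df = df.astype(str)
        _check_unique(df["sample_id"], "sample ids")
        key = df[["treatment", "bio_rep", "tech_rep"]].agg("\x1f".join, axis=1)
        if key.duplicated().any():
            bad = df.loc[key.duplicated(), "sample_id"].tolist()
            raise StructuralError(
                "(treatment, bio_rep, tech_rep) does not uniquely identify "
                f"samples; offending sample_ids: {bad}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def treatments(self) -> list[str]:
        """Distinct treatment levels in order of first appearance."""
        return list(dict.fromkeys(self.table["treatment"]))

    @property
    def blocks(self) -> list[str]:
        return list(dict.fromkeys(self.table["block"]))

    def reorder(self, sample_ids: list[str]) -> "DesignTable":
        df = self.table.set_index("sample_id").loc[sample_ids].reset_index()
        return DesignTable(df)


@dataclass
class TruthTable:
    """Per-gene ground truth: null (S0) vs differentially expressed (S1).

    ``true_log_effect`` is the natural-log group-2 minus group-1 effect and
    is exactly zero for S0 genes.
    """

    gene_ids: list[str]
    is_de: np.ndarray
    true_log_effect: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.is_de = np.asarray(self.is_de, dtype=bool)
        self.true_log_effect = np.asarray(self.true_log_effect, dtype=float)
        if not (len(self.gene_ids) == self.is_de.size == self.true_log_effect.size):
            raise StructuralError("truth table field lengths disagree")
        if np.any(self.true_log_effect[~self.is_de] != 0.0):
            bad = np.flatnonzero(~self.is_de & (self.true_log_effect != 0))[0]
            raise ValueError(
                f"gene {self.gene_ids[bad]} marked null but has nonzero effect"
            )

    @property
    def n_de(self) -> int:
        return int(self.is_de.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "is_de": self.is_de,
                "true_log_effect": self.true_log_effect,
            }
        )


@dataclass
class ResultTable:
    """Per-gene test output for one method on one dataset.

    ``p_value`` may be NaN for genes whose fit did not converge; evaluation
    drops those rows (recording how many) rather than guessing.
    """

    gene_ids: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene ids")
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        if not (len(self.gene_ids) == self.statistic.size == self.p_value.size):
            raise StructuralError("result table field lengths disagree")
        ok = np.isnan(self.p_value) | ((self.p_value >= 0) & (self.p_value <= 1))
        if not ok.all():
            bad = np.flatnonzero(~ok)[0]
            raise ValueError(
                f"p-value {self.p_value[bad]} outside [0, 1] for gene "
                f"{self.gene_ids[bad]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "statistic": self.statistic,
                "p_value": self.p_value,
                "method": self.method,
            }
        )


def validate_dataset(counts: CountMatrix, design: DesignTable):
    """Check a (counts, design) pair for mutual consistency.

    Returns the pair unchanged when every invariant holds; idempotent and
    side-effect free.  Sample identifiers must match in content and order.
    """
    if counts.sample_ids != design.sample_ids:
        missing = set(counts.sample_ids) - set(design.sample_ids)
        extra = set(design.sample_ids) - set(counts.sample_ids)
        if missing or extra:
            raise StructuralError(
                f"sample ids disagree: missing from design {sorted(missing)}, "
                f"absent from counts {sorted(extra)}"
            )
        raise StructuralError(
            "sample ids match as sets but not in order; reorder the design "
            "with DesignTable.reorder"
        )
    return counts, design
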