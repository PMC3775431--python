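"""Filtering, normalization and transformation of count matrices.

The pipeline applied to every benchmark dataset is: sum technical replicates,
filter low-expression genes on raw counts-per-million, then normalize by
either trimmed-mean-of-M-values (TMM) scale factors feeding a log-offset NB
model, or median-of-ratios size factors, or a log2-CPM transform feeding the
Gaussian engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import CountMatrix, DesignTable

__all__ = [
    "NormFactors",
    "SizeFactors",
    "collapse_technical",
    "filter_cpm",
    "tmm_factors",
    "size_factors_median_ratio",
    "log2_cpm",
]


@dataclass
class NormFactors:
    """Between-sample scale factors in the TMM convention.

    ``scale_factor`` is dimensionless with geometric mean 1 across samples;
    ``effective_library_size = library_size * scale_factor`` is what enters
    the model offset.
    """

    sample_ids: list[str]
    library_size: np.ndarray
    scale_factor: np.ndarray

    def __post_init__(self) -> None:
        self.library_size = np.asarray(self.library_size, dtype=float)
        self.scale_factor = np.asarray(self.scale_factor, dtype=float)
        if np.any(self.scale_factor <= 0):
            raise ValueError("scale factors must be positive")
        gm = np.exp(np.mean(np.log(self.scale_factor)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"scale factors must have geometric mean 1, got {gm}")

    @property
    def effective_library_size(self) -> np.ndarray:
        return self.library_size * self.scale_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "library_size": self.library_size,
                "scale_factor": self.scale_factor,
                "effective_library_size": self.effective_library_size,
            }
        )


@dataclass
class SizeFactors:
    """Median-of-ratios per-sample size factors."""

    sample_ids: list[str]
    size_factor: np.ndarray

    def __post_init__(self) -> None:
        self.size_factor = np.asarray(self.size_factor, dtype=float)
        if np.any(self.size_factor <= 0):
            raise ValueError("size factors must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "size_factor": self.size_factor}
        )


def collapse_technical(
    counts: CountMatrix, design: DesignTable
) -> tuple[CountMatrix, DesignTable]:
    """Sum technical replicates into one column per biological sample.

    Technical replicates add sequencing depth, not independent biological
    variation, so they are summed before filtering and analysis.  The
    returned design drops the ``tech_rep`` column (reset to a single level).
    Total reads are conserved.
    """
    df = design.table
    key = df[["treatment", "block", "bio_rep"]].agg("\x1f".join, axis=1)
    order = list(dict.fromkeys(key))
    new_cols, new_rows, new_ids = [], [], []
    for k in order:
        idx = np.flatnonzero((key == k).to_numpy())
        new_cols.append(counts.counts[:, idx].sum(axis=1))
        row = df.iloc[idx[0]].copy()
        # keep the original sample id when the biological sample had a single
        # technical replicate, otherwise synthesize a collapsed id
        row["sample_id"] = (
            df.iloc[idx[0]]["sample_id"] if len(idx) == 1
            else f"{row['treatment']}.{row['block']}.{row['bio_rep']}"
        )
        row["tech_rep"] = "t1"
        new_rows.append(row)
        new_ids.append(row["sample_id"])
    cm = CountMatrix(list(counts.gene_ids), new_ids, np.column_stack(new_cols))
    dt = DesignTable(pd.DataFrame(new_rows).reset_index(drop=True))
    return cm, dt


def filter_cpm(
    counts: CountMatrix, n_bio: int, min_cpm: float = 2.0
) -> tuple[CountMatrix, list[str]]:
    """Keep genes with ``min_cpm`` or more reads per million in at least
    ``n_bio`` libraries.

    ``n_bio`` is the number of biological replicates per group, so a gene
    expressed in only one full group survives.  CPM is computed on raw
    (unnormalized) library sizes; technical replicates must already be
    collapsed.
    """
    lib = counts.library_sizes().astype(float)
    if np.any(lib == 0):
        bad = counts.sample_ids[int(np.argmax(lib == 0))]
        raise ValueError(f"zero library size for sample {bad!r}")
    cpm = counts.counts / lib * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= n_bio
    filtered = counts.subset_genes(keep)
    return filtered, filtered.gene_ids


def _quantile_by_depth(counts: np.ndarray, lib: np.ndarray, p: float) -> np.ndarray:
    # per-sample p-th quantile of depth-scaled counts (R type-7 == numpy linear)
    return np.quantile(counts / lib, p, axis=0)


def tmm_factors(
    counts: CountMatrix,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values scale factors.

    The reference sample is the column whose 75th-percentile depth-scaled
    count is closest to the mean of those percentiles.  For each sample vs
    the reference, genes with a zero in either column are excluded; the
    log-ratios M are doubly trimmed (30% by M, 5% by absolute expression A,
    tails split equally) and averaged with inverse-variance precision
    weights.  Factors are rescaled to geometric mean 1.
    """
    y = counts.counts.astype(float)
    lib = counts.library_sizes().astype(float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if np.any(lib == 0):
        bad = counts.sample_ids[int(np.argmax(lib == 0))]
        raise ValueError(f"zero library size for sample {bad!r}")

    f75 = _quantile_by_depth(y, lib, 0.75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for k in range(y.shape[1]):
        if k == ref:
            continue
        yk, nk = y[:, k], lib[k]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(f"no usable genes for sample {counts.sample_ids[k]}; factor 1")
            continue
        m = np.log2((yk[ok] / nk) / (yr[ok] / nr))
        a = 0.5 * np.log2((yk[ok] / nk) * (yr[ok] / nr))
        w = 1.0 / ((nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok]))
        n = m.size
        if np.max(np.abs(m)) < 1e-6:  # columns proportional: factor exactly 1
            continue
        lo_m = np.floor(n * log_ratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            warnings.warn(
                f"all genes trimmed for sample {counts.sample_ids[k]}; factor 1"
            )
            continue
        factors[k] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(counts.sample_ids), lib, factors)


def size_factors_median_ratio(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each sample, the factor is the median over genes (positive in every
    sample) of the ratio of the sample's count to the gene's geometric mean
    across samples.
    """
    y = counts.counts.astype(float)
    all_positive = (y > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "size factors undefined: no gene has positive counts in all samples"
        )
    logy = np.log(y[all_positive])
    log_geo = logy.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logy - log_geo, axis=0))
    return SizeFactors(list(counts.sample_ids), s)


def log2_cpm(
    counts: CountMatrix, norm: NormFactors | None = None, prior: float = 0.5
) -> np.ndarray:
    """log2 counts-per-million on effective library sizes.

    ``x = log2((count + prior) / (effective_library_size + 1) * 1e6)``; the
    prior count and the +1 on the library size keep the transform finite for
    zeros.  This is the input to the Gaussian testing engines.
    """
    if norm is None:
        lib = counts.library_sizes().astype(float)
        eff = lib
        ids = counts.sample_ids
    else:
        eff = norm.effective_library_size
        ids = norm.sample_ids
    if list(ids) != list(counts.sample_ids):
        raise ValueError("norm factors sample ids do not match count matrix")
    return np.log2((counts.counts + prior) / (eff + 1.0) * 1e6)
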