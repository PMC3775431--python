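"""Model-free plasmode dataset construction.

A plasmode is built from real (or realistic) experimental counts so that the
empirical distribution and gene-gene correlation of the base data are kept,
while some truth is known by construction:

* *null plasmodes* reshuffle exchangeable base samples into arbitrary
  pseudo-groups — no gene is differentially expressed;
* *DE plasmodes* randomly partition samples into pseudo-groups within each
  block, then impose effects (estimated from the base data itself) on a
  chosen fraction of genes by binomial thinning, which keeps counts integer
  and preserves count-like mean-variance behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import CountMatrix, DesignTable, TruthTable
from . import de_tests

__all__ = [
    "NullPlasmodeConfig",
    "DEPlasmodeConfig",
    "DEGeneSet",
    "PlasmodeDataset",
    "make_null_plasmodes",
    "select_effect_set",
    "make_de_plasmodes",
    "spike_counts",
]


@dataclass
class NullPlasmodeConfig:
    """Settings for null plasmodes: p datasets of t pseudo-groups x r reps."""

    p: int = 10
    t: int = 2
    r: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1 or self.t < 2 or self.r < 1:
            raise ValueError("require p >= 1, t >= 2, r >= 1")


@dataclass
class DEPlasmodeConfig:
    """Settings for DE plasmodes.

    ``pi`` is the fraction of (filtered) genes spiked with an effect;
    ``effect_mode`` is ``sampled_from_G`` (random genes receive effects drawn
    with replacement from the selected set G) or ``own_effect_G_only``
    (spiked genes are drawn from G and keep their own estimated effect).
    """

    p: int = 10
    pi: float = 0.20
    q_threshold: float = 0.01
    effect_mode: str = "sampled_from_G"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ValueError("q_threshold must lie in (0, 1]")
        if self.effect_mode not in ("sampled_from_G", "own_effect_G_only"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


@dataclass
class DEGeneSet:
    """High-confidence DE genes of the base data with estimated effects."""

    gene_ids: list[str]
    log_fold_change: np.ndarray  # natural-log scale
    q_value: np.ndarray

    def __post_init__(self) -> None:
        self.log_fold_change = np.asarray(self.log_fold_change, dtype=float)
        self.q_value = np.asarray(self.q_value, dtype=float)
        if np.any((self.q_value < 0) | (self.q_value > 1)):
            raise ValueError("q-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PlasmodeDataset:
    counts: CountMatrix
    design: DesignTable
    truth: TruthTable
    provenance: dict[str, str]  # plasmode column -> base sample id


def make_null_plasmodes(
    base: CountMatrix,
    cfg: NullPlasmodeConfig,
    rng: np.random.Generator | None = None,
) -> list[PlasmodeDataset]:
    """Null plasmodes from exchangeable base samples.

    Each plasmode draws ``t * r`` distinct base columns uniformly without
    replacement, copies them unchanged, and assigns arbitrary pseudo-group
    labels (first r columns -> group 1, next r -> group 2, ...).  Every gene
    is truly null.  Exchangeability of the base samples is the caller's
    responsibility.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    need = cfg.t * cfg.r
    if need > base.n_samples:
        raise ValueError(
            f"t*r = {need} exceeds the {base.n_samples} available base samples"
        )
    out = []
    truth = TruthTable(
        list(base.gene_ids),
        np.zeros(base.n_genes, dtype=bool),
        np.zeros(base.n_genes),
    )
    for i in range(cfg.p):
        picks = rng.choice(base.n_samples, size=need, replace=False)
        sample_ids, rows, prov = [], [], {}
        for c, src in enumerate(picks):
            group = c // cfg.r + 1
            sid = f"p{i+1}_g{group}_r{c % cfg.r + 1}"
            sample_ids.append(sid)
            prov[sid] = base.sample_ids[src]
            rows.append(
                {
                    "sample_id": sid,
                    "treatment": f"g{group}",
                    "block": "block1",
                    "bio_rep": base.sample_ids[src],
                    "tech_rep": "t1",
                }
            )
        cm = CountMatrix(
            list(base.gene_ids), sample_ids, base.counts[:, picks].copy()
        )
        out.append(
            PlasmodeDataset(cm, DesignTable(pd.DataFrame(rows)), truth, prov)
        )
    return out


def select_effect_set(
    base: CountMatrix,
    design: DesignTable,
    q_threshold: float = 0.01,
) -> DEGeneSet:
    """Select the high-confidence DE gene set G from the base data.

    Fits the NB GLM (treatment + block, tagwise-shrunk dispersions) per
    gene, tests treatment by LRT, converts p-values to Benjamini-Hochberg
    q-values, and returns genes with q <= threshold along with their
    estimated natural-log treatment fold changes.  Expects counts already
    filtered.  An empty set is returned with a warning, never an error.
    """
    if len(design.treatments) < 2:
        raise ValueError("effect selection needs at least 2 treatment levels")
    from . import preprocess

    model = de_tests.ModelSpec.for_design(design)
    norm = preprocess.tmm_factors(base)
    offsets = np.log(norm.effective_library_size)
    disp = de_tests.estimate_dispersion(
        base, model, design, offsets, "tagwise_shrunk"
    )
    res = de_tests.nb_lrt(base, model, design, offsets, disp)

    Xf, names = de_tests.build_design_matrix(design, model.full_terms)
    fit = de_tests.fit_nb_glm_batch(base.counts, Xf, offsets, disp.phi)
    treat_cols = [j for j, nm in enumerate(names) if nm.startswith("treatment[")]
    lfc = fit["beta"][:, treat_cols[0]]

    ok = ~np.isnan(res.p_value)
    q = np.full(base.n_genes, np.nan)
    q[ok] = multipletests(res.p_value[ok], method="fdr_bh")[1]
    keep = ok & (q <= q_threshold)
    if not keep.any():
        warnings.warn(f"no gene passes q <= {q_threshold}; returning empty set")
    idx = np.flatnonzero(keep)
    return DEGeneSet(
        [base.gene_ids[i] for i in idx], lfc[idx], q[idx]
    )


def spike_counts(
    row: np.ndarray,
    target_columns: np.ndarray,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Impose a log effect on one gene's counts by binomial thinning.

    Counts in ``target_columns`` (the group on the DOWN side of the effect)
    are replaced by Binomial(y, exp(-|beta|)) draws; all other columns are
    returned verbatim.  Thinned values never exceed the originals, and a
    zero count stays zero for any beta.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    out = np.array(row, dtype=np.int64, copy=True)
    q = float(np.exp(-abs(beta)))
    if q >= 1.0:
        return out
    cols = np.asarray(target_columns)
    out[cols] = rng.binomial(out[cols], q)
    return out


def _balanced_partitions(
    design: DesignTable, rng: np.random.Generator
) -> np.ndarray:
    """Random within-block partition into two pseudo-groups, sizes as equal
    as possible; for odd block sizes the larger side alternates across
    blocks (in block order)."""
    labels = np.empty(len(design.sample_ids), dtype=object)
    bigger_first = True
    block = design.table["block"].to_numpy()
    for b in design.blocks:
        idx = np.flatnonzero(block == b)
        perm = idx[rng.permutation(idx.size)]
        n1 = idx.size // 2
        if idx.size % 2 == 1:
            n1 = n1 + 1 if bigger_first else n1
            bigger_first = not bigger_first
        labels[perm[:n1]] = "pg1"
        labels[perm[n1:]] = "pg2"
    return labels


def make_de_plasmodes(
    base: CountMatrix,
    design: DesignTable,
    G: DEGeneSet,
    cfg: DEPlasmodeConfig,
    rng: np.random.Generator | None = None,
) -> list[PlasmodeDataset]:
    """DE plasmodes by within-block randomization plus effect spiking.

    Per plasmode: samples are randomly partitioned into two pseudo-treatment
    groups within each block (balanced sizes); ``round(pi * T)`` genes are
    selected and each receives a natural-log effect beta taken from G (see
    ``effect_mode``); the effect is imposed by binomial thinning of the
    pseudo-group on the down side of beta.  Non-spiked genes are, within
    each block, a permutation of the base values; the truth table records
    the spiked genes and their betas.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    T = base.n_genes
    n_spike = int(round(cfg.pi * T))
    if n_spike > T:
        raise ValueError("round(pi * T) exceeds the number of genes")
    if len(G) == 0:
        raise ValueError("effect set G is empty; cannot spike effects")

    out = []
    gene_index = {g: i for i, g in enumerate(base.gene_ids)}
    for i in range(cfg.p):
        labels = _balanced_partitions(design, rng)
        if cfg.effect_mode == "sampled_from_G":
            spiked = rng.choice(T, size=n_spike, replace=False)
            betas = rng.choice(G.log_fold_change, size=n_spike, replace=True)
        else:  # own_effect_G_only
            g_rows = np.array([gene_index[g] for g in G.gene_ids])
            take = rng.choice(len(G), size=n_spike, replace=len(G) < n_spike)
            spiked, betas = g_rows[take], G.log_fold_change[take]

        counts = base.counts.copy()
        down1 = np.flatnonzero(labels == "pg1")  # thin pg1 when beta > 0
        down2 = np.flatnonzero(labels == "pg2")  # thin pg2 when beta < 0
        for g, beta in zip(spiked, betas):
            target = down1 if beta > 0 else down2
            counts[g] = spike_counts(counts[g], target, beta, rng)

        is_de = np.zeros(T, dtype=bool)
        effects = np.zeros(T)
        is_de[spiked] = True
        effects[spiked] = betas
        truth = TruthTable(list(base.gene_ids), is_de, effects)

        rows, prov = [], {}
        for c, sid in enumerate(base.sample_ids):
            rows.append(
                {
                    "sample_id": sid,
                    "treatment": str(labels[c]),
                    "block": design.table["block"].iloc[c],
                    "bio_rep": sid,
                    "tech_rep": "t1",
                }
            )
            prov[sid] = sid
        cm = CountMatrix(list(base.gene_ids), list(base.sample_ids), counts)
        out.append(
            PlasmodeDataset(cm, DesignTable(pd.DataFrame(rows)), truth, prov)
        )
    return out
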