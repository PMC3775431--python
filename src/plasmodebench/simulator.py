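"""Parametric over-dispersed Poisson simulation of RNA-seq counts.

Counts are generated from the hierarchical model

    y_ij ~ Poisson(lambda_ij),   log(lambda_ij) = O_ij + mu_i + e_ij,
    e_ij ~ Normal(0, sigma^2),

where O_ij is the known log library size, mu_i the group mean (natural-log
fraction-of-library scale) and e_ij a sample-specific residual shared by all
technical replicates of a biological sample.  This is deliberately *not* a
negative-binomial generator: the marginal distribution is a lognormal-Poisson
mixture, over-dispersed relative to Poisson but outside the model family of
the NB tests being benchmarked.

A simulation draws per-transcript parameters from a pool estimated from real
data, zeroes the treatment difference for transcripts assigned to the null
set S0, and emits a T x 2nr count matrix with full ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DesignTable, TruthTable

__all__ = [
    "TranscriptParams",
    "ParameterPool",
    "SimulationConfig",
    "SimulatedDataset",
    "estimate_parameters",
    "sample_truth",
    "simulate_dataset",
    "simulate_scenarios",
]

#: Hard ceiling on the Poisson log-rate; exp(700) is near the double limit.
MAX_LOG_RATE = 700.0


@dataclass
class TranscriptParams:
    """Group means (natural-log scale) and residual variance for one gene."""

    mu: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


@dataclass
class ParameterPool:
    """Ordered collection of per-transcript parameters with source gene ids."""

    params: list[TranscriptParams]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.params) == 0:
            raise ValueError("parameter pool is empty")
        if len(self.params) != len(self.gene_ids):
            raise ValueError("pool params and gene ids differ in length")

    def __len__(self) -> int:
        return len(self.params)


@dataclass
class SimulationConfig:
    """Settings for one simulated dataset (or one scenario cell)."""

    T: int = 5000
    K: int = 1
    n: int = 3
    r: int = 1
    p0: float = 0.1
    offset_kind: str = "lognormal"  # or "equal"
    offset_cv: float = 0.2
    offset_depth: float = 2.0e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 1 or self.K < 1 or self.n < 2 or self.r < 1:
            raise ValueError("require T >= 1, K >= 1, n >= 2, r >= 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.offset_kind not in ("equal", "lognormal"):
            raise ValueError("offset_kind must be 'equal' or 'lognormal'")


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    design: DesignTable
    offsets: np.ndarray  # per-sample natural-log library size
    truth: TruthTable


def estimate_parameters(
    counts: CountMatrix,
    design: DesignTable,
    offsets: np.ndarray,
) -> ParameterPool:
    """Estimate (mu_i, sigma^2) per gene by moment matching.

    For depth-corrected rates z_j = y_j / exp(O_j) in group i, the
    lognormal-Poisson model gives E z = exp(mu + sigma^2/2) =: m and
    Var z = m * E exp(-O) + (exp(sigma^2) - 1) m^2, so the excess variance
    over the Poisson contribution identifies sigma^2:

        sigma2_hat = log(1 + sum_i w_i v_i / sum_i w_i m_i^2),  w_i = n_i,
        mu_hat_i   = log(m_i) - sigma2_hat / 2.

    Genes with a zero mean rate in any group are dropped from the pool
    (their log mean is undefined).  Technical replicates must already be
    collapsed; each group needs at least 2 biological replicates.
    """
    offsets = np.asarray(offsets, dtype=float)
    treatment = design.table["treatment"].to_numpy()
    groups = list(dict.fromkeys(treatment))
    idx_by_group = [np.flatnonzero(treatment == g) for g in groups]
    for g, idx in zip(groups, idx_by_group):
        if idx.size < 2:
            raise ValueError(
                f"insufficient replication: group {g!r} has {idx.size} sample(s)"
            )
    z = counts.counts / np.exp(offsets)[None, :]
    m = np.column_stack([z[:, idx].mean(axis=1) for idx in idx_by_group])
    v_raw = np.column_stack([z[:, idx].var(axis=1, ddof=1) for idx in idx_by_group])
    shot = np.array([np.mean(np.exp(-offsets[idx])) for idx in idx_by_group])
    v = np.maximum(0.0, v_raw - m * shot[None, :])
    w = np.array([idx.size for idx in idx_by_group], dtype=float)

    keep = (m > 0).all(axis=1)
    params, gene_ids = [], []
    for g in np.flatnonzero(keep):
        sigma2 = math.log1p(
            float(np.sum(w * v[g]) / np.sum(w * m[g] ** 2))
        )
        mu = np.log(m[g]) - sigma2 / 2.0
        params.append(TranscriptParams(mu, sigma2))
        gene_ids.append(counts.gene_ids[g])
    return ParameterPool(params, gene_ids)


def sample_truth(
    pool: ParameterPool,
    T: int,
    p0: float,
    rng: np.random.Generator,
) -> tuple[list[TranscriptParams], TruthTable]:
    """Draw T transcripts from the pool and assign DE status.

    Exactly ``floor(p0 * T)`` transcripts form S1 and keep their group means
    (true effect = mu_2 - mu_1); the rest form S0 and have both group means
    replaced by their average, so their expected counts are equal across
    groups by construction.  Sampling is without replacement whenever the
    pool is large enough.
    """
    replace = len(pool) < T
    picks = rng.choice(len(pool), size=T, replace=replace)
    n_de = int(math.floor(p0 * T))
    de_idx = rng.choice(T, size=n_de, replace=False)
    is_de = np.zeros(T, dtype=bool)
    is_de[de_idx] = True

    params: list[TranscriptParams] = []
    effects = np.zeros(T)
    gene_ids = []
    for t, src in enumerate(picks):
        p = pool.params[src]
        gene_ids.append(f"t{t+1}:{pool.gene_ids[src]}")
        if is_de[t]:
            params.append(TranscriptParams(p.mu.copy(), p.sigma2))
            effects[t] = p.mu[1] - p.mu[0]
        else:
            mbar = float(p.mu.mean())
            params.append(TranscriptParams(np.full_like(p.mu, mbar), p.sigma2))
    truth = TruthTable(gene_ids, is_de, effects)
    return params, truth


def _draw_offsets(cfg: SimulationConfig, n_cols: int, rng) -> np.ndarray:
    if cfg.offset_kind == "equal":
        lib = np.full(n_cols, cfg.offset_depth)
    else:
        cv = cfg.offset_cv
        sigma = math.sqrt(math.log1p(cv**2))
        mu = math.log(cfg.offset_depth) - sigma**2 / 2.0
        lib = rng.lognormal(mean=mu, sigma=sigma, size=n_cols)
    return np.log(lib)


def simulate_dataset(
    cfg: SimulationConfig,
    params: list[TranscriptParams],
    truth: TruthTable,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Generate one T x 2nr count matrix from sampled transcript parameters.

    For each group i and biological replicate j a residual e_gij is drawn
    once per gene; all r technical replicates of that sample share it and
    differ only through independent Poisson noise (technical replication
    adds depth, not biological variation).
    """
    T = len(params)
    if T != len(truth.gene_ids):
        raise ValueError("params and truth length mismatch")
    n, r = cfg.n, cfg.r
    n_cols = 2 * n * r
    offsets = _draw_offsets(cfg, n_cols, rng)

    mu = np.stack([p.mu for p in params])  # (T, 2)
    sigma = np.sqrt(np.array([p.sigma2 for p in params]))  # (T,)

    counts = np.empty((T, n_cols), dtype=np.int64)
    sample_ids, rows = [], []
    col = 0
    for i in range(2):
        for j in range(n):
            e = rng.normal(0.0, 1.0, size=T) * sigma  # shared across tech reps
            for k in range(r):
                log_rate = offsets[col] + mu[:, i] + e
                if np.any(log_rate > MAX_LOG_RATE):
                    g = int(np.argmax(log_rate > MAX_LOG_RATE))
                    raise OverflowError(
                        f"rate overflow (exp argument > {MAX_LOG_RATE:g}) for "
                        f"gene {truth.gene_ids[g]}"
                    )
                counts[:, col] = rng.poisson(np.exp(log_rate))
                sid = f"g{i+1}_b{j+1}_t{k+1}"
                sample_ids.append(sid)
                rows.append(
                    {
                        "sample_id": sid,
                        "treatment": f"g{i+1}",
                        "block": "block1",
                        "bio_rep": f"b{j+1}",
                        "tech_rep": f"t{k+1}",
                    }
                )
                col += 1
    cm = CountMatrix(list(truth.gene_ids), sample_ids, counts)
    design = DesignTable(pd.DataFrame(rows))
    return SimulatedDataset(cm, design, offsets, truth)


def simulate_scenarios(
    cfg: SimulationConfig,
    pool: ParameterPool,
    n_levels: tuple[int, ...] = (3, 5, 10),
    r_levels: tuple[int, ...] = (1, 3, 5),
    seed: int | None = None,
) -> dict[tuple[int, int], list[SimulatedDataset]]:
    """Simulate K datasets in every (n, r) replication-scenario cell.

    Each cell draws independent truth assignments from its own recorded
    sub-seed (spawned from the master seed), so a (seed, config) pair fully
    determines every output.
    """
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    cells = [(n, r) for n in n_levels for r in r_levels]
    subseeds = master.spawn(len(cells))
    out: dict[tuple[int, int], list[SimulatedDataset]] = {}
    for (n, r), ss in zip(cells, subseeds):
        rng = np.random.default_rng(ss)
        datasets = []
        for _ in range(cfg.K):
            cell_cfg = SimulationConfig(
                T=cfg.T, K=1, n=n, r=r, p0=cfg.p0,
                offset_kind=cfg.offset_kind, offset_cv=cfg.offset_cv,
                offset_depth=cfg.offset_depth, seed=cfg.seed,
            )
            params, truth = sample_truth(pool, cfg.T, cfg.p0, rng)
            datasets.append(simulate_dataset(cell_cfg, params, truth, rng))
        out[(n, r)] = datasets
    return out
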