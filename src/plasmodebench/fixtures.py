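"""Synthetic base datasets standing in for public RNA-seq experiments.

The plasmode machinery needs base data with particular structure: a
*structureless* experiment whose samples are exchangeable (human B-cell
expression from unrelated male donors is the archetype — preset
``cheung-like``), and a *two-treatment, strongly blocked* experiment (two
inbred mouse strains sequenced across three flowcells — preset
``bottomly-like``).  These generators emulate that structure with negative
binomial counts from declared, versioned parameter distributions; they are
synthetic and are NOT fit to the real datasets, so the pipeline is fully
testable offline.  Real base tables can always be loaded via
:mod:`plasmodebench.io_tables` instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountMatrix, DesignTable, TruthTable
from .simulator import ParameterPool, TranscriptParams

__all__ = [
    "FixtureSpec",
    "PRESETS",
    "make_exchangeable_base",
    "make_blocked_base",
    "make_parameter_pool",
    "make_preset",
]


@dataclass
class FixtureSpec:
    """Declared distributions for one synthetic base dataset.

    Baseline log-means are natural-log *fractions of the library* (a gene at
    log(50e-6) averages 50 counts per million reads).  NB dispersions are
    gamma-distributed across genes unless ``dispersion_sd == 0``.
    """

    n_genes: int = 5000
    n_samples: int = 21
    logmean_loc: float = float(np.log(50e-6))
    logmean_scale: float = 1.5
    dispersion_mean: float = 0.15
    dispersion_shape: float = 2.0  # gamma shape; 0 means constant dispersion
    de_fraction: float = 0.0
    effect_low: float = float(np.log(2.0))
    effect_high: float = float(np.log(8.0))
    n_blocks: int = 1
    block_sd: float = 0.0  # per-(gene, block) log shift
    group_sizes: tuple[int, ...] = ()
    lib_depth: float = 5e6
    lib_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        for name in ("dispersion_mean", "lib_depth", "lib_cv", "logmean_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


PRESETS: dict[str, FixtureSpec] = {
    # 21 exchangeable samples, no structure
    "cheung-like": FixtureSpec(n_genes=5000, n_samples=21, seed=0),
    # 2 strains (10 + 11 samples) across 3 flowcell blocks, 10% DE genes
    "bottomly-like": FixtureSpec(
        n_genes=5000,
        n_samples=21,
        de_fraction=0.10,
        n_blocks=3,
        block_sd=0.30,
        group_sizes=(10, 11),
        dispersion_mean=0.10,
        seed=0,
    ),
}


def _library_sizes(spec: FixtureSpec, rng) -> np.ndarray:
    sigma = np.sqrt(np.log1p(spec.lib_cv**2))
    mu = np.log(spec.lib_depth) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=spec.n_samples)


def _dispersions(spec: FixtureSpec, rng) -> np.ndarray:
    if spec.dispersion_shape <= 0 or spec.dispersion_mean == 0:
        return np.full(spec.n_genes, spec.dispersion_mean)
    scale = spec.dispersion_mean / spec.dispersion_shape
    return rng.gamma(spec.dispersion_shape, scale, size=spec.n_genes)


def _nb_draw(mean: np.ndarray, phi: np.ndarray, rng) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2) via gamma-Poisson mixing."""
    out = np.empty(mean.shape, dtype=np.int64)
    pos = np.broadcast_to(phi, mean.shape) > 0
    if pos.any():
        shape = 1.0 / np.broadcast_to(phi, mean.shape)[pos]
        lam = rng.gamma(shape, mean[pos] / shape)
        out[pos] = rng.poisson(lam)
    if (~pos).any():
        out[~pos] = rng.poisson(mean[~pos])
    return out


def make_exchangeable_base(
    spec: FixtureSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, DesignTable]:
    """Structureless base data: every sample shares all gene-level means.

    Permuting sample labels leaves the joint distribution unchanged, so any
    pseudo-grouping of these samples is a true null.
    """
    spec = PRESETS["cheung-like"] if spec is None else spec
    if spec.de_fraction > 0 or spec.n_blocks > 1 or spec.block_sd > 0:
        raise ValueError("exchangeable base must not carry treatment/block effects")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lib = _library_sizes(spec, rng)
    logmean = rng.normal(spec.logmean_loc, spec.logmean_scale, size=spec.n_genes)
    phi = _dispersions(spec, rng)
    mean = np.exp(logmean)[:, None] * lib[None, :]
    counts = _nb_draw(mean, phi[:, None], rng)
    ids = [f"s{i+1}" for i in range(spec.n_samples)]
    cm = CountMatrix(
        [f"gene{i+1}" for i in range(spec.n_genes)], ids, counts
    )
    design = DesignTable(
        pd.DataFrame({"sample_id": ids, "treatment": ["all"] * spec.n_samples})
    )
    return cm, design


def make_blocked_base(
    spec: FixtureSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, DesignTable, TruthTable]:
    """Two-treatment base data with planted effects and block (flowcell)
    structure.

    A stated fraction of genes carries a treatment effect with magnitude
    uniform on [effect_low, effect_high] (natural-log scale, random sign);
    every gene additionally receives independent per-(gene, block) log
    shifts with standard deviation ``block_sd``, emulating a strong
    technical block effect.  Returns the planted truth.
    """
    spec = PRESETS["bottomly-like"] if spec is None else spec
    if len(spec.group_sizes) != 2:
        raise ValueError("blocked base needs exactly 2 treatment group sizes")
    if spec.n_blocks < 2:
        raise ValueError("blocked base needs >= 2 blocks")
    if sum(spec.group_sizes) != spec.n_samples:
        raise ValueError("group sizes must sum to n_samples")
    rng = np.random.default_rng(spec.seed) if rng is None else rng

    lib = _library_sizes(spec, rng)
    logmean = rng.normal(spec.logmean_loc, spec.logmean_scale, size=spec.n_genes)
    phi = _dispersions(spec, rng)

    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    effects = np.zeros(spec.n_genes)
    effects[de_idx] = rng.uniform(
        spec.effect_low, spec.effect_high, size=n_de
    ) * rng.choice([-1.0, 1.0], size=n_de)

    treatment = np.repeat(["t1", "t2"], spec.group_sizes)
    # interleave blocks across both treatment groups so block and treatment
    # are not confounded (each flowcell carries samples of both strains)
    block = np.array(
        [f"b{(i % spec.n_blocks) + 1}" for i in range(spec.n_samples)]
    )
    block_shift = rng.normal(
        0.0, spec.block_sd, size=(spec.n_genes, spec.n_blocks)
    ) if spec.block_sd > 0 else np.zeros((spec.n_genes, spec.n_blocks))
    block_of = np.array([int(b[1:]) - 1 for b in block])

    log_frac = (
        logmean[:, None]
        + np.where(treatment == "t2", effects[:, None], 0.0)
        + block_shift[:, block_of]
    )
    mean = np.exp(log_frac) * lib[None, :]
    counts = _nb_draw(mean, phi[:, None], rng)

    ids = [f"s{i+1}" for i in range(spec.n_samples)]
    gene_ids = [f"gene{i+1}" for i in range(spec.n_genes)]
    cm = CountMatrix(gene_ids, ids, counts)
    design = DesignTable(
        pd.DataFrame(
            {"sample_id": ids, "treatment": treatment, "block": block}
        )
    )
    truth = TruthTable(gene_ids, effects != 0, effects)
    return cm, design, truth


def make_parameter_pool(
    n: int = 5000,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    mu_loc: float = float(np.log(50e-6)),
    mu_scale: float = 1.5,
    delta_sds: tuple[float, float] = (0.5, 1.0),
    sigma2_shape: float = 2.0,
    sigma2_mean: float = 0.1,
) -> ParameterPool:
    """Draw a transcript parameter pool for the simulator.

    Group-1 means are Normal(log 50 CPM-scale, 1.5^2); treatment effects
    delta are an equal mixture of Normal(0, 0.5^2) and Normal(0, 1^2) so the
    DE set spans small to large effects; residual variances sigma^2 are
    Gamma(shape 2, mean 0.1).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    mu1 = rng.normal(mu_loc, mu_scale, size=n)
    which = rng.integers(0, len(delta_sds), size=n)
    delta = rng.normal(0.0, np.asarray(delta_sds)[which])
    sigma2 = rng.gamma(sigma2_shape, sigma2_mean / sigma2_shape, size=n)
    params = [
        TranscriptParams(np.array([m, m + d]), s)
        for m, d, s in zip(mu1, delta, sigma2)
    ]
    return ParameterPool(params, [f"pool{i+1}" for i in range(n)])


def make_preset(name: str, seed: int | None = None):
    """Build a named preset; returns the tuple its generator returns."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    if name == "cheung-like":
        return make_exchangeable_base(spec)
    return make_blocked_base(spec)
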