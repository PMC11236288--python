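"""Synthetic scRNA-seq counts with a designated enriched gene set.

The generator emulates the standard gamma-Poisson (negative binomial)
single-cell simulation scheme: per-gene baseline means are gamma
distributed, per-cell library sizes are log-normal, and counts for cell i
and gene g are negative binomial with mean

    mu_ig = libsize_i * m_g(group_i) / sum_g m_g(group_i)

and a fixed dispersion. Differential expression between the two phenotype
groups is introduced only inside a designated "enriched" gene set: each
member gene is DE with probability ``de_prob``, and its group-2 mean is
multiplied (or divided, with equal probability, mirroring up/down
regulation) by a factor drawn from exp(N(de_factor_size, 0.4^2)). Note
that a DE factor "size" of 0 still perturbs means (the factor is
log-normal around 1), giving subtle but non-trivial DE. A same-sized
"irrelevant" gene set with no DE serves as the specificity control.

Optionally the population is split into latent subpopulations (e.g. cell
types) that carry their own expression factors on the enriched set in
both groups; this produces the multi-cluster latent structure used to
test cell-type-informed training. Dropout beyond the NB sampling noise
and batch effects are deliberately not modelled.

Every random draw flows from ``seed`` through named substreams, so any
scenario is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .genesets import GeneSetCollection

_STREAMS = ("means", "de", "groups", "libsize", "counts", "subpops")


@dataclass
class SimConfig:
    """Generator parameters.

    ``de_factor_size`` is the location of the log-normal DE factor law
    exp(N(location, 0.4^2)); ``group_prob`` the fraction of cells in
    group 1. Defaults give 1000 balanced cells, 2000 genes, a 100-gene
    enriched set with half its genes DE, and droplet-scale library sizes.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    group_prob: float = 0.5
    de_factor_size: float = 1.0
    de_prob: float = 0.5
    de_factor_scale: float = 0.4
    enriched_set_size: int = 100
    irrelevant_set_size: int = 100
    nb_dispersion: float = 0.5
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    libsize_location: float = math.log(1e4)
    libsize_scale: float = 0.2
    n_subpops: int = 1
    subpop_de_prob: float = 0.5
    subpop_de_factor_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.group_prob <= 1.0 and 0.0 <= self.de_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_cells, self.n_genes, self.enriched_set_size,
               self.irrelevant_set_size, self.n_subpops) < 1:
            raise ValueError("sizes must be >= 1")
        if self.n_genes < self.enriched_set_size + self.irrelevant_set_size:
            raise ValueError("n_genes must cover both gene sets")
        if self.nb_dispersion <= 0 or self.mean_shape <= 0 or self.mean_rate <= 0:
            raise ValueError("dispersion and gamma parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    base_means: np.ndarray          # (N,) gamma baseline means
    de_indicator: np.ndarray        # (N,) bool, nonzero only in enriched set
    de_factor: np.ndarray           # (N,) realized group-2 factor (1 if not DE)
    enriched_genes: List[str]
    irrelevant_genes: List[str]
    groups: np.ndarray              # (n,) 1/2 phenotype
    subpops: Optional[np.ndarray]   # (n,) 1..n_subpops or None
    libsizes: np.ndarray            # (n,)
    subpop_factors: Optional[np.ndarray]  # (n_subpops, N) or None


def _rngs(seed: int) -> Dict[str, np.random.Generator]:
    return {name: np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(_STREAMS)}


def simulate_dataset(cfg: SimConfig
                     ) -> Tuple[ExpressionDataset, GeneSetCollection, SimTruth]:
    """Draw one dataset: raw counts, the two gene sets, and full truth."""
    rng = _rngs(cfg.seed)
    N, n = cfg.n_genes, cfg.n_cells
    gene_names = [f"g{i:05d}" for i in range(N)]

    base_means = rng["means"].gamma(shape=cfg.mean_shape,
                                    scale=1.0 / cfg.mean_rate, size=N)
    base_means = np.maximum(base_means, 1e-8)

    member_idx = rng["de"].choice(N, size=cfg.enriched_set_size
                                  + cfg.irrelevant_set_size, replace=False)
    enriched_idx = np.sort(member_idx[:cfg.enriched_set_size])
    irrelevant_idx = np.sort(member_idx[cfg.enriched_set_size:])

    de_indicator = np.zeros(N, dtype=bool)
    de_factor = np.ones(N)
    de_mask = rng["de"].random(cfg.enriched_set_size) < cfg.de_prob
    de_genes = enriched_idx[de_mask]
    de_indicator[de_genes] = True
    raw = np.exp(rng["de"].normal(cfg.de_factor_size, cfg.de_factor_scale,
                                  size=de_genes.size))
    flip = rng["de"].random(de_genes.size) < 0.5
    de_factor[de_genes] = np.where(flip, 1.0 / raw, raw)

    # deterministic group sizes, shuffled assignment
    n1 = int(round(cfg.group_prob * n))
    n1 = min(max(n1, 1), n - 1) if 0.0 < cfg.group_prob < 1.0 else n1
    groups = np.full(n, 2, dtype=np.int64)
    groups[:n1] = 1
    rng["groups"].shuffle(groups)

    subpops = subpop_factors = None
    if cfg.n_subpops > 1:
        subpops = rng["subpops"].integers(1, cfg.n_subpops + 1, size=n)
        subpop_factors = np.ones((cfg.n_subpops, N))
        for b in range(1, cfg.n_subpops):   # subpop 1 is the reference
            hit = rng["subpops"].random(cfg.enriched_set_size) \
                < cfg.subpop_de_prob
            genes_b = enriched_idx[hit]
            raw_b = np.exp(rng["subpops"].normal(
                cfg.subpop_de_factor_size, cfg.de_factor_scale,
                size=genes_b.size))
            flip_b = rng["subpops"].random(genes_b.size) < 0.5
            subpop_factors[b, genes_b] = np.where(flip_b, 1.0 / raw_b, raw_b)

    libsizes = rng["libsize"].lognormal(cfg.libsize_location,
                                        cfg.libsize_scale, size=n)

    means_by_group = np.stack([base_means, base_means * de_factor])  # (2, N)
    cell_means = means_by_group[groups - 1]                           # (n, N)
    if subpop_factors is not None:
        cell_means = cell_means * subpop_factors[subpops - 1]
    cell_means = cell_means / cell_means.sum(axis=1, keepdims=True)
    mu = cell_means * libsizes[:, None]

    # gamma-Poisson mixture = NB with var = mu + dispersion * mu^2
    shape = 1.0 / cfg.nb_dispersion
    lam = rng["counts"].gamma(shape=shape, scale=mu * cfg.nb_dispersion)
    X = rng["counts"].poisson(lam).astype(np.float64)

    ds = ExpressionDataset(X=X, gene_names=gene_names, y=groups,
                           q=subpops,
                           y_categories=[1, 2],
                           q_categories=(list(range(1, cfg.n_subpops + 1))
                                         if subpops is not None else []))
    enriched_genes = [gene_names[i] for i in enriched_idx]
    irrelevant_genes = [gene_names[i] for i in irrelevant_idx]
    sets = GeneSetCollection.from_members(
        {"enriched_set": enriched_genes, "irrelevant_set": irrelevant_genes},
        gene_names)
    truth = SimTruth(base_means=base_means, de_indicator=de_indicator,
                     de_factor=de_factor, enriched_genes=enriched_genes,
                     irrelevant_genes=irrelevant_genes, groups=groups,
                     subpops=subpops, libsizes=libsizes,
                     subpop_factors=subpop_factors)
    return ds, sets, truth


SWEEP_AXES = ("de_factor_size", "de_prob", "n_cells", "group_prob")


def scenario_sweep(axis: str, values: Sequence, base: SimConfig,
                   replicates: int = 1
                   ) -> Tuple[pd.DataFrame, List[Tuple[ExpressionDataset,
                                                       GeneSetCollection,
                                                       SimTruth]]]:
    """Generate datasets along one experimental axis.

    Returns a manifest (axis, value, replicate, seed) with one row per
    dataset, and the datasets in manifest order. Seeds derive
    deterministically from ``base.seed``.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    rows, datasets = [], []
    for vi, value in enumerate(values):
        for rep in range(replicates):
            seed = int(np.random.SeedSequence(
                entropy=base.seed,
                spawn_key=(vi, rep)).generate_state(1)[0] % (2 ** 31))
            cfg = replace(base, seed=seed, **{
                axis: (int(value) if axis == "n_cells" else float(value))})
            datasets.append(simulate_dataset(cfg))
            rows.append({"axis": axis, "value": value, "replicate": rep,
                         "seed": seed})
    return pd.DataFrame(rows), datasets


def sample_background_sets(ds: ExpressionDataset, sizes: Sequence[int],
                           count: int, exclude: Sequence[str] = (),
                           seed: int = 0) -> GeneSetCollection:
    """Random gene sets from non-enriched genes for specificity testing.

    Draws ``count`` distinct sets of each size in ``sizes`` from the
    dataset's genes minus ``exclude``.
    """
    pool = [g for g in ds.gene_names if g not in set(exclude)]
    rng = np.random.default_rng(seed)
    sets: Dict[str, List[str]] = {}
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"set size {size} exceeds {len(pool)} "
                             "available background genes")
        if math.comb(len(pool), size) < count:
            raise ValueError(
                f"cannot draw {count} distinct sets of size {size} "
                f"from {len(pool)} genes")
        seen = set()
        attempts = 0
        while len(seen) < count:
            draw = tuple(sorted(rng.choice(len(pool), size=size,
                                           replace=False).tolist()))
            attempts += 1
            if attempts > 1000 * count:
                raise ValueError("failed to draw enough distinct sets")
            if draw in seen:
                continue
            seen.add(draw)
            sets[f"bg_s{size}_r{len(seen) - 1}"] = [pool[i] for i in draw]
    return GeneSetCollection.from_members(sets, ds.gene_names)
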