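"""Seeded multi-batch negative-binomial count simulator.

Emulates the features of multi-section/multi-platform transcriptomics data
that drive batch effects: shared cell types with differential marker genes,
per-batch multiplicative gene shifts (the batch effect proper), per-batch
library-size differences (platform depth), and negative-binomial
overdispersion. Counts for cell c of type t in batch b at gene g are drawn

    counts ~ NB(mean = base_g * typefactor_gt * batchfactor_gb * libsize_cb)

with log batchfactor ~ Normal(0, batch_effect^2) per (gene, batch), so
``batch_effect = 0`` produces exchangeable batches (the null) and larger
values produce progressively stronger, classifier-detectable separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import IntegratedDataset


@dataclass
class SimConfig:
    n_batches: int = 3
    cells_per_batch: int = 300
    n_genes: int = 500
    n_cell_types: int = 3
    de_fraction: float = 0.1      # fraction of genes differential between types
    type_effect: float = 1.0      # log-fold scale of type marker up-regulation
    batch_effect: float = 1.0     # sd of per-(gene,batch) log shifts; 0 = null
    libsize_factor: tuple[float, float] = (0.7, 1.3)  # per-batch depth multiplier range
    nb_dispersion: float = 10.0   # gamma shape; larger = closer to Poisson
    with_spatial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_effect < 0:
            raise ValueError("batch_effect must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        for name in ("n_batches", "cells_per_batch", "n_genes", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


def simulate_batches(config: SimConfig | None = None) -> IntegratedDataset:
    """Generate a multi-batch dataset with ground-truth batch and type labels.

    Deterministic for a fixed config (identical seed gives bit-identical
    matrices). Negative-binomial sampling uses the gamma-Poisson mixture with
    gamma shape ``nb_dispersion``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    g, b, t = config.n_genes, config.n_batches, config.n_cell_types
    n_per = config.cells_per_batch
    n = b * n_per

    base = rng.lognormal(mean=1.0, sigma=1.0, size=g)  # baseline per-gene mean

    # type markers: de_fraction of genes split among types, multiplied up
    type_factor = np.ones((t, g))
    n_de = int(round(config.de_fraction * g))
    de_genes = rng.choice(g, size=n_de, replace=False)
    owner = rng.integers(0, t, size=n_de)
    for tt in range(t):
        type_factor[tt, de_genes[owner == tt]] = np.exp(config.type_effect)

    # batch effect: per-(gene, batch) multiplicative log-normal shift
    batch_factor = np.exp(rng.normal(0.0, config.batch_effect, size=(b, g)))

    # per-batch depth multiplier plus mild per-cell variation
    lo, hi = config.libsize_factor
    depth_b = rng.uniform(lo, hi, size=b)

    matrix = np.empty((n, g))
    batch = np.empty(n, dtype=object)
    cell_type = np.empty(n, dtype=object)
    row = 0
    for bb in range(b):
        types = rng.integers(0, t, size=n_per)
        libsize = depth_b[bb] * rng.lognormal(0.0, 0.1, size=n_per)
        mu = base[None, :] * type_factor[types] * batch_factor[bb][None, :] \
            * libsize[:, None]
        shape = config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        matrix[row:row + n_per] = rng.poisson(lam)
        batch[row:row + n_per] = f"batch{bb}"
        cell_type[row:row + n_per] = np.array([f"type{x}" for x in types], dtype=object)
        row += n_per

    spatial = rng.uniform(0.0, 100.0, size=(n, 2)) if config.with_spatial else None
    return IntegratedDataset(
        matrix=matrix,
        obs_ids=[f"cell{i}" for i in range(n)],
        gene_ids=[f"gene{j}" for j in range(g)],
        batch=batch,
        cell_type=cell_type,
        spatial=spatial,
    )
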