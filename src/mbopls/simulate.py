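"""Synthetic multi-block data with known latent structure.

Generates datasets carrying the statistical structure the multi-block
model assumes: one shared trait-correlated latent variable with sparse
feature loadings, block-specific trait-orthogonal latent variance,
population structure affecting both trait and features, Gaussian noise,
and missingness completely at random.  Everything is drawn from a single
seeded generator in a documented, fixed order so fixtures are stable.

Draw order per dataset: (1) Q-matrix rows (Dirichlet), (2) subpopulation
offsets for the trait, (3) shared latent scores, (4) trait noise, then
per block: (5) informative-feature indices, (6) signs/loadings,
(7) orthogonal latent scores and loadings, (8) feature-wise population
offsets, (9) noise matrix, (10) missingness mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import DataError, OmicsBlock, PopulationMembership, TraitVector

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "generate_null",
           "rdrs_like_spec"]


@dataclass
class SyntheticSpec:
    """Parameters of the generative model."""

    n_samples: int = 70
    n_blocks: int = 2
    features_per_block: tuple = (50, 40)
    n_subpopulations: int = 3
    dirichlet_concentration: float = 0.3
    trait_signal_strength: float = 0.7   # trait variance fraction from shared latent
    n_orth_latents_per_block: int = 1
    orth_variance_scale: float = 1.0
    n_informative_per_block: tuple = (10, 10)
    loading_scale: float = 1.0
    noise_sd: float = 0.3
    missing_fraction: float = 0.0
    population_effect_size: float = 0.0  # on trait and features
    seed: int = 0

    def __post_init__(self):
        self.features_per_block = tuple(self.features_per_block)
        if isinstance(self.n_informative_per_block, int):
            self.n_informative_per_block = (self.n_informative_per_block,) * self.n_blocks
        self.n_informative_per_block = tuple(self.n_informative_per_block)
        if len(self.features_per_block) != self.n_blocks:
            raise DataError("features_per_block length must equal n_blocks")
        if len(self.n_informative_per_block) != self.n_blocks:
            raise DataError("n_informative_per_block length must equal n_blocks")
        for p, k in zip(self.features_per_block, self.n_informative_per_block):
            if k > p:
                raise DataError("more informative features than features in a block")
        if not (0 <= self.trait_signal_strength <= 1):
            raise DataError("trait_signal_strength must be in [0, 1]")
        if not (0 <= self.missing_fraction < 1):
            raise DataError("missing_fraction must be in [0, 1)")
        if self.n_samples < 3 or self.n_blocks < 1 or self.n_subpopulations < 1:
            raise DataError("counts must be positive")


@dataclass
class SyntheticDataset:
    blocks: list
    trait: TraitVector
    q: PopulationMembership
    truth: dict = field(default_factory=dict)


def _standardize(v):
    return (v - v.mean()) / v.std()


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the generative model (reproducible from seed)."""
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_samples, spec.n_subpopulations
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    Q = rng.dirichlet([spec.dirichlet_concentration] * k, size=n)
    pop_offsets_trait = rng.normal(size=k)
    t = _standardize(rng.normal(size=n))
    trait_noise = rng.normal(size=n)

    s = spec.trait_signal_strength
    y = np.sqrt(s) * t + np.sqrt(1 - s) * _standardize(trait_noise)
    y = y + spec.population_effect_size * (Q @ pop_offsets_trait)

    blocks, informative, orth_scores = [], [], []
    for i in range(spec.n_blocks):
        p = spec.features_per_block[i]
        n_inf = spec.n_informative_per_block[i]
        idx = np.sort(rng.choice(p, size=n_inf, replace=False))
        w = np.zeros(p)
        if n_inf:
            signs = rng.choice([-1.0, 1.0], size=n_inf)
            mags = spec.loading_scale * (0.5 + rng.random(n_inf))
            w[idx] = signs * mags
        X = np.outer(t, w)
        t_os = []
        for _ in range(spec.n_orth_latents_per_block):
            t_o = _standardize(rng.normal(size=n))
            # orthogonalize against the shared latent so the planted
            # structure really is trait-orthogonal
            t_o = _standardize(t_o - (t_o @ t) / (t @ t) * t)
            p_o = rng.normal(scale=spec.orth_variance_scale, size=p)
            X = X + np.outer(t_o, p_o)
            t_os.append(t_o)
        pop_load = rng.normal(size=(k, p))
        X = X + spec.population_effect_size * (Q @ pop_load)
        X = X + spec.noise_sd * rng.normal(size=(n, p))
        if spec.missing_fraction > 0:
            mask = rng.random((n, p)) < spec.missing_fraction
            # never blank out a full column
            full = mask.all(axis=0)
            mask[0, full] = False
            X = np.where(mask, np.nan, X)
        fids = [f"B{i + 1}_F{j + 1:04d}" for j in range(p)]
        blocks.append(OmicsBlock(sample_ids, fids, X, platform=f"platform{i + 1}"))
        informative.append(idx.tolist())
        orth_scores.append(np.column_stack(t_os) if t_os else np.empty((n, 0)))

    trait = TraitVector(sample_ids, y, name="trait")
    q = PopulationMembership(sample_ids, Q)
    truth = {"informative": informative, "shared_latent": t,
             "orth_scores": orth_scores,
             "pop_offsets_trait": pop_offsets_trait}
    return SyntheticDataset(blocks=blocks, trait=trait, q=q, truth=truth)


def generate_null(spec: SyntheticSpec,
                  keep_population_effect_on_trait: bool = False) -> SyntheticDataset:
    """Dataset whose trait is independent of all block structure.

    The blocks are generated exactly as in :func:`generate`; the trait is
    then replaced by an independent draw (population effect on the trait
    optionally retained).
    """
    ds = generate(replace(spec, trait_signal_strength=0.0))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBADD]))
    y = _standardize(rng.normal(size=spec.n_samples))
    if keep_population_effect_on_trait:
        y = y + spec.population_effect_size * (ds.q.q @ ds.truth["pop_offsets_trait"])
    ds.trait = TraitVector(ds.trait.sample_ids, y, name="null_trait")
    ds.truth["informative"] = [[] for _ in range(spec.n_blocks)]
    return ds


def rdrs_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Default fixture shaped like a 70-sample, 4-platform field study."""
    params = dict(
        n_samples=70, n_blocks=4, features_per_block=(200, 150, 100, 80),
        n_subpopulations=3, dirichlet_concentration=0.3,
        trait_signal_strength=0.7, n_orth_latents_per_block=1,
        orth_variance_scale=1.0,
        n_informative_per_block=(20, 15, 10, 8), loading_scale=1.0,
        noise_sd=0.3, missing_fraction=0.05, population_effect_size=0.0,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticSpec(**params)
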