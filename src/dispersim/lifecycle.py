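"""Developmental switch, dispersal, fecundity, recruitment, mutation, extinction.

Scalar operations on :class:`~dispersim.core_model.Genotype` /
:class:`~dispersim.core_model.Individual` mirror the vectorized kernels the
engine uses; both share the same arithmetic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core_model import Genotype, Individual, SimulationConfig, World

__all__ = [
    "develop",
    "develop_world",
    "dispersal_phase",
    "fecundity",
    "recruit_patch",
    "sample_parent_indices",
    "mutate",
    "mutate_array",
    "apply_extinction",
]


def develop(genotype: Genotype, rng: np.random.Generator):
    """Run the developmental switch for one newborn.

    A threshold ``u`` is drawn uniformly from [0, 1); the individual
    becomes a disperser iff its dispersal tendency exceeds the threshold
    (``d > u``).  The matching locus pair is expressed irreversibly:
    dispersers express ``(l_d, e_d)``, residents ``(l_r, e_r)``.

    Returns ``(is_disperser, expressed_l, expressed_e)``.
    """
    u = rng.random()
    if genotype.d > u:
        return True, genotype.l_d, genotype.e_d
    return False, genotype.l_r, genotype.e_r


def develop_world(world: World, rng: np.random.Generator) -> None:
    """Vectorized developmental switch for the whole newborn cohort."""
    n = world.n_alive
    u = rng.random(n)
    disp = world.genotype[:, 0] > u
    world.is_disperser = disp
    world.expressed_l = np.where(disp, world.genotype[:, 2], world.genotype[:, 1])
    world.expressed_e = np.where(disp, world.genotype[:, 4], world.genotype[:, 3])
    world.developed = True


def dispersal_phase(world: World, cfg: SimulationConfig,
                    rng: np.random.Generator) -> int:
    """Single instantaneous dispersal event between the two foraging phases.

    Every disperser draws a uniform number; if it falls below the dispersal
    mortality it dies (removed entirely: no post-phase foraging, no
    reproduction).  Survivors relocate to a patch drawn uniformly from all
    patches, the natal patch included.  Residents are untouched.  Dispersal
    consumes no time.  Returns the number of dispersal deaths.
    """
    disp = world.is_disperser
    n_disp = int(disp.sum())
    if n_disp == 0:
        return 0
    u = rng.random(n_disp)
    dies = u < cfg.dispersal_mortality
    destinations = rng.integers(0, cfg.n_patches, size=n_disp)

    new_patch = world.current_patch.copy()
    new_patch[disp] = destinations
    world.current_patch = new_patch

    keep = np.ones(world.n_alive, dtype=bool)
    keep[np.flatnonzero(disp)[dies]] = False
    world.filter(keep)
    return int(dies.sum())


def fecundity(v_total, expressed_l, learning_cost):
    """Fecundity ``F = max(0, V_total * (1 - L * alpha))``.

    The raw expression goes negative once ``L > 1 / alpha`` (with the
    default cost 1.4, for ``L > ~0.714``); since ``F`` serves as a
    recruitment sampling weight it is floored at zero.
    """
    return np.maximum(0.0, np.asarray(v_total) * (1.0 - np.asarray(expressed_l) * learning_cost))


def sample_parent_indices(weights: np.ndarray, k: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw ``k`` parent positions with replacement, probability ~ weight.

    All-zero weights fall back to uniform sampling: an occupied patch
    where every fecundity is numerically zero should not go spuriously
    extinct."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total > 0.0:
        return rng.choice(len(weights), size=k, replace=True, p=weights / total)
    return rng.integers(0, len(weights), size=k)


def recruit_patch(occupants: Sequence[tuple[Individual, float]],
                  carrying_capacity: int,
                  rng: np.random.Generator) -> list[Genotype]:
    """Recruit the next generation of one patch.

    Samples exactly ``carrying_capacity`` offspring with replacement among
    the patch's occupants, each parent chosen with probability
    ``F / sum(F)``; offspring genotypes are exact copies of the parent's
    loci (mutation is applied separately).  An empty patch yields no
    offspring -- it can only be recolonized by immigrants.
    """
    if len(occupants) == 0:
        return []
    weights = np.array([f for _, f in occupants], dtype=float)
    idx = sample_parent_indices(weights, carrying_capacity, rng)
    return [occupants[i][0].genotype for i in idx]


def mutate(genotype: Genotype, mutation_prob: float, sd: float,
           rng: np.random.Generator) -> Genotype:
    """Mutate one genotype: each locus independently, with probability
    ``mutation_prob``, is redrawn from a normal distribution centred on the
    parental value with the given SD, clamped to [0, 1]."""
    values = genotype.as_array()
    fires = rng.random(len(values)) < mutation_prob
    proposals = rng.normal(values, sd)
    values = np.where(fires, np.clip(proposals, 0.0, 1.0), values)
    return Genotype.from_array(values)


def mutate_array(genotypes: np.ndarray, mutation_prob: float, sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized :func:`mutate` over an (n, 5) genotype array."""
    fires = rng.random(genotypes.shape) < mutation_prob
    proposals = rng.normal(genotypes, sd) if sd > 0 else genotypes
    return np.where(fires, np.clip(proposals, 0.0, 1.0), genotypes)


def apply_extinction(world: World, cfg: SimulationConfig, generation_index: int,
                     rng: np.random.Generator) -> World:
    """Periodic patch extinction, applied to the freshly recruited cohort.

    Every ``extinction_every`` generations (1-based index), ``extinction_count``
    distinct patches drawn uniformly at random are emptied.  Otherwise a
    no-op.  Consecutive events may strike the same patch again.
    """
    if (
        cfg.extinction_every is None
        or cfg.extinction_count == 0
        or generation_index % cfg.extinction_every != 0
    ):
        return world
    doomed = rng.choice(cfg.n_patches, size=cfg.extinction_count, replace=False)
    keep = ~np.isin(world.current_patch, doomed)
    world.filter(keep)
    return world
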