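"""Generation loop, replicate management, seeding, and time-series recording.

A single seeded :class:`numpy.random.Generator` drives every stochastic
event of a run, so ``(config, seed)`` fully determines every output byte.
Replicate ``k`` of a batch derives its seed deterministically from
``SeedSequence([base_seed, k])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    GenerationRecord,
    SimulationConfig,
    World,
    config_to_toml,
    init_world,
    validate_config,
)
from .foraging import forage_phase
from .lifecycle import (
    apply_extinction,
    develop_world,
    dispersal_phase,
    fecundity,
    mutate_array,
    sample_parent_indices,
)

__all__ = [
    "RunResult",
    "run_generation",
    "run_simulation",
    "run_replicates",
    "replicate_seed",
    "run_to_dataframe",
    "write_run_csv",
    "run_manifest",
]

#: Column order of the per-generation CSV.
CSV_COLUMNS = [
    "generation",
    "mean_D",
    "mean_L_R_locus",
    "mean_L_D_locus",
    "mean_E_R_locus",
    "mean_E_D_locus",
    "mean_L_expressed_residents",
    "mean_L_expressed_dispersers",
    "n_residents",
    "n_dispersers",
    "n_alive",
    "mean_F",
]


@dataclass
class RunResult:
    """Outcome of one simulation run.

    ``records`` holds one :class:`GenerationRecord` per completed
    generation; if the metapopulation went globally extinct the sequence
    is truncated and ``extinct_generation`` marks the generation whose
    recruitment produced no offspring.
    """

    config: SimulationConfig
    seed: int
    records: list[GenerationRecord] = field(default_factory=list)
    extinct: bool = False
    extinct_generation: int | None = None
    final_occupancy: list[int] = field(default_factory=list)

    @property
    def n_generations_run(self) -> int:
        return len(self.records)


def _census(world: World, cfg: SimulationConfig, generation: int) -> GenerationRecord:
    n = world.n_alive
    if n == 0:
        locus_means = {name: float("nan") for name in ("d", "l_r", "l_d", "e_r", "e_d")}
        return GenerationRecord(
            generation=generation,
            locus_means=locus_means,
            expressed_means={
                "l_residents": None,
                "l_dispersers": None,
                "e_residents": None,
                "e_dispersers": None,
            },
            n_residents=0,
            n_dispersers=0,
            patch_occupancy=[0] * cfg.n_patches,
            mean_fecundity=float("nan"),
        )
    means = world.genotype.mean(axis=0)
    disp = world.is_disperser
    res = ~disp

    def class_mean(values: np.ndarray, mask: np.ndarray) -> float | None:
        return float(values[mask].mean()) if mask.any() else None

    f = fecundity(world.v_total, world.expressed_l, cfg.learning_cost)
    return GenerationRecord(
        generation=generation,
        locus_means={
            "d": float(means[0]),
            "l_r": float(means[1]),
            "l_d": float(means[2]),
            "e_r": float(means[3]),
            "e_d": float(means[4]),
        },
        expressed_means={
            "l_residents": class_mean(world.expressed_l, res),
            "l_dispersers": class_mean(world.expressed_l, disp),
            "e_residents": class_mean(world.expressed_e, res),
            "e_dispersers": class_mean(world.expressed_e, disp),
        },
        n_residents=int(res.sum()),
        n_dispersers=int(disp.sum()),
        patch_occupancy=world.occupancy().tolist(),
        mean_fecundity=float(f.mean()),
    )


def _recruit(world: World, cfg: SimulationConfig, rng: np.random.Generator,
             uniform_fitness: bool) -> World:
    """Fitness-proportional recruitment, each occupied patch independently."""
    f = fecundity(world.v_total, world.expressed_l, cfg.learning_cost)
    if uniform_fitness:
        f = np.ones_like(f)
    offspring_genotypes: list[np.ndarray] = []
    offspring_patch: list[np.ndarray] = []
    for p in range(cfg.n_patches):
        idx = np.flatnonzero(world.current_patch == p)
        if len(idx) == 0:
            continue
        parents = idx[sample_parent_indices(f[idx], cfg.n_individuals, rng)]
        offspring_genotypes.append(world.genotype[parents])
        offspring_patch.append(np.full(cfg.n_individuals, p, dtype=np.int64))
    if offspring_genotypes:
        genotype = np.concatenate(offspring_genotypes)
        natal = np.concatenate(offspring_patch)
    else:
        genotype = np.empty((0, 5))
        natal = np.empty(0, dtype=np.int64)
    return World(cfg, genotype, natal)


def run_generation(world: World, cfg: SimulationConfig, generation_index: int,
                   rng: np.random.Generator,
                   uniform_fitness: bool = False,
                   intake_hook: Callable | None = None) -> tuple[World, GenerationRecord]:
    """Advance the world by one full generation.

    Order of events: developmental switch for the newborn cohort (skipped
    if the cohort already developed, e.g. founders) -> pre-dispersal
    foraging -> dispersal -> post-dispersal foraging -> census ->
    fecundity-proportional recruitment per patch -> mutation of all
    offspring -> periodic patch extinction.  Returns the offspring world
    and the census record.

    ``uniform_fitness`` replaces every recruitment weight with 1 (selection
    switched off) while leaving all other processes untouched; used for
    neutrality diagnostics.  ``intake_hook``, if given, receives
    ``(phase_name, PhaseIntake, world)`` after each foraging phase for
    conservation audits.
    """
    if not world.developed:
        develop_world(world, rng)
    intake = forage_phase(world, cfg, "before")
    if intake_hook is not None:
        intake_hook("before", intake, world)
    dispersal_phase(world, cfg, rng)
    intake = forage_phase(world, cfg, "after")
    if intake_hook is not None:
        intake_hook("after", intake, world)
    record = _census(world, cfg, generation_index)
    offspring = _recruit(world, cfg, rng, uniform_fitness)
    offspring.genotype = mutate_array(
        offspring.genotype, cfg.mutation_prob, cfg.mutation_sd, rng
    )
    apply_extinction(offspring, cfg, generation_index, rng)
    return offspring, record


def run_simulation(cfg: SimulationConfig, uniform_fitness: bool = False,
                   progress: Callable[[int, int], None] | None = None) -> RunResult:
    """Run a full simulation: world initialization plus ``n_generations``
    generations under one seeded generator.

    Global extinction truncates the run (a legitimate outcome at extreme
    parameters) and is flagged on the result rather than raised.
    """
    cfg = validate_config(cfg)
    rng = np.random.default_rng(cfg.seed)
    world = init_world(cfg, rng)
    result = RunResult(config=cfg, seed=cfg.seed)
    for gen in range(1, cfg.n_generations + 1):
        world, record = run_generation(world, cfg, gen, rng, uniform_fitness)
        result.records.append(record)
        if progress is not None:
            progress(gen, cfg.n_generations)
        if world.n_alive == 0:
            result.extinct = True
            result.extinct_generation = gen
            break
    result.final_occupancy = world.occupancy().tolist()
    return result


def replicate_seed(base_seed: int, k: int) -> int:
    """Deterministic seed for replicate ``k`` of a batch (always < 2**31)."""
    ss = np.random.SeedSequence([int(base_seed), int(k)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicates(cfg: SimulationConfig, n_replicates: int, base_seed: int,
                   uniform_fitness: bool = False) -> list[RunResult]:
    """Run ``n_replicates`` independent replicates of one configuration,
    with per-replicate seeds derived from ``base_seed``."""
    import dataclasses

    results = []
    for k in range(n_replicates):
        rep_cfg = dataclasses.replace(cfg, seed=replicate_seed(base_seed, k))
        results.append(run_simulation(rep_cfg, uniform_fitness=uniform_fitness))
    return results


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def run_to_dataframe(result: RunResult) -> pd.DataFrame:
    """One row per generation, columns as in :data:`CSV_COLUMNS`."""
    rows = []
    for rec in result.records:
        rows.append(
            {
                "generation": rec.generation,
                "mean_D": rec.locus_means["d"],
                "mean_L_R_locus": rec.locus_means["l_r"],
                "mean_L_D_locus": rec.locus_means["l_d"],
                "mean_E_R_locus": rec.locus_means["e_r"],
                "mean_E_D_locus": rec.locus_means["e_d"],
                "mean_L_expressed_residents": rec.expressed_means["l_residents"],
                "mean_L_expressed_dispersers": rec.expressed_means["l_dispersers"],
                "n_residents": rec.n_residents,
                "n_dispersers": rec.n_dispersers,
                "n_alive": rec.n_residents + rec.n_dispersers,
                "mean_F": rec.mean_fecundity,
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_run_csv(result: RunResult, path: str | Path) -> None:
    run_to_dataframe(result).to_csv(path, index=False)


def run_manifest(result: RunResult) -> dict:
    """JSON-serializable manifest sufficient to reproduce the run exactly."""
    return {
        "seed": result.seed,
        "n_generations_run": result.n_generations_run,
        "extinct": result.extinct,
        "extinct_generation": result.extinct_generation,
        "config_toml": config_to_toml(result.config),
    }


def write_run_manifest(result: RunResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(run_manifest(result), indent=2) + "\n")
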