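"""Shipped parameter presets for the two published experiments.

Two experiment families are provided:

* **Season-length sweep** -- symmetric phases ``t_before == t_after == T``
  for ``T`` in :data:`SEASON_PHASE_LENGTHS`; the hard-to-access resource
  has handling time 300 and each of the two patch types offers a different
  hard resource (R2 vs R3), so a disperser that switches patch type cannot
  reuse its practice.
* **Dispersal-timing sweep** -- fixed season length 20 split as
  ``(t_before, t_after)`` in :data:`TIMING_SPLITS`; handling time 150 and
  a stronger competition factor.

Both use 12 patches of 100 individuals, two equally frequent patch types
(first half of the patch indices type 1, second half type 2 -- spatial
arrangement is irrelevant under global dispersal), dispersal mortality
0.01, learning cost 1.4, mutation probability 0.1 with SD 0.1, and one
random patch extinction every second generation.
"""

from __future__ import annotations

from pathlib import Path

from .core_model import (
    PatchTypeSpec,
    ResourceSpec,
    SimulationConfig,
    config_to_toml,
    validate_config,
)

__all__ = [
    "SEASON_PHASE_LENGTHS",
    "TIMING_SPLITS",
    "season_length_config",
    "dispersal_timing_config",
    "neutral_drift_config",
    "write_preset_files",
]

#: Phase lengths T (with t_before = t_after = T) of the season-length sweep.
SEASON_PHASE_LENGTHS = (2, 4, 10, 15, 25, 50, 150, 250, 500, 1000, 2000)

#: (t_before, t_after) splits of the dispersal-timing sweep (season = 20).
TIMING_SPLITS = ((2, 18), (10, 10), (18, 2))


def _balanced_assignment(n_patches: int) -> tuple[int, ...]:
    half = n_patches // 2
    return tuple([1] * half + [2] * (n_patches - half))


def season_length_config(phase_length: int, n_generations: int = 300,
                         seed: int = 0) -> SimulationConfig:
    """Season-length experiment preset with ``t_before = t_after = phase_length``.

    Patch type 1 offers the easy resource R1 (abundance 1) plus hard
    resource R2 (abundance 5); patch type 2 offers R1 plus hard resource
    R3.  Hard resources: value 10, handling time 300, detectability 0.5.
    """
    return validate_config(
        SimulationConfig(
            n_patches=12,
            n_individuals=100,
            n_generations=n_generations,
            t_before=phase_length,
            t_after=phase_length,
            dispersal_mortality=0.01,
            learning_cost=1.4,
            mutation_prob=0.1,
            mutation_sd=0.1,
            competition_factor=2.0,
            extinction_every=2,
            extinction_count=1,
            resources=(
                ResourceSpec(1, value=1.0, handling_time=1.0, detectability=0.5),
                ResourceSpec(2, value=10.0, handling_time=300.0, detectability=0.5),
                ResourceSpec(3, value=10.0, handling_time=300.0, detectability=0.5),
            ),
            patch_types=(
                PatchTypeSpec(1, {1: 1.0, 2: 5.0}),
                PatchTypeSpec(2, {1: 1.0, 3: 5.0}),
            ),
            patch_type_assignment=_balanced_assignment(12),
            seed=seed,
        )
    )


def dispersal_timing_config(t_before: int, t_after: int,
                            n_generations: int = 500,
                            seed: int = 0) -> SimulationConfig:
    """Dispersal-timing experiment preset (season length ``t_before + t_after``,
    nominally 20).

    Hard resources have handling time 150; competition factor 6.  Patch
    type 1 offers R1 + R2, patch type 2 offers R1 + R3 (abundance zero for
    the other hard resource, stated explicitly in the preset files).
    """
    return validate_config(
        SimulationConfig(
            n_patches=12,
            n_individuals=100,
            n_generations=n_generations,
            t_before=t_before,
            t_after=t_after,
            dispersal_mortality=0.01,
            learning_cost=1.4,
            mutation_prob=0.1,
            mutation_sd=0.1,
            competition_factor=6.0,
            extinction_every=2,
            extinction_count=1,
            resources=(
                ResourceSpec(1, value=1.0, handling_time=1.0, detectability=0.5),
                ResourceSpec(2, value=10.0, handling_time=150.0, detectability=0.5),
                ResourceSpec(3, value=10.0, handling_time=150.0, detectability=0.5),
            ),
            patch_types=(
                PatchTypeSpec(1, {1: 1.0, 2: 5.0, 3: 0.0}),
                PatchTypeSpec(2, {1: 1.0, 2: 0.0, 3: 5.0}),
            ),
            patch_type_assignment=_balanced_assignment(12),
            seed=seed,
        )
    )


def neutral_drift_config(n_generations: int = 500) -> SimulationConfig:
    """Configuration for the neutrality diagnostic: the season-length world
    with every selective force removable by configuration removed
    (dispersal mortality 0, no patch extinction).

    Run with ``run_simulation(..., uniform_fitness=True)`` this leaves the
    learning and exploration loci with no selection at all, so their
    population means drift around the neutral expectation 0.5 under
    mutation pressure alone.  The dispersal-tendency locus is *not*
    neutral even then: local recruitment makes dispersal an escape from
    kin competition, which selects it upward.
    """
    import dataclasses

    return dataclasses.replace(
        season_length_config(10, n_generations=n_generations),
        dispersal_mortality=0.0,
        extinction_every=None,
        extinction_count=0,
    )


def write_preset_files(directory: str | Path) -> list[Path]:
    """Write every shipped preset as a TOML file into ``directory``.

    Season-length presets are named ``table2_S<season>.toml`` (season =
    2 * phase length), timing presets ``table3_t<t_before>.toml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for t in SEASON_PHASE_LENGTHS:
        path = directory / f"table2_S{2 * t}.toml"
        path.write_text(config_to_toml(season_length_config(t)))
        written.append(path)
    for t_before, t_after in TIMING_SPLITS:
        path = directory / f"table3_t{t_before}.toml"
        path.write_text(config_to_toml(dispersal_timing_config(t_before, t_after)))
        written.append(path)
    return written
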