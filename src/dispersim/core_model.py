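"""Domain types, configuration schema, validation, and world initialization.

The model world is a metapopulation of ``n_patches`` habitat patches joined
by global dispersal.  Each patch belongs to one of a small number of patch
types which differ only in the abundances of the resource types they offer.
Every individual carries five heritable loci, each a real number in [0, 1]:

* ``d``   -- dispersal tendency (probability-like threshold trait),
* ``l_r`` -- learning ability expressed by the resident phenotype,
* ``l_d`` -- learning ability expressed by the disperser phenotype,
* ``e_r`` -- exploration tendency expressed by the resident phenotype,
* ``e_d`` -- exploration tendency expressed by the disperser phenotype.

A developmental switch at birth irreversibly fixes each individual as a
resident or a disperser and selects which locus pair it expresses.

For performance the simulation engine operates on a struct-of-arrays
:class:`World`; the per-individual dataclasses exist as a convenience /
inspection surface and for small-scale tests.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "LOCI",
    "MAX_RESOURCE_TYPES",
    "ConfigError",
    "ResourceSpec",
    "PatchTypeSpec",
    "SimulationConfig",
    "Genotype",
    "Individual",
    "GenerationRecord",
    "World",
    "validate_config",
    "config_from_toml",
    "config_to_toml",
    "init_world",
]

#: Order of the heritable loci in all array representations.
LOCI = ("d", "l_r", "l_d", "e_r", "e_d")

#: Hard limit on distinct resource types per configuration.
MAX_RESOURCE_TYPES = 10


class ConfigError(ValueError):
    """A configuration failed validation; the message names the offending field."""


# ---------------------------------------------------------------------------
# Specification types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResourceSpec:
    """One resource type.

    Parameters
    ----------
    resource_id
        Small positive integer identifying the resource (1..10).
    value
        Fitness value of a single handled item.
    handling_time
        Practice units needed before an item yields its full value.
        ``handling_time == 1`` denotes a resource requiring no learning.
    detectability
        Probability-like ease of finding an item, in [0, 1].  Fast
        exploration discounts intake of hard-to-detect resources.
    """

    resource_id: int
    value: float
    handling_time: float
    detectability: float


@dataclass(frozen=True)
class PatchTypeSpec:
    """A patch type: a mapping from resource id to its abundance.

    Abundance is the maximum number of items of that resource a single
    individual can encounter per time step.  Resources absent from the
    mapping have abundance zero in patches of this type.
    """

    patch_type_id: int
    abundances: Mapping[int, float]


@dataclass(frozen=True)
class SimulationConfig:
    """Complete parameterization of one simulation run.

    The season (= lifespan, this is an annual-lifecycle model) consists of
    ``t_before`` foraging time steps, a single instantaneous dispersal
    event, and ``t_after`` further foraging time steps, followed by
    fitness-proportional recruitment of exactly ``n_individuals`` offspring
    in every occupied patch.
    """

    n_patches: int
    n_individuals: int
    n_generations: int
    t_before: int
    t_after: int
    dispersal_mortality: float
    learning_cost: float
    mutation_prob: float
    mutation_sd: float
    competition_factor: float
    resources: Sequence[ResourceSpec]
    patch_types: Sequence[PatchTypeSpec]
    patch_type_assignment: Sequence[int]
    extinction_every: int | None = None
    extinction_count: int = 0
    seed: int = 0

    @property
    def season_length(self) -> int:
        """Total lifespan in time steps (pre- plus post-dispersal phase)."""
        return self.t_before + self.t_after


@dataclass(frozen=True)
class Genotype:
    """The five heritable loci of one individual, each in [0, 1]."""

    d: float
    l_r: float
    l_d: float
    e_r: float
    e_d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.l_r, self.l_d, self.e_r, self.e_d])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "Genotype":
        return cls(*(float(v) for v in values))


@dataclass
class Individual:
    """Inspection view of one individual (the engine stores arrays).

    The phenotype triple ``(is_disperser, expressed_l, expressed_e)`` is
    fixed at birth by the developmental switch and never changes.
    """

    genotype: Genotype
    is_disperser: bool
    expressed_l: float
    expressed_e: float
    natal_patch: int
    current_patch: int
    experience: dict[int, int]
    v_total: float
    alive: bool = True


@dataclass
class GenerationRecord:
    """Per-generation census, taken after both foraging phases and the
    dispersal event but before recruitment, so the expressed-trait means
    describe exactly the cohort whose fitness differences drive that
    generation's selection."""

    generation: int
    locus_means: dict[str, float]
    expressed_means: dict[str, float | None]
    n_residents: int
    n_dispersers: int
    patch_occupancy: list[int]
    mean_fecundity: float


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = (
    "n_patches",
    "n_individuals",
    "n_generations",
    "t_before",
    "t_after",
    "dispersal_mortality",
    "learning_cost",
    "mutation_prob",
    "mutation_sd",
    "competition_factor",
    "resources",
    "patch_types",
    "patch_type_assignment",
)


def validate_config(cfg: SimulationConfig) -> SimulationConfig:
    """Check every invariant of a configuration and return a normalized copy.

    Raises
    ------
    ConfigError
        Naming the first offending field: missing value, out-of-range
        value, unknown ``resource_id``, duplicate ids, or a
        ``patch_type_assignment`` whose length does not match
        ``n_patches``.
    """
    for name in _REQUIRED_FIELDS:
        if getattr(cfg, name) is None:
            raise ConfigError(f"missing required field: {name}")

    if cfg.n_patches < 1:
        raise ConfigError("n_patches must be a positive integer")
    if cfg.n_individuals < 1:
        raise ConfigError("n_individuals must be a positive integer")
    if cfg.n_generations < 0:
        raise ConfigError("n_generations must be non-negative")
    if cfg.t_before < 1 or cfg.t_after < 1:
        raise ConfigError("t_before and t_after must be positive integers")
    if cfg.season_length < 2:
        raise ConfigError("season length t_before + t_after must be >= 2")
    if not 0.0 <= cfg.dispersal_mortality <= 1.0:
        raise ConfigError("dispersal_mortality must lie in [0, 1]")
    if cfg.learning_cost < 0.0:
        raise ConfigError("learning_cost must be non-negative")
    if not 0.0 <= cfg.mutation_prob <= 1.0:
        raise ConfigError("mutation_prob must lie in [0, 1]")
    if cfg.mutation_sd < 0.0:
        raise ConfigError("mutation_sd must be non-negative")
    if cfg.competition_factor <= 0.0:
        raise ConfigError("competition_factor must be positive")
    if cfg.extinction_every is not None and cfg.extinction_every < 1:
        raise ConfigError("extinction_every must be a positive integer or absent")
    if cfg.extinction_count < 0:
        raise ConfigError("extinction_count must be non-negative")
    if cfg.extinction_count > cfg.n_patches:
        raise ConfigError("extinction_count must not exceed n_patches")
    if cfg.seed is not None and cfg.seed < 0:
        raise ConfigError("seed must be non-negative")

    if len(cfg.resources) == 0:
        raise ConfigError("at least one resource type is required")
    if len(cfg.resources) > MAX_RESOURCE_TYPES:
        raise ConfigError(
            f"at most {MAX_RESOURCE_TYPES} resource types are supported"
        )
    seen_resources: set[int] = set()
    for res in cfg.resources:
        if res.resource_id < 1:
            raise ConfigError("resource_id must be a positive integer")
        if res.resource_id in seen_resources:
            raise ConfigError(f"duplicate resource_id: {res.resource_id}")
        seen_resources.add(res.resource_id)
        if res.value < 0.0:
            raise ConfigError(f"resource {res.resource_id}: value must be >= 0")
        if res.handling_time < 1.0:
            raise ConfigError(
                f"resource {res.resource_id}: handling_time must be >= 1"
            )
        if not 0.0 <= res.detectability <= 1.0:
            raise ConfigError(
                f"resource {res.resource_id}: detectability must lie in [0, 1]"
            )

    if len(cfg.patch_types) == 0:
        raise ConfigError("at least one patch type is required")
    seen_types: set[int] = set()
    for pt in cfg.patch_types:
        if pt.patch_type_id in seen_types:
            raise ConfigError(f"duplicate patch_type_id: {pt.patch_type_id}")
        seen_types.add(pt.patch_type_id)
        for rid, abundance in pt.abundances.items():
            if rid not in seen_resources:
                raise ConfigError(
                    f"patch type {pt.patch_type_id}: unknown resource_id {rid}"
                )
            if abundance < 0.0:
                raise ConfigError(
                    f"patch type {pt.patch_type_id}: abundance of resource "
                    f"{rid} must be >= 0"
                )

    if len(cfg.patch_type_assignment) != cfg.n_patches:
        raise ConfigError(
            "patch_type_assignment length "
            f"{len(cfg.patch_type_assignment)} != n_patches {cfg.n_patches}"
        )
    for tid in cfg.patch_type_assignment:
        if tid not in seen_types:
            raise ConfigError(f"patch_type_assignment: unknown patch_type_id {tid}")

    return dataclasses.replace(
        cfg,
        resources=tuple(cfg.resources),
        patch_types=tuple(
            PatchTypeSpec(pt.patch_type_id, dict(pt.abundances))
            for pt in cfg.patch_types
        ),
        patch_type_assignment=tuple(int(t) for t in cfg.patch_type_assignment),
        seed=0 if cfg.seed is None else int(cfg.seed),
    )


# ---------------------------------------------------------------------------
# TOML serialization
# ---------------------------------------------------------------------------


def config_from_toml(source: str | Path) -> SimulationConfig:
    """Parse and validate a configuration from TOML text or a file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".toml")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"TOML parse error: {exc}") from exc

    def section(name: str) -> dict:
        value = data.get(name)
        if value is None:
            raise ConfigError(f"missing required section: [{name}]")
        return value

    world = section("world")
    lifecycle = section("lifecycle")
    mutation = section("mutation")
    extinction = data.get("extinction", {})

    def req(table: dict, table_name: str, key: str):
        if key not in table:
            raise ConfigError(f"missing required field: {table_name}.{key}")
        return table[key]

    resources = tuple(
        ResourceSpec(
            resource_id=int(req(r, "resources", "resource_id")),
            value=float(req(r, "resources", "value")),
            handling_time=float(req(r, "resources", "handling_time")),
            detectability=float(req(r, "resources", "detectability")),
        )
        for r in data.get("resources", [])
    )
    patch_types = tuple(
        PatchTypeSpec(
            patch_type_id=int(req(pt, "patch_types", "patch_type_id")),
            abundances={
                int(k): float(v)
                for k, v in req(pt, "patch_types", "abundances").items()
            },
        )
        for pt in data.get("patch_types", [])
    )

    cfg = SimulationConfig(
        n_patches=int(req(world, "world", "n_patches")),
        n_individuals=int(req(world, "world", "n_individuals")),
        n_generations=int(req(world, "world", "n_generations")),
        patch_type_assignment=tuple(
            int(t) for t in req(world, "world", "patch_type_assignment")
        ),
        seed=int(world.get("seed", 0)),
        t_before=int(req(lifecycle, "lifecycle", "t_before")),
        t_after=int(req(lifecycle, "lifecycle", "t_after")),
        dispersal_mortality=float(req(lifecycle, "lifecycle", "dispersal_mortality")),
        learning_cost=float(req(lifecycle, "lifecycle", "learning_cost")),
        competition_factor=float(req(lifecycle, "lifecycle", "competition_factor")),
        mutation_prob=float(req(mutation, "mutation", "mutation_prob")),
        mutation_sd=float(req(mutation, "mutation", "mutation_sd")),
        extinction_every=(
            int(extinction["extinction_every"])
            if "extinction_every" in extinction
            else None
        ),
        extinction_count=int(extinction.get("extinction_count", 0)),
        resources=resources,
        patch_types=patch_types,
    )
    return validate_config(cfg)


def config_to_toml(cfg: SimulationConfig) -> str:
    """Serialize a configuration to TOML; round-trips exactly through
    :func:`config_from_toml`."""

    def fmt(v) -> str:
        if isinstance(v, bool):  # pragma: no cover - no boolean fields today
            return "true" if v else "false"
        if isinstance(v, float):
            return repr(v)
        return str(v)

    lines: list[str] = []
    lines.append("[world]")
    lines.append(f"n_patches = {cfg.n_patches}")
    lines.append(f"n_individuals = {cfg.n_individuals}")
    lines.append(f"n_generations = {cfg.n_generations}")
    assignment = ", ".join(str(t) for t in cfg.patch_type_assignment)
    lines.append(f"patch_type_assignment = [{assignment}]")
    lines.append(f"seed = {cfg.seed}")
    lines.append("")
    lines.append("[lifecycle]")
    lines.append(f"t_before = {cfg.t_before}")
    lines.append(f"t_after = {cfg.t_after}")
    lines.append(f"dispersal_mortality = {fmt(cfg.dispersal_mortality)}")
    lines.append(f"learning_cost = {fmt(cfg.learning_cost)}")
    lines.append(f"competition_factor = {fmt(cfg.competition_factor)}")
    lines.append("")
    lines.append("[mutation]")
    lines.append(f"mutation_prob = {fmt(cfg.mutation_prob)}")
    lines.append(f"mutation_sd = {fmt(cfg.mutation_sd)}")
    if cfg.extinction_every is not None or cfg.extinction_count:
        lines.append("")
        lines.append("[extinction]")
        if cfg.extinction_every is not None:
            lines.append(f"extinction_every = {cfg.extinction_every}")
        lines.append(f"extinction_count = {cfg.extinction_count}")
    for res in cfg.resources:
        lines.append("")
        lines.append("[[resources]]")
        lines.append(f"resource_id = {res.resource_id}")
        lines.append(f"value = {fmt(res.value)}")
        lines.append(f"handling_time = {fmt(res.handling_time)}")
        lines.append(f"detectability = {fmt(res.detectability)}")
    for pt in cfg.patch_types:
        lines.append("")
        lines.append("[[patch_types]]")
        lines.append(f"patch_type_id = {pt.patch_type_id}")
        items = ", ".join(
            f'"{rid}" = {fmt(float(a))}' for rid, a in sorted(pt.abundances.items())
        )
        lines.append(f"abundances = {{ {items} }}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# World state
# ---------------------------------------------------------------------------


class World:
    """Struct-of-arrays population state plus cached per-patch resource tables.

    Attributes
    ----------
    genotype : (n, 5) float array, columns ordered as :data:`LOCI`.
    is_disperser, expressed_l, expressed_e : phenotype arrays, fixed at birth.
    natal_patch, current_patch : int arrays of patch indices.
    experience : (n, n_resources) int array of cumulative practiced items,
        columns ordered as ``resource_ids``.
    v_total : accumulated resource value per individual.
    developed : whether the current cohort has passed the developmental switch.
    """

    __slots__ = (
        "cfg",
        "genotype",
        "is_disperser",
        "expressed_l",
        "expressed_e",
        "natal_patch",
        "current_patch",
        "experience",
        "v_total",
        "developed",
        "resource_ids",
        "values",
        "handling_times",
        "detectabilities",
        "abundance",
    )

    def __init__(self, cfg: SimulationConfig, genotype: np.ndarray,
                 natal_patch: np.ndarray):
        n = len(genotype)
        self.cfg = cfg
        self.genotype = np.asarray(genotype, dtype=float)
        self.natal_patch = np.asarray(natal_patch, dtype=np.int64)
        self.current_patch = self.natal_patch.copy()
        self.is_disperser = np.zeros(n, dtype=bool)
        self.expressed_l = np.zeros(n, dtype=float)
        self.expressed_e = np.zeros(n, dtype=float)
        self.v_total = np.zeros(n, dtype=float)
        self.developed = False

        self.resource_ids = tuple(r.resource_id for r in cfg.resources)
        self.values = np.array([r.value for r in cfg.resources])
        self.handling_times = np.array([r.handling_time for r in cfg.resources])
        self.detectabilities = np.array([r.detectability for r in cfg.resources])
        self.experience = np.zeros((n, len(self.resource_ids)), dtype=np.int64)

        by_type = {pt.patch_type_id: pt.abundances for pt in cfg.patch_types}
        self.abundance = np.array(
            [
                [by_type[tid].get(rid, 0.0) for rid in self.resource_ids]
                for tid in cfg.patch_type_assignment
            ]
        )

    @property
    def n_alive(self) -> int:
        return len(self.genotype)

    def occupancy(self) -> np.ndarray:
        """Number of living individuals per patch."""
        return np.bincount(self.current_patch, minlength=self.cfg.n_patches)

    def filter(self, keep: np.ndarray) -> None:
        """Drop individuals where ``keep`` is False (in place)."""
        self.genotype = self.genotype[keep]
        self.is_disperser = self.is_disperser[keep]
        self.expressed_l = self.expressed_l[keep]
        self.expressed_e = self.expressed_e[keep]
        self.natal_patch = self.natal_patch[keep]
        self.current_patch = self.current_patch[keep]
        self.experience = self.experience[keep]
        self.v_total = self.v_total[keep]

    def individuals(self) -> Iterator[Individual]:
        """Yield dataclass views of every living individual (small worlds)."""
        for i in range(self.n_alive):
            yield Individual(
                genotype=Genotype.from_array(self.genotype[i]),
                is_disperser=bool(self.is_disperser[i]),
                expressed_l=float(self.expressed_l[i]),
                expressed_e=float(self.expressed_e[i]),
                natal_patch=int(self.natal_patch[i]),
                current_patch=int(self.current_patch[i]),
                experience={
                    rid: int(self.experience[i, k])
                    for k, rid in enumerate(self.resource_ids)
                },
                v_total=float(self.v_total[i]),
            )


def init_world(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> World:
    """Create the founder population: ``n_individuals`` per patch, every
    locus drawn independently and uniformly from [0, 1].

    Founders pass through the developmental switch immediately; their
    experience ledgers are empty and ``v_total`` is zero.
    """
    from .lifecycle import develop_world  # deferred: lifecycle imports this module

    cfg = validate_config(cfg)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patches * cfg.n_individuals
    genotype = rng.uniform(0.0, 1.0, size=(n, len(LOCI)))
    natal = np.repeat(np.arange(cfg.n_patches), cfg.n_individuals)
    world = World(cfg, genotype, natal)
    develop_world(world, rng)
    return world
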