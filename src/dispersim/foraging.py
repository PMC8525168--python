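"""Phase-batched foraging economics.

Each half-season (the pre-dispersal and the post-dispersal phase) is
evaluated in one closed-form pass rather than time step by time step, since
the intake pipeline is defined on whole-phase aggregates:

1. encounters     ``N  = A * T * (1 + E)``
2. detection      ``N' = N * (1 - (1 - C) * E)``
3. learning       ``N'' = sum_j max(0, 1 - (H - 1) / (j * L))`` over the
   ``round(N')`` items practiced, with the experience index ``j``
   continuing across phases (and across patches, for a disperser that
   finds the same resource type again),
4. patch cap      ``Rmax = T * A * N_individuals / phi``
5. competition    every occupant's ``N''`` scaled by ``Rmax / sum(N'')``
   when the patch-wide total exceeds the cap.

Exploration ``E`` trades encounter quantity (step 1) against search
thoroughness (step 2); learning ability ``L`` controls how fast the
per-item handling inefficiency ``(H - 1) / (j * L)`` decays with practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import digamma

if TYPE_CHECKING:  # pragma: no cover
    from .core_model import SimulationConfig, World

__all__ = [
    "PhaseIntake",
    "max_encounters",
    "detected_items",
    "round_half_away",
    "handled_sum",
    "learning_sum",
    "patch_resource_cap",
    "apply_competition",
    "forage_phase",
]


@dataclass
class PhaseIntake:
    """Diagnostics of one foraging phase.

    Per-individual, per-resource arrays of shape ``(n, n_resources)``,
    satisfying ``0 <= post_competition <= handled <= encounters_rounded``,
    plus the per-patch caps and each individual's patch at evaluation time
    so patch-level conservation (``sum(post_competition) <= cap``) can be
    audited."""

    encounters_rounded: np.ndarray
    handled: np.ndarray
    post_competition: np.ndarray
    caps: np.ndarray
    patch: np.ndarray


def max_encounters(abundance, phase_length, exploration):
    """Maximum items of one resource encountered in a phase (step 1).

    Individuals move at least every second time step; exploration raises
    the pace, so an individual with ``exploration == 0`` encounters exactly
    half of what one with ``exploration == 1`` does.
    """
    return abundance * phase_length * (1.0 + exploration)


def detected_items(n_max, detectability, exploration):
    """Encounters discounted by search thoroughness (step 2).

    Fast explorers search less thoroughly, so hard-to-detect resources
    (low ``detectability``) are missed in proportion to ``exploration``.
    Equals ``n_max`` when ``detectability == 1`` or ``exploration == 0``.
    """
    return n_max * (1.0 - (1.0 - detectability) * exploration)


def round_half_away(x):
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def learning_sum(n_items, handling_time, learning, prior_experience):
    """Closed form of the learning-curve sum (step 3), broadcasting over arrays.

    Computes ``sum_{j=a}^{b} max(0, 1 - (H - 1)/(j * L))`` with
    ``a = prior + 1`` and ``b = prior + n_items``.  Terms are positive only
    for ``j > (H - 1) / L``, so the sum telescopes into a count minus a
    harmonic-number difference, evaluated through the digamma function:
    ``H_n = psi(n + 1) + gamma``.

    Conventions: ``H == 1`` makes every term exactly 1 (no learning
    required); ``L == 0`` with ``H > 1`` makes every term 0 (the L -> 0+
    limit: zero learning ability never cracks a hard resource).
    """
    n_items = np.asarray(n_items, dtype=np.int64)
    handling_time = np.asarray(handling_time, dtype=float)
    learning = np.asarray(learning, dtype=float)
    prior = np.asarray(prior_experience, dtype=np.int64)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = np.where(learning > 0.0, (handling_time - 1.0) / learning, np.inf)
    # strict inequality j * L > H - 1; at exact equality the term is 0
    j_min = np.floor(ratio) + 1.0
    a = np.maximum(prior + 1.0, j_min)
    b = prior.astype(float) + n_items
    active = b >= a

    a_safe = np.where(active, a, 1.0)
    b_safe = np.where(active, b, 1.0)
    count = b_safe - a_safe + 1.0
    ratio_safe = np.where(np.isfinite(ratio), ratio, 0.0)
    harmonic_diff = digamma(b_safe + 1.0) - digamma(a_safe)
    total = np.where(active, count - ratio_safe * harmonic_diff, 0.0)

    # H == 1 needs no learning regardless of L (including L == 0)
    no_learning = handling_time == 1.0
    total = np.where(no_learning, n_items.astype(float), total)
    return np.maximum(total, 0.0)


def handled_sum(n_items, handling_time, learning, prior_experience=0):
    """Items effectively handled out of ``n_items`` practiced (step 3).

    Returns ``(handled, new_experience)`` where ``new_experience`` advances
    the lifetime practice ledger by ``n_items``: the experience index ``j``
    enumerates handling attempts, so practice accrues even on items whose
    reward is later removed by competition.
    """
    handled = learning_sum(n_items, handling_time, learning, prior_experience)
    new_experience = np.asarray(prior_experience, dtype=np.int64) + np.asarray(
        n_items, dtype=np.int64
    )
    if handled.ndim == 0:
        return float(handled), int(new_experience)
    return handled, new_experience


def patch_resource_cap(phase_length, abundance, carrying_capacity, competition_factor):
    """Patch-wide ceiling on one resource's total intake per phase (step 4).

    Uses the fixed carrying capacity, not current occupancy, and the
    duration of the phase being evaluated.
    """
    return phase_length * abundance * carrying_capacity / competition_factor


def apply_competition(handled_by_individual, cap):
    """Scale co-located individuals' intake to the patch cap (step 5).

    If the summed intake exceeds ``cap``, every individual's amount is
    multiplied by ``cap / sum`` so the patch total equals the cap exactly;
    otherwise amounts pass through unchanged.  An all-zero intake vector is
    returned unchanged.
    """
    handled = np.asarray(handled_by_individual, dtype=float)
    total = handled.sum()
    if total > cap and total > 0.0:
        return handled * (cap / total)
    return handled.copy()


def forage_phase(world: "World", cfg: "SimulationConfig",
                 phase: str) -> PhaseIntake:
    """Run one whole foraging phase for every living individual (in place).

    ``phase`` is ``"before"`` or ``"after"``; it selects the phase duration
    used both for encounters (step 1) and the patch cap (step 4).  For each
    patch and resource, steps 1-3 are evaluated per occupant from its
    expressed exploration/learning and its pre-phase experience ledger (no
    within-phase feedback), then the competition scaling (step 5) is
    applied across the patch's occupants.  Each individual's ``v_total``
    gains its post-competition intake weighted by resource values, and its
    ledger advances by the items practiced.  Returns the phase diagnostics.
    """
    if phase not in ("before", "after"):
        raise ValueError(f"phase must be 'before' or 'after', got {phase!r}")
    t = cfg.t_before if phase == "before" else cfg.t_after
    if world.n_alive == 0:
        empty = np.zeros((0, len(world.resource_ids)))
        caps = patch_resource_cap(
            t, world.abundance, cfg.n_individuals, cfg.competition_factor
        )
        return PhaseIntake(
            empty.astype(np.int64), empty, empty, caps,
            np.zeros(0, dtype=np.int64),
        )

    patch = world.current_patch
    abundance = world.abundance[patch]  # (n, R)
    expl = world.expressed_e[:, None]
    learn = world.expressed_l[:, None]

    n_enc = max_encounters(abundance, t, expl)
    n_det = detected_items(n_enc, world.detectabilities[None, :], expl)
    n_items = round_half_away(n_det)
    handled = learning_sum(
        n_items, world.handling_times[None, :], learn, world.experience
    )

    caps = patch_resource_cap(
        t, world.abundance, cfg.n_individuals, cfg.competition_factor
    )  # (n_patches, R)
    totals = np.zeros_like(caps)
    np.add.at(totals, patch, handled)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(totals > caps, caps / totals, 1.0)
    post = handled * factor[patch]

    world.v_total += post @ world.values
    world.experience += n_items
    return PhaseIntake(n_items, handled, post, caps, patch.copy())
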