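"""Cross-replicate summaries, the resident-vs-disperser paired t test, and
the two experiment sweeps (season length, dispersal timing).

The plotted/compared learning quantities are population-wide *locus* means
(every individual carries both the resident and the disperser learning
allele, whichever it expresses): the mutation-selection-balance reasoning
about weakly expressed loci only applies to locus means including
non-expressing carriers.  Expressed-phenotype means are also carried along
for diagnostics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import SimulationConfig
from .engine import RunResult, replicate_seed, run_replicates, run_simulation

__all__ = [
    "ComparisonResult",
    "trait_means_at_equilibrium",
    "default_window",
    "paired_t_test",
    "season_length_sweep",
    "dispersal_timing_sweep",
]


@dataclass
class ComparisonResult:
    """Paired t test of per-replicate means (resident vs disperser learning)."""

    n: int
    mean_x: float
    mean_y: float
    t: float
    degrees_of_freedom: int
    p_value: float
    alpha: float
    significant: bool


def default_window(n_generations: int) -> int:
    """Trailing equilibrium window: final 10% of generations, at least 10.

    Trait trajectories equilibrate well before the end of the shipped run
    lengths; a fixed trailing window is a reproducible stand-in for visual
    equilibrium judgment."""
    return min(n_generations, max(10, n_generations // 10))


def trait_means_at_equilibrium(result: RunResult, window: int | None = None) -> dict:
    """Mean trait values over the final ``window`` generations of a run.

    Returns population-wide locus means (``mean_d``, ``mean_l_r_locus``,
    ``mean_l_d_locus``, ``mean_e_r_locus``, ``mean_e_d_locus``) plus
    expressed-phenotype means by class (``nan`` when a class was always
    empty in the window)."""
    n = result.n_generations_run
    if n == 0:
        raise ValueError("run has no recorded generations")
    if window is None:
        window = default_window(n)
    if not 1 <= window <= n:
        raise ValueError(f"window must lie in [1, {n}], got {window}")
    tail = result.records[n - window:]

    def mean_of(getter) -> float:
        values = [getter(rec) for rec in tail]
        values = [v for v in values if v is not None]
        if not values:
            return float("nan")
        return float(np.nanmean(values))

    return {
        "mean_d": mean_of(lambda r: r.locus_means["d"]),
        "mean_l_r_locus": mean_of(lambda r: r.locus_means["l_r"]),
        "mean_l_d_locus": mean_of(lambda r: r.locus_means["l_d"]),
        "mean_e_r_locus": mean_of(lambda r: r.locus_means["e_r"]),
        "mean_e_d_locus": mean_of(lambda r: r.locus_means["e_d"]),
        "mean_l_expressed_residents": mean_of(
            lambda r: r.expressed_means["l_residents"]
        ),
        "mean_l_expressed_dispersers": mean_of(
            lambda r: r.expressed_means["l_dispersers"]
        ),
    }


def paired_t_test(x: Sequence[float], y: Sequence[float],
                  alpha: float = 0.05) -> ComparisonResult:
    """Two-sided paired t test on per-replicate means.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = x - y`` and
    ``df = n - 1``.  Degenerate zero-variance differences use the
    convention ``p = 0`` for a nonzero mean difference and ``t = 0,
    p = 1`` for identical samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    n = len(x)
    if n < 2:
        raise ValueError("paired t test requires at least two pairs")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(mean_d)) * float("inf"), 0.0
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return ComparisonResult(
        n=n,
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        t=float(t),
        degrees_of_freedom=df,
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
    )


# ---------------------------------------------------------------------------
# Experiment sweeps
# ---------------------------------------------------------------------------


def _cell_replicates(cfg: SimulationConfig, n_replicates: int, base_seed: int,
                     cell_key: int) -> list[RunResult]:
    """Replicates of one sweep cell, seeds derived from (base_seed, cell, k)."""
    results = []
    for k in range(n_replicates):
        seed = int(
            np.random.SeedSequence([int(base_seed), int(cell_key), k])
            .generate_state(1)[0] % (2**31)
        )
        results.append(run_simulation(dataclasses.replace(cfg, seed=seed)))
    return results


def _replicate_rows(results: list[RunResult], window: int | None) -> list[dict]:
    rows = []
    for k, res in enumerate(results):
        means = trait_means_at_equilibrium(res, window)
        rows.append({"replicate": k, "seed": res.seed, **means})
    return rows


def season_length_sweep(base_cfg: SimulationConfig | None,
                        phase_lengths: Sequence[int],
                        n_replicates: int = 10,
                        base_seed: int = 0,
                        window: int | None = None,
                        alpha: float = 0.05):
    """Sweep symmetric season lengths ``S = 2 * T`` over ``phase_lengths``.

    For each ``T`` runs ``n_replicates`` replicates with
    ``t_before = t_after = T``, extracts equilibrium means, and applies
    the paired t test to the per-replicate means of the resident and
    disperser learning loci.

    Returns ``(summary, replicates, tests)``: a one-row-per-cell summary
    DataFrame, a one-row-per-(cell, replicate) tidy DataFrame, and a list
    of per-cell test-report dicts.
    """
    from .presets import season_length_config

    summary_rows, replicate_rows, tests = [], [], []
    for t in phase_lengths:
        if base_cfg is None:
            cfg = season_length_config(t)
        else:
            cfg = dataclasses.replace(base_cfg, t_before=int(t), t_after=int(t))
        results = _cell_replicates(cfg, n_replicates, base_seed, cell_key=int(t))
        rows = _replicate_rows(results, window)
        for row in rows:
            replicate_rows.append({"season_length": 2 * t, "t_phase": t, **row})
        l_r = np.array([r["mean_l_r_locus"] for r in rows])
        l_d = np.array([r["mean_l_d_locus"] for r in rows])
        d = np.array([r["mean_d"] for r in rows])
        cell = {
            "season_length": 2 * t,
            "t_phase": t,
            "mean_l_r": float(l_r.mean()),
            "sd_l_r": float(l_r.std(ddof=1)) if len(l_r) > 1 else float("nan"),
            "mean_l_d": float(l_d.mean()),
            "sd_l_d": float(l_d.std(ddof=1)) if len(l_d) > 1 else float("nan"),
            "mean_d": float(d.mean()),
        }
        if n_replicates >= 2:
            test = paired_t_test(l_r, l_d, alpha=alpha)
            cell.update(
                t_statistic=test.t,
                df=test.degrees_of_freedom,
                p_value=test.p_value,
                significant=test.significant,
            )
            tests.append(
                {
                    "cell": f"S={2 * t}",
                    "t": test.t,
                    "df": test.degrees_of_freedom,
                    "p": test.p_value,
                    "direction": "L_R>L_D" if test.mean_x > test.mean_y else "L_D>L_R",
                    "significant": test.significant,
                }
            )
        summary_rows.append(cell)
    return pd.DataFrame(summary_rows), pd.DataFrame(replicate_rows), tests


def dispersal_timing_sweep(base_cfg: SimulationConfig | None,
                           timings: Sequence[tuple[int, int]],
                           n_replicates: int = 10,
                           base_seed: int = 0,
                           window: int | None = None,
                           alpha: float = 0.05):
    """Sweep the within-season timing of dispersal at fixed season length.

    ``timings`` is a sequence of ``(t_before, t_after)`` splits whose sum
    must be constant.  Output format mirrors :func:`season_length_sweep`;
    the summary rows expose the U-shape diagnostics (mid-life dispersal
    depresses both the disperser learning locus and the population
    dispersal tendency relative to edge-of-life dispersal).
    """
    from .presets import dispersal_timing_config

    seasons = {tb + ta for tb, ta in timings}
    if len(seasons) > 1:
        raise ValueError(f"timings must share one season length, got {sorted(seasons)}")

    summary_rows, replicate_rows, tests = [], [], []
    for tb, ta in timings:
        if base_cfg is None:
            cfg = dispersal_timing_config(tb, ta)
        else:
            cfg = dataclasses.replace(base_cfg, t_before=int(tb), t_after=int(ta))
        results = _cell_replicates(
            cfg, n_replicates, base_seed, cell_key=1000 * int(tb) + int(ta)
        )
        rows = _replicate_rows(results, window)
        for row in rows:
            replicate_rows.append({"t_before": tb, "t_after": ta, **row})
        l_r = np.array([r["mean_l_r_locus"] for r in rows])
        l_d = np.array([r["mean_l_d_locus"] for r in rows])
        d = np.array([r["mean_d"] for r in rows])
        cell = {
            "t_before": tb,
            "t_after": ta,
            "mean_l_r": float(l_r.mean()),
            "mean_l_d": float(l_d.mean()),
            "mean_d": float(d.mean()),
            "sd_l_d": float(l_d.std(ddof=1)) if len(l_d) > 1 else float("nan"),
            "sd_d": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
        }
        if n_replicates >= 2:
            test = paired_t_test(l_r, l_d, alpha=alpha)
            cell.update(
                t_statistic=test.t,
                df=test.degrees_of_freedom,
                p_value=test.p_value,
                significant=test.significant,
            )
            tests.append(
                {
                    "cell": f"t_before={tb},t_after={ta}",
                    "t": test.t,
                    "df": test.degrees_of_freedom,
                    "p": test.p_value,
                    "direction": "L_R>L_D" if test.mean_x > test.mean_y else "L_D>L_R",
                    "significant": test.significant,
                }
            )
        summary_rows.append(cell)
    return pd.DataFrame(summary_rows), pd.DataFrame(replicate_rows), tests
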