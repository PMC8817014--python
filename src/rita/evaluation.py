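"""Metrics and plots for comparing assignment policies.

The headline quantities are per-period assignment proportions, average
cumulative outcome gains, and — for paired runs on the identical population
and noise — per-individual differences in final cumulative gain, summarised
overall and within the subgroups for whom each arm is the ground-truth
better choice.
"""

from __future__ import annotations

import dataclasses as dc
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "ComparisonSummary",
    "assignment_proportion",
    "average_cumulative_gain",
    "gain_difference",
    "subgroup_medians",
    "rita_rank_order",
    "summarize_comparison",
    "optimal_arm_fraction",
    "plot_assignment_proportions",
    "plot_average_gains",
    "plot_ranked_differences",
]


@dc.dataclass
class ComparisonSummary:
    """Headline statistics of one paired two-policy comparison.

    Differences are per-individual final cumulative gains of the first
    policy minus the second.  ``median_diff_a_optimal`` is the median among
    individuals whose ground-truth better arm is A (similarly for B);
    ``assignment_prop_a`` maps policy name to the per-period fraction
    assigned to arm A.
    """

    world_id: int
    policy_a: str
    policy_b: str
    mean_gain_diff: float
    sd_gain_diff: float
    median_diff_overall: float
    median_diff_a_optimal: float
    median_diff_b_optimal: float
    n_a_optimal: int
    n_b_optimal: int
    assignment_prop_a: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        d = {f.name: getattr(self, f.name) for f in dc.fields(self)
             if f.name != "assignment_prop_a"}
        return pd.DataFrame([d])


def assignment_proportion(traj: Trajectory, arm: str = "A",
                          period: int | None = None):
    """Fraction of individuals assigned ``arm`` in one period (1-based), or
    the whole per-period vector when ``period`` is None."""
    props = (traj.assignments == arm).mean(axis=1)
    if period is None:
        return props
    if not 1 <= period <= traj.periods:
        raise ValueError("period out of range")
    return float(props[period - 1])


def average_cumulative_gain(traj: Trajectory, period: int) -> float:
    """Mean over individuals of y_period − y_0 (period 0 gives 0)."""
    return float(np.mean(traj.gains(period)))


def gain_difference(traj_a: Trajectory, traj_b: Trajectory) -> np.ndarray:
    """Per-individual final-gain difference between two paired runs."""
    if not (
        np.array_equal(traj_a.ids, traj_b.ids)
        and np.array_equal(traj_a.y0, traj_b.y0)
    ):
        raise ValueError("trajectories are not paired runs on the same population")
    return traj_a.gains() - traj_b.gains()


def subgroup_medians(
    diffs: np.ndarray, optimal: Sequence[str]
) -> tuple[float, float, int, int]:
    """Medians of paired differences split by ground-truth better arm.

    Returns (median among A-optimal, median among B-optimal, n_A, n_B);
    an empty subgroup yields NaN for its median.
    """
    diffs = np.asarray(diffs, dtype=float)
    optimal = np.asarray(optimal)
    mask_a = optimal == "A"
    med = lambda x: float(np.median(x)) if len(x) else float("nan")
    return (
        med(diffs[mask_a]),
        med(diffs[~mask_a]),
        int(mask_a.sum()),
        int((~mask_a).sum()),
    )


def rita_rank_order(traj: Trajectory) -> np.ndarray:
    """Ids ordered ascending by final cumulative outcome (ties by id).

    Position 0 is the individual with the lowest final outcome under the
    given run; the last position the highest.
    """
    final = traj.y[traj.periods]
    order = np.lexsort((traj.ids, final))
    return traj.ids[order]


def optimal_arm_fraction(traj: Trajectory, period: int | None = None) -> float:
    """Fraction of individuals assigned their ground-truth better arm."""
    if period is None:
        period = traj.periods
    best = np.where(traj.effect_a >= traj.effect_b, "A", "B")
    return float(np.mean(traj.assignments[period - 1] == best))


def summarize_comparison(traj_a: Trajectory, traj_b: Trajectory) -> ComparisonSummary:
    """Full :class:`ComparisonSummary` for a paired run (first minus second)."""
    diffs = gain_difference(traj_a, traj_b)
    optimal = np.where(traj_a.effect_a >= traj_a.effect_b, "A", "B")
    med_a, med_b, n_a, n_b = subgroup_medians(diffs, optimal)
    return ComparisonSummary(
        world_id=traj_a.world_id,
        policy_a=traj_a.policy_name,
        policy_b=traj_b.policy_name,
        mean_gain_diff=float(np.mean(diffs)),
        sd_gain_diff=float(np.std(diffs, ddof=1)),
        median_diff_overall=float(np.median(diffs)),
        median_diff_a_optimal=med_a,
        median_diff_b_optimal=med_b,
        n_a_optimal=n_a,
        n_b_optimal=n_b,
        assignment_prop_a={
            traj_a.policy_name: assignment_proportion(traj_a),
            traj_b.policy_name: assignment_proportion(traj_b),
        },
    )


# --- plotting ---------------------------------------------------------------


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_assignment_proportions(trajectories: Sequence[Trajectory], path) -> None:
    """Per-period fraction assigned to arm A, one line per policy."""
    plt = _pyplot()
    fig, ax = plt.subplots()
    for traj in trajectories:
        ax.plot(np.arange(1, traj.periods + 1), assignment_proportion(traj),
                label=traj.policy_name)
    ax.set_xlabel("period")
    ax.set_ylabel("proportion assigned to A")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_average_gains(trajectories: Sequence[Trajectory], path) -> None:
    """Average cumulative outcome gain over periods, one line per policy."""
    plt = _pyplot()
    fig, ax = plt.subplots()
    for traj in trajectories:
        gains = [average_cumulative_gain(traj, t) for t in range(traj.periods + 1)]
        ax.plot(np.arange(traj.periods + 1), gains, label=traj.policy_name)
    ax.set_xlabel("period")
    ax.set_ylabel("average cumulative gain")
    ax.legend()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ranked_differences(
    traj_a: Trajectory, traj_b: Trajectory, path, bin_width: int = 10
) -> None:
    """Per-individual gains of both runs, ordered by the first run's final
    outcome rank and averaged within rank bins (cosmetic smoothing only)."""
    plt = _pyplot()
    order_ids = rita_rank_order(traj_a)
    pos = {int(i): k for k, i in enumerate(traj_a.ids)}
    idx = np.array([pos[int(i)] for i in order_ids])
    n = len(idx)
    edges = np.arange(0, n + bin_width, bin_width)
    fig, ax = plt.subplots()
    for traj in (traj_a, traj_b):
        g = traj.gains()[idx]
        binned = [g[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if a < n]
        centers = [min(b, n) - (min(b, n) - a) / 2
                   for a, b in zip(edges[:-1], edges[1:]) if a < n]
        ax.plot(centers, binned, label=traj.policy_name)
    ax.set_xlabel(f"rank by final outcome under {traj_a.policy_name}")
    ax.set_ylabel("cumulative gain")
    ax.legend()
    fig.savefig(path, dpi=150)
    plt.close(fig)
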