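"""Degree-ordered successive-deletion robustness analysis.

Victims are sorted by their degree in the intact network (descending, ties
by sorted node order — the ordering is static, degrees are not recomputed
as the graph shrinks). After each deletion the remaining graph's connected
components are counted (isolated nodes count as singleton components) and
the cumulative number of removed interactions is recorded. The study
contrast pairs an e-MDSet victim set against the equally sized set of
highest-degree essential proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .core_network import GeneSet, ProteinNetwork

__all__ = ["RobustnessTrajectory", "TrajectoryComparison", "deletion_trajectory", "compare_trajectories"]


@dataclass(frozen=True)
class RobustnessTrajectory:
    deletion_order: tuple[str, ...]
    n_components: tuple[int, ...]
    cumulative_removed_edges: tuple[int, ...]
    n_remaining_nodes: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.deletion_order) + 1),
                "deleted_protein": self.deletion_order,
                "n_components": self.n_components,
                "removed_edges": self.cumulative_removed_edges,
                "n_remaining_nodes": self.n_remaining_nodes,
            }
        )


@dataclass(frozen=True)
class TrajectoryComparison:
    trajectory_a: RobustnessTrajectory
    trajectory_b: RobustnessTrajectory
    label_a: str
    label_b: str

    def difference_frame(self) -> pd.DataFrame:
        """Per-step (a minus b) differences in components and removed edges."""
        a, b = self.trajectory_a, self.trajectory_b
        n = min(len(a.deletion_order), len(b.deletion_order))
        return pd.DataFrame(
            {
                "step": range(1, n + 1),
                "d_components": [
                    a.n_components[i] - b.n_components[i] for i in range(n)
                ],
                "d_removed_edges": [
                    a.cumulative_removed_edges[i] - b.cumulative_removed_edges[i]
                    for i in range(n)
                ],
            }
        )


def _degree_ordered(net: ProteinNetwork, proteins: set[str]) -> list[str]:
    return sorted(proteins, key=lambda v: (-net.degree(v), v))


def deletion_trajectory(net: ProteinNetwork, victims: set[str]) -> RobustnessTrajectory:
    """Delete victims one by one in static initial-degree order."""
    if not victims:
        raise ValueError("victim set is empty")
    if not victims <= net.nodes:
        raise ValueError("victims must be network nodes")
    order = _degree_ordered(net, victims)
    g = net.to_networkx().copy()
    total_edges = g.number_of_edges()
    comps, removed, remaining = [], [], []
    for v in order:
        g.remove_node(v)
        comps.append(nx.number_connected_components(g))
        removed.append(total_edges - g.number_of_edges())
        remaining.append(g.number_of_nodes())
    return RobustnessTrajectory(
        deletion_order=tuple(order),
        n_components=tuple(comps),
        cumulative_removed_edges=tuple(removed),
        n_remaining_nodes=tuple(remaining),
    )


def compare_trajectories(
    net: ProteinNetwork,
    set_a: set[str],
    set_b_pool: GeneSet,
    label_a: str = "set_a",
    label_b: str = "top-degree-pool",
) -> TrajectoryComparison:
    """Compare deletions of set_a against the |set_a| highest-degree
    members of a pool (e.g. essential proteins), ties by node order."""
    pool = set_b_pool.members & net.nodes
    if len(pool) < len(set_a):
        raise ValueError(
            f"pool has {len(pool)} network members, need >= {len(set_a)}"
        )
    set_b = set(_degree_ordered(net, pool)[: len(set_a)])
    return TrajectoryComparison(
        trajectory_a=deletion_trajectory(net, set_a),
        trajectory_b=deletion_trajectory(net, set_b),
        label_a=label_a,
        label_b=label_b,
    )
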