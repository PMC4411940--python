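"""Centrality statistics and label-resampling enrichment tests.

Implements the centrality–lethality battery: the degree-threshold
enrichment curve E_{i,>=k} = N_{i,>=k} / N^r_{i,>=k} averaged over label
randomizations, log-degree bin fractions, betweenness-centrality bottleneck
sets (top 20% of proteins), uniform label-resampling overlap tests, and the
one-sided Fisher exact (hypergeometric) overlap test.

All empirical p-values use the plus-one rule p = (1 + #extreme) / (1 + R),
so p is never zero and "p < 1e-4" corresponds to zero extreme draws at
R = 10,000. Null draws sample the observed number of marked proteins
uniformly without replacement from the network's nodes; results are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_network import GeneSet, ProteinNetwork

__all__ = [
    "EnrichmentResult",
    "DegreeEnrichmentCurve",
    "BetweennessScores",
    "betweenness",
    "bottleneck_set",
    "degree_enrichment_curve",
    "log_degree_bin_fractions",
    "set_overlap_enrichment",
    "fisher_overlap",
]


def empirical_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    """Plus-one-rule upper and lower tail probabilities."""
    r = len(null)
    p_ge = (1 + int(np.sum(null >= observed))) / (1 + r)
    p_le = (1 + int(np.sum(null <= observed))) / (1 + r)
    return p_ge, p_le


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed count vs a resampling null.

    ``ratio`` is observed / mean(null); values above 1 point to enrichment
    and below 1 to depletion. ``p_ge`` / ``p_le`` are plus-one-rule
    empirical tail probabilities.
    """

    observed: int
    null_mean: float
    null_sd: float
    ratio: float
    p_ge: float
    p_le: float
    n_randomizations: int
    seed: int | None = None

    @classmethod
    def from_null(
        cls, observed: int, null: np.ndarray, seed: int | None = None
    ) -> "EnrichmentResult":
        mean = float(np.mean(null))
        p_ge, p_le = empirical_p(null, observed)
        return cls(
            observed=int(observed),
            null_mean=mean,
            null_sd=float(np.std(null)),
            ratio=observed / mean if mean > 0 else math.nan,
            p_ge=p_ge,
            p_le=p_le,
            n_randomizations=len(null),
            seed=seed,
        )


@dataclass(frozen=True)
class DegreeEnrichmentCurve:
    """Per-threshold enrichment of marked proteins among proteins of
    degree >= k. Thresholds with an empty bin carry NaN statistics."""

    k_values: tuple[int, ...]
    n_geq_k: tuple[int, ...]          # N_{>=k}
    n_marked_geq_k: tuple[int, ...]   # N_{i,>=k}
    enrichment: tuple[float, ...]     # E_{i,>=k}
    null_mean: tuple[float, ...]
    null_sd: tuple[float, ...]
    p_ge: tuple[float, ...]
    p_le: tuple[float, ...]
    n_randomizations: int
    seed: int | None
    estimator: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "n_geq_k": self.n_geq_k,
                "n_marked_geq_k": self.n_marked_geq_k,
                "enrichment": self.enrichment,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "p_ge": self.p_ge,
                "p_le": self.p_le,
            }
        )


@dataclass(frozen=True)
class BetweennessScores:
    """Unnormalized betweenness c_B(v) over unordered node pairs."""

    scores: dict[str, float]
    node_order: tuple[str, ...] = field(default=())

    def top(self, quantile: float = 0.20) -> set[str]:
        return bottleneck_set(self, quantile)


def betweenness(net: ProteinNetwork) -> BetweennessScores:
    """c_B(v) = sum over unordered pairs s != t != v of σ_st(v)/σ_st.

    σ counts unweighted shortest paths; pairs in different components
    contribute zero, so disconnected graphs are handled per component.
    """
    raw = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return BetweennessScores(
        scores={v: float(raw[v]) for v in net.node_order},
        node_order=tuple(net.node_order),
    )


def bottleneck_set(scores: BetweennessScores, quantile: float = 0.20) -> set[str]:
    """The ceil(quantile * n) highest-betweenness proteins (bottlenecks).

    Ties at the cut are broken by sorted node order.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    n_top = math.ceil(quantile * len(scores.scores))
    ranked = sorted(scores.scores, key=lambda v: (-scores.scores[v], v))
    return set(ranked[:n_top])


def _null_marked_degree_counts(
    degrees: np.ndarray, m: int, k_values: np.ndarray, r: int, rng: np.random.Generator
) -> np.ndarray:
    """R x len(k_values) matrix of marked-protein counts at degree >= k
    for uniform draws of m proteins without replacement."""
    n = len(degrees)
    out = np.empty((r, len(k_values)), dtype=np.int64)
    for i in range(r):
        drawn = np.sort(degrees[rng.choice(n, size=m, replace=False)])
        out[i] = m - np.searchsorted(drawn, k_values, side="left")
    return out


def degree_enrichment_curve(
    net: ProteinNetwork,
    marked: GeneSet,
    k_values: list[int] | None = None,
    R: int = 10_000,
    seed: int | None = None,
    estimator: str = "ratio-of-means",
    min_bin: int = 10,
) -> DegreeEnrichmentCurve:
    """Enrichment of a marked set among proteins with >= k interactions.

    For each threshold k, N_{>=k} proteins have at least k interactions and
    N_{i,>=k} of them are marked. The null redraws |marked ∩ nodes| node
    labels uniformly without replacement R times. The default estimator is
    observed / mean(null counts); ``estimator="mean-of-ratios"`` instead
    averages per-draw ratios, skipping (and counting) draws with a zero
    null count. Default thresholds run k = 1 .. max degree, keeping only
    those with N_{>=k} >= ``min_bin``.
    """
    if estimator not in ("ratio-of-means", "mean-of-ratios"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if R < 1:
        raise ValueError("R must be >= 1")
    marked_in = sorted(marked.members & net.nodes)
    if not marked_in:
        raise ValueError("marked set does not intersect the network")
    order = net.node_order
    deg = np.array([net.degree(v) for v in order], dtype=np.int64)
    marked_mask = np.isin(np.array(order), np.array(marked_in))

    if k_values is None:
        max_deg = int(deg.max(initial=0))
        k_values = [
            k for k in range(1, max_deg + 1) if int(np.sum(deg >= k)) >= min_bin
        ]
    ks = np.asarray(sorted(k_values), dtype=np.int64)

    n_geq = np.array([int(np.sum(deg >= k)) for k in ks])
    observed = np.array([int(np.sum(marked_mask & (deg >= k))) for k in ks])

    rng = np.random.default_rng(seed)
    null = _null_marked_degree_counts(deg, len(marked_in), ks, R, rng)

    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0)
    enrich = np.full(len(ks), np.nan)
    p_ge = np.full(len(ks), np.nan)
    p_le = np.full(len(ks), np.nan)
    for j in range(len(ks)):
        if n_geq[j] == 0:
            continue  # undefined point, not an exception
        if estimator == "ratio-of-means":
            enrich[j] = observed[j] / null_mean[j] if null_mean[j] > 0 else np.nan
        else:
            nz = null[:, j] > 0
            enrich[j] = float(np.mean(observed[j] / null[nz, j])) if nz.any() else np.nan
        p_ge[j], p_le[j] = empirical_p(null[:, j], observed[j])

    return DegreeEnrichmentCurve(
        k_values=tuple(int(k) for k in ks),
        n_geq_k=tuple(int(x) for x in n_geq),
        n_marked_geq_k=tuple(int(x) for x in observed),
        enrichment=tuple(float(x) for x in enrich),
        null_mean=tuple(float(x) for x in null_mean),
        null_sd=tuple(float(x) for x in null_sd),
        p_ge=tuple(float(x) for x in p_ge),
        p_le=tuple(float(x) for x in p_le),
        n_randomizations=R,
        seed=seed,
        estimator=estimator,
    )


def log_degree_bin_fractions(
    net: ProteinNetwork, numerator: set[str], denominator: set[str]
) -> pd.DataFrame:
    """Fractions |numerator ∩ bin| / |denominator ∩ bin| in degree bins
    [2^j, 2^(j+1)). Degree-0 proteins are excluded; empty-denominator bins
    report NaN. Requires numerator ⊆ denominator ⊆ nodes.
    """
    if not numerator <= denominator:
        raise ValueError("numerator must be a subset of denominator")
    if not denominator <= net.nodes:
        raise ValueError("denominator must be a subset of network nodes")
    degs = net.degrees()
    max_deg = max((d for d in degs.values()), default=0)
    rows = []
    j = 0
    while 2**j <= max(max_deg, 1):
        lo, hi = 2**j, 2 ** (j + 1)
        in_bin = {v for v, d in degs.items() if lo <= d < hi}
        n_den = len(in_bin & denominator)
        n_num = len(in_bin & numerator)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_numerator": n_num,
                "n_denominator": n_den,
                "fraction": n_num / n_den if n_den else np.nan,
            }
        )
        j += 1
    return pd.DataFrame(rows)


def set_overlap_enrichment(
    net: ProteinNetwork,
    target: set[str],
    marked: GeneSet,
    R: int = 10_000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Enrichment of a marked set inside a fixed target set of nodes.

    Observed = |target ∩ marked ∩ nodes|; each null draw resamples
    |marked ∩ nodes| node labels uniformly without replacement and
    recounts. Used for bottleneck-protein enrichment and any other fixed
    target stratum.
    """
    if not target:
        raise ValueError("target set is empty")
    if not target <= net.nodes:
        raise ValueError("target must be a subset of network nodes")
    order = net.node_order
    marked_in = marked.members & net.nodes
    m = len(marked_in)
    target_mask = np.array([v in target for v in order])
    observed = len(target & marked_in)
    rng = np.random.default_rng(seed)
    n = len(order)
    null = np.empty(R, dtype=np.int64)
    for i in range(R):
        null[i] = int(target_mask[rng.choice(n, size=m, replace=False)].sum())
    return EnrichmentResult.from_null(observed, null, seed=seed)


def fisher_overlap(
    n_nodes: int, n_mdset: int, n_marked_in_net: int, n_overlap: int
) -> float:
    """One-sided Fisher exact p for an overlap at least this large.

    Upper-tail hypergeometric probability of drawing >= n_overlap marked
    proteins when n_mdset of n_nodes proteins are sampled and
    n_marked_in_net are marked.
    """
    if n_overlap > min(n_mdset, n_marked_in_net):
        raise ValueError("overlap exceeds a margin")
    if max(n_mdset, n_marked_in_net) > n_nodes or min(
        n_nodes, n_mdset, n_marked_in_net, n_overlap
    ) < 0:
        raise ValueError("inconsistent contingency counts")
    return float(hypergeom.sf(n_overlap - 1, n_nodes, n_marked_in_net, n_mdset))
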