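"""Protein-complex participation and intra/inter-complex interaction tests.

The complex participation coefficient of a protein i is

    P_i = sum_s (n_{i,s} / sum_s n_{i,s})^2

where n_{i,s} is the number of interaction partners of i belonging to
complex s, over N catalog complexes. P_i tends to 1 when i interacts
predominantly with a single complex and toward 1/N when its partners
spread evenly. A partner belonging to several complexes increments each
of them, and the denominator is the sum over complexes (not the plain
partner count), applying the formula literally under multi-membership.

Interactions within a focal stratum are classified as intra-complex (the
endpoints share at least one complex), inter-complex (both endpoints
complexed, sharing none) or excluded (an un-complexed endpoint). The null
model preserves complex sizes: each draw refills every complex by uniform
sampling without replacement from the universe of proteins appearing in
at least one real complex, then recounts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .core_network import ComplexCatalog, ProteinNetwork
from .enrichment import EnrichmentResult

__all__ = [
    "ParticipationResult",
    "ComplexInteractionCounts",
    "RankSumComparison",
    "participation_coefficients",
    "compare_participation",
    "count_complex_interactions",
    "complex_null_enrichment",
]


@dataclass(frozen=True)
class ParticipationResult:
    """P_i per protein (only where defined) and the per-protein count of
    complexed interaction partners."""

    values: dict[str, float]
    n_complexed_links: dict[str, int]

    def defined_for(self, proteins: set[str]) -> list[float]:
        return [self.values[p] for p in sorted(proteins) if p in self.values]


@dataclass(frozen=True)
class ComplexInteractionCounts:
    intra: int
    inter: int
    excluded: int

    @property
    def total(self) -> int:
        return self.intra + self.inter + self.excluded


@dataclass(frozen=True)
class RankSumComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    label_a: str = "a"
    label_b: str = "b"


def participation_coefficients(
    net: ProteinNetwork, catalog: ComplexCatalog
) -> ParticipationResult:
    if catalog.n_complexes == 0:
        raise ValueError("empty complex catalog")
    membership = catalog.membership()
    values: dict[str, float] = {}
    n_links: dict[str, int] = {}
    for v in net.node_order:
        counts: dict[str, int] = {}
        complexed_partners = 0
        for w in net.neighbors(v):
            cids = membership.get(w)
            if not cids:
                continue
            complexed_partners += 1
            for s in cids:
                counts[s] = counts.get(s, 0) + 1
        n_links[v] = complexed_partners
        total = sum(counts.values())
        if total > 0:
            values[v] = sum((c / total) ** 2 for c in counts.values())
    return ParticipationResult(values=values, n_complexed_links=n_links)


def compare_participation(
    group_a: set[str],
    group_b: set[str],
    result: ParticipationResult,
    label_a: str = "a",
    label_b: str = "b",
) -> RankSumComparison:
    """Two-sided Wilcoxon rank-sum on the P_i samples of two strata.

    Exact enumeration when both samples have <= 20 values and no ties
    across them; normal approximation with tie correction otherwise.
    """
    a = result.defined_for(group_a)
    b = result.defined_for(group_b)
    if not a or not b:
        raise ValueError("each group needs at least one protein with defined P")
    has_ties = len(set(a) | set(b)) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        method=method,
        label_a=label_a,
        label_b=label_b,
    )


def _classify_edges(
    edges: list[tuple[str, str]], masks: dict[str, int]
) -> tuple[int, int, int]:
    """Classify focal edges given per-protein complex bitmasks."""
    intra = inter = excluded = 0
    for u, v in edges:
        mu = masks.get(u, 0)
        mv = masks.get(v, 0)
        if mu == 0 or mv == 0:
            excluded += 1
        elif mu & mv:
            intra += 1
        else:
            inter += 1
    return intra, inter, excluded


def _bitmasks(catalog: ComplexCatalog) -> dict[str, int]:
    masks: dict[str, int] = {}
    for bit, cid in enumerate(sorted(catalog.complexes)):
        for p in catalog.complexes[cid]:
            masks[p] = masks.get(p, 0) | (1 << bit)
    return masks


def count_complex_interactions(
    net: ProteinNetwork, catalog: ComplexCatalog, focal: set[str]
) -> ComplexInteractionCounts:
    """Intra / inter / excluded counts over edges with both ends in focal."""
    if not focal <= net.nodes:
        raise ValueError("focal set must be a subset of network nodes")
    edges = [(u, v) for u, v in net.edges if u in focal and v in focal]
    intra, inter, excluded = _classify_edges(edges, _bitmasks(catalog))
    return ComplexInteractionCounts(intra=intra, inter=inter, excluded=excluded)


def complex_null_enrichment(
    net: ProteinNetwork,
    catalog: ComplexCatalog,
    focal: set[str],
    R: int = 10_000,
    seed: int | None = None,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Size-preserving complex-reassignment null for intra/inter counts.

    Each of R draws rebuilds the catalog with the same complex sizes,
    filling each complex independently by uniform sampling without
    replacement from the proteins appearing in >= 1 real complex, then
    recounts the focal stratum's intra- and inter-complex interactions.
    Returns (intra, inter) enrichment results.
    """
    if not focal <= net.nodes:
        raise ValueError("focal set must be a subset of network nodes")
    universe = sorted(catalog.proteins())
    sizes = [len(catalog.complexes[cid]) for cid in sorted(catalog.complexes)]
    if max(sizes, default=0) > len(universe):
        raise ValueError("a complex is larger than the sampling universe")

    edges = [(u, v) for u, v in net.edges if u in focal and v in focal]
    obs_intra, obs_inter, _ = _classify_edges(edges, _bitmasks(catalog))

    rng = np.random.default_rng(seed)
    n_u = len(universe)
    null_intra = np.empty(R, dtype=np.int64)
    null_inter = np.empty(R, dtype=np.int64)
    for i in range(R):
        masks: dict[str, int] = {}
        for bit, size in enumerate(sizes):
            flag = 1 << bit
            for j in rng.choice(n_u, size=size, replace=False):
                p = universe[j]
                masks[p] = masks.get(p, 0) | flag
        null_intra[i], null_inter[i], _ = _classify_edges(edges, masks)

    return (
        EnrichmentResult.from_null(obs_intra, null_intra, seed=seed),
        EnrichmentResult.from_null(obs_inter, null_inter, seed=seed),
    )
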