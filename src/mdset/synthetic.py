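"""Seeded generator of complete synthetic interactome studies.

Emulates the statistical structure of a binary (yeast-two-hybrid-style)
protein interaction study: a heavy-tailed network of 500–6,000 proteins
with mean degree around 3–6, an essential-gene list covering roughly
20–45% of proteins with a tunable log-degree coupling, overlapping protein
complexes of a few to a few dozen members with elevated intra-complex edge
density, and COG-style single-letter class labels with tunable per-class
degree bias. Essentiality is planted as a function of degree only — never
of dominating-set membership — so any dominating-set contrast downstream
is emergent rather than hard-wired.

One global seed feeds a ``numpy.random.SeedSequence`` that is split into
independent streams per planter, so adding a planter never perturbs the
draws of earlier ones; a config plus seed determines every output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .core_network import (
    ClassAnnotation,
    ComplexCatalog,
    GeneSet,
    ProteinNetwork,
    write_class_annotation,
    write_complex_catalog,
    write_edge_list,
    write_gene_set,
)

__all__ = [
    "StudyConfig",
    "SyntheticStudy",
    "generate_network",
    "plant_essentiality",
    "plant_complexes",
    "plant_classes",
    "generate_study",
]

DEFAULT_CLASS_ALPHABET = tuple("JKLDOMNPTUVWYZCEFGHI")


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    Defaults mirror the bacterial-interactome regime: ~1,200 proteins at
    mean degree ~4, essential fraction 0.3 with positive degree coupling,
    50 overlapping complexes of 3–25 members with a 0.10 co-member edge
    boost (plus 0.15 extra among essential co-members), and 20 class
    letters of which "J" is biased toward high-degree proteins.
    """

    n_nodes: int = 1200
    topology: str = "preferential-attachment"  # or "power-law-configuration"
    m: int = 2                      # links per new node (preferential attachment)
    gamma: float = 2.5              # tail exponent (configuration model)
    essential_fraction: float = 0.3
    essential_degree_coupling: float = 1.0   # log-odds per unit log-degree
    n_complexes: int = 50
    complex_size_range: tuple[int, int] = (3, 25)
    intra_complex_edge_boost: float = 0.10
    focal_intra_bias: float = 0.15
    class_alphabet: tuple[str, ...] = DEFAULT_CLASS_ALPHABET
    class_degree_bias: dict[str, float] = field(default_factory=lambda: {"J": 1.0})
    extra_code_probability: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.complex_size_range
        if not 0 < self.essential_fraction < 1:
            raise ValueError("essential_fraction must be in (0, 1)")
        if lo < 2 or lo > hi:
            raise ValueError("complex_size_range must satisfy 2 <= min <= max")
        if self.topology not in ("preferential-attachment", "power-law-configuration"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class SyntheticStudy:
    network: ProteinNetwork
    essential: GeneSet
    catalog: ComplexCatalog
    annotation: ClassAnnotation
    truth: dict


def _node_name(i: int) -> str:
    return f"P{i:05d}"


def generate_network(config: StudyConfig, rng: np.random.Generator | None = None) -> ProteinNetwork:
    """Heavy-tailed simple graph at the configured size.

    Preferential attachment gives mean degree ~ 2m (exactly
    2m(n-m)/n before any duplicate rejection); the power-law configuration
    model draws degrees from P(k) ∝ k^-γ, k = 1..floor(sqrt(n)), pairs
    stubs uniformly and simplifies.
    """
    if config.n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.topology == "preferential-attachment":
        if config.m >= config.n_nodes:
            raise ValueError("m must be smaller than n_nodes")
        g = nx.barabasi_albert_graph(config.n_nodes, config.m, seed=rng)
    else:
        kmax = max(2, int(math.isqrt(config.n_nodes)))
        ks = np.arange(1, kmax + 1)
        pk = ks.astype(float) ** (-config.gamma)
        pk /= pk.sum()
        degs = rng.choice(ks, size=config.n_nodes, p=pk)
        if degs.sum() % 2:
            degs[int(rng.integers(config.n_nodes))] += 1
        g = nx.configuration_model(degs.tolist(), seed=rng)
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
    edges = [(_node_name(u), _node_name(v)) for u, v in g.edges()]
    nodes = [_node_name(i) for i in range(config.n_nodes)]
    return ProteinNetwork(edges, nodes=nodes, name=f"synthetic-{config.topology}")


def _log_degree(net: ProteinNetwork) -> dict[str, float]:
    # degree-0 nodes take the baseline covariate log(1) = 0
    return {v: math.log(max(net.degree(v), 1)) for v in net.node_order}


def plant_essentiality(
    net: ProteinNetwork,
    fraction: float,
    beta: float,
    rng: np.random.Generator,
) -> GeneSet:
    """Label nodes essential with probability logistic(α + β·log k).

    α is calibrated by bisection so the expected essential fraction equals
    ``fraction`` to within 0.01; β = 0 reduces to uniform labels.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    z = np.array([_log_degree(net)[v] for v in net.node_order])

    def expected(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * z)))))

    lo, hi = -50.0, 50.0
    if not expected(lo) <= fraction <= expected(hi):
        raise ValueError(
            f"fraction {fraction} unattainable for beta={beta} on this degree sequence"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expected(mid) < fraction:
            lo = mid
        else:
            hi = mid
        if abs(expected(mid) - fraction) < 1e-6:
            break
    alpha = 0.5 * (lo + hi)
    assert abs(expected(alpha) - fraction) < 0.01
    probs = 1.0 / (1.0 + np.exp(-(alpha + beta * z)))
    draws = rng.random(len(probs)) < probs
    members = frozenset(v for v, e in zip(net.node_order, draws) if e)
    return GeneSet(members, label="essential")


def plant_complexes(
    net: ProteinNetwork,
    config: StudyConfig,
    essential: GeneSet,
    rng: np.random.Generator,
) -> tuple[ProteinNetwork, ComplexCatalog]:
    """Sample overlapping complexes and densify their internal wiring.

    Membership is biased toward high-degree proteins (weight k+1). Each
    co-member pair gains an edge with probability
    ``intra_complex_edge_boost``, raised by ``focal_intra_bias`` when both
    members are essential; the returned network stays simple.
    """
    order = net.node_order
    deg = np.array([net.degree(v) for v in order], dtype=float)
    weights = (deg + 1.0) / (deg + 1.0).sum()
    lo, hi = config.complex_size_range
    if hi > net.n_nodes:
        raise ValueError("complex size exceeds network size")
    complexes: dict[str, frozenset[str]] = {}
    new_edges: set[tuple[str, str]] = set()
    existing = net.edges
    ess = essential.members
    for c in range(config.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(order), size=size, replace=False, p=weights)
        members = sorted(order[i] for i in idx)
        complexes[f"CPX{c:04d}"] = frozenset(members)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                pair = (u, v)
                if pair in existing or pair in new_edges:
                    continue
                p = config.intra_complex_edge_boost
                if u in ess and v in ess:
                    p = min(1.0, p + config.focal_intra_bias)
                if rng.random() < p:
                    new_edges.add(pair)
    augmented = ProteinNetwork(
        list(existing | new_edges), nodes=order, name=net.name
    )
    return augmented, ComplexCatalog(complexes)


def plant_classes(
    net: ProteinNetwork,
    config: StudyConfig,
    rng: np.random.Generator,
) -> ClassAnnotation:
    """Assign each protein 1–2 class letters with per-class degree bias.

    Class weights are a softmax of bias_c · log k per protein, so a class
    with positive bias concentrates on high-degree proteins.
    """
    alphabet = list(config.class_alphabet)
    bias = np.array([config.class_degree_bias.get(c, 0.0) for c in alphabet])
    zmap = _log_degree(net)
    assignments: dict[str, frozenset[str]] = {}
    for v in net.node_order:
        logits = bias * zmap[v]
        w = np.exp(logits - logits.max())
        w /= w.sum()
        n_codes = 1 + int(rng.random() < config.extra_code_probability)
        idx = rng.choice(len(alphabet), size=n_codes, replace=False, p=w)
        assignments[v] = frozenset(alphabet[i] for i in idx)
    return ClassAnnotation(assignments)


def generate_study(config: StudyConfig, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Run all planters on independent seed streams; optionally write the
    study directory (network.tsv, essential.txt, complexes.tsv,
    annotation.tsv, truth.json) in the standard dialects."""
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    base = generate_network(config, rng=streams[0])
    essential = plant_essentiality(
        base, config.essential_fraction, config.essential_degree_coupling, streams[1]
    )
    network, catalog = plant_complexes(base, config, essential, streams[2])
    annotation = plant_classes(network, config, streams[3])

    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "class_alphabet"},
            "class_alphabet": "".join(config.class_alphabet),
        },
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_essential": len(essential.members),
        "n_complexes": catalog.n_complexes,
    }
    study = SyntheticStudy(
        network=network,
        essential=essential,
        catalog=catalog,
        annotation=annotation,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_list(network, out / "network.tsv")
        write_gene_set(essential, out / "essential.txt")
        write_complex_catalog(catalog, out / "complexes.tsv", dialect="long")
        write_class_annotation(annotation, out / "annotation.tsv")
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=2) + "\n")
    return study
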