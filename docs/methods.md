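# Methods

## The model

A binary protein interaction network is an undirected simple graph
G = (V, E) over protein identifiers, with Γ(v) the interaction partners of
v. A **dominating set** S ⊆ V contains, for every protein v, either v
itself or one of its partners; the **minimum dominating set (MDSet)**
solves the binary integer program

    min Σ_v x_v    s.t.    x_v + Σ_{w∈Γ(v)} x_w ≥ 1,    x_v ∈ {0, 1},

so each non-MDSet protein is reachable from the MDSet through a single
interaction. The domination number (the optimum) is unique; the optimal
set generally is not. Proteins are stratified into **essential** (an
externally supplied gene list intersected with V), **MDSet**, and
**e-MDSet** (essential ∩ MDSet), and each stratum's topological and
functional placement is quantified.

Assumptions: interactions are binary, unweighted and symmetric;
identifiers are opaque, case-sensitive strings shared across input files;
essentiality, complex membership and class annotation are taken as given.

## Solvers

* `solve_mdset(backend="milp")` — default; the stated program handed to
  HiGHS branch-and-bound through `scipy.optimize.milp`. Status `optimal`
  is reported only when optimality is proven; a time-limited solve returns
  the incumbent with its bound gap.
* `solve_mdset(backend="branch-and-bound")` — self-contained fallback:
  greedy incumbent, branching over the closed neighborhood of a
  least-coverable uncovered node, pruning with the combinatorial bound
  |chosen| + ⌈u/(Δ+1)⌉ (u uncovered nodes, Δ the maximum degree). Exact,
  but practical only to a few hundred nodes; intended for solver-free
  environments and as a cross-check.
* `brute_force_mdset` — subset enumeration in increasing cardinality,
  lexicographic within cardinality; the test oracle, refused above 20
  nodes. `greedy_mdset` — maximum-coverage heuristic, the upper bound and
  incumbent.

Isolated nodes are forced members (their constraint degenerates to
x_v ≥ 1), following the program literally. All tie-breaking — greedy
choices, branching order, bottleneck cuts, deletion order — uses sorted
node order, so identical input, backend and node set reproduce the
identical member set. MDSets are non-unique in general; one deterministic
solution per network is analyzed, matching how the downstream statistics
are defined.

## Statistics

**Degree-enrichment curve.** For threshold k, N_{≥k} proteins have at
least k interactions, N_{i,≥k} of them are marked (e.g. essential), and
E_{i,≥k} = N_{i,≥k} / N^r_{i,≥k}, where N^r is the count under uniform
redrawing of the |marked ∩ V| labels without replacement (default
R = 10,000 draws). Averaging ratios over draws is undefined whenever a
null draw yields zero, so the default estimator is observed / mean(null);
`estimator="mean-of-ratios"` averages per-draw ratios, skipping and
counting zero draws. The default threshold grid is k = 1 … max degree,
keeping thresholds with N_{≥k} ≥ 10; an empty bin yields an undefined
point rather than an error.

**Empirical tails.** All resampling tests report
p = (1 + #extreme)/(1 + R), so p ∈ (0, 1] and zero extreme draws at
R = 10,000 maps to p < 10⁻⁴. Fixed seeds make every result bit-identical
across runs.

**Bottlenecks.** Betweenness c_B(v) = Σ_{s≠t≠v} σ_st(v)/σ_st over
unordered pairs on unweighted geodesics (cross-component pairs contribute
zero). Bottlenecks are the ⌈0.20·n⌉ highest-c_B proteins, ties broken by
node order. Stratum enrichment among bottlenecks uses the uniform
label-resampling null above; the MDSet/essential overlap itself uses the
one-sided Fisher exact (hypergeometric upper tail) test.

**Robustness.** Victims are deleted in static initial-degree order
(descending, ties by node order); after each deletion the remaining
graph's component count (isolates included) and cumulative removed-edge
count are recorded. An adaptive reordering is deliberately not the
default — the contrast is defined on the intact network's degrees. The
comparison set is the equally sized top-degree subset of a pool
(typically essential proteins).

**Complex participation.** P_i = Σ_s (n_{i,s}/Σ_s n_{i,s})², with n_{i,s}
the partners of i in complex s. A partner in several complexes increments
each of them, and the denominator is Σ_s n_{i,s} rather than the distinct
partner count — the formula applied literally under multi-membership. P_i
is defined only for proteins with at least one complexed partner and lies
in [1/N, 1]. Strata are compared by a two-sided Wilcoxon rank-sum (exact
enumeration when both samples are ≤ 20 without ties, normal approximation
with tie correction otherwise).

**Intra/inter-complex interactions.** Focal-stratum edges are classified
intra (endpoints share ≥ 1 complex), inter (both complexed, sharing none)
or excluded (an un-complexed endpoint; excluded rather than inter because
the null only reassigns complexed proteins). The null preserves complex
sizes: each draw refills every complex uniformly without replacement from
the universe of proteins in ≥ 1 real complex and recounts. Conservation
intra + inter + excluded = |focal edges| holds in every draw.

**Functional classes.** Observed: per class, the number of focal proteins
carrying it (a multi-class protein counts once per class). The default
null permutes the multiset of class-code tokens across annotated universe
proteins, preserving each protein's code count and each class's global
total exactly; marginal i.i.d. resampling is available behind
`null="marginal"`. The universe is the annotated network proteins, not
the genome; the class alphabet is whatever the input file contains.

## Synthetic studies

The generator emulates the inputs of a binary (Y2H-style) interactome
study. Defaults, chosen once as the study regime:

| parameter | default | rationale |
|---|---|---|
| n_nodes | 1,200 | bacterial-interactome scale |
| topology | preferential attachment, m = 2 | heavy-tailed, mean degree ≈ 4 |
| essential_fraction | 0.30 | between the organisms' essential shares |
| essential_degree_coupling β | 1.0 | moderate centrality–lethality signal |
| n_complexes / sizes | 50 / 3–25 | overlapping, degree-biased membership |
| intra_complex_edge_boost | 0.10 | co-members wired above baseline |
| focal_intra_bias | 0.15 | extra wiring among essential co-members |
| class alphabet / bias | 20 letters, J biased +1.0 per log-degree | one planted class signal |

Essentiality is planted as logistic(α + β·log k) with α calibrated by
bisection to hit the target fraction within 0.01; the covariate is
log(max(k, 1)) so degree-0 nodes (possible under the alternative
power-law configuration topology) take the baseline. Essentiality depends
on degree only, never on MDSet membership: e-MDSet contrasts downstream
are emergent, and tests treat them qualitatively. Complex membership is
degree-biased (weight k + 1) so participation analyses have nondegenerate
support. Class labels are drawn per protein (1–2 codes) from a softmax of
per-class bias × log-degree. One global seed is split into per-planter
`SeedSequence` streams, so adding a planter never perturbs earlier draws
and a config determines every output byte.

What the generator does **not** emulate: assay false positives/negatives,
study-specific degree correlations (the paper-scale networks' exact
cleaning rules are unknown), locus-level structure behind essentiality,
or curated-complex nesting. Passing recovery tests therefore demonstrates
that the statistics detect the planted effects under the stated regime,
not that any particular biological dataset will show them.

## Numerical and design choices

* MILP time limit defaults to 600 s; a 1,200-node study solves in well
  under a second, and a 3,000-node scale-free network within seconds.
* Degenerate inputs: empty gene sets warn and propagate as zero overlaps;
  an empty focal stratum yields zero counts with undefined ratios; empty
  degree bins yield undefined curve points.
* The p-uniformity calibration check uses a Kolmogorov–Smirnov tolerance
  of 0.15: the overlap count is discrete (maximum point mass ≈ 0.09 at
  the calibration dimensions) and 500 replicates add ≈ 0.06 of KS
  sampling noise; genuine miscalibration shifts the CDF far beyond this.
* Planted-signal recovery simulations run at reduced resampling depth
  (R = 1,000) and moderate network sizes (300–1,200 nodes, 20–50 seeds),
  sizes chosen by power analysis so the stated effects are detected in
  ≥ 90% of seeds; the intra-complex recovery simulation states its
  planting strength as focal_intra_bias = 0.30 (the inter-complex
  depletion is a conservation side-effect of intra enrichment and needs
  the stronger planting to clear p ≤ 0.01 reliably at this scale).
* `scripts/acceptance.py` analyzes one default study at R = 2,000, deep
  enough for stable ratios and two-decimal empirical tails at this size.

## Known limitations

* Only one optimal MDSet is analyzed per network; enumerating the optimal
  set space (or its degree-anatomy variability) is out of scope, though
  `solve_mdset` is deterministic so sensitivity can be probed by
  permuting identifiers externally.
* The pure branch-and-bound backend's bound is weak on large sparse
  graphs; use the MILP backend beyond a few hundred nodes.
* No degree-preserving edge-rewiring nulls: all nulls resample labels or
  memberships, matching the analyses implemented here.
* No identifier mapping: inputs in mismatched namespaces silently produce
  low overlaps (a warning surfaces when a gene set misses the network
  entirely).
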