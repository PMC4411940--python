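# mdset

Minimum dominating sets in protein interaction networks — exact solvers,
enrichment statistics and a synthetic-study test bed.

## The problem

In a binary protein interaction network G = (V, E), a **minimum
dominating set (MDSet)** is the smallest set of proteins from which every
remaining protein can be reached through a single interaction. It solves

    min Σ_{v∈V} x_v    s.t.    x_v + Σ_{w∈Γ(v)} x_w ≥ 1,    x_v ∈ {0,1},

with Γ(v) the interaction partners of v. MDSet proteins are
"strategically placed": coverage of the whole network with the fewest
nodes, which is not the same as picking the hubs. Crossing the MDSet with
an essential-gene list yields the **e-MDSet** (essential ∩ MDSet), a
stratum whose topological and functional signals — degree enrichment
(centrality–lethality), betweenness bottleneck membership, targeted
deletion damage, protein-complex participation, COG functional-class
composition — this package quantifies with label-resampling null models
and exact tests.

The package is for network/systems biologists who have an interactome
edge list, and optionally an essential-gene list, a complex catalog and
functional-class annotations, and want the full MDSet analysis battery
with deterministic, seeded statistics — plus a generator of synthetic
studies with planted signals for validation without any downloads.

## Worked example

```python
import mdset
from mdset.synthetic import StudyConfig, generate_study

study = generate_study(StudyConfig(seed=7), out_dir="demo_study")
net = study.network                      # 1,200 proteins, 2,931 interactions

ds = mdset.solve_mdset(net)
parts = mdset.stratify(net, ds, study.essential)
print(ds.objective, ds.status)           # 205 optimal
print(parts.sizes)
# {'mdset': 205, 'essential_in_network': 376, 'e_mdset': 107, 'non_mdset': 995}

p = mdset.fisher_overlap(net.n_nodes, len(parts.mdset),
                         len(parts.essential_in_network), len(parts.e_mdset))
print(f"{p:.3g}")                        # 5.94e-12

curve = mdset.degree_enrichment_curve(net, study.essential, R=2000, seed=1)
for k, e, pg in zip(curve.k_values, curve.enrichment, curve.p_ge):
    print(k, round(e, 2), round(pg, 4))
# k>=1: E=1.00 p_ge=1.0000   ... k>=7: E=1.76 p_ge=0.0005 ...
```

Reading the numbers: the MDSet covers the 1,200-protein network with 205
proteins (17.1%); 107 of them are also essential, an overlap far beyond
the hypergeometric expectation (one-sided Fisher p ≈ 6×10⁻¹²) because the
generator plants a positive degree–essentiality coupling and MDSets
favour well-connected proteins. The enrichment curve E_{i,≥k} — essential
proteins observed among proteins with ≥ k interactions, divided by the
mean count over label randomizations — rises with k (1.00 at k ≥ 1 by
construction, 1.76 at k ≥ 7), the centrality–lethality pattern; plus-one
empirical p-values of 0.0005 at R = 2,000 mean no null draw reached the
observed count.

The same battery runs from the shell:

```sh
mdset simulate --seed 7 --out demo_study
mdset run --study demo_study --reps 10000 --seed 1 --out demo_out
# MDSet objective 205 (17.1% of nodes); report at demo_out/report.json
```

`report.json` contains every stage (network summary, MDSet, strata,
Fisher p, enrichment curves, log-degree bin fractions, bottleneck
enrichment, robustness trajectory contrast, participation coefficients
with a Wilcoxon rank-sum comparison, intra/inter-complex and
functional-class enrichment), each reproducible from the recorded seeds.
Subcommands `solve`, `enrich-degree`, `bottleneck`, `overlap`,
`complexes`, `robustness` and `classes` expose the stages individually
for real data files (TSV/SIF edge lists, one-ID-per-line gene sets,
long/wide complex catalogs, protein→class-letter tables).

See `docs/methods.md` for the statistical definitions, null models,
generator design and numerical choices.

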