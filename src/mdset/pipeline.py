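"""One-command orchestration of the full analysis battery.

Given a study directory (real or synthetic) containing at minimum a
network edge list, and optionally an essential-gene list, a complex
catalog and a class annotation, runs: MDSet solve -> strata -> network
summary, Fisher overlap, degree-enrichment curves, log-degree bin
fractions, bottleneck enrichment, robustness trajectories, participation
coefficients with a rank-sum contrast, intra/inter-complex enrichment and
functional-class enrichment, one pass per stratum where applicable.

Every stochastic stage draws its seed deterministically from the global
seed and a stable per-stage key, so single-stage re-runs reproduce the
report's entries exactly and stages are order-independent. Stages whose
inputs are missing are marked skipped; a stage-level failure is recorded
and does not abort independent stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np

from . import classes as fc
from . import complexes as cx
from . import enrichment as en
from . import robustness as rb
from . import solver
from .core_network import (
    GeneSet,
    ProteinNetwork,
    network_summary,
    read_class_annotation,
    read_complex_catalog,
    read_edge_list,
    read_gene_set,
)

logger = logging.getLogger(__name__)

__all__ = ["run_full_analysis", "stage_seed", "load_study"]

STRATA = ("essential", "mdset", "e_mdset")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(
        np.random.SeedSequence([seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


def load_study(study_dir: str | Path) -> dict:
    """Load whatever inputs the study directory provides.

    Expects ``network.tsv`` (required), and optionally ``essential.txt``,
    ``complexes.tsv`` (long dialect) and ``annotation.tsv``.
    """
    d = Path(study_dir)
    net_path = d / "network.tsv"
    if not net_path.exists():
        raise FileNotFoundError(f"no network file at {net_path}")
    study = {"network": read_edge_list(net_path)}
    if (d / "essential.txt").exists():
        study["essential"] = read_gene_set(d / "essential.txt", label="essential")
    if (d / "complexes.tsv").exists():
        study["catalog"] = read_complex_catalog(d / "complexes.tsv", dialect="long")
    if (d / "annotation.tsv").exists():
        study["annotation"] = read_class_annotation(d / "annotation.tsv")
    return study


def _mean_degree(net: ProteinNetwork, proteins: set[str]) -> float:
    if not proteins:
        return float("nan")
    return float(np.mean([net.degree(v) for v in proteins]))


def _enrichment_dict(r: en.EnrichmentResult) -> dict:
    return dataclasses.asdict(r)


def _nan_to_none(obj):
    """Report values must compare equal across re-runs; NaN never does."""
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run_full_analysis(
    study_dir: str | Path,
    reps: int = 10_000,
    seed: int = 0,
    time_limit: float = 600.0,
    backend: str = "milp",
    out_dir: str | Path | None = None,
) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    t0 = time.monotonic()
    study = load_study(study_dir)
    net: ProteinNetwork = study["network"]
    report: dict = {
        "study_dir": str(study_dir),
        "parameters": {
            "reps": reps,
            "seed": seed,
            "time_limit": time_limit,
            "backend": backend,
        },
        "skipped": [],
        "errors": {},
    }

    summ = network_summary(net)
    report["network_summary"] = dataclasses.asdict(summ)

    # --- MDSet and strata -------------------------------------------------
    mdset = solver.solve_mdset(net, time_limit=time_limit, backend=backend)
    report["mdset"] = {
        "objective": mdset.objective,
        "status": mdset.status,
        "fraction_of_nodes": mdset.objective / net.n_nodes,
        "mean_degree": _mean_degree(net, set(mdset.members)),
        "solver_info": mdset.solver_info,
    }

    strata: dict[str, set[str]] = {"mdset": set(mdset.members)}
    essential: GeneSet | None = study.get("essential")
    if essential is not None:
        parts = solver.stratify(net, mdset, essential)
        strata["essential"] = set(parts.essential_in_network)
        strata["e_mdset"] = set(parts.e_mdset)
        report["strata"] = {
            "sizes": parts.sizes,
            "mean_degrees": {
                name: _mean_degree(net, members) for name, members in strata.items()
            },
        }
        report["fisher_overlap_p"] = en.fisher_overlap(
            net.n_nodes,
            len(parts.mdset),
            len(parts.essential_in_network),
            len(parts.e_mdset),
        )
    else:
        report["skipped"].append("strata (no essential gene list)")

    def _run(stage: str, fn) -> None:
        t = time.monotonic()
        try:
            fn()
        except Exception as exc:  # stage isolation: record, continue
            logger.exception("stage %s failed", stage)
            report["errors"][stage] = f"{type(exc).__name__}: {exc}"
        logger.info("stage %s: %.1fs", stage, time.monotonic() - t)

    # --- degree-based enrichment -----------------------------------------
    def _degree_curves() -> None:
        out = {}
        for name, members in strata.items():
            if not members:
                continue
            curve = en.degree_enrichment_curve(
                net,
                GeneSet(frozenset(members), label=name),
                R=reps,
                seed=stage_seed(seed, f"degree-curve:{name}"),
            )
            out[name] = curve.to_frame().to_dict(orient="records")
        report["degree_enrichment"] = out

    _run("degree_enrichment", _degree_curves)

    def _log_bins() -> None:
        if "essential" not in strata:
            report["skipped"].append("log_degree_bins (no essential gene list)")
            return
        frame = en.log_degree_bin_fractions(
            net, strata["e_mdset"], strata["essential"]
        )
        report["log_degree_bins"] = frame.to_dict(orient="records")

    _run("log_degree_bins", _log_bins)

    # --- bottlenecks ------------------------------------------------------
    def _bottleneck() -> None:
        scores = en.betweenness(net)
        bn = en.bottleneck_set(scores, quantile=0.20)
        out = {"n_bottleneck": len(bn), "enrichment": {}}
        for name, members in strata.items():
            if not members:
                continue
            out["enrichment"][name] = _enrichment_dict(
                en.set_overlap_enrichment(
                    net,
                    bn,
                    GeneSet(frozenset(members), label=name),
                    R=reps,
                    seed=stage_seed(seed, f"bottleneck:{name}"),
                )
            )
        report["bottleneck"] = out

    _run("bottleneck", _bottleneck)

    # --- robustness -------------------------------------------------------
    def _robustness() -> None:
        if "e_mdset" not in strata or not strata["e_mdset"]:
            report["skipped"].append("robustness (no e-MDSet stratum)")
            return
        comp = rb.compare_trajectories(
            net,
            strata["e_mdset"],
            essential,
            label_a="e_mdset",
            label_b="top-degree essential",
        )
        diffs = comp.difference_frame()
        report["robustness"] = {
            "label_a": comp.label_a,
            "label_b": comp.label_b,
            "n_deleted": len(comp.trajectory_a.deletion_order),
            "final_components_a": comp.trajectory_a.n_components[-1],
            "final_components_b": comp.trajectory_b.n_components[-1],
            "final_removed_edges_a": comp.trajectory_a.cumulative_removed_edges[-1],
            "final_removed_edges_b": comp.trajectory_b.cumulative_removed_edges[-1],
            "mean_d_components": float(diffs["d_components"].mean()),
            "mean_d_removed_edges": float(diffs["d_removed_edges"].mean()),
        }
        if out_dir is not None:
            comp.trajectory_a.to_frame().to_csv(
                Path(out_dir) / "trajectory_e_mdset.tsv", sep="\t", index=False
            )
            comp.trajectory_b.to_frame().to_csv(
                Path(out_dir) / "trajectory_essential_hubs.tsv", sep="\t", index=False
            )

    _run("robustness", _robustness)

    # --- complexes --------------------------------------------------------
    catalog = study.get("catalog")

    def _participation() -> None:
        if catalog is None:
            report["skipped"].append("participation (no complex catalog)")
            return
        part = cx.participation_coefficients(net, catalog)
        out = {"per_stratum": {}}
        for name, members in strata.items():
            vals = part.defined_for(members)
            out["per_stratum"][name] = {
                "n_defined": len(vals),
                "mean_P": float(np.mean(vals)) if vals else float("nan"),
                "median_P": float(np.median(vals)) if vals else float("nan"),
            }
        if strata.get("e_mdset") and strata.get("essential"):
            try:
                comparison = cx.compare_participation(
                    strata["e_mdset"],
                    strata["essential"],
                    part,
                    label_a="e_mdset",
                    label_b="essential",
                )
                out["rank_sum"] = dataclasses.asdict(comparison)
            except ValueError as exc:
                out["rank_sum"] = {"error": str(exc)}
        report["participation"] = out

    _run("participation", _participation)

    def _complex_interactions() -> None:
        if catalog is None:
            report["skipped"].append("complex_interactions (no complex catalog)")
            return
        out = {}
        for name, members in strata.items():
            if not members:
                continue
            counts = cx.count_complex_interactions(net, catalog, members)
            intra, inter = cx.complex_null_enrichment(
                net,
                catalog,
                members,
                R=reps,
                seed=stage_seed(seed, f"complex-null:{name}"),
            )
            out[name] = {
                "counts": dataclasses.asdict(counts),
                "intra": _enrichment_dict(intra),
                "inter": _enrichment_dict(inter),
            }
        report["complex_interactions"] = out

    _run("complex_interactions", _complex_interactions)

    # --- functional classes ----------------------------------------------
    def _classes() -> None:
        annotation = study.get("annotation")
        if annotation is None:
            report["skipped"].append("class_enrichment (no annotation)")
            return
        universe = {p for p in net.nodes if p in annotation.assignments}
        out = {}
        for name, members in strata.items():
            focal = members & universe
            if not focal:
                continue
            table = fc.class_enrichment(
                annotation,
                universe,
                focal,
                R=reps,
                seed=stage_seed(seed, f"classes:{name}"),
            )
            out[name] = table.to_frame().to_dict(orient="records")
        report["class_enrichment"] = out

    _run("class_enrichment", _classes)

    report = _nan_to_none(report)
    report["runtime_seconds"] = round(time.monotonic() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float) + "\n"
        )
        with open(out / "mdset_members.txt", "w") as fh:
            for v in sorted(mdset.members):
                fh.write(v + "\n")
    return report
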