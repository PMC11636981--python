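"""End-to-end orchestration of the synthetic-to-candidates analysis chain.

One call runs: design + count simulation, CPM filtering, TMM, log-CPM,
precision weights, moderated DE, signed-hybrid network + TOM, module
detection/merging, eigengenes, module-trait/GS/MM statistics, graph
thresholding, MCC hubs, seed-set first-neighbour alliances, and the
GS/MM/DE candidate-gene selection for each requested condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import condition as cond
from . import expression as expr
from . import hubs as hb
from . import io as vio
from . import network as net
from . import simulate as sim


@dataclass
class PipelineResult:
    design: pd.DataFrame
    counts: pd.DataFrame
    truth: sim.GroundTruth
    filtered: pd.DataFrame
    factors: pd.Series
    logexpr: pd.DataFrame
    de_table: pd.DataFrame
    network: net.CoexpressionNetwork
    partition: net.ModulePartition
    module_trait_r: pd.DataFrame
    module_trait_p: pd.DataFrame
    gs: dict[str, pd.DataFrame]
    mm: pd.DataFrame
    graph: hb.ThresholdedGraph
    hub_table: pd.DataFrame
    neighbor_sets: dict[str, set[str]]
    alliance: hb.AllianceResult
    candidates: dict[str, pd.DataFrame]
    report: vio.RunReport
    extras: dict = field(default_factory=dict)


def _pairs_from_comparisons(comparisons: dict[str, list[str]]) -> list[tuple[str, str]]:
    pairs = []
    for names in comparisons.values():
        for name in names:
            a, _, b = name.partition("_vs_")
            if not b:
                raise ValueError(f"comparison {name!r} is not of the form a_vs_b")
            if (a, b) not in pairs:
                pairs.append((a, b))
    return pairs


def run_pipeline(
    config: sim.SimulationConfig | None = None,
    seed: int | None = None,
    beta: float = 8.0,
    conditions: tuple[str, ...] = ("sulfide", "oxygen"),
    comparisons: dict[str, list[str]] | None = None,
    n_top: int = 2500,
    min_weight: float = 0.05,
    min_degree: int = 2,
    top_k_per_node: int | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full chain on synthetic data; optionally write all artifacts."""
    config = config or sim.SimulationConfig()
    if seed is not None:
        config = sim.SimulationConfig(**{**config.__dict__, "rng_seed": seed})
    comparisons = comparisons or {
        c: list(cond.DEFAULT_COMPARISONS[c])
        for c in conditions
        if c in cond.DEFAULT_COMPARISONS
    }
    report = vio.RunReport(seed=config.rng_seed, config={"simulation": config})

    with report.time_stage("simulate"):
        design = sim.simulate_design(config)
        counts, truth = sim.simulate_module_counts(config, design)

    with report.time_stage("prep"):
        filtered = expr.filter_low_expression(counts)
        factors = expr.tmm_factors(filtered)
        logexpr = expr.log_expression(filtered, factors)

    with report.time_stage("de"):
        design_mat = expr.treatment_design(design)
        obs_w, sample_w = expr.precision_weights(logexpr, design_mat)
        contrasts = expr.pairwise_contrasts(design_mat, _pairs_from_comparisons(comparisons))
        de_table = expr.fit_and_moderate(
            logexpr, design_mat, contrasts, obs_weights=obs_w, sample_weights=sample_w
        )

    with report.time_stage("network"):
        subset = net.select_top_variable(logexpr, n=min(n_top, len(logexpr)))
        cx = net.build_network(subset, beta=beta)

    with report.time_stage("modules"):
        partition = net.detect_modules(cx.tom, cx.genes)
        partition = net.merge_modules(partition, subset)
        cond_vecs = pd.DataFrame(
            {c: cond.encode_condition(design, c) for c in conditions}
        )
        mt_r, mt_p = net.module_trait_correlation(partition.eigengenes, cond_vecs)
        gs = {c: net.gene_significance(subset, cond_vecs[c]) for c in conditions}
        mm = net.module_membership(subset, partition.eigengenes)

    with report.time_stage("hubs"):
        graph = hb.threshold_network(
            cx.genes, cx.tom,
            weight_source="tom", min_weight=min_weight,
            min_degree=min_degree, top_k_per_node=top_k_per_node,
        )
        hub_table = hb.rank_hubs(hb.mcc_scores(graph), graph)
        hub_table = hub_table.merge(
            partition.labels.rename("module"), left_on="gene", right_index=True, how="left"
        )

    with report.time_stage("alliance"):
        neighbor_sets = {
            name: hb.first_neighbors(graph, seeds)
            for name, seeds in truth.seed_sets.items()
        }
        alliance = hb.alliance_matrix(neighbor_sets)

    with report.time_stage("condition"):
        candidates = {}
        for c in conditions:
            if c not in comparisons:
                continue
            top_mods = cond.rank_modules_by_gs(gs[c], partition.labels, k=2)
            candidates[c] = cond.select_candidates(
                gs[c], mm, partition.labels, de_table, top_mods, comparisons[c]
            )

    result = PipelineResult(
        design=design, counts=counts, truth=truth, filtered=filtered,
        factors=factors, logexpr=logexpr, de_table=de_table, network=cx,
        partition=partition, module_trait_r=mt_r, module_trait_p=mt_p,
        gs=gs, mm=mm, graph=graph, hub_table=hub_table,
        neighbor_sets=neighbor_sets, alliance=alliance,
        candidates=candidates, report=report,
    )
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every documented pipeline output plus the run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = result.report

    vio.write_counts(result.counts, out / "counts.tsv")
    r.add_output("counts", out / "counts.tsv")
    vio.write_metadata(result.design, out / "metadata.csv")
    r.add_output("metadata", out / "metadata.csv")
    (out / "truth.json").write_text(result.truth.to_json() + "\n")
    r.add_output("truth", out / "truth.json")

    vio.write_table(result.factors.to_frame(), out / "tmm_factors.tsv")
    vio.write_table(result.logexpr, out / "logexpr.tsv")
    vio.write_table(result.de_table, out / "de.tsv", index=False)

    part = pd.DataFrame(
        {
            "gene": result.partition.labels.index,
            "module": result.partition.labels.values,
        }
    )
    own_mm = [
        result.mm.loc[g, f"ME{m}"] if m != "grey" and f"ME{m}" in result.mm.columns else float("nan")
        for g, m in zip(part["gene"], part["module"])
    ]
    part["mm_own"] = own_mm
    part["connectivity"] = result.network.connectivity.reindex(part["gene"]).values
    vio.write_table(part, out / "partition.tsv", index=False)
    vio.write_table(result.partition.eigengenes, out / "eigengenes.tsv")
    vio.write_table(result.module_trait_r, out / "module_trait_r.tsv")
    vio.write_table(result.module_trait_p, out / "module_trait_p.tsv")

    edges = result.graph.edge_table()
    vio.write_edge_list(edges, out / "edges.tsv")
    vio.write_sif(edges, out / "network.sif")
    vio.write_table(result.hub_table, out / "hubs.tsv", index=False)
    vio.write_table(result.alliance.membership, out / "upset_membership.tsv")
    (out / "alliance.json").write_text(
        pd.Series(
            {
                "pairwise": result.alliance.pairwise.to_dict(orient="records"),
                "intersections": result.alliance.intersections.to_dict(orient="records"),
                "neighbor_set_sizes": {
                    k: len(v) for k, v in result.alliance.neighbor_sets.items()
                },
            }
        ).to_json(indent=1)
        + "\n"
    )
    for c, table in result.candidates.items():
        vio.write_table(table, out / f"candidates_{c}.tsv", index=False)
    for name in (
        "de.tsv", "partition.tsv", "eigengenes.tsv", "module_trait_r.tsv",
        "edges.tsv", "hubs.tsv", "upset_membership.tsv", "alliance.json",
    ):
        r.add_output(name.split(".")[0], out / name)
    r.write(out / "run_report.json")
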