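"""Map-level summary statistics and pipeline orchestration.

``run_pipeline`` chains the full analysis — simulate (or load) genotypes,
classify and filter markers, two-point estimation, grouping, multipoint
ordering, homeology assembly, retrotransposon analyses, summary — writing
one TSV artifact per stage.  All randomness flows from the single seed in
the configuration, so a rerun with the same seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import grouping as grouping_mod
from . import io as cio
from . import te as te_mod
from .homeology import build_linkage_map
from .linkagemap import LinkageMap
from .multipoint import OrderingConfig, order_group
from .segregation import SegregationResult, filter_sdm, results_frame
from .simulate import (
    NBSProfileConfig,
    SimulationConfig,
    simulate_nbs_profiles,
    simulate_population,
    write_truth,
)
from .twopoint import all_pairs

log = logging.getLogger("canemap")


@dataclass
class MapSummary:
    n_linked_markers: int
    n_unlinked: int
    n_cgs: int
    total_length_cm: float
    density_cm: float
    cg_length_min: float
    cg_length_max: float
    cg_length_mean: float
    max_adjacent_gap_cm: float
    mapped_proportion: dict[str, float]     # per system: linked / SDM
    linked_by_cross: dict[str, int]
    n_integrated_cgs: int                   # CGs holding both D1 and D2 markers

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "linked_markers": self.n_linked_markers,
            "unlinked_markers": self.n_unlinked,
            "n_cgs": self.n_cgs,
            "total_length_cM": round(self.total_length_cm, 2),
            "density_cM": round(self.density_cm, 2),
            "cg_length_min_cM": round(self.cg_length_min, 2),
            "cg_length_max_cM": round(self.cg_length_max, 2),
            "cg_length_mean_cM": round(self.cg_length_mean, 2),
            "max_adjacent_gap_cM": round(self.max_adjacent_gap_cm, 2),
            "integrated_cgs": self.n_integrated_cgs,
        }
        for sysname, frac in sorted(self.mapped_proportion.items()):
            rows[f"mapped_prop_{sysname}_pct"] = round(100.0 * frac, 1)
        for cross, n in sorted(self.linked_by_cross.items()):
            rows[f"linked_{cross}"] = n
        return pd.DataFrame({"value": rows})


def map_summary(
    linkage_map: LinkageMap, seg_results: list[SegregationResult] | None = None
) -> MapSummary:
    """Summary statistics of an ordered map; rounding happens only at print."""
    cgs = linkage_map.ordered_cgs
    if not cgs:
        raise ValueError("empty map")
    lengths = [cg.length_cm for cg in cgs]
    total = float(sum(lengths))
    n_linked = linkage_map.n_linked_markers
    max_gap = 0.0
    linked_by_cross: dict[str, int] = {}
    n_integrated = 0
    for cg in cgs:
        pos = cg.positions_cm
        if len(pos) > 1:
            max_gap = max(max_gap, float(np.max(np.diff(pos))))
        crosses = [cg.cross_types[m] for m in cg.markers]
        for c in crosses:
            linked_by_cross[c] = linked_by_cross.get(c, 0) + 1
        if "D1" in crosses and "D2" in crosses:
            n_integrated += 1
    mapped_prop: dict[str, float] = {}
    if seg_results is not None:
        linked_markers = {m for cg in cgs for m in cg.markers}
        by_system: dict[str, list[SegregationResult]] = {}
        for r in seg_results:
            if r.kept:
                sysname = linkage_map.system_of.get(r.marker_id, "?")
                by_system.setdefault(sysname, []).append(r)
        for sysname, rs in by_system.items():
            n_sdm = len(rs)
            n_map = sum(1 for r in rs if r.marker_id in linked_markers)
            mapped_prop[sysname] = n_map / n_sdm if n_sdm else math.nan
    return MapSummary(
        n_linked_markers=n_linked,
        n_unlinked=len(linkage_map.unlinked),
        n_cgs=len(cgs),
        total_length_cm=total,
        density_cm=total / n_linked,
        cg_length_min=float(min(lengths)),
        cg_length_max=float(max(lengths)),
        cg_length_mean=total / len(cgs),
        max_adjacent_gap_cm=max_gap,
        mapped_proportion=mapped_prop,
        linked_by_cross=linked_by_cross,
        n_integrated_cgs=n_integrated,
    )


@dataclass
class PipelineResult:
    table: cio.MarkerTable
    seg_results: list[SegregationResult]
    linkage_map: LinkageMap
    summary: MapSummary
    artifacts: dict[str, Path]


def run_pipeline(
    outdir,
    sim_config: SimulationConfig | None = None,
    table: cio.MarkerTable | None = None,
    alpha_global: float = 0.05,
    lod_min: float = grouping_mod.DEFAULT_LOD_MIN,
    rf_max: float = grouping_mod.DEFAULT_RF_MAX,
    ordering: OrderingConfig = OrderingConfig(),
    bin_cm: float = 10.0,
    max_gap_cm: float = 5.0,
    nbs_config: NBSProfileConfig | None = None,
    known_ssr_loci: list[str] | None = None,
) -> PipelineResult:
    """Run every stage and write one artifact per stage under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if (sim_config is None) == (table is None):
        raise ValueError("provide exactly one of sim_config or table")
    if sim_config is not None:
        log.info("simulate: seed=%d", sim_config.seed)
        table, truth = simulate_population(sim_config)
        artifacts["markers"] = outdir / "markers.tsv"
        cio.write_marker_table(table, artifacts["markers"])
        artifacts["truth"] = outdir / "truth.tsv"
        write_truth(truth, artifacts["truth"])

    log.info("classify: %d markers, alpha=%g", len(table.records), alpha_global)
    seg_results, table1 = filter_sdm(table, alpha_global)
    artifacts["segregation"] = outdir / "segregation.tsv"
    results_frame(seg_results).to_csv(artifacts["segregation"], sep="\t", index=False)
    artifacts["summary_counts"] = outdir / "summary_counts.tsv"
    table1.to_csv(artifacts["summary_counts"], sep="\t")

    kept = [r for r in seg_results if r.kept]
    if len(kept) < 2:
        raise RuntimeError("twopoint stage: fewer than 2 markers kept")
    log.info("twopoint: %d kept markers", len(kept))
    estimates = all_pairs(seg_results, table)
    artifacts["twopoint"] = outdir / "twopoint.tsv"
    with open(artifacts["twopoint"], "wt") as fh:
        fh.write("marker_a\tmarker_b\tclass\tphase_p1\tphase_p2\trf\tLOD\n")
        for e in estimates:
            if e.informative:
                fh.write(
                    f"{e.marker_a}\t{e.marker_b}\t{e.pair_class}\t"
                    f"{e.best_phase.phase_p1 or '-'}\t{e.best_phase.phase_p2 or '-'}\t"
                    f"{e.rf_hat:.6f}\t{e.lod:.4f}\n"
                )
            else:
                fh.write(f"{e.marker_a}\t{e.marker_b}\t{e.pair_class}\t-\t-\t-\t-\n")

    log.info("group: LOD >= %g, rf <= %g", lod_min, rf_max)
    graph = grouping_mod.build_linkage_graph(
        estimates, lod_min, rf_max, markers=[r.marker_id for r in kept]
    )
    grouped = grouping_mod.co_segregation_groups(graph)
    artifacts["groups"] = outdir / "groups.tsv"
    with open(artifacts["groups"], "wt") as fh:
        fh.write("marker\tCG\n")
        for cg in grouped.groups:
            for m in cg.markers:
                fh.write(f"{m}\t{cg.name}\n")
        for m in grouped.unlinked:
            fh.write(f"{m}\tunlinked\n")

    cross_of = {r.marker_id: r.cross_type for r in seg_results}
    system_of = {rec.marker_id: rec.system.value for rec in table.records}
    est_lookup = {
        frozenset((e.marker_a, e.marker_b)): e for e in estimates
    }
    ordered = []
    for cg in grouped.groups:
        log.info("order: %s (%d markers)", cg.name, len(cg.markers))
        sub_lookup = {}
        for i, a in enumerate(cg.markers):
            for b in cg.markers[i + 1:]:
                key = frozenset((a, b))
                est = est_lookup.get(key)
                if est is not None:
                    sub_lookup[key] = est
        ordered.append(
            order_group(cg.name, cg.markers, table, cross_of, sub_lookup, ordering)
        )

    linkage_map, hgs = build_linkage_map(
        ordered, system_of, cross_of, unlinked=grouped.unlinked,
        known_loci=known_ssr_loci,
    )
    artifacts["map"] = outdir / "map.tsv"
    cio.export_map_text(linkage_map, artifacts["map"], format="tsv")
    artifacts["hgs"] = outdir / "hgs.tsv"
    with open(artifacts["hgs"], "wt") as fh:
        fh.write("CG\tHG\tstatus\tshared_loci\n")
        for hg in hgs:
            for cg_name in hg.core_cgs:
                loci = sorted(
                    {x for (a, b), s in hg.shared_loci.items()
                     if cg_name in (a, b) for x in s}
                )
                fh.write(f"{cg_name}\t{hg.name}\tcore\t{','.join(loci) or '-'}\n")
            for cg_name in hg.putative_cgs:
                loci = sorted(
                    {x for (a, b), s in hg.shared_loci.items()
                     if cg_name in (a, b) for x in s}
                )
                fh.write(f"{cg_name}\t{hg.name}\tputative\t{','.join(loci) or '-'}\n")
        for cg in linkage_map.ordered_cgs:
            if linkage_map.hg_of.get(cg.name, "U").startswith("U"):
                fh.write(f"{cg.name}\tU\tunassigned\t-\n")

    clusters = te_mod.call_clusters(linkage_map, "RT", max_gap_cm=max_gap_cm)
    artifacts["te_clusters"] = outdir / "te_clusters.tsv"
    with open(artifacts["te_clusters"], "wt") as fh:
        fh.write("Cluster\tMarkers\tCluster_size_cM\tHG\tCG\n")
        for i, cl in enumerate(clusters, start=1):
            hg = linkage_map.hg_of.get(cl.cg_name, "-")
            fh.write(
                f"{i}\t{', '.join(cl.markers)}\t{cl.span_cm:.2f}\t{hg}\t{cl.cg_name}\n"
            )
    counts = te_mod.bin_markers(linkage_map, "RT", bin_cm=bin_cm)
    artifacts["poisson"] = outdir / "te_poisson.tsv"
    try:
        fit = te_mod.poisson_gof(counts)
        with open(artifacts["poisson"], "wt") as fh:
            fh.write("x\tobserved\texpected\n")
            for x, (o, e) in enumerate(zip(fit.observed, fit.expected)):
                fh.write(f"{x}\t{o}\t{e:.4f}\n")
            fh.write(f"# lambda={fit.lambda_hat:.6f} chi2={fit.chi2:.4f} "
                     f"df={fit.df} p={fit.p_value:.3e}\n")
    except ValueError as exc:
        artifacts["poisson"].write_text(f"# not testable: {exc}\n")

    if nbs_config is not None:
        prof = simulate_nbs_profiles(nbs_config)
        est = te_mod.copy_number(prof.total_fragments, nbs_config.n_combinations)
        p1, p2 = te_mod.copy_number_per_parent(
            int(prof.parent1_counts.sum()), int(prof.parent2_counts.sum()),
            nbs_config.n_combinations,
        )
        artifacts["copynum"] = outdir / "copy_number.tsv"
        with open(artifacts["copynum"], "wt") as fh:
            fh.write("scope\ttotal_fragments\tn_combinations\traw\trounded\n")
            for scope, e in (("genome", est), ("parent1", p1), ("parent2", p2)):
                fh.write(f"{scope}\t{e.total_fragments}\t{e.n_combinations}\t"
                         f"{e.estimate_raw:.4f}\t{e.estimate_rounded}\n")

    summary = map_summary(linkage_map, seg_results)
    artifacts["summary"] = outdir / "map_summary.tsv"
    summary.to_frame().to_csv(artifacts["summary"], sep="\t")

    return PipelineResult(table, seg_results, linkage_map, summary, artifacts)
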