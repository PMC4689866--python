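"""End-to-end orchestration of the top-down and guide-gene pipelines.

``run_topdown``: collapse -> correlate -> threshold sweep -> signed network
at the chosen cutoff -> MCL inflation sweep scored by GO F-measure ->
enrichment -> hub calling -> DEG overlay, writing every stage artifact and
a JSON run manifest (thresholds, seed, input digests, stages completed).

``run_guidegene``: correlate -> mutual ranks -> guide expansion -> promoter
scan -> putative-target nomination -> motif enrichment, same manifest
contract.  Both are deterministic given inputs; only synthetic-data
generation consumes randomness.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, enrichment, guides, hubs, io, mcl, motifs, network
from .expression import call_degs, collapse_probes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression: str | Path = None
    design: str | Path = None
    annotations: str | Path = None
    promoters: str | Path = None
    guides: str | Path = None
    motif_dictionary: str | Path = None  # None -> built-in MYB dictionary
    outdir: str | Path = "."
    pcc_cutoff: float = 0.85
    fdr: float = 0.05
    fc_threshold: float = 1.5
    min_hub_degree: int = 5
    inflation_values: tuple = tuple(np.round(np.arange(1.1, 3.0 + 1e-9, 0.1), 2))
    mr_max: float = 5.0
    pcc_min: float = 0.6
    hierarchy_depth: int = 2
    proximal_window: int = 200
    control_condition: str | None = None
    treatment_condition: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pcc_cutoff < 1:
            raise ValueError("pcc_cutoff must be in (0, 1)")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _manifest(config: RunConfig, stages: list, inputs: dict, outdir: Path):
    payload = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "pcc_cutoff": config.pcc_cutoff,
            "fdr": config.fdr,
            "fc_threshold": config.fc_threshold,
            "min_hub_degree": config.min_hub_degree,
            "mr_max": config.mr_max,
            "pcc_min": config.pcc_min,
            "hierarchy_depth": config.hierarchy_depth,
            "proximal_window": config.proximal_window,
        },
        "input_digests": {k: _digest(v) for k, v in inputs.items() if v is not None},
        "stages_completed": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_topdown(config: RunConfig, probe_mapping: dict | None = None) -> dict:
    """Top-down network pipeline; returns a report dict, writes artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    report: dict = {}
    try:
        stage = "load"
        matrix = io.read_expression(config.expression, config.design)
        annotations = io.read_annotations(config.annotations,
                                          universe=matrix.gene_ids)

        stage = "collapse"
        if probe_mapping:
            matrix = collapse_probes(matrix, probe_mapping)
        stages.append(stage)

        stage = "correlate"
        corr = network.pearson_all_pairs(matrix)
        stages.append(stage)

        stage = "threshold_sweep"
        sweep = network.sweep_thresholds(
            corr, list(np.round(np.arange(0.5, 0.96, 0.05), 2)))
        sweep.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)
        stages.append(stage)

        stage = "build_network"
        net = network.build_network(corr, config.pcc_cutoff)
        io.write_edge_list(net, outdir / "edges.tsv")
        io.write_graphml(net.graph, outdir / "network.graphml")
        report["n_nodes"] = net.n_nodes()
        report["n_edges"] = net.n_edges()
        report["density"] = net.density()
        stages.append(stage)

        if net.n_edges() == 0:
            report["note"] = "no modules: network empty at this cutoff"
            (outdir / "no_modules.txt").write_text(report["note"] + "\n")
            _manifest(config, stages, {"expression": config.expression,
                                       "annotations": config.annotations}, outdir)
            return report

        stage = "mcl_sweep"
        best, table = mcl.inflation_sweep(net, annotations,
                                          I_values=config.inflation_values,
                                          fdr_threshold=config.fdr)
        table.to_csv(outdir / "inflation_sweep.tsv", sep="\t", index=False)
        io.write_module_membership(best, outdir / "modules.tsv")
        report["best_inflation"] = best.inflation_used
        report["n_modules"] = best.n_modules()
        report["modularity"] = best.modularity
        stages.append(stage)

        stage = "enrichment"
        records = enrichment.enrich_partition(best, annotations, config.fdr)
        import pandas as pd
        pd.DataFrame([vars(r) for r in records]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False)
        quality = enrichment.cluster_quality(best, records, annotations)
        report["f_measure"] = quality.f_measure
        stages.append(stage)

        stage = "hubs"
        module_of = {g: mid for mid, gs in best.modules.items() for g in gs}
        hub_table = hubs.find_hubs(net, config.min_hub_degree, module_of)
        hub_table.to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        report["n_hubs"] = len(hub_table)
        stages.append(stage)

        stage = "degs"
        if (matrix.design is not None and config.control_condition
                and config.treatment_condition):
            degs = call_degs(matrix, config.control_condition,
                             config.treatment_condition,
                             fc_threshold=config.fc_threshold,
                             p_threshold=config.fdr)
            degs.to_csv(outdir / "degs.tsv", sep="\t")
            report["n_degs"] = int(degs["is_de"].sum())
        stages.append(stage)
    except Exception as exc:
        raise RuntimeError(f"top-down pipeline failed at stage {stage!r}: {exc}") from exc
    _manifest(config, stages, {"expression": config.expression,
                               "design": config.design,
                               "annotations": config.annotations}, outdir)
    return report


def run_guidegene(config: RunConfig) -> dict:
    """Guide-gene pipeline; returns a report dict, writes artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = []
    report: dict = {}
    try:
        stage = "load"
        matrix = io.read_expression(config.expression, config.design)
        promoters = io.read_promoters(config.promoters)
        guide_ids = io.read_guides(config.guides)
        dictionary = (io.read_motif_dictionary(config.motif_dictionary)
                      if config.motif_dictionary else motifs.DEFAULT_MOTIFS)

        stage = "correlate"
        corr = network.pearson_all_pairs(matrix)
        stages.append(stage)

        stage = "mutual_ranks"
        mr = network.mutual_ranks(corr)
        stages.append(stage)

        stage = "expand"
        gconf = guides.GuideConfig(guides=tuple(guide_ids),
                                   hierarchy_depth=config.hierarchy_depth,
                                   mr_max=config.mr_max, pcc_min=config.pcc_min)
        gnet = guides.expand_from_guides(corr, mr, gconf)
        io.write_graphml(gnet.graph, outdir / "guide_network.graphml")
        report["n_nodes"] = gnet.graph.number_of_nodes()
        report["n_first_neighbors"] = len(gnet.first_neighbors())
        stages.append(stage)

        stage = "scan"
        member_proms = motifs.PromoterSet(
            sequences={g: s for g, s in promoters.sequences.items()
                       if g in gnet.graph.nodes},
            length=promoters.length)
        hits = motifs.scan_promoters(member_proms, dictionary)
        io.write_hits(hits, outdir / "motif_hits.tsv")
        stages.append(stage)

        stage = "nominate"
        table = guides.nominate_targets(gnet, hits)
        table.to_csv(outdir / "putative_targets.tsv", sep="\t", index=False)
        myb_targets, drought_targets = motifs.putative_target_filter(
            hits, genes=gnet.first_neighbors())
        report["n_putative_targets"] = len(myb_targets)
        report["n_drought_mbs_targets"] = len(drought_targets)
        prox, dist = motifs.proximal_distal_split(
            [h for h in hits if h.motif_id in motifs.DROUGHT_MBS_IDS],
            promoter_length=promoters.length, window=config.proximal_window)
        report["drought_mbs_proximal_fraction"] = prox
        report["drought_mbs_distal_fraction"] = dist
        stages.append(stage)

        stage = "motif_enrichment"
        import pandas as pd
        rows = []
        for mid in dictionary.ids():
            obs, exp, p = motifs.motif_enrichment(hits, member_proms, mid, dictionary)
            rows.append({"motif": mid, "observed": obs, "expected": exp, "p": p})
        pd.DataFrame(rows).to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
        stages.append(stage)
    except Exception as exc:
        raise RuntimeError(f"guide-gene pipeline failed at stage {stage!r}: {exc}") from exc
    _manifest(config, stages, {"expression": config.expression,
                               "promoters": config.promoters,
                               "guides": config.guides}, outdir)
    return report
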