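"""End-to-end pipeline: synthetic community (or provided inputs) ->
reference binning -> subclustering -> profile-HMM build + calibration ->
proteome screening -> degrader classification -> reciprocal-best-hit
confirmation -> pathway assignment -> gene-cluster localization -> MLSA
phylogeny -> report.

Every numeric threshold lives in :class:`PipelineConfig` (defaults: binning
id >= 30% / E <= 1e-30; RBH expansion id >= 25% / E <= 1e-30; confirmation
id >= 25% / E <= 1e-25; subclustering 50% identity, word size 3; HMM screen
E <= 1e-25; degrader rule >= 6 of 8 groups including the two mandatory ones;
pathway coverage >= 0.7; cluster gap <= 10 genes; 2,500 bootstrap
replicates) and is echoed verbatim into the run report.  Runs are
deterministic under a fixed seed: rerunning writes byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import __version__
from .align import default_scheme
from .classify import EnzymePanel, assign_pathway, classify_degrader, side_chain_profile
from .clusters import detect_clusters, locate_hits, replicon_summary
from .errors import ConfigurationError
from .evolution import random_protein
from .homology import build_graph, connected_components, greedy_cluster, retain_seeded
from .io import annotation_frame, write_annotation, write_fasta, write_tree, write_truth_table
from .msa import progressive_align, trim_columns
from .orthology import reciprocal_best_hits
from .phmm import ProfileHMM, build_profile, calibrate_evalue, screen_proteome
from .phylo import (
    bootstrap_support,
    build_supermatrix,
    distance_matrix,
    extract_markers,
    nj_tree,
    rf_distance,
)
from .simulate import CommunityConfig, GenomeRecord, ReferencePanel, TruthTable, generate_community

logger = logging.getLogger("steromine")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable threshold of the screen, with the published defaults."""

    binning_min_identity: float = 0.30
    binning_max_evalue: float = 1e-30
    rbh_expansion_min_identity: float = 0.25
    rbh_expansion_max_evalue: float = 1e-30
    rbh_confirmation_min_identity: float = 0.25
    rbh_confirmation_max_evalue: float = 1e-25
    subcluster_min_identity: float = 0.50
    subcluster_word_size: int = 3
    hmm_screen_max_evalue: float = 1e-25
    hmm_calibration_n: int = 1000
    classify_min_groups: int = 6
    mandatory_groups: Tuple[str, ...] = ("KshA", "HsaC")
    pathway_coverage_threshold: float = 0.7
    cluster_max_gap_genes: int = 10
    phylo_markers: Tuple[str, ...] = ("KshA", "HsaA", "HsaC", "HsaD")
    phylo_bootstrap: int = 2500
    n_reference_decoys: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "binning_min_identity",
            "rbh_expansion_min_identity",
            "rbh_confirmation_min_identity",
            "subcluster_min_identity",
            "pathway_coverage_threshold",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in (
            "binning_max_evalue",
            "rbh_expansion_max_evalue",
            "rbh_confirmation_max_evalue",
            "hmm_screen_max_evalue",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.classify_min_groups < 1:
            raise ConfigurationError("classify_min_groups must be positive")
        if self.cluster_max_gap_genes < 0:
            raise ConfigurationError("cluster_max_gap_genes must be non-negative")
        if self.phylo_bootstrap < 1:
            raise ConfigurationError("phylo_bootstrap must be positive")

    def echo(self) -> Dict:
        return asdict(self)


@dataclass
class RunReport:
    seed: int
    version: str
    config: Dict
    stage_counts: Dict[str, int] = field(default_factory=dict)
    verdicts: List[Dict] = field(default_factory=list)
    identity_matrices: Dict[str, Dict[str, Dict[str, float]]] = field(default_factory=dict)
    cluster_summaries: Dict[str, Dict] = field(default_factory=dict)
    trees: Dict[str, str] = field(default_factory=dict)
    congruence: Dict[str, float] = field(default_factory=dict)
    drop_reports: Dict[str, List[str]] = field(default_factory=dict)
    evaluation: Dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _derive_seed(base: int, salt: int) -> int:
    return int((base * 1000003 + salt * 7919 + 12345) % (2**31))


def _build_hmms(
    panel: ReferencePanel, config: PipelineConfig
) -> Tuple[List[ProfileHMM], Dict[str, str], Dict[str, int]]:
    """Bin training proteins, subcluster, and train one calibrated HMM per
    seeded subcluster.  Returns (hmms, hmm_to_group, counts)."""
    scheme = default_scheme()
    train = {p.id: p.sequence for p in panel.core() + panel.orthologs}
    group_of = {p.id: p.group for p in panel.core() + panel.orthologs}
    seeds = {p.id for p in panel.core()}
    graph = build_graph(
        train, config.binning_min_identity, config.binning_max_evalue, scheme
    )
    components = connected_components(graph)
    hmms: List[ProfileHMM] = []
    hmm_to_group: Dict[str, str] = {}
    n_subclusters = 0
    skipped: List[str] = []
    for comp in components:
        comp_seeds = seeds & comp
        if not comp_seeds:
            continue
        sub = greedy_cluster(
            {i: train[i] for i in sorted(comp)},
            config.subcluster_min_identity,
            config.subcluster_word_size,
            scheme,
        )
        sub = retain_seeded(sub, comp_seeds)
        group = group_of[min(comp_seeds)]
        for ci, members in enumerate(sub.clusters):
            n_subclusters += 1
            hmm_id = f"{group}.{ci + 1}"
            if len(members) < 2:
                skipped.append(hmm_id)
                continue
            aln = trim_columns(progressive_align({m: train[m] for m in members}, scheme))
            hmm = build_profile(aln, hmm_id=hmm_id, source_subcluster=hmm_id)
            hmm = calibrate_evalue(
                hmm,
                n_random=config.hmm_calibration_n,
                length_distribution=(100, 400),
                seed=_derive_seed(config.seed, len(hmms) + 1),
            )
            hmms.append(hmm)
            hmm_to_group[hmm_id] = group
    if skipped:
        logger.warning("skipped singleton subclusters: %s", skipped)
    counts = {"components": len(components), "subclusters": n_subclusters, "hmms": len(hmms)}
    return hmms, hmm_to_group, counts


def run_pipeline(
    config: PipelineConfig,
    community: Optional[CommunityConfig] = None,
    genomes: Optional[Dict[str, GenomeRecord]] = None,
    truth: Optional[TruthTable] = None,
    panel: Optional[ReferencePanel] = None,
    species_tree: Optional[TreeNode] = None,
    outdir: Optional[Path] = None,
) -> RunReport:
    """Execute every stage in order and return (and optionally persist) the
    run report.  Provide either a :class:`CommunityConfig` (synthetic run) or
    pre-built genomes plus a reference panel."""
    logger.info("pipeline start: seed=%d version=%s", config.seed, __version__)
    scheme = default_scheme()
    report = RunReport(seed=config.seed, version=__version__, config=config.echo())

    # --- stage 0: inputs -------------------------------------------------
    if community is not None:
        genomes, truth, panel, species_tree = generate_community(community, panel)
    if genomes is None or panel is None:
        raise ConfigurationError("need either a community config or genomes plus a panel")
    if config.classify_min_groups > len(panel.groups):
        raise ConfigurationError(
            f"classify_min_groups={config.classify_min_groups} exceeds the "
            f"{len(panel.groups)}-group panel"
        )
    genome_ids = sorted(genomes)
    report.stage_counts["genomes"] = len(genome_ids)
    report.stage_counts["proteins"] = sum(len(g.genes) for g in genomes.values())

    # --- stage 1-3: binning, subclustering, HMM training ------------------
    hmms, hmm_to_group, hmm_counts = _build_hmms(panel, config)
    report.stage_counts.update(hmm_counts)
    logger.info("built %d calibrated HMMs from %d subclusters", len(hmms), hmm_counts["subclusters"])

    # --- stage 4: screening ----------------------------------------------
    hits_by_genome = {}
    for gid in genome_ids:
        hits_by_genome[gid] = screen_proteome(
            hmms, genomes[gid].proteome(), gid, config.hmm_screen_max_evalue
        )
    report.stage_counts["hmm_hits"] = sum(len(h) for h in hits_by_genome.values())

    # --- stage 5: classification ------------------------------------------
    enzyme_panel = EnzymePanel(
        groups=list(panel.groups),
        mandatory=set(config.mandatory_groups) & set(panel.groups),
        hmm_to_group=hmm_to_group,
    )
    calls = {
        gid: classify_degrader(
            hits_by_genome[gid], enzyme_panel, config.classify_min_groups, gid
        )
        for gid in genome_ids
    }
    candidates = [gid for gid in genome_ids if calls[gid].is_degrader]
    report.stage_counts["putative_degraders"] = len(candidates)
    logger.info("classified %d putative degraders", len(candidates))

    # --- stage 6: RBH confirmation + pathway assignment --------------------
    ref_rng = np.random.default_rng(_derive_seed(config.seed, 999))
    ref_proteomes: Dict[str, Dict[str, str]] = {}
    panels: Dict[str, List[str]] = {}
    for template in panel.templates:
        queries = {p.id: p.sequence for p in panel.template_panel(template)}
        ref = dict(queries)
        for i in range(config.n_reference_decoys):
            ref[f"{template}|decoy{i + 1:03d}"] = random_protein(
                int(ref_rng.integers(100, 260)), ref_rng
            )
        ref_proteomes[template] = ref
        panels[template] = sorted(queries)

    rbh_maps: Dict[str, Dict[str, object]] = {gid: {} for gid in candidates}
    pathway_calls: Dict[str, Dict[str, float]] = {}
    side_chain: Dict[str, Dict[str, str]] = {}
    for gid in candidates:
        proteome = genomes[gid].proteome()
        maps = {}
        for template in panel.templates:
            maps[template] = reciprocal_best_hits(
                {p.id: p.sequence for p in panel.template_panel(template)},
                proteome,
                ref_proteomes[template],
                mode="confirmation",
                scoring=scheme,
            )
        rbh_maps[gid] = maps
        pathway_calls[gid] = assign_pathway(maps, panels, config.pathway_coverage_threshold)
        side_chain[gid] = {
            t: side_chain_profile(maps[t], panel.side_chain_ids(t))
            for t in pathway_calls[gid]
        }
        calls[gid].pathways = pathway_calls[gid]
    report.stage_counts["confirmed_degraders"] = sum(
        1 for gid in candidates if pathway_calls[gid]
    )

    for template in panel.templates:
        matrix: Dict[str, Dict[str, float]] = {}
        for gid in candidates:
            omap = rbh_maps[gid][template]
            matrix[gid] = {
                rid: round(e.identity, 4) for rid, e in sorted(omap.entries.items())
            }
        report.identity_matrices[template] = matrix

    report.verdicts = [
        {
            "genome_id": gid,
            "n_groups_present": len(calls[gid].groups_present),
            "groups_present": sorted(calls[gid].groups_present),
            "mandatory_satisfied": calls[gid].mandatory_satisfied,
            "verdict": calls[gid].verdict,
            "pathways": {k: round(v, 4) for k, v in sorted(calls[gid].pathways.items())},
            "side_chain": side_chain.get(gid, {}),
        }
        for gid in genome_ids
    ]

    # --- stage 7: gene-cluster localization --------------------------------
    cluster_calls = {}
    for gid in candidates:
        maps = rbh_maps[gid]
        gene_labels: Dict[str, str] = {}
        for template, omap in maps.items():
            for rid, entry in omap.entries.items():
                src = panel.by_id()[rid]
                label = src.group if src.group else rid.split("|", 1)[1]
                gene_labels.setdefault(entry.target_id, label)
        ann = annotation_frame(genomes[gid])
        located, unresolved = locate_hits(gene_labels, ann, gid, gene_labels)
        if unresolved:
            report.drop_reports.setdefault("unresolved_hits", []).extend(unresolved)
        rep_counts = ann.groupby("replicon_id").size().to_dict()
        circ = {r.id: r.circular for r in genomes[gid].replicons}
        cluster_calls[gid] = detect_clusters(
            located, config.cluster_max_gap_genes, rep_counts, circ
        )
    summaries = replicon_summary([c for cs in cluster_calls.values() for c in cs])
    report.stage_counts["gene_clusters"] = sum(len(c) for c in cluster_calls.values())
    for gid, s in summaries.items():
        report.cluster_summaries[gid] = {
            "n_clusters": s.n_clusters,
            "n_plasmid_clusters": s.n_plasmid_clusters,
            "plasmid_only": s.plasmid_only,
            "clusters": {
                cid: sorted(groups) for cid, groups in s.group_composition.items()
            },
        }

    # --- stage 8: MLSA phylogeny -------------------------------------------
    taxon_markers: Dict[str, Dict[str, Optional[str]]] = {}
    taxon_to_genome: Dict[str, str] = {}
    for gid in candidates:
        proteome = genomes[gid].proteome()
        multi = len(cluster_calls[gid]) > 1
        for call in cluster_calls[gid]:
            taxon = f"{gid}.{call.cluster_id}" if multi else gid
            taxon_to_genome[taxon] = gid
            markers: Dict[str, Optional[str]] = {}
            for m in config.phylo_markers:
                gene = next((g for g in call.members if g.group_label == m), None)
                markers[m] = proteome[gene.gene_id] if gene else None
            taxon_markers[taxon] = markers
    if len(taxon_markers) >= 3:
        kept, dropped = extract_markers(taxon_markers, config.phylo_markers)
        if dropped:
            report.drop_reports["incomplete_marker_taxa"] = dropped
        if len(kept) >= 3:
            sm = build_supermatrix(kept, config.phylo_markers)
            marker_tree, _support = bootstrap_support(
                sm, n_replicates=config.phylo_bootstrap, seed=_derive_seed(config.seed, 777)
            )
            report.trees["pathway_markers"] = str(marker_tree).strip()
            # 16S-like marker-gene tree over the same genomes
            genome_set = sorted({taxon_to_genome[t] for t in kept})
            if len(genome_set) >= 3:
                aln = trim_columns(
                    progressive_align({g: genomes[g].marker for g in genome_set})
                )
                from .phylo import Supermatrix

                marker_sm = Supermatrix(
                    taxa=genome_set,
                    rows=dict(zip(aln.ids, aln.rows)),
                    block_coords=[("marker", 0, aln.n_columns)],
                )
                gene_16s_tree = nj_tree(distance_matrix(marker_sm, p_cap=0.95))
                report.trees["marker_gene"] = str(gene_16s_tree).strip()
                renamed = marker_tree.copy()
                for tip in renamed.tips():
                    tip.name = taxon_to_genome.get(tip.name, tip.name)
                try:
                    report.congruence["rf_pathway_vs_marker_gene"] = float(
                        rf_distance(renamed, gene_16s_tree)
                    )
                except Exception:
                    pass
                if species_tree is not None:
                    report.trees["species"] = str(species_tree).strip()
                    report.congruence["rf_pathway_vs_species"] = float(
                        rf_distance(renamed, species_tree)
                    )
                    report.congruence["rf_marker_gene_vs_species"] = float(
                        rf_distance(gene_16s_tree, species_tree)
                    )

    # --- evaluation against truth ------------------------------------------
    if truth is not None:
        degraders = set(truth.degraders())
        non_degraders = set(genome_ids) - degraders
        tp = sum(1 for g in degraders if calls[g].is_degrader)
        tn = sum(1 for g in non_degraders if not calls[g].is_degrader)
        report.evaluation["sensitivity"] = tp / len(degraders) if degraders else float("nan")
        report.evaluation["specificity"] = (
            tn / len(non_degraders) if non_degraders else float("nan")
        )
        correct_pathway = sum(
            1
            for g in degraders
            if calls[g].is_degrader and set(pathway_calls.get(g, {})) == truth.rows[g].pathways
        )
        report.evaluation["pathway_accuracy"] = (
            correct_pathway / len(degraders) if degraders else float("nan")
        )
        # exact recovery of planted clusters as single calls
        n_truth_clusters = 0
        n_recovered = 0
        for g in degraders:
            truth_sets = [set(m) for m in truth.rows[g].cluster_memberships.values()]
            n_truth_clusters += len(truth_sets)
            call_sets = [set(c.member_ids) for c in cluster_calls.get(g, [])]
            for ts in truth_sets:
                if sum(1 for cs in call_sets if cs == ts) == 1:
                    n_recovered += 1
        report.evaluation["cluster_recovery"] = (
            n_recovered / n_truth_clusters if n_truth_clusters else float("nan")
        )
        flags_ok = sum(
            1
            for g in degraders
            if g in summaries and summaries[g].plasmid_only == truth.rows[g].plasmid_only
        )
        report.evaluation["plasmid_flag_accuracy"] = (
            flags_ok / len(degraders) if degraders else float("nan")
        )

    # --- persist -----------------------------------------------------------
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json() + "\n")
        pd.DataFrame(report.verdicts).to_csv(
            outdir / "verdicts.tsv", sep="\t", index=False
        )
        for template, matrix in report.identity_matrices.items():
            pd.DataFrame(matrix).to_csv(outdir / f"identity_{template}.tsv", sep="\t")
        for name, nwk in report.trees.items():
            (outdir / f"tree_{name}.nwk").write_text(nwk + "\n")
        if truth is not None:
            write_truth_table(truth, outdir / "truth.tsv")
        for gid in genome_ids:
            write_fasta(genomes[gid].proteome(), outdir / f"{gid}.faa")
            write_annotation(genomes[gid], outdir / f"{gid}.gff3")
        if species_tree is not None:
            write_tree(species_tree, outdir / "species_tree.nwk")
    logger.info("pipeline done")
    return report
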