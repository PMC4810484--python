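"""Synthetic communities of annotated bacterial genomes with planted
steroid-degradation gene clusters.

The generator emulates the study population of a genome-mining screen:

* a reference panel of eight core enzyme groups (KstD, KshA, HsaA, HsaC,
  HsaD, HsaE, HsaF, HsaG — KshA and HsaC flagged mandatory) present in three
  pathway templates (cholesterol, cholate, testosterone/cholate), plus
  template-specific accessory genes (three of them marked side-chain genes),
* proteomes in which pathway genes are diverged to a controlled identity to
  the panel references and arranged in one or two genomic clusters on a
  chromosome or plasmid,
* decoy genes (background-composition random proteins and "near-decoys"
  evolved to 10-20% identity, which exercise the screening thresholds near
  their decision boundary),
* a 16S-like marker gene evolved along a known species tree, and
* optional horizontal transfer of whole pathways: the recipient's pathway
  genes descend from the donor lineage while its marker follows the species
  tree.

Every planted locus is recorded in a :class:`TruthTable` so that each
downstream stage of the pipeline can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from skbio import TreeNode

from .errors import ConfigurationError, InputError
from .evolution import EvolutionModel, _evolve_once, evolve_along_tree, random_protein
from .alphabet import decode, encode

__all__ = [
    "CORE_GROUPS",
    "MANDATORY_GROUPS",
    "DEFAULT_TEMPLATES",
    "PanelProtein",
    "ReferencePanel",
    "CommunityConfig",
    "Gene",
    "Replicon",
    "GenomeRecord",
    "TruthRow",
    "TruthTable",
    "generate_reference_panel",
    "generate_community",
    "random_ultrametric_tree",
    "balanced_species_tree",
]

CORE_GROUPS = ["KstD", "KshA", "HsaA", "HsaC", "HsaD", "HsaE", "HsaF", "HsaG"]
MANDATORY_GROUPS = {"KshA", "HsaC"}
DEFAULT_TEMPLATES = ["cholesterol", "cholate", "testosterone_cholate"]

# divergence of each template's copy from the unobserved group ancestor;
# gives ~40-45% identity between template copies, comfortably above the
# 30%/25% identity filters and below the 50% subclustering threshold.
_TEMPLATE_DIVERGENCE = 0.62
_ORTHOLOG_IDENTITY = 0.85  # expansion homologs within a template's subcluster
_NEAR_DECOY_RANGE = (0.10, 0.20)
_MARKER_LENGTH = 600
_MARKER_RATE = 0.12  # marker substitutions per unit tree depth (conserved)


@dataclass(frozen=True)
class PanelProtein:
    """One labeled reference protein (core group member or accessory gene)."""

    id: str
    template: str
    group: Optional[str]  # None for accessory genes
    sequence: str
    mandatory: bool = False
    side_chain: bool = False


@dataclass
class ReferencePanel:
    """Reference pathway proteins with group labels, per pathway template."""

    groups: List[str]
    mandatory: Set[str]
    templates: List[str]
    proteins: List[PanelProtein]  # core + accessory, all templates
    orthologs: List[PanelProtein]  # expansion homologs for HMM training

    def core(self, template: Optional[str] = None) -> List[PanelProtein]:
        return [
            p
            for p in self.proteins
            if p.group is not None and (template is None or p.template == template)
        ]

    def accessory(self, template: str) -> List[PanelProtein]:
        return [p for p in self.proteins if p.group is None and p.template == template]

    def template_panel(self, template: str) -> List[PanelProtein]:
        """All query proteins of one pathway template (core + accessory)."""
        return [p for p in self.proteins if p.template == template]

    def side_chain_ids(self, template: str) -> List[str]:
        return [p.id for p in self.accessory(template) if p.side_chain]

    def by_id(self) -> Dict[str, PanelProtein]:
        return {p.id: p for p in self.proteins + self.orthologs}


def generate_reference_panel(
    n_groups: int = 8,
    length_range: Tuple[int, int] = (180, 320),
    seed: int = 0,
    templates: Sequence[str] = tuple(DEFAULT_TEMPLATES),
    n_accessory: int = 5,
    n_orthologs_per_protein: int = 2,
) -> ReferencePanel:
    """Labeled reference protein families: one core sequence per group per
    pathway template, template-specific accessory genes, and expansion
    homologs used downstream for profile training.

    The first eight groups carry the canonical enzyme-group names; exactly two
    (the KshA-like and HsaC-like groups) are flagged mandatory.
    """
    if n_groups < 1:
        raise InputError("n_groups must be at least 1")
    lo, hi = length_range
    if lo < 30 or hi < lo:
        raise InputError("length_range must be non-degenerate with lengths >= 30")
    rng = np.random.default_rng(seed)
    groups = [
        CORE_GROUPS[i] if i < len(CORE_GROUPS) else f"grp{i + 1}" for i in range(n_groups)
    ]
    mandatory = {g for g in groups if g in MANDATORY_GROUPS}
    if not mandatory:  # small panels still get up to two mandatory groups
        mandatory = set(groups[: min(2, len(groups))])
    model = EvolutionModel(seed=int(rng.integers(2**31)))
    proteins: List[PanelProtein] = []
    orthologs: List[PanelProtein] = []
    t_div = model.time_for_identity(_TEMPLATE_DIVERGENCE)
    t_orth = model.time_for_identity(_ORTHOLOG_IDENTITY)
    for group in groups:
        length = int(rng.integers(lo, hi + 1))
        ancestor = encode(random_protein(length, rng))
        for template in templates:
            seq = _evolve_once(ancestor, t_div, model, rng)
            pid = f"{template}|{group}"
            proteins.append(
                PanelProtein(
                    id=pid,
                    template=template,
                    group=group,
                    sequence=decode(seq),
                    mandatory=group in mandatory,
                )
            )
            for k in range(n_orthologs_per_protein):
                oseq = _evolve_once(seq, t_orth, model, rng)
                orthologs.append(
                    PanelProtein(
                        id=f"{pid}|orth{k + 1}",
                        template=template,
                        group=group,
                        sequence=decode(oseq),
                    )
                )
    for template in templates:
        for k in range(n_accessory):
            length = int(rng.integers(lo, hi + 1))
            proteins.append(
                PanelProtein(
                    id=f"{template}|acc{k + 1}",
                    template=template,
                    group=None,
                    sequence=random_protein(length, rng),
                    side_chain=k < 3,
                )
            )
    return ReferencePanel(
        groups=groups,
        mandatory=mandatory,
        templates=list(templates),
        proteins=proteins,
        orthologs=orthologs,
    )


# ---------------------------------------------------------------------------
# genomes and truth table


@dataclass(frozen=True)
class Gene:
    id: str
    replicon_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    sequence: str
    gene_index: int


@dataclass(frozen=True)
class Replicon:
    id: str
    replicon_type: str  # chromosome | plasmid
    length: int
    circular: bool


@dataclass
class GenomeRecord:
    id: str
    replicons: List[Replicon]
    genes: List[Gene]
    marker: str  # 16S-like marker gene sequence

    def proteome(self) -> Dict[str, str]:
        return {g.id: g.sequence for g in self.genes}


@dataclass
class TruthRow:
    genome_id: str
    is_degrader: bool
    pathways: Set[str]
    # (gene_id, group_label, replicon_id, start, end, strand)
    planted_loci: List[Tuple[str, str, str, int, int, str]]
    cluster_memberships: Dict[str, List[str]]  # cluster id -> planted gene ids
    plasmid_only: bool = False
    hgt_donor: Optional[str] = None


@dataclass
class TruthTable:
    rows: Dict[str, TruthRow]

    def degraders(self) -> List[str]:
        return sorted(g for g, r in self.rows.items() if r.is_degrader)

    def validate_against(self, genomes: Dict[str, GenomeRecord]) -> None:
        """Every planted locus appears exactly once in the annotation and lies
        within its replicon."""
        for gid, row in self.rows.items():
            genome = genomes[gid]
            by_id = {g.id: g for g in genome.genes}
            rep_len = {r.id: r.length for r in genome.replicons}
            assert row.is_degrader == bool(row.pathways)
            for gene_id, _group, rep, start, end, strand in row.planted_loci:
                gene = by_id[gene_id]
                assert (gene.replicon_id, gene.start, gene.end, gene.strand) == (
                    rep,
                    start,
                    end,
                    strand,
                )
                assert 0 <= start < end <= rep_len[rep]


@dataclass
class CommunityConfig:
    """Study conditions for one synthetic community."""

    n_genomes: int = 20
    degrader_fraction: float = 0.5
    pathway_templates: Sequence[str] = tuple(DEFAULT_TEMPLATES)
    target_identity_range: Tuple[float, float] = (0.5, 0.7)
    n_decoys_per_genome: int = 500
    n_near_decoys_per_genome: int = 5
    plasmid_probability: float = 0.25
    hgt_events: Sequence[Tuple[str, str, str]] = ()  # (donor, recipient, pathway)
    species_tree: Optional[TreeNode] = None
    n_clusters_per_degrader: int = 1
    decoy_length_range: Tuple[int, int] = (100, 260)
    intergenic_mean: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degrader_fraction <= 1.0:
            raise ConfigurationError("degrader_fraction must be in [0, 1]")
        lo, hi = self.target_identity_range
        if not (0.05 < lo <= hi <= 1.0):
            raise ConfigurationError("target identities must be in (0.05, 1.0]")
        if self.n_clusters_per_degrader not in (1, 2):
            raise ConfigurationError("n_clusters_per_degrader must be 1 or 2")
        if self.n_genomes < 1:
            raise ConfigurationError("n_genomes must be positive")

    def to_json(self) -> str:
        d = {
            k: (list(v) if isinstance(v, (tuple, set)) else v)
            for k, v in self.__dict__.items()
            if k != "species_tree"
        }
        d["hgt_events"] = [list(e) for e in self.hgt_events]
        return json.dumps(d, indent=2, sort_keys=True)


def random_ultrametric_tree(leaf_names: Sequence[str], rng: np.random.Generator) -> TreeNode:
    """Random binary ultrametric tree of depth 1.0 over the given leaves."""
    if len(leaf_names) < 2:
        raise InputError("need at least two leaves")

    def build(names: List[str], height: float) -> str:
        # newick of a clade whose root sits at `height` above the leaves
        if len(names) == 1:
            return names[0]
        child_height = height * rng.uniform(0.4, 0.85)
        k = int(rng.integers(1, len(names)))
        parts = []
        for sub in (names[:k], names[k:]):
            top = 0.0 if len(sub) == 1 else child_height
            parts.append(f"{build(sub, child_height)}:{height - top:.10f}")
        return "(" + ",".join(parts) + ")"

    names = list(leaf_names)
    rng.shuffle(names)
    return TreeNode.read([build(names, 1.0) + ";"])


def balanced_species_tree(
    leaf_names: Sequence[str], depth: float = 1.0, split: float = 0.6
) -> TreeNode:
    """Deterministic balanced ultrametric tree: every split puts its children
    at ``split`` times the parent height, so internal edges never collapse.
    Useful when downstream analyses need a well-resolved reference topology."""
    if len(leaf_names) < 2:
        raise InputError("need at least two leaves")

    def build(names: List[str], height: float) -> str:
        if len(names) == 1:
            return names[0]
        child_height = height * split
        mid = len(names) // 2
        parts = []
        for sub in (names[:mid], names[mid:]):
            top = 0.0 if len(sub) == 1 else child_height
            parts.append(f"{build(sub, child_height)}:{height - top:.10f}")
        return "(" + ",".join(parts) + ")"

    return TreeNode.read([build(list(leaf_names), depth) + ";"])


def _geometric_gap(rng: np.random.Generator, mean: int) -> int:
    return int(rng.geometric(1.0 / max(mean, 1)))


def _layout_replicon(
    genome_id: str,
    replicon: str,
    sequences: List[Tuple[str, str]],  # (gene_id, protein seq) in final order
    rng: np.random.Generator,
    intergenic_mean: int,
) -> Tuple[List[Gene], int]:
    genes = []
    pos = _geometric_gap(rng, intergenic_mean)
    for index, (gene_id, seq) in enumerate(sequences):
        span = 3 * len(seq) + 3
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                id=gene_id,
                replicon_id=replicon,
                start=pos,
                end=pos + span,
                strand=strand,
                sequence=seq,
                gene_index=index,
            )
        )
        pos += span + _geometric_gap(rng, intergenic_mean)
    return genes, pos


def generate_community(
    config: CommunityConfig, panel: Optional[ReferencePanel] = None
) -> Tuple[Dict[str, GenomeRecord], TruthTable, ReferencePanel, TreeNode]:
    """Generate a seeded community: genomes, truth table, panel, species tree.

    Pathway genes of each degrader descend from the pathway template's panel
    sequences evolved along the species tree (so that, absent HGT, per-pathway
    gene trees match the species tree restricted to degrader leaves); the
    tree's depth is rescaled per pathway so that leaf identities to the panel
    references fall in ``target_identity_range``.  HGT recipients instead
    receive pathway genes derived from the donor's leaf sequences; marker
    genes always follow the species tree.
    """
    # independent named streams: the marker and vertical-descent streams are
    # untouched by HGT configuration, so hgt_events can never perturb them
    ss = np.random.SeedSequence(config.seed)
    s_panel, s_tree, s_degr, s_evo, s_marker, s_hgt, s_genomes = ss.spawn(7)
    if panel is None:
        panel = generate_reference_panel(
            seed=int(np.random.default_rng(s_panel).integers(2**31))
        )
    genome_ids = [f"G{i + 1:02d}" for i in range(config.n_genomes)]
    tree = config.species_tree
    if tree is None:
        if config.n_genomes >= 2:
            tree = random_ultrametric_tree(genome_ids, np.random.default_rng(s_tree))
        else:
            raise ConfigurationError("a species tree requires at least 2 genomes")
    leaves = {t.name for t in tree.tips()}
    if set(genome_ids) - leaves:
        raise ConfigurationError("species tree must contain every genome as a leaf")

    for donor, recipient, pathway in config.hgt_events:
        if donor not in leaves or recipient not in leaves:
            raise ConfigurationError("HGT donor and recipient must be tree leaves")
        if pathway not in config.pathway_templates:
            raise ConfigurationError(f"unknown HGT pathway {pathway!r}")

    # --- designate degraders and their pathways -------------------------
    n_degraders = round(config.n_genomes * config.degrader_fraction)
    forced = []
    for donor, recipient, _ in config.hgt_events:
        for g in (donor, recipient):
            if g not in forced:
                forced.append(g)
    if len(forced) > n_degraders:
        raise ConfigurationError("more HGT participants than degrader quota")
    pool = [g for g in genome_ids if g not in forced]
    rng_degr = np.random.default_rng(s_degr)
    extra = list(rng_degr.choice(pool, size=n_degraders - len(forced), replace=False))
    degraders = sorted(forced + [str(g) for g in extra])

    templates = list(config.pathway_templates)
    pathway_of: Dict[str, str] = {}
    for i, g in enumerate(degraders):
        pathway_of[g] = templates[i % len(templates)]
    hgt_recipient_of: Dict[str, Tuple[str, str]] = {}
    for donor, recipient, pathway in config.hgt_events:
        if pathway_of.get(donor) != pathway:
            raise ConfigurationError(
                f"HGT pathway {pathway!r} is not planted in donor {donor}"
            )
        pathway_of[recipient] = pathway
        hgt_recipient_of[recipient] = (donor, pathway)

    # --- evolve pathway genes and markers along the tree ----------------
    rng_evo = np.random.default_rng(s_evo)
    model = EvolutionModel(seed=int(rng_evo.integers(2**31)))
    lo, hi = config.target_identity_range
    target_mid = (lo + hi) / 2.0
    depth = max(
        sum(n.length or 0.0 for n in t.ancestors() if n.length) + (t.length or 0.0)
        for t in tree.tips()
    )
    t_mid = model.time_for_identity(target_mid)
    gap_frac = min(0.5, model.indel_rate * t_mid * model.indel_length_mean)
    rate = model.time_for_identity(min(1.0, target_mid * (1.0 + gap_frac))) / depth

    pathway_leaf_seqs: Dict[str, Dict[str, Dict[str, str]]] = {}
    for template in templates:
        roots = {p.id: p.sequence for p in panel.template_panel(template)}
        tree_model = EvolutionModel(seed=int(rng_evo.integers(2**31)))
        pathway_leaf_seqs[template] = evolve_along_tree(roots, tree, tree_model, rate_scale=rate)

    rng_marker = np.random.default_rng(s_marker)
    marker_root = random_protein(_MARKER_LENGTH, rng_marker)
    marker_model = EvolutionModel(seed=int(rng_marker.integers(2**31)), indel_rate=0.005)
    marker_leaf = evolve_along_tree({"marker": marker_root}, tree, marker_model, rate_scale=_MARKER_RATE / depth)

    # HGT: recipient pathway genes re-derived from the donor's leaf sequences
    rng_hgt = np.random.default_rng(s_hgt)
    t_hgt = model.time_for_identity(0.97)
    for recipient, (donor, pathway) in hgt_recipient_of.items():
        donor_seqs = pathway_leaf_seqs[pathway][donor]
        hgt_model = EvolutionModel(seed=int(rng_hgt.integers(2**31)))
        pathway_leaf_seqs[pathway][recipient] = {
            pid: decode(_evolve_once(encode(seq), t_hgt, hgt_model, hgt_model.rng()))
            for pid, seq in donor_seqs.items()
        }

    # --- assemble genomes ----------------------------------------------
    genomes: Dict[str, GenomeRecord] = {}
    rows: Dict[str, TruthRow] = {}
    dlo, dhi = config.decoy_length_range
    panel_proteins = panel.proteins
    near_lo, near_hi = _NEAR_DECOY_RANGE
    genome_streams = s_genomes.spawn(len(genome_ids))
    for gid, g_seed in zip(genome_ids, genome_streams):
        g_rng = np.random.default_rng(g_seed)
        is_degrader = gid in pathway_of
        decoys: List[str] = []
        for _ in range(config.n_decoys_per_genome):
            decoys.append(random_protein(int(g_rng.integers(dlo, dhi + 1)), g_rng))
        for _ in range(config.n_near_decoys_per_genome):
            src = panel_proteins[int(g_rng.integers(len(panel_proteins)))]
            target = g_rng.uniform(near_lo, near_hi)
            t_near = model.time_for_identity(target)
            nd_model = EvolutionModel(seed=int(g_rng.integers(2**31)))
            decoys.append(decode(_evolve_once(encode(src.sequence), t_near, nd_model, nd_model.rng())))
        g_rng.shuffle(decoys)

        planted: List[Tuple[str, str]] = []  # (panel protein id, sequence)
        if is_degrader:
            template = pathway_of[gid]
            leaf_seqs = pathway_leaf_seqs[template][gid]
            order = [p.id for p in panel.template_panel(template)]
            planted = [(pid, leaf_seqs[pid]) for pid in order]

        # decide placement
        on_plasmid = is_degrader and g_rng.random() < config.plasmid_probability
        has_plasmid = on_plasmid or g_rng.random() < 0.3

        next_gene = [0]

        def gene_id() -> str:
            next_gene[0] += 1
            return f"{gid}_g{next_gene[0]:04d}"

        chrom_seqs: List[Tuple[str, str, Optional[str]]] = [
            (gene_id(), s, None) for s in decoys
        ]
        plasmid_seqs: List[Tuple[str, str, Optional[str]]] = []
        if has_plasmid:
            n_pl = int(g_rng.integers(15, 40))
            take = [chrom_seqs.pop() for _ in range(min(n_pl, len(chrom_seqs) - 5))]
            plasmid_seqs = take[::-1]

        cluster_members: Dict[str, List[str]] = {}
        planted_named: List[Tuple[str, str, str]] = []  # (gene_id, panel id, seq)
        if planted:
            runs: List[List[Tuple[str, str]]] = [planted]
            if config.n_clusters_per_degrader == 2 and len(planted) >= 4:
                split = len(planted) // 2
                runs = [planted[:split], planted[split:]]
            target_list = plasmid_seqs if on_plasmid else chrom_seqs
            for ci, run in enumerate(runs):
                named = [(gene_id(), seq, pid) for pid, seq in run]
                pos = int(g_rng.integers(0, len(target_list) + 1))
                target_list[pos:pos] = named
                cluster_members[f"{gid}_c{ci + 1}"] = [n[0] for n in named]
                planted_named.extend((n[0], n[2], n[1]) for n in named)

        chrom_genes, chrom_len = _layout_replicon(
            gid, f"{gid}_chr", [(g, s) for g, s, _ in chrom_seqs], g_rng, config.intergenic_mean
        )
        replicons = [
            Replicon(f"{gid}_chr", "chromosome", chrom_len + 200, True)
        ]
        genes = list(chrom_genes)
        if plasmid_seqs:
            pl_genes, pl_len = _layout_replicon(
                gid, f"{gid}_p1", [(g, s) for g, s, _ in plasmid_seqs], g_rng, config.intergenic_mean
            )
            replicons.append(Replicon(f"{gid}_p1", "plasmid", pl_len + 200, True))
            genes.extend(pl_genes)

        genomes[gid] = GenomeRecord(
            id=gid, replicons=replicons, genes=genes, marker=marker_leaf[gid]["marker"]
        )
        by_id = {g.id: g for g in genes}
        panel_by_id = panel.by_id()
        loci = []
        for gene_name, pid, _seq in planted_named:
            g = by_id[gene_name]
            src = panel_by_id[pid]
            label = src.group if src.group is not None else pid.split("|", 1)[1]
            loci.append((gene_name, label, g.replicon_id, g.start, g.end, g.strand))
        rows[gid] = TruthRow(
            genome_id=gid,
            is_degrader=is_degrader,
            pathways={pathway_of[gid]} if is_degrader else set(),
            planted_loci=loci,
            cluster_memberships=cluster_members,
            plasmid_only=bool(planted) and on_plasmid,
            hgt_donor=hgt_recipient_of.get(gid, (None,))[0],
        )

    truth = TruthTable(rows=rows)
    truth.validate_against(genomes)
    return genomes, truth, panel, tree
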