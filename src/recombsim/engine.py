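"""The forward-in-time driver.

The simulation walks the time segments of the (rescaled) tree in depth
order.  Within a segment every living branch draws a Poisson budget of
mutations, with mean ``l * L`` (branch lengths are expected substitutions
per site, so the whole-sequence expectation is length-proportional), and
of recombination attempts, with mean ``rho * l * L`` — i.e. attempts per
expected mutation equal the relative recombination rate rho.  The budgets
are then spent in random interleaved order across the co-existing
lineages, so all branches of a segment evolve simultaneously and can act
as donors in each other's recombination events.  At internal nodes the
parent genome is copied verbatim to each child; leaves are frozen at
their own depth.

Reproducibility: one seeded numpy Generator is consumed in a fixed order
(root sequence, then per segment: flux draws, budget draws, event loop),
so identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import stats as stats_mod
from .gene_flux import Genome, draw_flux_events, gain_gene, lose_gene
from .recombination import (BiasModel, RecombinationEvent, apply_recombination,
                            draw_tract, pick_donor)
from .seqmodel import (CodonRateProfile, MutationEvent, SubstitutionModel,
                       apply_mutation, build_model, draw_site,
                       random_sequence, str_to_seq)
from .tree import TimeSegment, TreeNode, parse_newick, rescale, time_segments

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "FluxRecord",
    "draw_budget",
    "run_segment",
    "simulate",
]

_DEPTH_TOL = 1e-9


@dataclass
class SimulationConfig:
    """All user-settable parameters of one run.

    ``rho`` is the recombination rate relative to the substitution rate;
    ``delta`` the mean recombination tract length in bp; ``scale`` the
    branch-length rescaling coefficient; flux rates are gene gains/losses
    per unit branch length.  Either ``tree_newick`` or ``tree_path`` must
    be given; the root genome is random (length/gc) unless a FASTA is
    supplied.
    """

    rho: float
    tree_newick: str | None = None
    tree_path: str | None = None
    length: int = 99_999
    gc: float = 0.5
    model: str = "JC69"
    model_params: dict = field(default_factory=dict)
    gtr_freqs: tuple[float, float, float, float] | None = None
    codon_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    delta: float = 100.0
    bias_enabled: bool = False
    phi: float = 18.1
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    scale: float = 1.0
    seed: int = 0
    gene_length: int = 999
    root_fasta_path: str | None = None
    output_dir: str | None = None

    def validate(self) -> None:
        if self.tree_newick is None and self.tree_path is None:
            raise ValueError("a tree (newick text or path) is required")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if self.delta < 1:
            raise ValueError("delta must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("flux rates must be non-negative")
        if self.root_fasta_path is None:
            if self.length < 3 or self.length % 3 != 0:
                raise ValueError("length must be a multiple of 3 and >= 3")
            if not 0.0 <= self.gc <= 1.0:
                raise ValueError("gc must be in [0, 1]")
        if self.gene_length < 3 or self.gene_length % 3 != 0:
            raise ValueError("gene_length must be a positive multiple of 3")


@dataclass
class FluxRecord:
    segment: int
    lineage: str
    kind: str  # "gain" | "loss" | "loss_skipped"
    gene_id: str | None


@dataclass
class SimulationResult:
    leaf_genomes: dict[str, Genome]
    mutations: list[tuple[int, str, MutationEvent]]
    recombinations: list[tuple[int, RecombinationEvent]]
    flux: list[FluxRecord]
    # one (segment, lineage, M_t, R_t) row per branch segment, so event
    # conservation can be checked against the realized logs
    budgets: list[tuple[int, str, int, int]]
    stats: "stats_mod.SimulationStats"
    tree: TreeNode
    segments: list[TimeSegment]
    root_gene_ids: list[str]
    config: SimulationConfig


def draw_budget(
    branch_overlap: float, L_current: int, rho: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Poisson mutation and recombination-attempt counts for one branch
    segment: means ``l * L`` and ``rho * l * L``."""
    if branch_overlap < 0:
        raise ValueError("branch overlap must be non-negative")
    mean = branch_overlap * L_current
    return int(rng.poisson(mean)), int(rng.poisson(rho * mean))


def _load_root_sequence(config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    if config.root_fasta_path is not None:
        from Bio import SeqIO

        records = list(SeqIO.parse(config.root_fasta_path, "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"root FASTA must hold exactly one record, found {len(records)}"
            )
        seq = str_to_seq(str(records[0].seq))
        if len(seq) % 3 != 0:
            raise ValueError("root genome length must be a multiple of 3")
        if len(seq) < 3:
            raise ValueError("root genome too short")
        return seq
    return random_sequence(config.length, config.gc, rng)


def run_segment(
    segment: TimeSegment,
    seg_idx: int,
    lineages: dict[TreeNode, Genome],
    config: SimulationConfig,
    model: SubstitutionModel,
    profile: CodonRateProfile,
    bias: BiasModel,
    rng: np.random.Generator,
    mutations: list,
    recombinations: list,
    flux: list,
    budget_log: list,
    gene_id_counter: "itertools.count",
) -> None:
    """Spend one segment's event budgets on its co-existing lineages.

    Gene gains/losses (whole genes) are applied per branch at segment
    start; mutation and recombination budgets are then interleaved: repeat
    picking a uniformly random lineage with remaining events, then one of
    its remaining events with probability proportional to the remaining
    mutation vs recombination counts.
    """
    members = segment.members
    member_nodes = [node for node, _ in members]

    if config.gain_rate > 0 or config.loss_rate > 0:
        for node, l in members:
            n_gain, n_loss = draw_flux_events(
                config.gain_rate, config.loss_rate, l, rng)
            kinds = ["gain"] * n_gain + ["loss"] * n_loss
            rng.shuffle(kinds)
            genome = lineages[node]
            for kind in kinds:
                if kind == "gain":
                    gid = f"hgt{next(gene_id_counter):06d}"
                    gain_gene(genome, gid, config.gc, config.gene_length, rng)
                    flux.append(FluxRecord(seg_idx, node.label, "gain", gid))
                else:
                    gid = lose_gene(genome, rng)
                    kind_out = "loss" if gid is not None else "loss_skipped"
                    flux.append(FluxRecord(seg_idx, node.label, kind_out, gid))

    # [node, remaining mutations, remaining recombination attempts]
    budgets: list[list[Any]] = []
    for node, l in members:
        m, r = draw_budget(l, lineages[node].length, config.rho, rng)
        budget_log.append((seg_idx, node.label, m, r))
        if m + r > 0:
            budgets.append([node, m, r])

    while budgets:
        i = int(rng.integers(len(budgets))) if len(budgets) > 1 else 0
        entry = budgets[i]
        node = entry[0]
        genome = lineages[node]
        if rng.random() * (entry[1] + entry[2]) < entry[1]:
            site = draw_site(profile, genome.length, rng)
            ev = apply_mutation(genome.seq, site, model, rng)
            mutations.append((seg_idx, node.label, ev))
            entry[1] -= 1
        else:
            donor_node = pick_donor(member_nodes, node, rng)
            if donor_node is None:
                recombinations.append((seg_idx, RecombinationEvent(
                    recipient=node.label, donor=None, start=0, length=0,
                    raw_length=0, status="no_donor")))
            else:
                tract = draw_tract(genome.length, config.delta, rng)
                ev = apply_recombination(
                    genome, lineages[donor_node], tract, bias, rng)
                recombinations.append((seg_idx, ev))
            entry[2] -= 1
        if entry[1] + entry[2] == 0:
            budgets[i] = budgets[-1]
            budgets.pop()


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run one full simulation; everything downstream of the seed is
    deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    newick = config.tree_newick
    if newick is None:
        with open(config.tree_path) as fh:
            newick = fh.read()
    tree = parse_newick(newick)
    if config.scale != 1.0:
        tree = rescale(tree, config.scale)
    segments = time_segments(tree)

    model = build_model(config.model, config.model_params,
                        gc=config.gc, freqs=config.gtr_freqs)
    profile = CodonRateProfile(config.codon_weights)
    bias = BiasModel(enabled=config.bias_enabled, phi=config.phi)

    root_seq = _load_root_sequence(config, rng)
    root_genome = Genome.from_root_sequence("root", root_seq,
                                            config.gene_length)
    root_gene_ids = root_genome.gene_ids

    leaf_genomes: dict[str, Genome] = {}
    lineages: dict[TreeNode, Genome] = {}

    def branch_to(node: TreeNode, genome: Genome) -> None:
        """Hand a genome to the lineages below ``node`` (copy per child);
        zero-length edges are crossed immediately."""
        if node.is_leaf():
            leaf_genomes[node.name] = genome
            return
        for child in node.children:
            child_genome = genome.copy(child.label)
            if child.branch_length is not None and child.branch_length <= 1e-12:
                branch_to(child, child_genome)
            else:
                lineages[child] = child_genome

    branch_to(tree, root_genome)

    mutations: list = []
    recombinations: list = []
    flux: list = []
    budget_log: list = []
    counter = itertools.count()

    for seg_idx, segment in enumerate(segments):
        run_segment(segment, seg_idx, lineages, config, model, profile,
                    bias, rng, mutations, recombinations, flux, budget_log,
                    counter)
        for node, _l in segment.members:
            if abs(node.depth - segment.end_depth) <= _DEPTH_TOL * max(
                    1.0, segment.end_depth):
                genome = lineages.pop(node)
                branch_to(node, genome)

    if lineages:  # every branch must terminate at some segment boundary
        raise AssertionError("unterminated lineages after final segment")

    sim_stats = stats_mod.finalize_stats(mutations, recombinations, config)
    return SimulationResult(
        leaf_genomes=leaf_genomes, mutations=mutations,
        recombinations=recombinations, flux=flux, budgets=budget_log,
        stats=sim_stats,
        tree=tree, segments=segments, root_gene_ids=root_gene_ids,
        config=config,
    )
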