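"""Gene gain and loss, core/accessory bookkeeping, and the homologous
coordinate mapping between genomes.

A :class:`Genome` is an ordered list of gene instances.  Genes are the unit
of gain and loss (whole genes only — no partial indels ever), and the
``gene_id`` identifies homology across lineages: two instances of the same
id in different genomes always have the same length.  Gains are modelled as
external horizontal transfers (a brand-new random sequence with a fresh id,
inherited by all descendants of the branch it lands on); losses remove a
uniformly chosen gene from the lineage.

Core genes are those present in every leaf genome of the finished dataset;
accessory genes are present in only a subset.  Classification is a property
of the final dataset, not a protection during simulation — a gene that is
core-so-far can still be lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqmodel import random_sequence

__all__ = [
    "GeneInstance",
    "Genome",
    "HomologyMap",
    "draw_flux_events",
    "gain_gene",
    "lose_gene",
    "homologous_interval",
    "core_gene_ids",
    "core_alignment",
]


@dataclass
class GeneInstance:
    """One gene copy: homology id plus its nucleotide sequence (codes)."""

    gene_id: str
    sequence: np.ndarray  # uint8 codes, length divisible by 3


class Genome:
    """Ordered gene repertoire of one lineage, stored as a concatenate.

    Internally the sequence is a single uint8 array plus gene boundary
    bookkeeping, so point mutations and tract copies are O(1)/vectorized;
    gene gain and loss rebuild the concatenate.
    """

    __slots__ = ("lineage", "_ids", "_lengths", "_seq", "_offsets", "_index")

    def __init__(self, lineage: str, gene_ids: list[str],
                 gene_lengths: np.ndarray, seq: np.ndarray) -> None:
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique within a genome")
        self.lineage = lineage
        self._ids = list(gene_ids)
        self._lengths = np.asarray(gene_lengths, dtype=np.int64)
        self._seq = np.asarray(seq, dtype=np.uint8)
        self._rebuild()

    def _rebuild(self) -> None:
        self._offsets = np.concatenate(([0], np.cumsum(self._lengths)))
        self._index = {g: i for i, g in enumerate(self._ids)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_root_sequence(cls, lineage: str, seq: np.ndarray,
                           gene_length: int) -> "Genome":
        """Partition a root concatenate into genes of fixed length.

        ``gene_length`` must be a multiple of 3; the last gene absorbs any
        remainder (itself a multiple of 3 when ``len(seq)`` is).
        """
        if gene_length < 3 or gene_length % 3 != 0:
            raise ValueError("gene_length must be a positive multiple of 3")
        L = len(seq)
        if L % 3 != 0:
            raise ValueError("root sequence length must be a multiple of 3")
        n_full = max(1, L // gene_length)
        lengths = [gene_length] * n_full
        lengths[-1] += L - gene_length * n_full
        ids = [f"g{i:05d}" for i in range(n_full)]
        return cls(lineage, ids, np.array(lengths), seq.copy())

    def copy(self, lineage: str | None = None) -> "Genome":
        return Genome(lineage or self.lineage, list(self._ids),
                      self._lengths.copy(), self._seq.copy())

    # -- views -------------------------------------------------------------

    @property
    def length(self) -> int:
        return int(self._seq.size)

    @property
    def seq(self) -> np.ndarray:
        return self._seq

    @property
    def gene_ids(self) -> list[str]:
        return list(self._ids)

    @property
    def genes(self) -> list[GeneInstance]:
        return [
            GeneInstance(g, self._seq[self._offsets[i]:self._offsets[i + 1]])
            for i, g in enumerate(self._ids)
        ]

    def n_genes(self) -> int:
        return len(self._ids)

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._index

    def gene_offset(self, gene_id: str) -> int:
        return int(self._offsets[self._index[gene_id]])

    def gene_length(self, gene_id: str) -> int:
        return int(self._lengths[self._index[gene_id]])

    def gene_sequence(self, gene_id: str) -> np.ndarray:
        i = self._index[gene_id]
        return self._seq[self._offsets[i]:self._offsets[i + 1]]

    def gene_index_at(self, pos: int) -> int:
        """Index of the gene containing concatenate position ``pos``."""
        if not 0 <= pos < self.length:
            raise IndexError(pos)
        return int(np.searchsorted(self._offsets, pos, side="right") - 1)

    # -- structural edits --------------------------------------------------

    def insert_gene(self, rank: int, gene_id: str, sequence: np.ndarray) -> None:
        if gene_id in self._index:
            raise ValueError(f"gene {gene_id!r} already present")
        rank = int(np.clip(rank, 0, len(self._ids)))
        pos = int(self._offsets[rank]) if rank < len(self._ids) else self.length
        self._ids.insert(rank, gene_id)
        self._lengths = np.insert(self._lengths, rank, len(sequence))
        self._seq = np.concatenate(
            [self._seq[:pos], np.asarray(sequence, dtype=np.uint8), self._seq[pos:]]
        )
        self._rebuild()

    def delete_gene(self, gene_id: str) -> None:
        i = self._index[gene_id]
        a, b = int(self._offsets[i]), int(self._offsets[i + 1])
        del self._ids[i]
        self._lengths = np.delete(self._lengths, i)
        self._seq = np.concatenate([self._seq[:a], self._seq[b:]])
        self._rebuild()


def draw_flux_events(
    gain_rate: float, loss_rate: float, branch_overlap: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Poisson counts of gene gains and losses on a branch segment.

    Rates are per unit branch length (expected substitutions per site), so
    counts are Poisson with means ``gain_rate * l`` and ``loss_rate * l``.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("flux rates must be non-negative")
    return (
        int(rng.poisson(gain_rate * branch_overlap)),
        int(rng.poisson(loss_rate * branch_overlap)),
    )


def gain_gene(genome: Genome, gene_id: str, gc: float, gene_length: int,
              rng: np.random.Generator) -> None:
    """Gain a brand-new gene (external horizontal transfer).

    A fresh random sequence of the configured GC content is inserted at a
    uniformly random rank in the gene order; descendants inherit it.
    """
    seq = random_sequence(gene_length, gc, rng)
    rank = int(rng.integers(genome.n_genes() + 1))
    genome.insert_gene(rank, gene_id, seq)


def lose_gene(genome: Genome, rng: np.random.Generator) -> str | None:
    """Delete a uniformly chosen gene; returns its id, or None if the genome
    is already empty (the event is skipped)."""
    if genome.n_genes() == 0:
        return None
    gid = genome.gene_ids[int(rng.integers(genome.n_genes()))]
    genome.delete_gene(gid)
    return gid


@dataclass
class HomologyMap:
    """Resolution of a recipient tract against a donor's gene repertoire.

    ``chunks`` are maximal runs (rec_start, don_start, length) over genes
    shared by both genomes; tract positions inside genes absent from the
    donor map nowhere.  When both tract breakpoints fall inside shared
    genes, whole accessory genes strictly between the breakpoint genes
    become candidates for insertion (donor-only) or deletion
    (recipient-only).
    """

    chunks: list[tuple[int, int, int]]
    homologous_bp: int
    breakpoints_shared: bool
    # (gene_id, anchor gene_id in recipient after which to insert)
    insertions: list[tuple[str, str]] = field(default_factory=list)
    deletions: list[str] = field(default_factory=list)


def homologous_interval(recipient: Genome, donor: Genome,
                        start: int, length: int) -> HomologyMap:
    """Map a recipient tract onto donor coordinates gene by gene."""
    if length < 1 or start < 0 or start + length > recipient.length:
        raise ValueError("tract out of bounds on recipient")
    end = start + length  # half-open
    i0 = recipient.gene_index_at(start)
    i1 = recipient.gene_index_at(end - 1)
    rec_ids = recipient.gene_ids
    rec_offsets = recipient._offsets

    chunks: list[tuple[int, int, int]] = []
    bp = 0
    for i in range(i0, i1 + 1):
        gid = rec_ids[i]
        if not donor.has_gene(gid):
            continue
        a = max(start, int(rec_offsets[i]))
        b = min(end, int(rec_offsets[i + 1]))
        don_start = donor.gene_offset(gid) + (a - int(rec_offsets[i]))
        chunks.append((a, don_start, b - a))
        bp += b - a

    shared = donor.has_gene(rec_ids[i0]) and donor.has_gene(rec_ids[i1])
    hmap = HomologyMap(chunks=chunks, homologous_bp=bp, breakpoints_shared=shared)
    if not shared or i0 == i1:
        return hmap

    # recipient-only genes strictly between the breakpoint genes are fully
    # covered by the tract -> whole-gene deletion candidates
    hmap.deletions = [
        rec_ids[i] for i in range(i0 + 1, i1)
        if not donor.has_gene(rec_ids[i])
    ]

    # donor-only genes strictly between the donor's copies of the breakpoint
    # genes -> whole-gene insertion candidates, anchored after the nearest
    # preceding donor gene also present in the recipient
    don_ids = donor.gene_ids
    r0 = don_ids.index(rec_ids[i0])
    r1 = don_ids.index(rec_ids[i1])
    if r0 < r1:
        for j in range(r0 + 1, r1):
            gid = don_ids[j]
            if recipient.has_gene(gid):
                continue
            anchor = None
            for k in range(j - 1, r0 - 1, -1):
                if recipient.has_gene(don_ids[k]):
                    anchor = don_ids[k]
                    break
            if anchor is not None:
                hmap.insertions.append((gid, anchor))
    return hmap


def core_gene_ids(leaf_genomes: dict[str, Genome]) -> list[str]:
    """Gene ids present in every leaf genome, in the canonical alignment
    order: root genes by id then gained genes by id (ids sort that way)."""
    it = iter(leaf_genomes.values())
    common = set(next(it).gene_ids)
    for g in it:
        common &= set(g.gene_ids)
    return sorted(common)


def core_alignment(leaf_genomes: dict[str, Genome]) -> dict[str, np.ndarray]:
    """Concatenated core-gene alignment, one equal-length row per leaf."""
    core = core_gene_ids(leaf_genomes)
    return {
        name: (np.concatenate([g.gene_sequence(gid) for gid in core])
               if core else np.empty(0, dtype=np.uint8))
        for name, g in leaf_genomes.items()
    }
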