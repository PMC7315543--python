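"""Homologous recombination (gene conversion) between co-existing lineages.

An event replaces a tract of the recipient genome, non-reciprocally, with
the homologous tract of a donor drawn from the same time segment.  Tract
start is uniform along the recipient; tract length is geometric with mean
``delta`` (support {1, 2, ...}, success probability 1/delta) and is
truncated at the right end of the genome, since genomes are linear.

A divergence bias can be enabled: the candidate tract is accepted with
probability p = 10^(-pi * phi), where pi is the per-site donor/recipient
divergence over the homologous portion of the tract and phi the slope of
the empirically log-linear decline of recombination with divergence (the
default, 18.1, is the value inferred for Streptococcus pneumoniae, which
sits between the known extremes of Bacillus subtilis and Escherichia coli).
Rejected events change nothing but are logged, so the realized rate is
visible.  Divergence is local to the tract — mismatch rejection senses the
sequence it touches, not genome-wide identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_flux import Genome, homologous_interval

__all__ = [
    "Tract",
    "BiasModel",
    "RecombinationEvent",
    "draw_tract",
    "acceptance_probability",
    "pick_donor",
    "apply_recombination",
]

DEFAULT_PHI = 18.1


@dataclass
class Tract:
    start: int
    length: int       # after truncation at the right genome end
    raw_length: int   # the geometric draw, before truncation


@dataclass
class BiasModel:
    """Divergence-dependent acceptance of recombination events."""

    enabled: bool = False
    phi: float = DEFAULT_PHI

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


@dataclass
class RecombinationEvent:
    """Outcome of one recombination attempt.

    ``status`` is one of ``accepted``, ``rejected_bias``, ``no_homology``
    or ``no_donor``; only accepted events change the recipient.
    """

    recipient: str
    donor: str | None
    start: int
    length: int
    raw_length: int
    homologous_bp: int = 0
    snps_exchanged: int = 0
    pi: float = 0.0
    accepted: bool = False
    status: str = "accepted"
    genes_inserted: list[str] = field(default_factory=list)
    genes_deleted: list[str] = field(default_factory=list)


def draw_tract(L: int, delta: float, rng: np.random.Generator) -> Tract:
    """Uniform start on [0, L); geometric length of mean ``delta``,
    truncated so the tract stays inside the linear genome."""
    if L < 1:
        raise ValueError("alignable length must be >= 1")
    if delta < 1:
        raise ValueError(f"mean tract length must be >= 1, got {delta}")
    start = int(rng.integers(L))
    raw = int(rng.geometric(1.0 / delta))
    return Tract(start=start, length=min(raw, L - start), raw_length=raw)


def acceptance_probability(pi: float, phi: float) -> float:
    """p = 10^(-pi * phi), clamped to [0, 1]."""
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return float(min(1.0, 10.0 ** (-pi * phi)))


def pick_donor(member_ids: list, recipient, rng: np.random.Generator):
    """Uniform donor among segment lineages excluding the recipient;
    None when the recipient is alone (event skipped, logged upstream)."""
    others = [m for m in member_ids if m is not recipient and m != recipient]
    if not others:
        return None
    return others[int(rng.integers(len(others)))]


def apply_recombination(
    recipient: Genome,
    donor: Genome,
    tract: Tract,
    bias: BiasModel,
    rng: np.random.Generator,
) -> RecombinationEvent:
    """Attempt one gene-conversion event; mutate the recipient in place.

    The tract is resolved against the donor gene by gene.  Positions inside
    genes the donor lacks are never written (no partial indels); if both
    breakpoints fall inside shared genes, entire accessory genes between
    them are inserted (donor-only) or deleted (recipient-only) as whole
    genes.  The donor is never modified.
    """
    event = RecombinationEvent(
        recipient=recipient.lineage, donor=donor.lineage,
        start=tract.start, length=tract.length, raw_length=tract.raw_length,
    )
    hmap = homologous_interval(recipient, donor, tract.start, tract.length)
    event.homologous_bp = hmap.homologous_bp
    if hmap.homologous_bp == 0:
        event.status = "no_homology"
        return event

    diffs = 0
    for a, d, n in hmap.chunks:
        diffs += int(np.count_nonzero(
            recipient.seq[a:a + n] != donor.seq[d:d + n]))
    event.pi = diffs / hmap.homologous_bp

    if bias.enabled:
        p = acceptance_probability(event.pi, bias.phi)
        if rng.random() >= p:
            event.status = "rejected_bias"
            return event

    for a, d, n in hmap.chunks:
        recipient.seq[a:a + n] = donor.seq[d:d + n]
    event.snps_exchanged = diffs
    event.accepted = True

    for gid in hmap.deletions:
        recipient.delete_gene(gid)
        event.genes_deleted.append(gid)
    for gid, anchor in hmap.insertions:
        rank = recipient.gene_ids.index(anchor) + 1
        recipient.insert_gene(rank, gid, donor.gene_sequence(gid).copy())
        event.genes_inserted.append(gid)
    return event
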