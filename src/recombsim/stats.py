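"""Run statistics: eta, the effective recombination rate r/m, and the
alignment-level checks (GC, segregating sites per codon position, ts/tv).

eta is the per-site SNP density of accepted recombination tracts
(total SNPs exchanged / total recombined bp), so that eta * delta is the
mean number of SNPs moved per event and the relation r/m = rho * eta *
delta is dimensionally consistent.  The per-event mean is also reported.
r/m itself is reported twice: via that formula and as the direct count
(SNPs exchanged / mutations).  Tract truncation at genome ends and bias
rejection make the two differ slightly; the direct count is the
authoritative realized value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimulationStats", "AlignmentSummary", "finalize_stats",
           "measure_alignment", "kappa_from_events"]


@dataclass
class SimulationStats:
    n_mutations: int = 0
    n_recomb_attempts: int = 0
    n_recomb_accepted: int = 0
    n_recomb_rejected_bias: int = 0
    n_no_donor: int = 0
    n_no_homology: int = 0
    total_recomb_bp: int = 0
    total_snps_exchanged: int = 0
    eta: float = 0.0
    eta_defined: bool = False
    eta_per_event: float = 0.0
    mean_tract_realized: float = 0.0
    r_over_m_formula: float = 0.0
    r_over_m_direct: float = 0.0
    rho: float = 0.0
    delta: float = 0.0

    def as_text(self) -> str:
        lines = []
        for key, val in self.__dict__.items():
            lines.append(f"{key} = {val}")
        return "\n".join(lines) + "\n"


def finalize_stats(mutations: list, recombinations: list, config) -> SimulationStats:
    """Aggregate the event logs into the headline statistics."""
    s = SimulationStats(rho=config.rho, delta=config.delta)
    s.n_mutations = len(mutations)
    accepted_bp = 0
    accepted_snps = 0
    accepted_len = 0
    for _seg, ev in recombinations:
        s.n_recomb_attempts += 1
        if ev.status == "no_donor":
            s.n_no_donor += 1
        elif ev.status == "no_homology":
            s.n_no_homology += 1
        elif ev.status == "rejected_bias":
            s.n_recomb_rejected_bias += 1
        else:
            s.n_recomb_accepted += 1
            accepted_bp += ev.homologous_bp
            accepted_snps += ev.snps_exchanged
            accepted_len += ev.length
    s.total_recomb_bp = accepted_bp
    s.total_snps_exchanged = accepted_snps
    if accepted_bp > 0:
        s.eta = accepted_snps / accepted_bp
        s.eta_defined = True
    if s.n_recomb_accepted > 0:
        s.eta_per_event = accepted_snps / s.n_recomb_accepted
        s.mean_tract_realized = accepted_len / s.n_recomb_accepted
    s.r_over_m_formula = config.rho * s.eta * config.delta
    if s.n_mutations > 0:
        s.r_over_m_direct = accepted_snps / s.n_mutations
    return s


@dataclass
class AlignmentSummary:
    n_sequences: int
    length: int
    gc_fraction: float
    # fraction of polymorphic columns among columns of each codon position
    segregating_fraction: tuple[float, float, float]
    segregating_total: int
    # distribution of true substitution events over codon positions (from
    # the event log, when provided)
    event_position_fractions: tuple[float, float, float] | None = None
    n_transitions: int | None = None
    n_transversions: int | None = None
    kappa_hat: float | None = None


def kappa_from_events(mutations: list) -> tuple[int, int, float]:
    """Transition and transversion counts from the true event log, and the
    per-event estimator kappa_hat = 2 * ts / tv (each transition target
    competes against two transversion targets)."""
    ts = sum(1 for _s, _l, ev in mutations if ev.is_transition)
    tv = len(mutations) - ts
    kappa = 2.0 * ts / tv if tv else float("inf")
    return ts, tv, kappa


def measure_alignment(alignment: dict[str, np.ndarray],
                      mutations: list | None = None) -> AlignmentSummary:
    """Summaries used to verify a run reproduced its input parameters."""
    if not alignment:
        raise ValueError("empty alignment")
    mat = np.vstack(list(alignment.values()))
    n, L = mat.shape
    if n < 2:
        raise ValueError("need at least two sequences")
    gc = float(np.mean((mat == 1) | (mat == 2)))  # C=1, G=2

    segregating = (mat != mat[0]).any(axis=0)
    seg_frac = []
    for k in range(3):
        cols = segregating[k::3]
        seg_frac.append(float(cols.mean()) if cols.size else 0.0)

    summary = AlignmentSummary(
        n_sequences=n, length=L, gc_fraction=gc,
        segregating_fraction=tuple(seg_frac),
        segregating_total=int(segregating.sum()),
    )
    if mutations:
        counts = np.zeros(3)
        for _s, _l, ev in mutations:
            counts[ev.codon_position - 1] += 1
        summary.event_position_fractions = tuple(counts / counts.sum())
        ts, tv, kappa = kappa_from_events(mutations)
        summary.n_transitions = ts
        summary.n_transversions = tv
        summary.kappa_hat = kappa
    return summary
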