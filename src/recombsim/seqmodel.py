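"""Root-sequence generation and nucleotide substitution.

Sequences are numpy ``uint8`` arrays with the encoding A=0, C=1, G=2, T=3.
Substitution models (JC69, K2P, K3P, GTR) are represented as *conditional
target distributions*: given that a substitution hits a site, the model
gives the probability of each of the three alternative bases.  The engine
draws the exact substitution count per branch segment from a Poisson
process, so the continuous-time waiting-time machinery of the usual matrix
exponential is unnecessary — only the target choice remains.

Codon-position rate heterogeneity (a proxy for purifying selection on
coding sequence) reweights *where* substitutions land, never how many
there are: the total count is imposed by the branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "SubstitutionModel",
    "CodonRateProfile",
    "MutationEvent",
    "random_sequence",
    "build_model",
    "draw_site",
    "apply_mutation",
    "seq_to_str",
    "str_to_seq",
]

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3
# purine<->purine and pyrimidine<->pyrimidine changes
_TRANSITION = {A: G, G: A, C: T, T: C}

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def str_to_seq(s: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = s[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return arr


def seq_to_str(seq: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[seq].tobytes().decode("ascii")


@dataclass
class SubstitutionModel:
    """Per-base conditional substitution weights.

    ``matrix[i, j]`` is P(new base = j | old base = i, substitution occurs);
    the diagonal is zero and every row sums to one.
    """

    name: str
    params: dict
    matrix: np.ndarray
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if (m < 0).any() or np.abs(np.diagonal(m)).max() > 0:
            raise ValueError("matrix needs zero diagonal, non-negative weights")
        rows = m.sum(axis=1)
        if np.abs(rows - 1.0).max() > 1e-12:
            raise ValueError("rows must be normalized")
        self.matrix = m
        self._cum = np.cumsum(m, axis=1)

    def draw_target(self, base: int, rng: np.random.Generator) -> int:
        return int(np.searchsorted(self._cum[base], rng.random(), side="right"))


@dataclass
class CodonRateProfile:
    """Relative substitution rates of codon positions 1, 2 and 3.

    Weights are renormalized to sum to one; they redistribute substitutions
    among position classes without changing the overall substitution rate.
    """

    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or (w < 0).any():
            raise ValueError("codon profile needs three non-negative weights")
        total = w.sum()
        if total <= 0:
            raise ValueError("codon profile weights are all zero")
        self.weights = tuple(w / total)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.weights)


UNIFORM_PROFILE = CodonRateProfile((1.0, 1.0, 1.0))


@dataclass
class MutationEvent:
    """One realized substitution: where it hit and what changed."""

    site: int
    old_base: int
    new_base: int
    codon_position: int  # 1, 2 or 3

    @property
    def is_transition(self) -> bool:
        return _TRANSITION[self.old_base] == self.new_base


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Generate an i.i.d. random nucleotide sequence of the given GC content.

    Each position is G or C with probability ``gc`` (split evenly between G
    and C) and A or T otherwise (split evenly).  ``length`` must be at least
    3 (the sequence stands for a concatenate of protein-coding genes).
    """
    if length < 3:
        raise ValueError(f"sequence length must be >= 3, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    u = rng.random(length)
    is_gc = u < gc
    half = rng.random(length) < 0.5
    seq = np.where(is_gc, np.where(half, G, C), np.where(half, A, T))
    return seq.astype(np.uint8)


def _normalize_rows(weights: np.ndarray) -> np.ndarray:
    w = np.array(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def build_model(
    name: str,
    params: dict | None = None,
    gc: float = 0.5,
    freqs: tuple[float, float, float, float] | None = None,
) -> SubstitutionModel:
    """Construct the conditional target distribution for a named model.

    JC69 — all three alternatives equally likely (1/3 each).
    K2P  — transitions weighted ``kappa``, each transversion 1.
    K3P  — transitions ``kappa1``; the A<->T and G<->C transversions
           ``kappa2``; the remaining transversions (A<->C, G<->T) 1.
    GTR  — weight(i->j) proportional to ``rates[i,j] * freq[j]`` with six
           exchangeability rates (order AC, AG, AT, CG, CT, GT) and
           equilibrium frequencies defaulting to
           (A, C, G, T) = ((1-gc)/2, gc/2, gc/2, (1-gc)/2), overridable
           via ``freqs`` (order A, C, G, T).
    """
    params = dict(params or {})
    name_u = name.upper()
    w = np.zeros((4, 4))

    if name_u == "JC69":
        w[:] = 1.0
    elif name_u == "K2P":
        kappa = float(params.get("kappa", 1.0))
        if kappa < 0:
            raise ValueError("kappa must be non-negative")
        w[:] = 1.0
        for i, j in _TRANSITION.items():
            w[i, j] = kappa
    elif name_u == "K3P":
        k1 = float(params.get("kappa1", 1.0))
        k2 = float(params.get("kappa2", 1.0))
        if k1 < 0 or k2 < 0:
            raise ValueError("kappa1/kappa2 must be non-negative")
        w[:] = 1.0
        for i, j in _TRANSITION.items():
            w[i, j] = k1
        for i, j in ((A, T), (T, A), (G, C), (C, G)):
            w[i, j] = k2
    elif name_u == "GTR":
        try:
            r = [float(params[k]) for k in ("ac", "ag", "at", "cg", "ct", "gt")]
        except KeyError as exc:
            raise ValueError(
                "GTR requires six exchangeability rates: ac, ag, at, cg, ct, gt"
            ) from exc
        if min(r) < 0:
            raise ValueError("GTR rates must be non-negative")
        if freqs is None:
            freqs = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
        f = np.asarray(freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("GTR frequencies must be 4 non-negatives summing to 1")
        ex = np.zeros((4, 4))
        pairs = [(A, C), (A, G), (A, T), (C, G), (C, T), (G, T)]
        for (i, j), rate in zip(pairs, r):
            ex[i, j] = ex[j, i] = rate
        w = ex * f[None, :]
        params["freqs"] = tuple(f)
    else:
        raise ValueError(f"unknown substitution model: {name!r}")

    matrix = _normalize_rows(w)
    return SubstitutionModel(name=name_u, params=params, matrix=matrix)


def draw_site(profile: CodonRateProfile, length: int, rng: np.random.Generator) -> int:
    """Sample a site so P(codon position k) is proportional to the profile
    weights, uniform among sites of the same position class.

    ``length`` must be divisible by 3 (concatenate of in-frame genes).
    """
    if length % 3 != 0:
        raise ValueError("sequence length must be divisible by 3")
    k = int(np.searchsorted(profile.cumulative, rng.random(), side="right"))
    return 3 * int(rng.integers(length // 3)) + k


def apply_mutation(
    seq: np.ndarray,
    site: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> MutationEvent:
    """Substitute the base at ``site`` in place; always a real change.

    Returns the event record (site, old base, new base, codon position).
    """
    old = int(seq[site])
    if old > 3:
        raise ValueError(f"non-ACGT base code {old} at site {site}")
    new = model.draw_target(old, rng)
    seq[site] = new
    return MutationEvent(site=site, old_base=old, new_base=new,
                         codon_position=site % 3 + 1)
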