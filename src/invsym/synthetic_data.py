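"""Synthetic inputs with known symmetry structure.

Every pipeline stage is testable offline against sequences whose
inversion-symmetry properties are known by construction:

``perfect_is``
    W followed by the reverse complement of W — every k-mer count equals
    its inverse's up to a junction effect of at most 2(k-1) windows, so
    E_k[X] is bounded by 2(k-1)/n_positions.
``iid``
    Independent draws from given base probabilities. Satisfies inversion
    symmetry in expectation; observed E_k[X] is pure sampling noise and
    grows as (4^k / 2L)^(1/2), reproducing the k-limit law.
``skewed``
    iid with base probabilities solved from target #T/#A and #G/#C count
    ratios — controlled violations of the second Chargaff rule.
``motif_repeat``
    A single motif tiled to length: strongly non-symmetric unless the
    motif is an inverse palindrome.

Count tables under the Poisson null and Bernoulli gene-strand tables are
generated directly, without a sequence, for model-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping

import numpy as np

from .kmer_stats import KmerCountTable, decode_kmer
from .sequence_io import GeneRecord, MaskPolicy, SequenceRecord, reverse_complement_sequence

__all__ = [
    "Structure",
    "SyntheticSpec",
    "generate_sequence",
    "generate_exact_composition",
    "generate_poisson_is_counts",
    "generate_gene_table",
    "skewed_base_probs",
]

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class Structure(str, Enum):
    IID = "iid"
    PERFECT_IS = "perfect_is"
    SKEWED = "skewed"
    MOTIF_REPEAT = "motif_repeat"


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic sequence; bit-reproducible given a seed."""

    length: int
    structure: Structure = Structure.IID
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    ta_ratio: float = 1.0
    gc_ratio: float = 1.0
    motif: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "structure", Structure(self.structure))
        if self.length < 1:
            raise ValueError("length must be positive")
        p = np.asarray(self.base_probs, dtype=float)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ValueError("base_probs must be 4 nonnegative reals summing to 1")
        if self.ta_ratio <= 0 or self.gc_ratio <= 0:
            raise ValueError("count ratios must be positive")
        if self.structure is Structure.MOTIF_REPEAT and not self.motif:
            raise ValueError("motif_repeat requires a motif")
        if self.structure is Structure.PERFECT_IS and self.length % 2:
            raise ValueError("perfect_is requires an even length")


def skewed_base_probs(
    base_probs: tuple[float, float, float, float], ta_ratio: float, gc_ratio: float
) -> np.ndarray:
    """Redistribute probability within the A/T and C/G pools to hit target ratios.

    Keeps p_A + p_T and p_C + p_G fixed and sets p_T / p_A = ta_ratio,
    p_G / p_C = gc_ratio, so expected count ratios match the targets.
    """
    pA, pC, pG, pT = base_probs
    w_at, w_gc = pA + pT, pC + pG
    return np.array(
        [
            w_at / (1 + ta_ratio),
            w_gc / (1 + gc_ratio),
            w_gc * gc_ratio / (1 + gc_ratio),
            w_at * ta_ratio / (1 + ta_ratio),
        ]
    )


def _iid(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def generate_sequence(spec: SyntheticSpec) -> SequenceRecord:
    """Generate one sequence according to the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.base_probs, dtype=float)
    if spec.structure is Structure.IID:
        residues = _iid(spec.length, probs, rng)
        rec_id = f"iid_L{spec.length}_s{spec.seed}"
    elif spec.structure is Structure.PERFECT_IS:
        half = _iid(spec.length // 2, probs, rng)
        residues = half + reverse_complement_sequence(half)
        rec_id = f"perfect_is_L{spec.length}_s{spec.seed}"
    elif spec.structure is Structure.SKEWED:
        residues = _iid(
            spec.length, skewed_base_probs(tuple(probs), spec.ta_ratio, spec.gc_ratio), rng
        )
        rec_id = f"skewed_ta{spec.ta_ratio}_gc{spec.gc_ratio}_L{spec.length}_s{spec.seed}"
    else:  # motif_repeat
        reps = spec.length // len(spec.motif) + 1
        residues = (spec.motif * reps)[: spec.length]
        rec_id = f"motif_{spec.motif}_L{spec.length}"
    return SequenceRecord(rec_id, residues, MaskPolicy.NONE)


def generate_exact_composition(
    counts: Mapping[str, int], seed: int = 0
) -> SequenceRecord:
    """A uniformly shuffled sequence with *exactly* the given base counts.

    Deterministic counterpart of the ``skewed`` mode, for tests that need
    the skew statistics to be exact rather than binomial.
    """
    bases = "".join(b * n for b, n in counts.items())
    if not bases:
        raise ValueError("empty composition")
    arr = np.array(list(bases))
    np.random.default_rng(seed).shuffle(arr)
    return SequenceRecord(f"exact_{'_'.join(f'{b}{n}' for b, n in counts.items())}",
                          "".join(arr), MaskPolicy.NONE)


def generate_poisson_is_counts(
    k: int,
    lam_fn: float | Callable[[str], float] | np.ndarray,
    seed: int = 0,
    *,
    source_id: str = "poisson_is",
) -> KmerCountTable:
    """Independent Poisson draws per k-mer, one table.

    ``lam_fn`` may be a scalar mean, a length-4^k array of means, or a
    callable from k-mer string to mean. Under the symmetry null the
    means must satisfy lam(S) = lam(S_inv); a scalar always does, and
    asymmetric means are allowed deliberately for alternative-hypothesis
    tests. ``n_positions`` is set to the realized total so the table
    validates.
    """
    n = 4**k
    if callable(lam_fn):
        lam = np.array([lam_fn(decode_kmer(c, k)) for c in range(n)], dtype=float)
    else:
        lam = np.broadcast_to(np.asarray(lam_fn, dtype=float), (n,))
    if (lam < 0).any():
        raise ValueError("Poisson means must be nonnegative")
    counts = np.random.default_rng(seed).poisson(lam)
    return KmerCountTable(k, counts, int(counts.sum()), source_id)


def generate_gene_table(
    n_genes: int,
    p_plus: float,
    chroms: list[str] | None = None,
    seed: int = 0,
) -> list[GeneRecord]:
    """Genes with strands drawn Bernoulli(p_plus), round-robin over chroms."""
    if not 0 <= p_plus <= 1:
        raise ValueError("p_plus must be a probability")
    chroms = chroms or ["chr1"]
    rng = np.random.default_rng(seed)
    plus = rng.random(n_genes) < p_plus
    return [
        GeneRecord(chroms[i % len(chroms)], "P" if plus[i] else "M", f"g{i}")
        for i in range(n_genes)
    ]
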