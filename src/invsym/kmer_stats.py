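"""k-mer counting and inverse-pair symmetry statistics.

The object of study is the full 4^k count table of one strand and, for a
chosen pairing of each k-mer S with a partner S*, the normalized
difference statistics

    X(S,S*) = |N(S) - N(S*)| / (N(S) + N(S*))        in [0, 1]
    Y(S,S*) = (N(S) - N(S*)) / (N(S) + N(S*))        in [-1, 1]
    Z(S,S*) = (N(S) - N(S*)) / sqrt(N(S) + N(S*))

Under inversion symmetry (the generalized second Chargaff rule) with
Poisson counts, Z is approximately standard normal; X then concentrates
near (N(S)+N(S*))^(-1/2), which is what makes E_k[X] a usable symmetry
criterion.

k-mers are encoded as base-4 integers, 2 bits per base, A=0 C=1 G=2 T=3,
most-significant base first, so integer order is lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .sequence_io import SequenceRecord

__all__ = [
    "KmerCountTable",
    "PairScheme",
    "SchemeKind",
    "AggregateStats",
    "count_kmers",
    "encode_kmer",
    "decode_kmer",
    "pair_partner",
    "partner_indices",
    "pair_stats",
    "aggregate",
    "s1_measure",
    "filter_cg",
]

MAX_K = 15  # 4^15 counts = 8 GiB of int64; refuse beyond without opt-in

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i

# histogram convention for the X distribution: fixed-width bins on [0, 1]
X_BIN_WIDTH = 0.02
X_BIN_EDGES = np.round(np.arange(0, 1 + X_BIN_WIDTH / 2, X_BIN_WIDTH), 10)

# |Z| < 1.65 covers ~90% of a standard normal; reported as a sanity column
Z_NORMAL_90 = 1.65


class SchemeKind(str, Enum):
    INVERSE = "inverse"
    REVERSE = "reverse"
    COMPLEMENT = "complement"
    RANDOM = "random"


@dataclass(frozen=True)
class PairScheme:
    """A pairing rule S -> S* over the 4^k k-mer set.

    ``inverse`` pairs each k-mer with its reverse complement, ``reverse``
    with its mirror image, ``complement`` with its in-place complement.
    ``random`` draws a seeded perfect matching without self-pairs, the
    control against which the structured pairings are judged.
    """

    kind: SchemeKind = SchemeKind.INVERSE
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", SchemeKind(self.kind))


@dataclass
class KmerCountTable:
    """Counts of all 4^k k-mers on one strand of one sequence."""

    k: int
    counts: np.ndarray  # int64, length 4^k, lexicographic index
    n_positions: int  # number of ACGT-only windows scanned
    source_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must have length 4^{self.k}")
        if int(self.counts.sum()) != self.n_positions:
            raise ValueError("sum(counts) must equal n_positions")


@dataclass
class AggregateStats:
    """Per-k summary of the pair statistics under one scheme.

    ``E_X`` averages X over the M_k k-mers with nonzero pair total; the
    remaining (4^k - M_k) "null pairs" are reported as ``null_fraction``.
    ``x_histogram`` carries bin masses over 0.02-wide bins (summing to 1
    over counted k-mers).
    """

    k: int
    scheme: PairScheme
    M_k: int
    E_X: float
    E_absZ: float
    sd_absZ: float
    null_fraction: float
    x_histogram: np.ndarray
    frac_absZ_lt_1_65: float


def encode_kmer(s: str) -> int:
    """Lexicographic integer code of a k-mer (A=0 C=1 G=2 T=3, MSB first)."""
    code = 0
    for c in s:
        v = _CODE[ord(c)]
        if v < 0:
            raise ValueError(f"non-ACGT character in k-mer {s!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def count_kmers(
    record: SequenceRecord | str, k: int, *, allow_large: bool = False
) -> KmerCountTable:
    """Count overlapping k-mers (step 1) on the given strand.

    Windows containing any non-ACGT character (hard-masked or excluded
    soft-masked positions) contribute nothing; ``n_positions`` is the
    number of windows actually counted and serves as the effective
    sequence length in all downstream normalizations.
    """
    if isinstance(record, SequenceRecord):
        residues, source_id = record.residues, record.id
    else:
        residues, source_id = record, ""
    L = len(residues)
    if k < 1 or k > L:
        raise ValueError(f"k={k} out of range for sequence of length {L}")
    if k > MAX_K and not allow_large:
        raise ValueError(f"k={k} exceeds the memory guard ({MAX_K}); pass allow_large")

    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    n_win = L - k + 1
    # base-4 horner over k shifted views; windows touching a -1 are invalidated
    kcodes = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for i in range(k):
        c = codes[i : i + n_win]
        valid &= c >= 0
        kcodes = (kcodes << 2) | np.where(c >= 0, c, 0)
    counts = np.bincount(kcodes[valid], minlength=4**k)
    return KmerCountTable(k, counts, int(valid.sum()), source_id)


def _digits(codes: np.ndarray, k: int) -> np.ndarray:
    """(n, k) array of base-4 digits, MSB first."""
    shifts = np.arange(2 * (k - 1), -1, -2, dtype=np.int64)
    return (codes[:, None] >> shifts[None, :]) & 3


def _from_digits(digits: np.ndarray) -> np.ndarray:
    k = digits.shape[1]
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return digits @ weights


def partner_indices(k: int, scheme: PairScheme) -> np.ndarray:
    """Partner code for every k-mer code under a scheme, as an index array.

    All four schemes produce bijections of {0, ..., 4^k - 1}; inverse,
    reverse and the random matching are involutions.
    """
    n = 4**k
    codes = np.arange(n, dtype=np.int64)
    if scheme.kind is SchemeKind.INVERSE:
        d = _digits(codes, k)
        return _from_digits((3 - d)[:, ::-1])
    if scheme.kind is SchemeKind.REVERSE:
        return _from_digits(_digits(codes, k)[:, ::-1])
    if scheme.kind is SchemeKind.COMPLEMENT:
        return _from_digits(3 - _digits(codes, k))
    # random: seeded Fisher-Yates permutation taken in adjacent pairs, an
    # involution without self-pairs (4^k is even, so no leftover)
    rng = np.random.default_rng(scheme.seed)
    order = rng.permutation(n)
    partner = np.empty(n, dtype=np.int64)
    partner[order[0::2]] = order[1::2]
    partner[order[1::2]] = order[0::2]
    return partner


def pair_partner(S: str, scheme: PairScheme) -> str:
    """The partner k-mer of S under the scheme."""
    k = len(S)
    code = encode_kmer(S)
    return decode_kmer(int(partner_indices(k, scheme)[code]), k)


def _pair_arrays(
    counts: np.ndarray, partner: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(N, N*, X, Z) per ordered k-mer; Z is NaN where N + N* = 0."""
    N = counts.astype(np.float64)
    N_star = N[partner]
    total = N + N_star
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(total > 0, np.abs(N - N_star) / total, 0.0)
        Z = np.where(total > 0, (N - N_star) / np.sqrt(total), np.nan)
    return N, N_star, X, Z


def pair_stats(table: KmerCountTable, scheme: PairScheme):
    """Per-k-mer pair statistics as a DataFrame (one row per ordered k-mer).

    Each unordered pair appears twice with opposite-sign Y; X is
    pair-symmetric so aggregates are unaffected. Z is NaN for null pairs.
    """
    import pandas as pd

    partner = partner_indices(table.k, scheme)
    N, N_star, X, Z = _pair_arrays(table.counts, partner)
    total = N + N_star
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = np.where(total > 0, (N - N_star) / total, 0.0)
    kmers = [decode_kmer(c, table.k) for c in range(4**table.k)]
    return pd.DataFrame(
        {
            "S": kmers,
            "S_star": [kmers[p] for p in partner],
            "N": table.counts,
            "N_star": table.counts[partner],
            "X": X,
            "Y": Y,
            "Z": Z,
        }
    )


def aggregate(table: KmerCountTable, scheme: PairScheme) -> AggregateStats:
    """Aggregate the pair statistics of a count table under one scheme.

    E_k[X] is the mean of X over the M_k k-mers counted at least once
    (N(S) > 0 and/or N(S*) > 0); k-mers whose whole pair is absent are
    excluded from every average and reported via ``null_fraction``.
    Since X is symmetric in the pair, averaging over ordered k-mers
    equals the unordered-pair average.
    """
    partner = partner_indices(table.k, scheme)
    _, _, X, Z = _pair_arrays(table.counts, partner)
    counted = ~np.isnan(Z)
    M_k = int(counted.sum())
    if M_k == 0:
        raise ValueError("no k-mer pair has nonzero total; statistics undefined")
    absZ = np.abs(Z[counted])
    Xc = X[counted]
    hist, _ = np.histogram(Xc, bins=X_BIN_EDGES)
    return AggregateStats(
        k=table.k,
        scheme=scheme,
        M_k=M_k,
        E_X=float(Xc.mean()),
        E_absZ=float(absZ.mean()),
        sd_absZ=float(absZ.std()),
        null_fraction=float((4**table.k - M_k) / 4**table.k),
        x_histogram=hist / M_k,
        frac_absZ_lt_1_65=float((absZ < Z_NORMAL_90).mean()),
    )


def s1_measure(table: KmerCountTable) -> float:
    """The L1-style inversion-symmetry index S1 in [0, 1].

    S1 = 1 - sum_S |N(S) - N(S_inv)| / sum_S (N(S) + N(S_inv)); the
    denominator equals twice the effective sequence length. S1 = 1 for a
    perfectly symmetric spectrum. Empirically 1 - S1 is roughly half of
    E_k[X] on near-symmetric spectra.
    """
    if table.n_positions == 0:
        raise ValueError("empty count table: S1 undefined")
    partner = partner_indices(table.k, PairScheme(SchemeKind.INVERSE))
    N = table.counts.astype(np.float64)
    N_star = N[partner]
    return float(1.0 - np.abs(N - N_star).sum() / (N + N_star).sum())


def _contains_cg(k: int) -> np.ndarray:
    """Boolean mask over codes whose k-mer string contains the CG dimer."""
    codes = np.arange(4**k, dtype=np.int64)
    d = _digits(codes, k)
    return ((d[:, :-1] == 1) & (d[:, 1:] == 2)).any(axis=1)


def filter_cg(table: KmerCountTable) -> KmerCountTable:
    """Zero out all k-mers containing the CG dinucleotide.

    CG-containing k-mers have an atypical count distribution (CpG
    depletion/islands); removing them tests whether a pairing's behavior
    is driven by that one feature. ``n_positions`` shrinks to the counts
    that remain.
    """
    if table.k < 2:
        raise ValueError("CG filtering requires k >= 2")
    counts = table.counts.copy()
    counts[_contains_cg(table.k)] = 0
    return KmerCountTable(table.k, counts, int(counts.sum()), table.source_id)
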