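"""Reading and normalizing DNA sequences and gene-strand tables.

All downstream statistics are computed on a single ("plus") strand: the
strand stored in the FASTA file. Counts of a k-mer's inverse are obtained
by scanning the same strand for the reverse-complement string, never by
scanning the opposite strand.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "MaskPolicy",
    "SequenceRecord",
    "GeneRecord",
    "read_fasta",
    "read_gene_table",
    "reverse_complement",
    "reverse",
    "complement",
]

_ALPHABET = frozenset("ACGTN")

# complement over the strict k-mer alphabet; used by the public string ops
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
# sequence-level complement, tolerant of hard-masked positions
_COMPLEMENT_N = str.maketrans("ACGTN", "TGCAN")


class MaskPolicy(str, Enum):
    """How soft-masked (lowercase) bases in assembly FASTA are treated.

    ``include_soft``
        Lowercase bases are case-folded and analyzed like any other base
        (the bare-chromosome analysis).
    ``exclude_soft``
        Lowercase bases become ``N`` and are skipped by the k-mer scan,
        reproducing analyses on repeat/low-complexity-masked chromosomes.
    ``none``
        No masking interpretation; case is folded and every base kept
        (equivalent in effect to ``include_soft``, named for intent).
    """

    INCLUDE_SOFT = "include_soft"
    EXCLUDE_SOFT = "exclude_soft"
    NONE = "none"


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence, normalized to the {A,C,G,T,N} alphabet."""

    id: str
    residues: str
    mask_policy_applied: MaskPolicy = MaskPolicy.INCLUDE_SOFT

    def __post_init__(self) -> None:
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(f"non-normalized residues {sorted(bad)!r} in {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its chromosome and coding strand (P = plus, M = minus)."""

    chrom: str
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.strand not in ("P", "M"):
            raise ValueError(f"strand must be P or M, got {self.strand!r}")


def normalize_residues(raw: str, policy: MaskPolicy) -> str:
    """Map raw FASTA characters onto {A,C,G,T,N} under a mask policy.

    Ambiguity codes (R, Y, S, W, ...) become N rather than raising: real
    assemblies contain them and the k-mer scan simply skips windows that
    touch them.
    """
    if policy is MaskPolicy.EXCLUDE_SOFT:
        # lowercase (soft-masked) positions are erased before case folding
        raw = "".join("N" if c.islower() else c for c in raw)
    s = raw.upper()
    return "".join(c if c in _ALPHABET else "N" for c in s)


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_fasta(
    path: str | Path, policy: MaskPolicy = MaskPolicy.INCLUDE_SOFT
) -> list[SequenceRecord]:
    """Read a FASTA or gzipped-FASTA file into normalized records.

    Parameters
    ----------
    path
        FASTA file, optionally gzip-compressed (detected by ``.gz`` suffix).
    policy
        Soft-mask handling; see :class:`MaskPolicy`.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If the file contains no sequences or an empty sequence.
    """
    records: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            residues = normalize_residues(str(rec.seq), policy)
            if not residues:
                raise ValueError(f"empty sequence {rec.id!r} in {path}")
            records.append(SequenceRecord(rec.id, residues, policy))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _check_kmer(s: str) -> None:
    if not s:
        raise ValueError("empty k-mer")
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"k-mer contains non-ACGT characters {sorted(bad)!r}")


def reverse_complement(s: str) -> str:
    """The inverse of a k-mer: reverse-complement, e.g. CGA -> TCG."""
    _check_kmer(s)
    return s.translate(_COMPLEMENT)[::-1]


def reverse(s: str) -> str:
    """The reverse of a k-mer, e.g. CGA -> AGC."""
    _check_kmer(s)
    return s[::-1]


def complement(s: str) -> str:
    """The in-place complement of a k-mer, e.g. CGA -> GCT."""
    _check_kmer(s)
    return s.translate(_COMPLEMENT)


def reverse_complement_sequence(s: str) -> str:
    """Reverse-complement a whole normalized sequence (N maps to N)."""
    return s.translate(_COMPLEMENT_N)[::-1]


_STRAND_MAP = {"+": "P", "-": "M", "−": "M", "P": "P", "M": "M"}


def _parse_gene_line(fields: list[str], lineno: int) -> GeneRecord:
    if len(fields) >= 6 and fields[1].isdigit() and fields[2].isdigit():
        chrom, name, strand = fields[0], fields[3], fields[5]
    elif len(fields) >= 3:
        chrom, strand, name = fields[0], fields[1], fields[2]
    else:
        raise ValueError(f"line {lineno}: expected BED6 or 3-column TSV, got {fields!r}")
    if strand not in _STRAND_MAP:
        raise ValueError(f"line {lineno}: strand {strand!r} not in {{+,-}}")
    return GeneRecord(chrom, _STRAND_MAP[strand], name)


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read gene strand annotations from BED6 or a (chrom, strand, name) TSV.

    BED is recognized per line by numeric start/end columns; strand comes
    from column 6. In the TSV form the strand is column 2. ``+``/``-`` are
    normalized to ``P``/``M``.
    """
    genes: list[GeneRecord] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_gene_line(line.split(), lineno))
    if not genes:
        raise ValueError(f"no gene records found in {path}")
    return genes


def iter_gene_counts(genes: list[GeneRecord]) -> Iterator[tuple[str, int, int]]:
    """Yield (chrom, n_plus, n_minus) per chromosome, in first-seen order."""
    order: list[str] = []
    counts: dict[str, list[int]] = {}
    for g in genes:
        if g.chrom not in counts:
            counts[g.chrom] = [0, 0]
            order.append(g.chrom)
        counts[g.chrom][0 if g.strand == "P" else 1] += 1
    for chrom in order:
        p, m = counts[chrom]
        yield chrom, p, m
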