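"""Emergence of inversion symmetry through segment-inversion rearrangements.

Genomes evolve through rearrangements, many of which are inversions of a
segment between two breakpoints: the segment is excised and reinserted
as its reverse complement. Each such event moves k-mer content from a
k-mer to its inverse, so an accumulation of inversions at many scales
drives the single-strand k-mer spectrum toward inversion symmetry even
when the starting material is strongly skewed. This module provides the
model-chromosome construction (enlarging a small, non-symmetric seed by
concatenating random subsequences of itself) and the rearrangement
process, so the buildup of symmetry can be measured with the E_k[X]
machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import MaskPolicy, SequenceRecord

__all__ = [
    "RearrangementConfig",
    "ModelChromosomeConfig",
    "build_model_chromosome",
    "invert_segment",
    "apply_rearrangements",
]

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


@dataclass(frozen=True)
class RearrangementConfig:
    """A batch of segment inversions with uniform breakpoints and lengths.

    Each event picks a start uniformly along the chromosome and a
    segment length uniformly in [2, max_segment_length]; segments
    reaching past the right end are clipped (the chromosome is linear).
    """

    n_events: int
    max_segment_length: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.max_segment_length < 2:
            raise ValueError("max_segment_length must be >= 2")


@dataclass(frozen=True)
class ModelChromosomeConfig:
    """Enlarge a seed sequence by concatenating random subsequences of it."""

    seed_sequence: SequenceRecord
    target_length: int
    subsequence_length_range: tuple[int, int] = (1_000, 16_000)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.subsequence_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid subsequence length range")
        if hi > self.seed_sequence.length:
            raise ValueError("subsequence range exceeds seed sequence length")
        if self.target_length < hi:
            raise ValueError("target_length must be >= max subsequence length")


def _to_array(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype=np.uint8).copy()


def _to_record(arr: np.ndarray, rec_id: str, policy: MaskPolicy) -> SequenceRecord:
    return SequenceRecord(rec_id, arr.tobytes().decode("ascii"), policy)


def build_model_chromosome(cfg: ModelChromosomeConfig) -> SequenceRecord:
    """Concatenate uniform random substrings of the seed up to target length.

    Substring start and length are drawn uniformly (length within the
    configured range); the final concatenation is truncated to exactly
    ``target_length``. The 1-mer composition of the output matches the
    seed's in expectation, preserving its Chargaff-rule violations.
    """
    rng = np.random.default_rng(cfg.seed)
    seed_arr = _to_array(cfg.seed_sequence.residues)
    lo, hi = cfg.subsequence_length_range
    parts: list[np.ndarray] = []
    total = 0
    while total < cfg.target_length:
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(seed_arr) - length + 1))
        parts.append(seed_arr[start : start + length])
        total += length
    out = np.concatenate(parts)[: cfg.target_length]
    return _to_record(
        out, f"{cfg.seed_sequence.id}_model", cfg.seed_sequence.mask_policy_applied
    )


def invert_segment(seq: SequenceRecord, start: int, end: int) -> SequenceRecord:
    """Replace seq[start:end) by its reverse complement (length preserved)."""
    if not (0 <= start < end <= seq.length):
        raise ValueError(f"invalid interval [{start}, {end}) for length {seq.length}")
    arr = _to_array(seq.residues)
    arr[start:end] = _COMP[arr[start:end]][::-1]
    return _to_record(arr, seq.id, seq.mask_policy_applied)


def apply_rearrangements(seq: SequenceRecord, cfg: RearrangementConfig) -> SequenceRecord:
    """Apply n_events successive random segment inversions.

    Every event conserves total length and the pooled base pairs
    {#A + #T, #C + #G}; nested and overlapping inversions arise
    naturally from the independent uniform draws.
    """
    rng = np.random.default_rng(cfg.seed)
    arr = _to_array(seq.residues)
    L = len(arr)
    starts = rng.integers(0, L, size=cfg.n_events)
    lengths = rng.integers(2, cfg.max_segment_length + 1, size=cfg.n_events)
    for s, l in zip(starts, lengths):
        e = min(int(s) + int(l), L)  # clip at the right end; linear chromosome
        seg = arr[s:e]
        arr[s:e] = _COMP[seg][::-1]
    return _to_record(arr, seq.id, seq.mask_policy_applied)
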