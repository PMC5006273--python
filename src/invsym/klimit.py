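"""E_k[X] profiles, the k-limit, window scans, and the KL ~ ln(L) law.

The k-limit KL of a sequence is the k at which the inverse-pair symmetry
measure E_k[X] is closest to a target (conventionally 0.1): the
effective range of k over which inversion symmetry holds. Because the
Poisson null makes E_k[X] grow like (4^k / 2L)^(1/2), KL grows
logarithmically with sequence length with slope 1/ln4 ~ 0.72 per ln(L),
a law that holds across species and across subsections of a chromosome.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .kmer_stats import AggregateStats, PairScheme, aggregate, count_kmers
from .sequence_io import MaskPolicy, SequenceRecord

__all__ = [
    "ISProfile",
    "KLimitResult",
    "KLimitRule",
    "WindowScanResult",
    "LogLengthFit",
    "is_profile",
    "k_limit",
    "window_scan",
    "fit_log_length",
    "load_reference_klimits",
]


class KLimitRule(str, Enum):
    CLOSEST_TO_TARGET = "closest_to_target"
    LAST_BELOW_TARGET = "last_below_target"


@dataclass
class ISProfile:
    """Per-k aggregate statistics over a contiguous k-range."""

    source_id: str
    scheme: PairScheme
    per_k: dict[int, AggregateStats]

    def __post_init__(self) -> None:
        ks = sorted(self.per_k)
        if ks and ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("k-range must be contiguous")

    def e_x(self) -> dict[int, float]:
        return {k: agg.E_X for k, agg in sorted(self.per_k.items())}


@dataclass(frozen=True)
class KLimitResult:
    KL: int
    criterion_value: float
    rule: KLimitRule
    target: float


@dataclass
class WindowScanResult:
    """E_k[X] evaluated independently on non-overlapping windows.

    Windows tile from position 0 (0-based, half-open); a trailing partial
    window is dropped so all windows share the same nominal length.
    """

    window_length: int
    k: int
    per_window_EX: list[float]
    mean_EX: float


@dataclass
class LogLengthFit:
    """Ordinary least squares of k-limit on ln(length)."""

    points: list[tuple[float, int]]
    slope: float
    intercept: float


def is_profile(
    record: SequenceRecord | str,
    k_min: int,
    k_max: int,
    scheme: PairScheme = PairScheme(),
    *,
    stop_above: float | None = None,
) -> ISProfile:
    """Compute E_k[X] (and companions) for each k in [k_min, k_max].

    ``stop_above`` optionally truncates the scan once E_k[X] exceeds that
    value — useful when only the k-limit is wanted, since E_k[X] is
    increasing in k in the symmetric regime.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    source_id = record.id if isinstance(record, SequenceRecord) else ""
    per_k: dict[int, AggregateStats] = {}
    for k in range(k_min, k_max + 1):
        agg = aggregate(count_kmers(record, k), scheme)
        per_k[k] = agg
        if stop_above is not None and agg.E_X > stop_above:
            break
    return ISProfile(source_id, scheme, per_k)


def k_limit(
    profile: ISProfile,
    target: float = 0.1,
    rule: KLimitRule | str = KLimitRule.CLOSEST_TO_TARGET,
) -> KLimitResult:
    """Determine the k-limit of a profile.

    ``closest_to_target``: KL = argmin_k |E_k[X] - target| (ties go to
    the smaller k). ``last_below_target``: the largest k with
    E_k[X] <= target (falling back to the smallest k if none is below).
    """
    rule = KLimitRule(rule)
    ex = profile.e_x()
    if not ex:
        raise ValueError("empty profile")
    if rule is KLimitRule.CLOSEST_TO_TARGET:
        KL = min(ex, key=lambda k: (abs(ex[k] - target), k))
    else:
        below = [k for k, v in ex.items() if v <= target]
        KL = max(below) if below else min(ex)
    return KLimitResult(KL, ex[KL], rule, target)


def window_scan(
    record: SequenceRecord | str,
    window_length: int,
    k: int,
    scheme: PairScheme = PairScheme(),
) -> WindowScanResult:
    """E_k[X] per non-overlapping window, plus the mean over windows.

    The section-level symmetry criterion is imposed on the mean of the
    per-window values, not on pooled counts.
    """
    residues = record.residues if isinstance(record, SequenceRecord) else record
    if window_length < k:
        raise ValueError("window_length must be >= k")
    n_windows = len(residues) // window_length
    if n_windows == 0:
        raise ValueError("sequence shorter than one window")
    per_window = []
    for i in range(n_windows):
        chunk = residues[i * window_length : (i + 1) * window_length]
        per_window.append(aggregate(count_kmers(chunk, k), scheme).E_X)
    return WindowScanResult(window_length, k, per_window, float(np.mean(per_window)))


def fit_log_length(points: list[tuple[float, int]]) -> LogLengthFit:
    """OLS regression of k-limit on ln(length) over (length, KL) points."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    x = np.log([p[0] for p in points])
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("lengths are all identical; fit is degenerate")
    res = stats.linregress(x, y)
    return LogLengthFit(list(points), float(res.slope), float(res.intercept))


def load_reference_klimits() -> pd.DataFrame:
    """Published (length, k-limit) reference points shipped with the package."""
    ref = importlib.resources.files("invsym.data") / "klimit_vs_length.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
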