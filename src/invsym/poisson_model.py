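"""The IS-Poisson null model and its closed-form predictions.

If inversion symmetry holds as a statement about distributions — N(S) and
N(S_inv) drawn iid — and counts are Poisson, then for each pair

    Z = (N(S) - N(S_inv)) / sqrt(N(S) + N(S_inv))

is approximately standard normal once the Poisson mean is large enough
for the CLT (lambda of a few tens). |Z| then follows the half-normal
distribution with mean sqrt(2/pi) ~ 0.798 and sd sqrt(1 - 2/pi) ~ 0.603,
which rounds to the (0.8, 0.6) signature of the null. The same algebra
yields the logarithmic growth of the k-limit with sequence length:
requiring E_k[X] = 0.8 c_k (4^k / 2L)^(1/2) to stay below a threshold
gives k < ln(L)/ln(4) + const, slope 1/ln4 ~ 0.72 per ln of length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .kmer_stats import KmerCountTable, PairScheme, SchemeKind, partner_indices

__all__ = [
    "HalfNormalMoments",
    "PoissonPairSimConfig",
    "CkEstimate",
    "halfnormal_moments",
    "predicted_absZ_moments",
    "simulate_poisson_pairs",
    "theoretical_klimit",
    "klimit_slope_per_ln_length",
    "estimate_ck",
]

# below this Poisson mean the normal approximation degrades noticeably
GAUSSIAN_LAMBDA_FLOOR = 30.0


@dataclass(frozen=True)
class HalfNormalMoments:
    """Moments of X = |Y| when Y ~ Gaussian(0, sigma_G)."""

    sigma_G: float
    mean_X: float
    sd_X: float
    ratio_sd_over_mean: float


@dataclass(frozen=True)
class PoissonPairSimConfig:
    """Simulation of iid Poisson count pairs under the symmetry null."""

    n_pairs: int
    lam: float | np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if np.any(np.asarray(self.lam) <= 0):
            raise ValueError("Poisson mean must be positive")


@dataclass(frozen=True)
class CkEstimate:
    """Average of f(S)^(-1/2), the slowly-varying factor in the k-limit law.

    f(S) = N(S) * 4^k / L is the count relative to the uniform
    expectation. ``c_k_weighted`` weights the average by |Z| (the form
    appearing in the k-limit derivation); ``c_k_plain`` is unweighted.
    """

    k: int
    c_k_weighted: float
    c_k_plain: float


def halfnormal_moments(sigma_G: float) -> HalfNormalMoments:
    """Closed-form half-normal moments: E[X] = sigma_G * sqrt(2/pi), etc."""
    if sigma_G <= 0:
        raise ValueError("sigma_G must be positive")
    mean = sigma_G * math.sqrt(2 / math.pi)
    sd = sigma_G * math.sqrt(1 - 2 / math.pi)
    return HalfNormalMoments(sigma_G, mean, sd, sd / mean)


def predicted_absZ_moments() -> tuple[float, float]:
    """(mean, sd) of |Z| under the null: (sqrt(2/pi), sqrt(1-2/pi)) ~ (0.8, 0.6)."""
    m = halfnormal_moments(1.0)
    return m.mean_X, m.sd_X


def simulate_poisson_pairs(cfg: PoissonPairSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw (N, N*) pairs iid Poisson(lam); reproducible from cfg.seed."""
    if np.any(np.asarray(cfg.lam) < GAUSSIAN_LAMBDA_FLOOR):
        warnings.warn(
            f"Poisson mean below {GAUSSIAN_LAMBDA_FLOOR:g}: Z will deviate "
            "from standard normal",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    N = rng.poisson(cfg.lam, size=cfg.n_pairs)
    N_star = rng.poisson(cfg.lam, size=cfg.n_pairs)
    return N, N_star


def theoretical_klimit(L: float, c_k: float = 1.0, threshold: float = 0.1) -> float:
    """The real k at which the null predicts E_k[X] reaches the threshold.

    Solves 0.8 * c_k * (4^k / 2L)^(1/2) = threshold for k, i.e.

        k = ln(2 L (threshold / (0.8 c_k))^2) / ln 4.

    The 0.8 is the asymptotic E[|Z|] of the null; c_k is the
    slowly-varying count-dispersion factor, near 1 in practice. The
    threshold defaults to the conventional 0.1 criterion but is a free
    choice.
    """
    if L <= 0 or c_k <= 0 or threshold <= 0:
        raise ValueError("L, c_k and threshold must be positive")
    mean_absZ = math.sqrt(2 / math.pi)
    return math.log(2 * L * (threshold / (mean_absZ * c_k)) ** 2) / math.log(4)


def klimit_slope_per_ln_length() -> float:
    """d(k-limit)/d(ln L) = 1/ln 4 ~ 0.72, independent of threshold and c_k."""
    return 1 / math.log(4)


def estimate_ck(table: KmerCountTable) -> CkEstimate:
    """Estimate c_k = <f(S)^(-1/2)> from an empirical count table.

    Zero-count k-mers are excluded (their f^(-1/2) diverges and they do
    not participate in the |Z| mass at the relevant k). Both the
    |Z|-weighted form (the one entering the k-limit derivation) and the
    unweighted average are returned.
    """
    N = table.counts.astype(np.float64)
    nz = N > 0
    if not nz.any():
        raise ValueError("no nonzero counts: c_k undefined")
    f = N * (4.0**table.k) / table.n_positions
    invsqrt_f = np.zeros_like(f)
    invsqrt_f[nz] = f[nz] ** -0.5
    plain = float(invsqrt_f[nz].mean())

    partner = partner_indices(table.k, PairScheme(SchemeKind.INVERSE))
    total = N + N[partner]
    with np.errstate(invalid="ignore", divide="ignore"):
        absZ = np.abs(N - N[partner]) / np.sqrt(total)
    w = np.where(nz & (total > 0), absZ, 0.0)
    weighted = float((invsqrt_f * w).sum() / w.sum()) if w.sum() > 0 else plain
    return CkEstimate(table.k, weighted, plain)
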