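"""Low-k deviations from inversion symmetry: skew and gene-strand tests.

At k = 1 inversion symmetry is the second Chargaff rule, #T = #A and
#G = #C on a single strand. Deviations are tiny in relative terms (Y of
order 10^-3 on human chromosomes) yet highly significant under the
Poisson null, because Z = Y * sqrt(pair total) scales with the square
root of chromosome length. The same Z test applies to gene counts on the
plus vs minus strand, and the two families of tests can be checked for
concordance: chromosomes where the plus strand carries both more T than
A, more G than C, and more genes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kmer_stats import KmerCountTable, PairScheme, SchemeKind, decode_kmer, partner_indices

__all__ = [
    "NucleotideSkewResult",
    "GeneStrandResult",
    "ConcordanceResult",
    "skew_from_ratio",
    "nucleotide_skew_test",
    "gene_strand_test",
    "kmer_pair_skew_table",
    "bh_fdr",
    "concordance",
    "load_reference_skews",
    "load_reference_gene_counts",
]


def _one_sided_p(Z: float) -> float:
    """P-value for the inequality in the observed direction: P(N(0,1) > |Z|)."""
    return float(stats.norm.sf(abs(Z)))


@dataclass(frozen=True)
class NucleotideSkewResult:
    """Strand skew test of #T vs #A and #G vs #C for one chromosome.

    Counts may be None when the result was built from published
    ratio/Z columns rather than from a sequence.
    """

    chrom: str
    n_T: int | None
    n_A: int | None
    n_G: int | None
    n_C: int | None
    ratio_TA: float
    ratio_GC: float
    Y_TA: float
    Y_GC: float
    Z_TA: float
    Z_GC: float
    p_TA: float
    p_GC: float
    q_TA: float | None = None
    q_GC: float | None = None

    @classmethod
    def from_ratio_and_z(
        cls, chrom: str, ratio_TA: float, ratio_GC: float, Z_TA: float, Z_GC: float
    ) -> "NucleotideSkewResult":
        return cls(
            chrom=chrom,
            n_T=None,
            n_A=None,
            n_G=None,
            n_C=None,
            ratio_TA=ratio_TA,
            ratio_GC=ratio_GC,
            Y_TA=skew_from_ratio(ratio_TA),
            Y_GC=skew_from_ratio(ratio_GC),
            Z_TA=Z_TA,
            Z_GC=Z_GC,
            p_TA=_one_sided_p(Z_TA),
            p_GC=_one_sided_p(Z_GC),
        )


@dataclass(frozen=True)
class GeneStrandResult:
    """Test of gene-count excess on the plus strand of one chromosome."""

    chrom: str
    n_P: int
    n_M: int
    Y_PM: float
    Z_PM: float
    p: float
    q: float | None = None


@dataclass
class ConcordanceResult:
    """Joint assessment of skew and gene-strand excesses across chromosomes.

    A chromosome is *considered* when all three tests (T vs A, G vs C,
    P vs M) are individually significant, and *concordant* when in
    addition all three excesses are positive. ``binomial_p`` is the
    two-sided binomial probability of the observed all-positive count
    among considered chromosomes under a fair-coin sign null.
    """

    n_considered: int
    n_concordant: int
    per_chrom_flags: pd.DataFrame
    binomial_p: float


def skew_from_ratio(r: float) -> float:
    """Y = (r - 1)/(r + 1), the normalized skew implied by a count ratio."""
    if r <= 0:
        raise ValueError("ratio must be positive")
    return (r - 1) / (r + 1)


def _pair_test(n1: int, n2: int) -> tuple[float, float, float]:
    """(Y, Z, one-sided p) for a count pair under the Poisson null."""
    total = n1 + n2
    if total <= 0:
        raise ValueError("pair total must be positive")
    Y = (n1 - n2) / total
    Z = (n1 - n2) / np.sqrt(total)
    return float(Y), float(Z), _one_sided_p(Z)


def nucleotide_skew_test(
    table: KmerCountTable, chrom: str = "", *, two_sided: bool = False
) -> NucleotideSkewResult:
    """Z tests of #T vs #A and #G vs #C from a k=1 count table.

    One-sided p-values in the observed direction by default (the
    convention for inequality tests of a directional excess); two-sided
    doubles them.
    """
    if table.k != 1:
        raise ValueError("nucleotide skew test requires a k=1 count table")
    n_A, n_C, n_G, n_T = (int(c) for c in table.counts)
    if n_T + n_A == 0 or n_G + n_C == 0:
        raise ValueError("zero pair total: skew undefined")
    Y_TA, Z_TA, p_TA = _pair_test(n_T, n_A)
    Y_GC, Z_GC, p_GC = _pair_test(n_G, n_C)
    if two_sided:
        p_TA, p_GC = min(1.0, 2 * p_TA), min(1.0, 2 * p_GC)
    return NucleotideSkewResult(
        chrom=chrom or table.source_id,
        n_T=n_T,
        n_A=n_A,
        n_G=n_G,
        n_C=n_C,
        ratio_TA=n_T / n_A if n_A else np.inf,
        ratio_GC=n_G / n_C if n_C else np.inf,
        Y_TA=Y_TA,
        Y_GC=Y_GC,
        Z_TA=Z_TA,
        Z_GC=Z_GC,
        p_TA=p_TA,
        p_GC=p_GC,
    )


def gene_strand_test(
    n_P: int, n_M: int, chrom: str = "", *, two_sided: bool = False
) -> GeneStrandResult:
    """Z test of gene-count excess on the plus strand."""
    Y, Z, p = _pair_test(n_P, n_M)
    if two_sided:
        p = min(1.0, 2 * p)
    return GeneStrandResult(chrom, n_P, n_M, Y, Z, p)


def kmer_pair_skew_table(table: KmerCountTable, *, two_sided: bool = False) -> pd.DataFrame:
    """Per-inverse-pair Z tests for arbitrary k (the k=2,3 generalization).

    One row per unordered inverse pair with nonzero total, columns
    (S, S_inv, N, N_inv, Y, Z, p, q); inverse palindromes are excluded
    (their pair difference is identically zero).
    """
    partner = partner_indices(table.k, PairScheme(SchemeKind.INVERSE))
    codes = np.arange(4**table.k)
    keep = codes < partner  # one row per unordered pair, no palindromes
    N = table.counts[keep]
    N_inv = table.counts[partner[keep]]
    total = N + N_inv
    nz = total > 0
    N, N_inv, total = N[nz], N_inv[nz], total[nz]
    sel = codes[keep][nz]
    Y = (N - N_inv) / total
    Z = (N - N_inv) / np.sqrt(total)
    p = stats.norm.sf(np.abs(Z))
    if two_sided:
        p = np.minimum(1.0, 2 * p)
    df = pd.DataFrame(
        {
            "S": [decode_kmer(int(c), table.k) for c in sel],
            "S_inv": [decode_kmer(int(partner[c]), table.k) for c in sel],
            "N": N,
            "N_inv": N_inv,
            "Y": Y,
            "Z": Z,
            "p": p,
        }
    )
    df["q"] = bh_fdr(df["p"].tolist())
    return df


def bh_fdr(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, each >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def attach_fdr(
    skews: list[NucleotideSkewResult], genes: list[GeneStrandResult]
) -> tuple[list[NucleotideSkewResult], list[GeneStrandResult]]:
    """BH-adjust each test family (all chromosomes, per statistic)."""
    q_TA = bh_fdr([s.p_TA for s in skews])
    q_GC = bh_fdr([s.p_GC for s in skews])
    q_g = bh_fdr([g.p for g in genes])
    skews = [replace(s, q_TA=qt, q_GC=qg) for s, qt, qg in zip(skews, q_TA, q_GC)]
    genes = [replace(g, q=q) for g, q in zip(genes, q_g)]
    return skews, genes


def concordance(
    skews: list[NucleotideSkewResult],
    genes: list[GeneStrandResult],
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Count chromosomes whose T>A, G>C and gene P>M excesses all agree.

    Significance per test uses the raw one-sided p against ``alpha``
    (BH q-values are attached to the flags table for reference).
    Chromosome sets must match between the two inputs.
    """
    skew_by = {s.chrom: s for s in skews}
    gene_by = {g.chrom: g for g in genes}
    if set(skew_by) != set(gene_by):
        raise ValueError("skew and gene results cover different chromosome sets")
    skews, genes = attach_fdr(
        [skew_by[c] for c in skew_by], [gene_by[c] for c in skew_by]
    )
    rows = []
    for s, g in zip(skews, genes):
        sig = (s.p_TA < alpha) and (s.p_GC < alpha) and (g.p < alpha)
        positive = (s.Z_TA > 0) and (s.Z_GC > 0) and (g.Z_PM > 0)
        rows.append(
            {
                "chrom": s.chrom,
                "Z_TA": s.Z_TA,
                "Z_GC": s.Z_GC,
                "Z_PM": g.Z_PM,
                "p_TA": s.p_TA,
                "p_GC": s.p_GC,
                "p_PM": g.p,
                "q_TA": s.q_TA,
                "q_GC": s.q_GC,
                "q_PM": g.q,
                "all_significant": sig,
                "all_positive": positive,
                "concordant": sig and positive,
            }
        )
    flags = pd.DataFrame(rows)
    n_considered = int(flags["all_significant"].sum())
    n_concordant = int(flags["concordant"].sum())
    if n_considered:
        binom_p = float(
            stats.binomtest(n_concordant, n_considered, 0.5, alternative="two-sided").pvalue
        )
    else:
        binom_p = float("nan")
    return ConcordanceResult(n_considered, n_concordant, flags, binom_p)


def load_reference_skews() -> list[NucleotideSkewResult]:
    """Published HG38 per-chromosome skew results shipped with the package."""
    ref = importlib.resources.files("invsym.data") / "human_nucleotide_skew.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [
        NucleotideSkewResult.from_ratio_and_z(
            r.chrom, r.ratio_TA, r.ratio_GC, r.Z_TA, r.Z_GC
        )
        for r in df.itertuples()
    ]


def load_reference_gene_counts() -> list[GeneStrandResult]:
    """Published HG38 per-chromosome gene strand counts, tested on load."""
    ref = importlib.resources.files("invsym.data") / "human_gene_strand.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return [gene_strand_test(r.n_plus, r.n_minus, r.chrom) for r in df.itertuples()]
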