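# Methods

## Statistics and conventions

For a k-mer S with count N(S) on the analyzed strand and a partner S\*
under a pairing scheme, the package computes
X = |N − N\*|/(N + N\*), its signed version Y, and the
variance-stabilized Z = (N − N\*)/√(N + N\*). The per-k summary E_k[X]
averages X over **ordered** k-mers with nonzero pair total; X is
symmetric in the pair, so this equals the unordered-pair average, and
the divisor M_k is the number of k-mers observed at least once (N(S) > 0
and/or N(S\*) > 0). k-mers whose whole pair is absent ("null pairs") are
excluded from all averages and reported as
null_fraction = (4^k − M_k)/4^k. Palindromic k-mers under a scheme
(e.g. inverse palindromes at even k) contribute X = 0 and are kept in
M_k; they slightly deflate E_k[X], which is the convention throughout.
Z is excluded (not zero-filled) from |Z| moments when N + N\* = 0.
|Z| standard deviations are population (ddof = 0) moments.

Counting scans the provided strand only, with overlapping windows at
step 1; any window containing a non-ACGT character contributes nothing.
The number of valid windows, `n_positions`, serves as the effective
length L in every normalization — assembly gaps and excluded soft-masked
runs therefore shorten L rather than diluting frequencies. k-mers are
encoded base-4 (A=0, C=1, G=2, T=3, most-significant base first), so
array index order is lexicographic order. A memory guard refuses k > 15
(4^15 int64 counts ≈ 8 GiB) unless explicitly overridden.

Soft-masking is a user policy: `include_soft` case-folds lowercase
bases (bare-chromosome analysis), `exclude_soft` turns them into N
(masked analysis). Ambiguity codes are mapped to N rather than rejected,
since real assemblies contain them and non-ACGT windows are skipped
anyway.

The X histogram uses fixed bins of width 0.02 on [0, 1]. The random
pairing scheme is a seeded Fisher–Yates permutation of the 4^k codes
taken in adjacent pairs — a perfect matching without self-pairs
(4^k is even), reproducible from its seed, and an involution like the
inverse and reverse schemes.

The alternative S1 index, 1 − Σ|N(S) − N(S_inv)| / Σ(N(S) + N(S_inv)),
is provided for comparison; its denominator equals twice the effective
length. On spectra with genome-like count dispersion E_k[X] ≈ 2(1 − S1):
E_k[X] weights rare and abundant k-mers equally while S1 is dominated by
abundant ones, and the factor approaches exp(σ²/2) for log-dispersion σ²
of the count spectrum, hence ≈ 2 at σ² = 2 ln 2 — the regime the
comparison test constructs explicitly.

## The IS-Poisson null model

If N(S) and N(S_inv) are iid Poisson with a common mean, their
difference over √(sum) is approximately standard normal once the mean
exceeds a few tens (the simulator warns below λ = 30). |Z| then follows
a half-normal law with mean √(2/π) ≈ 0.798 and sd √(1 − 2/π) ≈ 0.603
(ratio 0.755); rounded to one decimal this is the (0.8, 0.6) signature
used as the empirical fingerprint of symmetry-plus-noise. In this regime
E_k[X] ≈ 0.8·c_k·(4^k/2L)^½, where c_k is the average of f(S)^(−½)
(f(S) = N(S)·4^k/L, count relative to uniform) within the |Z|
weighting. Requiring E_k[X] below a threshold t gives the k-limit bound

    k < ln(2L·(t/(0.8 c_k))²) / ln 4,

whose slope in ln L is exactly 1/ln 4 ≈ 0.72 regardless of t and c_k.
The threshold defaults to the conventional 0.1 but is configurable — it
is a convention, not a derived constant. `estimate_ck` defaults c_k = 1
when no counts are supplied (it is a slowly varying factor near 1);
zero-count k-mers are excluded from the c_k average since their f^(−½)
diverges.

The k-limit rule defaults to *closest to target* (argmin |E_k[X] − t|,
ties to the smaller k, linear distance taken literally); a *last below
target* rule is provided for section-style analyses that impose
E_k[X] ≤ t. With E_k[X] roughly doubling per k the two rarely disagree.
Window scans tile non-overlapping windows from coordinate 0 (0-based,
half-open) and drop a trailing partial window so all windows share one
length; the section-level criterion uses the mean of per-window E_k[X],
not pooled counts. The KL-vs-ln L law is fitted by ordinary least
squares of KL on ln(length).

## Low-k deviation tests

The k = 1 tests compare #T vs #A and #G vs #C via the same Z statistic;
p-values are one-sided in the observed direction (inequality tests of a
directional excess; two-sided available by flag), and the identical test
applies to gene counts on the plus vs minus strand. Benjamini–Hochberg
adjustment is applied per family (all chromosomes, one statistic). The
concordance summary counts chromosomes where all three excesses
(T over A, G over C, genes on plus) are individually significant at the
raw one-sided α (q-values are attached for reference, and at the
shipped tables' magnitudes the raw-p and q decisions coincide) and share
the positive sign; a two-sided binomial test at sign probability ½
summarizes how surprising the all-positive count is among the considered
chromosomes. A generalization to arbitrary k reports per-inverse-pair
(S, S_inv, Z, p, q) tables with palindromes excluded.

Shipped reference tables (package data, plain TSV): 22 published
(length, k-limit) points; per-chromosome human skew ratios with their Z
values; and per-chromosome gene strand counts. Two chr1 skew Z entries
were garbled in the source material and are stored as approximate
reconstructions (Y·√(pair total) at the known chromosome length); they
are flagged in the file header and used only for sign/significance,
which the reconstruction cannot affect.

## Rearrangement simulator

A model chromosome is built from a small seed sequence by concatenating
substrings drawn with uniform start and uniform length (default range
1–16 kb — the construction needs pieces long enough to carry local k-mer
structure but short enough to mix; the range is configurable because no
canonical choice exists), then truncated to the target length. Each
rearrangement event inverts (reverse-complements in place) a segment
with uniform start and uniform length in [2, max_segment_length],
clipped at the right end — chromosomes are modeled as linear, so events
never wrap. Inversions conserve length exactly and the pooled
{#A+#T, #C+#G} composition; nested and overlapping events arise
naturally from independent draws. Because each event swaps k-mer content
between S and S_inv, accumulated events drive E_k[X] down toward the
Poisson noise floor even for strongly skewed seeds. Default scales are
desk-sized (a few hundred kb to a few Mb, 10³–10⁵ events); the qualitative
trend — monotone decrease of E_k[X] until a noise floor — is
scale-robust, which is what the tests assert.

## Synthetic data: what it emulates and what it does not

The generators produce (a) `perfect_is`: W + revcomp(W), which is
exactly self-inverse, so E_k[X] = 0 up to the generic junction bound
2(k−1)/n_positions (even length required; the bound is conservative);
(b) `iid`: independent draws from given base probabilities — symmetric
in expectation, with E_k[X] equal to pure sampling noise; (c) `skewed`:
iid with probabilities solved to hit target #T/#A and #G/#C expected
count ratios within fixed AT/GC pools (an exact-count multiset-shuffle
variant exists for deterministic tests); (d) `motif_repeat`: a tiled
motif, strongly asymmetric unless the motif is an inverse palindrome.
Poisson count tables are drawn directly per k-mer (scalar, array, or
callable means; symmetric means give the null), and gene tables draw
strands Bernoulli(p_plus). All generators are bit-reproducible from
their seed.

These inputs deliberately lack repeat families, CpG-island clustering,
isochores, and long-range correlation, so green tests demonstrate
correctness of the statistics and the internal consistency of the null
model — not that any real genome satisfies inversion symmetry. Real
FASTA input (plain or gzipped, soft- or hard-masked) is supported for
that purpose but never required by the test suite.

## Problem sizes and numerical choices

The test suite runs entirely on generated data: Poisson simulations at
65,536 pairs, sequences of 10⁴–10⁷ bp (the synthetic scaling-law check
uses one i.i.d. replicate per decade of length, with the profile scan
stopped once E_k[X] clearly exceeds the target), rearrangement runs of
2×10⁵–3×10⁵ bp with up to 2×10⁴ events, and 200–1000 replicates for
power and type-I-error calibration. The type-I/power checks draw base
counts directly as multinomial vectors (the sufficient statistic for the
k = 1 test), with one replicate routed through full sequence generation
to pin the equivalence; the power check uses a #T/#A ratio of 1.01 at
1 Mb, the smallest effect with essentially full one-sided power at that
length (expected Z ≈ 3.5). Floating-point comparisons in tests use
absolute tolerances at the precision each published value carries, and
statistical assertions use fixed seeds with 2–3σ bands.

## Known limitations

- Canonical-k-mer collapsing is deliberately absent: counts are
  strand-explicit, since the symmetry between a strand and itself is the
  object of study.
- No Markov / residual-symmetry analysis: a k-order Markov fit cannot
  by itself generate the higher-order statistic, and testing residual
  symmetry is out of scope.
- The null-pair fraction is defined as (4^k − M_k)/4^k, a proportion in
  [0, 1] by construction; alternative denominators can yield values
  above 1 on short genomes and are not reproduced.
- `estimate_ck` on sparse tables (large k) is sensitive to the excluded
  zero-count set; interpret it only where most k-mers are realized —
  the same regime where the k-limit formula applies.
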