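# Methods

This note documents the models implemented in `sigrev`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical decisions a user should know before trusting the output.

## Differential expression and signatures

The test is an empirical-Bayes moderated t. Per-gene sample variances `s²`
with `df` residual degrees of freedom are assumed exchangeable under a
scaled inverse-chi-square prior with hyperparameters `(d0, s0²)`. The prior
is fitted by moment-matching on `e = log s² − ψ(df/2) + log(df/2)`: the
excess of `Var(e)` over the sampling term `ψ′(df/2)` identifies `ψ′(d0/2)`,
inverted by Newton iteration on the trigamma function; the mean of `e`
then identifies `s0²`. Two degenerate regimes are handled explicitly:

- `Var(e) ≤ ψ′(df/2)` (variances essentially constant): `d0 = ∞` and
  `s0²` is the geometric mean variance; the statistic becomes a z-style
  test with variance `s0²` exactly.
- `d0 = 0` is allowed as the prior-free limit and reproduces the ordinary
  pooled-variance two-sample t exactly.

p-values come from the t distribution with `d0 + df` degrees of freedom and
are BH-adjusted (delegated to `statsmodels`; verified in-suite against a
direct step-up enumeration). Genes with zero variance in both groups and an
infinite-width test are reported at p = 1 with a flag rather than NaN.

Count matrices are converted to log2-CPM with a pseudo-count of 0.5 before
the moderated t. This is a deliberate simplification relative to a negative
binomial count model: at the 30+30 sample sizes and 2-unit planted fold
changes this pipeline targets, the log-CPM route recovers the planted genes
with recall ≥ 0.99 and empirical FDR ≈ 0 (measured by the acceptance
script); users analyzing shallow counts or tiny groups should prefer a
dedicated count model.

Signature cutoffs are `|log2FC| > 1` and `padj < 0.001`. "Fold-change > 1"
is read on the log2 scale (i.e. a 2-fold linear change); duplicate gene
labels (multiple probes) collapse to the lowest-p row before thresholding.

Matched-normal selection projects tumors and the normal pool into a
20-component PCA latent space fitted on the pooled samples and ranks pool
samples by their median Spearman correlation to the tumor samples there.
This replaces autoencoder-based matching used by large web platforms with a
deterministic, desk-scale analogue of the same intent; ties break
lexicographically by sample label.

The cross-signature "top DEG" ranking orders genes present in every
signature by the L1 norm of their |log2FC| vector across signatures,
descending. The upstream tooling this emulates does not define its
Manhattan-distance ranking operationally; this is our stated
interpretation.

## Reversal scoring

The enrichment score is the classic connectivity-map weighted-threshold KS
statistic with equal gene weights and the two-sided max rule (formula in
the README). Ties in the `a ≥ b` comparison take the positive branch for
determinism. Exact discreteness facts worth knowing:

- a set occupying the top `s` ranks of `N` scores `1 − s/N`, the bottom
  `s` ranks score `−(1 − (s−1)/N)`;
- consequently the extreme achievable |RGES| at `|U| = |D| = s` is
  `2 − (2s−1)/N` (≈ 1.899 at s = 50, N = 978), not 2 exactly.

RGES = ES_up − ES_down is zeroed when both scores share a sign: a profile
that pushes both the up- and down-set in the same direction is neither a
reverser nor a mimic. Signature genes absent from a profile's universe are
dropped for that profile (intersection semantics); an empty intersection is
an error naming the profile.

Dose/time adjustment: the reference condition is 10 µM / 24 h. The offsets
are the median over drugs of the mean RGES difference between non-reference
and reference profiles — a robust contrast rather than a fitted model,
adequate at library sizes where most drugs are inert. sRGES is then the
similarity-weighted mean of adjusted RGES per drug (missing cell lines get
weight 1, negative similarities clip to 0; all-zero weights fall back to
uniform with a warning).

Candidate rule: `sRGES < −0.25` AND raw RGES < −0.25 in ≥ 3 profiles
("more than two"), sorted ascending, top 100, duplicates across signatures
kept once at the lowest sRGES. Whether the support count should be read
per-profile or per-signature is ambiguous in the source toolchain; both
`srges` and `n_strong` are exposed so users can re-filter.

## Enrichment

Over-representation is the one-sided Fisher exact test (hypergeometric
upper tail) against an explicitly supplied background universe — the
universe is never guessed from the query. The combined score is
`−ln(p) · z` where `z` is the deviation of the observed significance rank
from its permutation-null mean (default 200 random query sets of matched
size, seeded), sign-flipped so larger = more enriched. This emulates the
EnrichR rank-correction z with a reproducible, self-contained null.
Consensus lists take the union of each signature's top-k terms by combined
score (k = 5 for pathway libraries, k = 20 for the cell-line variant) and
keep terms reaching `padj < 0.05` in at least one signature.

## Cell-line models and biomarkers

- **Similarity**: Spearman correlation between the signature's log2FC
  vector and each line's differential expression (line minus per-gene
  median across lines), restricted to U∪D; lines sharing < 10 signature
  genes are skipped with a warning.
- **Sensitivity**: normalized AUC = trapezoid of viability log2FC over
  log10 dose divided by the log10-dose span, so a flat curve at `v` has
  AUC = v and the value is invariant to rescaling the dose axis. The
  low-dose score is the mean viability at the `n_low = 3` smallest doses
  (≈ ≤ 0.16 µM on the default ladder). For monotone curves the low-dose
  score is always the least negative summary (AUC ≤ low-dose score ≤ 0).
  Correlations default to the AUC summary; per-dose values remain
  available, since an 8-point screen supports either.
- **Segment filter**: losses need ≥ 25 probes, gains ≥ 50 probes, cnLOH
  ≥ 5 Mb; intervals are 0-based half-open (a converter from 1-based
  inclusive is provided). Gene-level state is the type of the
  maximal-overlap retained segment; equal-overlap contradictions yield
  neutral with an ambiguity flag.
- **GISTIC-style categories** on `x = log2(copy ratio relative to ploidy
  + 1)` (neutral encodes to exactly 1): x < 0.3 → −2, < 0.8 → −1,
  ≤ 1.2 → 0, ≤ 1.55 → 1, else 2. Real GISTIC thresholds are
  sample-adaptive and not reproducible locally, so these bounds are fixed
  but configurable.
- **Dependency summary**: efficacy = 10th percentile of a gene's
  dependency scores across lines; selectivity = (median − 10th
  percentile) / (1.4826·MAD + ε). This is a stated simplification that
  preserves the efficacy/selectivity ranking semantics of interactive
  dependency browsers, not their exact definitions.

## Synthetic data: what it emulates and what it does not

The generators draw every input from one seed via
`SeedSequence(seed, spawn_key=(k,))` (k = 0 truth, 1 cohorts, 2 library,
3 viability screen, 4 segments, 5 gene sets), so stages regenerate
independently and reruns are bit-identical. Ground truth (planted log2FCs,
reverser identities, the biomarker link) is a separate channel read only by
tests.

Default study conditions: 978-gene universe; 30 tumor + 30 normal samples;
10% DE genes at |log2FC| = 2; variance prior d0 = 4, s0² = 0.05; 200 drugs
with 20 reversers at strength 0.8 profiled on 4 cell lines × an 8-point
4-fold dose ladder from 10 µM down to ~600 pM at 24 h; profile noise
sd 0.5; a 30-line viability screen with six biomarker-linked drugs at
planted CN–sensitivity Pearson r = −0.8. Reverser profiles subtract
`strength · potency(dose) · log2FC` with `potency(d) = d/(d+1)` — a
saturating law under which the 10 µM reference dose is near-maximal
(potency 10/11), mirroring typical perturbation-library dosing. Counts
mode uses a negative binomial with dispersion 0.1. Curve amplitudes are
capped at 0 (a drug is at worst inert) so noiseless viability is monotone
non-increasing in dose.

Not emulated: probe-level microarray artifacts, batch effects, inference
of full transcriptomes from landmark genes, chemical-structure clustering,
dependency-score estimation from raw screens, batch alignment of tumor and
cell-line expression, molecular subtyping, survival analysis. Passing
tests therefore demonstrate correctness of the statistical machinery and
decision rules under clean planted-effect conditions, not robustness to
the technical structure of real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance script use 978–20,000-gene simulations,
200-drug libraries (6,400 profiles) and 100-seed repetitions for the
correlation-recovery checks; these sizes give stable pass/fail behavior
for every planted effect while keeping a full run in the order of a
minute. Library scoring ranks all profiles in one vectorized pass and is
verified against the per-profile scalar path. The trigamma inversion runs
Newton to a 1e-10 relative step; BH outputs are clipped to [p, 1];
correlation rows with zero-variance features are flagged rather than
dropped silently.

## Known limitations

- The moderated t on log-CPM is an approximation for counts (above).
- The permutation null for the combined score costs `n_null` ORA passes
  per query size; for very large libraries users may want to lower
  `n_null` from 200 (minimum 100).
- The dose/time offset estimator needs drugs observed at both reference
  and non-reference conditions; otherwise it returns 0 with a warning
  (the default synthetic library has a single 24 h time point, so the
  time offset is always 0 there).
- Gene-level CN calls use maximal overlap, not length-weighted consensus;
  genes straddling many small segments may be called neutral.
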