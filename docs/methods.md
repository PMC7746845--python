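# Methods

`reopair` implements a two-part analysis for drug-response transcriptomics:
(1) selecting a resistant/sensitive cell-line experiment that best
represents clinical tissue, by sign-concordance of differential-expression
directions with survival-gene directions; and (2) building a
relative-expression-ordering (REO) gene-pair signature that predicts
relapse-free survival (RFS) from nothing but within-sample gene orderings.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic data does and does not establish.

## Survival screening

Each gene is tested with a univariate Cox proportional-hazards model,
h(t | x) = h0(t) · exp(βx), fitted by Newton–Raphson on the Efron partial
likelihood (Efron tie handling is the default of the major survival
libraries and behaves better than Breslow with tied event times). P-values
are two-sided Wald; the screen adjusts them with Benjamini–Hochberg and
keeps genes at q < `tissue_fdr` (default 0.2), tagged +1 when β > 0
(risk-increasing, comparable to "up in resistant") and −1 otherwise.

Numerical details: covariates are centered before fitting (the partial
likelihood is shift-invariant, the exponentials are not); convergence is
|score| < 1e−9 or 50 iterations with step-halving; a constant covariate
returns a degenerate fit (β = 0, p = 1, flagged); monotone likelihood
(separation) is detected when |β| escapes past 15 during iteration — the
fit is flagged non-converged with p undefined and the gene is excluded
from screening rather than surfacing as a spurious top hit.

A single-covariate fitter is implemented in the package because the
screening stages call it once per gene and once per candidate gene pair
(tens of thousands of fits); the test suite cross-checks it against
lifelines and against a brute-force partial-likelihood grid search.

## Differential expression (SAM)

Between resistant and sensitive cell lines the moderated statistic is
d_g = (mean_R − mean_S) / (s_g + s0), with s_g the pooled two-group
standard error and s0 a fudge factor stabilizing low-variance genes.
s0 = "auto" follows the Tusher-style exchangeability procedure: candidates
are the 0, 5, …, 100th percentiles of {s_g}; the candidate minimizing the
coefficient of variation of window-wise mad(d) across pooled-SE windows is
chosen (median of s_g as fallback for degenerate inputs). The choice is
logged and overridable.

The null distribution of |d| comes from group-label permutations computed
with the same s0. When the number of distinct label assignments is at most
`n_perm` (e.g. C(6,3) = 20 for a 3 vs 3 design) the assignments are
enumerated exhaustively, removing Monte-Carlo noise at typical cell-line
sample sizes; otherwise `n_perm` (default 1000) random assignments are
drawn. Per-gene q-values use the median false-call count,
q_g = median_perm #{|d*| ≥ |d_g|} / #{|d| ≥ |d_g|}, clipped to [0, 1] and
made monotone non-increasing in |d|; π0 is fixed at 1, which is
conservative. DEGs are genes with q < `deg_fdr` (default 0.2), signed by
the direction of d. Per-gene q-values (rather than a global Δ threshold)
make the FDR rule a simple filter.

## Concordance and cell-line model selection

For two signed gene lists, n is the size of the gene intersection and k
the number of intersecting genes with equal signs. Under the null that the
two analyses order genes independently, each overlapping gene agrees with
probability 1/2, so the significance of k is the one-sided binomial upper
tail P(X ≥ k), X ~ Binomial(n, 1/2). The test is one-sided by design —
only above-chance agreement is evidence of representativeness; there is no
two-sided option.

The tail is exact: rational arithmetic for n ≤ 64, otherwise a log-space
sum of pmf terms over the smaller side of the distribution (complemented
when k ≤ n/2). This keeps panel-scale tails near 1e−15 at full relative
accuracy and tails near 1 monotone; displayed values below 1e−16 print as
"<1.00E-16" while the float is retained.

BH adjustment is applied across the tissue-vs-cell-line panel (members
with an empty overlap are reported as NA and excluded from the BH family);
the pairwise cell-line table reports raw p. The representative cell line
is the panel member with the maximum consistency ratio among those with
adjusted p < 0.05; the pipeline stops with an explicit error when no
member qualifies (overridable).

Candidate genes are those significant in **every** tissue cohort with the
same sign and matching the representative cell line's DEG direction.

## Pathway over-representation

Hypergeometric upper tail P(X ≥ k) with N background genes, n query genes,
m set members in the background and k query∩set genes, BH-corrected across
tested sets. The background is the genes on the expression matrix (not the
genome), standard practice for array data; each set is intersected with
the background before m is counted, and sets with m = 0 are skipped.

## The REO pair signature

The primitive is the within-sample ordering indicator I(a > b): 1 iff gene
a is expressed strictly above gene b in that sample. It is invariant to
any strictly increasing per-sample transform, which is what makes pair
rules portable across platforms and batches; this invariance is asserted
end-to-end in the tests (exactly, not approximately). Equal values yield
0 — the sensitive-leaning call — a deterministic tie rule; ties have
probability zero on continuous data and occurrences are the caller's to
count.

**Step 1 (Set 1 → Set 2).** All C(n, 2) indicators over the candidate
genes are built; constant indicators (a gene always above another) are
dropped with a log message since they carry no information. Each remaining
indicator is fitted with the univariate Cox model, BH-adjusted, and kept at
q < `pair_fdr` (default 0.1). Retained pairs are orientation-normalized:
genes are swapped if β < 0, so "gene_hi above gene_lo" always votes high
risk with β > 0.

**Step 2 (Set 2 → Set 3).** Every non-empty subset of Set 2 is scored: a
sample is low risk when at least half of the subset's rules show the
sensitivity-associated ordering (indicator 0). "At least half" is read
inclusively (sensitive votes ≥ rules/2), which equals strict majority for
odd rule counts; a rule "votes sensitive" when its risk-oriented indicator
is 0, the only reading that aligns the vote with the Cox orientation. The
subset maximizing Harrell's C of the binary risk label (high = 1) is the
signature. The C-index predictor is the binary label, not the vote
fraction, because classification precedes scoring; the vote fraction
remains available as an alternative risk score.

Harrell's C counts pair (i, j) comparable iff t_i < t_j and subject i had
the event; concordant iff risk_i > risk_j; tied predicted risks contribute
0.5. Subset evaluation is vectorized through the comparable-pair matrix,
so the full 2^20 − 1 enumeration for a 20-pair Set 2 is feasible; ties in
C are broken toward smaller subsets, then lexicographic rule order, by
enumerating in that order and accepting only strict improvements. Set 2
sizes above 20 refuse exhaustive search unless the subset size is bounded;
a greedy forward search (add the best-improving rule until no improvement)
is the documented fallback for large Set 2.

Evaluation of a signature on a cohort reports group sizes, the
high-vs-low hazard ratio with Wald 95% CI, the two-group log-rank test
(via lifelines) and Kaplan–Meier step tables per group. If every sample
lands in one group the metrics are NaN with a warning, sizes still
reported.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, with known truth:

- **Cell line**: value = per-gene baseline (N(7, 1.5), log2-RMA-like)
  ± lfc/2 group shift for planted DE genes + N(0, noise_sd) noise.
  Defaults used in the analyses: 3 vs 3 samples, lfc = 3, noise_sd = 0.5 —
  large, clean effects, as engineered resistant-clone experiments show.
- **Tissue**: Gaussian expression (unit SD per gene); linear predictor
  η_s = Σ β_g x_{gs} over centered expression; event time
  T = H0⁻¹(−log U / e^η) (inverse cumulative-hazard transform, so the Cox
  model holds exactly); censoring C ~ Uniform(0, horizon) independent of
  covariates; time = min(T, C), event = [T ≤ C]. Baselines: exponential
  (rate/month) or Weibull. Defaults used: rate 0.015/month, horizon 120
  months, n = 250 — a ~50% event fraction over 10 years of follow-up,
  typical of long-run RFS cohorts.
- **Matched study**: the planted tissue genes reappear in the cell line
  with DEG sign equal to sign(β) for exactly round(ρ · n_planted) genes
  and the opposite sign for the rest, making the tissue/cell-line
  consistency hypothesis a tunable truth.
- **Pair-signature cohort**: hazard driven directly by planted pair
  orderings (each pair multiplies the hazard by e^{log_hr} in its risk
  orientation), for recovery tests of the pair engine.

One master seed spawns per-stage child seeds via `numpy.random
.SeedSequence`, so stages are independently reproducible and the whole
pipeline is byte-identical under a fixed seed.

What the generators do **not** emulate: probe-level noise, batch and
platform effects, correlated co-expression modules, non-proportional
hazards, informative censoring. Passing tests therefore establish
correctness of the statistical machinery and recoverability under the
model's own assumptions — not robustness to real-data violations of them.
(The REO invariance tests do establish the batch-robustness mechanism
itself, since monotone per-sample distortion is exactly what the indicator
is immune to.)

A known property worth flagging: with many simultaneously planted genes
the one-gene screening model is misspecified — the other planted genes act
as frailty and attenuate each univariate coefficient — so per-gene recovery
saturates below 100% even at large n (e.g. ~10–15 of 12–20 planted genes
at |β| = 1, n = 250–300). The analysis scripts and tests use planting
designs sized so that this attenuation is visible but not crippling; it
mirrors the real situation where univariate screens under-detect
polygenic survival signal.

## Problem sizes and runtime

The shipped analyses and tests run on 300-gene, 250-sample cohorts with a
12-gene planted truth, 3 vs 3 cell lines, and candidate sets of ~8 genes
(Set 1 = 28 pairs), completing in seconds; calibration tests use 100–200
replicates at n = 60. These sizes were chosen as the smallest at which
every stage's behavior (power, calibration, recovery) is clearly
expressed; all algorithms scale to array-scale inputs (the pair optimizer
is the only exponential step and is guarded as described).

## Known limitations

- Univariate screening only; no multivariate or penalized Cox.
- π0 = 1 in the SAM FDR makes the called-DEG count conservative.
- The exhaustive subset search optimizes training C-index with no inner
  validation, so the selected combination inherits winner's-curse optimism;
  held-out evaluation is the supported remedy.
- Expression ties break toward "sensitive"; on heavily rounded input this
  could bias votes (counted and logged, not corrected).
- Missing expression values are rejected, never imputed: imputation would
  silently corrupt within-sample orderings.
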