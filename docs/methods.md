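# Methods

## Problem setting

A reference gene for qPCR normalization must hold a near-constant transcript
level across every condition being compared. The package operationalizes the
search for such genes in a developmental series with two data layers: a
stage-wise RNA-seq RPKM matrix, used to *screen* candidates genome-wide, and
qPCR CT measurements of the short-listed candidates, used to *rank* their
stability and to *validate* them by normalizing known target genes back
against the RNA-seq profiles.

## Screening cascade

Per gene, over the ordered stages: min and max RPKM, the ratio
RPKM_max/min, the mean μ, sample SD, and CV = SD/μ. The cascade applies, in
order:

1. **expressed** — min RPKM ≥ `expressed_threshold` (default 0.17).
   "Expressed" is interpreted as expressed at *every* stage and the boundary
   is inclusive; this reading both suits a reference gene (which must be
   detectable in all conditions) and guarantees the max/min ratio is defined
   downstream. A gene whose minimum is 0 carries an undefined-ratio marker
   (NaN) and can never pass the stability filter.
2. **stability** — ratio < 2 and CV < 0.3, both strict.
3. **abundance** — min RPKM > 40, strict. The differing boundary conventions
   (inclusive for expression, strict here) follow the stated screen
   definitions exactly.
4. **top-N** — survivors sorted by ratio ascending; ties break by CV, then
   gene id (a deterministic, content-then-label rule). Default N = 5.
5. **annotation** — keep genes with one transcript, or two overlapping
   transcripts (one primer pair can capture both). Genes with ≥3 isoforms
   are dropped by default; `allow_multi_isoform=True` keeps them for users
   who accept isoform-specific primers. Missing annotation rows drop the
   gene with a warning (configurable).

Survivor sets are recorded at every stage and are invariantly nested. CV and
the max/min ratio are scale-free, so rescaling the whole matrix only moves
genes across the expression/abundance thresholds.

## Stability statistics

All four methods consume a replicate-collapsed CT matrix (genes g × samples
n). Technical replicates are averaged on the CT scale first (their SD is
kept as metadata); a flag-free alternative — feeding replicates as separate
samples — is available simply by not collapsing, but collapse-first is the
default because replicate noise is measurement noise, not biological signal.
Every SD in the package is the sample SD (n − 1); with n = 9 stages the
denominator choice is material, and the unbiased form is the safer default.

- **delta-CT.** statistic_i = mean_{j≠i} SD_s[CT_i(s) − CT_j(s)], in cycles.
- **geNorm.** Quantities q_i(s) = base^(min_s CT_i − CT_i(s)) with the
  per-gene minimum CT as calibrator — any per-gene affine calibrator yields
  identical results because it cancels in every pairwise ratio.
  M_i = mean_{j≠i} SD_s[log2(q_i/q_j)]. Since log2 q_i = (min CT_i − CT_i)·
  log2(base), at base 2 the full-set M is *identically* the delta-CT
  statistic; the test suite asserts this to 1e−12. Stepwise exclusion
  removes the highest-M gene (ties: the lexicographically last gene id, a
  deterministic choice) and recomputes until two genes remain; they form
  the most stable pair and share rank 1, the next gene taking rank 3. The
  reported per-gene M is the value at the step of exclusion (the shared
  two-gene M for the final pair). V_n/n+1 = SD_s[log2(NF_n/NF_{n+1})], with
  NF_n the geometric mean of the n most-stable genes' quantities, genes
  added in reverse exclusion order. V values are reported; no "V < 0.15"
  decision rule is applied.
- **BestKeeper.** Per gene: arithmetic and geometric mean CT, min, max, SD
  (cycles) and CV = 100·SD/mean (%); the index is the per-sample geometric
  mean CT over all candidates, and each gene's Pearson r against it is
  reported (NaN for a zero-variance gene). Ranking uses SD as the primary
  key and CV as tie-breaker: SD is in cycles — i.e. proportional to
  fold-change on the log2 scale — whereas CV divides by the mean CT, which
  mixes in the gene's absolute expression level.
- **NormFinder (single group).** With y = −CT (log2 expression up to an
  additive constant that cancels under double centering), residuals
  r_ij = y_ij − ȳ_i· − ȳ_·j + ȳ_·· give v_i = Σ_j r_ij²/(n−1). Taking
  expectations, E[v_i] = σ²_i(g−2)/g + Σ_k σ²_k / g²; inverting this linear
  system in closed form yields σ̂²_i = (g/(g−2))·v_i − Σv/((g−1)(g−2)).
  The estimator is unbiased but not non-negative at small n, so estimates
  are clamped at 0 before the square root; the stability value is σ̂_i.
  g ≥ 3 is required (the system is singular at g = 2). Groups (OP/RP) are
  analysed separately; no between-group bias term is estimated.

**Aggregation.** The cross-method rank is the geometric mean of the four
per-method ranks, re-ranked with shared ties. A method whose preconditions a
dataset cannot satisfy (e.g. g = 2 for geNorm) is skipped with a warning and
the aggregate uses the remaining methods.

## Normalization and validation

Comparative CT with equal-efficiency assumption: relative expression of
target t in sample s is 2^(−(CT_t(s) − CT_ref(s))), where CT_ref is the
arithmetic mean CT of the reference set — the log2 of the geometric mean of
their quantities, the standard multi-reference combination. No per-gene
efficiency correction is applied by default (the base is configurable).
An optional calibrator sample rescales the profile to 1 at that sample.

Concordance with RNA-seq is the Pearson r between log2 normalized expression
and log2 RPKM over stages matched by label (≥ 3 required). The log scale
makes r invariant to multiplicative rescaling of either profile, so no
inter-platform renormalization is needed; a linear-scale option exists.

Primer efficiency: least squares of CT on log2(dilution); slope b gives
E = 2^(1/b) − 1 and the QC pass requires R² > 0.99 and b > 0 (CT must rise
with dilution; a non-positive slope marks E undefined).

## Synthetic-data generator

The generator emulates a 9-stage developmental study at desk scale (default
2,000 genes: 12 designed-stable among 1,988 designed-variable; full scale is
a config change). Stable genes are log-normal around a constant mean
(log2 SD 0.05 → CV ≈ 0.035, comfortably inside the screen limits, with
means drawn above the abundance threshold); variable genes carry
mean-centered stage trends — monotone ramps, maternal-decay and
late-induction shapes, randomly oriented — with log2 amplitude 1.5–4
(max/min ratio ≥ 2^1.5 ≈ 2.8, outside the screen by construction) plus
log2 residual noise 0.15. CT data derive from the matrix via
CT = intercept − log2(RPKM) + δ_group,g + τ_g(s) + η, with per-gene priming
offsets δ ~ N(0, 0.5) (constant per gene, so they cancel from within-group
statistics by shift invariance), extra instability τ with σ ∈ [0.5, 1.5]
for variable genes only, and triplicate technical noise η ~ N(0, 0.1).
Noise is Normal on the CT (log2) scale throughout, matching the
multiplicative error structure of qPCR; with all noise at zero the CT
closed form is exact and quantities reconstruct to machine precision.
The intercept (34) places typical panel CTs in the 24–30 cycle range.

What the generator does **not** emulate: amplification curves and melt
curves, RNA-quality and reverse-transcription batch effects beyond a
per-gene constant, count noise at low expression, or correlated
co-regulation between genes. Passing recovery tests therefore shows the
statistics separate designed signal from designed noise under an idealized
log-normal model — not that any particular real gene is stable.

## Numerical choices and degenerate inputs

- Ranks are competition-style (1, 1, 3 on a tie) via exact float equality;
  deliberate symmetric constructions tie exactly, noisy data effectively
  never does.
- Zero-variance genes: delta-CT and geNorm SDs of 0 are legal; BestKeeper
  reports r as NaN and ranks the gene by SD alone.
- CT plausibility window 5–40 cycles: values outside are flagged in the
  dataset's validation report, never silently dropped.
- TSV round trips are bit-exact: writing uses shortest-repr floats and
  reading parses with Python's `float` (pandas' fast path can be 1 ulp off).
- Negative NormFinder variance estimates clamp to 0; at g = 6, n = 9 this is
  common for genuinely stable genes and simply ties them at stability 0.

## Problem sizes

The test suite and the acceptance script run synthetic studies at the sizes
the properties are stated for: 100 seeded 6-gene × 9-stage studies for
ranking recovery, 20 desk-scale (2,000-gene) screens, and NormFinder
recovery at g = 8, n = 500 over 20 seeds. The whole suite completes in a few
seconds on one CPU.

## Known limitations

- NormFinder is the single-group form; the two-group inter-group bias term
  of the original method is out of scope (groups are compared by running
  them separately, as the ranking workflow does).
- BestKeeper descriptive statistics use the SD rather than the original
  software's median absolute deviation; ranking by SD/CV is documented
  above and applied consistently.
- No efficiency-corrected (Pfaffl-style) ratio model; the comparative-CT
  base is configurable but uniform across genes.
- No statistical test is attached to the CV screen threshold; the filter is
  the plain inequality.
- Confidence intervals on fold changes and correlations are not computed.
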