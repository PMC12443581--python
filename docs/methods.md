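# Methods

## Assay model

A MeRIP two-channel array splits each transcript's molecules between two
dye channels: anti-m6A immunoprecipitation captures the methylated fraction
(labelled Cy5, the "IP" channel) and leaves the unmethylated remainder in
the supernatant (Cy3, "Sup"). Writing `E` for a transcript's latent log2
abundance and `m ∈ (0,1)` for its methylated fraction, the expected raw
intensities in one sample are

```
E[IP_raw]  = A · 2^E · m
E[Sup_raw] = A · 2^E · (1 − m)
```

with a global scanner scale `A`. After per-sample spike-in normalization
(below), the **m6A quantity** `IP_norm = log2(IP_raw) − anchor` estimates
`E + log2 m` up to a per-sample constant, and the **gene expression level**
`IP_norm + Sup_norm` estimates `2E + log2(m(1−m))`. Two consequences the
package makes explicit rather than hiding:

- the m6A quantity confounds methylation with abundance — a pure expression
  shift of δ log2 units moves the m6A quantity by δ as well;
- the expression level is not exactly invariant to the methylated fraction:
  two equally abundant transcripts with fractions `m` and `m'` differ by
  `log2(m(1−m)) − log2(m'(1−m'))`. The noise-free closed-form tests assert
  exactly these identities rather than assuming invariance.

## Spike-in normalization

The per-sample, per-channel anchor is the arithmetic mean of log2 spike-in
raw intensities (the log2 geometric mean of the raws), subtracted from every
probe's log2 intensity. This makes all normalized values invariant to
per-sample, per-channel multiplicative rescaling — the property the unit
suite checks to 1e−9. By default every spike-in probe with positive signal
in a channel enters that channel's anchor ("all" policy); a "matched"
policy (positive controls for IP, negative for Sup) is available because
vendor pipelines differ and no single convention is universal. Samples with
no usable spike-in in a channel are excluded with a warning rather than
silently floored.

Nonpositive or unparseable raw intensities become missing values, never
floored to a pseudo-count: flooring would fabricate signal before the log2.
A probe-sample missing in one channel leaves the m6A quantity defined (if
IP is present) but the expression level undefined.

Multiple probes per transcript are collapsed to one value by the median of
normalized values (even counts: mean of the central pair), after
normalization; the median is robust to a single misbehaving probe and the
collapse-after-normalization order keeps the anchor a pure per-sample
constant.

## QC filtering

Probes flagged Present or Marginal in at least `min_present` samples
(default 3, counted across all arrays, not per group) are retained.
Spike-in probes are always retained because the normalization anchor must
survive filtering. The filter is idempotent and never alters intensities.

## Differential testing

Per transcript, the log2 fold change is `mean(group 2) − mean(group 1)` of
the normalized log2 values ("up" = higher in the second group, the
involuting phase in the motivating design) and the p-value is a two-sided
unpaired t-test. The pooled-variance (Student) form is the default: with
three replicates per group and Gaussian log2 noise it is exactly calibrated,
whereas the Welch form is markedly conservative at n = 3 (empirical type-I
rate ≈ 0.036 at the 0.05 level) and would distort the null-calibration
guarantee; Welch remains available via `equal_var=False` for genuinely
heteroscedastic designs. Degenerate inputs are handled explicitly: fewer
than two finite values in a group gives a missing p (class `ns`, logged);
zero variance in both groups gives p = 1 for equal means and the smallest
positive float for unequal means, flagged — significance is never
fabricated from a 0/0.

Calls require the linear fold change strictly beyond 1.5 (boundary
excluded) *and* p < 0.05. Unadjusted p is the default calling criterion;
BH-adjusted p-values (our own step-up implementation, cross-checked against
brute-force and statsmodels) are always reported and can drive calls via
`use_adjusted`. Summaries pool the four small RNA classes (pri-miRNA,
pre-miRNA, snoRNA, snRNA) into one sncRNA group alongside mRNA and lncRNA.

Sample clustering uses 1 − Pearson correlation with average linkage; an
undefined correlation (constant sample vector) becomes distance 1 with a
warning. The k = 2 cut labels and a Newick rendering are returned.

## Joint integration

Transcripts are inner-joined on ID across the two measures; a quadrant
(hyper/hypo × up/down, methylation direction first) is assigned only when
both measures pass the thresholds. The global association (Pearson and
Spearman, the latter because array fold changes are heavy-tailed) is
computed over all joined transcripts by default — restricting to
significant ones is a flag — since the quadrant filter truncates both axes
and inflates correlation estimates.

## qPCR calculators

`%input = 2^−Ct_MeRIP / (2^−Ct_MeRIP + 2^−Ct_Sup) × 100`, computed in an
overflow-safe logistic form; it satisfies `%input(a,b) + %input(b,a) = 100`
exactly and is strictly increasing in the Ct gap. Relative expression is
`2^−ΔΔCt` with `ΔΔCt = (Ct_t − Ct_ref) − (Ct_t,cal − Ct_ref,cal)`, invariant
to plate-wide Ct offsets. Duplicate wells are averaged on the Ct scale
(averaging linear quantities would bias low-quantity wells). Amplification
efficiency is fixed at 2, which both formulas assume; standard-curve
efficiency correction is out of scope. Group summaries use a Welch t-test
with the conventional star coding (* < 0.05, ** < 0.01, *** < 0.001); no
calibration guarantee constrains this test, and replicate counts in qPCR
practice vary enough that the unequal-variance form is the safer default.

## Over-representation analysis

One-sided (enrichment) Fisher exact test, i.e. the hypergeometric upper
tail `P(X ≥ k)` of the overlap, BH-corrected across terms — the
one-sidedness is the ORA convention. The universe is caller-supplied and
should be the QC-retained annotated transcripts, not the whole genome;
query genes outside it are dropped with a logged count, and terms with no
member in the universe are skipped. Gene symbols are matched uppercase.
Gene sets are read from GMT files; no GO/KEGG content is bundled, so
enriched-term lists depend entirely on the annotation the user supplies.
The bubble-plot summary `z = (n_up − n_down) / √k` quantifies the
directional bias of a term's overlap.

## Synthetic-data generator

The generator draws, per transcript, a log2 abundance `E ~ N(13, 1.5²)` and
a methylated fraction `m ~ Beta(2, 5)` (mean ≈ 0.29, consistent with a
minority-methylated transcriptome), then applies planted effects to group 2:
differential methylation as a ±2 shift on the log-odds of `m` (median true
methylation ratio ≈ 2.8 for gains, well above the 1.5 fold-change
threshold) and differential expression as a ±1 log2 shift of `E`.
Intensities get independent lognormal noise `2^N(0, 0.25²)` per
probe-sample-channel; with `A = 1` the raws land in a 16-bit-scanner-like
10²–10⁵ range. Spike-ins emit a fixed 5000-unit level split 0.9/0.1
(positive controls) or 0/1 (negative controls), noise-free and always
flagged Present; QC flags are Absent with probability 0.02, else Present.
Defaults mirror the motivating study's design: 2 groups × 3 arrays and a
54,832-transcript census (41,263 mRNA, 10,492 lncRNA, 1,431 pri-miRNA,
943 pre-miRNA, 684 snoRNA, 19 snRNA); planted-effect fractions default to
the few-percent range typical of the detected calls. The RNG is split into
independent streams (truth, per-array noise, flags) from one seed, so the
full output is bit-reproducible.

`couple_dm_de` makes planted methylation changes carry a same-sign
expression shift, for studying the joint analysis under coupling; without
it the DM and DE subsets are drawn independently.

The qPCR simulator generates `Ct = base − log2(quantity) + N(0, σ_ct)` with
duplicate wells, a shared endogenous reference at quantity 1, and paired
MeRIP/Supernatant fractions splitting a planted %input.

What the generator does *not* emulate — and therefore what passing tests do
not demonstrate about real arrays: probe-sequence and hybridization
effects, spatial artifacts and background, dye bias between Cy5 and Cy3,
correlated (batch) noise across probes, heavy-tailed outliers, and
transcript-length or GC biases. Results on real data additionally depend on
vendor flag semantics and spike-in chemistry that the simulation idealizes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration and recovery
benchmarks at 10,000 transcripts with 3 arrays per group — large enough
that the binomial Monte-Carlo band on a 5% rejection rate is ±0.65% (3σ)
and that 1,000 planted effects estimate sensitivity to about ±1%, while a
full run stays in the tens of seconds. The exhaustive Fisher oracle sweep
covers every 2×2 table with universe size ≤ 30. Float comparisons in tests
use 1e−9 relative tolerance (1e−12 for the pure rescaling identity);
BH adjustment and the hypergeometric tail are exact to machine precision
against brute force. Ties in the median collapse and in BH use stable
ordering, so results are independent of input row order.

## Known limitations

- The m6A quantity's abundance confound (above) means "differential
  methylation" calls mix methylation-fraction and expression changes; the
  joint analysis reports both measures side by side precisely because the
  single-measure calls are not independent.
- With three replicates per group the t-test has limited power near the
  1.5-fold boundary; the planted-recovery guarantee holds for the
  generator's default effect size, not for arbitrarily small shifts.
- Unadjusted-p calling at a 54k-transcript scale implies a substantial
  absolute number of false positives; the BH column is reported for any
  downstream use that needs FDR control.
- No between-array normalization beyond the spike-in anchor is applied; if
  spike-in chemistry drifts across arrays, that drift propagates.
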