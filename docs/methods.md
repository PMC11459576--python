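# Methods

This note documents the statistical model behind `steppanel`, the
choices made where the underlying assay workflow is conventionally
under-specified, and what the synthetic validation does and does not
demonstrate.

## Normalization chain

Raw probe counts from a hybridization-counting panel are processed in a
fixed order per sample *s*:

1. **Background floor.** `b_s = mean + k·SD` of the sample's
   negative-control probes (sample SD, `ddof = 1`; default `k = 2`,
   config `background.k_sd`). Counts are *floored* at `b_s`
   (`max(count, b_s)`), not background-subtracted: subtraction produces
   zeros/negatives that poison the subsequent log2, while the floor
   caps the dynamic range at the detection limit, which is the intended
   semantics of "below background".
2. **Positive-control scaling.** `p_s` is the ratio of the cohort
   geometric mean of per-sample positive-probe geometric means to the
   sample's own positive geometric mean. This compensates
   lane-to-lane hybridization/counting efficiency. By construction
   `gm_s(p_s) = 1` (enforced to 1e-9), so the cohort's overall scale is
   conserved.
3. **geNorm housekeeping selection.** Candidate stability is
   `M_j = mean_{k≠j} SD_s(log2 a_j − log2 a_k)` computed on log2
   positive-scaled counts; the highest-M gene is removed iteratively
   (recomputing M each round) down to two genes. The pairwise variation
   `V(n, n+1)` is the SD across samples of
   `log2(NF_n / NF_{n+1})`, `NF_n` being the geometric mean of the *n*
   most stable candidates. The selected set is the smallest
   `n ≥ min_housekeepers` (default 3) with `V < 0.15`
   (config `genorm.v_threshold`); if no *n* qualifies, all candidates
   are kept and a warning is emitted. Cohorts with fewer than 3
   housekeeping candidates or fewer than 3 samples skip elimination and
   use every housekeeper (the stability measure is undefined there).
4. **Housekeeping scaling.** `h_s` mirrors the positive factor but on
   the selected housekeepers of the positive-scaled matrix;
   `gm_s(h_s) = 1`. The total per-sample factor is `NF_s = p_s·h_s`.

The implementation computes M from the sample covariance matrix
(`Var(x_j − x_k) = V_jj + V_kk − 2V_jk`); its equivalence to the naive
double loop is asserted to 1e-10 on random instances in the test suite
and the acceptance script.

## Log2 ratios against the universal reference

`R_gs = log2(norm_gs) − log2(norm_g,ref(batch(s)))`, where `ref(b)` is
the batch's pooled-tissue universal mRNA reference lane. Ratios are
computed for endogenous and housekeeping genes only; control probes are
excluded. A reference lane against itself is exactly 0. If any retained
normalized count is zero (only possible when a lane's negative controls
are all zero, so `b_s = 0`), a pseudo-count of 0.5 (config
`ratio.pseudo_count`) is added throughout before log2. The ratio is
invariant to any common rescaling of a sample and its reference.

Interpretation of "universal reference genes" as *the per-gene
normalized counts of the dedicated reference lane run in the same
batch* is a deliberate reading: the reference exists precisely to
absorb batch effects, so the denominator must come from the same run.

## Calling and subtyping

High expression is `R ≥ cutoff` with the inclusive default 1.0; the
assay's earlier validation criterion 2.0 remains available. The
dominant transcription regulator is the argmax of the four regulator
ratios provided the maximum clears the cutoff, else `NONE`. Exact
floating-point ties return `TIE(members)` — silent alphabetical
tie-breaks would fabricate a biological ordering. Profile labels count
high regulators: `NONE_HIGH / SINGLE / DOUBLE / TRIPLE / QUAD`.

Cohort percentages render at one decimal with round-half-up by
default; a `truncate` mode exists because published reports mix the two
conventions (26/35 appearing as 74.2 rather than 74.3).

## Agreement and correlation statistics

The panel call is the *test*, the orthogonal assay the *reference*:
`PPA = tp/(tp+fn)`, `NPA = tn/(tn+fp)`, `PPV = tp/(tp+fp)`,
`NPV = tn/(tn+fn)`, `OPA = (tp+tn)/n`, each ×100 with a Wilson 95% CI
(standard for diagnostic agreement at small n; the interval is clamped
to contain the point estimate and to [0, 100]). An empty denominator
yields NOT-ASSESSABLE, never 0 or 100. Pooling across markers sums
cells first (micro-average) — the only pooling that reproduces a
per-marker set and its pooled percentages simultaneously. IHC
positivity is *strictly* H-score > 10 while panel positivity is
*inclusively* ≥ cutoff; the asymmetry is intentional and preserved.

`reconstruct_marker_tables` inverts printed agreement percentages to
cell counts by enumerating all 2×2 tables of the stated size and
keeping combinations whose (pooled) metrics round to the printed
one-decimal values; it errors unless the joint solution is unique. The
shipped 12-sample worked example is uniquely determined this way.

Paired correlations default to Pearson on the log2 scale
(`log2(v + 0.5)`) and Spearman on the linear scale; zero variance in
either vector raises a degenerate-input error instead of returning NaN.

## Cohort comparison

Between-group tests default to two-sided Mann–Whitney U on log2 ratios
(robust at the n = 25–160 group sizes typical here), with Welch's t as
an option, Benjamini–Hochberg q-values across all tested genes (raw p
is also reported), and direction from group medians at `q < 0.05`. The
high-mean screen uses the arithmetic mean of log2 ratios with the same
inclusive ≥ 1 threshold as calling.

## Heterogeneity

For one patient's multi-site samples: discordant genes are those called
high at some sites and not others; the dominant-switch flag compares
full dominant labels including `NONE` and `TIE` (sites with double-high
profiles make the 4-way restriction too coarse); pairwise site distance
is the Hamming distance over the four regulator calls. These are
deliberate operationalizations — the field has no standard named
statistic for intermetastatic subtype heterogeneity.

## Synthetic cohorts

The generator emulates, per batch, one universal-reference lane whose
endogenous means define the per-gene baseline, and tumor lanes with
counts `NB(mean = baseline·2^R_true·lane, Var = μ + α·μ²)`. Key
defaults (all overridable on `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_samples`, `n_batches` | 35, 4 | cohort shape of a typical SCLC panel study |
| `subtype_props` | A 0.74 / N 0.20 / P 0.03 / none 0.03 | observed SCLC dominant-subtype mix |
| `regulator_high_mean` / `low_mean` | 2.0 / −1.0 log2 | ≈4-fold above reference for the driving regulator, suppressed otherwise |
| `regulator_sd` | 0.5 log2 | biological spread of regulator expression |
| `nb_dispersion` (α) | 0.1 | quadratic count overdispersion; 0 = deterministic counts (the noiseless limit) |
| `lane_size_sd` | 0.2 (ln) | lane-to-lane size factors |
| `hk_sd` | 0.1 log2 | housekeeping lognormal noise, no subtype effect |
| `neg_mean` | 5 counts | Poisson background level |
| `pos_ladder` | 128…0.125 fM | noiseless positive ladder × lane factor |
| `baseline_count`, `baseline_log2_sd` | 512, 1.0 | per-gene baseline level and spread |
| `coupled_genes` | DLL3→ASCL1 | co-expressed targets follow their regulator |

Reference lanes receive **Poisson counting noise only**: the universal
reference is the same pooled RNA aliquot in every run, so the
overdispersion term — which models tumor-to-tumor biological
variability — does not apply to it. At `nb_dispersion = 0` every count
noise source collapses to the rounded mean, giving the exact-recovery
limit used to validate the pipeline algebra end to end (ratios equal
truth to <1e-6 with integer-valued means).

RNG discipline: each sample owns a `numpy` Philox/PCG stream keyed by
`(seed, sample index)`; gene-level baselines and the IHC/TPM links use
dedicated offset keys. Growing a cohort therefore never perturbs
existing samples, and identical configs are bit-reproducible.

Paired assays: IHC H-scores are
`clamp(0, 300, round(slope·max(0, 2^R_true − 1) + ε))` (slope 50 per
linear fold, noise SD 15) — monotone in expectation, zero for
expression at or below reference; RNA-Seq log2 TPM is
`intercept + R_true + ε` (intercept 3, noise SD 0.3).

**What the generator does not emulate:** tumor purity gradients, probe
cross-hybridization, batch-specific background drift, correlated gene
modules beyond the explicit regulator coupling, FFPE degradation, or
any real-cohort parameter fit (no raw clinical counts are public).
Passing recovery tests therefore demonstrates the *pipeline's*
correctness under the assumed noise model, not assay performance on
real tissue.

## Validation sizes and observed behavior

Suite and acceptance sizes were chosen to finish in tens of seconds on
one CPU while keeping Monte-Carlo error small: 200-seed recovery runs
(35 samples each), 200-rep null simulations (204 genes, 20 + 20
samples), 100-instance oracle comparisons, 500→300-seed correlation
power checks.

Under the default study conditions the acceptance script measures
normalization-factor recovery at Pearson r ≈ 0.98 and dominant-label
accuracy ≈ 91%. The accuracy ceiling is structural, not a bug: with
α = 0.1 the measured log2 ratio carries ≈0.45 SD of count noise, and a
truly-high regulator (mean 2.0, SD 0.5) then falls below the cutoff
1.0 with probability ≈ Φ(−1/√(0.5² + 0.45²)) ≈ 7%, so roughly that
fraction of driven samples is called `NONE`. Reaching ≥95% accuracy
requires either lower overdispersion (α ≲ 0.05), a wider
high-mean-to-cutoff margin, or truth defined after thresholding — the
defaults were kept as the study conditions rather than tuned.

## Known limitations

- geNorm tie-breaking (equal M) removes the lexicographically last
  gene; any deterministic rule is equally defensible.
- The V < 0.15 stopping rule is a convention, not a statistical test.
- Pooled agreement treats markers as exchangeable; per-marker CIs are
  not simultaneous.
- The Mann–Whitney default reports exact/asymptotic p-values as chosen
  by scipy; at very small groups the achievable significance levels
  are discrete.
- One RCC file is assumed to be one lane and one sample; multi-lane
  designs must be encoded in the sample sheet.
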