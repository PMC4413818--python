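# Methods

## Problem setting

Two experimental conditions (a, b), each with replicate ChIP-seq
libraries of the same transcription factor, plus optional matched input
(non-immunoprecipitated chromatin) libraries. Peak calls per condition
define where binding occurs; the analysis asks where binding *differs*.
Because the reference features are themselves derived from the data and
total bound protein can differ between conditions, between-sample
normalization is the step this package treats most carefully.

## Reference regions and counting

All coordinates are 0-based half-open (BED convention); two intervals
overlap iff `a.start < b.end and b.start < a.end` (≥ 1 shared base).
Peaks from all inputs are merged transitively under that rule into a
sorted, non-overlapping reference set; strand is ignored for peaks and
kept for reads. Chromosome names are compared as exact strings, with a
warning when two inputs share none. Condition-level comparisons report
shared/unique counts per reference set (a peak in one condition may
overlap several in the other, so counts are reference-dependent); when
more than one ordered pair is compared the lower median of the pairwise
shared counts is reported — a deterministic choice for even counts.

Reads are single-end tagAlign records. Before counting they are either
*shifted* — collapsed to the single base at 5′ + k along the strand,
approximating the fragment midpoint (default k = 75 bp) — or *extended*
to an assumed fragment length L from the 5′ end (default L = 200 bp,
used for the input-subtraction route). Fragment-length estimation from
cross-correlation is out of scope; both parameters are configuration and
are recorded in the run log. Counting is coverageBed-like: a read adds 1
to every region it overlaps, so with shift preprocessing each read hits
at most one region and the effective library size (in-peak reads) never
exceeds the full library size; an extended read can legitimately count
in two adjacent regions. Duplicate reads are retained. Subsampling is a
uniform draw without replacement via a seeded numpy PCG64 permutation,
reproducible across platforms.

## Count model and normalization offsets

Counts follow a negative binomial with variance μ + φμ² (edgeR's
parameterization; φ = 0 is Poisson). Per-sample means are
μ_gs = λ_g,cond(s) · exp(o_gs). Every normalization is expressed through
the log-scale offsets o_gs, so one testing code path serves all methods,
and offsets are identified only up to an additive constant (tests assert
that shifting all offsets changes nothing downstream).

- **full / effective library size**: o_s = log N_s with N the total
  mapped reads or the column sum over reference regions.
- **TMM**: against a reference column (auto-chosen as the sample whose
  scaled 75th count percentile is closest to the mean), M and A values
  are computed over regions positive in both samples, the extreme 30% of
  M and 5% of A are trimmed, and the remaining M are averaged with
  inverse delta-method variance weights; factors are re-anchored to
  geometric mean 1 and o_s = log(N_s f_s). Fewer than 10 surviving
  regions falls back to factor 1 with a warning. The library size N may
  be full or effective (both combinations are used by the composed
  methods).
- **shared-peak MA regression** ("MAnorm3" route): per condition the
  mean over replicates of log2((y + 0.5)/N_eff,s · 10⁶) gives x̄; over
  regions shared by both conditions' peak sets, OLS fits
  M = intercept + slope·A with M = x̄_a − x̄_b, A = ½(x̄_a + x̄_b). The
  fitted trend is split symmetrically: condition-a samples receive the
  per-region offset +ln2·(intercept + slope·A_g)/2 and condition-b
  samples the negative, so the adjusted M of shared peaks is centred on
  zero with zero slope — the re-fit on adjusted values is numerically
  zero (≤ 1e-8), which is asserted. Regions outside the shared set get
  the trend evaluated at their own A. Sample-level offsets are
  log N_eff,s: since the M/A values are computed on effective-size-
  normalized counts the intercept carries no depth information, and the
  per-sample term is what corrects sequencing-depth imbalance (the mean
  log effective size, the common scale, is kept in the fit diagnostics).
  With a constant sample offset instead, a five-fold depth difference
  would pass through to the test untouched; the per-sample form is the
  one that both centres shared peaks and normalizes depth, and is
  asymptotically identical to the original MAnorm formulation in which
  raw-count M-values let the regression intercept absorb depth.
- **input subtraction** (before offsets are computed, DiffBind
  ordering): adjusted counts are
  max(round(y_gs − b_g,input(s) · min(1, N_s/N_input)), floor) with full
  library sizes — background is only ever scaled *down* — and floor = 1
  so every region remains testable. Subtraction is monotone and floored,
  both asserted.

## Differential tests

**NB exact test.** Counts are summed within condition: a sum of n i.i.d.
NB(μ, φ) is exactly NB(nμ, φ/n), so the condition total has size
n/φ_g (replicate depths are equal within condition in the simulated
designs; with unequal offsets this is an approximation, cross-checked
against brute-force enumeration). Offsets enter as condition normalized
sizes S = Σ_s exp(o_gs). Conditioning on t = t_a + t_b, the mass of each
split (k, t−k) is proportional to
NB(k; μ_a = t·S_a/(S_a+S_b), n_a/φ) · NB(t−k; μ_b, n_b/φ); the
two-sided p-value is the normalized mass of all splits as or less
probable than the observed one (probability-mass rule, ties included
once with relative tolerance 1e-9). The implementation enumerates all
t + 1 splits exactly (vectorized in chunks of ≤ 2×10⁶ terms), so p-values
agree with an independent scipy-based enumeration to < 1e-10 and reduce
to the exact binomial test in the Poisson limit. t = 0 regions get
p = 1 and log2FC 0. Reported log2FC is
log2((t_a/S_a + ε)/(t_b/S_b + ε)) with ε = 0.5/min(S); the A-value is
½·log2 of the product of the CPM-scaled normalized means.

**Dispersion.** The common φ maximizes the mean per-region Cox–Reid
adjusted profile likelihood: at each candidate φ the group abundances λ
are profiled out by Newton iteration in log λ and ½·log of their Fisher
information is subtracted. The CR adjustment matters — plain profile
likelihood is biased low by the two fitted group means per six samples
and would miss its own recovery tolerance. Optimization is bounded
golden-section/Brent on log φ ∈ [10⁻⁶, 10]. Tagwise estimates maximize
APL_g(φ) + (prior_df/residual_df) · mean APL(φ) (default prior_df = 10),
with the shared mean-APL term precomputed on a 120-point log-φ grid and
cubic-spline interpolated, and a vectorized per-region golden-section
search; prior_df → ∞ recovers the common value (asserted to 1e-3) and
small prior_df approaches each region's individual maximum. The composed
pipelines use the common dispersion; tagwise moderation is available as
its own step.

**voom + moderated t.** log2 CPM with a 0.5 count and N+1 library
pseudo-offset; per-region group-means fit; a lowess trend (span 0.5) of
√(residual sd) against average log2 count; weights are the trend
evaluated at each cell's fitted log-count, clamped to the trend range
and raised to the −4th power. The moderated t-test uses weighted group
means, residual variances squeezed toward a scaled-F prior
s̃² = (d₀s₀² + d s²)/(d₀ + d), with (d₀, s₀²) moment-matched on log s²
via trigamma inversion (zero-variance regions excluded; d₀ = ∞ handled
as a normal reference, d₀ = 0 recovering the ordinary weighted t-test),
and d₀ + d degrees of freedom.

**FDR.** Benjamini–Hochberg step-up (statsmodels), significance at
FDR < 0.05 throughout by default.

**Composed methods** (`run_differential`): `edgeR_full` (full-library
offsets), `edgeR_effective_tmm` (TMM on effective sizes),
`diffbind_full` / `diffbind_effective` (input subtraction, then TMM on
full / effective sizes, extend-mode counting in the CLI), `manorm3`
(shared-peak MA offsets), `voom_full`. Note that with an all-zero input,
`diffbind_full` is still not bit-identical to `edgeR_full` because the
DiffBind rows include TMM factors; the composition is instead asserted
equal to its manually assembled stages.

## Synthetic data

The count simulator draws per-region baselines 2^N(6, 2) and sets the
ChIP mean for region g, sample s to

    μ_gs = baseline_g · (present_cond + β·c_g,cond) · 2^(±Δ_g/2) · N_s / norm

with background fraction β = 0.1, CNA dosage multiplier c (default 2,
single-copy gain) applied to the background term only, the treatment
effect ±Δ/2 applied symmetrically so the designed log2FC is exactly Δ,
and norm = Σ baseline·(1+β) so expected column totals match the nominal
library sizes under the null. Matched input libraries (same nominal
depth as their ChIP sample) measure exactly the background term
β·baseline·c, so full-library-scaled subtraction removes the CNA-driven
background in expectation; applying the dosage to the *whole* mean
instead would make subtraction cancel from the fold change identically
and no input correction could ever help. Counts are NB(μ, φ) (Poisson at
φ = 0), deterministic given the seed, with all latents recorded.

Scenario defaults are the desk-scale study conditions used throughout
the tests: 16,000 regions, 3 replicates per condition, 5×10⁶-read
libraries (10⁶ vs 5×10⁶ for the depth-imbalance null), φ = 0.05, and for
the global gain f = 0.8 of regions changed with Δ = 2. The read-level
generator places non-overlapping peaks on one synthetic chromosome
("chrSim", avoiding name-normalization issues), emits signal reads whose
5′ ends sit half a fragment length from the summit on their strand (±20
bp jitter) plus a β-share of uniform background reads, and writes valid
tagAlign/narrowPeak/sample-sheet files.

What the simulations do *not* emulate: mappability and GC structure,
duplicate reads, realistic fragment-length distributions, peak-calling
noise (peak locations are known), or background whose level varies along
the genome other than through CNA flags. Passing tests therefore
demonstrate the statistical behaviour of the normalization/testing
machinery under the designed conditions, not end-to-end performance on
real ENCODE-scale data.

## Behaviours the test suite pins down

- Null control: at equal depth both library-size methods call 0 of
  16,000 regions at FDR < 0.05 (fixed seed); at five-fold depth
  imbalance the shared-peak MA pipeline keeps false positives below 1%.
- Sign flip: under a global gain, effective-library/TMM normalization
  gives truly-unchanged regions a negative median log2FC (< −0.5) while
  full-library keeps |median| < 0.2 and finds strictly more significant
  regions; the shared-peak route also finds strictly fewer than
  full-library, its no-change assumption being violated.
- CNA: with CNA-inflated background and no true binding change, input
  subtraction removes the fold-change bias in CNA regions and lowers
  their raw p < 0.05 false-positive rate. The contrast is asserted on
  raw p-values because under a global null the BH-significant set is
  empty for both pipelines — the modest residual elevation after
  subtraction (extra variance contributed by the subtracted input
  counts) mirrors the modest effect sizes this correction shows in
  practice.
- Exactness and calibration: enumeration oracles (≤ 1e-10), empirical
  type-I error in [0.03, 0.07] at α = 0.05, moderated-t null p-values
  KS-close to uniform (< 0.02 at 20,000 regions), dispersion recovered
  within 20%, median log2FC within 0.15 of truth.

## Numerical and design notes

- Degenerate inputs: empty peak files parse to empty sets; all-empty
  merges warn and return empty references; zero-total regions are
  untestable (p = 1); zero-variance A in the MA fit sets slope 0 with a
  warning; fewer than 2 residual df fails fast in the voom route; no
  replication fails fast in dispersion estimation.
- The evaluation clustering uses Gower's distance — range-normalized
  weighted Manhattan over the union of each run's top-k (default 100)
  regions ranked by FDR with |log2FC| tie-break — with weights equal to
  the fraction of runs calling a region significant; regions significant
  nowhere get 1/(2·n_runs) so they still contribute. Zero-range regions
  are dropped (standard Gower convention). Average-linkage; dendrogram
  exported as Newick plus a merge table.
- qPCR concordance requires a unique ≥ 1 bp mapping of each assayed
  region onto the reference and reports RMSE, Pearson r, and the paired
  table.
- All randomness flows from explicit integer seeds (numpy default_rng);
  pipeline runs are byte-reproducible, which the CLI tests assert.
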