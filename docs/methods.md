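# Methods

## Scope and model

`irdselect` prioritizes autosomal-recessive inherited-retinal-dystrophy
(AR-IRD) genes as gene-supplementation therapy targets by combining four
signals: population-genetic disease burden, real-world diagnostic yield,
cell-type expression context, and AAV delivery feasibility.

### Recessive burden

For a gene with pathogenic allele frequencies `q_1 .. q_k` in a population,
let `Q = Σ q_i` be the pooled pathogenic allele frequency. Under
Hardy–Weinberg random mating:

- **Genetic prevalence** `GP = Σ_i q_i² + Σ_{i<j} 2 q_i q_j = Q²` — the
  probability of carrying two pathogenic alleles, homozygous or compound
  heterozygous. Both the closed form and the explicit genotype enumeration
  are implemented; the enumeration is the independent cross-check and is
  quadratic in the variant count, so tests cap it at 8 variants.
- **Carrier frequency** `CF = 2Q(1−Q)` — the exact heterozygote frequency.
  Published burden estimates sometimes use the rare-allele approximation
  `2Q`; it is available as `mode="approx"`. The two agree to first order in
  `Q`, and `GP ≤ CF` holds for all `Q ≤ 2/3`, hence everywhere in the
  supported regime.
- **Expected affected individuals** `EAI = Σ_p GP_p · N_p` over ancestry
  strata with census sizes `N_p`. Lifetime genetic prevalence times census
  population, not incidence. The GLOBAL row of the prevalence table carries
  this sum together with the population-size-weighted mean CF and GP.
- **Couple transmission** `CF²/4` (both partners carriers × Mendelian ¼) is
  exposed as a cross-check; with the exact CF it equals `GP·(1−Q)²`
  identically, so its ratio to GP tends to 1 as `Q → 0`.

Assumptions: variants are independent sites within a gene (no linkage or
in-cis phasing correction); each population is panmictic with no admixture;
alleles are pre-classified as pathogenic. Total carrier counts across genes
are offered in two modes because published headline figures do not say
which was used: `union` (each person counted once,
`Σ_p N_p(1 − Π_g(1 − CF_gp))`, assuming independence across genes) and
`sum` (per-gene carrier counts added, double-counting multi-gene carriers).
Union is never larger than sum.

Pooled frequencies are accumulated with exactly-rounded summation
(`math.fsum`) so that zero-frequency variants are true no-ops; everything
else is ordinary double precision.

### Cohort meta-ranking

Studies enter as long tables of (study, cohort size, platform, gene,
diagnosed count). Inclusion requires an NGS-panel or whole-exome platform
and a cohort size **strictly greater than 50**; an optional per-study
`nonuniform_criteria` flag excludes studies whose diagnostic criteria are
not comparable (no operational definition exists, so it is an input flag).
Per-gene yields are diagnoses per *screened* proband (`d/N`). Pooling is a
weighted mean with weights defaulting to cohort size; a sequencing-depth
adjustment enters only as an explicit per-study weight override, since
depth is never quantified in source tables. A gene absent from a study is
missing (not assayed), not zero; a reported zero stays zero. Ranking ties
break deterministically by number of reporting studies, then gene symbol.
The sensitivity analysis re-runs filter+rank over a grid of minimum cohort
sizes and reports Spearman correlation of pooled yields and Jaccard overlap
of the top-10 against the baseline (threshold 50). No random-effects
meta-analysis or heterogeneity modelling is attempted: the procedure is a
weighted average by design.

### Expression summaries

Counts are depth-normalized per cell to 10,000 total and `log1p`-ed — the
conventional single-cell recipe. Highly-variable genes use the classic
binned-dispersion selection: per-gene mean and dispersion (variance/mean)
on the de-logged scale, dispersions z-scored within 20 equal-frequency mean
bins, and a gene kept iff `min_mean < mean < max_mean` and normalized
dispersion ≥ `min_disp` (defaults 0.0125, 3, 0.5 — the standard thresholds
for genome-wide matrices; on small simulated gene panels the de-logged
means are far larger, so callers pass a window suited to their matrix).
Dot-plot statistics per gene × cell type: fraction of cells with raw count
> 0 ("expressing" means raw evidence, not a normalized threshold) and mean
normalized expression over **all** cells of the type, recorded in the
output metadata. The tau specificity index
`τ = Σ_t (1 − m_t/max m) / (T−1)` turns the qualitative
ubiquitous-vs-specific call into a number: 0 for uniform, 1 for single-type
expression, invariant to positive rescaling; an all-zero profile is
reported as uniform (τ = 0). Clustering, PCA and label inference are out of
scope — cell-type labels are inputs.

### Candidate selection

A gene passes when, jointly: transcript length ≤ the AAV cargo limit
(default 4700 nt; 4.7 kb at 1 kb = 1000 nt, comparison inclusive at the
boundary); global EAI **strictly** above the reference gene (default RPE65,
the benchmark set by the first approved ocular gene therapy — strictness
means the reference itself never qualifies; a non-strict mode is exposed
because published shortlists do not state which was used); and
enzyme-coding (optional, on by default — partial catalytic restoration is
often therapeutic). Enzyme class is an input flag, never inferred. When a
gene has several transcripts, `collapse_transcripts` reduces to one length
per gene, defaulting to the maximum (conservative for cargo fit). The
scatter export pairs transcript length (x) with EAI (y), publication count
(bubble size) and enzyme class (colour), with the cargo limit as a vertical
reference line; log-scale hints live in the metadata sidecar, the data are
untransformed. The burden-vs-attention Spearman correlation is computed
over all genes without thresholding and flagged not-computable when ranks
are degenerate.

## Synthetic data: what it emulates and what it does not

The generators stand in for external resources (population allele-frequency
matrices, census demographics, pooled cohort tables, annotation joins, a
labelled retinal count matrix) so that every stage is testable offline.
Each generator has its own RNG stream derived from the master seed by a
fixed offset; a fixed seed yields byte-identical artifacts.

- **Alleles**: frequencies log-uniform in `10^-6..10^-2` by default —
  mimics a rare-variant spectrum without claiming realism of any database.
  Gene roles partition the range: planted candidates (and the high-burden
  decoys) draw from the top of the range with the maximum variant count,
  the reference from a middle band, background genes from the bottom, so
  per-population pooled frequencies are strictly ordered
  candidate > reference > background and burden recovery is guaranteed, not
  merely likely. The burden-tie decoy replicates the reference's frequency
  draws exactly. A degenerate range (min = max) collapses every draw to the
  point value. Five populations with census sizes of 5 × 10⁶ – 1.5 × 10⁹
  individuals give globally meaningful EAI magnitudes.
- **Cohorts**: per-study diagnosed counts are multinomial over genes plus
  an explicit undiagnosed category (diagnostic rate 0.6), which preserves
  the sum constraint against cohort size — the reason multinomial was
  chosen over independent Poisson counts. Gene probabilities are
  proportional to simulated burden, with the ten planted top genes boosted
  ~30-60× above the largest background weight so pooled dominance is
  essentially certain at the default cohort sizes. A quarter of studies
  violate inclusion criteria by construction (one at the exact
  cohort-size-50 boundary, one on a non-NGS platform) to exercise the
  filter. Genes with zero diagnoses in a study get no row, exercising the
  missing-vs-zero semantics.
- **Annotations**: candidate transcripts are 1200–4700 nt and enzyme-coding;
  the size decoy is exactly 4701 nt and otherwise perfect; the enzyme decoy
  is high-burden, short, non-enzyme. Background lengths are log-normal
  (~1.5–15 kb). Publication counts are Pareto-tailed and drawn
  independently of burden, so the burden-vs-attention correlation is near
  zero by construction — a testable analogue of the research-intensity /
  clinical-burden mismatch.
- **Counts**: negative-binomial (dispersion 2) over 600 cells × 6 retinal
  cell types. Markers have mean 25 in their own type and 0.01 elsewhere
  (fraction-expressing > 0.9 vs < 0.1); the planted top genes double as the
  ubiquitous set (mean 3, one rhodopsin-like abundant gene at mean 30);
  background mean 0.2. All-zero genes are dropped, and a manifest records
  markers, the ubiquitous set and drops.

What passing tests on these fixtures shows: the algebra, filters, ranking
and statistics behave as specified under controlled, recoverable structure.
What it does not show: realism of any input distribution — real allele
spectra, cohort panel compositions and retinal expression are all richer
than these stand-ins, and none of the generator distributions is an
inference about real data.

## Problem sizes and numerical choices

The test-suite and acceptance script use the default conditions — 60 genes
× 5 populations, 8 studies, 600 cells × 6 types — with 20 seeded replicates
for the recovery properties and 1000 random frequency sets for the
enumeration cross-check; the full suite runs in well under a minute.
Floats are written with 12 significant digits; tables are TSV (gene symbols
never contain tabs) and counts are Matrix Market, the de-facto sparse
single-cell exchange format. Equal-frequency dispersion bins collapse
duplicate edges and fall back to fewer bins (with a warning) when genes are
scarcer than bins; a single-gene or zero-variance bin contributes zero
normalized dispersion rather than an undefined z-score.

## Known limitations

- AR-only: no X-linked or dominant prevalence models, so genes like RHO or
  RPGR are outside the burden machinery even though they rank highly in
  diagnostic yield.
- No variant classification: inputs are pre-classified pathogenic alleles.
- No admixture or cross-population mating; the union carrier aggregate
  assumes independence of carrier status across genes.
- The pooled-yield model ignores between-study heterogeneity beyond the
  weighting, and panel composition differences enter only through the
  missing-vs-zero convention.
- Adult expression snapshots: the dot-plot statistics carry no
  developmental or temporal information.
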