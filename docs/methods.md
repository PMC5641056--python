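# Methods

This note documents the models behind each stage of `oncopass`, the
defaults and why they were chosen, the numerical decisions that affect
reproducibility, and what the synthetic benchmark does and does not show.

## Synthetic cohorts

`simulate_cohort` generates a four-layer cohort with known per-gene truth.
It is built to reproduce the statistical structure the analysis assumes,
not the biology of real breakpoints.

**Gene grid.** `n_genes` genes are placed on `n_chromosomes` chromosomes,
10 kb bodies every 100 kb. Driver loci are (chromosome, gene-index) pairs.

**Copy number.** Per sample and chromosome, the background is piecewise
constant: a Poisson(2) number of breakpoints split the chromosome into
blocks whose log-ratios are N(0, `cnv_noise_sd`), emulating segmented
array noise. Independently per driver, with probability `amp_frequency`
the sample carries an amplified segment centered on the driver whose
extent per side is Geometric(1/`segment_decay`) genes and whose log-ratio
is N(0.8, 0.1). The geometric extent yields the distance-decaying
co-amplification correlation seen around real amplicons. Amplification
frequencies in the 0.1–0.4 range match what recurrent oncogene amplicons
show in large tumor cohorts; the default is 0.3.

**Classes.** Genes within `round(segment_decay)` genes of a driver are
*amplicon* genes; a fraction `cr_low_fraction` of them are labelled
CR-low, the rest CR-high, everything else neutral.

**Expression.** log2(count+1) = baseline + slope·CNV + N(0, 0.3), with
baseline ~ U(6, 10) and slope = `dosage_slope` for CR-high genes, 0
otherwise. The 0.3 log2-unit residual keeps single-gene dosage
correlations for CR-high genes in the 0.6–0.8 band observed for strongly
coupled genes, given the amplicon's CNV variance.

**Methylation.** One probe per gene (multi-probe handling is exercised by
dedicated fixtures instead, keeping ground truth unambiguous):
beta = inv-logit(logit(b₀) + `methyl_compensation`·k·CNV + N(0, 0.2)),
b₀ ~ U(0.3, 0.7), k = +2 for CR-low genes (hypermethylation on gain — the
compensation mechanism), −2 for CR-high genes, 0 for neutral. The
inverse-logit keeps betas strictly inside (0, 1).

**Survival.** Exponential proportional hazards: baseline rate 1/1000 per
day; the linear predictor sums per-gene coefficients
(`hazard_coef_crhigh` for 5 CR-high outcome genes, `hazard_coef_crlow`
for 5 CR-low ones) times the standardized log2 expression. An exponential
baseline suffices because Cox estimation is baseline-free. Censoring
times are independent exponentials with rate chosen so a baseline subject
(linear predictor 0) is censored with probability `censor_rate`; this is
the simplest scheme that is genuinely independent of the event process
while hitting the requested rate at the cohort center.

All draws come from one `numpy` generator seeded by `seed`, so cohorts
are bit-identical across runs.

**What the generator does not emulate:** tumor purity and ploidy shifts,
subclonal mixtures, realistic breakpoint hotspots, probe-level
methylation chemistry, batch effects, or correlated expression programs
beyond dosage. Tests passing on these cohorts demonstrate that the
*pipeline* recovers planted structure at realistic effect sizes and
sample counts; they do not certify performance on real tumor data with
those additional noise sources.

## Segment → gene mapping

A gene's value in a sample is the length-weighted mean of segment
log-ratios over the covered bases of its body — equivalent to per-base
averaging, which the tests verify to 1e-9 on random fixtures. The gene
body (not a promoter window) defines the interval because segment means
measure dosage, not regulation. SEG input is 1-based inclusive and
converted to 0-based half-open internally. Overlapping segments within a
sample are rejected rather than resolved. Genes with no covered base are
missing, and missingness is handled pairwise in every correlation
(casewise deletion would discard whole samples for a single bad probe).

Gain/loss calls use `numpy` linear-interpolation percentiles (the most
common convention, stated here so results are reproducible) and strict
inequalities: 90th percentile > 0.50 for gain, 10th percentile < −0.50
for loss. A gene triggering both is reported in an explicit `both` error
state. The expression filter keeps genes with > 30 normalized counts in
at least ⌈10% of samples⌉.

## Profiles and enrichment

Profiles are Pearson correlations of the index gene's CNV against every
gene's row of the chosen layer; expression is log2(count+1)-transformed
first because normalized counts are heavy-tailed. Pearson is used across
profiles as well (Spearman is available as an option through the
underlying helpers). The correlation t-statistic
t = r·√((n−2)/(1−r²)) is available for plotting-style output.

Enrichment: samples are split at index CNV > 0.5; overexpression is a
Welch two-sample t-test on log2 counts (the simplest test consistent
with "difference in expression" between groups) at α = 0.001 with the
higher mean in the gain group; co-amplification is DNA-profile r > 0.4
by default (the same scale as the CR pivot, configurable); the P-value
is the exact hypergeometric upper tail of the overlap. The `trans_only`
scope drops the index gene's chromosome, separating in-cis passengers
from trans effects.

## CR classification

The classifier fits a Gaussian KDE (scipy, Silverman bandwidth) on a
512-point grid over [−1, 1], takes the two highest local maxima, and
places the cutoff at the minimum strictly between them. Valleys outside
[0.0, 0.8] (with one grid step of tolerance, so a symmetric density with
its valley exactly at 0 is not rejected) or unimodal densities fall back
to the fixed 0.4 cutoff. Ties at the cutoff go to CR-low — a documented
strict rule is required for determinism. The pathway stage uses the fixed
0.4 pivot; the classification stage fits the valley by default, and both
modes are exposed because per-cohort valleys and the fixed pivot are both
defensible.

## Methylation coupling

Per-gene CNV–beta Pearson correlations under an explicit probe policy
(`best_abs` keeps the probe with max |r|, `mean_beta` averages betas
first, `per_probe` reports all; all agree for single-probe genes — the
policy is reported in the output because any multi-probe summary is a
choice). Coherence is the Spearman ρ and OLS slope of CNV–beta r on
CNV–mRNA r across genes. Beta comparisons between copy-gain (CNV > 0.5)
and copy-neutral (|CNV| ≤ 0.5, operationalizing "2N" symmetrically with
the gain scale) samples use a two-sided Mann–Whitney test — betas are
bounded and non-normal — with the exact null when group sizes permit and
no ties are present. The deletion side (CNV < −0.5) reuses the same
machinery.

## Survival

`cox_univariate` maximizes the Cox partial likelihood with Efron's
approximation for ties (the default of the standard survival software)
by Newton–Raphson with step-halving; z = β̂/SE with the SE from the
observed information. The expression covariate is standardized to unit
variance so coefficients are comparable genome-wide. Convergence is
declared at a step or gradient below 1e-10 within 50 iterations;
non-convergence is flagged, not raised. The fit is verified against
direct numerical maximization of the hand-written partial likelihood
(1e-6) and cross-checked against `lifelines`; its permutation null is
calibrated (type-I error at |z| > 1.96 within [0.03, 0.07] at 200
subjects).

Stratification bands: better z < −2, poor z > 2, NS |z| ≤ 2 — the
boundary goes to NS. Kaplan–Meier curves and the log-rank statistic come
from `lifelines`; the default split is the expression median (tertiles
offered), and a cohort with no events yields flat curves with a flagged
(NaN) log-rank statistic.

## Pathway Flux

The walk is pinned normatively as: transition probability i→j
proportional to edge_weight(i,j)·value(j); restart probability 0.05 (a
standard network-propagation default, exposed in config) with restart
distribution proportional to the values; stationary π by power iteration
to L1 change < 1e-10; edge flux π(i)P(i→j) + π(j)P(j→i). Values are
2^(r − 0.4), so CR-high genes bias the walk above the neutral level 1 and
CR-low genes below it; genes absent from the data get exactly 1. The
transform's scale invariance (values are normalized inside the walk)
means only relative biases matter. Disconnected networks are walked per
component with each component's π weighted by its share of total node
value, keeping Σπ = 1.

A pathway's flux score sums member node flux and internal edge flux. The
null permutes *membership* within node-degree bins (exact degree up to
10, log₂ bins above), which controls for hub effects without rewiring
the network; z = (score − null mean)/null sd, with z = 0 when the null
is invariant (e.g. the all-nodes pathway). An exhaustive mode enumerates
every degree-matched member set for small networks and is verified
against full enumeration to 1e-12. Pathways are supplied as GMT files;
no pathway database is bundled.

## Pipeline

`run_pipeline` executes filter → calls → dosage → classify → profiles →
methylation → survival → netflux from one declarative config whose
defaults are the standard thresholds (0.50/−0.50 percentile calls, 30
counts/10%, pivot 0.4, α 0.001, z band ±2, restart 0.05). Stage TSVs are
written with a fixed `%.10g` float format, making runs with identical
configs and seeds byte-identical; the manifest records the config, its
SHA-256 hash, the seed and the package version. A stage failure halts
the run naming the stage and preserves the outputs already written.

## Problem sizes

The recovery benchmarks use 300-sample, 2000-gene cohorts with ≥ 100
amplicon genes (10 seeds per condition for classification, 20 for
coherence sign, 1000 permutations for Cox calibration); the pathway
benchmark uses 200-sample cohorts, ~190-node networks and 60 pathways of
8 genes at 400 membership permutations. These sizes were chosen to match
the scale at which the corresponding effects are identifiable in real
tumor cohorts while keeping the full benchmark suite runnable in minutes
on a laptop.

## Known limitations

* The valley detector assumes at most two dominant modes; heavily
  multimodal correlation distributions fall back to 0.4.
* The Cox screen is univariate by design — no clinical covariates,
  competing risks or multiple-testing correction are applied, matching
  its role as a ranking screen rather than a discovery procedure.
* The walk definition is this package's explicit formulation of
  value-biased propagation; other network-propagation tools differ in
  their edge-flux conventions, so absolute flux scores are not
  comparable across tools (z-scores against the membership null are the
  interpretable quantity).
* Segment mapping trusts the input segmentation; no recurrence calling
  (GISTIC-style) or purity correction is attempted.
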