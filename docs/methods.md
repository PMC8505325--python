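# Methods

This note documents the models and procedures implemented in `cyt`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical choices a maintainer would want to know.

## Cytolytic activity and stratification

CYT is the TPM-scale geometric mean of GZMA and PRF1 with a pseudocount
(default 0.01 TPM) so that a single zero does not annihilate the score; the
pseudocount is configurable and log2(CYT) is reported alongside. CYT is
scale-equivariant (multiplying both genes by c multiplies CYT by c at zero
pseudocount) and bounded above by the arithmetic mean of the two TPMs.

Stratification splits each tumor-type stratum (primary / metastatic; a pooled
mode exists) at the 25th and 75th percentiles, computed with linear
interpolation (numpy default, type 7). Samples strictly above the 75th
percentile are CYT-high, strictly below the 25th CYT-low, everything else mid.
Boundary ties therefore go to mid: the extreme groups stay conservative, an
all-tied stratum degenerates to all-mid, and for tie-free n divisible by 4
both extreme groups have exactly n/4 members. Strata with fewer than 4 samples
are skipped with a warning (all mid).

Gene-set scores are means of per-gene z-scores taken across samples (sample
standard deviation, n−1); the IFN-γ (6 genes) and expanded-immune (18 genes)
panels ship as module constants. Group comparisons are two-sided Mann–Whitney
U tests with midrank ties; families of tests are adjusted by Benjamini–
Hochberg, except signature-contribution comparisons which use Bonferroni
(adjusted p = min(1, m·p)).

## Mutation spectra

SBS-96 classification collapses every SNV onto the pyrimidine strand: a
purine reference is reverse-complemented together with its flanking bases.
The trinucleotide context comes from a table column when present, otherwise
from a reference FASTA (1-based inclusive coordinates, MAF convention).
Records with ambiguous bases are excluded and counted.

Two same-sample substitutions at adjacent positions are one doublet event,
classified on the canonical DBS-78 set (non-canonical reference doublets
reverse-complemented; for the four palindromic references the
lexicographically smaller of the two equivalent alts is canonical). Runs of
three or more adjacent substitutions are excluded from both matrices and
tallied. Column sums therefore conserve counts:
SNVs + 2·DBS + excluded = raw records.

The recurrently-mutated-gene test is a deliberately simplified frequency
test, labelled as such in its output metadata: per gene, the number of
mutated samples is tested against a background probability
1 − exp(−r·L) (r = cohort median per-Mb mutation rate, L = gene length in
Mb) with a one-sided binomial test and BH adjustment (significance at
q < 0.1). It has no covariate model and must not be read as a MutSigCV
replacement.

## Signature extraction and attribution

Extraction runs scikit-learn NMF with the Kullback–Leibler beta-divergence,
multiplicative updates, random initialization, max 1,000 iterations and
tolerance 1e-6, restarted n_restarts times (default 20) per candidate rank.
The restart signatures (L1-normalized) are clustered by k-means (k = rank)
and rank stability is the **minimum per-cluster mean silhouette** under
cosine distance — the weakest signature's cohesion. The mean silhouette was
tried first and rejected: three tight clusters can mask one scattered
spurious cluster and leave the mean near the threshold, whereas the minimum
drops sharply as soon as any signature fails to reproduce across restarts.
The selected rank is the largest one with stability ≥ 0.8 (configurable);
if none qualifies, the most stable rank is taken. Consensus signatures are
cluster centroids, L1-normalized; exposures are per-sample non-negative
least-squares fits rescaled to the sample's mutation count. Rank 1 is the
analytic KL fixed point (normalized row-sum profile, column-sum exposures)
and is assigned stability 1.

Matching to a reference catalog is greedy one-to-one on descending cosine
similarity with a floor (default 0.8); channel labels must align exactly and
misaligned catalogs fail loudly rather than silently permuting. Signature
co-occurrence uses presence = relative contribution > 0.05 and a two-sided
Fisher exact test; a zero cell triggers the Haldane 0.5 correction for the
odds ratio and flags the table degenerate.

## Kataegis

An event is a maximal run of ≥ 6 consecutive same-sample, same-chromosome
mutations whose mean successive inter-mutation distance is ≤ 1000 bp
(equivalently pos_j − pos_i ≤ 1000·(j − i)). The caller scans left to right,
takes the longest qualifying window starting at the current index, emits it
and resumes after it; events never overlap, chromosome boundaries always
break runs, and samples never pool. The suite checks the caller against an
independent window-enumeration oracle on random tables. No substitution-class
constraint is imposed on event membership; the 6-class composition is
reported so C-coordinated showers are visible in the output.

## Copy-number burden and recurrence

Per-segment thresholds follow the convention seg_mean ≥ 0.6 →
amplification, ≤ −0.4 → deletion. The phrase "sum of segment mean changes"
in the source material is read as these per-segment thresholds — the common
convention for zero-centered log-ratio segments.

The recurrence G-score bins the genome (1 Mb default); a segment contributes
|seg_mean| × overlap-fraction to every bin it overlaps, summed over samples,
separately for amplifications and deletions. The null distribution shifts
each sample's aberrant segments by a uniform random offset along the
concatenated genome (circular, so the per-sample multiset of segment lengths
and amplitudes is preserved exactly); empirical p-values have floor
1/(n_permutations + 1) and are BH-adjusted. This is a simplified,
"gistic-like" recurrence score: no peak deconvolution, no arm/focal
separation.

## Chromothripsis-like detection

Profiles are first simplified per sample chromosome: segments shorter than
10 kb are dropped, then adjacent segments with |Δ seg_mean| < 0.3 (the
signal distance) are merged with a length-weighted mean until no such pair
remains — the operation is idempotent and every surviving boundary is a
status change of at least the signal distance. A 50 Mb window sliding in
10 Mb steps flags windows with ≥ 20 switches whose local breakpoint rate is
extreme under a Poisson likelihood ratio against the sample's genome-wide
rate:

    log10 LR = [k·ln(λ1/λ0) − W·(λ1 − λ0)] / ln 10,  λ1 = k/W, λ0 = K/G.

The LR form is this package's own concrete choice (the tool it emulates does
not publish its statistic); it is closed-form, zero when the local rate
equals the background, strictly increasing in k beyond it, and reported as a
flagged +infinity sentinel when the background rate is zero. Qualifying
windows merge into maximal regions (falling back to the best single window
in the rare case a merged region dips below a threshold, so every reported
call satisfies both thresholds). Within a call, sub-regions with signal
≥ 0.15 / ≤ −0.15 are annotated as gains / losses — the display thresholds,
deliberately distinct from the 0.3 merging criterion — and genes from a
user-supplied BED-like table are attached by interval overlap.

## Heterogeneity

VAF = alt/(alt+ref); records without usable counts are dropped and counted.
MATH = 100 × 1.4826 × MAD / median of the sample's VAFs, the 1.4826 being
the Gaussian-consistency constant of the original MATH definition; MATH is
undefined (an error) at median 0 or fewer than 2 VAFs. VAF clustering fits
1-D Gaussian mixtures for k = 1..4, initial means at quantiles so a fixed
seed gives a deterministic fit, and selects k by BIC; fewer than 5 mutations
force k = 1 flagged low-confidence.

## Survival

Kaplan–Meier estimation and the Mantel–Cox log-rank test are computed
through lifelines (Greenwood 95% bands); the suite pins them to
hand-computed product-limit and O−E fixtures. The synergy analysis
dichotomizes each gene at its median (quartile cutpoints available) and
reports four log-rank contrasts — each gene high vs low, both-high vs rest,
both-low vs rest — with raw p-values (no multiplicity correction across the
four, a correction flag being a caller decision).

## Immunophenoscore

Per-gene z-scores across samples (sample sd, configurable to population sd)
feed factor scores (weighted means of member genes), category scores
(plain means of factors) for MHC, CP, EC and SC, and the aggregate
AZ = MHC + CP + EC + SC, where checkpoint and suppressor weights are
negative in the weight table itself. IPS = 0 for AZ ≤ 0, 10 for AZ ≥ 3,
otherwise round(AZ·10/3) with numpy half-to-even rounding. The bundled
weight table (`ips_weights_synthetic.tsv`) is a synthetic fixture following
the immunophenogram's category structure — the published gene/weight
assignments are not reproduced — and is an editable TSV so a user can drop
in the published table.

## Synthetic cohorts

The generator produces the four input tables with the structure the stages
assume, all from one seeded PCG64 generator (`numpy.random.Generator`) with
fixed per-stage spawn keys, so a fixed seed is byte-identical across runs
and platforms.

* **Expression**: GZMA and PRF1 are tied by a Gaussian copula whose Pearson
  parameter 2·sin(π·ρ_s/6) hits the target Spearman ρ (default 0.9; snapped
  to exact dependence at ρ_s = ±1). Immune-panel genes couple mildly
  (slope 0.6 on the latent cytolytic factor) so CYT-high tumors look
  inflamed; filler genes are independent log-normal.
* **Mutations**: per-sample channel counts are multinomial in the
  exposure-weighted mixture of catalog signatures. Default exposures are
  UV-dominated mixtures of 200–500 mutations with a low-concentration
  Dirichlet (α = 2 × [0.55, 0.25, 0.20]) so mixture fractions vary strongly
  across samples, emulating the near-mutual-exclusivity of UV and clock-like
  processes in melanoma cohorts — and keeping the count matrix identifiable
  for NMF. Background mutations land > 10 kb apart (jittered grid); planted
  kataegis showers are placed exactly as specified as C>T at TpC contexts;
  about half of all records are written on the purine strand to exercise
  strand collapse. Read counts are Binomial in a Beta-mixture VAF (default
  one clone at mean 0.40, concentration 40) at Poisson depth ~90.
* **Segments**: background chromosomes have ≤ 3 change points with
  |seg_mean| < 0.3; planted chromothriptic blocks alternate between
  +amplitude and −amplitude in ≥ 10 kb segments, so both the intra-block
  steps (2×amplitude) and the block edges (amplitude ≥ 0.3) survive
  signal-distance merging and the block yields both gains and losses.
* **Survival**: exponential event times with per-CYT-group hazards (defaults
  1/2400, 1/1600, 1/1000 per day for high/mid/low) and independent
  exponential censoring (1/2000 per day, ≈ 30–45% censoring).
* The bundled signature catalog holds four synthetic vectors (UV-like
  dipyrimidine C>T, a near-flat clock-like vector, an N[C>T]G deamination
  vector, and a uniform control); it is NOT COSMIC, and COSMIC v3.1 files
  load as a drop-in replacement.

What passing tests on these cohorts show is that the pipeline recovers
planted statistical structure at the stated tolerances; they say nothing
about caller artifacts, purity/ploidy, gene models or any other property of
real tumor data the generator does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
50-sample cohorts with 200–500 mutations each for signature recovery
(10 seeds, 20 restarts, ranks 2–5), 50 seeded tables of 500–2,000 mutations
for the kataegis oracle, 50 four-sample cohorts for chromothripsis, 2,000
null replicates of n = 100 for test calibration, and 199–200 permutations
for the G-score floor. Tolerances asserted in tests derive from analytic
oracles computed before freezing (e.g. the expected multinomial L1 error
Σ_c sqrt(2 p_c (1−p_c)/(π n)), which is ~0.078 for a near-flat 96-channel
vector at n = 10,000 — materially larger than for peaked vectors).

Known limitations: the chromothripsis LR is not numerically comparable to
CTLPScanner's unpublished statistic (thresholds are calibrated on the
synthetic profiles); the G-score permutation null treats chromosome
boundaries as soft (segments may wrap across them); the simplified SMG test
ignores mutational covariates entirely; and exposure attribution by NNLS is
least-squares, not Poisson-likelihood, which slightly underweights sparse
channels at low counts.
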