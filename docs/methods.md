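# Methods

## Data model and scales

RT-qPCR data enter as cycle-threshold (ct) values — the PCR cycle at which a
transcript's fluorescence crosses the detection threshold. ct is approximately
−log₂ of input template: one cycle ≈ a two-fold expression difference. Values
are validated to lie in (0, 45] cycles (assays here run 40 cycles; 45 leaves
headroom for other instruments). Technical replicates (rows sharing a sample
id) are collapsed by the arithmetic mean of ct before analysis. Missing cells
are an error by default; `drop_incomplete_samples` removes affected samples
instead, because every stability algorithm requires a complete gene × sample
block.

Relative quantities use the 2^−Δct convention with amplification efficiency
fixed at 2 (100%): q_ij = E^(ct_min,i − ct_ij), calibrated per gene to its
minimum ct, so the most expressed sample has q = 1. The calibrator choice
multiplies each gene's q by a constant; every downstream quantity (M values,
stability values, fold changes, V series) is invariant to it, which the test
suite asserts. Assay-specific efficiencies (e.g. 90–101% from standard
curves) can be carried as gene metadata and used via the `efficiency`
argument, but the default deliberately matches the plain 2^−Δct pipeline.

## BestKeeper

Per gene: SD of ct (sample SD, n−1 denominator, in cycles), CV = 100·SD/mean,
and Pearson r (and r²) against the BestKeeper index, the per-sample geometric
mean of ct over the candidate set being ranked (self-inclusive). Ranking:
genes with SD ≤ 1 cycle ordered by descending r², then genes with SD > 1
(more than two-fold template variation) likewise; ties break by ascending SD,
then gene label. The SD cut is applied strictly (> 1); SD = 1.00 is kept. "SD"
here is the standard deviation of ct — the historical BestKeeper add-in used
the mean absolute deviation, so numbers are not expected to match that tool
cell-for-cell. A gene with zero ct variance has an undefined correlation and
is rejected by name rather than silently dropped.

## NormFinder

On y = ct (valid because all statistics are sign-symmetric in log-expression):

1. per-sample centering: z_igj = y_igj − mean over genes of y_·gj, which
   absorbs sample-loading effects and any expression trend common to all
   genes;
2. intergroup deviation d_ig = (cell mean of z) − (gene's mean over groups);
   Σ_g d_ig = 0 by construction;
3. intragroup variance γ²_ig = within-cell sample variance of z;
4. shrinkage d̃_ig = d_ig · max(0, 1 − (γ²_ig/n_g)/(Σ_g d²_ig/(G−1))), and 0
   when Σ d² = 0 — noisy intergroup estimates are pulled toward zero so a
   gene is not penalized for bias it cannot statistically support;
5. stability ρ_i = (1/G) Σ_g (|d̃_ig| + √(γ²_ig/n_g)); one group only:
   ρ_i = √γ²_i.

γ² is used without the cross-gene correction factor of the original
formulation; with ≥ 4 candidate genes the centering contamination is modest
((k−1)²/k² weighting) and identical across genes, so rankings are unaffected
in simulation. The shrinkage constants are this package's documented
definition with the intended qualitative contract, not a numerical clone of
any published add-in.

Normalization-factor selection is greedy: start from the lowest-ρ gene, add
whichever gene minimizes the set stability
ρ_S = (1/G) Σ_g (|mean_{i∈S} d̃_ig| + √(Σ_{i∈S} γ²_ig/(|S|²n_g))), stop when
no addition reduces it (`max_nf_genes` caps the depth). Opposite-sign biases
cancel in the mean — the mechanism that lets a pair beat its best member. A
caution from simulation: with realistic group sizes (n ≈ 10) the d̃ estimates
of candidate genes are correlated through the shared centering, so the greedy
path is noisy near its stopping point; the deterministic cancellation
behavior is exact, but "which exact set" is only reproducible when the
stability gaps are large.

## GeNorm

M_j = mean over partners k≠j of SD over samples of log₂(q_j/q_k) (n−1
denominator throughout, matching BestKeeper). The highest-M gene is removed
and M recomputed until two genes remain; each gene's reported M is its value
at elimination, and the final two genes — mutually unresolvable — share rank 1
(competition ranking: the next gene is rank 3). Ties on max M remove the
later gene in input order. The V analysis builds NF_n, the per-sample
geometric mean of the n most stable genes, and
V_{n,n+1} = SD(log₂(NF_n/NF_{n+1})) for n = 2…G−1; the recommended NF size is
the smallest n with V below the threshold (default 0.15, configurable), or a
"none below threshold" flag. V is computed across the whole sample set of the
analysis step, not within groups.

Because two co-regulated genes (e.g. members of one gene family) hold each
other's M down artificially, the validation workflow checks GeNorm's top pair
against a user-supplied gene-family map: if both members share a family, the
one with the worse mean-rank consensus is excluded and GeNorm re-run on the
reduced set. The guard applies to GeNorm only; BestKeeper and NormFinder see
the full candidate set.

## Consensus, NF vetting and bias flags

Per analysis step (a configurable group subset, by default all-but-last
groups then all groups), the three per-gene ranks are averaged; ties break by
NormFinder ρ (the only model-based metric), then label. A proposed multi-gene
NF is accepted only if its ρ_S is strictly lower than the best single gene's
ρ — equality is a rejection, since the extra gene buys nothing.

Bias flags test, per gene, whether its non-normalized relative expression
differs between groups: a one-way fixed-effects ANOVA on log₂ q (the scale on
which qPCR noise is approximately Gaussian and homoscedastic), flagging
"biased" when p < α (default 0.05, no multiple-testing correction — each
flag is reported, not selected on). Fold changes are reported per group as
arithmetic means of the normalized values rescaled to the baseline-group
mean. Degenerate ANOVA inputs resolve by convention: zero between-group
variation → p = 1; zero within-group variation with any between-group
difference → p = 0. Cohort-characteristic comparisons use the Pearson
chi-square without continuity correction (all-zero categories dropped first;
a 2×2 table with Yates correction would not reproduce standard uncorrected
results) and the two-tailed Welch t-test.

## RNA-seq screen

Upper-quartile normalization: each sample's scale factor is the 75th
percentile of its nonzero counts (linear-interpolation percentile) divided by
the geometric mean of all samples' percentiles, keeping the output on the
count scale and making the operation idempotent. Filters act on
x = log₂(UQ + pseudocount), pseudocount 1 by default (configurable and
reported in output):

* mean(x) > 5 — strictly greater;
* SD(x) < 1 — strictly less;
* max |x − mean(x)| < 2 — a deviation of exactly 2 fails.

Passing genes are ranked by CV = SD(x)/mean(x). CV on this log scale is the
default because the filters are defined there; a linear-scale CV
(`linear_cv=True`) is exactly invariant to global count rescaling, whereas
the log-scale CV is only approximately so (the pseudocount shifts means
additively). Two datasets are screened independently; their passing
intersection is re-screened on the column-concatenated (shared-gene) matrix,
UQ-normalized afresh.

## Synthetic cohorts

`simulate_ct` draws ct_igj = baseline_i + shift_ig + b_gj + ε_igj with
b ~ N(0, sample_effect_sd²) shared by all genes of a sample (RNA input /
RT-efficiency loading) and ε ~ N(0, noise²_i). Generators are pure functions
of (scenario, seed); tests assert statistics, never the random stream.
Presets:

* **null** — 8 genes, baselines 15.6–29.6 cycles, three groups
  (preterm/fullterm/adult) of 10, no group effects, noise 0.5, loading SD
  0.5. Used for type-I-error calibration.
* **exchangeable** — identical baselines and noise, no effects; the only
  configuration in which every gene's rank is uniform by symmetry (with
  distinct baselines the geometric-mean BestKeeper index weights genes
  slightly differently, so exact uniformity holds only here).
* **paper-like** — 8 genes spanning the high-to-medium expression range, a
  common age trend (full-term −0.3, adult −1.0 cycles vs preterm; expression
  rising with age) with small per-gene deviations (≤ 0.15 cycles, mildest
  trend for RPLP0), noise 0.35, loading SD 0.5, n = 10 per group. The common
  trend is deliberately indistinguishable from a loading effect, so stability
  rankings respond only to the per-gene deviations while every gene still
  shows a small, statistically significant intergroup difference — the
  situation in which algorithm-validated reference genes can nonetheless
  carry systematic bias. `perturbed_paper_like_scenario` adds one gene with a
  +1-cycle group shift and one with 3× noise as designed-unstable truths.
* **screen-bench** — 2000 genes, two groups of 8, log-normal size factors
  (SD 0.2); 10 planted reference genes (mean ≈ 400 counts, dispersion 0.005,
  no group effect) that clear every filter with wide margins, ~10% strongly
  regulated genes (4-fold group effect → SD log₂ ≥ 1.5), and a low-expression
  background (mean log₂(UQ+1) ≈ 3–4.4). Planted-set recovery is exact by
  construction.

What the generators do *not* emulate: qPCR efficiency differences between
assays, inter-plate effects, non-Gaussian ct outliers, count-matrix batch
effects, or correlated biological regulation between candidate genes beyond
the designed shifts. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model, not
robustness to those real-data pathologies.

A quantitative limitation found in simulation: in the combined perturbation
scenario the 3×-noise gene's ρ acquires a heavy upper tail (its shrinkage
factor fluctuates with the estimated intergroup spread), overlapping the
shifted gene's ρ in roughly 10% of cohorts at n = 10 per group. The shifted
gene therefore ranks last in NormFinder in ~90% of cohorts, not ≳95% as the
separated single-perturbation scenarios achieve; the two designed
instabilities compete for last place. BestKeeper's demotion rule identifies
the noisy gene in ~97% of the same cohorts.

## Problem sizes and numerics

Default verification sizes: 100 random 5×8 tables for oracle equivalence
(tolerance 1e−10 against loop-based reimplementations), 100 seeds for
recovery rates, 1000 gene-level tests for ANOVA calibration, 10⁴ replicates
for Welch calibration, 50 seeds for screen exactness — chosen so the full
suite completes in well under a minute of simulation time while keeping
binomial uncertainty on rates ≈ 1–2 percentage points. All SDs use the n−1
denominator; geometric means are computed in log space; percentile = linear
interpolation; boundary tests construct float-exact values (e.g. SD exactly
1.0) rather than relying on rounding.
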