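# Methods

This note records the models, conventions and numerical choices behind
`periomics`, in the order the pipeline runs them.

## Biomass and diversity

Purified plaque DNA mixes human and microbial material, so microbial DNA is
estimated as total DNA × (microbial reads / total reads), and a species'
absolute abundance is its relative abundance times that microbial DNA.
Species-level relative abundances may sum to less than 100 % (unclassified
remainder); the unassigned DNA is simply not attributed to any species, so
biomass column sums equal microbial DNA × (species sum / 100) exactly.

Shannon diversity uses the natural log over renormalised nonzero
proportions (configurable base); it is scale-invariant, so relative and
absolute abundances give identical values. The prevalence filter reads
"at least 10 %" literally: a species is kept when its nonzero count reaches
`ceil(0.10 × n_samples)`, so 1 of 10 samples suffices.

## Repeated-measures correlation

The screen estimates the *common within-subject* association of two
repeatedly measured variables: both are centered on their subject means and
the Pearson correlation of the centered values is taken. This equals the
ANCOVA formulation with subject intercepts (enforced against a dummy-coded
least-squares oracle to 1e-10 in the tests); degrees of freedom are
`N − k − 1` for `N` complete pairs from `k` subjects, and the two-sided
p-value comes from `t = r√(df/(1−r²))`. Missing pairs are dropped pairwise
per variable pair (complete-case). A 10th-root transform is applied to
abundances and biomarker panels before screening; the bounded clinical
indices GBI and MGI are left untransformed by default (configurable). All
p-values are reported without multiple-comparison adjustment; formatted
output prints values below 0.001 as "<0.001".

Because sequencing samples are pooled per (subject, condition, visit) while
biomarkers are per site, a taxon–factor pair is aligned by averaging the
three sites of the matching condition. Taxon–taxon correlations use the
same estimator. The screen defaults to absolute biomass rather than
relative abundance — biomass is what tracks severity, and relative
abundances are compositionally constrained — with a flag to switch.

## Clustering and networks

Taxa are clustered on the rows of the taxon × factor r-matrix with
Euclidean distance and complete linkage (the usual heatmap-dendrogram
defaults; both configurable), cut at three clusters, labelled I–III in
increasing order of mean correlation with the nine factors.

Pathogenic selection keeps named taxa (placeholder identifiers such as
GGB/SGB/OTU bins are excluded by a name filter) with p < 0.001 for **all**
nine factors, then scans correlation thresholds on a 0.01 grid and keeps
the threshold whose surviving count is closest to 20, ties resolved toward
the larger threshold — a deterministic reading of "approximately twenty".
Network edges use the inclusive rule `r ≥ 0.6`; constellations are maximal
cliques of at least four taxa (exact clique enumeration, audited against an
independent pairwise-threshold check), reported largest first. Halo taxa
attach to a constellation core at `r ≥ 0.5, p < 0.05` without joining the
clique. Commensal selection defaults to "p > 0.05 for at least six of nine
factors", with a negative-correlation variant (`criterion="negative_r"`)
available; its network draws signed edges for `|r| > 0.1` (strict) and
p < 0.05.

## Responder classification

A random forest (400 trees, fixed seed 12345) learns baseline site states
from the full analyte panel. Permutation importance is measured as mean
decrease in accuracy × 100, i.e. percentage points, and features below 2
are dropped before the final refit — the cutoff is applied on the scale the
reference importance plots print. Per-class accuracy is out-of-bag recall
per true class. Bit-reproducibility is plumbed through model, bootstrap and
importance at fixed library versions; identical trees across different
library versions are not promised.

Month-24 measurements are pushed through the baseline-trained model, and
each site's transition from its **recorded** baseline category (not the
model's baseline prediction — the recorded category anchors the design) to
its predicted month-24 state maps to a call: P→G, P→H, G→H and H→H respond;
P→P, G→G, G→P, H→G and H→P do not. The arm × call table is tested with a
Yates-corrected chi-square, the correction term `|O−E|−0.5` floored at
zero; continuity correction is on by default, matching the default of the
common statistical environments for 2×2 tables. Fisher's exact test enumerates the hypergeometric support
and sums probabilities ≤ that of the observed table (relative tolerance
1e-7). The analysis unit defaults to the condition-pooled sample (three per
subject and visit, matching the pooled sequencing design); per-site units
are available via `responder_unit="site"` because the two granularities
genuinely differ in the field.

## LPS calibration

Onset time is the linearly interpolated moment the cumulative trapezoid
AUC of a well's fluorescence first reaches 30 % of its final (saturation)
value, computed on the raw cumulative curve without smoothing. It is
invariant to positive rescaling of the signal. The calibration
`log(conc) = a·(1/onset) + b` uses the natural log — the model is
self-consistent for any base, so one is fixed and documented — and is fit
by OLS over the standard series; with exactly two distinct concentrations
the fit is flagged degenerate (R² = 1 by construction). Estimates outside
the 0.01–3 µg/mL standard range are reported with an `extrapolated` flag
rather than clipped: the range is the span of the standards, not a physical
bound. Flat-zero curves are rejected (onset undefined).

## Statistics suite

Independent t-tests pool variances by default so that the two-group ANOVA
reconstructed from printed summary statistics satisfies F = t² exactly.
Wilcoxon signed-rank drops zero differences and is exact for n ≤ 25 without
ties, otherwise a continuity- and tie-corrected normal approximation
(validated against full 2ⁿ enumeration and sign-flip permutation). Identical
paired vectors return statistic 0, p = 1 (no difference and no evidence of
one); a constant nonzero shift has zero variance and is an error.
Kruskal–Wallis is tie-corrected; Dunn's z uses pooled mean ranks with the
tie-corrected variance and unadjusted two-sided normal p-values (for two
groups, z² = H, which the tests verify). Kruskal–Wallis + Dunn is wired to
the two-arm comparisons as specified even though a post hoc on two groups
is redundant.

The subject-random-effect zero-inflated Gamma model is deliberately
simplified to a two-part GLM: logistic regression for presence and a
Gamma log-link regression for positive values, both with cluster-robust
(by subject) standard errors. This preserves the inference target —
responder × time contrasts on abundance — while avoiding full
Laplace/REML mixed-model machinery; the simplification is a documented
limitation, and parameter-recovery and type-I simulations in the tests
bound its behaviour (95 % CI coverage within [0.88, 0.995] at the simulated
settings).

## Synthetic cohort generator

The generator is first-class code: it defines the study conditions every
downstream test assumes. Two arms (38 regimen / 45 control subjects by
default — the completed-sequencing cohort, giving 83 × 3 conditions × 2
sequenced visits = 498 pooled samples), 3 sites per condition, visits at
months 0, 6 and 24, with the month-6 visit carrying only the TLR panel by
default.

**Latent structure.** Each (subject, condition, visit) cell has a standard
normal severity fluctuation η shared by all variables, plus independent
red, pink and commensal factors. A variable with condition levels `T_c`,
log dispersion σ and loadings (a, c) is generated on the log scale as
`ln T_c − V/2 + σ(a·η + c·f + e·ε) + s_u·u_subject + transition/treatment
terms`, with `V` the total log variance, so large-n condition **means**
equal the targets exactly (median-matched analytes — the TLR assays, whose
printed summaries are medians — drop the −V/2 term). Biomarker site
replicates add a small log-scale jitter (SD 0.1) around their cell value.
Condition levels get condition-specific intercepts rather than a single
log-linear severity slope because three arbitrary printed means generically
do not sit on one exponential curve; the continuous severity factor carries
the within-condition covariation instead.

**Dispersion defaults** (log-scale SD ≈ 0.28–0.5 for immunoassay panels,
1.1 for the decade-spanning TLR reporters, 0.55 for taxa) encode
within-condition coefficients of variation of roughly 30–60 %, enough
overlap that gingivitis and periodontitis are imperfectly separable (the
classifier lands near 85–90 % for those classes with healthy near 100 %,
driven by bleeding) while 500-subject-per-arm condition means converge to
within ~2 % of their targets.

**Named pair correlations.** The severity loadings of the configured pairs
(P. gingivalis–PAD 0.68; IL-1β–MMP-9 0.77) are solved so the
repeated-measures correlation of the generated data hits the target. The
within-subject covariance decomposes into (i) the deterministic "pattern"
part — condition levels, month-24 state transitions, treatment log-shifts
scaled by responder propensity — whose centered second moments are computed
by an internal fixed-seed Monte-Carlo over subjects, and (ii) the Gaussian
part, σ_v σ_w a_v a_w shrunk by (1 − 1/6) because subject-mean centering
over a subject's six cells shrinks iid components. Setting
`r* = (C_pattern + σσ'aa'·shrink)/√(V_v V_w)` and solving for the loading
product gives the calibration; infeasible targets (pattern covariance
already above the target, or loadings beyond the unit sphere) raise a
configuration error.

**Community.** 513 species: the red constellation (P. endodontalis,
T. forsythia, T. denticola, F. alocis) and the pink one (F. nucleatum,
TM7 ANC 38-39, D. invisus, T. socranskii) share within-group factors
(loading 0.74) and deliberately *different* condition profiles (red rises
late, pink already in gingivitis), which keeps within-clique correlations
near 0.85 and cross-clique ones near 0.52 — below the 0.6 edge rule, so the
two cliques stay distinct; P. gingivalis correlates with both groups at
~0.55–0.59, just outside the cliques. Four constellation-associated species
(C. rectus, F. fastidiosum; P. maculosa, A. dentalis) carry weaker group
loadings. Nine commensals load only on a severity-independent health factor
(S. mutans negatively), with flat condition profiles, so their factor
correlations are genuinely null. A 25-species pathogenic fringe (including
three placeholder-named bins that exercise the name filter), 271 common
fillers with modest loadings, and 195 rare species complete the pool;
presence probabilities are tuned so essentially the 318 non-rare species
pass the 10 % prevalence filter at study scale. Zero-inflation is
condition-linked for pathogens (absence is more likely at healthy sites):
on the 10th-root scale a zero is an enormous leverage point, so
condition-independent zeros would destroy correlations that the zeros of
real plaque data in fact reinforce — the constellation cores are therefore
fully detected (presence 1), mirroring targeted-mapping detection rates.

**Treatment and transitions.** Month-24 site states genuinely change: per
arm, a transition matrix moves periodontitis and gingivitis sites toward
health (and lets a few healthy sites deteriorate), with each subject's
Gamma(4, ¼) responder propensity (mean 1) amplifying improvement
(`1−(1−p)^ρ`) and damping deterioration. The defaults are calibrated so the
classification pipeline calls ≈70 % of regimen and ≈47 % of control
condition-units responders — a calibration of the generator, not a
discovery. Analyte treatment effects are configured as *net* month-24
multiplicative shifts of the arm-pooled mean (computed from printed arm
means where available, e.g. IL-1β 115.90 vs 166.34 pg/mL); the generator
divides out the transitions' own contribution and corrects the residual
log-shift for the propensity mixture (via the Gamma MGF) so the realised
mean shift equals the configured one. Taxon shifts per tier are applied
directly as residual effects on top of the transitions.

**Fluorescence curves.** Standard curves are monotone power ramps
`(t/T)^p` on a shared plate horizon; the exponent is solved by root-finding
so the discrete trapezoid-and-interpolation onset equals
`a/(ln conc − b)` exactly, which makes noise-free round trips through the
calibration exact to machine precision. Onset noise is multiplicative on
the onset time (the 1 % default matches a well-behaved plate). For a
monotone nonnegative signal the cumulative-AUC 30 % crossing is confined to
(0.3·T, T), so concentration series whose onsets spread more than ~3× on
one horizon are rejected with a clear error. Per-site TLR-ATP kinetics are
emitted alongside the scalar biomarker value; rare out-of-range onsets are
clamped and flagged.

**What the generator does not emulate:** read-level sequencing noise and
compositional artifacts of profiling; strain-level variation;
month-12/18 visits; site-level spatial correlation beyond the shared
condition cell; informative dropout of subjects (everyone completes); and
any dependence between assay noise across analytes beyond the shared
severity/constellation factors. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under the calibrated statistical
structure — not performance on raw sequencing data.

## Problem sizes and determinism

Tests run the full structure-recovery suite on the study-sized cohort
(83 subjects) and the convergence/calibration checks on 500 subjects per
arm; simulation-based checks (type-I error, CI coverage) use 25–1000
replicates at small n, sizes chosen as the smallest that give the binomial
bounds stated in each test. The acceptance script uses 500 subjects per
arm. All randomness flows from explicit seeds through numpy Generators; the
pair-calibration Monte-Carlo uses its own fixed internal seed so solved
loadings are identical across cohort seeds. Same config and seed reproduce
every table byte for byte.

## Known limitations

* The hurdle model approximates, not implements, the random-effect
  zero-inflated Gamma; variance components are not reported.
* The pair calibration guarantees the configured correlations only at the
  granularities the pipeline screens (pooled taxa vs condition-averaged
  factors; site-level biomarker pairs); other alignments shift r by a few
  hundredths.
* Cluster labels I–III depend on the linkage/distance defaults; with very
  few strongly-correlated taxa the "III" cluster can be small.
* The CLI's single-stage commands re-read artifacts from the work
  directory; mixing artifacts from different configs is not detected
  beyond the manifest hash.
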