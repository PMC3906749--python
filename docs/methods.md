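# Methods

This note documents the models and procedures `msetkit` implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions made
where the design was genuinely open.

## Differential-expression ranking

Expression is handled on the log2 scale throughout; fold changes are
reported on the linear scale as the ratio of back-transformed group
means (2^mean-log2), postpartum over virgin, so values above 1 mean
higher postpartum expression.  Per-gene significance is a two-sided
Welch *t*-test on the log2 values.  This is a deliberate stand-in for
array-specific summarization and empirical-Bayes moderated fits
(PLIER/limma-style): the contribution of this package is everything
downstream of a ranked `(symbol, p, fold change)` table, and the Welch
test is the assumption-light per-gene default.  Degenerate rows are
resolved by convention: zero variance in both groups with equal means
gives *p* = 1; with unequal means the *p* floor (smallest positive
float) is reported.

BH-FDR *q*-values use the standard step-up rule (delegated to
`statsmodels.multipletests(method="fdr_bh")` and verified against a
brute-force implementation of the definition in the tests).  The
significant set uses a *strict* nominal threshold (*p* < α, ties at α
excluded), keeps annotated symbols only, and collapses duplicate probes
to the smallest *p* — the collapse rule is our choice; nothing in the
emulated workflow pins it down.

## Gene-list curation

Symbols are canonicalized to first-letter-upper display form with
whitespace trimmed; matching is therefore case-insensitive, which is
how human-database symbols (SHANK3) are matched to mouse-style array
symbols (Shank3).  No orthology mapping is attempted — a documented
limitation, acceptable because symbol-level matching is what the
emulated workflow used.  Lists are restricted to the measured
background before any testing; members absent from the array are
counted and excluded so they cannot inflate *K*.  A list that is empty
after restriction is carried as "excluded (too small)" rather than
dropped silently.  Pairwise Jaccard similarity above 0.8 flags a pair
of lists as near-duplicates; they are flagged and reported, never
auto-removed, so the analyst reproduces the manual exclusion step.  The
0.8 threshold is a stated stand-in — the original screen was visual.

## MSET

The test statistic is the match count *k* between the significant set
(size *n*) and a background-restricted list (size *K*).  The null is
built by *B* draws (default 10,000) of *n* symbols uniformly without
replacement from the unique annotated background (size *N*).  Sampling
is at the gene level, not the probe level: match counts are reported as
genes, so genes are the exchangeable unit.  The one-sided empirical p

    p_emp = (1 + #{null >= k}) / (B + 1)

uses the add-one permutation convention: it can never be 0, its floor
1/(B+1) is attained when *k* beats every null draw, and the null
support is exactly {(1+j)/(B+1)}.  Each draw is realized as the *n*
smallest of *N* iid uniform keys, vectorized in chunks, so a full
10,000-draw test on a 5,000-gene background runs in seconds.

Because the draws are without replacement, the null match count is
exactly Hypergeometric(*N*, *K*, *n*).  The package keeps the
closed-form tail as an independent oracle (`hypergeom_tail`, backed by
`scipy.stats.hypergeom.sf`) and the test suite requires
|p_emp − P(X ≥ k)| ≤ 3·√(p(1−p)/B) across a grid of configurations —
the sampling machinery is never trusted on its own.

**Calibration and ties.** The raw `p_emp` is *conservative* whenever
null draws tie with the observed count, which is unavoidable for
small-integer match counts; it is therefore super-uniform under the
null, not exactly uniform.  The exactly-uniform statistic under
exchangeability is the tie-randomized null rank
(`randomized_null_rank`), which resolves ties between the observed
count and null counts uniformly at random.  Calibration diagnostics
KS-test that statistic against Uniform(0,1); the raw p is separately
checked to be conservative at α = 0.05.

**Null-shape screen.** A null with sample skewness |g₁| > 1 or mean
below 5 matches is flagged as unreliable (an explicit, reproducible
version of discarding visibly skewed null densities; tiny lists produce
exactly such nulls).  Degenerate (zero-variance) nulls are always
flagged.

**Panels.** Each list in a panel gets an independent random substream
derived from the master seed and the list's *name* (CRC32), so adding
or removing lists never perturbs another list's result.  Control lists
(expected non-enriched) run through the identical machinery.  The
multi-list report collects matched genes appearing on ≥ 2 lists of the
same disorder category.  No correction across lists is applied by
default — panel p-values are reported raw, as is conventional for this
test; the BH utility is available to the analyst.

**Robustness re-run.** `robustness_rerun` removes named symbols from
the significant set (shrinking *n*) while leaving the background
unchanged — the genes were measured; only their claim to significance
is withdrawn — and reports paired before/after panels with per-list p
deltas.  This mirrors re-testing after removal of genes that failed
downstream verification.

## Weighted co-expression network

Genes entering the network are the annotated rows with nominal
*p* < 0.05 (configurable), duplicates collapsed to genes first.  The
network is **unsigned**: a_ij = |cor(x_i, x_j)|^β, the historical
default of the method.  The soft-threshold power β is chosen as the
smallest candidate in 1..30 whose scale-free topology fit reaches
R² > 0.8 — connectivities k_i = Σ_j a_ij are binned into 10 equal-width
bins and log10(frequency) is regressed on log10(mean k); a
non-negative slope scores 0 — falling back to the argmax R² with a
warning when no power qualifies.  Topological overlap is the standard
ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij).

**Module detection** is average-linkage hierarchical clustering of
1 − ω with a *static* cut at 0.99 × the maximum merge height; flat
clusters below 30 genes join the unassigned pool.  The dynamic hybrid
tree cut is deliberately not reimplemented; the static cut is the
classical alternative and its height fraction is configurable.  Note
the fraction multiplies the maximum merge height (the classical static
convention): chance-level gene pairs sit at dissimilarity ≈ 1 and merge
above the cut, so pure-noise inputs correctly fragment into unassigned
singletons, while genuinely co-expressed blocks merge far below it.
Modules whose eigengenes are closer than the merge threshold 0.25
(dissimilarity 1 − cor) are merged iteratively, recomputing eigengenes
after each merge, with a smallest-label tie-break so the result is
independent of input order.  Surviving modules are labeled by size rank
in the conventional color order (largest = "turquoise", then "blue").

The **module eigengene** is the first right singular vector of the
per-gene standardized module submatrix, sign-oriented so its mean
correlation with member genes is non-negative; variance explained is
the first squared singular value's share.  The **module–trait
statistic** is the Pearson correlation of the eigengene with the 0/1
phenotype (0 = virgin, 1 = postpartum, so positive r = postpartum-
associated), with two-sided p from t = r√(n−2)/√(1−r²) on n−2 df.
At n = 12 this gives p = 4.6e-4 for r = 0.85 and p = 2.3e-6 for
r = 0.95.  (Published figures of this kind sometimes label the
correlation "R²"; 0.85 reproduces the reported p only when read as r,
so the package reports r and leaves the label discrepancy to the
reader.)

**Regulator edges.** For a chosen module, all within-module gene pairs
with at least one endpoint in the regulator catalog are exported with
the TOM similarity as weight (raw adjacency available as an option —
which weight a published network figure used is typically unstated),
optionally keeping only the top-k edges per regulator, sorted by weight
with a stable symbol tie-break, in Cytoscape-importable TSV form.

**Choosing β on planted-module data.** Scale-free selection is
meaningful for real transcriptome networks but ill-posed for synthetic
two-factor data, which is not scale-free (the selector then falls back
to argmax with a warning).  The module-recovery analyses therefore pass
an explicit β = 21, the power used in the emulated study.  A high power
matters structurally here: two modules planted with trait correlations
+0.85 and −0.85 share the trait factor, so their eigen-signals
correlate at −0.7225 and only |cor|^β with large β pushes the
cross-module overlap above the static cut.

## REST-style qPCR

The efficiency-corrected expression ratio of a target *t* is
E_t^ΔCt(t) / geomean over references r of E_r^ΔCt(r), with
ΔCt = mean control Ct − mean treated Ct and per-gene amplification
efficiency E ∈ (1, 2].  Efficiencies must be supplied explicitly per
gene, or via an explicit global flag recorded on the assay — there is
no silent default.  Missing Ct values drop that sample for that gene
only, with at least 2 observations per group per gene enforced.
Adding a constant to all Ct values of one sample (a loading artifact)
cancels exactly.

Significance is a two-sided sample-level label-permutation test on the
log-ratio, permuting the group labels jointly for target and
references.  The exact fixed-reallocation scheme of the original REST
software is unpublished; a label-permutation test is the documented
stand-in, two-sided because both up- and down-regulation are reported.
When the number of distinct treated-set allocations C(m, m_t) is at
most B (default 2,000) — e.g. 924 at 6+6, 20 at 3+3 — the full
allocation set is enumerated and p = #{|stat| ≥ |observed|}/total
(exact, flagged in the result); otherwise B Monte-Carlo permutations
give the add-one p.  At 3+3 the two-sided enumeration floor is
2/20 = 0.1, so no 3+3 design can reach 0.05 — the result object says
so via its `exact`/`n_permutations` fields.  A direction (up/down) is
called only when p < 0.05.

## Synthetic-data generator

The generator emulates the study design the package targets: 6 + 6
samples, a desk-scale universe of 5,000 symbols (configurable; standing
in for a 35,557-target array), log2-scale generation with per-gene
Gaussian noise.  Componentwise:

* **Baselines** ~ N(7, 1.5²) log2 units, microarray-like intensity.
* **DE genes**: a fraction (default 5%, i.e. 250 genes at the default
  size) get a planted log2 fold change.  `fc_range` gives the
  *magnitude* range — default 1.4–2.0, drawn log-uniformly — and
  `down_fraction` (default 0.5) of the DE genes are inverted below 1,
  so planted fold changes straddle 1 while staying bounded away from
  it.  A degenerate range (x, x) plants a fixed fold change.  The
  default magnitude keeps per-gene Welch power at α = 0.01 high enough
  that the significant set at the default size is on the order of the
  planted DE count (~250–300), the regime the enrichment power
  analyses assume.  Noise SD defaults to 0.2 log2 units — a
  conventional choice; the emulated study reports no variance
  components to calibrate against.
* **Modules**: disjoint gene blocks (default 60 and 40) driven by a
  per-module eigen-signal e = r·t + √(1−r²)·g, where t is the
  standardized 0/1 trait and g a random residual orthogonalized
  against t *and against previous modules' residuals*, then
  renormalized — so the sample correlation cor(e, trait) equals the
  planted r exactly and distinct modules are genuinely distinct
  in-sample (with only 12 samples, unconstrained residuals would
  occasionally be near-collinear by chance and silently collapse the
  planted truth).  Gene loadings are U(0.8, 1.2).  Module genes are
  excluded from the DE draw by default so the two kinds of planted
  truth stay separable; a flag allows overlap.
* **Gene-list panels**: each list draws round(ρ·size) members
  uniformly from the true-DE genes and the rest uniformly from the
  remainder of the universe, without replacement; ρ is recorded as
  ground truth.  Default panel: four disorder-style lists with
  ρ 0.4–0.5 in three categories plus three ρ = 0 control lists.
* **Regulator catalog**: 37 transcription factors, 17 co-factors, and
  7 chromatin remodeling factors (the category counts reported in the
  emulated study), preferentially assigned to module and DE genes so
  the catalog intersects the interesting parts of the study.
* **qPCR**: Ct = baseline − shift(group)/log2(E) + noise, shift
  applied in the postpartum group, references generated with shift 0.
  Shifts are in log2 units so the true ratio is 2^shift independent of
  E.  Default targets mirror familiar verification genes (Oxtr, Socs2,
  Gabre, Ace) with shifts matching fold changes of about 1.14, 1.63,
  0.73, and 0.91; references are Hmbs and Hprt; Ct noise SD 0.15.

Everything is deterministic given the seed.

**What the generator does not emulate** — and hence what passing tests
do not establish about real arrays: probe-level intensity structure and
normalization artifacts, heteroskedastic and correlated per-gene noise,
batch effects, estrous-cycle covariates, heavy-tailed fold-change
distributions, and annotation errors.  Recovery results on this
generator validate the *machinery* (the tests are exact or calibrated
against oracles), not the biology of any particular dataset.

## Problem sizes used in the automated analyses

The acceptance script and end-to-end tests run at sizes chosen as
desk-scale defaults: the oracle-equivalence grid spans backgrounds of
500–5,000 genes at B = 10,000; null calibration uses 500 replicate
lists at B = 1,000 on a 2,000-gene background; power and robustness use
100 replicate 5,000-gene studies (250 planted DE genes, ρ = 0.5 lists
of 50, B = 1,000, 20% of matched genes removed for the re-run); module
recovery uses a 400-gene study with the two planted modules and no
planted DE (trait-driven DE genes are intercorrelated through the
binary phenotype and are not part of the two-module structure — the
combined configuration is exercised separately in the unit tests);
REST power uses 100 replicates at a planted ratio of 2 with exact
924-allocation enumeration.

## Known limitations

* Welch ranking ignores the variance-moderation benefits of
  empirical-Bayes fits at n = 6 per group; rankings on real small-n
  arrays will differ from limma-style pipelines.
* Symbol-level, case-insensitive matching only; no ortholog service.
* The static tree cut is cruder than the dynamic hybrid cut; very
  unequal module densities can shear off or absorb genes near the cut,
  and chance-correlated noise genes adjacent to a strong module may be
  absorbed into it.
* The REST permutation unit is the sample; replicate-level
  fixed-reallocation (as in the original closed-source tool) is not
  reproduced.
* MSET panel p-values are reported without cross-list correction, as
  is conventional for the test; users comparing many lists should apply
  the provided BH utility to the panel column themselves.
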