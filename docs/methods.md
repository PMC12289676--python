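# Methods

This note documents the statistical machinery implemented in `udpharm`,
the assumptions behind the synthetic-study generator, the numerical
choices, and the known limitations. Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Uniform design (`udpharm.design`)

A U_n(n^s) table is built by the good-lattice-point rule
`level(i, j) = ((i·g_j − 1) mod n) + 1`, i = 1..n, with generators g_j
drawn from the integers in [1, n) coprime with n. Every column is a
permutation of 1..n, so each factor visits every level exactly once. When
the caller does not fix the generators, the s-subset minimizing the
centered L2 discrepancy

CD²(P) = (13/12)^s − (2/n) Σ_i Π_j (1 + ½|u_ij − ½| − ½|u_ij − ½|²)
       + (1/n²) Σ_i Σ_k Π_j (1 + ½|u_ij − ½| + ½|u_kj − ½| − ½|u_ij − u_kj|)

(levels mapped to u = (level − ½)/n) is selected by exhaustive search over
the C(φ(n), s) candidate subsets; ties break to the lexicographically
smallest set. For seven runs and six factors all six coprime generators
are required, so the table is unique up to column assignment; columns are
assigned to herbs in formula order (ZR, GCR, LAR, CR, FF, PR).

Levels map to doses linearly: dose = low + (level − 1)/(n − 1) · (high −
low). Default per-herb ranges are the reference formulation dose ± 50%
(ZR 4 g, GCR 6 g, LAR 9 g, CR 6 g, FF 4 g, PR 6 g), overridable. The
choice of a linear, equally spaced mapping is a modeling decision; no
pharmacokinetic spacing is attempted.

Interspecies scaling uses the body-surface-area convention: animal dose
(g/kg/day) = human daily dose (g) / human mass (kg) × factor, with 6.3 as
the human→rat factor. 35 g/day for a 70 kg adult gives 0.5 g/kg/day and a
rat-equivalent 3.15 g/kg/day.

## Composite scoring (`udpharm.scoring`)

**Ulcer index.** Each lesion scores by length: punctate (by default
length < 1 mm) → 1; < 2 mm → 2; 2–3 mm → 3; 3–4 mm → 4; > 4 mm → 5. The
stated bands leave the boundaries ambiguous; we close each band on its
left edge ([2, 3], (3, 4]). An erosion width above 1 mm doubles the
lesion's score. The index is the sum over lesions, hence additive over
lesion lists.

**Entropy weights.** Indicators are min–max normalized with an
orientation (the lower-is-better form is the reflection (Wmax − W)/(Wmax
− Wmin)). For the normalized matrix x (samples × indicators), shares
p_ij = x_ij/Σ_i x_ij give Shannon entropies e_j = −(1/ln n) Σ_i p_ij ln
p_ij (with 0·ln 0 = 0) and weights E_j = (1 − e_j)/Σ_k (1 − e_k).
Constant columns carry no information and receive weight zero. Weights
are computed on per-animal values within the analyzed samples; the
min–max envelope is the set of all analyzed samples. Composites are
convex combinations of values in [0, 1], so Y ∈ [0, 1], the best
observed profile scores 1, and improving any component (toward its
favorable direction, within the envelope) never lowers Y.

The six published composite specifications (MRS, RF, GIC, SIC, LF, HIC)
ship as fixtures with their reported weights; each weight set sums to 1
within 1e−4.

## Dose–effect models (`udpharm.herbfx`)

The response is the per-run mean of the indicator over the animals of
each uniform-design formulation. Doses are Z-scored per herb, expanded
into the 6 + 6 + 15 = 27 linear, quadratic and pairwise-interaction
terms, and the term columns are Z-scored again so coefficients are
comparable across terms.

Selection is two-stage. LASSO with the penalty minimizing leave-one-out
CV error (n = 7 observations) keeps a candidate set; bidirectional
stepwise search then minimizes AIC = n·log(RSS/n) + 2·edf over single-term
moves, with additions restricted to the LASSO survivors, deletions
unrestricted, ties preferring deletion then term order, and the model
size capped at n − 2 terms so p-values retain at least two residual
degrees of freedom. The final OLS fit reports raw coefficients (on the
standardized-term scale), standardized coefficients (× sd(term)/sd(y)),
per-term t-test p-values, R² and the overall F-test p-value.

**Known limitation — aliasing and small-n AIC.** With seven run means the
27 term columns span at most a six-dimensional space. Measured
consequences (reproduced by `experiments.spra_recovery`): the centered
term columns contain aliases correlated up to r = 0.96, including pairs
where an alias correlates more strongly with a generating signal than the
generating term itself, so the LASSO path can be structurally unable to
activate a true term; and because any ~5 independent columns nearly
saturate 7 observations, n·log(RSS/n) rewards near-saturated fits and
stepwise AIC systematically prefers larger models than the truth
regardless of the noise level. Exact-support recovery of a 2-term truth
is therefore near zero under these conditions, and the selected model
must be read as a sparse description of the dose–response surface over
the design region, not as a recovery of generating terms. Single-term
and restricted-candidate recovery, sign consistency of well-identified
fits, and the size cap are all verified by tests.

## PLSR and VIP (`udpharm.plsr`)

NIPALS with both blocks autoscaled (mean 0, sample SD 1, ddof = 1). Per
component the inner loop alternates w = X'u/‖X'u‖, t = Xw, q = Y't/t't,
u = Yq/q'q until the score vector changes by less than 1e−10 (at most 500
iterations, else a convergence error); X and Y are deflated by the
rank-one approximations t p' and t q'. Because q is the least-squares
projection of the Y-residual on t, the explained Y-variance decomposes
exactly: SS_a = (t'a t_a)(q'a q_a)/SS(Y), each SS_a ≥ 0 and Σ SS_a ≤ 1.
The component count is the smallest A whose cumulative explained
Y-variance exceeds 0.80 (configurable); if the threshold is never
reached the maximum usable count is returned with a warning. Components
are probed incrementally so an ill-conditioned deep component ends the
search instead of aborting it.

VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a); since weight columns
are unit-norm and the per-component shares sum to 1, Σ_j VIP_j² = p on
every fit. Predictors with VIP strictly above 1 are screened in,
descending. Genus relative abundances and peak areas enter as-is after
autoscaling (no log-ratio transform — see limitations); columns with
missing values are rejected rather than imputed.

## Piecewise SEM (`udpharm.psem`)

The mediation hypothesis is a DAG over exogenous herb-dose terms,
mediators and outcomes. Each non-exogenous node is fitted by Gaussian
OLS on its parents. The d-separation basis set contains one claim per
non-adjacent pair — the topologically later variable is the regression
response, conditioning on the union of both variables' parents — and each
claim is tested by the two-sided t-test of X's coefficient in the OLS of
Y on {X} ∪ conditioning set, matching the Gaussian component models.
Fisher's C = −2 Σ ln p_i is compared to χ² with 2k degrees of freedom
(k = 0 yields the saturated convention C = 0, p = 1; p-values of exactly
0 are clamped at 1e−300 with a warning). K counts every estimated
likelihood parameter — slopes, intercepts and residual variances — so
AIC = C + 2K. Pruning removes the single worst path with p ≥ α (default
0.05), one at a time to avoid order artifacts, refitting after each
removal; a model pruned to no edges is returned flagged empty.

Calibration, measured by the packaged experiments: the claim test's
type-I error sits in [0.03, 0.07] at α = 0.05 over 500 null replicates
(n = 500); for data generated from a chain DAG with standardized paths
0.8 at n = 200, adequacy (p > 0.05) holds in ≥ 90% of seeds; omitting a
standardized 0.6 edge is detected (p < 0.05) in ≥ 90%.

## Synthetic studies (`udpharm.simdata`)

The generator emulates the study structure: 10 groups (healthy control,
injured model, reference formulation, seven design formulations) × 5
animals. Treated animals follow endpoint = intercept + Σ β_t·t(doses) +
N(0, σ²) with terms on the standardized scale of the design's seven runs;
control and model groups get configured healthy/injured means (±2
SD-equivalents by default, with treated intercepts in between —
partial repair). Default noise SD is 0.25 on the standardized endpoint
scale. Mediators are generated in topological order as linear functions
of their declared parents plus Gaussian noise; genus latents pass through
a per-row softmax so abundances are compositional (rows sum to 1), peak
latents are exponentiated so areas are positive log-normals; outcomes add
their mediator contributions. Noise streams are keyed by (seed, variable
name), so output is byte-deterministic under a fixed seed and a
variable's draws do not shift when unrelated variables are added.

What the generator does **not** emulate: measurement-scale heterogeneity
across ELISA kits, count noise and sparsity of 16S data, batch effects,
or nonlinearities beyond the declared polynomial; passing tests therefore
demonstrate correctness of the machinery under its own assumptions, not
performance on real assay data. One deliberate realism is kept: because
genus abundances are closed (softmax), genera are mutually negatively
coupled in a way no linear DAG over terms explains — so a path model that
wires several genera into one outcome is *correctly* rejected by the
d-separation test, as the end-to-end pipeline example shows.

## Pipeline defaults and problem sizes

The one-command pipeline scores the six composites with data-estimated
entropy weights, fits one dose-effect model per composite on the seven
design runs, screens mediators per block with the 0.80 ncomp rule and
VIP > 1 (top three carried forward), fits and prunes one path model per
outcome at α = 0.05, and writes Spearman liver-vs-gastric matrices
(unadjusted p by default; Benjamini–Hochberg opt-in). Every artifact
embeds the seed and a configuration hash; identical configurations
reproduce byte-identical CSVs.

The packaged experiments use 100 seeds per recovery question (500 for
type-I calibration), 7 runs × 5 replicates for the dose-effect stage, 35
samples for screening, and n = 200 for path-model checks — sizes chosen
to mirror the emulated study and keep the full suite in the tens of
seconds on one CPU.
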