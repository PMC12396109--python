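# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `carveflux`, in the order the pipeline runs them.

## Problem setting

A genome-scale metabolic model (GEM) is a stoichiometric matrix *S*
(metabolites × reactions), flux bounds lb ≤ v ≤ ub, gene–protein–reaction
(GPR) boolean rules, and a designated biomass pseudo-reaction. At
quasi-steady state the feasible fluxes form the polytope
P = {v : S v = 0, lb ≤ v ≤ ub}. Given a universal (organism-wide) GEM and a
per-condition list of expressed genes, the pipeline produces a
condition-specific GEM, characterizes its flux distribution, and converts
that characterization into gene-level scores that can sit alongside
ordinary differential-expression output.

## GPR rules

Rules are boolean expressions over gene identifiers with `and` (complex:
all subunits required) and `or` (isozymes: any suffices); `and` binds
tighter than `or`. The parser accepts the `AND/OR` and `&&/||` dialects
found in different model exports and normalizes on parse. Gene identifiers
are matched by exact string comparison after whitespace trimming; no
symbol/ID conversion is attempted — count tables must be keyed on the
model's gene namespace. An *empty* rule is represented as absence rather
than as TRUE or FALSE, because exchange, biomass and spontaneous reactions
carry no genetic evidence either way and need their own treatment during
carving and projection.

## Expression filter

Default rule (per condition): gene kept iff (i) CPM ≥
`min_count / median(library sizes) × 10⁶` in at least
`ceil(min_prop × n_samples)` of the condition's samples, and (ii) summed
counts ≥ `min_total_count`. Defaults `min_count = 10`,
`min_total_count = 15`, `min_prop = 0.7` follow the widely used
count-filtering practice in differential-expression analysis. Library size
is the raw column sum (UMI counts; no normalization factors). Filtering is
computed within each condition — one expressed list feeding one carve per
condition — since the carve consumes per-condition presence. A gene with
zero counts in a condition is never called expressed, regardless of
thresholds. Two simpler alternatives (raw count ≥ k in ≥ m samples; fixed
CPM cutoff) are selectable.

## Carving

Evidence score per reaction r: +1 if its GPR evaluates TRUE against the
expressed set, −`penalty_absent` (default 1.0) if FALSE, 0 if there is no
GPR. The MILP selects inclusion indicators y_r maximizing

  Σ_{s_r>0} s_r·y_r + Σ_{s_r<0} s_r·y_r − penalty_nogpr·Σ_{s_r=0} y_r

subject to S v = 0, lb_r·y_r ≤ v_r ≤ ub_r·y_r, and biomass functionality
v_bio ≥ f_min · v_bio^max (f_min default 0.1; the universal maximum is
computed by LP first). A supported (positive-score) reaction is rewarded
only when it *carries* flux: each such reaction gets two direction binaries
y⁺, y⁻ with

  ε·y⁺ + lb·y⁻ ≤ v ≤ ub·y⁺ − ε·y⁻,  y⁺ + y⁻ ≤ 1,  y = y⁺ + y⁻,

which enforces |v| ≥ ε (default ε = 10⁻⁴ flux units) exactly when the
reaction counts toward the objective. A formulation that merely splits
v = v⁺ − v⁻ and requires v⁺ + v⁻ ≥ ε·y does not achieve this (the split is
not forced tight, so v⁺ = v⁻ = ε/2 satisfies it at v = 0); the direction-
binary form is the standard linearization and is what the implementation
uses. The biomass reaction is unconditionally included. Score magnitudes
(+1 / −1 / −0.01) are chosen so one supported reaction outweighs many
GPR-less carriers; all are configurable. Exchange bounds are taken verbatim
from the universal model, overridable by a medium TSV. The solve is a
single deterministic HiGHS MILP with relative gap 10⁻⁶; ties between
equal-objective subnetworks are broken by the solver, and the report
records the objective value so alternates can be detected.

Blocked reactions (FVA range within ±10⁻⁶) are removed before sampling so
the polytope is bounded and full-dimensional in its affine hull; the
operation is idempotent.

## Flux sampling

**Global sampler** — artificial-centering hit-and-run. Warmup: 2N LP
vertices (every reaction's FVA minimum and maximum, then random ±eᵢ
objectives), re-projected onto the null space of S once (LP residuals
~10⁻⁷ would otherwise leak out of the null space). Each step draws a
stored warmup vertex, takes direction d = (vertex − center)/‖·‖, computes
the feasible chord through the current point from the bounds only (the
steady-state constraint is invariant along d), and jumps to a uniform
point on the chord. The center is the running mean of all accepted points.
Every `thinning`-th step is recorded (default 100 for desk-scale runs;
production-scale runs on full human GEMs use 10 000). Walker and center
are re-projected onto the null space every 1000 steps: because the center
update feeds the walker's rounding error back into future directions, the
residual otherwise grows exponentially (~×10 per 1000 steps from 10⁻¹⁶).
With projection, recorded samples satisfy |S v| < 10⁻¹² in practice
(tolerance asserted: 10⁻⁶) and bounds exactly. Degenerate directions
(norm < 10⁻¹²) are re-drawn; 1000 consecutive failures abort with a
pointer to `remove_blocked`.

**Corner sampler** — n LPs maximizing random standard-normal objectives;
each optimum is a vertex/face point, so this view weighs the extreme
phenotypes. Corner samples are not a Markov chain and are excluded from
convergence testing.

**Stopping rule.** After each batch (default 5000 recorded samples) the
Geweke z is computed for every reaction and the Raftery–Lewis requirement
for the 50 highest-variance reactions; the chain is converged when ≥95 %
of reactions satisfy |z| < 1.96 and the length exceeds the largest
Raftery–Lewis requirement, with a hard cap (default 150 000).
Non-convergence at the cap is a reported state, not an error. The two
sampling methods are independent, user-selectable alternatives. All
randomness flows from one user-visible seed; batch continuation uses the
same generator state, so runs are bit-reproducible.

**Geweke z** compares the first 10 % and last 50 % segment means,
normalized by spectral-density-at-zero variance estimates (Bartlett window
over the first 4 % of lags; plain variance is the documented fallback when
the windowed estimate is non-positive, and the report records which
estimator ran). Chains constant up to rounding score 0.

**Raftery–Lewis** (q = 0.025, r = 0.005, s = 0.95 by default): binarize at
the empirical q-quantile, find the smallest thinning k at which a
first-order two-state Markov chain beats second-order by BIC, estimate
transition probabilities α, β, and return
k · (2−α−β)αβ/(α+β)³ · (Φ⁻¹((s+1)/2)/r)² plus burn-in. Chains shorter than
the independence minimum (≈3746 at the defaults) raise an error; a chain
that never leaves one state at the chosen thinning reports the
independence minimum as a floor rather than dividing by zero.

## Reaction scoring

Pearson correlation (Spearman selectable) of flux columns; a zero-variance
column has correlation 0 against everything *including itself*. RCC_i =
Σ_j |corr_ij| with the self term included — under this convention, and only
under it, the score range [0, N] is attained at both ends (0 by constant
columns, N by perfect coupling). Mean flux and sample standard deviation
(ddof 1) complete the per-reaction table.

Differential comparison over the union of two carved models: Δmean flux
and Δrcc are A − B with the absent side contributing 0 (union semantics —
presence/absence is itself the carving signal; membership flags allow
filtering to the intersection). Significance: two-sided Welch test on
every `test_stride`-th sample (default: at most 1000 per side) — sampler
draws are autocorrelated, and a naive per-sample test would overstate
significance; the stride is written into the output. Degenerate cases: two
constant columns give p = 1 when equal and 0 otherwise; a reaction absent
from one side compares the present column against an identically-zero
column (p = 0 when the mean is more than one standard error from zero,
else a one-sample test). No reaction-level multiple-testing correction is
applied; correction happens downstream at gene-set level.

## Gene projection

A gene belongs to every reaction whose GPR mentions it. Default
aggregation over a gene's reactions is the value largest in magnitude with
its sign (max-|·|): a gene is as important as its most important reaction;
mean and sum are selectable and the full gene×reaction long table is
always emitted so nothing is lost. The gene-level p-value is the
best reaction's p-value, not a combined one — combining overlapping,
autocorrelated tests would require machinery out of scope here, and the
choice is recorded in the output. Signature selection applies
|Δusage| > 0.5 (raw flux units) with p < 0.05, at gene level after
projection; a config flag allows reaction-level pre-filtering instead.
Thresholds are parameters, not constants.

## Enrichment

ORA: upper-tail hypergeometric per set (sets intersected with the universe
first), Benjamini–Hochberg across sets. The default universe is the carved
models' gene set, not the genome — the signature is drawn from model
genes, and a genome universe would inflate enrichment. GSEA is pre-ranked
(weight exponent 1) with a gene-permutation null, since the input is one
score per gene rather than per-sample expression; NES divides by the mean
|null ES| of matching sign and the empirical p carries a +1 pseudocount.
Annotations are user-supplied GMT files; no database is bundled.

## Reporting

MA-like table: mean log2(CPM + 1) over the two conditions' samples
(pseudocount 1; the expression-axis transform is a presentation choice)
against the projected Δusage. Volcano table: external DE statistics with
point size |Δusage| and a |log2FC| > 1 flag. The interactive viewer is
replaced by these plot-ready TSVs (optional static PNGs); the manifest
records inputs (SHA-256), seeds, thresholds, package versions and
convergence status, making reruns auditable.

## Synthetic fixtures and what they show

The toy universal model is a linear uptake → backbone → biomass → sink
chain (unit stoichiometry, irreversible reactions, uptake bound 10) with
optional gene-labeled branch routes; maximal biomass equals the uptake
bound by construction. Synthetic counts are negative-binomial with mean
200 for expressed genes, 1 otherwise (dispersion 0.1 — variance
μ + 0.1μ²), a deliberately extreme on/off separation so that end-to-end
tests stress carving and sampling rather than the filter; tighter
separations are available for filter-focused tests.

The two-condition ground-truth pair places its single branch across the
full internal backbone. This is a geometric necessity, not a convenience:
with a partial-span branch, the extra degree of freedom changes the
*volume* weighting of the uptake marginal under uniform sampling (mean
uptake 2·ub/3 with the branch versus ub/2 without), so out-of-span
backbone reactions would acquire a spurious Δ ≈ +ub/6 and exact recovery
would be false for any correct sampler. With the full span, backbone
deltas are negative (≈ −ub/6, reported by the reverse contrast) and the
branch delta is ≈ +ub/3, so the forward signature is exactly the branch
gene.

What the fixtures do **not** emulate: realistic GEM scale (thousands of
reactions), reversible reactions and loops, realistic media, sequencing
artifacts, sample-level biological variance, or identifier-mapping noise.
Passing tests therefore demonstrate algorithmic correctness at small
scale, determinism, and calibrated diagnostics — not biological validity
on real human data.

## Problem sizes and defaults used in verification

Verification runs use toy models of 5–9 reactions, 10 000-sample global
chains at thinning 100, 1000-corner samples, 200 diagnostic chains of
10 000 points, and full pipeline runs whose convergence rule stops at
5000 samples per condition. These sizes are chosen so the whole
verification suite is a desk-scale computation; the algorithms themselves
have no small-scale assumptions, and production settings (thinning 10 000,
cap 150 000) are plain configuration.

## Known limitations

- No loopless-flux correction: thermodynamically infeasible cycles, if
  present in the input model, are sampled as feasible.
- No gap-filling or medium inference; an infeasible carve at the requested
  f_min is reported, not repaired.
- Gene-level p-values are inherited from a single reaction; they order
  genes sensibly but are not calibrated family-wise error rates.
- Exact recovery guarantees apply to the fixture geometry; on real models,
  signature content depends on medium, f_min and threshold choices.
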