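# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the limits of what the tests demonstrate.

## Units and conventions

Ages are Ma before present (larger = older); edges store durations in
Ma; traits are log10 lengths in log10 mm (raw mm tables are transformed
on read, disable with `--no-log`). Working in log10 means fitted OU
optima back-transform directly to millimetres (10^2.17 ≈ 148 mm). Rate
units: σ² in (log10 mm)²/Ma, α in 1/Ma, drift μ in log10 mm/Ma. Rate
multipliers r are dimensionless, relative to the background.

All variance estimates are ML (divisor n, not REML), so log-likelihoods
are comparable across models with different mean structures and AICc
arithmetic is coherent. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1). Parameter
counts are deliberately explicit and are reported next to every AICc:

- BM, one trait: k = 2 (σ², root state). Two traits: k = 5 (three
  entries of R, two root states). n in the AICc correction is the number
  of scalar observations (tips × traits).
- Each accepted rate shift adds 1 (the scalar). The shift's location is
  searched over but not counted — the convention of the stepwise-search
  literature; if a different convention is preferred, the reported k and
  lnL allow recomputation.
- OU family (one trait): BM1 k=2, BMS 3, OU1 3, OUM 4, OUMV 5, OUMA 5,
  OUMVA 6 (each α, each σ², each θ, one root-mean/θ set as listed).
- PGLS: k = #coefficients + 1 (σ²) + 1 when λ is profiled.

## Time-scaling

Internal nodes are first dated by their oldest descendant tip (FAD by
default; drawing uniformly between FAD and LAD is available, seeded, for
sensitivity replicates). This dating necessarily creates zero-duration
edges; three repairs are provided.

**equal_oldest.** Edges are visited in preorder (root-to-tip,
left-to-right — ties among equally old descendants are resolved by this
fixed order). A zero edge pulls in the chain of consecutive zero edges up
to the nearest ancestral edge with positive duration; the spanned time is
re-divided evenly over donor + chain by re-spacing the intermediate node
ages. Because chain edges are consecutive zeros, re-spacing only raises
intermediate nodes, so no other edge can become negative and tip dates
never move. The root stem (5 or 10 Ma typically) is the ultimate donor,
which is why its choice propagates into basal branch lengths. Worked
two-taxon example (FADs 150 and 140, stem 5): the node is dated 150 with
a zero edge to the older tip; stem + zero edge share 5 Ma equally, so the
node moves to 152.5 and the edges become 2.5 and 12.5 Ma.

**mbl.** Postorder pass forcing every edge to at least the minimum
(default 2 Ma) by pushing internal nodes rootward; tip dates unchanged.

**add.** Top-down pass adding the increment (default 1 Ma) to every edge
of the basic dating. Tip dates shift by the accumulated increments; this
is the one method that moves tips, and it is documented as such because
keeping every edge at exactly basic + increment and keeping all tip dates
fixed are mutually inconsistent constraints.

## Brownian kernel

Likelihoods are computed two ways: Felsenstein pruning (contrasts), and
dense GLS via Cholesky on the explicit phylogenetic covariance
V[i,j] = Σ duration×r over shared root-to-MRCA edges. The two routes are
verified to agree to 1e-8 on random trees, uni- and bivariate; the dense
route doubles as the internal oracle wherever the fast path is used.
Multivariate rates use a matrix-normal model with row covariance V and
column covariance R; a proportional scalar on R over an edge set is
mathematically identical to inflating those durations, which the tests
assert exactly. Zero-duration edges are rejected up front with the edge
named; identical trait values (singular ML R) raise a explicit
degenerate-data error. Polytomies are accepted in I/O but refused by all
likelihood code until resolved.

## Rate-shift search

Candidates at each step are internal non-root nodes whose subtree has at
least `min_clade` (default 5) tips, each tried as a clade shift (subtree
edges incl. stem) and a branch shift (stem only); `min_clade` applies to
branch candidates too by default, with a flag to lift it. The best
candidate is chosen by likelihood with a deterministic tie-break (closer
to the root, then lower node id); its location is then frozen and all
accepted scalars are re-optimized jointly (locations fixed, values
free). Overlapping shifts assign rates innermost-wins; rates are
assigned, not multiplied.

Scalar optimization is on the log scale over [1e-6, 1e6] by a coarse
grid followed by bounded Brent refinement — deterministic, and with the
grid spanning twelve decades it dominates any small set of fixed
multistarts. Candidate scans are made cheap by whitening the data with
the Cholesky factor of the current model's covariance and
eigendecomposing each candidate's shift-contribution matrix in that
metric; every likelihood evaluation during the scalar search is then
O(n). For repeated fits on one tree (calibration, bias, power), the
per-candidate eigenbases are computed once and reused across replicates.
A dense-Cholesky path handles the rare candidates whose edges overlap a
previous shift with mixed rates, and joint re-optimization
(Nelder-Mead on log scalars) always runs dense.

Confidence intervals are profile-likelihood: the scalar is swept until
the profile (other scalars re-optimized) drops 1.92 lnL units (χ²₁/2 at
5%); no finite crossing below 1e6 is reported as an unbounded upper
limit — the typical outcome for shifts on very short branches, whose
scalars are bounded below but not above by the data.

The acceptance threshold is not a fixed constant: constant-rate BM data
are simulated on the analysis tree (default 1000 replicates), the best
single-shift model is fitted to each, and the 95th percentile of
AICc(BM) − AICc(one shift) becomes the cutoff. On study-shaped 71-tip
trees this lands around 7–9 and holds the realized false-rejection rate
near 5% on fresh null data.

## OU regime models

Edges are painted by named clades (nested clades innermost-wins);
painting is stem-exclusive by default — the stem edge leading to a clade
keeps the surrounding regime — with a flag, because node-state
assignment conventions differ between implementations and both paintings
are worth comparing. The root state is the root regime's optimum: the
mean of that regime's stationary distribution, with no free
ancestral-state parameter. Treating the root *value* as fixed (rather
than drawing it from the stationary distribution) is what makes the
α → 0 limit collapse exactly onto BM — a genuinely stationary root has
variance σ²/(2α), which diverges in that limit.

For piecewise-constant (α, σ², θ) per edge, means and covariances have
exact recursions used everywhere (no closed-form shortcuts): the regime
weight vector satisfies w(child) = e^{−αt} w(parent) + (1−e^{−αt}) on the
edge's regime (rows sum to 1 by construction); the state variance
satisfies P(child) = e^{−2αt} P(parent) + σ²(1−e^{−2αt})/(2α) (with the
α→0 series limit); and Cov(i,j) = exp(−(A_i + A_j − 2A_mrca)) P(mrca),
where A is the accumulated ∫α from the root. All exponents are
path-differences, hence non-positive — numerically safe for any α in the
searched range (log10 α ∈ [−8, 2]). These recursions are validated
against an exact edge-by-edge Monte-Carlo simulator, not against any
closed form.

Optima are profiled by GLS and the global σ² scale analytically; the
remaining shape parameters are optimized by bounded L-BFGS-B from five
deterministic log-α starts. Optimum standard errors come from the
observed information of the *full* likelihood (central-difference
Hessian over shape, scale and optima): GLS errors conditional on the
fitted α understate optimum uncertainty, and the full-information errors
restore near-nominal 2-SE coverage in recovery simulations. Akaike
weights are exp(−ΔAICc/2), normalized, and fits from different datasets
are refused in a comparison.

## Directional trends

Model B adds a drift term: E[x_i] = μ0 + μ·depth_i with BM covariance;
model A fixes μ = 0. Both are GLS fits with σ² profiled; the LRT uses
χ²₁. On an ultrametric tree (relative tip-depth spread < 1e-6) μ and μ0
are perfectly confounded, and the fit is refused with an explanatory
error rather than returning an arbitrary answer. Type-I error is
verified ≈5% on non-ultrametric trees.

## PGLS ANCOVA

The design uses treatment contrasts with Aves as the reference level, so
each non-reference coefficient directly tests a difference from Aves;
the reference is configurable. λ multiplies off-diagonal covariances
only; it is profiled by ML on a 0.01 grid over [0, 1] with bounded
refinement, and boundary estimates are flagged. λ = 1 reproduces the BM
GLS regression exactly (cross-checked against the BM engine); λ = 0 is
weighted least squares with weights 1/tip-depth, which equals OLS only
when tips are equally deep. Coefficient tests use the unbiased residual
variance on n − p degrees of freedom; the reported R² is a GLS R²,
1 − RSS/SST in the λ-whitened metric with SST about the GLS grand mean
(stated in the output metadata, since several R² conventions exist).

## Simulation studies

One master seed spawns independent per-replicate substreams, so any
replicate is reproducible in isolation and whole studies are bit-for-bit
repeatable. The bias audit simulates the constant-rate null, fits the
best single-shift model, and histograms shift locations as signed node
offsets from the focal node (negative = outside the focal clade,
positive = inside, 0 = the focal stem). The power study plants branch
shifts of 10–1000× on the focal stem and counts replicates in which the
calibrated search accepts a branch shift exactly there; medians of the
recovered multiplier are reported among detections, and are subject to
selection bias whenever power is below ~50% (only large apparent jumps
get detected, inflating the conditional median). The branch sweep
rescales the focal stem over a grid (default 0.1 then 1–500 Ma,
log-spaced — the spacing is a package choice), profiles the constant-BM
lnL, reports the 1.92-lnL support interval, and, given a threshold, the
longest stem at which a focal branch shift remains significant.

## Synthetic data

The generator produces study-shaped inputs with full ground truth: a
random binary cladogram, iid fossil first-appearance dates over
66–168 Ma, and — crucially — branch durations produced by the package's
own `equal_oldest` time-scaler. Dating nodes by their oldest descendants
gives every internal node a tip anchored near its age and makes internal
edges short relative to terminal ones (median ≈1 vs ≈17 Ma on 71-tip
draws). That structure is what controls the detectability of a shift on
a short internal stem: the focal-clade contrast is compared against the
"effective resistance" from the focal node to nearby tips, and fossil
anchors keep it small. With naive tree shapes (long shared internal
edges) a 500× planted shift is detected in well under 20% of replicates;
with equal-scaled shapes detection at 500× sits near 50% and the median
recovered multiplier within a factor of 2 — the regime in which
branch-shift inference on real fossil trees operates.

The focal clade (registered as "Paraves", ~35% of tips, at least two
edges from the root — a shift on a root-child edge is confounded with
the free root state) has its stem set to 0.31 Ma by raising the focal
node toward its parent and compensating on its child edges, so all tip
dates stay put. A nested inner clade ("Aves", about half the focal tips)
supports three-level analyses. Presets give 71 tips with two traits, 76
and 125 with one. Background σ² = 4e-4 (log10 mm)²/Ma around a root
state of 2.2 log10 mm keeps simulated femora in the realistic
~20 mm–1 m range. Trait models: BM with planted shifts (defaults ×166
branch, ×8.5 clade), two-regime OU (defaults θ = 2.17/1.76 log10 mm,
a miniaturization), or group-wise allometry with phylogenetic residuals
at a stated λ (mixing a BM draw with independent depth-scaled noise,
which realizes the λ-transformed covariance exactly).

What the generator does **not** emulate: temporal clustering of clades in
the fossil record (FADs are iid), measurement error and intraspecific
variation, missing-data patterns correlated with age or size, and
real-tree topological idiosyncrasies. Passing recovery tests therefore
demonstrate estimator correctness under the stated generating model, not
robustness to those complications.

## Problem sizes used in tests and the acceptance script

Tests and `scripts/acceptance.py` use sizes chosen to keep Monte-Carlo
error well inside the asserted margins: 200 random trees for the
pruning-vs-GLS oracle; 1000 calibration + 400 fresh-null replicates for
type-I control; 150–200 replicates per power level; 200 replicates at
200 tips for OU optimum coverage (20 for the acceptance script's median
optima); 500–1000 replicates for trend type-I; 12–15 replicates for λ
recovery medians. The acceptance script completes in a few minutes on
one CPU.

## Known limitations

- Multivariate rate shifts scale the whole trait covariance matrix by a
  single scalar; element-wise covariance changes are out of scope.
- OU models are univariate; no multivariate OU, no stochastic-mapping
  regime inference.
- The stepwise shift search is greedy: it conditions on earlier shift
  locations and can land on statistically equivalent "mirror image"
  solutions (e.g. marking the complement of a fast region as slow) when
  a planted shift covers much of the tree — a property of the model
  class, not of this implementation.
- Profile CIs assume a unimodal profile; a non-monotone profile triggers
  a warning and a conservative bound.
- Rate multipliers on very short branches are bounded below but
  effectively unbounded above; expect unbounded upper CIs there.
- `mbl` can be infeasible if constraints conflict (reported as an
  error); `add` shifts tip dates by construction.
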