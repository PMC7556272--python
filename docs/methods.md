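# Methods

`mcinet` implements a three-scale analysis of brain functional networks
built from ROI time series, together with a two-layer random-forest
classifier, and exercises the whole stack on a synthetic cohort with
planted ground truth.  This note records the models, the defaults and
the design decisions that were genuinely open.

## Connectivity model

Functional connectivity between ROIs i and j is the absolute Pearson
correlation |r_ij| of their time series; the N×N matrix (diagonal forced
to 0) defines a fully connected weighted undirected network per subject.
Group-level networks are element-wise means of the individual matrices
("connectivity backbone").  Negative correlations are folded by the
modulus; no Fisher z-transform is applied.

Networks are sparsified proportionally: at sparsity s the K =
round(s·N(N−1)/2) strongest edges are retained **with their weights**
(information in the FC is kept; nothing is binarized).  The analysis
grid spans 5–50% in 1% steps (46 points).  Two conventions are ours
because no standard exists: K uses half-to-even rounding, and ties at
the cutoff break by ascending (i, j) order.  Both make edge sets
deterministic and strictly nested in s, which several invariants (and
the hub-stability analysis) rely on.

A zero-variance ROI is degenerate but not fatal: its correlations are
set to 0 with a warning, mirroring how a masked-out region would behave.

## Scale I: global metrics

* **Weight→length map**: shortest-path metrics use length = 1/w.  The
  map is not forced by the connectivity model; 1/w is the dominant
  convention for FC networks and keeps strong connections short.
* **Clustering C**: Onnela weighted form, ŵ = w/max(w), C_i =
  (k_i(k_i−1))⁻¹ Σ (ŵ_ij ŵ_ih ŵ_jh)^⅓, nodes of degree < 2 contribute
  0; C is the mean over all N nodes.  The max-weight normalization keeps
  C ∈ [0, 1].
* **Characteristic path length L**: mean shortest-path distance over
  *reachable* ordered pairs.  Isolated ROIs exist below ~9% sparsity, so
  infinite distances are excluded rather than propagated; the
  unreachable-pair fraction is always reported next to L.
* **Global efficiency GE**: mean of 1/d with 1/∞ = 0, robust to
  disconnection by construction.
* **Small-worldness SW** = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) against
  degree-preserving rewired nulls (Maslov–Sneppen double-edge swaps, 10
  attempted swaps per edge, weights travelling with the edges, so both
  the degree sequence and the weight multiset are preserved exactly).
  Null k is seeded with seed+k.  The reference count defaults to 1,000;
  the demo profile uses 50 (group level) / 20 (subject level), which is
  enough for a ratio whose null value is 1 within a few percent.

## Scale II: hubs

Nodal betweenness bc_i uses weighted shortest paths (Brandes
accumulation via igraph, unordered-pair convention, endpoints excluded).
Equal-length paths are counted with multiplicity by fractional
accumulation; no perturbation is applied to break floating-point ties.
BC_i = bc_i/⟨bc⟩ normalizes by the network mean, so ⟨BC⟩ = 1 exactly and
any constant-factor counting convention cancels — which is why the
convention choice is safe.  A hub is BC_i > 2.5 (strict inequality);
1.5 and 2.0 are supported as looser alternates.  Hub stability across
the grid is the fraction of sparsities at which an ROI is flagged; we
summarize "stable" as ≥ 2/3, a reporting choice.

Per-subject bc (individual networks) feeds the group statistics and the
classifier; group-level hub tables use the group-mean network.  The two
paths never mix.

## Scale III: communities

Modularity is the weighted Newman Q at resolution 1.  Detection is
seeded multi-restart Louvain (default 20 restarts, best Q kept); module
labels are canonicalized so module 1 contains the lowest ROI index,
making crosswalk tables reproducible.  The permutation test re-detects
communities on degree-preserving rewired nulls (a weight-shuffling null
that keeps topology is available as an alternate) and reports
p = (1 + #{Q_null ≥ Q_obs})/(1 + n_perm).  The observed Q is computed
with the *same* restart budget as the nulls so the two statistics are
exchangeable under the null; a larger budget for the observed network
alone would bias p downward.

## Statistics

Continuous demographics pass a Lilliefors gate at α = 0.05 per group:
t-test when both groups look normal, Wilcoxon rank-sum otherwise.
Gender uses the two-sided Fisher exact test.  Each network metric enters
a logistic regression group ~ metric + gender (Wald p for the metric
coefficient); gender is the only covariate throughout, and nodal tests
additionally carry a Bonferroni 0.05/116 flag.  No correction is applied
across sparsities or across the four global metrics.  Metric–score
associations are partial Pearson correlations after residualizing both
variables on gender (0/1), p from a t distribution on n−3 df; a constant
covariate degrades gracefully to the plain Pearson correlation (n−2 df).
Perfect separation in a logistic fit is flagged and the p reported as
missing rather than numeric.

## Two-layer random forest

The feature table at one sparsity has exactly 124 columns: ADAS13,
CDRSB, MMSE, FAQ, C, L, GE, SW, bc_1..bc_116.  Layer 1 ranks features by
out-of-bag permutation importance: each tree's OOB rows are recovered by
replaying its bootstrap draw, every feature column is permuted among the
OOB rows, and the mean OOB misclassification increase is the importance
(an impurity-based ranking is available by flag; permutation-OOB is the
default because it measures importance through OOB error).  Layer 2
trains on the top-N features inside a stratified 10-fold outer / 5-fold
inner nested CV tuning the number of trees {100, 200, 500} and maximum
depth {2, 3, 5, unbounded}; grids are configuration, not science, and
are overridable.  Metrics (accuracy, sensitivity, specificity) pool the
out-of-fold predictions; AUC uses the pooled out-of-fold class
probabilities.  N sweeps 5–30, best N by accuracy with ties to the
smaller N.

**Leakage.**  Ranking all features once on the full table before
cross-validation lets held-out labels influence feature selection and
inflates accuracy.  The default therefore re-ranks within every outer
training fold; `global_ranking` restores the single-global-ranking variant
for comparison.  A dedicated test asserts that flipping a held-out
subject's label cannot change the features selected for that subject's
fold.

## Synthetic cohort

Each subject's T×N series (default 135×116) is i.i.d. over time from a
zero-mean Gaussian whose correlation matrix carries the planted truth;
an AR(1) knob exists for robustness checks but defaults to 0 because
Pearson r is the only statistic consumed downstream.  The matrix is
rho_in within each of 4 contiguous modules, rho_out between, plus
hub_boost on the off-module rows/columns of planted hub ROIs, then
repaired to the nearest PSD matrix by eigenvalue clipping and rescaled
to unit diagonal.

**Hub feasibility bound.**  Correlation geometry caps how strongly one
node can correlate with many mutually weakly-correlated nodes: for four
equal modules the feasible hub-to-all correlation is roughly
√rho_in·(1+3c)/√(4+12c) with c = rho_out/rho_in, which exceeds rho_in
only when rho_in < (1+3c)²/(4+12c) (0.5 at c = 1/3).  Under proportional
thresholding a hub's edges survive the sparsest grids only if they
outrank within-module edges, so a grid-wide betweenness hub requires a
moderate rho_in.  The defaults — rho_in = 0.30, rho_out = 0.10,
hub_boost = 0.25, giving repaired hub edges ≈ 0.34 — sit just inside the
bound.  At rho_in = 0.6 (the regime used for the module-recovery test,
where it is appropriate) no PSD-feasible hub can be retained below ~24%
sparsity, whatever the boost.

**Case-group effect** (MCI): between-module correlation +0.05 (diffuse
hyperconnectivity → shorter paths, higher GE, less localized modules),
the first planted hub loses its boost, and planted module 1 is split in
two (relabelled second half).  These reproduce the qualitative study
findings: decreased L / increased GE in cases, a hub present in controls
but not cases, and a module that fragments.

**Scores.**  ADAS13, CDRSB, MMSE, FAQ are linear in the subject's mean
absolute FC (z-scored across the cohort) plus a case shift and Gaussian
noise.  Control-group means/SDs follow the published demographics values
with the group columns swapped into the clinically standard direction
(the printed table is internally inconsistent; cases must be impaired:
higher ADAS13/CDRSB/FAQ, lower MMSE).  Coefficient signs align with the
planted pathology — impairment-scaled scores load positively on mean FC
and MMSE negatively — so the network coupling reinforces rather than
cancels the case shifts.  Gender is Bernoulli per group with the
published male fractions (46/82 controls, 36/93 cases).

**What the generator does not emulate**: temporal autocorrelation and
band-limited spectra of BOLD signals, scanner/motion artifacts,
inter-subject variability in module layout, heavy-tailed FC
distributions, and realistic (much smaller) effect sizes.  Group
differences here are deliberately strong so recovery is unambiguous;
classifier accuracies consequently saturate near 1.0 on the demo cohort
and say nothing about achievable clinical accuracy.  Passing tests
demonstrate correctness and calibration of the machinery, not expected
performance on rs-fMRI data.

**Chance hubs in null cohorts.**  Because thresholded edge sets nest
across the grid, a single noise network carries the same fluctuation
through all 46 sparsities, and 1–3 ROIs can persist as spurious hubs in
any one null cohort.  The meaningful null property is therefore
irreproducibility across replicate cohorts — no ROI is *systematically*
a hub — and that is what the null-hub test asserts.

## Problem sizes and numerical choices

The default ("demo") run uses 30+30 subjects, small-worldness on an
11-point sub-grid (multiples of 5% plus the 16% working sparsity) with
50 nulls at group level and 20 per subject, 200 permutations for the
modularity test, a {100, 200}×{3, unbounded} classifier grid and a
top-N sweep over {5, 10, 15, 20, 25, 30}; `RunConfig.study_profile()`
restores the study-scale settings (1,000 nulls/permutations, full 5–30
sweep, full grids).  Calibration tests run the permutation test on
40-node networks (100 replicates × 200 permutations, single-restart
detection for observed and nulls alike) and the type-I-error checks on
feature-level simulations.  All randomness descends from one master
seed through fixed per-stage offsets; identical seed and config
reproduce every table byte for byte.

Known limitations: Louvain is a greedy heuristic, so the detected
module count near degenerate optima can vary with seed (4 vs 5 modules
for the split case group); L over reachable pairs is not comparable
across networks with very different fragmentation; permutation-OOB
importances of correlated features split credit between them.
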