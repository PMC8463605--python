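# Methods

## The problem

Epilepsy surgery aims to stop seizures by removing or disconnecting the
epileptogenic zone (EZ).  Resections are often larger than necessary, and
which connections actually matter for seizure spread differs between
patients.  `virtres` implements an individualized virtual-resection
workflow on structural brain networks: simulate seizure propagation,
score candidate disconnections with a fast spectral surrogate, and search
for the smallest set of connections whose removal retains most of the
effect of the full surgical disconnection.

## Propagation model

Seizure spread is modelled as a discrete-time stochastic
susceptible–infected–recovered (SIR) process on the binarized structural
network.  Regions are inactive (S), ictally active (I), or refractory
(R).  Updates are synchronous; at each step

* a susceptible node with `m` currently active neighbors becomes active
  with probability `1 − (1 − β)^m` (independent per-contact
  transmission), and
* every node that was active at the start of the step becomes refractory
  with probability `γ`; a node activated in step `t` is therefore
  infectious for at least one full step and cannot recover in step `t`
  itself.

The independent-per-contact form and the synchronous-update/recovery
timing are deliberate fixed choices; discrete-time SIR conventions differ
between implementations and these two are documented rather than inferred.

The severity readout is `I(t₀)`, the mean fraction of *currently* active
nodes at `t₀ = 10`, averaged over 10,000 runs of 200 steps — an
early-propagation speed measure.  `I(t)` counts state I only; a
cumulative (I+R) curve is available via `sir_ensemble(..., cumulative=True)`.
Large outbreaks occur when the spreading rate `λ = β/γ` exceeds the
spectral epidemic threshold `λ_c = 1/λ_max(A)`.

**Calibration.**  `γ` is fixed at 0.03 per step.  `β` is raised on the
grid 0.001, 0.002, … until, on average, at least 98% of nodes end the run
refractory, using 1,000-run ensembles per grid point (configurable; the
returned β is then used at the full 10,000-run ensemble size).  On the
default synthetic networks this lands at β ≈ 0.030–0.040.  Note that the
98% criterion is governed by two mechanisms: the takeoff probability of
the few initial lineages (binding for very small seeds) and the
reachability of the weakest nodes (binding otherwise).  This is why the
generator defaults to multi-region seeds; see below.

## The eigenvector-centrality surrogate

Running the SIR ensemble inside a combinatorial optimizer is infeasible,
so a resection is scored by the drop in mean eigenvector centrality (EC)
of the EZ nodes after edge removal.  EC — the leading eigenvector of the
adjacency matrix — tracks participation in the dominant spreading mode,
and nodal EC correlates strongly with single-seed `I(t=10)` on these
networks (checked explicitly by `validate_surrogate`; per-subject Pearson
r ≈ 0.95, pooled ≈ 0.9 at the default study conditions).

Conventions: unit Euclidean norm; non-negative orientation; on
disconnected graphs the *global* leading eigenvector, so components that
do not attain the top eigenvalue get EC 0 (a fully disconnected seed has
EC exactly 0, which anchors the normalization).  Near-degenerate top
eigenvalues (gap < 1e-10) are resolved by the eigensolver's ordering and
flagged with a warning; this matters only for contrived symmetric graphs,
not connectome-scale networks.  The public `eigenvector_centrality` uses
dense symmetric eigendecomposition (exact at these sizes); the annealer's
inner loop uses a warm-started sparse power iteration on the shifted
operator `A + I` (same eigenvectors; strictly dominant top eigenvalue
even on bipartite components) at tolerance 1e-10, and every returned plan
is re-scored with the exact dense path.

The normalized EC difference divides by the effect of removing *all*
candidate connections, so a full disconnection is exactly 100%.

## Candidate connections and the search

Candidates are all binarized edges from an EZ node to a non-EZ node —
exactly the connections an actual resection severs; seed-internal edges
are excluded.  For each resection size k the best k-subset is found by
simulated annealing (state: k-subset; move: swap one selected for one
unselected candidate; Metropolis acceptance; schedule T₀ = 1, f(T) = 0.8T,
stop at 1e-8 or 1000 consecutive rejections, ≤ 300 tries / ≤ 20 successes
per temperature).  Five independent restarts are run per size and the
best state kept; on every tested small instance this attains the exact
enumeration optimum (`brute_force_optimize` is the oracle).

The best-effect-per-size curve is additionally guarded for monotonicity:
each size also evaluates the previous size's best plan greedily augmented
by its single best extra candidate, and keeps the better.  The guard can
only raise a size's best effect.  The optimal size k\* is the smallest k
whose EC difference reaches 90% of the full-resection effect (the 0.9
fraction is an explicitly arbitrary, configurable threshold); on default
cohorts k\* ≈ 0.7 K, i.e. roughly a quarter of the connections are spared
for a 10% effect concession.

Comparison strategies pick the same k\* edges by static measures — edge
betweenness, or EC / degree / betweenness of the non-seed endpoint
(unnormalized unordered-pair betweenness conventions, ties broken by
lexicographic edge order) — or uniformly at random (100 draws, reported
as mean ± sd).

## Synthetic cohorts

Patient tractography cannot be shared, so cohorts are generated
synthetically, targeting the observable properties the method depends on
rather than anatomy:

* **Degree-corrected hierarchical block model.**  Node propensities
  `a_i = exp(hub_strength · z_i)` with standard-normal `z` floored at
  −0.4 sd (every region keeps minimal connectivity); expected edge weight
  ∝ `a_i a_j`, ×3 within a lobe-like sub-block (6 per hemisphere), ×0.5
  across hemispheres; multiplicative log-normal noise (σ = 0.6); the full
  weighted matrix is thresholded to the 460 strongest edges (11% of 4186)
  and binarized.  Disconnected realizations are rejected (≤ 100 retries).
* **Why lobes:** in a flat two-block product-weight model at fixed
  density, the weakest nodes end with degree 1 and their count varies per
  realization; the 98% sweep criterion then quantizes the calibrated β on
  that count, misaligning subjects.  Lobe blocks guarantee every region
  strong local edges (min degree 2–4), which keeps β in a tight,
  realistic band.
* **Shared template.**  Subjects of a cohort mix a cohort-level template
  field with subject noise, mirroring the high inter-subject consistency
  of real structural connectomes (the study cohort's average matrix
  reproduces individual-matrix results, indicating small inter-patient
  variation).  Subject-specific variance of the regional field scales
  with template hubness (up to 35% for hubs, zero at the weak end) —
  inter-individual variability concentrates in association/hub cortex,
  and conserving the weak tail keeps the calibrated β in a tight band
  across a cohort, as observed in the real cohort.  The tract (edge)
  field is 2% subject-specific: the binarized backbone is the most
  conserved structure.
* **EZ seeds** are contiguous: a uniformly sampled anchor plus randomly
  chosen binary neighbors.  Default sizes are 3–5 regions.  One- or
  two-region seeds are excluded from the defaults because the 98%
  calibration criterion is then dominated by single-lineage extinction
  (mean final R ≤ takeoff probability), which forces β ≈ 1.5/deg(seed) —
  far above the regime in which early propagation is discriminative — and
  the real cohort's calibrated β range (≈ 0.03) implies effectively
  multi-region seeds.
* **Determinism:** per-subject streams are derived from
  `(master_seed, subject_index)`, the template from `(master_seed, 2³¹)`,
  so cohorts are reproducible and order-independent.

What the generator does *not* emulate: anatomical geometry and distances,
atlas label semantics, tract-length or curvature effects, pathology.
Passing tests on these cohorts show the pipeline's internal consistency
and that its claims hold on hub-heterogeneous, modular, fixed-density
networks — not that any specific clinical result transfers to a given
patient.

Default observable scales at the study conditions (92 nodes, 11%
density): degree CV ≈ 0.4–0.7, candidate counts ≈ 35 ± 15, calibrated
β ≈ 0.030–0.040, per-subject EC~I(10) correlation ≈ 0.92–0.99.

## Statistics

Strategy efficacies are compared across subjects with paired t-tests;
spared vs removed candidate connections with unpaired t-tests on edge
betweenness and the non-seed endpoint's EC/degree/betweenness,
Benjamini–Hochberg-corrected across the four measures (`fdr_bh`, backed
by statsmodels); outcome groups with unpaired t-tests on pre-resection
I(t₀), seed EC and post-resection I(t₀), plus an (uncorrected) chi-square
test on a binary location label.  All tests are two-sided at α = 0.05.
Outcome labels in synthetic cohorts are random metadata for
null-distribution testing only — no clinical effect is simulated.

## Numerical choices and problem sizes

* Density thresholding keeps `round(d·N(N−1)/2)` edges
  (half-away-from-zero); weight ties at the cutoff are broken by
  ascending (i, j) order.  The log-weight variant uses `ln(1+w)`
  (defined at 0 and for sub-unit weights; tract counts are ≫ 1 so the
  offset is immaterial).
* Monte-Carlo readouts that only need `I(t₀)` simulate `t₀` steps;
  ensembles freeze and skip extinct runs.
* The test suite and acceptance script use reduced but statistically
  adequate sizes — 1,000-run calibration/validation ensembles, 5–19
  subject cohorts, 2–5 annealing restarts — chosen so Monte-Carlo error
  stays well inside the asserted tolerances; the per-quantity ensemble
  sizes are recorded alongside each result.

## Known limitations

* The surrogate is validated for early propagation (`I(t=10)`) on
  binarized networks; weighted-network EC analyses are supported
  (`log_transform`, weighted EC) but SIR runs are binary-only.
* EC under post-resection disconnection is a convention (global leading
  eigenvector); alternative per-component conventions would change
  normalized effects on degenerate graphs.
* The annealing step-accounting follows the generic annealer convention
  listed above; other implementations may bookkeep tries/successes
  differently and reach slightly different states on large instances
  (restarts + the exact re-scoring make the returned plans stable).
* Group comparisons on synthetic cohorts are null checks only.
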