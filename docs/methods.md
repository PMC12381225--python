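# Methods

## Overview

`morbnet` implements an unsupervised multimorbidity-mapping pipeline for
ischemic heart disease (IHD) cohorts.  The object of study is the pre-index
diagnosis history of each patient: every level-4 ICD-10 code assigned before
the patient's index coronary angiography (CAG/CCTA) is counted into a
patients × codes "bag-of-words" matrix.  Patients are embedded by truncated
SVD, connected into a cosine patient-similarity network, clustered with the
Markov Cluster (MCL) algorithm, and the resulting multimorbidity clusters are
characterized by cause-specific survival models and phenotypic enrichment.
Because the national-registry data this kind of analysis targets are
access-restricted, the package ships a synthetic registry-cohort generator
with planted cluster structure; every stage is validated by recovering the
planted truth.

## Cohort construction

* **Index date** — the earliest CAG/CCTA performed during a hospital contact
  that also carries an IHD code (I20–I25).  Contacts are linked by a shared
  contact identifier; patients without a qualifying procedure are excluded.
* **Count matrix** — raw counts of code assignments strictly before the
  index (optionally before `index − washout_days`, washout ∈ {0, 90, 180,
  365} days for sensitivity analyses).  Codes are truncated to their first
  four alphanumerics ("level 4").  Excluded: the cohort-defining IHD codes
  and chapters for pregnancy, perinatal conditions, congenital
  malformations, injuries, external causes and administrative contact codes
  (prefixes O, P, Q, S, T, V–Y, Z); after that, codes carried by fewer than
  5 patients.  Patients with empty histories keep all-zero rows — they
  surface as singletons downstream, which is informative (in large IHD
  cohorts roughly 6% of patients have no prior diagnoses).
* **Percentages** in summary tables use decimal half-up rounding to one
  decimal, the convention of printed registry tables.
* A tf-idf variant (`tf × ln(n/df)`, df = carrier count) is provided for
  robustness analyses of the frequency scaling.

## Embedding and similarity network

* **Truncated SVD** (scikit-learn randomized solver, 10 iterations, random
  seed 42).  The retained rank is the smallest k whose cumulative explained
  variance reaches the target (default 50%), capped at 41 components and at
  `min(n, p) − 1`.  On registry-scale IHD data ~41 components reach 50%;
  on small synthetic cohorts the rule typically retains fewer.
* **Cosine similarity** between embedded patient vectors defines edge
  weights; edges below 0.35 are dropped.  The threshold trades density
  against topology: below it, cosine similarity between sparse diagnosis
  profiles is dominated by noise.  Zero-norm patients (no retained codes)
  become isolated nodes.
* **Neighbor ceiling** (the `#ceilnb` transform): each node keeps at most
  8000 neighbors, deleting its weakest edges first.  The published tool does
  not fully specify the ordering, so this implementation fixes a
  deterministic contract: nodes are processed in decreasing order of initial
  degree (ties by node index); deletions are mutual and proceed in
  increasing weight (ties by neighbor index).  This is an approximation of
  the original mcl-edge behaviour, not a bit-exact port.
* **Weight shift** — all weights are decremented by the global minimum so
  the smallest weight is 0.0, as the MCL manual recommends.  If all weights
  are equal the shift zeroes the graph and MCL degenerates to pure
  connectivity; a warning is emitted.

## Markov clustering

MCL simulates flow on the graph by alternating **expansion** (matrix
squaring, T ← T·T) and **inflation** (entrywise power Γ_r, then column
renormalization) on a column-stochastic matrix until (near-)idempotence.

* **Pre-inflation 0.5** homogenizes the edge-weight distribution (entrywise
  square root before normalization); the **main inflation is 2.0**, the MCL
  default, which controls cluster granularity.  Both are exposed in
  `MCLParams`.
* **Self-loops**: each node receives a loop with weight equal to its maximum
  incident weight (1.0 for isolated nodes).  Loop policy differs between mcl
  versions; this choice is fixed and config-exposed.
* **Prune/select/recover** (resource scheme `-P 7000 -S 800 -R 900 -pct
  90`): after each expansion and each inflation, entries below 1/7000 are
  pruned per column; if more than 800 entries survive, the 800 largest are
  kept; if the retained mass falls below 90% of the pre-prune column mass,
  the column is rebuilt from the 900 largest pre-prune entries.  Columns are
  renormalized after pruning, so every intermediate matrix is
  column-stochastic to 1e−9.  Exact parity with the C implementation's
  adaptive pruning is *not* promised; the correctness contract — tested
  exhaustively on random graphs — is that the pruned iteration extracts the
  same partition as a dense no-pruning iteration.
* **Convergence** — maximum absolute entrywise change between successive
  iterates below 1e−8 (simple, testable); a non-converged run returns its
  last iterate with a flag.
* **Cluster extraction** — attractors are nodes with positive diagonal mass
  in the limit matrix; attractors exchanging flow form attractor systems;
  every other node joins the system receiving its largest flow (ties to the
  system containing the smallest attractor index).
* **Finalization** — clusters below the minimum size are flagged
  unclustered (members kept, not deleted) and the rest are relabelled
  C1…Ck by decreasing size.  The registry-scale default is 500 patients
  (≈0.7% of a 72k cohort); synthetic desk-scale cohorts scale this
  proportionally (`scaled_min_size`, floored at 20).

## Robustness

Perturb → re-cluster → compare against the reference clustering:

* **Dilution** — every edge deleted independently with probability α,
  α ∈ [0, 0.5]; 20 replicates per α.  α = 0 leaves the graph unchanged, and
  since the pipeline is deterministic that cell is computed once and
  replicated.
* **Shuffle** — degree-preserving randomization by repeated double-edge
  swaps (≥10·|E| attempted swaps; networkx implementation), preserving the
  node set, edge count and exact degree sequence; weights are reassigned by
  a random permutation of the original multiset.  This is the fully
  randomized endpoint of the configuration-model interpolation family, used
  as the maximal-disruption contrast to dilution.
* **Metrics** — variation of information VI = H(a) + H(b) − 2I(a;b)
  (natural logarithm by default; base exposed) and van Dongen's split-join
  distance 2n − Σ_A max_B |A∩B| − Σ_B max_A |A∩B|.  Unclustered nodes enter
  as their own singletons so node sets stay identical across perturbations.
  VI values below 1e−12 are snapped to exactly 0 so that VI(a,a) = 0 holds
  despite floating-point noise (any genuine disagreement on n nodes yields
  VI ≫ 1e−12).

Matrix-level variants (tf-idf scaling; 3/6/12-month washouts) reuse the same
sweep by supplying alternative count matrices.

## Survival analysis

* **Composite "new ischemic event"** — earliest of (a) MI/unstable-angina
  hospitalization at least 30 days post-index, (b) revascularization at
  least 90 days post-index, (c) any death with an IHD cause (primary or
  secondary, no minimum window).  The 30/90-day rules remove the planned
  work-up of the index presentation (the bulk of early re-hospitalizations
  and revascularizations belong to it) from the endpoint.
* **Competing risks** are handled as **cause-specific hazards**: non-IHD
  death censors the ischemic analysis; by default the composite ischemic
  event censors the non-IHD-death analysis (config-switchable).
  Subdistribution (Fine–Gray) modelling is deliberately out of scope.
* Follow-up is truncated at 5 years.
* **Per-cluster Cox models** — one model per cluster: binary membership +
  sex + a restricted cubic spline of age at index with 3 knots at the
  10th/50th/90th percentiles (Harrell's truncated-power natural-spline
  basis, linear in the tails; knot placement is the standard default).
  Wald 95% CIs; Holm adjustment across the per-outcome family of clusters.
  A cluster with zero events is reported with missing HR and excluded from
  the adjustment family.
* **Holm adjustment** supports a fixed nominal family size m that may
  exceed the number of supplied p-values (m = 465 for the pairwise age
  comparisons between 31 clusters); this is why it is implemented in-package
  (statsmodels' implementation, used as a cross-check in tests, fixes
  m = len(p)).
* **Age comparisons** — Tukey's HSD (scipy's studentized-range
  implementation) over all k(k−1)/2 cluster pairs, then Holm with the fixed
  family size.

## Characterization

* **O/E enrichment** — observed frequency = carrier prevalence of a code in
  a cluster; expected = prevalence in the whole clustered cohort.  O/E > 2
  flags enrichment; 0 < O/E < 1 an "inverse change"; a cluster whose ten
  largest O/E ratios sum to less than 50 shows "little enrichment".
  Prevalence (not mean count) is the natural reading of code frequency for
  enrichment; a count-based variant would weight recurrent admissions.
* **Polypharmacy** — more than five distinct ATC codes, each redeemed at
  least twice within one year pre-index (strict "more than five").
  Prescription enrichment windows run from 2 years to 1 week pre-index.
* **Laboratory scores** — the analysis subcohort requires sodium,
  potassium, hemoglobin and creatinine sampled within 90 days pre-index
  (completeness proxy for standard-of-care data capture); per patient and
  test the sample closest to the index is used (ties: the later sample);
  tests available for <50% of the subcohort are dropped.  Each value is
  classified −1/0/+1 against its reference interval (inclusive bounds count
  as within — the clinical convention); the cluster score is the mean.
  Clusters are ordered by complete-linkage hierarchical clustering on
  Euclidean distances between score rows.
* **Trait scores** — standardized per-patient scores (polygenic-score
  stand-ins; genotype-level simulation is out of scope) compared per
  (cluster, trait) by two-sided Wilcoxon rank-sum tests against all other
  clustered patients, with a Hodges–Lehmann location-shift effect size
  (median of pairwise differences, computed exactly up to 5×10⁶ pairs and on
  a strided subsample beyond) and Benjamini–Hochberg FDR over all
  cluster × trait tests.  Unclustered patients are excluded from the
  comparison pool by default.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes, not
the surface realism of registry data:

* Each patient belongs to one latent multimorbidity group.  Diagnosis
  multisets are Poisson(mean ≈ 8.1 by default, matching large IHD cohorts)
  draws from a categorical code distribution mixing the group's dedicated
  code block (propensity `within_group_code_prob`) with a uniform background
  (`background_code_prob`).
* Sex (~63% male by default), age (mean 63.9 y, sd 11.9 y) and index dates
  follow group-configurable marginals.  An index-defining CAG procedure and
  IHD-coded contact are emitted per patient so the index-selection rule is
  exercised end to end.
* Outcomes are independent cause-specific exponentials (defaults ≈5%/yr for
  ischemic events, ≈4%/yr non-IHD death — the ballpark of published IHD
  cohorts) scaled by group log hazard ratios, with administrative censoring
  at 5 years; ischemic events are emitted as a mix of MI/UAP
  hospitalizations, revascularizations and IHD-cause deaths so the
  composite-endpoint rules see realistic record types.
* Laboratory values are Normal(group shift, 1) on a standardized scale
  (one unit = half the reference interval), so a zero shift makes the
  −1/0/+1 classifier symmetric; trait scores are Normal(group shift, 1)
  standardized cohort-wide; prescriptions are drawn so the polypharmacy rule
  fires with a group-specific probability.
* Dates are integer days from a fixed epoch; there is no calendar
  structure, no ICD-10 ontology hierarchy, no code co-occurrence beyond the
  group blocks, and no correlation between diagnosis load and hazards
  unless planted.  Passing recovery tests therefore demonstrates the
  pipeline's correctness under its own model assumptions — not performance
  on real registry data, where code usage drifts over time and group
  structure is far fuzzier.

## Study conditions for the standing experiments

* **Planted recovery** — n = 1500 patients, 3 equal groups, 150 codes (30
  per group), within-group propensity 0.45, background 0.02, mean 6 codes
  per patient.  This condition is chosen to sit in the regime where the
  clustering is essentially correct (ARI > 0.9 versus the planted labels)
  *and* the similarity graph is sparse enough that edge dilution measurably
  degrades the clustering.  At much stronger separation the thresholded
  graph becomes three near-cliques and even 50% dilution leaves the
  clustering bit-identical, which would make robustness curves
  uninformative (VI identically zero at every α).
* **Hazard-ratio recovery** — two groups of 2000, true cause-specific
  HR = 2 for the ischemic cause; 100 replicates for estimate and CI
  coverage; type-I error measured by permuting membership labels (200
  replicates, 3 null clusters each, Holm-adjusted).
* **Characterization recovery** — n = 5000, 4 groups; one group carries a
  0.5 s.d. shift in one trait; lab shifts are zero so lab scores measure
  the null; the planted code blocks provide the enrichment truth.
* Desk-scale sizes (1.5k–5k patients) keep the full test suite and the
  acceptance script within minutes on one CPU while leaving every rule and
  threshold at its registry-scale default except the minimum cluster size,
  which scales proportionally.

## Known limitations

* `#ceilnb` and the prune/select/recover scheme follow fixed deterministic
  contracts that approximate, but are not bit-identical to, the original
  mcl-edge/mcl implementations.
* The cosine graph is computed exactly (block-wise dense); no
  approximate-nearest-neighbor shortcut is provided, so cohorts far beyond
  ~10⁵ patients need more memory-aware scheduling.
* The generator's independence assumptions (codes conditionally independent
  given group; exponential hazards; Gaussian traits) are simplifications;
  none of the recovery results certify behaviour under model
  misspecification.
* Printed-table reproduction covers the tally arithmetic of the original
  registry analysis, not its raw-data estimates, which are not reproducible
  without restricted registry access.
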