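# morbnet

Multimorbidity patient-similarity-network clustering for ischemic heart
disease (IHD) cohorts.

Patients with IHD differ enormously in the diseases they bring to their
index presentation, and that heterogeneity — not the IHD itself — often
drives their prognosis.  `morbnet` maps this heterogeneity without
pre-specifying the number or nature of patient subgroups: it turns each
patient's pre-index diagnosis history into a count vector, embeds the
patients × codes matrix, clusters the resulting patient-similarity network,
and then asks whether the discovered clusters differ in outcomes, medication
burden, laboratory profiles and genetic trait scores.  It is written for
epidemiologists and clinical data scientists working with registry-style
EHR extracts (diagnosis, prescription, laboratory and cause-of-death
tables), and ships a synthetic registry-cohort generator so the whole
pipeline is testable without access-restricted data.

## Method

1. **Count matrix** — bag-of-words counts of level-4 ICD-10 codes assigned
   strictly before the index date (the patient's first IHD-conclusive
   CAG/CCTA).  IHD codes (I20–I25), non-informative chapters, and codes
   carried by <5 patients are excluded.
2. **Embedding** — truncated SVD (randomized solver, seed 42, 10
   iterations); the rank is the smallest *k* whose cumulative explained
   variance reaches 50%, capped at 41.
3. **Similarity network** — edge weight = cosine of embedded vectors;
   edges < 0.35 dropped; each node capped at 8000 neighbors (`#ceilnb`,
   weakest edges first); weights shifted so the minimum is 0.
4. **Markov clustering (MCL)** — expansion T ← T·T alternating with
   inflation Γ₂ (entrywise square, column renormalization), pre-inflation
   0.5, pruning scheme `-P 7000 -S 800 -R 900 -pct 90`; clusters below 500
   patients (proportionally less on small cohorts) are set aside; clusters
   are labelled C1…Ck by decreasing size.
5. **Robustness** — re-cluster after edge dilution (deletion probability
   α ∈ [0, 0.5]) and degree-preserving shuffling; compare with the
   variation of information VI = H(a)+H(b)−2I(a;b) and van Dongen's
   split-join distance.
6. **Characterization** — per cluster: member-vs-rest cause-specific Cox
   models (sex + 3-knot restricted cubic age spline, 5-year truncation,
   Holm adjustment) for new ischemic events, non-IHD death and all-cause
   mortality; Tukey HSD age contrasts; observed/expected (O/E) diagnosis
   enrichment (O/E > 2 = enriched); polypharmacy (>5 recurrent
   prescriptions within 1 year pre-index); laboratory −1/0/+1 reference
   scores; Wilcoxon rank-sum tests of standardized trait scores with
   Benjamini–Hochberg FDR.

See `docs/methods.md` for every parameter, numerical contract and known
limitation.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on a
synthetic cohort of 1,500 patients in three planted multimorbidity groups:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_cluster_pipeline.py
```

prints

```
count matrix: 1500 patients x 149 codes (8338 non-zeros)
similarity graph: 125806 edges over 1500 nodes
MCL: 4 clusters of >= 20 patients, sizes [500, 494, 464, 40], 2 unclustered
adjusted Rand index vs planted groups: 0.908
```

The three large clusters recover the three planted groups almost exactly
(adjusted Rand index 0.908 against the hidden labels); a small fourth
cluster and two singletons absorb the residual noise.  Robustness
(`analysis/03_robustness.py`) shows the clustering degrades gradually under
edge dilution and collapses under shuffling:

```
          vi  split_join
alpha
0.0    0.000         0.0
0.1    0.046        16.4
0.3    0.092        36.4
0.5    0.159        71.2
degree-preserving shuffle: mean VI 1.190, mean split-join 998
```

Mean VI rises monotonically with the fraction of deleted edges and the
degree-preserving shuffle is an order of magnitude more disruptive — the
cluster signal lives in the topology, not the degree sequence.

`analysis/04_survival.py` fits the per-cluster Cox models (no hazard
differences are planted, so no cluster reaches Holm-adjusted significance)
and reports a calibration experiment with a planted cause-specific hazard
ratio of 2.0:

```
HR-recovery calibration (true cause-specific HR 2.0, n=2000/arm,
10 replicates): mean HR 2.057, CI coverage 10/10
```

`analysis/05_characterization.py` shows each recovered cluster enriched
(O/E up to ~3) for its group's dedicated code block and depleted elsewhere,
near-zero laboratory scores (no shifts planted), and 0 of 56 trait tests
significant at FDR < 0.05 under the null.  `analysis/06_published_tallies.py`
recomputes the tally arithmetic of the original registry analysis from its
printed cluster table: 7 of 31 clusters (20,221 patients) significantly
associated with new ischemic events — 5 at increased risk (9,590 patients),
2 at decreased risk (10,631) — and 23 clusters with all-cause mortality.

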