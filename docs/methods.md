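# Methods

This note records the models implemented in `assemblyscape`, their
assumptions, the numerical choices that matter, what the synthetic-data
generator does and does not emulate, and the known limitations.

## 1. The null-model inference chain

### βMNTD

For communities *A* and *B* with relative abundances f and patristic
distances d_ij (sum of branch lengths on the tip-to-tip path),

βMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d_ij + Σ_{j∈B} f_jB · min_{i∈A} d_ij ].

The unweighted variant replaces f by 1/richness.  A taxon present in both
communities has min d = 0 (its conspecific in the other community counts as
its nearest taxon), so identical communities have βMNTD = 0.

All pairs are computed at once: with F the samples × OTUs abundance matrix
and M[s, i] = min over taxa j present in sample s of d_ij, the full matrix
is ½(F·Mᵀ + (F·Mᵀ)ᵀ).  This identity is exercised against an explicit
nested-loop implementation (to 1e−10) and against picante's `comdistnt`
(R) on a fixture.

### βNTI

βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null over `n_null`
(default 999) taxa-shuffle randomisations: each replicate draws one uniform
permutation of taxon identities on the patristic distance matrix and the
whole βMNTD matrix is recomputed under it.  One permutation per replicate is
shared by all sample pairs — the classic community-matrix randomisation —
which keeps the per-pair null marginal distribution identical to per-pair
shuffling while allowing the matrix-product evaluation above (999 nulls for
435 pairs × 300 OTUs run in ~3 s).  All permutations derive from the
config seed up front, so results are independent of evaluation order.

Degenerate pairs (sd_null = 0) are returned as NaN with a warning and
excluded from classification.  This includes the fully-shared-composition
case: shared taxa contribute zero to βMNTD in every null replicate as well
(the shuffle moves both copies together), so an identical pair has no null
variance rather than an extreme z-score.

*Assumption to be aware of*: βNTI detects selection only if the selected
trait carries phylogenetic signal — close relatives must have similar
environmental optima.  Without that, selection moves taxa, not clades, and
the phylogenetic null cannot see it.  The synthetic generator builds this
signal in (Brownian trait evolution); for real data it is an assumption.

### RCbray

For each pair, the observed Bray–Curtis dissimilarity is ranked within a
null ensemble of probabilistically assembled community pairs.  Each null
community preserves the observed sample's richness R and total abundance N:
R species are drawn without replacement with probability proportional to
metacommunity occupancy (fraction of samples occupied; Gumbel top-k
sampling), each receives one individual, and the remaining N − R individuals
are assigned multinomially with probability proportional to metacommunity
relative abundance over the drawn species.  Then

RCbray = 2·[ (#{BC_null < BC_obs} + ½·#{BC_null = BC_obs}) / n_null − ½ ] ∈ [−1, 1].

One ensemble of n_null null communities is generated per sample (per-sample
seed substreams); replicate k of pair (a, b) compares a's k-th and b's k-th
null communities.  Within any pair the two null communities are independent,
so the per-pair null distribution is unchanged; ensembles are merely reused
across pairs sharing a sample (S·n_null assemblies instead of
2·pairs·n_null).  Because row totals are preserved, null and observed BC
share a fixed denominator per pair and ties are detected exactly.

### Classification and contributions

Per pair: βNTI > 2 → heterogeneous selection; βNTI < −2 → homogeneous
selection; otherwise RCbray > 0.95 → dispersal limitation; RCbray < −0.95 →
homogenizing dispersal; else drift.  Boundary ties follow the strict
inequalities: βNTI = ±2 falls to the stochastic branch, RCbray = ±0.95 to
drift.  Contributions are percentages of classified pairs, reported with all
five processes (zeros included) overall, per stratum, or per
latitudinal-difference bin ([e_k, e_{k+1}) half-open, last bin closed).

### Dominance-threshold detection

Pairs are pooled into consecutive [k·w, (k+1)·w) bins (default w = 2°) and
collapsed to deterministic (both selection classes) vs stochastic (both
dispersal classes + drift).  A bin is deterministic-dominant when
deterministic pairs form a strict majority; a 50/50 tie counts as
stochastic.  The detected threshold is the left edge of the first bin of the
final unbroken deterministic run, provided a stochastic-dominant bin
precedes it; bins with fewer than `min_pairs` (default 5) pairs are excluded
from the scan; `None` when dominance never switches.

## 2. Pattern statistics

Shannon diversity is −Σ p ln p (nats).  Group comparisons use the
Mann–Whitney/Wilcoxon rank-sum test (exact for small tie-free samples,
tie-corrected normal approximation otherwise).  Bray–Curtis is
Σ|x−y| / Σ(x+y).  NMDS is non-metric MDS on the Bray–Curtis matrix (Kruskal
stress-1, default k = 2, 20 restarts of which one is initialised from
principal-coordinates analysis, tolerance 1e−6); stress of the returned
configuration is the minimum over restarts.  ANOSIM uses Clarke's statistic
R = (mean between-group rank − mean within-group rank) / (M/2) with
M = n(n−1)/2 and average ranks on ties, so R ∈ [−1, 1] and perfectly
separated groups give R = 1; p is the add-one permutation estimator.
Distance–decay regresses similarity (defined as 1 − Bray–Curtis) on
Δlatitude by ordinary least squares and reports Spearman's ρ with both its
naive p and, optionally, a Mantel-permutation p — sample pairs are not
independent, so the naive p is anti-conservative and both are shown.

## 3. Driver attribution

Mantel r is the Pearson or Spearman (default) correlation of the vectorised
upper triangles; p permutes rows/columns of the first matrix jointly
(one-tailed toward positive association by default, the convention for
distance matrices; two-tailed available).  Spearman under permutation equals
Pearson on rank-transformed matrices, so matrices are pre-ranked once.
The partial Mantel statistic is the first-order partial correlation
r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)); its permutation scheme
permutes x and recomputes the statistic.  `driver_analysis` reports, per
driver: the standard test, first-order partials controlling each other
driver, and an all-others control via sequential OLS residualisation of the
condensed vectors, ranked by the all-others partial r.  A degenerate control
(a driver duplicating the response) yields NaN for that partial rather than
an error.  Geographic distance is great-circle (haversine) with mean Earth
radius 6371.0 km.

## 4. The synthetic metacommunity generator

The generator emulates the downstream inputs of a coastal latitudinal
survey: tens of samples along a 19–40° gradient (44 water / 25 sediment
matches the emulated study design), hundreds of OTUs on a Yule (pure-birth)
phylogeny, temperature cooling linearly with latitude (default 0.7 °C per
degree plus noise), a mild independent salinity gradient, longitudes
tracking a NE-trending coastline, and four trophic groups each assembled
under its own regime with truth labels recorded.

Per sample, expected relative abundance is base_i · w_i(site), with base_i a
lognormal metacommunity abundance, and `reads_per_sample` (default 20,000,
of the order of a typical rarefaction depth) individuals drawn multinomially:

- **selection** — w = exp(−(optimum − T_site)²/(2σ²)); optima evolve by
  Brownian motion on the tree (creating the phylogenetic signal βNTI
  requires) and are rescaled linearly onto the realised site-temperature
  range so the gradient's ends filter for disjoint clades.
- **neutral_drift** — w = 1.
- **dispersal_limited** — each OTU has a uniform random "home" coordinate;
  w = exp(−distance-to-home / kernel).  Homes are random with respect to the
  phylogeny, so turnover is taxonomic, not phylogenetic (dispersal
  limitation, not spurious selection).
- **homogenizing** — mass effects: one realised migrant pool is drawn once,
  and every sample receives a without-replacement subsample of it
  (fraction `migration_rate`, default 0.9, of its reads) plus a small
  independent multinomial complement — communities share realised
  individuals and end up more similar than common-pool sampling alone.

Two calibrated evenness/noise constants (chosen once, by scanning the
generator against the framework's own definitions, then frozen):

- `base_lognormal_sigma = 2.5`.  Microbial abundance distributions are
  highly uneven; with much lower values every OTU occurs in every sample at
  realistic depths and βMNTD's null degenerates (all pairs share all taxa).
  2.5 yields ~70% mean occupancy at 300 OTUs × 20k reads.
- `drift_sigma = 0.3` — per-sample lognormal jitter of expected abundances,
  the ecological-drift component proper.  Pure multinomial resampling is
  sequencing noise, and communities built that way are *more* similar than
  the Raup–Crick null ensemble (RCbray → −1, i.e. the framework would call
  them homogenized, not drifting).  0.3 sits in the middle of the regime in
  which the framework's own classification calls neutral communities drift
  (97–99% of pairs) while βNTI stays calibrated (≈2% beyond ±2).

### The planted dominance-threshold scenario

`threshold_scenario(threshold_deg)` plants a stochastic→deterministic
dominance switch without hand-coding one: selection contrast between two
sites grows with their temperature difference ΔT = env_slope·Δlat, and
dominance flips once ΔT reaches about 1.8 niche breadths
(`SWITCH_CONTRAST_SIGMAS`, calibrated once), so the slope is set to
1.8·σ/threshold.  The switch scale is a property of a *realised* landscape —
across random trees/traits/abundance draws it wanders by several degrees and
some landscapes never switch — so the scenario pins a reference landscape
(`REFERENCE_LANDSCAPE_SEED`: tree, trait history, sites, metacommunity
abundances) and replicate seeds vary what is genuinely stochastic in a
repeated study: ecological drift, multinomial sampling, and the null-model
draws.  Recovery of the planted 8° switch within ± one 2° bin succeeds in
≥ 9/10 replicates across master seeds.

### What the generator does not emulate

Sequence-level artefacts (PCR bias, chimeras, OTU-clustering error),
speciation, temporal dynamics, interactions between trophic groups, and
selection on more than one trait at a time (salinity-driven selection can be
emulated by relabelling, since only the site covariate differs).  Passing
tests therefore validate the inference machinery under its own stated
assumptions — phylogenetic trait signal, a well-sampled metacommunity, one
dominant selective axis — not the biology of any particular survey.

## 5. Numerical and design choices

- Rarefaction is a multivariate-hypergeometric subsample (without
  replacement), per sample, seeded; samples below depth are dropped and
  logged.  Trophic sub-tables exclude samples whose group total is below the
  group's rarefaction depth by default.
- βNTI uses abundance-weighted βMNTD by default; both weighted and
  unweighted variants are exposed.
- sd = 0 null distributions, and pairs with undefined βNTI, are excluded
  from contributions with a warning and a count, never silently.
- Null-model sizes used in the shipped validation runs: 999 randomisations
  for calibration checks, 299 for the replicated recovery scenarios (the
  z-score and rank statistics stabilise well below that; sizes are stated
  with each result).
- Master seeds spawn independent substreams (numpy `SeedSequence`) for
  tree, traits, sites, metacommunity, assembly and null models, so every
  pipeline stage is independently reproducible and the full chain is
  byte-identical across runs with the same seed.
- Tie-breaks: βNTI exactly ±2 → stochastic branch; RCbray exactly ±0.95 →
  drift; a 50/50 dominance bin → stochastic.

## 6. Limitations

- The Raup–Crick classification is sensitive to how the real data's
  compositional variance compares with its specific null ensemble; the
  drift/dispersal split (unlike the selection split) has no absolute
  calibration and should be read comparatively.
- Shared environmental filtering between similar sites can register as
  homogenizing dispersal (communities more similar than random assembly)
  rather than homogeneous selection when the within-filter composition is
  tightly shared; the two are mechanistically distinct but observationally
  adjacent in this framework.
- Mantel-type tests have known inflated type-I error under strong spatial
  autocorrelation of both matrices; the package reports permutation p-values
  as the framework prescribes and leaves causal reading to the analyst.
- The dominance-threshold detector reports a bin edge; its resolution is the
  bin width, and sparse far ends of a gradient (few long-distance pairs) are
  excluded by the `min_pairs` rule rather than smoothed.
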