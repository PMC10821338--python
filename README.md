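# assemblyscape

Phylogenetic null-model inference of ecological community-assembly processes
and their spatial-scale dependence, for microbial (e.g. 18S rRNA OTU)
community surveys along environmental gradients.

Microbial community composition is shaped by a mix of deterministic
processes (environmental selection) and stochastic ones (dispersal and
ecological drift), and their balance shifts with the spatial scale over
which communities are compared.  `assemblyscape` implements the standard
null-model framework for quantifying that balance from an OTU table, a
phylogeny and per-sample metadata, and ships a synthetic metacommunity
generator with planted ground truth so that the whole inference chain can be
validated without any sequencing data.

## The method

For each pair of communities *A*, *B*:

1. **βMNTD** — the abundance-weighted beta mean nearest taxon distance

   βMNTD = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d_ij + Σ_{j∈B} f_jB · min_{i∈A} d_ij ]

   where f are relative abundances and d_ij patristic (tip-to-tip
   branch-length) distances on the phylogeny.

2. **βNTI** — the z-score of the observed βMNTD against a null distribution
   obtained by shuffling taxon positions on the phylogeny (999 taxa-shuffle
   randomisations):  βNTI = (βMNTD_obs − μ_null) / σ_null.
   βNTI > 2 indicates **heterogeneous selection**, βNTI < −2 **homogeneous
   selection**.

3. **RCbray** — for pairs with |βNTI| ≤ 2, the Bray–Curtis-based Raup–Crick
   index locates the observed Bray–Curtis dissimilarity within a null
   ensemble of communities assembled probabilistically from the
   metacommunity (species membership weighted by occupancy, individuals by
   relative abundance), rescaled to [−1, 1].  RCbray > 0.95 indicates
   **dispersal limitation**, RCbray < −0.95 **homogenizing dispersal**, and
   |RCbray| ≤ 0.95 **ecological drift**.

4. The relative contribution of each of the five processes is the
   percentage of sample pairs it classifies — overall, per trophic group,
   and per latitudinal-difference bin — and a dominance scan over fine
   Δlatitude bins detects the spatial scale at which the community switches
   from stochasticity-dominated to selection-dominated assembly.

Around this core the package provides the accompanying pattern statistics
(Shannon diversity, Wilcoxon rank-sum comparison, Bray–Curtis, NMDS
ordination, ANOSIM, distance–decay regression of similarity on latitudinal
separation) and driver attribution for βNTI via standard and partial Mantel
tests against Δtemperature, Δsalinity, Δlatitude and great-circle distance.

## Worked example

Simulate a two-trophic-group study (autotrophs under temperature selection,
mixotrophs under pure drift) along a 19–40°N gradient and classify every
sample pair:

```python
from assemblyscape import (
    RegimeConfig, generate_dataset, patristic_distances, bnti_matrix,
    rc_bray_matrix, classify_processes, process_contributions,
    binned_contributions, NullModelConfig,
)
from assemblyscape.drivers import env_delta_matrix

configs = {
    "autotroph": RegimeConfig(regime="selection", n_otus=150, n_samples=30,
                              selection_sigma=1.4, reads_per_sample=5000),
    "mixotroph": RegimeConfig(regime="neutral_drift", n_otus=150, n_samples=30,
                              reads_per_sample=5000),
}
dataset = generate_dataset(configs, seed=42)
table, tree, metadata = dataset.table, dataset.tree, dataset.metadata

distances = patristic_distances(tree, table.otu_ids)
config = NullModelConfig(n_null=299, seed=42)
bnti = bnti_matrix(table, distances, config)
rcbray = rc_bray_matrix(table, config)
classification = classify_processes(bnti, rcbray)

delta_lat = env_delta_matrix(metadata, "latitude")
print(process_contributions(classification).round(1).to_string())
print(binned_contributions(classification, delta_lat, [0, 5, 10, 15, 21]).round(1).to_string())
```

Output:

```
         heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  drift  n_pairs
stratum
all                         52.9                    0.9                  13.6                     4.6   28.0      435

         heterogeneous_selection  homogeneous_selection  dispersal_limitation  homogenizing_dispersal  drift  n_pairs
stratum
0-5                         21.0                    2.4                   7.8                    12.0   56.9      167
5-10                        56.6                    0.0                  23.5                     0.0   19.9      136
10-15                       84.1                    0.0                  15.9                     0.0    0.0       88
15-21                       100.0                   0.0                   0.0                     0.0    0.0       44
```

Read the binned table top to bottom: among nearby sample pairs (Δlatitude
0–5°) stochastic processes — drift above all — dominate, while pairs
spanning more than 15° of latitude are classified as heterogeneous selection
without exception.  That monotone hand-over from stochasticity to selection
with increasing spatial separation is exactly the planted structure of the
`selection` regime: sites further apart on the gradient filter for
increasingly disjoint clades of the temperature-optimum phylogeny, while the
drift half of the community contributes scale-independent noise.

The same analyses are available from a shell:

```sh
assemblyscape simulate --seed 42 --out sim/
assemblyscape prepare  --otu-table sim/otu_table.tsv --annotation sim/trophic.tsv \
                       --depth 18244 --seed 42 --out prep/
assemblyscape assembly --otu-table sim/otu_table.tsv --tree sim/tree.nwk \
                       --metadata sim/metadata.tsv --nnull 999 --seed 42 --out asm/
assemblyscape drivers  --bnti asm/bnti.tsv --metadata sim/metadata.tsv \
                       --nperm 999 --seed 42 --out drivers.tsv
```

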