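# planktonet

Linking marine plankton community structure to biogeochemistry. `planktonet`
is a Python toolkit for analyses that connect amplicon sequence variant (ASV)
tables from multi-year ocean transect surveys — 16S (prokaryotes) and 18S
(eukaryotes) — to concurrent biogeochemical measurements: net community
production (NCP, mmol O₂ m⁻² d⁻¹), particulate organic carbon (POC,
µmol C L⁻¹) and nitrogen (PON, µmol N L⁻¹). It is written for microbial
oceanographers who have processed ASV tables in hand and want to go from
"who is there" to "who covaries with the biogeochemistry, and with whom do
they co-occur".

The pipeline has six layers, each usable on its own:

1. **`data_model`** — count-table ingest, rarefaction (multivariate
   hypergeometric), relative abundance, taxon-group assignment into six
   phytoplankton-containing groups (*Prochlorococcus*, *Synechococcus*,
   Archaeplastida, Dinoflagellata, Haptophyta, photosynthetic Stramenopiles),
   **persistence** classification (persistent = detected in all three survey
   years; ephemeral = 1–2 years), and biogeographic region labels from the
   salinity front (34.82 ppt) and chlorophyll-*a* front (0.15 mg m⁻³) that
   bound the subtropical gyre (NPSG) and the southern/northern transition
   zone (STZ/NTZ).
2. **`community`** — Bray–Curtis dissimilarities, non-metric multidimensional
   scaling (Kruskal stress-1), ANOSIM and EnvFit permutation tests, and the
   subset-vs-whole comparison quantifying how closely each persistence class
   tracks the full community.
3. **`varpart`** — the mixed linear model. Each group contributes a
   sample × sample kernel **K_g** (Gower-centered, PSD-projected Bray–Curtis
   similarity of the group-restricted composition), and a trait is modeled as

   y = Xβ + Σ_g u_g + ε, u_g ~ N(0, σ²_g K_g), ε ~ N(0, σ²_e I)

   with fixed effects X (year×month, size fraction, depth bin) and variance
   components estimated by REML (average-information updates, EM fallback).
   The output is the fraction of trait variance attributable to each group,
   f_g = σ²_g / (Σσ² + σ²_e), with AIC/BIC and per-group covariation signs
   from BLUPs.
4. **`coabundance`** — weighted co-abundance modules: soft-thresholded
   correlation networks (|r|^β) on persistent phytoplankton ASVs, topological
   overlap (TOM), average-linkage module detection with eigengene merging,
   module–trait correlation against Box–Cox-transformed traits, and a
   robustness check of memberships across soft powers 1–8.
5. **`cooccur`** — sparse conditional co-occurrence networks in the
   SPIEC-EASI style: centered-log-ratio transform, per-node L1-penalized
   neighborhood regressions along a λ path, StARS stability selection of λ,
   and an undirected weighted graph ("or" rule, mean weights).
6. **`neighborhood`** — the integrative step: candidate ASVs from
   trait-positive modules, their weighted first-degree network neighbors,
   same-module enrichment of positive neighbors, and known-association
   positive controls (e.g. the *Braarudosphaera*–UCYN-A symbiosis).

A first-class synthetic generator (`simulate`) produces gradient-structured
multi-year surveys with planted truth — group niches along latitude, two size
fractions, persistence classes, co-abundance modules, a sparse precision
matrix (logistic-normal-multinomial counts), and traits with prescribed
per-group variance fractions — so every layer's recovery can be scored.
`benchmarks` runs those scoring experiments.

## Worked example

The package ships a small example survey (60 samples across 2016/2017/2019,
152 ASVs, both markers and size fractions) with traits planted at fractions
0.45 (Archaeplastida), 0.20 (Dinoflagellata), 0.0 (Haptophyta), residual
0.35:

```python
from planktonet import datasets, community, varpart
from planktonet.data_model import classify_persistence, relative_abundance

ds = datasets.load_example()
table = ds.combined_table()

labels = classify_persistence(ds.tables_by_year())
rel = relative_abundance(table)
print(len(labels.persistent_asvs()), "persistent of", table.n_asvs)
print(f"{100 * rel[labels.persistent_asvs()].sum(axis=1).mean():.1f}%")

D = community.bray_curtis_matrix(rel)
ano = community.anosim(D, ds.metadata.loc[table.sample_ids, "region"], seed=0)
print(f"ANOSIM by region: R = {ano.statistic:.2f}, p = {ano.p_value:.3f}")

kernels = [varpart.build_group_kernel(table, ds.taxonomy.asvs_in_group(g), name=g)
           for g in ("Archaeplastida", "Dinoflagellata", "Haptophyta")]
fit = varpart.fit_multikernel_reml(
    ds.traits["NCP"].reindex(table.sample_ids).to_numpy(), None, kernels)
print({k: round(v, 2) for k, v in fit.fractions.items()})
```

prints

```
106 persistent of 152
89.7%
ANOSIM by region: R = 0.10, p = 0.003
{'Archaeplastida': 0.47, 'Dinoflagellata': 0.05, 'Haptophyta': 0.21, 'residual': 0.28}
```

Persistent ASVs dominate relative abundance (89.7%) and regions separate
weakly but significantly in community space. The variance partition recovers
the dominant planted contributor (Archaeplastida, 0.47 vs planted 0.45); at
only 60 samples the two correlated minor kernels trade off against each other
(Dinoflagellata/Haptophyta). At the benchmark size of n = 200 the mean
absolute fraction error drops below 0.08 — see the reproduction script below.

The same steps are available from the shell:

```bash
planktonet simulate --seed 3 --out fx/
planktonet community --fixture fx/ --out out/comm/
planktonet varpart  --fixture fx/ --response NCP --out out/ncp.json
planktonet modules  --fixture fx/ --power auto --out out/mod/
planktonet cooccur  --fixture fx/ --seed 0 --out out/net/
planktonet integrate --fixture fx/ --modules-dir out/mod/ \
    --network-dir out/net/ --validate "Braarudosphaera:UCYN-A" --out out/int/
```

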