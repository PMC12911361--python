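# Methods

This note documents the statistical machinery, the synthetic study
conditions, and the numerical choices. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

An `AsvTable` is a samples × ASVs matrix of non-negative integer counts for
one marker gene (16S or 18S), or for both concatenated over shared samples
("mixed", used for co-occurrence networks). Rarefaction draws exactly
`depth` reads per sample without replacement (multivariate hypergeometric),
drops shallower samples with a warning, and can never introduce an ASV that
was absent — depth defaults to the minimum sample total so nothing is
dropped. Persistence is evaluated after rarefaction by default (the call is
exposed so raw counts can be used instead): an ASV is detected in a year if
any sample of that year has a positive count, persistent if detected in all
three years, ephemeral if in one or two.

Taxon groups are a deterministic function of lineage strings: the two
cyanobacterial genera at any rank, the three eukaryotic divisions at
division rank, and Stramenopiles only when the class is one of the eight
photosynthetic (diatom and related) classes; everything else is `Other`.
Regions come from per-sample hydrography when available — NPSG above the
34.82 ppt isohaline, then the 0.15 mg m⁻³ chlorophyll cut splitting STZ
(below) from NTZ — with interpolated per-cruise front latitudes as the
fallback. Both cuts are configuration defaults, not constants.

## Community statistics

Bray–Curtis d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on relative abundances. NMDS
minimizes Kruskal stress-1 by SMACOF majorization (scikit-learn's nonmetric
MDS); one restart is seeded from classical scaling of the dissimilarity
matrix, the rest are random, and every candidate's stress is re-evaluated
with a single isotonic-regression definition so restarts are comparable.
Convergence: stress change < 1e-6 or 500 iterations.

ANOSIM uses midranks of the condensed distances,
R = (mean between-group rank − mean within-group rank)/(M/2), with the
permutation p-value (1 + #{R* ≥ R})/(B+1); groups need ≥ 2 members. EnvFit
regresses the centered variable on the ordination axes; r² = 1 − SSres/SStot,
the arrow is the unit coefficient vector, and p permutes the variable.

The subset-vs-whole comparison renormalizes one persistence class within a
sample × group cell and takes its Bray–Curtis distance to the cell's full
composition. Because the classes partition the ASVs, this distance equals
one minus the class's abundance share, so a persistent class holding ~90% of
abundance sits near 0.1 — the statistic is a share-weighted fidelity measure.
Aggregation defaults to per-sample-per-group; per-sample and pooled units are
available.

## Kernel variance partitioning

Each group's kernel is built from the Bray–Curtis matrix D of its restricted,
renormalized composition: S = −½·C(D∘D)C (Gower centering), eigenvalues
clipped at zero (Bray–Curtis is non-Euclidean, so small negative eigenvalues
are expected and recorded in provenance), and the result rescaled to
trace = n. Samples with zero group abundance are imputed as a uniform
composition by default (keeping the sample set aligned across kernels),
droppable or fatal by configuration.

The mixed model y = Xβ + Σ u_g + ε is fit by REML. The optimizer takes
average-information steps with step-halving so the restricted likelihood
never decreases, falls back to the guaranteed-ascent EM update when a step
fails, and enforces σ² ≥ 0 by projection to a floor of 1e-10·var(y).
Convergence is declared when the relative parameter change falls below 1e-6
(default) or the likelihood has plateaued (per-iteration gain below
1e-8·max(1, |ℓ|) — components pinned at the non-negativity boundary can
leave the remaining parameters creeping along a flat ridge); non-convergence
raises an error carrying the trajectory. Kernel pairs that are numerically identical (including a
kernel equal to the identity, which aliases the residual) are detected and
flagged as non-identifiable. AIC = −2ℓ_R + 2k and BIC = −2ℓ_R + k·log n with
k = #variance components + rank(X); the likelihood basis (REML) is recorded
with the output, since REML criteria are only comparable across models with
the same fixed effects. Covariation signs correlate each group's BLUP
û_g = σ²_g K_g V⁻¹(y − Xβ̂) with the group's total relative abundance per
sample; groups with fraction < 0.01 or a non-significant correlation report
no sign. Fixed effects default to intercept + year×month + size fraction +
depth bin, with aliased dummy columns dropped by pivoted QR. Traits enter the
mixed model untransformed (Box–Cox applies to the module-detection stage);
missing trait values are removed listwise per response.

## Co-abundance modules

Correlations are computed on **log₁₀ relative abundance** (pseudo-fraction:
half the smallest nonzero proportion), standardized per ASV. Raw proportions
are right-skewed enough that Pearson correlation between genuinely
co-abundant ASVs is attenuated several-fold; the log scale restores it. This
is the one place the pipeline departs from "standardized relative abundance"
as the correlation input, and it is deliberate.

Adjacency is unsigned |r|^β (signed available). The soft power is chosen by
the scale-free fit criterion (binned log₁₀ p(k) vs log₁₀ k regression,
index −sign(slope)·R², smallest β reaching 0.8 else the argmax). TOM follows
TOMᵢⱼ = (Σᵤ AᵢᵤAᵤⱼ + Aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − Aᵢⱼ) with the shared-neighbor
sum excluding i and j and unit diagonal.

Module detection is a fixed-height cut of the average-linkage dendrogram of
1 − TOM plus eigengene merging, standing in for the dynamic hybrid tree cut:
when no cut height is given, candidate cuts are placed at the largest gaps
between merge heights (upper half of the dendrogram, plus the
everything-in-one-branch cut) and the candidate maximizing weighted TOM
modularity wins. This adapts the cut to the soft power, which a single fixed
height cannot do. Module quality is judged in correlation space — mean
intra-branch |r| must reach 0.3 and exceed 1.5× the mean |r| outside the
branch — deliberately independent of β so that the powers-1–8 robustness
check compares like with like; loose branches and branches below the minimum
size (5) stay unassigned ("grey"). Modules whose eigengenes correlate above
1 − 0.25 are merged. Labels are colors in decreasing size order from a fixed
palette; no attempt is made to reproduce any particular study's colors.

Eigengenes are first principal-component scores of the standardized member
profiles, sign-oriented so the mean member correlation is positive, and
scaled to unit variance. Module–trait tests are Pearson correlations of
eigengene vs Box–Cox-transformed trait (scipy's profile-likelihood λ; inputs
shifted positive by min+1 when needed, shift recorded), two-sided t reference
with n−2 df, pairwise deletion, NA below 3 paired observations. Power
stability rebuilds the partition at each power and reports, per reference
module, the best Jaccard overlap with any module of the rebuilt partition.

## Sparse co-occurrence

CLR: x → log(x+1) − mean log(x+1) per sample (pseudocount 1). The estimator
is Meinshausen–Bühlmann neighborhood selection: each standardized CLR column
is lasso-regressed on all others along a geometric path of 20 λ values from
λ_max (the largest absolute pairwise correlation, at which all neighborhoods
are empty) down to 0.01·λ_max. StARS subsamples the data (50 subsamples of
⌊10√n⌋ samples, ⌊0.8n⌋ below n=144), measures per-edge selection frequencies
θₑ under the "or" rule, computes instability D(λ) = mean 2θₑ(1−θₑ),
monotonizes from the sparse end, and selects the **densest** λ with
monotonized D ≤ β = 0.05 — the least regularization that is still stable; if
none qualifies the sparsest λ is returned flagged. The final graph refits on
the full data at λ*: an undirected edge exists where either directed
selection fired ("or"; "and" available), weighted by the mean of the
available directed coefficients; the directed map is kept for out-degree
ranking. 16S and 18S tables are concatenated over shared samples into one
network; samples missing a marker are dropped with a warning.

## Neighborhood integration

Candidates are the members of modules with r > 0 and p < 0.05 for at least
one trait (raw p-values by default, mirroring direct-quotation reporting;
Benjamini–Hochberg available). First-degree neighbors are all incident
edges, sorted by symmetrized weight with lexicographic tie-breaks. The
crosstab splits neighbors by weight sign and module, and tests same-module
enrichment of positive vs negative edges by a Haldane-corrected odds ratio
with a label-shuffling permutation p; with no negative (or positive) edges
the ratio is undefined (NaN). Known-association checks resolve taxon labels
case-insensitively against any lineage rank and report connecting edges —
the pipeline's internal positive control.

## Synthetic study conditions

The generator emulates three yearly cruises along a 22–42°N transect, ten
stations by default, two size fractions per station, one depth stratum
(configurable). Salinity declines linearly through 34.82 ppt at 32.3°N; the
chlorophyll front sits near 34.3°N, giving NPSG/STZ/NTZ structure. Latent
log-abundance per ASV = baseline (N(0, 0.7²)) + 2.0 × a Gaussian latitude
niche (group optima: *Prochlorococcus* 26°, Dinoflagellata 27.5°, Haptophyta
31°, photosynthetic Stramenopiles 36°, *Synechococcus* 37°, Archaeplastida
38°; per-ASV jitter sd 1.5°) + small-fraction enrichment (log 4 for
*Prochlorococcus* and Archaeplastida, log 3 Stramenopiles, log 2.5
Haptophyta, matching the several-fold small-fraction enrichment such surveys
report) + module loadings + multivariate Gaussian noise whose precision
matrix is the planted co-occurrence truth (chain by default; hub and random
with heterogeneous strengths available). Counts are multinomial per marker
with lognormal depth (mean 3×10⁴). Ephemeral ASVs (30% by default, assigned
1–2 years) are excluded from the multinomial outside their years; each ASV
scheduled present in a year is guaranteed at least one read there, so
persistence classes round-trip exactly.

Planted modules are latent factors shared by member ASVs (loading 3.0,
members drawn from persistent phytoplankton ASVs). The factor matrix is
orthogonalized in-sample: at n = 60, chance correlations between independent
draws reach |r| ≈ 0.3 and would merge "independent" planted modules at low
soft powers, contradicting the truth the recovery benchmarks score against.
Traits are built from the generated community itself: u_g ~ N(0, K_g) with
K_g the group's Bray–Curtis Gower kernel, each component rescaled so its
empirical variance share hits the planted fraction exactly (`exact=True`),
plus white residual; responses are affinely mapped to realistic units (NCP
12 ± 8 mmol O₂ m⁻² d⁻¹, POC 5 ± 1.1 µmol C L⁻¹, PON 0.8 ± 0.17 µmol N L⁻¹ —
fraction estimates are invariant to this affine map; POC/PON are floored at
a trace level).

What the generator does **not** emulate: real surveys' taxon richness
(hundreds of ASVs, not thousands), read-depth distributions, rRNA copy-number
variation, overdispersion beyond the logistic-normal, depth-resolved
structure, or taxonomically realistic lineage frequencies. Passing recovery
benchmarks therefore demonstrates correctness of the estimators under the
planted model, not performance guarantees on field data.

## Benchmark problem sizes

Chosen so the whole battery runs in a few minutes on one CPU: variance
partitioning at n = 200 samples × 20 replicates with kernels from three
groups (one planted null); the REML grid oracle at n = 30 with a 20³ grid
over the three variance components (0.01–3 × var(y), geometric); module
recovery at 150 phytoplankton ASVs × 60 samples with four planted modules
and a factor-linked trait (noise sd 0.5); network recovery at p = 40,
n = 300 over 10 planted random graphs (density 0.05, partial-correlation
strengths U(0.3, 0.5) — heterogeneous strengths are what make the
edge-count-matched marginal-correlation baseline beatable, since weak direct
edges then rank below strong two-step indirect correlations); known-pair
controls at p = 30, n = 300 with one strong planted edge (strength 0.5)
between taxonomically named control ASVs and two isolated negative-control
ASVs; calibration with 200 null replicates (ANOSIM: 20 samples, random
2-group labels, 199 permutations; module–trait: trait shuffled against fixed
eigengenes).

## Known limitations

- The REML fractions of strongly correlated kernels trade off at small n
  (visible in the bundled 60-sample example); the sum of the involved
  fractions is much better determined than the split.
- The adaptive cut considers only the eight largest merge-height gaps; a
  pathological dendrogram could hide the right cut in a smaller gap
  (an explicit `cut_height` bypasses the heuristic).
- StARS instability is computed under the same edge rule used for the final
  graph; switching rules after selection is not supported.
- Lasso selection paths are not exactly nested: at near-saturated densities
  the "and"-rule edge count can dip by an edge or two along the path.
- The Box–Cox λ is fit by continuous optimization, so on data where the
  profile likelihood is flat (already-normal traits) the reported λ scatters
  widely even though the transform is effectively affine.
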