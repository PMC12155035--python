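# Methods

## The problem

Genome-wide association studies (GWAS) assume exchangeable samples;
population structure violates that assumption and inflates test
statistics. The standard fix — projecting genotypes onto leading principal
components (PCs) and including them as fixed-effect covariates — captures
broad, linear axes of ancestry well, but recent, fine-scale structure
(the kind that shapes rare-variant sharing within a superficially
homogeneous cohort) is discrete and localized, and PCs of common variants
smooth over it.

Identity-by-descent (IBD) segments are direct evidence of recent shared
ancestry: a long segment (several cM) implies a common ancestor within the
last tens of generations. This package converts pairwise IBD sharing into
continuous per-sample covariates — spectral components (SPCs) — that encode
exactly that recent structure.

## The SPC pipeline

1. **Segments.** Input is a flat table of IBD segments (two sample ids,
   autosome, physical span, genetic length in cM). Detection itself
   (phasing + an IBD caller such as iLASH) is out of scope; the simulation
   path supplies ground-truth segments instead.
2. **Aggregation.** Segment lengths are summed per unordered pair of
   individuals over all chromosomes and haplotype pairings. Overlapping
   segments are summed, not merged.
3. **Graph.** An undirected edge joins a pair whenever its total *strictly
   exceeds* a threshold `l` (default 6 cM; 10 and 15 are conventional
   alternatives). The binary adjacency matrix A has a_ij = 1 for edges,
   zero diagonal.
4. **Spectral embedding.** The symmetrically normalized Laplacian

       L_sym = I − D⁺^{1/2} A D⁺^{1/2}

   where D is the degree diagonal and D⁺ its Moore–Penrose inverse, has
   eigenvalues in [0, 2]. The eigenvectors of the *smallest* eigenvalues
   are the SPCs: they are the smoothest functions on the graph, so nearby
   (recently related) samples receive similar coordinates, and the first
   non-trivial eigenvector cuts the graph along its weakest link (the
   Fiedler property). SPCs are used exactly like PCs downstream.

The Moore–Penrose convention gives an isolated vertex an identity row in
L_sym, hence the exact eigen-pair (1, e_i); isolated samples therefore get
well-defined (near-zero) coordinates in the leading SPCs rather than
missing values, and covariate files stay complete.

Eigenvalue-zero eigenvectors are *included* by default: for a connected
graph the λ=0 vector is ∝ D^{1/2}·1 (a degree signal) and for a
disconnected graph the zero eigenvectors encode component membership —
both are structure. `skip_trivial` (CLI `--skip-trivial`) drops
eigenvalues below 1e-10 for users who prefer their own intercept.

### Numerical route

The k smallest eigen-pairs of L_sym are computed as the k largest of
M = D⁺^{1/2} A D⁺^{1/2} with λ = 1 − μ, which Lanczos iteration handles far
better than a shift-invert solve at 0. Graphs with n ≤ 2000 are solved
densely (`numpy.linalg.eigh`); the sparse solver's start vector is seeded,
so results are deterministic. Each eigenvector's sign is fixed so its
largest-magnitude entry is positive (ties → lowest index). Repeated
eigenvalues return an arbitrary orthonormal basis of the eigenspace;
comparisons across runs must therefore use subspace angles, and the test
suite does.

## Simulation framework

`gridsim` simulates an N×N stepping-stone grid with msprime:

| parameter | default | meaning |
|---|---|---|
| `grid_n` | 4 | demes per side (16 demes) |
| `diploids_per_deme` | 100 | samples drawn per deme |
| `deme_size` | 1000 | diploid effective size of each deme |
| `migration_rate` | 0.05 | per-generation exchange with each rook neighbour |
| `t_ancestral` | 300 | generations to the single-population merge |
| `t_dtwf` | 150 | most recent generations run under DTWF |
| `chromosomes` | one 50 Mb at 1.149e-8 | (length_bp, recomb rate) pairs |
| `mutation_rate` | 1.25e-8 | per bp per generation |
| `ancestral_size` | deme_size × n_demes | merged population size |

Migration is rook (4-neighbour) adjacency at 0.05 per adjacent pair per
generation, which puts adjacent-deme F_ST near 0.005 — the divergence
scale of neighbouring administrative counties in a homogeneous national
cohort, and the regime in which fine-scale structure is invisible to a
handful of common-variant PCs. The most recent 150 generations run under
the discrete-time Wright–Fisher model so that long-IBD-segment lengths are
realistic; earlier history uses the standard coalescent. Deme effective
size and mutation rate are not published quantities for the reference
design; the defaults above are conventional choices (human consensus
mutation rate; a deme size that keeps within-deme relatedness plausible)
and both are prominent, configurable fields.

**True IBD.** Segments are read off the simulated ancestry
(`tskit.ibd_segments`): maximal intervals over which two haplotypes share
the same ancestral node, kept when genetic length (span × recombination
rate × 100) is ≥ `min_cM` (default 3, a typical detection floor).
Haplotype pairs within one individual are excluded. This replaces the
phase→detect noise path of real pipelines, so the graph here is noise-free
relative to one built from called IBD — tests on it say nothing about
robustness to phasing artifacts or false-positive segments.

**Presets.** `small4x4` (16 demes × 100 diploids, one 50 Mb chromosome)
runs in ~2 minutes and is the desk-scale workhorse; `large5x5` (25 demes ×
200 diploids) feeds uncommon-variant analyses; `paper8k` (8,000 diploids,
22 chromosomes with GRCh38 lengths) mirrors the full design and is
cluster-scale — documented, not CI-run.

## Phenotype models

* **smooth** — y ~ 𝒩(mean_row, σ²), mean_row falling linearly from 2σ (top
  row) to 0 (bottom row). Purely environmental; h² = 0 by construction.
* **sharp** — one target deme at 𝒩(μ, (m·σ)²), every other deme 𝒩(0, σ²).
  The multiplier m defaults to 1, with m = 2 available (both variants
  circulate); μ defaults to 2σ. Non-linear in coordinates, h² = 0.
* **polygenic** — one causal SNP drawn uniformly from every 1 kb window
  ([w·1000, (w+1)·1000), per chromosome) that contains a segregating site;
  β_j ~ 𝒩(0, [2p_j(1−p_j)]^α) with α = −1 by default, so each causal
  variant contributes equally in expectation across the frequency
  spectrum. The genetic score is rescaled in-sample to variance h²
  (default 0.8) and the noise term is drawn, orthogonalized against the
  score, and rescaled to 1 − h², making the realized heritability exact to
  machine precision — a deterministic test surface rather than an
  expectation. α is a knob, not a fitted quantity: the published
  normalization ties the global scale to total heritability, which the
  explicit rescaling supplies directly.

## Evaluation statistics

* **GWAS** — covariate-adjusted OLS: y and each dosage column are
  residualized on [1, C] via one QR factorization; slope, SE on n−c−2 df,
  two-sided t p-value (floored at 1e-300). Equals the per-variant multiple
  regression exactly; verified against that oracle at 1e-8. Mixed models
  are deliberately not re-implemented — linear regression is the
  simulation-faithful analogue when phenotypes carry no indirect genetic
  effects or cryptic-relatedness structure.
* **Inflation** — λ = median(χ²)/0.4549364231, with a seeded percentile
  bootstrap (B = 1000) over variants for the 95% CI; the CI method is a
  package choice, stated in the output.
* **PVE** — R² of y on [1, C], plus adjusted R². At desk-scale n the raw
  value carries a c/n chance level (25/1600 ≈ 1.6%), so model comparisons
  use the adjusted value; with c = 25 and n = 1600 the sampling SD of
  adjusted R² is still ≈ 0.4%, which bounds how small a PVE difference is
  interpretable at that n.
* **Coordinate R²** — OLS of deme row (and column) index on the
  covariates; the structure-recovery score.
* **Moran's I** — (n/W)·Σw_ij z_i z_j / Σz², null expectation −1/(n−1).
  For simulated data the helper applies rook weights to per-deme means.
* **Causal stratification** — variants are causal, in LD with causal
  (max r² within ±1 Mb strictly above 0.1, both configurable), or
  non-causal; Wilcoxon rank-sum compares −log10 p between two covariate
  models per stratum.
* **Haseman–Elston** — the heritability stand-in (REML/GREML is out of
  scope): regress y_i·y_j on GRM_ij over pairs, slope clipped to [0,1],
  delete-one-sample jackknife SE computed from per-sample partial sums.
  The GRM uses 2p(1−p) standardization; at small n this differs from the
  empirical variance by a few percent, which bounds the estimator's
  accuracy in the single-variant limit.

## Problem sizes used by the tests and the acceptance script

The shipped checks run the 4×4 / 1,600-diploid / 50 Mb configuration
(about 2 minutes of simulation, ~340k sites) for structure recovery,
inflation, PVE, calibration and heritability, with two further seeds of
the same configuration for the ordering checks, and the 5×5 /
5,000-diploid configuration for the uncommon-variant (10 < MAC < 100)
inflation. These sizes keep a full run on one CPU in the tens of minutes.

Scaling down has one qualitative consequence, measured and documented
rather than hidden: the 6 cM threshold is a *genome-wide* sharing cutoff,
and a single 50 Mb chromosome carries ~57 cM of map against ~3,500 cM in
the 22-chromosome design, so the relatedness graph is ~70× sparser (mean
degree ≈ 10 rather than hundreds). The spectral embedding still orders
ahead of PCs on every axis and controls inflation to λ ≈ 1.0–1.1, but
8 SPCs recover coordinate R² ≈ 0.6 at this scale, not the ≈ 0.9 of the
full design — the corresponding full-scale assertion in the acceptance
suite fails at desk scale and is retained as a known scale limitation.
Below this scale the effect is sharper still: at 40 diploids/deme on
30 Mb the graph drops below its useful density and the SPC-vs-PC ordering
itself inverts, which is why the ordering checks run at the 1,600-sample
configuration and not smaller.

## Known limitations

* True IBD only: no phasing/detection noise model, so robustness to
  switch errors and false positives is untested here.
* Constant per-chromosome recombination rates (the simulator runs with
  constant rates; genetic lengths use the same constant, never a map
  file).
* Unrelated-sample assumption downstream: no mixed model, no
  cryptic-relatedness handling, no binary traits, no gene–environment
  interaction.
* The bundled 22-chromosome table pairs GRCh38 lengths with *average*
  recombination rates; only chromosome 1's values are tied to a published
  single-chromosome design.
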