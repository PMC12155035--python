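# spc — spectral components of IBD-sharing graphs

Population structure confounds genetic association studies: when allele
frequencies and environments both vary across a cohort, genome-wide
association tests inherit spurious signal and inflated statistics. The
standard remedy — principal components (PCs) of the genotype matrix as
fixed-effect covariates — captures broad, linear ancestry gradients but
misses the *recent*, fine-scale structure that shapes rare-variant
sharing inside superficially homogeneous cohorts.

This package implements **spectral components (SPCs)**: continuous
per-sample covariates derived from the graph of pairwise
identity-by-descent (IBD) sharing. Long IBD segments certify common
ancestors within the last tens of generations, so a graph whose edges
join pairs with substantial total sharing is a direct map of recent
structure. SPCs are the eigenvectors of the smallest eigenvalues of that
graph's symmetrically normalized Laplacian

    L_sym = I − D⁺^{1/2} A D⁺^{1/2},   eigenvalues in [0, 2],

where A is the thresholded (default > 6 cM aggregate sharing, strict)
binary adjacency matrix, D the degree diagonal and D⁺ its Moore–Penrose
inverse. The smallest-eigenvalue eigenvectors are the smoothest functions
on the graph — recently related samples get similar coordinates — and drop
into any pipeline that consumes PC covariate files.

The package also ships the evaluation framework used to validate the
method: a stepping-stone deme-grid coalescent simulation with
ground-truth IBD (msprime/tskit), three phenotype architectures
(environmental smooth cline, environmental sharp point effect, polygenic
with exact in-sample h²), and the comparison statistics — genotype PCA,
covariate-adjusted GWAS, genomic inflation λ with bootstrap CI, PVE,
deme-coordinate R², Moran's I, causal stratification and Haseman–Elston
heritability. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 4×4 deme grid (16 demes × 100 diploids, one 50 Mb chromosome,
migration 0.05 between rook-adjacent demes, ancestral merge 300
generations ago, Wright–Fisher dynamics for the most recent 150), build
the 6 cM IBD graph from ground-truth segments ≥ 3 cM, and compare SPCs
with genotype PCs:

```python
from spc import gridsim
from spc.gridsim import get_preset, filter_by_frequency, extract_true_ibd
from spc.ibd_graph import aggregate_pairwise, build_graph, to_adjacency, graph_summary
from spc.spectral import build_laplacian, compute_spcs
from spc.assoc_eval import CovariateSet, genotype_pca, coordinate_r2

result = gridsim.simulate_grid(get_preset("small4x4", seed=7))
pairs = aggregate_pairwise(extract_true_ibd(result, min_cM=3.0))
graph = build_graph(pairs, threshold_cM=6.0, samples=result.samples)
print(graph_summary(graph))

basis = compute_spcs(build_laplacian(to_adjacency(graph)), k=25, seed=1)
spc8 = CovariateSet(result.samples, basis.vectors[:, :8],
                    [f"SPC{i+1}" for i in range(8)], kind="SPC")
common = filter_by_frequency(result.genotypes, ("maf_gt", 0.01))
pc25 = genotype_pca(common, k=25)

print("8 SPCs  R^2 (vert, horiz):", coordinate_r2(spc8, result.labels))
print("25 PCs  R^2 (vert, horiz):", coordinate_r2(pc25, result.labels))
```

Output (seed 7):

```
{'n_vertices': 1600, 'n_edges': 7488, 'n_components': 2, 'degree_quantiles': [0.0, 7.0, 9.0, 12.0, 25.0], 'n_isolated': 1}
8 SPCs  R^2 (vert, horiz): (0.608464423251095, 0.6045212866787195)
25 PCs  R^2 (vert, horiz): (0.4543258835800603, 0.4255650764792044)
```

Eight SPCs predict the (row, column) deme of origin better than 25
genotype PCs: the IBD graph carries recent-structure information that the
leading common-variant axes do not. (At this single-chromosome desk
scale the graph is ~70× sparser than in a 22-chromosome design, where
the same comparison reaches R² ≈ 0.9 for SPCs — see `docs/methods.md`.)
The same covariates control GWAS confounding: on a purely environmental
north–south cline phenotype, the common-variant genomic inflation factor
on this run is λ = 1.016 with 25 SPCs against λ = 1.079 with 25 PCs.

The same pipeline is available from the shell for file-based workflows:

```
spc simulate --preset small4x4 --seed 7 --out-prefix sim/
spc graph --ibd sim/ibd.tsv --dialect generic6 --threshold-cm 6 --out sim/graph.npz
spc decompose --graph sim/graph.npz -k 25 --out sim/spcs.eigenvec
spc pheno --kind smooth --labels sim/labels.tsv --sigma 1 --seed 1 --out pheno.tsv
spc gwas --genotypes sim/genotypes.vcf --pheno pheno.tsv \
         --covar sim/spcs.eigenvec --maf-gt 0.01 --out gwas.tsv
```

Component files follow the PLINK `.eigenvec` layout (`FID IID SPC1 …`),
so they drop directly into external association tools.

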