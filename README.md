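# nichetrace

Spatial niche analysis of premalignant tissue from single-cell-resolution
spatial transcriptomics, plus transcriptome-based copy-number
classification for dissociated cohorts.

Premalignant pancreas epithelium does not occupy discrete states: most
cells vary along a continuum linking a gastric-like identity to a
progenitor-like identity, and the surrounding microenvironment — fibroblast
and myeloid states, tissue morphology, ligand–receptor programs — shifts
coherently with the local position of the epithelium along that continuum.
`nichetrace` implements the quantitative machinery to measure this
coupling:

- **Diffusion continua.** A Markov diffusion operator is built on a kNN
  graph with an adaptive Gaussian kernel (affinity
  `exp(-d_ij² / σ_i σ_j)`, σ_i = distance to the 10th neighbour; kernel
  symmetrized and row-normalized). Its non-trivial eigenvectors (diffusion
  components, DCs) order cells along state continua; eigenvalue powers give
  diffusion distances `d(i,j)² = Σ_l λ_l^{2t} (ψ_l(i) − ψ_l(j))²` and
  operator powers `Pᵗ X` impute sparse counts.
- **Niches.** A niche is every cell within r = 60 μm of an anchor cell —
  the length scale of a glandular lesion. Niches get composition vectors,
  an ordering by the mean epithelial DC of their gastric/progenitor
  members, and compartment-specific expression matrices
  `X^{c×n×m}` (counts summed per compartment per niche, size-factor
  normalized, log1p, z-scored across niches).
- **Morphometry from centroids alone.** Lesions are connected components
  of the ≤ 20 μm epithelial contact graph; lumens are recovered on a
  5 μm/px raster by hole-filling of the dilated epithelial bitmap plus
  iterative short-range propagation; features are summarized along the DC
  in equal-width bins.
- **Communication modules.** Gene–gene graphs on niche expression
  (Pearson r > 0.2), Jaccard refinement (drop < 0.05, add > 0.95),
  overlapping module detection, module scoring in canonical
  gastric/progenitor niche sets (flag at mean z > 0.2), and cognate
  ligand–receptor channel ranking by trend coordination along the niche
  continuum.
- **Karyotype inference.** Windowed log2-ratio profiles against a diploid
  reference (min_threshold 0.1, pseudocount 0.1, clip ±3, window 100 genes,
  median recentering), chromosome-level gain/loss calls at ±0.16, and
  classification of cells as genomically *quiet* (< 9 events) or
  *rearranged*, with an optional iterative within-cohort reference.
- **Differential-abundance annotation.** Transcriptomic neighbourhoods are
  labelled by dominant state (excluding the least-pure 5%), scored for
  spatial progenitor enrichment `ln(niche fraction / dataset fraction)`,
  and tested for condition imbalance with an exact test + BH correction.

Everything is exercisable end-to-end on a bundled synthetic-tissue
generator (`nichetrace.simdata`) that emits glandular lesions with lumens,
a latent gastric→progenitor gradient, niche-coupled stromal/myeloid states,
lymph-node blobs, sparse Xenium-like count panels, and dissociated cohorts
with planted chromosome-scale gains/losses — with full ground truth.

## Worked example

```python
from nichetrace.pipeline import run_pipeline
from nichetrace.simdata import SimConfig

res = run_pipeline(seed=0, config=SimConfig(
    seed=0, n_lesions=3, cells_per_lesion=(300, 400),
    stroma_density=9000, fov=(700.0, 700.0)))
```

On this ~5,400-cell tissue the pipeline prints:

```
cells analyzed:            5439
DC1 vs latent (Spearman):  0.923
progenitor niches:         34.6% of niches
progenitor module (myeloid): Cd274, Csf2rb, Il18, Il1b, Itgax, Spp1
progenitor module (epithelial): Il18, Il18rap, Itgb3, Jag1, Lifr, Notch3, Sdc1, Tgfbr1, Tgfbr2
ligand ligand_compartment receptor receptor_compartment  trend_rho
  Il18            myeloid  Il18rap           epithelial   0.809109
  Spp1            myeloid    Itgb3           epithelial   0.798988
```

Reading this: the first diffusion component of the epithelial expression
recovers the planted gastric→progenitor gradient almost perfectly
(Spearman 0.92); 34.6% of niches fall in bins where progenitor-like cells
outnumber gastric-like cells (the canonical progenitor niche); module
detection finds the planted niche-coupled communication programs in the
myeloid and epithelial compartments; and the top-ranked cognate channels
(Il18→Il18rap, Spp1→Itgb3) pair a myeloid ligand with an epithelial
receptor whose niche-expression trends rise together along the continuum.

The same chain is available from the shell:

```bash
nichetrace simulate --config cfg.yaml --out sim/ --seed 4
nichetrace run      --config cfg.yaml --out run/ --seed 4
nichetrace cnv      --counts counts/ --reference-mask ref.txt --out cnv/
```

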