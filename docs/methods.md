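# Methods

This note documents the models and procedures implemented in `nichetrace`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Diffusion model

The operator is built on a k-nearest-neighbour graph (default k = 30,
Euclidean metric in the supplied latent space). The affinity between
neighbours is an adaptive Gaussian kernel
`a_ij = exp(-d_ij² / (σ_i σ_j))` with σ_i the distance to the cell's 10th
neighbour (`bandwidth_neighbor = 10`), so the kernel width tracks local
density. Self-affinities are 1. The kernel is symmetrized as
`W = (A + Aᵀ)/2` and the Markov operator is `P = D⁻¹W`. No density (α)
normalization is applied; the option exists implicitly by pre-processing
the latent space, and the kernel construction is pluggable through
`model_from_affinity`.

Eigendecomposition goes through the symmetric conjugate
`M = D^{-1/2} W D^{-1/2}` so all eigenvalues are real; eigenvectors of `P`
are recovered as `D^{-1/2} v`. Two determinism measures: a fixed start
vector for the Lanczos iteration, and — when the unit eigenvalue is
(near-)repeated because the graph is effectively disconnected — a rotation
of that eigenspace so its first vector is the exact stationary eigenvector.
The remaining vectors of the block are then orthogonal to the constant and
their signs partition the components, which keeps the two-cluster behaviour
of the second eigenvector well-defined. Component signs are fixed so the
entry of the largest magnitude is positive.

Diffusion components are eigenvectors 2..m (unit norm). The number of
informative components can be chosen by the second-eigengap rule: rank all
consecutive eigenvalue drops and keep everything above the second-largest
drop (the largest is normally the trivial gap under λ₁ = 1; equal drops
resolve to the earlier position).

Diffusion distance uses
`d(i,j)² = Σ_{l≥2} λ_l^{2t} (ψ_l(i) − ψ_l(j))²` with t = 1 by default; t is
exposed because the appropriate diffusion time depends on how much local
noise should be suppressed. Imputation is `Pᵗ X` with t = 3 by default —
larger t shares information over wider neighbourhoods. Condition-aware
imputation rebuilds the operator within each condition on the shared latent
space so no expression information crosses experimental groups.

## Niche framework

A niche is the set of cells within r = 60 μm (boundary inclusive) of an
anchor cell, computed per sample; 60 μm is the scale of a glandular lesion,
so the niche is the natural unit for "the community around this cell".
Every cell anchors a niche; analyses frequently restrict anchors to
epithelial cells.

*Composition.* Counts per category always; fractions at compartment level
over non-`mixed` member cells, and at state level within the state's own
compartment, masked when the niche holds fewer than 10 cells of that
compartment (too few cells make fractions meaningless).

*Ordering.* The niche analog of the gastric→progenitor DC is the mean DC
over the niche's gastric-like/progenitor-like members, defined only for
niches with ≥ 10 such cells (the quote defining the rule names those two
classes, so other epithelial states do not count; a flag exposes the
alternative). Binned into 100 uniform bins over the observed range,
half-open with the last bin closed.

*Expression tensor.* For each (compartment, niche): member counts summed,
divided by the niche-compartment total (the size factor), scaled by the
median size factor over occupied niches, log1p, then z-scored per gene over
occupied niches. Niches without cells of a compartment are masked, never
zero-filled; zero-variance genes get z = 0 rather than NaN/inf.

*Gene trends.* Mean z per (compartment, bin, gene); bins holding fewer than
10 binned niches are masked — sparsely populated bins sit between
well-sampled stretches of the continuum (e.g. at lesion boundaries) and
carry mostly sampling noise. Genes are ordered by a landmark: argmax,
argmin, or the sign-change bin. The sign change is located as the best
two-piece sign changepoint (the bin minimizing the number of bins whose
sign disagrees with a single-step trend), which is robust to isolated
flips where the mean z hovers near zero; a first-flip rule is not.

*Canonical niche sets.* Progenitor niches are those in bins where the
median progenitor-like fraction exceeds the median gastric-like fraction;
the gastric set mirrors the progenitor set's bin count from the low end of
the axis. The realized percentages are always recomputed from the data —
they are a property of the tissue, not a constant of the method.

*Enrichment scores.* `ln(niche fraction of a state / dataset fraction)`,
with the fraction taken relative to the state's compartment within the
niche. Zero niche fractions are floored at half the minimum observed
nonzero fraction so the log is defined; the floor is exposed. The
progenitor-association gate is score > 2 together with gastric score < 0,
both strict.

*Neighbourhood annotation.* Imported (or internally sampled) transcriptomic
neighbourhoods are labelled by their dominant state. Pure neighbourhoods
have infinite dominance and are never excluded; among mixed ones, the
bottom 5% by dominance ratio (most-frequent over second-most-frequent
state) are flagged. The spatial score applies the enrichment-score logic to
the union of the members' niche cells. The built-in condition test is a
two-sided Fisher exact test per neighbourhood (inside vs outside ×
condition) with Benjamini–Hochberg correction and Haldane-corrected
log-fold-changes; it stands in for count-model differential-abundance
tools when only a binary membership and condition labels are available.

*Conditional density.* Paired per-niche state frequencies are
log10-transformed with each vector's minimum nonzero value as pseudocount,
histogrammed in 2D, and column-normalized, so the conditional distribution
of one state's frequency given another's is displayed independently of the
marginal.

*In silico dissection.* The parenchyma is epithelial cells plus everything
within 200 μm of one; lymph nodes are connected components (> 250 cells,
strictly) of the ≤ 30 μm graph over lymph-node immune states and are
removed.

## Morphometry

All features derive from cell centroids. Lesions: connected components of
the ≤ 20 μm epithelial contact graph (a cell diameter), ids assigned by
component (min x, min y) for determinism. Rasterization: 5 μm/px grid over
the centroid extent, per-pixel centroid counts smoothed with an isotropic
Gaussian (σ = 3 px = 15 μm). The foreground cutoff is expressed per unit
area — 0.01 cells/μm², i.e. 0.25 smoothed counts per 5-μm pixel. Two
reasons: it makes the foreground invariant under raster resolution, and it
places the tissue boundary at the half-plateau crossing of the smoothed
edge profile, which a symmetric kernel localizes at the true edge (an
absolute per-pixel cutoff far below the plateau instead pushes the
boundary tens of μm into any empty region, swallowing small lumens).

Lumens combine two constructions. Closed lumens: the epithelial bitmap is
dilated with a 10-px disk (one iteration), holes unreachable from the
border are filled, the mask is eroded with the same disk (returning
boundaries to scale), and background pixels inside it are lumen. Open
lumens: background pixels within 20 μm of an epithelial pixel seed the
lumen, which grows in ≤ 20 μm steps to a fixed point (capped at 100
iterations; the cap is never reached on realistic fields). Per-anchor
lumen area counts lumen pixel centers within 60 μm. DC summaries use 11
equal-width bins with median/IQR per bin.

## Copy-number inference

Expression is library-size normalized (no log) identically for query and
reference. The reference profile is the per-gene mean over reference
cells; genes with mean < 0.1, genes in configured excluded groups
(co-regulated clusters that mimic focal amplifications, e.g. digestive
enzyme families), and mitochondrial/ribosomal genes are dropped. Per cell:
`r_g = clip(log2((x_g + 0.1)/(μ_g + 0.1)), −3, 3)`, then a rolling mean
over 100 consecutive genes per chromosome keeping only fully interior
windows (end trimming avoids edge bias; windows are labelled by their
center gene, left-of-center for even windows). Profiles are recentered by
the per-cell median, then summarized per chromosome
(recenter-then-summarize), binarized at > 0.16 (gain) / < −0.16 (loss),
and cells are classified *quiet* when the event count is strictly below 9.
The iterative reference: after a first pass, cells whose mean on a
configured recurrent chromosome stays ≤ 0.17 become the reference for a
second pass, falling back to the initial reference (with a warning) when
fewer than 20 qualify.

## Communication modules

Within one compartment, the niche-expression z-matrix restricted to
communication genes gives a Pearson correlation graph (edge iff r > 0.2,
strict; pairs sharing < 10 occupied niches get no edge; constant genes are
isolated with a warning). Jaccard refinement computes, on the original
graph's neighbour sets with endpoints excluded, the similarity of each
connected pair (remove if < 0.05) and each neighbour-sharing non-edge (add
if > 0.95); both rules read the pre-refinement graph and apply
simultaneously, so the outcome is order-independent. Module detection is a
deterministic overlapping community detector: maximal cliques (size ≥ 3,
largest first) seed modules, each seed greedily absorbs neighbours
connected to ≥ 60% of the module while conductance stays below 0.5,
modules below the minimum size (4) are discarded and near-duplicates
(Jaccard ≥ 0.6) deduplicated. The detector satisfies the contract
downstream code relies on — overlap allowed, internal density enforced,
deterministic — and is pluggable if a different community algorithm is
preferred. Modules are flagged progenitor-associated when the mean z of
their genes over canonical progenitor niches exceeds 0.2 (strict). Cognate
channels pair a ligand in a flagged module of one compartment with a
receptor (every complex subunit) in a flagged module of another, ranked by
the Spearman correlation of their bin-averaged trends, then by module
scores. A small curated mouse ligand–receptor table ships for tests; full
databases are supplied as TSV.

## Synthetic tissue generator

The generator emulates the statistical structure the analysis assumes, at
desk scale, with full ground truth:

- **Geometry.** Glandular lesions are annuli (uniform cell placement
  between a lumen radius and a 100 μm lesion radius) at non-overlapping
  centers in a rectangular field; stroma is uniform outside lesion disks;
  lymph nodes are dense disks of lymphoid cells. Densities default to the
  high cellularity of injured premalignant pancreas (~12,000 stromal
  cells/mm², lesions ~0.02 cells/μm², > 100 cells per 60-μm niche).
- **Latent gradient.** Each lesion carries a latent gastric(0) →
  progenitor(1) value (evenly spread by center x by default, or supplied);
  cells jitter around it (σ = 0.06). Epithelial states discretize at 0.5.
- **Niche coupling.** Stromal/myeloid state probabilities follow a
  logistic function (steepness 6) of the local mean epithelial latent
  within 60 μm, so `Tnc-myCAF` fibroblasts and `Itgax-mac` myeloid cells
  concentrate near progenitor-like epithelium — the coupling the niche
  stage must recover. Effect sizes are not published quantities; the
  defaults are chosen once for a clearly detectable but not trivial shift
  and exposed in the config.
- **Counts.** Negative-binomial (Gamma–Poisson) with shared size r = 10 —
  the mild overdispersion of UMI/in-situ counts. Strongly overdispersed
  counts (r ≈ 2) would make the per-gene log2-ratio SD ≈ 1/(√r·ln2)
  regardless of depth, leaving chromosome-scale inference no signal at the
  published ±0.16 thresholds — such data lacks the structure the method
  assumes. Gene responses along the latent axis come from a small curve
  library (flat, linear up/down, early/late sigmoids at 0.3/0.7); genes
  outside their home compartment express at 5% of baseline; per-cell
  module factors (log-normal, σ = 0.6) give planted communication modules
  their correlation structure. The default panel's gastric baselines are
  balanced so total epithelial output is roughly constant along the
  gradient — real tissue does not grossly change total mRNA across this
  state switch, and an unbalanced panel would let relative-abundance
  normalization shift apparent onsets of unrelated genes.
- **CNV cohorts.** Genome-ordered panels (default 4 chromosomes × 600
  genes — the realistic density of retained genes per chromosome;
  log-normal baselines, lognormal(1.0, 0.8)) with per-cell chromosome
  events multiplying expected counts by 1.5 (gain) / 0.5 (loss).
- **Determinism.** One master RNG per generate call plus per-cell
  substreams spawned from the seed, so identical configs are byte-identical
  and counts are stable under panel reordering.

What it does **not** emulate: segmentation errors and transcript
misassignment between adjacent cells, spatial autocorrelation of technical
noise, batch effects, 3D sectioning artefacts, doublets, or realistic
transcriptome-wide gene–gene covariance. Passing recovery tests therefore
demonstrates the correctness and calibration of the machinery on data with
known structure, not robustness to every artefact of real tissue sections.

## Problem sizes and defaults used in the checks

The bundled checks run at desk scale, chosen to make the statistical
properties measurable while keeping the whole suite fast: gradient
recovery on ~2,000 epithelial cells (5 seeds), karyotype recovery on 200
cells + 100 reference cells, niche-coupling recovery on ~7,000-cell
tissues (20 seeds), morphometry on an annulus of 500 epithelial cells in
dense stroma, module recovery on 400-niche z-matrices, calibration on 200
neighbourhoods / 5,000 anchors, and an end-to-end run on a ~5,400-cell
tissue.

## Known limitations

- The lumen foreground threshold interacts with tissue density; very
  sparse tissue (≪ 0.01 cells/μm²) is classified background wholesale, and
  open-lumen propagation can then creep along background gaps near
  epithelium. Densely cellular tissue (the regime the defaults target) is
  unaffected.
- Niche expression mixes cell states within a compartment; trends reflect
  the average program of the compartment, not single-cell resolution.
- The changepoint sign-landmark assumes a single monotone switch; genes
  with non-monotone trends are better ordered by argmax/argmin.
- The condition test treats neighbourhoods independently (no spatial or
  overlap correction beyond BH); overlapping neighbourhoods share cells
  and their q-values are correlated.
- Diffusion-component recovery degrades when a condition has fewer cells
  than ~2k on a panel this small; the operator parameters (k, bandwidth
  neighbour) are exposed for smaller data.
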