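"""Cell/gene filtering, normalization, censoring, signature scoring.

Shared substrate for the downstream niche, diffusion and communication
stages. Normalization is median-of-size-factors scaling on linear counts by
default, because sparse in-situ panels are dominated by low-expression
regulatory and communication genes for which log transformation mostly
amplifies dropout noise. Genes flagged ``excluded_from_embedding`` (negative
controls, mitochondrial/ribosomal content, transgenes) stay in the matrix
but contribute neither to size factors nor to feature selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "filter_cells",
    "normalize_counts",
    "triangle_threshold",
    "censor_genes",
    "score_signature",
    "normalize_scores",
    "pseudocolor",
    "DegenerateHistogramError",
]


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has no usable shape for triangle thresholding."""


def _totals(X, exclude_mask=None) -> np.ndarray:
    """Per-cell total counts, optionally masking excluded genes."""
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool)
        X = X[:, keep]
    if sparse.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def filter_cells(
    X,
    min_counts: int = 25,
    excluded_genes=None,
) -> tuple[np.ndarray, float]:
    """Keep cells with at least ``min_counts`` total transcripts.

    Negative-control / excluded genes (boolean mask over genes) do not count
    toward the total. Returns (boolean keep-mask, fraction removed).
    """
    if min_counts < 0:
        raise ValueError("min_counts must be >= 0")
    totals = _totals(X, excluded_genes)
    mask = totals >= min_counts
    if not mask.any():
        raise ValueError("no cells pass filter")
    return mask, 1.0 - mask.mean()


def normalize_counts(
    X,
    log_transform: bool = False,
    pseudocount: float = 1.0,
    excluded_genes=None,
):
    """Median-scaled size-factor normalization.

    value = count / size_factor * median(size_factor); size factors are total
    counts excluding flagged genes. With ``log_transform`` the result is
    log(value + pseudocount). Returns (matrix, size_factors). Excluded genes
    are normalized like the rest but never enter the size factors.
    """
    size_factors = _totals(X, excluded_genes)
    if (size_factors <= 0).any():
        raise ValueError(
            "zero size factor encountered; filter cells before normalizing"
        )
    scale = np.median(size_factors) / size_factors
    if sparse.issparse(X):
        out = sparse.diags(scale) @ X.tocsr().astype(float)
        if log_transform:
            out = out.toarray()
            out = np.log(out + pseudocount)
    else:
        out = np.asarray(X, dtype=float) * scale[:, None]
        if log_transform:
            out = np.log(out + pseudocount)
    return out, size_factors


def triangle_threshold(counts, edges) -> float:
    """Zack triangle threshold on a histogram.

    Draws the line from the peak bin to the farthest nonzero tail bin and
    returns the bin edge under the point of maximal perpendicular distance
    between histogram and line. Axes are rescaled to [0, 1] before the
    geometric construction so the result is invariant to units. Ties break
    toward the smaller threshold.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if counts.ndim != 1 or len(edges) != len(counts) + 1:
        raise ValueError("expected 1D counts with len(edges) == len(counts)+1")
    if len(counts) < 3:
        raise ValueError("need at least 3 bins")
    nonzero = np.flatnonzero(counts)
    if len(nonzero) == 0:
        raise ValueError("histogram has no occupied bin")
    if len(nonzero) == 1:
        raise DegenerateHistogramError("degenerate histogram: single occupied bin")

    peak = int(np.argmax(counts))
    # farthest nonzero bin from the peak; tie -> the left tail, which yields
    # the smaller threshold
    lo, hi = nonzero[0], nonzero[-1]
    tail = lo if (peak - lo) >= (hi - peak) else hi
    if tail == peak:
        raise DegenerateHistogramError("degenerate histogram: peak equals tail")

    span = np.arange(min(peak, tail), max(peak, tail) + 1)
    x = (span - span[0]) / (span[-1] - span[0])
    y = counts[span] / counts.max()
    if span[0] == peak:
        (x0, y0), (x1, y1) = (0.0, y[0]), (1.0, y[-1])
    else:
        (x0, y0), (x1, y1) = (1.0, y[-1]), (0.0, y[0])
    # perpendicular distance to the peak->tail chord, counted only where the
    # histogram dips below the chord (the classic construction; keeps the
    # threshold in the valley rather than on a secondary mode)
    yline = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    dist = (yline - y) / np.hypot(1.0, (y1 - y0) / (x1 - x0))
    dist[dist < 0] = 0.0
    if np.allclose(dist, 0.0):
        raise DegenerateHistogramError("degenerate histogram: flat between peak and tail")
    best = span[int(np.argmax(dist))]  # argmax is stable -> smaller index wins
    return float(edges[best])


@dataclass
class CensorResult:
    passed: np.ndarray  # boolean over genes
    threshold: float
    used_fallback: bool


def censor_genes(
    ref_detection: list[pd.DataFrame],
    spatial_detection: pd.DataFrame,
    min_ref: float = 0.01,
    n_bins: int = 25,
) -> CensorResult:
    """Compartment-aware gene censoring.

    A gene is retained iff (a) some subpopulation of at least one dissociated
    reference detects it in >= ``min_ref`` of cells, and (b) its maximal
    subpopulation detection rate in the spatial data reaches the triangle
    threshold computed on the flattened spatial detection-rate histogram.
    Each frame is subpopulations x genes of detection fractions.
    """
    genes = spatial_detection.columns
    for ref in ref_detection:
        if not ref.columns.equals(genes):
            raise ValueError("gene sets of detection matrices do not align")

    ref_ok = np.zeros(len(genes), dtype=bool)
    for ref in ref_detection:
        ref_ok |= (ref.to_numpy() >= min_ref).any(axis=0)

    flat = spatial_detection.to_numpy().ravel()
    hist, edges = np.histogram(flat, bins=n_bins, range=(0.0, 1.0))
    used_fallback = False
    try:
        thr = triangle_threshold(hist, edges)
    except DegenerateHistogramError:
        warnings.warn(
            "triangle threshold undefined on the detection histogram; "
            "falling back to min_ref"
        )
        thr = min_ref
        used_fallback = True

    spatial_ok = spatial_detection.to_numpy().max(axis=0) >= thr
    return CensorResult(passed=ref_ok & spatial_ok, threshold=thr,
                        used_fallback=used_fallback)


def score_signature(
    normalized,
    gene_names,
    gene_set,
    reference_cells=None,
) -> np.ndarray:
    """Average z-scored expression of a gene set per cell.

    z-scores use mean/SD (population n) over ``reference_cells`` (default all
    cells), so an anchored reference cohort can define the scale against
    which other conditions are scored. Zero-variance genes are dropped with a
    warning rather than producing infinities.
    """
    gene_names = list(gene_names)
    idx = [gene_names.index(g) for g in gene_set if g in gene_names]
    missing = [g for g in gene_set if g not in gene_names]
    if not idx:
        raise ValueError(f"no signature genes measured; missing: {missing}")
    X = normalized[:, idx]
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    ref = X if reference_cells is None else X[np.asarray(reference_cells, bool)]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)  # population SD
    keep = sd > 0
    if not keep.all():
        dropped = [gene_names[idx[k]] for k in np.flatnonzero(~keep)]
        warnings.warn(f"dropping zero-variance signature genes: {dropped}")
    if not keep.any():
        raise ValueError("all signature genes have zero variance in the reference")
    z = (X[:, keep] - mu[keep]) / sd[keep]
    return z.mean(axis=1)


def normalize_scores(S, quantile: float = 0.95) -> np.ndarray:
    """Quantile-saturated score normalization to [0, 1] per signature.

    Subtract each column's minimum, divide by its ``quantile`` quantile and
    clip to [0, 1]. The 95th quantile suits dissociated-style score maps,
    the 90th the sparser in-situ scores; both are a parameter away.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must be in (0, 1]")
    S = np.asarray(S, dtype=float)
    S = S - S.min(axis=0)
    q = np.quantile(S, quantile, axis=0)
    q[q == 0] = 1.0
    return np.clip(S / q, 0.0, 1.0)


def pseudocolor(S, W) -> np.ndarray:
    """Multi-signature pseudocoloring: RGB = clip(S @ W, 0, 1).

    ``S`` is cells x signatures of scores already normalized to [0, 1]
    (see :func:`normalize_scores`); ``W`` is signatures x 3 RGB rows.
    Summation then clipping lets co-occurring signatures saturate into
    mixed colors.
    """
    S = np.asarray(S, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (S.shape[1], 3):
        raise ValueError("W must be signatures x 3")
    return np.clip(S @ W, 0.0, 1.0)
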