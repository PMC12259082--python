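"""Transcriptome-based copy-number inference and karyotype classification.

Chromosome-scale gains and losses shift the expression of whole genomic
neighbourhoods coherently. The inference follows the windowed log-ratio
strategy: library-size-normalized expression of each cell is compared with a
diploid reference profile gene by gene, log2 ratios are clipped and averaged
over sliding windows of consecutive genes along each chromosome, and per-cell
profiles are recentered by their median. Cells are then summarized per
chromosome, binarized into gain/loss/neutral events, and classified as
genomically 'quiet' or 'rearranged' by their event count. A second,
within-cohort reference pass can strip a recurrent event from the reference.

Two deliberate departures from naive inferCNV-style smoothing: gene groups
whose co-regulation mimics focal amplification (e.g. digestive-enzyme
clusters) are excluded up front, and only fully interior windows are kept so
chromosome ends do not bias the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "CnvConfig",
    "KaryotypeProfile",
    "library_size_normalize",
    "reference_profile",
    "smoothed_log_ratio",
    "recenter",
    "chromosome_summary",
    "classify_karyotype",
    "infer_karyotype",
    "refine_reference",
]


@dataclass
class CnvConfig:
    min_threshold: float = 0.1  # minimal reference mean expression per gene
    pseudocount: float = 0.1  # in numerator and denominator of the log2 ratio
    clip: tuple[float, float] = (-3.0, 3.0)
    window_size: int = 100  # consecutive genes per sliding window
    gain_cut: float = 0.16
    loss_cut: float = -0.16
    quiet_max_events: int = 9  # exclusive: quiet iff events < 9
    refine_chromosome: str | None = None
    refine_cut: float = 0.17
    min_refined_reference: int = 20
    excluded_gene_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        if not (self.loss_cut < 0 < self.gain_cut):
            raise ValueError("need loss_cut < 0 < gain_cut")
        if not (self.clip[0] <= 0 <= self.clip[1]):
            raise ValueError("clip interval must contain 0")


@dataclass
class KaryotypeProfile:
    smoothed: pd.DataFrame  # cells x window positions (recentered log2 ratios)
    window_chrom: pd.Series  # chromosome of each window position
    chrom_summary: pd.DataFrame  # cells x chromosomes, mean log2 ratio
    events: pd.DataFrame  # cells x chromosomes in {gain, loss, neutral}
    event_count: pd.Series
    classification: pd.Series  # quiet / rearranged


def library_size_normalize(X) -> np.ndarray:
    """Counts / total * median total, no log. Applied identically to query
    and reference so the input contract holds regardless of upstream mode."""
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cell with zero total counts; filter first")
    return X / totals[:, None] * np.median(totals)


def _order_genes(gene_anno: pd.DataFrame) -> pd.Index:
    """Genes ordered by (chromosome, genomic_order); chromosome order is the
    order of first appearance in the annotation."""
    chroms = pd.unique(gene_anno["chromosome"])
    rank = {c: i for i, c in enumerate(chroms)}
    key = gene_anno["chromosome"].map(rank) * (gene_anno["genomic_order"].max() + 1)
    return gene_anno.index[np.argsort(key + gene_anno["genomic_order"], kind="stable")]


def reference_profile(
    ref_norm: np.ndarray,
    gene_anno: pd.DataFrame,
    cfg: CnvConfig,
    mito_ribo_mask=None,
) -> tuple[pd.Series, pd.Index]:
    """Per-gene mean of the (library-size normalized) reference plus the
    retained gene set, ordered along the genome.

    A gene is retained iff its reference mean is >= ``min_threshold`` and it
    belongs to no excluded gene group and is not mitochondrial/ribosomal.
    """
    if ref_norm.shape[0] == 0:
        raise ValueError("empty reference")
    means = pd.Series(ref_norm.mean(axis=0), index=gene_anno.index)
    excluded = set()
    for group in cfg.excluded_gene_groups:
        excluded.update(group)
    keep = (means >= cfg.min_threshold) & ~means.index.isin(excluded)
    if mito_ribo_mask is not None:
        keep &= ~np.asarray(mito_ribo_mask, dtype=bool)
    ordered = [g for g in _order_genes(gene_anno) if keep[g]]
    if not ordered:
        raise ValueError("no analyzable chromosome: all genes filtered")
    retained = pd.Index(ordered)
    counts = gene_anno.loc[retained, "chromosome"].value_counts()
    if (counts < cfg.window_size).all():
        raise ValueError("no analyzable chromosome: every chromosome has fewer "
                         f"retained genes than window_size={cfg.window_size}")
    return means[retained], retained


def smoothed_log_ratio(
    query_norm: np.ndarray,
    gene_index: pd.Index,
    reference_means: pd.Series,
    gene_anno: pd.DataFrame,
    cfg: CnvConfig,
) -> tuple[np.ndarray, pd.Series]:
    """Clipped log2 ratios smoothed along the genome.

    Per gene: r = clip(log2((x + p)/(mu + p)), clip). Per chromosome: rolling
    mean over ``window_size`` consecutive retained genes, keeping only fully
    interior windows (chromosome ends are trimmed). Window positions are
    labelled by their center gene (left-of-center for even windows).
    Chromosomes with fewer retained genes than the window are skipped with a
    warning. Returns (cells x positions array, per-position chromosome).
    """
    cols = gene_index.get_indexer(reference_means.index)
    if (cols < 0).any():
        raise ValueError("reference genes missing from query matrix")
    x = query_norm[:, cols]
    mu = reference_means.to_numpy()
    r = np.log2((x + cfg.pseudocount) / (mu + cfg.pseudocount))
    np.clip(r, cfg.clip[0], cfg.clip[1], out=r)

    chrom = gene_anno.loc[reference_means.index, "chromosome"].to_numpy()
    w = cfg.window_size
    blocks, labels = [], []
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        if len(sel) < w:
            warnings.warn(f"chromosome {c}: {len(sel)} retained genes < window "
                          f"{w}; skipped")
            continue
        sub = r[:, sel]
        csum = np.cumsum(np.pad(sub, ((0, 0), (1, 0))), axis=1)
        roll = (csum[:, w:] - csum[:, :-w]) / w  # fully interior windows
        blocks.append(roll)
        centers = sel[np.arange(len(sel) - w + 1) + (w - 1) // 2]
        labels.extend(
            (c, reference_means.index[i]) for i in centers
        )
    if not blocks:
        raise ValueError("no chromosome long enough for the smoothing window")
    smoothed = np.concatenate(blocks, axis=1)
    window_chrom = pd.Series([c for c, _ in labels],
                             index=[g for _, g in labels], name="chromosome")
    return smoothed, window_chrom


def recenter(smoothed: np.ndarray) -> np.ndarray:
    """Subtract each cell's median window value (per-cell median becomes 0)."""
    return smoothed - np.median(smoothed, axis=1, keepdims=True)


def chromosome_summary(smoothed: np.ndarray, window_chrom: pd.Series) -> pd.DataFrame:
    """Mean recentered log2 ratio per (cell, chromosome)."""
    out = {}
    for c in pd.unique(window_chrom.to_numpy()):
        out[c] = smoothed[:, (window_chrom == c).to_numpy()].mean(axis=1)
    return pd.DataFrame(out)


def classify_karyotype(chrom_summary: pd.DataFrame, cfg: CnvConfig):
    """Binarize chromosome summaries into events and call quiet/rearranged.

    gain if mean > gain_cut, loss if mean < loss_cut, else neutral; a cell is
    'quiet' iff its event count is strictly below ``quiet_max_events``.
    """
    vals = chrom_summary.to_numpy()
    if not np.isfinite(vals).all():
        raise ValueError("non-finite chromosome summary")
    events = np.where(vals > cfg.gain_cut, "gain",
                      np.where(vals < cfg.loss_cut, "loss", "neutral"))
    events = pd.DataFrame(events, index=chrom_summary.index,
                          columns=chrom_summary.columns)
    event_count = (events != "neutral").sum(axis=1)
    classification = pd.Series(
        np.where(event_count < cfg.quiet_max_events, "quiet", "rearranged"),
        index=chrom_summary.index,
    )
    return events, event_count, classification


def infer_karyotype(
    counts,
    gene_anno: pd.DataFrame,
    reference_mask,
    cfg: CnvConfig,
    cell_index=None,
    mito_ribo_mask=None,
) -> KaryotypeProfile:
    """One full inference pass: normalize, profile the reference, smooth,
    recenter, summarize, classify."""
    norm = library_size_normalize(counts)
    ref_mask = np.asarray(reference_mask, dtype=bool)
    means, retained = reference_profile(norm[ref_mask], gene_anno, cfg,
                                        mito_ribo_mask=mito_ribo_mask)
    smoothed, window_chrom = smoothed_log_ratio(
        norm, gene_anno.index, means, gene_anno, cfg
    )
    smoothed = recenter(smoothed)
    summary = chromosome_summary(smoothed, window_chrom)
    if cell_index is None:
        cell_index = pd.RangeIndex(norm.shape[0])
    summary.index = cell_index
    events, n_events, classification = classify_karyotype(summary, cfg)
    return KaryotypeProfile(
        smoothed=pd.DataFrame(smoothed, index=cell_index,
                              columns=window_chrom.index),
        window_chrom=window_chrom,
        chrom_summary=summary,
        events=events,
        event_count=n_events,
        classification=classification,
    )


def refine_reference(
    counts,
    gene_anno: pd.DataFrame,
    initial_reference_mask,
    cfg: CnvConfig,
    cell_index=None,
) -> tuple[KaryotypeProfile, KaryotypeProfile, np.ndarray]:
    """Two-pass inference with a within-cohort diploid reference.

    The first pass uses the initial reference; cells whose mean log2 ratio on
    ``cfg.refine_chromosome`` stays <= ``cfg.refine_cut`` become the refined
    reference for a second pass. If too few cells qualify the initial
    reference is kept with a warning. Returns (first pass, second pass,
    refined mask).
    """
    if cfg.refine_chromosome is None:
        raise ValueError("cfg.refine_chromosome must be set")
    first = infer_karyotype(counts, gene_anno, initial_reference_mask, cfg,
                            cell_index=cell_index)
    if cfg.refine_chromosome not in first.chrom_summary.columns:
        raise ValueError(f"refine chromosome {cfg.refine_chromosome} not analyzable")
    below = (first.chrom_summary[cfg.refine_chromosome] <= cfg.refine_cut).to_numpy()
    if below.sum() < cfg.min_refined_reference:
        warnings.warn("refined reference too small; keeping initial reference")
        refined_mask = np.asarray(initial_reference_mask, dtype=bool)
    else:
        refined_mask = below
    second = infer_karyotype(counts, gene_anno, refined_mask, cfg,
                             cell_index=cell_index)
    return first, second, refined_mask
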