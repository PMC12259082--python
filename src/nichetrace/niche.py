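"""Radius-based multicellular niches and everything computed on them.

A niche is the set of cells within a fixed radius (default 60 um, the scale
of a glandular lesion) of an anchor cell; every cell anchors a niche and
niches never span samples. On this index the module computes composition
vectors, an ordering of niches along the average epithelial
gastric->progenitor diffusion component, compartment-specific niche
expression (the c x n x m tensor), gene trends along the niche continuum,
canonical gastric/progenitor niche sets, enrichment scores, annotated
differential-abundance neighborhoods with a permutation-calibrated exact
test, conditional cell-state densities, rank-sum group scoring, and in
silico dissection of the parenchyma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.sparse.csgraph import connected_components
from scipy.stats import fisher_exact, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NicheIndex",
    "NicheBinning",
    "NicheExpressionTensor",
    "NeighborhoodSet",
    "build_niche_index",
    "niche_composition",
    "order_niches",
    "niche_expression",
    "gene_trends",
    "canonical_niche_sets",
    "enrichment_score",
    "select_enriched_anchors",
    "sample_neighborhoods",
    "annotate_neighborhoods",
    "neighborhood_condition_test",
    "conditional_density",
    "group_score_test",
    "dissect_parenchyma",
]


@dataclass
class NicheIndex:
    """Sparse anchor -> member incidence of the radius graph."""

    radius: float
    anchors: np.ndarray  # positional indices of anchor cells
    membership: sparse.csr_matrix  # anchors x cells, boolean
    cell_ids: pd.Index

    @property
    def member_counts(self) -> np.ndarray:
        return np.asarray(self.membership.sum(axis=1)).ravel()

    def members(self, a: int) -> np.ndarray:
        """Member cell positions for anchor row a."""
        return self.membership.indices[
            self.membership.indptr[a] : self.membership.indptr[a + 1]
        ]


@dataclass
class NicheBinning:
    niche_dc: np.ndarray  # per anchor; NaN where too few qualifying cells
    bin_id: np.ndarray  # per anchor; -1 where unbinned
    bin_edges: np.ndarray
    n_bins: int


@dataclass
class NicheExpressionTensor:
    """Per-compartment niche expression, z-scored across unmasked niches."""

    z: dict[str, np.ndarray]  # compartment -> niches x genes
    normalized: dict[str, np.ndarray]  # pre-z (post log if requested)
    mask: dict[str, np.ndarray]  # compartment -> boolean (niche has cells)
    genes: pd.Index
    compartments: list[str]


@dataclass
class NeighborhoodSet:
    members: dict[int, np.ndarray]  # id -> member cell positions
    dominant_state: dict[int, str] = field(default_factory=dict)
    dominance_ratio: dict[int, float] = field(default_factory=dict)
    excluded: dict[int, bool] = field(default_factory=dict)
    spatial_score: dict[int, float] = field(default_factory=dict)
    condition_counts: pd.DataFrame | None = None


def build_niche_index(
    cells: pd.DataFrame,
    radius: float = 60.0,
    anchor_filter=None,
) -> NicheIndex:
    """All cells within ``radius`` um of each anchor, computed per sample.

    The boundary is inclusive (distance <= radius). ``anchor_filter`` is an
    optional boolean mask over cells restricting which cells anchor a niche;
    membership always draws on all cells of the anchor's sample.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = len(cells)
    anchor_mask = (
        np.ones(n, dtype=bool)
        if anchor_filter is None
        else np.asarray(anchor_filter, dtype=bool)
    )
    rows, cols = [], []
    positions = np.arange(n)
    for _, grp in cells.groupby("sample", sort=False):
        idx = positions[cells.index.get_indexer(grp.index)]
        xy = grp[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(xy)
        local_anchors = np.flatnonzero(anchor_mask[idx])
        for la in local_anchors:
            nb = tree.query_ball_point(xy[la], radius)
            rows.extend([idx[la]] * len(nb))
            cols.extend(idx[j] for j in nb)
    anchors = np.flatnonzero(anchor_mask)
    row_of = np.full(n, -1)
    row_of[anchors] = np.arange(len(anchors))
    membership = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (row_of[rows], cols)),
        shape=(len(anchors), n),
    )
    return NicheIndex(radius=radius, anchors=anchors, membership=membership,
                      cell_ids=cells.index)


def _one_hot(labels: np.ndarray, categories: list) -> sparse.csr_matrix:
    cat_of = {c: i for i, c in enumerate(categories)}
    col = np.array([cat_of[v] for v in labels])
    return sparse.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), col)),
        shape=(len(labels), len(categories)),
    )


def niche_composition(
    index: NicheIndex,
    cells: pd.DataFrame,
    level: str = "compartment",
    min_compartment_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and fractions of categories per niche.

    level='compartment': fractions over all non-mixed member cells.
    level='state': fractions within the state's own compartment, masked
    (NaN) where the niche carries fewer than ``min_compartment_cells`` cells
    of that compartment. Cells labelled 'mixed' never enter fractions.
    Returns (counts, fractions) indexed by anchor cell id.
    """
    if level not in ("compartment", "state"):
        raise ValueError("level must be 'compartment' or 'state'")
    labels = cells[level].to_numpy()
    comp = cells["compartment"].to_numpy()
    known = set(pd.unique(labels))
    cats = sorted(known)
    G = index.membership.astype(float)
    counts = pd.DataFrame(
        (G @ _one_hot(labels, cats)).toarray(),
        index=index.cell_ids[index.anchors], columns=cats,
    )
    unmixed = comp != "mixed"
    if level == "compartment":
        denom = np.asarray(G[:, unmixed].sum(axis=1)).ravel()
        num = (G[:, unmixed] @ _one_hot(labels[unmixed],
                                        cats)).toarray()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = num / denom[:, None]
    else:
        comp_cats = sorted(set(pd.unique(comp)))
        comp_counts = (G @ _one_hot(comp, comp_cats)).toarray()
        state_comp = (
            cells.loc[unmixed].groupby("state", observed=True)["compartment"]
            .agg(lambda s: s.mode().iat[0])
        )
        frac = np.full_like(counts.to_numpy(), np.nan, dtype=float)
        for j, state in enumerate(cats):
            if state not in state_comp.index:
                continue  # states occurring only in mixed cells
            c = state_comp[state]
            denom = comp_counts[:, comp_cats.index(c)]
            ok = denom >= min_compartment_cells
            frac[ok, j] = counts.to_numpy()[ok, j] / denom[ok]
    fractions = pd.DataFrame(frac, index=counts.index, columns=cats)
    return counts, fractions


def order_niches(
    index: NicheIndex,
    dc: pd.Series,
    qualifying_states=("gastric-like", "progenitor-like"),
    states: pd.Series | None = None,
    min_epithelial: int = 10,
    n_bins: int = 100,
) -> NicheBinning:
    """Order niches by average epithelial DC and bin the ordering.

    ``dc`` holds per-cell DC values (indexed by cell id) for at least all
    cells of the qualifying states; ``states`` is the per-cell state label.
    A niche gets a DC only when it holds >= ``min_epithelial`` qualifying
    cells. Bins are uniform over the observed niche-DC range, half-open with
    the last bin closed.
    """
    if states is None:
        raise ValueError("states series required")
    qual = states.isin(qualifying_states).to_numpy()
    vals = np.where(qual, dc.reindex(states.index).to_numpy(), 0.0)
    vals = np.where(np.isfinite(vals), vals, 0.0)
    G = index.membership
    n_qual = np.asarray(G[:, qual].sum(axis=1)).ravel()
    sums = G @ (vals * qual)
    niche_dc = np.full(G.shape[0], np.nan)
    ok = n_qual >= min_epithelial
    niche_dc[ok] = sums[ok] / n_qual[ok]
    if not ok.any():
        raise ValueError("no niche holds enough qualifying epithelial cells")

    lo, hi = np.nanmin(niche_dc), np.nanmax(niche_dc)
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_id = np.full(G.shape[0], -1)
    b = np.searchsorted(edges, niche_dc[ok], side="right") - 1
    b[b == n_bins] = n_bins - 1  # close the last bin
    bin_id[ok] = b
    return NicheBinning(niche_dc=niche_dc, bin_id=bin_id, bin_edges=edges,
                        n_bins=n_bins)


def niche_expression(
    index: NicheIndex,
    counts,
    compartments: pd.Series,
    genes: pd.Index,
    log1p: bool = True,
    which_compartments=None,
) -> NicheExpressionTensor:
    """Compartment-specific niche expression tensor.

    Per (compartment, niche): sum member counts of that compartment, divide
    by the niche-compartment size factor (total counts), scale by the median
    size factor over unmasked niches, optionally log1p, then z-score per
    gene over unmasked niches. Niches without cells of a compartment are
    masked, not zero.
    """
    X = counts.tocsr() if sparse.issparse(counts) else sparse.csr_matrix(counts)
    comp = compartments.to_numpy()
    cats = (sorted(set(pd.unique(comp))) if which_compartments is None
            else list(which_compartments))
    G = index.membership.astype(float)
    z_out, norm_out, mask_out = {}, {}, {}
    for c in cats:
        sel = comp == c
        S = (G[:, sel] @ X[sel]).toarray()  # niches x genes summed counts
        size = S.sum(axis=1)
        mask = size > 0
        norm = np.full_like(S, np.nan)
        if mask.any():
            med = np.median(size[mask])
            norm[mask] = S[mask] / size[mask, None] * med
            if log1p:
                norm[mask] = np.log1p(norm[mask])
        z = np.full_like(S, np.nan)
        if mask.any():
            mu = norm[mask].mean(axis=0)
            sd = norm[mask].std(axis=0)
            sd_safe = np.where(sd > 0, sd, 1.0)
            z[mask] = (norm[mask] - mu) / sd_safe
            z[np.ix_(mask, sd == 0)] = 0.0
        z_out[c], norm_out[c], mask_out[c] = z, norm, mask
    return NicheExpressionTensor(z=z_out, normalized=norm_out, mask=mask_out,
                                 genes=genes, compartments=cats)


def gene_trends(
    tensor: NicheExpressionTensor,
    binning: NicheBinning,
    landmark: str = "argmax",
    min_niches_per_bin: int = 10,
) -> tuple[dict[str, np.ndarray], dict[str, pd.Index]]:
    """Mean z per (compartment, bin, gene) plus a per-gene trend ordering.

    landmark in {'argmax', 'argmin', 'sign_change'}: the bin where a gene
    peaks, bottoms out, or where its mean z switches sign (best two-piece
    changepoint). Gene order sorts by landmark bin with ties broken by gene
    name. Bins holding fewer than ``min_niches_per_bin`` niches are masked:
    sparsely populated bins sit between the well-sampled stretches of the
    niche continuum and carry mostly sampling noise.
    """
    if landmark not in ("argmax", "argmin", "sign_change"):
        raise ValueError("unknown landmark")
    trends, orders = {}, {}
    for c in tensor.compartments:
        z, mask = tensor.z[c], tensor.mask[c]
        out = np.full((binning.n_bins, z.shape[1]), np.nan)
        for b in range(binning.n_bins):
            sel = (binning.bin_id == b) & mask
            if sel.sum() >= max(min_niches_per_bin, 1):
                out[b] = z[sel].mean(axis=0)
        trends[c] = out
        occupied = np.flatnonzero(~np.isnan(out).all(axis=1))
        lm = np.full(z.shape[1], np.inf)
        if len(occupied):
            sub = out[occupied]
            if landmark == "argmax":
                lm = occupied[np.nanargmax(sub, axis=0)]
            elif landmark == "argmin":
                lm = occupied[np.nanargmin(sub, axis=0)]
            else:
                # sign-change landmark: the best two-piece sign changepoint,
                # i.e. the bin minimizing the number of bins whose sign
                # disagrees with a step that starts at the trend's initial
                # sign and ends at its final sign. Robust to isolated noisy
                # flips on either side; ties break to the earlier bin. Genes
                # that never switch sign sort last.
                sign = np.sign(np.nan_to_num(sub))
                lm = np.full(z.shape[1], occupied[-1], dtype=float)
                for g in range(sub.shape[1]):
                    s = sign[:, g]
                    pos_before = np.r_[0, np.cumsum(s > 0)]
                    neg_before = np.r_[0, np.cumsum(s < 0)]
                    n_pos, n_neg = pos_before[-1], neg_before[-1]
                    if n_pos == 0 or n_neg == 0:
                        continue  # never switches sign; sorts last
                    b = np.arange(len(s) + 1)
                    cost_up = pos_before[b] + (n_neg - neg_before[b])
                    cost_down = neg_before[b] + (n_pos - pos_before[b])
                    if cost_up.min() <= cost_down.min():
                        best = int(np.argmin(cost_up))
                    else:
                        best = int(np.argmin(cost_down))
                    lm[g] = occupied[min(best, len(s) - 1)]
        key = pd.DataFrame({"lm": lm, "gene": tensor.genes})
        orders[c] = pd.Index(
            key.sort_values(["lm", "gene"], kind="stable")["gene"]
        )
    return trends, orders


def canonical_niche_sets(
    state_fractions: pd.DataFrame,
    binning: NicheBinning,
    progenitor_state: str = "progenitor-like",
    gastric_state: str = "gastric-like",
) -> dict:
    """Canonical progenitor and gastric niche sets.

    Progenitor bins are those where the median progenitor fraction (among
    epithelial members) exceeds the median gastric fraction; the progenitor
    set is the union of their niches. The gastric set mirrors the count of
    progenitor bins from the low end of the axis. The realized fraction of
    niches is reported rather than assumed.
    """
    binned = binning.bin_id >= 0
    prog = state_fractions[progenitor_state].to_numpy()
    gast = state_fractions[gastric_state].to_numpy()
    prog_bins = []
    for b in range(binning.n_bins):
        sel = binned & (binning.bin_id == b)
        if not sel.any():
            continue
        if np.nanmedian(prog[sel]) > np.nanmedian(gast[sel]):
            prog_bins.append(b)
    if not prog_bins:
        warnings.warn("no bin satisfies the progenitor rule; empty set")
    occupied = sorted({b for b in binning.bin_id[binned]})
    gast_bins = occupied[: len(prog_bins)]
    prog_mask = binned & np.isin(binning.bin_id, prog_bins)
    gast_mask = binned & np.isin(binning.bin_id, gast_bins)
    total = binned.sum()
    return {
        "progenitor_niches": np.flatnonzero(prog_mask),
        "gastric_niches": np.flatnonzero(gast_mask),
        "progenitor_bins": prog_bins,
        "gastric_bins": gast_bins,
        "progenitor_pct": 100.0 * prog_mask.sum() / total,
        "gastric_pct": 100.0 * gast_mask.sum() / total,
    }


def enrichment_score(
    index: NicheIndex,
    cells: pd.DataFrame,
    target_state: str,
    reference_compartment: str = "epithelial",
) -> np.ndarray:
    """ln(niche fraction of target state / dataset fraction), per anchor.

    Fractions are taken relative to the reference compartment's cells in the
    niche; anchors without reference cells are NaN. Zero niche fractions are
    floored at half the minimum observed nonzero fraction so the log is
    defined.
    """
    states = cells["state"].to_numpy()
    comp = cells["compartment"].to_numpy()
    in_ref = comp == reference_compartment
    is_target = (states == target_state) & in_ref
    if not is_target.any():
        raise ValueError(f"state {target_state!r} absent from dataset")
    dataset_frac = is_target.sum() / in_ref.sum()
    G = index.membership
    n_ref = np.asarray(G[:, in_ref].sum(axis=1)).ravel()
    n_tgt = np.asarray(G[:, is_target].sum(axis=1)).ravel()
    score = np.full(G.shape[0], np.nan)
    ok = n_ref > 0
    frac = n_tgt[ok] / n_ref[ok]
    nz = frac[frac > 0]
    floor = nz.min() / 2.0 if len(nz) else 0.5 / n_ref[ok].max()
    frac = np.where(frac > 0, frac, floor)
    score[ok] = np.log(frac / dataset_frac)
    return score


def select_enriched_anchors(
    progenitor_score: np.ndarray,
    gastric_score: np.ndarray,
    progenitor_cut: float = 2.0,
    gastric_cut: float = 0.0,
) -> np.ndarray:
    """Anchors specifically enriched for the progenitor state: progenitor
    score strictly > 2 and gastric score < 0 (boundaries excluded)."""
    return (progenitor_score > progenitor_cut) & (gastric_score < gastric_cut)


def sample_neighborhoods(
    latent: np.ndarray,
    prop: float = 0.05,
    k: int = 30,
    seed: int = 0,
) -> NeighborhoodSet:
    """Built-in transcriptomic neighborhood sampler.

    Random index cells (proportion ``prop``) with their k nearest neighbours
    in latent space; a lightweight stand-in for externally computed
    differential-abundance neighbourhoods, which can be imported instead.
    """
    from sklearn.neighbors import NearestNeighbors

    latent = np.asarray(latent, dtype=float)
    rng = np.random.default_rng(seed)
    n = latent.shape[0]
    n_index = max(1, int(round(prop * n)))
    idx = rng.choice(n, size=n_index, replace=False)
    nn = NearestNeighbors(n_neighbors=min(k, n)).fit(latent)
    _, ind = nn.kneighbors(latent[idx])
    return NeighborhoodSet(members={i: row for i, row in enumerate(ind)})


def annotate_neighborhoods(
    nbhd: NeighborhoodSet,
    cells: pd.DataFrame,
    index: NicheIndex,
    target_state: str = "progenitor-like",
    purity_exclusion_quantile: float = 0.05,
) -> NeighborhoodSet:
    """Label neighbourhoods by dominant state and score spatial enrichment.

    Pure neighbourhoods (one state) get infinite dominance and are never
    excluded; among mixed ones, the lowest ``purity_exclusion_quantile`` by
    dominance ratio (most-frequent over second-most-frequent state) are
    flagged excluded but kept. The spatial score is
    ln(frequency of the target state among the union of members' niche cells
    / dataset frequency).
    """
    states = cells["state"].to_numpy()
    dataset_frac = (states == target_state).mean()
    row_of = np.full(len(cells), -1)
    row_of[index.anchors] = np.arange(len(index.anchors))

    ratios = {}
    for nid, members in nbhd.members.items():
        if len(members) == 0:
            raise ValueError(f"empty neighborhood {nid}")
        vc = pd.Series(states[members]).value_counts()
        nbhd.dominant_state[nid] = vc.index[0]
        if len(vc) == 1:
            nbhd.dominance_ratio[nid] = np.inf
        else:
            nbhd.dominance_ratio[nid] = float(vc.iloc[0] / vc.iloc[1])
            ratios[nid] = nbhd.dominance_ratio[nid]
        # spatial score over union of members' niche cells
        anchor_rows = row_of[members]
        anchor_rows = anchor_rows[anchor_rows >= 0]
        if len(anchor_rows):
            union = np.unique(index.membership[anchor_rows].indices)
            frac = (states[union] == target_state).mean()
            if frac == 0:
                frac = 0.5 / len(union)
            nbhd.spatial_score[nid] = float(np.log(frac / dataset_frac))
        else:
            nbhd.spatial_score[nid] = np.nan
    if ratios:
        cut = np.quantile(list(ratios.values()), purity_exclusion_quantile)
    for nid in nbhd.members:
        nbhd.excluded[nid] = bool(
            nid in ratios and ratios[nid] <= cut and len(ratios) > 1
        )
    return nbhd


def neighborhood_condition_test(
    nbhd: NeighborhoodSet,
    conditions: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Exact 2x2 test of condition balance per neighbourhood.

    For each neighbourhood, a two-sided Fisher exact test on (inside vs
    outside) x (condition A vs rest), Benjamini-Hochberg corrected across
    neighbourhoods; the log-fold-change of condition proportions uses a
    Haldane 0.5 correction. Requires >= 2 conditions.
    """
    cond = np.asarray(conditions)
    levels = pd.unique(cond)
    if len(levels) < 2:
        raise ValueError("need at least 2 conditions")
    a_label = levels[0]
    is_a = cond == a_label
    n = len(cond)
    rows = []
    for nid, members in nbhd.members.items():
        inside = np.zeros(n, dtype=bool)
        inside[members] = True
        a_in = int((is_a & inside).sum())
        b_in = int((~is_a & inside).sum())
        a_out = int((is_a & ~inside).sum())
        b_out = int((~is_a & ~inside).sum())
        _, p = fisher_exact([[a_in, b_in], [a_out, b_out]], alternative="two-sided")
        p_in = (a_in + 0.5) / (a_in + b_in + 1.0)
        p_out = (a_out + 0.5) / (a_out + b_out + 1.0)
        lfc = float(np.log2(p_in / (1 - p_in)) - np.log2(p_out / (1 - p_out)))
        rows.append((nid, a_in, b_in, lfc, p))
    out = pd.DataFrame(rows, columns=["neighborhood", "n_a", "n_b", "lfc", "p"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.set_index("neighborhood")


def conditional_density(
    x_fractions,
    y_fractions,
    n_bins_x: int = 20,
    n_bins_y: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-normalized joint density of log-transformed paired fractions.

    Each axis is log10(fraction + its minimum nonzero value); the 2D
    histogram is normalized so every occupied x-column sums to 1 (empty
    columns are NaN). Returns (density, x_edges, y_edges).
    """
    x = np.asarray(x_fractions, dtype=float)
    y = np.asarray(y_fractions, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    for v in (x, y):
        if not (v > 0).any():
            raise ValueError("all-zero fraction vector; pseudocount undefined")
    x = np.log10(x + x[x > 0].min())
    y = np.log10(y + y[y > 0].min())
    H, xe, ye = np.histogram2d(x, y, bins=(n_bins_x, n_bins_y))
    colsum = H.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = H / colsum[:, None]
    D[colsum == 0] = np.nan
    return D, xe, ye


def group_score_test(
    tensor: NicheExpressionTensor,
    gene_set,
    niche_sets: dict,
    replicate_labels: pd.Series | np.ndarray,
    group_a: str = "progenitor_niches",
    group_b: str = "gastric_niches",
) -> pd.DataFrame:
    """Per-replicate mean z over a gene set in two niche groups, with a
    two-sided Wilcoxon rank-sum p-value per compartment.

    Small samples use the exact null distribution (via mannwhitneyu
    method='exact'); replicates without niches in a group are dropped with a
    warning.
    """
    rep = np.asarray(replicate_labels)
    gidx = [i for i, g in enumerate(tensor.genes) if g in set(gene_set)]
    if not gidx:
        raise ValueError("no gene of the set is measured")
    rows = []
    for c in tensor.compartments:
        z, mask = tensor.z[c], tensor.mask[c]
        per_rep = {}
        for gname, group in ((group_a, niche_sets[group_a]),
                             (group_b, niche_sets[group_b])):
            in_group = np.zeros(z.shape[0], dtype=bool)
            in_group[np.asarray(group, dtype=int)] = True
            scores = []
            for r in pd.unique(rep):
                sel = in_group & mask & (rep == r)
                if not sel.any():
                    warnings.warn(f"replicate {r} has no niches in {gname}; dropped")
                    continue
                scores.append(float(np.nanmean(z[np.ix_(sel, gidx)])))
            per_rep[gname] = scores
        a, b = per_rep[group_a], per_rep[group_b]
        if len(a) >= 1 and len(b) >= 1:
            method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
            p = float(mannwhitneyu(a, b, alternative="two-sided",
                                   method=method).pvalue)
        else:
            p = np.nan
        rows.append((c, a, b, p))
    return pd.DataFrame(rows, columns=["compartment", f"scores_{group_a}",
                                       f"scores_{group_b}", "p"]).set_index(
        "compartment"
    )


def dissect_parenchyma(
    cells: pd.DataFrame,
    epithelial_radius: float = 200.0,
    ln_link: float = 30.0,
    ln_min_cells: int = 250,
    ln_states=("B-cell", "CD4-T", "CD8-T"),
) -> tuple[np.ndarray, float]:
    """In silico dissection: keep the epithelial parenchyma, drop lymph nodes.

    Includes epithelial cells plus any cell within ``epithelial_radius`` of
    one, then removes cells belonging to lymph-node components: connected
    components (> ``ln_min_cells`` cells, strictly) of the <= ``ln_link`` um
    graph over lymph-node-state cells. Per sample. Returns (mask, retained
    fraction).
    """
    comp = cells["compartment"].to_numpy()
    states = cells["state"].to_numpy()
    if not (comp == "epithelial").any():
        raise ValueError("no epithelial cells")
    include = np.zeros(len(cells), dtype=bool)
    ln_member = np.zeros(len(cells), dtype=bool)
    positions = np.arange(len(cells))
    for _, grp in cells.groupby("sample", sort=False):
        idx = positions[cells.index.get_indexer(grp.index)]
        xy = grp[["x_um", "y_um"]].to_numpy()
        epi = comp[idx] == "epithelial"
        if epi.any():
            tree = cKDTree(xy[epi])
            d, _ = tree.query(xy, k=1)
            include[idx] = d <= epithelial_radius
        ln = np.isin(states[idx], ln_states)
        if ln.any():
            sub = xy[ln]
            tree = cKDTree(sub)
            pairs = tree.query_pairs(ln_link, output_type="ndarray")
            adj = sparse.csr_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                shape=(len(sub), len(sub)),
            )
            ncomp, labels = connected_components(adj, directed=False)
            sizes = np.bincount(labels)
            big = sizes > ln_min_cells
            ln_member[idx[ln]] = big[labels]
    mask = include & ~ln_member
    return mask, float(mask.mean())
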