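"""Communication-module discovery on niche expression.

Ligand/receptor genes whose niche-level expression co-varies within one
cellular compartment form communication modules. The pipeline: build a
gene-gene graph from Pearson correlations of z-scored niche expression
(edge iff r > rho), refine it with Jaccard similarity of neighbourhoods
(drop spurious edges, add edges within tight communities), detect
potentially overlapping modules with a deterministic clique-seeded
conductance expander, flag modules upregulated in the canonical progenitor
or gastric niche sets, and finally pair flagged modules across compartments
through a cognate ligand-receptor table, ranking channels by how tightly
the partners' trends along the niche continuum are coordinated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "CommGraphConfig",
    "Module",
    "LRTable",
    "load_builtin_lr_table",
    "correlation_graph",
    "jaccard_refine",
    "detect_modules",
    "module_niche_score",
    "cognate_channels",
]


@dataclass
class CommGraphConfig:
    rho: float = 0.2  # Pearson threshold, strict
    jaccard_drop: float = 0.05
    jaccard_add: float = 0.95
    min_module_size: int = 4
    min_shared_niches: int = 10
    conductance_max: float = 0.5
    dedupe_jaccard: float = 0.6

    def __post_init__(self):
        if not (0 < self.rho < 1):
            raise ValueError("rho must be in (0, 1)")
        if not (0 <= self.jaccard_drop < self.jaccard_add <= 1):
            raise ValueError("need 0 <= jaccard_drop < jaccard_add <= 1")


@dataclass
class Module:
    genes: tuple[str, ...]
    compartment: str = ""
    niche_scores: dict[str, float] = field(default_factory=dict)
    flagged: bool = False


@dataclass
class LRTable:
    """Cognate ligand-receptor pairs; receptor complexes are gene tuples."""

    rows: list[tuple[str, tuple[str, ...], str]]

    def __post_init__(self):
        seen = set()
        for lig, rec, _ in self.rows:
            key = (lig, tuple(rec))
            if key in seen:
                raise ValueError(f"duplicate ligand-receptor row {key}")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path) -> "LRTable":
        df = pd.read_csv(path, sep="\t")
        rows = [
            (r.ligand, tuple(r.receptor_subunits.split(";")), r.pathway)
            for r in df.itertuples()
        ]
        return cls(rows)


def load_builtin_lr_table() -> LRTable:
    """Small curated table of mouse cognate pairs shipped with the package."""
    with resources.files("nichetrace.data").joinpath("lr_pairs.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return LRTable(
        [(r.ligand, tuple(r.receptor_subunits.split(";")), r.pathway)
         for r in df.itertuples()]
    )


def correlation_graph(
    z: np.ndarray,
    genes,
    cfg: CommGraphConfig = CommGraphConfig(),
    mask=None,
) -> nx.Graph:
    """Gene graph with an edge iff Pearson r of niche expression > rho.

    ``z`` is niches x genes (z-scored niche expression); ``mask`` restricts
    to unmasked niches. The inequality is strict. Constant genes become
    isolated nodes with a warning.
    """
    genes = list(genes)
    zm = z if mask is None else z[np.asarray(mask, bool)]
    if zm.shape[0] < cfg.min_shared_niches:
        raise ValueError("fewer unmasked niches than min_shared_niches")
    sd = zm.std(axis=0)
    G = nx.Graph()
    G.add_nodes_from(genes)
    const = np.flatnonzero(sd == 0)
    if len(const):
        warnings.warn(f"constant genes isolated: {[genes[i] for i in const]}")
    ok = sd > 0
    if ok.sum() < 2:
        return G
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(zm[:, ok].T)
    names = [g for g, o in zip(genes, ok) if o]
    iu, ju = np.triu_indices(len(names), k=1)
    hit = R[iu, ju] > cfg.rho
    for i, j in zip(iu[hit], ju[hit]):
        G.add_edge(names[i], names[j])
    return G


def _jaccard(G: nx.Graph, u, v) -> float:
    """Jaccard similarity of neighbour sets, endpoints excluded."""
    nu = set(G.neighbors(u)) - {u, v}
    nv = set(G.neighbors(v)) - {u, v}
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def jaccard_refine(G: nx.Graph, cfg: CommGraphConfig = CommGraphConfig()) -> nx.Graph:
    """Drop low-Jaccard edges and add high-Jaccard non-edges.

    Both rules are evaluated on the *original* graph's neighbour sets
    (endpoints excluded) and applied simultaneously, so removals never
    influence additions.
    """
    H = G.copy()
    for u, v in G.edges:
        if _jaccard(G, u, v) < cfg.jaccard_drop:
            H.remove_edge(u, v)
    nodes = sorted(G.nodes, key=str)
    for i, u in enumerate(nodes):
        # candidate partners share at least one neighbour
        cands = {w for nb in G.neighbors(u) for w in G.neighbors(nb)}
        for v in sorted(cands, key=str):
            if str(v) <= str(u) or G.has_edge(u, v):
                continue
            if _jaccard(G, u, v) > cfg.jaccard_add:
                H.add_edge(u, v)
    return H


def _conductance(G: nx.Graph, nodes: set) -> float:
    cut = sum(1 for u in nodes for v in G.neighbors(u) if v not in nodes)
    vol = sum(G.degree(u) for u in nodes)
    vol_rest = sum(dict(G.degree).values()) - vol
    denom = min(vol, vol_rest)
    if denom == 0:
        return 0.0 if cut == 0 else 1.0
    return cut / denom


def detect_modules(
    G: nx.Graph,
    cfg: CommGraphConfig = CommGraphConfig(),
    seed: int = 0,
) -> list[Module]:
    """Overlapping community detection by clique seeding and conductance
    expansion.

    Maximal cliques (largest first, lexicographic tie-break) seed candidate
    modules; each seed greedily absorbs neighbours connected to >= 60% of
    the module while this keeps conductance below the configured ceiling.
    Near-duplicate modules are deduplicated by Jaccard overlap; modules may
    still share genes (overlap is the point). Deterministic for a fixed
    graph; ``seed`` is accepted for interface stability.
    """
    cliques = [tuple(sorted(c, key=str)) for c in nx.find_cliques(G) if len(c) >= 3]
    cliques.sort(key=lambda c: (-len(c), tuple(map(str, c))))
    accepted: list[set] = []
    for seed_clique in cliques:
        module = set(seed_clique)
        while True:
            cands = sorted(
                {v for u in module for v in G.neighbors(u)} - module, key=str
            )
            best = None
            for v in cands:
                frac = sum(1 for u in module if G.has_edge(u, v)) / len(module)
                if frac >= 0.6 and (best is None or frac > best[0]):
                    best = (frac, v)
            if best is None:
                break
            trial = module | {best[1]}
            if _conductance(G, trial) >= cfg.conductance_max:
                break
            module = trial
        if len(module) < cfg.min_module_size:
            continue
        if _conductance(G, module) >= cfg.conductance_max:
            continue
        dup = any(
            len(module & m) / len(module | m) >= cfg.dedupe_jaccard
            for m in accepted
        )
        if not dup:
            accepted.append(module)
    if not accepted:
        warnings.warn("no module of the minimal size detected")
    return [Module(genes=tuple(sorted(m))) for m in accepted]


def module_niche_score(
    modules: list[Module],
    tensor,
    niche_sets: dict,
    compartment: str,
    flag_set: str = "progenitor_niches",
    flag_cut: float = 0.2,
) -> list[Module]:
    """Mean z of module genes over each canonical niche set, with the
    progenitor-association flag at mean z strictly > ``flag_cut``."""
    z = tensor.z[compartment]
    mask = tensor.mask[compartment]
    gene_pos = {g: i for i, g in enumerate(tensor.genes)}
    for mod in modules:
        mod.compartment = compartment
        cols = [gene_pos[g] for g in mod.genes if g in gene_pos]
        for name, niches in niche_sets.items():
            if not str(name).endswith("_niches"):
                continue
            sel = np.zeros(z.shape[0], dtype=bool)
            sel[np.asarray(niches, dtype=int)] = True
            sel &= mask
            mod.niche_scores[name] = (
                float(np.nanmean(z[np.ix_(sel, cols)])) if sel.any() and cols
                else np.nan
            )
        mod.flagged = bool(mod.niche_scores.get(flag_set, np.nan) > flag_cut)
    return modules


def _bin_trend(tensor, binning, compartment: str, genes: list[str]) -> np.ndarray:
    """Mean z of a gene set per occupied niche bin (NaN elsewhere)."""
    z, mask = tensor.z[compartment], tensor.mask[compartment]
    cols = [i for i, g in enumerate(tensor.genes) if g in set(genes)]
    out = np.full(binning.n_bins, np.nan)
    for b in range(binning.n_bins):
        sel = (binning.bin_id == b) & mask
        if sel.any():
            out[b] = np.nanmean(z[np.ix_(sel, cols)])
    return out


def cognate_channels(
    modules_by_compartment: dict[str, list[Module]],
    lr: LRTable,
    tensor,
    binning,
) -> pd.DataFrame:
    """Rank cognate ligand-receptor channels between flagged modules.

    A channel requires the ligand in a flagged module of one compartment and
    every receptor subunit in a flagged module of a different compartment.
    Channels are ranked by the Spearman correlation of the partners'
    bin-averaged trends along the niche continuum, then by the sum of module
    scores.
    """
    if not lr.rows:
        raise ValueError("empty ligand-receptor table")
    flagged_genes: dict[str, set] = {}
    score_of: dict[str, dict[str, float]] = {}
    for comp, mods in modules_by_compartment.items():
        flagged_genes[comp] = set()
        score_of[comp] = {}
        for m in mods:
            if m.flagged:
                for g in m.genes:
                    flagged_genes[comp].add(g)
                    score_of[comp][g] = max(
                        score_of[comp].get(g, -np.inf),
                        m.niche_scores.get("progenitor_niches", np.nan),
                    )
    rows = []
    comps = sorted(modules_by_compartment)
    for lig, rec, pathway in lr.rows:
        for ca in comps:
            if lig not in flagged_genes[ca]:
                continue
            for cb in comps:
                if cb == ca:
                    continue
                if not all(r in flagged_genes[cb] for r in rec):
                    continue
                t_lig = _bin_trend(tensor, binning, ca, [lig])
                t_rec = _bin_trend(tensor, binning, cb, list(rec))
                ok = np.isfinite(t_lig) & np.isfinite(t_rec)
                rho = (
                    float(spearmanr(t_lig[ok], t_rec[ok]).statistic)
                    if ok.sum() >= 3 else np.nan
                )
                msum = score_of[ca][lig] + min(score_of[cb][r] for r in rec)
                rows.append((lig, ca, ";".join(rec), cb, pathway, rho, msum))
    out = pd.DataFrame(
        rows, columns=["ligand", "ligand_compartment", "receptor",
                       "receptor_compartment", "pathway", "trend_rho",
                       "module_score"],
    )
    return out.sort_values(["trend_rho", "module_score"],
                           ascending=False, kind="stable").reset_index(drop=True)
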