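"""Synthetic premalignant-tissue generator with full ground truth.

Emulates the statistical structure of an imaging-based spatial panel
(Xenium-like): a few hundred genes, tens of counts per cell, glandular
epithelial lesions with lumens, an epithelial gastric->progenitor latent
gradient, stromal and myeloid states whose frequencies are coupled to the
local epithelial gradient, and dense lymph-node blobs. A companion
generator plants chromosome-scale copy-number events in dissociated-style
cohorts for karyotype-inference testing.

Everything is driven by a single integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.special import expit

__all__ = [
    "GeneSpec",
    "SimConfig",
    "SimTruth",
    "generate_tissue",
    "generate_cnv_cohort",
    "default_panel",
    "default_cnv_panel",
]

#: compartment labels the analysis recognises
COMPARTMENTS = (
    "epithelial",
    "fibroblast",
    "myeloid",
    "lymphoid",
    "endothelial",
    "mural",
    "other",
    "mixed",
)

# response-curve library: multiplicative factor as a function of the latent
# gastric(0) -> progenitor(1) coordinate
_RESPONSES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "flat": lambda u: np.ones_like(u),
    "up": lambda u: 0.2 + 1.8 * u,
    "down": lambda u: 2.0 - 1.8 * u,
    "early": lambda u: 0.2 + 1.8 * expit((u - 0.3) / 0.08),
    "late": lambda u: 0.2 + 1.8 * expit((u - 0.7) / 0.08),
}


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the simulated panel.

    baseline is the negative-binomial mean in the gene's home compartment at
    response factor 1. coupling > 0 means the gene responds to the *local*
    mean epithelial latent (niche-coupled) rather than the cell's own latent.
    """

    name: str
    chromosome: str
    genomic_order: int
    baseline: float
    compartment: str = "all"
    response: str = "flat"
    coupling: float = 0.0
    module: str | None = None
    is_communication: bool = False
    excluded: bool = False

    def __post_init__(self):
        if self.baseline < 0:
            raise ValueError(f"gene {self.name}: baseline mean must be >= 0")
        if self.response not in _RESPONSES:
            raise ValueError(f"gene {self.name}: unknown response '{self.response}'")


@dataclass
class SimConfig:
    """Study conditions for one synthetic tissue.

    Lengths are micrometres; stroma_density is cells per mm^2. lumen_radius 0
    means solid lesions without lumens. gradient_field maps lesion index to a
    latent value in [0, 1]; by default lesions are spread evenly along the
    gradient in order of center x.
    """

    seed: int = 0
    n_lesions: int = 6
    cells_per_lesion: tuple[int, int] = (450, 650)
    stroma_density: float = 12000.0
    lesion_radius: float = 100.0
    lumen_radius: float = 30.0
    lumen_radius_range: tuple[float, float] | None = None
    fov: tuple[float, float] = (1000.0, 1000.0)
    gradient_field: Mapping[int, float] | None = None
    panel: Sequence[GeneSpec] = field(default_factory=lambda: default_panel())
    nb_dispersion: float = 10.0
    lymph_nodes: Sequence[tuple[tuple[float, float], float, int]] = ()
    conditions: Sequence[tuple[str, Mapping[str, float]]] = (("ctrl", {}),)
    lesion_centers: Sequence[tuple[float, float]] | None = None
    niche_radius: float = 60.0
    coupling_steepness: float = 6.0
    latent_noise: float = 0.06
    module_sigma: float = 0.6
    background_frac: float = 0.05

    def validate(self) -> None:
        if self.lumen_radius < 0 or self.lumen_radius >= self.lesion_radius:
            if self.lumen_radius != 0 and self.lumen_radius >= self.lesion_radius:
                raise ValueError("lumen_radius must be < lesion_radius")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.lesion_centers is not None:
            w, h = self.fov
            for cx, cy in self.lesion_centers:
                if not (0 <= cx <= w and 0 <= cy <= h):
                    raise ValueError("lesion center outside field of view")
        names = [g.name for g in self.panel]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in panel")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    latent: pd.Series  # per-cell latent DC (NaN for non-epithelial)
    lesion_id: pd.Series  # -1 = none
    lymph_node_id: pd.Series  # -1 = none
    local_dc: pd.Series  # mean epithelial latent within niche radius
    cnv_events: pd.DataFrame | None = None  # cells x chromosomes, {gain,loss,neutral}
    modules: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    coupling_targets: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "latent": {k: (None if np.isnan(v) else float(v)) for k, v in self.latent.items()},
            "lesion_id": {k: int(v) for k, v in self.lesion_id.items()},
            "lymph_node_id": {k: int(v) for k, v in self.lymph_node_id.items()},
            "local_dc": {k: (None if np.isnan(v) else float(v)) for k, v in self.local_dc.items()},
            "modules": self.modules,
            "coupling_targets": self.coupling_targets,
            "warnings": self.warnings,
        }
        if self.cnv_events is not None:
            payload["cnv_events"] = {
                cell: dict(row) for cell, row in self.cnv_events.iterrows()
            }
        return json.dumps(payload, indent=1, sort_keys=True)


def default_panel() -> list[GeneSpec]:
    """A compact panel emulating a curated in-situ gene set.

    Gastric markers fall and progenitor markers rise along the latent
    gradient; one module per stromal compartment carries niche-coupled
    communication genes; a block of flat housekeeping genes and a pair of
    negative-control probes round out the panel.
    """
    panel: list[GeneSpec] = []
    order = {f"chr{c}": 0 for c in range(1, 6)}

    def add(name, chrom, **kw):
        order[chrom] += 1
        panel.append(GeneSpec(name, chrom, order[chrom], **kw))

    # epithelial gradient genes; gastric baselines are set so the panel's
    # total epithelial output stays roughly constant along the gradient
    # (real tissue does not grossly change total mRNA across this state
    # switch, and a drifting total would distort relative-abundance trends)
    for i, name in enumerate(["Anxa10", "F5", "Onecut2", "Elf3", "Tff1", "Gkn2"]):
        add(name, "chr1", baseline=6.5, compartment="epithelial", response="down")
    for name in ["Msn", "S100a4", "Anxa2"]:
        add(name, "chr1", baseline=3.5, compartment="epithelial", response="early")
    for name in ["Hmga2", "Vim", "Krt17"]:
        add(name, "chr1", baseline=3.5, compartment="epithelial", response="late")
    # fibroblast: universal (down) vs wound-healing myCAF module (up, coupled)
    for name in ["Tnxb", "Dpt", "Cxcl12"]:
        add(name, "chr2", baseline=3.0, compartment="fibroblast", response="down",
            coupling=1.0)
    for name in ["Tnc", "Postn", "Tgfb1", "Pdgfb", "Jag1", "Lif"]:
        add(name, "chr2", baseline=3.0, compartment="fibroblast", response="up",
            coupling=1.0, module="fib_wound", is_communication=True)
    # myeloid: resident (down) vs progenitor-niche module (up, coupled)
    for name in ["Maf", "Cd163"]:
        add(name, "chr3", baseline=3.0, compartment="myeloid", response="down",
            coupling=1.0)
    for name in ["Itgax", "Cd274", "Il18", "Csf2rb", "Spp1", "Il1b"]:
        add(name, "chr3", baseline=3.0, compartment="myeloid", response="up",
            coupling=1.0, module="mye_prog", is_communication=True)
    # epithelial receptors for the stromal ligands (communication partners)
    for name in ["Tgfbr1", "Tgfbr2", "Notch3", "Itgb3", "Sdc1", "Il18rap", "Lifr"]:
        add(name, "chr4", baseline=2.5, compartment="epithelial", response="up",
            module="epi_rec", is_communication=True)
    # lymphoid markers
    for name in ["Cd19", "Cd4", "Cd8a"]:
        add(name, "chr4", baseline=4.0, compartment="lymphoid", response="flat")
    # housekeeping
    for i in range(8):
        add(f"Hk{i}", "chr5", baseline=5.0, compartment="all", response="flat")
    # negative controls, excluded from embeddings and size factors
    for i in range(2):
        add(f"NegCtrl{i}", "chr5", baseline=0.05, compartment="all",
            response="flat", excluded=True)
    return panel


def default_cnv_panel(
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 600,
    seed: int = 7,
    mean_log_baseline: float = 1.0,
    sd_log_baseline: float = 0.8,
) -> list[GeneSpec]:
    """Genome-ordered panel for copy-number simulations.

    Baselines are log-normal to emulate the skewed expression-level
    distribution of real transcriptomes.
    """
    rng = np.random.default_rng(seed)
    panel = []
    for c in range(1, n_chromosomes + 1):
        base = rng.lognormal(mean_log_baseline, sd_log_baseline, genes_per_chromosome)
        for i in range(genes_per_chromosome):
            panel.append(
                GeneSpec(f"g{c}_{i}", f"chr{c}", i + 1, float(base[i]))
            )
    return panel


def _gene_annotation(panel: Sequence[GeneSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": [g.name for g in panel],
            "chromosome": [g.chromosome for g in panel],
            "genomic_order": [g.genomic_order for g in panel],
            "is_communication": [g.is_communication for g in panel],
            "excluded_from_embedding": [g.excluded for g in panel],
        },
        index=[g.name for g in panel],
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial (Gamma-Poisson) draw; dispersion >= 1e6 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion >= 1e6:
        return rng.poisson(mean)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(dispersion, mean[pos] / dispersion)
    return rng.poisson(lam)


def _place_lesion_centers(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.lesion_centers is not None:
        return np.asarray(cfg.lesion_centers, dtype=float)
    w, h = cfg.fov
    margin = cfg.lesion_radius
    centers: list[np.ndarray] = []
    min_sep = 2.0 * cfg.lesion_radius + 20.0
    for _ in range(5000):
        if len(centers) == cfg.n_lesions:
            break
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < cfg.n_lesions:
        raise ValueError("could not place lesion centers without overlap; enlarge fov")
    return np.asarray(centers)


def generate_tissue(config: SimConfig) -> tuple[pd.DataFrame, AnnData, SimTruth]:
    """Simulate one tissue per condition and return (cells, counts, truth).

    cells is the per-cell table (cell_id, x_um, y_um, sample, condition,
    compartment, state); counts is an AnnData with sparse integer counts and
    the panel annotation in .var; truth carries per-cell latent values,
    lesion/lymph-node membership and the planted module gene sets.
    """
    config.validate()
    if config.n_lesions == 0 and config.stroma_density == 0 and not config.lymph_nodes:
        raise ValueError("empty tissue")

    master = np.random.default_rng(config.seed)
    panel = list(config.panel)
    truth_warnings: list[str] = []

    rows = []  # cell table rows
    latents = []  # per-cell latent driver (NaN outside epithelium)
    lesion_ids = []
    ln_ids = []

    for cond_idx, (cond_label, state_mult) in enumerate(config.conditions):
        sample = f"{cond_label}_s{cond_idx}"
        rng = np.random.default_rng(master.integers(2**31))
        centers = (
            _place_lesion_centers(config, rng)
            if config.n_lesions > 0
            else np.zeros((0, 2))
        )
        # latent value per lesion: user-supplied map or even spread along x-rank
        if config.gradient_field is not None:
            lesion_latent = np.array(
                [config.gradient_field[j] for j in range(len(centers))], dtype=float
            )
        elif len(centers) > 1:
            lesion_latent = np.empty(len(centers))
            lesion_latent[np.argsort(centers[:, 0], kind="stable")] = np.linspace(
                0.0, 1.0, len(centers)
            )
        else:
            lesion_latent = np.full(len(centers), 0.5)

        # --- epithelial cells on lesion annuli
        for j, (cx, cy) in enumerate(centers):
            n = int(rng.integers(config.cells_per_lesion[0], config.cells_per_lesion[1] + 1))
            if config.lumen_radius_range is not None:
                r0, r1 = config.lumen_radius_range
                lumen_r = r0 + (r1 - r0) * lesion_latent[j]
            else:
                lumen_r = config.lumen_radius
            r = np.sqrt(rng.uniform(lumen_r**2, config.lesion_radius**2, n))
            theta = rng.uniform(0, 2 * np.pi, n)
            x, y = cx + r * np.cos(theta), cy + r * np.sin(theta)
            u = np.clip(
                lesion_latent[j] + rng.normal(0, config.latent_noise, n), 0.0, 1.0
            )
            for i in range(n):
                state = "progenitor-like" if u[i] >= 0.5 else "gastric-like"
                rows.append((x[i], y[i], sample, cond_label, "epithelial", state))
                latents.append(u[i])
                lesion_ids.append(j)
                ln_ids.append(-1)

        # --- stromal / myeloid / endothelial scatter (outside lesion disks)
        w, h = config.fov
        n_stroma = int(round(config.stroma_density * (w / 1000.0) * (h / 1000.0)))
        placed = 0
        guard = 0
        stroma_xy = []
        while placed < n_stroma and guard < 50 * max(n_stroma, 1):
            guard += 1
            p = rng.uniform([0, 0], [w, h])
            if len(centers) and np.min(np.hypot(*(centers - p).T)) < config.lesion_radius:
                continue
            stroma_xy.append(p)
            placed += 1
        stroma_xy = np.asarray(stroma_xy) if stroma_xy else np.zeros((0, 2))
        comp_draw = rng.choice(
            ["fibroblast", "myeloid", "endothelial"], size=len(stroma_xy),
            p=[0.5, 0.3, 0.2],
        )
        for p, comp in zip(stroma_xy, comp_draw):
            rows.append((p[0], p[1], sample, cond_label, comp, "__pending__"))
            latents.append(np.nan)
            lesion_ids.append(-1)
            ln_ids.append(-1)

        # --- lymph nodes
        for node_idx, (center, radius, n_cells) in enumerate(config.lymph_nodes):
            center = np.asarray(center, dtype=float)
            if len(centers) and np.min(np.hypot(*(centers - center).T)) < (
                radius + config.lesion_radius
            ):
                msg = f"lymph node {node_idx} overlaps a lesion; emitting both"
                warnings.warn(msg)
                truth_warnings.append(msg)
            rr = radius * np.sqrt(rng.uniform(0, 1, n_cells))
            th = rng.uniform(0, 2 * np.pi, n_cells)
            states = rng.choice(["B-cell", "CD4-T", "CD8-T"], size=n_cells,
                                p=[0.5, 0.3, 0.2])
            for i in range(n_cells):
                rows.append(
                    (center[0] + rr[i] * np.cos(th[i]), center[1] + rr[i] * np.sin(th[i]),
                     sample, cond_label, "lymphoid", states[i])
                )
                latents.append(np.nan)
                lesion_ids.append(-1)
                ln_ids.append(node_idx)

    cells = pd.DataFrame(rows, columns=["x_um", "y_um", "sample", "condition",
                                        "compartment", "state"])
    cells.insert(0, "cell_id", [f"cell_{i:06d}" for i in range(len(cells))])
    cells = cells.set_index("cell_id", drop=False)
    latent = pd.Series(latents, index=cells.index, name="latent")
    lesion_id = pd.Series(lesion_ids, index=cells.index, name="lesion_id")
    ln_id = pd.Series(ln_ids, index=cells.index, name="lymph_node_id")

    # --- local niche DC: mean epithelial latent within the niche radius,
    # computed per sample; cells with no epithelial neighbour fall back to the
    # sample mean epithelial latent
    local_dc = np.full(len(cells), np.nan)
    for sample, grp in cells.groupby("sample", sort=False):
        idx = cells.index.get_indexer(grp.index)
        epi = grp["compartment"].to_numpy() == "epithelial"
        xy = grp[["x_um", "y_um"]].to_numpy()
        if epi.sum() == 0:
            continue
        tree = cKDTree(xy[epi])
        epi_lat = latent.to_numpy()[idx][epi]
        neigh = tree.query_ball_point(xy, config.niche_radius)
        fallback = float(np.mean(epi_lat))
        vals = np.array(
            [np.mean(epi_lat[n]) if len(n) else fallback for n in neigh]
        )
        local_dc[idx] = vals
    local_dc = pd.Series(local_dc, index=cells.index, name="local_dc")

    # --- niche-coupled stromal state assignment
    rng_states = np.random.default_rng(master.integers(2**31))
    coupled = {"fibroblast": ("Tnc-myCAF", "Tnxb-fibro"),
               "myeloid": ("Itgax-mac", "Maf-mac")}
    cond_mult = {label: dict(m) for label, m in config.conditions}
    state_col = cells["state"].to_numpy(dtype=object)
    comp_col = cells["compartment"].to_numpy()
    cond_col = cells["condition"].to_numpy()
    for i in range(len(cells)):
        if state_col[i] != "__pending__":
            continue
        comp = comp_col[i]
        if comp == "endothelial":
            state_col[i] = "endothelial"
            continue
        hi, lo = coupled[comp]
        p = expit(config.coupling_steepness * (local_dc.iloc[i] - 0.5))
        p = float(np.clip(p * cond_mult[cond_col[i]].get(hi, 1.0), 0.0, 1.0))
        state_col[i] = hi if rng_states.uniform() < p else lo
    cells["state"] = state_col

    # --- counts: NB per cell with deterministic per-cell substreams
    gene_anno = _gene_annotation(panel)
    baselines = np.array([g.baseline for g in panel])
    comp_of_gene = np.array([g.compartment for g in panel])
    coupling = np.array([g.coupling for g in panel])
    responses = [_RESPONSES[g.response] for g in panel]
    module_of_gene = np.array([g.module or "" for g in panel])
    module_names = sorted({m for m in module_of_gene if m})

    rng_mod = np.random.default_rng(master.integers(2**31))
    eta = rng_mod.normal(0.0, config.module_sigma, (len(cells), len(module_names)))
    mod_index = {m: k for k, m in enumerate(module_names)}

    cell_seeds = np.random.SeedSequence(config.seed).spawn(len(cells))
    u_own = np.where(np.isfinite(latent.to_numpy()), latent.to_numpy(), 0.5)
    u_loc = np.where(np.isfinite(local_dc.to_numpy()), local_dc.to_numpy(), 0.5)
    M = np.empty((len(cells), len(panel)))
    for gidx in range(len(panel)):
        u = u_loc if coupling[gidx] > 0 else u_own
        M[:, gidx] = baselines[gidx] * responses[gidx](u)
    off = (comp_of_gene[None, :] != "all") & (comp_of_gene[None, :] != comp_col[:, None])
    M[off] = np.broadcast_to(
        baselines[None, :] * config.background_frac, M.shape
    )[off]
    for gidx in np.flatnonzero(module_of_gene != ""):
        factor = np.exp(
            eta[:, mod_index[module_of_gene[gidx]]] - config.module_sigma**2 / 2
        )
        M[~off[:, gidx], gidx] *= factor[~off[:, gidx]]
    X = np.zeros((len(cells), len(panel)), dtype=np.int32)
    for i in range(len(cells)):
        X[i] = _nb_draw(np.random.default_rng(cell_seeds[i]), M[i], config.nb_dispersion)

    adata = AnnData(
        X=sparse.csr_matrix(X),
        obs=cells.drop(columns="cell_id"),
        var=gene_anno,
    )
    truth = SimTruth(
        latent=latent,
        lesion_id=lesion_id,
        lymph_node_id=ln_id,
        local_dc=local_dc,
        modules={
            "fibroblast": {"fib_wound": [g.name for g in panel if g.module == "fib_wound"]},
            "myeloid": {"mye_prog": [g.name for g in panel if g.module == "mye_prog"]},
            "epithelial": {"epi_rec": [g.name for g in panel if g.module == "epi_rec"]},
        },
        coupling_targets={"fibroblast": "Tnc-myCAF", "myeloid": "Itgax-mac"},
        warnings=truth_warnings,
    )
    return cells, adata, truth


def generate_cnv_cohort(
    config: SimConfig,
    events: pd.DataFrame,
    fold_gain: float = 1.5,
    fold_loss: float = 0.5,
    window_size: int = 100,
) -> tuple[AnnData, SimTruth]:
    """Dissociated-style cohort with planted chromosome-scale events.

    events: cells x chromosomes frame of {'gain','loss','neutral'}; expected
    counts of genes on a gained chromosome are multiplied by fold_gain, lost
    ones by fold_loss. The panel must carry >= window_size genes per
    chromosome for downstream windowed inference; shortfalls are recorded as
    warnings in the returned truth.
    """
    config.validate()
    panel = list(config.panel)
    gene_anno = _gene_annotation(panel)
    chrom_sizes = gene_anno["chromosome"].value_counts()
    truth_warnings = [
        f"chromosome {c} has {n} genes < window {window_size}"
        for c, n in chrom_sizes.items()
        if n < window_size
    ]
    for w in truth_warnings:
        warnings.warn(w)

    fold = {"gain": fold_gain, "loss": fold_loss, "neutral": 1.0}
    baselines = np.array([g.baseline for g in panel])
    chrom_of_gene = gene_anno["chromosome"].to_numpy()

    cell_seeds = np.random.SeedSequence(config.seed).spawn(len(events))
    X = np.zeros((len(events), len(panel)), dtype=np.int32)
    for i, (cell, row) in enumerate(events.iterrows()):
        factors = np.array([fold[row.get(c, "neutral")] for c in chrom_of_gene])
        X[i] = _nb_draw(
            np.random.default_rng(cell_seeds[i]), baselines * factors,
            config.nb_dispersion,
        )

    obs = pd.DataFrame(index=pd.Index(events.index.astype(str), name="cell_id"))
    adata = AnnData(X=sparse.csr_matrix(X), obs=obs, var=gene_anno)
    idx = adata.obs_names
    nanseries = pd.Series(np.nan, index=idx)
    truth = SimTruth(
        latent=nanseries,
        lesion_id=pd.Series(-1, index=idx),
        lymph_node_id=pd.Series(-1, index=idx),
        local_dc=nanseries.copy(),
        cnv_events=events.set_axis(idx, axis=0),
        warnings=truth_warnings,
    )
    return adata, truth
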