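"""End-to-end orchestration: simulate -> preprocess -> diffusion -> niche ->
morphology -> communication modules.

One call runs the whole analysis on a synthetic tissue under a fixed seed
and returns every intermediate product, so the full chain is exercisable
and reproducible without external data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import commnet, diffusion, io, morphology, niche, preprocess, simdata

__all__ = ["run_pipeline"]


def run_pipeline(
    seed: int = 0,
    config: simdata.SimConfig | None = None,
    out_dir=None,
    n_diffusion_comps: int = 5,
    niche_radius: float = 60.0,
    n_bins: int = 50,
) -> dict:
    """Run the full niche-analysis chain on one synthetic tissue.

    Returns a dict with the simulation (cells, counts, truth), the epithelial
    diffusion component, the niche index/binning/tensor, morphology features
    and the detected communication modules and channels. If ``out_dir`` is
    given, the declared text outputs are written there.
    """
    cfg = config or simdata.SimConfig(seed=seed)
    cells, adata, truth = simdata.generate_tissue(cfg)

    # preprocessing: cell filter + linear normalization
    excl = adata.var["excluded_from_embedding"].to_numpy()
    keep, removed_frac = preprocess.filter_cells(adata.X, min_counts=25,
                                                 excluded_genes=excl)
    cells = cells[keep]
    adata = adata[keep].copy()
    norm, size_factors = preprocess.normalize_counts(adata.X,
                                                     excluded_genes=excl)
    norm = norm.toarray() if hasattr(norm, "toarray") else norm

    # diffusion continuum on gastric/progenitor epithelial cells
    epi = cells["state"].isin(["gastric-like", "progenitor-like"]).to_numpy()
    feat = norm[np.ix_(epi, ~excl)]
    model = diffusion.build_diffusion_operator(
        feat, k=min(30, epi.sum() - 2), bandwidth_neighbor=10
    )
    comps = diffusion.diffusion_components(model, n_diffusion_comps)
    dc1 = pd.Series(np.nan, index=cells.index)
    dc1[epi] = comps[:, 0]
    # orient DC1 so it increases with the progenitor state
    prog = (cells["state"] == "progenitor-like").to_numpy()[epi]
    if np.nanmean(comps[prog, 0]) < np.nanmean(comps[~prog, 0]):
        dc1[epi] = -comps[:, 0]

    truth_latent = truth.latent[cells.index]
    ok = epi & truth_latent.notna().to_numpy()
    rho_latent = float(abs(spearmanr(dc1[ok], truth_latent[ok]).statistic))

    # niches
    index = niche.build_niche_index(cells, radius=niche_radius)
    binning = niche.order_niches(index, dc1, states=cells["state"],
                                 min_epithelial=10, n_bins=n_bins)
    counts_tbl, frac_tbl = niche.niche_composition(index, cells, level="state")
    tensor = niche.niche_expression(
        index, adata.X, cells["compartment"], adata.var_names,
        which_compartments=["epithelial", "fibroblast", "myeloid"],
    )
    sets = niche.canonical_niche_sets(frac_tbl, binning)

    # morphology
    lesion_id, lesion_sizes = morphology.lesion_components(cells)
    raster = morphology.rasterize(cells)
    lumen = morphology.lumen_mask(raster)
    epi_mask = (cells["compartment"] == "epithelial").to_numpy()
    lumen_area = morphology.niche_lumen_area(
        raster, lumen, cells.loc[epi_mask, ["x_um", "y_um"]].to_numpy()
    )

    # communication modules on niche expression of communication genes
    comm = adata.var["is_communication"].to_numpy()
    ccfg = commnet.CommGraphConfig()
    modules_by_comp: dict[str, list] = {}
    for comp in ("fibroblast", "myeloid", "epithelial"):
        z = tensor.z[comp][:, comm]
        mods = commnet.detect_modules(
            commnet.jaccard_refine(
                commnet.correlation_graph(
                    z, adata.var_names[comm], ccfg, mask=tensor.mask[comp]
                ),
                ccfg,
            ),
            ccfg,
        )
        modules_by_comp[comp] = commnet.module_niche_score(
            mods, tensor, sets, comp
        )
    lr = commnet.load_builtin_lr_table()
    channels = commnet.cognate_channels(modules_by_comp, lr, tensor, binning)

    results = {
        "cells": cells,
        "counts": adata,
        "truth": truth,
        "removed_fraction": removed_frac,
        "dc1": dc1,
        "dc1_truth_spearman": rho_latent,
        "niche_index": index,
        "binning": binning,
        "state_fractions": frac_tbl,
        "tensor": tensor,
        "canonical_sets": sets,
        "lesion_sizes": lesion_sizes,
        "lumen_area": lumen_area,
        "modules": modules_by_comp,
        "channels": channels,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_cell_table(cells, out / "cells.tsv")
        io.write_counts_mtx(adata, out / "counts")
        io.write_truth_json(truth, out / "truth.json")
        dc1.rename("dc1").to_csv(out / "dc1.tsv", sep="\t")
        frac_tbl.to_csv(out / "niche_state_fractions.tsv", sep="\t")
        lesion_sizes.rename_axis("lesion_id").to_csv(
            out / "lesion_sizes.tsv", sep="\t"
        )
        channels.to_csv(out / "channels.tsv", sep="\t", index=False)
        mod_rows = [
            {"compartment": comp, "module": i, "flagged": m.flagged,
             "genes": ";".join(m.genes), **m.niche_scores}
            for comp, mods in modules_by_comp.items()
            for i, m in enumerate(mods)
        ]
        pd.DataFrame(mod_rows).to_csv(out / "modules.tsv", sep="\t",
                                      index=False)
    return results
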