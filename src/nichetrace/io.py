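"""Text-based I/O: cell tables as TSV, counts as MatrixMarket triplets,
ground truth as JSON, neighbourhood memberships as two-column TSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_cell_table",
    "read_cell_table",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_truth_json",
    "write_neighborhoods_tsv",
    "read_neighborhoods_tsv",
]

CELL_COLUMNS = ["cell_id", "x_um", "y_um", "sample", "condition",
                "compartment", "state"]


def write_cell_table(cells: pd.DataFrame, path) -> None:
    out = cells.copy()
    if "cell_id" not in out.columns:
        out = out.reset_index().rename(columns={"index": "cell_id"})
    out[CELL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return cells.set_index("cell_id", drop=False)


def write_counts_mtx(adata: AnnData, outdir) -> None:
    """CellRanger-style triplet: matrix.mtx + features.tsv + barcodes.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(outdir / "matrix.mtx", X.T.tocoo())  # genes x cells on disk
    adata.var.reset_index(names="gene").to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_counts_mtx(indir) -> AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    var = pd.read_csv(indir / "features.tsv", sep="\t").set_index("gene")
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.DataFrame(index=pd.Index(barcodes.astype(str), name="cell_id"))
    return AnnData(X=X, obs=obs, var=var)


def write_truth_json(truth, path) -> None:
    Path(path).write_text(truth.to_json())


def write_neighborhoods_tsv(members: dict, cell_ids, path) -> None:
    rows = [
        (nid, cell_ids[m]) for nid in sorted(members) for m in members[nid]
    ]
    pd.DataFrame(rows, columns=["neighborhood_id", "cell_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_neighborhoods_tsv(path, cell_ids) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    pos = pd.Index(cell_ids).get_indexer(df["cell_id"])
    if (pos < 0).any():
        raise ValueError("neighborhood file references unknown cell ids")
    return {
        int(nid): grp.to_numpy()
        for nid, grp in pd.Series(pos).groupby(df["neighborhood_id"].to_numpy())
    }
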