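"""Diffusion operator, diffusion components, distances and imputation.

The operator is built on a kNN graph with an adaptive Gaussian kernel: the
per-cell bandwidth is the distance to the 10th nearest neighbour, and the
affinity between neighbours i and j is exp(-d_ij^2 / (sigma_i sigma_j)).
The kernel is symmetrized as (A + A^T)/2 and row-normalized into a Markov
operator P. Eigendecomposition goes through the symmetric conjugate
D^{1/2} P D^{-1/2}, so all eigenvalues are real and eigenvectors are
recovered for P itself. Diffusion components are the non-trivial
eigenvectors; powers of P drive neighbour-sharing imputation; diffusion
distance is the spectral l2 distance weighted by eigenvalue powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import eigsh
from sklearn.neighbors import NearestNeighbors

from .preprocess import triangle_threshold

__all__ = [
    "DiffusionModel",
    "build_diffusion_operator",
    "model_from_affinity",
    "diffusion_components",
    "select_components_by_eigengap",
    "diffusion_distance",
    "impute",
    "impute_by_condition",
    "discretize_component",
]


@dataclass
class DiffusionModel:
    operator: sparse.csr_matrix  # row-stochastic n x n
    bandwidths: np.ndarray  # per-cell adaptive kernel width
    eigenvalues: np.ndarray  # descending, eigenvalues[0] == 1
    eigenvectors: np.ndarray  # n x n_eigs right eigenvectors of the operator
    k: int
    stationary: np.ndarray  # row sums of the symmetric kernel (unnormalized pi)


def build_diffusion_operator(
    latent: np.ndarray,
    k: int = 30,
    bandwidth_neighbor: int = 10,
    n_eigs: int = 20,
) -> DiffusionModel:
    """Markov diffusion operator on a kNN graph with adaptive Gaussian kernel.

    ``latent`` is cells x dims. Requires n > k > bandwidth_neighbor >= 1.
    Duplicated points can give a zero bandwidth; those are replaced by the
    smallest positive bandwidth with a warning.
    """
    latent = np.asarray(latent, dtype=float)
    n = latent.shape[0]
    if not (n > k > bandwidth_neighbor >= 1):
        raise ValueError("need n > k > bandwidth_neighbor >= 1")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(latent)
    dist, ind = nn.kneighbors(latent)  # includes self at distance 0
    sigma = dist[:, bandwidth_neighbor].copy()
    if (sigma == 0).any():
        pos = sigma[sigma > 0]
        if len(pos) == 0:
            raise ValueError("all pairwise distances are zero; no nontrivial geometry")
        warnings.warn("zero adaptive bandwidth from duplicate points; substituting "
                      "smallest positive bandwidth")
        sigma[sigma == 0] = pos.min()

    rows = np.repeat(np.arange(n), k + 1)
    cols = ind.ravel()
    aff = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    A = sparse.csr_matrix((aff, (rows, cols)), shape=(n, n))
    model = model_from_affinity(A, n_eigs=n_eigs, k=k)
    model.bandwidths = sigma
    return model


def model_from_affinity(A, n_eigs: int = 20, k: int = 0) -> DiffusionModel:
    """Symmetrize an affinity matrix and build the Markov diffusion model.

    The kernel is (A + A^T)/2; the operator is its row normalization. Exposed
    so operators can be built from any affinity graph, not only the adaptive
    Gaussian kNN kernel.
    """
    A = sparse.csr_matrix(A)
    n = A.shape[0]
    W = (A + A.T) / 2.0
    deg = np.asarray(W.sum(axis=1)).ravel()
    if (deg <= 0).any():
        raise ValueError("affinity matrix has an isolated all-zero row")
    P = sparse.diags(1.0 / deg) @ W

    # eigendecomposition via the symmetric conjugate M = D^-1/2 W D^-1/2
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    M = sparse.diags(d_inv_sqrt) @ W @ sparse.diags(d_inv_sqrt)
    n_eigs = min(n_eigs, n - 1)
    v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic start vector
    vals, vecs = eigsh(M, k=n_eigs, which="LA", v0=v0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # With (near-)disconnected graphs the unit eigenvalue is repeated and
    # eigsh returns an arbitrary basis of that subspace. Rotate the block so
    # its first vector is the exact stationary eigenvector sqrt(deg); the
    # remaining block vectors are then orthogonal to the constant, so their
    # signs partition the components.
    unit = vals > 1 - 1e-9
    if unit.sum() > 1:
        u = np.sqrt(deg)
        u /= np.linalg.norm(u)
        Q, _ = np.linalg.qr(np.column_stack([u, vecs[:, unit]]))
        vecs[:, unit] = Q[:, : unit.sum()]
    phi = d_inv_sqrt[:, None] * vecs  # right eigenvectors of P

    return DiffusionModel(
        operator=P.tocsr(),
        bandwidths=np.zeros(n),
        eigenvalues=vals,
        eigenvectors=phi,
        k=k,
        stationary=deg,
    )


def diffusion_components(model: DiffusionModel, n_comps: int) -> np.ndarray:
    """Non-trivial diffusion components (eigenvectors 2..n_comps+1).

    Columns are unit-norm with the sign fixed so the entry of largest
    magnitude is positive. Raises if the requested number of informative
    components is unavailable (e.g. all cells identical).
    """
    avail = model.eigenvectors.shape[1] - 1
    if n_comps > avail:
        raise ValueError(f"requested {n_comps} components, only {avail} available")
    # a repeated unit eigenvalue means disconnected/degenerate structure with
    # no usable continuum past the constant vector
    if np.sum(model.eigenvalues > 1 - 1e-10) > n_comps + 1:
        raise ValueError("degenerate spectrum: no nontrivial components")
    comps = model.eigenvectors[:, 1 : n_comps + 1].copy()
    comps /= np.linalg.norm(comps, axis=0)
    flip = comps[np.argmax(np.abs(comps), axis=0), np.arange(n_comps)] < 0
    comps[:, flip] *= -1
    return comps


def select_components_by_eigengap(eigenvalues) -> int:
    """Number of eigenvectors to retain by the second-eigengap criterion.

    Computes the drops between consecutive eigenvalues and returns the
    position of the second-largest drop (stable order, so equal drops are
    taken earliest-first). The largest drop is usually the one below the
    trivial unit eigenvalue; the second marks the end of the informative
    spectrum.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 4:
        raise ValueError("need at least 4 eigenvalues")
    gaps = ev[:-1] - ev[1:]
    order = np.argsort(-gaps, kind="stable")
    return int(order[1]) + 1


def diffusion_distance(
    model: DiffusionModel,
    query_cells,
    target_cells,
    n_eigs: int,
    t: int = 1,
) -> np.ndarray:
    """Per-query minimal diffusion distance to any target cell.

    d(i,j)^2 = sum_{l=2}^{n_eigs+1} lambda_l^{2t} (psi_l(i) - psi_l(j))^2.
    """
    query = np.asarray(query_cells)
    target = np.asarray(target_cells)
    if target.size == 0:
        raise ValueError("empty target set")
    if n_eigs + 1 > model.eigenvectors.shape[1]:
        raise ValueError("n_eigs exceeds available eigenvectors")
    lam = model.eigenvalues[1 : n_eigs + 1] ** t
    psi = model.eigenvectors[:, 1 : n_eigs + 1] * lam
    from scipy.spatial.distance import cdist

    d = cdist(psi[query], psi[target])
    return d.min(axis=1)


def impute(model: DiffusionModel, counts, t: int = 3):
    """Neighbour-sharing imputation: P^t @ counts (t = 0 returns the input)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, float)
    out = X.copy()
    for _ in range(t):
        out = model.operator @ out
    return out


def impute_by_condition(
    latent: np.ndarray,
    counts,
    conditions,
    k: int = 30,
    bandwidth_neighbor: int = 10,
    t: int = 3,
):
    """Impute separately per condition on a shared latent space.

    Rebuilds the operator within each condition so expression information is
    never shared across experimental groups.
    """
    conditions = np.asarray(conditions)
    X = counts.toarray() if sparse.issparse(counts) else np.asarray(counts, float)
    out = np.empty_like(X, dtype=float)
    for cond in pd_unique(conditions):
        mask = conditions == cond
        model = build_diffusion_operator(
            np.asarray(latent)[mask], k=k, bandwidth_neighbor=bandwidth_neighbor
        )
        out[mask] = impute(model, X[mask], t=t)
    return out


def pd_unique(values):
    """Order-preserving unique (first occurrence)."""
    seen, out = set(), []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def discretize_component(
    dc_values,
    n_bins_for_density: int = 50,
    orientation: str | None = None,
    scores=None,
) -> tuple[np.ndarray, float]:
    """Binary split of a diffusion component by triangle threshold on its
    density histogram.

    The positive side is oriented either explicitly (``orientation`` in
    {'high', 'low'}) or as the side containing the cell with the maximal
    caller-supplied score. Returns (labels, threshold).
    """
    dc = np.asarray(dc_values, dtype=float)
    if len(np.unique(dc)) < 2:
        raise ValueError("all component values identical; nothing to discretize")
    hist, edges = np.histogram(dc, bins=n_bins_for_density)
    thr = triangle_threshold(hist, edges)
    above = dc > thr
    if orientation is None:
        if scores is None:
            raise ValueError(
                "orientation unresolvable: provide scores or an explicit "
                "orientation flag"
            )
        orientation = "high" if above[int(np.argmax(scores))] else "low"
    if orientation not in ("high", "low"):
        raise ValueError("orientation must be 'high' or 'low'")
    labels = above if orientation == "high" else ~above
    return labels, thr
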