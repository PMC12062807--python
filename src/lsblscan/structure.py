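"""Population structure: dosage PCA, IBS distances, neighbor-joining.

PCA uses Patterson variance standardization: missing dosages are imputed
to the site mean, sites are centered by 2p and scaled by sqrt(2p(1-p))
(monomorphic sites dropped), and components come from the eigen-
decomposition of the sample covariance of the standardized matrix.
Identity-by-state distance is 1 minus the mean fraction of shared
alleles over co-called sites.  Neighbor-joining is the Saitou-Nei
agglomeration with a deterministic smallest-index tie-break; negative
branch lengths are floored at zero with the deficit shifted to the
sister branch, so path lengths are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lsblscan.variants import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    coords: pd.DataFrame  # samples x PC1..PCk
    explained_pct: np.ndarray  # per component, % of positive-eigenvalue variance
    eigenvalues: np.ndarray


def pca(geno: GenotypeMatrix, k: int = 10) -> PcaResult:
    """Principal components of the standardized dosage matrix.

    Each component is oriented so that its largest-magnitude sample
    coordinate is positive, making signs stable across runs.
    """
    if k > geno.n_samples:
        raise ValueError("k exceeds sample count")
    dos = geno.dosage.astype(np.float64)
    called = dos != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(called, dos, 0.0).sum(axis=0) / n
    p = mean / 2.0
    poly = (n > 0) & (p > 0) & (p < 1)
    dos = np.where(called, dos, mean[None, :])[:, poly]
    scale = np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    m = (dos - 2.0 * p[poly][None, :]) / scale[None, :]

    cov = (m @ m.T) / m.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos_sum = eigvals[eigvals > 0].sum()
    explained = np.where(eigvals > 0, eigvals / pos_sum * 100.0, 0.0)[:k]

    coords = eigvecs[:, :k] * np.sqrt(np.maximum(eigvals[:k], 0.0))[None, :]
    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    frame = pd.DataFrame(
        coords, index=geno.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PcaResult(frame, explained, eigvals[:k])


def ibs_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """1 - mean allele-sharing fraction per sample pair.

    Per co-called site the similarity is (2 - |d_i - d_j|) / 2; pairs
    with no co-called sites are NaN.  Returns a symmetric DataFrame with
    zero diagonal.
    """
    dos = geno.dosage
    ind = {g: (dos == g).astype(np.float64) for g in (0, 1, 2)}
    called = (dos != MISSING).astype(np.float64)
    co_called = called @ called.T
    # |d_i - d_j| summed over co-called sites: 1 for {0,1} and {1,2}, 2 for {0,2}
    diff1 = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    )
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (diff1 + 2.0 * diff2) / (2.0 * co_called)
    dist[co_called == 0] = np.nan
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=geno.samples, columns=geno.samples)


# ----------------------------------------------------------------------------
# neighbor-joining
# ----------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label: str | None, children: list | None = None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.17g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(dist: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> str:
    """Unrooted Saitou-Nei neighbor-joining tree as a Newick string.

    On additive (tree-metric) input the topology and branch lengths are
    recovered exactly.  Joins are chosen by minimum Q with ties broken
    by the lexicographically smallest active index pair; negative branch
    lengths are floored at zero and the deficit moved to the sister
    branch.
    """
    if isinstance(dist, pd.DataFrame):
        labels = labels or list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = labels or [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    full = np.zeros((2 * n - 1, 2 * n - 1))
    full[:n, :n] = d
    d = full
    nodes: dict[int, _Node] = {i: _Node(labels[i]) for i in range(n)}
    active = list(range(n))
    next_idx = n

    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        row_sums = sub.sum(axis=1)
        q = (m - 2.0) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> lexicographically smallest (i, j) pair
        flat = np.argmin(q)
        best = q.flat[flat]
        ties = np.argwhere(np.isclose(q, best, rtol=0, atol=1e-12))
        ties = ties[ties[:, 0] < ties[:, 1]]
        ai, aj = min((int(i), int(j)) for i, j in ties)
        i, j = idx[ai], idx[aj]

        dij = d[i, j]
        vi = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (m - 2.0))
        vj = dij - vi
        # floor negatives, shifting deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0

        new = next_idx
        next_idx += 1
        nodes[new] = _Node(None, [(nodes.pop(i), vi), (nodes.pop(j), vj)])
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j = active
    bl = max(d[i, j], 0.0)
    root = _Node(None, [(nodes.pop(i), bl), (nodes.pop(j), 0.0)])
    # present as the conventional unrooted trifurcation when possible
    return root.newick() + ";"
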