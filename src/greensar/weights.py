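"""Kernel spatial weight matrices with adaptive bandwidths.

The weight of neighbor j seen from point i is a triangular kernel
``w_ij = max(0, 1 - d_ij / h_i)`` with the adaptive bandwidth ``h_i`` set to
the distance from i to its (k+1)-th nearest neighbor, so that the k nearest
neighbors all receive strictly positive weight.  Rows are standardized to
sum to one.  Because bandwidths adapt per point the matrix is asymmetric;
no symmetrization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from greensar.points import PointSet


@dataclass
class SpatialWeightMatrix:
    """Sparse nonnegative spatial weights with zero diagonal.

    Attributes
    ----------
    W : scipy.sparse.csr_matrix
        The (row-standardized) weight matrix.
    k : int
        Neighbor count parameter used to build the kernel.
    bandwidths : ndarray
        Per-point adaptive bandwidth h_i in meters.
    standardized : bool
        Whether rows have been scaled to sum to one.
    """

    W: sp.csr_matrix
    k: int
    bandwidths: np.ndarray
    standardized: bool = False

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    def require_standardized(self) -> None:
        s = self.row_sums()
        nz = s > 0
        if not np.allclose(s[nz], 1.0, atol=1e-10):
            raise ValueError("weight matrix is not row-standardized")

    def to_coo_text(self, path) -> None:
        """Write the nonzero entries as 'i j w' coordinate-list text."""
        coo = self.W.tocoo()
        with open(path, "w") as fh:
            fh.write(f"# n={self.n} k={self.k} standardized={self.standardized}\n")
            for i, j, w in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i} {j} {w:.17g}\n")

    @classmethod
    def from_coo_text(cls, path) -> "SpatialWeightMatrix":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            data = np.loadtxt(fh, ndmin=2)
        n = int(meta["n"])
        W = sp.csr_matrix((data[:, 2], (data[:, 0].astype(int), data[:, 1].astype(int))),
                          shape=(n, n))
        return cls(W=W, k=int(meta["k"]), bandwidths=np.full(n, np.nan),
                   standardized=meta["standardized"] == "True")


def build_kernel_weights(points: PointSet, k: int = 15,
                         standardize: bool = True) -> SpatialWeightMatrix:
    """Build the adaptive-bandwidth triangular kernel weight matrix.

    Parameters
    ----------
    points : PointSet
        Study locations (projected coordinates, meters).
    k : int
        Number of nearest neighbors receiving positive weight; the bandwidth
        h_i is the distance to the (k+1)-th nearest neighbor. Must satisfy
        1 <= k < n.
    standardize : bool
        Row-standardize the result (the default, as required by the spatial
        regression machinery).
    """
    n = points.n
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < n; got k={k}, n={n}")
    coords = points.coords
    tree = cKDTree(coords)
    # k+2 columns: self, k neighbors, and the (k+1)-th used as bandwidth
    dist, idx = tree.query(coords, k=k + 2)
    if np.any(dist[:, 1] == 0):
        dup = points.ids[dist[:, 1] == 0]
        raise ValueError(f"duplicate coordinates for point ids {dup.tolist()}; "
                         "adaptive bandwidths require distinct locations")
    h = dist[:, k + 1]
    w = np.maximum(0.0, 1.0 - dist[:, 1:k + 1] / h[:, None])
    rows = np.repeat(np.arange(n), k)
    W = sp.csr_matrix((w.ravel(), (rows, idx[:, 1:k + 1].ravel())), shape=(n, n))
    W.eliminate_zeros()
    swm = SpatialWeightMatrix(W=W, k=k, bandwidths=h, standardized=False)
    return row_standardize(swm) if standardize else swm


def row_standardize(swm: SpatialWeightMatrix) -> SpatialWeightMatrix:
    """Scale each nonzero row to sum to one; zero rows stay zero.

    Idempotent.  Returns a new SpatialWeightMatrix; the input is unchanged.
    """
    if (swm.W.data < 0).any():
        raise ValueError("weights must be nonnegative")
    s = swm.row_sums()
    zero_rows = np.flatnonzero(s == 0)
    if zero_rows.size:
        import warnings

        warnings.warn(f"{zero_rows.size} row(s) have no neighbors and remain zero",
                      stacklevel=2)
    inv = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    W = sp.diags(inv) @ swm.W
    return SpatialWeightMatrix(W=W.tocsr(), k=swm.k, bandwidths=swm.bandwidths,
                               standardized=True)
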