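"""The 22 shape/topology descriptors used to match grids against ligands.

A feature vector describes any point set -- a sparse free-atom grid or a
ligand conformer -- by translation/rotation-invariant quantities, ordered:

==========  =============================================================
indices     feature
==========  =============================================================
1-11        third-order moment invariants (3 from the second-order moment
            tensor, 8 involving the third-order tensor)
12          chirality index (pseudoscalar; sign flips under reflection)
13-14       interatomic distances: mean pairwise and diameter, A
15-18       connectivity: extreme eigenvalues of the Burden matrix
19-21       central moments (variance, skewness, excess kurtosis) of the
            distances of the points from their centroid
22          number of points
==========  =============================================================

All except the point count are independent of how many atoms the cloud
contains only through the per-point averaging of the moment tensors; no
spatial rescaling is applied.  Only the connectivity features and the point
count are conformation-invariant.

Moment-invariant basis
----------------------
With S the per-point-averaged second central moment tensor and T the third,
define the auxiliary vectors V_i = T_ijj, W_k = S_ij T_ijk, U_k = (S^2)_ij
T_ijk and the matrix M_il = T_ijk T_ljk.  The eleven invariants are the
full contractions

    tr S,  tr S^2,  det S,
    T:T,  V.V,  V.S.V,  W.V,  W.W,  tr(M S),  W.S.W,  V.S^2.V

-- every index is contracted, so each is invariant under proper rotation,
and central moments make them translation-invariant.  Each is reported as
its signed d-th root, where d is the invariant's degree in length units, so
all eleven carry Angstrom units and comparable dynamic ranges.  The
chirality index is the signed 15th root of det[V W U]: the three vectors
acquire a common sign flip per reflection, so the determinant is a
pseudoscalar (and vanishes for planar sets, where all three vectors lie in
the plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .config import FeatureConfig
from .errors import EmptyInputError, TooSmallError

__all__ = [
    "N_FEATURES",
    "FEATURE_CATEGORIES",
    "PseudoBondGraph",
    "moment_invariants",
    "chirality_index",
    "distance_features",
    "pseudo_connectivity",
    "connectivity_features",
    "distance_distribution_moments",
    "feature_vector",
    "burden_matrix_from_bonds",
    "extreme_eigenvalues",
]

N_FEATURES = 22

#: slices of the feature vector by descriptor category
FEATURE_CATEGORIES = {
    "moment_invariants": slice(0, 11),
    "chirality": slice(11, 12),
    "distances": slice(12, 14),
    "connectivity": slice(14, 18),
    "centroid_distance_moments": slice(18, 21),
    "atom_count": slice(21, 22),
}


@dataclass
class PseudoBondGraph:
    """Undirected pseudo-bond graph over point indices (pseudo-order 1)."""

    n_nodes: int
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if len(self.edges) and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise EmptyInputError("pseudo-bond graph has a self-loop")


def _signed_root(x: float, degree: int) -> float:
    return float(np.sign(x) * np.abs(x) ** (1.0 / degree))


def _moment_tensors(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = points - points.mean(axis=0)
    n = len(x)
    s = x.T @ x / n
    t = np.einsum("ni,nj,nk->ijk", x, x, x) / n
    return s, t


def moment_invariants(points: np.ndarray) -> np.ndarray:
    """Eleven rotation/translation-invariant moment descriptors (A units).

    Collinear (or smaller) point sets are degenerate: the second-order
    invariants are still computed but every invariant involving the
    third-order tensor is reported as 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise TooSmallError("moment invariants need >= 3 points")
    s, t = _moment_tensors(points)
    out = np.zeros(11)
    out[0] = _signed_root(np.trace(s), 2)
    out[1] = _signed_root(np.trace(s @ s), 4)
    out[2] = _signed_root(np.linalg.det(s), 6)
    if np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-9) < 2:
        return out  # collinear: third-order invariants degenerate to 0
    v = np.einsum("ijj->i", t)
    w = np.einsum("ij,ijk->k", s, t)
    m = np.einsum("ijk,ljk->il", t, t)
    s2 = s @ s
    out[3] = _signed_root(np.einsum("ijk,ijk->", t, t), 6)
    out[4] = _signed_root(v @ v, 6)
    out[5] = _signed_root(v @ s @ v, 8)
    out[6] = _signed_root(w @ v, 6)
    out[7] = _signed_root(w @ w, 6)
    out[8] = _signed_root(np.trace(m @ s), 8)
    out[9] = _signed_root(w @ s @ w, 8)
    out[10] = _signed_root(v @ s2 @ v, 10)
    return out


def chirality_index(points: np.ndarray) -> float:
    """Pseudoscalar moment descriptor: negates under reflection."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 4:
        return 0.0  # degenerate: a <4-point set is never chiral
    s, t = _moment_tensors(points)
    v = np.einsum("ijj->i", t)
    w = np.einsum("ij,ijk->k", s, t)
    u = np.einsum("ij,ijk->k", s @ s, t)
    return _signed_root(np.linalg.det(np.column_stack([v, w, u])), 15)


def distance_features(points: np.ndarray) -> np.ndarray:
    """Mean pairwise interatomic distance and diameter, A."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise TooSmallError("distance features need >= 2 points")
    d = pdist(points)
    return np.array([d.mean(), d.max()])


def pseudo_connectivity(
    points: np.ndarray, config: FeatureConfig | None = None
) -> PseudoBondGraph:
    """Pseudo-bonds between free atoms: edge iff distance <= cutoff.

    The default 1.8 A cutoff spans the free-atom attachment window
    ([1.2, 1.7] A) without bridging the looser 2.3 A cluster linkage.
    """
    cfg = config or FeatureConfig()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise EmptyInputError("pseudo_connectivity needs points")
    pairs = cKDTree(points).query_pairs(cfg.pseudo_bond_cutoff, output_type="ndarray")
    return PseudoBondGraph(n_nodes=len(points), edges=pairs)


def burden_matrix_from_bonds(
    n: int,
    bonds,
    diagonal: np.ndarray | float,
) -> np.ndarray:
    """Burden connectivity matrix.

    Diagonal holds the atomic property (atomic number for real atoms, the
    carbon-equivalent constant for pseudo-atoms); bonded pairs contribute
    0.1 x bond order off-diagonal and every other pair the background
    0.001, making the matrix dense, symmetric and real.
    """
    b = np.full((n, n), 0.001)
    for edge in bonds:
        i, j = int(edge[0]), int(edge[1])
        order = float(edge[2]) if len(edge) > 2 else 1.0
        b[i, j] = b[j, i] = 0.1 * order
    np.fill_diagonal(b, diagonal)
    return b


def extreme_eigenvalues(matrix: np.ndarray) -> np.ndarray:
    """Two smallest and two largest eigenvalues, ascending.

    For n < 4 the four slots are filled by duplicating the extreme
    eigenvalues (n = 2 gives (e0, e0, e1, e1); n = 3 gives
    (e0, e1, e1, e2)).
    """
    ev = np.linalg.eigvalsh(matrix)
    n = len(ev)
    if n >= 4:
        return np.array([ev[0], ev[1], ev[-2], ev[-1]])
    if n == 3:
        return np.array([ev[0], ev[1], ev[1], ev[2]])
    if n == 2:
        return np.array([ev[0], ev[0], ev[1], ev[1]])
    return np.array([ev[0]] * 4)


def connectivity_features(
    graph: PseudoBondGraph | list,
    elements: list[str] | None = None,
    n_nodes: int | None = None,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Four Burden-eigenvalue features from a bond or pseudo-bond graph."""
    cfg = config or FeatureConfig()
    if isinstance(graph, PseudoBondGraph):
        n = graph.n_nodes
        bonds = graph.edges
    else:
        bonds = graph
        if n_nodes is None:
            raise TooSmallError("n_nodes required with an explicit bond list")
        n = n_nodes
    if n < 2:
        raise TooSmallError("connectivity features need >= 2 nodes")
    if elements is not None:
        from .ligands import _ATOMIC_NUMBERS  # local import avoids a cycle

        diagonal = np.array([_ATOMIC_NUMBERS[e] for e in elements], dtype=float)
    else:
        diagonal = cfg.pseudo_atom_diagonal
    return extreme_eigenvalues(burden_matrix_from_bonds(n, bonds, diagonal))


def distance_distribution_moments(points: np.ndarray) -> np.ndarray:
    """Variance, skewness and excess kurtosis of centroid distances.

    Bias-uncorrected sample formulas throughout (population variance;
    skewness m3/m2^1.5; kurtosis m4/m2^2 - 3).  A degenerate distribution
    (all points equidistant from the centroid) reports (0, 0, 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        raise TooSmallError("distance-distribution moments need >= 2 points")
    r = np.linalg.norm(points - points.mean(axis=0), axis=1)
    var = float(np.var(r))
    if var < 1e-18:
        return np.zeros(3)
    return np.array(
        [var, float(stats.skew(r, bias=True)), float(stats.kurtosis(r, bias=True))]
    )


def feature_vector(
    points: np.ndarray,
    graph: PseudoBondGraph | None = None,
    elements: list[str] | None = None,
    bonds: list | None = None,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Assemble the full 22-feature descriptor of a point set.

    For ligand conformers pass ``bonds`` (+ ``elements``) so the
    connectivity features use the true bond graph; for sparse grids the
    pseudo-bond graph is derived from the points when not supplied.

    Library molecules always have at least five atoms, but heavily thinned
    grids of the smallest blobs can drop to three or four points; those
    still carry usable shape signal, so vectors are defined down to three
    points via the documented degenerate rules (chirality 0 below four
    points, duplicated extreme Burden eigenvalues below four nodes).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise TooSmallError("feature vectors are defined for >= 3 points")
    if bonds is not None:
        conn = connectivity_features(bonds, elements, n_nodes=len(points), config=config)
    else:
        if graph is None:
            graph = pseudo_connectivity(points, config)
        conn = connectivity_features(graph, elements, config=config)
    return np.concatenate(
        [
            moment_invariants(points),
            [chirality_index(points)],
            distance_features(points),
            conn,
            distance_distribution_moments(points),
            [float(len(points))],
        ]
    )
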