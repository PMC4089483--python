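"""Sparse-grid construction: parameterize a density blob as free atoms.

The blob is converted to a pseudo-atomic point cloud in four steps:

1. Greedy placement of free atoms onto high-density voxels, each new atom
   attached within [1.2, 1.7] A of an already-placed atom and at least
   1.2 A from all of them, so the cloud respects bonded-atom geometry
   without assuming any chemical identity.
2. Single-linkage clustering at 2.0 A; only the cluster nearest the user's
   point of interest is kept.
3. The atoms' interpolated density values are sorted in descending order
   and a running standard deviation of the three successive differences is
   computed; peaks in this sigma profile mark density edges where weak
   extraneous points begin, and up to five such peaks become thinning
   thresholds.
4. Each threshold drops the atoms below it and the survivors are
   re-clustered at the relaxed 2.3 A cutoff, yielding up to five candidate
   sparse grids for shape comparison.

Grid quality against known ligand coordinates is measured by a symmetric
nearest-neighbour RMSD (NNRMSD) that penalizes both missing and spurious
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp
from scipy.spatial import cKDTree

from .config import GridConfig
from .density_maps import DensityMap, interpolate_many
from .errors import EmptyBlobError, EmptyInputError, ParameterError, TooSmallError

__all__ = [
    "FreeAtomCloud",
    "ThinningProfile",
    "SparseGrid",
    "place_free_atoms",
    "connected_cluster",
    "sigma_profile",
    "detect_thresholds",
    "build_sparse_grids",
    "nnrmsd",
    "write_grid_pdb",
]


@dataclass
class FreeAtomCloud:
    """Pseudo-atomic points with their interpolated density values."""

    points: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.densities = np.asarray(self.densities, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ThinningProfile:
    """Sorted density profile with its running-sigma sequence."""

    sorted_densities: np.ndarray
    sigmas: np.ndarray  # sigma[i] defined for i >= 3, aligned to index i-3
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SparseGrid:
    """One thinned, re-clustered candidate grid."""

    points: np.ndarray
    threshold_index: int

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def n_points(self) -> int:
        return len(self.points)


def place_free_atoms(
    dmap: DensityMap,
    seed_point: np.ndarray,
    config: GridConfig | None = None,
) -> FreeAtomCloud:
    """Greedily place free atoms onto high-density voxels near a seed point.

    Candidate voxels are those with density >= floor_sigma x sigma_level.
    Placement starts at the highest-density candidate within the snap
    radius of ``seed_point`` and repeatedly adds the highest-density
    remaining candidate that lies within the attachment window of at least
    one placed atom and outside the exclusion radius of all of them,
    stopping at the atom cap or on exhaustion.
    """
    cfg = config or GridConfig()
    seed_point = np.asarray(seed_point, dtype=float)
    if dmap.sigma_level <= 0:
        raise EmptyBlobError("map is flat; no density to parameterize")
    floor = cfg.floor_sigma * dmap.sigma_level
    idx = np.argwhere(dmap.values >= floor)
    if idx.size == 0:
        raise EmptyBlobError("no voxel above the density floor")
    coords = dmap.node_coords(idx)
    dens = dmap.values[idx[:, 0], idx[:, 1], idx[:, 2]]

    near = np.linalg.norm(coords - seed_point, axis=1) <= cfg.seed_snap_radius
    if not np.any(near):
        raise EmptyBlobError(
            f"no voxel above the floor within {cfg.seed_snap_radius} A "
            "of the seed point"
        )
    order = np.argsort(dens)[::-1]  # densest first
    start = order[np.argmax(near[order])]

    tree = cKDTree(coords)
    # candidate states: 0 free, 1 attachable, 2 consumed/excluded
    state = np.zeros(len(coords), dtype=np.int8)
    rank = np.empty(len(coords), dtype=int)
    rank[order] = np.arange(len(coords))  # density rank, 0 = densest

    placed: list[int] = []

    def consume(i: int) -> None:
        state[i] = 2
        placed.append(i)
        neigh = tree.query_ball_point(coords[i], cfg.attach_max)
        for j in neigh:
            if state[j] == 2:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d < cfg.exclusion:
                state[j] = 2  # inside exclusion radius of a placed atom
            elif d >= cfg.attach_min:
                if state[j] == 0:
                    state[j] = 1

    consume(start)
    while len(placed) < cfg.atom_cap:
        attachable = np.where(state == 1)[0]
        if attachable.size == 0:
            break
        nxt = attachable[np.argmin(rank[attachable])]
        consume(nxt)

    points = coords[placed]
    densities = interpolate_many(dmap, points)
    return FreeAtomCloud(points=points, densities=densities)


def connected_cluster(
    points: np.ndarray, anchor: np.ndarray, cutoff: float
) -> np.ndarray:
    """Indices of the single-linkage component containing the point nearest
    ``anchor``; edges connect pairs closer than ``cutoff``."""
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise EmptyInputError("no points to cluster")
    anchor = np.asarray(anchor, dtype=float)
    tree = cKDTree(points)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(points)
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = sp.csgraph.connected_components(graph, directed=False)
    nearest = int(np.argmin(np.linalg.norm(points - anchor, axis=1)))
    return np.where(labels == labels[nearest])[0]


def sigma_profile(densities: np.ndarray) -> ThinningProfile:
    """Sort densities descending and compute the running sigma sequence.

    For each index i >= 3, sigma_i is the sample SD (n-1 denominator) of
    the three successive differences d[i-3]-d[i-2], d[i-2]-d[i-1],
    d[i-1]-d[i].
    """
    d = np.sort(np.asarray(densities, dtype=float))[::-1]
    if len(d) < 5:
        raise TooSmallError("sigma profile needs at least 5 density values")
    diffs = -np.diff(d)  # successive drops, length n-1
    windows = np.lib.stride_tricks.sliding_window_view(diffs, 3)
    sigmas = np.std(windows, axis=1, ddof=1)
    return ThinningProfile(sorted_densities=d, sigmas=sigmas)


def detect_thresholds(
    profile: ThinningProfile, config: GridConfig | None = None
) -> ThinningProfile:
    """Locate peaks in the sigma sequence and turn them into thresholds.

    A peak is strictly the greatest sigma within a +/- window and exceeds
    mean(sigma) + peak_min_sd x SD(sigma).  The most prominent qualifying
    peaks (highest sigma first, at most five) become thresholds: the
    density value at the peak's atom index.  With no qualifying peak a
    single threshold retaining every atom is returned.
    """
    cfg = config or GridConfig()
    s = profile.sigmas
    d = profile.sorted_densities
    n = len(s)
    level = s.mean() + cfg.peak_min_sd * s.std()
    peaks = []
    w = cfg.peak_window
    for i in range(n):
        lo, hi = max(0, i - w), min(n, i + w + 1)
        window = s[lo:hi]
        if s[i] <= level:
            continue
        if s[i] > np.max(np.delete(window, i - lo)):
            peaks.append(i)
    if not peaks:
        thresholds = np.array([d[-1]])  # keep everything
    else:
        peaks.sort(key=lambda i: -s[i])
        peaks = peaks[: cfg.max_thresholds]
        # sigma index i corresponds to sorted atom index i+3; the threshold
        # keeps atoms with density >= the value at the peak position
        thresholds = np.array(sorted((d[i + 3] for i in peaks), reverse=True))
    return ThinningProfile(sorted_densities=d, sigmas=s, thresholds=thresholds)


def build_sparse_grids(
    dmap: DensityMap,
    seed_point: np.ndarray,
    config: GridConfig | None = None,
) -> list[SparseGrid]:
    """Full chain: place, cluster, profile, thin, re-cluster.

    Returns up to five grids ordered by threshold (highest first); grids
    with fewer than ``min_grid_points`` points are discarded.
    """
    cfg = config or GridConfig()
    cloud = place_free_atoms(dmap, seed_point, cfg)
    keep = connected_cluster(cloud.points, seed_point, cfg.cluster_cutoff)
    points = cloud.points[keep]
    dens = cloud.densities[keep]
    if len(points) < 5:
        if len(points) >= cfg.min_grid_points:
            return [SparseGrid(points=points, threshold_index=1)]
        raise EmptyBlobError("cluster near the seed point is too small")
    profile = detect_thresholds(sigma_profile(dens), cfg)
    grids: list[SparseGrid] = []
    for k, thr in enumerate(profile.thresholds, start=1):
        mask = dens >= thr
        if mask.sum() < cfg.min_grid_points:
            continue
        sub = points[mask]
        keep2 = connected_cluster(sub, seed_point, cfg.recluster_cutoff)
        if len(keep2) < cfg.min_grid_points:
            continue
        grids.append(SparseGrid(points=sub[keep2], threshold_index=k))
    if not grids:
        keep2 = connected_cluster(points, seed_point, cfg.recluster_cutoff)
        grids.append(SparseGrid(points=points[keep2], threshold_index=1))
    return grids


def nnrmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric nearest-neighbour RMSD between two point sets (A).

    sqrt( (sum_a min_b |a-b|^2 + sum_b min_a |b-a|^2) / (|A|+|B|) )

    Symmetrizing over both directions penalizes points of either set with
    no counterpart in the other (missing as well as spurious density).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("nnrmsd needs two non-empty point sets")
    da = cKDTree(b).query(a)[0]
    db = cKDTree(a).query(b)[0]
    return float(np.sqrt((np.sum(da**2) + np.sum(db**2)) / (len(a) + len(b))))


def write_grid_pdb(grid: SparseGrid, densities: np.ndarray | None, path) -> None:
    """Export a grid as PDB dummy atoms (element X, occupancy = density)."""
    lines = []
    occ = densities if densities is not None else np.ones(grid.n_points)
    for i, (p, q) in enumerate(zip(grid.points, occ), start=1):
        lines.append(
            f"HETATM{i:5d}  X   GRD A{1:4d}    "
            f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{min(q, 999.99):6.2f}{0.0:6.2f}"
            f"           X"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
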