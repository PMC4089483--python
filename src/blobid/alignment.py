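"""Conformationally flexible superposition of a ligand onto a sparse grid.

The ligand's three principal axes are aligned with those of the grid in
the four proper-rotation sign combinations (+x+y+z, -x-y+z, +x-y-z,
-x+y-z), each explored independently.  Within each, a genetic algorithm
searches torsion space: individuals are torsion states on a 60 degree
grid, evaluated by applying the torsions, least-squares superposing onto
the current nearest-neighbour grid points (a few iterative-closest-point
rounds), and scoring with a saturating per-pair reward

    score = (1/k) sum_i exp(-d_i^2 / (2 sigma_s^2)),   sigma_s = 0.5 A,

where k is the number of ligand atoms and d_i each atom's nearest-grid
distance.  The saturation means one well-matched pair outscores two
half-matched neighbours, biasing the superposition towards clean atom
pairings and leaving surplus grid points unpaired.  Crossover mixes elite
torsion vectors and a uniform +/-10 degree shake refines them; clashing
offspring are rejected.  Only torsions and rigid motion are searched, so
every output conformer preserves the reference stereochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import AlignConfig
from .errors import DegenerateAxesError, EmptyInputError
from .ligands import (
    Molecule,
    TorsionDriver,
    _min_pair_distance,
    _nonbonded_pairs,
)
from .sparse_grid import SparseGrid

__all__ = [
    "TorsionState",
    "AlignmentResult",
    "principal_axes",
    "pair_score",
    "ga_align",
    "AXIS_SIGN_COMBOS",
]

#: the four proper-rotation sign combinations of the principal axes
AXIS_SIGN_COMBOS = (
    (1.0, 1.0, 1.0),
    (-1.0, -1.0, 1.0),
    (1.0, -1.0, -1.0),
    (-1.0, 1.0, -1.0),
)


@dataclass
class TorsionState:
    """One angle per rotatable bond, degrees in [0, 360)."""

    angles: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.mod(np.asarray(self.angles, dtype=float), 360.0)


@dataclass
class AlignmentResult:
    coords: np.ndarray
    score: float
    axis_combo: int
    torsions: TorsionState
    degenerate_axes: bool = False
    #: best population score per generation, concatenated over axis combos
    trace: list | None = None


def principal_axes(points: np.ndarray) -> np.ndarray:
    """Ordered orthonormal principal axes of a point set.

    Rows are eigenvectors of the centered second-moment tensor by
    descending eigenvalue; the sign convention makes the largest-magnitude
    component of the first two axes positive and the third axis completes
    a right-handed frame.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise DegenerateAxesError("principal axes need >= 3 points")
    x = points - points.mean(axis=0)
    cov = x.T @ x / len(x)
    lam, vec = np.linalg.eigh(cov)
    lam, vec = lam[::-1], vec[:, ::-1]
    if lam[1] <= 1e-10 * max(lam[0], 1e-30):
        raise DegenerateAxesError("points are collinear; axes undefined")
    axes = vec.T
    for i in range(2):
        k = int(np.argmax(np.abs(axes[i])))
        if axes[i][k] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def pair_score(
    lig_coords: np.ndarray,
    grid_points: np.ndarray,
    sigma: float = 0.5,
) -> float:
    """Saturating nearest-neighbour reward in [0, 1]; 1 = every atom on a
    grid point."""
    lig_coords = np.atleast_2d(np.asarray(lig_coords, dtype=float))
    grid_points = np.atleast_2d(np.asarray(grid_points, dtype=float))
    if lig_coords.size == 0 or grid_points.size == 0:
        raise EmptyInputError("pair_score needs two non-empty point sets")
    d = cKDTree(grid_points).query(lig_coords)[0]
    return float(np.mean(np.exp(-(d**2) / (2.0 * sigma**2))))


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ p + t ~ q."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, qc - r @ pc


def _icp_superpose(
    coords: np.ndarray, grid: np.ndarray, tree: cKDTree, iterations: int
) -> np.ndarray:
    """Refresh nearest-neighbour pairs and re-superpose a few times."""
    for _ in range(iterations):
        nn = tree.query(coords)[1]
        r, t = _kabsch(coords, grid[nn])
        coords = coords @ r.T + t
    return coords


def ga_align(
    mol: Molecule,
    start_conformer: np.ndarray,
    grid: SparseGrid,
    config: AlignConfig | None = None,
) -> AlignmentResult:
    """Flexible GA superposition of a conformer onto a sparse grid.

    Each of the four axis-sign combinations is searched independently and
    the best individual over all four is returned.  Fully seeded.  When
    the grid's axes are degenerate (nearly collinear points) the identity
    orientation is used and the result flagged.
    """
    cfg = config or AlignConfig()
    grid_pts = grid.points
    tree = cKDTree(grid_pts)
    driver = TorsionDriver(mol)
    nb = _nonbonded_pairs(mol)
    n_tor = driver.n_torsions
    steps = 6  # 60-degree torsion grid

    # reference conformation with the requested starting geometry
    base_mol_coords = np.asarray(start_conformer, dtype=float)
    work = Molecule(
        code=mol.code, name=mol.name, elements=list(mol.elements),
        coords=base_mol_coords, bonds=list(mol.bonds),
        rotatable=list(mol.rotatable),
    )
    driver = TorsionDriver(work)

    def clash_free(coords: np.ndarray) -> bool:
        return nb.size == 0 or _min_pair_distance(coords, nb) >= 2.0

    degenerate = False
    try:
        grid_axes = principal_axes(grid_pts)
    except DegenerateAxesError:
        degenerate = True

    def orient(coords: np.ndarray, signs) -> np.ndarray:
        """Principal-axes alignment of a conformer onto the grid."""
        if degenerate:
            return coords - coords.mean(axis=0) + grid_pts.mean(axis=0)
        try:
            lig_axes = principal_axes(coords)
        except DegenerateAxesError:
            return coords - coords.mean(axis=0) + grid_pts.mean(axis=0)
        rot = grid_axes.T @ np.diag(signs) @ lig_axes
        centered = coords - coords.mean(axis=0)
        return centered @ rot.T + grid_pts.mean(axis=0)

    def evaluate(angles: np.ndarray, signs) -> tuple[float, np.ndarray]:
        coords = driver.apply(angles)
        if not clash_free(coords):
            return -1.0, coords
        coords = orient(coords, signs)
        coords = _icp_superpose(coords, grid_pts, tree, cfg.icp_iterations)
        return pair_score(coords, grid_pts, cfg.score_sigma), coords

    best = AlignmentResult(
        coords=base_mol_coords.copy(), score=-1.0, axis_combo=0,
        torsions=TorsionState(np.zeros(n_tor)), degenerate_axes=degenerate,
        trace=[],
    )
    combos = AXIS_SIGN_COMBOS if not degenerate else AXIS_SIGN_COMBOS[:1]
    trace: list[float] = []
    for ci, signs in enumerate(combos):
        if n_tor == 0:
            score, coords = evaluate(np.zeros(0), signs)
            trace.append(score)
            if score > best.score:
                best = AlignmentResult(
                    coords=coords, score=score, axis_combo=ci,
                    torsions=TorsionState(np.zeros(0)),
                    degenerate_axes=degenerate,
                )
            continue
        # each axis combo gets its own stream so its search is self-contained
        rng = np.random.default_rng([cfg.seed, ci])
        pop = rng.integers(0, steps, size=(cfg.population, n_tor)) * 60.0
        pop[0] = 0.0  # the starting torsion state always participates
        for _ in range(cfg.generations):
            scored = []
            for angles in pop:
                score, coords = evaluate(angles, signs)
                scored.append((score, angles, coords))
            scored.sort(key=lambda s: -s[0])
            trace.append(scored[0][0])
            if scored[0][0] > best.score:
                best = AlignmentResult(
                    coords=scored[0][2], score=scored[0][0], axis_combo=ci,
                    torsions=TorsionState(scored[0][1]),
                    degenerate_axes=degenerate,
                )
            elite = [s[1] for s in scored[: cfg.elite]]
            children = [e.copy() for e in elite]  # elitism
            while len(children) < cfg.population:
                pa, pb = rng.choice(len(elite), size=2)
                mask = rng.random(n_tor) < 0.5
                child = np.where(mask, elite[pa], elite[pb])
                child = child + rng.uniform(-cfg.shake_deg, cfg.shake_deg, n_tor)
                children.append(np.mod(child, 360.0))
            pop = np.array(children)
    best.trace = trace
    return best
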