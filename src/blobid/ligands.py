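"""Small-molecule handling: topology, conformers, BCUT redundancy clustering.

Molecules are heavy-atom only throughout: at the map resolutions in scope
(1.0-2.5 A) hydrogen positions are not interpretable, and neither the
density parameterization nor the shape descriptors can see them.

Conformers are produced by torsion driving: every rotatable bond is turned
on a 60 degree grid (exhaustively when the grid is small, by seeded random
sampling when it explodes) and states with intramolecular clashes are
rejected.  Bond lengths and angles are untouched, so each conformer keeps
the reference stereochemistry exactly.  Ring puckers are not enumerated;
alternative puckers enter the library as separate entries.

Ligand redundancy is reduced with BCUT descriptors -- eigenvalues of the
Burden connectivity matrix -- which depend only on the bond graph, so
ligands with identical heavy-atom substructure (indistinguishable in the
density) cluster together.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .config import ConformerConfig
from .errors import FormatError, ParameterError, TooSmallError, TopologyError
from .features import burden_matrix_from_bonds, extreme_eigenvalues

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "ConformerSet",
    "LigandGroup",
    "read_molecule",
    "perceive_topology",
    "generate_conformers",
    "bcut_descriptors",
    "cluster_ligands",
    "builtin_library",
    "COVALENT_RADII",
]

#: covalent radii (A) for bond perception from coordinates
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
    "Fe": 1.32, "Mg": 1.41, "Zn": 1.22, "Mn": 1.39, "Co": 1.26, "Ni": 1.24,
}

_ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "Br": 35, "I": 53, "Se": 34, "Fe": 26, "Mg": 12, "Zn": 30,
    "Mn": 25, "Co": 27, "Ni": 28,
}


@dataclass
class Molecule:
    """Heavy-atom small molecule with bond graph and rotatable torsions.

    ``bonds`` are (i, j, order) with order in {1, 1.5, 2, 3}; ``rotatable``
    indexes into ``bonds``.
    """

    code: str
    name: str
    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]]
    rotatable: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def atomic_numbers(self) -> np.ndarray:
        return np.array([_ATOMIC_NUMBERS[e] for e in self.elements], dtype=float)

    def validate(self) -> None:
        g = self.graph()
        if self.n_atoms > 1 and not nx.is_connected(g):
            raise TopologyError(
                f"{self.code}: bond graph has "
                f"{nx.number_connected_components(g)} components"
            )
        for i, j, _ in self.bonds:
            d = float(np.linalg.norm(self.coords[i] - self.coords[j]))
            if not 1.0 <= d <= 2.0:
                raise TopologyError(
                    f"{self.code}: bond {i}-{j} has length {d:.2f} A"
                )


@dataclass
class ConformerSet:
    """A molecule with up to ``max_conformers`` torsion-driven coordinate sets."""

    molecule: Molecule
    conformers: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.conformers)

    def validate(self, clash_distance: float = 2.0, tol: float = 0.05) -> None:
        mol = self.molecule
        ref = _bond_lengths(mol.coords, mol.bonds)
        nb = _nonbonded_pairs(mol)
        for c in self.conformers:
            if np.max(np.abs(_bond_lengths(c, mol.bonds) - ref)) > tol:
                raise TopologyError(f"{mol.code}: conformer distorts bond lengths")
            if nb.size and _min_pair_distance(c, nb) < clash_distance:
                raise TopologyError(f"{mol.code}: conformer has a clash")


@dataclass
class LigandGroup:
    """Ligands with indistinguishable heavy-atom substructure."""

    members: list[str]
    representative: str

    def __post_init__(self) -> None:
        if not self.members or self.representative not in self.members:
            raise ParameterError("group representative must be a member")


def _bond_lengths(coords: np.ndarray, bonds) -> np.ndarray:
    idx = np.array([(i, j) for i, j, _ in bonds], dtype=int)
    return np.linalg.norm(coords[idx[:, 0]] - coords[idx[:, 1]], axis=1)


def _nonbonded_pairs(mol: Molecule) -> np.ndarray:
    bonded = {(min(i, j), max(i, j)) for i, j, _ in mol.bonds}
    pairs = [
        (i, j)
        for i, j in itertools.combinations(range(mol.n_atoms), 2)
        if (i, j) not in bonded
    ]
    return np.array(pairs, dtype=int) if pairs else np.empty((0, 2), dtype=int)


def _min_pair_distance(coords: np.ndarray, pairs: np.ndarray) -> float:
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(d.min())


# ---------------------------------------------------------------------------
# reading molecules

def _mol_from_rdkit(rdmol: Chem.Mol, code: str, name: str) -> Molecule:
    rdmol = Chem.RemoveHs(rdmol)
    conf = rdmol.GetConformer()
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = np.array(
        [list(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())]
    )
    bonds = []
    for b in rdmol.GetBonds():
        order = 1.5 if b.GetIsAromatic() else float(b.GetBondTypeAsDouble())
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    mol = Molecule(code=code, name=name, elements=elements, coords=coords,
                   bonds=bonds)
    mol.rotatable = _rotatable_bonds(mol)
    return mol


def _embed_smiles(smiles: str, seed: int) -> Chem.Mol:
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FormatError(f"unparsable SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(rdmol, params) != 0:
            raise FormatError(f"3D embedding failed for {smiles!r}")
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMolecule(rdmol, maxIters=500)
    return rdmol


def read_molecule(
    source: str,
    fmt: str | None = None,
    code: str = "LIG",
    name: str = "",
    min_heavy_atoms: int = 5,
    embed_seed: int = 7,
) -> Molecule:
    """Read a molecule from SDF/PDB text, a file path, or a SMILES string.

    Hydrogens are stripped.  Bonds come from the file when present;
    PDB HETATM input without CONECT records falls back to distance-based
    perception.  SMILES input is given seeded 3D coordinates.  Molecules
    with fewer than ``min_heavy_atoms`` heavy atoms are rejected.
    """
    if fmt is None:
        low = str(source).lower()
        if low.endswith(".sdf") or low.endswith(".mol"):
            fmt = "sdf"
        elif low.endswith(".pdb"):
            fmt = "pdb"
        elif "\n" in source and ("HETATM" in source or "ATOM" in source):
            fmt = "pdbblock"
        elif "\n" in source:
            fmt = "sdfblock"
        else:
            fmt = "smiles"
    if fmt in ("sdf", "pdb"):
        text = Path(source).read_text()
        fmt += "block"
    else:
        text = source
    if fmt == "sdfblock":
        rdmol = Chem.MolFromMolBlock(text, removeHs=False)
    elif fmt == "pdbblock":
        rdmol = Chem.MolFromPDBBlock(text, removeHs=False)
    elif fmt == "smiles":
        rdmol = _embed_smiles(text, embed_seed)
    else:
        raise ParameterError(f"unknown molecule format {fmt!r}")
    if rdmol is None:
        raise FormatError(f"cannot parse molecule input ({fmt})")
    mol = _mol_from_rdkit(rdmol, code, name)
    if fmt == "pdbblock" and not any(o > 1 for *_, o in mol.bonds):
        # PDB connectivity is unreliable; re-perceive from geometry
        mol.bonds, mol.rotatable = perceive_topology(mol.elements, mol.coords)
    if mol.n_atoms < min_heavy_atoms:
        raise TooSmallError(
            f"{code}: {mol.n_atoms} heavy atoms < minimum {min_heavy_atoms}"
        )
    mol.validate()
    return mol


def perceive_topology(
    elements: list[str], coords: np.ndarray
) -> tuple[list[tuple[int, int, float]], list[int]]:
    """Perceive bonds and rotatable torsions from coordinates alone.

    Two atoms are bonded iff their distance is at most 1.15 x the sum of
    their covalent radii.  Rotatable bonds are non-ring single bonds whose
    endpoints are both non-terminal.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ParameterError("non-finite coordinates")
    n = len(elements)
    radii = np.array([COVALENT_RADII[e] for e in elements])
    bonds: list[tuple[int, int, float]] = []
    if n > 1:
        d = squareform(pdist(coords))
        limit = 1.15 * (radii[:, None] + radii[None, :])
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] <= limit[i, j]:
                    bonds.append((i, j, 1.0))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in bonds)
    if n > 1 and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise TopologyError(f"disconnected bond graph: components {comps}")
    mol = Molecule(code="", name="", elements=list(elements), coords=coords,
                   bonds=bonds)
    return bonds, _rotatable_bonds(mol)


def _rotatable_bonds(mol: Molecule) -> list[int]:
    g = mol.graph()
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            ring_edges.add((min(a, b), max(a, b)))
    rot = []
    for k, (i, j, order) in enumerate(mol.bonds):
        if order != 1.0:
            continue
        if (min(i, j), max(i, j)) in ring_edges:
            continue
        if g.degree(i) < 2 or g.degree(j) < 2:
            continue
        rot.append(k)
    return rot


# ---------------------------------------------------------------------------
# torsion driving

class TorsionDriver:
    """Applies torsion states to a molecule's reference conformation.

    Rotatable bonds are processed proximal-to-distal from a root atom, the
    distal fragment rotating about the bond axis, so torsions compose
    consistently and bond lengths/angles are preserved exactly.
    """

    def __init__(self, mol: Molecule):
        self.mol = mol
        g = mol.graph()
        depth = nx.single_source_shortest_path_length(g, 0)
        entries = []
        for k in mol.rotatable:
            i, j, _ = mol.bonds[k]
            if depth[j] < depth[i]:
                i, j = j, i  # i is proximal to the root
            h = g.copy()
            h.remove_edge(i, j)
            distal = sorted(nx.node_connected_component(h, j))
            entries.append((depth[i], i, j, np.array(distal, dtype=int)))
        entries.sort(key=lambda e: e[0])
        self.entries = [(i, j, distal) for _, i, j, distal in entries]

    @property
    def n_torsions(self) -> int:
        return len(self.entries)

    def apply(self, angles_deg: np.ndarray) -> np.ndarray:
        coords = self.mol.coords.copy()
        for (i, j, distal), angle in zip(self.entries, angles_deg):
            if angle % 360.0 == 0.0:
                continue
            axis = coords[j] - coords[i]
            axis /= np.linalg.norm(axis)
            rot = _axis_angle_matrix(axis, np.deg2rad(angle))
            coords[distal] = (coords[distal] - coords[j]) @ rot.T + coords[j]
        return coords


def _axis_angle_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def generate_conformers(
    mol: Molecule,
    max_n: int | None = None,
    step_deg: float | None = None,
    config: ConformerConfig | None = None,
) -> ConformerSet:
    """Drive rotatable torsions over a step grid, rejecting clashes.

    When the full torsion grid fits the cap every clash-free state is
    returned; otherwise a seeded random pool is drawn from the grid and a
    maximum-dissimilarity (farthest-point RMSD) subset of ``max_n`` is
    kept, always including the reference conformation.
    """
    cfg = config or ConformerConfig()
    max_n = max_n if max_n is not None else cfg.max_conformers
    step = step_deg if step_deg is not None else cfg.step_deg
    driver = TorsionDriver(mol)
    nb = _nonbonded_pairs(mol)

    def clash_free(coords: np.ndarray) -> bool:
        return nb.size == 0 or _min_pair_distance(coords, nb) >= cfg.clash_distance

    if driver.n_torsions == 0:
        return ConformerSet(molecule=mol, conformers=[mol.coords.copy()])

    steps = int(round(360.0 / step))
    n_states = steps**driver.n_torsions
    conformers: list[np.ndarray] = []
    if n_states <= cfg.enumeration_limit:
        for state in itertools.product(range(steps), repeat=driver.n_torsions):
            coords = driver.apply(np.array(state, dtype=float) * step)
            if clash_free(coords):
                conformers.append(coords)
    else:
        rng = np.random.default_rng(
            (cfg.seed + zlib.crc32(mol.code.encode())) % 2**31
        )
        if clash_free(mol.coords):
            conformers.append(mol.coords.copy())
        target_pool = cfg.oversample * max_n
        attempts = 0
        while len(conformers) < target_pool and attempts < 20 * target_pool:
            attempts += 1
            state = rng.integers(0, steps, size=driver.n_torsions)
            coords = driver.apply(state.astype(float) * step)
            if clash_free(coords):
                conformers.append(coords)
    if len(conformers) > max_n:
        conformers = _max_dissimilar_subset(conformers, max_n)
    if not conformers:
        conformers = [mol.coords.copy()]  # reference is always available
    return ConformerSet(molecule=mol, conformers=conformers)


def _max_dissimilar_subset(
    conformers: list[np.ndarray], k: int
) -> list[np.ndarray]:
    """Greedy farthest-point selection on plain coordinate RMSD."""
    stack = np.stack(conformers)
    n = len(stack)
    chosen = [0]
    min_d = _rmsd_to(stack, stack[0])
    while len(chosen) < k:
        nxt = int(np.argmax(min_d))
        chosen.append(nxt)
        min_d = np.minimum(min_d, _rmsd_to(stack, stack[nxt]))
    return [conformers[i] for i in chosen]


def _rmsd_to(stack: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.sum((stack - ref) ** 2, axis=2), axis=1))


# ---------------------------------------------------------------------------
# BCUT descriptors and redundancy clustering

def bcut_descriptors(mol: Molecule) -> np.ndarray:
    """Four BCUT descriptors: extreme eigenvalues of the Burden matrix.

    Diagonal = atomic number; off-diagonal = 0.1 x bond order for bonded
    pairs, 0.001 otherwise.  Output is (lowest, 2nd lowest, 2nd highest,
    highest); coordinates play no role, so the descriptors are
    conformation-invariant.
    """
    matrix = burden_matrix_from_bonds(
        mol.n_atoms, mol.bonds, diagonal=mol.atomic_numbers()
    )
    return extreme_eigenvalues(matrix)


def cluster_ligands(
    mols: list[Molecule], k: int, seed: int = 0
) -> list[LigandGroup]:
    """Seeded k-means on BCUT descriptors; groups substructure-redundant
    ligands.  Each group's representative is its member of median size."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(mols):
        raise ParameterError(f"k={k} exceeds {len(mols)} molecules")
    x = np.array([bcut_descriptors(m) for m in mols])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(x)
    groups = []
    for label in range(k):
        members = [m for m, lab in zip(mols, km.labels_) if lab == label]
        if not members:
            continue
        members.sort(key=lambda m: (m.n_atoms, m.code))
        rep = members[(len(members) - 1) // 2]
        groups.append(
            LigandGroup(members=[m.code for m in members],
                        representative=rep.code)
        )
    return groups


# ---------------------------------------------------------------------------
# embedded mini-library

#: code, name, SMILES — common cryo/buffer compounds and endogenous ligands
_LIBRARY_SMILES: list[tuple[str, str, str]] = [
    ("SO4", "Sulfate ion", "OS(=O)(=O)O"),
    ("PO4", "Phosphate ion", "OP(=O)(O)O"),
    ("IMD", "Imidazole", "c1c[nH]cn1"),
    ("PGO", "S-1,2-propanediol", "CC(O)CO"),
    ("GOL", "Glycerol", "OCC(O)CO"),
    ("PYR", "Pyruvic acid", "CC(=O)C(=O)O"),
    ("DIO", "1,4-diethylene dioxide", "C1COCCO1"),
    ("PEG", "Di(hydroxyethyl)ether", "OCCOCCO"),
    ("MLI", "Malonate ion", "OC(=O)CC(=O)O"),
    ("IPH", "Phenol", "Oc1ccccc1"),
    ("MPD", "(4S)-2-methyl-2,4-pentanediol", "CC(O)CC(C)(C)O"),
    ("TRS", "Tris buffer", "OCC(N)(CO)CO"),
    ("DTT", "1,4-dithiothreitol", "SCC(O)C(O)CS"),
    ("MLT", "D-malate", "OC(=O)C(O)CC(=O)O"),
    ("POP", "Pyrophosphate", "OP(=O)(O)OP(=O)(O)O"),
    ("PGA", "2-phosphoglycolic acid", "OC(=O)COP(=O)(O)O"),
    ("TLA", "L-(+)-tartaric acid", "OC(=O)C(O)C(O)C(=O)O"),
    ("AKG", "2-oxoglutaric acid", "OC(=O)CCC(=O)C(=O)O"),
    ("ADE", "Adenine", "Nc1ncnc2[nH]cnc12"),
    ("PEP", "Phosphoenolpyruvate", "OC(=O)C(=C)OP(=O)(O)O"),
    ("TAM", "Tris(hydroxyethyl)aminomethane", "NC(CCO)(CCO)CCO"),
    ("ORO", "Orotic acid", "OC(=O)C1=CC(=O)NC(=O)N1"),
    ("CAM", "Camphor", "CC1(C)C2CCC1(C)C(=O)C2"),
    ("HC4", "para-coumaric acid", "OC(=O)C=Cc1ccc(O)cc1"),
    ("NHE", "2-(N-cyclohexylamino)ethanesulfonic acid",
     "OS(=O)(=O)CCNC1CCCCC1"),
    ("MES", "2-(N-morpholino)ethanesulfonic acid",
     "OS(=O)(=O)CCN1CCOCC1"),
    ("CIT", "Citric acid", "OC(=O)CC(O)(CC(=O)O)C(=O)O"),
    ("PG4", "Tetraethylene glycol", "OCCOCCOCCOCCO"),
    ("CXS", "3-cyclohexylamino-1-propanesulfonic acid",
     "OS(=O)(=O)CCCNC1CCCCC1"),
    ("BTB", "Bis-tris buffer", "OCCN(CCO)C(CO)(CO)CO"),
    ("EPE", "HEPES", "OCCN1CCN(CCS(=O)(=O)O)CC1"),
    ("PLP", "Pyridoxal-5'-phosphate", "Cc1ncc(COP(=O)(O)O)c(C=O)c1O"),
    ("1PE", "Pentaethylene glycol", "OCCOCCOCCOCCOCCO"),
    ("MYR", "Myristic acid", "CCCCCCCCCCCCCC(=O)O"),
    ("BTN", "Biotin", "OC(=O)CCCCC1SCC2NC(=O)NC12"),
    ("H4B", "5,6,7,8-tetrahydrobiopterin",
     "CC(O)C(O)C1CNc2nc(N)[nH]c(=O)c2N1"),
    ("B3P", "Bis-tris propane", "OCC(CO)(CO)NCCCNC(CO)(CO)CO"),
    ("P6G", "Hexaethylene glycol", "OCCOCCOCCOCCOCCOCCO"),
    ("ADN", "Adenosine", "Nc1ncnc2n(cnc12)C1OC(CO)C(O)C1O"),
    ("GSH", "Glutathione", "NC(CCC(=O)NC(CS)C(=O)NCC(=O)O)C(=O)O"),
    ("AMP", "Adenosine monophosphate",
     "Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)O)C(O)C1O"),
    ("5GP", "Guanosine 5'-monophosphate",
     "Nc1nc2n(cnc2c(=O)[nH]1)C1OC(COP(=O)(O)O)C(O)C1O"),
    ("THP", "Thymidine 3',5'-diphosphate",
     "Cc1cn(C2CC(OP(=O)(O)O)C(COP(=O)(O)O)O2)c(=O)[nH]c1=O"),
    ("ADP", "Adenosine 5'-diphosphate",
     "Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)OP(=O)(O)O)C(O)C1O"),
    ("ATP", "Adenosine 5'-triphosphate",
     "Nc1ncnc2n(cnc12)C1OC(COP(=O)(O)OP(=O)(O)OP(=O)(O)O)C(O)C1O"),
    ("NAD", "Nicotinamide adenine dinucleotide",
     "NC(=O)c1ccc[n+](C2OC(COP(=O)(O)OP(=O)(O)OCC3OC(n4cnc5c(N)ncnc54)"
     "C(O)C3O)C(O)C2O)c1"),
]

_LIBRARY_CACHE: list[Molecule] | None = None


def builtin_library() -> list[Molecule]:
    """The embedded mini-library of common crystallographic ligands.

    Covers cryoprotectants, buffers, PEG oligomers and nucleotide-like
    scaffolds from roughly 5 to 44 heavy atoms.  Coordinates are generated
    once per process from the embedded SMILES with a fixed seed; each call
    returns fresh copies.
    """
    global _LIBRARY_CACHE
    if _LIBRARY_CACHE is None:
        mols = []
        for code, name, smiles in _LIBRARY_SMILES:
            mols.append(read_molecule(smiles, fmt="smiles", code=code, name=name))
        _LIBRARY_CACHE = mols
    return [
        Molecule(
            code=m.code, name=m.name, elements=list(m.elements),
            coords=m.coords.copy(), bonds=list(m.bonds),
            rotatable=list(m.rotatable),
        )
        for m in _LIBRARY_CACHE
    ]


def write_sdf(mol: Molecule, path: str | Path, coords: np.ndarray | None = None) -> None:
    """Write a molecule (optionally with replacement coordinates) as SDF."""
    c = mol.coords if coords is None else np.asarray(coords, dtype=float)
    lines = [mol.code, "  blobid", "", ""]
    lines[3] = f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    for el, xyz in zip(mol.elements, c):
        lines.append(
            f"{xyz[0]:10.4f}{xyz[1]:10.4f}{xyz[2]:10.4f} {el:<3s} 0  0  0  0  0"
        )
    for i, j, order in mol.bonds:
        o = 4 if order == 1.5 else int(order)
        lines.append(f"{i + 1:3d}{j + 1:3d}{o:3d}  0")
    lines += ["M  END", "$$$$"]
    Path(path).write_text("\n".join(lines) + "\n")
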