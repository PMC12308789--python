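"""Molecule container, SMILES -> 3D construction, and XYZ file I/O.

A :class:`Molecule` is the unit every pipeline stage consumes and produces:
both the neutral input M and each protonated/deprotonated charge-state
geometry are Molecules.  Coordinates are Cartesian angstroms; bonds carry
fractional orders (1.5 for aromatic) when built from a SMILES, and order 1
when perceived from interatomic distances for XYZ input.
"""

from __future__ import annotations

import dataclasses
import math
import os

import numpy as np

from .elements import ATOMIC_MASS, atomic_mass, covalent_radius
from .errors import EmbeddingError, InputError, ParseError

# distance-based bond perception: bonded if r <= tolerance * (rcov_i + rcov_j)
BOND_PERCEPTION_TOLERANCE = 1.25

_XYZ_RECORD = "%-2s %12.6f %12.6f %12.6f"


@dataclasses.dataclass
class Molecule:
    """Element symbols + 3D coordinates + net formal charge + bond list.

    Parameters
    ----------
    name : str
        Text label carried through the pipeline and into output filenames.
    elements : list of str
        Ordered element symbols.
    coords : (n, 3) ndarray
        Cartesian coordinates in angstrom.
    formal_charge : int
        Net charge: 0 for a neutral input, +1/-1 for generated models.
    bonds : list of (int, int, float)
        ``(i, j, order)`` with ``i < j``; required for site perception.
    """

    name: str
    elements: list[str]
    coords: np.ndarray
    formal_charge: int = 0
    bonds: list[tuple[int, int, float]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise InputError(
                f"molecule '{self.name}': {len(self.elements)} elements but "
                f"coordinate array of shape {self.coords.shape}"
            )
        if self.coords.size and not np.all(np.isfinite(self.coords)):
            raise InputError(f"molecule '{self.name}': non-finite coordinates")
        if self.formal_charge not in (-1, 0, 1):
            raise InputError(
                f"molecule '{self.name}': formal charge {self.formal_charge} "
                "outside the supported {-1, 0, +1} range"
            )
        n = len(self.elements)
        norm = []
        for i, j, order in self.bonds:
            if i == j or not (0 <= i < n) or not (0 <= j < n):
                raise InputError(
                    f"molecule '{self.name}': invalid bond ({i}, {j}) for {n} atoms"
                )
            a, b = (i, j) if i < j else (j, i)
            norm.append((a, b, float(order)))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, index: int) -> list[tuple[int, float]]:
        """Indices bonded to ``index`` with the bond order of each link."""
        out = []
        for i, j, order in self.bonds:
            if i == index:
                out.append((j, order))
            elif j == index:
                out.append((i, order))
        return sorted(out)

    def valence(self, index: int) -> float:
        """Sum of bond orders at an atom (hydrogens count like any neighbor)."""
        return sum(order for _, order in self.neighbors(index))

    def copy(self, name: str | None = None) -> "Molecule":
        return Molecule(
            name=self.name if name is None else name,
            elements=list(self.elements),
            coords=self.coords.copy(),
            formal_charge=self.formal_charge,
            bonds=list(self.bonds),
        )

    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(el) for el in self.elements])


def center_of_mass(mol: Molecule) -> np.ndarray:
    """Mass-weighted mean position, angstrom."""
    if mol.n_atoms == 0:
        raise InputError("center of mass of an empty molecule is undefined")
    m = mol.masses()
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


def perceive_bonds(elements: list[str], coords: np.ndarray) -> list[tuple[int, int, float]]:
    """Single bonds wherever two atoms sit within 1.25x the sum of their
    covalent radii.  Deterministic; orders are all 1 (distances cannot
    distinguish bond multiplicity)."""
    n = len(elements)
    radii = np.array([covalent_radius(el) for el in elements])
    bonds: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = BOND_PERCEPTION_TOLERANCE * (radii[i] + radii[j])
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                bonds.append((i, j, 1.0))
    return bonds


def parse_smiles_to_3d(
    smiles: str,
    seed: int = 0,
    steps_per_atom: int = 10,
    name: str | None = None,
) -> Molecule:
    """Build a 3D-embedded neutral molecule from a SMILES string.

    Hydrogens are made explicit, coordinates come from a distance-geometry
    embedding, and the geometry is relaxed with the MMFF94 force field for
    ``max(200, steps_per_atom * n_atoms)`` steps — a floor that guarantees
    relaxation for tiny molecules while letting the budget grow with size
    and rotatable-bond count.  Deterministic for a fixed seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if steps_per_atom < 1:
        raise InputError("steps_per_atom must be >= 1")
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None or rdmol.GetNumAtoms() == 0:
        raise InputError(f"unparsable SMILES string: {smiles!r}")
    if Chem.GetFormalCharge(rdmol) != 0:
        raise InputError(
            f"SMILES {smiles!r} carries a net charge; the pipeline expects a "
            "neutral input and generates the charged models itself"
        )
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    conf_id = AllChem.EmbedMolecule(rdmol, params)
    if conf_id < 0:
        # retry with perturbed seeds before giving up
        for attempt in range(1, 6):
            params.randomSeed = (int(seed) + attempt * 7919) % (2**31 - 1)
            params.useRandomCoords = True
            conf_id = AllChem.EmbedMolecule(rdmol, params)
            if conf_id >= 0:
                break
        else:
            raise EmbeddingError(f"3D embedding failed for SMILES {smiles!r}")
    n = rdmol.GetNumAtoms()
    steps = max(200, steps_per_atom * n)
    try:
        AllChem.MMFFOptimizeMolecule(rdmol, maxIters=steps)
    except Exception:  # pragma: no cover - MMFF lacks params for rare atoms
        AllChem.UFFOptimizeMolecule(rdmol, maxIters=steps)
    conf = rdmol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(n)])
    elements = [a.GetSymbol() for a in rdmol.GetAtoms()]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
        for b in rdmol.GetBonds()
    ]
    return Molecule(
        name=name if name is not None else smiles,
        elements=elements,
        coords=coords,
        formal_charge=0,
        bonds=bonds,
    )


def read_xyz(path: str | os.PathLike) -> Molecule:
    """Read a standard XYZ file; bonds are perceived from covalent radii."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty XYZ file", line=1)
    try:
        n_declared = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"expected an atom count, got {lines[0]!r}", line=1) from None
    records = [ln for ln in lines[2:] if ln.strip()]
    if len(records) < n_declared:
        raise ParseError(
            f"header declares {n_declared} atoms but only "
            f"{len(records)} coordinate records follow",
            line=len(lines),
        )
    elements: list[str] = []
    coords: list[list[float]] = []
    for k in range(n_declared):
        lineno = 3 + k
        parts = records[k].split()
        if len(parts) < 4:
            raise ParseError(f"malformed record {records[k]!r}", line=lineno)
        el = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if el not in ATOMIC_MASS:
            raise ParseError(f"unknown element symbol {parts[0]!r}", line=lineno)
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(
                f"non-numeric coordinate in {records[k]!r}", line=lineno
            ) from None
        elements.append(el)
        coords.append(xyz)
    arr = np.array(coords).reshape(n_declared, 3)
    name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Molecule(
        name=name,
        elements=elements,
        coords=arr,
        formal_charge=0,
        bonds=perceive_bonds(elements, arr),
    )


def write_xyz(mol: Molecule, path: str | os.PathLike, comment: str = "") -> None:
    """Write standard XYZ with 6-decimal coordinates; refuses empty molecules."""
    if mol.n_atoms == 0:
        raise InputError("refusing to write a 0-atom XYZ file")
    comment = comment.replace("\n", " ")
    lines = ["%d" % mol.n_atoms, comment]
    for el, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(_XYZ_RECORD % (el, x, y, z))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    pa = a - a.mean(axis=0)
    pb = b - b.mean(axis=0)
    h = pa.T @ pb
    u, _, vt = np.linalg.svd(h)
    d = math.copysign(1.0, np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return float(np.sqrt(np.mean(np.sum((pa @ rot - pb) ** 2, axis=1))))
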