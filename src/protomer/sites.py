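"""Titratable-site perception and charge-state model generation.

For the [M+H]+ mode every nitrogen or oxygen that can still accept a proton
(total bond order below its neutral maximum, so quaternary/nitro N and
pyrrole-type aromatic N-H are excluded) yields one protonated model; for
[M-H]- every N-H or O-H group yields one deprotonated model.  Carbon and
"othergen" (P, S, Se) titration are out of scope — the energy model is
trained only on the N/O sites common in IM-MS experiments.

Sites that are equivalent under the molecular graph's automorphisms (the
two amine hydrogens of glycine, the two ortho carbons of phenol) collapse
to a single representative so downstream refinement never optimizes
redundant copies.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InputError, NoTitratableSitesError, ProtomerError
from .molecule import Molecule

PROTONATION = "protonation"
DEPROTONATION = "deprotonation"

MODE_LABELS = {PROTONATION: "[M+H]+", DEPROTONATION: "[M-H]-"}
# accept the ion-mode spellings users type
_MODE_ALIASES = {
    "protonation": PROTONATION,
    "[m+h]+": PROTONATION,
    "m+h": PROTONATION,
    "mh": PROTONATION,
    "positive": PROTONATION,
    "deprotonation": DEPROTONATION,
    "[m-h]-": DEPROTONATION,
    "m-h": DEPROTONATION,
    "negative": DEPROTONATION,
}

NH_BOND_LENGTH = 1.02  # angstrom, new proton on N
OH_BOND_LENGTH = 0.98  # angstrom, new proton on O


def normalize_mode(mode: str) -> str:
    key = mode.strip().lower().replace("−", "-").replace(" ", "")
    try:
        return _MODE_ALIASES[key]
    except KeyError:
        raise InputError(
            f"unknown ion mode {mode!r}; expected '[M+H]+' or '[M-H]-'"
        ) from None


@dataclasses.dataclass(frozen=True)
class TitratableSite:
    """An N or O atom eligible for proton gain/loss in one ion mode."""

    atom_index: int
    element: str
    mode: str
    acidic_h_index: int | None = None

    def __post_init__(self) -> None:
        if self.element not in ("N", "O"):
            raise InputError(
                f"titratable sites are limited to N and O, got {self.element!r}"
            )
        if self.mode == DEPROTONATION and self.acidic_h_index is None:
            raise InputError("deprotonation sites must name the acidic hydrogen")


@dataclasses.dataclass
class ChargeStateModel:
    """One protonated or deprotonated structure ("Z") with its rankings.

    ``initial_rank_r`` is the first-pass (regression) rank, ``final_rank_R``
    the post-refinement rank; both are 1-based with 1 = most stable.
    """

    parent_name: str
    mode: str
    cba_index: int
    geometry: Molecule
    predicted_re: float | None = None
    refined_energy: float | None = None
    refined_re: float | None = None
    initial_rank_r: int | None = None
    final_rank_R: int | None = None
    mole_fraction: float | None = None

    @property
    def cba_element(self) -> str:
        return self.geometry.elements[self.cba_index]

    @property
    def label(self) -> str:
        return f"{self.cba_element}{self.cba_index}"


def symmetry_classes(mol: Molecule) -> list[int]:
    """Graph-automorphism equivalence classes by iterative neighborhood
    refinement (Morgan-style).  Atoms with equal class labels are
    topologically interchangeable."""
    labels = [(mol.elements[i], round(mol.valence(i), 2)) for i in range(mol.n_atoms)]
    codes = _canonicalize(labels)
    for _ in range(mol.n_atoms):
        refined = [
            (codes[i], tuple(sorted((round(o, 2), codes[j]) for j, o in mol.neighbors(i))))
            for i in range(mol.n_atoms)
        ]
        new_codes = _canonicalize(refined)
        if new_codes == codes:
            break
        codes = new_codes
    return codes


def _canonicalize(labels: list) -> list[int]:
    order = {lab: k for k, lab in enumerate(sorted(set(labels), key=repr))}
    return [order[lab] for lab in labels]


def _is_nitro_nitrogen(mol: Molecule, index: int) -> bool:
    terminal_o = 0
    for j, _ in mol.neighbors(index):
        if mol.elements[j] == "O" and len(mol.neighbors(j)) == 1:
            terminal_o += 1
    return terminal_o >= 2


def find_titratable_sites(mol: Molecule, mode: str) -> list[TitratableSite]:
    """Enumerate N/O sites for one ion mode, in ascending atom index.

    Protonation keeps every N or O with lone-pair capacity: N with total
    bond order < 4 (rejecting quaternary N, nitro N and aromatic N-H whose
    lone pair sits in the pi system) and any O with total bond order <= 2.
    Deprotonation keeps every N-H / O-H group.  Symmetry-equivalent sites
    are collapsed to the lowest-index representative.
    """
    mode = normalize_mode(mode)
    if mol.formal_charge != 0:
        raise InputError("site perception expects the neutral input molecule")
    sites: list[TitratableSite] = []
    for i, el in enumerate(mol.elements):
        if el not in ("N", "O"):
            continue
        if mode == PROTONATION:
            valence = mol.valence(i)
            if el == "N":
                if valence >= 3.5 or _is_nitro_nitrogen(mol, i):
                    continue
            else:
                if valence > 2.1:
                    continue
            sites.append(TitratableSite(i, el, PROTONATION))
        else:
            h_neighbors = [j for j, _ in mol.neighbors(i) if mol.elements[j] == "H"]
            if h_neighbors:
                sites.append(TitratableSite(i, el, DEPROTONATION, min(h_neighbors)))
    return _collapse_equivalent(mol, sites)


def _collapse_equivalent(
    mol: Molecule, sites: list[TitratableSite]
) -> list[TitratableSite]:
    classes = symmetry_classes(mol)
    seen: set[int] = set()
    out = []
    for site in sites:  # already in ascending atom index
        cls = classes[site.atom_index]
        if cls in seen:
            continue
        seen.add(cls)
        out.append(site)
    return out


def place_proton(mol: Molecule, site: TitratableSite) -> Molecule:
    """Append a proton at the site atom, pointing away from its bonds.

    The new H sits 1.02 angstrom from N / 0.98 from O along the direction
    opposite the normalized sum of existing bond vectors — the exact length
    is immaterial because geometries are re-optimized downstream.  A
    geometrically buried site (direction norm < 1e-6) falls back to an
    arbitrary perpendicular direction.
    """
    if site.mode != PROTONATION:
        raise InputError("place_proton requires a protonation site")
    pos = mol.coords[site.atom_index]
    vec = np.zeros(3)
    for j, _ in mol.neighbors(site.atom_index):
        bond = mol.coords[j] - pos
        norm = np.linalg.norm(bond)
        if norm > 1e-8:
            vec += bond / norm
    if np.linalg.norm(vec) < 1e-6:
        direction = _any_perpendicular(mol, site.atom_index)
    else:
        direction = -vec / np.linalg.norm(vec)
    length = NH_BOND_LENGTH if site.element == "N" else OH_BOND_LENGTH
    new_h = pos + length * direction
    out = mol.copy()
    out.elements.append("H")
    out.coords = np.vstack([out.coords, new_h])
    out.bonds.append((site.atom_index, out.n_atoms - 1, 1.0))
    out.formal_charge = 1
    return Molecule(out.name, out.elements, out.coords, 1, out.bonds)


def _any_perpendicular(mol: Molecule, index: int) -> np.ndarray:
    neighbors = mol.neighbors(index)
    if neighbors:
        ref = mol.coords[neighbors[0][0]] - mol.coords[index]
    else:
        ref = np.array([1.0, 0.0, 0.0])
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, trial)) > 0.9 * np.linalg.norm(ref):
        trial = np.array([0.0, 1.0, 0.0])
    perp = np.cross(ref, trial)
    return perp / np.linalg.norm(perp)


def remove_proton(mol: Molecule, site: TitratableSite) -> Molecule:
    """Delete the acidic hydrogen; later atom indices shift down by one."""
    if site.mode != DEPROTONATION or site.acidic_h_index is None:
        raise InputError("remove_proton requires a deprotonation site")
    h = site.acidic_h_index
    bonded = any(
        {i, j} == {site.atom_index, h} for i, j, _ in mol.bonds
    )
    if not bonded or mol.elements[h] != "H":
        raise ProtomerError(
            f"internal consistency error: atom {h} is not a hydrogen bonded "
            f"to site atom {site.atom_index}"
        )

    def remap(idx: int) -> int:
        return idx - 1 if idx > h else idx

    elements = [el for k, el in enumerate(mol.elements) if k != h]
    coords = np.delete(mol.coords, h, axis=0)
    bonds = [
        (remap(i), remap(j), order)
        for i, j, order in mol.bonds
        if h not in (i, j)
    ]
    return Molecule(mol.name, elements, coords, -1, bonds)


def enumerate_models(mol: Molecule, mode: str) -> list[ChargeStateModel]:
    """One :class:`ChargeStateModel` per titratable site.

    Raises :class:`NoTitratableSitesError` when the molecule carries no
    eligible N/O site — such molecules are out of scope for this tool.
    """
    mode = normalize_mode(mode)
    sites = find_titratable_sites(mol, mode)
    if not sites:
        raise NoTitratableSitesError(
            f"no titratable sites: '{mol.name}' has no N/O site eligible for "
            f"{MODE_LABELS[mode]} modeling, so it is out of scope for this tool"
        )
    models = []
    for site in sites:
        if mode == PROTONATION:
            geom = place_proton(mol, site)
            cba = site.atom_index
        else:
            geom = remove_proton(mol, site)
            cba = site.atom_index - (1 if site.acidic_h_index < site.atom_index else 0)
        geom.name = f"{mol.name}_{geom.elements[cba]}{cba}"
        models.append(
            ChargeStateModel(
                parent_name=mol.name,
                mode=MODE_LABELS[mode],
                cba_index=cba,
                geometry=geom,
            )
        )
    return models
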