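"""The 10-descriptor feature vector for one charge-state model.

The descriptors tether a charged 3D geometry to steric/electronic context:
polarizability of the charge-bearing atom (CBA); the distance triangle
between the CBA, the center of mass (COM) and the center of
electronegativity (COE = electronegativity-weighted mean position); the
interaction angle spanned at the COE between the COM and CBA directions;
molecular surface area; and the O / N / halogen / "othergen" (S, P, Se)
element counts.  All ten are invariant under rigid motion, so the learned
energy model sees conformation, not pose.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .elements import (
    HALOGENS,
    OTHERGENS,
    electronegativity,
    polarizability,
    vdw_radius,
)
from .errors import InputError
from .molecule import Molecule, center_of_mass
from .sites import ChargeStateModel

FEATURE_NAMES: tuple[str, ...] = (
    "cba_polarizability",
    "dist_cba_com",
    "dist_cba_coe",
    "dist_com_coe",
    "interaction_angle",
    "msa",
    "n_oxygen",
    "n_nitrogen",
    "n_halogen",
    "n_othergen",
)

PROBE_RADIUS = 1.4  # angstrom, water-sized probe
N_SURFACE_POINTS = 3840  # dots per atom in the Shrake-Rupley quadrature
DEGENERACY_EPS = 1e-8  # angstrom, ray-length floor for the interaction angle


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    cba_polarizability: float  # cubic angstrom
    dist_cba_com: float  # angstrom
    dist_cba_coe: float  # angstrom
    dist_com_coe: float  # angstrom
    interaction_angle: float  # degrees in [0, 180]
    msa: float  # square angstrom
    n_oxygen: int
    n_nitrogen: int
    n_halogen: int
    n_othergen: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in FEATURE_NAMES}


def compute_coe(mol: Molecule) -> np.ndarray:
    """Center of electronegativity: sum_i e_i r_i / sum_i e_i (Pauling)."""
    if mol.n_atoms == 0:
        raise InputError("COE of an empty molecule is undefined")
    weights = np.array([electronegativity(el) for el in mol.elements])
    return (weights[:, None] * mol.coords).sum(axis=0) / weights.sum()


def interaction_angle(
    com: np.ndarray,
    coe: np.ndarray,
    cba: np.ndarray,
    with_flag: bool = False,
):
    """Angle (degrees) at the COE vertex between the COE->COM and COE->CBA
    rays.  Degenerate geometry — either ray shorter than 1e-8 angstrom —
    returns 0 and, when ``with_flag`` is set, a degeneracy flag."""
    a = np.asarray(com, dtype=float) - np.asarray(coe, dtype=float)
    b = np.asarray(cba, dtype=float) - np.asarray(coe, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < DEGENERACY_EPS or nb < DEGENERACY_EPS:
        return (0.0, True) if with_flag else 0.0
    # atan2 form: well-conditioned at 0 and 180 deg, unlike acos
    angle = math.degrees(
        math.atan2(float(np.linalg.norm(np.cross(a, b))), float(np.dot(a, b)))
    )
    return (angle, False) if with_flag else angle


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere quadrature (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _detune(points: np.ndarray) -> np.ndarray:
    """Fixed rotation moving the template poles off the frame axes, so the
    spiral's structured spacing never lines up with an occlusion boundary
    centered on a bonded neighbor."""
    a, b = 0.6154797086703873, 1.2341234123412341  # arbitrary fixed angles
    ra = np.array(
        [[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]]
    )
    rb = np.array(
        [[1, 0, 0], [0, math.cos(b), -math.sin(b)], [0, math.sin(b), math.cos(b)]]
    )
    return points @ (ra @ rb).T


_SPHERE_TEMPLATE = _detune(_fibonacci_sphere(N_SURFACE_POINTS))


def _local_frame(coords: np.ndarray, i: int) -> np.ndarray:
    """Orthonormal frame anchored to atom ``i``'s molecular environment.

    Axes are built from the directions to the nearest other atoms, chosen
    deterministically by (distance, index).  Distances and indices are
    rigid-motion invariants, so the same reference atoms are picked for any
    pose and the frame co-rotates exactly with the molecule — which makes
    the dot-sampled surface area below a true rigid-motion invariant
    without relying on principal axes (unstable for near-symmetric tops).
    """
    n = len(coords)
    if n == 1:
        return np.eye(3)
    order = sorted(
        (j for j in range(n) if j != i),
        key=lambda j: (float(np.linalg.norm(coords[j] - coords[i])), j),
    )
    u = coords[order[0]] - coords[i]
    u = u / np.linalg.norm(u)
    v = None
    for j in order[1:]:
        w = coords[j] - coords[i]
        w = w - np.dot(w, u) * u
        norm = np.linalg.norm(w)
        if norm > 1e-6:
            v = w / norm
            break
    if v is None:
        # collinear environment: occlusion by on-axis spheres is invariant
        # under rotation about u, so any perpendicular completes the frame
        trial = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = np.cross(u, trial)
        v /= np.linalg.norm(v)
    return np.column_stack([u, v, np.cross(u, v)])


def molecular_surface_area(mol: Molecule, probe_radius: float = PROBE_RADIUS) -> float:
    """Solvent-accessible surface area by Shrake-Rupley dot sampling.

    Each atom's sphere (van der Waals radius + probe) carries a 960-point
    deterministic quadrature oriented by the atom's local environment
    frame, so the value is invariant under rigid motion of the input
    coordinates.  A dot survives if it lies outside every other augmented
    sphere.
    """
    if mol.n_atoms == 0:
        raise InputError("surface area of an empty molecule is undefined")
    radii = np.array([vdw_radius(el) for el in mol.elements]) + probe_radius
    coords = mol.coords
    total = 0.0
    for i in range(mol.n_atoms):
        frame = _local_frame(coords, i)
        dots = coords[i] + radii[i] * (_SPHERE_TEMPLATE @ frame.T)
        accessible = np.ones(len(dots), dtype=bool)
        for j in range(mol.n_atoms):
            if j == i:
                continue
            if np.linalg.norm(coords[i] - coords[j]) >= radii[i] + radii[j]:
                continue
            d2 = ((dots - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > radii[j] ** 2
        total += (
            4.0 * math.pi * radii[i] ** 2 * accessible.sum() / N_SURFACE_POINTS
        )
    return float(total)


def element_counts(mol: Molecule) -> tuple[int, int, int, int]:
    """(n_oxygen, n_nitrogen, n_halogen, n_othergen) exact counts."""
    n_o = sum(el == "O" for el in mol.elements)
    n_n = sum(el == "N" for el in mol.elements)
    n_hal = sum(el in HALOGENS for el in mol.elements)
    n_other = sum(el in OTHERGENS for el in mol.elements)
    return n_o, n_n, n_hal, n_other


def cba_polarizability(element: str) -> float:
    """Static dipole polarizability of the charge-bearing atom, cubic
    angstrom, from the snapshotted table."""
    return polarizability(element)


def featurize(model: ChargeStateModel) -> FeatureVector:
    """All 10 descriptors of one charge-state model's charged geometry."""
    mol = model.geometry
    com = center_of_mass(mol)
    coe = compute_coe(mol)
    cba = mol.coords[model.cba_index]
    n_o, n_n, n_hal, n_other = element_counts(mol)
    return FeatureVector(
        cba_polarizability=cba_polarizability(model.cba_element),
        dist_cba_com=float(np.linalg.norm(cba - com)),
        dist_cba_coe=float(np.linalg.norm(cba - coe)),
        dist_com_coe=float(np.linalg.norm(com - coe)),
        interaction_angle=interaction_angle(com, coe, cba),
        msa=molecular_surface_area(mol),
        n_oxygen=n_o,
        n_nitrogen=n_n,
        n_halogen=n_hal,
        n_othergen=n_other,
    )
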