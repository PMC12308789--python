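"""Second-pass screen: surrogate substitution, short "soft" geometry
optimization under a pluggable potential, final reranking, and Boltzmann
mole fractions.

The optimization is deliberately shallow (50 minimizer steps by default):
enough to relax the placed proton and compare models on a common energy
footing, short enough to avoid structural artifacts and keep per-model
cost low.  Potentials with a restricted element set (the bundled
neural-network backend covers H, C, N, O, F, Cl, S) are extended by
surrogacy: Br/I are optimized as Cl and P/Se as S, then switched back —
the intermediate geometry, not the exact element, is what the reranking
needs.
"""

from __future__ import annotations

import abc
import dataclasses
import math

import numpy as np

from .elements import covalent_radius, electronegativity
from .errors import (
    ConfigurationError,
    InputError,
    OptimizationError,
    ProtomerError,
    UnsupportedElementError,
)
from .molecule import Molecule
from .sites import ChargeStateModel

GAS_CONSTANT_KCAL = 1.98720425864e-3  # kcal/(mol K)
DEFAULT_TEMPERATURE = 298.15  # K
DEFAULT_MAX_STEPS = 50

# element -> closest supported stand-in for restricted potentials
SUBSTITUTION_RULES: dict[str, str] = {"Br": "Cl", "I": "Cl", "P": "S", "Se": "S"}

# convergence threshold on the max force component, kcal/(mol A)
# (about 0.05 eV/A)
FORCE_CONVERGENCE = 1.15


@dataclasses.dataclass(frozen=True)
class SubstitutionMap:
    """Record of element swaps so they can be reversed after optimization."""

    entries: tuple[tuple[int, str, str], ...]  # (index, original, surrogate)

    def __len__(self) -> int:
        return len(self.entries)


class PotentialBackend(abc.ABC):
    """Contract every refinement potential fulfils.

    ``minimize`` must be deterministic on fixed input and must never return
    an energy above the input geometry's single-point energy (monotone
    descent); energies are kcal/mol at this interface regardless of the
    backend's native units.
    """

    name: str = "base"
    supported_elements: frozenset[str] = frozenset()

    @abc.abstractmethod
    def energy(self, mol: Molecule) -> float:
        """Single-point energy, kcal/mol."""

    @abc.abstractmethod
    def minimize(self, mol: Molecule, max_steps: int) -> tuple[Molecule, float]:
        """Locally relax the geometry for at most ``max_steps`` iterations."""


class _GradientDescentMixin:
    """Monotone steepest-descent minimizer with an adaptive step size.

    Each iteration takes one trial step along the force; an uphill trial is
    rejected and the step halved, a downhill one accepted and the step
    grown.  The best geometry seen is returned, which guarantees the
    descent contract, and iteration stops early once the largest force
    component drops below the convergence threshold.
    """

    initial_step = 0.05  # angstrom along the normalized force

    def minimize(self, mol: Molecule, max_steps: int) -> tuple[Molecule, float]:
        coords = mol.coords.copy()
        energy = self._checked_energy(mol, coords)
        best_coords, best_energy = coords.copy(), energy
        step = self.initial_step
        for _ in range(max_steps):
            grad = self._gradient(mol, coords)
            fmax = float(np.abs(grad).max())
            if fmax < FORCE_CONVERGENCE:
                break
            direction = -grad / max(fmax, 1e-12)
            trial = coords + step * direction
            trial_energy = self._checked_energy(mol, trial)
            if trial_energy < energy:
                coords, energy = trial, trial_energy
                step = min(step * 1.2, 0.2)
                if energy < best_energy:
                    best_coords, best_energy = coords.copy(), energy
            else:
                step = max(step * 0.5, 1e-6)
        out = mol.copy()
        out.coords = best_coords
        return out, best_energy

    def _checked_energy(self, mol: Molecule, coords: np.ndarray) -> float:
        probe = mol.copy()
        probe.coords = coords
        e = self.energy(probe)
        if not math.isfinite(e):
            raise OptimizationError(
                f"backend '{self.name}' returned a non-finite energy for "
                f"'{mol.name}'"
            )
        return e

    def _gradient(self, mol: Molecule, coords: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class ToyBackend(_GradientDescentMixin, PotentialBackend):
    """Deterministic classical pair potential for tests and demos.

    Energy terms (kcal/mol): harmonic bond stretches with equilibrium
    lengths from covalent radii, a short-range exponential repulsion
    between non-bonded atoms, and a screened Coulomb term with partial
    charges proportional to each atom's electronegativity offset from the
    molecular mean.  It is a real potential with analytic gradients — not
    a physical one — and its element coverage mirrors the neural-network
    backend so surrogate substitution is exercised identically.
    """

    name = "toy"
    supported_elements = frozenset({"H", "C", "N", "O", "F", "Cl", "S"})

    bond_k = 600.0  # kcal/(mol A^2)
    repulsion_a = 500.0  # kcal/mol
    repulsion_rho = 0.35  # angstrom
    coulomb_k = 332.06  # kcal A / (mol e^2)
    charge_scale = 0.2  # e per Pauling unit of electronegativity offset

    def _terms(self, mol: Molecule, coords: np.ndarray):
        n = mol.n_atoms
        chi = np.array([electronegativity(el) for el in mol.elements])
        charges = self.charge_scale * (chi - chi.mean())
        bonded = {(i, j) for i, j, _ in mol.bonds}
        r0 = {
            (i, j): covalent_radius(mol.elements[i]) + covalent_radius(mol.elements[j])
            for i, j in bonded
        }
        return n, charges, bonded, r0

    def energy(self, mol: Molecule) -> float:
        coords = mol.coords
        n, charges, bonded, r0 = self._terms(mol, coords)
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if (i, j) in bonded:
                    e += 0.5 * self.bond_k * (d - r0[(i, j)]) ** 2
                else:
                    e += self.repulsion_a * math.exp(-d / self.repulsion_rho)
                    e += self.coulomb_k * charges[i] * charges[j] / max(d, 0.1)
        return e

    def _gradient(self, mol: Molecule, coords: np.ndarray) -> np.ndarray:
        n, charges, bonded, r0 = self._terms(mol, coords)
        grad = np.zeros_like(coords)
        for i in range(n):
            for j in range(i + 1, n):
                rij = coords[i] - coords[j]
                d = float(np.linalg.norm(rij))
                if d < 1e-9:
                    continue
                unit = rij / d
                if (i, j) in bonded:
                    dV = self.bond_k * (d - r0[(i, j)])
                else:
                    dV = -self.repulsion_a / self.repulsion_rho * math.exp(
                        -d / self.repulsion_rho
                    )
                    if d > 0.1:
                        dV += -self.coulomb_k * charges[i] * charges[j] / d**2
                grad[i] += dV * unit
                grad[j] -= dV * unit
        return grad


class ANI2xBackend(_GradientDescentMixin, PotentialBackend):
    """ANI-2x neural-network potential (optional; needs torchani)."""

    name = "ani2x"
    supported_elements = frozenset({"H", "C", "N", "O", "F", "Cl", "S"})

    _HARTREE_TO_KCAL = 627.509474

    def __init__(self):  # pragma: no cover - optional heavy dependency
        try:
            import torch
            import torchani
        except ImportError:
            raise ConfigurationError(
                "the 'ani2x' backend needs the optional torchani dependency "
                "(pip install protomer[ani]); the 'toy' backend has no "
                "external requirements"
            ) from None
        self._torch = torch
        self._model = torchani.models.ANI2x(periodic_table_index=False)
        self._species_order = {el: k for k, el in enumerate(
            ("H", "C", "N", "O", "S", "F", "Cl"))}

    def _tensors(self, mol, coords):  # pragma: no cover
        torch = self._torch
        species = torch.tensor(
            [[self._species_order[el] for el in mol.elements]], dtype=torch.long
        )
        xyz = torch.tensor(coords[None], dtype=torch.float64, requires_grad=True)
        return species, xyz

    def energy(self, mol: Molecule) -> float:  # pragma: no cover
        species, xyz = self._tensors(mol, mol.coords)
        e = self._model((species, xyz)).energies
        return float(e.item()) * self._HARTREE_TO_KCAL

    def _gradient(self, mol, coords):  # pragma: no cover
        species, xyz = self._tensors(mol, coords)
        e = self._model((species, xyz)).energies
        grad = self._torch.autograd.grad(e.sum(), xyz)[0]
        return grad.detach().numpy()[0] * self._HARTREE_TO_KCAL


_BACKENDS = {"toy": ToyBackend, "ani2x": ANI2xBackend}


def get_backend(name: str) -> PotentialBackend:
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown potential backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None
    return cls()


def surrogate_substitute(
    mol: Molecule, supported: frozenset[str] | set[str]
) -> tuple[Molecule, SubstitutionMap]:
    """Swap unsupported elements for their closest supported stand-ins
    (Br/I -> Cl, P/Se -> S); geometry is untouched."""
    entries = []
    elements = list(mol.elements)
    for idx, el in enumerate(elements):
        if el in supported:
            continue
        surrogate = SUBSTITUTION_RULES.get(el)
        if surrogate is None or surrogate not in supported:
            raise UnsupportedElementError(
                f"element '{el}' (atom {idx}) is neither supported by the "
                "potential nor covered by a surrogate rule"
            )
        elements[idx] = surrogate
        entries.append((idx, el, surrogate))
    out = Molecule(mol.name, elements, mol.coords.copy(), mol.formal_charge, list(mol.bonds))
    return out, SubstitutionMap(tuple(entries))


def restore_substitutions(mol: Molecule, submap: SubstitutionMap) -> Molecule:
    """Put original element symbols back, keeping optimized coordinates."""
    elements = list(mol.elements)
    for idx, original, surrogate in submap.entries:
        if idx >= len(elements):
            raise ProtomerError(
                f"substitution index {idx} out of range for {len(elements)} atoms"
            )
        if elements[idx] != surrogate:
            raise ProtomerError(
                f"atom {idx} is {elements[idx]!r}, expected surrogate {surrogate!r}"
            )
        elements[idx] = original
    return Molecule(mol.name, elements, mol.coords.copy(), mol.formal_charge, list(mol.bonds))


def soft_optimize(
    mol: Molecule,
    backend: PotentialBackend,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[Molecule, float]:
    """Short local relaxation; returns (geometry, energy kcal/mol).

    ``max_steps=0`` returns the input with its single-point energy.  The
    descent contract is enforced here as well: the result never has a
    higher energy than the input geometry.
    """
    if max_steps < 0:
        raise InputError("max_steps must be >= 0")
    unsupported = {el for el in mol.elements if el not in backend.supported_elements}
    if unsupported:
        raise UnsupportedElementError(
            f"backend '{backend.name}' does not support {sorted(unsupported)}; "
            "run surrogate_substitute first"
        )
    start_energy = backend.energy(mol)
    if not math.isfinite(start_energy):
        raise OptimizationError(
            f"backend '{backend.name}' returned a non-finite energy for '{mol.name}'"
        )
    if max_steps == 0:
        return mol.copy(), float(start_energy)
    optimized, energy = backend.minimize(mol, max_steps)
    if not math.isfinite(energy):
        raise OptimizationError(
            f"backend '{backend.name}' minimization diverged for '{mol.name}'"
        )
    if energy > start_energy:
        return mol.copy(), float(start_energy)
    return optimized, float(energy)


def final_rank(models: list[ChargeStateModel]) -> list[ChargeStateModel]:
    """Rerank by refined energy: RE = E - min(E), Rank 1 = lowest.

    Ties go to the better (lower) initial rank.  The Rank-1 model is the
    assigned major equilibrium charge state.
    """
    if not models:
        raise InputError("no models to rank")
    for m in models:
        if m.refined_energy is None:
            raise InputError(f"model {m.label} has no refined energy")
    e_min = min(m.refined_energy for m in models)
    for m in models:
        m.refined_re = float(m.refined_energy - e_min)
    ranked = sorted(
        models, key=lambda m: (m.refined_re, m.initial_rank_r or 0, m.cba_index)
    )
    for rank, m in enumerate(ranked, start=1):
        m.final_rank_R = rank
    return ranked


def mole_fractions(
    relative_energies: list[float], temperature: float = DEFAULT_TEMPERATURE
) -> list[float]:
    """Boltzmann populations x_i = exp(-RE_i/RT) / sum_j exp(-RE_j/RT)."""
    if len(relative_energies) == 0:
        raise InputError("mole fractions of an empty ensemble are undefined")
    if temperature <= 0:
        raise InputError("temperature must be positive")
    res = np.asarray(relative_energies, dtype=float)
    if res.min() < -1e-9:
        raise InputError("relative energies must be >= 0")
    weights = np.exp(-res / (GAS_CONSTANT_KCAL * temperature))
    return list(weights / weights.sum())
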