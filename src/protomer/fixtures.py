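"""Deterministic toy molecules, hand-verified site tables, and a synthetic
training-table generator.

Everything the test suite and the demos need is generated here with no
download: a library of twelve frozen small-molecule geometries spanning
the pipeline's chemistry (amines, carboxylic acids, aromatic N, an S
heterocycle, a bromoarene, and ethane as a no-site negative control), the
expected titratable-site assignments for each, and a generator of labeled
feature tables with a planted, recoverable energy signal standing in for
a quantum-chemistry-labeled training set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ._toy_data import TOY_DATA
from .errors import InputError
from .features import FEATURE_NAMES
from .molecule import Molecule
from .ranker import TrainingTable

# Default planted signal: relative energy rises with CBA-COE distance at
# 3 kcal/mol per angstrom over a 0-10 A span (30 kcal/mol signal range),
# observed through 10%-of-range Gaussian noise (3 kcal/mol).
DEFAULT_PLANTED_WEIGHTS = {"dist_cba_coe": 3.0}
DEFAULT_NOISE_SD = 3.0

# descriptor sampling spans chosen to mimic plausible physical ranges
_FEATURE_RANGES = {
    "cba_polarizability": (0.5, 4.0),  # cubic angstrom
    "dist_cba_com": (0.0, 10.0),  # angstrom
    "dist_cba_coe": (0.0, 10.0),
    "dist_com_coe": (0.0, 10.0),
    "interaction_angle": (0.0, 180.0),  # degrees
    "msa": (50.0, 800.0),  # square angstrom
}
_COUNT_FEATURES = ("n_oxygen", "n_nitrogen", "n_halogen", "n_othergen")
_MAX_COUNT = 6


def toy_library() -> dict[str, Molecule]:
    """Name -> Molecule for the twelve frozen fixture structures."""
    out = {}
    for name, data in TOY_DATA.items():
        out[name] = Molecule(
            name=name,
            elements=list(data["elements"]),
            coords=np.array(data["coords"], dtype=float),
            formal_charge=0,
            bonds=[tuple(b) for b in data["bonds"]],
        )
    return out


def expected_sites() -> dict[tuple[str, str], list[dict]]:
    """Hand-verified titratable-site ground truth, (name, mode) keyed.

    Each descriptor gives the site atom's index and element, plus the
    acidic hydrogen index for deprotonation sites.  Verified by manual
    inspection of the frozen structures: carbonyl and hydroxyl oxygens are
    distinct sites, symmetry-equivalent hydrogens collapse to one,
    pyrrole-type aromatic N-H is not protonatable (its lone pair is in the
    pi system), and S-H / C-H groups are never titratable here.
    """
    P, D = "protonation", "deprotonation"

    def site(idx, el, h=None):
        d = {"atom_index": idx, "element": el}
        if h is not None:
            d["acidic_h_index"] = h
        return d

    return {
        ("water", P): [site(0, "O")],
        ("water", D): [site(0, "O", 1)],
        ("ammonia", P): [site(0, "N")],
        ("ammonia", D): [site(0, "N", 1)],
        ("pyridine", P): [site(3, "N")],  # ring N; no O-H/N-H to lose
        ("pyridine", D): [],
        ("acetic_acid", P): [site(2, "O"), site(3, "O")],  # C=O and O-H
        ("acetic_acid", D): [site(3, "O", 7)],  # carboxyl O-H
        ("glycine", P): [site(0, "N"), site(3, "O"), site(4, "O")],
        ("glycine", D): [site(0, "N", 5), site(4, "O", 9)],
        ("ethanolamine", P): [site(0, "N"), site(3, "O")],
        ("ethanolamine", D): [site(0, "N", 4), site(3, "O", 10)],
        ("thiolane_acetic_acid", P): [site(0, "O"), site(2, "O")],  # S not titratable
        ("thiolane_acetic_acid", D): [site(0, "O", 9)],
        ("bromoaminophenol", P): [site(0, "N"), site(8, "O")],
        ("bromoaminophenol", D): [site(0, "N", 9), site(8, "O", 14)],
        ("cysteine", P): [site(0, "N"), site(5, "O"), site(6, "O")],
        ("cysteine", D): [site(0, "N", 7), site(6, "O", 13)],  # S-H excluded
        ("imidazole", P): [site(4, "N")],  # pyridine-type N only
        ("imidazole", D): [site(2, "N", 7)],  # the N-H
        ("ethane", P): [],
        ("ethane", D): [],
        ("formamide", P): [site(0, "N"), site(2, "O")],  # amide N is kept
        ("formamide", D): [site(0, "N", 3)],
    }


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic labeled training table.

    ``planted_weights`` maps feature names to linear energy coefficients;
    the raw energy of a model is the weighted feature sum plus Gaussian
    noise of ``noise_sd`` kcal/mol, and labels are re-zeroed per system.
    """

    n_systems: int = 200
    models_per_system: tuple[int, int] = (3, 8)
    planted_weights: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PLANTED_WEIGHTS)
    )
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    extra_noise_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not any(w != 0 for w in self.planted_weights.values()):
            raise InputError("at least one planted weight must be nonzero")
        if self.models_per_system[0] < 1 or (
            self.models_per_system[1] < self.models_per_system[0]
        ):
            raise InputError("models_per_system must be a valid (lo, hi) range")
        unknown = set(self.planted_weights) - set(FEATURE_NAMES)
        if unknown - set(self.extra_noise_features):
            raise InputError(f"planted weights name unknown features: {unknown}")


def synthetic_training_table(
    spec: SyntheticSpec, return_truth: bool = False
) -> TrainingTable | tuple[TrainingTable, np.ndarray]:
    """Draw a reproducible training table with a planted linear signal.

    Per system, ``models_per_system`` rows are drawn with features sampled
    uniformly over physically plausible spans; raw energies are the planted
    weighted sum plus N(0, noise_sd); re_label is raw minus the per-system
    minimum so every system's best model sits at exactly 0 kcal/mol.
    Columns named in ``extra_noise_features`` are appended as pure U(0,1)
    noise carrying no energy signal (useful for importance checks).

    With ``return_truth`` the noiseless per-system relative energies (the
    ground truth the noisy labels observe) are returned alongside, for
    recovery checks; the truth never enters the table itself.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.models_per_system
    rows = []
    truths = []
    for sysno in range(spec.n_systems):
        n_models = int(rng.integers(lo, hi + 1))
        block: dict[str, np.ndarray] = {}
        for name, (a, b) in _FEATURE_RANGES.items():
            block[name] = rng.uniform(a, b, size=n_models)
        for name in _COUNT_FEATURES:
            block[name] = rng.integers(0, _MAX_COUNT + 1, size=n_models).astype(float)
        for name in spec.extra_noise_features:
            block[name] = rng.uniform(0.0, 1.0, size=n_models)
        signal = np.zeros(n_models)
        for name, w in spec.planted_weights.items():
            signal += w * block[name]
        raw = signal + rng.normal(0.0, spec.noise_sd, size=n_models)
        block["re_label"] = raw - raw.min()
        block["system_id"] = np.array([f"sys{sysno:04d}"] * n_models, dtype=object)
        rows.append(pd.DataFrame(block))
        truths.append(signal - signal.min())
    frame = pd.concat(rows, ignore_index=True)
    ordered = [*FEATURE_NAMES, *spec.extra_noise_features, "re_label", "system_id"]
    table = TrainingTable(frame[ordered])
    if return_truth:
        return table, np.concatenate(truths)
    return table
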