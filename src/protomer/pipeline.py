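"""End-to-end orchestration: input -> enumerate -> rank -> prune -> refine
-> final ranking -> report.

``run`` takes a SMILES string or an XYZ path plus a :class:`PipelineConfig`
and returns a :class:`JobReport`; results (one XYZ per surviving model, a
human-readable summary and a machine-readable JSON sidecar) land under
``<output_root>/completed/<molecule name>/``.  The sidecar carries no
timestamps, so seeded reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import re as _re
import time
import zipfile

from .errors import ProtomerError, StageError
from .molecule import Molecule, parse_smiles_to_3d, read_xyz, write_xyz
from .ranker import (
    RankerModel,
    SelectionStats,
    acceptance_capacity,
    load_ranker,
    predict_and_rank,
    select_models,
)
from .refinement import (
    DEFAULT_MAX_STEPS,
    DEFAULT_TEMPERATURE,
    final_rank,
    get_backend,
    mole_fractions,
    restore_substitutions,
    soft_optimize,
    surrogate_substitute,
)
from .sites import enumerate_models, normalize_mode, MODE_LABELS

logger = logging.getLogger("protomer")

_REPORT_JSON = "report.json"
_REPORT_TXT = "report.txt"


@dataclasses.dataclass
class PipelineConfig:
    mode: str = "[M+H]+"
    seed: int = 0
    backend: str = "toy"
    max_steps: int = DEFAULT_MAX_STEPS
    temperature: float = DEFAULT_TEMPERATURE
    ranker_path: str | None = None
    output_root: str = "."
    zip_output: bool = False
    molecule_name: str | None = None
    steps_per_atom: int = 10

    def __post_init__(self) -> None:
        self.mode = normalize_mode(self.mode)
        if self.max_steps < 0:
            raise ProtomerError("max_steps must be >= 0")


@dataclasses.dataclass
class JobReport:
    """Per-model results plus selection stats and provenance."""

    molecule_name: str
    mode: str
    records: list[dict]
    capacity: float
    n_enumerated: int
    n_forwarded: int
    selection: dict
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "JobReport":
        return cls(**json.loads(text))


def _sanitize_name(raw: str) -> str:
    return _re.sub(r"[^A-Za-z0-9_.-]+", "_", raw).strip("_") or "molecule"


def _molecule_name(source: str, mol: Molecule, config: PipelineConfig) -> str:
    if config.molecule_name:
        return _sanitize_name(config.molecule_name)
    if source.lower().endswith(".xyz"):
        return _sanitize_name(os.path.splitext(os.path.basename(source))[0])
    digest = hashlib.sha256(source.encode()).hexdigest()[:10]
    return _sanitize_name(f"mol_{digest}")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs (%s)", name, dt, exc)
                if isinstance(exc, ProtomerError) and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run(
    source: str,
    config: PipelineConfig,
    ranker: RankerModel | None = None,
) -> JobReport:
    """Execute the full pipeline on one molecule and write its outputs.

    ``source`` is a SMILES string or a path to an XYZ file.  A trained
    ranker must be supplied either directly or through
    ``config.ranker_path``.  Raises a user-facing error (wrapped with the
    failing stage's name) before creating the output directory, so failed
    jobs leave nothing behind.
    """
    if ranker is None:
        if config.ranker_path is None:
            raise ProtomerError(
                "no ranker: pass a RankerModel or set config.ranker_path"
            )
        ranker = load_ranker(config.ranker_path)

    with _stage("build"):
        if source.lower().endswith(".xyz") or os.path.exists(source):
            mol = read_xyz(source)
        else:
            mol = parse_smiles_to_3d(
                source, seed=config.seed, steps_per_atom=config.steps_per_atom
            )
    name = _molecule_name(source, mol, config)
    mol.name = name

    with _stage("enumerate"):
        models = enumerate_models(mol, config.mode)
    with _stage("rank"):
        ranked = predict_and_rank(ranker, models)
        stats = acceptance_capacity(
            ranker.training_rmse, [m.predicted_re for m in ranked]
        )
        forwarded = select_models(ranked, stats)
    backend = get_backend(config.backend)
    with _stage("refine"):
        for model in forwarded:
            substituted, submap = surrogate_substitute(
                model.geometry, backend.supported_elements
            )
            t0 = time.perf_counter()
            optimized, energy = soft_optimize(substituted, backend, config.max_steps)
            logger.info(
                "model %s: refined in %.2fs (E = %.3f kcal/mol)",
                model.label, time.perf_counter() - t0, energy,
            )
            model.geometry = restore_substitutions(optimized, submap)
            model.refined_energy = energy
    with _stage("final_rank"):
        final = final_rank(forwarded)
        fractions = mole_fractions(
            [m.refined_re for m in final], temperature=config.temperature
        )
        for model, x in zip(final, fractions):
            model.mole_fraction = float(x)

    records = [
        {
            "model_id": m.geometry.name,
            "cba_element": m.cba_element,
            "cba_index": m.cba_index,
            "initial_rank_r": m.initial_rank_r,
            "final_rank_R": m.final_rank_R,
            "predicted_re_kcal_mol": round(m.predicted_re, 6),
            "refined_re_kcal_mol": round(m.refined_re, 6),
            "refined_energy_kcal_mol": round(m.refined_energy, 6),
            "mole_fraction": round(m.mole_fraction, 6),
        }
        for m in final
    ]
    report = JobReport(
        molecule_name=name,
        mode=MODE_LABELS[config.mode],
        records=records,
        capacity=round(stats.capacity, 6),
        n_enumerated=len(ranked),
        n_forwarded=len(final),
        selection={
            "rmse_kcal_mol": round(stats.rmse, 6),
            "re_min_kcal_mol": round(stats.re_min, 6),
            "sigma_kcal_mol": round(stats.sigma, 6),
            "variance_s": round(stats.variance_s, 6),
            "capacity": round(stats.capacity, 6),
        },
        provenance={
            "seed": config.seed,
            "backend": config.backend,
            "mode": MODE_LABELS[config.mode],
            "max_steps": config.max_steps,
            "temperature_K": config.temperature,
            "source": source,
        },
    )
    with _stage("write"):
        out_dir = write_report(report, config.output_root, models=final)
        if config.zip_output:
            _zip_directory(out_dir)
    return report


def write_report(report: JobReport, output_root: str, models=None) -> str:
    """Write the job outputs under ``output_root/completed/<name>/``.

    One XYZ per model (filename encodes final rank and charge-bearing
    atom), an aligned text summary, and a JSON sidecar that round-trips
    to an equal :class:`JobReport`.  Returns the job directory path.
    """
    out_dir = os.path.join(output_root, "completed", report.molecule_name)
    os.makedirs(out_dir, exist_ok=True)
    if models:
        for m in models:
            fname = f"{report.molecule_name}_rank{m.final_rank_R}_cba{m.cba_index}.xyz"
            comment = (
                f"rank={m.final_rank_R} cba={m.cba_element}{m.cba_index} "
                f"RE={m.refined_re:.6f}kcal/mol x={m.mole_fraction:.6f}"
            )
            write_xyz(m.geometry, os.path.join(out_dir, fname), comment)
    with open(os.path.join(out_dir, _REPORT_JSON), "w") as fh:
        fh.write(report.to_json() + "\n")
    with open(os.path.join(out_dir, _REPORT_TXT), "w") as fh:
        fh.write(_format_text_report(report))
    return out_dir


def _format_text_report(report: JobReport) -> str:
    lines = [
        f"Charge-state report for {report.molecule_name}  (mode {report.mode})",
        f"generated {time.strftime('%Y-%m-%d %H:%M:%S')}",
        "",
        f"models enumerated : {report.n_enumerated}",
        f"models forwarded  : {report.n_forwarded}"
        f"  (acceptance capacity = {report.capacity:.4f})",
        "",
        f"{'R':>3} {'r':>3}  {'CBA':<6} {'pred RE':>10} {'RE':>10} "
        f"{'mole frac':>10}",
        f"{'':>3} {'':>3}  {'':<6} {'kcal/mol':>10} {'kcal/mol':>10} {'':>10}",
        "-" * 48,
    ]
    for rec in report.records:
        lines.append(
            f"{rec['final_rank_R']:>3} {rec['initial_rank_r']:>3}  "
            f"{rec['cba_element'] + str(rec['cba_index']):<6} "
            f"{rec['predicted_re_kcal_mol']:>10.3f} "
            f"{rec['refined_re_kcal_mol']:>10.3f} "
            f"{rec['mole_fraction']:>10.4f}"
        )
    lines.append("")
    lines.append(
        "Rank 1 is the assigned major equilibrium gas-phase charge state."
    )
    return "\n".join(lines) + "\n"


def _zip_directory(directory: str) -> str:
    archive = directory.rstrip(os.sep) + ".zip"
    root = os.path.dirname(directory)
    with zipfile.ZipFile(archive, "w", zipfile.ZIP_DEFLATED) as zf:
        for base, _dirs, files in os.walk(directory):
            for f in sorted(files):
                full = os.path.join(base, f)
                zf.write(full, os.path.relpath(full, root))
    return archive
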