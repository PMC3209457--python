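"""End-to-end orchestration: structure → ENM/NMA → (optional) dynamics → report.

``run`` executes the full comparative analysis for a (structure, motif,
mutations) triple: the wild type and every mutant network are built,
diagonalized and summarized (cross-correlation map, motif coupling score,
NMA B-factors); if a simulation block is configured, each variant is
additionally propagated with Langevin dynamics and the trajectory
statistics (whole/motif RMSD series, trailing-window means and B-factors)
are collected.  Every numeric claim in the report is backed by a CSV
written to the output directory, and a provenance block (config hash,
seeds, package version) makes the run reproducible.

The wild type is always computed, even when only mutants are requested:
all mutant statements are deltas against the wild type.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import dynamics, enm, geometry
from .exceptions import SelectionError
from .structio import (
    MutationSpec,
    Selection,
    Structure,
    read_structure,
    resolve_selection,
)

__all__ = ["RunConfig", "VariantResult", "Report", "run", "compare_variants"]

logger = logging.getLogger("motifdyn.pipeline")

WILD_TYPE = "WT"


def _parse_selection(node) -> Selection:
    if isinstance(node, dict) and "start" in node:
        return Selection.from_range(
            int(node["start"]), int(node["stop"]), node.get("chain")
        )
    if isinstance(node, dict) and "residues" in node:
        return Selection(node["residues"], node.get("chain"))
    if isinstance(node, (list, tuple, set)):
        return Selection(node)
    raise ValueError(f"cannot parse selection from {node!r}")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    motif: Selection
    mutations: tuple[MutationSpec, ...]
    structure_path: str | None = None
    ligand_selection: Selection | None = None
    cutoff: float = enm.DEFAULT_CUTOFF
    gamma: float = enm.DEFAULT_GAMMA
    n_modes: int = enm.DEFAULT_N_MODES
    correlation_weighting: enm.CorrelationWeighting = "inverse_eigenvalue"
    simulation: dynamics.SimulationParams | None = None
    save_trajectories: bool = False
    output_dir: str = "motifdyn_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        enm_block = raw.get("enm", {})
        mutations = tuple(
            MutationSpec(
                residue_number=int(m["residue"]),
                from_aa=str(m.get("from", "UNK")),
                to_aa=str(m.get("to", "UNK")),
                spring_scale=float(m.get("spring_scale", 0.5)),
                chain_id=m.get("chain"),
            )
            for m in raw.get("mutations", [])
        )
        sim = raw.get("simulation")
        return cls(
            motif=_parse_selection(raw["motif"]),
            mutations=mutations,
            structure_path=raw.get("structure"),
            ligand_selection=(
                _parse_selection(raw["ligand"]) if raw.get("ligand") else None
            ),
            cutoff=float(enm_block.get("cutoff", enm.DEFAULT_CUTOFF)),
            gamma=float(enm_block.get("gamma", enm.DEFAULT_GAMMA)),
            n_modes=int(enm_block.get("n_modes", enm.DEFAULT_N_MODES)),
            correlation_weighting=enm_block.get(
                "weighting", "inverse_eigenvalue"
            ),
            simulation=(
                dynamics.SimulationParams(
                    timestep=float(sim.get("timestep", 0.01)),
                    n_steps=int(sim.get("n_steps", 200_000)),
                    save_every=int(sim.get("save_every", 100)),
                    kT=float(sim.get("kT", 1.0)),
                    friction=float(sim.get("friction", 1.0)),
                    seed=int(sim.get("seed", 0)),
                )
                if sim
                else None
            ),
            save_trajectories=bool(raw.get("save_trajectories", False)),
            output_dir=raw.get("output_dir", "motifdyn_out"),
            log_level=raw.get("log_level", "INFO"),
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "structure": self.structure_path,
                "motif": sorted(self.motif.residue_numbers),
                "motif_chain": self.motif.chain_id,
                "mutations": [
                    (m.residue_number, m.from_aa, m.to_aa, m.spring_scale, m.chain_id)
                    for m in self.mutations
                ],
                "ligand": (
                    sorted(self.ligand_selection.residue_numbers)
                    if self.ligand_selection
                    else None
                ),
                "enm": [self.cutoff, self.gamma, self.n_modes, self.correlation_weighting],
                "sim": (
                    [
                        self.simulation.timestep,
                        self.simulation.n_steps,
                        self.simulation.save_every,
                        self.simulation.kT,
                        self.simulation.friction,
                        self.simulation.seed,
                    ]
                    if self.simulation
                    else None
                ),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class VariantResult:
    """All computed observables for one variant (wild type or mutant)."""

    name: str
    mutation: MutationSpec | None
    coupling_scores: dict[str, float]              # mutation label → score
    correlation: enm.CorrelationMap
    nma_bfactors: np.ndarray
    mean_motif_bfactor_nma: float
    mean_motif_rmsd: float | None = None
    traj_bfactors: np.ndarray | None = None
    mean_motif_bfactor_traj: float | None = None
    ligand_distance: float | None = None


@dataclass
class Report:
    """Output bundle of one run: per-variant results, file map, provenance."""

    variants: dict[str, VariantResult]
    motif_residues: list[int]
    files: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _variant_seed(base_seed: int, index: int) -> int:
    """Stable, collision-free per-variant seed below 2^31."""
    return (base_seed * 1_000_003 + index * 7919) % (2**31 - 1)


def _write_matrix_csv(path: Path, matrix: np.ndarray, labels: np.ndarray) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, float_format="%.10g")


def _write_profile_csv(path: Path, values: np.ndarray, labels: np.ndarray, name: str) -> None:
    pd.DataFrame({"residue": labels, name: values}).to_csv(
        path, index=False, float_format="%.10g"
    )


def run(config: RunConfig, structure: Structure | None = None) -> Report:
    """Execute the comparative wild-type / mutant analysis.

    ``structure`` may be passed directly (e.g. a synthetic fixture);
    otherwise it is read from ``config.structure_path``.  All selections
    are resolved against the structure before any computation starts, so a
    bad residue number fails fast.
    """
    logging.basicConfig(level=config.log_level)
    if structure is None:
        if config.structure_path is None:
            raise ValueError("config has no structure path and no structure was given")
        structure = read_structure(config.structure_path)

    # fail fast: resolve every selection up front
    motif_idx = resolve_selection(structure, config.motif)
    for mut in config.mutations:
        resolve_selection(structure, Selection([mut.residue_number], mut.chain_id))
    if config.ligand_selection is not None:
        resolve_selection(structure, config.ligand_selection)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = structure.residue_numbers
    files: dict[str, str] = {}
    variants: dict[str, VariantResult] = {}

    variant_defs: list[tuple[str, MutationSpec | None]] = [(WILD_TYPE, None)]
    variant_defs += [(m.label, m) for m in config.mutations]

    for v_index, (name, mutation) in enumerate(variant_defs):
        muts = (mutation,) if mutation else ()
        logger.info("variant %s: building %d-site network (cutoff %.1f Å)",
                    name, structure.n_sites, config.cutoff)
        model = enm.build_hessian(
            structure, cutoff=config.cutoff, gamma=config.gamma, mutations=muts
        )
        modes = enm.diagonalize(model)
        corr = enm.cross_correlation(
            modes,
            n_modes=config.n_modes,
            weighting=config.correlation_weighting,
            residue_numbers=labels,
        )
        bfac = enm.nma_bfactors(modes, residue_numbers=labels)

        coupling: dict[str, float] = {}
        for m in config.mutations:
            (site_idx,) = resolve_selection(
                structure, Selection([m.residue_number], m.chain_id)
            )
            coupling[m.label] = enm.coupling_score(corr, int(site_idx), motif_idx)

        ligand_distance = None
        if config.ligand_selection is not None and mutation is not None:
            ligand_distance = geometry.min_distance(
                structure,
                Selection([mutation.residue_number], mutation.chain_id),
                config.ligand_selection,
            )

        result = VariantResult(
            name=name,
            mutation=mutation,
            coupling_scores=coupling,
            correlation=corr,
            nma_bfactors=bfac.values,
            mean_motif_bfactor_nma=float(np.mean(bfac.values[motif_idx])),
            ligand_distance=ligand_distance,
        )

        prefix = out / name
        _write_matrix_csv(Path(f"{prefix}_correlation.csv"), corr.matrix, labels)
        np.savetxt(f"{prefix}_correlation.mat", corr.matrix, fmt="%.10g")
        _write_profile_csv(
            Path(f"{prefix}_bfactors_nma.csv"), bfac.values, labels, "bfactor_nma"
        )
        files[f"{name}/correlation_csv"] = f"{prefix}_correlation.csv"
        files[f"{name}/correlation_mat"] = f"{prefix}_correlation.mat"
        files[f"{name}/bfactors_nma"] = f"{prefix}_bfactors_nma.csv"

        if config.simulation is not None:
            params = config.simulation.with_seed(
                _variant_seed(config.simulation.seed, v_index)
            )
            logger.info("variant %s: Langevin run, %d steps (seed %d)",
                        name, params.n_steps, params.seed)
            traj = dynamics.simulate(model, params)
            rmsd_all = dynamics.trajectory_rmsd(traj, selection=None)
            rmsd_motif = dynamics.trajectory_rmsd(traj, selection=motif_idx)
            result.mean_motif_rmsd = dynamics.mean_rmsd(rmsd_motif, window=0.5)
            traj_b = dynamics.trajectory_bfactors(traj, window=0.5)
            result.traj_bfactors = traj_b.values
            result.mean_motif_bfactor_traj = float(np.mean(traj_b.values[motif_idx]))

            for label_name, series in (("rmsd_all", rmsd_all), ("rmsd_motif", rmsd_motif)):
                path = Path(f"{prefix}_{label_name}.csv")
                pd.DataFrame({"time": series.times, "rmsd": series.values}).to_csv(
                    path, index=False, float_format="%.10g"
                )
                files[f"{name}/{label_name}"] = str(path)
            _write_profile_csv(
                Path(f"{prefix}_bfactors_traj.csv"), traj_b.values, labels,
                "bfactor_traj",
            )
            files[f"{name}/bfactors_traj"] = f"{prefix}_bfactors_traj.csv"
            if config.save_trajectories:
                dynamics.write_trajectory(
                    traj, f"{prefix}_trajectory.pdb", f"{prefix}_trajectory.meta"
                )
                files[f"{name}/trajectory"] = f"{prefix}_trajectory.pdb"

        variants[name] = result

    provenance = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "base_seed": config.simulation.seed if config.simulation else None,
        "variant_seeds": {
            name: _variant_seed(config.simulation.seed, i)
            for i, (name, _) in enumerate(variant_defs)
        }
        if config.simulation
        else {},
    }
    report = Report(
        variants=variants,
        motif_residues=sorted(config.motif.residue_numbers),
        files=files,
        provenance=provenance,
    )
    _write_report_text(report, out / "report.txt")
    files["report"] = str(out / "report.txt")
    return report


def _write_report_text(report: Report, path: Path) -> None:
    lines = ["motifdyn run report", "=" * 40]
    lines.append(f"motif residues: {report.motif_residues}")
    for name, v in report.variants.items():
        lines.append("")
        lines.append(f"[{name}]")
        for label, score in v.coupling_scores.items():
            lines.append(f"  coupling({label} ↔ motif) = {score:.6f}")
        lines.append(f"  mean motif B-factor (NMA) = {v.mean_motif_bfactor_nma:.6f}")
        if v.mean_motif_rmsd is not None:
            lines.append(f"  mean motif RMSD (trailing half) = {v.mean_motif_rmsd:.6f}")
        if v.mean_motif_bfactor_traj is not None:
            lines.append(
                f"  mean motif B-factor (trajectory) = {v.mean_motif_bfactor_traj:.6f}"
            )
        if v.ligand_distance is not None:
            lines.append(f"  min Cα distance to ligand selection = {v.ligand_distance:.3f} Å")
    lines.append("")
    lines.append("[provenance]")
    for key, val in report.provenance.items():
        lines.append(f"  {key}: {val}")
    path.write_text("\n".join(lines) + "\n")


def compare_variants(report: Report) -> pd.DataFrame:
    """Per-mutant deltas against the wild type.

    Positive ``delta_*`` values mean the mutant exceeds the wild type
    (larger coupling / motif RMSD / motif B-factor).  Requires the report
    to contain the wild type and at least one mutant.
    """
    if WILD_TYPE not in report.variants:
        raise ValueError("report contains no wild-type variant")
    if len(report.variants) < 2:
        raise ValueError("need at least one mutant variant to compare")
    wt = report.variants[WILD_TYPE]
    rows = []
    for name, v in report.variants.items():
        if name == WILD_TYPE:
            continue
        row = {"variant": name}
        if name in v.coupling_scores and name in wt.coupling_scores:
            row["delta_coupling"] = v.coupling_scores[name] - wt.coupling_scores[name]
        row["delta_mean_motif_bfactor_nma"] = (
            v.mean_motif_bfactor_nma - wt.mean_motif_bfactor_nma
        )
        if v.mean_motif_rmsd is not None and wt.mean_motif_rmsd is not None:
            row["delta_mean_motif_rmsd"] = v.mean_motif_rmsd - wt.mean_motif_rmsd
        if (
            v.mean_motif_bfactor_traj is not None
            and wt.mean_motif_bfactor_traj is not None
        ):
            row["delta_mean_motif_bfactor_traj"] = (
                v.mean_motif_bfactor_traj - wt.mean_motif_bfactor_traj
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
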