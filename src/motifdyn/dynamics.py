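"""Overdamped Langevin dynamics on the elastic-network potential.

Generates stochastic trajectories whose stationary distribution is exactly
the Boltzmann distribution of the harmonic network, which makes every
trajectory statistic checkable against the normal-mode covariance in closed
form.  The integrator is Euler–Maruyama Brownian dynamics:

    x ← x − (Δt/ζ) H (x − x₀) + sqrt(2 kT Δt / ζ) η,    η ~ N(0, 1)^{3N}

with H the network Hessian, x₀ the input (equilibrium) structure, ζ the
friction coefficient and kT the thermal energy, all in reduced units.  The
noise term is the thermostat: kT = 0 reduces the scheme to steepest-descent
relaxation toward x₀.

Trajectory analyses mirror standard MD practice: RMSD time series against
the starting conformation (whole structure or motif-restricted) and
per-residue B-factors computed over a trailing window of the run, after
superposing the window frames onto their iteratively refined mean
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import geometry
from .enm import BFactorProfile, ENMModel
from .exceptions import StabilityError
from .structio import Structure, write_multi_model

__all__ = [
    "SimulationParams",
    "Trajectory",
    "TimeSeries",
    "simulate",
    "trajectory_rmsd",
    "mean_rmsd",
    "trajectory_bfactors",
    "write_trajectory",
]

#: |Δx| larger than this (reduced length units) in one step aborts the run.
_DIVERGENCE_LIMIT = 1.0e3


@dataclass(frozen=True)
class SimulationParams:
    """Reduced-unit Langevin run settings.

    Defaults mirror a short production MD protocol: 200 000 integration
    steps with coordinates saved every 100 steps, and the analysis
    conventions downstream use the trailing half of the run.
    """

    timestep: float = 0.01
    n_steps: int = 200_000
    save_every: int = 100
    kT: float = 1.0
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.timestep > 0:
            raise ValueError("timestep must be > 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        if self.n_steps < self.save_every:
            raise ValueError("n_steps must be >= save_every")
        if self.kT < 0:
            raise ValueError("kT must be >= 0")
        if not self.friction > 0:
            raise ValueError("friction must be > 0")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class Trajectory:
    """Saved frames of one Langevin run.

    ``frames[0]`` is always the starting (reference) conformation; one
    frame is stored every ``params.save_every`` steps thereafter.
    """

    frames: np.ndarray          # (n_frames, N, 3)
    params: SimulationParams
    reference: Structure

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Simulation time of each saved frame (reduced units)."""
        return (
            np.arange(self.n_frames) * self.params.save_every * self.params.timestep
        )


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


def _rigid_null_basis(hessian: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the numerically-zero (rigid-body) eigenspace."""
    evals, evecs = np.linalg.eigh(hessian)
    tol = 1e-8 * float(evals[-1])
    return evecs[:, np.abs(evals) < tol]


def simulate(
    model: ENMModel,
    params: SimulationParams,
    initial_coords: np.ndarray | None = None,
    remove_rigid_motion: bool = True,
) -> Trajectory:
    """Run Euler–Maruyama Brownian dynamics on an elastic-network model.

    Fully reproducible: the same (model, params, seed) triple yields
    bit-identical frames.  ``initial_coords`` starts the run away from the
    network minimum (useful for relaxation studies; with kT = 0 the scheme
    is plain gradient descent back to the equilibrium structure).  A step
    displacing any coordinate by more than 10³ reduced length units raises
    :class:`~motifdyn.exceptions.StabilityError` naming the step.

    ``remove_rigid_motion`` (default on) projects the thermal noise onto
    the internal-mode subspace, the analogue of the center-of-mass motion
    removal customary in MD.  The linearized network exerts no restoring
    force along the six rigid-body modes, so unprojected noise makes their
    amplitudes diffuse without bound; because a *finite* displacement along
    an infinitesimal-rotation mode is a shear rather than a rotation, that
    drift distorts the molecule in a way no rigid-body fit can undo.  With
    the projection the run samples exactly the Boltzmann distribution of
    the internal modes.
    """
    n = model.n_sites
    hessian = model.hessian
    x0 = model.structure.coords.reshape(-1).astype(float)
    dt = params.timestep
    zeta = params.friction
    drift = dt / zeta
    noise_amp = np.sqrt(2.0 * params.kT * dt / zeta)
    rng = np.random.default_rng(params.seed)

    if initial_coords is None:
        start = model.structure.coords
    else:
        start = np.asarray(initial_coords, dtype=float)
        if start.shape != (n, 3):
            raise ValueError(f"initial_coords shape {start.shape} != ({n}, 3)")
    n_frames = params.n_steps // params.save_every + 1
    frames = np.empty((n_frames, n, 3))
    frames[0] = start
    x = start.reshape(-1).astype(float).copy()
    null_basis = (
        _rigid_null_basis(hessian)
        if (remove_rigid_motion and params.kT > 0)
        else None
    )
    frame_i = 1
    for step in range(1, params.n_steps + 1):
        dx = -drift * (hessian @ (x - x0))
        if params.kT > 0:
            eta = rng.standard_normal(3 * n)
            if null_basis is not None:
                eta -= null_basis @ (null_basis.T @ eta)
            dx += noise_amp * eta
        if np.abs(dx).max() > _DIVERGENCE_LIMIT:
            raise StabilityError(
                f"divergent displacement at step {step}: |Δx| > {_DIVERGENCE_LIMIT:g}; "
                f"reduce the timestep"
            )
        x += dx
        if step % params.save_every == 0:
            frames[frame_i] = x.reshape(n, 3)
            frame_i += 1
    reference = (
        model.structure
        if initial_coords is None
        else model.structure.with_coords(start)
    )
    return Trajectory(frames=frames[:frame_i], params=params, reference=reference)


def trajectory_rmsd(
    t: Trajectory,
    selection: Sequence[int] | None = None,
    fit_mode: geometry.FitMode = "fit_all",
) -> TimeSeries:
    """Per-frame RMSD against the starting conformation.

    ``selection=None`` measures all sites (the fit is then over all sites
    regardless of ``fit_mode``); an index list restricts the measurement to
    those sites under the chosen fitting convention.
    """
    ref = t.reference.coords
    values = np.empty(t.n_frames)
    for i, frame in enumerate(t.frames):
        if selection is None:
            values[i] = geometry.rmsd(frame, ref, fit=True)
        else:
            values[i] = geometry.motif_rmsd(frame, ref, np.asarray(selection), fit_mode)
    # the frame-0 self-comparison is exactly zero; the fitted value only
    # differs by sqrt-machine-epsilon noise from the rotation solve
    if np.array_equal(t.frames[0], ref):
        values[0] = 0.0
    return TimeSeries(times=t.times, values=values)


def mean_rmsd(ts: TimeSeries, window: float = 0.5, from_end: bool = True) -> float:
    """Mean of a time series over a leading or trailing fraction of frames.

    ``window=0.5, from_end=True`` is the "analyze only the second half of
    the trajectory" convention.
    """
    if not 0 < window <= 1:
        raise ValueError(f"window must be in (0, 1], got {window}")
    n = len(ts.values)
    k = int(np.ceil(window * n))
    if k < 1:
        raise ValueError("window selects no frames")
    chunk = ts.values[-k:] if from_end else ts.values[:k]
    return float(np.mean(chunk))


def _window_frames(t: Trajectory, window: float) -> np.ndarray:
    if not 0 < window <= 1:
        raise ValueError(f"window must be in (0, 1], got {window}")
    k = int(np.ceil(window * t.n_frames))
    if k < 10:
        raise ValueError(
            f"window of {k} frames is too short for fluctuation statistics "
            f"(need >= 10)"
        )
    return t.frames[-k:]


def _fit_frame(frame: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Least-squares rigid fit of one frame onto the running mean.

    The 2-site (dimer) case has an underdetermined Kabsch problem; there
    the optimal fit is centroid matching plus the minimal rotation
    aligning the inter-site vectors, handled explicitly.
    """
    if frame.shape[0] >= 3:
        return geometry.superpose(frame, mean).apply(frame)
    import warnings

    from scipy.spatial.transform import Rotation

    fc, mc = frame.mean(axis=0), mean.mean(axis=0)
    with warnings.catch_warnings():
        # scipy flags the single-vector fit as underdetermined; the free
        # spin about the bond axis does not move the sites, so any
        # minimizer it returns is optimal here
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors((mean - mc)[-1:], (frame - fc)[-1:])
    return (frame - fc) @ rot.as_matrix().T + mc


def trajectory_bfactors(
    t: Trajectory, window: float = 0.5, n_fit_rounds: int = 3
) -> BFactorProfile:
    """Per-residue B-factors from a trailing window of the trajectory.

    The window frames are superposed onto their mean structure, the mean is
    recomputed, and the procedure iterated (3 rounds by default) so that
    rigid-body drift does not inflate the fluctuations.  Then

        B_i = (8π²/3) ⟨|r_i − ⟨r_i⟩|²⟩

    on the same arbitrary prefactor scale as the NMA prediction, making the
    two directly comparable.
    """
    frames = _window_frames(t, window).copy()
    mean = frames.mean(axis=0)
    for _ in range(n_fit_rounds):
        for i in range(frames.shape[0]):
            frames[i] = _fit_frame(frames[i], mean)
        mean = frames.mean(axis=0)
    msf = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)
    return BFactorProfile(
        values=(8.0 * np.pi**2 / 3.0) * msf,
        source="trajectory",
        residue_numbers=t.reference.residue_numbers,
    )


def write_trajectory(t: Trajectory, path, metadata_path=None) -> None:
    """Persist a trajectory as a multi-model PDB plus a key-value sidecar."""
    structures = [t.reference.with_coords(f) for f in t.frames]
    write_multi_model(structures, path)
    if metadata_path is not None:
        p = t.params
        with open(metadata_path, "w") as fh:
            for key, val in (
                ("timestep", p.timestep),
                ("n_steps", p.n_steps),
                ("save_every", p.save_every),
                ("kT", p.kT),
                ("friction", p.friction),
                ("seed", p.seed),
                ("n_frames", t.n_frames),
                ("n_sites", t.reference.n_sites),
            ):
                fh.write(f"{key} {val}\n")
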