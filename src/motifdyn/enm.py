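"""Anisotropic elastic-network model: Hessian, normal modes, correlations.

The protein is modeled as a network of Cα sites connected by Hookean
springs: every pair of sites closer than a distance cutoff interacts
through the potential

    V = (γ_ij / 2) * (|r_ij| - |r_ij^0|)^2

whose second-order expansion about the input structure gives, per contact,
the 3×3 Hessian super-element  -γ_ij (d dᵀ)/|d|²  with d the equilibrium
separation vector.  The input structure is the energy minimum by
construction, so no minimization precedes the normal-mode analysis:
diagonalizing the (mass-weighted) 3N×3N Hessian yields six zero-frequency
rigid-body modes plus 3N-6 internal modes.

A point mutation enters as a perturbation of the network: every spring
incident to the mutated site is rescaled by the mutation's ``spring_scale``
(< 1 models the loss of hydrophobic packing caused by a
hydrophobic→hydrophilic substitution).  When both endpoints of a contact
are mutated the scales multiply.

From the modes this module derives the two standard NMA observables:

* the residue cross-correlation map  C_ij = K_ij / sqrt(K_ii K_jj), where
  K_ij = Σ_k u_k,i · u_k,j / λ_k  accumulates the lowest nonzero modes
  (+1 = concerted motion, −1 = anti-correlated motion);
* predicted B-factors  B_i = (8π²/3) kT K_ii, the mean-square fluctuation
  of each site about its equilibrium position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .exceptions import ConnectivityError, DegeneracyError, SelectionError
from .structio import MutationSpec, Structure, resolve_selection, Selection

__all__ = [
    "ENMModel",
    "ModeSet",
    "CorrelationMap",
    "BFactorProfile",
    "build_hessian",
    "diagonalize",
    "cross_correlation",
    "nma_bfactors",
    "coupling_score",
    "write_modes",
]

#: Default interaction cutoff in Å (common Cα anisotropic-network practice).
DEFAULT_CUTOFF = 13.0
#: Default spring constant (arbitrary units; sets the energy scale).
DEFAULT_GAMMA = 1.0
#: Default number of low-frequency modes entering the correlation map.
DEFAULT_N_MODES = 50

CorrelationWeighting = Literal["inverse_eigenvalue", "equal"]


@dataclass
class ENMModel:
    """An assembled elastic network: structure, parameters, 3N×3N Hessian."""

    structure: Structure
    cutoff: float
    gamma: float
    masses: np.ndarray
    mutations: tuple[MutationSpec, ...]
    hessian: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.structure.n_sites


@dataclass
class ModeSet:
    """Eigenvalues/eigenvectors of a mass-weighted network Hessian.

    ``frequencies_squared`` are the eigenvalues λ_k in ascending order;
    ``modes[:, k]`` is the orthonormal eigenvector u_k.  The first
    ``n_zero`` entries are the numerically-zero rigid-body modes.
    """

    frequencies_squared: np.ndarray
    modes: np.ndarray
    n_zero: int
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_sites(self) -> int:
        return self.modes.shape[0] // 3

    @property
    def n_nonzero(self) -> int:
        return len(self.frequencies_squared) - self.n_zero

    def nonzero(self, n_modes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """The ``n_modes`` lowest nonzero eigenpairs (all if ``None``)."""
        lo = self.n_zero
        hi = len(self.frequencies_squared) if n_modes is None else lo + n_modes
        return self.frequencies_squared[lo:hi], self.modes[:, lo:hi]


@dataclass
class CorrelationMap:
    """Normalized residue–residue cross-correlations in [-1, 1]."""

    matrix: np.ndarray
    n_modes_used: int
    residue_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]


@dataclass
class BFactorProfile:
    """Per-residue B-factors (Å² scale, arbitrary prefactor)."""

    values: np.ndarray
    source: Literal["nma", "trajectory"]
    residue_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]


def _pair_spring_constants(
    s: Structure, gamma: float, mutations: Sequence[MutationSpec]
) -> np.ndarray:
    """Per-site spring scale vector; contact constant is gamma * scale_i * scale_j."""
    scale = np.ones(s.n_sites)
    for mut in mutations:
        sel = Selection([mut.residue_number], mut.chain_id)
        (idx,) = resolve_selection(s, sel)
        scale[idx] *= mut.spring_scale
    return gamma * np.outer(scale, scale)


def build_hessian(
    s: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    mutations: Iterable[MutationSpec] = (),
    masses: np.ndarray | None = None,
) -> ENMModel:
    """Assemble the anisotropic-network Hessian for a structure.

    Parameters
    ----------
    s : Structure
        Cα sites; at least 3, not all collinear.
    cutoff : float
        Interaction cutoff in Å; pairs farther apart carry no spring.
    gamma : float
        Uniform spring constant for unperturbed contacts.
    mutations : iterable of MutationSpec
        Each rescales all springs incident to its residue by
        ``spring_scale`` (scales multiply if both endpoints are mutated).
    masses : array, optional
        Per-site masses for mass-weighted diagonalization; default uniform 1.

    Raises
    ------
    ConnectivityError
        If the contact graph is disconnected at this cutoff (the model
        would have spurious zero modes).
    DegeneracyError
        Fewer than 3 sites or an all-collinear structure.
    """
    if not cutoff > 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    if not gamma > 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    n = s.n_sites
    if n < 2:
        raise DegeneracyError(f"elastic network needs >= 2 sites, got {n}")
    coords = s.coords
    # the 2-site dimer is admitted as the closed-form reference case
    # (one stretch mode, 5 rigid-body modes); larger collinear chains are
    # genuinely floppy under the pair potential and are rejected
    if n >= 3 and np.linalg.matrix_rank(coords - coords.mean(axis=0), tol=1e-8) < 2:
        raise DegeneracyError("all sites are collinear; the network is degenerate")
    mutations = tuple(mutations)
    masses = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    if masses.shape != (n,) or np.any(masses <= 0):
        raise ValueError("masses must be positive with one entry per site")

    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(contact, directed=False)
    if n_comp != 1:
        raise ConnectivityError(
            f"contact graph splits into {n_comp} components at cutoff "
            f"{cutoff} Å; increase the cutoff"
        )
    gammas = _pair_spring_constants(s, gamma, mutations)

    # vectorized super-element assembly: for each contact (i, j),
    # H[i,j] block = -γ_ij d dᵀ / |d|², diagonal blocks minus the row sum
    diff = coords[:, None, :] - coords[None, :, :]          # (n, n, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        blocks = (
            -gammas[:, :, None, None]
            * diff[:, :, :, None]
            * diff[:, :, None, :]
            / (dist**2)[:, :, None, None]
        )
    blocks[~contact] = 0.0
    blocks[np.arange(n), np.arange(n)] = -blocks.sum(axis=1)
    hessian = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    hessian = 0.5 * (hessian + hessian.T)  # symmetrize rounding noise
    return ENMModel(
        structure=s,
        cutoff=cutoff,
        gamma=gamma,
        masses=masses,
        mutations=mutations,
        hessian=hessian,
    )


def diagonalize(m: ENMModel) -> ModeSet:
    """Full spectrum of the mass-weighted Hessian, ascending.

    Mass-weighting is applied as M^{-1/2} H M^{-1/2}; with the default
    uniform masses this is the plain Hessian.  Modes with
    |λ| < 1e-8 × λ_max are classified as rigid-body zero modes; more than
    six of them means the network is floppy and the model is rejected.
    """
    n = m.n_sites
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(m.masses), 3)
    mw = m.hessian * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    evals, evecs = scipy.linalg.eigh(mw)
    lam_max = float(evals[-1])
    if lam_max <= 0:
        raise DegeneracyError("Hessian has no positive eigenvalues")
    tol = 1e-8 * lam_max
    n_zero = int(np.sum(np.abs(evals) < tol))
    if n_zero > 6:
        raise DegeneracyError(
            f"{n_zero} numerically zero modes (expected 6): floppy network"
        )
    return ModeSet(
        frequencies_squared=evals, modes=evecs, n_zero=n_zero, masses=m.masses
    )


def _mode_covariance(
    ms: ModeSet, n_modes: int | None, weighting: CorrelationWeighting
) -> tuple[np.ndarray, int]:
    """3×3-block-traced covariance K_ij over the lowest nonzero modes."""
    avail = ms.n_nonzero
    if n_modes is None:
        n_modes = avail
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > avail:
        warnings.warn(
            f"requested {n_modes} modes but only {avail} nonzero modes exist; "
            f"clamping",
            stacklevel=3,
        )
        n_modes = avail
    lam, vec = ms.nonzero(n_modes)
    n = ms.n_sites
    u = vec.T.reshape(n_modes, n, 3)                       # (k, site, xyz)
    w = 1.0 / lam if weighting == "inverse_eigenvalue" else np.ones(n_modes)
    k_ij = np.einsum("k,kia,kja->ij", w, u, u)
    return k_ij, n_modes


def cross_correlation(
    ms: ModeSet,
    n_modes: int | None = DEFAULT_N_MODES,
    weighting: CorrelationWeighting = "inverse_eigenvalue",
    residue_numbers: np.ndarray | None = None,
) -> CorrelationMap:
    """Residue cross-correlation map from the lowest nonzero normal modes.

    ``weighting="inverse_eigenvalue"`` (default) accumulates the covariance
    with each mode weighted by 1/λ_k, i.e. the thermal covariance truncated
    to the requested modes; ``"equal"`` averages the per-mode outer
    products without weighting.  Either way the result is normalized to a
    correlation: C_ij = K_ij / sqrt(K_ii K_jj), with a unit diagonal.
    Requesting more modes than exist clamps with a warning, so small toy
    systems work with the standard 50-mode default.
    """
    k_ij, used = _mode_covariance(ms, n_modes, weighting)
    d = np.sqrt(np.diag(k_ij))
    corr = k_ij / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMap(matrix=corr, n_modes_used=used, residue_numbers=residue_numbers)


def nma_bfactors(
    ms: ModeSet,
    n_modes: int | None = None,
    kT: float = 1.0,
    residue_numbers: np.ndarray | None = None,
) -> BFactorProfile:
    """Predicted B-factors B_i = (8π²/3) kT K_ii from the mode covariance.

    With ``n_modes=None`` all nonzero modes contribute and K equals the
    Hessian pseudo-inverse (times kT), the exact thermal covariance of the
    harmonic model.
    """
    k_ij, _ = _mode_covariance(ms, n_modes, "inverse_eigenvalue")
    values = (8.0 * np.pi**2 / 3.0) * kT * np.diag(k_ij)
    return BFactorProfile(values=values, source="nma", residue_numbers=residue_numbers)


def coupling_score(
    cm: CorrelationMap,
    site: int,
    motif: Sequence[int],
    exclude_self: bool = True,
) -> float:
    """Mean absolute correlation between one site and a motif, in [0, 1].

    A scalar summary of how strongly the fluctuations of ``site`` (e.g. a
    mutation position) are coupled to the motif's collective motion; both
    concerted and anti-correlated coupling count.
    """
    n = cm.n_sites
    if not 0 <= site < n:
        raise SelectionError(f"site index {site} out of range for {n} sites")
    motif_idx = [int(j) for j in motif]
    if any(j < 0 or j >= n for j in motif_idx):
        raise SelectionError("motif indices out of range")
    if exclude_self:
        motif_idx = [j for j in motif_idx if j != site]
    if not motif_idx:
        raise SelectionError("motif is empty after excluding the site itself")
    return float(np.mean(np.abs(cm.matrix[site, motif_idx])))


def write_modes(ms: ModeSet, path) -> None:
    """Plain-text mode table: one record per mode, eigenvalue then 3N components."""
    with open(path, "w") as fh:
        fh.write(f"# n_sites {ms.n_sites} n_zero {ms.n_zero}\n")
        for k in range(ms.modes.shape[1]):
            comps = " ".join(f"{x:.10g}" for x in ms.modes[:, k])
            fh.write(f"{ms.frequencies_squared[k]:.10g} {comps}\n")
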