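"""Rigid-body superposition and distance statistics on Cα coordinate sets.

Implements the two measurements a trajectory analysis is built from:
least-squares (Kabsch) superposition with the derived RMSD — globally or
restricted to a motif — and minimum Cα–Cα distances between two residue
selections (e.g. a mutation site and a ligand-binding site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .exceptions import DegeneracyError, SelectionError, ShapeError
from .structio import Selection, Structure, resolve_selection

__all__ = [
    "SuperpositionResult",
    "superpose",
    "rmsd",
    "motif_rmsd",
    "min_distance",
]

FitMode = Literal["fit_all", "fit_motif"]


@dataclass(frozen=True)
class SuperpositionResult:
    """A proper rigid transform ``x -> rotation @ x + translation`` and the
    RMSD it achieves."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _check_pair(a: np.ndarray, b: np.ndarray, min_sites: int = 1) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise ShapeError(f"expected (N, 3) coordinate sets, got {a.shape} and {b.shape}")
    if a.shape[0] != b.shape[0]:
        raise ShapeError(f"site counts differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < min_sites:
        raise DegeneracyError(f"need at least {min_sites} sites, got {a.shape[0]}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ShapeError("coordinates must be finite")
    return a, b


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns the proper rotation (det +1, never a reflection) and translation
    minimizing the RMSD between the transformed mobile set and the
    reference, together with that minimal RMSD.

    Raises
    ------
    ShapeError
        Mismatched site counts or non-finite input.
    DegeneracyError
        Fewer than 3 sites, or a collinear/degenerate reference for which
        the rotation is not determined.
    """
    mobile, reference = _check_pair(mobile, reference, min_sites=3)
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    # rank < 2 → all points on a line (or a point): rotation underdetermined
    if np.linalg.matrix_rank(ref0, tol=1e-8 * max(1.0, np.abs(ref0).max())) < 2:
        raise DegeneracyError("reference sites are collinear; superposition is degenerate")
    rot, rssd = Rotation.align_vectors(ref0, mob0)
    value = float(rssd) / np.sqrt(mobile.shape[0])
    matrix = rot.as_matrix()
    return SuperpositionResult(
        rotation=matrix,
        translation=ref_c - matrix @ mob_c,
        rmsd=value,
    )


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """Root-mean-square deviation between two coordinate sets in Å.

    With ``fit=True`` the sets are first optimally superposed, giving the
    conventional trajectory RMSD "with respect to the starting
    conformation"; with ``fit=False`` the raw per-site deviation is used.
    """
    a, b = _check_pair(a, b)
    if fit:
        return superpose(a, b).rmsd
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def motif_rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    motif: np.ndarray,
    fit_mode: FitMode = "fit_all",
) -> float:
    """RMSD over motif sites only, under one of two fitting conventions.

    ``fit_all`` superposes on *all* sites and then measures the deviation of
    the motif sites — motion of the motif relative to the whole structure
    contributes.  ``fit_motif`` superposes on the motif sites themselves and
    measures only internal motif deformation.
    """
    frame, reference = _check_pair(frame, reference)
    motif = np.asarray(motif, dtype=int)
    if motif.size == 0:
        raise SelectionError("motif index list is empty")
    if motif.min() < 0 or motif.max() >= frame.shape[0]:
        raise SelectionError("motif indices out of range")
    if fit_mode == "fit_all":
        sup = superpose(frame, reference)
        moved = sup.apply(frame)
        d = moved[motif] - reference[motif]
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
    if fit_mode == "fit_motif":
        return superpose(frame[motif], reference[motif]).rmsd
    raise ValueError(f"unknown fit_mode {fit_mode!r}")


def min_distance(s: Structure, sel_a: Selection, sel_b: Selection) -> float:
    """Minimum Cα–Cα distance (Å) between two disjoint residue selections.

    This is the coarse-grained analogue of the closest-atom distance used to
    ask how far a mutation site sits from a binding site; being Cα-based it
    upper-bounds nothing and should be read as a backbone-level distance.
    """
    idx_a = resolve_selection(s, sel_a)
    idx_b = resolve_selection(s, sel_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("selections overlap; min_distance requires disjoint sets")
    return float(cdist(s.coords[idx_a], s.coords[idx_b]).min())
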