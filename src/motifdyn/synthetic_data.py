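"""Seeded toy Cα structures for exercising the analysis pipeline.

Real inputs to this package are homology models or crystal structures that
cannot be redistributed; the generators here produce compact, connected
folds with the geometric properties the elastic-network analysis assumes,
so every stage — Hessian build, mode spectra, Langevin runs, motif
statistics — can be driven end to end without any external file.

Three fixture families:

``helix``
    An ideal α-helical Cα trace (rise 1.5 Å/residue, twist 100°, helix
    radius 2.3 Å — the canonical parameters giving the 3.8 Å Cα–Cα virtual
    bond).
``helix_loop_helix``
    Two packed antiparallel helices joined by a 4-residue loop.  The loop
    emulates the situation where a cofactor-binding segment sits on the
    connector between secondary-structure elements; its residues are
    recorded as the default "motif" in the structure metadata, together
    with a suggested motif-adjacent mutation site.
``cloud``
    Points drawn uniformly in a sphere with a 3.5 Å minimum-separation
    rejection rule — a fold-free control with realistic packing density.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .exceptions import GenerationError
from .structio import Structure

__all__ = ["ToySpec", "make_structure", "perturb"]

#: Ideal α-helix Cα parameters (Å, degrees): produce ~3.8 Å virtual bonds.
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3

#: Axis-to-axis distance of the packed helix pair in helix_loop_helix (Å).
_HELIX_PACKING_DISTANCE = 9.0

#: Hard-sphere diameter for the cloud generator (Å).
_MIN_SEPARATION = 3.5

_MAX_ATTEMPTS = 100_000


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one synthetic structure."""

    kind: Literal["helix", "helix_loop_helix", "cloud"]
    n_residues: int
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    radius: float = HELIX_RADIUS
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("n_residues must be >= 3")
        if self.kind == "helix_loop_helix" and self.n_residues < 10:
            raise ValueError("helix_loop_helix needs >= 10 residues")
        if not (self.rise > 0 and self.radius > 0):
            raise ValueError("rise and radius must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _helix_coords(n: int, rise: float, twist: float, radius: float) -> np.ndarray:
    theta = np.deg2rad(twist) * np.arange(n)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )


def _bezier(p0, p1, p2, p3, ts) -> np.ndarray:
    ts = ts[:, None]
    return (
        (1 - ts) ** 3 * p0
        + 3 * (1 - ts) ** 2 * ts * p1
        + 3 * (1 - ts) * ts**2 * p2
        + ts**3 * p3
    )


def _helix_loop_helix(spec: ToySpec) -> tuple[np.ndarray, dict]:
    n = spec.n_residues
    n_loop = 4
    n_a = (n - n_loop) // 2
    n_b = n - n_loop - n_a
    helix_a = _helix_coords(n_a, spec.rise, spec.twist, spec.radius)
    helix_b = _helix_coords(n_b, spec.rise, spec.twist, spec.radius)
    # second helix antiparallel, packed alongside the first
    helix_b = helix_b * np.array([1.0, 1.0, -1.0])
    helix_b += np.array(
        [_HELIX_PACKING_DISTANCE, 0.0, float(helix_a[-1, 2])]
    )
    a_end, b_start = helix_a[-1], helix_b[0]
    lift = np.array([0.0, 0.0, 4.0 * spec.rise])
    ts = np.linspace(0.0, 1.0, n_loop + 2)[1:-1]
    loop = _bezier(a_end, a_end + lift, b_start + lift, b_start, ts)
    coords = np.vstack([helix_a, loop, helix_b])
    motif = list(range(n_a + 1, n_a + n_loop + 1))      # residue numbers, 1-based
    meta = {
        "motif_residues": motif,
        "suggested_mutation_site": n_a,                 # last residue of helix A
    }
    return coords, meta


def _cloud(spec: ToySpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    sphere_radius = 3.0 * n ** (1.0 / 3.0)
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise GenerationError(
                f"could not place {n} points with {_MIN_SEPARATION} Å separation "
                f"after {_MAX_ATTEMPTS} attempts"
            )
        p = rng.uniform(-sphere_radius, sphere_radius, 3)
        if np.linalg.norm(p) > sphere_radius:
            continue
        if points and np.min(
            np.linalg.norm(np.asarray(points) - p, axis=1)
        ) < _MIN_SEPARATION:
            continue
        points.append(p)
    return np.asarray(points)


def make_structure(spec: ToySpec) -> Structure:
    """Generate one synthetic Cα structure from a recipe.

    Deterministic given ``spec.seed``.  helix_loop_helix fixtures record
    their loop motif and a motif-adjacent mutation site under
    ``metadata["motif_residues"]`` / ``metadata["suggested_mutation_site"]``.
    """
    rng = np.random.default_rng(spec.seed)
    meta: dict = {"toy_spec": spec}
    if spec.kind == "helix":
        coords = _helix_coords(spec.n_residues, spec.rise, spec.twist, spec.radius)
    elif spec.kind == "helix_loop_helix":
        coords, extra = _helix_loop_helix(spec)
        meta.update(extra)
    elif spec.kind == "cloud":
        coords = _cloud(spec, rng)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    n = spec.n_residues
    return Structure(
        chain_ids=np.full(n, "A"),
        residue_numbers=np.arange(1, n + 1),
        residue_names=np.full(n, "ALA"),
        coords=coords,
        metadata=meta,
    )


def perturb(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Add isotropic Gaussian coordinate noise; ``sigma=0`` is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return s.with_coords(s.coords)
    rng = np.random.default_rng(seed)
    return s.with_coords(s.coords + rng.normal(0.0, sigma, s.coords.shape))
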