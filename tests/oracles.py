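"""Independent reference implementations used to validate the package.

Each oracle here deliberately takes the dumbest correct route (double
loops, dense pseudo-inverse, grid search) so it shares no code path with
the implementation it checks.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.spatial.transform import Rotation


def hessian_double_loop(
    coords: np.ndarray, cutoff: float, gamma: float, site_scales: np.ndarray | None = None
) -> np.ndarray:
    """Naive element-wise ANM Hessian assembly with explicit loops."""
    n = coords.shape[0]
    if site_scales is None:
        site_scales = np.ones(n)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = coords[i] - coords[j]
            r = np.sqrt(d @ d)
            if r > cutoff:
                continue
            g = gamma * site_scales[i] * site_scales[j]
            block = -g * np.outer(d, d) / (r * r)
            h[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
            h[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
    return h


def pseudoinverse_covariance(hessian: np.ndarray) -> np.ndarray:
    """Site covariance K_ij as 3×3-block traces of the Hessian pseudo-inverse."""
    n = hessian.shape[0] // 3
    pinv = scipy.linalg.pinvh(hessian, rtol=1e-6)
    k = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            k[i, j] = np.trace(pinv[3 * i : 3 * i + 3, 3 * j : 3 * j + 3])
    return k


def min_distance_double_loop(a: np.ndarray, b: np.ndarray) -> float:
    best = np.inf
    for p in a:
        for q in b:
            best = min(best, float(np.linalg.norm(p - q)))
    return best


def _rmsd_for_rotvecs(rotvecs: np.ndarray, mob0: np.ndarray, ref0: np.ndarray) -> np.ndarray:
    rots = Rotation.from_rotvec(rotvecs)
    n = mob0.shape[0]
    sq = np.zeros(len(rotvecs))
    for k in range(n):
        sq += np.sum((rots.apply(mob0[k]) - ref0[k]) ** 2, axis=1)
    return np.sqrt(sq / n)


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations by axis-angle grid search plus a
    derivative-free polish; never touches the closed-form Kabsch solution."""
    mob0 = mobile - mobile.mean(axis=0)
    ref0 = reference - reference.mean(axis=0)
    # ~500 Fibonacci-sphere axes × 2° angle steps
    n_axes = 500
    k = np.arange(n_axes)
    phi = np.arccos(1 - 2 * (k + 0.5) / n_axes)
    theta = np.pi * (1 + 5**0.5) * k
    axes = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    angles = np.deg2rad(np.arange(1.0, 180.1, 2.0))
    rotvecs = (axes[:, None, :] * angles[None, :, None]).reshape(-1, 3)
    rotvecs = np.vstack([[0.0, 0.0, 0.0], rotvecs])
    values = _rmsd_for_rotvecs(rotvecs, mob0, ref0)
    best = rotvecs[np.argmin(values)]
    res = scipy.optimize.minimize(
        lambda v: _rmsd_for_rotvecs(v[None], mob0, ref0)[0],
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(res.fun)
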