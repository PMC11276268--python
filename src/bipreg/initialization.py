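"""Automatic coarse pose initialization.

Iterative 2D-3D registration only converges from within a capture range
around the true pose, and the rotation parameters are the fragile ones.
The search space of rotations is therefore subdivided evenly: a 4 x 4 x 4
Euler grid gives 64 starting poses sharing one translation guess, a
capped registration is run from each, and the start with the smallest
registration RMSE is kept as the coarse approximation.  No prior pose
knowledge is required.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .estimation import RegistrationOptions, RegistrationResult, register
from .exceptions import BipregError, InitializationError
from .geometry import CameraModel, PointCloud, Pose, triangulate

__all__ = ["generate_start_poses", "default_translation_guess", "coarse_search"]

_GRID_ANGLES_DEG = (-135.0, -45.0, 45.0, 135.0)


def generate_start_poses(translation_guess: Sequence[float]) -> list[Pose]:
    """The 64 starting poses: an even 4^3 Euler grid at one translation.

    Each of omega, phi, kappa takes the values {-135, -45, 45, 135}
    degrees (the centers of an even fourfold subdivision of the circle),
    giving 64 rotations whose geodesic covering radius over SO(3) is well
    inside the capture range demonstrated by the coarse search.
    """
    t = np.asarray(translation_guess, dtype=float)
    return [
        Pose.from_degrees(t[0], t[1], t[2], om, ph, ka)
        for om in _GRID_ANGLES_DEG
        for ph in _GRID_ANGLES_DEG
        for ka in _GRID_ANGLES_DEG
    ]


def default_translation_guess(cameras: Sequence[CameraModel]) -> np.ndarray:
    """Midpoint of the two optical axes' closest approach.

    Places the model centroid in the middle of the measurement volume;
    assumes the model cloud is expressed about its centroid (the
    synthetic phantoms are).
    """
    c1, c2 = cameras[0], cameras[1]
    return triangulate(c1, c2, (c1.xp, c1.yp), (c2.xp, c2.yp))


def coarse_search(
    cloud: PointCloud,
    cameras: Sequence[CameraModel],
    master_points: Sequence[np.ndarray],
    translation_guess: Optional[Sequence[float]] = None,
    opts: Optional[RegistrationOptions] = None,
    coarse_iters: int = 10,
    return_details: bool = False,
):
    """Select the best of the 64 starting poses by registration RMSE.

    A registration capped at ``coarse_iters`` outer iterations is run
    from every start; the resulting pose with the smallest 2D RMSE wins
    (ties broken by lowest start index, so the selection is independent
    of evaluation order).  Full convergence is left to the caller, who
    should re-register from the returned pose.

    Returns the winning coarse ``Pose`` (optionally with the per-start
    RMSE array and results).
    """
    opts = opts or RegistrationOptions()
    # the coarse phase matches by optimal assignment: greedy nearest-point
    # matching from starts ~60 degrees away locks small unlabeled bead
    # constellations into wrong permutations (near-flip local minima)
    capped = replace(opts, max_outer=coarse_iters, max_iter=25, tol=max(opts.tol, 1e-6), assignment="optimal")
    if translation_guess is None:
        translation_guess = default_translation_guess(cameras)
    starts = generate_start_poses(translation_guess)
    rms = np.full(len(starts), np.inf)
    results: list[Optional[RegistrationResult]] = [None] * len(starts)
    for i, start in enumerate(starts):
        try:
            res = register(cloud, cameras, master_points, start, capped)
        except BipregError:
            continue
        results[i] = res
        rms[i] = res.rms_2d
    if not np.any(np.isfinite(rms)):
        raise InitializationError("all 64 starting poses failed to register", rms_per_start=rms)
    best = int(np.argmin(rms))  # argmin returns the first (lowest-index) minimum
    pose = results[best].pose
    if return_details:
        return pose, rms, results
    return pose
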