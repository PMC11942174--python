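"""Spherical-probe pore-radius profiling of ion-channel coordinates.

At each sample plane along the pore axis the profiler finds the largest
sphere, centered in that plane, that touches no atom: the probe radius is
max over center positions of min over atoms of (center-to-atom distance −
atom van der Waals radius). This is the quantity the HOLE program reports,
computed here with a deterministic coarse lateral grid followed by local
simplex refinement instead of simulated annealing, so results are exactly
reproducible and checkable against brute-force grids.

The pore axis must be supplied (channels are conventionally pre-oriented
with the 4-fold symmetry axis along z); no automatic axis detection is
attempted. All lengths are in Å.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "BONDI_RADII",
    "PoreProfileResult",
    "vdw_radii_for",
    "pore_profile",
    "min_radius_near",
]

#: Bondi van der Waals radii (Å) for common elements; override per element
#: via the ``radii`` argument of :func:`pore_profile`.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "K": 2.75,
    "NA": 2.27,
}


def vdw_radii_for(
    elements: Sequence[str], radii: Mapping[str, float] | None = None
) -> np.ndarray:
    """Per-atom vdW radii from the Bondi table with optional overrides."""
    table = dict(BONDI_RADII)
    if radii:
        for k, v in radii.items():
            if v <= 0:
                raise ValueError(f"vdW radius for {k!r} must be positive")
            table[k.upper()] = float(v)
    out = np.empty(len(elements))
    for i, e in enumerate(elements):
        key = str(e).upper()
        if key not in table:
            raise ValueError(f"no vdW radius for element {e!r}; supply an override")
        out[i] = table[key]
    return out


@dataclass
class PoreProfileResult:
    """Axial pore-radius profile and its constriction minimum.

    ``samples`` columns: z, radius, cx, cy (probe center), capped flag.
    ``min_z``/``min_radius`` locate the tightest constriction;
    ``min_residues`` lists the residue ids nearest the constriction probe
    when residue ids were supplied.
    """

    z: np.ndarray
    radius: np.ndarray
    center_xy: np.ndarray  # (n, 2)
    capped: np.ndarray  # (n,) bool
    min_z: float
    min_radius: float
    min_residues: list[int]


def _axis_rotation(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending ``axis`` to +z."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if not np.isclose(n, 1.0, atol=1e-6):
        raise ValueError("axis must be a unit vector")
    a = a / n
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, z)
    c = float(np.dot(a, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _clearance(cxy: np.ndarray, z: float, xyz: np.ndarray, vdw: np.ndarray) -> float:
    """min over atoms of (distance from (cx, cy, z) to atom − vdW radius)."""
    d = np.sqrt(
        (xyz[:, 0] - cxy[0]) ** 2 + (xyz[:, 1] - cxy[1]) ** 2 + (xyz[:, 2] - z) ** 2
    )
    return float(np.min(d - vdw))


def pore_profile(
    coords: np.ndarray,
    elements: Sequence[str],
    radii: Mapping[str, float] | None = None,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
    z_range: tuple[float, float] | None = None,
    z_step: float = 0.5,
    max_probe: float = 10.0,
    lateral_bound: float = 5.0,
    grid_step: float = 0.1,
    residue_ids: Sequence[int] | None = None,
) -> PoreProfileResult:
    """Maximal-probe-radius profile along a straight pore axis.

    At each z the probe center is optimized over the plane within
    ``lateral_bound`` of the axis: a deterministic hill-climb on a coarse
    lateral grid at ``grid_step`` (0.1 Å), seeded from the previous
    plane's optimal center (the axis for the first plane) so the probe
    stays in the pore's own basin rather than jumping outside the wall,
    followed by Nelder–Mead refinement from the best grid cell. Radii are
    capped at ``max_probe`` (flagged), including planes with no atoms in
    reach — a capped sample, not an error.
    """
    if z_step <= 0 or grid_step <= 0:
        raise ValueError("z_step and grid_step must be positive")
    xyz = np.asarray(coords, dtype=float) - np.asarray(axis_point, dtype=float)
    R = _axis_rotation(np.asarray(axis, dtype=float))
    xyz = xyz @ R.T
    vdw = vdw_radii_for(elements, radii)
    if z_range is None:
        z_range = (float(xyz[:, 2].min()), float(xyz[:, 2].max()))
    zs = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)

    g = np.arange(-lateral_bound, lateral_bound + 0.5 * grid_step, grid_step)
    n_g = len(g)

    rad = np.empty(len(zs))
    centers = np.empty((len(zs), 2))
    capped = np.zeros(len(zs), dtype=bool)
    reach = vdw.max() + max_probe + lateral_bound
    prev_center = np.zeros(2)  # start the climb on the axis
    for i, z in enumerate(zs):
        near = np.abs(xyz[:, 2] - z) <= reach
        if not near.any():
            rad[i], centers[i], capped[i] = max_probe, (0.0, 0.0), True
            continue
        sub, subv = xyz[near], vdw[near]
        # clearance lattice over the lateral grid (vectorized)
        d = np.sqrt(
            (g[:, None, None] - sub[None, None, :, 0]) ** 2
            + (g[None, :, None] - sub[None, None, :, 1]) ** 2
            + (z - sub[None, None, :, 2]) ** 2
        )
        clear = (d - subv[None, None, :]).min(axis=2)
        outside = g[:, None] ** 2 + g[None, :] ** 2 > lateral_bound**2
        clear[outside] = -np.inf
        # greedy 8-neighbor hill-climb from the previous plane's center
        ci = int(np.clip(round((prev_center[0] + lateral_bound) / grid_step), 0, n_g - 1))
        cj = int(np.clip(round((prev_center[1] + lateral_bound) / grid_step), 0, n_g - 1))
        while True:
            i0, i1 = max(ci - 1, 0), min(ci + 2, n_g)
            j0, j1 = max(cj - 1, 0), min(cj + 2, n_g)
            patch = clear[i0:i1, j0:j1]
            k = np.unravel_index(int(np.argmax(patch)), patch.shape)
            ni, nj = i0 + k[0], j0 + k[1]
            if clear[ni, nj] <= clear[ci, cj]:
                break
            ci, cj = ni, nj
        start = np.array([g[ci], g[cj]])

        def objective(c):
            # keep the refinement inside the lateral search bound
            if c[0] ** 2 + c[1] ** 2 > lateral_bound**2:
                return 1e6
            return -_clearance(c, z, sub, subv)

        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
        )
        if -res.fun >= clear[ci, cj]:
            c_opt, r = res.x, float(-res.fun)
        else:
            c_opt, r = start, float(clear[ci, cj])
        r = max(r, 0.0)
        if r >= max_probe:
            r, capped[i] = max_probe, True
        rad[i] = r
        centers[i] = c_opt
        prev_center = np.asarray(c_opt)

    imin = int(np.argmin(rad))
    min_res: list[int] = []
    if residue_ids is not None:
        rids = np.asarray(residue_ids, dtype=int)
        center3 = np.array([centers[imin, 0], centers[imin, 1], zs[imin]])
        d = np.linalg.norm(xyz - center3, axis=1) - vdw
        near = d <= rad[imin] + 1.0  # residues lining the constriction
        min_res = sorted(set(rids[near].tolist()))
    return PoreProfileResult(
        z=zs,
        radius=rad,
        center_xy=centers,
        capped=capped,
        min_z=float(zs[imin]),
        min_radius=float(rad[imin]),
        min_residues=min_res,
    )


def min_radius_near(
    profile: PoreProfileResult,
    residue_ids: Sequence[int],
    coords: np.ndarray,
    atom_residue_ids: Sequence[int],
    window: float = 4.0,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    axis_point: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[float, float]:
    """Local profile minimum within ±``window`` Å of the given residues.

    The residues' mean axial coordinate defines the search center (e.g. the
    helical-bundle-crossing phenylalanine ring of an inward-rectifier
    pore). A monotone profile inside the window returns the endpoint
    minimum with a warning; residues outside the profiled z-range are an
    error.
    """
    rids = np.asarray(atom_residue_ids, dtype=int)
    mask = np.isin(rids, np.asarray(residue_ids, dtype=int))
    if not mask.any():
        raise ValueError("none of the residues are present in the coordinates")
    xyz = np.asarray(coords, dtype=float) - np.asarray(axis_point, dtype=float)
    R = _axis_rotation(np.asarray(axis, dtype=float))
    z0 = float((xyz @ R.T)[mask, 2].mean())
    if z0 < profile.z.min() or z0 > profile.z.max():
        raise ValueError(
            f"residue axial coordinate {z0:.2f} Å is outside the profiled range"
        )
    sel = np.abs(profile.z - z0) <= window
    if not sel.any():
        raise ValueError("window contains no profile samples")
    zw, rw = profile.z[sel], profile.radius[sel]
    j = int(np.argmin(rw))
    if j in (0, len(rw) - 1) and len(rw) > 2:
        import warnings

        warnings.warn(
            "profile is monotone within the window; endpoint minimum returned",
            stacklevel=2,
        )
    return float(zw[j]), float(rw[j])
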