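"""Independent reference implementations used only by the test suite.

Each oracle deliberately takes a different computational route from the
package code it checks: quaternion (Horn) superposition vs SVD Kabsch,
similarity-matrix round-recount Butina vs neighbor-set sphere exclusion,
plain all-pairs distance loops vs k-d tree contact counting, and a dense
lateral grid scan vs coarse-grid + simplex pore probing.
"""

from __future__ import annotations

import numpy as np


def horn_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Horn's closed-form quaternion solution for optimal rigid superposition."""
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    A, B = P - pc, Q - qc
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, np.argmax(w)]
    q0, q1, q2, q3 = q
    R = np.array(
        [
            [
                q0**2 + q1**2 - q2**2 - q3**2,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0**2 - q1**2 + q2**2 - q3**2,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0**2 - q1**2 - q2**2 + q3**2,
            ],
        ]
    )
    t = qc - pc @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def brute_force_butina(bit_sets: list[frozenset], ids: list[str], cutoff: float):
    """Sphere-exclusion clustering via an explicit similarity matrix.

    Recomputes every compound's unassigned-neighbor count from the matrix
    each round; ties broken by ascending compound id. Returns the same
    assignment mapping as the package's butina_cluster.
    """
    n = len(bit_sets)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            u = len(bit_sets[i] | bit_sets[j])
            sim[i, j] = len(bit_sets[i] & bit_sets[j]) / u if u else 0.0
    assigned = np.zeros(n, dtype=bool)
    assignment: dict[str, int] = {}
    cluster = 0
    order = np.argsort(np.array(ids, dtype=object))
    while not assigned.all():
        counts = []
        for i in range(n):
            if assigned[i]:
                counts.append(-1)
            else:
                counts.append(
                    int(((sim[i] >= cutoff) & ~assigned & (np.arange(n) != i)).sum())
                )
        best_count = max(counts)
        # ascending-id tie break among the max-count compounds
        centroid = next(
            int(i) for i in order if not assigned[i] and counts[i] == best_count
        )
        members = [centroid] + [
            j
            for j in range(n)
            if j != centroid and not assigned[j] and sim[centroid, j] >= cutoff
        ]
        for m in members:
            assignment[ids[m]] = cluster
            assigned[m] = True
        cluster += 1
    return assignment


def brute_force_contact_fractions(run, residue_ids, heavy_mask, ligand_idx, cutoff):
    """All-pairs min-distance contact fractions for one run; plain loops."""
    n_frames = run.shape[0]
    out: dict[int, float] = {}
    lig = sorted(set(int(i) for i in ligand_idx))
    for rid in sorted(set(int(r) for r in residue_ids)):
        atoms = [
            i
            for i in range(run.shape[1])
            if residue_ids[i] == rid and heavy_mask[i] and i not in lig
        ]
        if not atoms:
            continue
        hits = 0
        for f in range(n_frames):
            dmin = min(
                float(np.linalg.norm(run[f, a] - run[f, l]))
                for a in atoms
                for l in lig
            )
            if dmin <= cutoff:
                hits += 1
        out[rid] = hits / n_frames
    return out


def dense_grid_pore_radius(xyz, vdw, z, bound=5.0, step=0.02):
    """Max probe radius at one z by a dense lateral grid scan."""
    g = np.arange(-bound, bound + step / 2, step)
    gx, gy = np.meshgrid(g, g)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(
        (centers[:, 0, None] - xyz[None, :, 0]) ** 2
        + (centers[:, 1, None] - xyz[None, :, 1]) ** 2
        + (z - xyz[None, :, 2]) ** 2
    )
    return float((d - vdw[None, :]).min(axis=1).max())
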