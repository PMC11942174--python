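"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator is a pure function of its spec: the same spec and seed
produce bit-identical output, and every truth record carries the seed it
was generated with. The fixtures emulate, at desk scale:

* ``gen_trajectory`` — a multi-run MD-like ensemble of a ligand in a
  pocket, with planted per-fragment center-of-mass jitter (isotropic
  Gaussian, per-fragment σ), planted per-residue contact occupancies
  realized exactly against the analyzer's own distance definition
  (minimum heavy-atom pair distance), and optional per-frame rigid-body
  drift that pocket alignment must remove;
* ``gen_plate`` — an Rb+ efflux dose-response plate drawn from a known
  variable-slope Hill inhibition curve, with an untransfected-background
  channel and multiplicative log-normal noise on the raw signals (raw
  instrument readings are positive, so noise is multiplicative on signals
  rather than additive on fractions);
* ``gen_library`` — a fingerprint library with planted Butina-recoverable
  cluster structure and known-binder look-alikes for the novelty filter;
* ``gen_pore`` — atom-tiled cylinder / constricted-cylinder pore walls
  whose analytic probe-radius profile (wall radius − atom radius) is the
  truth for the profiler.

The toy pocket geometry places residues on a ring around a central ligand;
contact occupancies are planted by moving the planted residue's outermost
side-chain atom to a fixed distance inside (2.8 Å) or outside (its resting
position, ≥ 6 Å) the contact cutoff relative to the nearest ligand heavy
atom of that frame, so planted truths hold exactly even under fragment
jitter. Pocket Cα atoms never move relative to the pocket frame, keeping
the alignment reference clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .efflux import WELL_COLUMNS, hill_curve
from .pocket import Topology, TrajectoryEnsemble
from .triage import FingerprintRecord

__all__ = [
    "TrajectorySpec",
    "PlateSpec",
    "LibrarySpec",
    "PoreSpec",
    "gen_trajectory",
    "gen_plate",
    "gen_library",
    "gen_pore",
    "cylinder_profile",
    "constricted_profile",
]

_CONTACT_DISTANCE = 2.8  # Å, planted in-contact heavy-atom distance (< 3.5)
_RING_RADIUS = 12.0  # Å, pocket Cα ring radius


# --------------------------------------------------------------------------
# trajectory fixtures


@dataclass
class TrajectorySpec:
    """MD-like ensemble fixture: runs, frames, jitter, contacts, drift.

    ``fragment_sigmas`` maps fragment labels (``"a"``..``"e"``) to the
    isotropic per-axis jitter SD in Å; ``contact_plan`` maps
    ``(residue_id, run_index)`` to a target contact occupancy in [0, 1];
    ``global_drift`` scales a per-frame rigid rotation+translation applied
    to all atoms (0 disables it).
    """

    n_runs: int = 5
    n_frames: int = 100
    pocket_residues: Sequence[int] = tuple(range(1, 13))
    fragment_sigmas: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.0 for k in "abcde"}
    )
    contact_plan: Mapping[tuple[int, int], float] = field(default_factory=dict)
    global_drift: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1 or self.n_frames < 1:
            raise ValueError("n_runs and n_frames must be >= 1")
        for k, s in self.fragment_sigmas.items():
            if s < 0:
                raise ValueError(f"fragment {k!r} sigma must be >= 0")
            if k not in "abcde":
                raise ValueError(f"unknown fragment label {k!r}")
        for (rid, run), q in self.contact_plan.items():
            if rid not in self.pocket_residues:
                raise ValueError(
                    f"infeasible contact plan: residue {rid} not in the pocket"
                )
            if not 0 <= run < self.n_runs:
                raise ValueError(f"infeasible contact plan: run {run} out of range")
            if not 0.0 <= q <= 1.0:
                raise ValueError(
                    f"infeasible contact plan: occupancy {q} for residue {rid} "
                    "outside [0, 1]"
                )


def _base_geometry(spec: TrajectorySpec):
    """Static atom table and resting coordinates of the toy pocket."""
    atoms = []  # (id, name, element, resid, resname, chain)
    coords = []
    aid = 1
    for i, rid in enumerate(spec.pocket_residues):
        theta = 2 * math.pi * i / len(spec.pocket_residues)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        for name, r_off, z in (("CA", _RING_RADIUS, 0.0),
                               ("CB", _RING_RADIUS - 1.5, 0.3),
                               ("CG", _RING_RADIUS - 3.0, 0.0)):
            atoms.append((aid, name, "C", rid, "POC", "A"))
            coords.append(u * r_off + np.array([0.0, 0.0, z]))
            aid += 1
    fragments: dict[str, list[int]] = {}
    lig_rid = max(spec.pocket_residues) + 100
    for k, frag in enumerate("abcde"):
        phi = 2 * math.pi * k / 5
        center = 1.5 * np.array([math.cos(phi), math.sin(phi), 0.0])
        ids = []
        for j in range(2):
            atoms.append((aid, f"C{k}{j}", "C", lig_rid, "LIG", "L"))
            coords.append(center + np.array([0.0, 0.0, 0.5 * (j - 0.5)]))
            ids.append(aid)
            aid += 1
        if frag == "a":  # one hydrogen exercises heavy-atom exclusion
            atoms.append((aid, "H01", "H", lig_rid, "LIG", "L"))
            coords.append(center + np.array([0.4, 0.0, 0.0]))
            ids.append(aid)
            aid += 1
        fragments[frag] = ids
    topo = Topology(
        atom_ids=np.array([a[0] for a in atoms]),
        elements=np.array([a[2] for a in atoms], dtype=object),
        residue_ids=np.array([a[3] for a in atoms]),
        residue_names=np.array([a[4] for a in atoms], dtype=object),
        chain_ids=np.array([a[5] for a in atoms], dtype=object),
        atom_names=np.array([a[1] for a in atoms], dtype=object),
        selections={
            "pocket_ca": [a[0] for a in atoms if a[1] == "CA"],
            "pocket": [a[0] for a in atoms if a[4] == "POC"],
            "ligand": [a[0] for a in atoms if a[4] == "LIG"],
        },
    )
    return topo, np.array(coords), fragments, lig_rid


def _random_rotation(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(-max_angle, max_angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * K @ K


def gen_trajectory(spec: TrajectorySpec):
    """Build (Topology, TrajectoryEnsemble, AtomGroupScheme, truth record).

    Contact occupancies are realized in exactly ``round(q · n_frames)``
    frames per planted (residue, run), chosen without replacement by the
    seeded RNG; frame 0 of each run is the resting geometry (no jitter, no
    drift), serving as the mobility reference.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    topo, base, fragments, lig_rid = _base_geometry(spec)
    heavy = topo.heavy_mask
    lig_heavy_idx = topo.indices(topo.selections["ligand"])
    lig_heavy_idx = lig_heavy_idx[heavy[lig_heavy_idx]]

    # contact schedules: planted frames per (residue, run)
    schedule: dict[tuple[int, int], np.ndarray] = {}
    realized: dict[str, float] = {}
    for (rid, run), q in spec.contact_plan.items():
        k = round(q * spec.n_frames)
        frames = rng.choice(spec.n_frames, size=k, replace=False)
        schedule[(rid, run)] = np.sort(frames)
        realized[f"{rid}:{run}"] = k / spec.n_frames

    cg_index = {}  # residue id -> array index of its innermost (CG) atom
    for rid in spec.pocket_residues:
        sel = np.flatnonzero(
            (topo.residue_ids == rid) & (topo.atom_names == "CG")
        )
        cg_index[rid] = int(sel[0])

    runs = []
    for run in range(spec.n_runs):
        frames = np.empty((spec.n_frames, topo.n_atoms, 3))
        for f in range(spec.n_frames):
            xyz = base.copy()
            if f > 0:  # frame 0 is the resting reference
                for frag, ids in fragments.items():
                    sigma = spec.fragment_sigmas.get(frag, 0.0)
                    if sigma > 0:
                        xyz[topo.indices(ids)] += rng.normal(0, sigma, size=3)
            # plant contacts against this frame's actual ligand coordinates
            for (rid, prun), fr in schedule.items():
                if prun != run:
                    continue
                ci = cg_index[rid]
                u = base[ci, :2]
                u = np.append(u / np.linalg.norm(u), 0.0)
                lig = xyz[lig_heavy_idx]
                # nearest ligand heavy atom along the residue's radial line
                j = int(np.argmin(np.linalg.norm(lig - base[ci], axis=1)))
                if f in fr:
                    xyz[ci] = lig[j] + u * _CONTACT_DISTANCE
                # else: CG stays at rest, >= 6 Å from any ligand atom
            if spec.global_drift > 0 and f > 0:
                R = _random_rotation(rng, 0.1 * spec.global_drift)
                t = rng.uniform(-spec.global_drift, spec.global_drift, size=3)
                xyz = xyz @ R.T + t
            frames[f] = xyz
        runs.append(frames)

    truth = {
        "seed": spec.seed,
        "n_runs": spec.n_runs,
        "n_frames": spec.n_frames,
        "fragment_sigmas": dict(spec.fragment_sigmas),
        "planted_occupancy": realized,
        "contact_frames": {k: v.tolist() for k, v in
                           ((f"{r}:{ru}", fr) for (r, ru), fr in schedule.items())},
        "contact_distance": _CONTACT_DISTANCE,
    }
    return topo, TrajectoryEnsemble(runs), dict(fragments), truth


# --------------------------------------------------------------------------
# dose-response plate fixtures


@dataclass
class PlateSpec:
    """Efflux plate fixture drawn from a known Hill inhibition curve.

    ``hill_truth`` is (top, bottom, ic50 µM, slope) of the planted curve on
    the fractional-efflux scale; ``background_fraction`` is the
    untransfected (endogenous) fractional efflux added to every
    transfected well and carried alone by untransfected control wells.
    """

    hill_truth: tuple[float, float, float, float] = (0.7, 0.05, 9.23, 1.0)
    doses: Sequence[float] = (0.0, 1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 200.0)
    n_technical: int = 2
    n_biological: int = 3
    noise_cv: float = 0.05
    background_fraction: float = 0.1
    condition: str = "WT"
    total_signal: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        top, bottom, ic50, slope = self.hill_truth
        if ic50 <= 0:
            raise ValueError("planted ic50 must be > 0")
        if not 0 <= bottom <= top:
            raise ValueError("need 0 <= bottom <= top")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if not 0 <= self.background_fraction < top:
            raise ValueError("background_fraction must lie in [0, top)")
        if self.background_fraction + top > 1.0:
            raise ValueError("background + top exceeds 1: fractions would leave [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_technical < 1 or self.n_biological < 1:
            raise ValueError("replicate counts must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_plate(spec: PlateSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate one efflux plate; returns (well table, truth record).

    The noiseless fractional efflux of a transfected well at dose x is
    ``background_fraction + hill(x)``; untransfected wells carry the
    background alone. Signals are split from ``total_signal`` by that
    fraction and multiplied by unit-mean log-normal noise of the stated
    CV, independently per signal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    top, bottom, ic50, slope = spec.hill_truth
    rows = []
    for b in range(spec.n_biological):
        for dose in spec.doses:
            f = spec.background_fraction + float(
                hill_curve(dose, top, bottom, ic50, slope)
            )
            for t in range(spec.n_technical):
                e = f * spec.total_signal * _lognormal_factor(rng, spec.noise_cv, None)
                l = (1 - f) * spec.total_signal * _lognormal_factor(
                    rng, spec.noise_cv, None
                )
                rows.append(
                    (spec.condition, dose, t, b, float(e), float(l), False)
                )
        for t in range(spec.n_technical):  # untransfected background controls
            f = spec.background_fraction
            e = f * spec.total_signal * _lognormal_factor(rng, spec.noise_cv, None)
            l = (1 - f) * spec.total_signal * _lognormal_factor(
                rng, spec.noise_cv, None
            )
            rows.append(("untransfected", 0.0, t, b, float(e), float(l), True))
    wells = pd.DataFrame(rows, columns=WELL_COLUMNS)
    truth = {
        "seed": spec.seed,
        "hill_truth": {"top": top, "bottom": bottom, "ic50_uM": ic50, "slope": slope},
        "background_fraction": spec.background_fraction,
        "noise_cv": spec.noise_cv,
        "condition": spec.condition,
    }
    return wells, truth


# --------------------------------------------------------------------------
# fingerprint library fixtures


@dataclass
class LibrarySpec:
    """Fingerprint library with planted clusters and known-binder copies.

    ``cluster_plan`` lists (size, bit-flip rate) per planted cluster: each
    cluster grows from a random seed fingerprint whose bits members flip
    independently at the stated rate. ``known_binder_seeds`` compounds are
    exact-structure look-alikes of generated known binders (flip rate 0),
    which the novelty filter must remove. Remaining compounds are random
    background. Scores default to uniform(0, 1) unless ``score_model`` is
    given a callable mapping compound id -> score.
    """

    n_compounds: int = 60
    n_bits: int = 256
    n_on_bits: int = 32
    cluster_plan: Sequence[tuple[int, float]] = ((10, 0.0), (10, 0.0))
    known_binder_seeds: int = 3
    score_model: Callable[[str], float] | None = None
    seed: int = 0

    def validate(self) -> None:
        planted = sum(s for s, _ in self.cluster_plan) + self.known_binder_seeds
        if planted > self.n_compounds:
            raise ValueError("cluster sizes + binder copies exceed n_compounds")
        for s, rate in self.cluster_plan:
            if s < 1:
                raise ValueError("cluster sizes must be >= 1")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("flip rates must lie in [0, 1]")
        if not 0 < self.n_on_bits <= self.n_bits:
            raise ValueError("need 0 < n_on_bits <= n_bits")


def _random_fp(rng: np.random.Generator, n_bits: int, n_on: int) -> frozenset[int]:
    return frozenset(int(b) for b in rng.choice(n_bits, size=n_on, replace=False))


def _flip(
    rng: np.random.Generator, fp: frozenset[int], n_bits: int, rate: float
) -> frozenset[int]:
    if rate == 0:
        return fp
    bits = set(fp)
    flips = np.flatnonzero(rng.random(n_bits) < rate)
    for b in flips:
        b = int(b)
        bits.symmetric_difference_update({b})
    return frozenset(bits)


def _props(rng: np.random.Generator) -> dict[str, float]:
    return {
        "mw": float(rng.uniform(250, 480)),
        "logp": float(rng.uniform(0.5, 4.5)),
        "hbd": int(rng.integers(0, 5)),
        "hba": int(rng.integers(1, 9)),
        "toxicophore_alerts": 0,
    }


def gen_library(spec: LibrarySpec) -> tuple[list[FingerprintRecord], dict]:
    """Build (records, truth record) with planted cluster/binder structure."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[FingerprintRecord] = []
    truth_clusters: dict[str, list[str]] = {}
    binder_fps: list[frozenset[int]] = []
    lookalikes: list[str] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"CMP{counter:05d}"

    for b in range(spec.known_binder_seeds):
        kb = _random_fp(rng, spec.n_bits, spec.n_on_bits)
        binder_fps.append(kb)
        cid = next_id()
        lookalikes.append(cid)
        records.append(FingerprintRecord(cid, kb, None, _props(rng)))

    for c, (size, rate) in enumerate(spec.cluster_plan):
        seed_fp = _random_fp(rng, spec.n_bits, spec.n_on_bits)
        members = []
        for _ in range(size):
            cid = next_id()
            members.append(cid)
            records.append(
                FingerprintRecord(
                    cid, _flip(rng, seed_fp, spec.n_bits, rate), None, _props(rng)
                )
            )
        truth_clusters[f"cluster{c}"] = members

    while len(records) < spec.n_compounds:
        cid = next_id()
        records.append(
            FingerprintRecord(
                cid, _random_fp(rng, spec.n_bits, spec.n_on_bits), None, _props(rng)
            )
        )

    scored = []
    for rec in records:
        s = (
            spec.score_model(rec.compound_id)
            if spec.score_model is not None
            else float(rng.uniform(0, 1))
        )
        scored.append(
            FingerprintRecord(rec.compound_id, rec.bits, s, rec.properties)
        )
    truth = {
        "seed": spec.seed,
        "clusters": truth_clusters,
        "known_binders": [sorted(fp) for fp in binder_fps],
        "binder_lookalikes": lookalikes,
    }
    return scored, truth


# --------------------------------------------------------------------------
# pore fixtures


def cylinder_profile(
    z_min: float, z_max: float, step: float, wall_radius: float
) -> dict[float, float]:
    """Constant-radius wall profile over a contiguous z-range."""
    return {
        float(z): float(wall_radius)
        for z in np.arange(z_min, z_max + 0.5 * step, step)
    }


def constricted_profile(
    z_min: float,
    z_max: float,
    step: float,
    wall_radius: float,
    min_wall_radius: float,
    z_constriction: float,
    width: float = 3.0,
) -> dict[float, float]:
    """Cylinder with a smooth Gaussian constriction at ``z_constriction``."""
    zs = np.arange(z_min, z_max + 0.5 * step, step)
    depth = wall_radius - min_wall_radius
    return {
        float(z): float(
            wall_radius - depth * math.exp(-0.5 * ((z - z_constriction) / width) ** 2)
        )
        for z in zs
    }


@dataclass
class PoreSpec:
    """Atom-tiled pore wall of known geometry.

    ``wall_radius_profile`` maps axial coordinate z (Å) to the inner wall
    radius at that z; atoms of ``atom_radius`` tile each ring at roughly
    ``atom_spacing``. The analytic probe-radius truth at each z is
    wall radius − atom radius.
    """

    wall_radius_profile: Mapping[float, float] = field(
        default_factory=lambda: cylinder_profile(-10.0, 10.0, 0.5, 4.0)
    )
    atom_radius: float = 1.5
    atom_spacing: float = 0.5
    element: str = "C"
    seed: int = 0

    def validate(self) -> None:
        if self.atom_radius <= 0 or self.atom_spacing <= 0:
            raise ValueError("atom_radius and atom_spacing must be positive")
        if not self.wall_radius_profile:
            raise ValueError("wall profile is empty")
        zs = sorted(self.wall_radius_profile)
        gaps = np.diff(zs)
        if len(gaps) and (gaps.max() > 2.05 * min(gaps)):
            raise ValueError("wall profile must cover a contiguous z-range")
        if any(r <= 0 for r in self.wall_radius_profile.values()):
            raise ValueError("wall radii must be positive")


def gen_pore(spec: PoreSpec) -> tuple[dict, dict]:
    """Tile the stated wall with atoms; return (coordinate set, truth).

    The coordinate set dict holds ``coords`` (n, 3), ``elements``,
    ``residue_ids`` (one residue per ring, numbered from 1 along z) and the
    ``radii`` override mapping the tile element to ``atom_radius``. The
    truth records the analytic profile, its minimum, and a coarse-tiling
    warning flag when angular gaps exceed the atom radius.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coords, rids = [], []
    coarse = False
    zs = sorted(spec.wall_radius_profile)
    for ring, z in enumerate(zs, start=1):
        # atom centers sit on the stated wall radius, so the analytic probe
        # radius on-axis is wall_radius - atom_radius
        wall = spec.wall_radius_profile[z]
        n_ring = max(8, int(math.ceil(2 * math.pi * wall / spec.atom_spacing)))
        gap = 2 * math.pi * wall / n_ring
        if gap > spec.atom_radius:
            coarse = True
        phase = rng.uniform(0, 2 * math.pi)
        for k in range(n_ring):
            a = phase + 2 * math.pi * k / n_ring
            coords.append((wall * math.cos(a), wall * math.sin(a), z))
            rids.append(ring)
    probe_truth = {
        z: float(spec.wall_radius_profile[z] - spec.atom_radius) for z in zs
    }
    zmin = min(probe_truth, key=probe_truth.get)
    coordset = {
        "coords": np.array(coords),
        "elements": [spec.element] * len(coords),
        "residue_ids": np.array(rids),
        "radii": {spec.element: spec.atom_radius},
    }
    truth = {
        "seed": spec.seed,
        "probe_radius_profile": probe_truth,
        "min_probe_radius": probe_truth[zmin],
        "min_z": float(zmin),
        "coarse_tiling": coarse,
    }
    return coordset, truth
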