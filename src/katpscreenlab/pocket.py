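"""Binding-pocket dynamics analysis of MD coordinate ensembles.

Given a multi-run ensemble of frames (e.g. five independent production
runs of a ligand-bound channel), this module

* superposes every frame onto frame 0 of its own run on a pocket
  selection (Kabsch least-squares rigid fit), removing global channel
  motion so that only motion relative to the pocket remains;
* tracks the center of mass of named ligand fragments through the aligned
  frames and summarizes each fragment's mobility as the root-mean-square
  scalar displacement from its initial (frame 0) position;
* computes per-residue contact fractions — the fraction of frames in which
  a residue's minimum heavy-atom distance to the ligand is within a cutoff
  (3.5 Å by default) — and aggregates them into a retained binding-residue
  set with an at-least-30%-in-at-least-3-of-5-runs rule.

Coordinates are in Å. Hydrogens are excluded from contacts and centers of
mass by default; per-frame neighbor searches use a k-d tree, whose
correctness is anchored by an exhaustive all-pairs oracle in the test
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "AtomGroupScheme",
    "MobilityReport",
    "ContactReport",
    "kabsch_superpose",
    "align_ensemble",
    "group_com_trace",
    "contact_fractions",
    "aggregate_contacts",
    "frequency_report",
]

# monoisotopic-ish masses for the elements fixtures use; others fall back to 12
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


@dataclass
class Topology:
    """Static atom table plus named selections.

    ``atom_ids`` are unique serial numbers (PDB convention, 1-based);
    residue ids are 1-based and user-facing. ``selections`` maps a name
    (e.g. ``"pocket_ca"``, ``"ligand"``) to a list of atom ids.
    """

    atom_ids: np.ndarray  # (n,) int
    elements: np.ndarray  # (n,) str
    residue_ids: np.ndarray  # (n,) int
    residue_names: np.ndarray  # (n,) str
    chain_ids: np.ndarray  # (n,) str
    atom_names: np.ndarray | None = None
    selections: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=int)
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom ids must be unique")
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        if self.atom_names is not None:
            self.atom_names = np.asarray(self.atom_names, dtype=object)
        self._index = {int(a): i for i, a in enumerate(self.atom_ids)}
        for name, ids in self.selections.items():
            unknown = [a for a in ids if a not in self._index]
            if unknown:
                raise ValueError(f"selection {name!r} references unknown atoms {unknown}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_MASSES.get(str(e), 12.0) for e in self.elements])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([str(e).upper() != "H" for e in self.elements])

    def indices(self, atom_ids: Sequence[int]) -> np.ndarray:
        """Array positions for the given atom serial numbers."""
        try:
            return np.array([self._index[int(a)] for a in atom_ids], dtype=int)
        except KeyError as exc:
            raise ValueError(f"unknown atom id {exc.args[0]}") from None

    def selection_indices(self, name: str) -> np.ndarray:
        if name not in self.selections:
            raise ValueError(f"no selection named {name!r}")
        return self.indices(self.selections[name])


@dataclass
class TrajectoryEnsemble:
    """Coordinate stacks for several independent runs sharing one topology."""

    runs: list[np.ndarray]  # each (n_frames, n_atoms, 3), Å
    stride: int = 1

    def __post_init__(self) -> None:
        self.runs = [np.asarray(r, dtype=float) for r in self.runs]
        if not self.runs:
            raise ValueError("ensemble must contain at least one run")
        n_atoms = self.runs[0].shape[1]
        for i, r in enumerate(self.runs):
            if r.ndim != 3 or r.shape[2] != 3:
                raise ValueError(f"run {i} is not a (frames, atoms, 3) array")
            if r.shape[1] != n_atoms:
                raise ValueError(f"run {i} atom count {r.shape[1]} != {n_atoms}")
            if not np.all(np.isfinite(r)):
                raise ValueError(f"run {i} contains non-finite coordinates")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


# an ordered group-label -> atom-id list map (ligand fragments a..e, or one
# group per residue of interest); groups may overlap and need not partition
AtomGroupScheme = Mapping[str, Sequence[int]]


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` with the proper rotation (det +1) and
    translation mapping ``mobile`` onto ``reference`` as
    ``mobile @ R.T + t``. Requires >= 3 non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) selection; superposition undefined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def align_ensemble(
    ensemble: TrajectoryEnsemble, topology: Topology, selection: str | Sequence[int]
) -> TrajectoryEnsemble:
    """Superpose every frame onto frame 0 of its own run over a selection.

    The rigid transform fitted on the selection (pocket Cα atoms in the
    intended use) is applied to *all* atoms of the frame, so ligand and
    peptide atoms ride along.
    """
    idx = (
        topology.selection_indices(selection)
        if isinstance(selection, str)
        else topology.indices(selection)
    )
    aligned_runs = []
    for run_i, run in enumerate(ensemble.runs):
        ref = run[0, idx]
        out = np.empty_like(run)
        out[0] = run[0]
        for f in range(1, run.shape[0]):
            try:
                R, t, _ = kabsch_superpose(run[f, idx], ref)
            except ValueError as exc:
                raise ValueError(f"run {run_i} frame {f}: {exc}") from None
            out[f] = run[f] @ R.T + t
        aligned_runs.append(out)
    return TrajectoryEnsemble(aligned_runs, stride=ensemble.stride)


@dataclass
class MobilityReport:
    """Per-fragment COM traces and displacement SDs.

    ``com`` maps group label -> list (per run) of (n_frames, 3) COM traces.
    ``sd_per_run`` holds, per group and run, the root-mean-square scalar
    distance of the COM from its frame-0 position; ``sd_pooled`` is the
    root-mean of the per-run values. For isotropic positional jitter of
    standard deviation σ per axis the expected pooled SD is √3·σ.
    """

    com: dict[str, list[np.ndarray]]
    sd_per_run: pd.DataFrame  # index: group, columns: run index
    sd_pooled: pd.Series  # index: group


def group_com_trace(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    scheme: AtomGroupScheme,
    mass_weighted: bool = True,
    heavy_only: bool = True,
) -> MobilityReport:
    """Center-of-mass traces and mobility SDs per named atom group.

    The ensemble is expected to be pocket-aligned already. COM is
    mass-weighted over heavy atoms by default; a geometric center of all
    atoms is available via the flags for sensitivity checks.
    """
    masses_all = topology.masses
    heavy_all = topology.heavy_mask
    com: dict[str, list[np.ndarray]] = {}
    sd = {}
    for label, atom_ids in scheme.items():
        if len(atom_ids) == 0:
            raise ValueError(f"group {label!r} is empty")
        idx = topology.indices(atom_ids)
        if heavy_only:
            idx = idx[heavy_all[idx]]
            if len(idx) == 0:
                raise ValueError(
                    f"group {label!r} contains only hydrogens under heavy-atom-only COM"
                )
        w = masses_all[idx] if mass_weighted else np.ones(len(idx))
        w = w / w.sum()
        traces, sds = [], []
        for run in ensemble.runs:
            trace = np.einsum("fai,a->fi", run[:, idx], w)
            d = np.linalg.norm(trace - trace[0], axis=1)
            traces.append(trace)
            sds.append(float(np.sqrt(np.mean(d**2))))
        com[label] = traces
        sd[label] = sds
    sd_df = pd.DataFrame.from_dict(sd, orient="index")
    pooled = np.sqrt((sd_df**2).mean(axis=1))
    return MobilityReport(com=com, sd_per_run=sd_df, sd_pooled=pooled)


@dataclass
class ContactReport:
    """Per-residue, per-run ligand contact fractions.

    ``fractions``: DataFrame indexed by residue id, one column per run,
    whole-ligand contact fraction. ``group_fractions`` holds the same per
    ligand fragment. ``n_frames`` lists frames per run.
    """

    fractions: pd.DataFrame
    group_fractions: dict[str, pd.DataFrame]
    n_frames: list[int]
    cutoff: float


def _contact_counts(
    run: np.ndarray,
    residue_indices: dict[int, np.ndarray],
    ligand_idx: np.ndarray,
    cutoff: float,
) -> dict[int, int]:
    """Frames in contact per residue for one run (k-d tree per frame)."""
    counts = {rid: 0 for rid in residue_indices}
    prot_idx = np.concatenate(list(residue_indices.values()))
    prot_rid = np.concatenate(
        [np.full(len(v), rid) for rid, v in residue_indices.items()]
    )
    for f in range(run.shape[0]):
        tree = cKDTree(run[f, ligand_idx])
        d, _ = tree.query(run[f, prot_idx], k=1, distance_upper_bound=cutoff * 1.0001)
        hit_rids = np.unique(prot_rid[d <= cutoff])
        for rid in hit_rids:
            counts[int(rid)] += 1
    return counts


def contact_fractions(
    ensemble: TrajectoryEnsemble,
    topology: Topology,
    ligand_selection: str | Sequence[int],
    scheme: AtomGroupScheme | None = None,
    cutoff: float = 3.5,
) -> ContactReport:
    """Fraction of frames each residue spends in close contact with the ligand.

    A residue is in contact in a frame iff the minimum heavy-atom pair
    distance between any of its atoms and any ligand atom is <= ``cutoff``
    (inclusive). The per-group breakdown repeats the computation with each
    fragment's atoms in place of the full ligand. Monotone non-decreasing
    in the cutoff by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_idx = (
        topology.selection_indices(ligand_selection)
        if isinstance(ligand_selection, str)
        else topology.indices(ligand_selection)
    )
    heavy = topology.heavy_mask
    lig_idx = lig_idx[heavy[lig_idx]]
    if len(lig_idx) == 0:
        raise ValueError("ligand selection is empty (or all hydrogens)")

    lig_set = set(lig_idx.tolist())
    residue_indices: dict[int, np.ndarray] = {}
    for rid in np.unique(topology.residue_ids):
        idx = np.flatnonzero((topology.residue_ids == rid) & heavy)
        idx = np.array([i for i in idx if i not in lig_set], dtype=int)
        if len(idx):
            residue_indices[int(rid)] = idx

    frames = [run.shape[0] for run in ensemble.runs]

    def fractions_for(selection_idx: np.ndarray) -> pd.DataFrame:
        cols = {}
        for r, run in enumerate(ensemble.runs):
            counts = _contact_counts(run, residue_indices, selection_idx, cutoff)
            cols[r] = {rid: counts[rid] / run.shape[0] for rid in counts}
        return pd.DataFrame(cols).sort_index()

    whole = fractions_for(lig_idx)
    groups: dict[str, pd.DataFrame] = {}
    if scheme is not None:
        for label, atom_ids in scheme.items():
            gi = topology.indices(atom_ids)
            gi = gi[heavy[gi]]
            if len(gi) == 0:
                raise ValueError(f"group {label!r} has no heavy atoms")
            groups[label] = fractions_for(gi)
    return ContactReport(
        fractions=whole, group_fractions=groups, n_frames=frames, cutoff=cutoff
    )


def aggregate_contacts(
    report: ContactReport,
    inclusion_fraction: float = 0.30,
    run_quorum: int | None = None,
) -> set[int]:
    """Residues in contact >= ``inclusion_fraction`` of frames in enough runs.

    Both comparisons are inclusive ("at least"). The default quorum is 3 of
    5 runs, generalized to ceil(3/5 · n_runs) for other ensemble sizes.
    """
    n_runs = report.fractions.shape[1]
    if run_quorum is None:
        run_quorum = math.ceil(3 * n_runs / 5)
    if run_quorum > n_runs:
        raise ValueError(f"run quorum {run_quorum} exceeds number of runs {n_runs}")
    if run_quorum < 1:
        raise ValueError("run quorum must be >= 1")
    ok = (report.fractions >= inclusion_fraction).sum(axis=1) >= run_quorum
    return set(report.fractions.index[ok].astype(int))


def frequency_report(
    report: ContactReport, display_threshold: float = 0.40
) -> pd.DataFrame:
    """Residue-by-fragment mean contact-fraction table at a display threshold.

    Rows are restricted to residues whose whole-ligand contact fraction,
    averaged across runs, is *strictly greater* than the threshold; the
    per-fragment columns for those rows are reported unfiltered.
    """
    mean_whole = report.fractions.mean(axis=1)
    keep = mean_whole[mean_whole > display_threshold].index
    out = pd.DataFrame({"ligand": mean_whole.loc[keep]})
    for label, df in report.group_fractions.items():
        out[label] = df.mean(axis=1).reindex(keep)
    return out.sort_values("ligand", ascending=False)
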