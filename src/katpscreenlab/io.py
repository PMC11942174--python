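"""Text-format readers and writers shared across the pipeline stages.

Formats: PDB (topology + one coordinate frame), multi-frame XYZ (coordinate
ensembles, one file per run), CSV (efflux plate wells), TSV (fingerprint
libraries: id, score, sorted bit indices), JSON (reports, truth records).
Coordinates are in Å; residue ids are 1-based (PDB convention) in every
user-facing file.

The PDB reader preserves 1-based residue ids and insertion codes, takes
elements from columns 77–78, and falls back to inferring the element from
the atom name (with a logged warning) when those columns are blank;
malformed ATOM records are rejected with their line number.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .efflux import WELL_COLUMNS
from .pocket import Topology, TrajectoryEnsemble
from .triage import FingerprintRecord

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_trajectory",
    "write_trajectory",
    "read_plate_csv",
    "write_plate_csv",
    "read_fingerprint_tsv",
    "write_fingerprint_tsv",
    "write_json",
]

logger = logging.getLogger(__name__)

_ELEMENTS_2 = {"CL", "BR", "NA", "MG", "ZN", "FE", "CA", "MN", "SE"}


def _element_from_name(raw_field: str) -> str:
    """Infer an element from the 4-char atom-name field.

    PDB left-pads one-letter-element atom names (`` CA `` is an α-carbon);
    a name starting in the first column with a recognized two-letter symbol
    (``CL``, ``BR``, ...) is taken as that element.
    """
    field = raw_field[:4]
    s = "".join(ch for ch in field.strip() if ch.isalpha()).upper()
    if not s:
        raise ValueError(f"cannot infer element from atom name {raw_field!r}")
    if not field.startswith(" ") and s[:2] in _ELEMENTS_2:
        return s[:2].capitalize()
    return s[0]


def read_pdb(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Parse ATOM/HETATM records into a Topology and an (n, 3) coordinate array."""
    path = Path(path)
    ids, names, elements, rids, rnames, chains, icodes = [], [], [], [], [], [], []
    coords = []
    warned_fallback = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path.name}:{lineno}: truncated ATOM record")
            try:
                ids.append(int(line[6:11]))
                names.append(line[12:16].strip())
                rnames.append(line[17:20].strip())
                chains.append(line[21].strip() or "A")
                rids.append(int(line[22:26]))
                icodes.append(line[26].strip())
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed ATOM record ({exc})"
                ) from None
            elem = line[76:78].strip() if len(line) >= 78 else ""
            if not elem:
                elem = _element_from_name(line[12:16])
                if not warned_fallback:
                    logger.warning(
                        "%s: element columns blank; inferring elements from atom names",
                        path.name,
                    )
                    warnings.warn(
                        f"{path.name}: elements inferred from atom names",
                        stacklevel=2,
                    )
                    warned_fallback = True
            elements.append(elem.capitalize())
    if not ids:
        raise ValueError(f"{path.name}: no ATOM records found")
    topo = Topology(
        atom_ids=np.array(ids),
        elements=np.array(elements, dtype=object),
        residue_ids=np.array(rids),
        residue_names=np.array(rnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        atom_names=np.array(names, dtype=object),
    )
    return topo, np.array(coords)


def write_pdb(path: str | Path, topology: Topology, coords: np.ndarray) -> None:
    """Write one frame as fixed-width ATOM records (element in cols 77–78)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinate shape does not match topology")
    names = (
        topology.atom_names
        if topology.atom_names is not None
        else topology.elements
    )
    with open(path, "w") as fh:
        for i in range(topology.n_atoms):
            name = str(names[i])[:4]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<3s} {chain:1s}{rid:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=int(topology.atom_ids[i]),
                    name=name,
                    res=str(topology.residue_names[i])[:3],
                    chain=str(topology.chain_ids[i])[:1],
                    rid=int(topology.residue_ids[i]),
                    x=coords[i, 0],
                    y=coords[i, 1],
                    z=coords[i, 2],
                    occ=1.0,
                    b=0.0,
                    el=str(topology.elements[i]).upper()[:2],
                )
            )
        fh.write("END\n")


def write_xyz_frames(
    path: str | Path, elements: Sequence[str], frames: np.ndarray
) -> None:
    """Multi-frame XYZ: natoms / comment / element x y z, repeated per frame."""
    frames = np.asarray(frames, dtype=float)
    n_atoms = frames.shape[1]
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"frame {f}\n")
            for e, (x, y, z) in zip(elements, frame):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a multi-frame XYZ file -> (elements, (frames, atoms, 3) array)."""
    path = Path(path)
    lines = Path(path).read_text().splitlines()
    frames, elements = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path.name}:{i + 1}: expected atom count") from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path.name}:{i + 1}: truncated frame")
        elems, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ValueError(f"{path.name}:{i + 3 + j}: malformed XYZ row")
            elems.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = elems
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path.name}: no frames found")
    return elements, np.array(frames)


def write_trajectory(
    out_dir: str | Path, topology: Topology, ensemble: TrajectoryEnsemble
) -> list[Path]:
    """Write frame 0 as PDB plus one multi-frame XYZ per run; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(out_dir / "topology.pdb", topology, ensemble.runs[0][0])
    paths = []
    for r, run in enumerate(ensemble.runs):
        p = out_dir / f"run{r}.xyz"
        write_xyz_frames(p, [str(e) for e in topology.elements], run)
        paths.append(p)
    return paths


def read_trajectory(
    paths: Sequence[str | Path], topology: Topology, stride: int = 1
) -> TrajectoryEnsemble:
    """Load one multi-frame XYZ per run into an ensemble; runs keep file order."""
    runs = []
    for r, p in enumerate(paths):
        _, frames = read_xyz_frames(p)
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"run {r} ({Path(p).name}): atom count {frames.shape[1]} does not "
                f"match topology ({topology.n_atoms})"
            )
        runs.append(frames)
    return TrajectoryEnsemble(runs, stride=stride)


def write_plate_csv(path: str | Path, wells: pd.DataFrame) -> None:
    """Plate wells CSV in the shared schema (doses in µM)."""
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"plate table lacks columns {missing}")
    wells[WELL_COLUMNS].to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {missing}")
    df["is_untransfected"] = df["is_untransfected"].astype(bool)
    return df


def write_fingerprint_tsv(
    path: str | Path, records: Sequence[FingerprintRecord]
) -> None:
    """TSV: compound id, score, sorted space-separated bit indices, properties JSON."""
    with open(path, "w") as fh:
        fh.write("compound_id\tscore\tbits\tproperties\n")
        for r in records:
            bits = " ".join(str(b) for b in sorted(r.bits))
            score = "" if r.score is None else repr(float(r.score))
            fh.write(
                f"{r.compound_id}\t{score}\t{bits}\t{json.dumps(dict(r.properties))}\n"
            )


def read_fingerprint_tsv(path: str | Path) -> list[FingerprintRecord]:
    path = Path(path)
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["compound_id", "score", "bits"]:
            raise ValueError(f"{path.name}: unexpected fingerprint TSV header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path.name}:{lineno}: malformed row")
            cid, score_s, bits_s = parts[0], parts[1], parts[2]
            props = json.loads(parts[3]) if len(parts) > 3 and parts[3] else {}
            bits = frozenset(int(b) for b in bits_s.split()) if bits_s else frozenset()
            score = float(score_s) if score_s else None
            records.append(FingerprintRecord(cid, bits, score, props))
    return records


def write_json(path: str | Path, obj) -> None:
    """JSON with numpy-friendly conversion."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
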