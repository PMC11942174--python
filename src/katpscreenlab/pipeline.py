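"""Pipeline configuration and the umbrella stage runner.

A pipeline config is one YAML document with an optional sub-config per
stage (``triage``, ``efflux``, ``pocketdyn``, ``pore``), a global seed,
an output directory and a log level. The schema is strict: unknown keys
anywhere are fatal, which catches silent threshold typos (0.3 vs 0.03)
before any stage runs. Input files are pre-flight checked before the
first stage executes, and every run writes a provenance manifest (package
and library versions, seed, config digest, input digests) next to the
stage reports. Identical config + seed yields identical report digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .efflux import fit_hill, preprocess
from .io import (
    read_fingerprint_tsv,
    read_pdb,
    read_plate_csv,
    read_trajectory,
    write_json,
)
from .pocket import (
    aggregate_contacts,
    align_ensemble,
    contact_fractions,
    frequency_report,
    group_com_trace,
)
from .pore import pore_profile
from .triage import TriageConfig, lipinski_predicates, run_funnel

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_STAGE_KEYS: dict[str, set[str]] = {
    "triage": {
        "library", "known_binders", "novelty_cutoff", "cluster_cutoff",
        "top_n", "n_select", "use_default_filters",
    },
    "efflux": {"plate", "reference_condition", "condition"},
    "pocketdyn": {
        "topology", "runs", "align_selection", "ligand_selection",
        "fragments", "cutoff", "inclusion_fraction", "run_quorum",
        "display_threshold",
    },
    "pore": {
        "pdb", "radii", "axis", "zmin", "zmax", "z_step", "max_probe",
        "lateral_bound",
    },
}
_TOP_KEYS = {"seed", "out_dir", "log_level", "stages"} | set(_STAGE_KEYS)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict schema)."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = {}
        for name, allowed in _STAGE_KEYS.items():
            if name in raw:
                sub = raw[name] or {}
                bad = set(sub) - allowed
                if bad:
                    raise ValueError(
                        f"unknown keys in stage {name!r}: {sorted(bad)}"
                    )
                stages[name] = sub
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "pipeline_out")),
            log_level=str(raw.get("log_level", "INFO")),
            stages=stages,
        )

    def digest(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "stages": self.stages}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    return PipelineConfig.from_dict(raw)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _input_paths(cfg: PipelineConfig) -> list[Path]:
    paths: list[Path] = []
    for name, sub in cfg.stages.items():
        for key in ("library", "known_binders", "plate", "topology", "pdb"):
            if key in sub:
                paths.append(Path(sub[key]))
        for p in sub.get("runs", []):
            paths.append(Path(p))
    return paths


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write per-stage reports.

    Any stage error aborts the run, naming the stage; outputs written up to
    that point are flagged as partial in the manifest. Returns the manifest.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    missing = [str(p) for p in _input_paths(cfg) if not p.exists()]
    if missing:
        raise FileNotFoundError(f"pre-flight: missing input files {missing}")

    import numpy, pandas, scipy  # noqa: PLC0415

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "inputs": {str(p): _file_digest(p) for p in _input_paths(cfg)},
        "stages_run": [],
        "partial": False,
    }

    try:
        for name, sub in cfg.stages.items():
            stage_dir = out / name
            stage_dir.mkdir(exist_ok=True)
            logger.info("running stage %s", name)
            if name == "triage":
                _run_triage(sub, stage_dir)
            elif name == "efflux":
                _run_efflux(sub, stage_dir)
            elif name == "pocketdyn":
                _run_pocketdyn(sub, stage_dir)
            elif name == "pore":
                _run_pore(sub, stage_dir)
            manifest["stages_run"].append(name)
    except Exception as exc:
        manifest["partial"] = True
        write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    write_json(out / "manifest.json", manifest)
    return manifest


def _run_triage(sub: dict, stage_dir: Path) -> None:
    library = read_fingerprint_tsv(sub["library"])
    known = (
        [r.bits for r in read_fingerprint_tsv(sub["known_binders"])]
        if "known_binders" in sub
        else []
    )
    tc = TriageConfig(
        novelty_cutoff=sub.get("novelty_cutoff", 0.5),
        cluster_cutoff=sub.get("cluster_cutoff", 0.35),
        top_n=sub.get("top_n", 30_000),
        n_select=sub.get("n_select", 96),
        filter_predicates=(
            lipinski_predicates() if sub.get("use_default_filters", True) else ()
        ),
    )
    report = run_funnel(library, known, tc)
    clusters = report.pop("clusters")
    report["cluster_assignment"] = clusters.assignment
    write_json(stage_dir / "funnel_report.json", report)


def _run_efflux(sub: dict, stage_dir: Path) -> None:
    wells = read_plate_csv(sub["plate"])
    ref = sub["reference_condition"]
    table = preprocess(wells, ref)
    cond = sub.get("condition", ref)
    df = table.data[table.data["condition"] == cond]
    fits = {}
    for b, g in df.groupby("biological_rep"):
        fit = fit_hill(g["dose_uM"].to_numpy(), g["fraction"].to_numpy())
        fits[int(b)] = {
            "top": fit.top, "bottom": fit.bottom, "ic50_uM": fit.ic50,
            "slope": fit.slope, "se_ic50": fit.se_ic50,
            "converged": fit.converged,
        }
    table.data.to_csv(stage_dir / "fractions.csv", index=False)
    write_json(
        stage_dir / "fit.json",
        {"reference_condition": ref, "condition": cond, "fits": fits},
    )


def _run_pocketdyn(sub: dict, stage_dir: Path) -> None:
    topo, _ = read_pdb(sub["topology"])
    topo.selections["align"] = list(map(int, sub["align_selection"]))
    topo.selections["ligand"] = list(map(int, sub["ligand_selection"]))
    ens = read_trajectory(sub["runs"], topo)
    aligned = align_ensemble(ens, topo, "align")
    scheme = {k: list(map(int, v)) for k, v in sub.get("fragments", {}).items()}
    report = contact_fractions(
        aligned, topo, "ligand", scheme or None, cutoff=sub.get("cutoff", 3.5)
    )
    retained = aggregate_contacts(
        report,
        inclusion_fraction=sub.get("inclusion_fraction", 0.30),
        run_quorum=sub.get("run_quorum"),
    )
    report.fractions.to_csv(stage_dir / "contact_fractions.csv")
    freq = frequency_report(report, sub.get("display_threshold", 0.40))
    freq.to_csv(stage_dir / "frequency_report.csv")
    summary = {"retained_residues": sorted(retained)}
    if scheme:
        mob = group_com_trace(aligned, topo, scheme)
        mob.sd_per_run.to_csv(stage_dir / "mobility_sd.csv")
        summary["pooled_sd"] = mob.sd_pooled.to_dict()
    write_json(stage_dir / "summary.json", summary)


def _run_pore(sub: dict, stage_dir: Path) -> None:
    topo, coords = read_pdb(sub["pdb"])
    axis = tuple(float(x) for x in sub.get("axis", (0, 0, 1)))
    zr = None
    if "zmin" in sub and "zmax" in sub:
        zr = (float(sub["zmin"]), float(sub["zmax"]))
    prof = pore_profile(
        coords,
        [str(e) for e in topo.elements],
        radii=sub.get("radii"),
        axis=axis,
        z_range=zr,
        z_step=sub.get("z_step", 0.5),
        max_probe=sub.get("max_probe", 10.0),
        lateral_bound=sub.get("lateral_bound", 5.0),
        residue_ids=topo.residue_ids,
    )
    import pandas as pd

    pd.DataFrame({"z": prof.z, "radius": prof.radius}).to_csv(
        stage_dir / "profile.csv", index=False
    )
    write_json(
        stage_dir / "minimum.json",
        {
            "min_z": prof.min_z,
            "min_radius": prof.min_radius,
            "nearest_residues": prof.min_residues,
        },
    )
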