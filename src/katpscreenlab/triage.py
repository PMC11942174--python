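"""Post-scoring virtual-screen triage funnel.

Implements the compound-selection stages that follow pose scoring in a
structure-based virtual screen: novelty filtering against known binders
(Tanimoto in ECFP4-like bit space), score ranking and truncation, Butina
sphere-exclusion diversity clustering, property filters, and final candidate
selection (one best-scoring member per cluster).

Fingerprints are plain bit-index sets; generating them from SMILES is
delegated to RDKit via :func:`fingerprint_from_smiles` and is optional —
the funnel itself needs no chemistry toolkit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, Mapping, Sequence

__all__ = [
    "FingerprintRecord",
    "TriageConfig",
    "ClusterAssignment",
    "MissingPropertyError",
    "tanimoto",
    "novelty_filter",
    "rank_and_truncate",
    "butina_cluster",
    "apply_filters",
    "select_candidates",
    "run_funnel",
    "lipinski_predicates",
    "fingerprint_from_smiles",
]


@dataclass(frozen=True)
class FingerprintRecord:
    """One library compound: id, binary fingerprint, score and properties.

    ``bits`` holds the indices of set bits of a binary substructure
    fingerprint (ECFP4-like; length configurable upstream). ``score`` is a
    predicted-affinity rank score from a pluggable source (higher = better).
    """

    compound_id: str
    bits: FrozenSet[int]
    score: float | None = None
    properties: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))


@dataclass
class TriageConfig:
    """Funnel parameters; defaults follow the published screening protocol."""

    novelty_cutoff: float = 0.5
    cluster_cutoff: float = 0.35
    top_n: int = 30_000
    n_select: int = 96
    filter_predicates: Sequence[tuple[str, Callable[[FingerprintRecord], bool]]] = ()

    def __post_init__(self) -> None:
        for name in ("novelty_cutoff", "cluster_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.top_n < 1 or self.n_select < 1:
            raise ValueError("top_n and n_select must be >= 1")


@dataclass
class ClusterAssignment:
    """Butina clustering result: compound -> cluster, with centroids."""

    assignment: dict[str, int]
    centroids: list[str]
    singleton: list[bool]

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def members(self, cluster: int) -> list[str]:
        return sorted(c for c, k in self.assignment.items() if k == cluster)


class MissingPropertyError(KeyError):
    """A filter predicate referenced a property absent from a record."""

    def __init__(self, compound_id: str, prop: str):
        super().__init__(prop)
        self.compound_id = compound_id
        self.property_name = prop

    def __str__(self) -> str:  # noqa: D105
        return (
            f"compound {self.compound_id!r} lacks property "
            f"{self.property_name!r} required by a filter predicate"
        )


def tanimoto(a: Iterable[int], b: Iterable[int]) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two bit-index sets.

    Two empty fingerprints are defined to have similarity 0 (with a
    warning): the conservative choice, preventing spurious novelty
    exclusion or cluster merging of featureless records.
    """
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        warnings.warn(
            "Tanimoto of two empty fingerprints; defined as 0.0", stacklevel=2
        )
        return 0.0
    return len(sa & sb) / union


def novelty_filter(
    library: Sequence[FingerprintRecord],
    known_binders: Sequence[Iterable[int]],
    cutoff: float = 0.5,
) -> tuple[list[FingerprintRecord], list[dict]]:
    """Exclude compounds too similar to any known binder.

    A compound is excluded iff its maximum Tanimoto similarity to any known
    binder is *strictly greater* than ``cutoff`` (a compound at exactly the
    cutoff is retained). Returns the retained records and an exclusion log
    naming, per excluded compound, the offending binder index and the
    similarity reached.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    binder_sets = [frozenset(b) for b in known_binders]
    retained: list[FingerprintRecord] = []
    log: list[dict] = []
    for rec in library:
        best_sim, best_idx = -1.0, -1
        for i, kb in enumerate(binder_sets):
            s = tanimoto(rec.bits, kb) if (rec.bits or kb) else 0.0
            if s > best_sim:
                best_sim, best_idx = s, i
        if binder_sets and best_sim > cutoff:
            log.append(
                {
                    "compound_id": rec.compound_id,
                    "binder_index": best_idx,
                    "similarity": best_sim,
                }
            )
        else:
            retained.append(rec)
    return retained, log


def rank_and_truncate(
    library: Sequence[FingerprintRecord], top_n: int
) -> list[FingerprintRecord]:
    """Sort by descending score (ties: ascending id) and keep the top ``top_n``."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    for rec in library:
        if rec.score is None:
            raise ValueError(f"record {rec.compound_id!r} has no score")
    ordered = sorted(library, key=lambda r: (-r.score, r.compound_id))
    return ordered[:top_n]


def _neighbor_lists(
    records: Sequence[FingerprintRecord], cutoff: float
) -> list[set[int]]:
    n = len(records)
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        bi = records[i].bits
        for j in range(i + 1, n):
            bj = records[j].bits
            union = len(bi | bj)
            sim = (len(bi & bj) / union) if union else 0.0
            if sim >= cutoff:
                nbrs[i].add(j)
                nbrs[j].add(i)
    return nbrs


def butina_cluster(
    subset: Sequence[FingerprintRecord], cutoff: float
) -> ClusterAssignment:
    """Butina sphere-exclusion clustering at a Tanimoto similarity cutoff.

    Neighbor lists are built at similarity >= ``cutoff``; the unassigned
    compound with the most *unassigned* neighbors (recounted each round,
    ties broken by ascending compound id) becomes the next centroid and
    absorbs its unassigned neighbors.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    ids = [r.compound_id for r in subset]
    if len(set(ids)) != len(ids):
        raise ValueError("compound ids must be unique within a library")
    nbrs = _neighbor_lists(subset, cutoff)
    unassigned = set(range(len(subset)))
    assignment: dict[str, int] = {}
    centroids: list[str] = []
    singleton: list[bool] = []
    while unassigned:
        centroid = min(
            unassigned, key=lambda i: (-len(nbrs[i] & unassigned), ids[i])
        )
        cluster = {centroid} | (nbrs[centroid] & unassigned)
        k = len(centroids)
        for i in cluster:
            assignment[ids[i]] = k
        centroids.append(ids[centroid])
        singleton.append(len(cluster) == 1)
        unassigned -= cluster
    return ClusterAssignment(assignment, centroids, singleton)


def _prop(rec: FingerprintRecord, name: str) -> float:
    try:
        return rec.properties[name]
    except KeyError:
        raise MissingPropertyError(rec.compound_id, name) from None


def lipinski_predicates() -> list[tuple[str, Callable[[FingerprintRecord], bool]]]:
    """Lipinski-style oral-availability predicates plus a toxicophore-alert flag.

    These stand in for the proprietary medicinal-chemistry filter set used
    in the original screen: rule-of-five property bounds (MW <= 500,
    logP <= 5, HBD <= 5, HBA <= 10) and rejection of any record carrying a
    positive ``toxicophore_alerts`` count if that property is present.
    """
    preds: list[tuple[str, Callable[[FingerprintRecord], bool]]] = [
        ("mw<=500", lambda r: _prop(r, "mw") <= 500.0),
        ("logp<=5", lambda r: _prop(r, "logp") <= 5.0),
        ("hbd<=5", lambda r: _prop(r, "hbd") <= 5),
        ("hba<=10", lambda r: _prop(r, "hba") <= 10),
        (
            "no_toxicophore_alerts",
            lambda r: r.properties.get("toxicophore_alerts", 0) == 0,
        ),
    ]
    return preds


def apply_filters(
    records: Sequence[FingerprintRecord],
    predicates: Sequence[tuple[str, Callable[[FingerprintRecord], bool]]],
) -> tuple[list[FingerprintRecord], dict[str, int]]:
    """Retain records passing every named predicate; count rejections per predicate.

    A record is rejected by the *first* predicate it fails (evaluation is
    ordered), so rejection counts attribute each loss to one predicate.
    """
    rejections = {name: 0 for name, _ in predicates}
    retained: list[FingerprintRecord] = []
    for rec in records:
        for name, pred in predicates:
            if not pred(rec):
                rejections[name] += 1
                break
        else:
            retained.append(rec)
    return retained, rejections


def select_candidates(
    clusters: ClusterAssignment,
    records: Sequence[FingerprintRecord],
    n_select: int,
) -> list[str]:
    """Pick at most one compound per cluster, best-scoring member first.

    Clusters are visited in order of their best member's score (descending,
    ties by id); from each, the best-scoring member is taken; the output has
    min(n_select, n_clusters) ids.
    """
    if n_select < 1:
        raise ValueError("n_select must be >= 1")
    by_id = {r.compound_id: r for r in records}
    missing = set(clusters.assignment) - set(by_id)
    if missing:
        raise ValueError(f"clusters reference unknown compounds: {sorted(missing)}")
    best: dict[int, FingerprintRecord] = {}
    for cid, k in clusters.assignment.items():
        rec = by_id[cid]
        if rec.score is None:
            raise ValueError(f"record {cid!r} has no score")
        cur = best.get(k)
        if cur is None or (-rec.score, rec.compound_id) < (-cur.score, cur.compound_id):
            best[k] = rec
    ordered = sorted(best.values(), key=lambda r: (-r.score, r.compound_id))
    return [r.compound_id for r in ordered[:n_select]]


def run_funnel(
    library: Sequence[FingerprintRecord],
    known_binders: Sequence[Iterable[int]],
    config: TriageConfig | None = None,
) -> dict:
    """Run the full funnel: novelty -> rank -> cluster -> filter -> select.

    Returns a report dict with the stage-by-stage counts, the exclusion and
    rejection logs, the cluster assignment, and the selected compound ids.
    The funnel is order-stable: permuting the input order never changes the
    selected set (all ties are broken on compound id).
    """
    cfg = config or TriageConfig()
    retained, exclusion_log = novelty_filter(
        library, known_binders, cfg.novelty_cutoff
    )
    top = rank_and_truncate(retained, cfg.top_n)
    clusters = butina_cluster(top, cfg.cluster_cutoff)
    filtered, rejections = apply_filters(top, cfg.filter_predicates)
    kept_ids = {r.compound_id for r in filtered}
    pruned = ClusterAssignment(
        {c: k for c, k in clusters.assignment.items() if c in kept_ids},
        clusters.centroids,
        clusters.singleton,
    )
    selected = select_candidates(pruned, filtered, cfg.n_select) if filtered else []
    return {
        "counts": {
            "input": len(library),
            "after_novelty": len(retained),
            "after_truncation": len(top),
            "n_clusters": clusters.n_clusters,
            "after_filters": len(filtered),
            "selected": len(selected),
        },
        "exclusion_log": exclusion_log,
        "filter_rejections": rejections,
        "clusters": clusters,
        "selected": selected,
    }


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048) -> frozenset[int]:
    """ECFP4 (Morgan radius-2) bit-index set from a SMILES string via RDKit.

    Optional convenience; requires the ``chem`` extra. The funnel operates
    on precomputed bit-sets and never calls this internally.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "fingerprint_from_smiles requires rdkit (install the 'chem' extra)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return frozenset(gen.GetFingerprint(mol).GetOnBits())
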