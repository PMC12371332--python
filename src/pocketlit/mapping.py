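"""Mapping literature-extracted residues onto a specific PDB structure.

Residue lists quoted in papers rarely map verbatim onto a deposited
structure: constructs are renumbered or mutated, and chain identifiers in
the text are unreliable, especially for homomultimers. The mapping stage
therefore

1. assigns each extracted pocket to candidate chains by positional sequence
   similarity (fraction of pocket residues present in the chain with
   matching residue number, insertion code and name; threshold 0.6,
   inclusive), using the quoted chain ids only as a tie-breaking hint;
2. spatially clusters all chain-mapped residues with MeanShift (which needs
   no preset cluster count) on heavy-atom centroids;
3. matches clusters back to the pocket with an overlap threshold (0.7,
   inclusive, normalized by pocket size);
4. emits a single *interface pocket* per matched cluster spanning ≥2 chains
   — otherwise one replica of the mapped residues per candidate chain, the
   homomer case.

An optional constant-offset scan (±k residue numbering shifts) is available
for renumbered constructs; it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import MeanShift

from .extraction import ExtractedPocket
from .structures import ProteinStructure, ResidueRef

logger = logging.getLogger(__name__)

__all__ = [
    "ChainAssignment",
    "ResidueCluster",
    "MappedPocket",
    "UnmappablePocketError",
    "chain_similarity",
    "assign_chains",
    "map_to_chain",
    "cluster_residues",
    "match_cluster_to_pocket",
    "resolve_pockets",
]

DEFAULT_CHAIN_THRESHOLD = 0.6
DEFAULT_CLUSTER_THRESHOLD = 0.7
DEFAULT_BANDWIDTH = 8.0  # Å


class UnmappablePocketError(ValueError):
    """No chain reaches the similarity threshold for a pocket."""

    def __init__(self, pocket_name: str, best_chain: str | None, best_score: float):
        self.pocket_name = pocket_name
        self.best_chain = best_chain
        self.best_score = best_score
        super().__init__(
            f"pocket {pocket_name!r} maps to no chain "
            f"(best: {best_chain!r} at {best_score:.3f})"
        )


@dataclass(frozen=True)
class ChainAssignment:
    pocket_name: str
    candidates: tuple[tuple[str, float, int], ...]  # (chain_id, similarity, numbering offset)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _, _ in self.candidates)


@dataclass(frozen=True)
class ResidueCluster:
    members: tuple[ResidueRef, ...]
    centroid: np.ndarray
    chains: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty residue cluster")


@dataclass(frozen=True)
class MappedPocket:
    """An extracted pocket resolved onto structure residues.

    ``interface`` pockets carry residues spanning ≥2 chains from one spatial
    cluster; non-interface pockets are per-chain replicas, ``chains`` naming
    the single chain of the replica.
    """

    source: ExtractedPocket
    residues: tuple[ResidueRef, ...]
    interface: bool
    chains: frozenset[str]

    def __post_init__(self) -> None:
        spanned = {r.chain_id for r in self.residues}
        if self.interface and len(spanned) < 2:
            raise ValueError("interface pocket must span at least two chains")

    @property
    def name(self) -> str:
        return self.source.name

    @property
    def residue_keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.residues)

    @property
    def identity(self) -> tuple[str, str, tuple[str, ...]]:
        """Stable identity for merge bookkeeping (source doc, name, chains)."""
        return (self.source.provenance.doc_id, self.source.name, tuple(sorted(self.chains)))


# ---------------------------------------------------------------------------
# Chain assignment
# ---------------------------------------------------------------------------

def chain_similarity(
    pocket_residues: Sequence[ResidueRef],
    structure: ProteinStructure,
    chain_id: str,
    offset: int = 0,
) -> float:
    """Fraction of pocket residues found in a chain with agreeing names.

    A pocket residue counts as present when a residue with the same
    ``(res_id + offset, icode)`` exists in the chain *and* its name matches.
    """
    if not pocket_residues:
        raise ValueError("chain_similarity: empty pocket residue list")
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure")
    hits = 0
    for ref in pocket_residues:
        res = structure.get_residue(chain_id, ref.res_id + offset, ref.icode)
        if res is not None and res.ref.res_name == ref.res_name:
            hits += 1
    return hits / len(pocket_residues)


def assign_chains(
    pocket: ExtractedPocket,
    structure: ProteinStructure,
    chain_threshold: float = DEFAULT_CHAIN_THRESHOLD,
    offset_scan: int = 0,
) -> ChainAssignment:
    """All chains whose similarity reaches the threshold (inclusive).

    The chain ids quoted in the literature act only as a tie-breaking hint
    in the candidate ordering — never as a hard constraint, since quoted
    chain ids are frequently wrong. With ``offset_scan = k > 0``, constant
    numbering shifts in ``[-k, k]`` are tried per chain and the best kept.
    """
    hinted = {r.chain_id for r in pocket.residues}
    best_overall: tuple[float, str | None, int] = (0.0, None, 0)
    candidates: list[tuple[str, float, int]] = []
    for chain_id in structure.chain_ids:
        best_score, best_offset = 0.0, 0
        for offset in range(-offset_scan, offset_scan + 1):
            score = chain_similarity(pocket.residues, structure, chain_id, offset)
            if score > best_score:
                best_score, best_offset = score, offset
        if best_score > best_overall[0]:
            best_overall = (best_score, chain_id, best_offset)
        if best_score >= chain_threshold:
            candidates.append((chain_id, best_score, best_offset))
    if not candidates:
        raise UnmappablePocketError(pocket.name, best_overall[1], best_overall[0])
    candidates.sort(key=lambda c: (-c[1], c[0] not in hinted, c[0]))
    return ChainAssignment(pocket_name=pocket.name, candidates=tuple(candidates))


def map_to_chain(
    pocket_residues: Sequence[ResidueRef],
    structure: ProteinStructure,
    chain_id: str,
    offset: int = 0,
) -> list[ResidueRef]:
    """Structure-resolved refs for the pocket residues present in a chain."""
    mapped = []
    for ref in pocket_residues:
        res = structure.get_residue(chain_id, ref.res_id + offset, ref.icode)
        if res is not None and res.ref.res_name == ref.res_name:
            mapped.append(res.ref)
    return mapped


# ---------------------------------------------------------------------------
# Spatial clustering
# ---------------------------------------------------------------------------

def cluster_residues(
    structure: ProteinStructure,
    residues: Sequence[ResidueRef],
    bandwidth: float = DEFAULT_BANDWIDTH,
) -> list[ResidueCluster]:
    """MeanShift clustering of residues on their heavy-atom centroids.

    The cluster count is found by the algorithm, not prescribed. Output is
    deterministic for identical input order: clusters are emitted in order
    of their first member's position in ``residues``.
    """
    if not residues:
        raise ValueError("cluster_residues: no residues to cluster")
    points = []
    for ref in residues:
        res = structure.find(ref)
        if res is None:
            raise KeyError(f"residue {ref.token()} not in structure")
        points.append(res.heavy_centroid())
    pts = np.asarray(points)
    if len(pts) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        labels = MeanShift(bandwidth=bandwidth).fit(pts).labels_
    order: dict[int, int] = {}
    grouped: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        lab = int(lab)
        order.setdefault(lab, len(order))
        grouped.setdefault(lab, []).append(i)
    clusters = []
    for lab in sorted(grouped, key=order.get):
        idx = grouped[lab]
        members = tuple(residues[i] for i in idx)
        clusters.append(
            ResidueCluster(
                members=members,
                centroid=pts[idx].mean(axis=0),
                chains=frozenset(r.chain_id for r in members),
            )
        )
    return clusters


def match_cluster_to_pocket(
    cluster: ResidueCluster,
    pocket_mapped: dict[str, Sequence[ResidueRef]],
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> tuple[float, bool]:
    """Does a spatial cluster represent this pocket?

    Overlap is normalized by the pocket's mapped size. When the pocket maps
    to several candidate chains its chain assignment is ambiguous, so
    residue identity falls back to ``(res_id, icode)`` alone; with a single
    candidate chain full keys are compared. Matched iff overlap ≥ threshold
    (inclusive).
    """
    if not pocket_mapped:
        return 0.0, False
    if len(pocket_mapped) > 1:
        cluster_ids = {(r.res_id, r.icode) for r in cluster.members}
        pocket_ids = {(r.res_id, r.icode) for refs in pocket_mapped.values() for r in refs}
    else:
        cluster_ids = {r.key for r in cluster.members}
        pocket_ids = {r.key for refs in pocket_mapped.values() for r in refs}
    if not pocket_ids:
        return 0.0, False
    overlap = len(cluster_ids & pocket_ids) / len(pocket_ids)
    return overlap, overlap >= cluster_threshold


# ---------------------------------------------------------------------------
# Full resolution
# ---------------------------------------------------------------------------

def resolve_pockets(
    pockets: Sequence[ExtractedPocket],
    structure: ProteinStructure,
    chain_threshold: float = DEFAULT_CHAIN_THRESHOLD,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    bandwidth: float = DEFAULT_BANDWIDTH,
    offset_scan: int = 0,
) -> list[MappedPocket]:
    """Resolve each extracted pocket onto the structure.

    Per pocket: assign candidate chains, map the residues onto every
    candidate, cluster all mapped residues jointly, and emit either one
    interface pocket per matched multi-chain cluster or per-chain replicas
    of the mapped residues. Unmappable pockets are logged and skipped.
    """
    mapped_out: list[MappedPocket] = []
    for pocket in pockets:
        try:
            assignment = assign_chains(pocket, structure, chain_threshold, offset_scan)
        except UnmappablePocketError as exc:
            logger.warning("skipping unmappable pocket: %s", exc)
            continue
        mapped_by_chain: dict[str, list[ResidueRef]] = {}
        for chain_id, _score, offset in assignment.candidates:
            refs = map_to_chain(pocket.residues, structure, chain_id, offset)
            if refs:
                mapped_by_chain[chain_id] = refs

        all_mapped: list[ResidueRef] = []
        seen: set[tuple[str, int, str]] = set()
        for refs in mapped_by_chain.values():
            for r in refs:
                if r.key not in seen:
                    seen.add(r.key)
                    all_mapped.append(r)

        clusters = cluster_residues(structure, all_mapped, bandwidth)
        interface_clusters = []
        for cl in clusters:
            overlap, matched = match_cluster_to_pocket(cl, mapped_by_chain, cluster_threshold)
            if matched and len(cl.chains) >= 2:
                interface_clusters.append((cl, overlap))

        if interface_clusters:
            for cl, overlap in interface_clusters:
                logger.info(
                    "pocket %r: interface cluster across chains %s (overlap %.2f)",
                    pocket.name, sorted(cl.chains), overlap,
                )
                mapped_out.append(
                    MappedPocket(
                        source=pocket,
                        residues=cl.members,
                        interface=True,
                        chains=cl.chains,
                    )
                )
        else:
            for chain_id, refs in mapped_by_chain.items():
                mapped_out.append(
                    MappedPocket(
                        source=pocket,
                        residues=tuple(refs),
                        interface=False,
                        chains=frozenset({chain_id}),
                    )
                )
    return mapped_out
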