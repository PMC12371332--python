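"""Deterministic synthetic fixtures for the whole pipeline.

Generates every input the pocket pipeline consumes — multi-chain structures
with planted cavities, Fpocket-layout alpha-sphere directories, paper-like
markdown documents, ground-truth annotation JSONs and canned mock-backend
responses — from a single :class:`FixtureSpec`, with known ground truth and
full determinism under a fixed seed.

The geometry is idealized, not physically realistic protein conformation:
chains run along straight backbone traces (3.8 Å residue spacing, parallel
chains 10 Å apart), and each planted pocket repositions its residues onto a
ring of radius ~5 Å around a cavity center lifted away from the traces, so
the cavity is concave, its residues cluster spatially, and alpha spheres
placed at the center contact a majority of each residue's atoms. Interface
pockets split the ring between two adjacent chains placed in contact;
replica pockets plant one ring per chain at well-separated centers
(≥ ~25 Å, comfortably beyond the 8 Å clustering bandwidth).

Noise knobs emulate the failure modes the real pipeline must survive:
constant numbering offsets between literature and structure, corrupted
residue names, malformed residue tokens, split pocket entries and
hallucinated residues in the mock extraction responses (the canned
refinement responses restore the clean truth, mirroring what the refinement
stage is for).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .corpus import PaperAnnotation, PaperDocument, PocketAnnotation, write_annotation
from .extraction import MockBackend
from .geometry import AlphaSphere, GeometricPocket
from .structures import (
    Atom,
    ProteinStructure,
    Residue,
    ResidueRef,
    THREE_TO_ONE,
    vdw_radius,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "PlantedPocket",
    "PlantedTruth",
    "CorpusBundle",
    "make_structure",
    "make_alpha_spheres",
    "make_corpus",
    "planted_truth",
]

_AMINO = sorted(THREE_TO_ONE)          # 20 names, fixed order
_BACKBONE_STEP = 3.8                   # Å between consecutive residues
_CHAIN_SPACING = 10.0                  # Å between parallel chain traces
_CAGE_RADIUS = 5.0                     # Å ring radius around a cavity center
_CAGE_Z = 15.0                         # cavity centers sit above the traces
_CAGE_ATOMS = 5                        # heavy atoms per planted residue
_ELEMENTS = ("N", "C", "C", "O", "C", "C", "S", "C")


@dataclass(frozen=True)
class PlantedPocket:
    """One pocket to plant: residue ids, placement mode, chains involved."""

    name: str
    residue_ids: tuple[int, ...]
    interface: bool = False
    chains: tuple[str, ...] | None = None  # None: all chains (replicas) / first two (interface)


@dataclass
class FixtureSpec:
    """Everything that determines a synthetic benchmark instance."""

    seed: int = 0
    n_chains: int = 1
    residues_per_chain: int = 30
    pockets: tuple[PlantedPocket, ...] = ()
    decoy_count: int = 0
    n_negative_docs: int = 1
    target_name: str = "Synthetic target protein STP-1"
    # noise knobs
    numbering_offset: int = 0        # literature ids = structure ids + offset
    name_corruption_rate: float = 0.0
    token_corruption_rate: float = 0.0
    split_pockets: bool = False      # extraction responses split each pocket in two
    hallucinated_residues: int = 0   # bogus residues appended in extraction responses

    def chain_ids(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_chains)]

    def validate(self) -> None:
        for p in self.pockets:
            if not p.residue_ids:
                raise ValueError(f"pocket {p.name!r}: no residues")
            bad = [i for i in p.residue_ids if not 1 <= i <= self.residues_per_chain]
            if bad:
                raise ValueError(f"pocket {p.name!r}: residue ids {bad} outside chain (1..{self.residues_per_chain})")
            if p.interface and self.n_chains < 2:
                raise ValueError(f"interface pocket {p.name!r} needs ≥2 chains")
        if self.decoy_count and self.residues_per_chain < 10:
            raise ValueError("decoys need at least 10 residues per chain")


def _res_name(res_id: int) -> str:
    return _AMINO[res_id % len(_AMINO)]


def _pocket_chains(spec: FixtureSpec, pocket: PlantedPocket) -> list[str]:
    if pocket.chains is not None:
        return list(pocket.chains)
    return spec.chain_ids()[:2] if pocket.interface else spec.chain_ids()


def _cage_center(spec: FixtureSpec, p_idx: int, pocket: PlantedPocket, chain_idx: int) -> np.ndarray:
    x = 20.0 + 60.0 * p_idx + 25.0 * chain_idx
    if pocket.interface:
        return np.array([20.0 + 60.0 * p_idx, _CHAIN_SPACING * chain_idx + _CHAIN_SPACING / 2, _CAGE_Z])
    return np.array([x, _CHAIN_SPACING * chain_idx, _CAGE_Z])


def _cage_positions(center: np.ndarray, n: int) -> list[np.ndarray]:
    """Ring directions around a cavity center, one per residue."""
    out = []
    for k in range(n):
        theta = 2.0 * np.pi * k / max(n, 1)
        direction = np.array([np.cos(theta), 0.0, np.sin(theta)])
        out.append((center, direction, k))
    return out


def _cage_atom_coords(center: np.ndarray, direction: np.ndarray, k: int) -> list[np.ndarray]:
    # radial shells 4.0, 4.4, ... Å; alternating small y offsets break coplanarity
    coords = []
    for a in range(_CAGE_ATOMS):
        radial = 4.0 + 0.4 * a
        y_off = 0.3 * (1 if (a + k) % 2 else -1)
        coords.append(center + direction * radial + np.array([0.0, y_off, 0.0]))
    return coords


@dataclass
class PlantedTruth:
    """Ground truth of one planted pocket after structure generation."""

    name: str
    interface: bool
    residues_by_chain: dict[str, tuple[ResidueRef, ...]]
    literature_residues: tuple[ResidueRef, ...]
    centers: dict[str, np.ndarray]

    def all_planted(self) -> frozenset[ResidueRef]:
        if self.interface:
            return frozenset(r for refs in self.residues_by_chain.values() for r in refs)
        # replicas: the full planted set is per chain; pool everything
        return frozenset(r for refs in self.residues_by_chain.values() for r in refs)


def _plan(spec: FixtureSpec) -> list[PlantedTruth]:
    """Chain/residue placement plan shared by all generators."""
    spec.validate()
    truths: list[PlantedTruth] = []
    for p_idx, pocket in enumerate(spec.pockets):
        chains = _pocket_chains(spec, pocket)
        residues_by_chain: dict[str, tuple[ResidueRef, ...]] = {}
        centers: dict[str, np.ndarray] = {}
        if pocket.interface:
            ca, cb = chains[0], chains[1]
            half = len(pocket.residue_ids) // 2
            residues_by_chain[ca] = tuple(
                ResidueRef(ca, _res_name(i), i) for i in pocket.residue_ids[:half]
            )
            residues_by_chain[cb] = tuple(
                ResidueRef(cb, _res_name(i), i) for i in pocket.residue_ids[half:]
            )
            ci = spec.chain_ids().index(ca)
            center = _cage_center(spec, p_idx, pocket, ci)
            centers["interface"] = center
            lit = residues_by_chain[ca] + residues_by_chain[cb]
        else:
            for chain in chains:
                ci = spec.chain_ids().index(chain)
                residues_by_chain[chain] = tuple(
                    ResidueRef(chain, _res_name(i), i) for i in pocket.residue_ids
                )
                centers[chain] = _cage_center(spec, p_idx, pocket, ci)
            lit = residues_by_chain[chains[0]]
        truths.append(
            PlantedTruth(
                name=pocket.name,
                interface=pocket.interface,
                residues_by_chain=residues_by_chain,
                literature_residues=lit,
                centers=centers,
            )
        )
    return truths


def planted_truth(spec: FixtureSpec) -> list[PlantedTruth]:
    """Ground truth (placement plan) for a spec, without building anything."""
    return _plan(spec)


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def make_structure(spec: FixtureSpec) -> ProteinStructure:
    """Deterministic multi-chain structure with the planted cavities.

    All chains share one sequence (names cycle through the 20 standard
    residues by residue number), so homomer replica mapping is exercised
    naturally. Planted residues are moved onto their cavity ring; everything
    else lies on the backbone trace with 4–8 heavy atoms per residue.
    """
    truths = _plan(spec)
    cage_slots: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, int]] = {}
    for t_idx, truth in enumerate(truths):
        for chain, refs in truth.residues_by_chain.items():
            center = truth.centers["interface"] if truth.interface else truth.centers[chain]
            positions = _cage_positions(center, sum(len(r) for r in truth.residues_by_chain.values())) \
                if truth.interface else _cage_positions(center, len(refs))
            if truth.interface:
                # ring slots are shared across the two chains, in literature order
                ordered = [r for rs in truth.residues_by_chain.values() for r in rs]
                for slot, ref in zip(positions, ordered):
                    cage_slots[(ref.chain_id, ref.res_id)] = slot
            else:
                for slot, ref in zip(positions, refs):
                    cage_slots[(chain, ref.res_id)] = slot

    structure = ProteinStructure()
    for ci, chain in enumerate(spec.chain_ids()):
        for res_id in range(1, spec.residues_per_chain + 1):
            name = _res_name(res_id)
            slot = cage_slots.get((chain, res_id))
            if slot is not None:
                center, direction, k = slot
                coords = _cage_atom_coords(center, direction, k)
            else:
                base = np.array([_BACKBONE_STEP * res_id, _CHAIN_SPACING * ci, 0.0])
                n_atoms = 4 + (res_id % 5)
                coords = [
                    base + np.array([0.4 * (a % 3), 0.3 * (a % 2), 0.5 * (a // 2) - 0.5])
                    for a in range(n_atoms)
                ]
            atoms = [
                Atom(
                    serial=0,
                    name=f"{_ELEMENTS[a % len(_ELEMENTS)]}{a}",
                    element=_ELEMENTS[a % len(_ELEMENTS)],
                    coords=c,
                    vdw_radius=vdw_radius(_ELEMENTS[a % len(_ELEMENTS)]),
                    is_heavy=True,
                )
                for a, c in enumerate(coords)
            ]
            structure.add_residue(chain, Residue(ref=ResidueRef(chain, name, res_id), atoms=atoms))
    return structure


# ---------------------------------------------------------------------------
# Alpha spheres (Fpocket layout)
# ---------------------------------------------------------------------------

def _cavity_spheres(center: np.ndarray) -> list[AlphaSphere]:
    spheres = [AlphaSphere(center=center.copy(), radius=4.0)]
    for off in ((1.5, 0.0, 0.0), (-1.5, 0.0, 0.0), (0.0, 0.0, 1.5)):
        spheres.append(AlphaSphere(center=center + np.array(off), radius=2.5))
    return spheres


def _pocket_from_residues(idx: int, structure: ProteinStructure, refs, spheres) -> GeometricPocket:
    atoms, atom_res = [], []
    for ref in refs:
        res = structure.find(ref)
        for a in res.atoms:
            atoms.append(a)
            atom_res.append(res.ref)
    return GeometricPocket(id=idx, spheres=spheres, atoms=atoms, atom_residues=atom_res)


def make_alpha_spheres(
    structure: ProteinStructure,
    spec: FixtureSpec,
    out_dir: str | Path | None = None,
) -> list[GeometricPocket]:
    """Alpha-sphere pocket sets covering each planted cavity, plus decoys.

    One geometric pocket per planted cavity (per replica chain for homomer
    pockets) and ``spec.decoy_count`` decoy pockets over the tail residues
    of chain A, far from every cavity. When ``out_dir`` is given the pockets
    are serialized in the Fpocket ``pockets/pocket<N>_atm.pdb`` +
    ``pocket<N>_vert.pqr`` layout so that ``read_fpocket_dir`` round-trips.
    """
    truths = _plan(spec)
    pockets: list[GeometricPocket] = []
    idx = 1
    for truth in truths:
        if truth.interface:
            refs = [r for rs in truth.residues_by_chain.values() for r in rs]
            pockets.append(_pocket_from_residues(idx, structure, refs, _cavity_spheres(truth.centers["interface"])))
            idx += 1
        else:
            for chain, refs in truth.residues_by_chain.items():
                pockets.append(_pocket_from_residues(idx, structure, refs, _cavity_spheres(truth.centers[chain])))
                idx += 1

    chain_a = spec.chain_ids()[0]
    planted_ids = {i for p in spec.pockets for i in p.residue_ids}
    tail = [i for i in range(spec.residues_per_chain, 0, -1) if i not in planted_ids]
    for d in range(spec.decoy_count):
        ids = tail[3 * d: 3 * d + 3]
        if len(ids) < 3:
            raise ValueError("not enough free tail residues for the requested decoys")
        refs = [structure.get_residue(chain_a, i).ref for i in ids]
        centroid = np.mean(
            [a.coords for i in ids for a in structure.get_residue(chain_a, i).atoms], axis=0
        )
        spheres = [AlphaSphere(center=centroid + np.array([0.0, 0.0, 2.0]), radius=3.0)]
        pockets.append(_pocket_from_residues(idx, structure, refs, spheres))
        idx += 1

    if out_dir is not None:
        pockets_dir = Path(out_dir) / "pockets"
        pockets_dir.mkdir(parents=True, exist_ok=True)
        for gp in pockets:
            sub = ProteinStructure()
            for ref in gp.residue_refs():
                res = structure.find(ref)
                sub.add_residue(ref.chain_id, res)
            write_pdb(sub, pockets_dir / f"pocket{gp.id}_atm.pdb")
            lines = []
            for si, s in enumerate(gp.spheres, start=1):
                x, y, z = s.center
                lines.append(
                    f"ATOM  {si:5d} APOL STP     1    "
                    f"{x:8.3f} {y:8.3f} {z:8.3f} {0.0:8.4f} {s.radius:8.4f}"
                )
            (pockets_dir / f"pocket{gp.id}_vert.pqr").write_text("\n".join(lines) + "\n")
    return pockets


# ---------------------------------------------------------------------------
# Corpus + mock responses
# ---------------------------------------------------------------------------

def _fenced(payload: dict) -> str:
    return "```json\n" + json.dumps(payload, indent=2) + "\n```\n"


def _lit_tokens(spec: FixtureSpec, refs, rng: np.random.Generator) -> list[str]:
    """Literature-level tokens for planted residues, with noise applied."""
    tokens = []
    for ref in refs:
        res_id = ref.res_id + spec.numbering_offset
        name = ref.res_name
        if spec.name_corruption_rate and rng.random() < spec.name_corruption_rate:
            name = _AMINO[(_AMINO.index(name) + 7) % len(_AMINO)]
        tokens.append(f"{ref.chain_id}:{name}:{res_id}")
    return tokens


@dataclass
class CorpusBundle:
    documents: list[PaperDocument]
    annotations: list[PaperAnnotation]
    responses: dict[tuple[str, str], str] = field(default_factory=dict)

    def backend(self) -> MockBackend:
        return MockBackend(self.responses, self.documents)


_NEGATIVE_TEXT = """# Expression and purification of {target}

We report an optimized protocol for recombinant expression of {target}
in E. coli and its purification by affinity chromatography. Yields reached
12 mg per litre of culture. Thermal-shift assays confirmed the folded state
of the purified protein. No structural or ligand-binding characterization
was performed in this study.
"""

_POSITIVE_TEXT = """# Structural basis of ligand recognition by {target}

We determined the binding determinants of {target} by mutational scanning
and docking. {body}
"""


def make_corpus(spec: FixtureSpec, out_dir: str | Path | None = None) -> CorpusBundle:
    """Paper-like documents, annotations and canned mock responses.

    Three tiers mirror a realistic benchmark: negative-control documents
    with no binding-site description, one single-site document per planted
    pocket, and (when ≥2 pockets are planted) one multi-site document
    covering them all. Canned responses are consistent with the planted
    truth, optionally corrupted by the spec's noise knobs on the extraction
    stage; refinement responses always return the clean truth.
    """
    rng = np.random.default_rng(spec.seed)
    truths = _plan(spec)
    docs: list[PaperDocument] = []
    annotations: list[PaperAnnotation] = []
    responses: dict[tuple[str, str], str] = {}

    def lit_pocket_payload(truth: PlantedTruth, tokens: list[str]) -> dict:
        return {
            "name": truth.name,
            "description": f"{truth.name} of {spec.target_name}",
            "residues": tokens,
        }

    # negative controls
    for k in range(spec.n_negative_docs):
        doc_id = f"negative_{k + 1}"
        docs.append(PaperDocument(doc_id, spec.target_name, _NEGATIVE_TEXT.format(target=spec.target_name)))
        annotations.append(PaperAnnotation(doc_id=doc_id, target_name=spec.target_name, relevant=False))
        responses[("relevance", doc_id)] = _fenced(
            {"relevant": False, "reasons": "no residue-level binding-site description"}
        )

    # one single-site paper per pocket (+ one multi-site paper if ≥2 pockets)
    doc_plans: list[tuple[str, list[PlantedTruth]]] = [
        (f"paper_{i + 1}", [truth]) for i, truth in enumerate(truths)
    ]
    if len(truths) >= 2:
        doc_plans.append(("paper_multi", list(truths)))

    for doc_id, doc_truths in doc_plans:
        tokens_per_truth = [_lit_tokens(spec, t.literature_residues, rng) for t in doc_truths]
        body = "\n\n".join(
            f"The {t.name} is lined by residues {', '.join(tokens)}."
            for t, tokens in zip(doc_truths, tokens_per_truth)
        )
        docs.append(PaperDocument(doc_id, spec.target_name, _POSITIVE_TEXT.format(target=spec.target_name, body=body)))
        annotations.append(
            PaperAnnotation(
                doc_id=doc_id,
                target_name=spec.target_name,
                relevant=True,
                pockets=[
                    PocketAnnotation(**lit_pocket_payload(t, tokens))
                    for t, tokens in zip(doc_truths, tokens_per_truth)
                ],
            )
        )
        responses[("relevance", doc_id)] = _fenced(
            {"relevant": True, "reasons": "residue-level binding sites described"}
        )

        extracted = []
        for t, tokens in zip(doc_truths, tokens_per_truth):
            tokens = list(tokens)
            if spec.token_corruption_rate:
                tokens = [
                    tok if rng.random() >= spec.token_corruption_rate else f"A:XYZ:{i}"
                    for i, tok in enumerate(tokens)
                ]
            if spec.hallucinated_residues:
                tokens += [
                    f"{t.literature_residues[0].chain_id}:TRP:{900 + h}"
                    for h in range(spec.hallucinated_residues)
                ]
            if spec.split_pockets and len(tokens) >= 4:
                half = len(tokens) // 2
                extracted.append({**lit_pocket_payload(t, tokens[:half]), "name": f"{t.name} (segment 1)"})
                extracted.append({**lit_pocket_payload(t, tokens[half:]), "name": f"{t.name} (segment 2)"})
            else:
                extracted.append(lit_pocket_payload(t, tokens))
        responses[("extraction", doc_id)] = _fenced({"pockets": extracted})
        responses[("refinement", doc_id)] = _fenced(
            {"pockets": [lit_pocket_payload(t, tokens) for t, tokens in zip(doc_truths, tokens_per_truth)]}
        )

    bundle = CorpusBundle(documents=docs, annotations=annotations, responses=responses)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "papers").mkdir(parents=True, exist_ok=True)
        (out / "annotations").mkdir(parents=True, exist_ok=True)
        (out / "responses").mkdir(parents=True, exist_ok=True)
        for doc in docs:
            (out / "papers" / f"{doc.doc_id}.md").write_text(doc.text, encoding="utf-8")
        for ann in annotations:
            write_annotation(ann, out / "annotations" / f"{ann.doc_id}.json")
        for (stage, doc_id), text in responses.items():
            (out / "responses" / f"{doc_id}__{stage}.txt").write_text(text, encoding="utf-8")
    return bundle
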