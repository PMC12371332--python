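"""Fpocket-style geometric pockets: reading, literature filtering, merging.

Fpocket represents each candidate pocket as a set of alpha spheres plus the
protein atoms lining them, written as ``pockets/pocket<N>_atm.pdb`` and
``pockets/pocket<N>_vert.pqr``. This module consumes that layout (it never
re-runs the Voronoi detection itself), derives each pocket's residue set via
an atom-in-sphere contact rule, keeps only pockets whose residues overlap a
literature-mapped pocket by Jaccard index, and merges overlapping survivors
— including pockets supported by the same literature pocket, which is how
fragmented sub-pockets and multi-paper descriptions of one physical site
get consolidated.

Contact rule: a heavy atom is "in contact" with an alpha sphere when its
center lies within (sphere radius + contact tolerance, default 1.0 Å) of
the sphere center; a residue belongs to a pocket when at least a threshold
fraction of its heavy atoms are in contact (default 0.5). Selection keeps a
geometric pocket when its residue-set Jaccard with some mapped pocket is ≥
the pocket-match threshold (default 0.3, inclusive); merging unions pockets
whose residue Jaccard strictly exceeds the merge threshold (default 0.5) or
that share a supporting literature pocket, closed transitively.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .mapping import MappedPocket
from .structures import Atom, ProteinStructure, ResidueRef, parse_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaSphere",
    "GeometricPocket",
    "SelectedPocket",
    "MergedPocket",
    "read_fpocket_dir",
    "residue_contact_fraction",
    "geometric_pocket_residues",
    "jaccard",
    "select_pockets",
    "merge_pockets",
]

DEFAULT_CONTACT_TOL = 1.0      # Å added to the sphere radius for contact
DEFAULT_RESIDUE_MATCH = 0.5    # min fraction of residue atoms in contact
DEFAULT_POCKET_MATCH = 0.3     # min Jaccard between geometric and mapped residues
DEFAULT_MERGE_OVERLAP = 0.5    # residue Jaccard strictly above this merges pockets


@dataclass(frozen=True)
class AlphaSphere:
    center: np.ndarray  # (3,) Å
    radius: float
    polarity: bool | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError(f"alpha sphere radius must be positive, got {self.radius}")

    @property
    def key(self) -> tuple:
        return (round(self.center[0], 3), round(self.center[1], 3), round(self.center[2], 3), round(self.radius, 3))


@dataclass
class GeometricPocket:
    """One Fpocket candidate: alpha spheres plus the lining protein atoms."""

    id: int
    spheres: list[AlphaSphere]
    atoms: list[Atom]
    atom_residues: list[ResidueRef]  # parallel to ``atoms``

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError(f"pocket {self.id}: no alpha spheres")
        if not self.atoms:
            raise ValueError(f"pocket {self.id}: no pocket atoms")
        if len(self.atoms) != len(self.atom_residues):
            raise ValueError(f"pocket {self.id}: atoms/residues length mismatch")

    def residue_refs(self) -> list[ResidueRef]:
        seen: set[tuple] = set()
        out = []
        for ref in self.atom_residues:
            if ref.key not in seen:
                seen.add(ref.key)
                out.append(ref)
        return out


# ---------------------------------------------------------------------------
# Fpocket output reading
# ---------------------------------------------------------------------------

_ATM_RE = re.compile(r"pocket(\d+)_atm\.pdb$")


def _read_vert_pqr(path: Path) -> list[AlphaSphere]:
    """Alpha spheres from an Fpocket ``*_vert.pqr`` file.

    PQR records are whitespace-separated with the last five numeric fields
    being x, y, z, charge, radius.
    """
    spheres = []
    for line in path.read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        fields = line.split()
        try:
            x, y, z, _charge, radius = (float(v) for v in fields[-5:])
        except (ValueError, IndexError):
            logger.warning("%s: unparseable PQR record skipped: %r", path.name, line)
            continue
        spheres.append(AlphaSphere(center=np.array([x, y, z]), radius=radius))
    return spheres


def read_fpocket_dir(path: str | Path) -> list[GeometricPocket]:
    """Load all pockets from an Fpocket output directory.

    ``path`` may be the run directory (containing ``pockets/``) or the
    ``pockets`` directory itself. Pockets missing their vert/atm partner
    file are skipped with a warning; an empty directory yields ``[]``.
    """
    root = Path(path)
    pockets_dir = root / "pockets" if (root / "pockets").is_dir() else root
    if not pockets_dir.is_dir():
        raise FileNotFoundError(f"no Fpocket pockets directory at {path}")

    out: list[GeometricPocket] = []
    for atm_path in sorted(pockets_dir.glob("pocket*_atm.pdb"),
                           key=lambda p: int(_ATM_RE.search(p.name).group(1))):
        idx = int(_ATM_RE.search(atm_path.name).group(1))
        vert_path = pockets_dir / f"pocket{idx}_vert.pqr"
        if not vert_path.exists():
            logger.warning("pocket %d: %s missing, pocket skipped", idx, vert_path.name)
            continue
        try:
            structure = parse_pdb(atm_path)
            spheres = _read_vert_pqr(vert_path)
            atoms: list[Atom] = []
            atom_res: list[ResidueRef] = []
            for _cid, res in structure.iter_residues():
                for atom in res.atoms:
                    atoms.append(atom)
                    atom_res.append(res.ref)
            out.append(GeometricPocket(id=idx, spheres=spheres, atoms=atoms, atom_residues=atom_res))
        except (ValueError, OSError) as exc:
            logger.warning("pocket %d unreadable (%s), skipped", idx, exc)
    return out


# ---------------------------------------------------------------------------
# Residue derivation and overlap
# ---------------------------------------------------------------------------

def residue_contact_fraction(
    residue_atoms: Sequence[Atom],
    spheres: Sequence[AlphaSphere],
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> float:
    """Fraction of a residue's heavy atoms in contact with the sphere set."""
    heavy = [a for a in residue_atoms if a.is_heavy]
    if not heavy:
        raise ValueError("residue_contact_fraction: no heavy atoms")
    if not spheres:
        return 0.0
    coords = np.array([a.coords for a in heavy])          # (n, 3)
    centers = np.array([s.center for s in spheres])       # (m, 3)
    cutoffs = np.array([s.radius + contact_tol for s in spheres])
    d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    in_contact = (d <= cutoffs[None, :]).any(axis=1)
    return float(in_contact.sum()) / len(heavy)


def geometric_pocket_residues(
    pocket: GeometricPocket,
    structure: ProteinStructure | None = None,
    residue_match_threshold: float = DEFAULT_RESIDUE_MATCH,
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> frozenset[ResidueRef]:
    """Residues of a geometric pocket under the contact-fraction rule.

    Candidate residues are those appearing in the pocket's atom file; their
    heavy atoms are taken from ``structure`` when given (the atm file may
    list only the lining atoms), falling back to the pocket's own atoms.
    A residue qualifies when its contact fraction is ≥ the threshold and at
    least one atom is in contact — so threshold 0 means "any contact".
    """
    by_res: dict[tuple, list[Atom]] = {}
    ref_by_key: dict[tuple, ResidueRef] = {}
    for atom, ref in zip(pocket.atoms, pocket.atom_residues):
        by_res.setdefault(ref.key, []).append(atom)
        ref_by_key.setdefault(ref.key, ref)

    kept = []
    for key, own_atoms in by_res.items():
        ref = ref_by_key[key]
        atoms = own_atoms
        if structure is not None:
            res = structure.find(ref)
            if res is not None:
                atoms = res.heavy_atoms
        frac = residue_contact_fraction(atoms, pocket.spheres, contact_tol)
        if frac > 0.0 and frac >= residue_match_threshold:
            kept.append(ref)
    return frozenset(kept)


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |A∩B| / |A∪B| over residue(-key) sets; 0 if both empty."""
    a = {x.key if isinstance(x, ResidueRef) else x for x in set_a}
    b = {x.key if isinstance(x, ResidueRef) else x for x in set_b}
    union = a | b
    if not union:
        logger.debug("jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Selection and merging
# ---------------------------------------------------------------------------

@dataclass
class SelectedPocket:
    """A geometric pocket retained by literature support."""

    pocket: GeometricPocket
    residues: frozenset[ResidueRef]
    supports: list[MappedPocket]
    support_jaccards: list[float]


def select_pockets(
    geom: Sequence[GeometricPocket],
    mapped: Sequence[MappedPocket],
    structure: ProteinStructure | None = None,
    pocket_match_jaccard: float = DEFAULT_POCKET_MATCH,
    residue_match_threshold: float = DEFAULT_RESIDUE_MATCH,
    contact_tol: float = DEFAULT_CONTACT_TOL,
) -> list[SelectedPocket]:
    """Keep geometric pockets whose residues overlap a mapped pocket.

    A pocket is retained iff its Jaccard index with at least one mapped
    pocket's residue set reaches ``pocket_match_jaccard`` (inclusive); every
    qualifying mapped pocket is recorded as support.
    """
    selected: list[SelectedPocket] = []
    for gp in geom:
        residues = geometric_pocket_residues(gp, structure, residue_match_threshold, contact_tol)
        supports, jacs = [], []
        for mp in mapped:
            j = jaccard(residues, mp.residue_keys)
            if j >= pocket_match_jaccard and j > 0.0:
                supports.append(mp)
                jacs.append(j)
        if supports:
            selected.append(SelectedPocket(pocket=gp, residues=residues, supports=supports, support_jaccards=jacs))
        else:
            logger.info("geometric pocket %d discarded: no literature support", gp.id)
    return selected


@dataclass
class MergedPocket:
    """Union of one or more selected pockets treated as one binding site."""

    ids: tuple[int, ...]
    spheres: list[AlphaSphere]
    atoms: list[Atom]
    residues: frozenset[ResidueRef]
    supports: list[MappedPocket]
    name: str
    description: str = ""

    @property
    def residue_keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.residues)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def merge_pockets(
    selected: Sequence[SelectedPocket],
    merge_overlap_threshold: float = DEFAULT_MERGE_OVERLAP,
) -> list[MergedPocket]:
    """Merge selected pockets that describe one physical site.

    Two pockets join when their residue-set Jaccard strictly exceeds the
    merge threshold, or when they share a supporting literature pocket;
    groups are closed transitively (union–find). Merged pockets union their
    spheres (deduplicated), atoms and residues, and consolidate the names
    and descriptions of all supporting literature pockets — possibly from
    different papers.
    """
    n = len(selected)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            share_support = bool(
                {mp.identity for mp in selected[i].supports}
                & {mp.identity for mp in selected[j].supports}
            )
            if share_support or jaccard(selected[i].residues, selected[j].residues) > merge_overlap_threshold:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    merged: list[MergedPocket] = []
    for root in sorted(groups):
        idx = groups[root]
        spheres: list[AlphaSphere] = []
        sphere_keys: set[tuple] = set()
        atoms: list[Atom] = []
        atom_keys: set[tuple] = set()
        residues: set[ResidueRef] = set()
        supports: list[MappedPocket] = []
        support_ids: set[tuple] = set()
        for i in idx:
            sel = selected[i]
            for s in sel.pocket.spheres:
                if s.key not in sphere_keys:
                    sphere_keys.add(s.key)
                    spheres.append(s)
            for a, ref in zip(sel.pocket.atoms, sel.pocket.atom_residues):
                akey = (ref.key, a.name)
                if akey not in atom_keys:
                    atom_keys.add(akey)
                    atoms.append(a)
            residues |= sel.residues
            for mp in sel.supports:
                if mp.identity not in support_ids:
                    support_ids.add(mp.identity)
                    supports.append(mp)
        names = sorted({mp.name for mp in supports})
        descriptions = sorted({mp.source.description for mp in supports if mp.source.description})
        merged.append(
            MergedPocket(
                ids=tuple(sorted(selected[i].pocket.id for i in idx)),
                spheres=spheres,
                atoms=atoms,
                residues=frozenset(residues),
                supports=supports,
                name=" / ".join(names) if names else f"pocket {idx[0]}",
                description=" | ".join(descriptions),
            )
        )
    return merged
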