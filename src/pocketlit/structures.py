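"""Protein structure I/O and residue identity.

Parses PDB files into a light-weight chain/residue/atom model carrying the
information the pocket pipeline needs: heavy-atom coordinates, per-element
Van der Waals radii and ``(chain, residue number, insertion code)`` identity.
Parsing is delegated to :mod:`gemmi`; alternate locations are resolved to the
highest-occupancy conformer (ties broken by altloc letter), and waters and
hydrogens are dropped by default since all pocket geometry downstream is
heavy-atom based.

Also home to the residue *token* grammar (``"A:TYR:123"``) used by the
literature-extraction stages and the annotation files.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "ResidueRef",
    "Residue",
    "ProteinStructure",
    "EmptyStructureError",
    "ResidueTokenError",
    "parse_pdb",
    "write_pdb",
    "chain_sequence",
    "vdw_radius",
    "parse_residue_token",
    "format_residue_token",
    "one_letter_code",
    "DEFAULT_VDW_RADIUS",
]


class EmptyStructureError(ValueError):
    """Raised when a PDB source contains no polymer atoms after filtering."""


class ResidueTokenError(ValueError):
    """Raised when a residue token cannot be parsed."""


# ---------------------------------------------------------------------------
# Van der Waals radii (Bondi-type values, Å). Used for grid pruning.
# ---------------------------------------------------------------------------

DEFAULT_VDW_RADIUS = 1.70

VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "B": 1.92, "SI": 2.10, "ZN": 1.39, "CU": 1.40, "NI": 1.63, "MG": 1.73,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "FE": 1.94, "MN": 1.90, "CO": 1.92,
}


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Å for an element symbol.

    Unknown symbols fall back to ``DEFAULT_VDW_RADIUS`` (1.70 Å, carbon-like)
    with a logged warning rather than failing, so that exotic hetero-elements
    never abort grid construction.
    """
    r = VDW_RADII.get(element.strip().upper())
    if r is None:
        logger.warning(
            "unknown element %r: falling back to default VdW radius %.2f Å",
            element, DEFAULT_VDW_RADIUS,
        )
        return DEFAULT_VDW_RADIUS
    return r


# ---------------------------------------------------------------------------
# Residue naming tables
# ---------------------------------------------------------------------------

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Nonstandard residues accepted in literature tokens and annotations.
EXTENDED_RESIDUES: frozenset[str] = frozenset({"MSE", "SEC", "PYL", "HYP", "PTR", "SEP", "TPO"})

#: Aliases applied when computing one-letter sequences (selenomethionine etc.).
SEQUENCE_ALIASES: dict[str, str] = {"MSE": "M", "SEC": "C", "PYL": "K"}

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL"})


def one_letter_code(res_name: str, alias_nonstandard: bool = True) -> str:
    """One-letter code for a residue name; nonstandard residues map to 'X'.

    With ``alias_nonstandard`` (default), common aliases such as MSE → M are
    applied before falling back to 'X'.
    """
    name = res_name.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    if alias_nonstandard and name in SEQUENCE_ALIASES:
        return SEQUENCE_ALIASES[name]
    return "X"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueRef:
    """Identity of a residue at the literature or structure level.

    Equality and hashing use ``(chain_id, res_id, icode)`` only; ``res_name``
    is carried along for verification (a literature residue whose name
    disagrees with the structure at the same position is *not* a match, but
    that check is done explicitly by the mapping stage, not by ``==``).
    """

    chain_id: str
    res_name: str
    res_id: int
    icode: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "res_name", self.res_name.upper())
        object.__setattr__(self, "icode", self.icode.strip())

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_id, self.icode)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueRef):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def token(self) -> str:
        """Canonical token form, e.g. ``"A:TYR:123"`` or ``"A:TYR:123B"``."""
        return f"{self.chain_id}:{self.res_name}:{self.res_id}{self.icode}"


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    vdw_radius: float
    is_heavy: bool

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): invalid coordinates")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: non-positive VdW radius")


@dataclass(eq=False)
class Residue:
    ref: ResidueRef
    atoms: list[Atom] = field(default_factory=list)

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_centroid(self) -> np.ndarray:
        """Mean position of the heavy atoms — the residue's representative
        point for spatial clustering."""
        heavy = self.heavy_atoms
        if not heavy:
            raise ValueError(f"residue {self.ref.token()} has no heavy atoms")
        return np.mean([a.coords for a in heavy], axis=0)


class ProteinStructure:
    """Ordered chains of residues with grouped atoms.

    ``chains`` maps chain id → ordered residue list; residue identity
    ``(chain_id, res_id, icode)`` is unique across the structure.
    """

    def __init__(self, chains: Mapping[str, list[Residue]] | None = None):
        self.chains: dict[str, list[Residue]] = {}
        self._index: dict[tuple[str, int, str], Residue] = {}
        if chains:
            for cid, residues in chains.items():
                for res in residues:
                    self.add_residue(cid, res)

    def add_residue(self, chain_id: str, residue: Residue) -> None:
        key = (chain_id, residue.ref.res_id, residue.ref.icode)
        if key in self._index:
            logger.warning("duplicate residue %s skipped", residue.ref.token())
            return
        self.chains.setdefault(chain_id, []).append(residue)
        self._index[key] = residue

    # -- lookups ----------------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def get_residue(self, chain_id: str, res_id: int, icode: str = "") -> Residue | None:
        return self._index.get((chain_id, res_id, icode))

    def find(self, ref: ResidueRef) -> Residue | None:
        return self._index.get(ref.key)

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for cid, residues in self.chains.items():
            for res in residues:
                yield cid, res

    def heavy_atoms(self) -> list[Atom]:
        return [a for _, res in self.iter_residues() for a in res.heavy_atoms]

    def n_residues(self) -> int:
        return len(self._index)

    def n_atoms(self) -> int:
        return sum(len(res.atoms) for _, res in self.iter_residues())


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, then altloc letter."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for variants in by_name.values():
        variants.sort(key=lambda a: (-a.occ, a.altloc))
        chosen.append(variants[0])
    chosen.sort(key=lambda a: a.serial)
    return chosen


def parse_pdb(
    source: str | Path,
    exclude_waters: bool = True,
    exclude_hydrogens: bool = True,
) -> ProteinStructure:
    """Parse PDB text or a PDB file into a :class:`ProteinStructure`.

    Only the first MODEL is read. Waters and hydrogens are excluded by
    default (all downstream geometry is heavy-atom based); pass
    ``exclude_hydrogens=False`` to keep protons. Alternate locations are
    resolved to the highest-occupancy conformer.

    Raises
    ------
    EmptyStructureError
        If no residues remain after filtering (e.g. a water-only file).
    FileNotFoundError / OSError
        If ``source`` names a path that cannot be read.
    """
    if isinstance(source, Path):
        st = gemmi.read_structure(str(source), format=gemmi.CoorFormat.Pdb)
    elif "\n" in source or source.lstrip()[:6] in ("ATOM  ", "HETATM") or source.startswith(("HEADER", "CRYST", "MODEL")):
        st = gemmi.read_pdb_string(source)
    else:
        st = gemmi.read_structure(source, format=gemmi.CoorFormat.Pdb)

    if len(st) == 0:
        raise EmptyStructureError("no models in PDB source")
    model = st[0]

    structure = ProteinStructure()
    for chain in model:
        cid = chain.name.strip()
        for gres in chain:
            if exclude_waters and (gres.is_water() or gres.name.upper() in _WATER_NAMES):
                continue
            atoms: list[Atom] = []
            for gatom in _resolve_altlocs(gres):
                elem = gatom.element.name.upper()
                is_heavy = not gatom.element.is_hydrogen
                if exclude_hydrogens and not is_heavy:
                    continue
                atoms.append(
                    Atom(
                        serial=gatom.serial,
                        name=gatom.name,
                        element=elem,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        vdw_radius=vdw_radius(elem),
                        is_heavy=is_heavy,
                    )
                )
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            ref = ResidueRef(cid, gres.name, gres.seqid.num, icode)
            structure.add_residue(cid, Residue(ref=ref, atoms=atoms))

    if structure.n_residues() == 0:
        raise EmptyStructureError("PDB source contains no polymer atoms after filtering")
    return structure


def write_pdb(structure: ProteinStructure, path: str | Path | None = None) -> str:
    """Serialize a structure back to PDB text (fixtures and debugging).

    Atom serials are renumbered sequentially; occupancy 1.00, B-factor 0.00.
    """
    lines: list[str] = []
    serial = 0
    for cid, residues in structure.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:5d} {name:4s} {res.ref.res_name:>3s} "
                    f"{cid:1s}{res.ref.res_id:4d}{res.ref.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def chain_sequence(
    structure: ProteinStructure,
    chain_id: str,
    alias_nonstandard: bool = True,
) -> str:
    """One-letter sequence of a chain, in residue order.

    Nonstandard residues map to 'X' (or via ``SEQUENCE_ALIASES`` when
    ``alias_nonstandard`` is on, the default — e.g. MSE → M). An empty
    ``chain_id`` on a single-chain structure selects that chain.
    """
    if chain_id == "" and len(structure.chains) == 1:
        chain_id = next(iter(structure.chains))
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure (has {structure.chain_ids})")
    return "".join(
        one_letter_code(res.ref.res_name, alias_nonstandard)
        for res in structure.chains[chain_id]
    )


# ---------------------------------------------------------------------------
# Residue tokens
# ---------------------------------------------------------------------------

_CANONICAL_RE = re.compile(
    r"^(?P<chain>[A-Za-z0-9]{0,4}):(?P<name>[A-Za-z]{3}):(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$"
)
_COMPACT3_RE = re.compile(r"^(?P<name>[A-Za-z]{3})\s?(?P<num>-?\d+)(?P<icode>[A-Za-z]?)$")
_COMPACT1_RE = re.compile(r"^(?P<name>[A-Za-z])(?P<num>\d+)(?P<icode>[A-Za-z]?)$")


def _check_res_name(name: str, token: str) -> str:
    name = name.upper()
    if name not in THREE_TO_ONE and name not in EXTENDED_RESIDUES:
        raise ResidueTokenError(f"unrecognized residue name {name!r} in token {token!r}")
    return name


def parse_residue_token(token: str, default_chain: str = "A") -> ResidueRef:
    """Parse a residue token into a :class:`ResidueRef`.

    Accepted forms (insertion code as a trailing letter is allowed in each):

    - canonical ``"A:TYR:123"`` — chain, 3-letter name, number;
    - compact ``"TYR123"`` — 3-letter name + number, chain defaults;
    - one-letter ``"Y123"`` — expanded via the standard code table.

    Raises :class:`ResidueTokenError` for unknown residue names or
    non-integer numbers, identifying the offending token.
    """
    text = token.strip()
    if not text:
        raise ResidueTokenError("empty residue token")
    m = _CANONICAL_RE.match(text)
    if m:
        name = _check_res_name(m["name"], token)
        chain = m["chain"] or default_chain
        return ResidueRef(chain, name, int(m["num"]), m["icode"])
    if ":" in text:
        raise ResidueTokenError(f"malformed residue token {token!r}")
    m = _COMPACT3_RE.match(text)
    if m:
        name = _check_res_name(m["name"], token)
        return ResidueRef(default_chain, name, int(m["num"]), m["icode"])
    m = _COMPACT1_RE.match(text)
    if m:
        one = m["name"].upper()
        if one not in ONE_TO_THREE:
            raise ResidueTokenError(f"unrecognized one-letter code in token {token!r}")
        return ResidueRef(default_chain, ONE_TO_THREE[one], int(m["num"]), m["icode"])
    raise ResidueTokenError(f"malformed residue token {token!r}")


def format_residue_token(ref: ResidueRef) -> str:
    """Inverse of :func:`parse_residue_token` for the canonical form."""
    return ref.token()


def residue_key_set(residues: Iterable[ResidueRef]) -> frozenset[tuple[str, int, str]]:
    """Canonical ``(chain, res_id, icode)`` key set for overlap arithmetic."""
    return frozenset(r.key for r in residues)
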