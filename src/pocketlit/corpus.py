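"""Benchmark corpus I/O: per-paper annotation JSONs and paper markdown.

Each benchmark paper has a ground-truth annotation file listing the
small-molecule binding sites it explicitly describes — the site's name,
description and constituent residues — or ``relevant: false`` for
negative-control papers that describe no site. Papers themselves are
GROBID-style markdown text consumed verbatim.

The JSON dialect is documented in ``schema/annotation.schema.json``::

    {
      "doc_id": "smith2020",
      "target_name": "ABL1 kinase",
      "relevant": true,
      "pockets": [
        {"name": "ATP site",
         "description": "catalytic ATP-binding cleft",
         "residues": ["A:LYS:271", "A:ASP:381"]}
      ]
    }

Residues are tokens in the ``CHAIN:RESNAME:RESID[ICODE]`` format; a loader
shim also accepts field-based residue objects (``{"chain": .., "name": ..,
"number": ..}``) and a few common key aliases so that externally produced
benchmark files load without conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .structures import ResidueRef, ResidueTokenError, parse_residue_token

__all__ = [
    "PocketAnnotation",
    "PaperAnnotation",
    "PaperDocument",
    "AnnotationError",
    "read_annotation",
    "write_annotation",
    "read_paper_markdown",
]


class AnnotationError(ValueError):
    """Annotation JSON failed schema or invariant validation."""


_POCKET_KEY_ALIASES = {"binding_sites": "pockets", "sites": "pockets"}
_DOC_KEY_ALIASES = {"paper_id": "doc_id", "id": "doc_id", "target": "target_name", "protein": "target_name"}


def _coerce_residue(entry: Any) -> ResidueRef:
    if isinstance(entry, ResidueRef):
        return entry
    if isinstance(entry, str):
        return parse_residue_token(entry)
    if isinstance(entry, dict):
        chain = entry.get("chain") or entry.get("chain_id") or "A"
        name = entry.get("name") or entry.get("res_name") or entry.get("residue")
        num = entry.get("number") if "number" in entry else entry.get("res_id")
        icode = entry.get("icode", "") or ""
        if name is None or num is None:
            raise ResidueTokenError(f"residue object missing name/number: {entry!r}")
        return parse_residue_token(f"{chain}:{name}:{int(num)}{icode}")
    raise ResidueTokenError(f"unsupported residue entry {entry!r}")


class PocketAnnotation(BaseModel):
    """A named binding site with its constituent residues (ground truth)."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    name: str = Field(min_length=1)
    description: str = ""
    residues: list[ResidueRef]

    @field_validator("residues", mode="before")
    @classmethod
    def _parse_residues(cls, v: Any) -> list[ResidueRef]:
        if not isinstance(v, (list, tuple)):
            raise ValueError("residues must be a list")
        try:
            return [_coerce_residue(e) for e in v]
        except ResidueTokenError as exc:
            raise ValueError(str(exc)) from exc

    @field_validator("residues")
    @classmethod
    def _non_empty_unique(cls, v: list[ResidueRef]) -> list[ResidueRef]:
        if not v:
            raise ValueError("pocket must list at least one residue")
        if len({r.key for r in v}) != len(v):
            dupes = sorted({r.token() for r in v if sum(s.key == r.key for s in v) > 1})
            raise ValueError(f"duplicate residues in pocket: {dupes}")
        return v

    @property
    def residue_keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.residues)


class PaperAnnotation(BaseModel):
    """Ground-truth annotation for one benchmark paper.

    ``relevant = false`` marks a negative-control paper and implies an empty
    pocket list; a relevant paper with no pockets must be explicitly flagged
    ``inconsistent`` (used for papers whose site description could not be
    resolved to residues).
    """

    doc_id: str = Field(min_length=1)
    target_name: str = ""
    relevant: bool
    pockets: list[PocketAnnotation] = Field(default_factory=list)
    inconsistent: bool = False

    @model_validator(mode="before")
    @classmethod
    def _apply_aliases(cls, data: Any) -> Any:
        if isinstance(data, dict):
            for old, new in {**_DOC_KEY_ALIASES, **_POCKET_KEY_ALIASES}.items():
                if old in data and new not in data:
                    data[new] = data.pop(old)
        return data

    @model_validator(mode="after")
    def _check_consistency(self) -> "PaperAnnotation":
        if not self.relevant and self.pockets:
            raise ValueError("negative-control annotation (relevant=false) must have no pockets")
        if self.relevant and not self.pockets and not self.inconsistent:
            raise ValueError("relevant annotation with no pockets must be flagged inconsistent")
        return self


@dataclass(frozen=True)
class PaperDocument:
    """A research article as GROBID-style markdown text."""

    doc_id: str
    target_name: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"paper document {self.doc_id!r} has empty text")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> PaperAnnotation:
    """Load and validate one per-paper annotation JSON.

    Raises :class:`AnnotationError` with the offending fields on schema
    violations or malformed residue tokens.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict) and "doc_id" not in data and "paper_id" not in data and "id" not in data:
        data["doc_id"] = path.stem
    try:
        return PaperAnnotation.model_validate(data)
    except Exception as exc:  # pydantic.ValidationError
        raise AnnotationError(f"{path}: {exc}") from exc


def write_annotation(annotation: PaperAnnotation, path: str | Path) -> None:
    """Serialize an annotation so that :func:`read_annotation` round-trips it."""
    payload = {
        "doc_id": annotation.doc_id,
        "target_name": annotation.target_name,
        "relevant": annotation.relevant,
        "pockets": [
            {
                "name": p.name,
                "description": p.description,
                "residues": [r.token() for r in p.residues],
            }
            for p in annotation.pockets
        ],
    }
    if annotation.inconsistent:
        payload["inconsistent"] = True
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8")


def read_paper_markdown(path: str | Path, target_name: str, doc_id: str | None = None) -> PaperDocument:
    """Load a paper markdown file; line endings are normalized to ``"\\n"``.

    ``doc_id`` defaults to the file stem. Empty files are rejected.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").replace("\r\n", "\n").replace("\r", "\n")
    if not text.strip():
        raise AnnotationError(f"{path}: empty paper document")
    return PaperDocument(doc_id=doc_id or path.stem, target_name=target_name, text=text)
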