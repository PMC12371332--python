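"""Three-stage prompted extraction of binding pockets from article text.

The workflow runs (i) paper relevance assessment, (ii) pocket extraction and
(iii) pocket refinement over a pluggable text-completion backend, all stages
with the same backend. Prompts are shipped as editable text assets under
``prompts/`` and require each stage to answer inside a fenced JSON block;
the parser takes the first valid block and retries a malformed response a
configurable number of times before raising.

Backends implement a single ``complete(prompt, document) -> str`` method.
Two are provided: a thin adapter for OpenAI-style chat-completion HTTP
services, and a deterministic mock driven by canned responses keyed by
``(stage, doc_id)`` — the workhorse for offline testing, since identical
inputs always produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Protocol

from .corpus import PaperDocument
from .structures import (
    ResidueRef,
    ResidueTokenError,
    format_residue_token,
    parse_residue_token,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Backend",
    "MockBackend",
    "OpenAICompatBackend",
    "BackendError",
    "ResponseFormatError",
    "ContextBudgetError",
    "RelevanceDecision",
    "ExtractedPocket",
    "ExtractionConfig",
    "assess_relevance",
    "extract_pockets",
    "refine_pockets",
    "run_extraction_pipeline",
    "parse_residue_token",
    "load_prompt",
    "STAGES",
]

STAGES = ("relevance", "extraction", "refinement")


class BackendError(RuntimeError):
    """The completion backend failed after all retries."""


class ResponseFormatError(ValueError):
    """No parseable fenced JSON block after all retries."""


class ContextBudgetError(ValueError):
    """Document exceeds the configured character budget for the backend."""


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class Backend(Protocol):
    """Text-completion backend contract."""

    name: str

    def complete(self, prompt: str, document: str) -> str: ...


_STAGE_RE = re.compile(r"TASK CODE:\s*(RELEVANCE|EXTRACTION|REFINEMENT)")


class MockBackend:
    """Deterministic backend replaying canned responses.

    Responses are keyed by ``(stage, doc_id)``. The stage is read from the
    ``TASK CODE:`` line every prompt template begins with; the document id is
    resolved by exact text match against the registered documents. Identical
    ``(prompt, document)`` calls always return the identical response.
    """

    name = "mock"

    def __init__(self, responses: dict[tuple[str, str], str], documents: list[PaperDocument]):
        self.responses = dict(responses)
        self._doc_ids = {doc.text: doc.doc_id for doc in documents}
        self.calls: list[tuple[str, str]] = []

    @classmethod
    def from_dir(cls, path: str | Path, documents: list[PaperDocument]) -> "MockBackend":
        """Load canned responses from ``<doc_id>__<stage>.txt`` files."""
        responses: dict[tuple[str, str], str] = {}
        for f in sorted(Path(path).glob("*__*.txt")):
            doc_id, _, stage = f.stem.rpartition("__")
            if stage not in STAGES:
                logger.warning("ignoring canned response with unknown stage: %s", f.name)
                continue
            responses[(stage, doc_id)] = f.read_text(encoding="utf-8")
        return cls(responses, documents)

    def complete(self, prompt: str, document: str) -> str:
        m = _STAGE_RE.search(prompt)
        if not m:
            raise BackendError("mock backend: prompt carries no TASK CODE")
        stage = m.group(1).lower()
        doc_id = self._doc_ids.get(document)
        if doc_id is None:
            raise BackendError("mock backend: unknown document text")
        self.calls.append((stage, doc_id))
        try:
            return self.responses[(stage, doc_id)]
        except KeyError:
            raise BackendError(f"mock backend: no canned response for ({stage}, {doc_id})") from None


class OpenAICompatBackend:
    """Minimal adapter for OpenAI-style ``/chat/completions`` services.

    Uses only the standard library; intended for interactive use against a
    locally configured endpoint. Temperature defaults to 0 so repeated calls
    are as reproducible as the service allows.
    """

    def __init__(self, base_url: str, model: str, api_key: str = "", temperature: float = 0.0, timeout: float = 120.0):
        self.name = f"openai:{model}"
        self.base_url = base_url.rstrip("/")
        self.model = model
        self.api_key = api_key
        self.temperature = temperature
        self.timeout = timeout

    def complete(self, prompt: str, document: str) -> str:
        import urllib.request

        payload = json.dumps(
            {
                "model": self.model,
                "temperature": self.temperature,
                "messages": [
                    {"role": "system", "content": prompt},
                    {"role": "user", "content": document},
                ],
            }
        ).encode()
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=payload,
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode())
        except OSError as exc:
            raise BackendError(f"backend request failed: {exc}") from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError) as exc:
            raise BackendError(f"unexpected backend response shape: {exc}") from exc


# ---------------------------------------------------------------------------
# Domain types and config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelevanceDecision:
    relevant: bool
    reasons: str = ""


@dataclass(frozen=True)
class Provenance:
    doc_id: str
    stage: str  # "extracted" | "refined"

    def __post_init__(self) -> None:
        if self.stage not in ("extracted", "refined"):
            raise ValueError(f"invalid stage tag {self.stage!r}")


@dataclass(frozen=True)
class ExtractedPocket:
    """A binding site parsed from a paper: name, description, residue list."""

    name: str
    description: str
    residues: tuple[ResidueRef, ...]
    provenance: Provenance

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"pocket {self.name!r}: duplicate residues")

    @property
    def residue_keys(self) -> frozenset[tuple[str, int, str]]:
        return frozenset(r.key for r in self.residues)


@dataclass
class ExtractionConfig:
    retries: int = 2                 # re-asks after a malformed response
    default_chain: str = "A"
    max_document_chars: int = 600_000  # loud failure instead of silent truncation
    refine_fallback: bool = True     # on refinement backend failure, keep extraction output
    extra_format: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Prompts and response parsing
# ---------------------------------------------------------------------------

def load_prompt(stage: str, **fields: str) -> str:
    """Load a stage prompt template and substitute its fields."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    text = resources.files("pocketlit.prompts").joinpath(f"{stage}.txt").read_text(encoding="utf-8")
    return text.format(**fields)


_FENCE_RE = re.compile(r"```(?:json)?\s*\n(.*?)```", re.DOTALL)


def _first_json_block(response: str) -> object | None:
    for m in _FENCE_RE.finditer(response):
        try:
            return json.loads(m.group(1))
        except json.JSONDecodeError:
            continue
    # tolerate a bare JSON object without fences
    text = response.strip()
    if text.startswith("{"):
        try:
            return json.loads(text)
        except json.JSONDecodeError:
            return None
    return None


def _ask(backend: Backend, prompt: str, doc: PaperDocument, config: ExtractionConfig, validate) -> object:
    """Call the backend, parse/validate the response, retrying on bad format."""
    if len(doc.text) > config.max_document_chars:
        raise ContextBudgetError(
            f"document {doc.doc_id!r} has {len(doc.text)} chars, "
            f"budget is {config.max_document_chars}"
        )
    last_problem = "no attempt made"
    for attempt in range(config.retries + 1):
        response = backend.complete(prompt, doc.text)
        data = _first_json_block(response)
        if data is not None:
            try:
                return validate(data)
            except (KeyError, TypeError, ValueError) as exc:
                last_problem = f"invalid payload: {exc}"
        else:
            last_problem = "no parseable JSON block"
        logger.warning(
            "%s: malformed response on attempt %d/%d (%s)",
            doc.doc_id, attempt + 1, config.retries + 1, last_problem,
        )
    raise ResponseFormatError(f"document {doc.doc_id!r}: {last_problem} after {config.retries + 1} attempts")


def _validate_relevance(data: object) -> RelevanceDecision:
    if not isinstance(data, dict) or not isinstance(data.get("relevant"), bool):
        raise ValueError("expected object with boolean 'relevant'")
    return RelevanceDecision(relevant=data["relevant"], reasons=str(data.get("reasons", "")))


def _parse_pocket_payload(data: object, doc_id: str, stage: str, default_chain: str) -> list[ExtractedPocket]:
    if not isinstance(data, dict) or not isinstance(data.get("pockets"), list):
        raise ValueError("expected object with a 'pockets' list")
    pockets: list[ExtractedPocket] = []
    for entry in data["pockets"]:
        if not isinstance(entry, dict) or "name" not in entry or "residues" not in entry:
            raise ValueError(f"pocket entry missing name/residues: {entry!r}")
        residues: list[ResidueRef] = []
        seen = set()
        for token in entry["residues"]:
            try:
                ref = parse_residue_token(str(token), default_chain=default_chain)
            except ResidueTokenError as exc:
                logger.warning("%s/%s: dropping invalid residue token: %s", doc_id, entry["name"], exc)
                continue
            if ref.key in seen:
                continue
            seen.add(ref.key)
            residues.append(ref)
        if not residues:
            logger.warning("%s: pocket %r has no valid residues, dropped", doc_id, entry["name"])
            continue
        pockets.append(
            ExtractedPocket(
                name=str(entry["name"]),
                description=str(entry.get("description", "")),
                residues=tuple(residues),
                provenance=Provenance(doc_id=doc_id, stage=stage),
            )
        )
    return pockets


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def assess_relevance(
    doc: PaperDocument,
    backend: Backend,
    config: ExtractionConfig | None = None,
) -> RelevanceDecision:
    """Stage (i): is this paper about the target and residue-level sites?"""
    config = config or ExtractionConfig()
    prompt = load_prompt("relevance", target_name=doc.target_name)
    return _ask(backend, prompt, doc, config, _validate_relevance)


def extract_pockets(
    doc: PaperDocument,
    backend: Backend,
    config: ExtractionConfig | None = None,
) -> list[ExtractedPocket]:
    """Stage (ii): parse distinct binding pockets with residue lists.

    Invalid residue tokens are dropped with a logged warning; a pocket is
    kept as long as at least one valid residue remains.
    """
    config = config or ExtractionConfig()
    prompt = load_prompt("extraction", target_name=doc.target_name)
    return _ask(
        backend, prompt, doc, config,
        lambda data: _parse_pocket_payload(data, doc.doc_id, "extracted", config.default_chain),
    )


def refine_pockets(
    doc: PaperDocument,
    pockets: list[ExtractedPocket],
    backend: Backend,
    config: ExtractionConfig | None = None,
) -> list[ExtractedPocket]:
    """Stage (iii): fix splits/omissions, drop non-small-molecule sites.

    The backend may merge, split, drop or augment pockets; the returned list
    carries ``refined`` stage tags and re-validated residues. If the backend
    fails and ``config.refine_fallback`` is on (default), the unrefined
    input is returned with a warning instead of aborting.
    """
    config = config or ExtractionConfig()
    pockets_json = json.dumps(
        {
            "pockets": [
                {
                    "name": p.name,
                    "description": p.description,
                    "residues": [format_residue_token(r) for r in p.residues],
                }
                for p in pockets
            ]
        },
        indent=2,
    )
    prompt = load_prompt("refinement", target_name=doc.target_name, pockets_json=pockets_json)
    try:
        return _ask(
            backend, prompt, doc, config,
            lambda data: _parse_pocket_payload(data, doc.doc_id, "refined", config.default_chain),
        )
    except (BackendError, ResponseFormatError) as exc:
        if not config.refine_fallback:
            raise
        logger.warning("%s: refinement failed (%s); keeping unrefined pockets", doc.doc_id, exc)
        return [replace(p, provenance=Provenance(doc.doc_id, "refined")) for p in pockets]


def run_extraction_pipeline(
    doc: PaperDocument,
    backend: Backend,
    config: ExtractionConfig | None = None,
) -> tuple[RelevanceDecision, list[ExtractedPocket]]:
    """Run relevance → extraction → refinement for one paper.

    Documents judged irrelevant short-circuit with an empty pocket list;
    extraction and refinement are never invoked for them. All stages use the
    same backend.
    """
    config = config or ExtractionConfig()
    decision = assess_relevance(doc, backend, config)
    if not decision.relevant:
        return decision, []
    pockets = extract_pockets(doc, backend, config)
    refined = refine_pockets(doc, pockets, backend, config)
    return decision, refined
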