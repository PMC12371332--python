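"""End-to-end orchestration: papers → pockets → mapping → grids.

``run_pipeline`` drives the full method for one target: each paper passes
the relevance filter, pocket extraction and refinement; pockets pooled over
all papers are mapped onto the structure; Fpocket candidates are filtered
by literature support and merged; and each final pocket is converted to a
cleaned volumetric grid. Every input paper ends in exactly one terminal
state (``filtered`` / ``extracted`` / ``errored``), stage errors are
reported per item and never abort the remaining work, and a machine-
readable run report carries per-stage counts and collected warnings.
Reports contain no wall-clock data, so identical inputs with the same seed
and a deterministic backend reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field, field_validator

from . import geometry, grid as gridmod, mapping
from .corpus import PaperDocument
from .extraction import (
    Backend,
    BackendError,
    ContextBudgetError,
    ExtractedPocket,
    ExtractionConfig,
    ResponseFormatError,
    run_extraction_pipeline,
)
from .geometry import GeometricPocket, MergedPocket, SelectedPocket
from .grid import PocketGrid
from .mapping import MappedPocket
from .structures import ProteinStructure

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineConfig(BaseModel):
    """All tunable parameters of the pipeline, with their defaults.

    Thresholds are fractions in [0, 1]; distances in Å. The chain (0.6) and
    cluster (0.7) matching thresholds follow the mapping stage's empirical
    settings; the grid step is 1.5 Å.
    """

    chain_match_threshold: float = Field(default=0.6, ge=0.0, le=1.0)
    cluster_match_threshold: float = Field(default=0.7, ge=0.0, le=1.0)
    residue_match_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    pocket_match_jaccard: float = Field(default=0.3, ge=0.0, le=1.0)
    merge_overlap_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    eval_match_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    grid_spacing: float = Field(default=1.5, gt=0.0)
    bandwidth: float = Field(default=8.0, gt=0.0)
    contact_tol: float = Field(default=1.0, ge=0.0)
    offset_scan: int = Field(default=0, ge=0)
    retries: int = Field(default=2, ge=0)
    seed: int = 0
    backend: str = "mock"
    apply_vdw_prune: bool = True
    max_document_chars: int = Field(default=600_000, gt=0)

    @field_validator("backend")
    @classmethod
    def _known_backend(cls, v: str) -> str:
        if v not in ("mock", "api"):
            raise ValueError(f"unknown backend {v!r}")
        return v

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(retries=self.retries, max_document_chars=self.max_document_chars)


@dataclass
class PipelineResult:
    grids: list[PocketGrid]
    merged_pockets: list[MergedPocket]
    selected_pockets: list[SelectedPocket]
    mapped_pockets: list[MappedPocket]
    pockets: list[ExtractedPocket]
    report: dict

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True) + "\n"


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(f"{record.name.removeprefix('pocketlit.')}: {record.getMessage()}")


def run_pipeline(
    papers: Sequence[PaperDocument],
    structure: ProteinStructure,
    fpocket_dir: str | Path | None,
    backend: Backend,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full literature-driven pocket prioritization for one target.

    ``fpocket_dir`` may be None or missing: mapped pockets are still
    produced, the geometric selection and grid stages are skipped and the
    report says so explicitly.
    """
    config = config or PipelineConfig()
    ext_cfg = config.extraction_config()

    collector = _WarningCollector()
    pkg_logger = logging.getLogger("pocketlit")
    pkg_logger.addHandler(collector)
    try:
        # --- stage 1-3: per-paper LLM workflow --------------------------------
        paper_states: dict[str, dict] = {}
        pooled: list[ExtractedPocket] = []
        for doc in papers:
            try:
                decision, pockets = run_extraction_pipeline(doc, backend, ext_cfg)
            except (BackendError, ResponseFormatError, ContextBudgetError) as exc:
                logger.warning("paper %s errored: %s", doc.doc_id, exc)
                paper_states[doc.doc_id] = {"state": "errored", "error": str(exc)}
                continue
            if not decision.relevant:
                paper_states[doc.doc_id] = {"state": "filtered", "n_pockets": 0}
            else:
                paper_states[doc.doc_id] = {"state": "extracted", "n_pockets": len(pockets)}
                pooled.extend(pockets)

        # --- stage 4: residue mapping ----------------------------------------
        mapped = mapping.resolve_pockets(
            pooled,
            structure,
            chain_threshold=config.chain_match_threshold,
            cluster_threshold=config.cluster_match_threshold,
            bandwidth=config.bandwidth,
            offset_scan=config.offset_scan,
        )

        # --- stage 5: geometric selection + merge -----------------------------
        geom: list[GeometricPocket] = []
        selected: list[SelectedPocket] = []
        merged: list[MergedPocket] = []
        grids: list[PocketGrid] = []
        geometric_state = "skipped: no Fpocket directory"
        if fpocket_dir is not None and Path(fpocket_dir).exists():
            geom = geometry.read_fpocket_dir(fpocket_dir)
            selected = geometry.select_pockets(
                geom,
                mapped,
                structure,
                pocket_match_jaccard=config.pocket_match_jaccard,
                residue_match_threshold=config.residue_match_threshold,
                contact_tol=config.contact_tol,
            )
            merged = geometry.merge_pockets(selected, config.merge_overlap_threshold)
            geometric_state = "done"

            # --- stage 6: grids ----------------------------------------------
            for mp in merged:
                g = gridmod.build_grid(mp, spacing=config.grid_spacing, provenance=mp.name)
                g = gridmod.hull_filter(g, mp.atoms)
                if config.apply_vdw_prune:
                    g = gridmod.vdw_prune(g, structure)
                grids.append(g)
        elif fpocket_dir is not None:
            logger.warning("fpocket directory %s missing: geometric stages skipped", fpocket_dir)
            geometric_state = f"skipped: {fpocket_dir} missing"
    finally:
        pkg_logger.removeHandler(collector)

    report = {
        "config": config.model_dump(),
        "papers": paper_states,
        "counts": {
            "papers_total": len(papers),
            "papers_filtered": sum(s["state"] == "filtered" for s in paper_states.values()),
            "papers_extracted": sum(s["state"] == "extracted" for s in paper_states.values()),
            "papers_errored": sum(s["state"] == "errored" for s in paper_states.values()),
            "pockets_pooled": len(pooled),
            "pockets_mapped": len(mapped),
            "interface_pockets": sum(mp.interface for mp in mapped),
            "geometric_candidates": len(geom),
            "geometric_selected": len(selected),
            "final_pockets": len(merged),
            "grids": len(grids),
            "grid_points": [len(g) for g in grids],
        },
        "geometric_stage": geometric_state,
        "final_pockets": [
            {
                "name": mp.name,
                "source_ids": list(mp.ids),
                "n_spheres": len(mp.spheres),
                "n_residues": len(mp.residues),
                "residues": sorted(r.token() for r in mp.residues),
            }
            for mp in merged
        ],
        "warnings": collector.messages,
    }
    return PipelineResult(
        grids=grids,
        merged_pockets=merged,
        selected_pockets=selected,
        mapped_pockets=mapped,
        pockets=pooled,
        report=report,
    )
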