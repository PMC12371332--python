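"""Volumetric grid representation of alpha-sphere pockets.

Sphere sets are awkward to merge, split or hand to docking tools, so the
final pockets are converted to a point lattice: a rectangular grid with
1.5 Å steps spanning the bounding box of the pocket heavy atoms, keeping
only nodes inside some alpha sphere. Two cleaning passes follow: a convex
hull built on the pocket heavy atoms removes nodes protruding into bulk
solvent (alpha spheres often stick out of the cavity mouth), and a Van der
Waals pass deletes nodes closer than the VdW radius to any protein atom.

Membership conventions: sphere membership and hull membership are inclusive
(boundary nodes kept); VdW pruning is strict (a node exactly at the radius
survives). The lattice is anchored at the bounding-box minimum and includes
the max face when it lands on a node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .structures import Atom, ProteinStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PocketGrid",
    "build_grid",
    "hull_filter",
    "vdw_prune",
    "write_grid",
    "read_grid_dx",
    "DEFAULT_SPACING",
]

DEFAULT_SPACING = 1.5  # Å
_EPS = 1e-9


@dataclass
class PocketGrid:
    """Retained lattice nodes of one pocket.

    Every point lies on ``origin + k * spacing`` for integer ``k`` per axis;
    points are unique. ``shape`` is the full lattice extent the grid was
    built on (needed to serialize a scalar-field mask).
    """

    origin: np.ndarray          # (3,) Å
    spacing: float
    points: np.ndarray          # (n, 3) Å
    shape: tuple[int, int, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if len(self.points):
            steps = (self.points - self.origin) / self.spacing
            if not np.allclose(steps, np.round(steps), atol=1e-6):
                raise ValueError("grid points are off-lattice")
            if len(np.unique(np.round(steps).astype(int), axis=0)) != len(self.points):
                raise ValueError("duplicate grid points")

    def __len__(self) -> int:
        return len(self.points)

    def indices(self) -> np.ndarray:
        return np.round((self.points - self.origin) / self.spacing).astype(int)

    def replace_points(self, points: np.ndarray) -> "PocketGrid":
        return PocketGrid(self.origin, self.spacing, points, self.shape, self.provenance)


def _heavy_coords(atoms: Sequence[Atom]) -> np.ndarray:
    coords = np.array([a.coords for a in atoms if a.is_heavy])
    if coords.size == 0:
        raise ValueError("no heavy atoms")
    return coords


def build_grid(pocket, spacing: float = DEFAULT_SPACING, provenance: str = "") -> PocketGrid:
    """Lattice over the pocket atoms' bounding box, kept inside the spheres.

    ``pocket`` needs ``atoms`` (with ≥1 heavy atom) and ``spheres``
    attributes (:class:`~pocketlit.geometry.GeometricPocket` or
    :class:`~pocketlit.geometry.MergedPocket`). The lattice is anchored at
    the per-axis coordinate minimum and extends to the maximum; a node is
    retained iff it lies within some alpha sphere (``≤ radius``). A
    zero-extent axis degenerates to a single layer with a warning.
    """
    coords = _heavy_coords(pocket.atoms)
    if not pocket.spheres:
        raise ValueError("build_grid: pocket has no alpha spheres")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    counts = np.floor((hi - lo) / spacing + _EPS).astype(int) + 1
    for ax in range(3):
        if hi[ax] - lo[ax] <= _EPS:
            logger.warning("degenerate bounding box on axis %d: single-layer grid", ax)
    axes = [lo[ax] + spacing * np.arange(counts[ax]) for ax in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    centers = np.array([s.center for s in pocket.spheres])
    radii = np.array([s.radius for s in pocket.spheres])
    d = np.linalg.norm(nodes[:, None, :] - centers[None, :, :], axis=2)
    inside = (d <= radii[None, :] + _EPS).any(axis=1)
    return PocketGrid(
        origin=lo,
        spacing=spacing,
        points=nodes[inside],
        shape=tuple(int(c) for c in counts),
        provenance=provenance or getattr(pocket, "name", str(getattr(pocket, "id", ""))),
    )


def hull_filter(grid: PocketGrid, pocket_heavy_atoms: Sequence[Atom]) -> PocketGrid:
    """Drop grid points strictly outside the convex hull of the pocket atoms.

    Boundary points are retained. With fewer than 4 atoms or a degenerate
    (coplanar) configuration the hull is undefined and the grid is returned
    unchanged with a warning.
    """
    coords = _heavy_coords(pocket_heavy_atoms)
    if len(grid) == 0:
        return grid
    if len(coords) < 4:
        logger.warning("hull_filter: fewer than 4 heavy atoms, grid unchanged")
        return grid
    try:
        hull = ConvexHull(coords)
    except QhullError:
        logger.warning("hull_filter: degenerate (coplanar) atom set, grid unchanged")
        return grid
    # hull.equations rows are [normal | offset]; inside ⇔ n·x + b ≤ 0 for all facets
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    inside = (grid.points @ normals.T + offsets[None, :] <= _EPS).all(axis=1)
    return grid.replace_points(grid.points[inside])


def vdw_prune(grid: PocketGrid, structure: ProteinStructure) -> PocketGrid:
    """Delete points closer than the Van der Waals radius to a protein atom.

    Strict comparison: a point at exactly the radius is kept. An empty
    structure leaves the grid unchanged.
    """
    if len(grid) == 0:
        return grid
    atoms = structure.heavy_atoms()
    if not atoms:
        return grid
    coords = np.array([a.coords for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms])
    keep = np.ones(len(grid), dtype=bool)
    tree = cKDTree(grid.points)
    for r in np.unique(radii):
        sub = coords[radii == r]
        for hits in tree.query_ball_point(sub, r - _EPS):
            keep[hits] = False
    return grid.replace_points(grid.points[keep])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_grid(grid: PocketGrid, fmt: str, path: str | Path) -> None:
    """Write a grid as pseudo-atom PDB, OpenDX scalar field, or raw XYZ.

    - ``"pdb"``: one HETATM pseudo-atom per retained point (visualization);
    - ``"dx"``: 0/1 occupancy mask over the full lattice (OpenDX ASCII);
    - ``"xyz"``: one ``x y z`` line per point.
    """
    path = Path(path)
    if len(grid) == 0:
        logger.warning("writing empty grid to %s", path)
    if fmt == "pdb":
        lines = []
        for i, (x, y, z) in enumerate(grid.points, start=1):
            lines.append(
                f"HETATM{i % 100000:5d}  C   GRD P{1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "dx":
        nx, ny, nz = grid.shape
        mask = np.zeros(grid.shape, dtype=int)
        if len(grid):
            idx = grid.indices()
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        ox, oy, oz = grid.origin
        s = grid.spacing
        header = (
            f"object 1 class gridpositions counts {nx} {ny} {nz}\n"
            f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n"
            f"delta {s:.6f} 0.000000 0.000000\n"
            f"delta 0.000000 {s:.6f} 0.000000\n"
            f"delta 0.000000 0.000000 {s:.6f}\n"
            f"object 2 class gridconnections counts {nx} {ny} {nz}\n"
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = mask.ravel()  # x-major, z fastest: OpenDX convention
        body_lines = []
        for i in range(0, len(flat), 3):
            body_lines.append(" ".join(f"{v:.1f}" for v in flat[i:i + 3]))
        path.write_text(header + "\n".join(body_lines) + "\n")
    elif fmt == "xyz":
        path.write_text("".join(f"{x:.3f} {y:.3f} {z:.3f}\n" for x, y, z in grid.points))
    else:
        raise ValueError(f"unknown grid format {fmt!r} (use pdb, dx or xyz)")


def read_grid_dx(path: str | Path) -> PocketGrid:
    """Read back an OpenDX mask written by :func:`write_grid`."""
    lines = Path(path).read_text().splitlines()
    counts = origin = None
    deltas = []
    data_start = None
    for i, line in enumerate(lines):
        if line.startswith("object 1"):
            counts = tuple(int(v) for v in line.split()[-3:])
        elif line.startswith("origin"):
            origin = np.array([float(v) for v in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append([float(v) for v in line.split()[1:4]])
        elif "data follows" in line:
            data_start = i + 1
            break
    if counts is None or origin is None or data_start is None or len(deltas) != 3:
        raise ValueError(f"{path}: not a grid DX file")
    spacing = deltas[0][0]
    values = np.array(
        [float(v) for line in lines[data_start:] for v in line.split()]
    ).reshape(counts)
    idx = np.argwhere(values > 0.5)
    points = origin[None, :] + idx * spacing
    return PocketGrid(origin=origin, spacing=spacing, points=points, shape=counts)
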