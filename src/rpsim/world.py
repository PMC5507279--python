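"""Toroidal arena geometry, the molecular entities living in it, and
proximity queries.

All positions live on a 2D torus (periodic boundaries in both axes), chosen
so that no molecule ever experiences an edge.  Distances and midpoints use
the minimal-image convention: the shortest of all periodic images of the
separation vector.  One length unit equals one cell side of the source
lattice model, so published rate constants transfer without rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.spatial import cKDTree

REPLICASE = "replicase"
PARASITE = "parasite"

MoleculeSpecies = Literal["replicase", "parasite"]


@dataclass(frozen=True)
class TorusGeometry:
    """Periodic rectangular arena; positions are canonical in [0,W) x [0,H)."""

    width: float
    height: float

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("torus dimensions must be positive")

    @property
    def shape(self) -> np.ndarray:
        return np.array([self.width, self.height], dtype=float)


@dataclass
class Molecule:
    """One RNA agent.

    Attributes
    ----------
    species : "replicase" or "parasite"; immutable for the molecule's life.
    a : affinity towards replicases, in [0, 1]; governs both complex
        formation (via ``a * (1 - l)``) and complex stability (dissociation
        rate ``1 - a`` when this molecule is the template).
    l : probability of being in a folded state, in [0, 1]; a folded
        molecule is unavailable as a template.
    rlt : remaining lifetime until spontaneous decay, in time units.
    """

    id: int
    species: MoleculeSpecies
    x: float
    y: float
    a: float
    l: float
    rlt: float
    radius: float = 0.5

    def __post_init__(self):
        if self.species not in (REPLICASE, PARASITE):
            raise ValueError(f"unknown species {self.species!r}")
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.l <= 1.0):
            raise ValueError("attributes a and l must lie in [0, 1]")
        if self.rlt < 0:
            raise ValueError("remaining lifetime must be non-negative")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class Complex:
    """A bound catalyst-template pair ("virtual species").

    The catalyst is always a replicase; the template may be either species.
    ``ttr`` is the time to replication, ``dissociation_rlt`` the remaining
    time until spontaneous dissociation.  The components' own lifetime
    clocks as of complex formation are stored so they can be restored on
    dissociation (frozen-clock mode) or kept ticking (ticking mode).
    """

    catalyst: Molecule
    template: Molecule
    x: float
    y: float
    ttr: float
    dissociation_rlt: float
    stored_catalyst_rlt: float
    stored_template_rlt: float

    def __post_init__(self):
        if self.catalyst.species != REPLICASE:
            raise ValueError("complex catalyst must be a replicase")


def wrap_position(p, geom: TorusGeometry):
    """Map a point (or array of points, shape (..., 2)) to its canonical
    representative in [0, width) x [0, height)."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("position must be finite")
    box = geom.shape
    out = p - box * np.floor(p / box)
    # floating edge: x - W*floor(x/W) can return exactly W for tiny negatives
    out = np.where(out >= box, 0.0, out)
    return out


def minimal_image(delta, geom: TorusGeometry):
    """Shortest periodic image of a separation vector (or array of them)."""
    delta = np.asarray(delta, dtype=float)
    box = geom.shape
    return delta - box * np.floor(delta / box + 0.5)


def torus_distance(p, q, geom: TorusGeometry):
    """Euclidean distance under the minimal-image convention."""
    d = minimal_image(np.asarray(q, dtype=float) - np.asarray(p, dtype=float), geom)
    return np.sqrt(np.sum(d * d, axis=-1))


def torus_midpoint(p, q, geom: TorusGeometry):
    """Point halfway along the minimal-image segment from p to q, wrapped.

    Undefined (ambiguous) when p and q are exactly antipodal on either
    axis, in which case a ValueError is raised; callers only use this for
    colliding molecules, far inside the unambiguous regime.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = minimal_image(q - p, geom)
    if np.any(np.isclose(np.abs(d), geom.shape / 2.0)):
        raise ValueError("midpoint of antipodal points on a torus is ambiguous")
    return wrap_position(p + 0.5 * d, geom)


class SpatialIndex:
    """Fixed-radius neighbor queries over a set of canonical positions.

    Thin wrapper around a periodic k-d tree (``scipy.spatial.cKDTree`` with
    ``boxsize``).  A range query returns exactly the set a brute-force
    all-pairs scan returns, with *strict* inequality on the radius: ties at
    exactly the query radius are excluded, matching the collision rule.
    """

    def __init__(self, positions, geom: TorusGeometry):
        self.geom = geom
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.positions.size and (
            self.positions.min() < 0
            or np.any(self.positions >= geom.shape)
        ):
            raise ValueError("positions must be canonical (wrapped) on the torus")
        self._tree = (
            cKDTree(self.positions, boxsize=geom.shape)
            if len(self.positions)
            else None
        )

    def __len__(self) -> int:
        return len(self.positions)

    def query_radius(self, i: int, radius: float) -> set[int]:
        """Indices of all *other* points strictly within ``radius`` of point i."""
        if radius <= 0:
            raise ValueError("query radius must be positive")
        if self._tree is None:
            return set()
        cand = self._tree.query_ball_point(self.positions[i], radius)
        out = set()
        for j in cand:
            if j == i:
                continue
            if torus_distance(self.positions[i], self.positions[j], self.geom) < radius:
                out.add(j)
        return out


def neighbors_within(index: SpatialIndex, entity_id: int, radius: float) -> set[int]:
    """All other entities whose center-to-center torus distance to the query
    entity is strictly below ``radius``; never contains the query entity."""
    return index.query_radius(entity_id, radius)
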