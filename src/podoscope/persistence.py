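"""Persistent homology of superlevel-set filtrations on pixel grids.

The image is triangulated with the Freudenthal rule: vertices are pixels,
edges connect orthogonal neighbours plus the upper-left/lower-right diagonal
pair of every unit cell, and the two triangles inside each cell are filled.
Each edge/face carries the minimum of its incident pixel intensities
(upper-star rule), and the filtration sweeps the intensity threshold
downward (superlevel sets).

Degree-0 classes are connected components: one per local maximum of the
image under the induced 6-neighbourhood, born at the maximum's intensity
and dying (elder rule) when the component merges into an older one.  The
globally maximal component never merges; it is assigned death = the global
minimum intensity so every class has a finite persistence.

Degree-1 classes are holes.  They are computed through the planar duality
between holes of the superlevel complex and interior connected components
of the complementary sublevel pixel set under the same 6-neighbourhood:
a hole is born when its interior pixel region detaches from the image
boundary and dies when its deepest interior pixel enters the superlevel
set.  The hole's locus is that interior minimum pixel.  Holes touching the
image boundary are not holes (the boundary is not closed off).

Exact intensity ties are permitted and broken by row-major pixel order;
the detection layer avoids them anyway by adding uniqueness noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import Image2D

__all__ = [
    "NEIGHBOR_OFFSETS",
    "PersistenceFeature",
    "FiltrationComplex",
    "build_filtration",
    "compute_persistence",
    "diagram_to_frame",
    "write_diagram_csv",
]

#: Freudenthal 6-neighbourhood: 4 orthogonal neighbours plus the
#: upper-left and lower-right diagonal neighbours.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1),
    (-1, 0),
    (0, -1),
    (0, 1),
    (1, 0),
    (1, 1),
)


@dataclass(frozen=True)
class PersistenceFeature:
    """One (birth, death) pair of the filtration, localised to a pixel."""

    degree: int
    birth: float
    death: float
    locus: tuple[int, int]

    @property
    def persistence(self) -> float:
        """p = |b - d|, in intensity units."""
        return abs(self.birth - self.death)


@dataclass
class FiltrationComplex:
    """Explicit Freudenthal complex of an image with upper-star values.

    Simplices are stored as flat pixel indices (row-major).  The complex
    is mainly a checkable contract -- :func:`compute_persistence` sweeps
    the same structure implicitly for speed.
    """

    shape: tuple[int, int]
    vertex_values: np.ndarray  # (V,)
    edges: np.ndarray  # (E, 2) vertex indices
    edge_values: np.ndarray  # (E,)
    faces: np.ndarray  # (F, 3) vertex indices
    face_values: np.ndarray  # (F,)

    @property
    def n_vertices(self) -> int:
        return self.vertex_values.size

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces


def build_filtration(image: Image2D) -> FiltrationComplex:
    """Build the full Freudenthal complex with upper-star values.

    For an R x C grid: V = R*C, E = (R-1)*C + R*(C-1) + (R-1)*(C-1),
    F = 2*(R-1)*(C-1); the Euler characteristic is 1.
    """
    a = image.values
    rows, cols = a.shape
    idx = np.arange(rows * cols).reshape(rows, cols)

    edge_list = []
    # vertical, horizontal, and the upper-left/lower-right diagonal
    if rows > 1:
        edge_list.append(np.stack([idx[:-1, :].ravel(), idx[1:, :].ravel()], axis=1))
    if cols > 1:
        edge_list.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    if rows > 1 and cols > 1:
        edge_list.append(
            np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()], axis=1)
        )
    edges = (
        np.concatenate(edge_list, axis=0)
        if edge_list
        else np.empty((0, 2), dtype=int)
    )

    if rows > 1 and cols > 1:
        tl = idx[:-1, :-1].ravel()
        tr = idx[:-1, 1:].ravel()
        bl = idx[1:, :-1].ravel()
        br = idx[1:, 1:].ravel()
        faces = np.concatenate(
            [
                np.stack([tl, tr, br], axis=1),  # upper triangle of each cell
                np.stack([tl, bl, br], axis=1),  # lower triangle
            ],
            axis=0,
        )
    else:
        faces = np.empty((0, 3), dtype=int)

    flat = a.ravel()
    return FiltrationComplex(
        shape=(rows, cols),
        vertex_values=flat.copy(),
        edges=edges,
        edge_values=flat[edges].min(axis=1) if edges.size else np.empty(0),
        faces=faces,
        face_values=flat[faces].min(axis=1) if faces.size else np.empty(0),
    )


class _UnionFind:
    """Array-based union-find with path halving (no union by rank: the
    merge direction is dictated by the elder rule)."""

    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return int(i)

    def attach(self, child_root: int, parent_root: int) -> None:
        self.parent[child_root] = parent_root


def _neighbor_indices(rows: int, cols: int) -> list[np.ndarray]:
    """Flat index offsets of the Freudenthal neighbours for every pixel.

    Returns, per offset, an array of neighbour flat indices with -1 where
    the neighbour falls outside the grid.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    out = []
    for dr, dc in NEIGHBOR_OFFSETS:
        nr, nc = rr + dr, cc + dc
        valid = (nr >= 0) & (nr < rows) & (nc >= 0) & (nc < cols)
        flat = np.where(valid, nr * cols + nc, -1)
        out.append(flat.ravel())
    return out

def _persistence_h0(a: np.ndarray) -> list[PersistenceFeature]:
    rows, cols = a.shape
    n = rows * cols
    flat = a.ravel()
    # descending sweep; ties resolved by row-major pixel order
    order = np.argsort(-flat, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    neighbors = _neighbor_indices(rows, cols)
    nbr = np.stack(neighbors, axis=1)  # (n, 6)

    uf = _UnionFind(n)
    added = np.zeros(n, dtype=bool)
    birth_rank = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)  # per root
    birth_pixel = np.full(n, -1, dtype=np.int64)  # per root

    feats: list[PersistenceFeature] = []
    for i in order:
        i = int(i)
        added[i] = True
        birth_rank[i] = rank[i]
        birth_pixel[i] = i
        for j in nbr[i]:
            j = int(j)
            if j < 0 or not added[j]:
                continue
            ri, rj = uf.find(i), uf.find(j)
            if ri == rj:
                continue
            # elder rule: the component with the earlier (higher) birth wins
            if birth_rank[ri] < birth_rank[rj]:
                elder, younger = ri, rj
            else:
                elder, younger = rj, ri
            bp = int(birth_pixel[younger])
            if bp != i:
                # a trivial pair (the current pixel merging straight into a
                # neighbour) is not a feature: only components born at an
                # earlier local maximum die here
                feats.append(
                    PersistenceFeature(
                        degree=0,
                        birth=float(flat[bp]),
                        death=float(flat[i]),
                        locus=(bp // cols, bp % cols),
                    )
                )
            uf.attach(younger, elder)
    # essential class: the globally maximal component survives the sweep;
    # assign death = global minimum so its persistence is finite
    root = uf.find(int(order[0]))
    bp = int(birth_pixel[root])
    feats.append(
        PersistenceFeature(
            degree=0,
            birth=float(flat[bp]),
            death=float(flat.min()),
            locus=(bp // cols, bp % cols),
        )
    )
    return feats


def _persistence_h1(a: np.ndarray) -> list[PersistenceFeature]:
    rows, cols = a.shape
    n = rows * cols
    if rows < 3 or cols < 3:
        return []  # every pixel touches the boundary: no interior holes
    flat = a.ravel()
    # ascending sweep over the complementary (sublevel) pixel set
    order = np.argsort(flat, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    neighbors = _neighbor_indices(rows, cols)
    nbr = np.stack(neighbors, axis=1)

    rr = np.arange(n) // cols
    cc = np.arange(n) % cols
    on_boundary = (rr == 0) | (rr == rows - 1) | (cc == 0) | (cc == cols - 1)

    OUTSIDE = n  # virtual node for the unbounded complement region
    uf = _UnionFind(n + 1)
    added = np.zeros(n + 1, dtype=bool)
    added[OUTSIDE] = True
    min_rank = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    min_rank[OUTSIDE] = -1  # the outside is older than everything
    min_pixel = np.full(n + 1, -1, dtype=np.int64)

    feats: list[PersistenceFeature] = []

    def merge(i: int, j: int, value: float, current: int) -> None:
        ri, rj = uf.find(i), uf.find(j)
        if ri == rj:
            return
        if min_rank[ri] < min_rank[rj]:
            elder, younger = ri, rj
        else:
            elder, younger = rj, ri
        mp = int(min_pixel[younger])
        if mp != current:
            # the dying complement component is an interior hole of the
            # superlevel complex: born at `value`, filled at its minimum
            # pixel; a component that is just the current pixel is trivial
            feats.append(
                PersistenceFeature(
                    degree=1,
                    birth=float(value),
                    death=float(flat[mp]),
                    locus=(mp // cols, mp % cols),
                )
            )
        uf.attach(younger, elder)

    for i in order:
        i = int(i)
        added[i] = True
        min_rank[i] = rank[i]
        min_pixel[i] = i
        for j in nbr[i]:
            j = int(j)
            if j >= 0 and added[j]:
                merge(i, j, flat[i], i)
        if on_boundary[i]:
            merge(i, OUTSIDE, flat[i], i)
    return feats


def compute_persistence(image: Image2D, degree: int) -> list[PersistenceFeature]:
    """Persistence diagram of the superlevel-set filtration of ``image``.

    Parameters
    ----------
    image
        Input intensity grid.  Pairwise-distinct pixel values are
        recommended so every feature has an unambiguous locus.
    degree
        0 for connected components, 1 for holes.

    Returns
    -------
    list of :class:`PersistenceFeature`
        Degree 0: one feature per Freudenthal-neighbourhood local maximum,
        locus at that maximum.  Degree 1: one feature per hole, locus at
        the minimum-intensity pixel interior to the hole.
    """
    if degree not in (0, 1):
        raise ValueError(f"degree must be 0 or 1, got {degree!r}")
    a = image.values
    if degree == 0:
        return _persistence_h0(a)
    return _persistence_h1(a)


def diagram_to_frame(features: list[PersistenceFeature]) -> pd.DataFrame:
    """Tabulate a diagram: degree, birth, death, persistence, locus."""
    return pd.DataFrame(
        {
            "degree": [f.degree for f in features],
            "birth": [f.birth for f in features],
            "death": [f.death for f in features],
            "persistence": [f.persistence for f in features],
            "locus_row": [f.locus[0] for f in features],
            "locus_col": [f.locus[1] for f in features],
        }
    )


def write_diagram_csv(path, features: list[PersistenceFeature]) -> None:
    diagram_to_frame(features).to_csv(path, index=False)
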