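"""Antipodally symmetric sphere tessellations and uniform direction sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .core import ValidationError


@dataclass
class SphereTessellation:
    """Unit-sphere triangulation with vertex neighbor graph.

    Vertices come in antipodal pairs (the icosphere is centrally symmetric),
    which lets ODF peaks be deduplicated across hemispheres.
    """

    vertices: np.ndarray
    faces: np.ndarray
    neighbors: np.ndarray = field(repr=False, default=None)  # padded (n, k)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        norms = np.linalg.norm(self.vertices, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValidationError("tessellation vertices must be unit vectors")
        if self.neighbors is None:
            self.neighbors = _neighbor_table(len(self.vertices), self.faces)
        # antipodal pairing: every vertex's antipode must be present
        dots = self.vertices @ self.vertices.T
        if np.any(dots.min(axis=1) > -1 + 1e-9):
            raise ValidationError("tessellation is not antipodally symmetric")

    def __len__(self) -> int:
        return len(self.vertices)

    @classmethod
    def icosphere(cls, subdivisions: int = 4) -> "SphereTessellation":
        """Subdivided icosahedron; 4 subdivisions give 2562 vertices
        (1281 antipodal pairs)."""
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        v = np.asarray(mesh.vertices, dtype=float)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return cls(v, np.asarray(mesh.faces, dtype=np.int64))


def _neighbor_table(n_vertices: int, faces: np.ndarray) -> np.ndarray:
    nb = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        nb[a].update((b, c))
        nb[b].update((a, c))
        nb[c].update((a, b))
    width = max(len(s) for s in nb)
    table = np.empty((n_vertices, width), dtype=np.int64)
    for i, s in enumerate(nb):
        row = sorted(s)
        # pad with a repeated real neighbor: padding with the vertex itself
        # would make the strict local-maximum test vacuously false
        table[i] = row + [row[0]] * (width - len(row))
    return table


def fibonacci_directions(n: int, rotate_seed: int | None = None) -> np.ndarray:
    """n roughly uniform unit vectors (spherical Fibonacci lattice)."""
    i = np.arange(n)
    z = (2 * i + 1) / n - 1
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    golden = np.pi * (3 - np.sqrt(5))
    dirs = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z], axis=1)
    if rotate_seed is not None:
        rng = np.random.default_rng(rotate_seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        dirs = dirs @ q.T
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
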