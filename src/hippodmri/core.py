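"""Shared data types for the ex vivo hippocampal diffusion MRI pipeline.

All volumes live on a :class:`VolumeGrid` (0-based voxel indices, RAS affine,
world coordinates in mm).  Diffusion encodings are carried per volume by a
:class:`GradientScheme` because the acquisition protocol varies the pulse
separation ``Delta`` and the echo time ``TE`` from shell to shell, which plain
bval/bvec files cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Water proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_WATER_PROTON = 2.6752218744e8

#: Canonical 22-row hippocampal subfield legend: label -> (part, structure).
#: 7 head, 8 body and 7 tail regions; 0 is background and never appears here.
HIPPOCAMPAL_LEGEND: dict[int, tuple[str, str]] = {
    1: ("head", "Entorhinal cortex"),
    2: ("head", "Subicular complex"),
    3: ("head", "CA1"),
    4: ("head", "CA2/CA3"),
    5: ("head", "Dentate gyrus"),
    6: ("head", "Alveus"),
    7: ("head", "Lacunosum-molecular layer"),
    8: ("body", "Entorhinal cortex"),
    9: ("body", "Subicular complex"),
    10: ("body", "CA1"),
    11: ("body", "CA2/CA3"),
    12: ("body", "Dentate gyrus"),
    13: ("body", "Alveus"),
    14: ("body", "Fimbria"),
    15: ("body", "Lacunosum-molecular layer"),
    16: ("tail", "Subicular complex"),
    17: ("tail", "CA1"),
    18: ("tail", "CA2/CA3"),
    19: ("tail", "Dentate gyrus"),
    20: ("tail", "Alveus"),
    21: ("tail", "Fimbria"),
    22: ("tail", "Lacunosum-molecular layer"),
}

#: White-matter structures of the legend (used by the phantom's T2 contrast).
WHITE_MATTER_STRUCTURES = ("Alveus", "Fimbria")


class ValidationError(ValueError):
    """Raised when a data object violates one of its declared invariants."""


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3-D voxel grid with a RAS voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vs = tuple(float(v) for v in self.voxel_size)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vs)
        aff = np.asarray(self.affine, dtype=float)
        object.__setattr__(self, "affine", aff)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {shape}")
        if any(v <= 0 for v in vs):
            raise ValidationError(f"voxel sizes must be positive, got {vs}")
        if aff.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size: float = 0.3) -> "VolumeGrid":
        """Axis-aligned RAS grid with isotropic spacing (default 0.3 mm)."""
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(tuple(shape), (voxel_size,) * 3, aff)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size)
            and np.allclose(self.affine, other.affine)
        )


@dataclass
class GradientScheme:
    """Per-volume diffusion encoding.

    Parameters
    ----------
    b : (n,) array, s/mm^2
    directions : (n, 3) array of unit vectors (arbitrary for b = 0 rows).
    Delta, delta, TE : (n,) arrays, ms.  ``Delta`` is the separation of the
        two diffusion gradient pulses, ``delta`` their width.
    gamma : gyromagnetic ratio, rad s^-1 T^-1.
    """

    b: np.ndarray
    directions: np.ndarray
    Delta: np.ndarray
    delta: np.ndarray
    TE: np.ndarray
    gamma: float = GAMMA_WATER_PROTON

    def __post_init__(self) -> None:
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        n = self.b.shape[0]
        for name in ("Delta", "delta", "TE"):
            setattr(self, name, np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (n,)).copy())
        if self.directions.shape != (n, 3):
            raise ValidationError("directions must be (n, 3)")
        if np.any(self.b < 0):
            raise ValidationError("b values must be >= 0")
        dwi = self.b > 0
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if dwi.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("b > 0 directions must be unit vectors")
        if np.any(self.delta >= self.Delta):
            raise ValidationError("delta must be < Delta")
        if np.any(self.TE <= 0):
            raise ValidationError("TE must be > 0")
        for _, idx in self.shells():
            if not np.any(self.b[idx] == 0):
                raise ValidationError("every shell grouping needs a b = 0 entry")

    def __len__(self) -> int:
        return int(self.b.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b == 0

    def shells(self) -> list[tuple[float, np.ndarray]]:
        """Group volumes into shells by their timing (Delta, delta, TE).

        Returns ``(nominal_b, indices)`` pairs sorted by nominal b, where the
        nominal b is the maximum b of the group (its b = 0 entries share the
        shell's echo time).
        """
        keys = np.round(np.stack([self.Delta, self.delta, self.TE], axis=1), 6)
        uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
        out = []
        for k in range(len(uniq)):
            idx = np.flatnonzero(inverse == k)
            out.append((float(self.b[idx].max()), idx))
        out.sort(key=lambda t: t[0])
        return out

    def select(self, index: np.ndarray) -> "GradientScheme":
        return GradientScheme(
            self.b[index], self.directions[index], self.Delta[index],
            self.delta[index], self.TE[index], self.gamma,
        )


@dataclass
class DWIDataset:
    """4-D diffusion-weighted signal with its grid, scheme and mask."""

    grid: VolumeGrid
    signal: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValidationError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[:3] != self.grid.shape:
            raise ValidationError("signal spatial shape does not match grid")
        if self.signal.shape[3] != len(self.scheme):
            raise ValidationError(
                f"{self.signal.shape[3]} volumes but {len(self.scheme)} scheme rows")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")

    def select_volumes(self, index: np.ndarray) -> "DWIDataset":
        return DWIDataset(self.grid, self.signal[..., index],
                          self.scheme.select(index), self.mask)


@dataclass
class LabelMap:
    """Integer parcellation volume with a (part, structure) legend."""

    grid: VolumeGrid
    labels: np.ndarray
    legend: dict[int, tuple[str, str]] = field(
        default_factory=lambda: dict(HIPPOCAMPAL_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("labels must be integer-valued")
        if self.labels.shape != self.grid.shape:
            raise ValidationError("labels shape does not match grid")
        if np.any(self.labels < 0):
            raise ValidationError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValidationError(f"labels missing from legend: {sorted(missing)}")


@dataclass
class Tractogram:
    """Streamlines as polylines of world-mm points.

    ``provenance`` records the local model (``dti``/``qbi``), the tracking
    algorithm (``srd``/``srp``) and the RNG seed used.
    """

    streamlines: list[np.ndarray]
    step_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float).reshape(-1, 3)
                            for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([
            float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())
            for s in self.streamlines
        ])
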