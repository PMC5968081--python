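"""Streamline regularized deterministic (SRD) and probabilistic (SRP) tracking.

Both trackers step bidirectionally from each seed with a fixed step (default
70 um), restricting candidate directions to a cone (default half-angle 30
degrees) around the incoming direction and blending the chosen direction with
the incoming one through an inertial low-pass ("regularized" streamlining):

    step_dir = normalize(w * incoming + (1 - w) * chosen)

SRD picks the admissible candidate with the highest amplitude; SRP samples
among admissible candidates with probability proportional to the voxel's
min-max normalized ODF amplitude (the orientation-independent baseline of
the Funk-Radon ODF carries no directional information, so it is removed
before sampling).  Streamlines outside the [min_length, max_length] gate are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Tractogram, ValidationError, VolumeGrid
from .local_models import SphericalHarmonicField, TensorField
from .shm import real_sh_basis
from .sphere import SphereTessellation


@dataclass
class TrackingConfig:
    step: float = 0.07  # mm
    max_angle: float = 30.0  # degrees per step
    seeds_per_voxel: int = 8
    min_length: float = 0.5  # mm
    max_length: float = 100.0  # mm
    amplitude_threshold: float = 0.1  # relative ODF cutoff
    inertia_weight: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValidationError("step must be > 0")
        if not 0 < self.max_angle <= 90:
            raise ValidationError("max_angle must lie in (0, 90]")
        if not self.min_length < self.max_length:
            raise ValidationError("need min_length < max_length")
        if not 0 <= self.inertia_weight < 1:
            raise ValidationError("inertia_weight must lie in [0, 1)")


class _Interpolator:
    """Trilinear interpolation of per-voxel coefficient vectors."""

    def __init__(self, grid: VolumeGrid, values: np.ndarray):
        self.grid = grid
        self.values = values
        self.inv = np.linalg.inv(grid.affine)

    def __call__(self, point_world: np.ndarray) -> np.ndarray:
        p = self.inv[:3, :3] @ point_world + self.inv[:3, 3]
        f = np.floor(p).astype(int)
        t = p - f
        shape = self.grid.shape
        acc = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    if w == 0.0:
                        continue
                    i = min(max(f[0] + dx, 0), shape[0] - 1)
                    j = min(max(f[1] + dy, 0), shape[1] - 1)
                    k = min(max(f[2] + dz, 0), shape[2] - 1)
                    acc = acc + w * self.values[i, j, k]
        return acc


class OdfDirectionField:
    """Q-ball direction field: trilinear SH interpolation, tessellated eval."""

    model = "qbi"

    def __init__(self, field: SphericalHarmonicField, mask: np.ndarray,
                 sphere: SphereTessellation | None = None):
        self.grid = field.grid
        self.mask = np.asarray(mask, dtype=bool)
        self.sphere = sphere or SphereTessellation.icosphere(3)
        self._interp = _Interpolator(field.grid, field.coefficients)
        self._B = real_sh_basis(field.order, self.sphere.vertices)
        # full antipodal direction set: vertices already contain both signs
        self.directions = self.sphere.vertices

    def candidates(self, point_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All tessellation directions with min-max normalized amplitudes."""
        coeff = self._interp(point_world)
        odf = self._B @ coeff
        lo, hi = odf.min(), odf.max()
        if hi - lo <= 0:
            return self.directions, np.zeros(len(odf))
        return self.directions, (odf - lo) / (hi - lo)


class TensorDirectionField:
    """DTI direction field: one candidate axis (principal eigenvector), FA
    amplitude."""

    model = "dti"

    def __init__(self, field: TensorField, mask: np.ndarray):
        self.grid = field.grid
        self.mask = np.asarray(mask, dtype=bool)
        self._interp = _Interpolator(field.grid, field.tensors)

    def candidates(self, point_world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        six = self._interp(point_world)
        D = np.array([[six[0], six[3], six[4]],
                      [six[3], six[1], six[5]],
                      [six[4], six[5], six[2]]])
        w, v = np.linalg.eigh(D)
        w = np.clip(w, 0.0, None)
        md = w.mean()
        den = np.linalg.norm(w)
        fa = np.sqrt(1.5) * np.linalg.norm(w - md) / den if den > 0 else 0.0
        e1 = v[:, 2]
        return np.stack([e1, -e1]), np.array([fa, fa])


def _inside(field, point: np.ndarray) -> bool:
    inv = getattr(field, "_inv_affine", None)
    if inv is None:
        inv = np.linalg.inv(field.grid.affine)
        field._inv_affine = inv
    v = np.rint(inv[:3, :3] @ point + inv[:3, 3]).astype(int)
    shape = field.grid.shape
    if np.any(v < 0) or np.any(v >= shape):
        return False
    return bool(field.mask[tuple(v)])


def generate_seeds(mask: np.ndarray, grid: VolumeGrid, config: TrackingConfig,
                   ) -> np.ndarray:
    """``seeds_per_voxel`` uniform random world points in each masked voxel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    if config.seeds_per_voxel <= 0:
        raise ValidationError("seeds_per_voxel must be >= 1")
    rng = np.random.default_rng(config.rng_seed)
    vox = np.argwhere(mask)
    offsets = rng.uniform(-0.5, 0.5,
                          size=(len(vox), config.seeds_per_voxel, 3))
    ijk = vox[:, None, :] + offsets
    pts = ijk.reshape(-1, 3) @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return pts


def _half_track(field, start: np.ndarray, first_dir: np.ndarray,
                config: TrackingConfig, rng: np.random.Generator | None,
                budget: float) -> list[np.ndarray]:
    """Track from ``start`` along ``first_dir`` until termination."""
    cos_cone = np.cos(np.deg2rad(config.max_angle))
    pts = []
    direction = first_dir
    point = start.copy()
    length = 0.0
    while length + config.step <= budget:
        nxt = point + config.step * direction
        if not _inside(field, nxt):
            break
        pts.append(nxt)
        point = nxt
        length += config.step
        dirs, amps = field.candidates(point)
        admissible = (dirs @ direction) >= cos_cone
        if not admissible.any():
            break
        amax = amps.max()
        if amax <= 0:
            break
        admissible &= amps >= config.amplitude_threshold * amax
        if not admissible.any():
            break
        cand_dirs, cand_amps = dirs[admissible], amps[admissible]
        if rng is None:
            chosen = cand_dirs[int(np.argmax(cand_amps))]
        else:
            p = cand_amps / cand_amps.sum()
            chosen = cand_dirs[rng.choice(len(cand_dirs), p=p)]
        blended = (config.inertia_weight * direction
                   + (1.0 - config.inertia_weight) * chosen)
        n = np.linalg.norm(blended)
        if n == 0:
            break
        direction = blended / n
    return pts


def _initial_direction(field, seed: np.ndarray, config: TrackingConfig,
                       rng: np.random.Generator | None) -> np.ndarray | None:
    dirs, amps = field.candidates(seed)
    amax = amps.max()
    if amax <= 0:
        return None
    ok = amps >= config.amplitude_threshold * amax
    if not ok.any():
        return None
    if rng is None:
        return dirs[ok][int(np.argmax(amps[ok]))]
    p = amps[ok] / amps[ok].sum()
    return dirs[ok][rng.choice(int(ok.sum()), p=p)]


def _track(field, seeds: np.ndarray, config: TrackingConfig,
           probabilistic: bool) -> Tractogram:
    streamlines = []
    for i, seed in enumerate(np.atleast_2d(seeds)):
        rng = (np.random.default_rng((config.rng_seed, i))
               if probabilistic else None)
        if not _inside(field, seed):
            continue
        d0 = _initial_direction(field, seed, config, rng)
        if d0 is None:
            continue
        half = 0.5 * config.max_length
        fwd = _half_track(field, seed, d0, config, rng, half)
        bwd = _half_track(field, seed, -d0, config, rng, half)
        line = np.array(list(reversed(bwd)) + [seed] + fwd)
        if len(line) < 2:
            continue
        length = config.step * (len(line) - 1)
        if config.min_length <= length <= config.max_length:
            streamlines.append(line)
    return Tractogram(streamlines, config.step, {
        "model": getattr(field, "model", "unknown"),
        "algorithm": "srp" if probabilistic else "srd",
        "rng_seed": config.rng_seed,
    })


def track_srd(field, seeds: np.ndarray, config: TrackingConfig) -> Tractogram:
    """Deterministic tracking: best admissible direction at every step."""
    return _track(field, seeds, config, probabilistic=False)


def track_srp(field, seeds: np.ndarray, config: TrackingConfig) -> Tractogram:
    """Probabilistic tracking: sample admissible directions by ODF amplitude.

    The per-streamline RNG is seeded from (rng_seed, seed index) so reruns
    with the same configuration are bit-identical.
    """
    return _track(field, seeds, config, probabilistic=True)
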