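"""Local reconstruction models: DTI and analytical Q-ball imaging.

DTI is fit by weighted linear least squares on the log signal (one
reweighting pass with weights equal to the squared predicted signal).  The
analytical Q-ball estimate decomposes the single-shell signal onto the real
symmetric spherical-harmonics basis with Laplace-Beltrami regularization and
obtains the diffusion ODF through the Funk-Radon transform, which is diagonal
in that basis (Funk-Hecke): each coefficient is scaled by 2*pi*P_l(0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import DWIDataset, ValidationError, VolumeGrid
from .shm import (funk_radon_diagonal, laplace_beltrami, n_coefficients,
                  real_sh_basis)
from .sphere import SphereTessellation

log = logging.getLogger(__name__)

_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors (6 unique components, mm^2/s)."""

    grid: VolumeGrid
    tensors: np.ndarray  # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    s0: np.ndarray
    valid: np.ndarray
    n_clamped: int = 0  # negative-eigenvalue clamp events

    def full_tensors(self) -> np.ndarray:
        out = np.zeros(self.tensors.shape[:-1] + (3, 3))
        for k, (i, j) in enumerate(_TENSOR_IDX):
            out[..., i, j] = self.tensors[..., k]
            out[..., j, i] = self.tensors[..., k]
        return out

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending) and eigenvectors; eigenvalues clamped >= 0."""
        w, v = np.linalg.eigh(self.full_tensors())
        n_neg = int((w < 0).sum())
        if n_neg:
            log.info("clamped %d negative tensor eigenvalues", n_neg)
        return np.clip(w, 0.0, None), v


@dataclass
class SphericalHarmonicField:
    """Per-voxel real even-order SH coefficients representing ODFs."""

    grid: VolumeGrid
    order: int
    coefficients: np.ndarray  # (..., n_coeff)
    basis: str = "real symmetric, ascending l then m"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.coefficients.shape[-1] != n_coefficients(self.order):
            raise ValidationError("coefficient count does not match order")


@dataclass
class PeakSet:
    """Up to 3 antipodally-deduplicated ODF peaks per voxel."""

    directions: np.ndarray  # (..., 3, 3)
    amplitudes: np.ndarray  # (..., 3); descending, 0 past count
    counts: np.ndarray  # (...,)
    min_separation: float = 25.0


def _design_matrix(scheme_b: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    g = dirs
    b = scheme_b[:, None]
    return np.concatenate([
        np.ones_like(b),
        -b * g[:, 0:1] ** 2, -b * g[:, 1:2] ** 2, -b * g[:, 2:3] ** 2,
        -2 * b * g[:, 0:1] * g[:, 1:2],
        -2 * b * g[:, 0:1] * g[:, 2:3],
        -2 * b * g[:, 1:2] * g[:, 2:3],
    ], axis=1)


def fit_dti(dwi: DWIDataset, shell_selector=None) -> TensorField:
    """Weighted linear least-squares tensor fit on the log signal.

    ``shell_selector`` is an optional predicate on b (e.g. ``lambda b: b <=
    4500``) restricting the volumes used.  Nonpositive signals are excluded
    per voxel; voxels with fewer than 7 usable measurements are invalid.
    """
    b = dwi.scheme.b
    keep = np.ones(len(b), dtype=bool) if shell_selector is None else \
        np.array([bool(shell_selector(x)) for x in b])
    b, dirs = b[keep], dwi.scheme.directions[keep]
    if (b > 0).sum() < 6 or (b == 0).sum() < 1:
        raise ValidationError("DTI needs >= 6 DW directions and >= 1 b0")
    uniq_dirs = np.unique(np.round(np.abs(dirs[b > 0]), 6), axis=0)
    if len(uniq_dirs) < 6:
        raise ValidationError("DTI needs >= 6 unique directions")

    X = _design_matrix(b, dirs)
    shape = dwi.grid.shape
    tensors = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    n_clamped = 0

    sig4 = dwi.signal[..., keep]
    for ijk in np.argwhere(dwi.mask):
        y = sig4[tuple(ijk)]
        usable = y > 0
        if usable.sum() < 7:
            continue
        Xu, ly = X[usable], np.log(y[usable])
        beta, *_ = np.linalg.lstsq(Xu, ly, rcond=None)
        # one reweighting pass, weights = squared predicted signal
        w = np.exp(Xu @ beta) ** 2
        Xw = Xu * w[:, None]
        try:
            beta = np.linalg.solve(Xu.T @ Xw, Xw.T @ ly)
        except np.linalg.LinAlgError:
            pass
        idx = tuple(ijk)
        s0[idx] = np.exp(beta[0])
        tensors[idx] = beta[1:]
        valid[idx] = True
    return TensorField(dwi.grid, tensors, s0, valid, n_clamped)


def tensor_metrics(field: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """FA, MD and color-encoded direction (RGB = |e1| * FA) maps."""
    w, v = field.eigensystem()
    md = w.mean(axis=-1)
    num = np.linalg.norm(w - md[..., None], axis=-1)
    den = np.linalg.norm(w, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.where(field.valid, fa, 0.0)
    md = np.where(field.valid, md, 0.0)
    e1 = v[..., :, 2]  # principal eigenvector (largest eigenvalue)
    ced = np.abs(e1) * fa[..., None]
    return fa, md, ced


def principal_directions(field: TensorField) -> np.ndarray:
    _, v = field.eigensystem()
    return v[..., :, 2]


def fit_aqbi(dwi: DWIDataset, order: int = 8, lambda_reg: float = 0.006,
             shell_b: float | None = None) -> SphericalHarmonicField:
    """Analytical Q-ball ODF reconstruction on a single shell.

    The signal (as attenuation S/S0) is decomposed as c = (B^T B +
    lambda*L)^{-1} B^T s with L = diag((l(l+1))^2); the ODF coefficients are
    c'_j = 2*pi*P_l(0) * c_j, and the result is scaled so the l = 0 term
    integrates to 1 over the sphere.
    """
    shells = [(bb, idx) for bb, idx in dwi.scheme.shells() if bb > 0]
    if not shells:
        raise ValidationError("no diffusion-weighted shell present")
    if shell_b is None:
        shell_b = shells[0][0]  # lowest nonzero b by convention
    cand = [idx for bb, idx in shells if abs(bb - shell_b) < 1e-6]
    if not cand:
        raise ValidationError(f"no shell at b = {shell_b}")
    idx = cand[0]
    dw = idx[dwi.scheme.b[idx] > 0]
    b0 = np.flatnonzero(dwi.scheme.b0_mask)
    ncoef = n_coefficients(order)
    if len(dw) < ncoef:
        raise ValidationError(
            f"order {order} needs >= {ncoef} directions, got {len(dw)}")

    B = real_sh_basis(order, dwi.scheme.directions[dw])
    L = laplace_beltrami(order)
    solver = np.linalg.solve(B.T @ B + lambda_reg * np.diag(L), B.T)
    frt = funk_radon_diagonal(order)

    s0 = dwi.signal[..., b0].mean(axis=-1)
    shape = dwi.grid.shape
    coeffs = np.zeros(shape + (ncoef,))
    valid = dwi.mask & (s0 > 0)
    atten = dwi.signal[valid][:, dw] / s0[valid][:, None]
    c = atten @ solver.T
    codf = c * frt[None, :]
    # normalize to unit integral: the sphere integral is c0 * sqrt(4*pi)
    scale = codf[:, 0] * np.sqrt(4 * np.pi)
    good = scale > 0
    codf[good] /= scale[good, None]
    coeffs[valid] = codf
    return SphericalHarmonicField(dwi.grid, order, coeffs, valid=valid)


def evaluate_odf(field: SphericalHarmonicField, directions: np.ndarray) -> np.ndarray:
    """ODF amplitudes at unit ``directions`` for every voxel, (..., n_dirs)."""
    B = real_sh_basis(field.order, directions)
    return field.coefficients @ B.T


def extract_peaks(field: SphericalHarmonicField, sphere: SphereTessellation,
                  relative_threshold: float = 0.5,
                  min_separation: float = 25.0,
                  max_peaks: int = 3) -> PeakSet:
    """ODF peaks as strict local maxima over the tessellation graph.

    The relative threshold applies to baseline-subtracted amplitudes
    (amplitude minus the voxel's ODF minimum): the Funk-Radon ODF carries a
    large orientation-independent baseline, so lobe height above that floor
    is the meaningful quantity.  Peaks are greedily selected in descending
    amplitude, enforcing ``min_separation`` degrees and merging antipodes.
    """
    if not 0 <= relative_threshold <= 1:
        raise ValidationError("relative_threshold must be in [0, 1]")
    B = real_sh_basis(field.order, sphere.vertices)
    shape = field.coefficients.shape[:-1]
    dirs = np.zeros(shape + (max_peaks, 3))
    amps = np.zeros(shape + (max_peaks,))
    counts = np.zeros(shape, dtype=np.int64)
    cos_sep = np.cos(np.deg2rad(min_separation))

    voxels = np.argwhere(field.valid) if field.valid is not None else \
        np.argwhere(np.ones(shape, dtype=bool))
    for ijk in voxels:
        odf = B @ field.coefficients[tuple(ijk)]
        is_max = odf > odf[sphere.neighbors].max(axis=1)
        cand = np.flatnonzero(is_max)
        if cand.size == 0:
            continue
        base = odf.min()
        height = odf[cand] - base
        tallest = height.max()
        cand = cand[height >= relative_threshold * tallest]
        order_idx = cand[np.argsort(odf[cand])[::-1]]
        chosen: list[int] = []
        for j in order_idx:
            vj = sphere.vertices[j]
            if all(abs(vj @ sphere.vertices[k]) < cos_sep for k in chosen):
                chosen.append(j)
            if len(chosen) == max_peaks:
                break
        idx = tuple(ijk)
        counts[idx] = len(chosen)
        for p, j in enumerate(chosen):
            dirs[idx + (p,)] = sphere.vertices[j]
            amps[idx + (p,)] = odf[j]
    return PeakSet(dirs, amps, counts, min_separation)
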