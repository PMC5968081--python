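"""T2 relaxometry: mapping, histogram mode analysis, inter-shell compensation.

The multi-echo spin-echo series is fit voxelwise with the mono-exponential
decay ``S(TE) = S0 exp(-TE/T2)``: a log-linear least-squares fit provides the
initial estimate, refined by Levenberg-Marquardt on the exponential model.
Shells acquired at longer echo times lose signal as ``exp(-dTE/T2)``; the
compensation stage multiplies them back by ``exp(+dTE/T2(v))`` voxelwise so
all shells match the intensity scale of the lowest-TE shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde

from .core import DWIDataset, ValidationError, VolumeGrid


@dataclass
class MSMESeries:
    """Multi-spin-multi-echo 4-D series with its echo-time list (ms)."""

    grid: VolumeGrid
    signal: np.ndarray
    echo_times: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.signal.ndim != 4 or self.signal.shape[:3] != self.grid.shape:
            raise ValidationError("signal must be 4-D on the series grid")
        if self.echo_times.ndim != 1 or self.echo_times.size < 2:
            raise ValidationError("need at least 2 echoes")
        if self.signal.shape[3] != self.echo_times.size:
            raise ValidationError("4th dimension must equal echo count")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValidationError("echo times must be strictly increasing")


@dataclass
class T2Map:
    """Voxelwise T2 (ms) and S0, with an explicit validity mask."""

    grid: VolumeGrid
    t2: np.ndarray
    s0: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for arr in (self.t2, self.s0, self.valid):
            if arr.shape != self.grid.shape:
                raise ValidationError("map shape does not match grid")
        if np.any(self.t2[self.valid] <= 0):
            raise ValidationError("valid voxels must have T2 > 0")


#: Default MSME protocol: 12 echoes linearly spaced from 6.4 to 76.8 ms.
DEFAULT_ECHO_TIMES = np.linspace(6.4, 76.8, 12)


def fit_t2_map(series: MSMESeries, mask: np.ndarray) -> T2Map:
    """Voxelwise mono-exponential T2 fit.

    Nonpositive samples are excluded (the log is undefined there); a voxel is
    marked invalid when fewer than 2 usable echoes remain or when the decay
    estimate is non-physical (T2 <= 0, i.e. non-decaying series).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid.shape:
        raise ValidationError("mask shape does not match grid")
    if not mask.any():
        raise ValidationError("empty mask")
    te = series.echo_times
    t2 = np.zeros(series.grid.shape)
    s0 = np.zeros(series.grid.shape)
    valid = np.zeros(series.grid.shape, dtype=bool)

    for ijk in np.argwhere(mask):
        y = series.signal[tuple(ijk)]
        usable = y > 0
        if usable.sum() < 2:
            continue
        t, ly = te[usable], np.log(y[usable])
        # log-linear LS: ln S = ln S0 - TE/T2
        A = np.stack([np.ones_like(t), -t], axis=1)
        (ln_s0, inv_t2), *_ = np.linalg.lstsq(A, ly, rcond=None)
        # a non-decaying voxel has an unbounded T2: flag invalid rather
        # than report an arbitrary huge value
        t2_cap = 50.0 * (te[-1] - te[0])
        if inv_t2 <= 1.0 / t2_cap or not np.isfinite(inv_t2):
            continue
        x0 = np.array([np.exp(ln_s0), 1.0 / inv_t2])

        def resid(x, t=t, y=y[usable]):
            return x[0] * np.exp(-t / x[1]) - y

        try:
            sol = least_squares(resid, x0, method="lm", max_nfev=200)
            s0_hat, t2_hat = sol.x
        except Exception:
            s0_hat, t2_hat = x0
        if 0 < t2_hat < t2_cap and s0_hat > 0 and np.isfinite(t2_hat):
            idx = tuple(ijk)
            t2[idx], s0[idx], valid[idx] = t2_hat, s0_hat, True
    return T2Map(series.grid, t2, s0, valid)


def histogram_modes(values: np.ndarray, mask: np.ndarray | None = None,
                    n_modes: int = 2) -> np.ndarray:
    """Locations of the ``n_modes`` highest KDE modes, in ascending order.

    Gaussian KDE with Silverman's bandwidth, evaluated on a 512-point grid;
    modes are strict local maxima of the density.  If fewer maxima exist than
    requested, the ones found are returned with a warning.
    """
    values = np.asarray(values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("empty mask")
    if n_modes not in (1, 2):
        raise ValidationError("n_modes must be 1 or 2")
    if np.ptp(values) == 0:
        return np.array([values[0]])[:n_modes]
    kde = gaussian_kde(values, bw_method="silverman")
    pad = 0.05 * np.ptp(values)
    grid = np.linspace(values.min() - pad, values.max() + pad, 512)
    dens = kde(grid)
    # local maxima; tolerate exact two-point plateaus (symmetric samples can
    # tie the two grid points straddling a mode) by collapsing runs
    up = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:]) & \
         ((dens[1:-1] > dens[:-2]) | (dens[1:-1] > dens[2:]))
    cand = np.flatnonzero(up) + 1
    peaks = cand[np.diff(cand, prepend=-10) > 1] if cand.size else cand
    if peaks.size < n_modes:
        warnings.warn(f"only {peaks.size} density maxima found, "
                      f"{n_modes} requested")
    top = peaks[np.argsort(dens[peaks])[::-1][:n_modes]]
    return np.sort(grid[top])


def compensation_factor(t2: np.ndarray, delta_te: float) -> np.ndarray:
    """Voxelwise factor exp(+delta_te / T2) undoing the extra T2 decay."""
    return np.exp(delta_te / t2)


def compensate_t2(shell: DWIDataset, t2_map: T2Map, delta_te: float) -> DWIDataset:
    """Multiply every volume by exp(delta_te / T2(v)) voxelwise.

    ``delta_te`` (ms) is TE(shell) - TE(reference shell), >= 0.  Voxels with
    an invalid T2 estimate are left unchanged.
    """
    if delta_te < 0:
        raise ValidationError("delta_te must be >= 0")
    if t2_map.grid.shape != shell.grid.shape:
        raise ValidationError("T2 map grid does not match shell grid")
    out = shell.signal.copy()
    if delta_te > 0:
        ok = t2_map.valid
        out[ok] = out[ok] * compensation_factor(t2_map.t2[ok], delta_te)[:, None]
    return DWIDataset(shell.grid, out, shell.scheme, shell.mask)


def compensate_dataset(dwi: DWIDataset, t2_map: T2Map) -> DWIDataset:
    """Equalize all shells to the lowest-TE shell's intensity scale."""
    shells = dwi.scheme.shells()
    te_ref = min(float(dwi.scheme.TE[idx[0]]) for _, idx in shells)
    out = dwi.signal.copy()
    for _, idx in shells:
        d_te = float(dwi.scheme.TE[idx[0]]) - te_ref
        if d_te > 0:
            fac = np.ones(dwi.grid.shape)
            fac[t2_map.valid] = compensation_factor(t2_map.t2[t2_map.valid], d_te)
            out[..., idx] *= fac[..., None]
    return DWIDataset(dwi.grid, out, dwi.scheme, dwi.mask)
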