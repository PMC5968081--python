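"""Four-compartment ex vivo NODDI with a stationary-water compartment.

The voxel signal attenuation is the volume-fraction-weighted sum of four
compartments:

    A = f_ic * A_ic + f_ec * A_ec + f_iso * A_iso + f_stat * A_stat

* ``A_ic``  — intra-neurite water in zero-radius cylinders (sticks) whose
  orientations follow a Watson distribution with concentration ``kappa``
  around the mean orientation ``mu``;
* ``A_ec``  — extra-cellular water in a Watson-orientation-averaged
  cylindrically symmetric Gaussian tensor with the tortuosity constraint
  ``d_perp = d_par * (1 - f_ic_star)``;
* ``A_iso`` — free water, isotropic Gaussian, ``exp(-b * d_iso)``;
* ``A_stat``— water trapped in fixed (formalin cross-linked) glial cells,
  unattenuated by diffusion weighting: ``A_stat = 1``.  This compartment is
  specific to chemically fixed tissue.

The global fractions derive from the nested parametrization

    f_stat = (1 - f_iso) * f'_stat
    f_ic   = (1 - f_iso) * (1 - f'_stat) * f*_ic
    f_ec   = (1 - f_iso) * (1 - f'_stat) * (1 - f*_ic)

so that the four fractions always close to 1.  The intrinsic diffusivities
are fixed ex vivo values: d_par = 0.16e-3 mm^2/s (mean grey-matter
diffusivity of fixed tissue) and d_iso = 2.0e-3 mm^2/s (free water at 20 C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.optimize import least_squares
from scipy.special import i0e

from .core import DWIDataset, GradientScheme, LabelMap, ValidationError, VolumeGrid

log = logging.getLogger(__name__)

D_PARALLEL_EX_VIVO = 0.16e-3  # mm^2/s, fixed-tissue intrinsic diffusivity
D_ISO_FREE_WATER = 2.0e-3  # mm^2/s, free water at 20 C

_GL_NODES, _GL_WEIGHTS = leggauss(64)
# map from [-1, 1] to t = cos(theta) in [0, 1]; symmetric integrands only
_T = 0.5 * (_GL_NODES + 1.0)
_W = 0.5 * _GL_WEIGHTS


def kappa_to_odi(kappa: np.ndarray | float) -> np.ndarray | float:
    """Orientation dispersion index ODI = (2/pi) * arctan(1/kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(divide="ignore"):
        out = (2.0 / np.pi) * np.arctan(np.where(kappa > 0, 1.0 / kappa, np.inf))
    return out if out.ndim else float(out)


def odi_to_kappa(odi: np.ndarray | float) -> np.ndarray | float:
    odi = np.asarray(odi, dtype=float)
    out = 1.0 / np.tan(np.pi / 2.0 * odi)
    return out if out.ndim else float(out)


def derive_fractions(f_iso: float, f_stat_prime: float,
                     f_ic_star: float) -> tuple[float, float, float]:
    """(f_ic, f_ec, f_stat) from the nested fractions; closes with f_iso to 1."""
    for name, x in (("f_iso", f_iso), ("f_stat_prime", f_stat_prime),
                    ("f_ic_star", f_ic_star)):
        if not 0.0 <= x <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {x}")
    f_stat = (1.0 - f_iso) * f_stat_prime
    rest = (1.0 - f_iso) * (1.0 - f_stat_prime)
    return rest * f_ic_star, rest * (1.0 - f_ic_star), f_stat


@dataclass
class NoddiParams:
    """Nested-fraction NODDI parameters for one voxel."""

    f_iso: float
    f_stat_prime: float
    f_ic_star: float
    kappa: float
    mu: np.ndarray
    d_parallel: float = D_PARALLEL_EX_VIVO
    d_iso: float = D_ISO_FREE_WATER
    s0: float = 1.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        n = np.linalg.norm(self.mu)
        if n == 0:
            raise ValidationError("mu must be a nonzero vector")
        self.mu = self.mu / n
        if self.kappa < 0:
            raise ValidationError("kappa must be >= 0")
        derive_fractions(self.f_iso, self.f_stat_prime, self.f_ic_star)

    @property
    def odi(self) -> float:
        return float(kappa_to_odi(self.kappa))

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        """(f_ic, f_ec, f_stat, f_iso) global volume fractions."""
        f_ic, f_ec, f_stat = derive_fractions(
            self.f_iso, self.f_stat_prime, self.f_ic_star)
        return f_ic, f_ec, f_stat, self.f_iso


def _log_sphere_integral(lam_a: np.ndarray, lam_b: np.ndarray,
                         lam_c: np.ndarray) -> np.ndarray:
    """log of the unit-sphere integral of exp(u^T diag(lam) u), up to 4*pi.

    Taking lam_a as the polar axis, the azimuthal integral is a Bessel I0;
    the polar integral uses 64-point Gauss-Legendre on cos(theta) in [0, 1]
    (the integrand is antipodally symmetric).  Returns
    log( (1/4pi) * integral ), stable for large concentrations.
    """
    lam_a, lam_b, lam_c = np.broadcast_arrays(lam_a, lam_b, lam_c)
    t2 = _T**2  # (64,)
    s2 = 1.0 - t2
    mean_bc = 0.5 * (lam_b + lam_c)
    half_diff = 0.5 * (lam_b - lam_c)
    # exponent per (sample, node); subtract max for stability
    expo = (lam_a[..., None] * t2 + mean_bc[..., None] * s2
            + np.abs(half_diff[..., None] * s2))
    m = expo.max(axis=-1, keepdims=True)
    integ = np.sum(_W * np.exp(expo - m)
                   * i0e(half_diff[..., None] * s2), axis=-1)
    return np.log(integ) + m[..., 0]


def watson_stick_attenuation(b: np.ndarray, cos_angle: np.ndarray,
                             kappa: float, d_parallel: float) -> np.ndarray:
    """Watson-averaged stick attenuation.

    Averages exp(-b * d_par * (g.u)^2) over stick orientations u following a
    Watson(kappa, mu) distribution; ``cos_angle`` is g.mu per measurement.
    The average is a ratio of two sphere integrals of exponentiated quadratic
    forms; the numerator form kappa*mu*mu^T - b*d_par*g*g^T has rank 2, so
    its eigenvalues come from a closed-form 2x2 problem.
    """
    b = np.asarray(b, dtype=float)
    c = np.clip(np.asarray(cos_angle, dtype=float), -1.0, 1.0)
    alpha = b * d_parallel
    c2 = c**2
    s2 = 1.0 - c2
    tr = kappa - alpha
    det = -kappa * alpha * s2
    disc = np.sqrt(np.clip(tr**2 - 4.0 * det, 0.0, None))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    log_num = _log_sphere_integral(lam1, lam2, np.zeros_like(lam1))
    log_den = _log_sphere_integral(np.full_like(lam1, kappa),
                                   np.zeros_like(lam1), np.zeros_like(lam1))
    return np.exp(log_num - log_den)


def watson_tau1(kappa: float) -> float:
    """First orientation moment tau_1 = E[(u.mu)^2] of a Watson distribution."""
    num = np.sum(_W * _T**2 * np.exp(kappa * (_T**2 - 1.0)))
    den = np.sum(_W * np.exp(kappa * (_T**2 - 1.0)))
    return float(num / den)


def extracellular_adc(b: np.ndarray, cos_angle: np.ndarray, kappa: float,
                      f_ic_star: float, d_parallel: float) -> np.ndarray:
    """g^T D_ec g for the Watson-averaged tortuous extra-cellular tensor.

    The single-cylinder tensor has axial d_par and radial d_perp = d_par *
    (1 - f*_ic); averaging over Watson orientations with moment tau_1 gives
    D_ec = d_perp I + (d_par - d_perp) * (tau1 * mu mu^T
           + (1 - tau1)/2 * (I - mu mu^T)).
    """
    d_perp = d_parallel * (1.0 - f_ic_star)
    tau1 = watson_tau1(kappa)
    c2 = np.clip(np.asarray(cos_angle, dtype=float), -1.0, 1.0) ** 2
    adc = d_perp + (d_parallel - d_perp) * (
        tau1 * c2 + 0.5 * (1.0 - tau1) * (1.0 - c2))
    return adc


def noddi_forward(params: NoddiParams, scheme: GradientScheme) -> np.ndarray:
    """Noiseless signal attenuation A in [0, 1] for every scheme entry.

    b = 0 entries return exactly 1.  Diffusion kernels are evaluated under
    the Gaussian, diffusion-time-independent assumption, so only b matters.
    """
    b = scheme.b
    cosang = scheme.directions @ params.mu
    a_ic = watson_stick_attenuation(b, cosang, params.kappa, params.d_parallel)
    a_ec = np.exp(-b * extracellular_adc(b, cosang, params.kappa,
                                         params.f_ic_star, params.d_parallel))
    a_iso = np.exp(-b * params.d_iso)
    f_ic, f_ec, f_stat = derive_fractions(
        params.f_iso, params.f_stat_prime, params.f_ic_star)
    A = f_ic * a_ic + f_ec * a_ec + params.f_iso * a_iso + f_stat
    A = np.where(b == 0, 1.0, A)
    return A


@dataclass
class NoddiFitConfig:
    """Grid-initialized bounded nonlinear least-squares fit settings."""

    d_parallel: float = D_PARALLEL_EX_VIVO
    d_iso: float = D_ISO_FREE_WATER
    fraction_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 11))
    odi_grid: np.ndarray = field(
        default_factory=lambda: np.array([0.04, 0.16, 0.36, 0.64, 0.84]))
    max_nfev: int = 400
    xtol: float = 1e-10
    ftol: float = 1e-12


@dataclass
class NoddiParamMap:
    """Per-voxel fitted parameters with fit diagnostics."""

    grid: VolumeGrid
    f_iso: np.ndarray
    f_stat_prime: np.ndarray
    f_ic_star: np.ndarray
    odi: np.ndarray
    mu: np.ndarray  # (..., 3)
    residual_norm: np.ndarray
    iterations: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    d_parallel: float = D_PARALLEL_EX_VIVO
    d_iso: float = D_ISO_FREE_WATER

    def global_fractions(self) -> dict[str, np.ndarray]:
        """Derived (f_ic, f_ec, f_stat, f_iso) maps; they close to 1."""
        rest = (1.0 - self.f_iso) * (1.0 - self.f_stat_prime)
        return {
            "f_ic": rest * self.f_ic_star,
            "f_ec": rest * (1.0 - self.f_ic_star),
            "f_stat": (1.0 - self.f_iso) * self.f_stat_prime,
            "f_iso": self.f_iso.copy(),
        }


def _grid_search(atten: np.ndarray, b: np.ndarray, cosang: np.ndarray,
                 cfg: NoddiFitConfig) -> tuple[float, float, float, float]:
    """Coarse best (f_iso, f'_stat, f*_ic, ODI) by sum-of-squares."""
    fr = cfg.fraction_grid
    a_iso = np.exp(-b * cfg.d_iso)
    best = (np.inf, 0.0, 0.0, 0.0, cfg.odi_grid[0])
    for odi in cfg.odi_grid:
        kappa = float(odi_to_kappa(odi))
        a_ic = watson_stick_attenuation(b, cosang, kappa, cfg.d_parallel)
        for fstar in fr:
            a_ec = np.exp(-b * extracellular_adc(b, cosang, kappa, fstar,
                                                 cfg.d_parallel))
            inner = fstar * a_ic + (1.0 - fstar) * a_ec  # (m,)
            # A = (1-fiso)[(1-fs)*inner + fs] + fiso*a_iso over fs x fiso grids
            mix = ((1.0 - fr)[:, None] * inner[None, :]
                   + fr[:, None])  # (fs, m)
            A = ((1.0 - fr)[:, None, None] * mix[None, :, :]
                 + fr[:, None, None] * a_iso[None, None, :])  # (fiso, fs, m)
            A[..., b == 0] = 1.0
            sse = ((A - atten[None, None, :]) ** 2).sum(axis=-1)
            k = np.unravel_index(np.argmin(sse), sse.shape)
            if sse[k] < best[0]:
                best = (float(sse[k]), float(fr[k[0]]), float(fr[k[1]]),
                        float(fstar), float(odi))
    return best[1], best[2], best[3], best[4]


def _spherical(mu: np.ndarray) -> tuple[float, float]:
    theta = float(np.arccos(np.clip(mu[2], -1.0, 1.0)))
    phi = float(np.arctan2(mu[1], mu[0]))
    return theta, phi


def fit_noddi(dwi: DWIDataset, config: NoddiFitConfig | None = None,
              mu_init: np.ndarray | None = None) -> NoddiParamMap:
    """Voxelwise fit of the four-compartment model.

    The mean orientation is initialized from the DTI principal eigenvector
    (computed internally unless ``mu_init`` is given), the nested fractions
    and ODI from a coarse grid search, then all five free parameters are
    refined by bounded nonlinear least squares (trust-region reflective).
    """
    cfg = config or NoddiFitConfig()
    shells = [bb for bb, _ in dwi.scheme.shells() if bb > 0]
    if len(shells) < 2:
        log.warning("single-shell input: isotropic and stationary fractions "
                    "are poorly identified")
    b0 = np.flatnonzero(dwi.scheme.b0_mask)
    if b0.size == 0:
        raise ValidationError("scheme has no b = 0 volume")

    if mu_init is None:
        from .local_models import fit_dti, principal_directions
        mu_init = principal_directions(fit_dti(dwi))

    b = dwi.scheme.b
    dirs = dwi.scheme.directions
    shape = dwi.grid.shape
    out = {k: np.zeros(shape) for k in
           ("f_iso", "f_stat_prime", "f_ic_star", "odi", "residual_norm")}
    mu_map = np.zeros(shape + (3,))
    iters = np.zeros(shape, dtype=np.int64)
    conv = np.zeros(shape, dtype=bool)

    lo = np.array([0.0, 0.0, 0.0, 1e-3, -np.pi, -2 * np.pi])
    hi = np.array([1.0, 1.0, 1.0, 0.999, 2 * np.pi, 2 * np.pi])

    for ijk in np.argwhere(dwi.mask):
        idx = tuple(ijk)
        y = dwi.signal[idx]
        s0 = y[b0].mean()
        if s0 <= 0:
            continue
        atten = y / s0
        mu0 = mu_init[idx]
        if np.linalg.norm(mu0) == 0:
            mu0 = np.array([0.0, 0.0, 1.0])
        cosang = dirs @ (mu0 / np.linalg.norm(mu0))
        fiso0, fs0, fstar0, odi0 = _grid_search(atten, b, cosang, cfg)
        theta0, phi0 = _spherical(mu0)
        x0 = np.clip(np.array([fiso0, fs0, fstar0, odi0, theta0, phi0]),
                     lo + 1e-9, hi - 1e-9)

        def resid(x):
            th, ph = x[4], x[5]
            mu = np.array([np.sin(th) * np.cos(ph),
                           np.sin(th) * np.sin(ph), np.cos(th)])
            p = NoddiParams(x[0], x[1], x[2], float(odi_to_kappa(x[3])), mu,
                            cfg.d_parallel, cfg.d_iso)
            return noddi_forward(p, dwi.scheme) - atten

        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                max_nfev=cfg.max_nfev, xtol=cfg.xtol,
                                ftol=cfg.ftol)
            x = sol.x
            ok = bool(sol.success)
            nfev, cost = int(sol.nfev), float(np.linalg.norm(sol.fun))
        except Exception:  # keep the grid optimum on optimizer failure
            x, ok, nfev = x0, False, 0
            cost = float(np.linalg.norm(resid(x0)))
        out["f_iso"][idx], out["f_stat_prime"][idx] = x[0], x[1]
        out["f_ic_star"][idx], out["odi"][idx] = x[2], x[3]
        th, ph = x[4], x[5]
        mu = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph),
                       np.cos(th)])
        mu_map[idx] = mu * np.sign(mu[2]) if mu[2] != 0 else mu
        out["residual_norm"][idx] = cost
        iters[idx] = nfev
        conv[idx] = ok
    return NoddiParamMap(dwi.grid, out["f_iso"], out["f_stat_prime"],
                         out["f_ic_star"], out["odi"], mu_map,
                         out["residual_norm"], iters, conv, dwi.mask.copy(),
                         cfg.d_parallel, cfg.d_iso)


def region_statistics(scalar_map: np.ndarray, labels: LabelMap,
                      mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-region mean/SD table (label, part, structure, mean, sd, n_voxels)."""
    scalar_map = np.asarray(scalar_map, dtype=float)
    if scalar_map.shape != labels.grid.shape:
        raise ValidationError("map shape does not match label grid")
    sel = np.ones(labels.grid.shape, dtype=bool) if mask is None else \
        np.asarray(mask, dtype=bool)
    rows = []
    present = set(np.unique(labels.labels).tolist()) - {0}
    for lab in sorted(present):
        if lab not in labels.legend:
            raise ValidationError(f"label {lab} missing from legend")
        part, structure = labels.legend[lab]
        vox = (labels.labels == lab) & sel
        vals = scalar_map[vox]
        rows.append({
            "label": lab, "part": part, "structure": structure,
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std()) if vals.size else np.nan,
            "n_voxels": int(vals.size),
        })
    return pd.DataFrame(rows)
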