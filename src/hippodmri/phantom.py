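"""Digital hippocampus-like phantom and acquisition simulation.

The phantom is a stylized layered slab, not an anatomically faithful
hippocampus: its purpose is to exercise every pipeline stage on geometry with
the study's salient features — a coherent high-neurite-density white-matter
sheet (alveus/fimbria-like), a low-density high-stationary-fraction
pyramidal-like layer, a dispersed molecular-like layer, a two-population 90
degree fiber crossing, a free-water rim, an anterior-to-posterior neurite
density gradient, and a bimodal T2 contrast between white and grey matter.
Labels reuse the canonical 22-region subfield legend so downstream
connectomics code paths run unchanged.

Acquisitions are simulated with the four-compartment forward model
(two-population voxels superpose attenuations linearly by weight), optional
per-volume T2 weighting exp(-TE/T2), and Rician noise whose per-shell sigma
is the shell's own mean b = 0 signal divided by the shell SNR (the b = 0
SNRs measured for the three shells were 9.9, 7.6 and 4.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (HIPPOCAMPAL_LEGEND, WHITE_MATTER_STRUCTURES, DWIDataset,
                   GradientScheme, LabelMap, ValidationError, VolumeGrid)
from .microstructure import NoddiParams, noddi_forward
from .relaxometry import DEFAULT_ECHO_TIMES, MSMESeries, T2Map
from .sphere import fibonacci_directions

#: Three-shell ex vivo protocol: (b s/mm^2, TE ms, Delta ms), delta = 4.3 ms.
HYDI_SHELLS = ((4500.0, 24.2, 14.4), (7500.0, 39.8, 30.0), (10000.0, 54.8, 45.0))
PULSE_WIDTH_MS = 4.3
#: Measured b = 0 SNR per shell, low to high b.
DEFAULT_SHELL_SNRS = (9.9, 7.6, 4.2)

T2_WHITE_MS = 36.3
T2_GREY_MS = 46.4
T2_FREE_MS = 200.0


def hydi_scheme(n_dirs: int = 60, n_b0: int = 1) -> GradientScheme:
    """Three-shell multi-diffusion-time scheme (60 directions/shell)."""
    bs, gs, Ds, ds, tes = [], [], [], [], []
    for k, (b, te, Delta) in enumerate(HYDI_SHELLS):
        dirs = fibonacci_directions(n_dirs, rotate_seed=k)
        for _ in range(n_b0):
            bs.append(0.0)
            gs.append([0.0, 0.0, 0.0])
            Ds.append(Delta)
            ds.append(PULSE_WIDTH_MS)
            tes.append(te)
        for g in dirs:
            bs.append(b)
            gs.append(g)
            Ds.append(Delta)
            ds.append(PULSE_WIDTH_MS)
            tes.append(te)
    return GradientScheme(np.array(bs), np.array(gs), np.array(Ds),
                          np.array(ds), np.array(tes))


def hardi_scheme(n_dirs: int = 500, b: float = 4500.0, n_b0: int = 6) -> GradientScheme:
    """Single-shell high-angular-resolution scheme (TE 24.2 ms, Delta 14.4 ms)."""
    dirs = fibonacci_directions(n_dirs)
    n = n_b0 + n_dirs
    bs = np.concatenate([np.zeros(n_b0), np.full(n_dirs, b)])
    gs = np.concatenate([np.tile([0.0, 0.0, 0.0], (n_b0, 1)), dirs])
    return GradientScheme(bs, gs, np.full(n, 14.4), np.full(n, PULSE_WIDTH_MS),
                          np.full(n, 24.2))


@dataclass(frozen=True)
class LayerSpec:
    """One laminar compartment of the phantom slab."""

    structure: str
    y_range: tuple[int, int]  # half-open voxel rows
    f_ic_star: float
    f_stat_prime: float
    f_iso: float
    odi: float
    orientation: tuple[float, float, float]


#: Laminar blueprint (y rows of the interior box).  Layer values are scenario
#: choices: a white sheet at f*_ic 0.6, a pyramidal-like layer at 0.1 with a
#: high stationary fraction, a dispersed molecular-like layer at 0.3.
DEFAULT_LAYERS = (
    LayerSpec("Alveus", (0, 4), 0.60, 0.05, 0.0, 0.04, (0, 0, 1)),
    LayerSpec("CA1", (4, 8), 0.10, 0.40, 0.0, 0.36, (0, 1, 0)),
    LayerSpec("CA2/CA3", (8, 12), 0.30, 0.15, 0.0, 0.16, (0, 1, 0)),
    LayerSpec("Lacunosum-molecular layer", (12, 16), 0.30, 0.10, 0.05, 0.60,
              (0, 1, 0)),
    LayerSpec("Dentate gyrus", (16, 19), 0.25, 0.15, 0.0, 0.30, (0, 1, 0)),
    LayerSpec("Subicular complex", (19, 22), 0.35, 0.10, 0.0, 0.25, (0, 1, 0)),
)


@dataclass
class PhantomSpec:
    """Phantom geometry, microstructure scenario and acquisition noise."""

    shape: tuple[int, int, int] = (24, 24, 48)
    voxel_size: float = 0.3
    layers: tuple[LayerSpec, ...] = DEFAULT_LAYERS
    gradient_slope: float = 0.02  # f*_ic decrease per mm, anterior -> posterior
    crossing_weights: tuple[float, float] = (0.55, 0.45)
    snr_per_shell: tuple[float, ...] = DEFAULT_SHELL_SNRS
    s0: float = 1000.0
    t2_jitter_sd: float = 1.5  # ms, within-class T2 variability
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.shape):
            raise ValidationError("phantom needs at least 8 voxels per axis")
        if abs(sum(self.crossing_weights) - 1.0) > 1e-12:
            raise ValidationError("crossing weights must sum to 1")


@dataclass
class GroundTruth:
    """Labels plus per-voxel microstructure truth and fiber orientations."""

    labels: LabelMap
    mask: np.ndarray  # all simulated voxels incl. free-water rim
    f_iso: np.ndarray
    f_stat_prime: np.ndarray
    f_ic_star: np.ndarray
    odi: np.ndarray
    t2: np.ndarray  # ms
    s0: np.ndarray
    orientations: np.ndarray  # (..., 2, 3) unit vectors (zero row = absent)
    weights: np.ndarray  # (..., 2), sums to 1 where any population exists

    @property
    def grid(self) -> VolumeGrid:
        return self.labels.grid

    def t2_map(self) -> T2Map:
        return T2Map(self.grid, np.where(self.mask, self.t2, 0.0),
                     np.where(self.mask, self.s0, 0.0), self.mask.copy())


def _legend_key(part: str, structure: str) -> int | None:
    for lab, (p, s) in HIPPOCAMPAL_LEGEND.items():
        if p == part and s == structure:
            return lab
    return None


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Deterministic construction of the layered phantom ground truth."""
    nx, ny, nz = spec.shape
    grid = VolumeGrid.isotropic(spec.shape, spec.voxel_size)
    labels = np.zeros(spec.shape, dtype=np.int32)
    f_iso = np.zeros(spec.shape)
    f_sp = np.zeros(spec.shape)
    f_star = np.zeros(spec.shape)
    odi = np.full(spec.shape, 0.04)
    orients = np.zeros(spec.shape + (2, 3))
    weights = np.zeros(spec.shape + (2,))
    rng = np.random.default_rng(spec.rng_seed)

    # interior tissue box; 1-voxel free-water rim around it
    x0, x1 = 1, nx - 1
    y0, y1 = 1, ny - 1
    z0, z1 = 1, nz - 1
    box = np.zeros(spec.shape, dtype=bool)
    box[x0:x1, y0:y1, z0:z1] = True
    rim = np.zeros(spec.shape, dtype=bool)
    rim[x0 - 1:x1 + 1, y0 - 1:y1 + 1, z0 - 1:z1 + 1] = True
    rim &= ~box

    part_of_z = np.empty(nz, dtype=object)
    thirds = np.array_split(np.arange(z0, z1), 3)
    for part, zs in zip(("head", "body", "tail"), thirds):
        for z in zs:
            part_of_z[z] = part

    interior_height = y1 - y0
    xmid = (x0 + x1) // 2
    for layer in spec.layers:
        ya = y0 + min(layer.y_range[0], interior_height)
        yb = y0 + min(layer.y_range[1], interior_height)
        if yb <= ya:
            continue
        u = np.asarray(layer.orientation, dtype=float)
        u /= np.linalg.norm(u)
        for z in range(z0, z1):
            part = part_of_z[z]
            structure = layer.structure
            # body/tail split the white sheet into alveus and fimbria; the
            # tail has no entorhinal cortex, the head no fimbria
            for x_lo, x_hi in ((x0, xmid), (xmid, x1)):
                struct = structure
                if structure == "Alveus" and part in ("body", "tail") \
                        and x_lo == xmid:
                    struct = "Fimbria"
                if structure == "Subicular complex" and part != "tail" \
                        and x_lo == xmid:
                    struct = "Entorhinal cortex"
                lab = _legend_key(part, struct)
                if lab is None:
                    lab = _legend_key(part, structure)
                labels[x_lo:x_hi, ya:yb, z] = lab
                f_iso[x_lo:x_hi, ya:yb, z] = layer.f_iso
                f_sp[x_lo:x_hi, ya:yb, z] = layer.f_stat_prime
                f_star[x_lo:x_hi, ya:yb, z] = layer.f_ic_star
                odi[x_lo:x_hi, ya:yb, z] = layer.odi
                orients[x_lo:x_hi, ya:yb, z, 0] = u
                weights[x_lo:x_hi, ya:yb, z, 0] = 1.0

    # anterior (low z) -> posterior f*_ic gradient in grey-matter labels
    if spec.gradient_slope != 0.0:
        grey = np.zeros(spec.shape, dtype=bool)
        for lab, (_, structure) in HIPPOCAMPAL_LEGEND.items():
            if structure not in WHITE_MATTER_STRUCTURES:
                grey |= labels == lab
        z_mm = (np.arange(nz) - 0.5 * (nz - 1)) * spec.voxel_size
        delta = -spec.gradient_slope * z_mm  # positive slope: anterior higher
        f_star = np.clip(f_star + np.where(grey, delta[None, None, :], 0.0),
                         0.0, 1.0)

    # two-population 90 degree crossing block between the CA layers
    cz0, cz1 = nz // 2 - 4, nz // 2 + 4
    cy0, cy1 = y0 + 8, y0 + 12
    crossing = np.zeros(spec.shape, dtype=bool)
    crossing[x0:x1, cy0:cy1, cz0:cz1] = labels[x0:x1, cy0:cy1, cz0:cz1] > 0
    w1, w2 = spec.crossing_weights
    orients[crossing] = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    weights[crossing] = np.array([w1, w2])

    # free-water rim
    f_iso[rim] = 1.0
    f_sp[rim] = 0.0
    f_star[rim] = 0.0
    weights[rim] = 0.0
    weights[rim, 0] = 1.0
    orients[rim, 0] = np.array([0.0, 0.0, 1.0])

    mask = (labels > 0) | rim

    t2 = np.zeros(spec.shape)
    white = np.zeros(spec.shape, dtype=bool)
    for lab, (_, structure) in HIPPOCAMPAL_LEGEND.items():
        if structure in WHITE_MATTER_STRUCTURES:
            white |= labels == lab
    grey_vox = (labels > 0) & ~white
    t2[white] = T2_WHITE_MS
    t2[grey_vox] = T2_GREY_MS
    t2[rim] = T2_FREE_MS
    if spec.t2_jitter_sd > 0:
        t2[mask] += rng.normal(0.0, spec.t2_jitter_sd, size=int(mask.sum()))
        t2[mask] = np.clip(t2[mask], 1.0, None)

    s0 = np.where(mask, spec.s0, 0.0)
    label_map = LabelMap(grid, labels)
    truth = GroundTruth(label_map, mask, f_iso, f_sp, f_star, odi, t2, s0,
                        orients, weights)
    _validate_truth(truth)
    return truth


def _validate_truth(truth: GroundTruth) -> None:
    tissue = truth.labels.labels > 0
    if not np.array_equal(tissue | ((truth.f_iso == 1.0) & truth.mask),
                          truth.mask):
        raise ValidationError("labels + free-water rim must partition the mask")
    wsum = truth.weights.sum(axis=-1)
    active = truth.mask
    if not np.allclose(wsum[active], 1.0):
        raise ValidationError("population weights must sum to 1 in the mask")


def add_rician_noise(values: np.ndarray, sigma: float,
                     rng: np.random.Generator | int = 0) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((v + n1)^2 + n2^2), n1, n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    values = np.asarray(values, dtype=float)
    if sigma == 0:
        return values.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, size=values.shape)
    n2 = rng.normal(0.0, sigma, size=values.shape)
    return np.sqrt((values + n1) ** 2 + n2**2)


def simulate_dwi(truth: GroundTruth, scheme: GradientScheme,
                 snr_per_shell: tuple[float, ...] | None = None,
                 t2_weighting: bool = False,
                 rng_seed: int = 0) -> DWIDataset:
    """Forward-simulate the multi-shell acquisition from the ground truth.

    Two-population voxels superpose the forward attenuations linearly by
    weight.  With ``t2_weighting`` the per-volume factor exp(-TE/T2(v)) is
    applied (shells then differ in their b = 0 intensity, as acquired).
    Rician noise uses per-shell sigma = (mean b = 0 signal of that shell
    over the mask) / SNR; pass ``snr_per_shell=None`` or ``()`` for a
    noiseless data set.
    """
    shells = scheme.shells()
    if snr_per_shell:
        if len(snr_per_shell) != len(shells):
            raise ValidationError(
                f"{len(snr_per_shell)} SNRs for {len(shells)} shells")

    nvol = len(scheme)
    signal = np.zeros(truth.grid.shape + (nvol,))
    vox = np.argwhere(truth.mask)
    cols = np.column_stack([
        truth.f_iso[truth.mask], truth.f_stat_prime[truth.mask],
        truth.f_ic_star[truth.mask], truth.odi[truth.mask],
        truth.orientations[truth.mask].reshape(len(vox), 6),
        truth.weights[truth.mask],
    ])
    uniq, inverse = np.unique(np.round(cols, 9), axis=0, return_inverse=True)
    from .microstructure import odi_to_kappa

    atten_by_group = np.empty((len(uniq), nvol))
    for gidx, row in enumerate(uniq):
        fiso, fsp, fstar, odi = row[:4]
        mus = row[4:10].reshape(2, 3)
        ws = row[10:12]
        A = np.zeros(nvol)
        for mu, w in zip(mus, ws):
            if w <= 0:
                continue
            mu_use = mu if np.linalg.norm(mu) > 0 else np.array([0.0, 0.0, 1.0])
            p = NoddiParams(fiso, fsp, fstar, float(odi_to_kappa(odi)), mu_use)
            A += w * noddi_forward(p, scheme)
        atten_by_group[gidx] = A

    flat = atten_by_group[inverse] * truth.s0[truth.mask][:, None]
    if t2_weighting:
        flat = flat * np.exp(-scheme.TE[None, :] / truth.t2[truth.mask][:, None])
    signal[truth.mask] = flat

    if snr_per_shell:
        rng = np.random.default_rng(rng_seed)
        noisy = signal.copy()
        for snr, (_, idx) in zip(snr_per_shell, shells):
            b0_idx = idx[scheme.b[idx] == 0]
            ref = signal[truth.mask][:, b0_idx].mean()
            sigma = ref / snr
            noisy[..., idx] = add_rician_noise(signal[..., idx], sigma, rng)
        signal = noisy
    return DWIDataset(truth.grid, signal, scheme, truth.mask.copy())


def simulate_msme(t2_map: T2Map, s0_map: np.ndarray,
                  echo_times: np.ndarray = DEFAULT_ECHO_TIMES,
                  snr: float = 0.0, rng_seed: int = 0) -> MSMESeries:
    """Multi-echo spin-echo series S0 * exp(-TE/T2) with optional Rician noise.

    ``snr = 0`` is the noiseless sentinel; otherwise sigma = mean masked S0
    divided by ``snr``.
    """
    echo_times = np.asarray(echo_times, dtype=float)
    if np.any(np.diff(echo_times) <= 0):
        raise ValidationError("echo times must be strictly increasing")
    if np.any(t2_map.t2[t2_map.valid] <= 0):
        raise ValidationError("nonpositive T2 inside the mask")
    s0_map = np.asarray(s0_map, dtype=float)
    sig = np.zeros(t2_map.grid.shape + (echo_times.size,))
    ok = t2_map.valid
    sig[ok] = s0_map[ok][:, None] * np.exp(
        -echo_times[None, :] / t2_map.t2[ok][:, None])
    if snr > 0:
        sigma = float(s0_map[ok].mean()) / snr
        sig = add_rician_noise(sig, sigma, np.random.default_rng(rng_seed))
    return MSMESeries(t2_map.grid, sig, echo_times)


# ---------------------------------------------------------------------------
# Simple stick phantoms for tractography experiments

#: White-matter-like stick diffusivity for fiber-geometry phantoms (mm^2/s).
#: At b = 4500 this gives b*d = 4.5, enough angular contrast for the
#: Funk-Radon ODF to separate crossing fiber populations.
D_STICK_WM = 1.0e-3


def stick_dataset(grid: VolumeGrid, mask: np.ndarray,
                  orientations: np.ndarray, weights: np.ndarray,
                  scheme: GradientScheme, d_stick: float = D_STICK_WM,
                  s0: float = 1000.0,
                  snr: float | None = None, rng_seed: int = 0) -> DWIDataset:
    """DWI data from pure stick populations (no dispersion)."""
    nvol = len(scheme)
    b, g = scheme.b, scheme.directions
    signal = np.zeros(grid.shape + (nvol,))
    for ijk in np.argwhere(mask):
        idx = tuple(ijk)
        A = np.zeros(nvol)
        for mu, w in zip(orientations[idx], weights[idx]):
            if w <= 0:
                continue
            A += w * np.exp(-b * d_stick * (g @ mu) ** 2)
        A[b == 0] = 1.0
        signal[idx] = s0 * A
    if snr:
        sigma = s0 / snr
        signal = add_rician_noise(signal, sigma, rng_seed)
    return DWIDataset(grid, signal, scheme, np.asarray(mask, dtype=bool))


def straight_bundle_dataset(shape: tuple[int, int, int] = (10, 10, 40),
                            voxel_size: float = 0.3,
                            scheme: GradientScheme | None = None,
                            d_stick: float = D_STICK_WM,
                            snr: float | None = None,
                            rng_seed: int = 0) -> DWIDataset:
    """Uniform z-aligned fiber slab (default 10x10x40 voxels at 0.3 mm)."""
    grid = VolumeGrid.isotropic(shape, voxel_size)
    mask = np.ones(shape, dtype=bool)
    orients = np.zeros(shape + (2, 3))
    orients[..., 0, :] = (0.0, 0.0, 1.0)
    weights = np.zeros(shape + (2,))
    weights[..., 0] = 1.0
    scheme = scheme or hardi_scheme(n_dirs=60, n_b0=1)
    return stick_dataset(grid, mask, orients, weights, scheme, d_stick,
                         snr=snr, rng_seed=rng_seed)


def crossing_dataset(shape: tuple[int, int, int] = (15, 5, 15),
                     voxel_size: float = 0.3,
                     bar_half_width: int = 1,
                     weights_xz: tuple[float, float] = (0.55, 0.45),
                     scheme: GradientScheme | None = None,
                     d_stick: float = D_STICK_WM,
                     snr: float | None = None,
                     rng_seed: int = 0) -> tuple[DWIDataset, np.ndarray]:
    """Two orthogonal bars (x-arm and z-arm) crossing at the center.

    Returns the data set and the boolean crossing-block mask.  The x-arm
    carries the slightly dominant weight so the DTI principal direction in
    the crossing is deterministic.
    """
    nx, ny, nz = shape
    grid = VolumeGrid.isotropic(shape, voxel_size)
    cz, cx = nz // 2, nx // 2
    xarm = np.zeros(shape, dtype=bool)
    xarm[:, :, cz - bar_half_width:cz + bar_half_width + 1] = True
    zarm = np.zeros(shape, dtype=bool)
    zarm[cx - bar_half_width:cx + bar_half_width + 1, :, :] = True
    mask = xarm | zarm
    crossing = xarm & zarm
    orients = np.zeros(shape + (2, 3))
    weights = np.zeros(shape + (2,))
    orients[xarm, 0] = (1.0, 0.0, 0.0)
    weights[xarm, 0] = 1.0
    orients[zarm, 1] = (0.0, 0.0, 1.0)
    weights[zarm, 1] = 1.0
    weights[crossing, 0] = weights_xz[0]
    weights[crossing, 1] = weights_xz[1]
    # normalize single-arm voxels
    wsum = weights.sum(axis=-1, keepdims=True)
    np.divide(weights, wsum, out=weights, where=wsum > 0)
    scheme = scheme or hardi_scheme(n_dirs=60, n_b0=1)
    data = stick_dataset(grid, mask, orients, weights, scheme, d_stick,
                         snr=snr, rng_seed=rng_seed)
    return data, crossing
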