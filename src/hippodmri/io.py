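"""Readers and writers for the pipeline's standard formats.

NIfTI-1 for volumes (via nibabel, float32 images), a TSV dialect for gradient
schemes (columns ``b gx gy gz Delta_ms delta_ms TE_ms`` — bval/bvec cannot
carry the per-shell timing this protocol varies), TCK for tractograms, TSV for
connectivity matrices and tables, YAML sidecars for stage configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import (GAMMA_WATER_PROTON, DWIDataset, GradientScheme, LabelMap,
                   Tractogram, ValidationError, VolumeGrid)

SCHEME_COLUMNS = ("b", "gx", "gy", "gz", "Delta_ms", "delta_ms", "TE_ms")


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                      np.asarray(img.affine, dtype=float))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), _grid_from_img(img)


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def read_labels(path: str | Path, legend: dict | None = None) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    labels = np.rint(labels).astype(np.int32)
    kwargs = {} if legend is None else {"legend": legend}
    return LabelMap(_grid_from_img(img), labels, **kwargs)


def write_labels(labelmap: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(labelmap.labels.astype(np.int16), labelmap.grid.affine)
    nib.save(img, str(path))


def write_scheme_tsv(scheme: GradientScheme, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SCHEME_COLUMNS) + "\n")
        for i in range(len(scheme)):
            row = (scheme.b[i], *scheme.directions[i], scheme.Delta[i],
                   scheme.delta[i], scheme.TE[i])
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_scheme_tsv(path: str | Path, gamma: float = GAMMA_WATER_PROTON) -> GradientScheme:
    rows = []
    with open(path) as fh:
        header = fh.readline().split()
        if tuple(header) != SCHEME_COLUMNS:
            raise ValidationError(
                f"bad scheme header {header!r}; expected {SCHEME_COLUMNS}")
        for line in fh:
            if line.strip():
                rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty scheme file")
    return GradientScheme(arr[:, 0], arr[:, 1:4], arr[:, 4], arr[:, 5],
                          arr[:, 6], gamma)


def scheme_from_bval_bvec(
    bval_path: str | Path,
    bvec_path: str | Path,
    Delta_ms: float,
    delta_ms: float,
    TE_ms: float,
    gamma: float = GAMMA_WATER_PROTON,
) -> GradientScheme:
    """Import an FSL bval/bvec pair; Delta/delta/TE must be supplied."""
    b = np.loadtxt(bval_path).reshape(-1)
    g = np.loadtxt(bvec_path)
    # FSL layout is 3 rows (x, y, z) by n columns; transpose to (n, 3)
    if g.shape[0] == 3 and g.shape[1] == b.size:
        g = g.T
    if g.shape != (b.size, 3):
        raise ValidationError("bvec shape does not match bval count")
    norms = np.linalg.norm(g, axis=1)
    nz = (b > 0) & (norms > 0)
    g = g.copy()
    g[nz] = g[nz] / norms[nz, None]
    return GradientScheme(b, g, Delta_ms, delta_ms, TE_ms, gamma)


def read_dwi(
    image_path: str | Path,
    scheme_path: str | Path,
    mask_path: str | Path | None = None,
) -> DWIDataset:
    """Load a 4-D DWI NIfTI + scheme TSV (+ optional mask) as a dataset.

    Without an explicit mask, voxels with positive signal in the first b = 0
    volume are taken as foreground.
    """
    signal, grid = read_volume(image_path)
    if signal.ndim != 4:
        raise ValidationError("DWI image must be 4-D")
    scheme = read_scheme_tsv(scheme_path)
    if len(scheme) != signal.shape[3]:
        raise ValidationError(
            f"scheme has {len(scheme)} rows for {signal.shape[3]} volumes")
    if mask_path is not None:
        mdata, mgrid = read_volume(mask_path)
        if mgrid.shape != grid.shape:
            raise ValidationError("mask grid does not match image grid")
        mask = mdata > 0
    else:
        b0 = np.flatnonzero(scheme.b0_mask)
        if b0.size == 0:
            raise ValidationError("scheme contains no b = 0 volume")
        mask = signal[..., b0[0]] > 0
    return DWIDataset(grid, signal, scheme, mask)


def write_dwi(dwi: DWIDataset, image_path: str | Path, scheme_path: str | Path,
              mask_path: str | Path | None = None) -> None:
    write_volume(dwi.signal, dwi.grid, image_path)
    write_scheme_tsv(dwi.scheme, scheme_path)
    if mask_path is not None:
        write_volume(dwi.mask.astype(np.float32), dwi.grid, mask_path)


# ---------------------------------------------------------------------------
# Tractograms (TCK, world mm)

def write_tractogram_tck(tractogram: Tractogram, path: str | Path) -> None:
    tg = nib.streamlines.Tractogram(tractogram.streamlines,
                                    affine_to_rasmm=np.eye(4))
    hdr = {"step_size": str(tractogram.step_size)}
    for key, val in tractogram.provenance.items():
        hdr[f"hippodmri_{key}"] = str(val)
    nib.streamlines.save(tg, str(path), header=hdr)


def read_tractogram_tck(path: str | Path) -> Tractogram:
    tck = nib.streamlines.load(str(path))
    hdr = tck.header
    step = float(hdr.get("step_size", 0.0))
    prov = {k[len("hippodmri_"):]: v for k, v in hdr.items()
            if str(k).startswith("hippodmri_")}
    return Tractogram([np.asarray(s) for s in tck.streamlines], step, prov)


# ---------------------------------------------------------------------------
# Connectivity matrices

def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write a ConnectivityMatrix as a TSV with region-name header row/column."""
    legend = matrix.legend
    names = [f"{part}:{structure}" for part, structure in legend.values()]
    if len(names) != matrix.counts.shape[0]:
        raise ValidationError("legend does not cover every matrix row")
    with open(path, "w") as fh:
        fh.write("region\t" + "\t".join(names) + "\n")
        for name, row in zip(names, matrix.counts):
            fh.write(name + "\t" + "\t".join(str(int(c)) for c in row) + "\n")


def read_matrix_tsv(path: str | Path):
    from .connectomics import ConnectivityMatrix

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows, names = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    if names != header:
        raise ValidationError("matrix TSV row/column names disagree")
    legend = {}
    for i, name in enumerate(names, start=1):
        part, _, structure = name.partition(":")
        legend[i] = (part, structure)
    return ConnectivityMatrix(np.asarray(rows, dtype=np.int64), legend)


# ---------------------------------------------------------------------------
# Sidecar logs

def write_sidecar(path: str | Path, stage: str, config: dict) -> None:
    """Record a stage's full configuration (and any RNG seed) next to its output."""
    doc = {"stage": stage, "config": json.loads(json.dumps(config, default=str))}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_sidecar(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
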