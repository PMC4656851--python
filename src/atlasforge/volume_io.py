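"""Reading, writing and conditioning of 3D intensity stacks.

Supports multi-page TIFF (one page per z slice, one channel per file) and
NIfTI-1.  NIfTI spacing is stored in the header in millimetres; microscopy
grids are micrometre-scale, so zooms are written as um * 1e-3 and converted
back to um on read.  When a TIFF carries no resolution metadata, a sidecar
JSON (``<stack>.json`` with a ``spacing_um`` field) supplies it.

The conditioning steps mirror a confocal acquisition pipeline: linear spectral
unmixing of two simultaneously acquired channels, stitching of rostral and
caudal tiles by exhaustive integer-offset normalized cross-correlation, top
quantile saturation normalization, and resampling of the anisotropic native
grid (1 x 1 x 2 um) to isotropic spacing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage

from .errors import DegenerateInputError, StitchFailureError
from .grids import BinaryMask, Spacing, VolumeGrid, require_congruent

__all__ = [
    "MixingMatrix",
    "read_volume",
    "write_volume",
    "normalize_saturate",
    "unmix_channels",
    "stitch_pair",
    "resample_isotropic",
]

#: fraction of voxels saturated during intensity normalization (top 0.01%)
DEFAULT_SATURATE_FRACTION = 1e-4


@dataclass(frozen=True)
class MixingMatrix:
    """2x2 linear map from true fluorophore abundances to detected channels.

    Row i gives the contribution of each fluorophore to detected channel i.
    Must be invertible with positive diagonal (each dye is detected mainly in
    its own channel).
    """

    coefficients: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        m = self.as_array()
        if m.shape != (2, 2):
            raise ValueError("mixing matrix must be 2x2")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("mixing matrix is singular")
        if m[0, 0] <= 0 or m[1, 1] <= 0:
            raise ValueError("mixing matrix diagonal must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)

    @classmethod
    def from_flat(cls, values) -> "MixingMatrix":
        a11, a12, a21, a22 = (float(v) for v in values)
        return cls(((a11, a12), (a21, a22)))


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path: str | Path, spacing: Spacing | None = None) -> VolumeGrid:
    """Read a volume from NIfTI-1 or multi-page TIFF.

    TIFF pages are z slices with rows = y and columns = x; the array is
    transposed to the package's (x, y, z) axis order.  ``spacing`` overrides
    any metadata; otherwise NIfTI zooms (mm -> um) or the TIFF sidecar JSON
    are used, falling back to the native 1 x 1 x 2 um.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            spacing = tuple(float(z) * 1000.0 for z in zooms)  # mm -> um
        return VolumeGrid(data, spacing)
    # multi-page TIFF: (z, y, x) -> (x, y, z)
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None, :, :]
    data = np.transpose(np.asarray(pages, dtype=np.float64), (2, 1, 0))
    if spacing is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            spacing = tuple(float(s) for s in meta["spacing_um"])
        else:
            spacing = (1.0, 1.0, 2.0)
    return VolumeGrid(data, spacing)


def write_volume(v: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii/.nii.gz) or multi-page TIFF + sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag([v.spacing[0] / 1000.0, v.spacing[1] / 1000.0, v.spacing[2] / 1000.0, 1.0])
        img = nib.Nifti1Image(v.data.astype(np.float32), affine)
        img.header.set_zooms(tuple(s / 1000.0 for s in v.spacing))
        nib.save(img, str(path))
    else:
        pages = np.transpose(v.data, (2, 1, 0)).astype(np.float32)
        tifffile.imwrite(str(path), pages)
        _sidecar_path(path).write_text(json.dumps({"spacing_um": list(v.spacing)}))


def write_mask(m: BinaryMask, path: str | Path) -> None:
    write_volume(VolumeGrid(m.data.astype(np.float64), m.spacing), path)


def read_mask(path: str | Path, spacing: Spacing | None = None) -> BinaryMask:
    v = read_volume(path, spacing)
    return BinaryMask(v.data > 0.5, v.spacing)


# ---------------------------------------------------------------------------
# Conditioning


def normalize_saturate(
    v: VolumeGrid, fraction: float = DEFAULT_SATURATE_FRACTION
) -> VolumeGrid:
    """Rescale intensities to [0, 1], saturating the top ``fraction`` of voxels.

    The saturation point q is the intensity at sorted index
    ceil((1 - fraction) * (N - 1)) — the "higher" order-statistic quantile.
    Voxels at or above q clip to 1.0; the ordering of sub-quantile
    intensities is preserved.  With ``fraction=0`` this is a plain
    divide-by-max.  Using an order statistic (rather than an interpolated
    quantile) makes the operation exactly idempotent: once q maps to 1.0,
    re-normalizing finds q' = 1.0.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    q = float(np.quantile(v.data, 1.0 - fraction, method="higher"))
    if q <= 0:
        raise DegenerateInputError("cannot normalize: saturation quantile is zero")
    return v.with_data(np.clip(v.data / q, 0.0, 1.0))


def unmix_channels(
    chA: VolumeGrid, chB: VolumeGrid, m: MixingMatrix
) -> tuple[VolumeGrid, VolumeGrid]:
    """Invert a 2x2 spectral mixing model voxelwise.

    Solves ``m @ [a, b]^T = [chA, chB]^T`` for the true abundances a, b and
    clips negative solutions (noise-driven) to zero.
    """
    require_congruent(chA, chB)
    inv = np.linalg.inv(m.as_array())
    a = inv[0, 0] * chA.data + inv[0, 1] * chB.data
    b = inv[1, 0] * chA.data + inv[1, 1] * chB.data
    return chA.with_data(np.clip(a, 0.0, None)), chB.with_data(np.clip(b, 0.0, None))


MIN_STITCH_OVERLAP = 8  # voxels along y


def _ncc_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return -np.inf
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def stitch_pair(
    rostral: VolumeGrid,
    caudal: VolumeGrid,
    max_offset: int | tuple[int, int, int],
) -> tuple[tuple[int, int, int], VolumeGrid, float]:
    """Stitch a rostral and a caudal tile of the same brain.

    Searches integer offsets of the caudal stack's origin relative to the
    rostral stack's origin, within ``max_offset`` voxels per axis (a scalar
    broadcasts to all three axes; mounting shifts are 3D, so all axes are
    searched).  An offset is admissible when the tiles overlap by at least
    8 voxels along y and at least 1 voxel along x and z.  The offset
    maximizing NCC over the overlap wins; the fused volume blends the overlap
    with a linear ramp along y and copies non-overlap voxels verbatim.

    Returns ``(offset, fused, best_ncc)``; callers may reject low ``best_ncc``
    (e.g. structure-free stacks correlate poorly at every offset).
    """
    if not np.allclose(rostral.spacing, caudal.spacing):
        raise StitchFailureError("tiles must share voxel spacing")
    mo = np.broadcast_to(np.asarray(max_offset, dtype=int), (3,))
    if (mo < 0).any():
        raise ValueError("max_offset must be non-negative")
    nr = np.array(rostral.shape)
    nc = np.array(caudal.shape)

    best: tuple[float, tuple[int, int, int]] | None = None
    for dx in range(-mo[0], mo[0] + 1):
        for dy in range(-mo[1], mo[1] + 1):
            for dz in range(-mo[2], mo[2] + 1):
                off = np.array([dx, dy, dz])
                lo = np.maximum(0, off)
                hi = np.minimum(nr, nc + off)
                span = hi - lo
                if span[1] < MIN_STITCH_OVERLAP or span[0] < 1 or span[2] < 1:
                    continue
                r_ov = rostral.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                c_lo = lo - off
                c_ov = caudal.data[c_lo[0]:c_lo[0] + span[0],
                                   c_lo[1]:c_lo[1] + span[1],
                                   c_lo[2]:c_lo[2] + span[2]]
                score = _ncc_flat(r_ov, c_ov)
                key = (dx, dy, dz)
                if best is None or score > best[0]:
                    best = (score, key)
    if best is None:
        raise StitchFailureError(
            f"no candidate offset with >= {MIN_STITCH_OVERLAP} voxels of y overlap"
        )
    score, (dx, dy, dz) = best
    fused = _fuse(rostral, caudal, (dx, dy, dz))
    return (dx, dy, dz), fused, score


def _fuse(rostral: VolumeGrid, caudal: VolumeGrid, offset: tuple[int, int, int]) -> VolumeGrid:
    off = np.array(offset)
    nr = np.array(rostral.shape)
    nc = np.array(caudal.shape)
    lo = np.minimum(0, off)          # fused-origin relative to rostral origin
    hi = np.maximum(nr, nc + off)
    shape = tuple(hi - lo)
    acc = np.zeros(shape)
    wacc = np.zeros(shape)

    def paste(data: np.ndarray, origin: np.ndarray, weight: np.ndarray) -> None:
        s = tuple(slice(o, o + n) for o, n in zip(origin - lo, data.shape))
        acc[s] += data * weight
        wacc[s] += weight

    # weights are 1 outside the y-overlap window and ramp linearly across it
    # (rostral 1 -> 0, caudal 0 -> 1); the small floor keeps voxels covered by
    # a single tile at unit weight after normalization, i.e. copied verbatim.
    ov_lo = max(0, offset[1])                       # rostral y coords
    ov_hi = min(rostral.shape[1], caudal.shape[1] + offset[1])
    span = max(ov_hi - ov_lo, 1)
    ramp = np.linspace(1.0, 0.0, span) if span > 1 else np.array([0.5])
    wy_r = np.ones(rostral.shape[1])
    wy_r[ov_lo:ov_hi] = ramp
    wy_c = np.ones(caudal.shape[1])
    wy_c[ov_lo - offset[1]:ov_hi - offset[1]] = 1.0 - ramp
    wy_r = np.maximum(wy_r, 1e-6)
    wy_c = np.maximum(wy_c, 1e-6)
    paste(rostral.data, np.zeros(3, int), wy_r[None, :, None])
    paste(caudal.data, off, wy_c[None, :, None])
    with np.errstate(invalid="ignore"):
        fused = np.where(wacc > 0, acc / np.maximum(wacc, 1e-30), 0.0)
    return VolumeGrid(fused, rostral.spacing)


def estimate_z_attenuation(
    specimen_ref: VolumeGrid,
    template_ref: VolumeGrid,
    footprint_fraction: float = 0.10,
    min_voxels: int = 50,
) -> float:
    """Estimate the exponential depth-attenuation coefficient (per um).

    Single-orientation confocal stacks lose fluorescence with imaging depth.
    Because the broad reference channel labels the same underlying pattern in
    every specimen, the ratio of the specimen's suprathreshold slice-mean
    intensity to the template's, as a function of depth, isolates the
    specimen's residual attenuation.  A weighted log-linear fit of that ratio
    against depth yields the decay coefficient; slices with fewer than
    ``min_voxels`` suprathreshold voxels in either volume are skipped.
    Returns 0.0 when there is too little depth coverage to fit (or when the
    fit says intensity grows with depth).
    """
    require_congruent(specimen_ref, template_ref)
    ts = footprint_fraction * float(np.quantile(specimen_ref.data, 1 - 1e-4))
    tt = footprint_fraction * float(np.quantile(template_ref.data, 1 - 1e-4))
    sz = specimen_ref.spacing[2]
    zs, logratio, wts = [], [], []
    for k in range(specimen_ref.shape[2]):
        s_sl = specimen_ref.data[:, :, k]
        t_sl = template_ref.data[:, :, k]
        s_vox = s_sl > ts
        t_vox = t_sl > tt
        if s_vox.sum() >= min_voxels and t_vox.sum() >= min_voxels:
            zs.append(k * sz)
            logratio.append(np.log(s_sl[s_vox].mean() / t_sl[t_vox].mean()))
            wts.append(min(s_vox.sum(), t_vox.sum()))
    if len(zs) < 4:
        return 0.0
    z = np.asarray(zs, float)
    y = np.asarray(logratio)
    w = np.sqrt(np.asarray(wts, float))
    A = np.vstack([np.ones_like(z), z]).T
    coef, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    return float(max(-coef[1], 0.0))


def correct_z_attenuation(v: VolumeGrid, coefficient: float) -> VolumeGrid:
    """Undo exponential depth attenuation: multiply slice z by exp(c * z_um)."""
    if coefficient < 0:
        raise ValueError("attenuation coefficient must be >= 0")
    z_um = np.arange(v.shape[2]) * v.spacing[2]
    return v.with_data(v.data * np.exp(coefficient * z_um)[None, None, :])


def resample_isotropic(v: VolumeGrid, target: float) -> VolumeGrid:
    """Trilinearly resample onto isotropic ``target`` um spacing.

    Voxel i sits at physical coordinate ``i * spacing``; the output grid spans
    the same physical extent (endpoints preserved to within one voxel).
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    if np.allclose(v.spacing, (target, target, target)):
        return VolumeGrid(v.data.copy(), (target, target, target))
    new_shape = tuple(
        max(1, int(round((n - 1) * s / target)) + 1) for n, s in zip(v.shape, v.spacing)
    )
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, v.spacing)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(v.data, np.stack(coords), order=1, mode="nearest")
    return VolumeGrid(data, (target, target, target))
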