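"""Affine registration to a reference brain and NCC-based quality control.

Registration quality is measured throughout by normalized cross-correlation
(NCC): the Pearson correlation of voxel intensities between two aligned
volumes, optionally restricted to a mask.  Specimens are aligned to the
reference by maximizing NCC over a 6/9/12 parameter affine transform with a
derivative-free coordinate-wise line search with step halving, run over a
factor-2 multi-resolution pyramid and terminated when the translation step
falls below ``min_step`` micrometres.

The best reference brain is chosen empirically from a calibration set of
specimens that were scanned, remounted and rescanned: after registering both
scans of every specimen to a candidate, the duplicate-scan NCC upper-bounds
the registration quality achievable through that candidate, and candidates
are ranked by the mean duplicate-scan NCC of the broadly expressed reference
channel (masked to the candidate's own expression footprint, which makes the
comparison more stringent; the sparser reporter channel is left unmasked
because it need not overlap the reference pattern).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import RegistrationFailureError, ZeroVarianceError
from .grids import BinaryMask, Spacing, VolumeGrid, require_congruent

__all__ = [
    "AffineTransform",
    "ncc",
    "affine_register",
    "apply_affine",
    "Scan",
    "CalibrationSpecimen",
    "CalibrationSet",
    "ReferenceRankTable",
    "rank_reference_candidates",
]

#: intensities above this fraction of a volume's saturated maximum count as
#: part of its expression footprint when used as an NCC mask
FOOTPRINT_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# Transform


@dataclass
class AffineTransform:
    """12-parameter spatial map between floating and reference physical space.

    ``matrix`` is the 3x4 array ``[A | b]`` such that a floating-space point
    x (um) maps to ``A @ x + b`` in reference space (um).  ``dof`` records the
    family the transform was estimated in: 6 (rigid), 9 (rigid + anisotropic
    scale) or 12 (full affine).
    """

    matrix: np.ndarray
    dof: int = 12

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise ValueError(f"affine matrix must be 3x4, got {m.shape}")
        if abs(np.linalg.det(m[:, :3])) < 1e-12:
            raise ValueError("linear part of affine transform is singular")
        if self.dof not in (6, 9, 12):
            raise ValueError(f"dof must be 6, 9 or 12, got {self.dof}")
        if self.dof == 6:
            R = m[:, :3]
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
                raise ValueError("dof=6 requires an orthonormal linear part")
        self.matrix = m

    @classmethod
    def identity(cls, dof: int = 12) -> "AffineTransform":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]), dof)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map points of shape (..., 3) from floating to reference space."""
        return np.asarray(pts, float) @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(np.hstack([Ainv, (-Ainv @ self.translation)[:, None]]),
                               dof=12 if self.dof != 6 else 6)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        A = self.linear @ other.linear
        b = self.linear @ other.translation + self.translation
        return AffineTransform(np.hstack([A, b[:, None]]), dof=max(self.dof, other.dof))

    def rotation_angle_deg(self) -> float:
        """Total rotation angle of the orthogonal polar factor, in degrees."""
        U, _, Vt = np.linalg.svd(self.linear)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            R = U @ np.diag([1, 1, -1]) @ Vt
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self, spacing: Spacing | None = None) -> dict:
        d = {"matrix": self.matrix.tolist(), "dof": self.dof}
        if spacing is not None:
            d["spacing_um"] = list(spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"], float), int(d.get("dof", 12)))

    def save(self, path: str | Path, spacing: Spacing | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(spacing), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NCC


def ncc(a: VolumeGrid, b: VolumeGrid, mask: BinaryMask | None = None) -> float:
    """Normalized cross-correlation (Pearson r) between two aligned volumes.

    Computed over all voxels, or over mask-true voxels when ``mask`` is given.
    Symmetric in its arguments and invariant to positive affine intensity
    rescaling.  A zero-variance evaluation domain raises
    :class:`ZeroVarianceError` rather than silently returning 0, so quality
    tables never hide degenerate comparisons.
    """
    require_congruent(a, b)
    if mask is not None:
        require_congruent(a, mask)
        x = a.data[mask.data]
        y = b.data[mask.data]
    else:
        x = a.data.ravel()
        y = b.data.ravel()
    if x.size < 2:
        raise ZeroVarianceError("NCC needs at least 2 voxels in the evaluation domain")
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt((x * x).sum())
    sy = np.sqrt((y * y).sum())
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("NCC undefined: zero intensity variance in evaluation domain")
    return float(np.clip((x * y).sum() / (sx * sy), -1.0, 1.0))


# ---------------------------------------------------------------------------
# Resampling through a transform


def apply_affine(
    v: VolumeGrid,
    t: AffineTransform,
    out_shape: tuple[int, int, int] | None = None,
    out_spacing: Spacing | None = None,
    interp: str = "trilinear",
) -> VolumeGrid:
    """Resample ``v`` onto an output grid through ``t``.

    ``t`` maps floating (input) physical coordinates to reference (output)
    physical coordinates; each output voxel is pulled through ``t``'s inverse
    and sampled in the input.  Out-of-field voxels are 0.  Use
    ``interp="nearest"`` for masks (preserves the value set) and
    ``interp="cubic"`` for a final high-quality reformat (sharper than
    trilinear at thresholded footprint boundaries; undershoot is clipped to
    keep intensities non-negative).
    """
    if out_shape is None:
        out_shape = v.shape
    if out_spacing is None:
        out_spacing = v.spacing
    order = {"trilinear": 1, "nearest": 0, "cubic": 3}[interp]
    inv = t.inverse()
    idx = np.indices(out_shape, dtype=np.float64)
    # output voxel index -> output physical -> input physical -> input index
    A = inv.linear * np.asarray(out_spacing)[None, :] / np.asarray(v.spacing)[:, None]
    b = inv.translation / np.asarray(v.spacing)
    coords = np.einsum("ij,j...->i...", A, idx) + b[:, None, None, None]
    data = ndimage.map_coordinates(v.data, coords, order=order, mode="constant", cval=0.0)
    if order > 1:
        data = np.clip(data, 0.0, None)
    return VolumeGrid(data, out_spacing)


def warp_mask(m: BinaryMask, t: AffineTransform,
              out_shape: tuple[int, int, int] | None = None,
              out_spacing: Spacing | None = None) -> BinaryMask:
    v = VolumeGrid(m.data.astype(np.float64), m.spacing)
    w = apply_affine(v, t, out_shape, out_spacing, interp="nearest")
    return BinaryMask(w.data > 0.5, w.spacing)


# ---------------------------------------------------------------------------
# Optimization

# parameter classes: translation um, rotation deg, log-scale, shear
_N_PARAMS = {6: 6, 9: 9, 12: 12}


def _params_to_transform(p: np.ndarray, dof: int,
                         c_flt: np.ndarray, c_ref: np.ndarray) -> AffineTransform:
    """Build T(x) = c_ref + R(angles) S(scales) H(shears) (x - c_flt) + t."""
    tx, ty, tz, rx, ry, rz = p[:6]
    scales = np.exp(p[6:9]) if dof >= 9 else np.ones(3)
    shears = p[9:12] if dof == 12 else np.zeros(3)
    ax, ay, az = np.radians([rx, ry, rz])
    Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)], [0, np.sin(ax), np.cos(ax)]])
    Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0], [-np.sin(ay), 0, np.cos(ay)]])
    Rz = np.array([[np.cos(az), -np.sin(az), 0], [np.sin(az), np.cos(az), 0], [0, 0, 1]])
    H = np.array([[1, shears[0], shears[1]], [0, 1, shears[2]], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ H @ np.diag(scales)
    b = c_ref + np.array([tx, ty, tz]) - A @ c_flt
    return AffineTransform(np.hstack([A, b[:, None]]), dof)


def _intensity_centroid(v: VolumeGrid) -> np.ndarray:
    w = v.data
    total = w.sum()
    if total <= 0:
        raise RegistrationFailureError("cannot centre an all-zero volume")
    idx = np.indices(v.shape)
    com = np.array([(idx[i] * w).sum() for i in range(3)]) / total
    return com * np.asarray(v.spacing)


def _pyramid(v: VolumeGrid, levels: int) -> list[VolumeGrid]:
    """Factor-2 smooth+decimate pyramid, coarsest first."""
    out = [v]
    for _ in range(levels - 1):
        prev = out[0]
        sm = ndimage.gaussian_filter(prev.data, sigma=1.0)
        dec = sm[::2, ::2, ::2]
        if min(dec.shape) < 4:
            break
        out.insert(0, VolumeGrid(np.clip(dec, 0, None), tuple(2 * s for s in prev.spacing)))
    return out


def affine_register(
    floating: VolumeGrid,
    reference: VolumeGrid,
    dof: int = 12,
    levels: int = 3,
    min_step: float = 1.0,
    max_iter_per_level: int = 60,
) -> AffineTransform:
    """Estimate the affine transform maximizing NCC(warp(floating), reference).

    A coordinate-wise line search with step halving (the step-size vocabulary
    of classical morphometry registration tools) runs at each pyramid level
    from coarse to fine, starting from an identity transform that aligns the
    two intensity centroids; each level terminates when its translation step
    falls below ``min_step`` um (coarser levels stop at proportionally larger
    steps).  Rotation, log-scale and shear steps shrink in lockstep.

    Raises :class:`RegistrationFailureError` when the metric is degenerate
    (e.g. a constant volume has no gradient to follow).
    """
    if dof not in (6, 9, 12):
        raise ValueError("dof must be 6, 9 or 12")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if floating.data.std() == 0 or reference.data.std() == 0:
        raise RegistrationFailureError("constant volume: registration metric is flat")

    c_flt = _intensity_centroid(floating)
    c_ref = _intensity_centroid(reference)
    pyr_f = _pyramid(floating, levels)
    pyr_r = _pyramid(reference, levels)
    n_lv = min(len(pyr_f), len(pyr_r))
    pyr_f, pyr_r = pyr_f[-n_lv:], pyr_r[-n_lv:]

    n_active = _N_PARAMS[dof]
    p = np.zeros(12)

    def metric(pv: np.ndarray, flt: VolumeGrid, ref: VolumeGrid) -> float:
        t = _params_to_transform(pv, dof, c_flt, c_ref)
        warped = apply_affine(flt, t, ref.shape, ref.spacing)
        try:
            return ncc(warped, ref)
        except ZeroVarianceError:
            return -np.inf

    improved_any = False
    for lv, (flt, ref) in enumerate(zip(pyr_f, pyr_r)):
        scale = 2 ** (n_lv - 1 - lv)
        floor = min_step * scale
        # step per parameter class; translations in um, rotations in degrees
        steps = np.empty(12)
        steps[0:3] = 4.0 * floor
        steps[3:6] = 4.0 * floor            # degrees, tied to the um floor
        steps[6:9] = 0.02 * scale
        steps[9:12] = 0.02 * scale
        best = metric(p, flt, ref)
        if not np.isfinite(best):
            raise RegistrationFailureError("flat registration metric")
        for _ in range(max_iter_per_level):
            moved = False
            for i in range(n_active):
                for sign in (+1.0, -1.0):
                    trial = p.copy()
                    trial[i] += sign * steps[i]
                    val = metric(trial, flt, ref)
                    if val > best + 1e-12:
                        p, best, moved = trial, val, True
                        improved_any = True
                        break
            if not moved:
                steps *= 0.5
                if steps[0] < floor:
                    break
    t = _params_to_transform(p, dof, c_flt, c_ref)
    # never return something worse than the plain identity start
    if floating.congruent(reference):
        try:
            id_score = ncc(floating, reference)
            final = ncc(apply_affine(floating, t, reference.shape, reference.spacing), reference)
            if final < id_score and not improved_any:
                return AffineTransform.identity(dof)
        except ZeroVarianceError:
            pass
    return t


# ---------------------------------------------------------------------------
# Reference selection from a calibration set


@dataclass
class Scan:
    """One confocal acquisition: a broad reference channel plus a reporter."""

    reference_channel: VolumeGrid
    reporter_channel: VolumeGrid

    def __post_init__(self) -> None:
        require_congruent(self.reference_channel, self.reporter_channel)


@dataclass
class CalibrationSpecimen:
    """A specimen scanned twice (remounted in between)."""

    specimen_id: str
    scan1: Scan
    scan2: Scan

    def __post_init__(self) -> None:
        if not np.allclose(self.scan1.reference_channel.spacing,
                           self.scan2.reference_channel.spacing):
            raise ValueError("both scans of a specimen must share spacing")


@dataclass
class CalibrationSet:
    specimens: list[CalibrationSpecimen]

    def __post_init__(self) -> None:
        if len(self.specimens) < 1:
            raise ValueError("calibration set needs at least one specimen")


@dataclass
class ReferenceRankTable:
    """Per-candidate duplicate-scan NCC means and the resulting ranking."""

    candidate_ids: list[str]
    reference_ncc_mean: list[float]
    reporter_ncc_mean: list[float]
    rank: list[int]
    failures: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "candidate": self.candidate_ids,
                "reference_ncc_mean": self.reference_ncc_mean,
                "reporter_ncc_mean": self.reporter_ncc_mean,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    @property
    def best(self) -> str:
        return self.candidate_ids[int(np.argmin(self.rank))]


def rank_reference_candidates(
    candidates: list[VolumeGrid],
    cal: CalibrationSet,
    dof: int = 12,
    levels: int = 3,
    min_step: float = 1.0,
    mask_threshold: float = FOOTPRINT_THRESHOLD,
    candidate_ids: list[str] | None = None,
) -> ReferenceRankTable:
    """Rank candidate reference brains by duplicate-scan NCC.

    For every candidate, both scans of every calibration specimen are
    registered to it (by their reference channel) and reformatted onto the
    candidate grid.  Per specimen, the NCC between the two reformatted scans
    is computed for the reference channel over a stringent mask that excludes
    pixels outside the expression pattern: the intersection of the
    candidate's suprathreshold footprint (> ``mask_threshold`` of its
    saturated maximum) with both warped scans' own footprints.  Restricting
    to jointly expressing voxels matters: a plain candidate-footprint mask
    over a poorly aligned pair pools expressing and background voxels, and
    that two-cluster structure inflates the Pearson correlation enough to
    reward bad references.  The sparser reporter channel is compared
    unmasked (its pattern need not overlap the reference pattern at all).
    Candidates are ranked by descending mean reference-channel NCC; ties
    keep input order.  Failed registrations are recorded per cell, excluded
    from means, and a candidate whose comparisons all failed ranks last.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    if candidate_ids is None:
        candidate_ids = [f"candidate{i}" for i in range(len(candidates))]

    ref_means: list[float] = []
    rep_means: list[float] = []
    failures: dict[str, list[str]] = {}
    def footprint(v: VolumeGrid) -> np.ndarray:
        sat = float(np.quantile(v.data, 1.0 - 1e-4))
        return v.data > mask_threshold * sat

    for cid, cand in zip(candidate_ids, candidates):
        cand_fp = footprint(cand)
        ref_vals: list[float] = []
        rep_vals: list[float] = []
        fails: list[str] = []
        for spec in cal.specimens:
            try:
                warped = []
                for scan in (spec.scan1, spec.scan2):
                    t = affine_register(scan.reference_channel, cand, dof, levels, min_step)
                    warped.append(
                        (
                            apply_affine(scan.reference_channel, t, cand.shape, cand.spacing),
                            apply_affine(scan.reporter_channel, t, cand.shape, cand.spacing),
                        )
                    )
                mask = BinaryMask(
                    cand_fp & footprint(warped[0][0]) & footprint(warped[1][0]),
                    cand.spacing,
                )
                ref_vals.append(ncc(warped[0][0], warped[1][0], mask))
                rep_vals.append(ncc(warped[0][1], warped[1][1]))
            except (RegistrationFailureError, ZeroVarianceError) as exc:
                fails.append(f"{spec.specimen_id}: {exc}")
        if fails:
            failures[cid] = fails
        ref_means.append(float(np.mean(ref_vals)) if ref_vals else -np.inf)
        rep_means.append(float(np.mean(rep_vals)) if rep_vals else -np.inf)

    order = sorted(range(len(candidates)), key=lambda i: (-ref_means[i], i))
    rank = [0] * len(candidates)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    clean = [m if np.isfinite(m) else float("nan") for m in ref_means]
    clean_rep = [m if np.isfinite(m) else float("nan") for m in rep_means]
    return ReferenceRankTable(list(candidate_ids), clean, clean_rep, rank, failures)
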