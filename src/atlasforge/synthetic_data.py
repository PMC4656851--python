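"""Phantom brains, specimen cohorts, line panels and calibration sets.

Every generator is a pure function of its spec and seed, and emits ground
truth (analytic masks, true affine transforms, exact footprints and overlap
matrices) alongside the volumes, so the whole pipeline is testable without
any acquired data.

The phantom emulates the salient statistics of live larval confocal stacks:

* a common ellipsoidal brain shape carrying a broad, textured reference
  channel (the stand-in for a pan-glutamatergic marker);
* line-specific reporter structures (Gaussian blobs for nuclei, soft
  capsules along polylines for tracts) that are Bernoulli-dropped per
  specimen to mimic variegated transgene expression;
* a per-specimen affine mounting jitter shared by both channels;
* exponential fluorescence attenuation along z (single-orientation
  acquisition loses signal with imaging depth);
* Gaussian read noise with optional Poisson shot noise.

It deliberately does not model the optical PSF, photobleaching, or nonrigid
inter-individual shape variation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .grids import BinaryMask, Spacing, VolumeGrid
from .registration import (
    AffineTransform,
    CalibrationSet,
    CalibrationSpecimen,
    Scan,
    _params_to_transform,
    apply_affine,
)

__all__ = [
    "Blob",
    "Tract",
    "PhantomSpec",
    "default_structures",
    "make_reference_brain",
    "render_structures",
    "make_specimen",
    "make_line_panel",
    "make_calibration_set",
]


@dataclass(frozen=True)
class Blob:
    """A Gaussian cell cluster: peak * exp(-|r - center|^2 / 2 sigma^2)."""

    center: tuple[float, float, float]  # um
    sigma: float  # um
    peak: float = 1.0


@dataclass(frozen=True)
class Tract:
    """A soft capsule of given radius around a polyline (an axon bundle)."""

    points: tuple[tuple[float, float, float], ...]  # um
    radius: float  # um
    peak: float = 1.0


Structure = Blob | Tract


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic imaging model; ``seed`` fixes everything.

    Defaults approximate a 6 dpf larval brain at one tenth scale on the
    native anisotropic grid, sized so a full multi-specimen cohort is cheap
    to simulate: 96 x 160 x 64 voxels at 1 x 1 x 2 um.  Jitter ranges match
    typical agarose-mounting variation (a few degrees / micrometres), the
    z-attenuation coefficient 0.004/um halves intensity over ~170 um of
    depth, and variegation keeps each structure with probability 0.9 per
    specimen.
    """

    shape: tuple[int, int, int] = (96, 160, 64)
    spacing: Spacing = (1.0, 1.0, 2.0)
    semi_axes: tuple[float, float, float] = (42.0, 70.0, 55.0)  # um
    structures: tuple[Structure, ...] = ()
    variegation_p: float = 0.9
    noise_sigma: float = 0.02
    poisson: bool = False
    z_attenuation: float = 0.004  # per um of depth
    jitter_rot_deg: float = 5.0
    jitter_trans_um: float = 5.0
    jitter_log_scale: float = 0.0
    seed: int = 0

    @property
    def center(self) -> np.ndarray:
        """Physical centre of the grid, um."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def validate(self) -> None:
        if not 0.0 <= self.variegation_p <= 1.0:
            raise PhantomSpecError("variegation probability must be in [0, 1]")
        if self.noise_sigma < 0 or self.z_attenuation < 0:
            raise PhantomSpecError("noise sigma and z attenuation must be >= 0")
        for s in self.structures:
            pts = [s.center] if isinstance(s, Blob) else list(s.points)
            for p in pts:
                r = (np.asarray(p) - self.center) / np.asarray(self.semi_axes)
                if (r ** 2).sum() > 1.0:
                    raise PhantomSpecError(f"structure point {p} lies outside the brain ellipsoid")


def _physical_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")  # type: ignore[return-value]


def default_structures(
    spec: PhantomSpec, n_blobs: int = 5, with_tract: bool = True
) -> tuple[Structure, ...]:
    """A reproducible panel of blobs (plus one tract) inside the brain."""
    rng = np.random.default_rng(spec.seed + 101)
    semi = np.asarray(spec.semi_axes)
    structures: list[Structure] = []
    for _ in range(n_blobs):
        # rejection-free: sample inside 70% of the ellipsoid radius
        u = rng.uniform(-0.7, 0.7, size=3)
        while (u ** 2 / 0.49).sum() > 1.0:
            u = rng.uniform(-0.7, 0.7, size=3)
        center = spec.center + u * semi
        structures.append(Blob(tuple(center), sigma=float(rng.uniform(4.0, 9.0)),
                               peak=float(rng.uniform(0.7, 1.0))))
    if with_tract:
        y0, y1 = spec.center[1] - 0.5 * semi[1], spec.center[1] + 0.5 * semi[1]
        pts = tuple(
            (float(spec.center[0] + rng.uniform(-6, 6)), float(y),
             float(spec.center[2] + rng.uniform(-6, 6)))
            for y in np.linspace(y0, y1, 4)
        )
        structures.append(Tract(pts, radius=4.0, peak=0.8))
    return tuple(structures)


def make_reference_brain(spec: PhantomSpec) -> tuple[VolumeGrid, BinaryMask]:
    """The template: a textured ellipsoidal reference channel + analytic mask.

    Intensity falls off smoothly toward the ellipsoid surface and carries a
    seeded low-frequency texture (so registration has features to lock onto);
    outside the ellipsoid it is exactly zero.  The returned mask is the
    analytic ellipsoid membership — the ground truth that brain-mask
    extraction is judged against.
    """
    spec.validate()
    X, Y, Z = _physical_coords(spec)
    c = spec.center
    semi = np.asarray(spec.semi_axes)
    r2 = (((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2
          + ((Z - c[2]) / semi[2]) ** 2)
    inside = r2 <= 1.0
    rng = np.random.default_rng(spec.seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=3.0)
    texture = texture / max(np.abs(texture).max(), 1e-12)
    intensity = np.where(inside, (1.0 - 0.6 * r2) * (1.0 + 0.35 * texture), 0.0)
    return VolumeGrid(np.clip(intensity, 0.0, None), spec.spacing), BinaryMask(inside, spec.spacing)


def render_structures(spec: PhantomSpec, structures) -> VolumeGrid:
    """Noiseless rendering of a reporter pattern on the template grid."""
    X, Y, Z = _physical_coords(spec)
    img = np.zeros(spec.shape)
    for s in structures:
        if isinstance(s, Blob):
            d2 = (X - s.center[0]) ** 2 + (Y - s.center[1]) ** 2 + (Z - s.center[2]) ** 2
            img += s.peak * np.exp(-d2 / (2.0 * s.sigma ** 2))
        else:
            d2min = np.full(spec.shape, np.inf)
            pts = np.asarray(s.points)
            P = np.stack([X, Y, Z], axis=-1)
            for a, b in zip(pts[:-1], pts[1:]):
                ab = b - a
                denom = float(ab @ ab)
                t = np.clip(((P - a) @ ab) / max(denom, 1e-12), 0.0, 1.0)
                closest = a + t[..., None] * ab
                d2min = np.minimum(d2min, ((P - closest) ** 2).sum(axis=-1))
            img += s.peak * np.exp(-d2min / (2.0 * (s.radius / 1.5) ** 2))
    return VolumeGrid(np.clip(img, 0.0, None), spec.spacing)


def _sample_jitter(spec: PhantomSpec, rng: np.random.Generator) -> AffineTransform:
    """A random mounting transform (specimen physical -> template physical)."""
    p = np.zeros(12)
    p[0:3] = rng.uniform(-spec.jitter_trans_um, spec.jitter_trans_um, size=3)
    p[3:6] = rng.uniform(-spec.jitter_rot_deg, spec.jitter_rot_deg, size=3)
    if spec.jitter_log_scale > 0:
        p[6:9] = rng.uniform(-spec.jitter_log_scale, spec.jitter_log_scale, size=3)
    c = spec.center
    dof = 12 if spec.jitter_log_scale > 0 else 6
    return _params_to_transform(p, dof, c, c)


def _corrupt(ideal: VolumeGrid, truth: AffineTransform, spec: PhantomSpec,
             rng: np.random.Generator) -> VolumeGrid:
    """Jitter, attenuate along depth, and add seeded noise."""
    moved = apply_affine(ideal, truth.inverse(), ideal.shape, ideal.spacing)
    z_um = np.arange(spec.shape[2]) * spec.spacing[2]
    img = moved.data * np.exp(-spec.z_attenuation * z_um)[None, None, :]
    if spec.poisson:
        photons = 200.0
        img = rng.poisson(np.clip(img, 0, None) * photons) / photons
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return VolumeGrid(np.clip(img, 0.0, None), spec.spacing)


def make_specimen(
    brain: VolumeGrid,
    structures,
    spec: PhantomSpec,
    seed: int,
) -> tuple[VolumeGrid, VolumeGrid, AffineTransform, tuple[int, ...]]:
    """One simulated double-labelled larva.

    Structures are kept independently with probability ``spec.variegation_p``
    (variegated expression); both channels are moved by the same sampled
    mounting jitter, depth-attenuated and noised.  Returns
    ``(reporter, reference, truth, kept)`` where ``truth`` maps specimen
    physical coordinates onto the template (what registration must recover)
    and ``kept`` indexes the structures present in this specimen.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    kept = tuple(i for i in range(len(structures))
                 if rng.uniform() < spec.variegation_p)
    reporter_ideal = render_structures(spec, [structures[i] for i in kept])
    truth = _sample_jitter(spec, rng)
    reference = _corrupt(brain, truth, spec, rng)
    reporter = _corrupt(reporter_ideal, truth, spec, rng)
    return reporter, reference, truth, kept


# ---------------------------------------------------------------------------
# Line panels with exact ground truth


def _near_cubic_factors(n: int) -> tuple[int, int, int]:
    best = (1, 1, n)
    best_score = float("inf")
    for a in range(1, int(round(n ** (1 / 3))) + 2):
        if n % a:
            continue
        m = n // a
        for b in range(a, int(np.sqrt(m)) + 1):
            if m % b:
                continue
            c = m // b
            score = max(a, b, c) - min(a, b, c)
            if score < best_score:
                best, best_score = (a, b, c), score
    return best


def make_line_panel(n_lines: int, design: dict, spec: PhantomSpec):
    """An atlas of noiseless planted expression patterns with exact truth.

    ``design["kind"]`` selects the layout:

    * ``"tiling"`` — the brain mask is cut into ``n_lines`` contiguous
      y-slabs of near-equal voxel count; footprints are disjoint and their
      union is the whole mask.
    * ``"random_blobs"`` — each line is a union of
      ``design.get("blobs_per_line", 2)`` axis-aligned boxes planted inside
      the brain (boxes may overlap between lines).
    * ``"pair_overlap"`` — exactly two lines, each a box, intersecting in a
      block of exactly ``design["overlap_voxels"]`` voxels.

    Returns ``(atlas, truth)`` where ``truth`` has per-line footprint masks
    (``footprints``), the pairwise overlap-voxel matrix (``overlap``), and
    the brain mask.  Line volumes are the footprints at intensity 1.0, so
    search counts on the panel are exact.
    """
    from .atlas_build import Atlas, LineRecord  # local import: avoid cycle

    if n_lines < 1:
        raise PhantomSpecError("need at least one line")
    spec.validate()
    brain, mask = make_reference_brain(spec)
    kind = design.get("kind", "tiling")
    footprints: dict[str, np.ndarray] = {}
    ids = [f"y{300 + i}Et" for i in range(n_lines)]

    if kind == "tiling":
        ycounts = mask.data.sum(axis=(0, 2))
        cum = np.cumsum(ycounts)
        total = cum[-1]
        if total == 0:
            raise PhantomSpecError("empty brain mask")
        bounds = [0]
        for k in range(1, n_lines):
            bounds.append(int(np.searchsorted(cum, total * k / n_lines)))
        bounds.append(mask.shape[1])
        for lid, (lo, hi) in zip(ids, zip(bounds[:-1], bounds[1:])):
            fp = np.zeros(spec.shape, bool)
            fp[:, lo:hi, :] = mask.data[:, lo:hi, :]
            footprints[lid] = fp
    elif kind == "random_blobs":
        rng = np.random.default_rng(spec.seed + 7)
        per_line = int(design.get("blobs_per_line", 2))
        half = np.asarray(design.get("box_halfsize_vox", (6, 8, 4)), int)
        inside = np.argwhere(mask.data)
        for lid in ids:
            fp = np.zeros(spec.shape, bool)
            for _ in range(per_line):
                c = inside[rng.integers(len(inside))]
                lo = np.maximum(c - half, 0)
                hi = np.minimum(c + half, np.asarray(spec.shape))
                fp[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
            footprints[lid] = fp & mask.data
    elif kind == "pair_overlap":
        if n_lines != 2:
            raise PhantomSpecError("pair_overlap design needs exactly 2 lines")
        n_ov = int(design["overlap_voxels"])
        a, b, c = _near_cubic_factors(n_ov)
        cx, cy, cz = (np.asarray(spec.shape) / 2).astype(int)
        # shared block of exactly a*b*c voxels at the grid centre
        shared = (slice(cx, cx + a), slice(cy, cy + b), slice(cz, cz + c))
        fpA = np.zeros(spec.shape, bool)
        fpA[cx - 8:cx + a, cy - 10:cy + b, cz - 4:cz + c] = True
        fpB = np.zeros(spec.shape, bool)
        fpB[shared] = True
        fpB[cx:cx + a + 8, cy:cy + b + 10, cz:cz + c + 4] = True
        if (fpA & fpB).sum() != n_ov:  # boxes must intersect only in `shared`
            raise PhantomSpecError("infeasible overlap design for this grid")
        footprints[ids[0]], footprints[ids[1]] = fpA, fpB
    else:
        raise PhantomSpecError(f"unknown panel design {kind!r}")

    lines = []
    for lid in ids:
        vol = VolumeGrid(footprints[lid].astype(np.float64), spec.spacing)
        lines.append(LineRecord(line_id=lid, driver="Gal4", volume=vol, n_specimens=3))
    atlas = Atlas(spacing=spec.spacing, shape=spec.shape,
                  brain_mask=mask, lines=lines)
    overlap = np.zeros((n_lines, n_lines), int)
    for i, a_id in enumerate(ids):
        for j, b_id in enumerate(ids):
            overlap[i, j] = int((footprints[a_id] & footprints[b_id]).sum())
    truth = {
        "footprints": {lid: BinaryMask(fp, spec.spacing) for lid, fp in footprints.items()},
        "overlap": overlap,
        "line_ids": ids,
        "brain_mask": mask,
    }
    return atlas, truth


def make_calibration_set(
    brain: VolumeGrid,
    n_specimens: int,
    spec: PhantomSpec,
    structures=None,
) -> CalibrationSet:
    """Duplicate-scan specimens: same larva, independent remount and noise.

    Each specimen owns a variegated reporter pattern; its two scans share
    that pattern but draw independent mounting jitters and noise — the
    simulated analogue of scanning, remounting and rescanning.
    """
    if n_specimens < 1:
        raise PhantomSpecError("need at least one specimen")
    spec.validate()
    if structures is None:
        structures = spec.structures or default_structures(spec)
    specimens = []
    for i in range(n_specimens):
        rng = np.random.default_rng(spec.seed + 1000 + i)
        kept = [s for s in structures if rng.uniform() < spec.variegation_p]
        reporter_ideal = render_structures(spec, kept)
        scans = []
        for _ in range(2):
            truth = _sample_jitter(spec, rng)
            scans.append(
                Scan(
                    reference_channel=_corrupt(brain, truth, spec, rng),
                    reporter_channel=_corrupt(reporter_ideal, truth, spec, rng),
                )
            )
        specimens.append(CalibrationSpecimen(f"fish{i + 1}", scans[0], scans[1]))
    return CalibrationSet(specimens)
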