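"""Averaging registered specimens, brain-mask extraction and atlas assembly.

A transgenic line's atlas entry is the voxelwise mean of at least three
registered specimens, each saturation-normalized first so that dim larvae
contribute on the same scale as bright ones; averaging fills in structure
missing from any one larva through variegated expression.  The brain mask is
derived from the two broad reference channels (pan-neuronal and
pan-glutamatergic): their mean is binarized by Otsu's threshold on nonzero
voxels, morphologically closed, small components dropped and internal holes
filled.  A user-supplied mask can override the automatic one (mirroring the
manual mask curation such data normally receives); the atlas records which
it was given.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import CardinalityError, MaskFailureError, UnknownLineError
from .grids import BinaryMask, Spacing, VolumeGrid, require_congruent
from .volume_io import DEFAULT_SATURATE_FRACTION, normalize_saturate, read_volume, write_volume

__all__ = [
    "IntegrationSite",
    "LineRecord",
    "Atlas",
    "average_registered",
    "build_brain_mask",
    "mask_volume",
    "save_atlas",
    "load_atlas",
]

MIN_SPECIMENS = 3  # averaged atlas entries need at least three larvae


@dataclass(frozen=True)
class IntegrationSite:
    """Genomic integration of the enhancer-trap transgene (0-based, half-open)."""

    chromosome: str
    position: int
    nearest_gene: str = ""
    site_class: str = "intergenic"  # intergenic | exon | intron1 | intron2+

    def __post_init__(self) -> None:
        if self.site_class not in {"intergenic", "exon", "intron1", "intron2+"}:
            raise ValueError(f"unknown integration class {self.site_class!r}")


@dataclass
class LineRecord:
    """One transgenic line: its averaged registered volume plus metadata."""

    line_id: str
    driver: str  # Gal4 | Cre | direct
    volume: VolumeGrid
    n_specimens: int
    annotations: list[str] = field(default_factory=list)
    integration: IntegrationSite | None = None
    provisional: bool = False  # set to bypass the >= 3 specimen rule off-atlas

    def __post_init__(self) -> None:
        if self.driver not in {"Gal4", "Cre", "direct"}:
            raise ValueError(f"driver must be Gal4, Cre or direct, got {self.driver!r}")
        if self.n_specimens < MIN_SPECIMENS and not self.provisional:
            raise CardinalityError(
                f"{self.line_id}: averaged entries need >= {MIN_SPECIMENS} specimens, "
                f"got {self.n_specimens}"
            )


@dataclass
class Atlas:
    """The searchable collection: reference grid, brain mask, line volumes."""

    spacing: Spacing
    shape: tuple[int, int, int]
    brain_mask: BinaryMask
    lines: list[LineRecord] = field(default_factory=list)
    term_rois: dict[str, BinaryMask] = field(default_factory=dict)
    mask_provenance: str = "auto"  # auto | user

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if self.brain_mask.shape != self.shape:
            raise ValueError("brain mask must live on the reference grid")
        seen = set()
        for rec in self.lines:
            if rec.line_id in seen:
                raise ValueError(f"duplicate line id {rec.line_id!r}")
            seen.add(rec.line_id)
            if rec.volume.shape != self.shape:
                raise ValueError(f"{rec.line_id}: volume not on the reference grid")
        for term, roi in self.term_rois.items():
            if roi.shape != self.shape:
                raise ValueError(f"term ROI {term!r} not on the reference grid")

    @property
    def line_ids(self) -> list[str]:
        return [rec.line_id for rec in self.lines]

    def get(self, line_id: str) -> LineRecord:
        for rec in self.lines:
            if rec.line_id == line_id:
                return rec
        raise UnknownLineError(line_id)

    def add(self, rec: LineRecord) -> None:
        if rec.line_id in self.line_ids:
            raise ValueError(f"duplicate line id {rec.line_id!r}")
        if rec.volume.shape != self.shape:
            raise ValueError(f"{rec.line_id}: volume not on the reference grid")
        self.lines.append(rec)


# ---------------------------------------------------------------------------
# Operations


def average_registered(
    volumes: list[VolumeGrid],
    saturate_fraction: float = DEFAULT_SATURATE_FRACTION,
    allow_fewer: bool = False,
) -> VolumeGrid:
    """Normalize each registered specimen, then take the voxelwise mean.

    Normalization uses per-input (not pooled) saturation quantiles so a dim
    specimen is not swamped by a bright one.  Fewer than three inputs is an
    error unless ``allow_fewer`` is set (non-atlas use).
    """
    if len(volumes) < MIN_SPECIMENS and not allow_fewer:
        raise CardinalityError(
            f"averaging needs >= {MIN_SPECIMENS} registered specimens, got {len(volumes)}"
        )
    if not volumes:
        raise CardinalityError("no volumes to average")
    require_congruent(*volumes)
    normed = [normalize_saturate(v, saturate_fraction) for v in volumes]
    return volumes[0].with_data(np.mean([v.data for v in normed], axis=0))


def build_brain_mask(
    refA: VolumeGrid,
    refB: VolumeGrid,
    close_radius: float = 4.0,
    min_component: int = 1000,
) -> BinaryMask:
    """Extract the brain mask from two broad reference channels.

    The voxelwise mean of the two channels is binarized by Otsu's threshold
    computed over the full volume — background voxels included, so the
    threshold separates tissue from background rather than bright from dim
    tissue and the faded brain periphery is retained — then morphologically
    closed with a ``close_radius``-um spacing-aware ellipsoidal footprint,
    components smaller than ``min_component`` voxels dropped, and internal
    holes filled both in 3D and slice-wise along z.  Symmetric in its two
    inputs.
    """
    require_congruent(refA, refB)
    mean = (refA.data + refB.data) / 2.0
    if not (mean > 0).any():
        raise MaskFailureError("reference channels are all zero")
    if mean.min() == mean.max():
        thresh = mean.min() / 2.0
    else:
        thresh = threshold_otsu(mean)
    binary = mean > thresh
    if not binary.any():
        raise MaskFailureError("binarization produced an empty mask")
    if close_radius > 0:
        footprint = _ellipsoid_footprint(close_radius, refA.spacing)
        binary = ndimage.binary_closing(binary, structure=footprint)
    if min_component > 1:
        binary = _drop_small_components(binary, min_component)
    if not binary.any():
        raise MaskFailureError("no connected component survived the size filter")
    binary = ndimage.binary_fill_holes(binary)
    for k in range(binary.shape[2]):  # slice-wise: tubes open along z
        binary[:, :, k] = ndimage.binary_fill_holes(binary[:, :, k])
    return BinaryMask(binary, refA.spacing)


def _drop_small_components(binary: np.ndarray, min_component: int) -> np.ndarray:
    labels, n = ndimage.label(binary)
    if n == 0:
        return binary
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component
    keep[0] = False
    return keep[labels]


def _ellipsoid_footprint(radius_um: float, spacing: Spacing) -> np.ndarray:
    r_vox = np.maximum(np.floor(radius_um / np.asarray(spacing)).astype(int), 0)
    if (r_vox == 0).all():
        return np.ones((1, 1, 1), bool)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return d2 <= radius_um ** 2


def mask_volume(v: VolumeGrid, m: BinaryMask) -> VolumeGrid:
    """Zero every voxel outside the mask; inside voxels are untouched."""
    require_congruent(v, m)
    return v.with_data(np.where(m.data, v.data, 0.0))


# ---------------------------------------------------------------------------
# Disk format: a directory with atlas.json + one NIfTI per line


def save_atlas(atlas: Atlas, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(VolumeGrid(atlas.brain_mask.data.astype(np.float64), atlas.spacing),
                 d / "brain_mask.nii")
    meta = {
        "spacing_um": list(atlas.spacing),
        "shape": list(atlas.shape),
        "mask_provenance": atlas.mask_provenance,
        "lines": [],
        "term_rois": {},
    }
    ann_rows = []
    integ_rows = []
    for rec in atlas.lines:
        fname = f"{rec.line_id}.nii"
        write_volume(rec.volume, d / fname)
        meta["lines"].append(
            {"line_id": rec.line_id, "driver": rec.driver,
             "n_specimens": rec.n_specimens, "volume": fname}
        )
        for term in rec.annotations:
            ann_rows.append({"line_id": rec.line_id, "term": term, "note": ""})
        if rec.integration is not None:
            integ_rows.append(
                {"chrom": rec.integration.chromosome,
                 "start": rec.integration.position,
                 "end": rec.integration.position + 1,
                 "line_id": rec.line_id,
                 "nearest_gene": rec.integration.nearest_gene,
                 "class": rec.integration.site_class}
            )
    for term, roi in atlas.term_rois.items():
        fname = f"roi_{term.replace(' ', '_')}.nii"
        write_volume(VolumeGrid(roi.data.astype(np.float64), atlas.spacing), d / fname)
        meta["term_rois"][term] = fname
    (d / "atlas.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(ann_rows, columns=["line_id", "term", "note"]).to_csv(
        d / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(integ_rows, columns=["chrom", "start", "end", "line_id",
                                      "nearest_gene", "class"]).to_csv(
        d / "integrations.tsv", sep="\t", index=False)


def load_atlas(directory: str | Path) -> Atlas:
    d = Path(directory)
    meta = json.loads((d / "atlas.json").read_text())
    spacing = tuple(meta["spacing_um"])
    shape = tuple(meta["shape"])
    mask_v = read_volume(d / "brain_mask.nii", spacing)
    brain_mask = BinaryMask(mask_v.data > 0.5, spacing)
    ann = pd.read_csv(d / "annotations.tsv", sep="\t") if (d / "annotations.tsv").exists() \
        else pd.DataFrame(columns=["line_id", "term", "note"])
    integ = pd.read_csv(d / "integrations.tsv", sep="\t") if (d / "integrations.tsv").exists() \
        else pd.DataFrame(columns=["chrom", "start", "end", "line_id", "nearest_gene", "class"])
    lines = []
    for entry in meta["lines"]:
        vol = read_volume(d / entry["volume"], spacing)
        terms = ann.loc[ann["line_id"] == entry["line_id"], "term"].tolist()
        site = None
        hit = integ[integ["line_id"] == entry["line_id"]]
        if len(hit):
            row = hit.iloc[0]
            site = IntegrationSite(str(row["chrom"]), int(row["start"]),
                                   str(row["nearest_gene"]), str(row["class"]))
        lines.append(LineRecord(entry["line_id"], entry["driver"], vol,
                                int(entry["n_specimens"]), terms, site))
    term_rois = {}
    for term, fname in meta.get("term_rois", {}).items():
        roi_v = read_volume(d / fname, spacing)
        term_rois[term] = BinaryMask(roi_v.data > 0.5, spacing)
    return Atlas(spacing, shape, brain_mask, lines, term_rois,
                 meta.get("mask_provenance", "auto"))
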