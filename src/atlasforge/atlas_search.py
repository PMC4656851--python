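"""Voxel, ROI and anatomical-term queries over the atlas.

A "fluorescent" voxel is one whose normalized averaged intensity reaches the
threshold tau (default 0.1 on [0, 1] volumes — a deliberate, logged choice;
there is no field-standard cutoff).  ROI searches rank
lines by the number of fluorescent voxels inside the region; both the
fraction of the ROI covered and the fraction of the line's own footprint
falling in the ROI are reported so callers can rank either way.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_build import Atlas
from .errors import EmptyROIError
from .grids import BinaryMask

__all__ = ["DEFAULT_TAU", "ROI", "SearchHit", "point_query", "make_roi",
           "roi_search", "term_search", "hits_to_frame"]

DEFAULT_TAU = 0.1


@dataclass
class ROI:
    """A realized region of interest on the atlas reference grid."""

    mask: BinaryMask
    definition: dict

    @property
    def size(self) -> int:
        return self.mask.count


@dataclass(frozen=True)
class SearchHit:
    """One line's match against an ROI."""

    line_id: str
    count: int            # suprathreshold voxels inside the ROI
    roi_fraction: float   # count / ROI size
    line_fraction: float  # count / line's total suprathreshold voxels
    empty: bool           # flagged instead of dropped when count == 0


def point_query(atlas: Atlas, voxel: tuple[int, int, int], tau: float = DEFAULT_TAU) -> list[str]:
    """Lines expressing at a single voxel, brightest first.

    Returns the ids of all lines whose averaged intensity at ``voxel`` is at
    least ``tau``, sorted by descending intensity (ties by line id).
    """
    _check_tau(tau)
    idx = tuple(int(v) for v in voxel)
    if len(idx) != 3 or any(i < 0 or i >= n for i, n in zip(idx, atlas.shape)):
        raise IndexError(f"voxel {voxel} outside grid {atlas.shape}")
    hits = [(rec.volume.data[idx], rec.line_id) for rec in atlas.lines
            if rec.volume.data[idx] >= tau]
    hits.sort(key=lambda h: (-h[0], h[1]))
    return [lid for _, lid in hits]


def make_roi(atlas: Atlas, definition: dict) -> ROI:
    """Realize an ROI definition as a binary mask on the reference grid.

    Definitions (``definition["kind"]``):

    * ``box`` — two corner voxels ``lo``, ``hi``; half-open ``[lo, hi)``.
    * ``sphere`` — ``center`` voxel + ``radius_um`` (radius 0 keeps the
      centre voxel).
    * ``mask`` — an explicit :class:`BinaryMask` under ``"mask"``.
    * ``from_line`` — ``line_id`` + ``tau``: the line's suprathreshold
      footprint.
    """
    kind = definition.get("kind")
    shape = atlas.shape
    if kind == "box":
        lo = np.clip(np.asarray(definition["lo"], int), 0, shape)
        hi = np.clip(np.asarray(definition["hi"], int), 0, shape)
        m = np.zeros(shape, bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    elif kind == "sphere":
        center = np.asarray(definition["center"], float)
        radius = float(definition["radius_um"])
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        d2 = sum(((g - c) * s) ** 2
                 for g, c, s in zip(grids, center, atlas.spacing))
        m = d2 <= radius ** 2
    elif kind == "mask":
        mask = definition["mask"]
        if mask.shape != shape:
            raise ValueError("mask ROI not on the reference grid")
        m = mask.data.copy()
    elif kind == "from_line":
        rec = atlas.get(definition["line_id"])
        tau = float(definition.get("tau", DEFAULT_TAU))
        _check_tau(tau)
        m = rec.volume.data >= tau
    else:
        raise ValueError(f"unknown ROI kind {kind!r}")
    if not m.any():
        raise EmptyROIError(f"ROI definition {kind!r} realized to zero voxels")
    safe_def = {k: v for k, v in definition.items() if k != "mask"}
    return ROI(BinaryMask(m, atlas.spacing), safe_def)


def roi_search(
    atlas: Atlas,
    roi: ROI,
    tau: float = DEFAULT_TAU,
    exclude: str | None = None,
) -> list[SearchHit]:
    """Rank all lines by fluorescent-voxel count inside an ROI.

    Every line (minus ``exclude``) gets a hit; zero-count lines are included
    but flagged.  Sorting is by descending count, ties by ascending line id,
    so results are deterministic.
    """
    _check_tau(tau)
    if roi.size == 0:
        raise EmptyROIError("cannot search an empty ROI")
    sel = roi.mask.data
    hits = []
    for rec in atlas.lines:
        if rec.line_id == exclude:
            continue
        supra = rec.volume.data >= tau
        count = int((supra & sel).sum())
        total = int(supra.sum())
        hits.append(
            SearchHit(
                line_id=rec.line_id,
                count=count,
                roi_fraction=count / roi.size,
                line_fraction=count / total if total else 0.0,
                empty=count == 0,
            )
        )
    hits.sort(key=lambda h: (-h.count, h.line_id))
    return hits


def term_search(
    atlas: Atlas, term: str, tau: float = DEFAULT_TAU
) -> tuple[list[str], list[SearchHit] | None]:
    """Anatomical-term query: annotation lookup plus optional spatial search.

    ``annotated`` lists lines whose annotation list contains ``term``
    (case-insensitive exact match).  When the atlas carries an ROI mask for
    the term, a spatial :func:`roi_search` through it is returned as well;
    otherwise the spatial component is ``None``.  Unknown terms yield empty
    results rather than errors.
    """
    if not term:
        raise ValueError("term must be nonempty")
    needle = term.strip().lower()
    annotated = [rec.line_id for rec in atlas.lines
                 if any(t.strip().lower() == needle for t in rec.annotations)]
    spatial = None
    for known, mask in atlas.term_rois.items():
        if known.strip().lower() == needle and mask.count > 0:
            spatial = roi_search(atlas, ROI(mask, {"kind": "term", "term": known}), tau)
            break
    return annotated, spatial


def hits_to_frame(hits: list[SearchHit]) -> pd.DataFrame:
    """Search results as a TSV-ready table with 1-based ranks."""
    return pd.DataFrame(
        {
            "line_id": [h.line_id for h in hits],
            "count": [h.count for h in hits],
            "roi_fraction": [h.roi_fraction for h in hits],
            "line_fraction": [h.line_fraction for h in hits],
            "rank": np.arange(1, len(hits) + 1),
        }
    )


def _check_tau(tau: float) -> None:
    # values just above 1 are allowed as degenerate "match nothing" probes
    if tau < 0.0 or tau > 1.5:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
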