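"""Intersectional (Gal4 x Cre) expression prediction and coverage statistics.

A cross between a Gal4 driver and a Cre driver expresses the switch reporter
only in cells carrying both transgenes; on registered averaged volumes the
predicted intersection is the set of voxels suprathreshold in both lines.
Because averaged volumes encode labeling frequency rather than single-cell
certainty, a graded strength map (the voxelwise minimum of the two
intensities) accompanies the binary mask.  The default threshold for
"strongly fluorescent" voxels in intersection prediction is 0.5 — stricter
than the 0.1 search default, since co-expression calls should rest on robust
signal in both channels.

Coverage statistics express each line's suprathreshold footprint as a
fraction of the brain mask (the pan-neuronal extent of the CNS), plus the
union coverage of a whole line set.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas_build import Atlas
from .errors import MaskFailureError
from .grids import BinaryMask, VolumeGrid, require_congruent

__all__ = [
    "DEFAULT_TAU_STRONG",
    "CoverageReport",
    "intersect_patterns",
    "line_coverage",
    "union_coverage",
    "coverage_report",
]

DEFAULT_TAU_STRONG = 0.5


def intersect_patterns(
    a: VolumeGrid,
    b: VolumeGrid,
    tau_a: float = DEFAULT_TAU_STRONG,
    tau_b: float = DEFAULT_TAU_STRONG,
) -> tuple[BinaryMask, VolumeGrid]:
    """Predicted co-expression of two lines.

    ``mask`` holds voxels suprathreshold in both volumes; ``strength`` is
    ``min(a, b)`` inside the mask and 0 outside.  Commutative when the
    thresholds are swapped along with the volumes.
    """
    require_congruent(a, b)
    for tau in (tau_a, tau_b):
        if not 0.0 <= tau <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {tau}")
    mask = (a.data >= tau_a) & (b.data >= tau_b)
    strength = np.where(mask, np.minimum(a.data, b.data), 0.0)
    return BinaryMask(mask, a.spacing), a.with_data(strength)


def _footprint(atlas: Atlas, line_id: str, tau: float) -> np.ndarray:
    return atlas.get(line_id).volume.data >= tau


def line_coverage(atlas: Atlas, line_id: str, tau: float = 0.1) -> float:
    """Fraction of brain-mask voxels where the line is suprathreshold."""
    brain = atlas.brain_mask.data
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise MaskFailureError("atlas brain mask is empty")
    return float((_footprint(atlas, line_id, tau) & brain).sum() / n_brain)


def union_coverage(atlas: Atlas, line_ids, tau: float = 0.1) -> float:
    """Coverage of the union of several lines' footprints (idempotent in ids)."""
    ids = list(line_ids)
    if not ids:
        raise ValueError("need at least one line id")
    brain = atlas.brain_mask.data
    n_brain = int(brain.sum())
    if n_brain == 0:
        raise MaskFailureError("atlas brain mask is empty")
    union = np.zeros(atlas.shape, bool)
    for lid in ids:
        union |= _footprint(atlas, lid, tau)
    return float((union & brain).sum() / n_brain)


@dataclass
class CoverageReport:
    """Per-line brain coverage plus summary statistics and the union."""

    tau: float
    fractions: dict[str, float]
    union: float

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.fractions.values())))

    @property
    def median(self) -> float:
        return float(np.median(list(self.fractions.values())))

    @property
    def min(self) -> float:
        return float(np.min(list(self.fractions.values())))

    @property
    def max(self) -> float:
        return float(np.max(list(self.fractions.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"line_id": list(self.fractions), "coverage": list(self.fractions.values())}
        ).sort_values("coverage", ascending=False).reset_index(drop=True)

    def summary(self) -> dict:
        return {
            "tau": self.tau,
            "n_lines": len(self.fractions),
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "union": self.union,
        }


def coverage_report(atlas: Atlas, tau: float = 0.1) -> CoverageReport:
    """Coverage fractions for every line plus the union, at one shared tau.

    A single threshold is used for both the per-line fractions and the
    union so the two are directly comparable.
    """
    if not atlas.lines:
        raise ValueError("atlas has no lines")
    fractions = {rec.line_id: line_coverage(atlas, rec.line_id, tau) for rec in atlas.lines}
    return CoverageReport(tau=tau, fractions=fractions,
                          union=union_coverage(atlas, atlas.line_ids, tau))
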