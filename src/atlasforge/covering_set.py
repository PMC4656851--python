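"""Greedy covering-set selection: tile a template domain with minimal overlap.

For systematic "nested" screening one wants a small panel of lines whose
thresholded footprints jointly cover a template expression domain while
double-labeling as little of it as possible.  "Minimal overlap" is
formalized as an overlap-penalized greedy objective: at each step the
candidate maximizing

    gain = (new template voxels covered) - lambda * (template voxels
           overlapping already-selected footprints)

is added.  At ``lambda = 0`` this is the textbook greedy maximum-coverage
algorithm with its (1 - 1/e) approximation guarantee; ``lambda > 0``
(default 1) strictly discourages double-labeling.  Coverage is computed on
binary footprints, not graded intensities, because screening concerns which
neurons are genetically accessible, not how bright they appear.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas_build import Atlas
from .errors import EmptyROIError
from .grids import BinaryMask

__all__ = ["CoverSetResult", "greedy_cover", "subdivide_line"]


@dataclass
class CoverSetResult:
    """Ordered selection with per-step and cumulative accounting."""

    selected: list[str]
    marginal_gain: list[float]        # new-coverage fraction added per step
    cumulative_coverage: list[float]  # fraction of template covered after each step
    overlap_fraction: float           # template voxels covered >= 2 times / template size
    target_reached: bool
    parameters: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return self.cumulative_coverage[-1] if self.cumulative_coverage else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.selected) + 1),
                "line_id": self.selected,
                "marginal_coverage": self.marginal_gain,
                "cumulative_coverage": self.cumulative_coverage,
            }
        )

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "marginal_coverage": self.marginal_gain,
            "cumulative_coverage": self.cumulative_coverage,
            "overlap_fraction": self.overlap_fraction,
            "target_reached": self.target_reached,
            "parameters": self.parameters,
        }


def greedy_cover(
    atlas: Atlas,
    template: BinaryMask,
    candidates,
    tau: float = 0.1,
    overlap_penalty: float = 1.0,
    target: float = 1.0,
    max_lines: int | None = None,
) -> CoverSetResult:
    """Select lines covering ``template`` greedily with an overlap penalty.

    Stops when cumulative coverage reaches ``target``, when no remaining
    candidate has positive gain, or after ``max_lines`` selections.  Ties in
    gain break lexicographically by line id, so the result is deterministic
    and independent of candidate input order.  An unreachable target is
    reported in the result, not raised.
    """
    ids = sorted(set(candidates))
    if not ids:
        raise ValueError("empty candidate set")
    if not 0.0 <= target <= 1.0:
        raise ValueError(f"target must be in [0, 1], got {target}")
    if overlap_penalty < 0:
        raise ValueError("overlap penalty must be >= 0")
    tmpl = template.data
    n_tmpl = int(tmpl.sum())
    if n_tmpl == 0:
        raise EmptyROIError("template mask is empty")

    # footprints restricted to the template: coverage and overlap both live there
    foot = {lid: (atlas.get(lid).volume.data >= tau) & tmpl for lid in ids}
    covered = np.zeros(atlas.shape, bool)
    multi = np.zeros(atlas.shape, bool)  # voxels covered >= 2 times
    selected: list[str] = []
    gains: list[float] = []
    cumulative: list[float] = []
    remaining = list(ids)
    limit = max_lines if max_lines is not None else len(ids)

    while remaining and len(selected) < limit:
        best_lid = None
        best_gain = 0.0
        for lid in remaining:  # sorted, so ties keep the smallest id
            fp = foot[lid]
            new = int((fp & ~covered).sum())
            ov = int((fp & covered).sum())
            gain = new - overlap_penalty * ov
            if gain > best_gain:
                best_gain, best_lid = gain, lid
        if best_lid is None:
            break
        fp = foot[best_lid]
        new_frac = int((fp & ~covered).sum()) / n_tmpl
        multi |= fp & covered
        covered |= fp
        selected.append(best_lid)
        remaining.remove(best_lid)
        gains.append(new_frac)
        cumulative.append(int(covered.sum()) / n_tmpl)
        if cumulative[-1] >= target - 1e-12:
            break

    return CoverSetResult(
        selected=selected,
        marginal_gain=gains,
        cumulative_coverage=cumulative,
        overlap_fraction=int(multi.sum()) / n_tmpl,
        target_reached=bool(cumulative and cumulative[-1] >= target - 1e-12),
        parameters={"tau": tau, "overlap_penalty": overlap_penalty,
                    "target": target, "max_lines": max_lines},
    )


def subdivide_line(
    atlas: Atlas,
    line_id: str,
    tau: float = 0.1,
    overlap_penalty: float = 1.0,
    target: float = 1.0,
    max_lines: int | None = None,
) -> CoverSetResult:
    """Cover one line's expression domain with the other lines in the atlas.

    The template is the line's suprathreshold footprint intersected with the
    brain mask; the line itself is excluded from the candidates.
    """
    rec = atlas.get(line_id)
    tmpl = (rec.volume.data >= tau) & atlas.brain_mask.data
    if not tmpl.any():
        raise EmptyROIError(f"{line_id}: footprint empty after thresholding at {tau}")
    candidates = [lid for lid in atlas.line_ids if lid != line_id]
    if not candidates:
        raise ValueError("atlas has no other lines to cover with")
    return greedy_cover(atlas, BinaryMask(tmpl, atlas.spacing), candidates,
                        tau, overlap_penalty, target, max_lines)
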