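"""Density-based homogenisation of blink maps.

dSTORM videos differ widely in how many blinks they yield per unit nuclear
area, which confounds density-based clustering across samples.  Each nucleus
is therefore reduced to a common global density (default 0.001 blinks/nm²) by
keeping only the blinks from the last k acquisition frames, with k chosen so
the retained density best approximates the target.  Late frames are preferred
because early acquisition frames are the unstable ones.  Nuclei whose density
cannot approach the target within tolerance are flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BlinkMap

__all__ = ["HomogenisationResult", "homogenise", "TARGET_DENSITY"]

#: common global blink density all nuclei are reduced to (blinks/nm²)
TARGET_DENSITY = 0.001


@dataclass
class HomogenisationResult:
    blinks: BlinkMap
    k: int
    achieved_density: float
    target_density: float
    accepted: bool

    def __repr__(self) -> str:  # compact audit line
        return (
            f"HomogenisationResult(k={self.k}, achieved={self.achieved_density:.2e}, "
            f"target={self.target_density:.2e}, accepted={self.accepted})"
        )


def homogenise(
    blinks: BlinkMap,
    target_density: float = TARGET_DENSITY,
    tolerance: float = 0.10,
) -> HomogenisationResult:
    """Select the frame suffix whose blink density best matches the target.

    Scans every suffix length k = 1 .. max_frame (counting blinks with
    frame ≥ max_frame − k + 1) and keeps the k minimising the absolute
    deviation |count/area − target|; ties go to the smallest k (latest
    frames only).  The scan is exhaustive — per-frame counts need not make
    |density − target| unimodal in k.

    ``accepted`` is False when the best relative deviation exceeds
    ``tolerance``; such nuclei are excluded from group statistics downstream.
    """
    if blinks.frames is None:
        raise ValueError("homogenisation needs frame-stamped blinks")
    if blinks.roi.area <= 0:
        raise ValueError("ROI area must be positive")
    if len(blinks) == 0:
        empty = BlinkMap(np.empty((0, 2)), blinks.roi, frames=np.empty(0, dtype=int))
        return HomogenisationResult(empty, 0, 0.0, target_density, accepted=False)

    max_frame = int(blinks.frames.max())
    # suffix count for each k: blinks with frame >= max_frame - k + 1
    counts = np.bincount(blinks.frames, minlength=max_frame + 1)[1:]  # frames 1..max
    suffix_counts = np.cumsum(counts[::-1])  # index k-1 -> count in last k frames
    dev = np.abs(suffix_counts / blinks.roi.area - target_density)
    k = int(np.argmin(dev)) + 1  # argmin returns the first (smallest k) on ties

    cut = max_frame - k + 1
    keep = blinks.frames >= cut
    kept = BlinkMap(blinks.xy[keep], blinks.roi, frames=blinks.frames[keep])
    achieved = len(kept) / blinks.roi.area
    accepted = abs(achieved - target_density) <= tolerance * target_density
    return HomogenisationResult(kept, k, achieved, target_density, accepted)
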