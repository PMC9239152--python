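"""Per-cell fluorescence focus analytics: counts, colocalization, polar distance.

Consumes focus tables produced by external segmentation/spot-detection
software (one row per focus with the parent cell geometry).  Distances are
in pixels.  Colocalization of a green focus means at least one red focus in
the same cell strictly closer than the threshold (default 6 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Cell",
    "FociSummary",
    "colocalization_fraction",
    "distance_to_nearest_pole",
    "focus_count_matrix",
]

Point = tuple[float, float]


@dataclass
class Cell:
    """One segmented cell: poles, dimensions and per-channel focus points."""

    id: str
    pole_a: Point
    pole_b: Point
    length: float
    width: float
    foci: dict[str, list[Point]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pole_a == self.pole_b:
            raise ValueError(f"cell {self.id!r}: poles coincide")

    def foci_of(self, channel: str) -> list[Point]:
        return self.foci.get(channel, [])


@dataclass
class FociSummary:
    """Joint focus-count table plus marginal statistics for a strain."""

    n_cells: int
    joint_percent: dict[tuple[int, int], float]
    mean_foci: dict[str, float]
    zero_fraction: dict[str, float]


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def colocalization_fraction(
    cells: Sequence[Cell],
    threshold: float = 6.0,
    channel_a: str = "green",
    channel_b: str = "red",
) -> float:
    """Fraction of channel-a foci with a channel-b partner closer than threshold.

    The inequality is strict ("fewer than"): a pair at exactly the threshold
    distance does not colocalize.  Cells without channel-a foci contribute
    nothing to the denominator.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not cells:
        raise ValueError("empty cell list")
    n_a = 0
    n_coloc = 0
    for cell in cells:
        reds = cell.foci_of(channel_b)
        for g in cell.foci_of(channel_a):
            n_a += 1
            if any(_dist(g, r) < threshold for r in reds):
                n_coloc += 1
    if n_a == 0:
        raise ValueError(f"no {channel_a!r} foci in any cell")
    return n_coloc / n_a


def distance_to_nearest_pole(cell: Cell, focus: Point) -> float:
    """Euclidean pixel distance from a focus to the nearer cell pole."""
    return min(_dist(focus, cell.pole_a), _dist(focus, cell.pole_b))


def focus_count_matrix(
    cells: Sequence[Cell],
    channel_a: str = "green",
    channel_b: str = "red",
) -> FociSummary:
    """Joint (n_a, n_b) focus-count percentages and marginal statistics."""
    n = len(cells)
    joint: dict[tuple[int, int], int] = {}
    tot = {channel_a: 0, channel_b: 0}
    zero = {channel_a: 0, channel_b: 0}
    for cell in cells:
        na = len(cell.foci_of(channel_a))
        nb = len(cell.foci_of(channel_b))
        joint[(na, nb)] = joint.get((na, nb), 0) + 1
        tot[channel_a] += na
        tot[channel_b] += nb
        zero[channel_a] += na == 0
        zero[channel_b] += nb == 0
    joint_percent = {k: 100.0 * v / n for k, v in joint.items()} if n else {}
    mean_foci = {ch: (tot[ch] / n if n else 0.0) for ch in (channel_a, channel_b)}
    zero_fraction = {ch: (zero[ch] / n if n else 0.0) for ch in (channel_a, channel_b)}
    return FociSummary(
        n_cells=n,
        joint_percent=joint_percent,
        mean_foci=mean_foci,
        zero_fraction=zero_fraction,
    )
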