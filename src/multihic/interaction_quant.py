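"""Region-based interreplicon interaction statistics.

Scores are sums of normalized contact scores over fixed regions of
(column, row) bin-pair space, doubled to account for the mirrored region
across the main diagonal, and expressed as percentages of a wild-type
reference after subtracting a background map's score.

Two built-in regions, in global bin coordinates of the default 570-bin
layout (x = column = primary-chromosome bin, y = row = secondary-chromosome
bin):

* the origin-origin rectangle x in [122, 163], y in [363, 402];
* the chromosome-alignment area: the union of two overlapping
  parallelograms with vertices (13, 285), (63, 285), (220, 492), (270, 492)
  and (13, 492), (63, 492), (220, 285), (270, 285), minus the
  origin-origin rectangle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .hic_pipeline import ContactMap

__all__ = [
    "QuantRegion",
    "ori_rectangle",
    "alignment_region",
    "region_membership",
    "region_sum",
    "ori_interaction_score",
    "alignment_score",
    "relative_interaction",
    "ORI_X_RANGE",
    "ORI_Y_RANGE",
    "PARALLELOGRAM_1",
    "PARALLELOGRAM_2",
]

ORI_X_RANGE = (122, 163)
ORI_Y_RANGE = (363, 402)
# vertex order: the two top corners then the two bottom corners of each band
PARALLELOGRAM_1 = ((13, 285), (63, 285), (220, 492), (270, 492))
PARALLELOGRAM_2 = ((13, 492), (63, 492), (220, 285), (270, 285))


@dataclass(frozen=True)
class QuantRegion:
    """A set of (x, y) bin pairs given by a rectangle or parallelogram union.

    Rectangles are inclusive bin ranges.  Each parallelogram is four
    vertices; membership is boundary-inclusive.  ``excluded`` is an optional
    rectangle removed from the region.  ``double_count_overlap`` sums the
    two parallelograms independently instead of their union (off by
    default: overlapping pairs are counted once).
    """

    kind: str  # "rectangle" | "parallelogram-union"
    x_range: Optional[tuple[int, int]] = None
    y_range: Optional[tuple[int, int]] = None
    parallelograms: tuple[tuple[tuple[int, int], ...], ...] = ()
    excluded: Optional[tuple[tuple[int, int], tuple[int, int]]] = None
    double_count_overlap: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "parallelogram-union"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "rectangle" and (self.x_range is None or self.y_range is None):
            raise ValueError("rectangle region needs x_range and y_range")
        if self.kind == "parallelogram-union" and not self.parallelograms:
            raise ValueError("parallelogram-union region needs vertex lists")


def ori_rectangle() -> QuantRegion:
    """The origin-origin quantification rectangle."""
    return QuantRegion(
        kind="rectangle", x_range=ORI_X_RANGE, y_range=ORI_Y_RANGE, name="ori1-ori2"
    )


def alignment_region(double_count_overlap: bool = False) -> QuantRegion:
    """The chromosome-alignment area (parallelogram union minus ori rectangle)."""
    return QuantRegion(
        kind="parallelogram-union",
        parallelograms=(PARALLELOGRAM_1, PARALLELOGRAM_2),
        excluded=(ORI_X_RANGE, ORI_Y_RANGE),
        double_count_overlap=double_count_overlap,
        name="ch1-ch2-alignment",
    )


def _parallelogram_row_range(verts, y: int) -> Optional[tuple[int, int]]:
    """Inclusive x-range of a vertical-sided parallelogram at row y, or None."""
    ys = [v[1] for v in verts]
    y_lo, y_hi = min(ys), max(ys)
    if not (y_lo <= y <= y_hi):
        return None
    # the two edges of constant slope connect top corners to bottom corners
    (x1, ya), (x2, _), (x3, yb), (x4, _) = verts
    # interpolate both slanted edges at this row
    t = (y - ya) / (yb - ya)
    lo = x1 + t * (x3 - x1)
    hi = x2 + t * (x4 - x2)
    if lo > hi:
        lo, hi = hi, lo
    return math.ceil(lo - 1e-9), math.floor(hi + 1e-9)


def _in_excluded(region: QuantRegion, x: int, y: int) -> bool:
    if region.excluded is None:
        return False
    (xl, xh), (yl, yh) = region.excluded
    return xl <= x <= xh and yl <= y <= yh


def region_membership(region: QuantRegion, n_bins: int) -> list[tuple[int, int]]:
    """Integer (x, y) bin pairs inside the region, boundary inclusive.

    With ``double_count_overlap`` the overlap of the two parallelograms is
    listed twice.  All pairs must lie within [1, n_bins]^2.
    """
    pairs: list[tuple[int, int]] = []
    if region.kind == "rectangle":
        xl, xh = region.x_range
        yl, yh = region.y_range
        if not (1 <= xl <= xh <= n_bins and 1 <= yl <= yh <= n_bins):
            raise ValueError("rectangle outside matrix bounds")
        for y in range(yl, yh + 1):
            for x in range(xl, xh + 1):
                if not _in_excluded(region, x, y):
                    pairs.append((x, y))
        return pairs

    ys = sorted({v[1] for p in region.parallelograms for v in p})
    if ys[0] < 1 or ys[-1] > n_bins:
        raise ValueError("parallelogram vertices outside matrix bounds")
    for y in range(ys[0], ys[-1] + 1):
        ranges = [_parallelogram_row_range(p, y) for p in region.parallelograms]
        ranges = [r for r in ranges if r is not None]
        if region.double_count_overlap:
            for lo, hi in ranges:
                for x in range(lo, hi + 1):
                    if not _in_excluded(region, x, y):
                        pairs.append((x, y))
        else:
            xs: set[int] = set()
            for lo, hi in ranges:
                xs.update(range(lo, hi + 1))
            for x in sorted(xs):
                if not _in_excluded(region, x, y):
                    pairs.append((x, y))
    for x, y in pairs:
        if not (1 <= x <= n_bins and 1 <= y <= n_bins):
            raise ValueError(f"region pair ({x}, {y}) outside matrix bounds")
    return pairs


def region_sum(cmap: ContactMap, region: QuantRegion) -> float:
    """2 x sum of map scores over the region (mirror across the diagonal).

    Warns if the region touches the main diagonal, where the mirror factor
    would double-count.
    """
    pairs = region_membership(region, cmap.n_bins)
    if any(x == y for x, y in pairs):
        warnings.warn(
            "quantification region touches the main diagonal; "
            "mirror factor double-counts diagonal entries",
            stacklevel=2,
        )
    m = cmap.matrix
    s = sum(m[y - 1, x - 1] for x, y in pairs)
    return 2.0 * float(s)


def ori_interaction_score(cmap: ContactMap) -> float:
    """Doubled score sum over the origin-origin rectangle."""
    if cmap.n_bins < ORI_Y_RANGE[1]:
        raise ValueError(
            f"map has {cmap.n_bins} bins; origin rectangle needs >= {ORI_Y_RANGE[1]}"
        )
    return region_sum(cmap, ori_rectangle())


def alignment_score(cmap: ContactMap, double_count_overlap: bool = False) -> float:
    """Doubled score sum over the chromosome-alignment area."""
    ymax = max(v[1] for p in (PARALLELOGRAM_1, PARALLELOGRAM_2) for v in p)
    if cmap.n_bins < ymax:
        raise ValueError(f"map has {cmap.n_bins} bins; alignment area needs >= {ymax}")
    return region_sum(cmap, alignment_region(double_count_overlap))


def relative_interaction(s_sample: float, s_wt: float, s_bg: float) -> float:
    """Percent of the wild-type score after background subtraction.

    100 * (S_sample - S_bg) / (S_wt - S_bg).  The reference scores fix the
    scale: the wild type maps to 100, the background to 0; values below 0
    or above 100 are legitimate.
    """
    if s_wt == s_bg:
        raise ValueError("wild-type and background scores are equal; scale undefined")
    # ratio first: sample == wt then gives exactly 100.0, sample == bg exactly 0.0
    return 100.0 * ((s_sample - s_bg) / (s_wt - s_bg))
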