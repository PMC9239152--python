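"""Multipartite genome coordinate system and binning.

The genome is an ordered list of replicons, each with its own 1-based
coordinate system.  Bins are fixed-width (the last bin of a replicon may be
partial) and indexed globally, 1-based, in replicon order.  The primary
(circular) chromosome may be rotated so that a chosen coordinate becomes
position 1; this places its replication origin near the centre of its bin
range, which is how published contact maps for this genome are displayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "RepliconSpec",
    "GenomeLayout",
    "build_layout",
    "default_layout",
    "rearrange_ch1",
    "unrearrange_ch1",
    "coord_to_global_bin",
]


@dataclass(frozen=True)
class RepliconSpec:
    """One replicon: name, length in bp, topology, optional origin position.

    ``origin_pos`` refers to the native (un-rotated) reference coordinate,
    1-based.
    """

    name: str
    length: int
    topology: str = "circular"
    origin_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"replicon {self.name!r}: length must be positive")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"replicon {self.name!r}: bad topology {self.topology!r}")
        if self.origin_pos is not None and not (1 <= self.origin_pos <= self.length):
            raise ValueError(
                f"replicon {self.name!r}: origin_pos {self.origin_pos} outside [1, {self.length}]"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered replicons plus the global bin index map.

    ``bin_ranges`` maps replicon name to an inclusive 1-based global bin
    range ``(first, last)``.  ``ch1_start_offset`` is the rotation applied to
    the first replicon's coordinates before binning (0 disables it).
    """

    replicons: tuple[RepliconSpec, ...]
    bin_size: int = 10_000
    ch1_start_offset: int = 1_400_000
    bin_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_bins: int = 0

    def replicon(self, name: str) -> RepliconSpec:
        for rep in self.replicons:
            if rep.name == name:
                return rep
        raise KeyError(f"unknown replicon {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.replicons)

    def n_bins_of(self, name: str) -> int:
        first, last = self.bin_ranges[name]
        return last - first + 1

    def is_rearranged(self, name: str) -> bool:
        """True if coordinates of this replicon are rotated before binning."""
        rep = self.replicons[0]
        return (
            name == rep.name
            and rep.topology == "circular"
            and self.ch1_start_offset != 0
        )

    def origin_bin(self, name: str) -> int:
        """Global bin holding the replicon's origin (after any rotation)."""
        rep = self.replicon(name)
        if rep.origin_pos is None:
            raise ValueError(f"replicon {name!r} has no origin_pos")
        return coord_to_global_bin(name, rep.origin_pos, self)

    def bin_to_replicon(self, global_bin: int) -> tuple[str, int]:
        """Map a global bin back to (replicon name, local 1-based bin)."""
        for name, (first, last) in self.bin_ranges.items():
            if first <= global_bin <= last:
                return name, global_bin - first + 1
        raise ValueError(f"global bin {global_bin} outside [1, {self.n_bins}]")


def build_layout(
    replicons: Sequence[RepliconSpec],
    bin_size: int = 10_000,
    ch1_start_offset: int = 1_400_000,
) -> GenomeLayout:
    """Assign contiguous global bin ranges to replicons in order.

    Bins per replicon is ``ceil(length / bin_size)``; a partial final bin is
    kept as its own bin.
    """
    if not replicons:
        raise ValueError("empty replicon list")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if ch1_start_offset < 0:
        raise ValueError("ch1_start_offset must be >= 0")
    ranges: dict[str, tuple[int, int]] = {}
    nxt = 1
    for rep in replicons:
        nb = math.ceil(rep.length / bin_size)
        ranges[rep.name] = (nxt, nxt + nb - 1)
        nxt += nb
    return GenomeLayout(
        replicons=tuple(replicons),
        bin_size=bin_size,
        ch1_start_offset=ch1_start_offset,
        bin_ranges=ranges,
        n_bins=nxt - 1,
    )


# Default C58-like four-replicon genome.  Origin positions are placed so
# that, at 10-kb bins with the 1,400-kb rotation, the origins fall at global
# bins 143 (Ch1), 382 (Ch2), 521 (pAt) and 559 (pTi) — inside the published
# quantification windows.
_C58_REPLICONS = (
    RepliconSpec("Ch1", 2_841_000, "circular", origin_pos=2_825_000),
    RepliconSpec("Ch2", 2_076_000, "linear", origin_pos=965_000),
    RepliconSpec("pAt", 542_000, "circular", origin_pos=271_000),
    RepliconSpec("pTi", 216_000, "circular", origin_pos=108_000),
)


def default_layout(bin_size: int = 10_000, ch1_start_offset: int = 1_400_000) -> GenomeLayout:
    """The bundled four-replicon layout (Ch1, Ch2, pAt, pTi at 10-kb bins)."""
    return build_layout(_C58_REPLICONS, bin_size=bin_size, ch1_start_offset=ch1_start_offset)


def rearrange_ch1(pos: int, layout: GenomeLayout) -> int:
    """Rotate a native primary-chromosome coordinate by the layout offset.

    Returns ``((pos - 1 - offset) mod L) + 1`` where L is the length of the
    first replicon.  With offset 0 this is the identity.
    """
    rep = layout.replicons[0]
    if not (1 <= pos <= rep.length):
        raise ValueError(f"position {pos} outside [1, {rep.length}] on {rep.name}")
    return (pos - 1 - layout.ch1_start_offset) % rep.length + 1


def unrearrange_ch1(pos: int, layout: GenomeLayout) -> int:
    """Inverse of :func:`rearrange_ch1`."""
    rep = layout.replicons[0]
    if not (1 <= pos <= rep.length):
        raise ValueError(f"position {pos} outside [1, {rep.length}] on {rep.name}")
    return (pos - 1 + layout.ch1_start_offset) % rep.length + 1


def coord_to_global_bin(replicon: str, pos: int, layout: GenomeLayout) -> int:
    """Map (replicon, 1-based position) to the global 1-based bin index.

    Coordinates on the rotated primary chromosome are rearranged first.
    """
    rep = layout.replicon(replicon)
    if not (1 <= pos <= rep.length):
        raise ValueError(f"position {pos} outside [1, {rep.length}] on {replicon}")
    if layout.is_rearranged(replicon):
        pos = rearrange_ch1(pos, layout)
    first, _ = layout.bin_ranges[replicon]
    return first + (pos - 1) // layout.bin_size
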