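"""ChIP/input enrichment tracks, binning and peak quantification.

Both libraries are normalized to their total read counts; enrichment is the
per-base-pair ratio of the normalized coverages.  Positions with zero input
coverage are masked (NaN) unless a pseudocount is supplied.  Peaks are
summarized as above-baseline area, which is linear in occupancy and robust
to window width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "CoverageTrack",
    "EnrichmentTrack",
    "enrichment",
    "bin_track",
    "peak_score",
    "relative_enrichment",
]


@dataclass
class CoverageTrack:
    """Per-base-pair nonnegative read counts, one array per replicon."""

    counts: dict[str, np.ndarray]
    label: str = ""
    total_reads: Optional[float] = None

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, arr in self.counts.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"track {name!r} must be 1-D")
            if (a < 0).any():
                raise ValueError(f"track {name!r} has negative counts")
            clean[name] = a
        self.counts = clean
        if self.total_reads is None:
            self.total_reads = float(sum(a.sum() for a in clean.values()))

    @property
    def replicons(self) -> tuple[str, ...]:
        return tuple(self.counts)


@dataclass
class EnrichmentTrack:
    """Per-base-pair ChIP/input ratios; masked positions are NaN."""

    values: dict[str, np.ndarray]
    bin_size: int = 1

    def mask(self, replicon: str) -> np.ndarray:
        return np.isnan(self.values[replicon])


def enrichment(
    chip: CoverageTrack,
    inp: CoverageTrack,
    pseudocount: float = 0.0,
) -> EnrichmentTrack:
    """Per-bp (chip/chip_total) / (input/input_total).

    Zero-input positions are masked unless ``pseudocount`` > 0, in which
    case it is added to both per-bp counts before normalization.
    """
    if set(chip.counts) != set(inp.counts):
        raise ValueError("chip and input tracks cover different replicons")
    if chip.total_reads <= 0 or inp.total_reads <= 0:
        raise ValueError("zero-total track cannot be normalized")
    out: dict[str, np.ndarray] = {}
    for name, c in chip.counts.items():
        i = inp.counts[name]
        if c.shape != i.shape:
            raise ValueError(f"replicon {name!r}: length mismatch between chip and input")
        cn = (c + pseudocount) / chip.total_reads
        im = (i + pseudocount) / inp.total_reads
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cn / im
        r[im == 0] = np.nan
        out[name] = r
    return EnrichmentTrack(values=out, bin_size=1)


def bin_track(track: EnrichmentTrack, bin_size: int) -> dict[str, np.ndarray]:
    """Mean of unmasked per-bp values in fixed-size bins (partial last bin ok).

    Fully-masked bins come back as NaN.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    out: dict[str, np.ndarray] = {}
    for name, vals in track.values.items():
        n = len(vals)
        nb = -(-n // bin_size)
        binned = np.full(nb, np.nan)
        for b in range(nb):
            chunk = vals[b * bin_size : (b + 1) * bin_size]
            if np.isfinite(chunk).any():
                binned[b] = np.nanmean(chunk)
        out[name] = binned
    return out


def peak_score(
    track: EnrichmentTrack,
    window: tuple[str, int, int],
    baseline: float = 1.0,
) -> float:
    """Sum of max(value - baseline, 0) over unmasked bp in a 1-based window."""
    replicon, start, end = window
    if replicon not in track.values:
        raise KeyError(f"unknown replicon {replicon!r}")
    vals = track.values[replicon]
    if not (1 <= start <= end <= len(vals)):
        raise ValueError(f"window [{start}, {end}] outside replicon of {len(vals)} bp")
    w = vals[start - 1 : end]
    finite = w[np.isfinite(w)]
    if finite.size == 0:
        raise ValueError("window is fully masked")
    return float(np.clip(finite - baseline, 0.0, None).sum())


def relative_enrichment(sample_score: float, reference_score: float) -> float:
    """Sample peak score as a percentage of the reference peak score."""
    if reference_score <= 0:
        raise ValueError("reference score must be positive")
    return 100.0 * sample_score / reference_score
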