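"""Synthetic contact maps, contact records, ChIP tracks and focus tables.

The generators produce data with the statistical structure the analysis
modules assume — intrareplicon distance decay, interarm anti-diagonals,
origin-clustering blocks, an X-shaped interchromosomal alignment band,
ChIP peaks over Poisson background, and per-cell focus tables with tunable
colocalization — so the full pipeline can be exercised and validated
without any external data.

All generators are deterministic given their seed.  Feature strengths act
additively on the expected contact map, so region sums respond linearly to
them; this is what makes parameter-recovery tests exact on noiseless maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .foci_analysis import Cell
from .chip_quant import CoverageTrack
from .genome_model import GenomeLayout
from .hic_pipeline import ContactMap, ContactRecord

__all__ = [
    "MapModelParams",
    "ChipModelParams",
    "FociModelParams",
    "simulate_contact_map",
    "simulate_contact_records",
    "simulate_chip_tracks",
    "simulate_foci",
]


# ---------------------------------------------------------------------------
# contact maps


@dataclass(frozen=True)
class MapModelParams:
    """Knobs for the expected contact-map model.

    The expected entry for an intrareplicon pair at bin distance d is
    ``background + (d + 1) ** -decay_exponent`` (circular distance on
    circular replicons); interarm, origin-cluster and alignment strengths
    are added on their designated regions only.  ``noise_pairs`` > 0
    returns a multinomial sample of that many contacts instead of the
    expected map.
    """

    decay_exponent: float = 1.0
    interarm_strength: float = 0.5
    ori_cluster_strength: float = 1.0
    alignment_strength: float = 0.5
    background: float = 0.01
    noise_pairs: int = 0
    seed: int = 0
    band_halfwidth: int = 25  # half-width of interarm / alignment bands, bins
    ori_halfwidth: int = 20  # origin neighbourhood half-width, bins

    def validate(self) -> None:
        for name in (
            "interarm_strength",
            "ori_cluster_strength",
            "alignment_strength",
            "background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_pairs < 0:
            raise ValueError("noise_pairs must be >= 0")
        if self.band_halfwidth < 0 or self.ori_halfwidth < 0:
            raise ValueError("band widths must be >= 0")


def _local_bins(layout: GenomeLayout, name: str) -> tuple[int, int]:
    first, last = layout.bin_ranges[name]
    return first, last


def _ori_window(layout: GenomeLayout, name: str, halfwidth: int) -> tuple[int, int]:
    """Global bin window around a replicon's origin, clipped to the replicon."""
    first, last = layout.bin_ranges[name]
    ob = layout.origin_bin(name)
    return max(first, ob - halfwidth), min(last, ob + halfwidth)


def expected_contact_map(layout: GenomeLayout, params: MapModelParams) -> np.ndarray:
    """Dense expected (noise-free) contact matrix for the model."""
    params.validate()
    n = layout.n_bins
    m = np.full((n, n), params.background, dtype=float)

    # intrareplicon distance decay
    for rep in layout.replicons:
        first, last = _local_bins(layout, rep.name)
        nb = last - first + 1
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :])
        if rep.topology == "circular":
            d = np.minimum(d, nb - d)
        m[first - 1 : last, first - 1 : last] += (d + 1.0) ** (-params.decay_exponent)

    # interarm anti-diagonal (reflection about the origin) on the two chromosomes
    if params.interarm_strength > 0:
        for rep in layout.replicons[:2]:
            if rep.origin_pos is None:
                continue
            first, last = _local_bins(layout, rep.name)
            ob = layout.origin_bin(rep.name)
            idx = np.arange(first, last + 1)
            s = idx[:, None] + idx[None, :]
            band = np.abs(s - 2 * ob) <= params.band_halfwidth
            m[first - 1 : last, first - 1 : last][band] += params.interarm_strength

    # origin-cluster blocks for every pair of distinct replicons
    if params.ori_cluster_strength > 0:
        wins = [
            _ori_window(layout, rep.name, params.ori_halfwidth)
            for rep in layout.replicons
            if rep.origin_pos is not None
        ]
        for a in range(len(wins)):
            for b in range(a + 1, len(wins)):
                (al, ah), (bl, bh) = wins[a], wins[b]
                m[bl - 1 : bh, al - 1 : ah] += params.ori_cluster_strength
                m[al - 1 : ah, bl - 1 : bh] += params.ori_cluster_strength

    # X-shaped Ch1-Ch2 alignment: bins equidistant from the two origins
    if params.alignment_strength > 0 and len(layout.replicons) >= 2:
        r1, r2 = layout.replicons[0], layout.replicons[1]
        if r1.origin_pos is not None and r2.origin_pos is not None:
            f1, l1 = _local_bins(layout, r1.name)
            f2, l2 = _local_bins(layout, r2.name)
            o1, o2 = layout.origin_bin(r1.name), layout.origin_bin(r2.name)
            x = np.arange(f1, l1 + 1)
            y = np.arange(f2, l2 + 1)
            dx = x[None, :] - o1  # columns: Ch1
            dy = y[:, None] - o2  # rows: Ch2
            band = (np.abs(dy - dx) <= params.band_halfwidth) | (
                np.abs(dy + dx) <= params.band_halfwidth
            )
            m[f2 - 1 : l2, f1 - 1 : l1][band] += params.alignment_strength
            m[f1 - 1 : l1, f2 - 1 : l2][band.T] += params.alignment_strength

    return m


def _sample_symmetric(expected: np.ndarray, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sample of unordered bin pairs; returns a symmetric count matrix."""
    n = expected.shape[0]
    iu, ju = np.triu_indices(n)
    w = expected[iu, ju].astype(float)
    w[iu != ju] *= 2.0  # unordered off-diagonal pairs have both orientations
    total = w.sum()
    if total <= 0:
        raise ValueError("expected map has zero total; cannot sample")
    counts = rng.multinomial(n_pairs, w / total)
    m = np.zeros_like(expected)
    m[iu, ju] = counts
    return m + m.T  # diagonal doubles: one record adds 2 to m[i,i]


def simulate_contact_map(layout: GenomeLayout, params: MapModelParams) -> ContactMap:
    """Expected map, or a seeded multinomial sample of it when noise_pairs > 0."""
    expected = expected_contact_map(layout, params)
    if params.noise_pairs == 0:
        return ContactMap(matrix=expected, layout=layout, normalized=False)
    rng = np.random.default_rng(params.seed)
    sampled = _sample_symmetric(expected, params.noise_pairs, rng)
    return ContactMap(matrix=sampled, layout=layout, normalized=False)


def _bin_extent(layout: GenomeLayout, global_bin: int) -> tuple[str, int, int]:
    """Replicon and inclusive bp extent of a global bin, in binning coordinates."""
    name, local = layout.bin_to_replicon(global_bin)
    rep = layout.replicon(name)
    start = (local - 1) * layout.bin_size + 1
    end = min(local * layout.bin_size, rep.length)
    return name, start, end


def simulate_contact_records(
    cmap: ContactMap, n_pairs: int, seed: int = 0
) -> list[ContactRecord]:
    """Draw contact records whose bin pairs follow the map's probabilities.

    Coordinates are uniform within bins; positions on the rotated primary
    chromosome are emitted in native reference coordinates, so re-binning
    the records reproduces the drawn bin pairs.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if n_pairs == 0:
        return []
    layout = cmap.layout
    rng = np.random.default_rng(seed)
    n = cmap.n_bins
    iu, ju = np.triu_indices(n)
    w = cmap.matrix[iu, ju].astype(float)
    w[iu != ju] *= 2.0
    total = w.sum()
    if total <= 0:
        raise ValueError("contact map has zero total; cannot sample records")
    counts = rng.multinomial(n_pairs, w / total)
    ks = np.nonzero(counts)[0]
    b1 = np.repeat(iu[ks] + 1, counts[ks])
    b2 = np.repeat(ju[ks] + 1, counts[ks])

    # per-global-bin lookup tables for vectorised coordinate draws
    names = np.empty(n, dtype=object)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    rearranged = np.zeros(n, dtype=bool)
    for b in range(1, n + 1):
        name, lo_b, hi_b = _bin_extent(layout, b)
        names[b - 1], lo[b - 1], hi[b - 1] = name, lo_b, hi_b
        rearranged[b - 1] = layout.is_rearranged(name)

    def _draw(bins: np.ndarray) -> np.ndarray:
        idx = bins - 1
        pos = rng.integers(lo[idx], hi[idx] + 1)
        if rearranged.any():
            rot = rearranged[idx]
            rep0 = layout.replicons[0]
            pos[rot] = (pos[rot] - 1 + layout.ch1_start_offset) % rep0.length + 1
        return pos

    p1, p2 = _draw(b1), _draw(b2)
    return [
        ContactRecord(names[i1 - 1], int(x1), names[i2 - 1], int(x2))
        for i1, x1, i2, x2 in zip(b1, p1, b2, p2)
    ]


# ---------------------------------------------------------------------------
# ChIP tracks


@dataclass(frozen=True)
class ChipModelParams:
    """Peak list plus background rate and library sizes for track simulation.

    Each peak is (replicon, position, height, width): a Gaussian of the
    given height (in multiples of the background rate) and standard
    deviation ``width`` bp, centred at ``position`` on the native reference.
    """

    peak_sites: tuple[tuple[str, int, float, float], ...] = ()
    background_rate: float = 1.0
    library_sizes: tuple[float, float] = (4e7, 4e7)  # (chip, input)
    seed: int = 0

    def validate(self) -> None:
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        for rep, pos, height, width in self.peak_sites:
            if height < 0:
                raise ValueError(f"peak at {rep}:{pos}: height must be >= 0")
            if width <= 0:
                raise ValueError(f"peak at {rep}:{pos}: width must be positive")
        if any(s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive")


def simulate_chip_tracks(
    layout: GenomeLayout, params: ChipModelParams
) -> tuple[CoverageTrack, CoverageTrack]:
    """Seeded Poisson (chip, input) coverage tracks.

    The input rate is flat; the chip rate adds the Gaussian peaks.  Both
    rate profiles are scaled so their expected totals equal the requested
    library sizes before Poisson sampling.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    bg = params.background_rate
    input_rate: dict[str, np.ndarray] = {}
    chip_rate: dict[str, np.ndarray] = {}
    for rep in layout.replicons:
        input_rate[rep.name] = np.full(rep.length, bg)
        chip_rate[rep.name] = np.full(rep.length, bg)
    for rep_name, pos, height, width in params.peak_sites:
        rep = layout.replicon(rep_name)
        if not (1 <= pos <= rep.length):
            raise ValueError(f"peak position {pos} outside {rep_name}")
        x = np.arange(1, rep.length + 1)
        chip_rate[rep_name] += bg * height * np.exp(-0.5 * ((x - pos) / width) ** 2)

    def _sample(rate: dict[str, np.ndarray], lib: float, label: str) -> CoverageTrack:
        tot = sum(a.sum() for a in rate.values())
        scale = lib / tot
        counts = {name: rng.poisson(a * scale).astype(float) for name, a in rate.items()}
        return CoverageTrack(counts=counts, label=label)

    chip = _sample(chip_rate, params.library_sizes[0], "chip")
    inp = _sample(input_rate, params.library_sizes[1], "input")
    return chip, inp


# ---------------------------------------------------------------------------
# focus tables


@dataclass(frozen=True)
class FociModelParams:
    """Controls for per-cell focus-table simulation.

    ``count_dist`` maps per-cell focus number to probability (applies to the
    green channel; each green focus yields one red focus).  With probability
    ``coloc_prob`` a red focus is placed uniformly within ``coloc_jitter_px``
    of its green partner; otherwise it lands uniformly in the cell.  Green
    foci are drawn near a randomly chosen pole with half-normal spread
    ``polar_sigma_px`` along the cell axis.
    """

    n_cells: int = 1000
    coloc_prob: float = 0.9
    coloc_jitter_px: float = 2.0
    polar_sigma_px: float = 10.0
    count_dist: tuple[tuple[int, float], ...] = ((1, 1.0),)
    cell_length_px: float = 120.0
    cell_width_px: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0.0 <= self.coloc_prob <= 1.0):
            raise ValueError("coloc_prob must be in [0, 1]")
        if self.coloc_jitter_px < 0 or self.polar_sigma_px < 0:
            raise ValueError("pixel spreads must be >= 0")
        probs = [p for _, p in self.count_dist]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("count_dist probabilities must be >= 0 and sum to 1")
        if self.cell_length_px <= 0 or self.cell_width_px <= 0:
            raise ValueError("cell dimensions must be positive")


def simulate_foci(params: FociModelParams) -> list[Cell]:
    """Seeded per-cell focus tables with tunable colocalization."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    length, width = params.cell_length_px, params.cell_width_px
    counts = np.array([c for c, _ in params.count_dist])
    probs = np.array([p for _, p in params.count_dist])
    cells: list[Cell] = []
    for ci in range(params.n_cells):
        pole_a = (0.0, width / 2.0)
        pole_b = (length, width / 2.0)
        n_green = int(rng.choice(counts, p=probs))
        greens: list[tuple[float, float]] = []
        reds: list[tuple[float, float]] = []
        for _ in range(n_green):
            # half-normal displacement from a random pole along the axis
            dx = min(abs(rng.normal(0.0, params.polar_sigma_px)), length)
            gx = dx if rng.random() < 0.5 else length - dx
            gy = float(np.clip(rng.normal(width / 2.0, width / 8.0), 0.0, width))
            greens.append((gx, gy))
            if rng.random() < params.coloc_prob:
                # partner uniform in the disk of radius coloc_jitter_px
                r = params.coloc_jitter_px * np.sqrt(rng.random())
                theta = rng.random() * 2.0 * np.pi
                reds.append((gx + r * np.cos(theta), gy + r * np.sin(theta)))
            else:
                reds.append((rng.random() * length, rng.random() * width))
        cells.append(
            Cell(
                id=f"cell{ci:05d}",
                pole_a=pole_a,
                pole_b=pole_b,
                length=length,
                width=width,
                foci={"green": greens, "red": reds},
            )
        )
    return cells
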