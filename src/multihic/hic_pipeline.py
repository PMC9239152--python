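"""Contact-map construction and iterative normalization.

Raw maps are built by assigning each contact record to a pair of global
bins; normalization repeats the per-sweep update

    m_ij <- m_ij * T / (R_i * R_j)

(T = total score, R_i = marginal of bin i) until the maximum relative error
of the bin marginals is below tolerance, then rescales so every non-masked
row and column sums to 1.  Bins with zero raw marginal are masked: they are
left at zero and excluded from the convergence criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .genome_model import GenomeLayout, coord_to_global_bin

__all__ = [
    "ContactRecord",
    "ContactMap",
    "filter_pairs",
    "bin_contacts",
    "ice_normalize",
    "IceNotConverged",
]


class ContactRecord(NamedTuple):
    """One contact: two (replicon, coordinate) sides with optional fragment ids."""

    replicon1: str
    pos1: int
    replicon2: str
    pos2: int
    frag1: Optional[str] = None
    frag2: Optional[str] = None


@dataclass
class ContactMap:
    """Symmetric dense matrix of interaction scores over global bins."""

    matrix: np.ndarray
    layout: GenomeLayout
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"matrix must be square, got shape {m.shape}")
        if m.shape[0] != self.layout.n_bins:
            raise ValueError(
                f"matrix dimension {m.shape[0]} != layout n_bins {self.layout.n_bins}"
            )
        if (m < 0).any():
            raise ValueError("contact matrix has negative entries")
        self.matrix = m

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "ContactMap":
        return replace(self, matrix=self.matrix.copy())


class IceNotConverged(RuntimeError):
    """Raised when balancing does not reach tolerance within max_iter sweeps."""

    def __init__(self, result: "ContactMap", err: float, n_iter: int):
        self.result = result
        self.err = err
        self.n_iter = n_iter
        super().__init__(
            f"iterative normalization did not converge: relative error "
            f"{err:.3g} after {n_iter} sweeps"
        )


def filter_pairs(
    records: Sequence[ContactRecord],
) -> tuple[list[ContactRecord], dict[str, int]]:
    """Drop records whose two sides map to the same restriction fragment.

    Records without fragment ids pass through.  Returns the kept records and
    a class-count dict (``valid`` / ``same_fragment``).  This is a
    deliberately simplified stand-in for full ligation-product
    classification, which requires fragment maps and read orientations.
    """
    kept: list[ContactRecord] = []
    counts = {"valid": 0, "same_fragment": 0}
    for rec in records:
        if rec.frag1 is not None and rec.frag2 is not None and rec.frag1 == rec.frag2:
            counts["same_fragment"] += 1
        else:
            counts["valid"] += 1
            kept.append(rec)
    return kept, counts


def bin_contacts(records: Sequence[ContactRecord], layout: GenomeLayout) -> ContactMap:
    """Accumulate contact records into a raw symmetric matrix.

    Each record adds 1 to m[i,j] and 1 to m[j,i] (2 to the diagonal when
    i == j), so the matrix total is twice the record count.
    """
    n = layout.n_bins
    m = np.zeros((n, n), dtype=float)
    for rec in records:
        i = coord_to_global_bin(rec.replicon1, rec.pos1, layout) - 1
        j = coord_to_global_bin(rec.replicon2, rec.pos2, layout) - 1
        m[i, j] += 1.0
        m[j, i] += 1.0
    return ContactMap(matrix=m, layout=layout, normalized=False)


def ice_normalize(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 1000,
) -> ContactMap:
    """Balance a raw symmetric map so each unmasked row/column sums to 1.

    Per sweep, T, R are recomputed once and every entry is updated with
    m_ij * T/(R_i * R_j); convergence requires
    max_i |R_i - T/n| / (T/n) < tol over unmasked bins.  The converged map
    is divided by the common marginal so row sums equal 1.  Symmetry of the
    input is preserved exactly.
    """
    m = cmap.matrix.astype(float).copy()
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix must be symmetric")
    marg = m.sum(axis=1)
    mask = marg > 0  # unmappable/empty bins stay zero
    if not mask.any():
        raise ValueError("contact matrix has zero total; cannot normalize")
    n_eff = int(mask.sum())

    err = np.inf
    for _ in range(max_iter):
        row = m.sum(axis=1)
        total = row.sum()
        target = total / n_eff
        err = float(np.abs(row[mask] - target).max() / target)
        if err < tol:
            break
        factor = np.ones_like(row)
        factor[mask] = row[mask]
        m *= total / np.outer(factor, factor)
        m[~mask, :] = 0.0
        m[:, ~mask] = 0.0
    else:
        row = m.sum(axis=1)
        target = row.sum() / n_eff
        err = float(np.abs(row[mask] - target).max() / target)
        if err >= tol:
            partial = ContactMap(matrix=m / target, layout=cmap.layout, normalized=False)
            raise IceNotConverged(partial, err, max_iter)

    # single scalar rescale: preserves symmetry, sets common row sum to 1
    row = m.sum(axis=1)
    m /= row.sum() / n_eff
    out = ContactMap(matrix=m, layout=cmap.layout, normalized=True)
    return out
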