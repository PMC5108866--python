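"""Chaos Game Representation (CGR) point sets and FCGR k-mer matrices.

The chaos game walk starts at the centre of the unit square and moves
halfway toward the corner of each successive base; subsquare occupancy at
depth k is in one-to-one correspondence with k-mer counts, so the FCGR
matrix can be built either by binning CGR points or by direct k-mer
counting.  Both routes are provided and must agree — that equivalence is
the module's central invariant.

Corner assignment follows Jeffrey's convention: A=(0,0), C=(0,1), G=(1,1),
T=(1,0).  The map is configurable and stamped into every output so a plot
or matrix is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .seqio import SeqRecord, UNAMBIGUOUS

__all__ = [
    "CornerMap",
    "JEFFREY_CORNERS",
    "CGRPointSet",
    "FCGRMatrix",
    "cgr_points",
    "fcgr_matrix",
    "fcgr_from_points",
    "kmer_cell",
    "cell_labels",
]


class CGRError(ValueError):
    pass


@dataclass(frozen=True)
class CornerMap:
    """Assignment of the four bases to the unit square's corners."""

    a: tuple[float, float]
    c: tuple[float, float]
    g: tuple[float, float]
    t: tuple[float, float]

    def __post_init__(self) -> None:
        corners = {self.a, self.c, self.g, self.t}
        if len(corners) != 4 or corners != {(0, 0), (0, 1), (1, 0), (1, 1)}:
            raise CGRError("corners must be the four distinct corners of [0,1]^2")

    def corner(self, base: str) -> tuple[float, float]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}


JEFFREY_CORNERS = CornerMap(a=(0, 0), c=(0, 1), g=(1, 1), t=(1, 0))


@dataclass(frozen=True)
class CGRPointSet:
    """Ordered CGR walk points for one record (one point per processed base)."""

    points: np.ndarray = field(repr=False)  # (n, 2) in (0,1)^2
    record_id: str = ""
    corners: CornerMap = JEFFREY_CORNERS
    n_skipped: int = 0  # ambiguity codes skipped (walk state preserved)


@dataclass(frozen=True)
class FCGRMatrix:
    """2^k x 2^k k-mer count grid addressed by CGR quadrant recursion.

    ``counts[row, col]``: row 0 / col 0 is the subsquare touching y=0 / x=0,
    i.e. the A corner under the default map (orientation is part of the
    object so renderers can label it).
    """

    k: int
    counts: np.ndarray = field(repr=False)
    corners: CornerMap = JEFFREY_CORNERS
    record_id: str = ""

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def cgr_points(record: SeqRecord, corners: CornerMap = JEFFREY_CORNERS) -> CGRPointSet:
    """The chaos-game walk: p_i = (p_{i-1} + corner(s_i)) / 2, p_0 = centre.

    Ambiguity codes are skipped without resetting the walk, so the point
    count equals the number of unambiguous bases.
    """
    xs, ys = [], []
    x, y = 0.5, 0.5
    skipped = 0
    cmap = corners.as_dict()
    for b in record.residues:
        cn = cmap.get(b)
        if cn is None:
            skipped += 1
            continue
        x = (x + cn[0]) / 2.0
        y = (y + cn[1]) / 2.0
        xs.append(x)
        ys.append(y)
    if not xs:
        raise CGRError(f"record {record.id!r} has no unambiguous bases")
    return CGRPointSet(points=np.column_stack([xs, ys]), record_id=record.id,
                       corners=corners, n_skipped=skipped)


def kmer_cell(kmer: str, corners: CornerMap = JEFFREY_CORNERS) -> tuple[int, int]:
    """(row, col) of a k-mer's depth-k CGR subsquare.

    The most recent base sets the coarsest quadrant: for w_1..w_k the column
    index is sum_j x(w_j) * 2^(j-1) and likewise for rows, which is exactly
    where the CGR walk lands after reading w.
    """
    col = row = 0
    for j, b in enumerate(kmer):
        if b not in UNAMBIGUOUS:
            raise CGRError(f"k-mer {kmer!r} contains an ambiguity code")
        cx, cy = corners.corner(b)
        col += int(cx) << j
        row += int(cy) << j
    return row, col


def cell_labels(k: int, corners: CornerMap = JEFFREY_CORNERS) -> np.ndarray:
    """2^k x 2^k array of the k-mer owning each cell (for CSV headers, tests)."""
    side = 1 << k
    labels = np.empty((side, side), dtype=object)
    for kmer in ("".join(p) for p in product("ACGT", repeat=k)):
        r, c = kmer_cell(kmer, corners)
        labels[r, c] = kmer
    return labels


def fcgr_matrix(record: SeqRecord, k: int = 2,
                corners: CornerMap = JEFFREY_CORNERS) -> FCGRMatrix:
    """Count every overlapping k-mer into its CGR subsquare.

    k-mers spanning an ambiguity code are dropped, so on a record with a
    single contiguous unambiguous run the total is L_eff - k + 1.
    """
    if k < 1:
        raise CGRError(f"k must be >= 1, got {k}")
    s = record.residues
    side = 1 << k
    counts = np.zeros((side, side), dtype=np.int64)
    # incremental row/col update: shift in the newest base at weight 2^(k-1)
    run = 0
    row = col = 0
    half = 1 << (k - 1)
    mask = side - 1
    for b in s:
        if b not in UNAMBIGUOUS:
            run = 0
            row = col = 0
            continue
        cx, cy = corners.corner(b)
        col = (col >> 1) | (int(cx) * half)
        row = (row >> 1) | (int(cy) * half)
        run += 1
        if run >= k:
            counts[row & mask, col & mask] += 1
    if counts.sum() == 0:
        raise CGRError(
            f"record {record.id!r} has no {k} contiguous unambiguous bases")
    return FCGRMatrix(k=k, counts=counts, corners=corners, record_id=record.id)


def fcgr_from_points(points: CGRPointSet, k: int,
                     corners: CornerMap = JEFFREY_CORNERS) -> FCGRMatrix:
    """FCGR by binning CGR points at resolution 2^k (points i >= k only).

    Equals :func:`fcgr_matrix` on ambiguity-free input.  The point set must
    have been generated with the same corner map.
    """
    if points.corners != corners:
        raise CGRError("point set was generated with a different CornerMap")
    if k < 1 or k > points.points.shape[0]:
        raise CGRError(f"k={k} invalid for {points.points.shape[0]} points")
    side = 1 << k
    pts = points.points[k - 1:]
    cols = np.minimum((pts[:, 0] * side).astype(np.int64), side - 1)
    rows = np.minimum((pts[:, 1] * side).astype(np.int64), side - 1)
    counts = np.zeros((side, side), dtype=np.int64)
    np.add.at(counts, (rows, cols), 1)
    return FCGRMatrix(k=k, counts=counts, corners=corners,
                      record_id=points.record_id)
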