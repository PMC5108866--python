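"""Base composition, GC content and profile, and molecular weight.

GC is reported the way sequence repositories print it — as a percentage,
rounded to the nearest integer for tables — while the sliding-window profile
keeps full precision so its min/max/mean bands are exact.  Molecular weight
uses average masses of free 2'-deoxynucleoside-5'-monophosphates, the
convention consistent with per-site weights of ~327.4 Da seen in published
strain tables for ~1.5 kb 16S fragments; :func:`calibrate_weight_table`
recovers a weight table by least squares from observed (composition, weight)
pairs so the convention can be checked against any published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SeqRecord

__all__ = [
    "BaseComposition",
    "GCProfile",
    "WeightTable",
    "DEFAULT_WEIGHTS",
    "base_counts",
    "gc_percent",
    "gc_profile",
    "molecular_weight",
    "calibrate_weight_table",
    "gc_difference",
    "round_half_away",
]


class CompositionError(ValueError):
    pass


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class BaseComposition:
    a: int
    c: int
    g: int
    t: int
    other: int
    length: int

    def __post_init__(self) -> None:
        if self.a + self.c + self.g + self.t + self.other != self.length:
            raise CompositionError("base counts do not sum to sequence length")
        if min(self.a, self.c, self.g, self.t, self.other) < 0:
            raise CompositionError("negative base count")

    @property
    def unambiguous(self) -> int:
        return self.a + self.c + self.g + self.t


@dataclass(frozen=True)
class GCProfile:
    """Sliding-window GC values plus the three plotted summary bands."""

    window: int
    step: int
    positions: np.ndarray = field(repr=False)  # 1-based window starts
    values: np.ndarray = field(repr=False)     # GC% per window, unrounded
    min: float = 0.0
    max: float = 0.0
    mean: float = 0.0


@dataclass(frozen=True)
class WeightTable:
    """Per-base weights in Daltons plus a once-per-sequence adjustment."""

    a: float
    c: float
    g: float
    t: float
    terminal_adjustment: float = 0.0

    def __post_init__(self) -> None:
        if min(self.a, self.c, self.g, self.t) <= 0:
            raise CompositionError("base weights must be positive")

    @property
    def mean_weight(self) -> float:
        return (self.a + self.c + self.g + self.t) / 4.0


#: Average masses of free dNMPs (Da).  Residue (water-subtracted) masses of
#: ~313 Da/nt are excluded by published per-site weights near 327.4 Da.
DEFAULT_WEIGHTS = WeightTable(a=331.22, c=307.20, g=347.22, t=322.21,
                              terminal_adjustment=0.0)


def base_counts(record: SeqRecord) -> BaseComposition:
    """Exact symbol tally; every non-ACGT symbol is pooled under ``other``."""
    s = record.residues
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    return BaseComposition(a=a, c=c, g=g, t=t,
                           other=len(s) - a - c - g - t, length=len(s))


def gc_percent(record: SeqRecord, rounding: str = "nearest",
               count_ambiguous: bool = False) -> float:
    """GC content as a percentage.

    Ambiguity codes are excluded from numerator *and* denominator by default
    (``count_ambiguous=True`` keeps them in the denominator).  ``rounding``
    is ``"nearest"`` (integer, half away from zero — the table convention)
    or ``"none"``.
    """
    comp = base_counts(record)
    denom = comp.length if count_ambiguous else comp.unambiguous
    if comp.unambiguous == 0:
        raise CompositionError(
            f"record {record.id!r} has no unambiguous bases; GC undefined")
    pct = 100.0 * (comp.g + comp.c) / denom
    if rounding == "nearest":
        return float(round_half_away(pct))
    if rounding == "none":
        return pct
    raise ValueError(f"unknown rounding mode {rounding!r}")


def gc_profile(record: SeqRecord, window: int = 50, step: int = 1) -> GCProfile:
    """Sliding-window GC% along the sequence (values never rounded).

    Windows start every ``step`` nt; there are ``floor((L-window)/step)+1``
    of them.  Within a window, ambiguity codes are excluded from numerator
    and denominator, matching :func:`gc_percent`.
    """
    length = len(record.residues)
    if window < 1 or step < 1:
        raise CompositionError("window and step must be >= 1")
    if window > length:
        raise CompositionError(
            f"window {window} exceeds sequence length {length} for {record.id!r}")
    arr = np.frombuffer(record.residues.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_known = np.isin(arr, [ord(b) for b in "ACGT"]).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    cn = np.concatenate([[0], np.cumsum(is_known)])
    starts = np.arange(0, length - window + 1, step)
    num = cg[starts + window] - cg[starts]
    den = cn[starts + window] - cn[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, 100.0 * num / np.maximum(den, 1), np.nan)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise CompositionError(f"no window of {record.id!r} has unambiguous bases")
    return GCProfile(window=window, step=step, positions=starts + 1,
                     values=values, min=float(finite.min()),
                     max=float(finite.max()), mean=float(finite.mean()))


def molecular_weight(record: SeqRecord, table: WeightTable = DEFAULT_WEIGHTS,
                     ambiguous: str = "error") -> float:
    """Single-strand molecular weight in Daltons.

    ``ambiguous="error"`` (default) refuses records with ambiguity codes;
    ``ambiguous="mean"`` substitutes the table's mean base weight for them.
    """
    comp = base_counts(record)
    if comp.other and ambiguous == "error":
        raise CompositionError(
            f"record {record.id!r} has {comp.other} ambiguity codes; "
            "pass ambiguous='mean' to substitute the mean base weight")
    w = (comp.a * table.a + comp.c * table.c + comp.g * table.g
         + comp.t * table.t + table.terminal_adjustment)
    if comp.other and ambiguous == "mean":
        w += comp.other * table.mean_weight
    return w


def calibrate_weight_table(compositions: list[BaseComposition],
                           observed_weights: list[float],
                           fit_adjustment: bool = True):
    """Least-squares weight table from (composition, observed weight) pairs.

    Solves for the four base weights (and optionally a terminal adjustment)
    minimising the squared error against the observed weights.  Returns
    ``(WeightTable, residuals)`` where residuals are observed − fitted.
    """
    if len(compositions) != len(observed_weights) or not compositions:
        raise CompositionError("need matching, non-empty composition/weight lists")
    cols = [[c.a, c.c, c.g, c.t] + ([1.0] if fit_adjustment else [])
            for c in compositions]
    design = np.asarray(cols, dtype=float)
    y = np.asarray(observed_weights, dtype=float)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    adj = float(coef[4]) if fit_adjustment else 0.0
    table = WeightTable(a=float(coef[0]), c=float(coef[1]), g=float(coef[2]),
                        t=float(coef[3]), terminal_adjustment=adj)
    residuals = y - design @ coef
    return table, residuals


def gc_difference(a: SeqRecord, b: SeqRecord) -> float:
    """|ΔGC| between two records in percentage points (unrounded).

    A plain composition comparator offered in place of hybridization-style
    genome-distance services, which rely on unpublished algorithms.
    """
    return abs(gc_percent(a, rounding="none") - gc_percent(b, rounding="none"))
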