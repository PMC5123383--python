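"""Trapezoidal fuzzy read counts.

The number of reads a gene received is uncertain in the presence of
multireads.  The exact possibility distribution over integer counts can be
computed by enumeration (:func:`discrete_possibility`), but it is summarised
by four integers:

* ``A`` — reads mapping *only* to the gene (the count cannot be lower);
* ``B`` — reads having the gene as their strict best match;
* ``C`` — reads having the gene among their best matches (ties included);
* ``D`` — all reads with any record on the gene (the count cannot be higher).

These define a trapezoidal fuzzy number with membership 1 on [B, C], 0 at
A-1 and below and at D+1 and above, linear on the shoulders (the ±1
extension gives non-null possibility to the extreme counts A and D).  The
support width D-A quantifies multiread-induced uncertainty; genes untouched
by multireads collapse to a point A=B=C=D.

A punctual "rescue-like" centroid is also provided: every read is split
across its genes proportionally to its mapping possibilities, so summing the
centroids over genes returns the total number of mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_mappings import PossibilityTable

__all__ = [
    "TrapezoidalCount",
    "DiscreteCountPossibility",
    "compute_abcd",
    "compute_all_abcd",
    "discrete_possibility",
    "centroid_counts",
    "merge_technical",
    "merge_biological",
]

DEFAULT_TIE_TOL = 1e-9
BRUTE_FORCE_CAP = 20


@dataclass(frozen=True)
class TrapezoidalCount:
    """Fuzzy read count Tr[A-1, B, C, D+1] of one gene in one sample.

    The stored parameters are the raw ``a <= b <= c <= d`` bounds; the ±1
    shoulder extension is applied at membership-evaluation time only.
    Normalised trapezoids may carry non-integer parameters.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"require 0 <= A <= B <= C <= D, got {self}")

    # TrapezoidalCount.ZERO (the certain count of 0) is attached after the
    # class body.

    @property
    def is_point(self) -> bool:
        return self.a == self.d

    @property
    def support(self) -> tuple[float, float]:
        """Open support of the membership function, clipped at 0."""
        return (max(self.a - 1.0, 0.0), self.d + 1.0)

    @property
    def core(self) -> tuple[float, float]:
        return (self.b, self.c)

    def membership(self, x):
        """Membership degree at count ``x`` (scalar or array).

        0 at and below A-1, rising linearly to 1 at B, 1 on [B, C], falling
        linearly to 0 at D+1; negative counts always have membership 0.
        """
        x = np.asarray(x, dtype=float)
        a1 = self.a - 1.0
        d1 = self.d + 1.0
        up = (x - a1) / (self.b - a1)      # b - a1 >= 1 by construction
        down = (d1 - x) / (d1 - self.c)    # d1 - c >= 1
        m = np.clip(np.minimum(up, down), 0.0, 1.0)
        m = np.where(x < 0.0, 0.0, m)
        return m if m.ndim else float(m)

    def scaled(self, factor: float) -> "TrapezoidalCount":
        if not (np.isfinite(factor) and factor > 0):
            raise ValueError(f"scaling factor must be positive, got {factor!r}")
        return TrapezoidalCount(
            self.a / factor, self.b / factor, self.c / factor, self.d / factor
        )

    def __iter__(self):
        return iter((self.a, self.b, self.c, self.d))


TrapezoidalCount.ZERO = TrapezoidalCount(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DiscreteCountPossibility:
    """Exact possibility of each integer read count of one gene."""

    gene: str
    possibilities: Mapping[int, float]

    def support_bounds(self, tol: float = 1e-12) -> tuple[int, int]:
        ks = [k for k, p in self.possibilities.items() if p > tol]
        return (min(ks), max(ks)) if ks else (0, 0)

    def plateau_bounds(self, tol: float = 1e-12) -> tuple[int, int]:
        ks = [k for k, p in self.possibilities.items() if p >= 1.0 - tol]
        if not ks:
            raise ValueError(f"{self.gene}: possibility distribution has no plateau")
        return (min(ks), max(ks))

    def as_array(self) -> np.ndarray:
        n = max(self.possibilities) if self.possibilities else 0
        return np.array([self.possibilities.get(k, 0.0) for k in range(n + 1)])


def compute_all_abcd(
    table: PossibilityTable, tie_tol: float = DEFAULT_TIE_TOL
) -> pd.DataFrame:
    """Trapezoid parameters for every gene of a sample at once.

    Returns a DataFrame indexed by gene with integer columns A, B, C, D.
    Vectorised equivalent of calling :func:`compute_abcd` per gene.
    """
    df = table.df
    if df.empty:
        return pd.DataFrame(columns=["A", "B", "C", "D"], dtype=int)
    by_read = df.groupby("read_id", sort=False)["possibility"]
    rowmax = by_read.transform("max")
    n_records = by_read.transform("size")
    near_best = df["possibility"] >= rowmax - tie_tol
    n_near = near_best.groupby(df["read_id"], sort=False).transform("sum")
    out = pd.DataFrame(
        {
            "unique": n_records == 1,
            "strict": near_best & (n_near == 1),
            "near": near_best,
        },
        index=df.index,
    )
    agg = out.groupby(df["reference_id"]).sum()
    agg["D"] = df.groupby("reference_id").size()
    agg = agg.rename(columns={"unique": "A", "strict": "B", "near": "C"})
    return agg[["A", "B", "C", "D"]].astype(int).sort_index()


def compute_abcd(
    table: PossibilityTable, gene: str, tie_tol: float = DEFAULT_TIE_TOL
) -> TrapezoidalCount:
    """Trapezoidal fuzzy count of one gene.

    A gene absent from the table gets the zero trapezoid (a perfectly
    certain count of 0).  Best-match comparisons use ``tie_tol`` on the
    possibility scale: a strict best match beats every alternative by more
    than ``tie_tol``; ties within ``tie_tol`` of the best count towards C.
    """
    all_abcd = compute_all_abcd(table, tie_tol)
    if gene not in all_abcd.index:
        return TrapezoidalCount.ZERO
    row = all_abcd.loc[gene]
    return TrapezoidalCount(float(row.A), float(row.B), float(row.C), float(row.D))


def _gene_read_scores(
    table: PossibilityTable, gene: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per read touching ``gene``: (possibility on the gene, best possibility
    on any *other* gene, 0 for reads unique to the gene)."""
    df = table.df
    on_gene = df[df["reference_id"] == gene]
    reads = on_gene["read_id"].to_numpy()
    pi = on_gene["possibility"].to_numpy(dtype=float)
    others = df[(df["read_id"].isin(reads)) & (df["reference_id"] != gene)]
    fm = others.groupby("read_id")["possibility"].max()
    falsematch = fm.reindex(reads).fillna(0.0).to_numpy(dtype=float)
    return pi, falsematch


def discrete_possibility(
    table: PossibilityTable, gene: str, cap: int = BRUTE_FORCE_CAP
) -> DiscreteCountPossibility:
    """Exact discrete possibility distribution of a gene's read count.

    The possibility of count ``k`` is the best way of choosing ``k`` of the
    reads touching the gene as true matches and the rest as false matches:
    the max over size-``k`` subsets S of

    ``min( min_{r in S} poss(r -> gene), min_{r not in S} falsematch(r) )``

    where ``falsematch(r)`` is the read's best possibility on any other gene
    (0 if the read maps only to this gene, so count 0 is then impossible).

    Exhaustive enumeration over 2^n subsets; ``n > cap`` raises, directing
    the caller to the trapezoid approximation (:func:`compute_abcd`).
    """
    pi, falsematch = _gene_read_scores(table, gene)
    n = len(pi)
    if n > cap:
        raise ValueError(
            f"{gene}: {n} reads exceed the brute-force cap ({cap}); use the "
            "trapezoid approximation compute_abcd() instead"
        )
    if n == 0:
        return DiscreteCountPossibility(gene, {0: 1.0})
    subsets = np.arange(2 ** n, dtype=np.uint32)
    masks = (subsets[:, None] >> np.arange(n)) & 1  # (2^n, n) membership bits
    in_sel = masks.astype(bool)
    in_min = np.where(in_sel, pi, np.inf).min(axis=1)
    out_min = np.where(~in_sel, falsematch, np.inf).min(axis=1)
    val = np.minimum(in_min, out_min)
    val[np.isinf(val)] = 1.0  # only the empty/full subset of a 0-read gene
    k = in_sel.sum(axis=1)
    poss = {
        kk: float(val[k == kk].max()) for kk in range(n + 1)
    }
    return DiscreteCountPossibility(gene, poss)


def centroid_counts(table: PossibilityTable) -> pd.Series:
    """Rescue-like punctual counts: each read split across its genes in
    proportion to the mapping possibilities.

    The per-read shares sum to 1, so the centroids sum to the total number
    of mapped reads.
    """
    df = table.df
    if df.empty:
        return pd.Series(dtype=float, name="centroid")
    totals = df.groupby("read_id", sort=False)["possibility"].transform("sum")
    if (totals <= 0).any():
        bad = df.loc[totals <= 0, "read_id"].iloc[0]
        raise ValueError(f"read {bad!r} has non-positive total possibility")
    share = df["possibility"] / totals
    out = share.groupby(df["reference_id"]).sum().sort_index()
    out.name = "centroid"
    return out


def merge_technical(t1: TrapezoidalCount, t2: TrapezoidalCount) -> TrapezoidalCount:
    """Merge technical replicates: read counts add, so the four trapezoid
    parameters add componentwise."""
    return TrapezoidalCount(t1.a + t2.a, t1.b + t2.b, t1.c + t2.c, t1.d + t2.d)


def merge_biological(t1: TrapezoidalCount, t2: TrapezoidalCount) -> TrapezoidalCount:
    """Merge biological replicates into the envelope trapezoid
    Tr[min A, min B, max C, max D].

    Gene expression varies continuously in time across the cells of one
    condition, so when the two replicates disagree every intermediate count
    is treated as fully possible: disjoint inputs yield a plateau spanning
    the gap.
    """
    return TrapezoidalCount(
        min(t1.a, t2.a), min(t1.b, t2.b), max(t1.c, t2.c), max(t1.d, t2.d)
    )
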