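"""Read-to-gene mapping tables with graded possibility scores.

A sequencing read that aligns comparably well to several reference genes (a
*multiread*) has an ambiguous origin: paralogous gene families, overlapping
loci and sequencing errors all produce such reads.  Rather than discarding
multireads or resolving them probabilistically, every retained alignment is
annotated with a **possibility degree** in (0, 1]:

* 1 means the alignment is a fully plausible origin for the read;
* smaller values mean the alignment is worse than a perfect one, without
  excluding it (a low similarity can be due to sequencing errors or genuine
  variation in the sample).

Possibilities are *not* probabilities — the values attached to one read need
not sum to 1, and a read mapping equally well to two genes carries
possibility 1 on both.

Two alignment sources are supported:

* BLAST-style tabular output, where the possibility is the scaled product of
  percent identity and percent query coverage;
* SAM, where the possibility comes either from the MAPQ column scaled by 255
  or from a per-alignment score tag normalised by the read's best score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MappingRecord",
    "MappingValidationError",
    "PossibilityTable",
    "compute_possibility",
    "parse_blast_tabular",
    "parse_sam",
]

#: column order of the internal possibility-table TSV dialect
TABLE_COLUMNS = ("read_id", "reference_id", "possibility")

#: floor applied when a score would otherwise be 0 (records must stay in (0, 1])
POSSIBILITY_FLOOR = 1e-6


class MappingValidationError(ValueError):
    """Raised when alignment input violates the mapping-table contract."""


@dataclass(frozen=True)
class MappingRecord:
    """One read-to-gene alignment with its possibility degree.

    Attributes
    ----------
    read_id : str
        Opaque read identifier.
    reference_id : str
        Gene/transcript identifier the read aligns to.
    possibility : float
        Degree in (0, 1] that the read truly originates from this reference.
    """

    read_id: str
    reference_id: str
    possibility: float

    def __post_init__(self) -> None:
        p = self.possibility
        if not (isinstance(p, (int, float)) and math.isfinite(p) and 0.0 < p <= 1.0):
            raise MappingValidationError(
                f"possibility must lie in (0, 1], got {p!r} for "
                f"({self.read_id!r}, {self.reference_id!r})"
            )


class PossibilityTable:
    """All mapping records of one sample.

    The table is the in-memory currency of the whole pipeline: one row per
    (read, gene) alignment with its possibility.  Duplicate (read, gene)
    pairs are collapsed to the maximum possibility on construction — the
    possibility of an event is the best way it can occur.

    Parameters
    ----------
    df : pandas.DataFrame
        Columns ``read_id``, ``reference_id``, ``possibility``.
    sample_id : str
        Label of the sample the records belong to.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str = "sample") -> None:
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise MappingValidationError(f"missing column(s): {missing}")
        df = df.loc[:, list(TABLE_COLUMNS)].copy()
        df["possibility"] = df["possibility"].astype(float)
        if len(df):
            bad = ~(
                np.isfinite(df["possibility"])
                & (df["possibility"] > 0.0)
                & (df["possibility"] <= 1.0)
            )
            if bad.any():
                row = df[bad].iloc[0]
                raise MappingValidationError(
                    f"possibility must lie in (0, 1], got {row['possibility']!r} "
                    f"for ({row['read_id']!r}, {row['reference_id']!r})"
                )
            # best-alignment collapse for duplicated (read, gene) pairs
            df = (
                df.groupby(["read_id", "reference_id"], sort=False, as_index=False)[
                    "possibility"
                ]
                .max()
            )
        self.df = df.reset_index(drop=True)
        self.sample_id = sample_id

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[MappingRecord], sample_id: str = "sample"
    ) -> "PossibilityTable":
        rows = [(r.read_id, r.reference_id, r.possibility) for r in records]
        return cls(pd.DataFrame(rows, columns=list(TABLE_COLUMNS)), sample_id)

    @classmethod
    def read_tsv(cls, path: str | Path, sample_id: str | None = None) -> "PossibilityTable":
        """Read the internal TSV dialect (header line, '.' decimal, tabs)."""
        path = Path(path)
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"read_id": str, "reference_id": str},
            float_precision="round_trip",
        )
        return cls(df, sample_id or path.stem)

    # -- properties ---------------------------------------------------------

    @property
    def records(self) -> list[MappingRecord]:
        return [
            MappingRecord(r, g, p)
            for r, g, p in self.df.itertuples(index=False, name=None)
        ]

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def read_ids(self) -> pd.Index:
        return pd.Index(self.df["read_id"].unique())

    @property
    def n_reads(self) -> int:
        return self.df["read_id"].nunique()

    @property
    def genes(self) -> pd.Index:
        return pd.Index(sorted(self.df["reference_id"].unique()))

    def multiread_ids(self) -> pd.Index:
        """Reads with records on at least two genes."""
        sizes = self.df.groupby("read_id", sort=False).size()
        return pd.Index(sizes.index[sizes > 1])

    @property
    def multiread_fraction(self) -> float:
        n = self.n_reads
        return len(self.multiread_ids()) / n if n else 0.0

    # -- io -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the internal TSV dialect; floats use full precision so a
        read-back reproduces the table bit-for-bit."""
        self.df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PossibilityTable):
            return NotImplemented
        a = self.df.sort_values(["read_id", "reference_id"]).reset_index(drop=True)
        b = other.df.sort_values(["read_id", "reference_id"]).reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PossibilityTable({self.sample_id!r}: {self.n_records} records, "
            f"{self.n_reads} reads, {len(self.genes)} genes)"
        )


def compute_possibility(identity_pct: float, coverage_pct: float) -> float:
    """Turn alignment accuracy into a possibility degree.

    The score is the product of percent identity and percent query coverage,
    scaled to [0, 1]; a perfect full-length match (100/100) has possibility 1.

    Parameters
    ----------
    identity_pct, coverage_pct : float
        Percentages in [0, 100].

    Returns
    -------
    float
        ``(identity_pct / 100) * (coverage_pct / 100)``.
    """
    for name, value in (("identity_pct", identity_pct), ("coverage_pct", coverage_pct)):
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            raise MappingValidationError(f"{name} must be finite, got {value!r}")
        if not 0.0 <= value <= 100.0:
            raise MappingValidationError(f"{name} must lie in [0, 100], got {value!r}")
    return (identity_pct / 100.0) * (coverage_pct / 100.0)


def parse_blast_tabular(
    path: str | Path,
    *,
    read_col: int = 0,
    subject_col: int = 1,
    identity_col: int = 2,
    coverage_col: int = 3,
    identity_only: bool = False,
    sample_id: str | None = None,
) -> PossibilityTable:
    """Parse BLAST-style tabular output into a :class:`PossibilityTable`.

    Column indices are 0-based and configurable so that both the compact
    (read, subject, identity, coverage) layout and full ``outfmt 6`` layouts
    with an appended coverage column can be read.  With ``identity_only`` the
    possibility is the scaled identity alone; the default is the scaled
    product of identity and coverage.

    Duplicate (read, subject) pairs collapse to the maximum possibility.
    Scores of exactly 0 are floored at ``POSSIBILITY_FLOOR`` with a warning.
    """
    path = Path(path)
    needed = max(read_col, subject_col, identity_col, coverage_col) + 1
    rows: list[tuple[str, str, float]] = []
    floored = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < needed:
                raise MappingValidationError(
                    f"{path}:{lineno}: expected at least {needed} tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                identity = float(fields[identity_col])
                coverage = 100.0 if identity_only else float(fields[coverage_col])
            except ValueError as exc:
                raise MappingValidationError(f"{path}:{lineno}: {exc}") from exc
            try:
                p = compute_possibility(identity, coverage)
            except MappingValidationError as exc:
                raise MappingValidationError(f"{path}:{lineno}: {exc}") from exc
            if p == 0.0:
                p = POSSIBILITY_FLOOR
                floored += 1
            rows.append((fields[read_col], fields[subject_col], p))
    if floored:
        warnings.warn(
            f"{path}: {floored} alignment(s) had a zero score; floored at "
            f"{POSSIBILITY_FLOOR}",
            stacklevel=2,
        )
    if not rows:
        warnings.warn(f"{path}: no alignments found, returning empty table", stacklevel=2)
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return PossibilityTable(df, sample_id or path.stem)


def parse_sam(
    path: str | Path,
    score_mode: str = "mapq",
    *,
    tag: str = "AS",
    mapq_floor: float = 1.0 / 255.0,
    sample_id: str | None = None,
) -> PossibilityTable:
    """Parse a SAM/BAM file (secondary alignments retained) into possibilities.

    ``score_mode="mapq"`` scales the MAPQ column by 255, clamped to (0, 1]
    with records at MAPQ 0 floored at ``mapq_floor``.  Most aligners give
    multireads MAPQ 0, which flattens exactly the grading this method needs,
    so ``score_mode="tag"`` is the recommended alternative: the per-alignment
    score tag (default ``AS``) is scaled by the read's best score, making the
    best alignment of every read fully possible (possibility 1).
    """
    import pysam

    if score_mode not in ("mapq", "tag"):
        raise MappingValidationError(f"unknown score_mode {score_mode!r}")
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_name is None:
                continue
            if score_mode == "mapq":
                p = aln.mapping_quality / 255.0
                if p <= 0.0:
                    p = mapq_floor
                p = min(p, 1.0)
            else:
                try:
                    score = float(aln.get_tag(tag))
                except KeyError:
                    raise MappingValidationError(
                        f"{path}: alignment {aln.query_name!r} lacks the "
                        f"{tag!r} tag required by tag score mode"
                    ) from None
                p = score  # normalised per read below
            rows.append((aln.query_name, aln.reference_name, p))
    if not rows:
        warnings.warn(f"{path}: no mapped alignments, returning empty table", stacklevel=2)
        return PossibilityTable(
            pd.DataFrame(columns=list(TABLE_COLUMNS)), sample_id or path.stem
        )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if score_mode == "tag":
        best = df.groupby("read_id", sort=False)["possibility"].transform("max")
        if (best <= 0).any():
            bad = df.loc[best <= 0, "read_id"].iloc[0]
            raise MappingValidationError(
                f"{path}: read {bad!r} has best {tag} score <= 0; tag scores "
                "must be positive to be scaled into possibilities"
            )
        df["possibility"] = (df["possibility"] / best).clip(
            lower=POSSIBILITY_FLOOR, upper=1.0
        )
    return PossibilityTable(df, sample_id or path.stem)
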