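"""End-to-end possibilistic differential-expression run.

Order of operations for a case-control study:

1. parse each alignment file into a possibility table;
2. per gene and sample, build the trapezoidal fuzzy count and the
   rescue-like centroid; technical replicates (same sample id) merge by
   componentwise sum;
3. compute median-of-ratios size factors on punctual counts (centroids by
   default; unique counts when multireads are sporadic) and rescale every
   trapezoid and centroid;
4. merge biological replicates of a condition into the envelope trapezoid
   (centroids average);
5. fit the fold-change significance envelope — on within-condition
   replicate-vs-replicate fold changes when a condition has at least two
   biological replicates (a null comparison, so induced DE cannot inflate
   the envelope), otherwise on the case-vs-control cloud itself;
6. per gene, intersect the joint count relation with the three DE surfaces
   and assemble the result row (fuzzy counts, fuzzy FC, three possibilities,
   centroids, punctual FC);
7. rank by ascending same-expression possibility (most reliable DE first).

Everything is deterministic given inputs and configuration.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de_model import DEPossibility, DEThresholdModel, de_possibilities, fit_hyperbolas
from .fold_change import FuzzyFoldChange, fuzzy_fc, punctual_fc
from .fuzzy_counts import TrapezoidalCount, centroid_counts, compute_all_abcd
from .io_mappings import PossibilityTable, parse_blast_tabular, parse_sam
from .normalization import SizeFactorSet, size_factors

__all__ = [
    "SampleSpec",
    "RunConfig",
    "GeneResult",
    "RunResult",
    "PipelineError",
    "read_sample_sheet",
    "run",
    "run_experiment",
    "write_results",
    "read_results",
]

CONDITIONS = ("case", "control")
REPLICATE_KINDS = ("technical", "biological")
FORMATS = ("blast", "sam", "table")

RESULT_COLUMNS = (
    "gene",
    "case_a", "case_b", "case_c", "case_d",
    "control_a", "control_b", "control_c", "control_d",
    "fc_f1", "fc_f2", "fc_f3", "fc_f4",
    "p_under", "p_same", "p_over",
    "case_centroid", "control_centroid", "centroid_log2fc",
)


class PipelineError(ValueError):
    """Invalid sample sheet or unrunnable design."""


@dataclass(frozen=True)
class SampleSpec:
    """One row of the sample sheet."""

    path: str
    sample_id: str
    condition: str
    replicate_kind: str = "biological"
    format: str = "table"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise PipelineError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate_kind not in REPLICATE_KINDS:
            raise PipelineError(
                f"replicate_kind must be one of {REPLICATE_KINDS}, "
                f"got {self.replicate_kind!r}"
            )
        if self.format not in FORMATS:
            raise PipelineError(f"format must be one of {FORMATS}, got {self.format!r}")


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a run (all deterministic)."""

    quantile: float = 0.99        # per-bin |log2FC| quantile of the envelope
    grid_n: int = 64              # sup-min grid resolution per count axis
    min_possibility: float | None = None   # keep genes with over/under >= P and same < P
    min_abs_fc: float | None = None        # keep genes with |centroid FC| >= this
    direction: str = "case-over-control"
    tie_tol: float = 1e-9
    pseudo_fc: float = 0.0
    sporadic_threshold: float = 0.01  # multiread fraction below which unique counts feed normalization
    min_m: float = 1.0
    n_bins: int = 12
    min_points: int = 50          # fewest (m, fc) points acceptable for the envelope fit
    sam_score_mode: str = "tag"
    seed: int = 0                 # recorded for provenance; the run itself is deterministic

    def __post_init__(self) -> None:
        if self.direction not in ("case-over-control", "control-over-case"):
            raise PipelineError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class GeneResult:
    """One output row: fuzzy counts, fuzzy FC, DE possibilities, centroids."""

    gene: str
    case: TrapezoidalCount
    control: TrapezoidalCount
    fc: FuzzyFoldChange
    de: DEPossibility
    case_centroid: float
    control_centroid: float
    centroid_log2fc: float

    def as_row(self) -> tuple:
        return (
            self.gene,
            *self.case, *self.control, *self.fc,
            self.de.under, self.de.same, self.de.over,
            self.case_centroid, self.control_centroid, self.centroid_log2fc,
        )


@dataclass
class RunResult:
    rows: list[GeneResult]
    model: DEThresholdModel
    factors: SizeFactorSet
    diagnostics: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.as_row() for r in self.rows], columns=list(RESULT_COLUMNS)
        )


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    """Read the TSV sample sheet (path, sample_id, condition, replicate_kind,
    format); relative paths resolve against the sheet's directory."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["path", "sample_id", "condition"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"{path}: sample sheet lacks column(s) {missing}")
    specs = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        specs.append(
            SampleSpec(
                path=str(p),
                sample_id=row.sample_id,
                condition=row.condition,
                replicate_kind=getattr(row, "replicate_kind", "biological") or "biological",
                format=getattr(row, "format", "table") or "table",
            )
        )
    if not specs:
        raise PipelineError(f"{path}: empty sample sheet")
    return specs


def _parse_one(spec: SampleSpec, config: RunConfig) -> PossibilityTable:
    if spec.format == "blast":
        return parse_blast_tabular(spec.path, sample_id=spec.sample_id)
    if spec.format == "sam":
        return parse_sam(spec.path, score_mode=config.sam_score_mode,
                         sample_id=spec.sample_id)
    return PossibilityTable.read_tsv(spec.path, sample_id=spec.sample_id)


@dataclass
class _SampleCounts:
    """Per-sample (after technical merge) fuzzy and punctual counts."""

    abcd: pd.DataFrame            # gene x [A, B, C, D]
    centroid: pd.Series
    n_reads: int
    n_multireads: int


def _sample_counts(tables: Sequence[PossibilityTable], tie_tol: float) -> _SampleCounts:
    """Build counts for one sample, merging technical replicate files by sum."""
    abcd_total: pd.DataFrame | None = None
    centroid_total: pd.Series | None = None
    n_reads = n_multi = 0
    for table in tables:
        abcd = compute_all_abcd(table, tie_tol)
        cent = centroid_counts(table)
        abcd_total = abcd if abcd_total is None else abcd_total.add(abcd, fill_value=0)
        centroid_total = (
            cent if centroid_total is None else centroid_total.add(cent, fill_value=0.0)
        )
        n_reads += table.n_reads
        n_multi += len(table.multiread_ids())
    assert abcd_total is not None
    return _SampleCounts(abcd_total, centroid_total, n_reads, n_multi)


def _fit_points(
    cond_samples: Mapping[str, list[str]],
    centroids: Mapping[str, pd.Series],
    cond_centroid: Mapping[str, pd.Series],
) -> tuple[np.ndarray, str]:
    """(m, log2fc) cloud for the envelope fit and a label of its source."""
    pairs = []
    for cond, sids in cond_samples.items():
        pairs.extend(itertools.combinations(sids, 2))
    if pairs:
        ms, fcs = [], []
        for s1, s2 in pairs:
            c1, c2 = centroids[s1], centroids[s2]
            idx = c1.index.union(c2.index)
            v1 = c1.reindex(idx).fillna(0.0).to_numpy()
            v2 = c2.reindex(idx).fillna(0.0).to_numpy()
            ok = (v1 > 0) & (v2 > 0)
            ms.append((v1[ok] + v2[ok]) / 2.0)
            fcs.append(np.log2(v1[ok] / v2[ok]))
        return np.column_stack([np.concatenate(ms), np.concatenate(fcs)]), "replicates"
    v1 = cond_centroid["case"].to_numpy()
    v2 = cond_centroid["control"].to_numpy()
    ok = (v1 > 0) & (v2 > 0)
    pts = np.column_stack([(v1[ok] + v2[ok]) / 2.0, np.log2(v1[ok] / v2[ok])])
    return pts, "case-control"


def run_experiment(
    tables: Mapping[str, PossibilityTable | Sequence[PossibilityTable]],
    conditions: Mapping[str, str],
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Run the analysis on in-memory possibility tables.

    ``tables`` maps sample ids to one table (or a list of technical
    replicate tables to merge); ``conditions`` maps sample ids to
    "case"/"control".
    """
    present = set(conditions.values())
    if present != set(CONDITIONS):
        raise PipelineError(
            f"need samples for both conditions {CONDITIONS}, got {sorted(present)}"
        )

    per_sample: dict[str, _SampleCounts] = {}
    for sid, tbls in tables.items():
        if isinstance(tbls, PossibilityTable):
            tbls = [tbls]
        if not tbls:
            raise PipelineError(f"sample {sid!r} has no tables")
        per_sample[sid] = _sample_counts(tbls, config.tie_tol)

    gene_sets = [set(sc.abcd.index) for sc in per_sample.values()]
    genes = sorted(set().union(*gene_sets))
    if not set.intersection(*gene_sets):
        raise PipelineError("no gene is present in every sample")

    # --- normalization -----------------------------------------------------
    total_reads = sum(sc.n_reads for sc in per_sample.values())
    total_multi = sum(sc.n_multireads for sc in per_sample.values())
    multi_frac = total_multi / total_reads if total_reads else 0.0
    source = "unique" if multi_frac < config.sporadic_threshold else "centroid"
    if source == "unique":
        mat = pd.DataFrame(
            {sid: sc.abcd["A"].astype(float) for sid, sc in per_sample.items()}
        )
    else:
        mat = pd.DataFrame({sid: sc.centroid for sid, sc in per_sample.items()})
    mat = mat.reindex(genes).fillna(0.0)
    factors = size_factors(mat, source)

    norm_abcd: dict[str, pd.DataFrame] = {}
    norm_centroid: dict[str, pd.Series] = {}
    for sid, sc in per_sample.items():
        f = factors[sid]
        norm_abcd[sid] = sc.abcd.reindex(genes).fillna(0.0) / f
        norm_centroid[sid] = sc.centroid.reindex(genes).fillna(0.0) / f

    # --- biological envelope per condition ---------------------------------
    cond_samples: dict[str, list[str]] = {c: [] for c in CONDITIONS}
    for sid, cond in conditions.items():
        cond_samples[cond].append(sid)
    for cond, sids in cond_samples.items():
        if not sids:
            raise PipelineError(f"no samples for condition {cond!r}")
        sids.sort()

    cond_abcd: dict[str, pd.DataFrame] = {}
    cond_centroid: dict[str, pd.Series] = {}
    for cond, sids in cond_samples.items():
        a = pd.concat([norm_abcd[s]["A"] for s in sids], axis=1).min(axis=1)
        b = pd.concat([norm_abcd[s]["B"] for s in sids], axis=1).min(axis=1)
        c = pd.concat([norm_abcd[s]["C"] for s in sids], axis=1).max(axis=1)
        d = pd.concat([norm_abcd[s]["D"] for s in sids], axis=1).max(axis=1)
        cond_abcd[cond] = pd.DataFrame({"A": a, "B": b, "C": c, "D": d})
        cond_centroid[cond] = pd.concat(
            [norm_centroid[s] for s in sids], axis=1
        ).mean(axis=1)

    # --- significance envelope ---------------------------------------------
    pts, fit_source = _fit_points(cond_samples, norm_centroid, cond_centroid)
    model = fit_hyperbolas(
        pts, q=config.quantile, min_m=config.min_m, n_bins=config.n_bins,
        min_points=config.min_points,
    )

    # --- per-gene results ---------------------------------------------------
    reversed_dir = config.direction == "control-over-case"
    raw_abcd = {sid: sc.abcd for sid, sc in per_sample.items()}
    rows: list[GeneResult] = []
    ca, cb, cc, cd = (cond_abcd["case"][k].to_numpy() for k in "ABCD")
    ka, kb, kc, kd = (cond_abcd["control"][k].to_numpy() for k in "ABCD")
    case_cent = cond_centroid["case"].to_numpy()
    ctrl_cent = cond_centroid["control"].to_numpy()
    for i, gene in enumerate(genes):
        case_t = TrapezoidalCount(ca[i], cb[i], cc[i], cd[i])
        ctrl_t = TrapezoidalCount(ka[i], kb[i], kc[i], kd[i])
        de = de_possibilities(case_t, ctrl_t, model, config.grid_n)
        fc = fuzzy_fc(case_t, ctrl_t, config.pseudo_fc)
        pfc = punctual_fc(case_cent[i], ctrl_cent[i], config.pseudo_fc)
        if reversed_dir:
            de, fc, pfc = de.swapped(), fc.negated(), -pfc
        rows.append(
            GeneResult(
                gene, case_t, ctrl_t, fc, de,
                float(case_cent[i]), float(ctrl_cent[i]), pfc,
            )
        )

    rows.sort(key=lambda r: (r.de.same, -abs(r.centroid_log2fc), r.gene))
    if config.min_possibility is not None:
        # discretization cut: possibly DE (over/under >= P) and not possibly
        # unchanged (same < P) — a high same-possibility flags the gene as an
        # uncertain, potential false positive even when over/under is high
        p_cut = config.min_possibility
        rows = [
            r for r in rows
            if max(r.de.over, r.de.under) >= p_cut and r.de.same < p_cut
        ]
    if config.min_abs_fc is not None:
        rows = [r for r in rows if abs(r.centroid_log2fc) >= config.min_abs_fc]

    touched = pd.concat(
        [(df["D"] > df["A"]) for df in raw_abcd.values()], axis=1
    ).any(axis=1)
    diagnostics = {
        "n_genes": len(genes),
        "total_reads": int(total_reads),
        "multiread_read_fraction": multi_frac,
        "genes_touched_by_multireads_fraction": float(touched.mean()),
        "size_factor_source": source,
        "size_factors": {sid: factors[sid] for sid in per_sample},
        "fit_source": fit_source,
        "n_fit_points": int(pts.shape[0]),
        "per_sample_reads": {sid: sc.n_reads for sid, sc in per_sample.items()},
        "direction": config.direction,
    }
    return RunResult(rows, model, factors, diagnostics)


def run(
    samples: str | Path | Sequence[SampleSpec],
    config: RunConfig = RunConfig(),
) -> RunResult:
    """Run the analysis from a sample sheet path or a list of specs."""
    if isinstance(samples, (str, Path)):
        specs = read_sample_sheet(samples)
    else:
        specs = list(samples)
    if not specs:
        raise PipelineError("no samples given")
    tables: dict[str, list[PossibilityTable]] = {}
    conditions: dict[str, str] = {}
    for spec in specs:
        tables.setdefault(spec.sample_id, []).append(_parse_one(spec, config))
        prev = conditions.setdefault(spec.sample_id, spec.condition)
        if prev != spec.condition:
            raise PipelineError(
                f"sample {spec.sample_id!r} assigned to both conditions"
            )
    return run_experiment(tables, conditions, config)


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "Inf" if x > 0 else "-Inf"
    return format(x, ".6g")


def write_results(
    rows: Iterable[GeneResult], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Write the ranked result table as TSV: one header line, fixed column
    order, 6 significant digits, "Inf"/"-Inf" literals.  Byte-identical
    across runs on identical input."""
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            gene, *values = r.as_row()
            fh.write("\t".join([gene] + [_fmt(v) for v in values]) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table back (Inf literals parsed as floats)."""
    return pd.read_csv(path, sep="\t", comment="#")
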