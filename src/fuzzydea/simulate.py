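"""Synthetic two-condition experiments with known ground truth.

The generator emits per-sample possibility tables directly — the stage the
real pipeline reaches after alignment scoring — so every downstream step can
be exercised without running an aligner:

* each gene draws a baseline expression level (reads per sample) from a
  log-uniform range;
* a chosen set of genes is differentially expressed: 10 over-expressed at
  log2 FC +1 and 10 under-expressed at -1 by default, applied to the case
  condition, with two biological replicates per condition;
* a subset of the null genes is organised into paralog-style families whose
  reads may also align to the sibling genes: such decoy records carry graded
  possibilities just below 1, while the true gene always scores 1;
* per-sample read counts are Poisson draws around the (condition-scaled)
  baseline.

Reads are abstract records, not sequences; a tiny SAM emitter and the
bundled eleven-row worked example (three paralog-like genes, five reads)
support the alignment-parsing round trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_mappings import PossibilityTable, TABLE_COLUMNS, parse_blast_tabular

__all__ = [
    "SimConfig",
    "SimExperiment",
    "generate",
    "write_experiment",
    "random_small_table",
    "example_blast_text",
    "example_possibility_table",
    "write_example_sam",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic experiment.

    Defaults reproduce a desk-scale case-control design: 1000 genes, two
    biological replicates per condition, 10 genes induced at log2 FC +1 and
    10 at -1 (on moderately-to-highly expressed genes, where fold-change
    recovery is count-noise-limited rather than model-limited), and 100
    paralog families of three genes among the null genes whose reads can
    multimap.
    """

    n_genes: int = 1000
    n_families: int = 100
    family_size: int = 3
    #: log-uniform range of baseline reads per gene per sample
    reads_per_gene: tuple[float, float] = (50.0, 1500.0)
    #: fraction of family-gene reads that become multireads
    multiread_fraction: float = 0.5
    #: half-normal sd of the decoy possibility deficit (decoys score 1 - |N|)
    score_noise: float = 0.1
    n_de_over: int = 10
    n_de_under: int = 10
    induced_log2fc: float = 1.0
    #: DE genes draw their baseline from [de_min_reads, reads_per_gene[1]];
    #: at b reads the counting-noise sd of the recovered log2 FC is about
    #: sqrt(1.5/b)/ln2 (worst case, the halved condition of an under-expressed
    #: gene), so b >= 1250 keeps a +/-0.15 recovery window at >= 3 sd
    de_min_reads: float = 1250.0
    #: explicit (gene_name, log2fc) overrides; None builds the default set
    de_genes: tuple[tuple[str, float], ...] | None = None
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        n_de = self.n_de_over + self.n_de_under
        needed = self.n_families * self.family_size + n_de
        if needed > self.n_genes:
            raise ValueError(
                f"{self.n_families} families of {self.family_size} plus "
                f"{n_de} DE genes need {needed} genes, have {self.n_genes}"
            )
        if self.multiread_fraction < 0 or self.multiread_fraction > 1:
            raise ValueError("multiread_fraction must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")


@dataclass
class SimExperiment:
    """Generated experiment: per-sample tables plus the ground truth."""

    tables: dict[str, PossibilityTable]          # sample_id -> table
    conditions: dict[str, str]                   # sample_id -> case/control
    truth: pd.DataFrame                          # gene, condition, true_count, induced_log2fc
    de_genes: dict[str, float]                   # gene -> induced log2fc
    families: list[list[str]]
    config: SimConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tables)


def _gene_names(n: int) -> np.ndarray:
    return np.array([f"gene-{i:04d}" for i in range(1, n + 1)])


def generate(config: SimConfig) -> SimExperiment:
    """Generate the experiment deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    lo, hi = config.reads_per_gene

    # baselines for everybody, then the DE genes redrawn at higher expression
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))
    if config.de_genes is not None:
        de_map = {g: float(f) for g, f in config.de_genes}
        unknown = set(de_map) - set(genes)
        if unknown:
            raise ValueError(f"unknown DE gene(s): {sorted(unknown)}")
    else:
        n_de = config.n_de_over + config.n_de_under
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        de_lo = max(lo, config.de_min_reads)
        de_hi = max(hi, de_lo + 1.0)
        baselines[de_idx] = np.exp(
            rng.uniform(np.log(de_lo), np.log(de_hi), size=n_de)
        )
        de_map = {}
        for j, gi in enumerate(de_idx):
            fc = config.induced_log2fc if j < config.n_de_over else -config.induced_log2fc
            de_map[genes[gi]] = fc
    fc_per_gene = np.array([de_map.get(g, 0.0) for g in genes])

    # paralog families among the null genes
    null_idx = np.array([i for i, g in enumerate(genes) if g not in de_map])
    fam_pool = rng.permutation(null_idx)[: config.n_families * config.family_size]
    fam_matrix = fam_pool.reshape(config.n_families, config.family_size)
    family_of = np.full(config.n_genes, -1)
    for fi, members in enumerate(fam_matrix):
        family_of[members] = fi
    families = [[genes[i] for i in row] for row in fam_matrix]

    tables: dict[str, PossibilityTable] = {}
    conditions: dict[str, str] = {}
    truth_counts: dict[tuple[str, str], np.ndarray] = {}
    for condition in ("case", "control"):
        lam = baselines * np.exp2(fc_per_gene) if condition == "case" else baselines
        cond_total = np.zeros(config.n_genes, dtype=int)
        for rep in range(1, config.n_replicates + 1):
            sample_id = f"{condition}-{rep}"
            counts = rng.poisson(lam)
            cond_total += counts
            gene_idx = np.repeat(np.arange(config.n_genes), counts)
            n_reads = gene_idx.size
            read_ids = np.char.add(f"{sample_id}:r", np.arange(n_reads).astype(str))
            rows = [
                pd.DataFrame(
                    {
                        "read_id": read_ids,
                        "reference_id": genes[gene_idx],
                        "possibility": np.ones(n_reads),
                    }
                )
            ]
            # decoy records on family siblings
            in_family = family_of[gene_idx] >= 0
            is_multi = in_family & (rng.random(n_reads) < config.multiread_fraction)
            midx = np.flatnonzero(is_multi)
            if midx.size and config.family_size > 1:
                fams = fam_matrix[family_of[gene_idx[midx]]]      # (m, fs)
                keep = fams != gene_idx[midx][:, None]            # drop the true gene
                sib_gene_idx = fams[keep]                         # row-major flatten
                sib_read_ids = np.repeat(read_ids[midx], config.family_size - 1)
                deficit = np.minimum(
                    np.abs(rng.normal(0.0, config.score_noise, sib_gene_idx.size)),
                    0.4999,
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "read_id": sib_read_ids,
                            "reference_id": genes[sib_gene_idx],
                            "possibility": 1.0 - deficit,
                        }
                    )
                )
            df = pd.concat(rows, ignore_index=True)
            tables[sample_id] = PossibilityTable(df, sample_id)
            conditions[sample_id] = condition
        for gi, g in enumerate(genes):
            truth_counts[(g, condition)] = cond_total[gi]
    truth = pd.DataFrame(
        [
            (g, cond, int(truth_counts[(g, cond)]), de_map.get(g, 0.0))
            for g in genes
            for cond in ("case", "control")
        ],
        columns=["gene", "condition", "true_count", "induced_log2fc"],
    )
    return SimExperiment(tables, conditions, truth, de_map, families, config)


def write_experiment(exp: SimExperiment, outdir: str | Path) -> Path:
    """Write tables, truth table and a sample sheet; returns the sheet path.

    The sheet references the internal possibility-table dialect (format
    "table"); all replicates are biological.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet_rows = []
    for sample_id, table in exp.tables.items():
        path = outdir / f"{sample_id}.tsv"
        table.to_tsv(path)
        # paths in the sheet are relative to the sheet itself
        sheet_rows.append(
            (path.name, sample_id, exp.conditions[sample_id], "biological", "table")
        )
    sheet = pd.DataFrame(
        sheet_rows, columns=["path", "sample_id", "condition", "replicate_kind", "format"]
    )
    sheet_path = outdir / "samples.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    exp.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return sheet_path


def random_small_table(
    rng: np.random.Generator,
    max_reads: int = 12,
    max_genes: int = 5,
    sample_id: str = "random",
) -> PossibilityTable:
    """Small random mapping table for oracle cross-checks.

    Follows the score-normalised convention of the generator (and of SAM tag
    scoring): every read's best alignment has possibility 1, secondary
    alignments score in (0.2, 1).
    """
    n_reads = int(rng.integers(1, max_reads + 1))
    n_genes = int(rng.integers(1, max_genes + 1))
    genes = [f"g{j}" for j in range(n_genes)]
    rows = []
    for i in range(n_reads):
        k = int(rng.integers(1, min(3, n_genes) + 1))
        targets = rng.choice(n_genes, size=k, replace=False)
        best = int(rng.integers(0, k))
        for j, t in enumerate(targets):
            p = 1.0 if j == best else float(rng.uniform(0.2, 0.999))
            rows.append((f"r{i}", genes[t], p))
    return PossibilityTable(
        pd.DataFrame(rows, columns=list(TABLE_COLUMNS)), sample_id
    )


# ---------------------------------------------------------------------------
# bundled worked example: three paralog-like genes, five reads, eleven hits

_EXAMPLE_BLAST_ROWS = """\
read-1\tgene-1\t100\t100
read-2\tgene-1\t100\t100
read-2\tgene-2\t99\t80
read-2\tgene-3\t95\t80
read-3\tgene-1\t100\t100
read-3\tgene-2\t100\t100
read-4\tgene-1\t96\t90
read-4\tgene-2\t97\t90
read-4\tgene-3\t100\t100
read-5\tgene-1\t95\t80
read-5\tgene-2\t100\t100
"""


def example_blast_text() -> str:
    """BLAST-style tabular text of the bundled worked example."""
    return _EXAMPLE_BLAST_ROWS


def example_possibility_table() -> PossibilityTable:
    """The worked example parsed into possibilities (identity x coverage)."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(_EXAMPLE_BLAST_ROWS)
        name = fh.name
    try:
        return parse_blast_tabular(name, sample_id="example")
    finally:
        Path(name).unlink(missing_ok=True)


_EXAMPLE_SAM = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:gene-1\tLN:1000
@SQ\tSN:gene-2\tLN:1000
@SQ\tSN:gene-3\tLN:1000
read-1\t0\tgene-1\t100\t255\t50M\t*\t0\t0\t*\t*\tAS:i:60
read-2\t0\tgene-1\t120\t51\t50M\t*\t0\t0\t*\t*\tAS:i:60
read-2\t256\tgene-2\t130\t0\t50M\t*\t0\t0\t*\t*\tAS:i:45
read-3\t0\tgene-3\t200\t255\t50M\t*\t0\t0\t*\t*\tAS:i:60
"""


def write_example_sam(path: str | Path) -> Path:
    """Write a tiny SAM file with a secondary alignment, for parser tests."""
    path = Path(path)
    path.write_text(_EXAMPLE_SAM)
    return path
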