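# Methods

This note records the model implemented by `fuzzydea`, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Possibility scores for alignments

The method's primitive is a possibility degree π(r→g) ∈ (0, 1] for every
retained alignment: the degree to which gene *g* is a plausible origin of
read *r*. Possibilities are maxitive, not additive — a read that matches
two genes perfectly carries π = 1 on both, and nothing needs to sum to 1.
This is deliberately assumption-free: it encodes only "a worse alignment is
a less possible origin", with no generative model of multiread production.

Sources:

* **BLAST-style tabular hits** — π = (identity/100)·(coverage/100). The
  product is the default because identity alone ignores partial-length
  hits; an identity-only flag exists. Per-read scores are *not* rescaled to
  make the best hit 1 (the raw products already separate best from decoy
  hits). A zero score is floored at 1e-6 with a warning rather than
  dropped, since a recorded alignment is never strictly impossible.
* **SAM** — `mapq` mode scales column 5 by 255 (records at MAPQ 0 get a
  configurable floor, default 1/255). Because most aligners assign MAPQ 0
  to precisely the multireads this method cares about, the recommended
  `tag` mode instead scales a per-alignment score tag (default `AS`) by the
  read's best score, so every read's best alignment is fully possible.
  The pipeline default is `tag`.

Duplicate (read, gene) pairs collapse to the maximum possibility: the
possibility of an event is the best way it can occur.

## Fuzzy read counts

The exact possibility that a gene received k reads is a max-min
combinatorial quantity: the best way of choosing k of the reads touching
the gene as true matches (each contributing its π on the gene) while the
remaining reads are false matches. The false-match possibility of a read
is formalised here as its best possibility on any *other* gene, and 0 for a
read unique to the gene — the only reading under which a gene with a
unique read has possibility 0 of count 0. `discrete_possibility` computes
this by exhaustive enumeration (2^n subsets, capped at n = 20) and serves
as the oracle for the summary used everywhere else:

* A = number of reads unique to the gene,
* B = reads with the gene as strict best match,
* C = reads with the gene among the best matches (ties included),
* D = all reads touching the gene,

giving the trapezoid Tr[A−1, B, C, D+1] (membership 1 on [B, C], linear
shoulders, the ±1 extension granting non-null possibility to the extreme
counts A and D). The support/plateau of the enumeration equal [A, D] and
[B, C] whenever every read's best possibility is 1 — true for tag-scored
SAM input and for the synthetic generator; for raw BLAST products with a
sub-perfect best hit the plateau of the enumeration can sit below 1 while
the trapezoid idealises it to 1. Property tests therefore exercise the
score-normalised convention.

Best-match comparisons use a tolerance `tie_tol` (default 1e-9) on the
possibility scale: "strict best" exceeds every alternative by more than
`tie_tol`; ties within `tie_tol` of the best count toward C.

**Centroids.** Each read is split across its genes proportionally to π
(a rescue-like assignment driven by mapping score rather than by unique
counts). Centroids conserve the sample's read total exactly and always lie
within [A, D].

**Replicates.** Technical replicates add reads, so the four parameters add
componentwise. Biological replicates merge into the envelope
Tr[min A, min B, max C, max D]; when the replicates disagree, every
intermediate count is treated as fully possible, on the grounds that
expression varies continuously across the non-independent cells of one
condition. Merging folds pairwise (well defined: the operation is
associative, commutative and idempotent). Condition centroids are the mean
of the replicate centroids (after normalisation); technical replicate
centroids sum.

## Normalisation

Median-of-ratios size factors: the factor of a sample is the median over
genes (positive in every sample) of the ratio between the sample's count
and the gene's geometric mean across samples; the median of an even number
of genes is the arithmetic mean of the two middle values (on the log
scale). Punctual counts feeding the computation are the centroids by
default; when multireads are sporadic (< 1% of reads, configurable) the
unique counts A are used instead. Trapezoids and centroids are divided by
the factor; the ±1 shoulder extension is applied at membership-evaluation
time on the *normalised* parameters, so a normalised count keeps a ±1-read
halo regardless of scaling.

## The significance envelope and the three DE concepts

Fold-change variability in null comparisons grows sharply at low counts.
The envelope ±t(m) over mean expression m is estimated by:

1. collecting null (m, log₂FC) points — from within-condition
   replicate-vs-replicate comparisons when a condition has ≥ 2 biological
   replicates (a comparison with no true DE in it), otherwise from the
   case-vs-control cloud itself (valid under the usual assumption that only
   a minority of genes change);
2. binning m on a log-spaced grid (default 12 bins, ≥ 3 points per bin)
   and taking the per-bin quantile q of |log₂FC| (default q = 0.99);
3. least-squares fitting t(m) = a/(m+c) + b with a > 0 (strictly
   decreasing), b ≥ 0, c ≥ 0 to the bin quantiles at the bins' geometric
   centres.

If the parametric fit fails, a monotone interpolated envelope of the bin
quantiles is used; with fewer than three populated bins (toy inputs) a
piecewise-constant envelope is used, with a warning. Outside the fitted m
range, t is clamped to the range endpoints. A floor t ≥ 1e-3 log₂ units
keeps the derived widths finite when replicates are nearly identical; the
floor is far below any biologically meaningful fold change and does not
affect realistic fits. The functional family, q, bin count and the
replicate-pair fitting source are recorded in the run's JSON sidecar.

Infinite fold changes (a zero on one side) are excluded from the fit but
handled in the verdicts via limits (below).

At a given m, three membership functions over log₂FC cross possibility 0.5
at ±t(m):

* *same*: Gaussian exp(−fc²/(2σ²)) with σ = t/√(2 ln 2) — peak 1 at fc = 0,
  0.5 at ±t;
* *over*: logistic 1/(1+exp(−s(fc−t))) with s = ln(99)/t, so the
  possibility of over-expression at fc = 0 is 0.01;
* *under*: the mirror image.

The 0.5 crossing is the defining constraint; the steepness rule (ln 99)
and the Gaussian width are this package's concrete choices for otherwise
under-determined shapes. All three have infinite support, so verdicts are
graded rather than thresholded.

## Sup-min intersection

The joint possibility that the case has x reads and the control y is the
min t-norm of the two trapezoid memberships (non-interacting counts). Each
DE possibility is the sup over (x, y) of the min between this relation and
the concept surface evaluated at m = (x+y)/2, fc = log₂(x/y).

Numerics: the joint support [max(A−1,0), D+1]² is sampled on a 64×64 grid
(configurable) with the trapezoid knots always included exactly; the
result is then polished by local grid refinement around the best few
coarse cells (two refinement rounds, six starts), which brings the
approximation error well below 0.01 and makes 64- and 128-point grids
agree to that tolerance. A *point* trapezoid (A=B=C=D, no multireads) is
treated as a crisp count — its axis carries the single value — so for two
point counts the sup-min reduces exactly to evaluating the three
membership functions at the gene's (m, fc), mirroring the view of an
unambiguous gene as a point in the MA plane. Cells with x = 0 or y = 0 use
the fold-change limits (Gaussian → 0, sigmoids → 0/1); a cell at the
origin carries no evidence of change. Two all-zero trapezoids return
(under, same, over) = (0, 1, 0) with a degenerate flag. By the 0.5-crossing
construction, at least one of the three possibilities is ≥ 0.5 for any
valid pair of counts.

Orientation: "over-expressed" means case above control; a `--direction`
flag relabels the comparison for datasets annotated the other way around.

## Pipeline and output

Order of operations: parse → per-sample trapezoids and centroids →
technical merge (sum) → size factors and normalisation → biological
envelope merge → envelope fit → per-gene verdicts. Genes absent from a
sample contribute the zero trapezoid; an empty gene intersection across
samples is an error, as is a single-condition design. The run is fully
deterministic: re-running on identical inputs is byte-identical.

Each output row carries the normalised case and control trapezoids (4
values each), the fuzzy fold change (4 values, "Inf"/"-Inf" literals
allowed), the three possibilities, both centroids and the centroid log₂FC.
Rows sort by ascending same-expression possibility (most trustworthy DE
first), ties broken by |centroid FC| descending, then gene id. Two
optional cuts: `--min-abs-fc F` keeps |centroid log₂FC| ≥ F, and
`--min-possibility P` keeps genes that are possibly DE (over or under ≥ P)
*and* not possibly unchanged (same < P). The second clause is essential:
a gene with wide multiread uncertainty can have over-possibility ≈ 1 in a
null comparison simply because a higher count is possible — exactly the
false-positive pattern the same-expression possibility exists to flag.

## Synthetic experiments

The generator emits per-sample possibility tables directly — the stage the
real pipeline reaches after alignment scoring — plus a ground-truth table.
Defaults describe the study conditions used throughout the tests:

* 1000 genes, baseline expression log-uniform between 50 and 1500 reads
  per sample; two conditions, two biological replicates each, per-sample
  counts Poisson around the (condition-scaled) baseline;
* 10 genes over-expressed at log₂FC +1 and 10 under-expressed at −1 in the
  case condition. Induced genes draw their baseline from the upper range
  (≥ 1250 reads): at baseline b the counting-noise sd of the recovered
  centroid log₂FC is about √(1.5/b)/ln 2 (the under-expressed case, whose
  halved condition dominates the variance), so b ≥ 1250 keeps a ±0.15
  recovery window at ≥ 3 sd;
* 100 paralog families of 3 genes among the null genes; half of the reads
  originating from a family gene also hit their siblings (overall ≈ 15% of
  reads are multireads, ≈ 30% of genes touched). The true gene always
  scores π = 1; sibling decoys score 1 − |N(0, 0.1)| truncated into
  (0.5, 1), mimicking near-perfect paralog cross-matches.

What this emulates: graded mapping ambiguity concentrated in paralog
families, count noise, replicate structure, library-size effects (via the
normalisation path). What it does not: positional/isoform structure,
sequencing-error profiles, fragment-length effects, condition-dependent
mapping ambiguity, or real biological replicate dispersion beyond Poisson.
Passing tests therefore demonstrate that the possibilistic calculus
recovers induced fold changes and separates multiread-driven uncertainty
from genuine change under idealised noise — not that it is calibrated for
any particular organism or protocol.

Test problem sizes are chosen for quick runs: the recovery experiment uses
the 1000-gene default above; unit tests use 100–300 genes; the exhaustive
oracle cross-check uses 200 random samples of ≤ 12 reads and ≤ 5 genes.

## Known limitations

* The biological-replicate envelope widens with every replicate and never
  narrows; with many replicates same-expression possibilities drift upward
  (conservative). A dispersion-aware merge is future work.
* The discrete-count oracle is exponential in the reads per gene and is a
  verification tool, not a production path.
* The false-match convention (best possibility on any other gene) is one
  consistent formalisation; alternatives (e.g. products over decoys) would
  yield different shoulder shapes between A..B and C..D.
* The envelope family a/(m+c)+b is a pragmatic reconstruction of the
  fold-change variability boundary; it is configurable and logged, and the
  isotonic fallback covers data it cannot fit.
* MAPQ-based scoring inherits MAPQ's hostility to multireads; use tag
  scoring whenever the aligner emits per-alignment scores.
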