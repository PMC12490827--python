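# Methods

## Data model and conventions

A methylation call is one (molecule, cytosine) observation. The package
works on *protection* = 1 − methylated: 1 means the cytosine escaped the
exogenous methyltransferase, i.e. was protein-bound. Call positions are
1-based (methylation-extractor convention); genomic intervals and all BED
I/O are 0-based half-open, with conversion confined to the I/O boundary.
Strand is collapsed and cytosine context (GpC vs CpG) is not modelled:
any position carrying a call is a feature, which keeps the method agnostic
to the footprinted base and applicable to m6A-based assays with the same
call format.

By default a molecule enters a window only if it covers **every** distinct
cytosine observed inside it (`min_coverage_fraction = 1.0`). Analysis
windows of ~80 bp are narrow enough that 150 bp paired-end fragments span
them, and the strict default avoids distances dominated by missing data.
It is configurable downward; retained molecules keep their full extent
(positions outside the window) so that footprints running off the edge can
be flagged rather than silently truncated.

## Smoothing

Each molecule's binary values are smoothed with a rolling mean over a
centred window of `window_bp` = 40 bp (a TF-footprint-scale bandwidth:
wide enough to suppress single flipped calls, narrow enough not to erase
short footprints). The window is closed at both ends — positions q with
|q − p| ≤ 20 contribute at p — a convention stated explicitly because it
is otherwise ambiguous; on a 1 bp grid an isolated impulse therefore
influences positions spanning exactly 40 bp around it. Smoothing is
evaluated at observed cytosines only, not on a dense per-bp grid: the
downstream features are read at cytosines, so the dense version adds cost
but no information. Missing values are excluded from the mean, never
imputed.

## Distances and clustering

Features are the smoothed values at in-window cytosines. For molecules
i, j sharing observed positions S out of P in-window positions,

    d(i,j) = sqrt( (P / |S|) * Σ_{p∈S} (x_ip − x_jp)² )

— plain Euclidean distance for fully observed rows, rescaled by P/|S|
otherwise (the pairwise-complete convention). Pairs with no shared
position get the maximum finite distance plus one unit, placing them
maximally far apart without breaking symmetry. With the strict coverage
default these fallback paths are rarely exercised.

Clustering is classic PAM (Kaufman–Rousseeuw): greedy BUILD, then
best-improvement SWAP repeated while total cost strictly decreases. The
classic variant was chosen over faster PAM variants because its behaviour
is auditable step by step and window-scale inputs (tens to a few thousand
molecules) make speed irrelevant. All ties — in BUILD, SWAP and
assignment — break toward the lowest molecule/medoid index, so the module
contains no randomness and identical inputs give identical partitions.
Local optimality (no improving single swap) is asserted by exhaustive scan
in tests; on tiny random instances (n ≤ 10, k ≤ 3) BUILD+SWAP has matched
the brute-force optimum, and the test suite enforces cost ≤ 1.05× optimum
as the hard bound.

The requested k (default 16) is reduced by exactly 1 per iteration, each
time re-running PAM from scratch, until every cluster holds at least
`min_cluster_size` = 5 molecules or k = 1. This floor caps the number of
reported occupancy patterns and absorbs technical noise into larger
clusters. A window with fewer molecules than the floor returns a single
cluster flagged `low_coverage` instead of raising, so genome-wide runs
survive sparse windows.

## Footprint detection

Detection deliberately returns to the **raw** binary values: per cluster,
the mean protection is computed at each position covered by ≥ 50% of the
cluster's molecules (the coverage floor keeps one-molecule flanks from
creating phantom footprints). A cytosine is footprinted when its mean
protection is strictly above the 50% threshold; strictness means an exact
50/50 split is called accessible. For binary data the mean exceeds 50%
exactly when the median does (up to ties), so "mean" vs "median" is not a
substantive choice here.

Maximal consecutive runs of footprinted cytosines become footprints; runs
break only at an accessible cytosine, never at a genomic gap without
observed cytosines. Width is measured first-to-last footprinted cytosine,
inclusive — the alternative of extending to the midpoints of the flanking
accessible cytosines was rejected for determinism on irregular grids.
Width classes: < 5 bp noise, 5–75 bp TF, 76–120 bp unclassified (the gap
between the TF and nucleosome ranges has no natural owner and is excluded
from default output), > 120 bp nucleosome. A run touching the first or
last profile position lacks an accessible flank, so its full width cannot
be established: it is labelled "unrecognized", and this overrides any
width label.

## Aggregation and frequencies

TF footprints from different clusters are nodes of a graph with an edge
when both overlap fractions reach `min_overlap` = 0.75 — the reciprocal
reading prevents a 10 bp footprint from merging into a 70 bp one — or when
both map to the same motif (largest-overlap assignment, ≥ 1 bp, ties to
the lowest start then lexicographic name). Connected components become
aggregates: merging is transitive by design, since footprints of one
factor shift gradually across clusters and form chains. Consensus
boundaries are molecule-count-weighted means of member boundaries, rounded
half-up; weighting by evidence is the least surprising of the open
choices (union and intersection were considered and rejected as
systematically too wide/narrow).

A cluster contributes its molecules to an aggregate at most once, so an
aggregate's frequency — molecules in contributing clusters over all
molecules in the window — never exceeds 1. Distinct footprints may share
clusters (co-binding), so frequencies may sum above 1 *across* rows.
Nucleosome footprints are reported per cluster and not aggregated:
nucleosome positioning heterogeneity is signal, not noise, and merging
shifted nucleosomes would blur unphased arrays.

## Simulator

The simulator emulates what a methylation extractor hands downstream:
binary calls on a sparse cytosine grid (explicit positions, or irregular
4–12 bp spacing mimicking GpC/CpG density in regulatory DNA), molecules
drawn from a declared mixture of occupancy patterns, and independent
per-call flip noise. It does **not** model bisulfite conversion errors,
read-pair geometry, PCR duplicates, context-dependent enzyme efficiency or
partial molecule coverage (every simulated molecule spans the full grid) —
so passing tests demonstrate algorithmic correctness on idealized input,
not robustness to those artefacts. All randomness flows from the mandatory
seed; identical specs give byte-identical tables.

`make_boundary_fixture` builds the degenerate case used to probe decision
boundaries: a single protected stretch whose first and last protected
cytosines are exactly width − 1 bp apart on a regular grid, with ≥ 5
accessible cytosines on each flank and zero noise, so the detected width
equals the constructed width exactly.

## Pipeline and problem sizes

Regions wider than the tile width (80 bp) are split into consecutive
non-overlapping tiles processed independently; footprints are not
deduplicated across tile borders (a documented limitation — a footprint
straddling a border appears once per tile, typically as "unrecognized").

Tests and the acceptance script run on windows of 100–400 bp with 20–200
molecules — the scale of one real bait-captured locus — which exercises
every code path while keeping the whole suite in the seconds range. The
end-to-end recovery checks (two-pattern mixture, 200 molecules, 5% flip
noise) run clustering with k set to the number of simulated patterns:
with the default k = 16, PAM legitimately over-partitions noisy data into
pure sub-clusters, which preserves the TF frequency at the true site but
fragments the nucleosome calls of small sub-clusters; matching k to the
truth isolates the frequency-recovery property being tested. The default
k = 16 behaviour is itself tested separately (20 well-populated patterns
→ exactly 16 clusters, all ≥ 5 molecules).

## Known limitations

- No cross-tile footprint deduplication.
- Windows are analysed independently; no genome-wide joint model.
- The 76–120 bp "unclassified" class is reported only on request; callers
  interested in subnucleosomal particles should lower `--nuc-gt`.
- Frequencies are cluster-level: a footprint absent from a cluster's
  average but present on a minority of its molecules is not counted.
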