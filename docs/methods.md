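# Methods

## Coordinate and data conventions

All intervals are 0-based half-open (BED native) internally; GTF input is
converted at the parse boundary. Chromosome names are used verbatim — mixing
`chr1` and `1` datasets requires the explicit `harmonize_chr_prefix` read
option, so harmonization is auditable rather than silent. Coverage is stored
as fixed-width binned arrays per chromosome (default 50 bp bins). A bedGraph
record partially covering a bin contributes its length-weighted share and
uncovered positions count as zero, so the binned track conserves integrated
mass exactly (∑ bin × width = ∑ value × record length); overlapping bedGraph
records are rejected. Chromosomes absent from a track read as all-zero with
a warning instead of failing, because multi-marker datasets rarely cover
identical chromosome sets.

## Signal model

`rpkm_normalize` converts a per-bin read count c to c·10⁹/(w·N) for bin
width w and library size N (reads per kilobase per million). Region scores
are signal areas: ∑ over overlapping bins of bin value × overlapped width,
which is additive over partitions and invariant to bin refinement for
piecewise-constant tracks. Control (input) subtraction is available but off
by default, with clamping at zero; negative scores cannot enter the cutoff
computation. Profile matrices sample equal sub-windows of
[center − flank, center + flank) (reference-point) or the rescaled body plus
flanks (scale-regions); minus-strand rows are reversed and out-of-bounds
positions read zero so all rows have equal length. In scale-regions mode the
number of flank bins per side is a free parameter (default `n_bins // 2`);
profile window sizes are configuration, not claims about any particular
dataset.

## SE identification

Stitching merges consecutive peaks on a chromosome when the gap to the
growing region is ≤ the stitch distance (boundary inclusive; default
12.5 kb). Optional promoter filtering removes peaks fully inside TSS ± 2.5 kb
before stitching (off by default). Stitched regions are scored, sorted
ascending (ties by chromosome then start, so ranking is deterministic), and
the cutoff is placed on the unit-scaled rank–signal curve at
argmin (yᵢ − xᵢ) — the point where the supporting unit-slope line touches the
curve. Ties in the argmin resolve to the largest index and the SE comparison
is strict (> cutoff), so flat or exactly-linear curves yield zero SEs and
the tangent-point region itself is a TE: degenerate inputs fail safe toward
"no super-enhancers". An all-zero curve is degenerate (cutoff 0, no SEs);
a single stitched region is conservatively a TE, since one point defines no
curve. Because both axes are scaled, SE/TE membership is invariant to
positive rescaling of the track.

## Dynamics and consensus

Gain/lost/shared classification is presence/absence only (the package
deliberately does not test differential SE signal quantitatively): a treated
SE is shared when some control SE overlaps it by
≥ max(1 bp, f × shorter length) with f = 0 by default — the most permissive
reading, configurable when stricter reciprocal overlap is wanted. The
consensus across datasets keeps a region of the first dataset iff every
other dataset has a gain SE overlapping it under the same rule, and reports
the intersection span of the best-overlapping representatives. With at most
one representative per dataset per locus (the realistic regime for SE-scale
intervals) the result is invariant to dataset order; pathological nestings
where several representatives tie are resolved by largest overlap and may
depend on which dataset is listed first — a documented limitation. The
gene-level alternative intersects the nearest-TSS gene sets instead, which
is the better mode when datasets disagree on exact SE boundaries.

Nearest-TSS annotation uses the region center, floor((start+end)/2), against
strand-aware TSS positions (start for +, end − 1 for −), restricted to genes
on the same chromosome; ties go to the smaller TSS coordinate then
lexicographic gene id. Distance is reported as 0 when the center falls
inside the gene body.

## DEG integration

Benjamini–Hochberg adjustment (step-up, q capped at 1) fills missing
q-values; tables that already carry q-values are used as-is. Filtering is
boundary-inclusive: up = {log2fc ≥ t, q ≤ α}, down = {log2fc ≤ −t, q ≤ α},
defaults t = 1, α = 0.05. Candidate nomination is the exact, case-sensitive
triple intersection of SE-target, upregulated and disease gene sets;
identifiers differing only by case are flagged with a warning rather than
silently matched, since cross-species symbol mixing is a real failure mode.
The disease list carries no direction requirement by default (an optional
down-in-disease filter exists), because presence in the disease DEG set is
the weakest defensible criterion.

## Synthetic studies

The generator emulates a two-condition, multi-dataset enhancer landscape:
several datasets (cell line × marker) over one shared pseudo-assembly,
planted SE loci labelled shared-gain (treated-only, all datasets),
private-gain (treated-only, one dataset), lost (control-only) and
constitutive (both conditions), each a cluster of constituent peaks near its
target gene's TSS, plus isolated singleton background peaks. The genome is
partitioned into 45 kb slots so that features in different slots are
separated by > 12.5 kb and can never stitch together, and every planted
locus has a distinct target gene whose TSS is provably the nearest.

Coverage is a sum of boxcar bumps (amplitude 10 over SE constituents, 3 over
background peaks) plus zero-truncated Gaussian noise (σ = 1 by default).
Boxcars rather than peaked shapes keep region signals in closed form —
amplitude × length exactly when noiseless — so oracle tests are exact. All
peak coordinates are aligned to the bin width for the same reason. The DEG
table upregulates gain-SE targets (log2fc ~ N(2.5, 0.5), p ~ 10^U(−12,−8)),
downregulates lost-SE targets symmetrically, and draws null genes from
N(0, 0.3) with uniform p-values; the disease list contains the shared-gain
targets plus 30 random decoy genes. Everything derives from one seeded
generator, so identical parameters give byte-identical files.

Default sizes — 2 chromosomes × 10 Mb, 200 genes, 5 datasets, 1 shared-gain
+ 3 private-gain + 3 lost + 5 constitutive SEs per dataset, 4 constituents
of 1 kb spanning 30 kb per SE, 200 background peaks, 50 bp bins — keep a
full simulate → write → pipeline round under ~10 s while preserving the
qualitative structure: a long flat TE shelf with a sharp SE elbow on the
hockey-stick curve, and a single consensus locus.

What the simulation does **not** emulate: read-level sampling noise and
fragment-length effects, peak-caller boundary jitter, copy-number and
mappability artifacts, correlated chromatin domains, partially overlapping
SE boundaries between datasets, and cross-assembly coordinate differences.
Passing recovery tests therefore demonstrate the correctness of the interval
algebra, scoring, cutoff and set logic under the stated generative model —
not calling performance on real ChIP-seq, where peak quality and
normalization dominate.

## Numerical choices

Signal integration and mass-conservation checks use 1e-9 relative
tolerance; all set operations, stitching and cutoff placement are exact
integer/ordering logic. Score ties break by (chromosome, start); argmin ties
break to the largest index; annotation ties break to the smaller TSS then
gene id — every tie-break is deterministic, and the pipeline contains no
random stage (only the simulator consumes a seed). Pipeline configs are
validated eagerly with named-path errors before any stage runs; a failing
run still writes `report.json` with a `FAILED` status and the error message,
and successful reports embed every parameter, input checksums, and a
self-audit that recounts the emitted files.
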