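# Methods

## Coordinate conventions

All coordinates are 0-based, half-open (BED convention); GTF input is
converted on read (1-based inclusive start − 1). A `Genome` — an ordered
list of chromosome (name, length) pairs — fixes the coordinate universe
and the sort order of every interval collection. Coverage tracks are step
functions with bedGraph semantics: non-overlapping `(start, end, value)`
segments in RPM units, implicit 0 over uncovered bases. Interval means are
computed from the cumulative signal integral, so they are exact (no
binning) and O(log n) per query.

## Enhancer classifier

Two classes of genomic elements are featurized by the mean coverage of
each marker (DNase, H3K4me1, H3K27ac, H3K4me3) over the element:

- positives: a supplied set of known enhancer elements, used at their own
  spans (no length normalization);
- negatives: an equal number of gene promoters, TSS ± `promoter_flank`
  (default 1000 bp), drawn as a seed-deterministic uniform sample of the
  annotation; a sampled promoter overlapping an enhancer is resampled.

The element body alone is featurized by default (`feature_flank = 0`); a
symmetric flank can be configured and is stored in the model so training
and prediction always agree. One third of each class (`test_fraction =
1/3`, stratified, rounded half-up per class) is held out and scored as a
confusion matrix with "enhancer" as the positive class.

The classifier is a bagged ensemble of `n_trees = 500` decision trees
(scikit-learn `RandomForestClassifier`), `sqrt(#markers)` features per
split, unbounded depth — classical random-forest defaults. Predictions are
class probabilities; a window is classed enhancer at probability ≥ 0.5
(`prob_threshold`, exposed as a flag). The model is persisted as a single
joblib file with a format-version header plus markers, flank and seed, and
refuses to load on a version mismatch.

## Genome-wide calling

The genome is tiled into `window_size = 200` bp windows (final window per
chromosome truncated), each window is scored, and enhancer-classed windows
separated by gaps ≤ `merge_gap = 1` bp merge into continuous calls. A
merged call carries the *maximum* probability over its member windows —
the mean would dilute a strong central window with weak flanking ones.
Calls must overlap a DNase peak by ≥ `min_dhs_overlap = 1` bp to be
validated; the peak set is filtered on read at `dhs_q_max = 0.01` against
the narrowPeak −log10 q column, with the missing-value sentinel (−1)
failing the filter (validation must be conservative).

Validated calls are stratified by mean H3K27ac over the call: *active* at
or above the threshold, else *primed*. The default threshold is the
genome-wide mean of the H3K27ac track — an "above background" criterion
that adapts to library depth — and is overridable. eRNA quantification
reports the plus-strand mean as sense and minus-strand mean as antisense
coverage over the call span.

Metagene matrices cover call midpoints ± `metagene_flank = 3000` bp in
`metagene_bin = 50` bp bins (midpoint of an even-width call is
`start + width/2`); rows are ranked by decreasing mean of the ranking
track over the call, ties broken by genome order. Bins clipped at a
chromosome edge contribute the mean of their clipped part, zero-width
clips contribute 0.

## Signal normalization

- `rpgc_scale_factor = egs / (n_mapped × fragment_length)`: multiplying a
  raw fragment-pileup track by this factor makes the genome-wide mean
  coverage exactly 1 (1x depth).
- Effective genome size is the non-N base count of the FASTA (total
  genome length without one), and is always overridable. This is a
  deliberate approximation of mappability-based estimates: it keeps the
  scaling formula exact while avoiding a mappability model.
- Fragment length is estimated from strand-split read positions: plus 5′
  starts and minus 5′ ends are binned at 10 bp, and for each shift d in
  [0, max_shift] (default 400) the Pearson correlation between the plus
  density and the minus density shifted left by d is recorded; the
  estimate is the argmax, excluding shifts within read_length ± 10 bp
  (the phantom peak at the read length). Ties resolve to the smaller
  shift. The 10-bp bin bounds resolution at ±10 bp, which matches the
  accuracy the estimate is consumed at (read extension for pileups).

## Integration

FPKM_g = count_g × 1e9 / (length_g × library_total) with exonic-union
lengths; TPM_g = (count_g/length_g) × 1e6 / Σ_j (count_j/length_j), so TPM
sums to 1e6 whenever any count is positive. `library_total` defaults to
the sum of counts. Nearest-gene tables use unstranded edge-to-edge
distance (0 when overlapping; negative when the gene lies 5′ of the peak
on the forward axis), ties broken by (lower start, lexicographic id); a
TSS-anchored distance was considered but edge distance was chosen as the
default because peak-to-gene-body adjacency is what the join is used for.
Promoter-proximal co-occupancy windows are strand-aware: −250/+1000 bp
around the TSS with "upstream" meaning 5′ along the gene, so on the minus
strand the upstream arm extends toward larger coordinates. A gene is
co-occupied iff *every* supplied peak set overlaps its window by ≥ 1 bp;
genes sharing an id keep their first record in genome order.

## The simulator

The simulator emulates the input universe on a 2 × 1 Mb toy genome:
50 planted enhancers (60% active) and 150 genes, placed uniformly with
rejection sampling so any two planted elements are ≥ 2 kb apart. Signal
bumps are discretized Gaussians on a 10-bp grid:

| feature | tracks | shape |
|---|---|---|
| enhancer | DNase | central bump, amp 8, sd 100 |
| enhancer | H3K4me1 (+ H3K27ac if active) | bumps at center ± 250, amp 6, sd 120 — peak-valley-peak |
| active enhancer | GRO ± | divergent bumps at center ± 300, sd 150, amp 6 (sense) / 5 (antisense) |
| primed enhancer | GRO ± | same geometry, amp 1 |
| promoter | H3K4me3 amp 6 sd 250; DNase amp 5 sd 100; H3K4me1 amp 0.8 |
| expressed gene body | sense-strand GRO, flat 0.2 over the first 2 kb |

The 6:1 sense and 5:1 antisense active:primed eRNA amplitude ratios are
design defaults chosen to reflect the qualitative contrast between the
two states, not a fitted quantity. Background noise is exponential with
mean `0.05 × 8 / snr` (default snr 10) added to every bin; `snr = inf`
disables it. DHS peaks are one q-passing (−log10 q ∈ [2.5, 6]) 300-bp
peak per enhancer plus 40 background decoys with −log10 q < 2, so the
q < 0.01 filter removes exactly the decoys. Expression counts are
gamma-Poisson (dispersion 0.1) around planted log-normal means with a 10%
silent-gene fraction. Fragment-length fixtures place fragments uniformly;
plus reads start at fragment starts, minus reads end at fragment ends,
optionally with Poisson-distributed lengths.

Every simulator output is a pure function of (parameters, seed), and
every emitted file parses with the package's own readers.

**What the simulator does not model** — and hence what passing tests do
not show about real data: read-level noise (sequencing error, PCR
duplicates, mappability gaps), copy-number and GC biases, overlapping or
nested regulatory elements, enhancers inside gene bodies, cell-type
mixtures, and realistic class imbalance (real genomes are overwhelmingly
background; the planted density is chosen for test power, not realism).
The clean Gaussian signatures make the classification task easier than on
real tracks, so the near-perfect benchmark metrics characterize
correctness of the machinery, not expected field performance.

## Problem sizes and numerical notes

The benchmark used by the test suite and the acceptance script runs the
full pipeline on the default simulator (2 × 1 Mb genome, 10,050 scan
windows, 500-tree forest) across five seeds; oracle-equivalence checks
use ≥ 1000 randomized small instances per operation. These sizes keep the
whole suite within a couple of minutes on one CPU while leaving no stage
untested at scale boundaries (truncated windows, chromosome-edge clipping,
empty inputs).

Floating-point output (bedGraph values, probabilities) is written with
Python's shortest-repr formatting, which round-trips doubles exactly —
this is what makes "same seed, byte-identical outputs" hold. Scan results
are independent of chromosome processing order and of the sklearn thread
count; randomness enters only through explicit seeds.

## Known limitations

- Negatives are promoters only; there is no random-background class, so
  the classifier's behaviour on genomic background is an extrapolation
  (mitigated in practice by DHS validation).
- The fragment-length estimator implements the single cross-coverage
  maximum only — no multi-peak quality metrics.
- One TSS per gene id; multi-TSS genes keep their first record.
- No BAM/bigWig I/O: coverage arrives as bedGraph, read positions as TSV.
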