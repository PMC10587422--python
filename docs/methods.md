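# Methods

## Problem

Circular RNAs (circRNAs) are covalently closed RNA loops that bind
RNA-binding proteins (RBPs); a circRNA can act as a "sponge" whose bound
regions modulate the effective concentration of its protein partners.
Sequence-level classifiers answer only "does this window bind protein X?".
`circseg` instead treats binding-site discovery as 1-D semantic
segmentation: every nucleotide of a window receives a 0/1
(unbound/bound) label, analogous to pixel-level image segmentation.  This
keeps the positional information needed for motif extraction and removes
the need to fabricate negative sequences — the unbound positions of each
positive window are the negatives.

## Data model and window construction

Inputs are (sequence, binding interval) pairs: FASTA plus BED3+name.
Internally every coordinate is 0-based half-open on a circle; a BED
interval with `end <= start` wraps through the origin (circRNA has no
canonical linearization point, so wrap must be first-class).

A training window is cut around the midpoint of each binding interval,
`mid = floor((start + end) / 2)`, spanning `[mid - h, mid + h]` inclusive
for half-width `h ∈ {50, 100, 250}` — window lengths 101/201/501.  The
label array marks positions falling inside the interval.  Optional
negative windows are sampled uniformly from placements disjoint from the
interval; they are emitted for sequence-level comparisons but are not part
of segmentation training.  Redundant windows are removed by a greedy
ungapped-identity filter at threshold 0.8 (input order, keep-first), a
dependency-free stand-in for CD-HIT-style clustering; an externally
produced cluster file can be ingested instead.  Cross-validation uses a
seeded stratified 5-fold partition (positives/negatives stratified, fold
sizes within one).

One-hot encoding maps A/C/G/U to the four unit vectors (T is silently
normalized to U); ambiguous bases become all-zero rows, carry no
probability mass, and are excluded from motif counting.

## Architecture

The segmenter is a fully convolutional encoder-decoder over
`(positions, 4)` inputs:

- **Encoder** — feature-extraction modules of same-padded conv → ReLU →
  ceil-mode max-pool → dropout.  Defaults: 3 modules, kernel widths
  10/3/3, filters 16/32/64, pool factor 2, dropout 0.2.  The first-layer
  kernels double as 10-nt motif scanners whose weights are exposed for
  motif extraction.
- **Bottleneck (optional)** — global-average context injection: the
  per-channel positional mean is broadcast-added to every position.  Off
  by default (it showed no benefit in our grid runs, consistent with the
  motivation for making it a grid axis rather than a fixed part of the
  architecture).
- **Decoder** — deconvolutional modules of nearest-neighbour upsample →
  skip summation → batch norm → ReLU → conv.  Each module upsamples to the
  *recorded pre-pool length* of its mirrored encoder stage and sums with
  that stage's pre-pool activation; recording lengths makes odd lengths
  restore exactly (101 → 51 → 101 crops the final interpolated position).
  A width-1 conv adapter reconciles channel counts when a skip does not
  match.  The default decoder has 4 modules, the last a refinement module
  with upsample factor 1 that emits the 2-class head; summation happens
  after upsampling (the only ordering under which the operands have equal
  lengths).

Registered variants: `fcn-2x2` (2+2 stages), `fcn-3x3` (3+3), `fcn-3x4`
(3+4, default).  No dense layers anywhere, so output positions always
equal input positions for any window length.

All layers, backpropagation, and the Adam optimizer are implemented
directly on NumPy arrays (`circseg.nn`); gradients are verified against
finite differences in the test suite.  Batch norm uses batch statistics in
training and running averages (momentum 0.1) in eval.

## Loss

Bound sites are rare (~20% of a 101-nt benchmark window, ~2% of real
circRNA), so plain cross-entropy is dominated by easy negatives.  The
hard-negative-mining loss keeps the full positive term and restricts the
negative term to the hardest negatives:

    loss = mean(CE at label-1 sites) + mean(top-k CE at label-0 sites)
    k = max(1, floor(ratio * N_neg)),   ratio ∈ (0, 1]

Mining is batch-level (the standard reading; per-window mining is the
other possibility and is noted as unresolved), ties broken by site order.
With no positive sites the positive term is 0, keeping purely-negative
batches trainable.  The BCE baseline is the unweighted mean per-site
cross-entropy.  Grid values for the ratio: 0.3 / 0.5 / 0.7.

## Evaluation

Per-class intersection-over-union: `iou_c = |pred==c ∩ true==c| /
|pred==c ∪ true==c|`, `miou` their mean.  Counts are pooled over all
positions of the evaluated fold before division (micro-IoU); a class
absent from both prediction and truth scores 1.0 (vacuous agreement), with
raw counts exposed for re-aggregation.  The hyper-parameter grid crosses
window length (101/201/501) × loss (BCE, HNML at 3 ratios) × global
pooling (on/off) = 24 combinations, 8 per length; the selection rule fixes
the window length first, then maximizes `iou_1`, then `miou` — mirroring
the view that a nucleotide-level model should be judged on the bound
class, since longer windows inflate `iou_0` by adding easy negatives.

## Motif extraction

1. Predicted labels are collapsed into maximal runs of 1s with length ≥ 5
   (regions shorter than the kernel are extended symmetrically).
2. Inside each region every first-layer filter is slid over every
   admissible start; the arg-max (position, filter) pair yields one
   candidate k-mer (ties: leftmost, then lowest filter index).
3. Candidates are grouped by best filter and stacked into position
   frequency matrices; groups under 10 members are dropped.

Stacking requires alignment: a convolutional filter detects its motif at
an arbitrary constant register offset, so raw arg-max k-mers of one filter
are all displaced by the same shift and would yield a shifted consensus.
Predicted-region centres cannot fix this — the model centres its predicted
blobs on whatever it detects, so the register is unidentifiable from
predictions alone.  The window centre is a true anchor: positive windows
are constructed centred on the binding-interval midpoint, so the expected
motif start is `(M - W) // 2`.  Each group is shifted by the rounded mean
of its candidates' displacements from that anchor (outliers beyond one
motif width discarded; the mean, not the median, because placement jitter
spreads displacements near-uniformly and the median of a discrete uniform
sample is unstable).  `recenter=False` disables this.

PFMs are written in MEME minimal format (version 4, `ALPHABET= ACGU`) for
downstream comparison against motif databases, e.g. with TOMTOM; running
such comparisons is a user-side step.

## Distribution analyses

- **Positional histograms** count, per start position, windows whose
  log-odds score for a PFM (or exact match for a consensus) exceeds a
  threshold, default 75% of the maximum achievable score.
- **Sponge overlap** reports the fraction of histogram mass inside
  annotated binding intervals plus the smallest contiguous span holding
  ≥ 50% of the mass (two-pointer scan).
- **k-mer flank analysis** slides a width-12 window over each record,
  keeps k-mers above an occurrence threshold, and classifies each by
  which 50-nt quarter(s) of the window hold ≥ 30% of its positional mass:
  first quarter only → left-flank, last only → right-flank, first and
  last → both-flanks, any central quarter → binding-region.  The 4×50
  layout fits 201-nt windows; shorter windows are quartered
  proportionally with a logged warning.  The mass-fraction peak rule is
  this package's operationalization of an otherwise visual criterion.

## Synthetic benchmark

The generator emulates the structure of circRNA–RBP interaction data:
i.i.d. background circles (default 500 nt, uniform composition), one
binding region per circle (21 nt) placed uniformly, carrying one motif
instance sampled from a sharp 10-nt PWM (consensus probability 0.85),
jittered ≤ 3 nt around the region midpoint and corrupted per-base with
probability 0.05 (replacement drawn from the background composition).
Defaults were chosen once as a realistic single-motif regime: a 10-nt
core within a ~21-nt footprint matches typical CLIP-derived RBP sites,
and after centred window extraction it produces 101-nt windows whose
central fifth is bound — the qualitative imbalance the mined loss
targets.  What the generator does **not** model: read-pileup noise,
crosslink biases, multiple or overlapping binding proteins, composition
heterogeneity along the circle, or paralogous motif families.  Passing
the benchmark therefore demonstrates the pipeline's internal correctness
and sensitivity, not performance on real CLIP data.

## Training defaults and problem sizes

Adam (lr 1e-3, β = 0.9/0.999), batch 32, ≤ 30 epochs, early stop on the
training loss with patience 5 (no inner validation split); the best-loss
epoch's parameters are restored.  All randomness — initialization,
dropout, shuffling, fold assignment, simulation — derives from explicit
seeds, and identical seeds give bit-identical results.  The benchmark in
the test suite and `scripts/acceptance.py` uses 2,000 windows of length
101 with a single held-out fold and 3 training seeds; the grid-shape check
runs 1-epoch smoke training on 10-record datasets.  These sizes were
chosen so a complete desk-scale run finishes in minutes on one CPU core
while keeping the per-seed IoU stable to a few percent.

## Numerical choices and degenerate inputs

Ceil-mode pooling with −inf padding; upsample-and-crop to recorded
lengths; He initialization; loss computed in float64 via the log-sum-exp
trick; top-k selection by stable sort (deterministic under ties).  An
empty IoU union scores 1.0; an empty positional histogram yields a
flagged null overlap report; a binding interval that admits no disjoint
negative placement raises and the record is skipped with a log message.

## Known limitations

- The optimizer, filter counts, kernel widths, pooling factors and
  dropout rate are this package's declared defaults; grid results are
  comparable internally but not to any external run of the same
  architecture family.
- Register recentring assumes motifs concentrate near the window centre —
  true for midpoint-centred windows, not for arbitrary scanning windows;
  disable it (`recenter=False`) when that assumption fails.
- The redundancy filter honors the 0.8 identity threshold but not the
  word-filter heuristics of CD-HIT, so cluster membership can differ.
- Whether top-k mining should be per-window rather than per-batch is
  unresolved; batch-level is implemented.
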