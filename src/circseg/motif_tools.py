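"""Motif extraction and distribution analysis downstream of a trained model.

The extraction pipeline mirrors the filter-as-motif-scanner tradition of
convolutional sequence models: (1) predicted per-site labels are collapsed
into maximal runs ("predicted regions"); (2) inside each region, every
first-conv-layer filter is slid over every admissible start and the
arg-max (position, filter) pair yields one motif candidate; (3) candidates
grouped by their best filter are stacked — all share the kernel width, so no
alignment is needed — into position frequency matrices (PFMs), exportable in
MEME minimal format for downstream comparison against motif databases
(e.g. with TOMTOM).

Distribution analyses: positional histograms of motif matches across
windows, overlap of that mass with annotated binding ("sponge") intervals,
and the 12-mer flank analysis that classifies recurrent short sequences by
which 50-nt quarter of the window they concentrate in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataprep import ALPHABET, BindingInterval, LabeledWindow, one_hot_encode
from .synthdata import MotifModel

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# predicted regions and motif candidates
# ---------------------------------------------------------------------------

@dataclass
class PredictedRegion:
    window_id: str
    start: int
    end: int  # half-open, within the window
    mean_score: float = 0.0


def find_regions(
    labels: np.ndarray,
    min_run: int = 5,
    window_id: str = "window",
    scores: np.ndarray | None = None,
) -> list[PredictedRegion]:
    """Maximal runs of predicted 1s with length >= min_run, in order."""
    labels = np.asarray(labels).astype(np.int8)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    padded = np.concatenate([[0], labels, [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    regions = []
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            score = float(np.mean(scores[s:e])) if scores is not None else 0.0
            regions.append(PredictedRegion(window_id, int(s), int(e), score))
    return regions


@dataclass
class MotifCandidate:
    window_id: str
    subsequence: str
    position: int
    filter_index: int
    score: float
    # alignment context: window geometry plus flanking sequence so candidates
    # can be recentred when stacked into a PFM (see build_pfm)
    region_center: float = 0.0
    window_length: int = 0
    context: str = ""
    context_start: int = 0


#: flanking bases kept around each candidate so recentring can shift it
_CONTEXT_PAD = 8


def first_layer_activations(weights: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Valid-mode activations of the first-layer filters on one window.

    ``weights``: (k, 4, F); ``onehot``: (M, 4).  Returns (M - k + 1, F):
    row p is each filter's dot product with the k-mer starting at p.
    """
    k = weights.shape[0]
    M = onehot.shape[0]
    if k > M:
        raise ValueError("kernel wider than the window")
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(onehot, k, axis=0)  # (M-k+1, 4, k)
    return np.einsum("pck,kcf->pf", win, weights, optimize=True)


def score_candidates(
    model,
    window: LabeledWindow | str,
    regions: list[PredictedRegion],
) -> list[MotifCandidate]:
    """Best-scoring (position, filter) pair per predicted region.

    Regions shorter than the kernel width are extended symmetrically within
    the window (skipped with a log message when even that fails).  Ties go
    to the leftmost position, then the lowest filter index.
    """
    seq = window.sequence if isinstance(window, LabeledWindow) else window
    wid = window.seq_id if isinstance(window, LabeledWindow) else "window"
    W = model.first_conv_weights  # (k, 4, F)
    k = W.shape[0]
    M = len(seq)
    onehot = one_hot_encode(seq)
    acts = first_layer_activations(W, onehot)  # (M-k+1, F)
    out: list[MotifCandidate] = []
    for reg in regions:
        s, e = reg.start, reg.end
        if e - s < k:
            deficit = k - (e - s)
            s = max(0, s - deficit // 2 - deficit % 2)
            e = min(M, s + k)
            s = max(0, e - k)
        lo, hi = s, min(e - k, M - k)
        if hi < lo:
            log.info("region [%d,%d) on %s too short for width-%d scan; skipped",
                     reg.start, reg.end, wid, k)
            continue
        block = acts[lo : hi + 1]  # rows = starts lo..hi
        # C-order argmax: leftmost position first, then lowest filter index
        p_off, f = np.unravel_index(np.argmax(block), block.shape)
        pos = lo + int(p_off)
        ctx_start = max(0, pos - _CONTEXT_PAD)
        out.append(
            MotifCandidate(
                window_id=wid,
                subsequence=seq[pos : pos + k],
                position=pos,
                filter_index=int(f),
                score=float(block[p_off, f]),
                region_center=0.5 * (reg.start + reg.end),
                window_length=M,
                context=seq[ctx_start : pos + k + _CONTEXT_PAD],
                context_start=ctx_start,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PFMs and MEME minimal format
# ---------------------------------------------------------------------------

@dataclass
class PFM:
    """Position frequency matrix: 4 x W over A,C,G,U; columns sum to 1."""

    name: str
    matrix: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("matrix must be 4 x W")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("every PFM column must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))


def _recentred_subsequences(group: list[MotifCandidate], W: int) -> list[str]:
    """Shift a filter group's candidates by the group's register bias.

    A convolutional filter detects its motif at an arbitrary fixed offset
    from the motif start, so the raw arg-max k-mers of one filter are all
    displaced by the same shift.  Positive windows are constructed centred
    on the annotated binding interval, whose midpoint carries the motif, so
    the expected motif start is the window-centred position (M - W) // 2;
    the median displacement of a filter's arg-max positions from that
    anchor estimates the filter's register bias, and subtracting it aligns
    the stack without using any per-candidate ground truth.  The estimate
    is the rounded mean of the offsets after discarding outliers beyond one
    motif width (spurious candidates from background regions); per-sequence
    placement jitter spreads the offsets roughly uniformly, which makes the
    mean a much steadier centre estimate than the median.  Candidates whose
    shifted span leaves the recorded context are dropped.
    """
    offsets = [
        (c.window_length - W) // 2 - c.position for c in group if c.window_length
    ]
    if not offsets:
        return [c.subsequence for c in group]
    inliers = [o for o in offsets if abs(o) <= W] or offsets
    delta = int(np.floor(float(np.mean(inliers)) + 0.5))  # symmetric rounding
    if delta == 0:
        return [c.subsequence for c in group]
    out = []
    for c in group:
        start = (c.position + delta) - c.context_start
        if c.context and 0 <= start and start + W <= len(c.context):
            out.append(c.context[start : start + W])
        elif not c.context:
            out.append(c.subsequence)
    return out


def build_pfm(
    candidates: list[MotifCandidate],
    min_support: int = 10,
    name_prefix: str = "filter",
    recenter: bool = True,
) -> list[PFM]:
    """Stack candidates by best filter into per-filter PFMs.

    With ``recenter`` (the default) each filter group is first shifted by
    its estimated register bias (see :func:`_recentred_subsequences`), so
    the PFM reads in the motif's own frame rather than the filter's.
    Candidates containing ambiguous bases are excluded from counting.
    Groups below ``min_support`` are dropped.  Output is ordered by support
    (descending), ties by filter index.
    """
    if not candidates:
        return []
    widths = {len(c.subsequence) for c in candidates}
    if len(widths) != 1:
        raise ValueError(f"candidates have mixed widths: {sorted(widths)}")
    (W,) = widths
    groups: dict[int, list[MotifCandidate]] = {}
    for c in candidates:
        groups.setdefault(c.filter_index, []).append(c)
    pfms = []
    for f, members in groups.items():
        seqs = _recentred_subsequences(members, W) if recenter else [
            c.subsequence for c in members
        ]
        seqs = [s for s in seqs if all(b in ALPHABET for b in s)]
        if len(seqs) < min_support:
            continue
        counts = np.zeros((4, W))
        for s in seqs:
            for i, b in enumerate(s):
                counts[ALPHABET.index(b), i] += 1
        pfms.append(
            PFM(name=f"{name_prefix}_{f}", matrix=counts / counts.sum(axis=0),
                n_sites=len(seqs))
        )
    pfms.sort(key=lambda p: (-p.n_sites, p.name))
    return pfms


def write_meme(
    pfms: list[PFM],
    path,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """MEME minimal motif format (version 4, RNA alphabet)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGU", "",
             "Background letter frequencies"]
    lines.append(" ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, background)))
    lines.append("")
    for pfm in pfms:
        lines.append(f"MOTIF {pfm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pfm.width} "
            f"nsites= {pfm.n_sites} E= 0"
        )
        for col in pfm.matrix.T:
            lines.append(" " + " ".join(f"{v:.6f}" for v in col))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_meme(path) -> list[PFM]:
    """Reader for the minimal format written by :func:`write_meme`."""
    pfms: list[PFM] = []
    name = None
    rows: list[list[float]] = []
    n_sites = 1
    expect_w = 0

    def flush():
        nonlocal name, rows
        if name is not None and rows:
            mat = np.array(rows).T  # rows are positions -> 4 x W
            mat = mat / mat.sum(axis=0)  # renormalize rounded columns
            pfms.append(PFM(name=name, matrix=mat, n_sites=n_sites))
        name, rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush()
                name = line.split(maxsplit=1)[1].split()[0]
            elif line.startswith("letter-probability matrix"):
                toks = line.replace("=", " = ").split()
                if "w" in toks:
                    expect_w = int(toks[toks.index("w") + 2])
                n_sites = int(toks[toks.index("nsites") + 2]) if "nsites" in toks else 1
            elif name is not None and line and (line[0].isdigit() or line[0] == "."):
                vals = [float(t) for t in line.split()]
                if len(vals) == 4:
                    rows.append(vals)
    flush()
    for p in pfms:
        if expect_w and p is pfms[-1] and p.width != expect_w:
            log.warning("motif %s: parsed width %d", p.name, p.width)
    return pfms


# ---------------------------------------------------------------------------
# positional distributions
# ---------------------------------------------------------------------------

@dataclass
class PositionalHistogram:
    """Per-start-position match counts across a set of equal-length windows."""

    window_length: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.window_length:
            raise ValueError("counts must have one entry per window position")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _pattern_matcher(pattern, score_threshold, background):
    """Returns (width, fn(seq, start) -> bool)."""
    if isinstance(pattern, str):
        pat = pattern.upper().replace("T", "U")
        return len(pat), lambda seq, p: seq[p : p + len(pat)] == pat
    if isinstance(pattern, PFM):
        mat = pattern.matrix
    elif isinstance(pattern, MotifModel):
        mat = np.asarray(pattern.pwm).T
    else:
        mat = np.asarray(pattern)
    if mat.shape[0] != 4:
        raise ValueError("PFM pattern must be 4 x W")
    bg = np.asarray(background, dtype=float)
    logodds = np.log2(np.clip(mat, 1e-9, None) / bg[:, None])
    max_score = logodds.max(axis=0).sum()
    thr = 0.75 * max_score if score_threshold is None else score_threshold
    W = mat.shape[1]
    idx = {b: i for i, b in enumerate(ALPHABET)}

    def match(seq, p):
        s = 0.0
        for i in range(W):
            j = idx.get(seq[p + i])
            if j is None:
                return False
            s += logodds[j, i]
        return s >= thr

    return W, match


def motif_distribution(
    windows: list[LabeledWindow] | list[str],
    pattern,
    score_threshold: float | None = None,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PositionalHistogram:
    """Histogram over start positions of pattern matches.

    ``pattern`` may be a consensus string (exact match), a :class:`PFM`, a
    :class:`~circseg.synthdata.MotifModel`, or a raw 4 x W matrix (log-odds
    scan against ``background``; default threshold 75% of the maximum
    achievable score).
    """
    seqs = [w.sequence if isinstance(w, LabeledWindow) else w for w in windows]
    if not seqs:
        raise ValueError("no windows")
    M = len(seqs[0])
    W, match = _pattern_matcher(pattern, score_threshold, background)
    if W > M:
        raise ValueError("pattern wider than the windows")
    counts = np.zeros(M, dtype=np.int64)
    for seq in seqs:
        for p in range(len(seq) - W + 1):
            if match(seq, p):
                counts[p] += 1
    return PositionalHistogram(window_length=M, counts=counts)


@dataclass
class OverlapReport:
    """Fraction of histogram mass inside annotated intervals, plus the
    smallest contiguous span holding >= 50% of the mass."""

    fraction: float | None
    main_interval: tuple[int, int] | None
    empty: bool = False


def sponge_overlap(
    hist: PositionalHistogram, intervals: list[BindingInterval] | list[tuple[int, int]]
) -> OverlapReport:
    """Overlap of a positional distribution with binding ("sponge") intervals.

    Intervals are half-open on the histogram's coordinate axis.  An empty
    histogram yields a flagged null.
    """
    if hist.total == 0:
        return OverlapReport(fraction=None, main_interval=None, empty=True)
    inside = np.zeros(hist.window_length, dtype=bool)
    for iv in intervals:
        s, e = (iv.start, iv.end) if isinstance(iv, BindingInterval) else iv
        inside[s:e] = True
    frac = float(hist.counts[inside].sum() / hist.total)

    # smallest window holding >= 50% of the mass (two-pointer scan)
    target = 0.5 * hist.total
    c = hist.counts
    best: tuple[int, int] | None = None
    left = 0
    acc = 0
    for right in range(len(c)):
        acc += c[right]
        while acc - c[left] >= target:
            acc -= c[left]
            left += 1
        if acc >= target and (best is None or right + 1 - left < best[1] - best[0]):
            best = (left, right + 1)
    return OverlapReport(fraction=frac, main_interval=best)


# ---------------------------------------------------------------------------
# 12-mer flank analysis
# ---------------------------------------------------------------------------

@dataclass
class KmerStats:
    kmer: str
    total: int
    positional_counts: np.ndarray = field(repr=False)
    distribution_type: str = "unclassified"


_QUARTER_TYPES = {
    frozenset({0}): "left-flank",
    frozenset({3}): "right-flank",
    frozenset({0, 3}): "both-flanks",
}


def kmer_flank_analysis(
    windows: list[LabeledWindow] | list[str],
    k: int = 12,
    count_threshold: int = 10,
    peak_fraction: float = 0.3,
) -> list[KmerStats]:
    """Count width-k subsequences per start position and classify the
    frequent ones by where their mass concentrates.

    Every window is quartered (50/50/50/51 for 201-nt windows, the layout
    the four-interval scheme was designed for; shorter windows are quartered
    proportionally with a logged warning).  A quarter is a *peak* when it
    holds at least ``peak_fraction`` of the k-mer's positional mass; peak
    sets map to left-flank / right-flank / both-flanks, and any peak in the
    two central quarters classifies the k-mer as binding-region.  When no
    quarter reaches the fraction, the arg-max quarter decides.

    Only k-mers with total occurrences >= ``count_threshold`` are returned,
    ordered by total (descending).
    """
    seqs = [w.sequence if isinstance(w, LabeledWindow) else w for w in windows]
    if not seqs:
        raise ValueError("no windows")
    M = len(seqs[0])
    if k > M:
        raise ValueError(f"k={k} exceeds window length {M}")
    if M < 200:
        log.warning(
            "window length %d < 4 x 50; quartering proportionally (%s)",
            M, "/".join(str(q) for q in _quarter_lengths(M)),
        )
    n_starts = M - k + 1
    counts: dict[str, np.ndarray] = {}
    for seq in seqs:
        for p in range(n_starts):
            kmer = seq[p : p + k]
            arr = counts.get(kmer)
            if arr is None:
                arr = counts[kmer] = np.zeros(n_starts, dtype=np.int64)
            arr[p] += 1

    bounds = np.cumsum([0] + _quarter_lengths(M))
    out = []
    for kmer, arr in counts.items():
        total = int(arr.sum())
        if total < count_threshold:
            continue
        mass = np.array([
            arr[max(0, bounds[q]) : bounds[q + 1]].sum() for q in range(4)
        ], dtype=float)
        mass /= mass.sum()
        peaks = frozenset(np.flatnonzero(mass >= peak_fraction).tolist())
        if not peaks:
            peaks = frozenset({int(mass.argmax())})
        if peaks & {1, 2}:
            dist = "binding-region"
        else:
            dist = _QUARTER_TYPES.get(peaks, "binding-region")
        out.append(KmerStats(kmer=kmer, total=total, positional_counts=arr,
                             distribution_type=dist))
    out.sort(key=lambda s: (-s.total, s.kmer))
    return out


def _quarter_lengths(M: int) -> list[int]:
    q = M // 4
    return [q, q, q, M - 3 * q]


def plot_histogram(hist: PositionalHistogram, path, title: str = "") -> None:
    """Write a simple positional-distribution plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.bar(np.arange(hist.window_length), hist.counts, width=1.0)
    ax.set_xlabel("window position")
    ax.set_ylabel("matches")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
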