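"""Window construction for nucleotide-level binding-site segmentation.

A circRNA is a covalently closed loop, so every coordinate here lives on a
circle: intervals are 0-based half-open and an interval with ``end <= start``
wraps through the origin.  Training units are fixed-length windows centred on
the midpoint of an annotated protein-binding interval, with a per-site 0/1
label array marking the bound positions ("positive" windows), plus optional
windows sampled from the unbound remainder of the circle ("negative" windows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: supported half-widths -> window lengths 101 / 201 / 501
HALF_WIDTHS = (50, 100, 250)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map T->U (DNA input is silently treated as RNA)."""
    return seq.upper().replace("T", "U")


@dataclass
class CircSequence:
    """A (possibly circular) RNA sequence."""

    id: str
    bases: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.bases = normalize_sequence(self.bases)
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.bases)

    def fetch(self, start: int, end: int) -> str:
        """Substring on circular coordinates; ``end`` may exceed len or start may be negative."""
        n = len(self.bases)
        if end - start > n:
            raise ValueError("requested span longer than the sequence")
        if not self.circular and (start < 0 or end > n):
            raise IndexError(
                f"window [{start},{end}) outside linear sequence {self.id!r} of length {n}"
            )
        return "".join(self.bases[i % n] for i in range(start, end))


@dataclass
class BindingInterval:
    """0-based half-open protein-binding interval on a circular sequence.

    ``end <= start`` signals wrap through the origin; the length is then
    ``circ_len - start + end``.
    """

    seq_id: str
    start: int
    end: int

    def positions(self, circ_len: int) -> np.ndarray:
        """The set of circle positions covered, as an int array."""
        if self.start < 0 or self.start >= circ_len:
            raise ValueError(f"start {self.start} outside circle of length {circ_len}")
        if self.end > self.start:
            return np.arange(self.start, self.end)
        # wrapped
        return np.concatenate([np.arange(self.start, circ_len), np.arange(0, self.end)])

    def length(self, circ_len: int) -> int:
        return len(self.positions(circ_len))

    def contains(self, pos: int, circ_len: int) -> bool:
        pos %= circ_len
        if self.end > self.start:
            return self.start <= pos < self.end
        return pos >= self.start or pos < self.end


@dataclass
class LabeledWindow:
    """A fixed-length window plus the per-site 0/1 label array the model trains on."""

    seq_id: str
    sequence: str
    labels: np.ndarray
    provenance: str = "positive"  # positive | negative
    window_start: int | None = None  # circle coordinate of window position 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.labels) != len(self.sequence):
            raise ValueError("label array length must equal window length")
        if self.provenance == "positive" and self.labels.sum() < 1:
            raise ValueError("positive window must contain at least one label-1 site")
        if self.provenance == "negative" and self.labels.sum() != 0:
            raise ValueError("negative window must contain no label-1 sites")

    def __len__(self) -> int:
        return len(self.sequence)


def interval_midpoint(iv: BindingInterval, circ_len: int) -> int:
    """Midpoint of a (possibly wrapped) half-open interval: floor((start+end)/2)."""
    end = iv.end if iv.end > iv.start else iv.end + circ_len
    return ((iv.start + end) // 2) % circ_len


def extract_positive_window(
    seq: CircSequence, iv: BindingInterval, half_width: int
) -> LabeledWindow:
    """Cut the window centred on the binding-interval midpoint.

    The window spans ``[mid - half_width, mid + half_width]`` inclusive, i.e.
    ``2*half_width + 1`` positions (101/201/501 for half-widths 50/100/250),
    wrapping through the origin on circular sequences.  ``labels[i]`` is 1
    exactly where window position *i* falls inside the interval.
    """
    n = len(seq)
    if iv.length(n) < 1:
        raise ValueError("empty binding interval")
    mid = interval_midpoint(iv, n)
    start = mid - half_width
    end = mid + half_width + 1
    window = seq.fetch(start, end)
    labels = np.fromiter(
        (1 if iv.contains(p, n) else 0 for p in range(start, end)),
        dtype=np.int8,
        count=end - start,
    )
    return LabeledWindow(
        seq_id=seq.id,
        sequence=window,
        labels=labels,
        provenance="positive",
        window_start=start % n,
    )


def sample_negative_window(
    seq: CircSequence,
    iv: BindingInterval,
    length: int,
    rng: np.random.Generator,
) -> LabeledWindow:
    """Uniformly pick a window of ``length`` disjoint from the binding interval.

    Raises ``ValueError`` when no disjoint placement exists (callers should
    skip the record and log).
    """
    n = len(seq)
    bound = set(iv.positions(n).tolist())
    starts = [
        s
        for s in range(n)
        if not any(((s + off) % n) in bound for off in range(length))
    ]
    if not starts:
        raise ValueError(
            f"no window of length {length} disjoint from the binding interval on {seq.id!r}"
        )
    s = int(rng.choice(starts))
    return LabeledWindow(
        seq_id=seq.id,
        sequence=seq.fetch(s, s + length),
        labels=np.zeros(length, dtype=np.int8),
        provenance="negative",
        window_start=s,
    )


def one_hot_encode(sequence: str | LabeledWindow) -> np.ndarray:
    """Encode a window as an M x 4 one-hot matrix (columns A, C, G, U).

    Ambiguous symbols (e.g. N) become all-zero rows with a warning; clean rows
    each sum to exactly 1.
    """
    if isinstance(sequence, LabeledWindow):
        sequence = sequence.sequence
    sequence = normalize_sequence(sequence)
    mat = np.zeros((len(sequence), 4), dtype=np.float32)
    unknown = 0
    for i, b in enumerate(sequence):
        j = _BASE_INDEX.get(b)
        if j is None:
            unknown += 1
        else:
            mat[i, j] = 1.0
    if unknown:
        warnings.warn(
            f"{unknown} ambiguous base(s) encoded as all-zero rows", stacklevel=2
        )
    return mat


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` on the clean alphabet; zero rows -> 'N'."""
    out = []
    for row in np.asarray(mat):
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(ALPHABET[int(np.argmax(row))])
    return "".join(out)


def encode_batch(windows: list[LabeledWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack L windows of length M into an (L, M, 4) array and an (L, M) label array."""
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"windows have mixed lengths: {sorted(lengths)}")
    X = np.stack([one_hot_encode(w) for w in windows])
    y = np.stack([w.labels for w in windows]).astype(np.int64)
    return X, y


def pairwise_identity(a: str, b: str) -> float:
    """Global ungapped identity: matching positions / length (equal lengths)."""
    if len(a) != len(b):
        raise ValueError("identity is defined for equal-length windows")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def redundancy_filter(
    windows: list[LabeledWindow], identity_threshold: float = 0.8
) -> list[LabeledWindow]:
    """Greedy redundancy removal at a fixed identity threshold.

    Scans windows in input order and keeps one iff its ungapped identity to
    every previously kept window is strictly below the threshold — a
    dependency-free stand-in for greedy CD-HIT-style clustering at 0.8.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    kept: list[LabeledWindow] = []
    # integer codes make the pairwise comparison a vectorized equality test
    kept_codes: list[np.ndarray] = []
    for w in windows:
        code = np.frombuffer(w.sequence.encode(), dtype=np.uint8)
        redundant = any(
            (code == kc).mean() >= identity_threshold for kc in kept_codes
        )
        if not redundant:
            kept.append(w)
            kept_codes.append(code)
    return kept


def apply_cdhit_clusters(
    windows: list[LabeledWindow], cluster_of: dict[str, int]
) -> list[LabeledWindow]:
    """Keep one window per cluster using an externally produced clustering
    (e.g. a parsed CD-HIT ``.clstr`` file mapping window id -> cluster)."""
    seen: set[int] = set()
    kept = []
    for w in windows:
        c = cluster_of.get(w.seq_id)
        if c is None or c not in seen:
            kept.append(w)
            if c is not None:
                seen.add(c)
    return kept


@dataclass
class FoldSplit:
    """Assignment of each window to exactly one of k folds."""

    assignments: np.ndarray
    k: int = 5
    seed: int = field(default=0)

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


def make_folds(windows: list[LabeledWindow], k: int = 5, seed: int = 0) -> FoldSplit:
    """Seeded stratified partition into k near-equal folds.

    Stratification is by provenance (positive/negative) so each fold sees the
    same class mix; fold sizes differ by at most one.
    """
    if len(windows) < k:
        raise ValueError(f"need at least {k} windows for {k}-fold splitting")
    strata = np.array([0 if w.provenance == "positive" else 1 for w in windows])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(windows), dtype=np.int64)
    if len(np.unique(strata)) == 1:
        # StratifiedKFold rejects a single class; plain seeded partition
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(windows))
        for f in range(k):
            assignments[order[f::k]] = f
    else:
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(windows)), strata)):
            assignments[test_idx] = f
    return FoldSplit(assignments=assignments, k=k, seed=seed)
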