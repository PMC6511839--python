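"""Design, validation, and error-correcting decoding of multiplex sample indexes.

Samples pooled in one sequencing run are distinguished by a fixed-length DNA
index (8 nt by default) read alongside the UMI on the index read.  Decoding
must tolerate sequencing errors: a set of indexes whose minimum pairwise
Hamming distance is ``2e + 1`` can correct up to ``e`` substitutions
unambiguously (sphere-packing).  The default design — 8-mers at minimum
distance 3 — corrects any single substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IndexSet",
    "design_indexes",
    "greedy_code",
    "min_pairwise_hamming",
    "hamming",
    "assign_index",
    "IndexDecoder",
]

_ALPHABET = "ACGT"
_BASE_TO_DIGIT = {b: i for i, b in enumerate(_ALPHABET)}
# N (or any non-ACGT symbol) is encoded as 255 so it mismatches every base.
_AMBIGUOUS = 255


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_TO_DIGIT.get(b, _AMBIGUOUS) for b in seq.upper()],
                    dtype=np.uint8)


def _decode_digits(digits: Iterable[int]) -> str:
    return "".join(_ALPHABET[d] for d in digits)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class IndexSet:
    """A sample ↔ index table with a guaranteed minimum pairwise distance.

    Parameters
    ----------
    entries
        ``(sample_id, index_seq)`` pairs.  All sequences must share one
        length ``L`` over {A,C,G,T} and all sample ids must be unique.
    min_distance
        Lower bound on the pairwise Hamming distance that the set is
        required (and verified) to satisfy.
    """

    entries: list[tuple[str, str]]
    min_distance: int = 3
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not self.entries:
            raise ValueError("IndexSet needs at least one entry")
        ids = [s for s, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")
        L = len(self.entries[0][1])
        for sid, seq in self.entries:
            if len(seq) != L:
                raise ValueError(f"index length mismatch for {sid!r}")
            if any(b not in _ALPHABET for b in seq.upper()):
                raise ValueError(f"index for {sid!r} contains non-ACGT symbols")
        if len(self.entries) >= 2:
            d = min_pairwise_hamming(self)
            if d < self.min_distance:
                raise ValueError(
                    f"minimum pairwise Hamming distance {d} violates the "
                    f"declared bound {self.min_distance}")
        self._validated = True

    # -- accessors ----------------------------------------------------------
    @property
    def length(self) -> int:
        return len(self.entries[0][1])

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def truncated(self, effective_len: int) -> "IndexSet":
        """Restrict every index to its first ``effective_len`` bases.

        Demultiplexing may use a prefix of the stored index.  The error
        tolerance of the truncated set is whatever its own minimum pairwise
        distance supports, which can be smaller than that of the full set.
        """
        if not 1 <= effective_len <= self.length:
            raise ValueError("effective length out of range")
        entries = [(sid, seq[:effective_len]) for sid, seq in self.entries]
        seqs = [e[1] for e in entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError(
                f"{effective_len}-base prefixes are not unique; cannot demultiplex")
        d = _min_pairwise(np.vstack([_encode(s) for s in seqs])) if len(seqs) > 1 else effective_len
        return IndexSet(entries, min_distance=min(self.min_distance, d))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path, min_distance: int = 1) -> "IndexSet":
        """Read a two-column ``sample_id<TAB>index_seq`` table (# comments ignored)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed index table line: {line!r}")
                entries.append((parts[0], parts[1].upper()))
        return cls(entries, min_distance=min_distance)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.entries:
                fh.write(f"{sid}\t{seq}\n")


def _min_pairwise(mat: np.ndarray) -> int:
    # all-pairs Hamming distance via broadcasting; fine up to a few thousand codes
    n = mat.shape[0]
    best = mat.shape[1]
    for i in range(n - 1):
        d = int((mat[i + 1:] != mat[i]).sum(axis=1).min())
        if d < best:
            best = d
    return best


def min_pairwise_hamming(index_set: IndexSet | Sequence[str]) -> int:
    """Minimum Hamming distance over all unordered pairs of indexes."""
    seqs = index_set.sequences if isinstance(index_set, IndexSet) else list(index_set)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences differ in length")
    return _min_pairwise(np.vstack([_encode(s) for s in seqs]))


def _all_kmers(length: int) -> np.ndarray:
    """All 4^length sequences as a (4^length, length) digit matrix, lexicographic."""
    if length > 12:
        raise ValueError("exhaustive enumeration limited to length <= 12")
    codes = np.arange(4 ** length, dtype=np.int64)
    shifts = 2 * np.arange(length - 1, -1, -1)
    return ((codes[:, None] >> shifts) & 3).astype(np.uint8)


def _has_homopolymer(digits: np.ndarray, run: int) -> np.ndarray:
    """Boolean mask of rows containing a homopolymer of length >= run."""
    n, L = digits.shape
    if run <= 1 or L < run:
        return np.ones(n, dtype=bool) if run <= 1 else np.zeros(n, dtype=bool)
    same = digits[:, 1:] == digits[:, :-1]
    hit = np.zeros(n, dtype=bool)
    # run of `run` identical bases == run-1 consecutive True in `same`
    for start in range(L - run + 1):
        hit |= same[:, start:start + run - 1].all(axis=1)
    return hit


def greedy_code(length: int, min_distance: int,
                forbid_homopolymer: int | None = None,
                max_count: int | None = None) -> list[str]:
    """Greedy lexicographic Hamming code over {A,C,G,T}^length.

    Scans all ``4**length`` sequences in lexicographic order (A<C<G<T) and
    retains each sequence whose distance to every previously retained
    sequence is at least ``min_distance``.  Deterministic by construction.

    Parameters
    ----------
    forbid_homopolymer
        If given, candidate sequences containing a homopolymer run of this
        length or longer are rejected before the distance check.
    max_count
        Stop once this many sequences have been retained; ``None`` exhausts
        the scan and returns the full greedy code.
    """
    if length < 1 or not 1 <= min_distance <= length:
        raise ValueError("require length >= 1 and 1 <= min_distance <= length")
    pool = _all_kmers(length)
    if forbid_homopolymer is not None:
        pool = pool[~_has_homopolymer(pool, forbid_homopolymer)]
    picked: list[np.ndarray] = []
    while pool.shape[0] and (max_count is None or len(picked) < max_count):
        first = pool[0]
        picked.append(first)
        keep = (pool != first).sum(axis=1) >= min_distance
        pool = pool[keep]
    return [_decode_digits(p) for p in picked]


def design_indexes(count: int, length: int = 8, min_distance: int = 3,
                   forbid_homopolymer: int | None = None,
                   sample_prefix: str = "S") -> IndexSet:
    """Design ``count`` indexes of the given length and pairwise distance.

    Uses the deterministic greedy lexicographic scan; raises if the
    constraints cannot accommodate ``count`` sequences.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    seqs = greedy_code(length, min_distance, forbid_homopolymer, max_count=count)
    if len(seqs) < count:
        raise ValueError(
            f"only {len(seqs)} length-{length} indexes exist at distance "
            f">= {min_distance} under the given constraints; {count} requested")
    width = len(str(count))
    entries = [(f"{sample_prefix}{i + 1:0{width}d}", s) for i, s in enumerate(seqs)]
    return IndexSet(entries, min_distance=min_distance)


class IndexDecoder:
    """Vectorised nearest-index decoder with bounded error correction.

    Decoding returns the unique sample whose index lies within
    ``max_correct`` substitutions of the observed sequence; ``None`` when no
    index qualifies or when two or more tie at the minimal qualifying
    distance (a tie is never guessed: mis-assignment is worse than loss for
    single-cell samples).  ``N`` bases mismatch every base.
    """

    def __init__(self, index_set: IndexSet, max_correct: int = 1):
        if max_correct < 0:
            raise ValueError("max_correct must be >= 0")
        self.index_set = index_set
        self.max_correct = max_correct
        self._mat = np.vstack([_encode(s) for s in index_set.sequences])
        self._ids = index_set.sample_ids
        self._exact = {seq: sid for sid, seq in index_set.entries}

    def __call__(self, observed: str) -> str | None:
        observed = observed.upper()
        sid = self._exact.get(observed)
        if sid is not None:
            return sid
        if len(observed) != self._mat.shape[1]:
            raise ValueError(
                f"observed index length {len(observed)} != set length "
                f"{self._mat.shape[1]}")
        if self.max_correct == 0:
            return None
        d = (self._mat != _encode(observed)).sum(axis=1)
        dmin = int(d.min())
        if dmin > self.max_correct:
            return None
        hits = np.flatnonzero(d == dmin)
        if hits.size != 1:
            return None
        return self._ids[int(hits[0])]


def assign_index(observed: str, index_set: IndexSet, max_correct: int = 1) -> str | None:
    """Decode one observed index sequence against a set.

    Returns the sample id, or ``None`` (unassigned) when no index is within
    ``max_correct`` or the minimal qualifying distance is tied.
    """
    return IndexDecoder(index_set, max_correct)(observed)
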