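"""Repeated-sketch k-mer genetic similarity (GS).

Two samples' sequence content is compared through repeated bottom-k
sketches of their canonical 31-mer sets: for each of ``reps`` (default
10) repetitions, the ``sketch_size`` (default 10,000) k-mers with the
smallest values under a repetition-salted hash are selected from each
sample, the shared count N_i within each repetition is recorded, and

    GS = (N_1 + ... + N_reps) / N_sum

where N_sum = reps * sketch_size whenever both samples saturate every
sketch (the 100,000 of the default configuration), and otherwise
sum_i min(|sketch_a_i|, |sketch_b_i|) so GS stays in [0, 1] and a sample
scores 1 against itself.  Bottom-k selection under a shared seeded hash —
rather than uniform resampling — makes identical samples score exactly 1
and makes GS a consistent estimator of the containment of the smaller
k-mer set in the larger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SketchSet",
    "GSResult",
    "canonical_kmers",
    "build_sketch_set",
    "genetic_similarity",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(sequences, k: int = 31) -> set[str]:
    """Canonical k-mer set of a collection of DNA strings.

    Each window of length ``k`` contributes the lexicographic minimum of
    itself and its reverse complement; windows containing characters
    outside ACGT are skipped.  Sequences shorter than ``k`` contribute
    nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        # split into ACGT-only runs; windows never span an ambiguous base
        for run in _acgt_runs(seq):
            for i in range(len(run) - k + 1):
                kmer = run[i : i + k]
                rc = reverse_complement(kmer)
                out.add(kmer if kmer <= rc else rc)
    return out


def _acgt_runs(seq: str):
    run_start = None
    for i, ch in enumerate(seq):
        if ch in "ACGT":
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                yield seq[run_start:i]
                run_start = None
    if run_start is not None:
        yield seq[run_start:]


@dataclass
class SketchSet:
    """Per-sample repeated bottom-k sketches of a canonical k-mer set."""

    sample_id: str
    k: int
    sketch_size: int
    reps: int
    seed: int
    sketches: list[frozenset[str]] = field(default_factory=list)

    def params(self) -> tuple[int, int, int, int]:
        return (self.k, self.sketch_size, self.reps, self.seed)


@dataclass
class GSResult:
    """Pairwise genetic similarity with its per-repetition accounting."""

    sample_a: str
    sample_b: str
    shared_counts: list[int]
    n_sum: int
    gs: float


# ---------------------------------------------------------------------------
# hashing: 2-bit k-mer codes mixed with splitmix64, one salt per repetition


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # modular 64-bit arithmetic: wraparound is the point
    with np.errstate(over="ignore"):
        x = (x + _GOLDEN).astype(np.uint64)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return x ^ (x >> np.uint64(31))


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def encode_kmers(kmers: list[str], k: int) -> np.ndarray:
    """Pack k-mers (k <= 31) into uint64 codes, 2 bits per base."""
    if k > 31:
        raise ValueError("packed encoding supports k <= 31")
    buf = np.frombuffer("".join(kmers).encode("ascii"), dtype=np.uint8)
    mat = _BASE_CODE[buf].reshape(len(kmers), k)
    if (mat == 255).any():
        raise ValueError("k-mers must contain only ACGT")
    shifts = (np.uint64(2) * np.arange(k, dtype=np.uint64))[np.newaxis, :]
    return (mat.astype(np.uint64) << shifts).sum(axis=1, dtype=np.uint64)


def _rep_salt(seed: int, rep: int) -> np.ndarray:
    with np.errstate(over="ignore"):
        return _splitmix64(np.uint64(seed) * _GOLDEN + np.uint64(rep))


def build_sketch_set(
    kmers: set[str],
    sketch_size: int = 10_000,
    reps: int = 10,
    seed: int = 0,
    sample_id: str = "",
) -> SketchSet:
    """Build the repeated bottom-k sketches of one sample's k-mer set.

    Repetition ``r`` keeps the ``sketch_size`` k-mers with the smallest
    hash under a salt derived from ``(seed, r)``; if the set is smaller
    than ``sketch_size`` the whole set is the sketch.  Identical input
    sets under identical ``(seed, reps)`` yield identical sketches, so a
    sample always scores GS = 1 against itself.
    """
    if sketch_size <= 0:
        raise ValueError("sketch_size must be positive")
    if reps <= 0:
        raise ValueError("reps must be positive")
    if not kmers:
        raise ValueError("cannot sketch an empty k-mer set")
    ordered = sorted(kmers)  # stable order: sketches depend only on set content
    k = len(ordered[0])
    if any(len(m) != k for m in ordered):
        raise ValueError("all k-mers must share one length")
    codes = encode_kmers(ordered, k)
    sketches: list[frozenset[str]] = []
    arr = np.asarray(ordered, dtype=object)
    for r in range(reps):
        if len(ordered) <= sketch_size:
            sketches.append(frozenset(ordered))
            continue
        h = _splitmix64(codes ^ _rep_salt(seed, r))
        idx = np.argpartition(h, sketch_size)[:sketch_size]
        sketches.append(frozenset(arr[idx]))
    return SketchSet(sample_id, k, sketch_size, reps, seed, sketches)


def genetic_similarity(a: SketchSet, b: SketchSet) -> GSResult:
    """GS between two sketch sets built with identical parameters."""
    if a.params() != b.params():
        raise ValueError(
            f"sketch parameters differ: {a.params()} vs {b.params()}"
        )
    shared = [len(sa & sb) for sa, sb in zip(a.sketches, b.sketches)]
    saturated = all(
        len(sa) == a.sketch_size and len(sb) == a.sketch_size
        for sa, sb in zip(a.sketches, b.sketches)
    )
    if saturated:
        n_sum = a.reps * a.sketch_size
    else:
        n_sum = sum(min(len(sa), len(sb)) for sa, sb in zip(a.sketches, b.sketches))
    gs = sum(shared) / n_sum
    return GSResult(a.sample_id, b.sample_id, shared, n_sum, gs)
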