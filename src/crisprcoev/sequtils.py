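"""Low-level DNA string helpers shared across modules.

Coordinates follow one convention everywhere: external interfaces are
1-based inclusive on the forward strand, internal computation is 0-based
half-open. Conversion goes through :func:`to_zero_based` /
:func:`to_one_based` only.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Uppercase and check the alphabet; raise ValueError on junk."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return seq


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def exact_scan(genome: str, pattern: str) -> list[int]:
    """All 0-based start positions of exact occurrences of *pattern*."""
    hits = []
    i = genome.find(pattern)
    while i != -1:
        hits.append(i)
        i = genome.find(pattern, i + 1)
    return hits


def hamming_scan(genome: str, pattern: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All 0-based windows of ``len(pattern)`` within *max_mismatch* substitutions.

    Returns ``[(start0, mismatches), ...]`` in genome order. No indels are
    considered. A pattern longer than the genome yields an empty list.
    """
    if max_mismatch == 0:
        return [(p, 0) for p in exact_scan(genome, pattern)]
    m = len(pattern)
    if m == 0 or len(genome) < m:
        return []
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    p = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(g, m)
    mm = (windows != p).sum(axis=1)
    starts = np.nonzero(mm <= max_mismatch)[0]
    return [(int(s), int(mm[s])) for s in starts]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
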