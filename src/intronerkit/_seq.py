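"""Small nucleotide-string utilities shared across the package.

All sequences handled by intronerkit are uppercase ACGTN strings.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among non-N bases; 0.0 for empty/all-N input."""
    n = sum(1 for c in seq if c != "N")
    if n == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / n


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random sequence with the given expected GC fraction (iid bases)."""
    if length <= 0:
        return ""
    at = (1.0 - gc) / 2.0
    p = np.array([at, gc / 2.0, gc / 2.0, at])
    arr = rng.choice(_BASES, size=length, p=p)
    return arr.tobytes().decode("ascii")


def mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: set[int] | None = None,
) -> str:
    """Apply iid substitutions at the given per-site rate.

    Positions in `protected` are never altered.  Substitutions always change
    the base (drawn uniformly from the three alternatives).
    """
    if rate <= 0 or not seq:
        return seq
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    alts = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    for i in hits:
        i = int(i)
        if protected and i in protected:
            continue
        base = out[i]
        if base not in alts:
            continue
        out[i] = alts[base][int(rng.integers(3))]
    return "".join(out)


def kmer_entropy(seq: str, k: int = 3) -> float:
    """Shannon entropy (bits) of the k-mer composition of `seq`."""
    n = len(seq) - k + 1
    if n <= 0:
        return 0.0
    counts = Counter(seq[i : i + k] for i in range(n))
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def max_tandem_coverage(seq: str, max_unit: int = 6) -> float:
    """Largest fraction of `seq` covered by one perfect tandem run.

    Considers repeat units of 1..max_unit nt starting at every phase and
    returns (longest run length) / len(seq).
    """
    n = len(seq)
    if n == 0:
        return 0.0
    best = 0
    for u in range(1, max_unit + 1):
        i = 0
        while i + u <= n:
            unit = seq[i : i + u]
            j = i + u
            while j + u <= n and seq[j : j + u] == unit:
                j += u
            run = j - i
            if run > best and run >= 2 * u:
                best = run
            i += 1 if run < 2 * u else run - u
    return best / n


def iter_kmers(seq: str, k: int):
    """Yield (offset, kmer) for every k-mer of `seq` without Ns."""
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield i, km
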