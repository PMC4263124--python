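"""Strand-independent oligonucleotide signatures of contigs.

Each contig is summarised by the counts of its canonical pentamers
(a k-mer and its reverse complement are counted together, giving
4**5 / 2 = 512 dimensions for k=5).  The count vector is closed to
proportions and mapped through the centred log-ratio (CLR) transform,
which makes Euclidean geometry meaningful on the compositional profile
and is the coordinate system used for embedding and clustering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .errors import DomainError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base encoding A,C,G,T -> 0..3; everything else -> -1
_ENCODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def canonical_kmers(k: int = 5) -> tuple[str, ...]:
    """Sorted canonical k-mers over {A,C,G,T}.

    The canonical form of a k-mer is the lexicographically smaller of the
    k-mer and its reverse complement; for odd k no k-mer is its own reverse
    complement, so the set has exactly 4**k / 2 members (512 for k=5).
    """
    if k < 1:
        raise DomainError("k must be >= 1")
    canon = {
        min(km, reverse_complement(km))
        for km in ("".join(p) for p in itertools.product("ACGT", repeat=k))
    }
    return tuple(sorted(canon))


@lru_cache(maxsize=None)
def _canonical_index(k: int) -> np.ndarray:
    """Map every 4**k k-mer integer code to its canonical column 0..n-1."""
    kmers = canonical_kmers(k)
    col = {km: j for j, km in enumerate(kmers)}
    idx = np.empty(4 ** k, dtype=np.int64)
    for code, km in enumerate("".join(p) for p in itertools.product("ACGT", repeat=k)):
        idx[code] = col[min(km, reverse_complement(km))]
    return idx


def count_signature(sequence: str, k: int = 5) -> np.ndarray:
    """Canonical k-mer counts of a sequence (sliding window, step 1).

    Windows containing any non-ACGT symbol are skipped.  Raises
    :class:`DomainError` when no valid window exists.
    """
    codes = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    n_kmers = len(canonical_kmers(k))
    if n < k:
        raise DomainError(f"sequence of length {n} has no window of width {k}")
    # integer code of each window, base-4 big-endian
    window = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        cj = codes[j : j + n - k + 1]
        valid &= cj >= 0
        window = window * 4 + np.where(cj >= 0, cj, 0)
    if not valid.any():
        raise DomainError("sequence contains no ACGT-only window")
    counts = np.bincount(_canonical_index(k)[window[valid]], minlength=n_kmers)
    return counts


def clr_transform(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio transform of a count vector.

    ``v = counts + pseudocount`` is closed to proportions ``p`` and mapped to
    ``log p - mean(log p)``; the output sums to zero.
    """
    v = np.asarray(counts, dtype=float) + pseudocount
    if np.any(v <= 0):
        raise DomainError("counts + pseudocount must be strictly positive")
    p = v / v.sum()
    logp = np.log(p)
    return logp - logp.mean()


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases are excluded from the denominator."""
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        raise DomainError("sequence contains no unambiguous base")
    return gc / acgt


@dataclass
class Signature:
    """Pentamer profile of one contig."""

    contig_id: str
    counts: np.ndarray
    freqs: np.ndarray
    clr: np.ndarray
    gc_fraction: float
    length: int


def signature(contig_id: str, sequence: str, k: int = 5,
              pseudocount: float = 1.0) -> Signature:
    counts = count_signature(sequence, k=k)
    v = counts + pseudocount
    return Signature(
        contig_id=contig_id,
        counts=counts,
        freqs=v / v.sum(),
        clr=clr_transform(counts, pseudocount=pseudocount),
        gc_fraction=gc_fraction(sequence),
        length=len(sequence),
    )


def signature_matrix(sequences: dict[str, str], k: int = 5,
                     pseudocount: float = 1.0) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """CLR signature matrix for a set of contigs.

    Returns ``(ids, clr_matrix, meta)`` where ``meta`` holds per-contig
    length and G+C fraction indexed like ``ids``.
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    lengths: list[int] = []
    gcs: list[float] = []
    for cid, seq in sequences.items():
        sig = signature(cid, seq, k=k, pseudocount=pseudocount)
        ids.append(cid)
        rows.append(sig.clr)
        lengths.append(sig.length)
        gcs.append(sig.gc_fraction)
    meta = pd.DataFrame({"contig_id": ids, "length": lengths, "gc": gcs})
    return ids, np.vstack(rows), meta


def signature_table(sequences: dict[str, str], k: int = 5,
                    pseudocount: float = 1.0) -> pd.DataFrame:
    """Tidy per-contig table: contig, length, gc and the CLR columns."""
    ids, clr, meta = signature_matrix(sequences, k=k, pseudocount=pseudocount)
    cols = pd.DataFrame(clr, columns=[f"clr_{km}" for km in canonical_kmers(k)])
    return pd.concat([meta.reset_index(drop=True), cols], axis=1)
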