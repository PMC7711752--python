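"""Exact canonical k-mer sets and set-based genome similarity.

A genome is summarised as the set of its distinct canonical k-mers: for every
length-k window over ACGT, the lexicographically smaller of the window and its
reverse complement is kept, so the set is strand-invariant.  Two statistics are
defined on a pair of such sets:

* the Jaccard index ``|A ∩ B| / |A ∪ B|`` — the fraction of shared k-mers;
* a capture–recapture-corrected overlap share: the observed intersection minus
  the overlap expected between two random k-mer sets of the same sizes
  (``|A|·|B| / 4^k``), expressed as a share of the smaller set.  The correction
  makes the statistic ≈ 0 in expectation for unrelated genomes; it can be
  slightly negative and is at most ``1 − |A|/4^k``.

The full-set route is the slow reference path of the package: it is exact, but
sketch-based estimators (:mod:`taxodist.sketch`) are what one would use at
scale.  K-mers are held internally as 2-bit integer encodings (A=0, C=1, G=2,
T=3, big-endian within a 64-bit word); the public contract is over the string
set and :meth:`KmerSet.to_strings` recovers it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "KmerSet",
    "extract_canonical_kmers",
    "exact_jaccard",
    "corrected_overlap_share",
    "reverse_complement",
    "read_fasta",
    "kmer_set_from_fasta",
    "write_kmer_list",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# byte -> 2-bit code; 4 flags anything that is not an unambiguous base
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _encode(sequence: str) -> np.ndarray:
    """Map a string to per-base codes (0..3, or 4 for ambiguous characters)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def _canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes of one record; windows touching a non-ACGT base
    are skipped, so no k-mer spans an ambiguity break."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    invalid = codes > 3
    # window is bad if it contains any invalid base
    csum = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(invalid, out=csum[1:])
    bad = (csum[k:] - csum[: n - k + 1]) > 0
    safe = np.where(invalid, 0, codes).astype(np.uint64)
    comp = np.uint64(3) - safe
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    two = np.uint64(2)
    for i in range(k):
        fwd = (fwd << two) | safe[i : m + i]
        # reverse complement: most-significant base is complement of the last
        rev = (rev << two) | comp[k - 1 - i : m + k - 1 - i]
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def _decode(code: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for shift in range(2 * (k - 1), -2, -2):
        out.append(bases[(code >> shift) & 3])
    return "".join(out)


@dataclass(frozen=True)
class KmerSet:
    """Distinct canonical k-mers of one genome.

    ``codes`` is a sorted, unique ``uint64`` array of 2-bit encodings.  Because
    the encoding is order-preserving (A<C<G<T and fixed length), sorting by
    code equals lexicographic sorting of the k-mer strings.
    """

    k: int
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def cardinality(self) -> int:
        return int(self.codes.size)

    def __len__(self) -> int:
        return self.cardinality

    def __contains__(self, kmer: str) -> bool:
        return kmer in set(self.to_strings()) if self.codes.size else False

    def to_strings(self) -> list[str]:
        """The k-mer set as sorted strings (the public contract)."""
        return [_decode(int(c), self.k) for c in self.codes]

    def intersection_size(self, other: "KmerSet") -> int:
        _check_same_k(self, other)
        return int(
            np.intersect1d(self.codes, other.codes, assume_unique=True).size
        )


def _check_same_k(a: KmerSet, b: KmerSet) -> None:
    if a.k != b.k:
        raise ValueError(f"mismatched k-mer lengths: {a.k} != {b.k}")


def extract_canonical_kmers(
    sequence_records: Iterable[str] | str, k: int = 16
) -> KmerSet:
    """Distinct canonical k-mers over all records of a genome.

    Records are processed independently (k-mers never span record boundaries)
    and windows containing any non-ACGT character are skipped.  Input with no
    record of length >= k yields an empty set, not an error.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(sequence_records, str):
        sequence_records = [sequence_records]
    parts = [_canonical_codes(_encode(rec), k) for rec in sequence_records]
    if parts:
        codes = np.unique(np.concatenate(parts))
    else:
        codes = np.empty(0, dtype=np.uint64)
    return KmerSet(k=k, codes=codes)


def exact_jaccard(a: KmerSet, b: KmerSet) -> float:
    """``|A ∩ B| / |A ∪ B|`` — the fraction of shared k-mers."""
    _check_same_k(a, b)
    if a.cardinality == 0 and b.cardinality == 0:
        raise ValueError("Jaccard of two empty k-mer sets is undefined")
    inter = a.intersection_size(b)
    union = a.cardinality + b.cardinality - inter
    return inter / union


def corrected_overlap_share(a: KmerSet, b: KmerSet) -> float:
    """Chance-corrected k-mer overlap as a share of the smaller set.

    ``(|A ∩ B| − |A|·|B|/4^k) / min(|A|, |B|)``.  The subtracted term is the
    expected overlap of two independent uniform-random k-mer sets of the same
    sizes (a capture–recapture argument), so unrelated genomes score ≈ 0.
    The value of a set against itself is exactly ``1 − |A|/4^k``.
    """
    _check_same_k(a, b)
    if a.cardinality == 0 or b.cardinality == 0:
        raise ValueError("corrected overlap share needs two non-empty sets")
    inter = a.intersection_size(b)
    random_overlap = a.cardinality * b.cardinality / 4**a.k
    return (inter - random_overlap) / min(a.cardinality, b.cardinality)


# ---------------------------------------------------------------------------
# FASTA input / k-mer list output


def read_fasta(path: str | Path) -> list[str]:
    """Sequences of a (possibly gzip-compressed) multi-record FASTA file.

    Record IDs are irrelevant for k-mer extraction and are discarded.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:  # type: ignore[operator]
        return [str(rec.seq) for rec in SeqIO.parse(handle, "fasta")]


def kmer_set_from_fasta(path: str | Path, k: int = 16) -> KmerSet:
    return extract_canonical_kmers(read_fasta(path), k=k)


def write_kmer_list(kmer_set: KmerSet, path: str | Path) -> None:
    """Dump one canonical k-mer per line, lexicographically sorted, unique."""
    with open(path, "wt") as fh:
        for kmer in kmer_set.to_strings():
            fh.write(kmer + "\n")
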