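"""Sketch-based genome distance estimation.

Two fixed-size summaries of a genome's canonical k-mer set are provided:

* **bottom-s MinHash** — the ``s`` smallest distinct 64-bit hash values of the
  k-mers.  The Jaccard index of two genomes is estimated from the merged
  sketch (the ``s`` smallest values of the union), and transformed into a
  "Mash distance" ``D = −(1/k)·ln(2j/(1+j))``, a proxy for 1 − ANI under a
  Poisson model of independent point substitutions.
* **HyperLogLog** — ``2^p`` registers holding the maximum leading-zero rank of
  the hashed k-mers per bucket.  Cardinalities of each set and of their union
  (register-wise max) give a Jaccard estimate by inclusion–exclusion.

Hashing is a seedable splitmix64 finalizer applied to the 2-bit k-mer
encoding.  Sketches are deterministic for a fixed (input, k, size, seed) and
are serialisable to JSON so they can be computed once per genome and reused.
Hash values are not bit-compatible with any external tool; the contract is
statistical agreement of the estimated distances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .kmers import KmerSet

__all__ = [
    "MinHashSketch",
    "HllSketch",
    "DistanceValue",
    "ORIENTATION",
    "DEFAULT_HASH_SEED",
    "minhash_sketch",
    "sketch_jaccard",
    "mash_distance",
    "hll_sketch",
    "hll_cardinality",
    "hll_union",
    "hll_similarity",
    "save_sketch",
    "load_sketch",
]

DEFAULT_HASH_SEED = 42

#: how each method's value is oriented: "distance" = smaller means more
#: similar; "similarity" = larger means more similar
ORIENTATION = {
    "mash": "distance",
    "hll_similarity": "similarity",
    "kmer_overlap": "similarity",
}

_MASK64 = (1 << 64) - 1


def _splitmix64_int(x: int) -> int:
    """Scalar splitmix64 finalizer (Python ints, masked to 64 bits)."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)


def _hash64(codes: np.ndarray, seed: int) -> np.ndarray:
    """Vectorised seeded splitmix64 over uint64 k-mer codes."""
    salt = np.uint64(_splitmix64_int(seed & _MASK64))
    x = codes.astype(np.uint64) ^ salt
    with np.errstate(over="ignore"):
        x = x + np.uint64(0x9E3779B97F4A7C15)
        x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _codes_of(kmers: Union[KmerSet, np.ndarray]) -> tuple[np.ndarray, int]:
    if isinstance(kmers, KmerSet):
        return kmers.codes, kmers.k
    return np.asarray(kmers, dtype=np.uint64), 0


# ---------------------------------------------------------------------------
# MinHash


@dataclass(frozen=True)
class MinHashSketch:
    """Bottom-s sketch: the s smallest distinct hash values of the k-mers.

    ``hashes`` is strictly increasing and holds fewer than ``s`` values when
    the genome has fewer than ``s`` distinct k-mers (the sketch is then an
    exact representation of the hashed set).
    """

    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray = field(repr=False)


def minhash_sketch(
    kmers: Union[KmerSet, np.ndarray],
    k: int | None = None,
    s: int = 100_000,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> MinHashSketch:
    """Sketch a canonical k-mer set with capacity ``s`` (default 100,000)."""
    if s < 1:
        raise ValueError(f"sketch capacity s must be >= 1, got {s}")
    codes, inferred_k = _codes_of(kmers)
    k = inferred_k if k is None else k
    hashes = np.unique(_hash64(codes, hash_seed))
    return MinHashSketch(k=k, s=s, hash_seed=hash_seed, hashes=hashes[:s])


def _check_minhash_compat(a: MinHashSketch, b: MinHashSketch) -> None:
    if (a.k, a.s, a.hash_seed) != (b.k, b.s, b.hash_seed):
        raise ValueError(
            "incompatible MinHash sketches: "
            f"(k={a.k}, s={a.s}, seed={a.hash_seed}) vs "
            f"(k={b.k}, s={b.s}, seed={b.hash_seed})"
        )


def sketch_jaccard(a: MinHashSketch, b: MinHashSketch) -> float:
    """Merged-sketch Jaccard estimate.

    Let U be the ``min(s, |a ∪ b|)`` smallest values of the merged hash lists;
    the estimate is the fraction of U present in both sketches.  Using the
    merged sketch (rather than intersecting the two bottom-s lists directly)
    is the low-bias estimator the MinHash literature prescribes.
    """
    _check_minhash_compat(a, b)
    merged = np.concatenate([a.hashes, b.hashes])
    if merged.size == 0:
        raise ValueError("Jaccard of two empty sketches is undefined")
    merged.sort(kind="mergesort")
    # each sketch is unique, so a value occurs twice iff it is in both
    dup = merged[1:] == merged[:-1]
    keep = np.empty(merged.size, dtype=bool)
    keep[0] = True
    keep[1:] = ~dup
    union = merged[keep]
    n_u = min(a.s, union.size)
    in_both = merged[:-1][dup]  # sorted, unique
    shared = int(np.searchsorted(in_both, union[n_u - 1], side="right"))
    return shared / n_u


def mash_distance(j: float, k: int) -> float:
    """Mash distance ``D = −(1/k)·ln(2j/(1+j))``, capped at 1.

    ``j`` is a Jaccard index; ``j = 0`` maps to the cap (1.0) rather than
    infinity.  Under independent point substitutions at per-site rate ``d``
    the expected Jaccard is ``≈ 1/(2·e^{kd} − 1)``, making D an estimate of
    ``d``, i.e. of 1 − ANI.
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard index must be in [0, 1], got {j}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if j == 0.0:
        return 1.0
    return min(1.0, -math.log(2.0 * j / (1.0 + j)) / k)


# ---------------------------------------------------------------------------
# HyperLogLog


@dataclass(frozen=True)
class HllSketch:
    """HyperLogLog sketch: 2^p registers of max leading-zero ranks."""

    p: int
    k: int
    hash_seed: int
    registers: np.ndarray = field(repr=False)  # uint8, values in [0, 64-p+1]


def _bit_length64(w: np.ndarray) -> np.ndarray:
    """Exact bit length of uint64 values (vectorised, no float rounding)."""
    length = np.zeros(w.shape, dtype=np.int64)
    cur = w.copy()
    for s in (32, 16, 8, 4, 2, 1):
        big = cur >= (np.uint64(1) << np.uint64(s))
        length[big] += s
        cur[big] >>= np.uint64(s)
    return length + (cur > 0)


def hll_sketch(
    kmers: Union[KmerSet, np.ndarray],
    p: int = 20,
    k: int | None = None,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> HllSketch:
    """Fill 2^p registers (default p=20) from hashed canonical k-mers.

    The top ``p`` hash bits select a register; the rank is the position of the
    first set bit among the remaining ``64−p`` bits (``64−p+1`` if all zero).
    """
    if not 4 <= p <= 24:
        raise ValueError(f"p must be in [4, 24], got {p}")
    codes, inferred_k = _codes_of(kmers)
    k = inferred_k if k is None else k
    m = 1 << p
    registers = np.zeros(m, dtype=np.uint8)
    if codes.size:
        h = _hash64(codes, hash_seed)
        idx = (h >> np.uint64(64 - p)).astype(np.int64)
        w = h << np.uint64(p)  # low 64-p bits shifted to the top
        rho = np.where(w == 0, 64 - p + 1, 64 - _bit_length64(w) + 1).astype(
            np.uint8
        )
        np.maximum.at(registers, idx, rho)
    return HllSketch(p=p, k=k, hash_seed=hash_seed, registers=registers)


def _alpha(m: int) -> float:
    if m == 16:
        return 0.673
    if m == 32:
        return 0.697
    if m == 64:
        return 0.709
    return 0.7213 / (1.0 + 1.079 / m)


def _estimate_from_registers(registers: np.ndarray) -> float:
    m = registers.size
    counts = np.bincount(registers, minlength=66)
    inv_powers = np.ldexp(1.0, -np.arange(counts.size))
    raw = _alpha(m) * m * m / float(counts @ inv_powers)
    zeros = int(counts[0])
    if raw <= 2.5 * m and zeros > 0:  # small-range linear counting
        return m * math.log(m / zeros)
    return raw


def hll_cardinality(sketch: HllSketch) -> float:
    """Classic harmonic-mean estimate with small-range linear counting."""
    return _estimate_from_registers(sketch.registers)


def _check_hll_compat(a: HllSketch, b: HllSketch) -> None:
    if (a.p, a.k, a.hash_seed) != (b.p, b.k, b.hash_seed):
        raise ValueError(
            "incompatible HLL sketches: "
            f"(p={a.p}, k={a.k}, seed={a.hash_seed}) vs "
            f"(p={b.p}, k={b.k}, seed={b.hash_seed})"
        )


def hll_union(a: HllSketch, b: HllSketch) -> HllSketch:
    """Register-wise maximum: the sketch of the union of the two sets."""
    _check_hll_compat(a, b)
    return HllSketch(
        p=a.p,
        k=a.k,
        hash_seed=a.hash_seed,
        registers=np.maximum(a.registers, b.registers),
    )


def hll_similarity(
    a: HllSketch,
    b: HllSketch,
    card_a: float | None = None,
    card_b: float | None = None,
) -> float:
    """Jaccard estimate ``max(0, (Ĉ(a) + Ĉ(b) − Ĉ(a∪b)) / Ĉ(a∪b))``.

    ``card_a``/``card_b`` may pass in pre-computed cardinality estimates of
    the two sketches (they depend only on one sketch each, so callers looping
    over many pairs can compute them once per genome).
    """
    _check_hll_compat(a, b)
    card_u = _estimate_from_registers(
        np.maximum(a.registers, b.registers)
    )
    if card_u == 0.0:
        raise ValueError("Jaccard of two empty HLL sketches is undefined")
    if card_a is None:
        card_a = _estimate_from_registers(a.registers)
    if card_b is None:
        card_b = _estimate_from_registers(b.registers)
    return max(0.0, (card_a + card_b - card_u) / card_u)


# ---------------------------------------------------------------------------
# Distance records and sketch serialization


@dataclass(frozen=True)
class DistanceValue:
    """One method's value for one genome pair, with its orientation."""

    method: str  # mash | hll_similarity | kmer_overlap
    k: int
    value: float

    @property
    def orientation(self) -> str:
        return ORIENTATION[self.method]


_FORMAT_VERSION = 1


def save_sketch(sketch: Union[MinHashSketch, HllSketch], path: str | Path) -> None:
    """Serialise a sketch to a versioned JSON file for reuse across runs."""
    if isinstance(sketch, MinHashSketch):
        doc = {
            "format_version": _FORMAT_VERSION,
            "method": "minhash",
            "k": sketch.k,
            "s": sketch.s,
            "hash_seed": sketch.hash_seed,
            "payload": [int(h) for h in sketch.hashes],
        }
    elif isinstance(sketch, HllSketch):
        doc = {
            "format_version": _FORMAT_VERSION,
            "method": "hll",
            "k": sketch.k,
            "p": sketch.p,
            "hash_seed": sketch.hash_seed,
            "payload": sketch.registers.tolist(),
        }
    else:
        raise TypeError(f"not a sketch: {type(sketch)!r}")
    Path(path).write_text(json.dumps(doc))


def load_sketch(path: str | Path) -> Union[MinHashSketch, HllSketch]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported sketch file version in {path}")
    if doc["method"] == "minhash":
        return MinHashSketch(
            k=doc["k"],
            s=doc["s"],
            hash_seed=doc["hash_seed"],
            hashes=np.asarray(doc["payload"], dtype=np.uint64),
        )
    if doc["method"] == "hll":
        return HllSketch(
            p=doc["p"],
            k=doc["k"],
            hash_seed=doc["hash_seed"],
            registers=np.asarray(doc["payload"], dtype=np.uint8),
        )
    raise ValueError(f"unknown sketch method {doc['method']!r} in {path}")
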