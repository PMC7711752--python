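"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from taxodist.taxonomy import GenomeRecord, Lineage

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_canonical_kmers(sequences, k: int) -> set[str]:
    """Substring-enumeration oracle: canonical k-mers as plain strings."""
    if isinstance(sequences, str):
        sequences = [sequences]
    out: set[str] = set()
    for seq in sequences:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if any(c not in "ACGT" for c in window):
                continue
            rc = "".join(_COMP[c] for c in reversed(window))
            out.add(min(window, rc))
    return out


def random_dna(n: int, rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_record(accession: str, species="", genus="", family="",
                order="", class_="", phylum="") -> GenomeRecord:
    """Record with explicit taxa; blank strings mean the rank is missing."""
    from taxodist.taxonomy import MISSING_RANK

    def val(x):
        return x if x else MISSING_RANK

    return GenomeRecord(
        accession=accession,
        lineage=Lineage(
            species=val(species),
            genus=val(genus),
            family=val(family),
            order=val(order),
            class_=val(class_),
            phylum=val(phylum),
        ),
    )


def last_shared_rank(lin_a: Lineage, lin_b: Lineage) -> str | None:
    """Exhaustive oracle: the most specific rank at which two complete
    lineages agree (None if they differ even at phylum)."""
    from taxodist.taxonomy import RANKS

    shared = None
    for level in reversed(RANKS):  # phylum -> species
        if lin_a.taxon_at(level) != lin_b.taxon_at(level):
            break
        shared = level
    return shared


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20201024)
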