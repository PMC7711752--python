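"""Synthetic hierarchically structured clades of genomes.

Generates a registry of genomes whose pairwise divergence is layered by
taxonomic rank, so the whole pipeline (k-mer sets, sketches, rank strata,
thresholds) is testable without any download.  The tree is built top-down:
each taxon owns an ancestor sequence; the *first* child at every rank
inherits the parent ancestor unchanged (the parent's type lineage persists,
as in peripatric budding), while every further child is created by mutating
the parent ancestor at that rank's per-site divergence.  Genomes are leaves:
the first genome of a species is the species ancestor itself, the rest are
mutated at the strain divergence.

Consequences of this model worth knowing when reading test expectations:

* the minimum distance between two species of one genus is exactly the
  species-rank divergence (the type species vs. a budded sibling), so with
  the default profile (strain 0.002 ≪ species 0.03) the within-species and
  between-species strata are perfectly separable;
* lowering the species divergence toward twice the strain divergence makes
  the two strata collide (the type-genome pair of two sibling species is as
  close as two mutated strains of one species) — the breakdown regime.

Divergence is applied as independent per-site substitutions; indels are off
by default so closed-form k-mer survival arguments hold exactly.  Everything
is deterministic under the config seed, including the gzip bytes of written
FASTA files (mtime pinned to 0).
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import RANKS, GenomeRecord, Lineage

__all__ = [
    "CladeConfig",
    "SyntheticRegistry",
    "DEFAULT_DIVERGENCE",
    "random_genome",
    "mutate",
    "generate_registry",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: per-site substitution probability on the branch creating a new taxon at
#: each rank; strictly increasing from strain to phylum
DEFAULT_DIVERGENCE = {
    "strain": 0.002,
    "species": 0.03,
    "genus": 0.08,
    "family": 0.12,
    "order": 0.16,
    "class": 0.20,
    "phylum": 0.25,
}


@dataclass(frozen=True)
class CladeConfig:
    """Shape and divergence profile of a synthetic clade.

    ``n_*`` counts are per parent taxon; ``genomes_per_species`` may be an
    int or an inclusive (lo, hi) range sampled per species.  ``edge_cases``
    appends three curation test species to the first genus: a hybrid-named
    species and a strain-coded species (both with inflated within-species
    divergence, the artefacts name-based curation is meant to remove) and an
    overdispersed but normally named outlier species (which name-based
    curation cannot catch).
    """

    genome_length: int = 50_000
    gc_content: float = 0.5
    n_phyla: int = 2
    n_classes: int = 1
    n_orders: int = 1
    n_families: int = 1
    n_genera: int = 5
    n_species: int = 3
    genomes_per_species: int | tuple[int, int] = 3
    divergence_per_rank: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIVERGENCE)
    )
    indel_rate: float = 0.0
    edge_cases: bool = False
    seed: int = 42


@dataclass(frozen=True)
class SyntheticRegistry:
    """Generated genomes plus the divergences that produced them.

    ``truth`` maps each unordered accession pair (sorted tuple) to the sum of
    nominal branch divergences separating the two genomes on the generating
    tree — the quantity a distance estimator should recover.
    """

    records: tuple[GenomeRecord, ...]
    truth: dict[tuple[str, str], float]

    @property
    def sequences(self) -> dict[str, str]:
        return {r.accession: r.sequence for r in self.records}  # type: ignore[misc]

    def lineage_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            lin = r.lineage
            rows.append(
                {
                    "accession": r.accession,
                    "species": lin.species,
                    "genus": lin.genus,
                    "family": lin.family,
                    "order": lin.order,
                    "class": lin.class_,
                    "phylum": lin.phylum,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        """One gzipped FASTA per genome plus lineage and truth TSVs.

        Byte-identical across runs with the same config (gzip mtime pinned).
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in self.records:
            path = out_dir / f"{rec.accession}.fna.gz"
            with open(path, "wb") as raw:
                with gzip.GzipFile(
                    fileobj=raw, mode="wb", filename="", mtime=0
                ) as gz:
                    gz.write(f">{rec.accession}\n".encode())
                    seq = rec.sequence or ""
                    for i in range(0, len(seq), 80):
                        gz.write(seq[i : i + 80].encode() + b"\n")
        self.lineage_frame().to_csv(
            out_dir / "lineage.tsv", sep="\t", index=False
        )
        truth_rows = [
            {"accession_a": a, "accession_b": b, "divergence": d}
            for (a, b), d in sorted(self.truth.items())
        ]
        pd.DataFrame(truth_rows).to_csv(
            out_dir / "truth.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# sequence-level primitives


def random_genome(
    length: int, gc_content: float = 0.5, seed: int | np.random.Generator = 0
) -> str:
    """I.i.d. random genome with P(G)+P(C) = ``gc_content``, split evenly."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content must be in (0, 1), got {gc_content}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate(
    sequence: str,
    p_sub: float,
    indel_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate each site independently; indels are applied after substitutions.

    A substituted site gets one of the three other bases uniformly.  With
    per-site probability ``indel_rate`` a 1–10 bp event occurs, deletion or
    insertion (of random bases) with equal odds.
    """
    if not 0.0 <= p_sub < 1.0 or not 0.0 <= indel_rate < 1.0:
        raise ValueError("mutation probabilities must be in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    base_idx = np.searchsorted(_BASES, codes)  # ACGT assumed
    if p_sub > 0.0:
        hit = rng.random(codes.size) < p_sub
        n_hit = int(hit.sum())
        if n_hit:
            offset = rng.integers(1, 4, size=n_hit)
            base_idx[hit] = (base_idx[hit] + offset) % 4
    out = _BASES[base_idx]
    if indel_rate > 0.0:
        hit = np.flatnonzero(rng.random(out.size) < indel_rate)
        pieces: list[bytes] = []
        prev = 0
        for pos in hit:
            if pos < prev:
                continue  # swallowed by a previous deletion
            size = int(rng.integers(1, 11))
            if rng.random() < 0.5:  # deletion
                pieces.append(out[prev:pos].tobytes())
                prev = pos + size
            else:  # insertion
                ins = _BASES[rng.integers(0, 4, size=size)]
                pieces.append(out[prev : pos + 1].tobytes())
                pieces.append(ins.tobytes())
                prev = pos + 1
        pieces.append(out[prev:].tobytes())
        return b"".join(pieces).decode("ascii")
    return out.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# registry generation

# ranks from root to leaf, paired with the config count attribute
_TREE_LEVELS = (
    ("phylum", "n_phyla"),
    ("class", "n_classes"),
    ("order", "n_orders"),
    ("family", "n_families"),
    ("genus", "n_genera"),
    ("species", "n_species"),
)

_LEVEL_TAG = {
    "phylum": "Phy",
    "class": "Cla",
    "order": "Ord",
    "family": "Fam",
    "genus": "Gen",
}


@dataclass
class _Leaf:
    accession: str
    sequence: str
    lineage: Lineage
    # per-level nominal branch divergence from the parent taxon's ancestor
    branch: dict[str, float]
    flags: frozenset[str] = frozenset()


def _genome_count(cfg: CladeConfig, rng: np.random.Generator) -> int:
    g = cfg.genomes_per_species
    if isinstance(g, tuple):
        lo, hi = g
        return int(rng.integers(lo, hi + 1))
    return int(g)


def generate_registry(
    config: CladeConfig, out_dir: str | Path | None = None
) -> SyntheticRegistry:
    """Build the taxon tree and emit genomes, lineages and truth divergences.

    See the module docstring for the branching model.  When ``out_dir`` is
    given the registry is also written to disk (FASTA + lineage/truth TSVs).
    """
    div = dict(DEFAULT_DIVERGENCE)
    div.update(config.divergence_per_rank)
    for level, p in div.items():
        if not 0.0 <= p < 1.0:
            raise ValueError(f"divergence for {level!r} must be in [0, 1)")
    n_total = (
        config.n_phyla
        * config.n_classes
        * config.n_orders
        * config.n_families
        * config.n_genera
        * config.n_species
    )
    if n_total < 1:
        raise ValueError("configuration produces zero genomes")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    root = random_genome(config.genome_length, config.gc_content, rng)

    leaves: list[_Leaf] = []
    counters = {tag: itertools.count(1) for tag in _LEVEL_TAG.values()}
    acc_counter = itertools.count(1)

    edge_cases_pending = config.edge_cases

    def descend(
        level_idx: int,
        ancestor: str,
        names: dict[str, str],
        branches: dict[str, float],
    ) -> None:
        nonlocal edge_cases_pending
        level, count_attr = _TREE_LEVELS[level_idx]
        n_children = getattr(config, count_attr)
        if level == "species":
            genus = names["genus"]
            for i in range(n_children):
                child, p_branch = _child(ancestor, div["species"], i)
                species_name = f"{genus} epitheton{i + 1:02d}"
                _emit_species(
                    child,
                    species_name,
                    names,
                    {**branches, "species": p_branch},
                    div["strain"],
                )
            if edge_cases_pending:  # inject into the first genus only
                edge_cases_pending = False
                _emit_edge_cases(ancestor, genus, names, branches)
            return
        tag = _LEVEL_TAG[level]
        for i in range(n_children):
            child, p_branch = _child(ancestor, div[level], i)
            name = f"{tag}{next(counters[tag]):02d}"
            descend(
                level_idx + 1,
                child,
                {**names, level: name},
                {**branches, level: p_branch},
            )

    def _child(ancestor: str, p: float, index: int) -> tuple[str, float]:
        # type lineage: the first child inherits the ancestor unchanged
        if index == 0:
            return ancestor, 0.0
        return (
            mutate(ancestor, p, config.indel_rate, rng),
            p,
        )

    def _emit_species(
        ancestor: str,
        species_name: str,
        names: dict[str, str],
        branches: dict[str, float],
        p_strain: float,
        flags: frozenset[str] = frozenset(),
    ) -> None:
        lineage = Lineage(
            species=species_name,
            genus=names["genus"],
            family=names["family"],
            order=names["order"],
            class_=names["class"],
            phylum=names["phylum"],
        )
        for g in range(_genome_count(config, rng)):
            seq, p_branch = _child(ancestor, p_strain, g)
            leaves.append(
                _Leaf(
                    accession=f"GCA_{next(acc_counter):06d}",
                    sequence=seq,
                    lineage=lineage,
                    branch={**branches, "strain": p_branch},
                    flags=flags,
                )
            )

    def _emit_edge_cases(
        genus_ancestor: str,
        genus: str,
        names: dict[str, str],
        branches: dict[str, float],
    ) -> None:
        p_sp = div["species"]
        cases = (
            (f"{genus} epitheton01 x {genus} epitheton02", 2.0 * p_sp, "hybrid"),
            (f"{genus} sp. QX2020a", 1.5 * p_sp, "strain_named"),
            (f"{genus} overdispersum", 1.5 * p_sp, "outlier_species"),
        )
        for species_name, p_strain, flag in cases:
            anc, p_branch = (
                mutate(genus_ancestor, p_sp, config.indel_rate, rng),
                p_sp,
            )
            _emit_species(
                anc,
                species_name,
                names,
                {**branches, "species": p_branch},
                p_strain,
                flags=frozenset({flag}),
            )

    descend(0, root, {}, {})

    records = tuple(
        GenomeRecord(
            accession=leaf.accession,
            lineage=leaf.lineage,
            flags=leaf.flags,
            sequence=leaf.sequence,
        )
        for leaf in leaves
    )
    truth = _truth_divergences(leaves)
    registry = SyntheticRegistry(records=records, truth=truth)
    if out_dir is not None:
        registry.write(out_dir)
    return registry


def _truth_divergences(leaves: list[_Leaf]) -> dict[tuple[str, str], float]:
    """Sum of nominal branch divergences below the last shared taxon."""
    # levels from least to most specific, as stored in Lineage
    order = ("phylum", "class", "order", "family", "genus", "species")
    truth: dict[tuple[str, str], float] = {}
    for la, lb in itertools.combinations(leaves, 2):
        shared_idx = -1
        for i, level in enumerate(order):
            if la.lineage.taxon_at(level) == lb.lineage.taxon_at(level):
                shared_idx = i
            else:
                break
        d = la.branch.get("strain", 0.0) + lb.branch.get("strain", 0.0)
        for level in order[shared_idx + 1 :]:
            d += la.branch.get(level, 0.0) + lb.branch.get(level, 0.0)
        key = tuple(sorted((la.accession, lb.accession)))
        truth[key] = d  # type: ignore[index]
    return truth
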