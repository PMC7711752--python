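"""Lineage annotation, dataset curation, and rank-stratified pair enumeration.

Each genome carries a six-rank lineage (species, genus, family, order, class,
phylum).  An unordered pair of genomes belongs to the stratum of the most
specific rank at which the two lineages agree: the *species* stratum holds
pairs within one species; the *genus* stratum holds pairs of different species
in the same genus; and so on up to phylum.  Pairs differing even at the phylum
level fall outside all strata.  Taxa are compared as exact strings (no synonym
resolution beyond whitespace trimming); a genome missing a rank needed for a
stratum is skipped for that stratum.

Dataset shaping mirrors a registry-style workflow: species with too few
genomes are dropped, over-sequenced species are down-sampled at random, and a
curation pass removes hybrid-named species, species whose epithet is a bare
"sp." plus a strain code, and user-listed outlier genera/species.  Hybrid and
strain-name detection is regex-based and every removal is returned in an
audit list with its reason.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "MISSING_RANK",
    "Lineage",
    "GenomeRecord",
    "RankStratum",
    "DEFAULT_EXCLUDED_GENERA",
    "DEFAULT_EXCLUDED_SPECIES",
    "load_lineages",
    "filter_min_max_per_species",
    "curate",
    "enumerate_rank_pairs",
    "stratify_all",
    "parse_rankedlineage",
]

#: taxonomic levels from most to least specific
RANKS = ("species", "genus", "family", "order", "class", "phylum")

#: explicit sentinel for an unannotated rank (blank cells in the lineage TSV)
MISSING_RANK = "<missing>"

#: genera with unexpectedly short between-species distances, excluded by
#: default during curation
DEFAULT_EXCLUDED_GENERA = (
    "Komagataella",
    "Calonectria",
    "Coccidioides",
    "Alternaria",
)

#: species with unexpectedly high within-species diversity, excluded by
#: default during curation
DEFAULT_EXCLUDED_SPECIES = (
    "Rhizoctonia solani",
    "Debaryomyces hansenii",
    "Blumeria graminis",
    "Parastagonospora avenae",
    "Schyzophyllum commune",
    "Rhodotorula toruloides",
    "Hortaea werneckii",
    "Microbotryum violaceum",
)

# " x " (or the multiplication sign) between parent names, or the word hybrid
_HYBRID_RE = re.compile(r"(?:\s[xX×]\s|\bhybrid\b)", re.IGNORECASE)
# epithet that is "sp." followed by an alphanumeric strain code
_STRAIN_RE = re.compile(r"\bsp\.\s*[\w.\-]+", re.IGNORECASE)


@dataclass(frozen=True)
class Lineage:
    species: str = MISSING_RANK
    genus: str = MISSING_RANK
    family: str = MISSING_RANK
    order: str = MISSING_RANK
    class_: str = MISSING_RANK
    phylum: str = MISSING_RANK

    def taxon_at(self, level: str) -> str:
        if level == "class":
            level = "class_"
        return getattr(self, level)


@dataclass(frozen=True)
class GenomeRecord:
    """One assembly: accession key, FASTA location, lineage, curation flags.

    ``sequence`` optionally holds the genome in memory (synthetic registries);
    when absent the FASTA at ``path`` is the source of record.
    """

    accession: str
    lineage: Lineage
    path: Path | None = None
    flags: frozenset[str] = frozenset()
    sequence: str | None = field(default=None, repr=False)


@dataclass(frozen=True)
class RankStratum:
    """All unordered pairs whose most specific shared rank is ``level``.

    ``anchors[i]`` is the shared taxon of ``pairs[i]`` at that level.
    """

    level: str
    pairs: tuple[tuple[str, str], ...]
    anchors: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# lineage table input


def load_lineages(table: str | Path | IO[str]) -> dict[str, Lineage]:
    """Read a header-bearing lineage TSV into accession → :class:`Lineage`.

    Required columns: accession, species, genus, family, order, class,
    phylum.  Blank cells become :data:`MISSING_RANK`; duplicate accessions
    are rejected.
    """
    df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", *RANKS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lineage table lacks columns: {sorted(missing)}")
    df = df.apply(lambda col: col.str.strip())
    dups = df["accession"][df["accession"].duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate accession(s): {sorted(set(dups))}")
    out: dict[str, Lineage] = {}
    for row in df.itertuples(index=False):
        # itertuples mangles the "class" column name; rebuild positionally
        rec = dict(zip(df.columns, row))
        out[rec["accession"]] = Lineage(
            **{
                ("class_" if r == "class" else r): (rec[r] or MISSING_RANK)
                for r in RANKS
            }
        )
    return out


def parse_rankedlineage(
    dmp: str | Path | IO[str],
) -> pd.DataFrame:
    """Thin converter for NCBI ``rankedlineage.dmp`` rows.

    Returns a DataFrame with columns tax_id, tax_name, species, genus,
    family, order, class, phylum (blank fields become
    :data:`MISSING_RANK`).  Joining tax names to accessions is left to the
    caller; the pipeline itself consumes the plain lineage TSV.
    """
    rows = []
    handle = open(dmp) if isinstance(dmp, (str, Path)) else dmp
    try:
        for line in handle:
            parts = [p.strip() for p in line.rstrip("\n").split("\t|")]
            if len(parts) < 10:
                continue
            tax_id, name, species, genus, family, order, cls, phylum = (
                parts[0],
                parts[1],
                parts[2],
                parts[3],
                parts[4],
                parts[5],
                parts[6],
                parts[7],
            )
            rows.append(
                {
                    "tax_id": tax_id,
                    "tax_name": name,
                    "species": species or name or MISSING_RANK,
                    "genus": genus or MISSING_RANK,
                    "family": family or MISSING_RANK,
                    "order": order or MISSING_RANK,
                    "class": cls or MISSING_RANK,
                    "phylum": phylum or MISSING_RANK,
                }
            )
    finally:
        if isinstance(dmp, (str, Path)):
            handle.close()
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset shaping


def filter_min_max_per_species(
    records: Sequence[GenomeRecord],
    min_n: int = 3,
    max_n: int = 10,
    seed: int = 0,
) -> list[GenomeRecord]:
    """Keep species with >= ``min_n`` genomes, down-sampling to ``max_n``.

    Species with fewer than ``min_n`` genomes are dropped entirely; species
    with more than ``max_n`` are down-sampled uniformly at random (seeded).
    Records without a species annotation are dropped (their species count is
    unknowable).  Idempotent for fixed parameters.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[GenomeRecord]] = {}
    ordered_species: list[str] = []
    for rec in records:
        sp = rec.lineage.species
        if sp == MISSING_RANK:
            continue
        if sp not in by_species:
            by_species[sp] = []
            ordered_species.append(sp)
        by_species[sp].append(rec)
    kept: list[GenomeRecord] = []
    for sp in ordered_species:
        group = by_species[sp]
        if len(group) < min_n:
            continue
        if len(group) > max_n:
            idx = sorted(rng.choice(len(group), size=max_n, replace=False))
            group = [group[i] for i in idx]
        kept.extend(group)
    return kept


def _curation_reason(
    rec: GenomeRecord,
    exclude_genera: frozenset[str],
    exclude_species: frozenset[str],
    drop_hybrids: bool,
    drop_strain_named: bool,
) -> str | None:
    lin = rec.lineage
    if lin.genus in exclude_genera:
        return "outlier_genus"
    if lin.species in exclude_species:
        return "outlier_species"
    if drop_hybrids and lin.species != MISSING_RANK and _HYBRID_RE.search(
        lin.species
    ):
        return "hybrid"
    if (
        drop_strain_named
        and lin.species != MISSING_RANK
        and _STRAIN_RE.search(lin.species)
    ):
        return "strain_named"
    return None


def curate(
    records: Sequence[GenomeRecord],
    exclude_genera: Iterable[str] | None = None,
    exclude_species: Iterable[str] | None = None,
    drop_hybrids: bool = True,
    drop_strain_named: bool = True,
) -> tuple[list[GenomeRecord], list[tuple[str, str]]]:
    """Remove hybrid-named, strain-numbered and listed outlier taxa.

    Returns (retained records, audit list of (accession, reason)).  Reasons:
    outlier_genus, outlier_species, hybrid, strain_named.  Exclusion lists
    default to :data:`DEFAULT_EXCLUDED_GENERA` / :data:`DEFAULT_EXCLUDED_SPECIES`
    and are fully overridable (pass an empty iterable to disable).
    """
    genera = frozenset(
        DEFAULT_EXCLUDED_GENERA if exclude_genera is None else exclude_genera
    )
    species = frozenset(
        DEFAULT_EXCLUDED_SPECIES if exclude_species is None else exclude_species
    )
    kept: list[GenomeRecord] = []
    audit: list[tuple[str, str]] = []
    for rec in records:
        reason = _curation_reason(
            rec, genera, species, drop_hybrids, drop_strain_named
        )
        if reason is None:
            kept.append(rec)
        else:
            audit.append((rec.accession, reason))
            # keep the flag on the record in the audit trail only
    return kept, audit


# ---------------------------------------------------------------------------
# pair enumeration


def enumerate_rank_pairs(
    records: Sequence[GenomeRecord], level: str
) -> RankStratum:
    """All unordered pairs whose most specific shared rank is ``level``.

    Species level: pairs with identical species strings.  Any higher level L:
    pairs sharing the taxon at L but differing at the level immediately below
    L.  Records missing the taxon at either of those levels are skipped.
    Pairs are deduplicated, self-pairs excluded, accessions sorted within a
    pair, and the output order is deterministic.
    """
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}")
    rank_idx = RANKS.index(level)
    pairs: list[tuple[str, str]] = []
    anchors: list[str] = []
    if rank_idx == 0:  # within species
        groups: dict[str, list[str]] = {}
        for rec in sorted(records, key=lambda r: r.accession):
            sp = rec.lineage.species
            if sp == MISSING_RANK:
                continue
            groups.setdefault(sp, []).append(rec.accession)
        for sp in sorted(groups):
            for a, b in itertools.combinations(groups[sp], 2):
                pairs.append((a, b))
                anchors.append(sp)
    else:
        below = RANKS[rank_idx - 1]
        groups2: dict[str, dict[str, list[str]]] = {}
        for rec in sorted(records, key=lambda r: r.accession):
            anchor = rec.lineage.taxon_at(level)
            sub = rec.lineage.taxon_at(below)
            if anchor == MISSING_RANK or sub == MISSING_RANK:
                continue
            groups2.setdefault(anchor, {}).setdefault(sub, []).append(
                rec.accession
            )
        for anchor in sorted(groups2):
            subtaxa = groups2[anchor]
            for sub_a, sub_b in itertools.combinations(sorted(subtaxa), 2):
                for a in subtaxa[sub_a]:
                    for b in subtaxa[sub_b]:
                        pair = (a, b) if a < b else (b, a)
                        pairs.append(pair)
                        anchors.append(anchor)
    return RankStratum(level=level, pairs=tuple(pairs), anchors=tuple(anchors))


def stratify_all(
    records: Sequence[GenomeRecord],
) -> dict[str, RankStratum]:
    """One stratum per taxonomic level (cross-phylum pairs fall in none)."""
    return {level: enumerate_rank_pairs(records, level) for level in RANKS}
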