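"""End-to-end orchestration: filter → curate → sketch → distances → thresholds.

The run produces four TSV reports in the output directory:

* ``distances.tsv`` — one row per genome pair and method: accession_a,
  accession_b, level, anchor_taxon, method, k, value, orientation;
* ``summaries.tsv`` — per method and taxonomic level: n_pairs, median, mean;
* ``thresholds.tsv`` — per method and adjacent level pair: threshold,
  orientation, wrong-side share of each stratum, pooled misclassified,
  iterations, converged;
* ``audit.tsv`` — every genome dropped by filtering or curation, with reason.

Each genome is read and summarised once (k-mer set and, per method, sketch)
and reused across all strata; an optional cache directory persists sketches
between runs without changing any value.  All randomness (down-sampling,
hashing) flows from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import kmers as _kmers
from . import sketch as _sketch
from .sketch import ORIENTATION
from .taxonomy import (
    RANKS,
    GenomeRecord,
    RankStratum,
    curate,
    enumerate_rank_pairs,
    filter_min_max_per_species,
    load_lineages,
)
from .threshold import find_threshold, rank_summaries

__all__ = [
    "RunConfig",
    "PipelineResult",
    "GenomeIndex",
    "ADJACENT_LEVEL_PAIRS",
    "load_registry",
    "compute_pairwise",
    "run_all",
    "run_k_sweep",
]

METHODS = ("mash", "hll_similarity", "kmer_overlap")

#: adjacent rank comparisons, lower (more specific) stratum first
ADJACENT_LEVEL_PAIRS = (
    ("species", "genus"),
    ("genus", "family"),
    ("family", "order"),
    ("order", "class"),
    ("class", "phylum"),
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    input_dir: Path | None = None
    lineage_table: Path | None = None
    output_dir: Path | None = None
    methods: tuple[str, ...] = METHODS
    k: int = 16
    sketch_size: int = 100_000
    hll_p: int = 20
    hash_seed: int = _sketch.DEFAULT_HASH_SEED
    min_per_species: int = 3
    max_per_species: int = 10
    curate: bool = True
    exclude_genera: tuple[str, ...] | None = None
    exclude_species: tuple[str, ...] | None = None
    drop_hybrids: bool = True
    drop_strain_named: bool = True
    levels: tuple[str, ...] = RANKS
    seed: int = 42
    cache_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 8 <= self.k <= 32:
            raise ValueError(f"k must be in [8, 32], got {self.k}")
        if not self.methods:
            raise ValueError("at least one method must be selected")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown method(s): {sorted(unknown)}")


@dataclass
class PipelineResult:
    records: list[GenomeRecord]
    audit: pd.DataFrame
    distances: pd.DataFrame
    summaries: pd.DataFrame
    thresholds: pd.DataFrame


# ---------------------------------------------------------------------------
# genome access with per-genome caching


class GenomeIndex:
    """Lazily computed, memoised per-genome k-mer sets and sketches.

    ``cache_dir`` (optional) persists sketches as JSON between runs; cached
    and freshly computed sketches are interchangeable by construction.
    """

    def __init__(
        self,
        records: Sequence[GenomeRecord],
        k: int,
        sketch_size: int,
        hll_p: int,
        hash_seed: int,
        cache_dir: Path | None = None,
    ) -> None:
        self._records = {r.accession: r for r in records}
        self.k = k
        self.sketch_size = sketch_size
        self.hll_p = hll_p
        self.hash_seed = hash_seed
        self.cache_dir = Path(cache_dir) if cache_dir else None
        if self.cache_dir:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self._kmersets: dict[str, _kmers.KmerSet] = {}
        self._minhash: dict[str, _sketch.MinHashSketch] = {}
        self._hll: dict[str, _sketch.HllSketch] = {}
        self._hll_card: dict[str, float] = {}

    def _sequences(self, accession: str) -> list[str]:
        try:
            rec = self._records[accession]
        except KeyError:
            raise KeyError(f"unknown accession {accession!r}") from None
        if rec.sequence is not None:
            return [rec.sequence]
        if rec.path is None or not Path(rec.path).exists():
            raise FileNotFoundError(
                f"no FASTA available for accession {accession!r}"
                + (f" at {rec.path}" if rec.path else "")
            )
        seqs = _kmers.read_fasta(rec.path)
        if not seqs:
            raise ValueError(f"unreadable or empty FASTA for {accession!r}")
        return seqs

    def kmer_set(self, accession: str) -> _kmers.KmerSet:
        if accession not in self._kmersets:
            self._kmersets[accession] = _kmers.extract_canonical_kmers(
                self._sequences(accession), k=self.k
            )
        return self._kmersets[accession]

    def _cached(self, accession: str, kind: str):
        if not self.cache_dir:
            return None
        path = self.cache_dir / f"{accession}.{kind}.k{self.k}.json"
        if path.exists():
            return _sketch.load_sketch(path)
        return None

    def _store(self, accession: str, kind: str, sk) -> None:
        if self.cache_dir:
            path = self.cache_dir / f"{accession}.{kind}.k{self.k}.json"
            _sketch.save_sketch(sk, path)

    def minhash(self, accession: str) -> _sketch.MinHashSketch:
        if accession not in self._minhash:
            sk = self._cached(accession, "minhash")
            if sk is None or sk.s != self.sketch_size or sk.hash_seed != self.hash_seed:
                sk = _sketch.minhash_sketch(
                    self.kmer_set(accession),
                    s=self.sketch_size,
                    hash_seed=self.hash_seed,
                )
                self._store(accession, "minhash", sk)
            self._minhash[accession] = sk
        return self._minhash[accession]

    def hll(self, accession: str) -> _sketch.HllSketch:
        if accession not in self._hll:
            sk = self._cached(accession, "hll")
            if sk is None or sk.p != self.hll_p or sk.hash_seed != self.hash_seed:
                sk = _sketch.hll_sketch(
                    self.kmer_set(accession),
                    p=self.hll_p,
                    hash_seed=self.hash_seed,
                )
                self._store(accession, "hll", sk)
            self._hll[accession] = sk
        return self._hll[accession]

    def pair_value(self, method: str, acc_a: str, acc_b: str) -> float:
        if method == "mash":
            j = _sketch.sketch_jaccard(self.minhash(acc_a), self.minhash(acc_b))
            return _sketch.mash_distance(j, self.k)
        if method == "hll_similarity":
            a, b = self.hll(acc_a), self.hll(acc_b)
            for acc, sk in ((acc_a, a), (acc_b, b)):
                if acc not in self._hll_card:
                    self._hll_card[acc] = _sketch.hll_cardinality(sk)
            return _sketch.hll_similarity(
                a, b, self._hll_card[acc_a], self._hll_card[acc_b]
            )
        if method == "kmer_overlap":
            return _kmers.corrected_overlap_share(
                self.kmer_set(acc_a), self.kmer_set(acc_b)
            )
        raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# stages


def load_registry(
    input_dir: str | Path, lineage_table: str | Path
) -> list[GenomeRecord]:
    """Match lineage rows to ``<accession>.fna[.gz]`` files in ``input_dir``."""
    input_dir = Path(input_dir)
    lineages = load_lineages(lineage_table)
    records = []
    for accession, lineage in lineages.items():
        path = None
        for suffix in (".fna.gz", ".fna", ".fa.gz", ".fa", ".fasta.gz", ".fasta"):
            candidate = input_dir / f"{accession}{suffix}"
            if candidate.exists():
                path = candidate
                break
        records.append(
            GenomeRecord(accession=accession, lineage=lineage, path=path)
        )
    return records


def compute_pairwise(
    stratum: RankStratum,
    method: str,
    index: GenomeIndex,
) -> pd.DataFrame:
    """One distance record per pair of the stratum (symmetric in pair order)."""
    rows = []
    for (acc_a, acc_b), anchor in zip(stratum.pairs, stratum.anchors):
        rows.append(
            {
                "accession_a": acc_a,
                "accession_b": acc_b,
                "level": stratum.level,
                "anchor_taxon": anchor,
                "method": method,
                "k": index.k,
                "value": index.pair_value(method, acc_a, acc_b),
                "orientation": ORIENTATION[method],
            }
        )
    columns = [
        "accession_a",
        "accession_b",
        "level",
        "anchor_taxon",
        "method",
        "k",
        "value",
        "orientation",
    ]
    return pd.DataFrame(rows, columns=columns)


def _prepare_records(
    records: Sequence[GenomeRecord], config: RunConfig
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    before = {r.accession for r in records}
    filtered = filter_min_max_per_species(
        records,
        min_n=config.min_per_species,
        max_n=config.max_per_species,
        seed=config.seed,
    )
    audit_rows = [
        {"accession": acc, "reason": "species_size_filter"}
        for acc in sorted(before - {r.accession for r in filtered})
    ]
    kept = filtered
    if config.curate:
        kept, removal_audit = curate(
            filtered,
            exclude_genera=config.exclude_genera,
            exclude_species=config.exclude_species,
            drop_hybrids=config.drop_hybrids,
            drop_strain_named=config.drop_strain_named,
        )
        audit_rows.extend(
            {"accession": acc, "reason": reason} for acc, reason in removal_audit
        )
    audit = pd.DataFrame(audit_rows, columns=["accession", "reason"])
    return kept, audit


def run_all(
    records_or_config: Sequence[GenomeRecord] | RunConfig,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Execute the full workflow and (optionally) write the TSV reports.

    Accepts either a ``RunConfig`` whose ``input_dir``/``lineage_table``
    point at a registry on disk, or an in-memory record list plus a config.
    """
    if isinstance(records_or_config, RunConfig):
        config = records_or_config
        if config.input_dir is None or config.lineage_table is None:
            raise ValueError("config must set input_dir and lineage_table")
        records = load_registry(config.input_dir, config.lineage_table)
    else:
        records = list(records_or_config)
        if config is None:
            raise ValueError("a RunConfig is required")

    kept, audit = _prepare_records(records, config)
    index = GenomeIndex(
        kept,
        k=config.k,
        sketch_size=config.sketch_size,
        hll_p=config.hll_p,
        hash_seed=config.hash_seed,
        cache_dir=config.cache_dir,
    )

    strata = {
        level: enumerate_rank_pairs(kept, level) for level in config.levels
    }
    frames = []
    for method in config.methods:
        for level in config.levels:
            if len(strata[level]):
                frames.append(compute_pairwise(strata[level], method, index))
    distances = (
        pd.concat(frames, ignore_index=True)
        if frames
        else compute_pairwise(
            RankStratum(level="species", pairs=(), anchors=()), "mash", index
        )
    )

    summary_rows = []
    for method in config.methods:
        sub = distances[distances["method"] == method]
        for s in rank_summaries(sub):
            summary_rows.append(
                {
                    "method": method,
                    "level": s.level,
                    "n_pairs": s.n_pairs,
                    "median": s.median,
                    "mean": s.mean,
                }
            )
    summaries = pd.DataFrame(
        summary_rows, columns=["method", "level", "n_pairs", "median", "mean"]
    )

    threshold_rows = []
    for method in config.methods:
        sub = distances[distances["method"] == method]
        for lower_level, higher_level in ADJACENT_LEVEL_PAIRS:
            if lower_level not in config.levels or higher_level not in config.levels:
                continue
            lo = sub.loc[sub["level"] == lower_level, "value"].to_numpy()
            hi = sub.loc[sub["level"] == higher_level, "value"].to_numpy()
            if lo.size == 0 or hi.size == 0:
                continue
            res = find_threshold(lo, hi, orientation=ORIENTATION[method])
            threshold_rows.append(
                {
                    "level_pair": f"{lower_level}|{higher_level}",
                    "method": method,
                    "k": config.k,
                    "threshold": res.threshold,
                    "orientation": res.orientation,
                    "share_lower_wrong": res.share_lower_wrong,
                    "share_higher_wrong": res.share_higher_wrong,
                    "pooled_misclassified": res.pooled_misclassified,
                    "iterations": res.iterations,
                    "converged": res.converged,
                }
            )
    thresholds = pd.DataFrame(
        threshold_rows,
        columns=[
            "level_pair",
            "method",
            "k",
            "threshold",
            "orientation",
            "share_lower_wrong",
            "share_higher_wrong",
            "pooled_misclassified",
            "iterations",
            "converged",
        ],
    )

    result = PipelineResult(
        records=kept,
        audit=audit,
        distances=distances,
        summaries=summaries,
        thresholds=thresholds,
    )
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        distances.to_csv(out / "distances.tsv", sep="\t", index=False)
        summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
        audit.to_csv(out / "audit.tsv", sep="\t", index=False)
    return result


def run_k_sweep(
    records: Sequence[GenomeRecord],
    config: RunConfig,
    ks: Iterable[int] = (12, 14, 16, 18, 20, 22),
    level_pair: tuple[str, str] = ("species", "genus"),
) -> pd.DataFrame:
    """Repeat the ``level_pair`` thresholding over several k-mer sizes."""
    frames = []
    for k in ks:
        cfg = replace(
            config, k=k, levels=level_pair, output_dir=None, cache_dir=None
        )
        frames.append(run_all(list(records), cfg).thresholds)
    return pd.concat(frames, ignore_index=True)
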