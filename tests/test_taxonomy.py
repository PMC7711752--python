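"""Lineage parsing, curation filters and rank-stratified pair enumeration."""

import io
import itertools

import pytest
from hypothesis import given, settings, strategies as st

from taxodist.taxonomy import (
    MISSING_RANK,
    RANKS,
    GenomeRecord,
    curate,
    enumerate_rank_pairs,
    filter_min_max_per_species,
    load_lineages,
    parse_rankedlineage,
    stratify_all,
)

from conftest import last_shared_rank, make_record


HEADER = "accession\tspecies\tgenus\tfamily\torder\tclass\tphylum\n"


class TestLoadLineages:
    def test_full_row(self):
        tsv = HEADER + (
            "GCA_1\tHortaea werneckii\tHortaea\tTeratosphaeriaceae\t"
            "Capnodiales\tDothideomycetes\tAscomycota\n"
        )
        lin = load_lineages(io.StringIO(tsv))["GCA_1"]
        assert lin.species == "Hortaea werneckii"
        assert lin.genus == "Hortaea"
        assert lin.family == "Teratosphaeriaceae"
        assert lin.order == "Capnodiales"
        assert lin.class_ == "Dothideomycetes"
        assert lin.phylum == "Ascomycota"

    def test_blank_cell_becomes_sentinel(self):
        tsv = HEADER + "GCA_1\tA b\tA\t\tO\tC\tP\n"
        lin = load_lineages(io.StringIO(tsv))["GCA_1"]
        assert lin.family == MISSING_RANK

    def test_duplicate_accession_rejected(self):
        tsv = HEADER + "GCA_1\tA b\tA\tF\tO\tC\tP\nGCA_1\tA c\tA\tF\tO\tC\tP\n"
        with pytest.raises(ValueError, match="GCA_1"):
            load_lineages(io.StringIO(tsv))

    def test_missing_column_rejected(self):
        tsv = "accession\tspecies\tgenus\nGCA_1\tA b\tA\n"
        with pytest.raises(ValueError, match="family"):
            load_lineages(io.StringIO(tsv))


def test_parse_rankedlineage_dialect():
    row = (
        "436907\t|\tHortaea werneckii\t|\tHortaea werneckii\t|\tHortaea\t|\t"
        "Teratosphaeriaceae\t|\tCapnodiales\t|\tDothideomycetes\t|\t"
        "Ascomycota\t|\tFungi\t|\tEukaryota\t|\n"
    )
    df = parse_rankedlineage(io.StringIO(row))
    assert df.loc[0, "genus"] == "Hortaea"
    assert df.loc[0, "phylum"] == "Ascomycota"


def _species_records(sizes: dict[str, int]) -> list[GenomeRecord]:
    recs = []
    i = 0
    for species, n in sizes.items():
        for _ in range(n):
            i += 1
            recs.append(
                make_record(
                    f"GCA_{i}",
                    species=species,
                    genus=species.split()[0],
                    family="F",
                    order="O",
                    class_="C",
                    phylum="P",
                )
            )
    return recs


class TestFilterMinMax:
    def test_small_species_dropped_entirely(self):
        recs = _species_records({"A b": 2, "A c": 3})
        kept = filter_min_max_per_species(recs, seed=0)
        assert {r.lineage.species for r in kept} == {"A c"}
        assert len(kept) == 3

    def test_large_species_downsampled_to_max(self):
        recs = _species_records({"A b": 15})
        kept = filter_min_max_per_species(recs, seed=0)
        assert len(kept) == 10

    def test_downsampling_reproducible_and_idempotent(self):
        recs = _species_records({"A b": 15, "A c": 5})
        kept1 = filter_min_max_per_species(recs, seed=11)
        kept2 = filter_min_max_per_species(recs, seed=11)
        assert [r.accession for r in kept1] == [r.accession for r in kept2]
        again = filter_min_max_per_species(kept1, seed=11)
        assert [r.accession for r in again] == [r.accession for r in kept1]
        other = filter_min_max_per_species(recs, seed=12)
        assert len(other) == len(kept1)

    def test_missing_species_dropped(self):
        recs = _species_records({"A b": 3}) + [make_record("GCA_X", genus="A")]
        kept = filter_min_max_per_species(recs, seed=0)
        assert all(r.accession != "GCA_X" for r in kept)


class TestCurate:
    def test_hybrid_name_removed(self):
        recs = _species_records(
            {"Saccharomyces cerevisiae x Saccharomyces kudriavzevii": 1}
        )
        kept, audit = curate(recs, exclude_genera=(), exclude_species=())
        assert kept == []
        assert audit == [("GCA_1", "hybrid")]

    def test_default_outlier_genus_removed(self):
        recs = _species_records({"Coccidioides immitis": 1})
        kept, audit = curate(recs)
        assert kept == []
        assert audit[0][1] == "outlier_genus"

    def test_default_outlier_species_removed(self):
        recs = _species_records({"Hortaea werneckii": 1})
        kept, audit = curate(recs)
        assert kept == []
        assert audit[0][1] == "outlier_species"

    def test_strain_named_species_removed(self):
        recs = _species_records({"Neurospora sp. CHS2018a": 1})
        kept, audit = curate(recs, exclude_genera=(), exclude_species=())
        assert kept == []
        assert audit == [("GCA_1", "strain_named")]

    def test_switches_disable_rules(self):
        recs = _species_records(
            {"Neurospora sp. CHS2018a": 1, "A b x A c": 1}
        )
        kept, audit = curate(
            recs,
            exclude_genera=(),
            exclude_species=(),
            drop_hybrids=False,
            drop_strain_named=False,
        )
        assert len(kept) == 2 and audit == []

    def test_normal_binomial_survives(self):
        recs = _species_records({"Aspergillus fumigatus": 2})
        kept, audit = curate(recs)
        assert len(kept) == 2 and audit == []

    def test_idempotent(self):
        recs = _species_records(
            {"Hortaea werneckii": 2, "Aspergillus fumigatus": 2}
        )
        kept, _ = curate(recs)
        again, audit = curate(kept)
        assert [r.accession for r in again] == [r.accession for r in kept]
        assert audit == []


class TestEnumeratePairs:
    def test_species_level_combinatorics(self):
        recs = _species_records({"A b": 4})
        stratum = enumerate_rank_pairs(recs, "species")
        assert len(stratum) == 6  # C(4,2)

    def test_genus_level_cross_species(self):
        recs = _species_records({"A b": 3, "A c": 2})
        assert len(enumerate_rank_pairs(recs, "species")) == 3 + 1
        genus = enumerate_rank_pairs(recs, "genus")
        assert len(genus) == 3 * 2
        assert set(genus.anchors) == {"A"}

    def test_family_level_cross_genus(self):
        recs = (
            _species_records({"G1 a": 3})
            + [
                make_record(f"GCA_2{i}", species=sp, genus="G2", family="F",
                            order="O", class_="C", phylum="P")
                for i, sp in enumerate(["G2 a"] * 2 + ["G2 b"] * 2)
            ]
        )
        assert len(enumerate_rank_pairs(recs, "family")) == 3 * 4
        assert len(enumerate_rank_pairs(recs, "genus")) == 2 * 2

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rank_pairs([], "kingdom")

    def test_missing_rank_skipped(self):
        recs = [
            make_record("a1", species="A b", genus="A", family="F",
                        order="O", class_="C", phylum="P"),
            make_record("a2", species="A c", genus="A", family="",
                        order="O", class_="C", phylum="P"),
            make_record("a3", species="B a", genus="B", family="F",
                        order="O", class_="C", phylum="P"),
        ]
        fam = enumerate_rank_pairs(recs, "family")
        assert set(fam.pairs) == {("a1", "a3")}  # a2 lacks a family

    def test_pairs_unordered_deduplicated(self):
        recs = _species_records({"A b": 3})
        stratum = enumerate_rank_pairs(recs, "species")
        assert all(a < b for a, b in stratum.pairs)
        assert len(set(stratum.pairs)) == len(stratum.pairs)


@st.composite
def hierarchical_registry(draw):
    """Tree-consistent registry: names encode the path from the root."""
    recs = []
    i = 0
    for p in range(draw(st.integers(1, 2))):
        for c in range(draw(st.integers(1, 2))):
            for o in range(draw(st.integers(1, 2))):
                for f in range(draw(st.integers(1, 2))):
                    for g in range(draw(st.integers(1, 2))):
                        genus = f"G{p}{c}{o}{f}{g}"
                        for s in range(draw(st.integers(1, 2))):
                            for _ in range(draw(st.integers(1, 2))):
                                i += 1
                                recs.append(
                                    make_record(
                                        f"acc{i:03d}",
                                        species=f"{genus} s{s}",
                                        genus=genus,
                                        family=f"F{p}{c}{o}{f}",
                                        order=f"O{p}{c}{o}",
                                        class_=f"C{p}{c}",
                                        phylum=f"P{p}",
                                    )
                                )
    return recs


@settings(derandomize=True, max_examples=25)
@given(recs=hierarchical_registry())
def test_strata_partition_matches_exhaustive_oracle(recs):
    """Every complete-lineage pair lands in exactly the stratum of its most
    specific shared rank; cross-phylum pairs land nowhere."""
    strata = stratify_all(recs)
    seen = {}
    for level, stratum in strata.items():
        for pair in stratum.pairs:
            assert pair not in seen, "pair assigned to two strata"
            seen[pair] = level
    by_acc = {r.accession: r for r in recs}
    n_unassigned = 0
    for ra, rb in itertools.combinations(sorted(by_acc), 2):
        expected = last_shared_rank(by_acc[ra].lineage, by_acc[rb].lineage)
        assert seen.get((ra, rb)) == expected
        if expected is None:
            n_unassigned += 1
    n = len(recs)
    assert sum(len(s) for s in strata.values()) + n_unassigned == n * (n - 1) // 2
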