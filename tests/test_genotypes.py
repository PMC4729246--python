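"""Genotype parsing, dominant coding, genet assignment and diversity."""
import numpy as np
import pandas as pd
import pytest

from clonescape.genotypes import (
    GenotypeTable,
    read_genotypes,
    to_dominant_binary,
    assign_genets,
    diversity_stats,
    wide_to_canonical,
)
from conftest import table_from_sets


GENO_CSV = """individual,population,LocA,LocB
a1,north,150/158,200
a2,north,150/150,200/204
a3,south,.,204
"""


class TestReadGenotypes:
    def test_parses_slash_separated_missing_and_duplicate_alleles(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(GENO_CSV)
        gt = read_genotypes(path)
        assert gt.loci == ["LocA", "LocB"]
        assert gt.calls[0][0] == frozenset({150, 158})
        assert gt.calls[1][0] == frozenset({150})  # sets deduplicate
        assert gt.calls[2][0] == frozenset()       # '.' is missing
        assert gt.populations == ["north", "north", "south"]

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual,population,L1\na1,p,150/x\n")
        with pytest.raises(ValueError, match="a1.*L1"):
            read_genotypes(path)

    def test_too_many_alleles_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual,population,L1\na1,p,1/2/3\n")
        with pytest.raises(ValueError, match="ploidy"):
            read_genotypes(path, ploidy=2)

    def test_empty_file_and_duplicate_ids_rejected(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("individual,population,L1\n")
        with pytest.raises(ValueError):
            read_genotypes(empty)
        dup = tmp_path / "dup.csv"
        dup.write_text("individual,population,L1\na1,p,1\na1,p,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genotypes(dup)

    def test_roundtrip_through_canonical_csv(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(GENO_CSV)
        gt = read_genotypes(path)
        out = tmp_path / "out.csv"
        gt.to_csv(out)
        gt2 = read_genotypes(out)
        assert gt2.calls == gt.calls and gt2.individuals == gt.individuals

    def test_wide_layout_converter(self):
        df = pd.DataFrame(
            {"ind": ["a"], "pop": ["p"], "L1.1": [150], "L1.2": [158], "L2.1": [200], "L2.2": [0]}
        )
        out = wide_to_canonical(df, 2, ["L1", "L2"])
        assert out.loc[0, "L1"] == "150/158"
        assert out.loc[0, "L2"] == "200"


class TestDominantBinary:
    def test_presence_coding(self):
        gt = table_from_sets([[{150, 152}], [{152}]])
        bm = to_dominant_binary(gt)
        assert bm.columns == [("L1", 150), ("L1", 152)]
        assert bm.values.tolist() == [[1.0, 1.0], [0.0, 1.0]]

    def test_identical_calls_give_identical_rows(self):
        gt = table_from_sets([[{1, 2}, {5}]] * 4)
        bm = to_dominant_binary(gt)
        assert (bm.values == bm.values[0]).all()

    def test_missing_locus_masked_not_zero_filled(self):
        gt = table_from_sets([[{150}, {7}], [set(), {7, 9}]])
        bm = to_dominant_binary(gt)
        assert np.isnan(bm.values[1, 0])
        assert bm.values[1, 2] == 1.0

    def test_columns_ordered_loci_then_ascending_alleles(self):
        gt = table_from_sets([[{9, 3}, {200}], [{5}, {100}]])
        assert to_dominant_binary(gt).columns == [
            ("L1", 3), ("L1", 5), ("L1", 9), ("L2", 100), ("L2", 200)
        ]


class TestGenetAssignment:
    def test_identical_profiles_share_genet_single_allele_difference_splits(self):
        gt = table_from_sets([[{1, 2}, {5}], [{1, 2}, {5}], [{1, 2}, {5, 6}]])
        ga = assign_genets(gt)
        assert ga.genet_ids[0] == ga.genet_ids[1] != ga.genet_ids[2]
        assert ga.n_genets == 2
        assert list(ga.representative) == [True, False, True]

    def test_monomorphic_population_is_one_genet_with_zero_diversity(self):
        gt = table_from_sets([[{1, 2}, {5}]] * 10)
        ga = assign_genets(gt)
        assert ga.n_genets == 1
        div = diversity_stats(gt)
        assert div.loc[0, "D"] == 0.0 and div.loc[0, "n_genotypes"] == 1

    def test_missing_pattern_never_merges_with_complete(self):
        gt = table_from_sets([[{1}, {5}], [{1}, set()]])
        assert assign_genets(gt).n_genets == 2

    def test_order_insensitive_up_to_relabeling(self, rng):
        rows = [[{1}, {5}], [{2}, {5}], [{1}, {5}], [{2}, {6}]]
        gt = table_from_sets(rows)
        perm = rng.permutation(4)
        gt2 = gt.subset(perm)
        part1 = {}
        for ind, gid in zip(gt.individuals, assign_genets(gt).genet_ids):
            part1.setdefault(gid, set()).add(ind)
        part2 = {}
        for ind, gid in zip(gt2.individuals, assign_genets(gt2).genet_ids):
            part2.setdefault(gid, set()).add(ind)
        assert sorted(map(sorted, part1.values())) == sorted(map(sorted, part2.values()))

    def test_binary_row_dedup_matches_genet_count_on_complete_data(self, rng):
        rows = [
            [set(rng.choice(4, size=2) + 1) for _ in range(3)]
            for _ in range(30)
        ]
        gt = table_from_sets(rows)
        bm = to_dominant_binary(gt)
        unique_rows = len({tuple(r) for r in bm.values.tolist()})
        assert unique_rows == assign_genets(gt).n_genets


class TestDiversity:
    def test_hand_computed_presence_frequency_case(self):
        # one locus, sets {a},{a},{b}: p = (2/3, 1/3) -> NA=2, ENA=1/(5/9)=1.8,
        # genotype freqs (2/3, 1/3) -> D = (3/2)(1 - 5/9) = 2/3
        gt = table_from_sets([[{101}], [{101}], [{102}]])
        div = diversity_stats(gt)
        assert div.loc[0, "NA"] == 2
        assert div.loc[0, "ENA"] == pytest.approx(1.8, abs=1e-12)
        assert div.loc[0, "D"] == pytest.approx(2 / 3, abs=1e-12)

    def test_bruteforce_frequency_counter_agrees(self, rng):
        # independent oracle: count presence per allele by brute force
        rows = [[set(rng.choice(5, size=rng.integers(1, 4), replace=False) + 1)] for _ in range(12)]
        gt = table_from_sets(rows)
        counts = {}
        for row in rows:
            for a in row[0]:
                counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        ena = 1.0 / sum((c / tot) ** 2 for c in counts.values())
        div = diversity_stats(gt)
        assert div.loc[0, "NA"] == len(counts)
        assert div.loc[0, "ENA"] == pytest.approx(ena, abs=1e-12)

    def test_all_identical_ena_equals_locus_count(self):
        gt = table_from_sets([[{1}, {2}, {3}]] * 5)
        div = diversity_stats(gt)
        assert div.loc[0, "ENA"] == pytest.approx(3.0)
        assert div.loc[0, "D"] == 0.0

    def test_all_distinct_genotypes_give_d_one(self):
        gt = table_from_sets([[{k}] for k in range(1, 8)])
        assert diversity_stats(gt).loc[0, "D"] == pytest.approx(1.0)

    def test_invariants_on_random_tables(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 12))
            rows = [
                [set(rng.choice(6, size=rng.integers(1, 4), replace=False) + 1) for _ in range(3)]
                for _ in range(n)
            ]
            pops = [f"p{int(rng.integers(2))}" for _ in range(n)]
            gt = table_from_sets(rows, populations=pops)
            div = diversity_stats(gt)
            assert (div["ENA"] <= div["NA"] + 1e-12).all()
            assert ((div["D"] >= 0) & (div["D"] <= 1 + 1e-12)).all()
            assert (div["n_genotypes"] <= div["n"]).all()

    def test_individual_order_does_not_change_statistics(self, rng):
        rows = [[set(rng.choice(5, size=2, replace=False) + 1) for _ in range(3)] for _ in range(15)]
        pops = ["a"] * 8 + ["b"] * 7
        gt = table_from_sets(rows, populations=pops)
        perm = rng.permutation(15)
        div1 = diversity_stats(gt).set_index("pop").sort_index()
        div2 = diversity_stats(gt.subset(perm)).set_index("pop").sort_index()
        pd.testing.assert_frame_equal(div1, div2)

    def test_entirely_missing_locus_contributes_zero_with_warning(self, caplog):
        gt = table_from_sets([[{1}, set()], [{2}, set()], [{1}, {9}]],
                             populations=["a", "a", "b"])
        with caplog.at_level("WARNING"):
            div = diversity_stats(gt).set_index("pop")
        assert div.loc["a", "NA"] == 2  # only locus 1 contributes
        assert "missing" in caplog.text


def test_ploidy_validation():
    with pytest.raises(ValueError, match="ploidy"):
        table_from_sets([[{1, 2, 3}]], ploidy=2)
    with pytest.raises(ValueError):
        GenotypeTable(["a"], ["p"], ["L1"], [(frozenset({1}),)], ploidy=1)
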