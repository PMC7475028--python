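"""Species-overlap labelling, event extraction, fusion, pair selection."""

from __future__ import annotations

import pytest

import _oracles
from dupfate import trees
from dupfate.io import read_newick
from dupfate.trees import (
    DuplicationEvent,
    DuplicatePairCandidate,
    distant_species_filter,
    duplication_ratio_per_node,
    find_species_specific_duplications,
    fuse_overlapping_duplications,
    label_nodes_species_overlap,
    select_duplicate_pairs,
    verify_duplication_retained,
)


class TestSpeciesOverlap:
    def test_duplication_when_daughters_share_species(self):
        t = read_newick("((pisum_g1,pisum_g2)0.99,persicae_g1);")
        labels = label_nodes_species_overlap(t)
        by_depth = sorted(labels.items(), key=lambda kv: kv[0].level())
        assert by_depth[0][1] == "speciation"  # root
        assert by_depth[1][1] == "duplication"

    def test_all_speciation_when_disjoint(self):
        t = read_newick("((pisum_g1,persicae_g1),cedri_g1);")
        assert set(label_nodes_species_overlap(t).values()) == {"speciation"}

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            label_nodes_species_overlap(read_newick("(pisum_g1);"))

    def test_matches_bruteforce_oracle_on_random_trees(self, make_random_tree):
        for _ in range(50):
            t = make_random_tree(n_leaves=12, n_species=4)
            got = label_nodes_species_overlap(t)
            want = _oracles.species_overlap_labels(
                t, lambda lab: lab.split("_")[0]
            )
            assert got == want


class TestFindDuplications:
    def test_simple_pair(self):
        t = read_newick("((pisum_g1,pisum_g2)0.99,persicae_g1);")
        events = find_species_specific_duplications(t, "pisum")
        assert [sorted(e.members) for e in events] == [["pisum_g1", "pisum_g2"]]

    def test_no_focal_clade(self):
        t = read_newick("((pisum_g1,persicae_g1),cedri_g1);")
        assert find_species_specific_duplications(t, "pisum") == []

    def test_maximal_node_only(self):
        t = read_newick("(((pisum_a,pisum_b),pisum_c),persicae_x);")
        events = find_species_specific_duplications(t, "pisum")
        assert [sorted(e.members) for e in events] == [
            ["pisum_a", "pisum_b", "pisum_c"]
        ]

    def test_absent_focal_species(self):
        t = read_newick("((noxia_g1,persicae_g1),cedri_g1);")
        assert find_species_specific_duplications(t, "pisum") == []


class TestFusion:
    @pytest.mark.parametrize(
        "members, expected",
        [
            ([{"a", "b"}, {"a", "b"}], [{"a", "b"}]),
            ([{"a", "b"}, {"c", "d"}], [{"a", "b"}, {"c", "d"}]),
            # 1 shared / min size 3 = 1/3 <= 0.5 → unchanged
            ([{"a", "b", "c"}, {"c", "d", "e"}], [{"a", "b", "c"}, {"c", "d", "e"}]),
            # 1 shared / min size 2 = 0.5, not > 0.5 → unchanged
            ([{"a", "b"}, {"b", "c", "d"}], [{"a", "b"}, {"b", "c", "d"}]),
            # 2 shared / min size 2 = 1.0 → fused, and transitively with third
            ([{"a", "b"}, {"a", "b", "c"}, {"b", "c", "d"}],
             [{"a", "b", "c", "d"}]),
        ],
    )
    def test_fusion_rule(self, members, expected):
        events = [DuplicationEvent(members=frozenset(m)) for m in members]
        fused = fuse_overlapping_duplications(events)
        assert sorted(sorted(e.members) for e in fused) == sorted(
            sorted(m) for m in expected
        )

    def test_idempotent(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 7))
            member_sets = [
                frozenset(
                    f"g{int(x)}"
                    for x in rng.integers(0, 10, size=rng.integers(2, 5))
                )
                for _ in range(n)
            ]
            events = [
                DuplicationEvent(members=m) for m in member_sets if len(m) >= 2
            ]
            if not events:
                continue
            once = fuse_overlapping_duplications(events)
            twice = fuse_overlapping_duplications(once)
            assert sorted(sorted(e.members) for e in once) == sorted(
                sorted(e.members) for e in twice
            )


class TestPairSelection:
    TREE = (
        "(((pisum_g1,pisum_g2){sup},persicae_g1)1.0,"
        "(noxia_g1,cedri_g1)1.0)1.0;"
    )

    def _pairs(self, sup):
        t = read_newick(self.TREE.format(sup=sup))
        events = find_species_specific_duplications(t, "pisum")
        return select_duplicate_pairs(t, events, "pisum")

    def test_high_support_selected(self):
        pairs = self._pairs("0.99")
        assert len(pairs) == 1
        assert pairs[0].duplication_support == 0.99
        assert len(pairs[0].orthologs) == 3

    def test_low_support_rejected(self):
        assert self._pairs("0.90") == []

    def test_missing_support_skipped_with_warning(self, caplog):
        t = read_newick("((pisum_g1,pisum_g2),(persicae_g1,noxia_g1)1.0);")
        events = find_species_specific_duplications(t, "pisum")
        with caplog.at_level("WARNING"):
            pairs = select_duplicate_pairs(t, events, "pisum")
        assert pairs == []
        assert any("no support" in r.message for r in caplog.records)

    def test_expansion_pairs_only_at_tips(self):
        t = read_newick(
            "(((pisum_a,pisum_b)0.99,pisum_c)0.99,"
            "(persicae_g1,noxia_g1)1.0)1.0;"
        )
        events = find_species_specific_duplications(t, "pisum")
        pairs = select_duplicate_pairs(t, events, "pisum")
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("pisum_a", "pisum_b")]
        assert pairs[0].from_expansion

    def test_too_few_orthologs(self):
        t = read_newick("((pisum_g1,pisum_g2)0.99,persicae_g1)1.0;")
        events = find_species_specific_duplications(t, "pisum")
        assert select_duplicate_pairs(t, events, "pisum", min_orthologs=2) == []

    def test_pair_genes_belong_to_one_event(self):
        t = read_newick(
            "(((pisum_a,pisum_b)0.99,(persicae_g1,(pisum_c,pisum_d)0.99)1.0)1.0,"
            "(noxia_g1,cedri_g1)1.0)1.0;"
        )
        events = fuse_overlapping_duplications(
            find_species_specific_duplications(t, "pisum")
        )
        pairs = select_duplicate_pairs(t, events, "pisum")
        for pair in pairs:
            owners = [
                e for e in events if {pair.gene_a, pair.gene_b} <= e.members
            ]
            assert len(owners) == 1


class TestRetention:
    def _pair(self):
        return DuplicatePairCandidate(
            gene_a="pisum_g1", gene_b="pisum_g2",
            duplication_support=0.99, orthologs=[],
        )

    def test_sister_pair_retained(self):
        second = read_newick("((pisum_g1,pisum_g2),persicae_g1);")
        assert verify_duplication_retained(second, self._pair(), "pisum")

    def test_broken_topology_not_retained(self):
        second = read_newick("((pisum_g1,persicae_g1),pisum_g2);")
        assert not verify_duplication_retained(second, self._pair(), "pisum")

    def test_missing_paralog_errors(self):
        second = read_newick("((pisum_g1,persicae_g1),cedri_g1);")
        with pytest.raises(KeyError):
            verify_duplication_retained(second, self._pair(), "pisum")

    def test_agrees_with_mrca_species_oracle(self, make_random_tree):
        pair = self._pair()
        checked = 0
        for _ in range(200):
            t = make_random_tree(n_leaves=10, n_species=3)
            labels = [lf.taxon.label for lf in t.leaf_node_iter()]
            sp0 = [lab for lab in labels if lab.startswith("sp0_")]
            if len(sp0) < 2:
                continue
            pair = DuplicatePairCandidate(
                gene_a=sp0[0], gene_b=sp0[1],
                duplication_support=1.0, orthologs=[],
            )
            got = verify_duplication_retained(t, pair, "sp0")
            mrca = trees.mrca_of_leaves(t, [sp0[0], sp0[1]])
            want = all(
                lf.taxon.label.startswith("sp0_") for lf in mrca.leaf_iter()
            )
            assert got == want
            checked += 1
        assert checked >= 50


class TestDistantFilter:
    DISTANT = {"Dcitri", "Btabaci", "Dvitifoliae"}

    def _pair(self, species):
        return DuplicatePairCandidate(
            gene_a="a", gene_b="b", duplication_support=1.0,
            orthologs=[(sp, f"{sp}_g1") for sp in species],
        )

    def test_distant_only_discarded(self):
        assert not distant_species_filter(
            self._pair(["Dcitri", "Btabaci", "Dvitifoliae"]), self.DISTANT
        )

    def test_one_close_ortholog_keeps(self):
        assert distant_species_filter(
            self._pair(["Dcitri", "Mpersicae"]), self.DISTANT
        )

    def test_random_sets_match_subset_oracle(self, rng):
        universe = ["Dcitri", "Btabaci", "Dvitifoliae", "Ccedri", "Mpersicae"]
        for _ in range(100):
            k = int(rng.integers(1, len(universe) + 1))
            species = list(rng.choice(universe, size=k, replace=False))
            got = distant_species_filter(self._pair(species), self.DISTANT)
            assert got == (not set(species) <= self.DISTANT)


class TestDuplicationRatio:
    SPECIES_TREE = "((pisum,persicae),cedri);"

    def test_one_duplication_in_two_trees(self):
        st = read_newick(self.SPECIES_TREE)
        g1 = read_newick("((pisum_g1,pisum_g2),persicae_g1);")
        g2 = read_newick("((pisum_g3,persicae_g2),cedri_g1);")
        ratios = duplication_ratio_per_node(st, [g1, g2])
        assert ratios[frozenset({"pisum"})] == 0.5
        assert ratios[frozenset({"pisum", "persicae", "cedri"})] == 0.0

    def test_no_duplications_all_zero(self):
        st = read_newick(self.SPECIES_TREE)
        g = read_newick("((pisum_g1,persicae_g1),cedri_g1);")
        assert set(duplication_ratio_per_node(st, [g]).values()) == {0.0}

    def test_empty_gene_tree_set_errors(self):
        with pytest.raises(ValueError):
            duplication_ratio_per_node(read_newick(self.SPECIES_TREE), [])

    def test_planted_counts_recovered(self):
        from dupfate.datasets import FOCAL_SPECIES
        from dupfate.simulate import simulate_gene_trees
        from dupfate.io import read_newick as rn
        from dupfate.datasets import SPECIES_TREE_NEWICK

        st = rn(SPECIES_TREE_NEWICK)
        gts, truth = simulate_gene_trees(30, seed=9, duplication_fraction=0.4)
        ratios = duplication_ratio_per_node(st, gts)
        planted = int(truth["planted"].sum())
        assert ratios[frozenset({FOCAL_SPECIES})] == planted / 30
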