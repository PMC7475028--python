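"""NG86 rates, Fitch branch rates, fast/slow, filters, MNM, p-adjustment."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles
from dupfate import codon
from dupfate.codon import (
    ADJUSTMENT_METHODS,
    GENETIC_CODE,
    STOP_CODONS,
    adjust_pvalues,
    apply_pair_rate_filters,
    apply_rate_filters,
    branch_rates_on_pair_tree,
    call_positive_selection,
    classify_fast_slow,
    compute_median_identity,
    count_mnm,
    ng86_pairwise,
)
from dupfate.simulate import random_codon_sequence, simulate_pair_alignment

SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


class TestNG86:
    def test_identical_sequences_zero(self):
        r = ng86_pairwise("AAACCCGGG", "AAACCCGGG")
        assert (r.dn, r.ds) == (0.0, 0.0)

    def test_single_synonymous_difference(self):
        # Phe TTT→TTC: no amino-acid change
        r = ng86_pairwise("TTT", "TTC")
        assert r.dn == 0.0
        assert r.ps > 0.0 and r.pn == 0.0

    def test_symmetry_and_oracle_on_random_pairs(self, rng):
        for _ in range(10):
            a = random_codon_sequence(30, rng)
            b = random_codon_sequence(30, rng)
            fwd = ng86_pairwise(a, b)
            rev = ng86_pairwise(b, a)
            assert fwd.dn == rev.dn and fwd.ds == rev.ds
            odn, ods = _oracles.ng86(a, b)
            if math.isfinite(ods):
                assert fwd.ds == pytest.approx(ods, abs=1e-9)
            else:
                assert not math.isfinite(fwd.ds)
            if math.isfinite(odn):
                assert fwd.dn == pytest.approx(odn, abs=1e-9)

    def test_oracle_on_diverged_single_codon_swaps(self, rng):
        # close pairs: mutate a few positions of one sequence
        for _ in range(40):
            a = random_codon_sequence(20, rng)
            b = list(a)
            for _ in range(int(rng.integers(1, 6))):
                pos = int(rng.integers(len(b)))
                b[pos] = "ACGT"[int(rng.integers(4))]
            b = "".join(b)
            try:
                r = ng86_pairwise(a, b)
            except ValueError:
                continue  # mutation created an internal stop
            odn, ods = _oracles.ng86(a, b)
            if math.isfinite(ods) and math.isfinite(odn):
                assert r.dn == pytest.approx(odn, abs=1e-9)
                assert r.ds == pytest.approx(ods, abs=1e-9)

    def test_length_mismatch_and_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_pairwise("AAA", "AAAAAA")
        with pytest.raises(ValueError):
            ng86_pairwise("TAAAAA", "AAAAAA")


class TestBranchRates:
    def test_all_identical_all_zero(self):
        seq = "AAACCCGGGTTTACG"
        aln = {"a": seq, "b": seq, "o1": seq, "o2": seq}
        r = branch_rates_on_pair_tree(aln, "a", "b", ["o1", "o2"])
        assert r.pre.ds == r.pre.dn == 0.0
        assert all(x.ds == 0.0 and x.dn == 0.0 for x in r.post.values())
        assert r.ancestral == seq

    def test_hand_built_synonymous_change_on_one_branch(self):
        # 5 codons; copy b carries one synonymous change (CCC→CCT, Pro)
        anc = "AAACCCGGGTTTACG"
        b = "AAACCTGGGTTTACG"
        aln = {"a": anc, "b": b, "o1": anc, "o2": anc}
        r = branch_rates_on_pair_tree(aln, "a", "b", ["o1", "o2"])
        assert r.ancestral == anc
        assert r.post["a"].ds == 0.0 and r.post["a"].dn == 0.0
        assert r.post["b"].ds > 0.0 and r.post["b"].dn == 0.0
        assert r.pre.ds == 0.0

    def test_requires_two_outgroups(self):
        aln = {"a": "AAA", "b": "AAA", "o1": "AAA"}
        with pytest.raises(ValueError):
            branch_rates_on_pair_tree(aln, "a", "b", ["o1"])

    def test_omega_ordering_recovered_in_simulation(self, rng):
        hits = total = 0
        for i in range(40):
            aln, truth = simulate_pair_alignment(
                rng, n_codons=200, omega_a=0.1, omega_b=1.5
            )
            r = branch_rates_on_pair_tree(
                aln, truth.gene_a, truth.gene_b, truth.outgroups
            )
            oa = r.post[truth.gene_a].omega
            ob = r.post[truth.gene_b].omega
            if oa is None or ob is None:
                continue
            total += 1
            hits += ob > oa
        assert total >= 35
        assert hits / total >= 0.9


class TestFastSlow:
    def test_lowest_ds_is_slow(self):
        call = classify_fast_slow("p", "g1", "g2", 0.05, 0.20)
        assert (call.slow, call.fast) == ("g1", "g2")
        assert not call.tie

    def test_tie_breaks_lexicographically_and_flags(self):
        call = classify_fast_slow("p", "gB", "gA", 0.1, 0.1)
        assert (call.slow, call.fast) == ("gA", "gB")
        assert call.tie

    def test_random_tables_match_argmin(self, rng):
        for _ in range(100):
            da, db = rng.uniform(0, 2, size=2)
            call = classify_fast_slow("p", "x", "y", float(da), float(db))
            assert call.slow == ("x" if da < db else "y")
            assert call.ds_slow <= call.ds_fast

    def test_missing_ds_errors(self):
        with pytest.raises(ValueError):
            classify_fast_slow("p", "x", "y", None, 0.3)


class TestRateFilters:
    @pytest.mark.parametrize(
        "ds, kept",
        [(2.5, False), (0.005, False), (1.0, True), (2.0, True),
         (0.01, True), (math.inf, False)],
    )
    def test_boundaries(self, ds, kept):
        assert (("g" in apply_rate_filters({"g": ds}))) is kept

    def test_pure_predicate_order_independent(self, rng):
        ds = {f"g{i}": float(rng.uniform(0, 3)) for i in range(50)}
        shuffled = dict(sorted(ds.items(), key=lambda _: rng.random()))
        assert apply_rate_filters(ds) == apply_rate_filters(shuffled)

    def test_pair_filter_drops_whole_pair(self):
        pairs = {"p1": (0.5, 2.5), "p2": (0.5, 1.5), "p3": (0.005, 0.5)}
        assert apply_pair_rate_filters(pairs) == {"p2"}


class TestMNM:
    @pytest.mark.parametrize(
        "anc, der, mnm",
        [("AAA", "AGG", 1), ("AAA", "AAG", 0), ("AAAAAA", "AGGAAG", 1)],
    )
    def test_counting_rule(self, anc, der, mnm):
        assert count_mnm(anc, der).mnm_count == mnm

    def test_random_pairs_match_positionwise_oracle(self, rng):
        for _ in range(50):
            a = random_codon_sequence(20, rng)
            b = random_codon_sequence(20, rng)
            want = sum(
                1
                for i in range(0, 60, 3)
                if sum(x != y for x, y in zip(a[i : i + 3], b[i : i + 3])) > 1
            )
            assert count_mnm(a, b).mnm_count == want

    def test_percent_bounds(self, rng):
        a = random_codon_sequence(10, rng)
        b = random_codon_sequence(10, rng)
        assert 0.0 <= count_mnm(a, b).percent <= 100.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            count_mnm("AAA", "AAAAAA")


class TestAdjustPvalues:
    def test_bh_textbook_example(self):
        got = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_holm_two_values(self):
        got = adjust_pvalues([0.005, 0.04], "holm")
        assert np.allclose(got, [0.01, 0.04])

    def test_single_p_unchanged_for_all_methods(self):
        for method in ADJUSTMENT_METHODS:
            assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_matches_handrolled_oracle(self, rng):
        for _ in range(60):
            p = rng.uniform(0, 1, size=int(rng.integers(2, 15)))
            for method in ADJUSTMENT_METHODS:
                got = adjust_pvalues(p, method)
                want = _oracles.adjust(p, method)
                assert np.allclose(got, want, atol=1e-9), method

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        m=st.integers(min_value=1, max_value=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_vector_stays_equal(self, p, m):
        for method in ADJUSTMENT_METHODS:
            adjusted = adjust_pvalues([p] * m, method)
            assert np.allclose(adjusted, adjusted[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([-0.1, 0.5], "bh")


class TestSelectionCall:
    def test_any_method_below_alpha_selects(self):
        # one tiny p among many moderate ones: BH sends it below 0.01
        raw = {"g0": 1e-6, **{f"g{i}": 0.5 for i in range(1, 10)}}
        calls = call_positive_selection(raw)
        assert calls["g0"].positively_selected
        assert not calls["g5"].positively_selected

    def test_matches_min_over_methods_oracle(self, rng):
        raw = {f"g{i}": float(rng.uniform(0, 1)) for i in range(25)}
        calls = call_positive_selection(raw, alpha=0.01)
        p = np.array([raw[g] for g in sorted(raw)])
        mins = np.min(
            [_oracles.adjust(p, m) for m in ADJUSTMENT_METHODS], axis=0
        )
        for i, g in enumerate(sorted(raw)):
            assert calls[g].positively_selected == (mins[i] < 0.01)


class TestMedianIdentity:
    def test_identical_pair_is_100(self):
        aln = {"a": "AAATTT", "b": "AAATTT"}
        assert compute_median_identity(aln, as_protein=False) == {
            "a": 100.0, "b": 100.0,
        }

    def test_two_thirds_identity_nucleotide_mode(self):
        got = compute_median_identity({"a": "AAA", "b": "AAC"}, as_protein=False)
        assert got["a"] == pytest.approx(200 / 3)

    def test_single_sequence_errors(self):
        with pytest.raises(ValueError):
            compute_median_identity({"a": "AAA"})

    def test_random_alignments_match_allpairs_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 6))
            aln = {f"s{i}": random_codon_sequence(15, rng) for i in range(n)}
            got = compute_median_identity(aln, as_protein=False)
            names = sorted(aln)
            for a in names:
                vals = []
                for b in names:
                    if a == b:
                        continue
                    same = sum(
                        x == y for x, y in zip(aln[a], aln[b])
                    )
                    vals.append(100 * same / len(aln[a]))
                assert got[a] == pytest.approx(float(np.median(vals)), abs=1e-9)
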