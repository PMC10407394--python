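"""Clone calling by the CDR3 rule, intraclonal diversity, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from ighclone import (
    ClonePolicy,
    assess_intraclonal_diversity,
    call_clones,
    cdr3_identity,
    length_compatible,
    summarize_sample,
)
from ighclone.clones import format_inventory

from conftest import make_rearrangement
from _oracles import global_align_score

RNG_BASES = "ACGT"


def _random_cdr3(rng, length):
    return "".join(RNG_BASES[i] for i in rng.integers(0, 4, size=length))


def _substitute(seq, k, rng):
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestCdr3Identity:
    def test_identical_sequences_are_100(self):
        assert cdr3_identity("ACGT" * 8, "ACGT" * 8) == 100.0

    def test_one_substitution_in_ten_is_90(self):
        assert cdr3_identity("ACGTACGTAC", "ACGTACGTAA") == pytest.approx(90.0)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = _random_cdr3(rng, int(rng.integers(12, 40)))
            b = _random_cdr3(rng, int(rng.integers(12, 40)))
            assert cdr3_identity(a, b) == cdr3_identity(b, a)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            cdr3_identity("", "ACGT")

    def test_alignment_score_matches_bruteforce_dp(self):
        """The underlying global alignment agrees with an independent
        affine-gap Needleman-Wunsch on random pairs."""
        from ighclone.align import align_segment

        rng = np.random.default_rng(77)
        for _ in range(60):
            a = _random_cdr3(rng, int(rng.integers(10, 45)))
            b = _random_cdr3(rng, int(rng.integers(10, 45)))
            aln = align_segment(a, b, gene="", mode="global")
            assert aln.score == global_align_score(a, b)

    def test_identity_closed_form_for_substitution_only_pairs(self):
        """With substitutions only (no indels), the optimal end-to-end
        alignment is gapless and identity has a closed form."""
        rng = np.random.default_rng(88)
        for _ in range(60):
            n = int(rng.integers(15, 45))
            a = _random_cdr3(rng, n)
            k = int(rng.integers(0, max(1, n // 5)))
            b = _substitute(a, k, rng)
            assert cdr3_identity(a, b) == pytest.approx(100.0 * (n - k) / n)


class TestLengthRule:
    @pytest.mark.parametrize(
        "la,lb,expected",
        [(40, 40, True), (40, 42, True), (15, 13, False), (20, 21, True)],
    )
    def test_length_difference_bound_is_inclusive(self, la, lb, expected, policy):
        assert length_compatible("A" * la, "A" * lb, policy) is expected

    @settings(derandomize=True, max_examples=60)
    @given(la=st.integers(1, 80), lb=st.integers(1, 80))
    def test_symmetric_and_matches_formula(self, la, lb):
        policy = ClonePolicy()
        a, b = "A" * la, "A" * lb
        expected = 100.0 * abs(la - lb) / max(la, lb) <= 5.0
        assert length_compatible(a, b, policy) is expected
        assert length_compatible(b, a, policy) is expected


class TestCallClones:
    def test_same_v_identical_cdr3_merge(self, policy):
        recs = [
            make_rearrangement("c1", "IGHV3-30", "TGTACGTACGTACGTACGTACGTACGTAGG"),
            make_rearrangement("c2", "IGHV3-30", "TGTACGTACGTACGTACGTACGTACGTAGG"),
        ]
        clones = call_clones(recs, policy)
        assert len(clones) == 1
        assert clones[0].members == ["c1", "c2"]

    def test_different_v_gene_never_merges(self, policy):
        cdr3 = "TGTACGTACGTACGTACGTACGTACGTAGG"
        recs = [
            make_rearrangement("c1", "IGHV3-30", cdr3),
            make_rearrangement("c2", "IGHV1-69", cdr3),
        ]
        assert len(call_clones(recs, policy)) == 2

    def test_exactly_90_percent_identity_is_split(self, policy):
        """">90%" is strict: a pair at exactly 90.0% is not co-clonal."""
        a = "ACGTACGTAC"
        b = a[:-1] + "A"  # 9/10 = 90.0%
        assert cdr3_identity(a, b) == pytest.approx(90.0)
        recs = [
            make_rearrangement("c1", "IGHV3-30", a),
            make_rearrangement("c2", "IGHV3-30", b),
        ]
        assert len(call_clones(recs, policy)) == 2

    def test_exactly_5_percent_length_difference_merges(self, policy):
        """"maximal 5%" is inclusive: 40 vs 42 nt (5.0%) can merge."""
        a = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 nt
        b = a + "AC"  # 42 nt, identity 40/42 = 95.2%
        recs = [
            make_rearrangement("c1", "IGHV3-30", a),
            make_rearrangement("c2", "IGHV3-30", b),
        ]
        clones = call_clones(recs, policy)
        assert len(clones) == 1

    def test_records_without_cdr3_become_unclustered_singletons(self, policy):
        r = make_rearrangement("c1", "IGHV3-30", "ACGTACGTACGT")
        r.junction = None
        clones = call_clones([r], policy)
        assert len(clones) == 1
        assert clones[0].unclustered

    def test_planted_partition_recovered_exactly(self, policy):
        """3 planted clones (5/3/2 members) among 20 well-separated
        singletons are recovered with ARI 1.0."""
        rng = np.random.default_rng(55)
        recs, truth = [], []
        accepted = []

        def separated(c):
            return all(cdr3_identity(c, o) < 80.0 for o in accepted)

        k = 0
        for label, (size, gene) in enumerate(
            [(5, "IGHV3-30"), (3, "IGHV1-69"), (2, "IGHV3-30")]
        ):
            while True:
                founder = _random_cdr3(rng, 30)
                if separated(founder):
                    break
            accepted.append(founder)
            for _ in range(size):
                member = _substitute(founder, int(rng.integers(0, 2)), rng)
                recs.append(make_rearrangement(f"c{k}", gene, member))
                truth.append(f"clone{label}")
                k += 1
        for s in range(20):
            while True:
                cdr3 = _random_cdr3(rng, int(rng.integers(21, 45)))
                if separated(cdr3):
                    break
            accepted.append(cdr3)
            recs.append(make_rearrangement(f"c{k}", "IGHV3-30", cdr3))
            truth.append(f"s{s}")
            k += 1
        clones = call_clones(recs, policy)
        predicted = {}
        for c in clones:
            for m in c.members:
                predicted[m] = c.clone_id
        pred = [predicted[r.cell_id] for r in recs]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_partition_property_every_record_in_exactly_one_clone(self, policy):
        rng = np.random.default_rng(3)
        recs = [
            make_rearrangement(f"c{i}", "IGHV3-30", _random_cdr3(rng, 24))
            for i in range(25)
        ]
        clones = call_clones(recs, policy)
        members = [m for c in clones for m in c.members]
        assert sorted(members) == sorted(r.cell_id for r in recs)

    def test_complete_linkage_holds_within_every_clone(self, policy):
        """Every pair inside an emitted clone satisfies both thresholds."""
        rng = np.random.default_rng(10)
        recs = []
        for i in range(12):
            founder = _random_cdr3(rng, 27)
            for j_ in range(3):
                recs.append(
                    make_rearrangement(
                        f"c{i}_{j_}", "IGHV3-30", _substitute(founder, 1, rng)
                    )
                )
        clones = call_clones(recs, policy)
        by_id = {r.cell_id: r for r in recs}
        for c in clones:
            for x in range(len(c.members)):
                for y in range(x + 1, len(c.members)):
                    a = by_id[c.members[x]].cdr3_nt
                    b = by_id[c.members[y]].cdr3_nt
                    assert cdr3_identity(a, b) > policy.cdr3_min_identity_pct
                    assert length_compatible(a, b, policy)

    def test_single_linkage_chains_where_complete_splits(self, policy):
        base = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt
        a_ = base
        b_ = base[:2] + "TA" + base[4:]  # 2 subs vs a: 93.3%
        c_ = base[:2] + "TA" + base[4:26] + "TA" + base[28:]  # 2 subs vs b, 4 vs a
        assert cdr3_identity(a_, b_) > 90 and cdr3_identity(b_, c_) > 90
        assert cdr3_identity(a_, c_) < 90
        recs = [
            make_rearrangement("a", "IGHV3-30", a_),
            make_rearrangement("b", "IGHV3-30", b_),
            make_rearrangement("c", "IGHV3-30", c_),
        ]
        assert len(call_clones(recs, policy)) == 2  # complete linkage splits
        single = call_clones(recs, policy, linkage="single")
        assert len(single) == 1  # chaining a-b-c

    def test_partition_invariant_under_input_shuffles(self, policy):
        rng = np.random.default_rng(61)
        recs = []
        accepted = []
        for i in range(5):
            while True:
                founder = _random_cdr3(rng, 30)
                if all(cdr3_identity(founder, o) < 75.0 for o in accepted):
                    break
            accepted.append(founder)
            for j_ in range(2):
                recs.append(
                    make_rearrangement(
                        f"c{i}_{j_}", "IGHV3-30", _substitute(founder, 1, rng)
                    )
                )
        reference = {
            frozenset(c.members) for c in call_clones(recs, policy)
        }
        for shuffle_seed in range(5):
            order = np.random.default_rng(shuffle_seed).permutation(len(recs))
            shuffled = [recs[i] for i in order]
            partition = {
                frozenset(c.members) for c in call_clones(shuffled, policy)
            }
            assert partition == reference


class TestIntraclonalDiversity:
    def test_identical_members_show_no_diversity(self, policy):
        cdr3 = "ACGTACGTACGTACGTACGTACGTACG"
        positions = ((10, "A", "G"), (20, "C", "T"))
        recs = [
            make_rearrangement(f"c{i}", "IGHV3-30", cdr3, positions=positions)
            for i in range(3)
        ]
        clones = call_clones(recs, policy)
        assert len(clones) == 1
        assert clones[0].n_variants == 1
        assert not clones[0].intraclonal_diversity

    def test_extra_branch_mutations_create_diversity(self, policy):
        cdr3 = "ACGTACGTACGTACGTACGTACGTACG"
        shared = ((10, "A", "G"), (20, "C", "T"))
        extra = shared + ((30, "G", "A"), (40, "T", "C"))
        recs = [
            make_rearrangement("c1", "IGHV3-30", cdr3, positions=shared),
            make_rearrangement("c2", "IGHV3-30", cdr3, positions=extra),
        ]
        clones = call_clones(recs, policy)
        assert len(clones) == 1
        assert clones[0].n_variants == 2
        assert clones[0].intraclonal_diversity

    def test_singletons_never_flagged(self, policy):
        r = make_rearrangement("c1", "IGHV3-30", "ACGTACGTACGTACG")
        clone = call_clones([r], policy)[0]
        assert clone.n_variants == 1
        assert not clone.intraclonal_diversity

    def test_simulated_lineage_variant_count_matches_truth(self, germlines):
        from ighclone import CloneSpec, SimConfig, analyze, simulate_sample

        config = SimConfig(
            seed=23,
            n_cells=4,
            clone_spec=(CloneSpec(4, True, 2.0),),
            mutated_fraction=1.0,
        )
        sample = simulate_sample(config, germlines)
        truth_variants = len(
            {
                (frozenset(t.implanted_mutations), t.cdr3_nt)
                for t in sample.truth
            }
        )
        result = analyze(
            [(r.id, str(r.seq)) for r in sample.records],
            germlines,
            productive_only=False,
        )
        clones = [c for c in result.clones["sample1"] if c.size == 4]
        assert len(clones) == 1
        assert clones[0].n_variants == truth_variants
        assert clones[0].intraclonal_diversity == (truth_variants > 1)


class TestSummarize:
    def test_arithmetic_on_small_sample(self, policy):
        cdr3 = "ACGTACGTACGTACGTACGTACGTACG"
        recs = [
            make_rearrangement("c1", "IGHV3-30", cdr3, mutated=True),
            make_rearrangement("c2", "IGHV1-69", "TTTTGGGGCCCCAAAATTTTGGGGCCC"),
            make_rearrangement("c3", "IGHV3-30", cdr3, mutated=True),
            make_rearrangement("c4", "IGHV4-34", "AAAACCCCGGGGTTTTAAAACCCCGGG", mutated=True),
        ]
        clones = call_clones(recs, policy)
        s = summarize_sample("case1", recs, clones)
        assert s.pct_mutated == 75.0
        assert s.clone_inventory == [(2, "mutated")]
        assert s.n_clones_mutated == 1
        assert s.n_clones_unmutated == 0
        assert s.v_gene_usage == {"IGHV1-69": 1, "IGHV3-30": 2, "IGHV4-34": 1}

    def test_no_expanded_clones_gives_empty_inventory(self, policy):
        recs = [
            make_rearrangement("c1", "IGHV3-30", "ACGTACGTACGTACGTACGTACGTACG"),
            make_rearrangement("c2", "IGHV1-69", "TTTTGGGGCCCCAAAATTTTGGGGCCC"),
        ]
        s = summarize_sample("case1", recs, call_clones(recs, policy))
        assert s.clone_inventory == []

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            summarize_sample("case1", [], [])

    def test_inventory_formatting_mirrors_published_style(self):
        inventory = [
            (2, "unmutated"),
            (2, "unmutated"),
            (2, "mutated"),
            (2, "mutated"),
            (3, "mutated"),
        ]
        assert format_inventory(inventory, "unmutated") == "2x 2 cells"
        assert format_inventory(inventory, "mutated") == "2x 2 cells,1x 3 cells"
        assert format_inventory([], "mutated") == "0"
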