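import numpy as np
import pytest

from tigerpop import genotyping as gt
from tigerpop import synthetic as syn


def rep(sid, idx, **calls):
    return gt.ReplicateGenotype(sid, idx, dict(calls))


A, B, C = (100, 100), (100, 104), (104, 104)


class TestConsensus:
    def test_homozygote_confirmed_after_three(self):
        cons = gt.call_consensus([rep("s", i, L1=A) for i in range(1, 4)])
        assert cons.calls["L1"] == A
        assert cons.locus_status["L1"] == gt.CONFIRMED

    def test_heterozygote_confirmed_after_two(self):
        cons = gt.call_consensus(
            [rep("s", 1, L1=B), rep("s", 2, L1=B), rep("s", 3, L1=A)]
        )
        assert cons.calls["L1"] == B

    def test_neither_rule_met_is_unresolved(self):
        cons = gt.call_consensus([rep("s", 1, L1=A), rep("s", 2, L1=B)])
        assert cons.calls["L1"] is None
        assert cons.locus_status["L1"] == gt.UNRESOLVED

    def test_conflicting_confirmations_unresolved(self):
        reps = [rep("s", i, L1=A) for i in range(1, 4)]
        reps += [rep("s", i, L1=B) for i in range(4, 6)]
        cons = gt.call_consensus(reps)
        assert cons.locus_status["L1"] == gt.UNRESOLVED

    def test_all_missing_is_missing(self):
        cons = gt.call_consensus([rep("s", 1, L1=None), rep("s", 2, L1=None)])
        assert cons.locus_status["L1"] == gt.MISSING

    def test_recall_with_added_replicates(self):
        reps = [rep("s", 1, L1=B), rep("s", 2, L1=A)]
        assert gt.call_consensus(reps).locus_status["L1"] == gt.UNRESOLVED
        reps.append(rep("s", 3, L1=B))
        assert gt.call_consensus(reps).calls["L1"] == B

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="different samples"):
            gt.call_consensus([rep("s1", 1, L1=A), rep("s2", 2, L1=A)])

    def test_duplicate_replicate_index_rejected(self):
        with pytest.raises(ValueError, match="replicate_index"):
            gt.call_consensus([rep("s", 1, L1=A), rep("s", 1, L1=A)])

    def test_typed_allele_count_is_even(self):
        cons = gt.call_consensus(
            [rep("s", i, L1=A, L2=B, L3=None) for i in range(1, 4)]
        )
        assert cons.typed_allele_count == 4


class TestUsabilityGate:
    @pytest.mark.parametrize("n_confirmed,expected", [(7, True), (6, False), (8, True)])
    def test_fourteen_allele_gate(self, n_confirmed, expected):
        calls = {f"L{i}": A for i in range(8)}
        status = {
            f"L{i}": gt.CONFIRMED if i < n_confirmed else gt.UNRESOLVED
            for i in range(8)
        }
        cons = gt.ConsensusGenotype("s", calls, status, 4)
        assert gt.filter_usable(cons) is expected


def _cons(sid, calls):
    status = {
        loc: gt.CONFIRMED if c is not None else gt.MISSING for loc, c in calls.items()
    }
    return gt.ConsensusGenotype(sid, calls, status, 4)


class TestMatching:
    def test_identical_samples_merge(self):
        g = {f"L{i}": A for i in range(8)}
        inds = gt.match_individuals([_cons("a", g), _cons("b", dict(g))])
        assert len(inds) == 1
        assert inds[0].member_sample_ids == ["a", "b"]

    def test_one_allele_mismatch_merges(self):
        g1 = {f"L{i}": A for i in range(8)}
        g2 = dict(g1, L0=B)  # shares one allele at L0 -> 1 mismatch
        inds = gt.match_individuals([_cons("a", g1), _cons("b", g2)])
        assert len(inds) == 1

    def test_two_allele_mismatch_stays_separate(self):
        g1 = {f"L{i}": A for i in range(8)}
        g2 = dict(g1, L0=C)  # disjoint pair -> 2 mismatches
        inds = gt.match_individuals([_cons("a", g1), _cons("b", g2)])
        assert len(inds) == 2

    def test_missing_loci_do_not_count_as_mismatches(self):
        g1 = {"L0": A, "L1": B}
        g2 = {"L0": A, "L1": None}
        assert gt.genotype_mismatches(g1, g2) == 0

    def test_merge_is_input_order_independent(self, rng):
        genos = []
        for i in range(6):
            g = {f"L{j}": (100 + 4 * ((i + j) % 3),) * 2 for j in range(8)}
            genos.append(_cons(f"s{i}", g))
        genos.append(_cons("dup", dict(genos[0].calls)))
        ref = gt.match_individuals(genos)
        for _ in range(5):
            shuffled = list(genos)
            rng.shuffle(shuffled)
            out = gt.match_individuals(shuffled)
            assert sorted(tuple(i.member_sample_ids) for i in out) == sorted(
                tuple(i.member_sample_ids) for i in ref
            )

    def test_transitivity_conflict_merges_with_warning(self):
        # a~b (1 mismatch), b~c (1 mismatch), a vs c (2 mismatches)
        ga = {"L0": (100, 100), "L1": A}
        gb = {"L0": (100, 104), "L1": A}
        gc = {"L0": (104, 104), "L1": A}
        inds = gt.match_individuals([_cons("a", ga), _cons("b", gb), _cons("c", gc)])
        assert len(inds) == 1
        assert inds[0].merge_conflict

    def test_majority_call_on_merge(self):
        g1 = {"L0": A, "L1": B}
        g2 = {"L0": A, "L1": B}
        g3 = {"L0": B, "L1": B}
        inds = gt.match_individuals([_cons(s, g) for s, g in [("a", g1), ("b", g2), ("c", g3)]])
        assert len(inds) == 1
        assert inds[0].genotype["L0"] == A

    def test_empty_input(self):
        assert gt.match_individuals([]) == []


class TestSexAssignment:
    def test_y_marker_presence_means_male(self):
        assert gt.assign_sex([(True, True), (True, False)]) == "male"

    def test_repeated_y_absence_means_female(self):
        res = [(True, False)] * 3
        assert gt.assign_sex(res, positive_control_ok=True) == "female"

    def test_no_amplification_is_unknown(self):
        assert gt.assign_sex([(False, False)] * 3) == "unknown"

    def test_insufficient_negative_replicates_is_unknown(self):
        assert gt.assign_sex([(True, False)] * 2) == "unknown"

    def test_failed_positive_control_blocks_female_call(self):
        res = [(True, False)] * 3
        assert gt.assign_sex(res, positive_control_ok=False) == "unknown"

    def test_contaminated_negative_control_voids_batch(self):
        assert gt.assign_sex([(True, True)] * 3, negative_control_clean=False) == "unknown"


class TestGenepop:
    def _table(self):
        calls1 = {"LocA": (100, 104), "LocB": None}
        calls2 = {"LocA": (96, 96), "LocB": (104, 108)}
        return gt.GenepopTable(
            title="example",
            loci=["LocA", "LocB"],
            populations=[[("s1", calls1)], [("s2", calls2)]],
        )

    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "x.gen"
        table = self._table()
        gt.write_genepop(table, path)
        back = gt.parse_genepop(path)
        assert back.loci == table.loci
        assert back.populations == table.populations

    def test_missing_code_parses_to_missing(self, tmp_path):
        path = tmp_path / "x.gen"
        path.write_text("t\nL1\nPop\na , 0000\n")
        table = gt.parse_genepop(path)
        assert table.populations[0][0][1]["L1"] is None

    def test_two_digit_coding(self, tmp_path):
        path = tmp_path / "x.gen"
        path.write_text("t\nL1\nPop\na , 0912\n")
        assert gt.parse_genepop(path).populations[0][0][1]["L1"] == (9, 12)

    def test_comma_separated_locus_line(self, tmp_path):
        path = tmp_path / "x.gen"
        path.write_text("t\nL1, L2\nPop\na , 100100 0000\n")
        assert gt.parse_genepop(path).loci == ["L1", "L2"]

    def test_malformed_genotype_reports_line(self, tmp_path):
        path = tmp_path / "x.gen"
        path.write_text("t\nL1\nPop\na , 10x\n")
        with pytest.raises(ValueError, match=":4"):
            gt.parse_genepop(path)

    def test_missing_pop_line_rejected(self, tmp_path):
        path = tmp_path / "x.gen"
        path.write_text("t\nL1\n")
        with pytest.raises(ValueError, match="Pop"):
            gt.parse_genepop(path)


class TestConsensusAccuracy:
    def test_consensus_beats_single_replicates(self):
        # with dropout 0.2 and 3 replicates, confirmed calls must be
        # wrong less often than raw replicate calls (1,000 samples)
        cfg = syn.SyntheticConfig(
            seed=77, n_per_pop=500, dropout_rate=0.2, false_allele_rate=0.0,
            missing_rate=0.0, n_replicates=3, extra_replicates=0,
        )
        truth = syn.simulate_populations(cfg)
        reps = syn.simulate_replicate_amplifications(truth, cfg)
        sid_to_idx = {s: i for i, s in enumerate(truth.individuals["sample_id"])}
        by_sample = {}
        for r in reps:
            by_sample.setdefault(r.sample_id, []).append(r)

        raw_bad = raw_total = 0
        cons_bad = cons_total = 0
        for sid, rlist in by_sample.items():
            i = sid_to_idx[sid]
            true = {
                loc: tuple(truth.genotypes[i, l]) for l, loc in enumerate(truth.loci)
            }
            for r in rlist:
                for loc in truth.loci:
                    if true[loc][0] != true[loc][1]:
                        raw_total += 1
                        raw_bad += r.calls[loc] != true[loc]
            cons = gt.call_consensus(rlist, loci=truth.loci)
            for loc in truth.loci:
                if true[loc][0] != true[loc][1] and cons.calls[loc] is not None:
                    cons_total += 1
                    cons_bad += cons.calls[loc] != true[loc]
        assert cons_total > 100
        assert cons_bad / cons_total < raw_bad / raw_total

    def test_error_free_consensus_recovers_truth(self, clean_dataset):
        truth, reps, _, _ = clean_dataset
        by_sample = {}
        for r in reps:
            by_sample.setdefault(r.sample_id, []).append(r)
        sid_to_idx = {s: i for i, s in enumerate(truth.individuals["sample_id"])}
        for sid, rlist in by_sample.items():
            cons = gt.call_consensus(rlist, loci=truth.loci)
            i = sid_to_idx[sid]
            for l, loc in enumerate(truth.loci):
                assert cons.calls[loc] == tuple(truth.genotypes[i, l])
                assert cons.locus_status[loc] == gt.CONFIRMED
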