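import numpy as np
import pandas as pd
import pytest

from tigerpop import assignment as asg
from tigerpop import popgen as pg
from tigerpop import synthetic as syn


def make_freqs(calls_by_pop):
    return pg.allele_frequencies(
        (pop, calls) for pop, items in calls_by_pop.items() for calls in items
    )


@pytest.fixture(scope="module")
def two_pop_freqs():
    """Two populations, 60 individuals each, moderately differentiated."""
    cfg = syn.SyntheticConfig(f_st=0.2, n_per_pop=60, migrant_fraction=0.0, seed=31)
    truth = syn.simulate_populations(cfg)
    calls = [
        {loc: tuple(truth.genotypes[i, l]) for l, loc in enumerate(truth.loci)}
        for i in range(len(truth.individuals))
    ]
    freqs = pg.allele_frequencies(zip(truth.individuals["population"], calls))
    return truth, calls, freqs


class TestFrequencyLikelihood:
    def test_homozygote_hand_value(self):
        f = make_freqs({"P": [{"L1": (1, 2)}] * 5})
        ll = asg.frequency_likelihood({"L1": (1, 1)}, f, "P")
        assert ll == pytest.approx(np.log10(0.25), abs=1e-12)

    def test_heterozygote_hand_value(self):
        f = make_freqs({"P": [{"L1": (1, 2)}] * 5})
        ll = asg.frequency_likelihood({"L1": (1, 2)}, f, "P")
        assert 10**ll == pytest.approx(0.5, abs=1e-12)

    def test_absent_allele_uses_zero_freq(self):
        f = make_freqs({"P": [{"L1": (1, 1)}] * 5})
        ll = asg.frequency_likelihood({"L1": (9, 9)}, f, "P", zero_freq=0.01)
        assert ll == pytest.approx(np.log10(0.01**2), abs=1e-12)

    def test_leave_one_out_removes_own_alleles(self):
        f = make_freqs({"P": [{"L1": (1, 1)}, {"L1": (1, 2)}]})
        # removing one copy of each own allele leaves counts {1: 2}
        ll = asg.frequency_likelihood({"L1": (1, 2)}, f, "P", leave_one_out=True)
        assert ll == pytest.approx(np.log10(2 * 1.0 * 0.01), abs=1e-12)

    def test_unknown_population_rejected(self):
        f = make_freqs({"P": [{"L1": (1, 1)}] * 2})
        with pytest.raises(ValueError, match="no allele frequencies"):
            asg.frequency_likelihood({"L1": (1, 1)}, f, "Q")

    def test_no_shared_loci_rejected(self):
        f = make_freqs({"P": [{"L1": (1, 1)}] * 2})
        with pytest.raises(ValueError, match="no typed locus"):
            asg.frequency_likelihood({"L9": (1, 1)}, f, "P")


class TestExclusionTest:
    def test_deterministic_under_fixed_seed(self, two_pop_freqs):
        _, calls, freqs = two_pop_freqs
        a = asg.exclusion_test(calls[0], "China", freqs, n_sim=500, seed=5)
        b = asg.exclusion_test(calls[0], "China", freqs, n_sim=500, seed=5)
        assert a == b

    def test_foreign_alleles_excluded(self, two_pop_freqs):
        truth, calls, freqs = two_pop_freqs
        foreign = {loc: (200, 204) for loc in truth.loci}
        p = asg.exclusion_test(foreign, "China", freqs, n_sim=2000, seed=6)
        assert p <= 0.05

    def test_zero_sim_rejected(self, two_pop_freqs):
        _, calls, freqs = two_pop_freqs
        with pytest.raises(ValueError, match="n_sim"):
            asg.exclusion_test(calls[0], "China", freqs, n_sim=0, seed=1)

    def test_mean_p_near_half_under_null(self, two_pop_freqs, rng):
        truth, calls, freqs = two_pop_freqs
        ps = []
        for _ in range(100):
            fresh = {}
            for loc in truth.loci:
                pool = freqs.counts["China"][loc]
                alleles = list(pool)
                pr = np.array([pool[a] for a in alleles], float)
                pr /= pr.sum()
                fresh[loc] = tuple(sorted(rng.choice(alleles, 2, p=pr)))
            ps.append(
                asg.exclusion_test(
                    fresh, "China", freqs, n_sim=300, seed=int(rng.integers(2**31))
                )
            )
        assert 0.4 < np.mean(ps) < 0.6


class TestF0MigrantTest:
    def test_lambda_one_when_home_maximizes(self, two_pop_freqs):
        truth, calls, freqs = two_pop_freqs
        # a resident deep inside its own population's frequency profile
        lam, f0 = asg.f0_migrant_test(calls[0], "China", freqs, n_sim=500, seed=7)
        if lam == pytest.approx(1.0):
            assert f0 < 0.95

    def test_migrant_detected(self, two_pop_freqs):
        truth, calls, freqs = two_pop_freqs
        # Russian genotype labelled as sampled in China
        lam, f0 = asg.f0_migrant_test(calls[70], "China", freqs, n_sim=1000, seed=8)
        assert lam < 1.0
        assert f0 > 0.9

    def test_missing_home_population_rejected(self, two_pop_freqs):
        _, calls, freqs = two_pop_freqs
        with pytest.raises(ValueError, match="home population"):
            asg.f0_migrant_test(calls[0], "Mongolia", freqs, n_sim=100, seed=1)

    def test_reference_table_flags(self):
        # applying the 0.95 threshold to the published F0 column flags
        # exactly three individuals: a 13.04% dispersal rate
        df = asg.load_reference_assignment_table()
        flagged = df.loc[df["f0"] > 0.95, "sample"].tolist()
        assert flagged == ["B1", "B6", "B17"]
        assert 100 * len(flagged) / len(df) == pytest.approx(13.04, abs=0.01)


@pytest.fixture(scope="module")
def disjoint_geno():
    # two clusters fixed for entirely different alleles
    geno = np.zeros((12, 8, 2), dtype=np.int64)
    geno[6:] = 1
    return geno


@pytest.fixture(scope="module")
def disjoint():
    geno = np.zeros((16, 8, 2), dtype=np.int64)
    geno[8:] = 1
    declared = [0] * 8 + [1] * 8
    return geno, declared


class TestAdmixtureGibbs:
    def test_k1_gives_unit_q(self, disjoint_geno):
        cfg = asg.AdmixtureConfig(burn_in=200, reps=500, seed=1)
        res = asg.admixture_gibbs(disjoint_geno, cfg, k=1, seed=2)
        assert np.allclose(res.q, 1.0)

    def test_q_rows_sum_to_one(self, disjoint_geno):
        cfg = asg.AdmixtureConfig(burn_in=200, reps=500, seed=1)
        res = asg.admixture_gibbs(disjoint_geno, cfg, k=3, seed=3)
        assert np.allclose(res.q.sum(axis=1), 1.0, atol=1e-9)

    def test_disjoint_clusters_recovered(self, disjoint_geno):
        cfg = asg.AdmixtureConfig(burn_in=500, reps=2000, seed=1)
        res = asg.admixture_gibbs(disjoint_geno, cfg, k=2, seed=4)
        ref = np.zeros((12, 2))
        ref[:6, 0] = 1
        ref[6:, 1] = 1
        q = asg.align_q(ref, res.q)
        assert q[:6, 0].min() > 0.95
        assert q[6:, 1].min() > 0.95

    def test_label_switching_resolved_by_alignment(self, disjoint_geno):
        cfg = asg.AdmixtureConfig(burn_in=500, reps=2000, seed=1)
        a = asg.admixture_gibbs(disjoint_geno, cfg, k=2, seed=11)
        b = asg.admixture_gibbs(disjoint_geno, cfg, k=2, seed=12)
        aligned = asg.align_q(a.q, b.q)
        assert np.abs(aligned - a.q).max() < 0.05

    def test_column_permutation_recovered_exactly(self, rng):
        q = rng.dirichlet(np.ones(4), size=10)
        perm = rng.permutation(4)
        assert np.allclose(asg.align_q(q, q[:, perm]), q)

    def test_invalid_settings_rejected(self, disjoint_geno):
        with pytest.raises(ValueError, match="K"):
            asg.AdmixtureConfig(k=0)
        with pytest.raises(ValueError, match="reps"):
            asg.AdmixtureConfig(reps=0)
        cfg = asg.AdmixtureConfig(burn_in=10, reps=10, seed=1)
        with pytest.raises(ValueError, match="two individuals"):
            asg.admixture_gibbs(disjoint_geno[:1], cfg, k=2, seed=1)


class TestEvanno:
    def _runs(self, means, sd=1.0, n_runs=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for k, m in means.items():
            for run in range(n_runs):
                rows.append({"K": k, "run": run, "log_prob": m + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_elbow_detected(self):
        # log-probability rises sharply to K=2 then plateaus
        runs = self._runs({1: -500.0, 2: -300.0, 3: -295.0, 4: -293.0}, sd=2.0)
        ev = asg.evanno_delta_k(runs)
        assert ev.selected_k == 2

    def test_endpoints_undefined(self):
        runs = self._runs({1: -500.0, 2: -300.0, 3: -295.0})
        t = asg.evanno_delta_k(runs).table.set_index("K")
        assert np.isnan(t.loc[1, "delta_K"])
        assert np.isnan(t.loc[3, "delta_K"])

    def test_needs_three_k_values(self):
        with pytest.raises(ValueError, match="three"):
            asg.evanno_delta_k(self._runs({1: -10.0, 2: -5.0}))

    def test_needs_replicate_runs(self):
        with pytest.raises(ValueError, match="two runs"):
            asg.evanno_delta_k(self._runs({1: -10.0, 2: -5.0, 3: -4.0}, n_runs=1))

    def test_degenerate_identical_likelihoods_flagged(self):
        runs = self._runs({1: -10.0, 2: -5.0, 3: -4.0}, sd=0.0)
        with pytest.raises(ValueError, match="zero run-to-run SD"):
            asg.evanno_delta_k(runs)


class TestPopinfoModel:
    def test_zero_prior_forces_residency(self, disjoint):
        geno, declared = disjoint
        cfg = asg.AdmixtureConfig(migprior=0.0, seed=1)
        df = asg.popinfo_migrant_model(geno, declared, cfg, burn_in=20, reps=50, seed=2)
        assert (df["p_resident"] == 1.0).all()

    def test_f0_migrant_gets_high_posterior(self, disjoint):
        geno, declared = disjoint
        geno = geno.copy()
        geno[0] = 1  # declared pop 0, carries pure pop-1 genotype
        cfg = asg.AdmixtureConfig(migprior=0.05, gensback=2, seed=1)
        df = asg.popinfo_migrant_model(geno, declared, cfg, burn_in=100, reps=400, seed=3)
        assert df.loc[0, "p_migrant"] > 0.9
        assert df.loc[0, "flagged"]
        assert df.loc[1:, "p_resident"].min() > 0.5

    def test_deterministic_summary_under_fixed_seed(self, disjoint):
        geno, declared = disjoint
        cfg = asg.AdmixtureConfig(migprior=0.05, seed=1)
        a = asg.popinfo_migrant_model(geno, declared, cfg, burn_in=50, reps=100, seed=9)
        b = asg.popinfo_migrant_model(geno, declared, cfg, burn_in=50, reps=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="migprior"):
            asg.AdmixtureConfig(migprior=1.5)


class TestClassification:
    def _record(self, **kw):
        base = dict(
            individual_id="X",
            sampling_locality="China",
            q_home=0.5,
            f0_migrant_probability=0.4,
            candidate_localities=["China"],
            candidate_probs=[0.9],
        )
        base.update(kw)
        return asg.AssignmentRecord(**base)

    def test_single_foreign_locality_is_ms(self):
        rec = self._record(
            f0_migrant_probability=0.995,
            candidate_localities=["Russia"],
            candidate_probs=[0.831],
        )
        assert asg.classify_migrants(rec) == "MS"

    def test_dual_locality_foreign_top_is_mu_ms(self):
        rec = self._record(
            f0_migrant_probability=0.962,
            candidate_localities=["China", "Russia"],
            candidate_probs=[0.922, 0.993],
        )
        assert asg.classify_migrants(rec) == "MU/MS"

    def test_dual_locality_home_top_is_ms_mu(self):
        rec = self._record(
            sampling_locality="Russia",
            f0_migrant_probability=0.951,
            candidate_localities=["China", "Russia"],
            candidate_probs=[0.863, 0.940],
        )
        assert asg.classify_migrants(rec) == "MS/MU"

    def test_low_f0_is_resident(self):
        assert asg.classify_migrants(self._record(f0_migrant_probability=0.45)) == "-"

    def test_admixed_requires_mixed_q_and_undetermined_assignment(self):
        rec = self._record(
            q_home=0.5, candidate_localities=[], candidate_probs=[]
        )
        assert asg.classify_migrants(rec) == "admixed"
        rec2 = self._record(
            q_home=0.9, candidate_localities=[], candidate_probs=[]
        )
        assert asg.classify_migrants(rec2) == "-"

    def test_f0_with_no_candidates_is_mu(self):
        rec = self._record(
            f0_migrant_probability=0.99, candidate_localities=[], candidate_probs=[]
        )
        assert asg.classify_migrants(rec) == "MU"

    def test_tie_window_reports_joint_localities(self):
        cands, probs = asg.top_localities({"China": 0.93, "Russia": 0.86}, tie_window=0.1)
        assert set(cands) == {"China", "Russia"}
        cands, _ = asg.top_localities({"China": 0.93, "Russia": 0.4}, tie_window=0.1)
        assert cands == ["China"]


class TestF0Power:
    def test_power_increases_with_differentiation(self):
        # detection power of the residency test must rise with F_ST
        powers = {}
        for fst in (0.05, 0.2):
            hits = 0
            n_sims = 40
            for s in range(n_sims):
                cfg = syn.SyntheticConfig(
                    f_st=fst, n_per_pop=30, migrant_fraction=0.0, seed=5000 + s
                )
                truth = syn.simulate_populations(cfg)
                calls = [
                    {loc: tuple(truth.genotypes[i, l]) for l, loc in enumerate(truth.loci)}
                    for i in range(60)
                ]
                labels = list(truth.individuals["population"])
                labels[30] = "China"  # a Russian genotype sampled in China
                freqs = pg.allele_frequencies(zip(labels, calls))
                _, f0 = asg.f0_migrant_test(
                    calls[30], "China", freqs, n_sim=400, seed=s
                )
                hits += f0 > 0.95
            powers[fst] = hits / n_sims
        assert powers[0.2] > powers[0.05]
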