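"""Tests for the pseudogene-contamination coalescent simulator.

Analytic oracles: E[T2] = 1 for the balanced (S) class, rate-f coalescence
for the pseudogene class, Jukes-Cantor expected p-distance for a fixed
genealogy, and msprime as an independent neutral-coalescent reference for
whole distributions.
"""

import math

import dendropy
import msprime
import numpy as np
import pytest
from scipy import stats as sps

from slocus import coalescent as co
from slocus import ld


def harmonic(k):
    return sum(1.0 / i for i in range(1, k + 1))


class TestSimParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            co.SimParams(theta_s=0.0)
        with pytest.raises(ValueError):
            co.SimParams(c=1.5)
        with pytest.raises(ValueError):
            co.SimParams(t_d=0.0)
        with pytest.raises(ValueError):
            co.SimParams(theta_b=1.0, theta_s=0.1)

    def test_derived_quantities(self):
        p = co.SimParams(theta_s=0.2, r_over_mu=100.0, f=20.0, c=0.25)
        assert p.theta_p == pytest.approx(0.01)
        assert p.rho_site == pytest.approx(20.0)
        assert p.theta_b_effective == pytest.approx(0.2 / 2e6)
        assert p.n_contaminant == 6


class TestSimulateArg:
    def test_no_contamination_gives_single_tree(self, rng):
        trees, labels = co.simulate_arg(
            co.SimParams(theta_s=0.1, c=0.0, n_sample=6, L=40, r_over_mu=500.0), rng
        )
        assert trees.num_trees == 1
        assert labels == ["S"] * 6

    def test_zero_recombination_gives_single_tree(self, rng):
        trees, _ = co.simulate_arg(
            co.SimParams(theta_s=0.1, c=0.75, n_sample=8, L=40, r_over_mu=0.0), rng
        )
        assert trees.num_trees == 1

    def test_segments_partition_sites(self, rng):
        trees, _ = co.simulate_arg(
            co.SimParams(theta_s=1.0, c=0.5, n_sample=8, L=60, r_over_mu=100.0), rng
        )
        segs = trees.segments()
        assert segs[0][0] == 0 and segs[-1][1] == 60
        for (a, b), (c_, d) in zip(segs, segs[1:]):
            assert b == c_ and a < b
        assert all(a < b for a, b in segs)

    def test_every_marginal_tree_has_all_tips(self, rng):
        n = 7
        trees, _ = co.simulate_arg(
            co.SimParams(theta_s=1.0, c=0.5, n_sample=n, L=30, r_over_mu=200.0), rng
        )
        for start, _ in trees.segments():
            tree = dendropy.Tree.get(data=trees.to_newick(start), schema="newick")
            tips = sorted(int(leaf.taxon.label) for leaf in tree.leaf_node_iter())
            assert tips == list(range(n))

    def test_contaminant_label_counts(self, rng):
        for c, expect in [(0.25, 6), (0.5, 12), (0.75, 18), (0.0, 0), (1.0, 24)]:
            _, labels = co.simulate_arg(
                co.SimParams(theta_s=0.05, c=c, n_sample=24, L=4), rng
            )
            assert labels.count("P") == expect

    def test_pair_tmrca_expectations(self, rng):
        # balanced class: E[T2] = 1; pseudogene class with t_d >> 1/f:
        # rate-f exponential, E[T2] ~ 1/f
        reps = 6000
        s_params = co.SimParams(theta_s=0.1, c=0.0, n_sample=2, L=4)
        t_s = np.array(
            [co.simulate_arg(s_params, rng)[0].tmrca(0) for _ in range(reps)]
        )
        se = t_s.std() / math.sqrt(reps)
        assert abs(t_s.mean() - 1.0) < 3 * se
        p_params = co.SimParams(
            theta_s=0.1, c=1.0, f=20.0, t_d=3.0, n_sample=2, L=4, r_over_mu=0.0
        )
        t_p = np.array(
            [co.simulate_arg(p_params, rng)[0].tmrca(0) for _ in range(reps)]
        )
        se = t_p.std() / math.sqrt(reps)
        assert abs(t_p.mean() - 0.05) < 3 * se

    def test_pseudogene_times_stochastically_smaller(self, rng):
        # median pairwise TMRCA ratio P/S ~ 1/f for old duplications
        reps = 800
        f = 20.0
        med_s = np.median([
            co.simulate_arg(
                co.SimParams(theta_s=0.1, c=0.0, n_sample=2, L=4), rng
            )[0].tmrca(0)
            for _ in range(reps)
        ])
        med_p = np.median([
            co.simulate_arg(
                co.SimParams(theta_s=0.1, c=1.0, f=f, t_d=5.0, n_sample=2, L=4,
                             r_over_mu=0.0), rng
            )[0].tmrca(0)
            for _ in range(reps)
        ])
        assert med_p < med_s
        assert med_p / med_s == pytest.approx(1.0 / f, rel=0.35)

    def test_mixed_pair_coalesces_after_class_merge(self, rng):
        p = co.SimParams(
            theta_s=0.1, c=0.5, f=20.0, t_d=0.5, t_b=0.005, n_sample=2, L=4
        )
        times = [co.simulate_arg(p, rng)[0].tmrca(0) for _ in range(300)]
        assert min(times) >= 0.505


class TestAgainstNeutralReference:
    """msprime as an independent oracle for the f=1, c=0 neutral case."""

    def test_tmrca_distribution_matches_msprime(self, rng):
        reps = 3000
        ours = np.array([
            co.simulate_arg(
                co.SimParams(theta_s=0.1, c=0.0, n_sample=10, L=4), rng
            )[0].tmrca(0)
            for _ in range(reps)
        ])
        ref = []
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1.0, random_seed=i + 1
            )
            tree = ts.first()
            ref.append(tree.time(tree.root))
        assert sps.ks_2samp(ours, np.array(ref)).pvalue > 0.01

    def test_polymorphic_column_counts_match_msprime(self, rng):
        # finite-site JC in both simulators: count truly polymorphic columns
        reps, L, n = 1500, 100, 10
        p = co.SimParams(theta_s=0.1, c=0.0, n_sample=n, L=L)
        ours = []
        for _ in range(reps):
            sample = co.simulate_sample(p, rng)
            cols = sample.alignment
            ours.append(int(sum(len(set(cols[:, j])) > 1 for j in range(L))))
        ref = []
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=1.0,
                sequence_length=L, random_seed=i + 7,
            )
            mts = msprime.sim_mutations(
                ts, rate=0.05, model=msprime.JC69(), random_seed=i + 13
            )
            ref.append(sum(1 for v in mts.variants() if len(set(v.genotypes)) > 1))
        assert sps.ks_2samp(ours, ref).pvalue > 0.01


class TestEvolveSequences:
    def _fixed_pair_tree(self, L, tmrca=1.0):
        parent = np.full((L, 1), 2, dtype=np.int32)
        c1 = np.zeros((L, 1), dtype=np.int32)
        c2 = np.ones((L, 1), dtype=np.int32)
        node_time = np.array([0.0, 0.0, tmrca])
        return co.MarginalTreeSet(2, L, parent, c1, c2, node_time)

    def test_zero_branch_lengths_give_identical_sequences(self, rng):
        trees = self._fixed_pair_tree(100, tmrca=0.0)
        sample = co.evolve_sequences(trees, co.SimParams(theta_s=0.5), rng)
        assert (sample.alignment[0] == sample.alignment[1]).all()
        assert sample.n_mutations == 0

    def test_jc_expected_p_distance_on_fixed_tree(self, rng):
        # TMRCA 1, theta_s = 0.1: divergence d = 0.1 subs/site separates the
        # tips, so E[p] = 3/4 (1 - exp(-4 d / 3)) ~ 0.09365
        L = 10_000
        trees = self._fixed_pair_tree(L, tmrca=1.0)
        sample = co.evolve_sequences(trees, co.SimParams(theta_s=0.1), rng)
        p_hat = float(np.mean(sample.alignment[0] != sample.alignment[1]))
        expect = 0.75 * (1 - math.exp(-4 * 0.1 / 3))
        se = math.sqrt(expect * (1 - expect) / L)
        assert abs(p_hat - expect) < 3 * se

    def test_alignment_width_matches_length(self, rng):
        sample = co.simulate_sample(co.SimParams(theta_s=0.05, c=0.5, seed=3))
        assert sample.alignment.shape == (24, 327)

    def test_pair_diversity_equals_theta_s(self, rng):
        # mutation events per site between two S tips: theta_s * T2 on
        # average, i.e. E = theta_s in expectation
        reps, L, theta = 4000, 200, 0.1
        p = co.SimParams(theta_s=theta, c=0.0, n_sample=2, L=L)
        per_site = np.array([
            co.simulate_sample(p, rng).n_mutations / L for _ in range(reps)
        ])
        se = per_site.std() / math.sqrt(reps)
        assert abs(per_site.mean() - theta) < 3 * se


class TestSimulateSample:
    def test_same_seed_reproduces_alignment(self):
        p = co.SimParams(theta_s=0.2, c=0.5, r_over_mu=100.0, seed=11)
        s1 = co.simulate_sample(p)
        s2 = co.simulate_sample(p)
        assert (s1.alignment == s2.alignment).all()
        assert s1.source_labels == s2.source_labels

    def test_all_s_labels_without_contamination(self):
        sample = co.simulate_sample(co.SimParams(theta_s=0.05, c=0.0, seed=2))
        assert set(sample.source_labels) == {"S"}


class TestRunGrid:
    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            co.run_grid(reps=0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            co.run_grid(theta_s_values=[], reps=5)

    def test_deterministic_and_well_formed(self):
        kwargs = dict(
            theta_s_values=[0.1], t_d_values=[0.5], r_over_mu_values=[20.0],
            c_values=[0.5], reps=8, n_perm=50, seed=9,
        )
        df1 = co.run_grid(**kwargs)
        df2 = co.run_grid(**kwargs)
        assert df1["detections"].tolist() == df2["detections"].tolist()
        assert set(
            ["theta_s", "t_d", "r_over_mu", "c", "reps", "detections",
             "proportion", "se"]
        ) <= set(df1.columns)
        assert df1.loc[0, "theta_b"] == pytest.approx(0.1 / 2e6)
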