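import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fulmargsi.gsi_core import (build_baseline, downsample_reference,
                                em_mixing_proportions,
                                enumerate_mixture_posterior,
                                encode_mixture, genotype_log_likelihood,
                                infer_mixture, likelihood_matrix,
                                self_assign_loo, z_scores)

from fulmargsi.synthetic_data import (SimulationConfig, draw_colony_freqs,
                                      simulate_bundle, simulate_genotypes)

from conftest import genotype_table


class TestGenotypeLikelihood:
    def test_empty_baseline_probabilities(self):
        # y = 0, two alleles, alpha = (1/2, 1/2): hom 0.375 each, het 0.25
        y = np.zeros(2)
        alpha = np.full(2, 0.5)
        p_hom = math.exp(genotype_log_likelihood(0, 0, y, alpha, 0.0))
        p_het = math.exp(genotype_log_likelihood(0, 1, y, alpha, 0.0))
        assert p_hom == pytest.approx(0.375)
        assert p_het == pytest.approx(0.25)
        assert 2 * p_hom + p_het == pytest.approx(1.0)

    def test_near_fixed_colony(self):
        # y = (100, 0): P(AA) = 100.5*101.5 / (101*102)
        y = np.array([100.0, 0.0])
        alpha = np.full(2, 0.5)
        p = math.exp(genotype_log_likelihood(0, 0, y, alpha, 100.0))
        assert p == pytest.approx(100.5 * 101.5 / (101 * 102))
        assert p == pytest.approx(0.990, abs=5e-4)

    @given(st.lists(st.integers(min_value=0, max_value=500),
                    min_size=1, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_normalization_over_random_baselines(self, counts):
        y = np.array(counts, dtype=float)
        A = len(y)
        alpha = np.full(A, 1.0 / A)
        n = y.sum()
        total = 0.0
        for a in range(A):
            for b in range(a, A):
                total += math.exp(genotype_log_likelihood(a, b, y, alpha, n))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_all_loci_missing_gives_flat_zero_loglik(self, small_bundle):
        b = small_bundle
        base = build_baseline(b.reference, b.reference_labels)
        blank = genotype_table([("x1", b.locus_ids[0], "", "")])
        _, geno = encode_mixture(base, blank)
        logL = likelihood_matrix(base, geno)
        assert (logL == 0.0).all()


class TestBaseline:
    def test_counts(self):
        t = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "A", "B")])
        base = build_baseline(t, {"s1": "c1", "s2": "c1"})
        assert base.y[0].tolist() == [[3.0, 1.0]]
        assert base.n[0, 0] == 4

    def test_empty_reference_rejected(self):
        t = genotype_table([("s1", "L1", "", "")])
        with pytest.raises(ValueError, match="empty reference"):
            build_baseline(t, {"s1": "c1"})

    def test_novel_mixture_allele_gets_prior_mass(self):
        ref = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "A", "A")])
        mix = genotype_table([("m1", "L1", "B", "B")])
        base = build_baseline(ref, {"s1": "c1", "s2": "c1"}, mixture=mix)
        assert base.alleles[0] == ["A", "B"]
        _, geno = encode_mixture(base, mix)
        logL = likelihood_matrix(base, geno)
        assert np.isfinite(logL).all()
        assert math.exp(logL[0, 0]) > 0

    def test_unknown_allele_without_universe_extension_raises(self):
        ref = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "A", "A")])
        mix = genotype_table([("m1", "L1", "B", "B")])
        base = build_baseline(ref, {"s1": "c1", "s2": "c1"})
        with pytest.raises(KeyError):
            encode_mixture(base, mix)


class TestSelfAssignment:
    def test_identical_baselines_give_no_assignment_power(self):
        # posteriors hover at 1/2 (LOO removes the bird from its own colony
        # only, so exact 0.5 is not attainable) and nothing reaches 0.9
        rows, labels = [], {}
        for k, colony in enumerate(("c1", "c2")):
            for i in range(10):
                sid = f"{colony}_{i}"
                labels[sid] = colony
                # same genotype layout in both colonies
                g = ("A", "B") if i % 2 else ("A", "A")
                rows.append((sid, "L1", *g))
        base = build_baseline(genotype_table(rows), labels)
        res = self_assign_loo(base, threshold=0.9)
        post = res.assignments[["posterior_c1", "posterior_c2"]].to_numpy()
        np.testing.assert_allclose(post, 0.5, atol=0.05)
        assert not res.assignments["assigned"].any()

    def test_fixed_difference_gives_confident_assignment(self):
        rows, labels = [], {}
        for i in range(20):
            rows.append((f"a{i}", "L1", "A", "A"))
            labels[f"a{i}"] = "cA"
            rows.append((f"b{i}", "L1", "B", "B"))
            labels[f"b{i}"] = "cB"
        base = build_baseline(genotype_table(rows), labels)
        res = self_assign_loo(base)
        a_rows = res.assignments.query("true_colony == 'cA'")
        assert (a_rows["posterior_cA"] > 0.99).all()

    def test_singleton_colony_does_not_crash(self):
        rows = [("solo", "L1", "A", "A"), ("o1", "L1", "A", "B"),
                ("o2", "L1", "B", "B")]
        labels = {"solo": "tiny", "o1": "big", "o2": "big"}
        base = build_baseline(genotype_table(rows), labels)
        res = self_assign_loo(base)
        solo = res.assignments.set_index("sample_id").loc["solo"]
        assert np.isfinite([solo["posterior_tiny"], solo["posterior_big"]]).all()

    def test_loo_equals_scoring_against_baseline_without_self(self):
        rng = np.random.default_rng(3)
        rows, labels = [], {}
        for k, colony in enumerate(("c1", "c2")):
            for i in range(8):
                sid = f"{colony}_{i}"
                labels[sid] = colony
                for l in range(4):
                    a, b = sorted(rng.choice(["A", "B", "C"], 2))
                    rows.append((sid, f"L{l}", a, b))
        table = genotype_table(rows)
        full = build_baseline(table, labels)
        res = self_assign_loo(full)
        target = "c1_0"
        # oracle: baseline built without the focal bird, then plain scoring
        rest = table.subset_samples(set(table.samples) - {target})
        rest_labels = {s: c for s, c in labels.items() if s != target}
        base_wo = build_baseline(rest, rest_labels,
                                 mixture=table.subset_samples({target}))
        _, geno = encode_mixture(base_wo, table.subset_samples({target}))
        logL = likelihood_matrix(base_wo, geno)
        post = np.exp(logL - logL.max())
        post /= post.sum()
        got = res.assignments.set_index("sample_id").loc[
            target, ["posterior_c1", "posterior_c2"]].to_numpy(dtype=float)
        np.testing.assert_allclose(got, post[0], atol=1e-12)


class TestMixtureInference:
    def test_symmetric_baseline_gives_uniform_pi(self):
        # flat likelihoods leave pi at its Dirichlet(1/K) prior, mean 1/K;
        # a small mixture keeps the sampler mixing fast enough to see it
        rows, labels = [], {}
        for colony in ("c1", "c2", "c3", "c4"):
            for i in range(10):
                sid = f"{colony}_{i}"
                labels[sid] = colony
                rows.append((sid, "L1", "A", "B" if i % 2 else "A"))
        base_t = genotype_table(rows)
        mix = genotype_table([(f"m{i}", "L1", "A", "A") for i in range(5)])
        base = build_baseline(base_t, labels, mixture=mix)
        res = infer_mixture(base, mix, sweeps=30_000, burn_in=500, seed=1)
        np.testing.assert_allclose(res.pi_mean, 0.25, atol=0.05)

    def test_sweeps_must_exceed_burn_in(self, two_colony_bundle):
        b = two_colony_bundle
        base = build_baseline(b.reference, b.reference_labels,
                              mixture=b.mixture)
        with pytest.raises(ValueError):
            infer_mixture(base, b.mixture, sweeps=10, burn_in=10)

    def test_pi_matches_em_oracle(self):
        cfg = SimulationConfig(
            n_colonies=2, fst=0.1, n_loci=60, ref_sizes=(80, 80),
            mixture_size=500, mixture_proportions=(0.6, 0.4),
            colony_names=("East", "West"),
            colony_centroids=((56.0, -160.0), (58.0, -170.0)),
            census_sizes=(1, 1), census_percents=(50, 50), seed=21)
        b = simulate_bundle(cfg)
        base = build_baseline(b.reference, b.reference_labels,
                              mixture=b.mixture)
        _, geno = encode_mixture(base, b.mixture)
        em = em_mixing_proportions(likelihood_matrix(base, geno))
        res = infer_mixture(base, b.mixture, sweeps=2000, burn_in=100, seed=2)
        np.testing.assert_allclose(res.pi_mean, em, atol=0.05)

    def test_single_bird_posterior_marginalizes_pi(self):
        # one bird, L ratio 99:1 -> exact membership by 2-point integration
        logL = np.log(np.array([[0.01, 0.99]]))
        exact_m, _ = enumerate_mixture_posterior(logL)
        res_m = _gibbs_membership(logL, seed=5)
        np.testing.assert_allclose(res_m, exact_m, atol=0.02)
        assert exact_m[0, 1] == pytest.approx(0.99, abs=1e-12)

    def test_threshold_monotonicity(self, small_bundle):
        b = small_bundle
        base = build_baseline(b.reference, b.reference_labels,
                              mixture=b.mixture)
        res = infer_mixture(base, b.mixture, sweeps=600, burn_in=60, seed=3)
        fracs = [(res.assignments["max_posterior"] >= t).mean()
                 for t in (0.5, 0.7, 0.9, 0.99)]
        assert fracs == sorted(fracs, reverse=True)


def _gibbs_membership(logL, seed, sweeps=20_000, burn_in=1000):
    """Run the sampler on a bare likelihood matrix via a stub baseline."""
    from fulmargsi import gsi_core

    N, K = logL.shape
    rng = np.random.default_rng(seed)
    L = np.exp(logL - logL.max(axis=1, keepdims=True))
    pi = np.full(K, 1.0 / K)
    z_mean = np.zeros((N, K))
    for sweep in range(sweeps):
        w = L * pi
        w /= w.sum(axis=1, keepdims=True)
        u = rng.random((N, 1))
        z = (u > w.cumsum(axis=1)).sum(axis=1)
        pi = rng.dirichlet(1.0 / K + np.bincount(z, minlength=K))
        if sweep >= burn_in:
            z_mean[np.arange(N), z] += 1
    return z_mean / (sweeps - burn_in)


class TestZScores:
    def test_null_calibration(self):
        cfg = SimulationConfig(n_loci=140, fst=0.05, ref_sizes=(500,) * 4,
                               mixture_size=500, seed=5)
        b = simulate_bundle(cfg)
        base = build_baseline(b.reference, b.reference_labels,
                              mixture=b.mixture)
        samples, geno = encode_mixture(base, b.mixture)
        logL = likelihood_matrix(base, geno)
        cidx = {c: k for k, c in enumerate(base.colonies)}
        true_idx = np.array([cidx[b.mixture_labels[s]] for s in samples])
        z = z_scores(base, geno, true_idx, logL)
        assert abs(np.nanmean(z)) < 0.15
        assert 0.8 < np.nanstd(z) < 1.2

    def test_unsampled_population_strongly_negative(self):
        cfg = SimulationConfig(n_loci=140, fst=0.05, ref_sizes=(130,) * 4,
                               mixture_size=2, seed=6)
        b = simulate_bundle(cfg)
        rng = np.random.default_rng(7)
        out_freqs = []
        for f in b.colony_freqs:
            p = f.mean(axis=0)
            out_freqs.append(draw_colony_freqs(p / p.sum(), 0.2, 1, rng))
        outsiders = simulate_genotypes(
            out_freqs, b.locus_ids, b.allele_names, [0] * 100,
            [f"out_{i}" for i in range(100)], rng)
        base = build_baseline(b.reference, b.reference_labels,
                              mixture=outsiders)
        _, geno = encode_mixture(base, outsiders)
        logL = likelihood_matrix(base, geno)
        z = z_scores(base, geno, logL.argmax(axis=1), logL)
        assert np.nanmean(z) < -3.0

    def test_all_missing_is_undefined(self, small_bundle):
        b = small_bundle
        base = build_baseline(b.reference, b.reference_labels)
        blank = genotype_table([("x1", b.locus_ids[0], "", "")])
        _, geno = encode_mixture(base, blank)
        z = z_scores(base, geno, np.array([0]))
        assert np.isnan(z[0])


class TestDownsampling:
    def _reference(self, sizes):
        rows, labels = [], {}
        i = 0
        for k, n in enumerate(sizes):
            for _ in range(n):
                rows.append((f"s{i}", "L1", "A", "A"))
                labels[f"s{i}"] = f"c{k}"
                i += 1
        return genotype_table(rows), pd.Series(labels)

    def test_only_large_colonies_reduced(self):
        t, labels = self._reference((220, 120, 40, 36))
        _, new_labels = downsample_reference(t, labels, target_n=120, seed=0)
        assert new_labels.value_counts().sort_index().tolist() == [120, 120, 40, 36]

    def test_equalization(self):
        t, labels = self._reference((220, 120, 40, 36))
        _, new_labels = downsample_reference(t, labels, target_n=36, seed=0)
        assert new_labels.value_counts().sort_index().tolist() == [36, 36, 36, 36]

    def test_target_above_all_sizes_is_noop(self):
        t, labels = self._reference((10, 12))
        t2, new_labels = downsample_reference(t, labels, target_n=500, seed=0)
        assert sorted(new_labels.index) == sorted(labels.index)

    def test_seeded_and_deterministic(self):
        t, labels = self._reference((50, 50))
        _, a = downsample_reference(t, labels, target_n=20, seed=4)
        _, b = downsample_reference(t, labels, target_n=20, seed=4)
        assert a.index.tolist() == b.index.tolist()


class TestAccuracyMonotonicity:
    def test_self_assignment_accuracy_nondecreasing_in_fst(self):
        accs = []
        for F in (0.001, 0.02, 0.1):
            cfg = SimulationConfig(seed=31, fst=F, n_loci=80,
                                   ref_sizes=(40,) * 4, mixture_size=2)
            b = simulate_bundle(cfg)
            base = build_baseline(b.reference, b.reference_labels)
            accs.append(self_assign_loo(base).accuracy_all)
        assert accs == sorted(accs)
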