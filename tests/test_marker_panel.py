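import numpy as np
import pandas as pd
import pytest

from fulmargsi.marker_panel import (MicrohapLocus, SNPRecord,
                                    colony_allele_freqs, group_microhaps,
                                    ld_prune, rank_divergent_snps,
                                    select_panel, weir_cockerham_fst,
                                    write_bed)
from fulmargsi.synthetic_data import SimulationConfig, simulate_bundle

from conftest import genotype_table


class TestColonyAlleleFreqs:
    def test_counting(self):
        t = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "A", "B")])
        f = colony_allele_freqs(t, {"s1": "c1", "s2": "c1"})
        by_allele = f.set_index("allele")["frequency"]
        assert by_allele["A"] == 0.75
        assert by_allele["B"] == 0.25

    def test_all_missing_colony_is_undefined(self):
        t = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "", "")])
        f = colony_allele_freqs(t, {"s1": "c1", "s2": "c2"})
        assert set(f["colony"]) == {"c1"}  # c2 absent = undefined

    def test_monomorphic_colony(self):
        t = genotype_table([("s1", "L1", "A", "A"), ("s2", "L1", "A", "A")])
        f = colony_allele_freqs(t, {"s1": "c1", "s2": "c1"})
        assert f["frequency"].tolist() == [1.0]


class TestLDPrune:
    def test_distance_rule(self):
        snps = [SNPRecord("sc1", p) for p in (1, 50_000, 120_000)]
        kept = ld_prune(snps, min_dist=100_000)
        assert [s.position for s in kept] == [1, 120_000]

    def test_one_per_scaffold_kept(self):
        snps = [SNPRecord(f"sc{i}", 10) for i in range(3)]
        assert len(ld_prune(snps)) == 3

    def test_boundary_is_strict(self):
        snps = [SNPRecord("sc1", 1), SNPRecord("sc1", 100_001)]
        assert [s.position for s in ld_prune(snps, 100_000)] == [1]

    def test_never_two_within_min_dist(self):
        rng = np.random.default_rng(0)
        snps = [SNPRecord("sc1", int(p))
                for p in sorted(rng.integers(1, 10**6, size=200))]
        kept = ld_prune(snps, min_dist=50_000)
        pos = [s.position for s in kept]
        assert all(b - a > 50_000 for a, b in zip(pos, pos[1:]))


def brute_force_theta(genotypes, labels):
    """Independent W&C 1984 oracle: plain loops straight from the published
    component formulas, one allele at a time."""
    loci = sorted({l for _, l, *_ in genotypes})
    A_sum = D_sum = 0.0
    for locus in loci:
        calls = [(s, a, b) for s, l, a, b in genotypes if l == locus and a != ""]
        pops = sorted({labels[s] for s, _, _ in calls})
        r = len(pops)
        if r < 2:
            continue
        n = {p: sum(1 for s, _, _ in calls if labels[s] == p) for p in pops}
        if any(v == 0 for v in n.values()):
            continue
        nbar = sum(n.values()) / r
        nc = (r * nbar - sum(v * v for v in n.values()) / (r * nbar)) / (r - 1)
        alleles = sorted({x for _, a, b in calls for x in (a, b)})
        for al in alleles:
            p = {}
            h = {}
            for pop in pops:
                mine = [(a, b) for s, a, b in calls if labels[s] == pop]
                p[pop] = sum((a == al) + (b == al) for a, b in mine) / (2 * n[pop])
                h[pop] = sum(1 for a, b in mine if a != b and al in (a, b)) / n[pop]
            pbar = sum(n[pop] * p[pop] for pop in pops) / (r * nbar)
            s2 = sum(n[pop] * (p[pop] - pbar) ** 2 for pop in pops) / ((r - 1) * nbar)
            hbar = sum(n[pop] * h[pop] for pop in pops) / (r * nbar)
            if nbar <= 1:
                continue
            a_c = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b_c = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c_c = hbar / 2
            A_sum += a_c
            D_sum += a_c + b_c + c_c
    return A_sum / D_sum if D_sum else float("nan")


class TestWeirCockerham:
    def test_fixed_difference_theta_is_one(self):
        rows = [(f"s{i}", "L1", "A", "A") for i in range(20)]
        rows += [(f"t{i}", "L1", "B", "B") for i in range(20)]
        labels = {f"s{i}": "c1" for i in range(20)}
        labels |= {f"t{i}": "c2" for i in range(20)}
        res = weir_cockerham_fst(genotype_table(rows), labels, pairwise=False)
        assert res.theta == pytest.approx(1.0)

    def test_identical_populations_theta_nonpositive(self):
        rng = np.random.default_rng(1)
        rows, labels = [], {}
        for i in range(40):
            g = sorted(rng.choice(["A", "B"], 2))
            # same genotype in a mirrored sample of the other colony
            rows.append((f"s{i}", "L1", g[0], g[1]))
            rows.append((f"m{i}", "L1", g[0], g[1]))
            labels[f"s{i}"] = "c1"
            labels[f"m{i}"] = "c2"
        res = weir_cockerham_fst(genotype_table(rows), labels, pairwise=False)
        assert res.theta <= 1e-12

    def test_hand_computed_two_colony_example(self):
        # colony1: 10xAA + 10xAB; colony2: 5xAA + 15xBB
        rows, labels = [], {}
        i = 0
        for geno, cnt, col in [(("A", "A"), 10, "c1"), (("A", "B"), 10, "c1"),
                               (("A", "A"), 5, "c2"), (("B", "B"), 15, "c2")]:
            for _ in range(cnt):
                rows.append((f"s{i}", "L1", *geno))
                labels[f"s{i}"] = col
                i += 1
        res = weir_cockerham_fst(genotype_table(rows), labels, pairwise=False)
        # a = 2*0.125*18/19, b = 2*(20/19)*0.065625, c = 0.25
        assert res.theta == pytest.approx(0.37894736842105264, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            K = rng.integers(2, 4)
            L = rng.integers(1, 4)
            rows, labels = [], {}
            i = 0
            for k in range(K):
                for _ in range(rng.integers(4, 10)):
                    sid = f"s{i}"
                    labels[sid] = f"c{k}"
                    for l in range(L):
                        a, b = sorted(rng.choice(["A", "B", "C"], 2))
                        rows.append((sid, f"L{l}", a, b))
                    i += 1
            table = genotype_table(rows)
            res = weir_cockerham_fst(table, labels, pairwise=False,
                                     max_missing_fraction=None)
            oracle = brute_force_theta(
                [(r.sample_id, r.locus_id, r.allele_1, r.allele_2)
                 for r in table.calls.itertuples()], labels)
            if np.isnan(oracle):
                assert np.isnan(res.theta)
            else:
                assert res.theta == pytest.approx(oracle, abs=1e-10)

    def test_pairwise_matrix_symmetric_zero_diagonal(self, small_bundle):
        res = weir_cockerham_fst(small_bundle.reference,
                                 small_bundle.reference_labels)
        pw = res.pairwise
        assert np.allclose(pw.to_numpy(), pw.to_numpy().T)
        assert np.allclose(np.diag(pw.to_numpy()), 0.0)

    def test_theta_increases_with_drift(self):
        thetas = []
        for F in (0.005, 0.05, 0.2):
            cfg = SimulationConfig(seed=11, fst=F, n_loci=120,
                                   ref_sizes=(40,) * 4, mixture_size=2)
            b = simulate_bundle(cfg)
            res = weir_cockerham_fst(b.reference, b.reference_labels,
                                     pairwise=False)
            thetas.append(res.theta)
        assert thetas == sorted(thetas)


class TestRanking:
    def _freqs(self, rows):
        return pd.DataFrame(rows, columns=["colony", "locus_id", "allele",
                                           "frequency"])

    def test_largest_difference_wins(self):
        f = self._freqs([("c1", "S1", "A", 0.9), ("c2", "S1", "A", 0.5),
                         ("c1", "S1", "B", 0.1), ("c2", "S1", "B", 0.5),
                         ("c1", "S2", "A", 0.55), ("c2", "S2", "A", 0.45),
                         ("c1", "S2", "B", 0.45), ("c2", "S2", "B", 0.55)])
        top = rank_divergent_snps(f, "c1", "c2", top_k=1)
        assert top["locus_id"].tolist() == ["S1"]
        assert top["score"].iloc[0] == pytest.approx(0.4)

    def test_degenerate_tie_break_is_positional(self):
        f = self._freqs([(c, s, "A", 0.5) for c in ("c1", "c2")
                         for s in ("S1", "S2")])
        pos = {"S1": ("sc2", 5), "S2": ("sc1", 9)}
        top = rank_divergent_snps(f, "c1", "c2", snp_positions=pos, top_k=2)
        assert top["locus_id"].tolist() == ["S2", "S1"]  # sc1 before sc2

    def test_union_bound_and_permutation_invariance(self):
        rng = np.random.default_rng(2)
        rows = []
        for s in range(60):
            for c in ("c1", "c2", "c3", "c4"):
                p = rng.random()
                rows += [(c, f"S{s:02d}", "A", p), (c, f"S{s:02d}", "B", 1 - p)]
        f = self._freqs(rows)
        sel = select_panel(f, ["c1", "c2", "c3", "c4"], top_k=40)
        assert len(sel) <= 6 * 40
        shuffled = f.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert select_panel(shuffled, ["c1", "c2", "c3", "c4"],
                            top_k=40) == sel

    def test_top_k_beyond_available_returns_all(self):
        f = self._freqs([("c1", "S1", "A", 0.9), ("c2", "S1", "A", 0.1)])
        assert len(rank_divergent_snps(f, "c1", "c2", top_k=10)) == 1


class TestMicrohapGrouping:
    def test_window_rule(self):
        snps = [SNPRecord("sc1", 100), SNPRecord("sc1", 248)]
        loci = group_microhaps(snps, window=150)
        assert len(loci) == 1
        assert loci[0].snp_positions == (100, 248)

    def test_boundary_is_strict(self):
        snps = [SNPRecord("sc1", 100), SNPRecord("sc1", 250)]
        assert len(group_microhaps(snps, window=150)) == 2

    def test_bed_coordinates_zero_based_half_open(self, tmp_path):
        loci = group_microhaps([SNPRecord("sc1", 500)], window=150, flank=75)
        assert loci[0].bed_interval() == (424, 575)
        p = tmp_path / "amps.bed"
        write_bed(loci, p)
        assert p.read_text().split("\t")[:3] == ["sc1", "424", "575"]

    def test_flank_truncation_flagged(self):
        loci = group_microhaps([SNPRecord("sc1", 30)], window=150, flank=75)
        assert loci[0].flank_truncated
        assert loci[0].bed_interval()[0] == 0
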