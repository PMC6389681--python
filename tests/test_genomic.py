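"""Genotype QC, allele frequencies, G construction, tuning and H^-1."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sswgwas import (
    GenotypeSet,
    MarkerWeights,
    RelationshipMatrix,
    RunConfig,
    a_inverse,
    a_matrix,
    allele_freq,
    g_matrix,
    h_inverse,
    hwe_pvalue,
    lambda_norm,
    plant_qc_failures,
    qc_filter,
    subset_a22,
    tune_and_blend,
)
from sswgwas.datamodel import MISSING_CALL
from conftest import random_genotypes, random_pedigree


class TestHwe:
    def test_perfect_hwe(self):
        assert hwe_pvalue(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit_matches_chi2_oracle(self):
        # (50, 0, 50): p = 0.5, chi-square statistic equals n = 100
        p = hwe_pvalue(50, 0, 50)
        assert p == pytest.approx(float(stats.chi2.sf(100, df=1)))
        assert p < 1e-6

    def test_monomorphic_returns_one(self):
        assert hwe_pvalue(0, 0, 60) == 1.0
        assert hwe_pvalue(60, 0, 0) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hwe_pvalue(0, 0, 0)


class TestQcFilter:
    def test_monomorphic_removed_under_maf(self):
        g = random_genotypes(50, 5, seed=0)
        g.calls[:, 2] = 2
        filtered, report = qc_filter(g, RunConfig())
        assert g.markers["snp_id"].iloc[2] in report.removed_maf_ids
        assert filtered.n_markers == 4

    def test_callrate_failure_attributed_first(self):
        """A SNP failing call rate is never double-counted under MAF."""
        g = random_genotypes(100, 5, seed=1)
        g.calls[:89, 3] = MISSING_CALL  # call rate 0.11, also extreme freq noise
        _, report = qc_filter(g, RunConfig())
        sid = g.markers["snp_id"].iloc[3]
        assert sid in report.removed_callrate_ids
        assert sid not in report.removed_maf_ids

    def test_planted_fixture_counts(self):
        """100 SNPs with 7 call-rate, 11 MAF, 3 HWE planted failures
        (disjoint) leave exactly 79 retained."""
        g = random_genotypes(200, 100, seed=2, maf_low=0.2, maf_high=0.5)
        g, planted = plant_qc_failures(g, seed=3, n_callrate=7, n_maf=11, n_hwe=3)
        filtered, report = qc_filter(g, RunConfig())
        assert report.n_removed_callrate == 7
        assert report.n_removed_maf == 11
        assert report.n_removed_hwe == 3
        assert report.n_retained == 79
        assert sorted(report.removed_callrate_ids) == sorted(planted["callrate"])
        assert sorted(report.removed_maf_ids) == sorted(planted["maf"])
        assert sorted(report.removed_hwe_ids) == sorted(planted["hwe"])
        assert not filtered.has_missing

    def test_attribution_stable_under_shuffle(self):
        g = random_genotypes(200, 60, seed=4, maf_low=0.2)
        g, _ = plant_qc_failures(g, seed=5, n_callrate=4, n_maf=6, n_hwe=2)
        _, rep1 = qc_filter(g, RunConfig())
        rng = np.random.default_rng(6)
        perm = rng.permutation(g.n_markers)
        shuffled = GenotypeSet(
            animal_ids=list(g.animal_ids),
            markers=g.markers.iloc[perm].reset_index(drop=True),
            calls=g.calls[:, perm].copy(),
        )
        _, rep2 = qc_filter(shuffled, RunConfig())
        for attr in ("n_removed_callrate", "n_removed_maf", "n_removed_hwe", "n_retained"):
            assert getattr(rep1, attr) == getattr(rep2, attr)

    def test_boundary_values_retained(self):
        """Exactly-at-threshold SNPs survive (strict-inequality exclusion)."""
        # 10 animals, call rate exactly 0.9 (one missing), MAF exactly 0.05
        markers = pd.DataFrame({
            "snp_id": ["s1", "s2"], "chromosome": ["1", "1"], "position_bp": [100, 200],
        })
        calls = np.zeros((10, 2), dtype=np.int16)
        calls[0, 0] = MISSING_CALL  # call rate 0.9 at s1; freq of s1 among 9 typed
        calls[1:3, 0] = 1  # p = 2/18 = 0.111 > 0.05 keeps MAF clear
        calls[0, 1] = 1  # p = 1/20 = 0.05 exactly at the MAF boundary
        g = GenotypeSet(animal_ids=[f"a{i}" for i in range(10)], markers=markers, calls=calls)
        filtered, report = qc_filter(g, RunConfig())
        assert report.n_retained == 2

    def test_all_removed_is_hard_error(self):
        g = random_genotypes(50, 3, seed=7)
        g.calls[:] = 2
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(g, RunConfig())


class TestAlleleFreqAndLambda:
    def test_single_heterozygote_spread(self):
        g = random_genotypes(3, 1, seed=8)
        g.calls[:, 0] = [0, 1, 2]
        assert allele_freq(g)[0] == pytest.approx(0.5)

    def test_counting_oracle(self):
        g = random_genotypes(200, 20, seed=9)
        p = allele_freq(g)
        for j in range(20):
            copies = g.calls[:, j].sum()
            assert p[j] == pytest.approx(copies / (2 * 200))

    def test_lambda_closed_forms(self):
        assert lambda_norm(np.array([0.5])) == pytest.approx(2.0)
        m = 40
        assert lambda_norm(np.full(m, 0.5)) == pytest.approx(2.0 / m)

    def test_lambda_matches_term_sum(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.05, 0.95, 100)
        acc = sum(2 * pi * (1 - pi) for pi in p)
        assert lambda_norm(p) == pytest.approx(1.0 / acc)

    def test_lambda_rejects_fixed_alleles(self):
        with pytest.raises(ValueError):
            lambda_norm(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            lambda_norm(np.array([]))


class TestGMatrix:
    def test_single_snp_hand_case(self):
        g = random_genotypes(3, 1, seed=11)
        g.calls[:, 0] = [0, 1, 2]
        G = g_matrix(g, np.array([0.5])).values
        # Z = (-1, 0, 1), lambda = 2: G = 2 * outer(Z, Z)
        assert np.allclose(np.diag(G), [2.0, 0.0, 2.0])
        assert G[0, 2] == pytest.approx(-2.0)

    def test_zero_weights_rank_one(self):
        g = random_genotypes(30, 10, seed=12)
        p = allele_freq(g)
        d = np.zeros(10)
        d[4] = 1.0
        G = g_matrix(g, p, MarkerWeights(d)).values
        assert np.linalg.matrix_rank(G, tol=1e-10) <= 1

    def test_mean_diagonal_near_one(self):
        """Monte-Carlo expectation of the standard (d = 1) G."""
        g = random_genotypes(200, 1000, seed=13)
        G = g_matrix(g, allele_freq(g)).values
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.05

    def test_allele_flip_invariance(self):
        g = random_genotypes(40, 20, seed=14)
        p = allele_freq(g)
        G1 = g_matrix(g, p).values
        flipped = GenotypeSet(
            animal_ids=list(g.animal_ids),
            markers=g.markers.copy(),
            calls=(2 - g.calls).astype(np.int16),
        )
        G2 = g_matrix(flipped, allele_freq(flipped)).values
        assert np.abs(G1 - G2).max() < 1e-10


class TestTuneAndBlend:
    def _pair(self, seed, n=12):
        rng = np.random.default_rng(seed)
        ids = [f"a{i}" for i in range(n)]
        M1 = rng.standard_normal((n, 2 * n))
        M2 = rng.standard_normal((n, 2 * n))
        G = RelationshipMatrix(ids, M1 @ M1.T / (2 * n))
        A22 = RelationshipMatrix(ids, M2 @ M2.T / (2 * n) + np.eye(n) * 0.1)
        return G, A22

    def test_fixed_point(self):
        G, _ = self._pair(15)
        Gw, a, b = tune_and_blend(G, G, tau=0.05)
        assert (a, b) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))
        assert np.abs(Gw.values - G.values).max() < 1e-12

    def test_tau_one_returns_a22(self):
        G, A22 = self._pair(16)
        Gw, _, _ = tune_and_blend(G, A22, tau=1.0)
        assert np.abs(Gw.values - A22.values).max() < 1e-12

    @pytest.mark.parametrize("seed", [17, 18])
    def test_moment_matching_oracle(self, seed):
        """(a, b) solve the 2x2 linear system matching diagonal and
        overall means; check the tuned (unblended) moments directly."""
        G, A22 = self._pair(seed)
        Gw, a, b = tune_and_blend(G, A22, tau=0.0)
        assert np.mean(np.diag(Gw.values)) == pytest.approx(np.mean(np.diag(A22.values)), abs=1e-10)
        assert np.mean(Gw.values) == pytest.approx(np.mean(A22.values), abs=1e-10)

    def test_constant_g_degenerate(self):
        ids = ["a", "b"]
        G = RelationshipMatrix(ids, np.ones((2, 2)))
        A22 = RelationshipMatrix(ids, np.eye(2))
        with pytest.raises(ValueError, match="tune"):
            tune_and_blend(G, A22)


class TestHInverse:
    def test_no_genotyped_animals_reduces_to_ainv(self):
        ped = random_pedigree(40, seed=19)
        Ainv = a_inverse(ped)
        H = h_inverse(Ainv, np.empty((0, 0)), np.empty((0, 0)), ped.animal_ids, [])
        assert np.abs(H.values - Ainv).max() < 1e-10

    def test_gw_equal_a22_reduces_to_ainv(self):
        ped = random_pedigree(30, seed=20)
        A = a_matrix(ped)
        Ainv = a_inverse(ped)
        gen = A.animal_ids[-8:]
        A22 = subset_a22(A, gen).values
        A22inv = np.linalg.inv(A22)
        H = h_inverse(Ainv, A22inv, A22inv, ped.animal_ids, gen)
        assert np.abs(H.values - Ainv).max() < 1e-10

    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_dense_h_oracle(self, seed):
        """H^-1 assembly against explicit construction of the blended H.

        The joint pedigree-genomic covariance has the closed form
        H = [[A11 + A12 A22^-1 (Gw - A22) A22^-1 A21, A12 A22^-1 Gw],
             [Gw A22^-1 A21,                           Gw]];
        inverting it densely must reproduce the assembled H^-1.
        """
        ped = random_pedigree(30, seed=seed)
        n_gen = 10
        gen = ped.animal_ids[-n_gen:]
        A = a_matrix(ped)
        Ainv = a_inverse(ped)
        A22 = subset_a22(A, gen)
        A22inv = np.linalg.inv(A22.values)

        g = random_genotypes(n_gen, 60, seed=seed + 100, maf_low=0.3)
        g, _ = qc_filter(g, RunConfig())
        g.animal_ids = list(gen)
        Gstar = g_matrix(g, allele_freq(g))
        Gstar.animal_ids = list(gen)
        Gw, _, _ = tune_and_blend(Gstar, A22, tau=0.05)

        Hinv = h_inverse(Ainv, A22inv, np.linalg.inv(Gw.values), ped.animal_ids, gen)

        idx_gen = ped.index_of(gen)
        idx_non = np.array([i for i in range(ped.n_animals) if i not in set(idx_gen)])
        Afull = A.values
        A11 = Afull[np.ix_(idx_non, idx_non)]
        A12 = Afull[np.ix_(idx_non, idx_gen)]
        Gwv = Gw.values
        H11 = A11 + A12 @ A22inv @ (Gwv - A22.values) @ A22inv @ A12.T
        H12 = A12 @ A22inv @ Gwv
        n = ped.n_animals
        H = np.zeros((n, n))
        H[np.ix_(idx_non, idx_non)] = H11
        H[np.ix_(idx_non, idx_gen)] = H12
        H[np.ix_(idx_gen, idx_non)] = H12.T
        H[np.ix_(idx_gen, idx_gen)] = Gwv
        dense = np.linalg.inv(H)
        assert np.abs(Hinv.values - dense).max() < 1e-6

    def test_symmetry_and_outside_block(self):
        ped = random_pedigree(25, seed=23)
        gen = ped.animal_ids[-5:]
        A = a_matrix(ped)
        Ainv = a_inverse(ped)
        A22 = subset_a22(A, gen)
        g = random_genotypes(5, 40, seed=24, maf_low=0.3)
        g, _ = qc_filter(g, RunConfig())
        Gw, _, _ = tune_and_blend(
            RelationshipMatrix(gen, g_matrix(g, allele_freq(g)).values), A22, 0.05)
        H = h_inverse(Ainv, np.linalg.inv(A22.values), np.linalg.inv(Gw.values),
                      ped.animal_ids, gen)
        assert np.abs(H.values - H.values.T).max() < 1e-10
        idx_non = [i for i, a in enumerate(ped.animal_ids) if a not in set(gen)]
        assert np.abs(H.values[np.ix_(idx_non, idx_non)] - Ainv[np.ix_(idx_non, idx_non)]).max() == 0
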