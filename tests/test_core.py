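"""Unit and property tests for the disequilibrium estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zygld import (
    MISSING,
    TwoLocusCounts,
    locus_summary,
    two_locus_counts,
    composite_ld,
    trigenic_disequilibria,
    quadrigenic_disequilibrium,
    zygotic_ld,
    em_gametic_ld,
    pair_disequilibria,
    table_statistics,
    reconstruct_P_AABB,
    rug_genotype_probs,
    simulate_rug,
)
from zygld.io import GenotypeMatrix


def _counts_from_probs(P, n=1000):
    return TwoLocusCounts(counts=np.asarray(P) * n, n=n)


# random 9-cell probability tables via hypothesis
cell_tables = st.lists(st.integers(min_value=1, max_value=50),
                       min_size=9, max_size=9).map(
    lambda w: np.array(w, dtype=float).reshape(3, 3) / np.sum(w))


class TestLocusSummary:
    @pytest.mark.parametrize(
        "counts, p, D, f, hwd",
        [((30, 40, 30), 0.5, 0.05, 0.2, 4.0),   # counts = (aa, Aa, AA)
         ((25, 50, 25), 0.5, 0.0, 0.0, 0.0),
         ((50, 0, 50), 0.5, 0.25, 1.0, 100.0)],
    )
    def test_hand_computed_examples(self, counts, p, D, f, hwd):
        col = np.repeat([0, 1, 2], counts)
        s = locus_summary(col)
        assert s.p_A == pytest.approx(p)
        assert s.D_A == pytest.approx(D)
        assert s.f_A == pytest.approx(f)
        assert s.hwd_chisq == pytest.approx(hwd)
        assert s.pi_A + s.D_A >= 0

    def test_missing_calls_excluded(self):
        col = np.array([2, 2, 0, 0, MISSING, MISSING])
        s = locus_summary(col)
        assert s.n_called == 4
        assert s.p_A == pytest.approx(0.5)

    def test_monomorphic_flagged(self):
        s = locus_summary(np.array([2, 2, 2]))
        assert s.monomorphic
        assert np.isnan(s.f_A)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            locus_summary(np.array([MISSING, MISSING]))


class TestTwoLocusCounts:
    def test_direct_tabulation(self):
        dosages = np.array([[2, 2]] * 50 + [[0, 0]] * 50, dtype=np.int8)
        gm = GenotypeMatrix([f"a{i}" for i in range(100)], ["M1", "M2"], dosages)
        c = two_locus_counts(gm, 0, 1)
        assert c.counts[2, 2] == 50 and c.counts[0, 0] == 50
        assert c.counts.sum() == c.n == 100

    def test_pairwise_complete_rule(self):
        dosages = np.array([[2, 2], [MISSING, 1], [0, 0]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], ["M1", "M2"], dosages)
        c = two_locus_counts(gm, 0, 1)
        assert c.n == 2

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(17)
        dosages = rng.integers(-1, 3, size=(200, 4)).astype(np.int8)
        gm = GenotypeMatrix([f"a{i}" for i in range(200)],
                            [f"M{j}" for j in range(4)], dosages)
        c = two_locus_counts(gm, 1, 3)
        expect = np.zeros((3, 3))
        for a, b in dosages[:, [1, 3]]:
            if a != MISSING and b != MISSING:
                expect[a, b] += 1
        np.testing.assert_array_equal(c.counts, expect)

    def test_same_marker_rejected(self):
        gm = GenotypeMatrix(["a"], ["M1", "M2"], np.array([[1, 1]], dtype=np.int8))
        with pytest.raises(ValueError):
            two_locus_counts(gm, 1, 1)


class TestPairEstimators:
    def test_w1_fixture_exact(self, w1_counts):
        """50 AABB + 50 aabb: every component known in closed form."""
        assert composite_ld(w1_counts) == pytest.approx(0.5, abs=1e-15)
        d_aab, d_abb = trigenic_disequilibria(w1_counts)
        assert d_aab == pytest.approx(0.0, abs=1e-15)
        assert d_abb == pytest.approx(0.0, abs=1e-15)
        assert quadrigenic_disequilibrium(w1_counts) == pytest.approx(-0.25, abs=1e-15)
        omega, r2z = zygotic_ld(w1_counts)
        assert omega == pytest.approx(0.25, abs=1e-15)
        assert r2z == pytest.approx(1.0, abs=1e-12)

    def test_independence_gives_zeros(self, independent_probs):
        c = TwoLocusCounts.from_probs(independent_probs)
        assert composite_ld(c) == pytest.approx(0.0, abs=1e-15)
        assert quadrigenic_disequilibrium(c) == pytest.approx(0.0, abs=1e-15)
        omega, r2z = zygotic_ld(c)
        assert omega == pytest.approx(0.0, abs=1e-15)
        assert r2z == pytest.approx(0.0, abs=1e-15)

    def test_rug_reduction(self, rug_d01_probs):
        """Random union of gametes: Delta = D, omega = 2 pA pB D + D^2,
        trigenic and quadrigenic vanish."""
        c = TwoLocusCounts.from_probs(rug_d01_probs)
        assert composite_ld(c) == pytest.approx(0.1, abs=1e-14)
        d_aab, d_abb = trigenic_disequilibria(c)
        assert d_aab == pytest.approx(0.0, abs=1e-14)
        assert d_abb == pytest.approx(0.0, abs=1e-14)
        assert quadrigenic_disequilibrium(c) == pytest.approx(0.0, abs=1e-14)
        omega, _ = zygotic_ld(c)
        assert omega == pytest.approx(0.06, abs=1e-14)

    def test_trigenic_mixture_vs_bruteforce_moments(self, mix7030_probs):
        """70/30 Wahlund mixture: trigenic estimate equals an independent
        brute-force computation of the gene-triple moment expansion."""
        c = TwoLocusCounts.from_probs(mix7030_probs)
        d_aab, d_abb = trigenic_disequilibria(c)
        # independent route: explicit moments from the 9-cell table
        P = mix7030_probs
        pA = sum((x / 2) * P[x, y] for x in range(3) for y in range(3))
        pB = sum((y / 2) * P[x, y] for x in range(3) for y in range(3))
        P_AA = P[2, :].sum()
        D_A = P_AA - pA ** 2
        exy = sum(x * y * P[x, y] for x in range(3) for y in range(3))
        delta = exy / 2 - 2 * pA * pB
        P_AAB = sum(y * P[2, y] for y in range(3)) / 2
        expect = P_AAB - pA ** 2 * pB - pB * D_A - pA * delta
        assert d_aab == pytest.approx(expect, abs=1e-14)
        assert d_aab == pytest.approx(-0.043008, abs=1e-12)
        assert d_abb == pytest.approx(-0.043008, abs=1e-12)

    def test_composite_equals_half_dosage_covariance(self):
        rng = np.random.default_rng(11)
        P = rng.dirichlet(np.ones(9)).reshape(3, 3)
        c = TwoLocusCounts.from_probs(P)
        x = np.arange(3)
        exy = (P * np.outer(x, x)).sum()
        ex = (P.sum(axis=1) * x).sum()
        ey = (P.sum(axis=0) * x).sum()
        assert composite_ld(c) == pytest.approx((exy - ex * ey) / 2, abs=1e-14)

    def test_monomorphic_pair_rejected(self):
        P = np.zeros((3, 3))
        P[2, 2] = 0.5
        P[2, 0] = 0.5
        with pytest.raises(ValueError):
            composite_ld(TwoLocusCounts.from_probs(P))


class TestAlgebraicProperties:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(cell_tables)
    def test_zygotic_identity_inverts_exactly(self, P):
        """Rebuilding the AABB cell from the estimated components recovers
        the observed cell to machine precision for any table."""
        s = table_statistics(P)
        assert abs(reconstruct_P_AABB(s) - P[2, 2]) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(cell_tables)
    def test_locus_swap_symmetry(self, P):
        s = table_statistics(P)
        t = table_statistics(P.T.copy())
        assert t["d_AAB"] == pytest.approx(s["d_ABB"], abs=1e-12)
        assert t["d_ABB"] == pytest.approx(s["d_AAB"], abs=1e-12)
        assert t["delta_AB"] == pytest.approx(s["delta_AB"], abs=1e-12)
        assert t["delta_AABB"] == pytest.approx(s["delta_AABB"], abs=1e-12)
        assert t["omega_AABB"] == pytest.approx(s["omega_AABB"], abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(cell_tables)
    def test_allele_relabel_symmetry(self, P):
        """Relabeling A<->a at locus A negates Delta and D_ABB (one A gene),
        preserves D_AAB and Delta_AABB (even numbers of A genes), and leaves
        the composite squared correlation unchanged."""
        s = table_statistics(P)
        f = table_statistics(P[::-1, :].copy())
        assert f["delta_AB"] == pytest.approx(-s["delta_AB"], abs=1e-12)
        assert f["d_ABB"] == pytest.approx(-s["d_ABB"], abs=1e-12)
        assert f["d_AAB"] == pytest.approx(s["d_AAB"], abs=1e-12)
        assert f["delta_AABB"] == pytest.approx(s["delta_AABB"], abs=1e-12)
        den_s = (s["pi_A"] + s["D_A"]) * (s["pi_B"] + s["D_B"])
        den_f = (f["pi_A"] + f["D_A"]) * (f["pi_B"] + f["D_B"])
        if den_s > 1e-9:
            assert f["delta_AB"] ** 2 / den_f == pytest.approx(
                s["delta_AB"] ** 2 / den_s, rel=1e-9)

    def test_plugin_identity(self, mix7030_probs):
        """Estimators applied to exact population frequencies return the
        population parameters; applied to a sample, the same formulas on
        observed proportions."""
        exact = table_statistics(mix7030_probs)
        scaled = table_statistics(
            _counts_from_probs(mix7030_probs, 1_000_000).probs)
        for key in ("delta_AB", "d_AAB", "delta_AABB", "omega_AABB"):
            assert scaled[key] == pytest.approx(exact[key], abs=1e-12)


class TestEMGameticLD:
    def test_unambiguous_phase_closed_form(self, w1_counts):
        h, D, r2, info = em_gametic_ld(w1_counts)
        np.testing.assert_allclose(h, [0.5, 0, 0, 0.5], atol=1e-12)
        assert D == pytest.approx(0.25, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert info["converged"] and not info["flat"]

    def test_all_double_heterozygotes_flat(self):
        c = TwoLocusCounts(counts=np.array([[0, 0, 0], [0, 20, 0], [0, 0, 0]],
                                           dtype=float), n=20)
        h, D, r2, info = em_gametic_ld(c)
        assert info["flat"]
        assert D == 0.0 and r2 == 0.0

    def test_consistency_on_large_rug_sample(self):
        gm, truth = simulate_rug([0.35, 0.15, 0.15, 0.35], 100_000, seed=29)
        c = two_locus_counts(gm, 0, 1)
        _, D, r2, info = em_gametic_ld(c)
        assert info["converged"]
        assert D == pytest.approx(truth.d_gametic, abs=0.01)
        assert r2 == pytest.approx(0.16, abs=0.02)

    def test_em_matches_direct_likelihood_maximization(self):
        """EM haplotype frequencies maximize the multinomial likelihood:
        cross-check against a derivative-free optimizer on a sampled table."""
        from scipy.optimize import minimize

        gm, _ = simulate_rug([0.4, 0.2, 0.1, 0.3], 2000, seed=41)
        c = two_locus_counts(gm, 0, 1)
        h_em, _, _, info = em_gametic_ld(c)
        assert info["converged"]

        def nll(x):
            h = np.array([x[0], x[1], x[2], 1 - x.sum()])
            if (h <= 0).any():
                return 1e9
            P = rug_genotype_probs(h)
            return -(c.counts * np.log(P + 1e-300)).sum()

        res = minimize(nll, h_em[:3] + 0.01, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(h_em[:3], res.x, atol=5e-5)

    def test_preserves_allele_frequencies(self):
        rng = np.random.default_rng(7)
        P = rng.dirichlet(np.ones(9)).reshape(3, 3)
        c = TwoLocusCounts.from_probs(P)
        h, D, _, _ = em_gametic_ld(c)
        s = table_statistics(P)
        assert h[0] + h[1] == pytest.approx(s["p_A"], abs=1e-9)
        assert h[0] + h[2] == pytest.approx(s["p_B"], abs=1e-9)
        assert h.sum() == pytest.approx(1.0, abs=1e-12)
        assert D == pytest.approx(h[0] - s["p_A"] * s["p_B"], abs=1e-12)


class TestPairDisequilibria:
    def test_one_call_bundle_consistent(self, w1_counts):
        pdq = pair_disequilibria(w1_counts)
        assert pdq.delta_AB == pytest.approx(0.5)
        assert pdq.r2_gld == pytest.approx(1.0)
        assert pdq.r2_cld == pytest.approx(1.0)
        assert pdq.r2_zld == pytest.approx(1.0)
        assert pdq.flags == []

    def test_r2_bounds_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            P = rng.dirichlet(np.ones(9)).reshape(3, 3)
            pdq = pair_disequilibria(TwoLocusCounts.from_probs(P))
            for r2 in (pdq.r2_gld, pdq.r2_cld, pdq.r2_zld):
                assert -1e-12 <= r2 <= 1 + 1e-12
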