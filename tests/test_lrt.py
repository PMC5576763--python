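import numpy as np
import pytest

import _oracles as orc
from eqtlcausal import (
    DegenerateInputError,
    ValidationError,
    encode_genotypes,
    llr_controlled,
    llr_correlation,
    llr_independence,
    llr_primary,
    llr_profile,
    llr_relevance,
    llr_secondary,
    supernormalize,
)
from eqtlcausal.lrt import group_stats


def _random_triple(rng, n=60, n_v=3, a_effect=0.6, b_effect=0.5):
    E = rng.integers(0, n_v, n)
    while len(np.unique(E)) < n_v:
        E = rng.integers(0, n_v, n)
    A = supernormalize(rng.normal(size=n) + a_effect * E)
    B = supernormalize(rng.normal(size=n) + b_effect * A + 0.2 * E)
    return E, encode_genotypes(E), A, B


class TestCorrelation:
    def test_exact_orthogonal_is_zero(self):
        # tie-paired A against alternating B: exact zero inner product
        A = supernormalize(np.repeat([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 2))
        B = np.tile([1.0, -1.0], 6)
        B = (B - B.mean()) / B.std()
        assert float(B @ A) == pytest.approx(0.0, abs=1e-12)
        assert llr_correlation(A, B) == pytest.approx(0.0, abs=1e-12)

    def test_self_correlation_clamped_large(self, rng):
        A = supernormalize(rng.normal(size=30))
        val = llr_correlation(A, A)
        assert np.isfinite(val) and val > 1e3

    def test_matches_numeric_ml(self, rng):
        A = supernormalize(rng.normal(size=50))
        B = supernormalize(rng.normal(size=50) + 0.7 * A)
        assert llr_correlation(A, B) == pytest.approx(
            orc.numeric_llr_correlation(A, B), abs=1e-6)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            llr_correlation(supernormalize(rng.normal(size=10)),
                            supernormalize(rng.normal(size=12)))

    def test_refuses_raw_input(self, rng):
        with pytest.raises(ValidationError):
            llr_correlation(rng.normal(3, 5, size=20), rng.normal(size=20))


class TestPrimarySecondary:
    def test_zero_when_group_means_zero(self):
        # two genotype groups, A antisymmetric within each group
        E = encode_genotypes(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        A = np.array([1.0, -1.0, 2.0, -2.0, 1.5, -1.5, 0.5, -0.5])
        A = (A - A.mean()) / A.std()
        assert llr_primary(E, A) == pytest.approx(0.0, abs=1e-9)

    def test_pure_group_signal_clamped_large(self):
        E = encode_genotypes(np.array([0] * 5 + [1] * 5))
        A = np.array([-1.0] * 5 + [1.0] * 5)
        val = llr_primary(E, A)
        assert np.isfinite(val) and val > 1e3

    def test_matches_numeric_ml(self, rng):
        E, ev, A, _ = _random_triple(rng, n=40)
        assert llr_primary(ev, A) == pytest.approx(
            orc.numeric_llr_primary(E, A), abs=1e-6)

    def test_secondary_equals_primary_on_b(self, rng):
        E, ev, A, B = _random_triple(rng)
        assert llr_secondary(ev, B) == pytest.approx(llr_primary(ev, B))

    def test_single_category_rejected(self, rng):
        ev = encode_genotypes(np.zeros(20, dtype=int))
        with pytest.raises(DegenerateInputError):
            llr_primary(ev, supernormalize(rng.normal(size=20)))


class TestConditionalFamily:
    def test_independence_matches_numeric_ml(self, rng):
        E, ev, A, B = _random_triple(rng)
        assert llr_independence(ev, A, B) == pytest.approx(
            orc.numeric_llr_independence(E, A, B), abs=1e-6)

    def test_relevance_matches_numeric_ml(self, rng):
        E, ev, A, B = _random_triple(rng)
        assert llr_relevance(ev, A, B) == pytest.approx(
            orc.numeric_llr_relevance(E, A, B), abs=1e-6)

    def test_controlled_matches_numeric_ml(self, rng):
        E, ev, A, B = _random_triple(rng)
        assert llr_controlled(ev, A, B) == pytest.approx(
            orc.numeric_llr_controlled(E, A, B), abs=1e-6)

    def test_relevance_zero_for_unrelated_b(self):
        # B orthogonal to A (tie-paired A, alternating B) with zero group
        # means: every empirical cross-moment vanishes exactly
        E = encode_genotypes(np.array([0, 0, 1, 1] * 3))
        A = supernormalize(np.repeat([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 2))
        B = np.tile([1.0, -1.0], 6)
        B = (B - B.mean()) / B.std()
        st = group_stats(E, A, B)
        assert st.rho_hat[0] == pytest.approx(0.0, abs=1e-12)
        assert st.sigmaAB[0] == pytest.approx(1.0, abs=1e-12)
        assert llr_relevance(E, A, B) == pytest.approx(0.0, abs=1e-9)

    def test_controlled_zero_for_pure_pleiotropy(self):
        # B depending on E only with rho + sigmaAB - 1 = 0 empirically:
        # choose A antisymmetric within groups so all cross moments vanish
        E = encode_genotypes(np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        A = np.array([1.0, -1.0, 2.0, -2.0, 1.0, -1.0, 2.0, -2.0])
        A = (A - A.mean()) / A.std()
        B = np.array([-1.0] * 4 + [1.0] * 4)  # pure group signal
        B = (B - B.mean()) / B.std()
        st = group_stats(E, A, B)
        assert st.rho_hat[0] + st.sigmaAB[0] - 1 == pytest.approx(0.0, abs=1e-12)
        assert llr_controlled(E, A, B) == pytest.approx(0.0, abs=1e-9)


class TestIdentitiesAndInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_identities(self, seed):
        rng = np.random.default_rng(seed)
        _, ev, A, B = _random_triple(rng)
        p = llr_profile(ev, A, B)
        assert p.llr4 == pytest.approx(p.llr2 + p.llr5, abs=1e-9)
        assert p.llr3 == pytest.approx(p.llr4 - p.llr0, abs=1e-9)

    def test_non_negativity(self, rng):
        for _ in range(20):
            _, ev, A, B = _random_triple(rng, n=30)
            p = llr_profile(ev, A, B)
            for t in range(6):
                assert p.by_test(t) >= -1e-9

    def test_permutation_invariance(self, rng):
        E, ev, A, B = _random_triple(rng)
        p1 = llr_profile(ev, A, B)
        perm = rng.permutation(A.size)
        p2 = llr_profile(encode_genotypes(E[perm]), A[perm], B[perm])
        for t in range(6):
            assert p2.by_test(t) == pytest.approx(p1.by_test(t), abs=1e-12)

    def test_profile_of_self_pair(self, rng):
        _, ev, A, _ = _random_triple(rng)
        p = llr_profile(ev, A, A)
        assert p.llr0 > 1e3  # clamp-limited
        assert p.llr2 == pytest.approx(p.llr1, abs=1e-9)

    def test_batch_equals_scalar(self, rng):
        _, ev, A, _ = _random_triple(rng, n=30)
        Bs = np.vstack([supernormalize(np.random.default_rng(s).normal(size=30))
                        for s in range(100)])
        prof = llr_profile(ev, A, Bs)
        for i in (0, 17, 99):
            scalar = llr_profile(ev, A, Bs[i])
            for t in (0, 2, 3, 4, 5):
                assert np.asarray(prof.by_test(t))[i] == pytest.approx(
                    scalar.by_test(t), abs=1e-12)

    def test_sigma_bounds(self, rng):
        _, ev, A, B = _random_triple(rng)
        st = group_stats(ev, A, B)
        assert -1e-9 <= st.sigmaA2 <= 1 + 1e-9
        assert np.all(st.sigmaB2 <= 1 + 1e-9) and np.all(st.sigmaB2 >= -1e-9)
        assert np.all(np.abs(st.rho_hat) <= 1 + 1e-9)
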