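import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from thncdf.datatypes import FingerprintSet, SimilarityMatrix
from thncdf.exceptions import AlignmentError, ValidationError
from thncdf.similarity import (
    FusionConfig,
    GipParams,
    compute_similarities,
    fuse_drug,
    fuse_target,
    gip_bandwidth,
    gip_kernel,
    tanimoto_matrix,
)

# --- independent scalar oracles -------------------------------------------


def tanimoto_oracle(a, b):
    """Exhaustive bit enumeration."""
    inter = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    union = sum(1 for x, y in zip(a, b) if x == 1 or y == 1)
    if union == 0:
        return None  # 0/0
    return inter / union


def gip_oracle(profiles, gamma_prime=1.0):
    """Scalar double loop over rows and coordinates."""
    m = len(profiles)
    total = 0.0
    for row in profiles:
        total += sum(v * v for v in row)
    gamma = gamma_prime / (total / m)
    K = [[0.0] * m for _ in range(m)]
    for i in range(m):
        for j in range(m):
            d2 = sum((profiles[i][c] - profiles[j][c]) ** 2 for c in range(len(profiles[i])))
            K[i][j] = math.exp(-gamma * d2)
    return np.array(K)


def fps_from_rows(rows):
    return FingerprintSet([f"D{i}" for i in range(len(rows))], np.array(rows))


# --- Tanimoto --------------------------------------------------------------


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        fps = fps_from_rows([[1, 0, 1, 0], [1, 0, 1, 0]])
        assert tanimoto_matrix(fps).S[0, 1] == 1.0

    def test_disjoint_nonzero_is_zero(self):
        fps = fps_from_rows([[1, 1, 0, 0], [0, 0, 1, 1]])
        assert tanimoto_matrix(fps).S[0, 1] == 0.0

    def test_worked_example_one_third(self):
        # bits {1,2} vs {1,3}: intersection 1, union 3
        a = [0] * 166
        b = [0] * 166
        a[1] = a[2] = 1
        b[1] = b[3] = 1
        assert tanimoto_oracle(a, b) == pytest.approx(1 / 3)
        fps = fps_from_rows([a, b])
        assert tanimoto_matrix(fps).S[0, 1] == pytest.approx(1 / 3, abs=1e-15)

    def test_zero_fingerprint_policy(self):
        fps = fps_from_rows([[0, 0, 0], [0, 0, 0], [1, 0, 0]])
        S = tanimoto_matrix(fps).S
        assert S[0, 1] == 0.0  # 0/0 defined as 0 off-diagonal
        assert S[0, 0] == 1.0 and S[1, 1] == 1.0
        assert S[0, 2] == 0.0

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(np.int8, st.tuples(st.integers(2, 6), st.just(166)), elements=st.integers(0, 1))
    )
    def test_matches_exhaustive_oracle(self, bits):
        fps = fps_from_rows(bits.tolist())
        S = tanimoto_matrix(fps).S
        for i in range(len(bits)):
            for j in range(len(bits)):
                expected = tanimoto_oracle(bits[i], bits[j])
                if expected is None:
                    expected = 1.0 if i == j else 0.0
                assert S[i, j] == pytest.approx(expected, abs=1e-12)


# --- GIP bandwidth and kernel ---------------------------------------------


class TestGipBandwidth:
    def test_worked_example_two_thirds(self):
        gamma = gip_bandwidth(np.array([[1, 0], [1, 1]]), 1.0)
        assert gamma == pytest.approx(2 / 3, abs=1e-15)

    def test_single_profile_quarter(self):
        assert gip_bandwidth(np.array([[1, 1, 1, 1]]), 1.0) == pytest.approx(0.25)

    def test_linear_in_gamma_prime(self):
        P = np.array([[1, 0, 1], [0, 1, 1]])
        assert gip_bandwidth(P, 2.0) == pytest.approx(2 * gip_bandwidth(P, 1.0))

    def test_all_zero_profiles_error(self):
        with pytest.raises(ValidationError, match="degenerate"):
            gip_bandwidth(np.zeros((3, 4)))


class TestGipKernel:
    def test_orthogonal_unit_profiles(self):
        K = gip_kernel(np.array([[1, 0], [0, 1]]), GipParams(1.0)).S
        assert K[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_unit_diagonal(self):
        rng = np.random.default_rng(0)
        P = rng.integers(0, 2, (6, 9))
        P[0] = 1  # ensure non-degenerate
        K = gip_kernel(P).S
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_zero_profile_policies(self):
        P = np.array([[0, 0], [0, 0], [1, 1]])
        formula = gip_kernel(P, GipParams(1.0, "formula")).S
        zero = gip_kernel(P, GipParams(1.0, "zero")).S
        assert formula[0, 1] == 1.0
        assert zero[0, 1] == 0.0
        assert zero[0, 0] == 1.0  # diagonal untouched

    @settings(max_examples=30, deadline=None)
    @given(
        arrays(np.int8, st.tuples(st.integers(1, 8), st.integers(1, 8)),
               elements=st.integers(0, 1)).filter(lambda a: a.sum() > 0)
    )
    def test_matches_scalar_oracle(self, profiles):
        K = gip_kernel(profiles.astype(float)).S
        expected = gip_oracle(profiles.tolist())
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(K, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_in_gamma_prime(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.integers(0, 2, (7, 11)).astype(float)
        P[0, 0] = 1
        lo = gip_kernel(P, GipParams(0.5)).S
        hi = gip_kernel(P, GipParams(2.0)).S
        off = ~np.eye(7, dtype=bool)
        assert (hi[off] <= lo[off] + 1e-15).all()


# --- fusion ----------------------------------------------------------------


def random_sim(n, seed, ids=None):
    rng = np.random.default_rng(seed)
    A = rng.random((n, n))
    S = (A + A.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(ids or [f"e{i}" for i in range(n)], S)


class TestFusion:
    def test_alpha_zero_is_first_argument(self):
        a, b = random_sim(5, 1), random_sim(5, 2)
        np.testing.assert_array_equal(fuse_drug(a, b, FusionConfig(0.0)).S, a.S)

    def test_alpha_one_is_second_argument(self):
        a, b = random_sim(5, 1), random_sim(5, 2)
        np.testing.assert_array_equal(fuse_drug(a, b, FusionConfig(1.0)).S, b.S)

    def test_midpoint(self):
        a = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        b = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        assert fuse_drug(a, b, FusionConfig(0.5)).S[0, 1] == pytest.approx(0.3)

    def test_fuse_target_midpoint(self):
        a = SimilarityMatrix(["x", "y"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        b = SimilarityMatrix(["x", "y"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert fuse_target(a, b, FusionConfig(0.5)).S[0, 1] == pytest.approx(0.75)

    def test_id_mismatch_lists_difference(self):
        a = random_sim(3, 1, ids=["a", "b", "c"])
        b = random_sim(3, 2, ids=["a", "b", "d"])
        with pytest.raises(AlignmentError, match="'c'.*'d'|'d'.*'c'"):
            fuse_drug(a, b)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_linear_in_alpha(self, alpha):
        a, b = random_sim(6, 3), random_sim(6, 4)
        s0 = fuse_drug(a, b, FusionConfig(0.0)).S
        s1 = fuse_drug(a, b, FusionConfig(1.0)).S
        s = fuse_drug(a, b, FusionConfig(alpha)).S
        np.testing.assert_allclose(s, s0 + alpha * (s1 - s0), atol=1e-12)


# --- end-to-end similarity pipeline ---------------------------------------


class TestComputeSimilarities:
    def test_shapes_and_invariants(self, synth_default):
        im, fps, dp, _ = synth_default
        sim_drug, sim_tar = compute_similarities(im, fps, dp)
        for sm in (sim_drug, sim_tar):
            assert np.abs(sm.S - sm.S.T).max() <= 1e-12
            assert sm.S.min() >= 0.0 and sm.S.max() <= 1.0
        np.testing.assert_allclose(np.diag(sim_drug.S), 1.0)

    def test_without_disease_data_falls_back(self, synth_default, caplog):
        im, fps, _, _ = synth_default
        with caplog.at_level("WARNING"):
            _, sim_tar = compute_similarities(im, fps, None)
        assert sim_tar.n == im.n_targets

    def test_missing_fingerprints_hard_error(self, synth_default):
        im, fps, dp, _ = synth_default
        short = FingerprintSet(fps.drug_ids[:-1], fps.bits[:-1])
        with pytest.raises(ValidationError, match="missing"):
            compute_similarities(im, short, dp)
        # opt-in zero substitution succeeds
        compute_similarities(im, short, dp, allow_missing_fingerprints=True)


class TestSmilesFingerprints:
    rdkit = pytest.importorskip("rdkit")

    def test_identical_smiles_identical_fingerprints(self):
        from thncdf.similarity import fingerprints_from_smiles

        fps = fingerprints_from_smiles([("D1", "CCO"), ("D2", "CCO")])
        assert fps.length == 166
        S = tanimoto_matrix(fps).S
        assert S[0, 1] == 1.0

    def test_unparseable_smiles_names_drug(self):
        from thncdf.similarity import fingerprints_from_smiles

        with pytest.raises(ValidationError, match="D1"):
            fingerprints_from_smiles([("D1", "")])
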