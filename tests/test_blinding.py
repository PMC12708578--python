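"""Givens-rotation blinding: oracles are dense matrix products."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedlsh import _ops, blinding
from fedlsh.errors import (
    InvalidConfigError,
    InvalidDimensionError,
    InvalidKeyError,
    ProtocolError,
)

from conftest import dense_rotation_product


class TestSampleGivens:
    def test_dim_two_has_single_index_pair(self, rng):
        rot = blinding.sample_givens(2, rng)
        assert (rot.i, rot.j) == (0, 1)
        assert 0 < rot.theta < 2 * np.pi

    def test_seeded_determinism(self):
        a = blinding.sample_givens(5, np.random.default_rng(7))
        b = blinding.sample_givens(5, np.random.default_rng(7))
        assert a == b

    def test_index_pairs_uniform(self, rng):
        """Each of the 6 pairs at dim=4 appears with frequency 1/6 ± 0.02."""
        draws = [blinding.sample_givens(4, rng) for _ in range(10_000)]
        counts = {}
        for rot in draws:
            counts[(rot.i, rot.j)] = counts.get((rot.i, rot.j), 0) + 1
        assert len(counts) == 6
        for n in counts.values():
            assert abs(n / 10_000 - 1 / 6) < 0.02

    def test_rejects_dim_below_two(self, rng):
        with pytest.raises(InvalidDimensionError):
            blinding.sample_givens(1, rng)


class TestRotationAsDense:
    def test_quarter_turn_in_plane(self):
        g = blinding.rotation_as_dense(blinding.GivensRotation(0, 1, np.pi / 2), 2)
        assert np.allclose(g, [[0, 1], [-1, 0]], atol=1e-12)

    def test_half_turn_on_outer_plane(self):
        g = blinding.rotation_as_dense(blinding.GivensRotation(0, 2, np.pi), 3)
        assert np.allclose(np.diag(g), [-1, 1, -1], atol=1e-12)
        assert np.allclose(g - np.diag(np.diag(g)), 0, atol=1e-12)

    def test_always_orthogonal(self, rng):
        for _ in range(20):
            dim = int(rng.integers(2, 30))
            g = blinding.rotation_as_dense(blinding.sample_givens(dim, rng), dim)
            assert np.max(np.abs(g.T @ g - np.eye(dim))) <= 1e-12


class TestApplyRotations:
    def test_empty_list_is_identity(self, rng):
        M = rng.normal(size=(4, 3))
        assert np.array_equal(blinding.apply_left_rotations(M, []), M)
        assert np.array_equal(blinding.apply_right_rotations(M, []), M)

    def test_single_left_rotation_on_identity(self):
        rot = blinding.GivensRotation(0, 1, np.pi / 2)
        out = blinding.apply_left_rotations(np.eye(2), [rot])
        assert np.allclose(out, [[0, 1], [-1, 0]], atol=1e-12)

    def test_single_right_rotation_on_identity(self):
        rot = blinding.GivensRotation(0, 1, np.pi / 2)
        out = blinding.apply_right_rotations(np.eye(2), [rot])
        assert np.allclose(out, [[0, 1], [-1, 0]], atol=1e-12)

    def test_left_matches_dense_oracle(self, rng):
        M = rng.normal(size=(8, 5))
        rots = [blinding.sample_givens(8, rng) for _ in range(6)]
        dense = dense_rotation_product(rots, 8) @ M
        assert np.max(np.abs(blinding.apply_left_rotations(M, rots) - dense)) <= 1e-10

    def test_right_matches_dense_oracle(self, rng):
        M = rng.normal(size=(5, 8))
        rots = [blinding.sample_givens(8, rng) for _ in range(6)]
        dense = M @ dense_rotation_product(rots, 8)
        assert np.max(np.abs(blinding.apply_right_rotations(M, rots) - dense)) <= 1e-10

    def test_out_of_range_rotation_rejected(self, rng):
        M = rng.normal(size=(3, 3))
        big = blinding.GivensRotation(0, 5, 1.0)
        with pytest.raises(InvalidKeyError):
            blinding.apply_left_rotations(M, [big])
        with pytest.raises(InvalidKeyError):
            blinding.apply_right_rotations(M, [big])

    def test_sparsity_contract(self, rng):
        """At most 4·(row-or-column length) scalar multiplications per rotation."""
        M = rng.normal(size=(12, 7))
        rots = [blinding.sample_givens(12, rng) for _ in range(5)]
        counter = _ops.OpCounter()
        with _ops.counting(counter), _ops.phase("left"):
            blinding.apply_left_rotations(M, rots)
        assert counter.counts["left"] <= 4 * 7 * len(rots)
        rots_r = [blinding.sample_givens(7, rng) for _ in range(5)]
        with _ops.counting(counter), _ops.phase("right"):
            blinding.apply_right_rotations(M, rots_r)
        assert counter.counts["right"] <= 4 * 12 * len(rots_r)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        dim=st.integers(2, 64),
        l=st.integers(1, 16),
        seed=st.integers(0, 2**20),
    )
    def test_rotation_products_stay_orthogonal(self, dim, l, seed):
        rng = np.random.default_rng(seed)
        rots = [blinding.sample_givens(dim, rng) for _ in range(l)]
        g = dense_rotation_product(rots, dim)
        assert np.max(np.abs(g.T @ g - np.eye(dim))) <= 1e-10


class TestKeygen:
    def test_seeded_determinism(self):
        a = blinding.keygen(4, 4, 2, np.random.default_rng(3))
        b = blinding.keygen(4, 4, 2, np.random.default_rng(3))
        assert a == b

    def test_alpha_bounded(self, rng):
        alphas = [blinding.keygen(3, 3, 1, rng).alpha for _ in range(1000)]
        assert all(0.5 <= a <= 2.0 for a in alphas)

    def test_minimal_dims_index_domains(self, rng):
        key = blinding.keygen(2, 3, 1, rng)
        assert (key.left_rotations[0].i, key.left_rotations[0].j) == (0, 1)
        right = (key.right_rotations[0].i, key.right_rotations[0].j)
        assert right in {(0, 1), (0, 2), (1, 2)}

    def test_rejects_degenerate_dims(self, rng):
        with pytest.raises(InvalidDimensionError):
            blinding.keygen(1, 4, 1, rng)
        with pytest.raises(InvalidConfigError):
            blinding.keygen(4, 4, 0, rng)

    def test_key_file_round_trip(self, rng, tmp_path):
        key = blinding.keygen(6, 9, 3, rng)
        path = tmp_path / "key.json"
        key.save(path, seed=42)
        assert blinding.BlindingKey.load(path) == key


class TestEncryptDecrypt:
    def test_hand_case_identity_data(self):
        """X=I2, alpha=2, quarter-turn rotations both sides -> -2·I."""
        rot = blinding.GivensRotation(0, 1, np.pi / 2)
        key = blinding.BlindingKey(
            alpha=2.0, left_rotations=(rot,), right_rotations=(rot,), m=2, d=2
        )
        X = blinding.FeatureMatrix(values=np.eye(2), row_ids=["a", "b"])
        Xp = blinding.encrypt_data(X, key)
        assert np.allclose(Xp.values, [[-2, 0], [0, -2]], atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        key = blinding.keygen(4, 4, 1, rng)
        X = blinding.FeatureMatrix(values=rng.normal(size=(3, 4)), row_ids=list("abc"))
        with pytest.raises(InvalidKeyError):
            blinding.encrypt_data(X, key)
        with pytest.raises(InvalidKeyError):
            blinding.encrypt_projection(rng.normal(size=(2, 5)), key)

    def test_norm_conservation(self, random_instance):
        X, W, key = random_instance()
        Xp = blinding.encrypt_data(X, key)
        Wp = blinding.encrypt_projection(W, key)
        assert np.isclose(
            np.linalg.norm(Xp.values), abs(key.alpha) * np.linalg.norm(X.values), atol=1e-10
        )
        assert np.isclose(
            np.linalg.norm(Wp.values), abs(key.alpha) * np.linalg.norm(W), atol=1e-10
        )
        Hp = blinding.encrypted_product(Wp, Xp)
        assert np.isclose(
            np.linalg.norm(Hp.values),
            key.alpha**2 * np.linalg.norm(W @ X.values.T),
            atol=1e-9,
        )

    def test_encrypt_matches_dense_oracle(self, random_instance, rng):
        X, W, key = random_instance()
        P = dense_rotation_product(key.left_rotations, key.m)
        Q = dense_rotation_product(key.right_rotations, key.d)
        assert np.max(
            np.abs(blinding.encrypt_data(X, key).values - P @ (key.alpha * X.values) @ Q)
        ) <= 1e-10
        assert np.max(
            np.abs(blinding.encrypt_projection(W, key).values - (key.alpha * W) @ Q)
        ) <= 1e-10

    def test_zero_projection_encrypts_to_zero(self, rng):
        key = blinding.keygen(4, 4, 2, rng)
        Wp = blinding.encrypt_projection(np.zeros((3, 4)), key)
        assert np.allclose(Wp.values, 0)


class TestEncryptedProduct:
    def test_dot_product_case(self):
        Wp = blinding.EncryptedMatrix(np.array([[0.0, 1.0]]), "projection")
        Xp = blinding.EncryptedMatrix(np.array([[3.0, 4.0]]), "data")
        assert np.allclose(blinding.encrypted_product(Wp, Xp).values, [[4.0]])

    def test_dimension_mismatch_is_protocol_error(self, rng):
        Wp = blinding.EncryptedMatrix(rng.normal(size=(2, 3)), "projection")
        Xp = blinding.EncryptedMatrix(rng.normal(size=(4, 5)), "data")
        with pytest.raises(ProtocolError):
            blinding.encrypted_product(Wp, Xp)


class TestVerifyProduct:
    def test_honest_tables_always_accepted(self, random_instance, rng):
        X, W, key = random_instance()
        Xp = blinding.encrypt_data(X, key)
        Wp = blinding.encrypt_projection(W, key)
        Hp = blinding.encrypted_product(Wp, Xp)
        assert all(blinding.verify_product(Hp, Wp, Xp, rng) for _ in range(200))

    def test_perturbed_entry_rejected(self, random_instance, rng):
        X, W, key = random_instance()
        Xp = blinding.encrypt_data(X, key)
        Wp = blinding.encrypt_projection(W, key)
        Hp = blinding.encrypted_product(Wp, Xp)
        bad = blinding.EncryptedHashTable(Hp.values.copy())
        bad.values[2, 3] += 1.0
        rejected = sum(
            not blinding.verify_product(bad, Wp, Xp, rng) for _ in range(200)
        )
        assert rejected == 200

    def test_zero_everything_accepted(self, rng):
        Hp = blinding.EncryptedHashTable(np.zeros((3, 4)))
        Wp = blinding.EncryptedMatrix(np.zeros((3, 2)), "projection")
        Xp = blinding.EncryptedMatrix(np.zeros((4, 2)), "data")
        assert blinding.verify_product(Hp, Wp, Xp, rng)


class TestRecover:
    def test_full_round_trip(self, rng):
        """Blind → cloud product → recover equals the direct product."""
        X = blinding.FeatureMatrix(
            values=rng.normal(size=(10, 6)), row_ids=[str(k) for k in range(10)]
        )
        W = rng.normal(size=(8, 6))
        key = blinding.keygen(10, 6, 4, rng)
        Hp = blinding.encrypted_product(
            blinding.encrypt_projection(W, key), blinding.encrypt_data(X, key)
        )
        rec = blinding.recover(Hp, key)
        assert np.max(np.abs(rec.values - W @ X.values.T)) <= 1e-9

    def test_zero_table_recovers_to_zero(self, rng):
        key = blinding.keygen(5, 4, 2, rng)
        rec = blinding.recover(blinding.EncryptedHashTable(np.zeros((3, 5))), key)
        assert np.allclose(rec.values, 0)

    def test_small_hand_case_against_oracle(self, rng):
        rot = blinding.GivensRotation(0, 1, 1.0)
        key = blinding.BlindingKey(1.0, (rot,), (rot,), m=2, d=2)
        X = blinding.FeatureMatrix(values=np.array([[1.0, 2.0], [3.0, 4.0]]), row_ids=["a", "b"])
        W = np.array([[0.5, -1.0]])
        Hp = blinding.encrypted_product(
            blinding.encrypt_projection(W, key), blinding.encrypt_data(X, key)
        )
        assert np.max(np.abs(blinding.recover(Hp, key).values - W @ X.values.T)) <= 1e-12

    def test_shape_mismatch_rejected(self, rng):
        key = blinding.keygen(5, 4, 2, rng)
        with pytest.raises(InvalidKeyError):
            blinding.recover(blinding.EncryptedHashTable(np.zeros((3, 4))), key)
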