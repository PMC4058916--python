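"""Salted hashing, GF(2^m) arithmetic, secure-sketch publish/recover."""

import hashlib

import numpy as np
import pytest

from cryptokin.genome_encoding import (
    EncodingParams,
    ReferenceGenome,
    build_genomic_set,
)
from cryptokin.secure_sketch import (
    DuplicateElementError,
    GF2m,
    ParamsMismatchError,
    PrivateSketch,
    ProtocolParams,
    attempt_recover,
    first_primitive_poly,
    get_field,
    leakage_bound,
    private_sketch,
    publish,
    read_secure_sketch,
    salted_hash,
    security_margin,
    write_secure_sketch,
)
from cryptokin.secure_sketch import _gf_mul_int, _odd_syndromes
from conftest import make_individual


class TestField:
    def test_first_primitive_polys_match_known_values(self):
        # x^2+x+1, x^3+x+1, x^4+x+1, x^8+x^4+x^3+x^2+1 (the conventional ones)
        assert first_primitive_poly(2) == 0b111
        assert first_primitive_poly(3) == 0b1011
        assert first_primitive_poly(4) == 0b10011
        assert first_primitive_poly(8) == 0x11D

    def test_table_mul_agrees_with_carryless_reference(self):
        f = get_field(8)
        rng = np.random.default_rng(0)
        a = rng.integers(0, 256, 300)
        b = rng.integers(0, 256, 300)
        ref = np.array([_gf_mul_int(int(x), int(y), f.poly) for x, y in zip(a, b)])
        assert np.array_equal(f.mul(a, b), ref)

    def test_inverse_and_pow(self):
        f = get_field(8)
        xs = np.arange(1, 256, dtype=np.uint32)
        assert np.all(f.mul(xs, f.inv(xs)) == 1)
        assert np.all(f.pow(xs, f.n) == 1)  # Lagrange: x^(2^m - 1) = 1

    def test_quadratic_solver_recovers_constructed_roots(self):
        f = get_field(8)
        rng = np.random.default_rng(1)
        for _ in range(50):
            r1, r2 = (int(x) for x in rng.integers(1, 256, 2))
            if r1 == r2:
                continue
            b = r1 ^ r2
            c = int(f.mul(np.uint32(r1), np.uint32(r2)))
            assert set(f.solve_quadratic(b, c)) == {r1, r2}


class TestSaltedHash:
    def test_deterministic_and_in_range(self):
        p = ProtocolParams(k=10, t=5, salt=12345)
        h = salted_hash(987654321, p)
        assert h == salted_hash(987654321, p)
        assert 0 <= h < 2**24

    def test_zero_element_zero_salt_matches_sha256_oracle(self):
        p = ProtocolParams(k=10, t=5, m=24, salt=0)
        expected = int.from_bytes(hashlib.sha256(b"\x00").digest(), "big") >> 232
        assert salted_hash(0, p) == expected

    def test_salt_enters_as_arithmetic_addend(self):
        p = ProtocolParams(k=10, t=5, m=24, salt=100)
        q = ProtocolParams(k=10, t=5, m=24, salt=0)
        assert salted_hash(5, p) == salted_hash(105, q)

    def test_salt_is_exactly_100_bits(self):
        p = ProtocolParams.generate(k=10, t=5, seed=3)
        assert p.salt_bits == 100
        assert 0 <= p.salt < 2**100
        with pytest.raises(ValueError):
            ProtocolParams(k=10, t=5, salt=2**100)

    def test_different_salts_give_different_sketches(self):
        ref = ReferenceGenome("r", (("c", 8),))
        enc = EncodingParams(segment_length=4, genome_length=8)
        gset = build_genomic_set(make_individual("i", {"c": ([1], [2])}), ref, enc)
        a = private_sketch(gset, ProtocolParams(k=4, t=2, salt=1))
        b = private_sketch(gset, ProtocolParams(k=4, t=2, salt=2))
        assert a.elements != b.elements

    def test_equal_sets_same_salt_equal_sketches(self):
        ref = ReferenceGenome("r", (("c", 8),))
        enc = EncodingParams(segment_length=4, genome_length=8)
        p = ProtocolParams(k=4, t=2, salt=77)
        g1 = build_genomic_set(make_individual("x", {"c": ([1], [2])}), ref, enc)
        g2 = build_genomic_set(make_individual("y", {"c": ([1], [2])}), ref, enc)
        assert private_sketch(g1, p).elements == private_sketch(g2, p).elements

    def test_single_bit_segment_difference_changes_element(self):
        ref = ReferenceGenome("r", (("c", 8),))
        enc = EncodingParams(segment_length=8, genome_length=8)
        p = ProtocolParams(k=2, t=1, salt=9)
        g1 = build_genomic_set(make_individual("x", {"c": ([1], [])}), ref, enc)
        g2 = build_genomic_set(make_individual("y", {"c": ([2], [])}), ref, enc)
        s1 = private_sketch(g1, p)
        s2 = private_sketch(g2, p)
        assert s1.elements[0] != s2.elements[0]


class TestPublish:
    def test_size_contract_small_field(self):
        p = ProtocolParams(k=5, t=4, m=8, salt=1)  # d = 2
        priv = PrivateSketch("a", (1, 2, 3, 4, 5), p)
        pub = publish(priv, p)
        assert len(pub.published) == p.d == 2
        assert pub.payload_bits == p.d * 8
        assert len(pub.payload_bytes()) == p.d * 8 // 8

    def test_empty_set_rejected(self):
        p = ProtocolParams(k=0, t=0, m=8, salt=1)
        with pytest.raises(ValueError):
            publish(PrivateSketch("a", (), p), p)

    def test_duplicates_rejected_by_default_dropped_on_request(self):
        p = ProtocolParams(k=4, t=2, m=8, salt=1)
        priv = PrivateSketch("a", (1, 1, 2, 3), p)
        with pytest.raises(DuplicateElementError):
            publish(priv, p)
        pub = publish(priv, p, on_collision="drop")
        assert len(pub.published) == p.d

    def test_syndromes_equal_bruteforce_power_sums(self):
        p = ProtocolParams(k=5, t=2, m=8, salt=1)  # d = 6
        elems = (3, 7, 19, 101, 250)
        pub = publish(PrivateSketch("a", elems, p), p)
        f = get_field(8)
        for i, syn in enumerate(pub.published, start=1):
            acc = 0
            for a in elems:
                v = 1
                for _ in range(2 * i - 1):
                    v = _gf_mul_int(v, a, f.poly)
                acc ^= v
            assert syn == acc


class TestRecovery:
    def test_self_recovery_empty_difference(self):
        p = ProtocolParams(k=6, t=4, m=8, salt=5)
        priv = PrivateSketch("a", (2, 4, 8, 16, 32, 64), p)
        res = attempt_recover(publish(priv, p), priv)
        assert res.success
        assert res.a_minus_b == () and res.b_minus_a == ()
        assert res.shared_secret is not None

    def test_params_mismatch_is_an_error_not_a_failure(self):
        pa = ProtocolParams(k=4, t=2, m=8, salt=1)
        pb = ProtocolParams(k=4, t=2, m=8, salt=2)
        pub = publish(PrivateSketch("a", (1, 2, 3, 4), pa), pa)
        with pytest.raises(ParamsMismatchError):
            attempt_recover(pub, PrivateSketch("b", (1, 2, 3, 4), pb))

    def test_failure_carries_no_payload(self):
        p = ProtocolParams(k=4, t=3, m=8, salt=1)  # d = 2
        pub = publish(PrivateSketch("a", (1, 2, 3, 4), p), p)
        res = attempt_recover(pub, PrivateSketch("b", (10, 20, 30, 40), p))
        assert not res.success
        assert res.a_minus_b is None and res.b_minus_a is None
        assert res.shared_secret is None

    @pytest.mark.parametrize("backend,radius_of_d", [("syndrome", 1.0), ("char_poly", 0.5)])
    def test_roundtrip_within_radius(self, backend, radius_of_d):
        p = ProtocolParams(k=10, t=6, m=8, salt=3)  # d = 8
        rng = np.random.default_rng(0)
        univ = rng.permutation(np.arange(1, 256))
        A = sorted(int(x) for x in univ[:10])
        n_move = int(p.d * radius_of_d) // 2
        B = sorted(A[n_move:] + [int(x) for x in univ[10 : 10 + n_move]])
        pub = publish(PrivateSketch("a", tuple(A), p), p, backend=backend)
        res = attempt_recover(pub, PrivateSketch("b", tuple(B), p))
        assert res.success
        assert list(res.a_minus_b) == sorted(set(A) - set(B))
        assert list(res.b_minus_a) == sorted(set(B) - set(A))

    def test_exhaustive_small_universe_oracle(self):
        """Success iff |A triangle B| <= d, with the exact difference, on
        hundreds of random GF(2^8) instances (brute-force verified)."""
        n_ok = n_fail = 0
        for trial in range(400):
            rng = np.random.default_rng(10_000 + trial)
            k = int(rng.integers(3, 21))
            d = 2 * int(rng.integers(1, 5))
            t = k - d // 2
            if t < 0:
                continue
            p = ProtocolParams(k=k, t=t, m=8, salt=17)
            univ = rng.permutation(np.arange(1, 256))
            A = set(int(x) for x in univ[:k])
            n_swap = int(rng.integers(0, d + 3))
            B = set(sorted(A)[n_swap:]) | {int(x) for x in univ[k : k + n_swap]}
            delta = len(A ^ B)
            pub = publish(PrivateSketch("a", tuple(sorted(A)), p), p)
            res = attempt_recover(pub, PrivateSketch("b", tuple(sorted(B)), p))
            assert res.success == (delta <= p.d), (trial, delta, p.d)
            if res.success:
                assert list(res.a_minus_b) == sorted(A - B)
                assert list(res.b_minus_a) == sorted(B - A)
                n_ok += 1
            else:
                n_fail += 1
        assert n_ok > 50 and n_fail > 50  # both outcomes well exercised


class TestLeakageAccounting:
    def test_leakage_is_d_times_m(self):
        assert leakage_bound(ProtocolParams(k=10, t=9, m=24, salt=0)) == 48
        assert leakage_bound(ProtocolParams(k=10, t=10, m=24, salt=0)) == 0
        human = ProtocolParams(k=200_000, t=25_390, m=24, salt=0)
        assert human.d == 349_220
        assert leakage_bound(human) == 8_381_280

    def test_security_margin_strict_inequality_at_100(self):
        p = ProtocolParams(k=10, t=9, m=24, salt=0)  # leak 48
        assert security_margin(149, p) == (101, True)
        assert security_margin(148, p) == (100, False)
        assert security_margin(0, p)[1] is False

    def test_negative_entropy_rejected(self):
        with pytest.raises(ValueError):
            security_margin(-1, ProtocolParams(k=2, t=1, m=8, salt=0))


def test_secure_sketch_file_roundtrip(tmp_path):
    p = ProtocolParams(k=6, t=3, m=8, salt=11)
    pub = publish(PrivateSketch("alice", (9, 18, 27, 36, 45, 54), p), p)
    f1 = tmp_path / "alice.sketch"
    write_secure_sketch(pub, str(f1))
    back = read_secure_sketch(str(f1))
    assert back == pub
    f2 = tmp_path / "alice2.sketch"
    write_secure_sketch(back, str(f2))
    assert f1.read_bytes() == f2.read_bytes()
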