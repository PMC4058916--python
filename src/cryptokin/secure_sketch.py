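"""Salted-hash sketches and secure sketches for private set comparison.

The privacy layer works in three steps:

1. **Private sketch** — every genomic-set element ``s`` is replaced by
   ``h_m(s + r)``: the first ``m`` bits (default 24) of SHA-256 of the
   canonical big-endian encoding of the arithmetic sum of the element and a
   public 100-bit salt ``r`` shared by the protocol instance.  The hashed
   multiset is the individual's private key.
2. **Secure sketch** — the published public key.  The default backend is the
   syndrome (PinSketch-style) construction for set difference: interpret
   each m-bit element as a member of GF(2^m) and publish the ``d`` odd power
   sums ``syn_i = sum_a a^(2i-1)`` plus a verification hash, where
   ``d = 2(k - t)`` is the decoding tolerance derived from the set size
   ``k`` and the relatedness threshold ``t``.  An alternative backend
   publishes the top ``d`` coefficients of the monic characteristic
   polynomial (the Juels--Sudan form); without list decoding its unique
   decoding radius is ``d // 2``.
3. **Recovery** — a second party combines its own private sketch with a
   published sketch.  If the symmetric difference of the two element sets
   has size at most the tolerance, BCH-style decoding (Berlekamp--Massey
   plus root finding) returns exactly that difference; the verification
   hash confirms the reconstruction.  Otherwise recovery fails and reveals
   nothing beyond "not related at this tolerance".

The published sketch reveals at most ``d * m`` bits; ``security_margin``
compares that leakage with a caller-supplied genome entropy estimate.
"""

from __future__ import annotations

import base64
import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome_encoding import GenomicSet

__all__ = [
    "ProtocolParams",
    "PrivateSketch",
    "SecureSketch",
    "RecoveryResult",
    "ParamsMismatchError",
    "DuplicateElementError",
    "GF2m",
    "get_field",
    "first_primitive_poly",
    "salted_hash",
    "private_sketch",
    "publish",
    "attempt_recover",
    "leakage_bound",
    "security_margin",
    "write_secure_sketch",
    "read_secure_sketch",
]

SALT_BITS = 100
DEFAULT_ELEMENT_BITS = 24


class ParamsMismatchError(ValueError):
    """Raised when two artifacts were produced under different protocol params."""


class DuplicateElementError(ValueError):
    """Raised when a strict set is required but duplicate elements remain."""


# ---------------------------------------------------------------------------
# GF(2^m) arithmetic
# ---------------------------------------------------------------------------


def _clmul_int(a: int, b: int) -> int:
    res = 0
    while b:
        if b & 1:
            res ^= a
        a <<= 1
        b >>= 1
    return res


def _polymod_int(a: int, f: int) -> int:
    df = f.bit_length() - 1
    while a.bit_length() - 1 >= df and a:
        a ^= f << (a.bit_length() - 1 - df)
    return a


def _gf_mul_int(a: int, b: int, f: int) -> int:
    return _polymod_int(_clmul_int(a, b), f)


def _gf_pow_int(a: int, e: int, f: int) -> int:
    res = 1
    while e:
        if e & 1:
            res = _gf_mul_int(res, a, f)
        a = _gf_mul_int(a, a, f)
        e >>= 1
    return res


def _poly_gcd_int(a: int, b: int) -> int:
    while b:
        a, b = b, _polymod_int(a, b)
    return a


def _prime_factors(n: int) -> List[int]:
    out = []
    p = 2
    while p * p <= n:
        if n % p == 0:
            out.append(p)
            while n % p == 0:
                n //= p
        p += 1
    if n > 1:
        out.append(n)
    return out


def _is_irreducible(f: int, m: int) -> bool:
    if _gf_pow_int(2, 1 << m, f) != 2:  # x^(2^m) == x mod f
        return False
    for p in _prime_factors(m):
        h = _gf_pow_int(2, 1 << (m // p), f) ^ 2  # x^(2^(m/p)) - x
        if _poly_gcd_int(f, h) != 1:
            return False
    return True


@lru_cache(maxsize=None)
def first_primitive_poly(m: int) -> int:
    """Lexicographically-first primitive polynomial of degree m over GF(2),
    encoded as an integer with bit i = coefficient of x^i."""
    if m < 1:
        raise ValueError("degree must be >= 1")
    if m == 1:
        return 0b11  # x + 1
    order = (1 << m) - 1
    qs = _prime_factors(order)
    for f in range((1 << m) + 1, 1 << (m + 1), 2):  # constant term must be 1
        if not _is_irreducible(f, m):
            continue
        if all(_gf_pow_int(2, order // q, f) != 1 for q in qs):
            return f
    raise RuntimeError(f"no primitive polynomial of degree {m} found")


class GF2m:
    """GF(2^m) with vectorized log/antilog-table arithmetic.

    The generator is x (guaranteed primitive by the choice of polynomial).
    Element 0 has no logarithm; vector operations mask it explicitly.
    """

    def __init__(self, m: int, poly: int | None = None):
        self.m = m
        self.order = 1 << m
        self.n = self.order - 1
        self.poly = poly if poly is not None else first_primitive_poly(m)
        if self.poly.bit_length() - 1 != m:
            raise ValueError("polynomial degree does not match m")
        self._build_tables()

    def _build_tables(self) -> None:
        n = self.n
        exp = np.zeros(n, dtype=np.uint32)
        exp[0] = 1
        filled = 1
        while filled < n:
            take = min(filled, n - filled)
            # alpha^filled, computed in int arithmetic
            c = _gf_pow_int(2, filled, self.poly)
            exp[filled : filled + take] = self._scalar_vec_mul(c, exp[:take])
            filled += take
        self.exp2 = np.concatenate([exp, exp]).astype(np.uint32)
        log = np.zeros(self.order, dtype=np.int64)
        log[exp.astype(np.int64)] = np.arange(n, dtype=np.int64)
        log[0] = 0  # sentinel; zero operands are always masked
        self.log = log

    def _scalar_vec_mul(self, c: int, v: np.ndarray) -> np.ndarray:
        """Carry-less scalar * vector multiply with modular reduction."""
        acc = np.zeros(v.shape, dtype=np.uint64)
        vv = v.astype(np.uint64)
        red = np.uint64(self.poly & self.n)
        mask = np.uint64(self.n)
        one = np.uint64(1)
        shift = np.uint64(self.m - 1)
        while c:
            if c & 1:
                acc ^= vv
            c >>= 1
            carry = vv >> shift  # 0 or 1
            vv = ((vv << one) & mask) ^ (carry * red)
        return acc.astype(np.uint32)

    # -- element ops (scalars or arrays) -----------------------------------

    def mul(self, a, b):
        a = np.asarray(a, dtype=np.uint32)
        b = np.asarray(b, dtype=np.uint32)
        out = self.exp2[self.log[a] + self.log[b]]
        out = np.where((a == 0) | (b == 0), np.uint32(0), out)
        return out if out.shape else np.uint32(out)

    def inv(self, a):
        a = np.asarray(a, dtype=np.uint32)
        if np.any(a == 0):
            raise ZeroDivisionError("inverse of 0 in GF(2^m)")
        out = self.exp2[(self.n - self.log[a]) % self.n]
        return out if out.shape else np.uint32(out)

    def pow(self, a, e: int):
        """a ** e (e >= 0), vectorized; 0**0 = 1."""
        a = np.asarray(a, dtype=np.uint32)
        if e == 0:
            out = np.ones(a.shape, dtype=np.uint32)
            return out if out.shape else np.uint32(1)
        idx = (self.log[a] * (e % self.n if e >= self.n else e)) % self.n
        out = self.exp2[idx]
        out = np.where(a == 0, np.uint32(0), out)
        return out if out.shape else np.uint32(out)

    # -- polynomial ops; coefficient arrays are uint32, index = degree -----

    @staticmethod
    def _trim(p: np.ndarray) -> np.ndarray:
        nz = np.nonzero(p)[0]
        return p[: nz[-1] + 1] if nz.size else p[:1] * 0

    def poly_eval(self, p: np.ndarray, xs) -> np.ndarray:
        xs = np.asarray(xs, dtype=np.uint32)
        acc = np.full(xs.shape, p[-1], dtype=np.uint32)
        for c in p[-2::-1]:
            acc = self.mul(acc, xs) ^ np.uint32(c)
        return acc

    def poly_divmod(self, a: np.ndarray, f: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        f = self._trim(np.asarray(f, dtype=np.uint32))
        df = len(f) - 1
        if df < 0 or f[-1] == 0:
            raise ZeroDivisionError("division by zero polynomial")
        r = np.array(a, dtype=np.uint32, copy=True)
        if len(r) - 1 < df:
            return np.zeros(1, dtype=np.uint32), self._trim(r)
        q = np.zeros(len(r) - df, dtype=np.uint32)
        log, exp2 = self.log, self.exp2
        log_inv_lead = (self.n - log[f[-1]]) % self.n
        nz = np.nonzero(f[:-1])[0]
        flog_nz = log[f[nz]]
        for i in range(len(r) - 1, df - 1, -1):
            c = r[i]
            if c:
                lc = (log[c] + log_inv_lead) % self.n
                q[i - df] = exp2[lc]
                if nz.size:
                    r[i - df + nz] ^= exp2[flog_nz + lc]
                r[i] = 0
        return self._trim(q), self._trim(r)

    def poly_mod(self, a: np.ndarray, f: np.ndarray) -> np.ndarray:
        return self.poly_divmod(a, f)[1]

    def poly_gcd(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = self._trim(np.asarray(a, dtype=np.uint32))
        b = self._trim(np.asarray(b, dtype=np.uint32))
        while len(b) > 1 or b[0] != 0:
            a, b = b, self.poly_mod(a, b)
        if a[-1] != 1 and a[-1] != 0:  # make monic
            a = self.mul(a, np.uint32(self.inv(a[-1])))
        return self._trim(np.asarray(a, dtype=np.uint32))

    def poly_sq_mod(self, p: np.ndarray, f: np.ndarray) -> np.ndarray:
        """p(x)^2 mod f(x); squaring is coefficient-wise in characteristic 2."""
        sq = np.zeros(2 * len(p) - 1, dtype=np.uint32)
        sq[::2] = self.mul(p, p)
        return self.poly_mod(sq, f)

    # -- quadratic solver (Artin-Schreier) ---------------------------------

    def _artin_schreier_pivots(self):
        """Gaussian pivots for solving y^2 + y = a, built once per field."""
        if not hasattr(self, "_as_pivots"):
            pivots: Dict[int, Tuple[int, int]] = {}
            for j in range(self.m):
                e = 1 << j
                img = int(self.mul(np.uint32(e), np.uint32(e))) ^ e
                pre = e
                while img:
                    b = img.bit_length() - 1
                    if b in pivots:
                        pimg, ppre = pivots[b]
                        img ^= pimg
                        pre ^= ppre
                    else:
                        pivots[b] = (img, pre)
                        img = 0
            self._as_pivots = pivots
        return self._as_pivots

    def solve_artin_schreier(self, a: int) -> Optional[int]:
        """One solution y of y^2 + y = a, or None (the other is y ^ 1)."""
        pivots = self._artin_schreier_pivots()
        y = 0
        while a:
            b = a.bit_length() - 1
            if b not in pivots:
                return None
            img, pre = pivots[b]
            a ^= img
            y ^= pre
        return y

    def solve_quadratic(self, b: int, c: int) -> Optional[Tuple[int, int]]:
        """Distinct roots of x^2 + b x + c, or None (b = 0 gives a double root)."""
        if b == 0:
            return None
        binv = np.uint32(self.inv(np.uint32(b)))
        a = int(self.mul(self.mul(np.uint32(c), binv), binv))
        y = self.solve_artin_schreier(a)
        if y is None:
            return None
        x1 = int(self.mul(np.uint32(b), np.uint32(y)))
        return (x1, x1 ^ b)

    # -- root finding ------------------------------------------------------

    def poly_mul(self, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        if len(q) < len(p):
            p, q = q, p
        out = np.zeros(len(p) + len(q) - 1, dtype=np.uint32)
        for i, c in enumerate(p):
            if c:
                out[i : i + len(q)] ^= self.mul(q, np.uint32(c))
        return out

    def poly_from_roots(self, roots: np.ndarray) -> np.ndarray:
        """Monic product of (x - r) via a balanced product tree."""
        leaves = [np.array([r, 1], dtype=np.uint32) for r in roots]
        if not leaves:
            return np.ones(1, dtype=np.uint32)
        while len(leaves) > 1:
            nxt = [
                self.poly_mul(leaves[i], leaves[i + 1]) if i + 1 < len(leaves) else leaves[i]
                for i in range(0, len(leaves), 2)
            ]
            leaves = nxt
        return leaves[0]

    def find_roots(
        self,
        sigma: np.ndarray,
        rng: np.random.Generator,
        candidates: Optional[np.ndarray] = None,
    ) -> Optional[np.ndarray]:
        """All roots of sigma if it splits into distinct linear factors over
        the field (0 may be among them); otherwise None.

        ``candidates`` are points known to the caller (its own set elements);
        roots found among them are divided out before the generic trace-based
        factorization, which dominates the cost otherwise.
        """
        sigma = self._trim(np.asarray(sigma, dtype=np.uint32))
        deg = len(sigma) - 1
        if deg <= 0:
            return None
        if sigma[-1] != 1:
            sigma = self.mul(sigma, np.uint32(self.inv(sigma[-1])))
        if self.order <= (1 << 16):
            xs = np.arange(self.order, dtype=np.uint32)
            vals = self.poly_eval(sigma, xs)
            roots = xs[vals == 0]
            return roots if len(roots) == deg else None
        orig_deg = deg
        roots: List[int] = []
        if sigma[0] == 0:
            roots.append(0)
            sigma = self._trim(sigma[1:])
            if sigma[0] == 0:
                return None  # repeated root 0
            deg -= 1
        if candidates is not None and len(candidates) and deg > 0:
            cand = np.unique(np.asarray(candidates, dtype=np.uint32))
            cand = cand[cand != 0]
            hits = cand[self.poly_eval(sigma, cand) == 0]
            if len(hits):
                g = self.poly_from_roots(hits)
                q, r = self.poly_divmod(sigma, g)
                if np.any(r):
                    return None  # a repeated candidate root; not squarefree
                roots.extend(int(v) for v in hits)
                sigma = q
                deg = len(sigma) - 1
        if deg > 0:
            got = self._all_roots(sigma, rng)
            if got is None:
                return None
            roots.extend(got)
        if len(set(roots)) != orig_deg:
            return None
        return np.array(sorted(roots), dtype=np.uint32)

    def _all_roots(self, f: np.ndarray, rng: np.random.Generator) -> Optional[List[int]]:
        """Roots of monic f via Berlekamp-trace splitting; None unless f is a
        product of deg(f) distinct linear factors."""
        deg = len(f) - 1
        if deg == 1:
            return [int(f[0])]
        # Frobenius images x^(2^i) mod f and the splitting-field check
        frob = [np.array([0, 1], dtype=np.uint32)]
        for i in range(1, self.m):
            frob.append(self.poly_sq_mod(frob[-1], f))
        xq = self.poly_sq_mod(frob[-1], f)  # x^(2^m) mod f
        chk = np.zeros(max(len(xq), 2), dtype=np.uint32)
        chk[: len(xq)] = xq
        chk[1] ^= 1
        if np.any(chk):
            return None  # f does not split into distinct linear factors
        # random trace polynomials T_c(x) = sum_i c^(2^i) x^(2^i) mod f;
        # a candidate that fails to split a factor also fails for its
        # sub-factors (all their roots share the same trace), so recursion
        # resumes at the next index rather than re-trying spent candidates.
        n_cand = 8 * max(4, int(math.log2(deg + 1)) + 2)
        cands = []
        for _ in range(n_cand):
            c = int(rng.integers(1, self.order))
            T = np.zeros(deg, dtype=np.uint32)
            ci = np.uint32(c)
            for i in range(self.m):
                fi = frob[i]
                T[: len(fi)] ^= self.mul(fi, ci)
                ci = self.mul(ci, ci)
            cands.append(T)
        roots: List[int] = []
        self._trace_split(f, cands, 0, roots)
        return roots

    def _trace_split(
        self, f: np.ndarray, cands: List[np.ndarray], start: int, roots: List[int]
    ) -> None:
        deg = len(f) - 1
        if deg == 0:
            return
        if deg == 1:
            roots.append(int(f[0]))  # monic: root = constant term
            return
        if deg == 2:
            pair = self.solve_quadratic(int(f[1]), int(f[0]))
            if pair is None:
                raise RuntimeError("quadratic factor without distinct roots")
            roots.extend(pair)
            return
        # Cache reductions in a per-node copy so descendants reduce from the
        # nearest ancestor's version rather than from the top polynomial.
        cands = list(cands)
        for idx in range(start, len(cands)):
            T = self.poly_mod(cands[idx], f)
            cands[idx] = T
            g = self.poly_gcd(f, T)
            dg = len(g) - 1
            if 0 < dg < deg:
                h = self.poly_divmod(f, g)[0]
                # pre-reduce a window of upcoming candidates so descendants
                # reduce from this node's degree (telescoping costs)
                if dg > 2 or deg - dg > 2:
                    for w in range(idx + 1, min(idx + 7, len(cands))):
                        cands[w] = self.poly_mod(cands[w], f)
                self._trace_split(g, cands, idx + 1, roots)
                self._trace_split(h, cands, idx + 1, roots)
                return
        raise RuntimeError("trace splitting exhausted its candidate pool")


_FIELD_CACHE: Dict[Tuple[int, int], GF2m] = {}


def get_field(m: int, poly: int | None = None) -> GF2m:
    key = (m, poly if poly is not None else first_primitive_poly(m))
    if key not in _FIELD_CACHE:
        _FIELD_CACHE[key] = GF2m(m, key[1])
    return _FIELD_CACHE[key]


# ---------------------------------------------------------------------------
# Protocol parameters and sketches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolParams:
    """Shared parameters of one protocol instance.

    ``salt`` is a public 100-bit random value common to every participant —
    identical genome segments must hash identically across individuals or no
    matching is possible.  ``k`` is the nominal set size (2 elements per
    segment), ``t`` the matched-element threshold for relatedness, and the
    decoding tolerance is ``d = 2 (k - t)``: two size-k sets share at least
    t elements exactly when their symmetric difference has size <= d.
    """

    k: int
    t: int
    m: int = DEFAULT_ELEMENT_BITS
    salt: int = 0
    field_poly: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("element width m must be >= 1")
        if not 0 <= self.t <= self.k:
            raise ValueError("threshold t must lie in [0, k]")
        if not 0 <= self.salt < (1 << SALT_BITS):
            raise ValueError(f"salt must be a {SALT_BITS}-bit value")
        if self.field_poly is None:
            object.__setattr__(self, "field_poly", first_primitive_poly(self.m))

    @property
    def d(self) -> int:
        return 2 * (self.k - self.t)

    @property
    def salt_bits(self) -> int:
        return SALT_BITS

    def field(self) -> GF2m:
        return get_field(self.m, self.field_poly)

    def digest(self) -> str:
        payload = json.dumps(
            {"m": self.m, "k": self.k, "t": self.t, "salt": self.salt,
             "poly": self.field_poly},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def salt_id(self) -> str:
        return hashlib.sha256(self.salt.to_bytes(13, "big")).hexdigest()[:12]

    @classmethod
    def generate(cls, k: int, t: int, m: int = DEFAULT_ELEMENT_BITS,
                 seed: int | None = None) -> "ProtocolParams":
        rng = np.random.default_rng(seed)
        salt = int.from_bytes(rng.bytes(13), "big") >> 4  # exactly 100 bits
        return cls(k=k, t=t, m=m, salt=salt)


def _canonical_int_bytes(v: int) -> bytes:
    if v < 0:
        raise ValueError("negative value")
    return v.to_bytes(max(1, (v.bit_length() + 7) // 8), "big")


def salted_hash(element: int, params: ProtocolParams) -> int:
    """First m bits of SHA-256 of the canonical encoding of element + salt."""
    digest = hashlib.sha256(_canonical_int_bytes(element + params.salt)).digest()
    return int.from_bytes(digest, "big") >> (256 - params.m)


def _canonical_set_hash(values: Sequence[int], m: int) -> bytes:
    nbytes = (m + 7) // 8
    h = hashlib.sha256()
    for v in sorted(values):
        h.update(int(v).to_bytes(nbytes, "big"))
    return h.digest()


@dataclass(frozen=True)
class PrivateSketch:
    """The private key: the multiset of salted m-bit hashes of set elements."""

    individual_id: str
    elements: Tuple[int, ...]
    params: ProtocolParams

    def __post_init__(self) -> None:
        top = 1 << self.params.m
        if any(not 0 <= e < top for e in self.elements):
            raise ValueError("element outside field range")

    @property
    def k(self) -> int:
        return len(self.elements)

    def distinct_values(self) -> List[int]:
        """Strict-set view for the field layer (hash collisions keep one copy)."""
        return sorted(set(self.elements))


def private_sketch(gset: GenomicSet, params: ProtocolParams) -> PrivateSketch:
    """Hash every element of the genomic set under the shared salt.

    Homozygous duplicate segments are disambiguated before hashing (see
    GenomicSet.distinct_elements).  A hash output of 0 is remapped to 1
    because the zero field element is invisible to power-sum syndromes; the
    remap is deterministic, hence consistent across individuals.
    """
    values = tuple(
        salted_hash(v, params) or 1 for v in gset.distinct_elements()
    )
    return PrivateSketch(gset.individual_id, values, params)


@dataclass(frozen=True)
class SecureSketch:
    """The public key: d field elements plus a verification hash."""

    individual_id: str
    backend: str  # "syndrome" or "char_poly"
    d: int
    published: Tuple[int, ...]
    verification_hash: bytes
    params_digest: str
    m: int
    field_poly: int
    salt_id: str

    @property
    def payload_bits(self) -> int:
        return self.d * self.m

    def payload_bytes(self) -> bytes:
        acc = 0
        for v in self.published:
            acc = (acc << self.m) | int(v)
        nbytes = (self.payload_bits + 7) // 8
        acc <<= nbytes * 8 - self.payload_bits
        return acc.to_bytes(nbytes, "big")


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of a recovery attempt.

    Failures deliberately carry no payload: nothing derived from the other
    party's elements may leak through an unsuccessful attempt.
    """

    status: str  # "success" | "failure"
    a_minus_b: Tuple[int, ...] | None = None
    b_minus_a: Tuple[int, ...] | None = None
    shared_secret: bytes | None = None

    @property
    def success(self) -> bool:
        return self.status == "success"

    @classmethod
    def failure(cls) -> "RecoveryResult":
        return cls(status="failure")


# ---------------------------------------------------------------------------
# Syndromes, publication, recovery
# ---------------------------------------------------------------------------


def _odd_syndromes(field: GF2m, elements: np.ndarray, d: int) -> np.ndarray:
    """Power sums syn_i = sum_a a^(2i-1), i = 1..d, over nonzero elements."""
    out = np.zeros(d, dtype=np.uint32)
    if len(elements) == 0 or d == 0:
        return out
    la = field.log[np.asarray(elements, dtype=np.uint32)].astype(np.int64)
    n = field.n
    for i in range(1, d + 1):
        idx = (la * ((2 * i - 1) % n)) % n
        out[i - 1] = np.bitwise_xor.reduce(field.exp2[idx])
    return out


def _full_syndromes(field: GF2m, odd: np.ndarray) -> np.ndarray:
    """S[1..2d] from the d odd power sums; S[2j] = S[j]^2 in characteristic 2.
    Returned array is 1-indexed conceptually: entry j-1 holds S[j]."""
    d = len(odd)
    S = np.zeros(2 * d, dtype=np.uint32)
    S[0::2] = odd  # S[1], S[3], ...
    for j in range(2, 2 * d + 1, 2):
        half = S[j // 2 - 1]
        S[j - 1] = field.mul(half, half)
    return S


def _berlekamp_massey(field: GF2m, S: np.ndarray) -> Tuple[np.ndarray, int]:
    """Minimal LFSR (error-locator Lambda, Lambda[0] = 1) for syndrome
    sequence S[0..N-1]; returns (coefficients low-to-high, L)."""
    N = len(S)
    C = np.zeros(N + 1, dtype=np.uint32)
    B = np.zeros(N + 1, dtype=np.uint32)
    C[0] = B[0] = 1
    L, gap, b = 0, 1, np.uint32(1)
    for n in range(N):
        if L:
            terms = field.mul(C[1 : L + 1], S[n - L : n][::-1] if L <= n else
                              np.concatenate([S[n - 1 :: -1], np.zeros(L - n, dtype=np.uint32)]))
            delta = np.uint32(S[n] ^ np.bitwise_xor.reduce(terms))
        else:
            delta = np.uint32(S[n])
        if delta == 0:
            gap += 1
        else:
            coef = field.mul(delta, field.inv(b))
            if 2 * L <= n:
                T = C.copy()
                scaled = field.mul(B[: N + 1 - gap], coef)
                C[gap:] ^= scaled
                L, B, b, gap = n + 1 - L, T, delta, 1
            else:
                scaled = field.mul(B[: N + 1 - gap], coef)
                C[gap:] ^= scaled
                gap += 1
    return C[: L + 1], L


def publish(
    priv: PrivateSketch,
    params: ProtocolParams | None = None,
    *,
    backend: str = "syndrome",
    on_collision: str = "reject",
) -> SecureSketch:
    """Build the public secure sketch from a private sketch.

    The field layer requires a strict set.  Residual duplicates (truncated-
    hash collisions between distinct genomic elements) are rejected by
    default per the set contract; ``on_collision="drop"`` instead keeps one
    copy per value, which the pipeline uses since collisions are expected at
    rate ~k^2/2^(m+1) per individual and are covered by the documented
    matching margin.
    """
    params = params or priv.params
    if params.digest() != priv.params.digest():
        raise ParamsMismatchError("private sketch was built under different params")
    if len(priv.elements) == 0:
        raise ValueError("cannot publish a sketch of an empty set")
    distinct = priv.distinct_values()
    if len(distinct) != len(priv.elements) and on_collision == "reject":
        raise DuplicateElementError(
            f"{len(priv.elements) - len(distinct)} duplicate element(s) after disambiguation"
        )
    d = params.d
    if d <= 0:
        raise ValueError("tolerance d must be positive to publish")
    field = params.field()
    elems = np.array(distinct, dtype=np.uint32)
    if backend == "syndrome":
        published = tuple(int(v) for v in _odd_syndromes(field, elems, d))
    elif backend == "char_poly":
        published = tuple(_char_poly_top_coeffs(field, elems, d))
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return SecureSketch(
        individual_id=priv.individual_id,
        backend=backend,
        d=d,
        published=published,
        verification_hash=_canonical_set_hash(distinct, params.m),
        params_digest=params.digest(),
        m=params.m,
        field_poly=params.field_poly,
        salt_id=params.salt_id(),
    )


def _char_poly_top_coeffs(field: GF2m, elems: np.ndarray, d: int) -> List[int]:
    """Top d coefficients (below the monic leading 1) of prod (x - a)."""
    coeffs = np.zeros(1, dtype=np.uint32)
    coeffs[0] = 1  # monic, stored high-to-low
    for a in elems:
        nxt = np.zeros(len(coeffs) + 1, dtype=np.uint32)
        nxt[:-1] = coeffs
        nxt[1:] ^= field.mul(coeffs, np.uint32(a))
        coeffs = nxt
    top = coeffs[1 : d + 1]
    out = np.zeros(d, dtype=np.uint32)
    out[: len(top)] = top
    return [int(v) for v in out]


def _newton_power_sums(field: GF2m, e: np.ndarray) -> np.ndarray:
    """Power sums p_1..p_d from elementary symmetric e_1..e_d via Newton's
    identities in characteristic 2: p_k = sum_{i<k} e_i p_{k-i} (+ e_k, k odd)."""
    d = len(e)
    p = np.zeros(d + 1, dtype=np.uint32)
    for k in range(1, d + 1):
        acc = np.uint32(0)
        if k > 1:
            terms = field.mul(e[: k - 1], p[1:k][::-1])
            acc = np.bitwise_xor.reduce(terms)
        if k % 2 == 1:
            acc ^= e[k - 1]
        p[k] = acc
    return p[1:]


def _decode_difference(
    field: GF2m,
    S: np.ndarray,
    max_e: int,
    rng: np.random.Generator,
    candidates: Optional[np.ndarray] = None,
) -> Optional[np.ndarray]:
    """Locate the difference set from consecutive syndromes S[1..N].
    Returns the sorted nonzero roots, or None if decoding fails."""
    if not np.any(S):
        return np.empty(0, dtype=np.uint32)
    lam, L = _berlekamp_massey(field, S)
    if L == 0 or L > max_e or lam[L] == 0:
        return None
    sigma = lam[: L + 1][::-1].copy()  # roots of sigma are the difference elements
    roots = field.find_roots(sigma, rng, candidates=candidates)
    if roots is None or len(roots) != L or np.any(roots == 0):
        return None
    # confirm the located set reproduces every syndrome
    la = field.log[roots].astype(np.int64)
    for j in (1, len(S)):
        idx = (la * (j % field.n)) % field.n
        if np.bitwise_xor.reduce(field.exp2[idx]) != S[j - 1]:
            return None
    return roots


def attempt_recover(pub: SecureSketch, own: PrivateSketch) -> RecoveryResult:
    """Try to recover the symmetric difference between the published set and
    one's own set.  Succeeds iff |A(triangle)B| is within the backend's
    decoding radius AND the reconstructed set matches the verification hash.
    """
    params = own.params
    if pub.params_digest != params.digest():
        raise ParamsMismatchError(
            "secure sketch and private sketch belong to different protocol instances"
        )
    field = params.field()
    own_set = np.array(own.distinct_values(), dtype=np.uint32)
    d = pub.d
    # deterministic randomness for root splitting, derived from public data
    rng = np.random.default_rng(
        int.from_bytes(pub.verification_hash[:4], "big")
    )
    if pub.backend == "syndrome":
        own_syn = _odd_syndromes(field, own_set, d)
        delta_odd = np.asarray(pub.published, dtype=np.uint32) ^ own_syn
        S = _full_syndromes(field, delta_odd)
        max_e = d
    elif pub.backend == "char_poly":
        pub_p = _newton_power_sums(field, np.asarray(pub.published, dtype=np.uint32))
        own_p = _power_sums(field, own_set, d)
        S = pub_p ^ own_p
        max_e = d // 2
    else:
        return RecoveryResult.failure()
    diff = _decode_difference(field, S, max_e, rng, candidates=own_set)
    if diff is None:
        return RecoveryResult.failure()
    own_lookup = set(int(v) for v in own_set)
    b_minus_a = sorted(int(v) for v in diff if int(v) in own_lookup)
    a_minus_b = sorted(int(v) for v in diff if int(v) not in own_lookup)
    recovered = sorted((own_lookup - set(b_minus_a)) | set(a_minus_b))
    if _canonical_set_hash(recovered, params.m) != pub.verification_hash:
        return RecoveryResult.failure()
    secret = hashlib.sha256(b"cryptokin-secret" + _canonical_set_hash(recovered, params.m)).digest()
    return RecoveryResult(
        status="success",
        a_minus_b=tuple(a_minus_b),
        b_minus_a=tuple(b_minus_a),
        shared_secret=secret,
    )


def _power_sums(field: GF2m, elements: np.ndarray, d: int) -> np.ndarray:
    """All power sums p_1..p_d over nonzero elements."""
    out = np.zeros(d, dtype=np.uint32)
    if len(elements) == 0:
        return out
    la = field.log[np.asarray(elements, dtype=np.uint32)].astype(np.int64)
    for j in range(1, d + 1):
        idx = (la * (j % field.n)) % field.n
        out[j - 1] = np.bitwise_xor.reduce(field.exp2[idx])
    return out


# ---------------------------------------------------------------------------
# Leakage accounting
# ---------------------------------------------------------------------------


def leakage_bound(params: ProtocolParams) -> int:
    """Bits revealed by the published sketch (syndrome backend): d * m."""
    return params.d * params.m


def security_margin(assumed_entropy: float, params: ProtocolParams) -> Tuple[float, bool]:
    """Residual entropy after publication and whether it clears 100 bits.

    The genome-entropy estimate is supplied by the caller; the protocol is
    considered relatively secure only when the residual strictly exceeds
    100 bits of brute-force work.
    """
    if assumed_entropy < 0:
        raise ValueError("entropy estimate must be non-negative")
    residual = assumed_entropy - leakage_bound(params)
    return residual, residual > 100


# ---------------------------------------------------------------------------
# Serialization: JSON header line + base64 packed payload line
# ---------------------------------------------------------------------------

_SKETCH_VERSION = "1"


def write_secure_sketch(sk: SecureSketch, path: str) -> None:
    header = {
        "individual_id": sk.individual_id,
        "backend": sk.backend,
        "m": sk.m,
        "d": sk.d,
        "field_poly": sk.field_poly,
        "salt_id": sk.salt_id,
        "params_digest": sk.params_digest,
        "verification_hash": sk.verification_hash.hex(),
        "version": _SKETCH_VERSION,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        fh.write(base64.b64encode(sk.payload_bytes()).decode() + "\n")


def read_secure_sketch(path: str) -> SecureSketch:
    with open(path) as fh:
        header = json.loads(fh.readline())
        payload = base64.b64decode(fh.readline().strip())
    m, d = header["m"], header["d"]
    acc = int.from_bytes(payload, "big") >> (len(payload) * 8 - d * m)
    mask = (1 << m) - 1
    published = tuple((acc >> (m * (d - 1 - i))) & mask for i in range(d))
    return SecureSketch(
        individual_id=header["individual_id"],
        backend=header["backend"],
        d=d,
        published=published,
        verification_hash=bytes.fromhex(header["verification_hash"]),
        params_digest=header["params_digest"],
        m=m,
        field_poly=header["field_poly"],
        salt_id=header["salt_id"],
    )
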