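"""Minimum-free-energy RNA secondary structure prediction.

The energy model is a deliberately small, fully auditable subset of the
nearest-neighbor model:

* Watson-Crick + G:U wobble pairs only; stacking energies from an
  embedded doublet table (kcal/mol at 37 C).
* Hairpin loops carry a length-class initiation penalty; minimum loop
  size is 3 unpaired nt (so any pair (i, j) requires j - i >= 4).
* Bulges and internal loops cost a flat per-unpaired-nucleotide penalty
  (no stacking bonus across the loop).
* Multibranch loops cost a fixed closing penalty; branches and unpaired
  positions inside them are free.
* No dangles, no coaxial stacking, no pseudoknots.

Because the energy of a structure decomposes over loops, the Zuker-style
dynamic program in :func:`fold_mfe` is exact for this model, and
:func:`enumerate_min_energy` re-derives the optimum by brute-force
enumeration of every non-crossing pair set (practical up to 18 nt).
Energies will differ from full Turner-model folders in absolute value;
all screens built on top of this module are threshold-relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


_INF = 1e30
_EPS = 1e-6

#: minimum unpaired nucleotides in a hairpin loop
MIN_HAIRPIN_LOOP = 3
#: per-unpaired-nucleotide bulge / internal loop penalty (kcal/mol)
BULGE_NT_PENALTY = 1.0
#: fixed multibranch-loop closing penalty (kcal/mol)
MULTILOOP_CLOSE = 3.4
#: largest bulge/internal loop considered by the dynamic program
MAX_INTERIOR_UNPAIRED = 30

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_BASES = "ACGU"

# pair types: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5
_PAIR_TYPE = -np.ones((4, 4), dtype=np.int64)
for _t, (_x, _y) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_TYPE[_x, _y] = _t

# Watson-Crick stack doublets 5'-x x2-3' / 3'-y y2-5' (x:y and x2:y2 pair).
_WC_DOUBLETS = {
    ("A", "A", "U", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "U", "G", "A"): -2.08,
    ("C", "A", "G", "U"): -2.11,
    ("G", "U", "C", "A"): -2.24,
    ("G", "A", "C", "U"): -2.35,
    ("C", "G", "G", "C"): -2.36,
    ("G", "G", "C", "C"): -3.26,
    ("G", "C", "C", "G"): -3.42,
}
# close under strand-rotation symmetry: (x, x2, y, y2) == (y2, y, x2, x)
for (_x, _x2, _y, _y2), _e in list(_WC_DOUBLETS.items()):
    _WC_DOUBLETS[(_y2, _y, _x2, _x)] = _e

_PAIR_BASES = ["AU", "UA", "CG", "GC", "GU", "UG"]
_STACK = np.zeros((6, 6), dtype=np.float64)
for _i, _p in enumerate(_PAIR_BASES):
    for _j, _q in enumerate(_PAIR_BASES):
        _key = (_p[0], _q[0], _p[1], _q[1])
        if _key in _WC_DOUBLETS:
            _STACK[_i, _j] = _WC_DOUBLETS[_key]
        elif _i >= 4 and _j >= 4:  # wobble stacked on wobble
            _STACK[_i, _j] = -0.5
        else:  # one wobble pair in the stack
            _STACK[_i, _j] = -1.0

_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}


def hairpin_penalty(loop_len: int) -> float:
    """Hairpin-loop initiation energy for ``loop_len`` unpaired nt."""
    if loop_len < MIN_HAIRPIN_LOOP:
        return _INF
    if loop_len <= 9:
        return _HAIRPIN_INIT[loop_len]
    return _HAIRPIN_INIT[9] + 1.5 * math.log(loop_len / 9.0)


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int codes; T and U are synonymous."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


def pairable(x: str, y: str) -> bool:
    return _PAIR_TYPE[_CODE[x.upper()], _CODE[y.upper()]] >= 0


@dataclass(frozen=True)
class FoldResult:
    """A sequence with its predicted structure and free energy."""

    sequence: str
    structure: str
    energy: float
    pairs: tuple[tuple[int, int], ...] = field(default=())

    def pair_map(self) -> list[int]:
        """Partner index per position, -1 when unpaired."""
        pm = [-1] * len(self.sequence)
        for i, j in self.pairs:
            pm[i], pm[j] = j, i
        return pm


def _dot_bracket(n: int, pairs) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


# ---------------------------------------------------------------------------
# reference energy function (shared by the enumerator and the tests)
# ---------------------------------------------------------------------------

def structure_energy(seq: str, pairs) -> float:
    """Energy of an explicit non-crossing pair set under the embedded model.

    This is the defining scoring function: the dynamic program in
    :func:`fold_mfe` minimizes exactly this quantity.
    """
    codes = encode(seq)
    pairs = sorted(pairs)
    for i, j in pairs:
        if not (0 <= i < j < len(codes)):
            raise ValueError(f"pair ({i},{j}) out of bounds")
        if _PAIR_TYPE[codes[i], codes[j]] < 0:
            raise ValueError(f"({i},{j}) is not a legal base pair")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"pair ({i},{j}) closes a loop shorter than "
                             f"{MIN_HAIRPIN_LOOP} nt")
    # children[k] = pairs directly nested inside pairs[k]
    energy = 0.0
    for idx, (i, j) in enumerate(pairs):
        children = []
        for (p, q) in pairs:
            if i < p < q < j:
                # direct child iff no other pair encloses it within (i,j)
                if not any(i < a < p and q < b < j for (a, b) in pairs):
                    children.append((p, q))
        t1 = _PAIR_TYPE[codes[i], codes[j]]
        if not children:
            energy += hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            (p, q) = children[0]
            unpaired = (p - i - 1) + (j - q - 1)
            if unpaired == 0:
                t2 = _PAIR_TYPE[codes[p], codes[q]]
                energy += _STACK[t1, t2]
            else:
                energy += BULGE_NT_PENALTY * unpaired
        else:
            energy += MULTILOOP_CLOSE
    return energy


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def _enumerate_pairsets(codes: np.ndarray, i: int, j: int):
    """Yield every non-crossing pair list on [i, j] (inclusive)."""
    if i >= j:
        yield []
        return
    for rest in _enumerate_pairsets(codes, i + 1, j):
        yield rest
    for k in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
        if _PAIR_TYPE[codes[i], codes[k]] >= 0:
            for inner in _enumerate_pairsets(codes, i + 1, k - 1):
                for outer in _enumerate_pairsets(codes, k + 1, j):
                    yield [(i, k)] + inner + outer


def enumerate_min_energy(seq: str) -> FoldResult:
    """Exact MFE by exhaustive enumeration; refuses sequences > 18 nt.

    Ties are broken toward fewer pairs, then the lexicographically
    smallest dot-bracket string.
    """
    if len(seq) > 18:
        raise ValueError("enumerate_min_energy is limited to 18 nt")
    codes = encode(seq)
    n = len(codes)
    best = (0.0, 0, _dot_bracket(n, []), ())
    for pairs in _enumerate_pairsets(codes, 0, n - 1):
        e = structure_energy(seq, pairs)
        key = (round(e, 9), len(pairs), _dot_bracket(n, pairs))
        if key < best[:3]:
            best = (*key, tuple(sorted(pairs)))
    return FoldResult(seq, best[2], float(best[0]), best[3])


# ---------------------------------------------------------------------------
# dynamic program
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill_tables(codes, allowed, pair_type, stack, hp, bulge_nt, multi_close,
                 maxloop):  # pragma: no cover - compiled
    n = codes.shape[0]
    INF = 1e30
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: energy with (i, j) paired
            if span >= MIN_HAIRPIN_LOOP + 1:
                t1 = pair_type[codes[i], codes[j]]
                if t1 >= 0 and allowed[i] and allowed[j]:
                    best = hp[j - i - 1]
                    # stacked pair / bulge / internal loop
                    for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
                        du = k - i - 1
                        if du > maxloop:
                            break
                        lmin = k + MIN_HAIRPIN_LOOP + 1
                        for l in range(j - 1, lmin - 1, -1):
                            u = du + (j - l - 1)
                            if u > maxloop:
                                break
                            if V[k, l] < INF / 2:
                                if u == 0:
                                    t2 = pair_type[codes[k], codes[l]]
                                    cost = stack[t1, t2]
                                else:
                                    cost = bulge_nt * u
                                e = cost + V[k, l]
                                if e < best:
                                    best = e
                    # multibranch: >= 2 branches inside
                    for m in range(i + 1, j - 1):
                        if WM[i + 1, m] < INF / 2 and WM[m + 1, j - 1] < INF / 2:
                            e = multi_close + WM[i + 1, m] + WM[m + 1, j - 1]
                            if e < best:
                                best = e
                    V[i, j] = best
            # --- WM: >= 1 branch on [i, j], unpaired positions free
            best = WM[i + 1, j] if i + 1 <= j else INF
            for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i, l] < INF / 2:
                    tail = 0.0
                    if l < j and WM[l + 1, j] < 0.0:
                        tail = WM[l + 1, j]
                    e = V[i, l] + tail
                    if e < best:
                        best = e
            WM[i, j] = best
    # --- external loop
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        for i in range(0, j - MIN_HAIRPIN_LOOP):
            if V[i, j] < INF / 2:
                prev = W[i - 1] if i > 0 else 0.0
                e = prev + V[i, j]
                if e < best:
                    best = e
        W[j] = best
    return V, WM, W


def _eq(a: float, b: float) -> bool:
    return abs(a - b) < _EPS


class _Traceback:
    def __init__(self, codes, V, WM, W, hp):
        self.codes, self.V, self.WM, self.W, self.hp = codes, V, WM, W, hp
        self.pairs: list[tuple[int, int]] = []

    def external(self, j: int) -> None:
        while j >= 0:
            if j == 0:
                return
            if _eq(self.W[j], self.W[j - 1]):  # unpaired preferred on ties
                j -= 1
                continue
            found = False
            for i in range(0, j - MIN_HAIRPIN_LOOP):
                prev = self.W[i - 1] if i > 0 else 0.0
                if self.V[i, j] < _INF / 2 and _eq(self.W[j], prev + self.V[i, j]):
                    self.pair(i, j)
                    j = i - 1
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in external loop")

    def pair(self, i: int, j: int) -> None:
        self.pairs.append((i, j))
        codes, V, WM = self.codes, self.V, self.WM
        v = V[i, j]
        if _eq(v, self.hp[j - i - 1]):
            return
        t1 = _PAIR_TYPE[codes[i], codes[j]]
        for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
            du = k - i - 1
            if du > MAX_INTERIOR_UNPAIRED:
                break
            for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
                u = du + (j - l - 1)
                if u > MAX_INTERIOR_UNPAIRED:
                    break
                if V[k, l] < _INF / 2:
                    if u == 0:
                        t2 = _PAIR_TYPE[codes[k], codes[l]]
                        cost = _STACK[t1, t2]
                    else:
                        cost = BULGE_NT_PENALTY * u
                    if _eq(v, cost + V[k, l]):
                        self.pair(k, l)
                        return
        for m in range(i + 1, j - 1):
            if (WM[i + 1, m] < _INF / 2 and WM[m + 1, j - 1] < _INF / 2
                    and _eq(v, MULTILOOP_CLOSE + WM[i + 1, m] + WM[m + 1, j - 1])):
                self.multi(i + 1, m)
                self.multi(m + 1, j - 1)
                return
        raise AssertionError("traceback failure at pair")  # pragma: no cover

    def multi(self, i: int, j: int) -> None:
        V, WM = self.V, self.WM
        while i <= j:
            if i + 1 <= j and _eq(WM[i, j], WM[i + 1, j]):
                i += 1
                continue
            for l in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i, l] < _INF / 2:
                    tail = WM[l + 1, j] if l < j and WM[l + 1, j] < 0.0 else 0.0
                    if _eq(WM[i, j], V[i, l] + tail):
                        self.pair(i, l)
                        if tail < 0.0:
                            i = l + 1
                            break
                        return
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failure in multiloop")


@lru_cache(maxsize=4096)
def _fold_cached(seq: str, blocked: tuple[int, int] | None) -> FoldResult:
    codes = encode(seq)
    n = len(codes)
    allowed = np.ones(n, dtype=np.bool_)
    if blocked is not None:
        allowed[blocked[0]:blocked[1]] = False
    if n < MIN_HAIRPIN_LOOP + 2:
        return FoldResult(seq, "." * n, 0.0)
    hp = np.array([hairpin_penalty(x) if x >= MIN_HAIRPIN_LOOP else _INF
                   for x in range(n)])
    V, WM, W = _fill_tables(codes, allowed, _PAIR_TYPE, _STACK, hp,
                            BULGE_NT_PENALTY, MULTILOOP_CLOSE,
                            MAX_INTERIOR_UNPAIRED)
    mfe = min(0.0, float(W[n - 1]))
    if mfe > -_EPS:  # empty structure wins ties (fewer pairs)
        return FoldResult(seq, "." * n, 0.0)
    tb = _Traceback(codes, V, WM, W, hp)
    tb.external(n - 1)
    pairs = tuple(sorted(tb.pairs))
    return FoldResult(seq, _dot_bracket(n, pairs), mfe, pairs)


def fold_mfe(seq: str) -> FoldResult:
    """Predict the minimum-free-energy structure of ``seq``.

    Accepts RNA or DNA (T == U); returns a :class:`FoldResult` whose
    dot-bracket structure is in the original sequence orientation.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    return _fold_cached(seq.upper(), None)


def fold_constrained(seq: str, unpaired: tuple[int, int]) -> FoldResult:
    """MFE over structures where every position in ``unpaired`` is open.

    ``unpaired`` is a 0-based half-open interval.  The constrained energy
    is always >= the unconstrained :func:`fold_mfe` energy.
    """
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s, e = unpaired
    if not (0 <= s <= e <= len(seq)):
        raise ValueError(f"constraint interval {unpaired} out of bounds")
    return _fold_cached(seq.upper(), (s, e))


def opening_energy(seq: str, site: tuple[int, int]) -> float:
    """Energy cost of forcing ``site`` open: constrained minus free MFE."""
    return fold_constrained(seq, site).energy - fold_mfe(seq).energy


# ---------------------------------------------------------------------------
# intermolecular duplex
# ---------------------------------------------------------------------------

_DUPLEX_GAP_CAP = 10


def duplex_energy(a: str, b: str) -> float:
    """Minimum intermolecular-only pairing energy between ``a`` and ``b``.

    Both sequences are given 5'->3'; the duplex is antiparallel
    (``a[i]`` pairs ``b[j]`` with i increasing as j decreases).  No
    intramolecular pairs are considered.  Returns 0.0 when no pairing
    arrangement is favorable.
    """
    if len(a) > 40 or len(b) > 40:
        raise ValueError("duplex_energy is limited to sequences <= 40 nt")
    if not a or not b:
        return 0.0
    ca, cb = encode(a), encode(b)
    n, m = len(ca), len(cb)
    D = np.full((n, m), _INF)
    T = np.full((n, m), -1, dtype=np.int64)
    best_total = 0.0
    for i in range(n):
        for j in range(m - 1, -1, -1):
            t = _PAIR_TYPE[ca[i], cb[j]]
            if t < 0:
                continue
            T[i, j] = t
            best = 0.0  # open a new duplex at (i, j)
            for pi in range(max(0, i - 1 - _DUPLEX_GAP_CAP), i):
                for pj in range(j + 1, min(m, j + 2 + _DUPLEX_GAP_CAP)):
                    if D[pi, pj] < _INF / 2:
                        u = (i - pi - 1) + (pj - j - 1)
                        cost = (_STACK[T[pi, pj], t] if u == 0
                                else BULGE_NT_PENALTY * u)
                        e = D[pi, pj] + cost
                        if e < best:
                            best = e
            D[i, j] = best
            if best < best_total:
                best_total = best
    return float(best_total)
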