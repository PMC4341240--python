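"""Minimum-free-energy folding of short RNA/DNA sequences over nested structures.

The energy model is a deliberately small nearest-neighbor model: stacking
energies for Watson-Crick and G:U pairs, a flat terminal-loop penalty, and
length-linear bulge / interior / multibranch-loop penalties.  The constants
are pinned so that the dynamic program is exactly reproducible and can be
checked against exhaustive enumeration of all nested pairings on short
sequences.  Energies are in kcal/mol; more negative is more stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

INF = 1e9

# base codes
_BASE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair-type codes; -1 = not pairable
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_IDX = -np.ones((4, 4), dtype=np.int64)
for _k, (_a, _b) in enumerate([(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]):
    _PAIR_IDX[_a, _b] = _k

# stacking energy of inner pair q on outer pair p, kcal/mol
_WC_STACK = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4,
    ("GC", "AU"): -2.4, ("GC", "UA"): -2.2, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
}
STACK = np.zeros((6, 6))
for _i, _p in enumerate(PAIR_TYPES):
    for _j, _q in enumerate(PAIR_TYPES):
        if (_p, _q) in _WC_STACK:
            STACK[_i, _j] = _WC_STACK[(_p, _q)]
        elif _p in ("GU", "UG") and _q in ("GU", "UG"):
            STACK[_i, _j] = -0.5
        else:  # one wobble pair stacked on a Watson-Crick pair
            STACK[_i, _j] = -1.4

HAIRPIN_PENALTY = 5.0
BULGE_BASE = 3.0
BULGE_PER_NT = 1.0
INTERNAL_BASE = 4.0
INTERNAL_PER_NT = 0.5
MULTI_INIT = 4.0
MULTI_PER_UNPAIRED = 0.5
MULTI_PER_BRANCH = 0.0
MIN_LOOP = 3          # minimum unpaired bases in a hairpin loop
MAX_INTERIOR = 30     # cap on unpaired bases in a bulge/interior loop
_EPS = 1e-6

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 400


class FoldError(ValueError):
    pass


@dataclass(frozen=True)
class FoldResult:
    sequence: str
    structure: str
    mfe: float

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return structure_pairs(self.structure)


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_BASE[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise FoldError(f"non-ACGU(T) character in sequence: {exc.args[0]!r}") from exc


def _fill(codes, pair_idx, stack):
    """Zuker-style fill.  V[i,j]: best energy with (i,j) paired; WM[i,j]: best
    energy of a multiloop segment with >=1 branch; W[j]: best energy of prefix."""
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    W = np.zeros(n)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_idx[codes[i], codes[j]]
            if pt >= 0:
                best = HAIRPIN_PENALTY
                # stack / bulge / interior closed by (i,j) with inner pair (k,l)
                kmax = min(j - 1, i + MAX_INTERIOR + 2)
                for k in range(i + 1, kmax):
                    l1 = k - i - 1
                    for l in range(j - 1, k + MIN_LOOP, -1):
                        l2 = j - l - 1
                        if l1 + l2 > MAX_INTERIOR:
                            break
                        if V[k, l] >= INF:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = stack[pt, pair_idx[codes[k], codes[l]]]
                        elif l1 == 0 or l2 == 0:
                            e = BULGE_BASE + BULGE_PER_NT * (l1 + l2)
                        else:
                            e = INTERNAL_BASE + INTERNAL_PER_NT * (l1 + l2)
                        if e + V[k, l] < best:
                            best = e + V[k, l]
                # multibranch loop: >=2 branches inside (i,j)
                for m in range(i + 1, j - 1):
                    e = MULTI_INIT + WM[i + 1, m] + WM[m + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # WM
            wm = V[i, j] + MULTI_PER_BRANCH
            if WM[i + 1, j] + MULTI_PER_UNPAIRED < wm:
                wm = WM[i + 1, j] + MULTI_PER_UNPAIRED
            if WM[i, j - 1] + MULTI_PER_UNPAIRED < wm:
                wm = WM[i, j - 1] + MULTI_PER_UNPAIRED
            for m in range(i, j):
                if WM[i, m] + WM[m + 1, j] < wm:
                    wm = WM[i, m] + WM[m + 1, j]
            WM[i, j] = wm
    for j in range(n):
        w = W[j - 1] if j > 0 else 0.0
        for i in range(0, j):
            prev = W[i - 1] if i > 0 else 0.0
            if prev + V[i, j] < w:
                w = prev + V[i, j]
        if V[0, j] < w:
            w = V[0, j]
        W[j] = w
    return V, WM, W


try:  # optional JIT; the pure-Python fill is the reference path
    from numba import njit as _njit

    _fill_jit = _njit(cache=True)(_fill)
except Exception:  # pragma: no cover - numba present in normal installs
    _fill_jit = None

_use_jit = _fill_jit is not None


def _run_fill(codes):
    global _use_jit
    if _use_jit:
        try:
            return _fill_jit(codes, _PAIR_IDX, STACK)
        except Exception:  # pragma: no cover
            _use_jit = False
    return _fill(codes, _PAIR_IDX, STACK)


def _traceback(codes, V, WM, W):
    n = codes.shape[0]
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = []
    # external loop
    j = n - 1
    while j >= 0:
        prev = W[j - 1] if j > 0 else 0.0
        if j > 0 and abs(W[j] - W[j - 1]) < _EPS and W[j - 1] <= W[j] + _EPS:
            j -= 1
            continue
        hit = False
        for i in range(0, j + 1):
            p = W[i - 1] if i > 0 else 0.0
            if V[i, j] < INF and abs(p + V[i, j] - W[j]) < _EPS:
                stack.append(("V", i, j))
                j = i - 1
                hit = True
                break
        if not hit:
            j -= 1
    while stack:
        kind, i, j = stack.pop()
        if kind == "V":
            pairs.append((i, j))
            e = V[i, j]
            if abs(e - HAIRPIN_PENALTY) < _EPS:
                continue
            found = False
            pt = _PAIR_IDX[codes[i], codes[j]]
            kmax = min(j - 1, i + MAX_INTERIOR + 2)
            for k in range(i + 1, kmax):
                l1 = k - i - 1
                for l in range(j - 1, k + MIN_LOOP, -1):
                    l2 = j - l - 1
                    if l1 + l2 > MAX_INTERIOR:
                        break
                    if V[k, l] >= INF:
                        continue
                    if l1 == 0 and l2 == 0:
                        le = STACK[pt, _PAIR_IDX[codes[k], codes[l]]]
                    elif l1 == 0 or l2 == 0:
                        le = BULGE_BASE + BULGE_PER_NT * (l1 + l2)
                    else:
                        le = INTERNAL_BASE + INTERNAL_PER_NT * (l1 + l2)
                    if abs(le + V[k, l] - e) < _EPS:
                        stack.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for m in range(i + 1, j - 1):
                if abs(MULTI_INIT + WM[i + 1, m] + WM[m + 1, j - 1] - e) < _EPS:
                    stack.append(("WM", i + 1, m))
                    stack.append(("WM", m + 1, j - 1))
                    break
        else:  # WM segment
            e = WM[i, j]
            if abs(V[i, j] + MULTI_PER_BRANCH - e) < _EPS:
                stack.append(("V", i, j))
            elif abs(WM[i + 1, j] + MULTI_PER_UNPAIRED - e) < _EPS:
                stack.append(("WM", i + 1, j))
            elif abs(WM[i, j - 1] + MULTI_PER_UNPAIRED - e) < _EPS:
                stack.append(("WM", i, j - 1))
            else:
                for m in range(i, j):
                    if abs(WM[i, m] + WM[m + 1, j] - e) < _EPS:
                        stack.append(("WM", i, m))
                        stack.append(("WM", m + 1, j))
                        break
    return pairs


def fold(sequence: str) -> FoldResult:
    """Fold ``sequence`` (ACGU/T) into its minimum-energy nested structure.

    Returns a :class:`FoldResult` with the dot-bracket structure and the MFE
    in kcal/mol.  The empty structure has energy 0, so ``mfe <= 0`` always.
    """
    n = len(sequence)
    if not (MIN_FOLD_LEN <= n <= MAX_FOLD_LEN):
        raise FoldError(f"sequence length {n} outside [{MIN_FOLD_LEN}, {MAX_FOLD_LEN}]")
    codes = encode(sequence)
    V, WM, W = _run_fill(codes)
    mfe = float(W[n - 1])
    if mfe >= -_EPS:
        return FoldResult(sequence, "." * n, 0.0)
    pairs = _traceback(codes, V, WM, W)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult(sequence, "".join(db), mfe)


def structure_pairs(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise FoldError(f"bad dot-bracket character {c!r}")
    if stack:
        raise FoldError("unbalanced dot-bracket string")
    return sorted(pairs)


def enumerate_structures(n: int) -> list[list[tuple[int, int]]]:
    """All nested pairings of n positions with the minimum hairpin-loop size.
    Exponential: intended only for short oracle sequences (n <= ~16)."""
    memo: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < MIN_LOOP + 1:
            out = [[]]
        else:
            out = list(rec(i + 1, j))
            for k in range(i + MIN_LOOP + 1, j + 1):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append([(i, k)] + left + right)
        memo[(i, j)] = out
        return out

    return rec(0, n - 1)


def brute_force_mfe(sequence: str) -> float:
    """Exhaustive-enumeration MFE over all nested pairings; the independent
    oracle for the dynamic program on short sequences."""
    best = 0.0
    for pairs in enumerate_structures(len(sequence)):
        e = structure_energy(sequence, pairs)
        if e < best:
            best = e
    return best


def structure_energy(sequence: str, pairs) -> float:
    """Score an arbitrary nested structure under the same loop decomposition
    the dynamic program minimizes.  Used as the target of the enumeration
    oracle; infeasible structures (bad pairs, tight loops) score +inf."""
    codes = encode(sequence)
    pairs = sorted(pairs)
    pmap = {}
    for i, j in pairs:
        if not (0 <= i < j < len(codes)):
            return INF
        if _PAIR_IDX[codes[i], codes[j]] < 0:
            return INF
        if i in pmap or j in pmap:
            return INF
        pmap[i] = j
        pmap[j] = i
    energy = 0.0
    for i, j in pairs:
        # immediate children of (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in pmap and pmap[k] > k:
                children.append((k, pmap[k]))
                k = pmap[k] + 1
            elif k in pmap:
                return INF  # crossing pairs
            else:
                k += 1
        unpaired = (j - i - 1) - sum(l - a + 1 for a, l in children)
        if not children:
            if j - i - 1 < MIN_LOOP:
                return INF
            energy += HAIRPIN_PENALTY
        elif len(children) == 1:
            k, l = children[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                energy += STACK[_PAIR_IDX[codes[i], codes[j]],
                                _PAIR_IDX[codes[k], codes[l]]]
            elif l1 == 0 or l2 == 0:
                energy += BULGE_BASE + BULGE_PER_NT * (l1 + l2)
            else:
                energy += INTERNAL_BASE + INTERNAL_PER_NT * (l1 + l2)
        else:
            energy += (MULTI_INIT + MULTI_PER_UNPAIRED * unpaired
                       + MULTI_PER_BRANCH * len(children))
    return energy
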