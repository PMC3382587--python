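"""RNA secondary-structure prediction by free-energy minimization.

This module implements a Zuker-style dynamic program over nested secondary
structures (no pseudoknots) under a simple nearest-neighbor energy model:
stacking energies for the six canonical pairs (Watson-Crick plus G:U
wobbles) and linear penalties for hairpin, bulge, interior and multibranch
loops.  The parameter tables live in ``data/energy_params.yaml`` and are
deliberately small enough that the model can be evaluated on *any* nested
structure with :func:`structure_energy`, which makes the optimizer testable
against exhaustive enumeration at short lengths.

All sequences are handled in DNA alphabet (``T`` is folded as ``U``);
energies are reported in kcal/mol (negative = stable).  Internally the DP
works in integer centi-kcal to keep arithmetic exact.

The fill is accelerated with numba; the traceback (which is O(n) decisions)
runs in plain Python and is deterministic: candidate branches are examined
in a fixed order (hairpin, then interior loops by 5'-most inner pair, then
multiloop splits left to right), so ties always resolve toward the 5'-most
opening pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from numba import njit

__all__ = [
    "SecondaryStructure",
    "fold_rna",
    "structure_energy",
    "pair_index",
    "PARAMS",
]

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def _load_params() -> dict:
    with resources.files("ovamir").joinpath("data/energy_params.yaml").open() as fh:
        return yaml.safe_load(fh)


PARAMS = _load_params()

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair codes: 0 AU, 1 UA, 2 GC, 3 CG, 4 GU, 5 UG, -1 not pairable
_PT = np.full((5, 5), -1, dtype=np.int64)
_PT[0, 3] = 0  # A:T
_PT[3, 0] = 1  # T:A
_PT[2, 1] = 2  # G:C
_PT[1, 2] = 3  # C:G
_PT[2, 3] = 4  # G:T
_PT[3, 2] = 5  # T:G

_SCALE = 100  # centi-kcal integers inside the DP

STACK = np.asarray(
    [[int(round(v * _SCALE)) for v in row] for row in PARAMS["stack"]["matrix"]],
    dtype=np.int64,
)
_HA = int(round(PARAMS["hairpin"]["a"] * _SCALE))
_HB = int(round(PARAMS["hairpin"]["per_nt"] * _SCALE))
_BA = int(round(PARAMS["bulge"]["a"] * _SCALE))
_BB = int(round(PARAMS["bulge"]["per_nt"] * _SCALE))
_IA = int(round(PARAMS["internal"]["a"] * _SCALE))
_IB = int(round(PARAMS["internal"]["per_nt"] * _SCALE))
_MA = int(round(PARAMS["multiloop"]["a"] * _SCALE))
_MB = int(round(PARAMS["multiloop"]["per_branch"] * _SCALE))
_MC = int(round(PARAMS["multiloop"]["per_nt"] * _SCALE))
_MAXL = int(PARAMS["max_interior_span"])

_INF = np.int64(1) << 40
MIN_LOOP = 3
# shortest sequence that can contain a pair (MIN_LOOP enclosed + 2)
MIN_FOLD_LEN = MIN_LOOP + 2


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int codes (A,C,G,T/U -> 0..3; other -> 4)."""
    return np.array([_BASE.get(c, 4) for c in seq.upper()], dtype=np.int64)


def pair_index(a: str, b: str) -> int:
    """Pair code of bases ``a`` (5') and ``b`` (3'), or -1 if not pairable."""
    return int(_PT[_BASE.get(a.upper(), 4), _BASE.get(b.upper(), 4)])


# ---------------------------------------------------------------------------
# DP fill (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(enc, blocked, stack, pt, ha, hb, ba, bb, ia, ib, ma, mb, mc, maxl, inf):
    n = enc.shape[0]
    V = np.full((n, n), inf, dtype=np.int64)
    WM = np.full((n, n), inf, dtype=np.int64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # V: minimum energy with (i, j) paired
            if (
                span >= MIN_LOOP + 1
                and enc[i] < 4
                and enc[j] < 4
                and pt[enc[i], enc[j]] >= 0
                and not blocked[i]
                and not blocked[j]
            ):
                p = pt[enc[i], enc[j]]
                best = ha + hb * (j - i - 1)  # hairpin loop
                # stack / bulge / interior
                for k in range(i + 1, j - 1):
                    n1 = k - i - 1
                    if n1 > maxl:
                        break
                    for l in range(j - 1, k, -1):
                        n2 = j - l - 1
                        if n2 > maxl or n1 + n2 > maxl:
                            break
                        if V[k, l] < inf:
                            if n1 == 0 and n2 == 0:
                                c = stack[p, pt[enc[k], enc[l]]]
                            elif n1 == 0 or n2 == 0:
                                c = ba + bb * (n1 + n2)
                            else:
                                c = ia + ib * (n1 + n2)
                            v = V[k, l] + c
                            if v < best:
                                best = v
                # multiloop closure: >= 2 branches inside
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < inf and WM[k, j - 1] < inf:
                        v = ma + mb + WM[i + 1, k - 1] + WM[k, j - 1]
                        if v < best:
                            best = v
                V[i, j] = best
            # WM: multiloop segment with >= 1 branch
            best = inf
            if V[i, j] < inf:
                best = V[i, j] + mb
            if WM[i + 1, j] < inf and WM[i + 1, j] + mc < best:
                best = WM[i + 1, j] + mc
            if WM[i, j - 1] < inf and WM[i, j - 1] + mc < best:
                best = WM[i, j - 1] + mc
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < inf and WM[k, j] < inf:
                    v = WM[i, k - 1] + WM[k, j]
                    if v < best:
                        best = v
            WM[i, j] = best
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j):
            if V[i, j - 1] < inf:
                v = W[i] + V[i, j - 1]
                if v < best:
                    best = v
        W[j] = best
    return V, WM, W


# ---------------------------------------------------------------------------
# Traceback (Python; mirrors the fill order exactly)
# ---------------------------------------------------------------------------

def _trace(enc, V, WM, W, n):
    pairs: dict[int, int] = {}
    stack_ext = [("W", 0, n)]
    while stack_ext:
        kind, i, j = stack_ext.pop()
        if kind == "W":
            # W[j] over prefix [0, j); walk from the right
            while j > 0:
                if W[j] == W[j - 1]:
                    j -= 1
                    continue
                found = False
                for i0 in range(0, j):
                    if V[i0, j - 1] < _INF and W[j] == W[i0] + V[i0, j - 1]:
                        stack_ext.append(("V", i0, j - 1))
                        j = i0
                        found = True
                        break
                if not found:  # pragma: no cover - fill/trace mismatch guard
                    raise AssertionError("external traceback failed")
        elif kind == "V":
            pairs[i] = j
            pairs[j] = i
            p = _PT[enc[i], enc[j]]
            v = V[i, j]
            if v == _HA + _HB * (j - i - 1):
                continue
            done = False
            for k in range(i + 1, j - 1):
                n1 = k - i - 1
                if n1 > _MAXL:
                    break
                for l in range(j - 1, k, -1):
                    n2 = j - l - 1
                    if n2 > _MAXL or n1 + n2 > _MAXL:
                        break
                    if V[k, l] < _INF:
                        if n1 == 0 and n2 == 0:
                            c = STACK[p, _PT[enc[k], enc[l]]]
                        elif n1 == 0 or n2 == 0:
                            c = _BA + _BB * (n1 + n2)
                        else:
                            c = _IA + _IB * (n1 + n2)
                        if v == V[k, l] + c:
                            stack_ext.append(("V", k, l))
                            done = True
                            break
                if done:
                    break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if WM[i + 1, k - 1] < _INF and WM[k, j - 1] < _INF:
                    if v == _MA + _MB + WM[i + 1, k - 1] + WM[k, j - 1]:
                        stack_ext.append(("M", i + 1, k - 1))
                        stack_ext.append(("M", k, j - 1))
                        done = True
                        break
            if not done:  # pragma: no cover
                raise AssertionError("V traceback failed")
        else:  # WM segment
            v = WM[i, j]
            if V[i, j] < _INF and v == V[i, j] + _MB:
                stack_ext.append(("V", i, j))
                continue
            if WM[i + 1, j] < _INF and v == WM[i + 1, j] + _MC:
                stack_ext.append(("M", i + 1, j))
                continue
            if WM[i, j - 1] < _INF and v == WM[i, j - 1] + _MC:
                stack_ext.append(("M", i, j - 1))
                continue
            done = False
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < _INF and WM[k, j] < _INF and v == WM[i, k - 1] + WM[k, j]:
                    stack_ext.append(("M", i, k - 1))
                    stack_ext.append(("M", k, j))
                    done = True
                    break
            if not done:  # pragma: no cover
                raise AssertionError("WM traceback failed")
    return pairs


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecondaryStructure:
    """A nested RNA secondary structure with its model free energy."""

    dot_bracket: str
    pairs: dict  # position -> partner (symmetric)
    energy: float  # kcal/mol

    def __len__(self) -> int:
        return len(self.dot_bracket)


def fold_rna(sequence: str, unpaired: "set[int] | None" = None) -> SecondaryStructure:
    """Predict the minimum-free-energy nested structure of ``sequence``.

    Parameters
    ----------
    sequence:
        DNA or RNA string; ``T`` and ``U`` are equivalent.  ``N`` (or any
        other character) never pairs.
    unpaired:
        Optional set of 0-based positions constrained to stay unpaired
        (used by target-site accessibility scoring).

    Sequences too short to contain any pair (< ``MIN_FOLD_LEN``) are
    returned fully unpaired with energy 0.
    """
    n = len(sequence)
    if n < MIN_FOLD_LEN:
        return SecondaryStructure("." * n, {}, 0.0)
    enc = encode(sequence)
    blocked = np.zeros(n, dtype=np.bool_)
    if unpaired:
        for p in unpaired:
            if 0 <= p < n:
                blocked[p] = True
    V, WM, W = _fill(
        enc, blocked, STACK, _PT, _HA, _HB, _BA, _BB, _IA, _IB, _MA, _MB, _MC,
        np.int64(_MAXL), _INF,
    )
    energy = int(W[n])
    if energy >= 0:
        return SecondaryStructure("." * n, {}, 0.0)
    pairs = _trace(enc, V, WM, W, n)
    db = ["."] * n
    for i, j in pairs.items():
        if i < j:
            db[i] = "("
            db[j] = ")"
    return SecondaryStructure("".join(db), pairs, energy / _SCALE)


def min_energy(sequence: str, unpaired: "set[int] | None" = None) -> float:
    """Minimum model free energy (kcal/mol) without a traceback."""
    n = len(sequence)
    if n < MIN_FOLD_LEN:
        return 0.0
    enc = encode(sequence)
    blocked = np.zeros(n, dtype=np.bool_)
    if unpaired:
        for p in unpaired:
            if 0 <= p < n:
                blocked[p] = True
    _, _, W = _fill(
        enc, blocked, STACK, _PT, _HA, _HB, _BA, _BB, _IA, _IB, _MA, _MB, _MC,
        np.int64(_MAXL), _INF,
    )
    return min(int(W[n]), 0) / _SCALE


def structure_energy(sequence: str, pairs: dict) -> float:
    """Evaluate the model energy (kcal/mol) of an arbitrary nested structure.

    ``pairs`` maps each paired position to its partner (both directions).
    This is the reference evaluator of the energy model: the DP in
    :func:`fold_rna` minimizes exactly this quantity over all nested
    structures, which enumeration-based tests exploit.
    """
    enc = encode(sequence)
    opening = sorted(i for i, j in pairs.items() if i < j)
    total = 0
    for i in opening:
        j = pairs[i]
        if _PT[enc[i], enc[j]] < 0:
            raise ValueError(f"illegal pair {sequence[i]}:{sequence[j]} at ({i},{j})")
        if j - i - 1 < MIN_LOOP:
            raise ValueError(f"loop shorter than {MIN_LOOP} at ({i},{j})")
        # children: pairs directly enclosed by (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in pairs and pairs[k] > k:
                children.append((k, pairs[k]))
                k = pairs[k] + 1
            elif k in pairs:
                raise ValueError("pseudoknotted structure")
            else:
                k += 1
        p = _PT[enc[i], enc[j]]
        if not children:
            total += _HA + _HB * (j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += int(STACK[p, _PT[enc[k], enc[l]]])
            elif n1 == 0 or n2 == 0:
                total += _BA + _BB * (n1 + n2)
            else:
                total += _IA + _IB * (n1 + n2)
        else:
            unpaired_nt = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += _MA + _MB * (len(children) + 1) + _MC * unpaired_nt
    return total / _SCALE


def pairs_from_dot_bracket(db: str) -> dict:
    """Parse dot-bracket notation into a symmetric position->partner map."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs
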