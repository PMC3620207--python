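"""RNA secondary-structure prediction with a simple stacking-energy model.

The folder finds the nested (pseudoknot-free) structure minimising a
stack-additive energy: a base pair contributes its pair energy only when it
is directly enclosed by another pair (i.e. it stacks onto the pair outside
it); terminal pairs — the outermost pair of each helix — contribute 0.
Pair energies per stacked pair: GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 kcal/mol.
Hairpin loops must contain at least ``MIN_LOOP`` unpaired bases.

This is a deliberately transparent approximation, not a nearest-neighbour
thermodynamic model; ``FoldBackend`` lets a full thermodynamic folder
substitute wherever a (structure, energy) pair is consumed.
"""

from __future__ import annotations

from typing import Callable, Tuple

import numpy as np

MIN_LOOP = 3
INF = 1e9

#: energy (kcal/mol) a pair contributes when stacked onto an enclosing pair
PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

#: contract for a pluggable folding engine
FoldBackend = Callable[[str], Tuple[str, float]]

_VALID = set("ACGUT")


def _pair_matrix(seq: str) -> np.ndarray:
    """n x n matrix of pair energies; +INF where bases cannot pair."""
    n = len(seq)
    e = np.full((n, n), INF)
    for i in range(n):
        for j in range(n):
            val = PAIR_ENERGY.get((seq[i], seq[j]))
            if val is not None:
                e[i, j] = val
    return e


def fold(seq: str) -> Tuple[str, float]:
    """Fold an RNA/DNA sequence, returning (dot-bracket, energy in kcal/mol).

    Energy is ≤ 0; an unpairable sequence folds to all dots at 0.0.
    Raises ``ValueError`` on characters outside ACGU/T, naming the position.
    """
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid character {ch!r} at position {pos}")
    n = len(seq)
    if n == 0:
        return "", 0.0
    pe = _pair_matrix(seq)
    can = pe < INF / 2

    # W[i,j]  : best energy of any structure on seq[i..j]
    # Wna[i,j]: best energy with (i,j) NOT paired to each other
    # V[i,j]  : best energy given (i,j) paired, EXCLUDING e(i,j) itself —
    #           the enclosing pair (if any) adds it, so terminal pairs
    #           naturally score 0.
    W = np.zeros((n + 1, n + 1))
    Wna = np.zeros((n + 1, n + 1))
    V = np.full((n + 1, n + 1), INF)

    for l in range(1, n):  # span length j - i
        i_idx = np.arange(0, n - l)
        j_idx = i_idx + l
        # V: (i,j) paired (needs loop >= MIN_LOOP)
        if l > MIN_LOOP:
            inner = Wna[i_idx + 1, j_idx - 1].copy()
            stacked = V[i_idx + 1, j_idx - 1] + pe[i_idx + 1, j_idx - 1]
            v = np.minimum(inner, stacked)
            v[~can[i_idx, j_idx]] = INF
            V[i_idx, j_idx] = v
        # Wna: i unpaired, or i paired to some k < j
        wna = W[i_idx + 1, j_idx].copy()
        for m in range(MIN_LOOP + 1, l):
            cand = V[i_idx, i_idx + m] + W[i_idx + m + 1, j_idx]
            np.minimum(wna, cand, out=wna)
        Wna[i_idx, j_idx] = wna
        W[i_idx, j_idx] = np.minimum(wna, V[i_idx, j_idx])

    struct = ["."] * n
    _traceback(0, n - 1, "W", W, Wna, V, pe, struct)
    return "".join(struct), float(W[0, n - 1])


def _traceback(i: int, j: int, mode: str, W, Wna, V, pe, struct) -> None:
    """Recover one optimal structure from the filled matrices.

    ``mode`` names the matrix whose optimum the span [i, j] realises; all
    energies are exact sums of the half-integer pair terms, so float
    equality is safe.
    """
    if j - i < 1:
        return
    if mode == "W":
        if V[i, j] < INF / 2 and W[i, j] == V[i, j]:
            _traceback(i, j, "V", W, Wna, V, pe, struct)
        else:
            _traceback(i, j, "Wna", W, Wna, V, pe, struct)
        return
    if mode == "V":
        struct[i] = "("
        struct[j] = ")"
        a, b = i + 1, j - 1
        if b - a >= 1:
            if V[a, b] < INF / 2 and V[a, b] + pe[a, b] == V[i, j]:
                _traceback(a, b, "V", W, Wna, V, pe, struct)
            else:
                _traceback(a, b, "Wna", W, Wna, V, pe, struct)
        return
    # mode == "Wna": i unpaired, or i paired to k strictly inside the span
    if Wna[i, j] == W[i + 1, j]:
        _traceback(i + 1, j, "W", W, Wna, V, pe, struct)
        return
    for m in range(MIN_LOOP + 1, j - i):
        if V[i, i + m] < INF / 2 and V[i, i + m] + W[i + m + 1, j] == Wna[i, j]:
            _traceback(i, i + m, "V", W, Wna, V, pe, struct)
            _traceback(i + m + 1, j, "W", W, Wna, V, pe, struct)
            return
    raise AssertionError("traceback failed")  # pragma: no cover


def pair_partners(structure: str) -> np.ndarray:
    """Partner index per position from a dot-bracket string (-1 = unpaired).

    Raises ``ValueError`` on unbalanced brackets.
    """
    partner = np.full(len(structure), -1, dtype=int)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced ')' at position %d" % i)
            k = stack.pop()
            partner[k] = i
            partner[i] = k
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' at position %d" % stack[-1])
    return partner


def score_structure(seq: str, structure: str) -> float:
    """Energy of a given structure under the stacking model.

    Used for validation and by the enumeration oracle in the test-suite.
    """
    seq = seq.upper()
    partner = pair_partners(structure)
    total = 0.0
    for i, j in enumerate(partner):
        if j > i:
            if i - 1 >= 0 and j + 1 < len(seq) and partner[i - 1] == j + 1:
                total += PAIR_ENERGY[(seq[i], seq[j])]
    return total
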