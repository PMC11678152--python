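"""Low-level dynamic-programming kernels for RNA secondary structure.

The folding model is deliberately simple: a nested (pseudoknot-free)
structure is scored as the sum of base-pair energies (GC = -3, AU = -2,
GU = -1 kcal/mol) with a minimum hairpin loop of 3 unpaired nucleotides.
The same Nussinov-style kernel also folds consensus alignments, where the
"pair energy" of a column pair is an averaged, conservation-gated value
supplied by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# nucleotide encoding: A=0, C=1, G=2, U/T=3; anything else = 4 (never pairs)
_ENC = np.full(256, 4, dtype=np.int8)
for _c, _i in (("A", 0), ("C", 1), ("G", 2), ("U", 3), ("T", 3)):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

#: pair energies in kcal/mol; non-pairs get +1 (kernels treat >=0 as "no pair")
PAIR_ENERGY = np.full((5, 5), 1.0, dtype=np.float32)
for _a, _b, _e in ((2, 1, -3.0), (0, 3, -2.0), (2, 3, -1.0)):
    PAIR_ENERGY[_a, _b] = _e
    PAIR_ENERGY[_b, _a] = _e

MIN_HAIRPIN = 3  # minimum unpaired nucleotides enclosed by a pair


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes (A=0, C=1, G=2, U/T=3)."""
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def pair_energy_matrix(idx: np.ndarray) -> np.ndarray:
    """Dense n x n matrix of pair energies for a single encoded sequence."""
    return PAIR_ENERGY[idx[:, None], idx[None, :]]


@njit(cache=False, fastmath=True)
def nussinov_table(ep, min_hairpin):
    """Fill the minimum-energy DP table for arbitrary pair energies.

    ep[i, j] < 0 means positions i and j may pair with that energy.
    Returns the full table E with E[i, j] = minimum energy of i..j.
    """
    n = ep.shape[0]
    E = np.zeros((n, n), dtype=np.float32)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = E[i + 1, j]  # i unpaired
            if j - i > min_hairpin:
                e = ep[i, j]
                if e < 0.0:
                    v = e + (E[i + 1, j - 1] if j - 1 > i else np.float32(0.0))
                    if v < best:
                        best = v
            # bifurcation: i..k | k+1..j (also covers "j unpaired")
            for k in range(i, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return E


def mfe_energy(seq_idx: np.ndarray, min_hairpin: int = MIN_HAIRPIN) -> float:
    """Minimum folding energy of an encoded sequence (no traceback)."""
    n = seq_idx.shape[0]
    if n < min_hairpin + 2:
        return 0.0
    return float(nussinov_table(PAIR_ENERGY[seq_idx[:, None], seq_idx[None, :]], min_hairpin)[0, -1])


def traceback_pairs(E: np.ndarray, ep: np.ndarray, min_hairpin: int = MIN_HAIRPIN):
    """Recover one optimal set of pairs from a filled DP table."""
    n = E.shape[0]
    pairs = []
    if n == 0:
        return pairs
    stack = [(0, n - 1)]
    tol = 1e-4
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if abs(E[i, j] - E[i + 1, j]) < tol:
            stack.append((i + 1, j))
            continue
        if j - i > min_hairpin and ep[i, j] < 0:
            inner = E[i + 1, j - 1] if j - 1 > i else 0.0
            if abs(E[i, j] - (ep[i, j] + inner)) < tol:
                pairs.append((i, j))
                stack.append((i + 1, j - 1))
                continue
        done = False
        for k in range(i, j):
            if abs(E[i, j] - (E[i, k] + E[k + 1, j])) < tol:
                stack.append((i, k))
                stack.append((k + 1, j))
                done = True
                break
        if not done:  # numerical fallback; should not happen
            stack.append((i + 1, j))
    return pairs
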