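"""sRNA-mRNA interaction prediction and consensus target calling.

Two independent scorers evaluate each sRNA-mRNA pair:

* ``duplex_dp`` — minimum-free-energy intermolecular duplex under a
  nearest-neighbour stacking model (duplex initiation +4.1 kcal/mol,
  interior bulges of at most 2 nt penalised +3 kcal/mol per bulged
  nucleotide), constrained to interaction sites of at most ``max_len``
  nucleotides on either molecule;
* ``seed_extend`` — the best duplex anchored on a perfect Watson-Crick
  seed of at least ``seed_len`` consecutive pairs, extended without
  bulges.

A pair's "probability" is an empirical-null exceedance: the fraction of
dinucleotide-shuffled versions of the sRNA whose best duplex against the
same mRNA is less stable than the observed one. Consensus targets
require both scorers below the energy cutoff (default -20 kcal/mol) and
probability above 0.5; opposite-expression corroboration counts the
contrasts in which the sRNA and mRNA carry opposite DE calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from ._fold import encode
from .structure import dinucleotide_shuffle, rna

DUPLEX_INIT = 4.1  # kcal/mol, duplex initiation
BULGE_PENALTY = 3.0  # kcal/mol per bulged nucleotide
MIN_SRNA_LEN = 51  # sRNAs of <= 50 nt are excluded from target search
MAX_INTERACTION = 60
SEED_LEN = 7
ENERGY_CUT = -20.0
PROB_CUT = 0.5

# pair types: AU=0, CG=1, GC=2, UA=3, GU=4, UG=5 (first base from the sRNA)
_PAIR_IDX = np.full((5, 5), -1, dtype=np.int8)
for _a, _b, _p in ((0, 3, 0), (1, 2, 1), (2, 1, 2), (3, 0, 3), (2, 3, 4), (3, 2, 5)):
    _PAIR_IDX[_a, _b] = _p

_REV = {0: 3, 3: 0, 1: 2, 2: 1, 4: 5, 5: 4}

# nearest-neighbour stack free energies at 37 C (kcal/mol) for
# 5'-X1 X2-3' / 3'-Y1 Y2-5' with p1 = (X1,Y1), p2 = (X2,Y2).
# Watson-Crick block: Xia et al. style values; GU-containing stacks are
# approximate composites. Completed by the duplex-reversal symmetry
# T[p1][p2] = T[rev(p2)][rev(p1)].
_GIVEN = {
    (0, 0): -0.93, (0, 3): -1.10, (3, 0): -1.33,
    (1, 3): -2.08, (1, 0): -2.11, (2, 3): -2.24, (2, 0): -2.35,
    (1, 2): -2.36, (2, 2): -3.26, (2, 1): -3.42,
    (0, 4): -0.55, (0, 5): -1.36, (3, 4): -1.27, (3, 5): -1.00,
    (1, 4): -1.41, (1, 5): -2.11, (2, 4): -1.53, (2, 5): -2.51,
    (4, 4): -0.50, (4, 5): +0.47, (5, 4): -0.57,
}
STACK_ENERGY = np.full((6, 6), np.nan, dtype=np.float32)
for (_p1, _p2), _v in _GIVEN.items():
    STACK_ENERGY[_p1, _p2] = _v
    STACK_ENERGY[_REV[_p2], _REV[_p1]] = _v
assert not np.isnan(STACK_ENERGY).any()


@njit(cache=False)
def _duplex_dp(sr, mr, pair_idx, stack, max_len, init, bulge_pen):
    """Best-capped intermolecular duplex; returns (energy, si0, si1, sj0, sj1).

    The duplex is antiparallel: sRNA index increases 5'->3' while the
    paired mRNA index decreases. For each sRNA start the DP extends within
    a window of ``max_len`` sRNA positions; the mRNA-side span is capped
    by tracking the mRNA start of the incumbent path. Site intervals are
    half-open; a positive sentinel energy means no duplex was found.
    """
    n = sr.shape[0]
    m = mr.shape[0]
    INF = np.float32(1e9)
    best_e = INF
    bi0 = bi1 = bj0 = bj1 = -1
    H = np.empty((max_len, m), dtype=np.float32)
    M = np.empty((max_len, m), dtype=np.int32)
    for s in range(n):
        wmax = min(max_len, n - s)
        for w in range(wmax):
            for j in range(m):
                H[w, j] = INF
        for j in range(m):
            p = pair_idx[sr[s], mr[j]]
            if p >= 0:
                H[0, j] = init
                M[0, j] = j
        for w in range(1, wmax):
            p_here_row = sr[s + w]
            for j in range(m - 1):
                p = pair_idx[p_here_row, mr[j]]
                if p < 0:
                    continue
                acc = INF
                accM = -1
                # stack or a one-sided bulge of 1-2 nt on either strand
                for a, b in ((0, 0), (1, 0), (2, 0), (0, 1), (0, 2)):
                    wp = w - 1 - a
                    jp = j + 1 + b
                    if wp < 0 or jp >= m:
                        continue
                    h = H[wp, jp]
                    if h >= INF:
                        continue
                    if M[wp, jp] - j + 1 > max_len:
                        continue
                    if a == 0 and b == 0:
                        pp = pair_idx[sr[s + w - 1], mr[j + 1]]
                        e = h + stack[pp, p]
                    else:
                        e = h + bulge_pen * (a + b)
                    if e < acc:
                        acc = e
                        accM = M[wp, jp]
                if acc < INF:
                    H[w, j] = acc
                    M[w, j] = accM
                    if acc < best_e:
                        best_e = acc
                        bi0 = s
                        bi1 = s + w + 1
                        bj0 = j
                        bj1 = accM + 1
        # also allow single-pair duplexes from this start
        if wmax > 0:
            for j in range(m):
                if H[0, j] < best_e:
                    best_e = H[0, j]
                    bi0 = s
                    bi1 = s + 1
                    bj0 = j
                    bj1 = j + 1
        # starts beyond the first pairing position revisit sub-duplexes;
        # that redundancy is harmless for the minimum
    return best_e, bi0, bi1, bj0, bj1


@njit(cache=False)
def _duplex_dp_uncapped(sr, mr, pair_idx, stack, init, bulge_pen):
    """Unconstrained duplex DP; returns (energy, si0, si1, sj0, sj1).

    Whenever the unconstrained optimum's site already fits the
    interaction-length cap it equals the capped optimum, so this serves
    as a fast first tier for both scoring and null evaluation.
    """
    n = sr.shape[0]
    m = mr.shape[0]
    INF = np.float32(1e9)
    H = np.full((n, m), INF, dtype=np.float32)
    S0 = np.empty((n, m), dtype=np.int32)
    M0 = np.empty((n, m), dtype=np.int32)
    best_e = INF
    bi0 = bi1 = bj0 = bj1 = -1
    for i in range(n):
        for j in range(m - 1, -1, -1):
            p = pair_idx[sr[i], mr[j]]
            if p < 0:
                continue
            acc = init
            acc_s = i
            acc_m = j
            for a, b in ((0, 0), (1, 0), (2, 0), (0, 1), (0, 2)):
                ip = i - 1 - a
                jp = j + 1 + b
                if ip < 0 or jp >= m:
                    continue
                h = H[ip, jp]
                if h >= INF:
                    continue
                if a == 0 and b == 0:
                    pp = pair_idx[sr[i - 1], mr[j + 1]]
                    e = h + stack[pp, p]
                else:
                    e = h + bulge_pen * (a + b)
                if e < acc:
                    acc = e
                    acc_s = S0[ip, jp]
                    acc_m = M0[ip, jp]
            H[i, j] = acc
            S0[i, j] = acc_s
            M0[i, j] = acc_m
            if acc < best_e:
                best_e = acc
                bi0 = acc_s
                bi1 = i + 1
                bj0 = j
                bj1 = acc_m + 1
    return best_e, bi0, bi1, bj0, bj1


@dataclass
class InteractionPrediction:
    srna_id: str
    mrna_id: str
    energy: float
    probability: float  # NaN until computed against the null
    srna_site: tuple[int, int]
    mrna_site: tuple[int, int]
    scorer: str


def duplex_energy_dp(
    srna_seq: str,
    mrna_seq: str,
    max_len: int = MAX_INTERACTION,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Minimum duplex energy (duplex_dp scorer) and its site intervals."""
    sr = encode(rna(srna_seq))
    mr = encode(rna(mrna_seq))
    init = np.float32(DUPLEX_INIT)
    bp = np.float32(BULGE_PENALTY)
    e, i0, i1, j0, j1 = _duplex_dp_uncapped(sr, mr, _PAIR_IDX, STACK_ENERGY, init, bp)
    if i0 >= 0 and (i1 - i0 > max_len or j1 - j0 > max_len):
        e, i0, i1, j0, j1 = _duplex_dp(
            sr, mr, _PAIR_IDX, STACK_ENERGY, max_len, init, bp
        )
    if i0 < 0 or e >= 1e8:
        return 0.0, (0, 0), (0, 0)
    return float(e), (i0, i1), (j0, j1)


_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def duplex_energy_seed(
    srna_seq: str,
    mrna_seq: str,
    max_len: int = MAX_INTERACTION,
    seed_len: int = SEED_LEN,
) -> tuple[float, tuple[int, int], tuple[int, int]] | None:
    """Best seed-anchored duplex; None when no perfect seed exists."""
    sr = rna(srna_seq)
    mr = rna(mrna_seq)
    n, m = len(sr), len(mr)
    if n < seed_len or m < seed_len:
        return None
    # index mRNA k-mers; a seed pairs sr[i+t] with mr[j+k-1-t]
    index: dict[str, list[int]] = {}
    for j in range(m - seed_len + 1):
        index.setdefault(mr[j : j + seed_len], []).append(j)
    sr_idx = encode(sr)
    mr_idx = encode(mr)
    best = None
    for i in range(n - seed_len + 1):
        kmer = sr[i : i + seed_len]
        if any(c not in _WC for c in kmer):
            continue
        target = "".join(_WC[c] for c in kmer)[::-1]
        for j in index.get(target, ()):
            # pairs (i+t, j+seed_len-1-t); extend outward with stacks only
            lo_i, hi_i = i, i + seed_len - 1
            hi_j, lo_j = j + seed_len - 1, j
            while (
                lo_i > 0
                and hi_j + 1 < m
                and hi_i - lo_i + 2 <= max_len
                and _PAIR_IDX[sr_idx[lo_i - 1], mr_idx[hi_j + 1]] >= 0
            ):
                lo_i -= 1
                hi_j += 1
            while (
                hi_i + 1 < n
                and lo_j > 0
                and hi_i - lo_i + 2 <= max_len
                and _PAIR_IDX[sr_idx[hi_i + 1], mr_idx[lo_j - 1]] >= 0
            ):
                hi_i += 1
                lo_j -= 1
            # energy: initiation + stacks along the helix
            e = DUPLEX_INIT
            e_min = None
            site = None
            prev = _PAIR_IDX[sr_idx[lo_i], mr_idx[hi_j]]
            for t in range(1, hi_i - lo_i + 1):
                cur = _PAIR_IDX[sr_idx[lo_i + t], mr_idx[hi_j - t]]
                e += STACK_ENERGY[prev, cur]
                prev = cur
                if e_min is None or e < e_min:
                    e_min = e
                    site = ((lo_i, lo_i + t + 1), (hi_j - t, hi_j + 1))
            if e_min is None:
                e_min = e
                site = ((lo_i, lo_i + 1), (hi_j, hi_j + 1))
            if best is None or e_min < best[0]:
                best = (float(e_min), site[0], site[1])
    return best


def predict_targets(
    srna_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    max_len: int = MAX_INTERACTION,
    seed_len: int = SEED_LEN,
    min_srna_len: int = MIN_SRNA_LEN,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Run both scorers on every eligible sRNA against every mRNA.

    sRNAs shorter than ``min_srna_len`` are excluded with a reason code
    (second return value). Rows: srna_id, mrna_id, scorer, energy, site
    coordinates (half-open).
    """
    excluded: dict[str, str] = {}
    rows = []
    for sid, sseq in srna_seqs.items():
        if len(sseq) < min_srna_len:
            excluded[sid] = f"srna_too_short({len(sseq)}nt<{min_srna_len}nt)"
            continue
        for mid, mseq in mrna_seqs.items():
            if not mseq:
                raise ValueError(f"mRNA {mid} has empty sequence")
            e, ssite, msite = duplex_energy_dp(sseq, mseq, max_len)
            rows.append(
                dict(
                    srna_id=sid, mrna_id=mid, scorer="duplex_dp", energy=e,
                    srna_start=ssite[0], srna_end=ssite[1],
                    mrna_start=msite[0], mrna_end=msite[1],
                )
            )
            hit = duplex_energy_seed(sseq, mseq, max_len, seed_len)
            if hit is not None:
                e2, ssite2, msite2 = hit
                rows.append(
                    dict(
                        srna_id=sid, mrna_id=mid, scorer="seed_extend", energy=e2,
                        srna_start=ssite2[0], srna_end=ssite2[1],
                        mrna_start=msite2[0], mrna_end=msite2[1],
                    )
                )
    cols = [
        "srna_id", "mrna_id", "scorer", "energy",
        "srna_start", "srna_end", "mrna_start", "mrna_end",
    ]
    return pd.DataFrame(rows, columns=cols), excluded


def interaction_probability(
    srna_seq: str,
    mrna_seq: str,
    observed_energy: float,
    n_null: int = 100,
    rng: np.random.Generator | None = None,
    max_len: int = MAX_INTERACTION,
) -> float:
    """Empirical-null exceedance probability of an interaction energy.

    The null is the duplex_dp energy of dinucleotide-shuffled sRNAs
    against the same mRNA; the probability is the fraction of null
    energies strictly less stable than the observed one. NaN for a
    degenerate (constant) null.
    """
    rng = rng if rng is not None else np.random.default_rng()
    s = rna(srna_seq)
    null = np.empty(n_null)
    for i in range(n_null):
        null[i] = duplex_energy_dp(dinucleotide_shuffle(s, rng), mrna_seq, max_len)[0]
    if np.all(null == null[0]):
        return float("nan")
    return float((null > observed_energy).mean())


@dataclass
class TargetCall:
    srna_id: str
    mrna_id: str
    energy: float
    probability: float
    passes_energy: bool
    passes_probability: bool
    n_scorers_supporting: int
    oe_contrast_count: int
    consensus: bool
    global_regulator: bool = False


def call_targets(
    predictions: pd.DataFrame,
    srna_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    oe_pairs: pd.DataFrame | None = None,
    energy_cut: float = ENERGY_CUT,
    prob_cut: float = PROB_CUT,
    n_null: int = 100,
    rng: np.random.Generator | None = None,
    global_regulator_min_targets: int = 10,
) -> list[TargetCall]:
    """Consensus target calls from both scorers plus the null probability.

    A consensus target needs both scorers below ``energy_cut`` and a null
    exceedance probability above ``prob_cut``; the opposite-expression
    contrast count is attached when available. sRNAs with at least
    ``global_regulator_min_targets`` consensus targets are flagged as
    global regulators.
    """
    rng = rng if rng is not None else np.random.default_rng()
    oe_map: dict[tuple[str, str], int] = {}
    if oe_pairs is not None and len(oe_pairs):
        oe_map = {
            (r.srna_id, r.mrna_id): int(r.oe_contrast_count)
            for r in oe_pairs.itertuples()
        }
    calls: list[TargetCall] = []
    for (sid, mid), grp in predictions.groupby(["srna_id", "mrna_id"], sort=True):
        supporting = int((grp["energy"] < energy_cut).sum())
        best_energy = float(grp["energy"].min())
        passes_energy = best_energy < energy_cut
        prob = float("nan")
        passes_prob = False
        if supporting >= 2:
            # the null is only needed for candidates both scorers support
            prob = interaction_probability(
                srna_seqs[sid], mrna_seqs[mid], best_energy, n_null=n_null, rng=rng
            )
            passes_prob = bool(prob > prob_cut) if not np.isnan(prob) else False
        consensus = passes_energy and passes_prob and supporting >= 2
        calls.append(
            TargetCall(
                srna_id=sid,
                mrna_id=mid,
                energy=best_energy,
                probability=prob,
                passes_energy=passes_energy,
                passes_probability=passes_prob,
                n_scorers_supporting=supporting,
                oe_contrast_count=oe_map.get((sid, mid), 0),
                consensus=consensus,
            )
        )
    per_srna: dict[str, int] = {}
    for c in calls:
        if c.consensus:
            per_srna[c.srna_id] = per_srna.get(c.srna_id, 0) + 1
    for c in calls:
        c.global_regulator = per_srna.get(c.srna_id, 0) >= global_regulator_min_targets
    return calls


def targets_to_frame(calls: list[TargetCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
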