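"""Duplex energies, interaction gates and consensus target calling."""

import numpy as np
import pandas as pd
import pytest

from srnascan._fold import encode
from srnascan.targets import (
    BULGE_PENALTY,
    DUPLEX_INIT,
    STACK_ENERGY,
    _PAIR_IDX,
    _REV,
    _duplex_dp,
    call_targets,
    duplex_energy_dp,
    duplex_energy_seed,
    interaction_probability,
    predict_targets,
)

WC = str.maketrans("ACGU", "UGCA")


def revcomp(s):
    return s.translate(WC)[::-1]


def hand_nn_energy(srna_site, mrna_site):
    """Oracle: initiation plus hand-summed stack terms of a perfect duplex."""
    si, mi = encode(srna_site), encode(mrna_site)
    m = len(mrna_site)
    e = DUPLEX_INIT
    prev = _PAIR_IDX[si[0], mi[m - 1]]
    assert prev >= 0
    for t in range(1, len(srna_site)):
        cur = _PAIR_IDX[si[t], mi[m - 1 - t]]
        assert cur >= 0
        e += STACK_ENERGY[prev, cur]
        prev = cur
    return float(e)


def gc_rich(rng, n):
    return "".join(rng.choice(list("ACGU"), n, p=[0.1, 0.4, 0.4, 0.1]))


class TestStackTable:
    def test_reversal_symmetry(self):
        for p1 in range(6):
            for p2 in range(6):
                assert STACK_ENERGY[p1, p2] == pytest.approx(
                    STACK_ENERGY[_REV[p2], _REV[p1]]
                )

    def test_watson_crick_stacks_are_stabilising(self):
        assert (STACK_ENERGY[:4, :4] < 0).all()


class TestDuplexOracle:
    def test_agrees_with_hand_summed_oracle(self):
        """Both scorers hit the hand-summed NN energy on perfect duplexes."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            L = int(rng.integers(10, 30))
            s = gc_rich(rng, L)
            site = revcomp(s)
            mrna = "AAAA" + site + "AAAA"  # poly-A flanks cannot extend or seed
            srna = s + "A" * 45
            oracle = hand_nn_energy(s, site)
            e_dp, _, _ = duplex_energy_dp(srna, mrna)
            hit = duplex_energy_seed(srna, mrna)
            assert e_dp == pytest.approx(oracle, abs=0.01)
            assert hit is not None and hit[0] == pytest.approx(oracle, abs=0.01)

    def test_strong_site_clears_minus_20(self):
        rng = np.random.default_rng(3)
        s = gc_rich(rng, 25)
        mrna = gc_rich(rng, 80) + revcomp(s) + gc_rich(rng, 80)
        e_dp, _, _ = duplex_energy_dp(s + "A" * 40, mrna)
        e_seed = duplex_energy_seed(s + "A" * 40, mrna)[0]
        assert e_dp <= -20 and e_seed <= -20

    def test_energy_monotone_when_appending_complementary_stack(self):
        rng = np.random.default_rng(4)
        s = gc_rich(rng, 15)
        e1 = duplex_energy_dp(s + "A" * 45, "AAAA" + revcomp(s) + "AAAA")[0]
        s2 = s + "G"
        e2 = duplex_energy_dp(s2 + "A" * 45, "AAAA" + revcomp(s2) + "AAAA")[0]
        assert e2 <= e1

    def test_no_seed_means_no_seed_extend_hit(self):
        # mRNA lacking any 7-mer complement of the sRNA
        srna = "ACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGUACGU"
        mrna = "AAAAAAAAAAAAAAAAAAAAAAAAAAAAAA"
        assert duplex_energy_seed(srna, mrna) is None

    def test_interaction_cap_at_60_exact_boundary(self):
        rng = np.random.default_rng(8)
        s61 = gc_rich(rng, 61)
        e61, ssite, msite = duplex_energy_dp(s61, revcomp(s61))
        assert ssite[1] - ssite[0] <= 60 and msite[1] - msite[0] <= 60
        e60 = duplex_energy_dp(s61[:60], revcomp(s61[:60]))[0]
        # the best 60-nt sub-duplex of the 61-mer is at least as good as
        # the fixed first-60 window
        assert e61 <= e60 + 1e-3

    def test_capped_kernel_matches_two_tier_path(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            s = gc_rich(rng, 70)
            m = gc_rich(rng, 150)
            e_fast = duplex_energy_dp(s, m)[0]
            e_cap = float(
                _duplex_dp(
                    encode(s), encode(m), _PAIR_IDX, STACK_ENERGY, 60,
                    np.float32(DUPLEX_INIT), np.float32(BULGE_PENALTY),
                )[0]
            )
            assert e_fast == pytest.approx(e_cap, abs=1e-3)


class TestPredictTargets:
    def test_short_srna_excluded_with_reason(self):
        rng = np.random.default_rng(2)
        preds, excluded = predict_targets(
            {"short": gc_rich(rng, 45), "ok": gc_rich(rng, 60)},
            {"m": gc_rich(rng, 80)},
        )
        assert "short" in excluded and "srna_too_short" in excluded["short"]
        assert set(preds["srna_id"]) == {"ok"}

    def test_51nt_srna_is_eligible(self):
        rng = np.random.default_rng(2)
        preds, excluded = predict_targets(
            {"edge": gc_rich(rng, 51)}, {"m": gc_rich(rng, 80)}
        )
        assert excluded == {}
        assert (preds["srna_id"] == "edge").any()


class TestProbabilityAndConsensus:
    def test_planted_site_has_high_probability(self):
        rng = np.random.default_rng(5)
        s = gc_rich(rng, 25) + "A" * 50
        mrna = gc_rich(rng, 60) + revcomp(s[:25]) + gc_rich(rng, 60)
        e = duplex_energy_dp(s, mrna)[0]
        p = interaction_probability(s, mrna, e, rng=np.random.default_rng(0))
        assert p > 0.9

    def test_consensus_requires_both_scorers_and_probability(self):
        rng = np.random.default_rng(6)
        s = gc_rich(rng, 25) + "A" * 40
        target = gc_rich(rng, 50) + revcomp(s[:25]) + gc_rich(rng, 50)
        decoy = "".join(rng.choice(list("ACGU"), 120))
        srnas = {"s1": s}
        mrnas = {"hit": target, "decoy": decoy}
        preds, _ = predict_targets(srnas, mrnas)
        calls = call_targets(preds, srnas, mrnas, rng=np.random.default_rng(1))
        by_pair = {(c.srna_id, c.mrna_id): c for c in calls}
        hit = by_pair[("s1", "hit")]
        assert hit.consensus
        assert hit.n_scorers_supporting == 2 and hit.passes_probability

    def test_energy_passing_but_low_probability_is_not_consensus(self):
        calls = call_targets(
            pd.DataFrame(
                {
                    "srna_id": ["s", "s"],
                    "mrna_id": ["m", "m"],
                    "scorer": ["duplex_dp", "seed_extend"],
                    "energy": [-25.0, -25.0],
                    "srna_start": 0, "srna_end": 10,
                    "mrna_start": 0, "mrna_end": 10,
                }
            ),
            {"s": "ACGU" * 20},
            {"m": "ACGU" * 30},
            prob_cut=1.1,  # unreachable: equivalent to probability failing
            rng=np.random.default_rng(0),
        )
        assert calls[0].passes_energy and not calls[0].consensus

    def test_oe_counts_attached(self):
        oe = pd.DataFrame(
            {"srna_id": ["s"], "mrna_id": ["m"], "oe_contrast_count": [2]}
        )
        calls = call_targets(
            pd.DataFrame(
                {
                    "srna_id": ["s"], "mrna_id": ["m"], "scorer": ["duplex_dp"],
                    "energy": [-5.0],
                    "srna_start": 0, "srna_end": 10,
                    "mrna_start": 0, "mrna_end": 10,
                }
            ),
            {"s": "ACGU" * 20},
            {"m": "ACGU" * 30},
            oe_pairs=oe,
            rng=np.random.default_rng(0),
        )
        assert calls[0].oe_contrast_count == 2
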