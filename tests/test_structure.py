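"""Folding, shuffling, SCI, windowed screen and terminator detection."""

from collections import Counter
from functools import lru_cache

import numpy as np
import pytest

from srnascan.structure import (
    FamilyAlignment,
    ScreenPerformance,
    align_family,
    consensus_sci,
    detect_terminators,
    dinucleotide_shuffle,
    estimate_specificity_sensitivity,
    fold_mfe,
    randomize_alignment,
    scan_igr_windows,
    structure_z_score,
)

PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_mfe(seq):
    """Oracle: exhaustive enumeration of all nested structures (n <= ~14)."""

    @lru_cache(maxsize=None)
    def best(i, j):
        if j - i < 4:
            return 0.0
        # position i unpaired
        out = best(i + 1, j)
        # i paired with k
        for k in range(i + 4, j + 1):
            e = PAIR_E.get((seq[i], seq[k]))
            if e is None:
                continue
            out = min(out, e + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


def rand_rna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), n, p=p))


class TestFold:
    def test_unpairable_sequence_has_zero_energy(self):
        assert fold_mfe("AAAAAAA") == (0.0, set())

    def test_simple_helix(self):
        mfe, pairs = fold_mfe("GGGGAAAACCCC")
        assert mfe == -12.0
        assert pairs == {(0, 11), (1, 10), (2, 9), (3, 8)}

    def test_never_positive(self, rng):
        for _ in range(50):
            assert fold_mfe(rand_rna(rng, int(rng.integers(1, 40))))[0] <= 0.0

    def test_equals_exhaustive_enumeration(self, rng):
        """DP optimum equals brute-force enumeration for short sequences."""
        for _ in range(200):
            s = rand_rna(rng, int(rng.integers(5, 13)), gc=0.6)
            mfe, pairs = fold_mfe(s)
            assert mfe == pytest.approx(enumerate_mfe(s))
            # reported pairs are consistent with the reported energy
            assert sum(PAIR_E[(s[i], s[j])] for i, j in pairs) == pytest.approx(mfe)


def dinuc_vector(s):
    return Counter(zip(s, s[1:]))


class TestShuffle:
    def test_preserves_dinucleotide_counts(self, rng):
        seqs = [rand_rna(rng, int(rng.integers(10, 120))) for _ in range(20)]
        for s in seqs:
            for _ in range(50):
                sh = dinucleotide_shuffle(s, rng)
                assert dinuc_vector(sh) == dinuc_vector(s)

    def test_shuffles_vary(self, rng):
        s = rand_rna(rng, 80)
        assert len({dinucleotide_shuffle(s, rng) for _ in range(20)}) > 1


class TestZScore:
    def test_homopolymer_degenerate_background(self, rng):
        with pytest.warns(UserWarning, match="degenerate"):
            z = structure_z_score("A" * 50, n_shuffles=30, rng=rng)
        assert z == 0.0

    def test_planted_hairpin_is_stable(self, rng):
        """A planted 12-bp hairpin in a 60-nt context is stable in the
        median (z <= -2) and essentially always below the background."""
        zs = []
        for _ in range(20):
            stem = rand_rna(rng, 12, gc=0.9)
            comp = stem.translate(str.maketrans("ACGU", "UGCA"))[::-1]
            s = rand_rna(rng, 24) + stem + "GAAA" + comp + rand_rna(rng, 24)
            zs.append(structure_z_score(s, n_shuffles=30, rng=rng))
        assert np.median(zs) <= -2.0
        assert np.mean(np.array(zs) < 0) >= 0.95

    def test_small_n_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            structure_z_score("GGGGAAAACCCCGAUCGAUCGAUC", n_shuffles=10, rng=rng)


class TestSCI:
    def test_identical_rows_give_exactly_one(self):
        rows = ["GGGGAAAACCCCAUGCAUGC"] * 4
        assert consensus_sci(rows) == pytest.approx(1.0)

    def test_unrelated_rows_score_low(self, rng):
        vals = []
        for _ in range(20):
            rows = [rand_rna(rng, 60) for _ in range(6)]
            vals.append(consensus_sci(rows))
        assert np.mean(vals) < 0.3

    def test_compensatory_hairpins_keep_high_sci(self, rng):
        """GC<->CG swapped stems still fold to the same consensus."""
        stem = "GCGGCGGCGG"
        comp = stem.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        base = stem + "AAAA" + comp
        rows = [base]
        for _ in range(3):
            s = list(stem)
            c = list(comp)
            for k in range(len(stem)):
                if rng.random() < 0.3:  # swap the pair, keep the helix
                    s[k] = {"G": "C", "C": "G"}[s[k]]
                    c[len(stem) - 1 - k] = {"G": "C", "C": "G"}[c[len(stem) - 1 - k]]
            rows.append("".join(s) + "AAAA" + "".join(c))
        assert consensus_sci(rows) >= 0.8

    def test_all_gap_columns_removed(self):
        rows = ["GG-GGAAAACC-CC", "GG-GGAAAACC-CC"]
        assert consensus_sci(rows) == pytest.approx(1.0)

    def test_requires_two_rows(self):
        with pytest.raises(ValueError):
            consensus_sci(["ACGU"])


class TestAlignFamily:
    def test_low_divergence_family_aligns_to_reference(self, rng):
        ref = rand_rna(rng, 120, gc=0.7)
        seqs = {"ref": ref}
        for i in range(3):
            s = list(ref)
            for _ in range(4):
                s[int(rng.integers(len(s)))] = "A"
            seqs[f"o{i}"] = "".join(s)
        fam = align_family("f", seqs, "ref")
        assert fam.ids[0] == "ref"
        assert fam.rows[0].replace("-", "") == ref
        assert len({len(r) for r in fam.rows}) == 1


def hairpin_family(rng, n_rows=5, flank=70, stem_n=14):
    """Sequences sharing a strong two-hairpin element at a known locus."""
    core = ""
    for _ in range(2):
        stem = rand_rna(rng, stem_n, gc=0.9)
        comp = stem.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        core += stem + "GAAA" + comp + "AUC"
    left = rand_rna(rng, flank, gc=0.7)
    right = rand_rna(rng, flank, gc=0.7)
    ref = left + core + right
    seqs = {"ref": ref}
    for i in range(n_rows - 1):
        s = list(ref)
        for p in range(len(s)):
            if rng.random() < 0.03 and not (flank <= p < flank + len(core)):
                s[p] = rand_rna(rng, 1)
        seqs[f"o{i}"] = "".join(s)
    locus = (flank, flank + len(core))
    return align_family("fam", seqs, "ref"), locus


class TestScan:
    def test_planted_family_yields_overlapping_positive_call(self, rng):
        fam, locus = hairpin_family(rng)
        calls = scan_igr_windows(fam, rng=rng)
        pos = [c for c in calls if c.positive]
        assert pos, "no positive call on a planted conserved hairpin"
        assert any(
            min(c.window_end, locus[1]) - max(c.window_start, locus[0]) > 0
            for c in pos
        )

    def test_shuffled_alignment_rarely_positive(self, rng):
        fam, _ = hairpin_family(rng)
        n_pos = 0
        for _ in range(25):
            rand = randomize_alignment(fam, rng)
            calls = scan_igr_windows(rand, rng=rng)
            n_pos += any(c.positive for c in calls)
        assert n_pos <= 2

    def test_two_distinct_hairpins_give_two_calls(self, rng):
        """One region can harbor more than one structured RNA."""
        f1, _ = hairpin_family(rng, flank=40)
        f2, _ = hairpin_family(rng, flank=40)
        ref = f1.rows[0].replace("-", "") + rand_rna(rng, 260, gc=0.7) + f2.rows[0].replace("-", "")
        seqs = {"ref": ref}
        for i in range(4):
            seqs[f"o{i}"] = ref  # identical rows: conservation is perfect
        fam = align_family("two", seqs, "ref")
        calls = [c for c in scan_igr_windows(fam, rng=rng) if c.positive]
        assert len(calls) >= 2
        strands = {}
        for c in calls:
            strands.setdefault(c.strand, []).append(c)
        for group in strands.values():
            spans = sorted((c.window_start, c.window_end) for c in group)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1  # merged calls never overlap on a strand


class TestTerminators:
    def test_constructed_hairpin_with_t_tail(self):
        calls = detect_terminators("AAAAGCGCGCTTTTGCGCGCTTTTTTTT")
        assert len(calls) == 1
        c = calls[0]
        assert c.stem_len >= 6 and 3 <= c.loop_len <= 10 and c.u_tail_len >= 3

    def test_matches_brute_force_hairpin_scan(self):
        """Every reported locus is verified pairable by an explicit check."""
        seq = "AAAAGCGCGCTTTTGCGCGCTTTTTTTT"
        pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
        for c in detect_terminators(seq):
            for k in range(c.stem_len):
                a = seq[c.position + k]
                b = seq[c.position + 2 * c.stem_len + c.loop_len - 1 - k]
                assert (a, b) in pairs

    def test_poly_a_has_no_terminator(self):
        assert detect_terminators("A" * 50) == []

    def test_tail_requirement(self):
        # same hairpin but no downstream thymines
        assert detect_terminators("AAAAGCGCGCTTTTGCGCGCAAAAAAAA") == []

    def test_minus_strand_scan(self):
        seq = "AAAAGCGCGCTTTTGCGCGCTTTTTTTT"
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        calls = detect_terminators(rc, strand="-")
        assert len(calls) == 1


class TestPerformance:
    def test_reject_everything_screen(self, rng):
        fam, _ = hairpin_family(rng, n_rows=3, flank=30)
        perf = estimate_specificity_sensitivity(
            [fam],
            known_ncrna_ids={"fam"},
            n_iter=100,
            seed=1,
            p_threshold=2.0,  # nothing can exceed probability 2
        )
        assert perf.specificity == 1.0
        assert perf.sensitivity == 0.0

    def test_specificity_formula(self, monkeypatch, rng):
        """specificity = 1 - FP/n_iter, e.g. 21 positives in 1000 -> 0.979."""
        from srnascan import structure as st

        fam = FamilyAlignment("f", ["a", "b"], ["ACGUACGUACGUACGUACGU"] * 2)
        counter = {"i": 0}

        def fake_scan(f, rng=None, **kw):
            counter["i"] += 1
            positive = counter["i"] <= 21
            return [
                st.StructureCall("f", 0, 10, "+", -5.0, -3.0, 1.0, 0.9, positive)
            ]

        monkeypatch.setattr(st, "scan_igr_windows", fake_scan)
        perf = st.estimate_specificity_sensitivity([fam], n_iter=1000, seed=0)
        assert perf.n_false_positive == 21
        assert perf.specificity == pytest.approx(0.979)

    def test_sensitivity_formula(self):
        perf = ScreenPerformance(
            specificity=1.0, sensitivity=8 / 10, n_random=1000,
            n_false_positive=0, n_known=10, n_known_detected=8,
        )
        assert perf.sensitivity == pytest.approx(0.8)

    def test_small_n_iter_warns(self, rng):
        fam, _ = hairpin_family(rng, n_rows=3, flank=30)
        with pytest.warns(UserWarning, match="unstable"):
            estimate_specificity_sensitivity([fam], n_iter=5, seed=0)

    def test_randomization_preserves_row_composition(self, rng):
        fam, _ = hairpin_family(rng)
        rand = randomize_alignment(fam, rng)
        for a, b in zip(fam.rows, rand.rows):
            assert Counter(a) == Counter(b)
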