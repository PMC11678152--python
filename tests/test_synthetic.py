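"""Synthetic generator determinism, planted-signal properties, recovery."""

import numpy as np
import pytest

from srnascan.annotation_io import write_gff3, load_annotation_set
from srnascan.igr_core import extract_igrs
from srnascan.synthetic import (
    GroundTruth,
    SimulationConfig,
    evaluate_recovery,
    simulate_counts,
    simulate_strain_family,
)

SMALL = dict(
    genome_len=60_000, n_genes=40, n_strains=3, n_planted_srnas=5,
    n_target_pairs=3, n_decoy_mrnas=15, n_noise_srnas=5,
)


@pytest.fixture(scope="module")
def family():
    return simulate_strain_family(SimulationConfig(seed=11, **SMALL))


class TestStrainFamily:
    def test_same_seed_is_byte_identical(self, family):
        again = simulate_strain_family(SimulationConfig(seed=11, **SMALL))
        assert again.ref_genome == family.ref_genome
        for name in family.comparators:
            assert again.comparators[name][0] == family.comparators[name][0]

    def test_zero_divergence_gives_identical_comparators(self):
        cfg = SimulationConfig(seed=3, divergence=0.0, **SMALL)
        fam = simulate_strain_family(cfg)
        for genome, ann in fam.comparators.values():
            assert genome["chr"] == fam.ref_genome["chr"]

    def test_planted_loci_less_diverged_than_background(self, family):
        """Per-site mismatch inside planted loci stays below the background
        substitution rate for every comparator strain."""
        ref = family.ref_genome["chr"]
        for name, (genome, ann) in family.comparators.items():
            comp = genome["chr"]
            mism = tot = 0
            for locus in family.truth.planted_srna_loci:
                cs, ce = family.srna_locus_coords[name][locus["srna_id"]]
                ref_seq = ref[locus["start"] : locus["end"]]
                comp_seq = comp[cs:ce]
                assert len(ref_seq) == len(comp_seq)  # no indels in loci
                mism += sum(a != b for a, b in zip(ref_seq, comp_seq))
                tot += len(ref_seq)
            assert mism / tot < family.config.divergence

    def test_emitted_files_pass_annotation_validation(self, family, tmp_path):
        path = tmp_path / "ref.gff3"
        write_gff3(family.ref_annotation, path)
        back = load_annotation_set(family.ref_genome, path)
        assert len(back) == len(family.ref_annotation)

    def test_planted_igrs_resolve_to_extracted_igrs(self, family):
        igrs = {g.id for g in extract_igrs(family.ref_annotation, family.ref_genome)}
        assert set(family.truth.planted_conserved_igrs) <= igrs

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError):
            simulate_strain_family(
                SimulationConfig(seed=0, genome_len=5_000, n_genes=40)
            )


class TestCounts:
    @pytest.fixture(scope="class")
    def sim(self, family):
        cfg = family.config
        truth = GroundTruth(
            planted_srna_loci=family.truth.planted_srna_loci,
            planted_conserved_igrs=family.truth.planted_conserved_igrs,
        )
        counts, design, cats, lengths, mrnas = simulate_counts(
            cfg, family.srna_seqs, truth
        )
        return counts, design, cats, lengths, mrnas, truth

    def test_column_sums_positive(self, sim):
        counts = sim[0]
        assert (counts.sum(axis=0) > 0).all()

    def test_target_mrnas_carry_exact_complement_site(self, sim, family):
        comp = str.maketrans("ACGT", "TGCA")
        _, _, _, _, mrnas, truth = sim
        for sid, mid in truth.planted_target_pairs:
            srna = family.srna_seqs[sid]
            mseq = mrnas[mid]
            found = any(
                srna[i : i + family.config.site_len].translate(comp)[::-1] in mseq
                for i in range(len(srna) - family.config.site_len + 1)
            )
            assert found, f"no planted site for {sid} in {mid}"

    def test_planted_pairs_shift_oppositely(self, sim, family):
        counts, design, _, _, _, truth = sim
        tp = design["time_point"]
        for sid, mid in truth.planted_target_pairs:
            s_lfc = truth.planted_de_features[sid]
            m_lfc = truth.planted_de_features[mid]
            assert s_lfc == -m_lfc

    def test_zero_planted_lfc_centers_log_ratios(self, family):
        cfg = SimulationConfig(seed=11, planted_log2fc=0.0, **SMALL)
        truth = GroundTruth(
            planted_srna_loci=family.truth.planted_srna_loci,
            planted_conserved_igrs=family.truth.planted_conserved_igrs,
        )
        counts, design, _, _, _ = simulate_counts(cfg, family.srna_seqs, truth)
        tp = design["time_point"]
        a = counts.loc[:, tp[counts.columns] == "24h"].mean(axis=1)
        b = counts.loc[:, tp[counts.columns] == "96h"].mean(axis=1)
        ratios = np.log2((b + 1) / (a + 1))
        assert abs(ratios.mean()) < 0.2


class TestRecovery:
    TRUTH = GroundTruth(
        planted_srna_loci=[
            {"srna_id": f"s{i}", "replicon": "chr", "start": 100 * i, "end": 100 * i + 80, "igr_id": f"I{i}"}
            for i in range(4)
        ],
        planted_conserved_igrs=["I0", "I1", "I2", "I3"],
        planted_de_features={"s0": 3.0},
        planted_target_pairs=[("s0", "m0")],
    )

    def test_perfect_detector(self):
        outputs = {
            "conserved_igrs": {"I0", "I1", "I2", "I3"},
            "target_calls": [("s0", "m0")],
        }
        df = evaluate_recovery(outputs, self.TRUTH).set_index("stage")
        assert df.loc["conservation", "precision"] == 1.0
        assert df.loc["targets", "recall"] == 1.0

    def test_empty_detector_has_zero_recall_undefined_precision(self):
        df = evaluate_recovery({"target_calls": []}, self.TRUTH).set_index("stage")
        assert df.loc["targets", "recall"] == 0.0
        assert np.isnan(df.loc["targets", "precision"])

    def test_half_recovered_arithmetic(self):
        calls = [
            {"replicon": "chr", "start": 0, "end": 80},
            {"replicon": "chr", "start": 100, "end": 180},
        ]
        df = evaluate_recovery({"structure_calls": calls}, self.TRUTH).set_index("stage")
        assert df.loc["structure", "recall"] == pytest.approx(0.5)
        assert df.loc["structure", "precision"] == pytest.approx(1.0)

    def test_50_percent_overlap_rule(self):
        calls = [{"replicon": "chr", "start": 0, "end": 39}]  # 39 < 40 = half
        df = evaluate_recovery({"structure_calls": calls}, self.TRUTH).set_index("stage")
        assert df.loc["structure", "recall"] == 0.0
        calls = [{"replicon": "chr", "start": 0, "end": 40}]
        df = evaluate_recovery({"structure_calls": calls}, self.TRUTH).set_index("stage")
        assert df.loc["structure", "recall"] == pytest.approx(0.25)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_recovery({}, GroundTruth())

    def test_truth_json_round_trip(self, tmp_path):
        path = tmp_path / "truth.json"
        self.TRUTH.to_json(path)
        back = GroundTruth.from_json(path)
        assert back == self.TRUTH
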