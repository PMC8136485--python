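"""Generator contracts: planted structure, determinism, recovery bounds."""

import numpy as np
import pytest

from phagescreen import (
    FPGroundTruth,
    LibraryModel,
    assign_truth,
    emit_fastq,
    generate_library,
    simulate_counts,
    simulate_fp,
)
from phagescreen.enrichment import hamming_distance
from phagescreen.reads import DEFAULT_TEMPLATE, qc_read, translate_variable_region


class TestGenerateLibrary:
    @pytest.mark.parametrize("variants", [0, 3])
    def test_family_structure(self, variants):
        lib = generate_library(40, variants, seed=5)
        sizes = lib.groupby("family").size()
        assert (sizes == variants + 1).all()
        assert lib["peptide"].is_unique
        for fam, group in lib.groupby("family"):
            seed_pep = group["peptide"].iloc[0]
            for var in group["peptide"].iloc[1:]:
                assert hamming_distance(seed_pep, var) == 1

    def test_deterministic_under_seed(self):
        a = generate_library(30, 2, seed=42)
        b = generate_library(30, 2, seed=42)
        assert a.equals(b)
        c = generate_library(30, 2, seed=43)
        assert not a["peptide"].equals(c["peptide"])

    def test_space_exhaustion_errors(self):
        tiny = LibraryModel(peptide_length=2, alphabet="AC",
                            position_frequencies=np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="sequence space"):
            generate_library(5, 0, model=tiny, seed=0)

    def test_respects_position_frequencies(self):
        freqs = np.full((12, 20), 0.0)
        freqs[:, 0] = 1.0  # alanine everywhere
        model = LibraryModel(position_frequencies=freqs)
        lib = generate_library(1, 0, model=model, seed=0)
        assert lib["peptide"].iloc[0] == "A" * 12


class TestAssignTruth:
    def test_all_unresponsive_means_equal_frequencies(self):
        lib = generate_library(50, 1, seed=1)
        truth = assign_truth(lib, (0.0, -2.5, 2.5), seed=2)
        assert (truth["cls"] == "unresponsive").all()
        assert (truth["true_E"] == 0).all()
        np.testing.assert_allclose(truth["f_comp"], truth["f_noncomp"], rtol=1e-12)

    def test_family_members_share_truth(self):
        lib = generate_library(200, 2, seed=3)
        truth = assign_truth(lib, (0.4, -2.0, 1.0), seed=4)
        per_family = truth.groupby("family")[["true_E", "cls"]].nunique()
        assert (per_family == 1).all().all()
        assert truth.loc[truth["cls"] == "unresponsive", "true_E"].eq(0).all()
        assert abs(truth["f_noncomp"].sum() - 1) < 1e-9
        assert abs(truth["f_comp"].sum() - 1) < 1e-9

    def test_class_fraction_matches_weight(self):
        w = 0.3
        n = 10_000
        lib = generate_library(n, 0, seed=6)
        truth = assign_truth(lib, (w, -2.5, 2.5), seed=7)
        observed = (truth["cls"] == "responsive").mean()
        se = np.sqrt(w * (1 - w) / n)
        assert abs(observed - w) < 3 * se

    def test_sign_convention_depletion(self):
        """A strongly negative true E must deplete the competitor sample."""
        lib = generate_library(500, 0, seed=8)
        truth = assign_truth(lib, (0.5, -3.0, 0.5), seed=9)
        resp = truth[truth["cls"] == "responsive"]
        assert (resp["f_comp"] < resp["f_noncomp"]).all()


class TestSimulateCounts:
    def test_depth_conservation_and_replicates(self):
        lib = generate_library(100, 1, seed=10)
        truth = assign_truth(lib, seed=11)
        tables = simulate_counts(truth, depth=5000, n_replicates=3, seed=12)
        assert set(tables) == {"non-competitor", "competitor"}
        for reps in tables.values():
            assert len(reps) == 3
            for t in reps:
                assert t.depth == 5000
        # replicates are independent draws, not copies
        assert tables["non-competitor"][0].counts != tables["non-competitor"][1].counts

    def test_depth_one_single_read(self):
        lib = generate_library(20, 0, seed=13)
        truth = assign_truth(lib, seed=14)
        tables = simulate_counts(truth, depth=1, n_replicates=1, seed=15)
        t = tables["competitor"][0]
        assert t.depth == 1 and len(t.counts) == 1
        with pytest.raises(ValueError):
            simulate_counts(truth, depth=0, seed=0)

    def test_high_frequency_peptides_recovered(self):
        lib = generate_library(50, 0, seed=16)
        truth = assign_truth(lib, (0.0, -2.5, 2.5), seed=17)
        depth = 200_000
        t = simulate_counts(truth, depth, n_replicates=1, seed=18)["non-competitor"][0]
        top = truth.nlargest(10, "f_noncomp")
        for _, row in top.iterrows():
            f = row["f_noncomp"]
            c = t.counts.get(row["peptide"], 0)
            se = np.sqrt(f * (1 - f) / depth)
            assert abs(c / depth - f) < 4 * se


class TestEmitFastq:
    @pytest.fixture(scope="class")
    def small_counts(self):
        lib = generate_library(40, 0, seed=20)
        truth = assign_truth(lib, seed=21)
        return simulate_counts(truth, 3000, n_replicates=1, seed=22)["non-competitor"][0]

    def test_clean_reads_all_pass_and_roundtrip(self, small_counts):
        records = emit_fastq(small_counts, seed=23)
        assert len(records) == small_counts.depth
        recovered: dict[str, int] = {}
        for rec in records:
            res = qc_read(rec, DEFAULT_TEMPLATE)
            assert res.passed, res.reason
            pep = translate_variable_region(rec.dna[:36])
            recovered[pep] = recovered.get(pep, 0) + 1
        assert recovered == small_counts.counts

    def test_planted_corruption_recovered_downstream(self, small_counts):
        rates = {"wrong_length": 0.12, "flank_mismatch": 0.07, "low_quality": 0.07}
        records = emit_fastq(small_counts, corruption_rates=rates, seed=24)
        n = len(records)
        results = [qc_read(rec, DEFAULT_TEMPLATE) for rec in records]
        rejected = sum(not r.passed for r in results)
        p = sum(rates.values())
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rejected / n - p) < 3 * se
        # each planted class is rejected for its own reason
        by_reason = {}
        for rec, res in zip(records, results):
            cls = rec.id.rsplit(":", 1)[1]
            if not res.passed:
                by_reason.setdefault(cls, set()).add(res.reason.value)
        assert by_reason == {
            "wrong_length": {"wrong_length"},
            "flank_mismatch": {"flank_mismatch"},
            "low_quality": {"low_quality"},
        }

    def test_deterministic_under_seed(self, small_counts):
        a = emit_fastq(small_counts, seed=25)
        b = emit_fastq(small_counts, seed=25)
        assert [(r.dna, r.quality) for r in a] == [(r.dna, r.quality) for r in b]

    def test_rejects_invalid_rates(self, small_counts):
        with pytest.raises(ValueError):
            emit_fastq(small_counts, corruption_rates={"wrong_length": 1.2}, seed=0)
        with pytest.raises(ValueError, match="unknown corruption"):
            emit_fastq(small_counts, corruption_rates={"adapters": 0.1}, seed=0)


class TestSimulateFP:
    def test_noiseless_probe_curve_values(self):
        truth = FPGroundTruth(kd_true=10.0, p0_true=0.08, dpmax_true=0.135,
                              noise_sd=0.0, concentrations=np.array([0.0, 10.0, 1e6]))
        t = simulate_fp(truth, "probe_titration", seed=0)
        means = t.readings.mean(axis=1)
        assert means[0] == pytest.approx(0.08)
        assert means[1] == pytest.approx(0.08 + 0.135 / 2)
        assert means[2] == pytest.approx(0.08 + 0.135, rel=1e-4)

    def test_noiseless_competition_midpoint(self):
        truth = FPGroundTruth(kd_true=50.0, p0_true=0.1, dpmax_true=0.06,
                              noise_sd=0.0, concentrations=np.array([0.0, 50.0]))
        t = simulate_fp(truth, "competition", seed=0)
        means = t.readings.mean(axis=1)
        assert means[0] == pytest.approx(0.16)
        assert means[1] == pytest.approx(0.13)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            FPGroundTruth(kd_true=-1, p0_true=0, dpmax_true=0.1, noise_sd=0,
                          concentrations=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            FPGroundTruth(kd_true=1, p0_true=0, dpmax_true=0.1, noise_sd=0,
                          concentrations=np.array([1.0, 0.5]))
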