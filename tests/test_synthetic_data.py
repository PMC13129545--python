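"""Generators: determinism, constraint validation, end-to-end closure."""

import io

import numpy as np
import pytest

from caskinetics.errors import DesignError, DomainError
from caskinetics.kinetics_model import RateParameters, fit_stage1, fit_stage2
from caskinetics.pool_statistics import (RandomPoolModel, expected_pam_count,
                                         count_hits, scan_motif_sites)
from caskinetics.synthetic_data import (DEFAULT_FLANK_3, DEFAULT_FLANK_5,
                                        NoiseModel, PlateDesign,
                                        generate_designed_background,
                                        generate_random_dsDNA_pool,
                                        generate_random_ssRNA_pool,
                                        simulate_plate, table1_fixtures,
                                        write_fasta)
from caskinetics.trace_analysis import Trace, analyze_plate, traces_from_plate


def fasta_bytes(records):
    buf = io.StringIO()
    for rec in records:
        buf.write(f">{rec.id} {rec.description}\n{rec.seq}\n")
    return buf.getvalue()


class TestRandomPools:
    def test_dsDNA_pool_is_seed_deterministic(self):
        a = generate_random_dsDNA_pool(50, seed=42)
        b = generate_random_dsDNA_pool(50, seed=42)
        assert fasta_bytes(a) == fasta_bytes(b)
        assert fasta_bytes(a) != fasta_bytes(generate_random_dsDNA_pool(50, seed=43))

    def test_dsDNA_structure_and_flanks(self):
        records = generate_random_dsDNA_pool(5, seed=0)
        for rec in records:
            seq = str(rec.seq)
            assert len(seq) == 20 + 168 + 20
            assert seq.startswith(DEFAULT_FLANK_5) and seq.endswith(DEFAULT_FLANK_3)
        assert not scan_motif_sites(DEFAULT_FLANK_5)
        assert not scan_motif_sites(DEFAULT_FLANK_3)

    def test_flank_with_pam_is_rejected(self):
        with pytest.raises(DesignError):
            generate_random_dsDNA_pool(1, flank_5="GGTTTAGG", seed=0)

    def test_zero_core_length_gives_flanks_only(self):
        records = generate_random_dsDNA_pool(2, L=0, seed=0)
        assert str(records[0].seq) == DEFAULT_FLANK_5 + DEFAULT_FLANK_3

    def test_core_pam_count_matches_analytic_expectation(self):
        cores = [str(r.seq) for r in
                 generate_random_dsDNA_pool(3000, flank_5="", flank_3="", seed=1)]
        counts = np.array(count_hits(cores))
        expected = expected_pam_count(RandomPoolModel(L=168))
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 4 * se

    def test_ssRNA_pool_lengths_and_base_frequencies(self):
        records = generate_random_ssRNA_pool(400, seed=2)
        seqs = [str(r.seq) for r in records]
        assert all(len(s) == 183 for s in seqs)
        assert set("".join(seqs)) <= set("ACGU")
        joined = "".join(seqs)
        n = len(joined)
        se = np.sqrt(0.25 * 0.75 / n)
        for base in "ACGU":
            assert abs(joined.count(base) / n - 0.25) < 3 * se

    def test_ssRNA_seed_determinism(self):
        assert fasta_bytes(generate_random_ssRNA_pool(20, seed=9)) == \
            fasta_bytes(generate_random_ssRNA_pool(20, seed=9))

    def test_write_fasta_byte_identical(self, tmp_path):
        records = generate_random_dsDNA_pool(10, seed=5)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(records, p1)
        write_fasta(generate_random_dsDNA_pool(10, seed=5), p2)
        assert p1.read_bytes() == p2.read_bytes()


@pytest.fixture(scope="module")
def grna():
    return {r.name: r for r in table1_fixtures()}["gRNA 2"]


class TestDesignedBackgrounds:
    """Generator/validator separation: every design is checked with the
    independent motif scanner."""

    def test_v1_pam_without_seed_match(self, grna):
        seq = generate_designed_background(grna, "V1", seed=0)
        hits = scan_motif_sites(seq, grna_seed=grna.seed)
        assert len(hits) == 1
        assert hits[0].strand == "+" and hits[0].offset == 0
        assert hits[0].matched_seed_length < 4
        # distal 12-mer of the protospacer is retained
        assert seq.endswith(grna.spacer[8:].replace("U", "T"))

    def test_v2_full_target_without_pam(self, grna):
        seq = generate_designed_background(grna, "V2", seed=0)
        assert scan_motif_sites(seq) == []
        assert seq.endswith(grna.spacer.replace("U", "T"))

    def test_v3_single_pam_with_full_seed(self, grna):
        seq = generate_designed_background(grna, "V3", seed=0)
        hits = scan_motif_sites(seq, grna_seed=grna.seed)
        assert len(hits) == 1
        assert hits[0].matched_seed_length >= 8

    def test_v4_eight_pams_without_seed_matches(self, grna):
        seq = generate_designed_background(grna, "V4", seed=0)
        hits = scan_motif_sites(seq, grna_seed=grna.seed)
        assert len(hits) == 8
        assert all(h.matched_seed_length < 4 for h in hits)

    def test_designs_are_seed_deterministic(self, grna):
        for variant in ("V1", "V2", "V3", "V4"):
            assert generate_designed_background(grna, variant, seed=7) == \
                generate_designed_background(grna, variant, seed=7)

    def test_unknown_variant_errors(self, grna):
        with pytest.raises(DomainError):
            generate_designed_background(grna, "V5", seed=0)


class TestTable1Fixtures:
    def test_seventeen_validated_records(self):
        records = table1_fixtures()
        assert len(records) == 17
        assert all(len(r.spacer) == 20 and set(r.spacer) <= set("ACGU")
                   for r in records)

    def test_known_spacers(self):
        by_name = {r.name: r for r in table1_fixtures()}
        assert by_name["gRNA 9"].spacer == "UAAAUGAUAUAUACUUGAUU"
        assert by_name["gRNA 14"].seed == "AAAGAUAA"


TWO_CONDITION_DESIGN = PlateDesign(
    conditions=(("gRNA 2", "none", 0.0), ("gRNA 2", "dsDNA", 200.0)),
    seed=123,
)
TWO_CONDITION_RATES = {
    ("gRNA 2", "none"): RateParameters(1.8e4, 1e4),
    ("gRNA 2", "dsDNA"): RateParameters(1.8e4, 1e4, 1.1e6, 0.026),
}


class TestSimulatedPlates:
    def test_noiseless_replicates_identical(self):
        design = PlateDesign(conditions=(("gRNA 2", "none", 0.0),), seed=1)
        plate, sheet = simulate_plate(design, TWO_CONDITION_RATES,
                                      NoiseModel.noiseless())
        samples = [tr for tr in traces_from_plate(plate, sheet)
                   if not tr.is_negative_control]
        assert len(samples) == 3
        for tr in samples[1:]:
            np.testing.assert_array_equal(tr.values, samples[0].values)

    def test_seed_determinism_byte_identical_csv(self):
        a = simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES)
        b = simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES)
        assert a[0].to_csv(index=False) == b[0].to_csv(index=False)
        assert a[1].to_csv(index=False) == b[1].to_csv(index=False)

    def test_negative_controls_stay_near_baseline(self):
        plate, sheet = simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES)
        noise = NoiseModel()
        controls = [tr for tr in traces_from_plate(plate, sheet)
                    if tr.is_negative_control]
        assert controls
        upper = noise.baseline_offset_range[1] + 5 * noise.additive_sd
        assert all(tr.values.max() <= upper for tr in controls)

    def test_end_to_end_recovers_slowdown_direction(self):
        plate, sheet = simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES)
        result = analyze_plate(plate, sheet)
        assert len(result) == 1
        row = result.iloc[0]
        assert row["background"] == "dsDNA" and row["n_pairs"] == 9
        assert row["r_mean"] > 1.0
        # reproducible under the fixed design seed
        again = analyze_plate(*simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES))
        assert again.iloc[0]["r_mean"] == row["r_mean"]

    def test_missing_rates_for_condition_errors(self):
        with pytest.raises(DomainError):
            simulate_plate(TWO_CONDITION_DESIGN, {})


class TestPipelineClosure:
    """Noiseless wells round-trip through the two-stage fit to the
    generating rate constants."""

    def test_two_stage_fit_recovers_generating_rates(self):
        plate, sheet = simulate_plate(TWO_CONDITION_DESIGN, TWO_CONDITION_RATES,
                                      NoiseModel.noiseless())
        traces = traces_from_plate(plate, sheet)

        def first_sample(background):
            return next(tr for tr in traces
                        if not tr.is_negative_control and tr.background == background)

        from caskinetics.kinetics_model import AssayMix
        no_bg = first_sample("none")
        with_bg = first_sample("dsDNA")
        stage1 = fit_stage1(no_bg, AssayMix(), seed=0)
        truth = TWO_CONDITION_RATES[("gRNA 2", "dsDNA")]
        assert abs(stage1.params.k_on_t - truth.k_on_t) / truth.k_on_t < 0.01
        stage2 = fit_stage2(with_bg, stage1.params,
                            AssayMix(background_0=200.0), seed=0)
        assert abs(stage2.params.k_off_b - truth.k_off_b) / truth.k_off_b < 0.01
        assert abs(stage2.params.k_on_b - truth.k_on_b) / truth.k_on_b < 0.01
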