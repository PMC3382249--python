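import numpy as np
import pytest

from oracles import brute_force_perfect_arrays
from spidrevo.indels import backtranslate
from spidrevo.repeats import (
    build_consensus,
    classify_differences,
    consensus_dna_from_alignment,
    detect_subrepeats,
    detect_tandem_repeats,
    repeat_identity,
    single_residue_runs,
)
from spidrevo.sequences import BioSequence, MultipleAlignment
from spidrevo.simulate import sim_repeat_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestDetection:
    def test_perfect_array_matches_brute_force_scan(self):
        seq = "ARCN" * 5 + "QWERTY"
        arrays = detect_tandem_repeats(seq)
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.period, a.n_units, a.consensus) == (4, 5, "ARCN")
        assert a.mean_identity == 100.0
        assert a.coverage == pytest.approx(20 / 26)
        oracle = brute_force_perfect_arrays(seq, min_period=4)
        assert (a.span[0], a.span[1], a.period, a.n_units) in oracle

    def test_random_sequences_yield_no_arrays(self):
        # false-array probability at default thresholds < 1% over 100 seeds
        false_hits = 0
        for seed in range(100):
            rng = np.random.default_rng([990, seed])
            seq = "".join(rng.choice(list(AA), size=200))
            false_hits += bool(detect_tandem_repeats(seq))
        assert false_hits < 1 + 1  # < 1% plus one-count slack at n=100

    def test_two_planted_arrays_reported_in_order(self, rng):
        short = "".join(rng.choice(list(AA), size=8))
        long_unit = "".join(rng.choice(list(AA), size=141))
        spacer = "".join(rng.choice(list(AA), size=40))
        seq = short * 6 + spacer + long_unit * 3
        arrays = detect_tandem_repeats(seq)
        assert len(arrays) == 2
        assert arrays[0].period == 8 and arrays[0].n_units == 6
        assert arrays[1].period == 141 and arrays[1].n_units == 3
        assert arrays[0].span[1] <= arrays[1].span[0]

    def test_harmonic_periods_reduce_to_primitive_unit(self, rng):
        unit = "".join(rng.choice(list(AA), size=30))
        arrays = detect_tandem_repeats(unit * 6)
        assert len(arrays) == 1
        assert arrays[0].period == 30

    def test_too_short_sequence_returns_empty(self):
        assert detect_tandem_repeats("MKV") == []

    def test_arrays_table_columns(self):
        from spidrevo.repeats import arrays_table

        tbl = arrays_table(detect_tandem_repeats("ARCN" * 5 + "QWERTY"))
        assert list(tbl["period"]) == [4]
        assert list(tbl["copies"]) == [5]
        assert list(tbl["consensus"]) == ["ARCN"]

    def test_arrays_never_overlap_and_coverage_bounded(self, rng):
        sim = sim_repeat_protein(unit_len=20, n_units=5, sub_rate=0.03, seed=4)
        arrays = detect_tandem_repeats(sim.protein)
        spans = sorted(a.span for a in arrays)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert all(0 < a.coverage <= 1 for a in arrays)

    def test_planted_array_recovery(self):
        hits = 0
        for seed in range(20):
            sim = sim_repeat_protein(unit_len=180, n_units=6, sub_rate=0.02, seed=seed)
            arrays = detect_tandem_repeats(sim.protein)
            if len(arrays) != 1:
                continue
            a = arrays[0]
            true_start = sim.unit_intervals[0][0]
            true_end = sim.unit_intervals[-1][1]
            if (
                a.period == 180
                and abs(a.n_units - 6) <= 1
                and abs(a.span[0] - true_start) <= 2
                and abs(a.span[1] - true_end) <= 2
            ):
                hits += 1
        assert hits >= 19


class TestConsensus:
    @pytest.mark.parametrize(
        "units,expected",
        [
            (["AAB", "AAB", "AAB"], "AAB"),
            (["AAB", "ACB", "ADB"], "AXB"),  # middle column 1/3 ≤ 0.5 → X
            (["AAB", "AAB", "ACB"], "AAB"),  # 2/3 > 0.5
        ],
    )
    def test_majority_rule(self, units, expected):
        assert build_consensus(units) == expected

    def test_majority_gap_columns_dropped(self):
        assert build_consensus(["A-B", "A-B", "ACB"]) == "AB"

    def test_noiseless_copies_give_true_unit(self):
        sim = sim_repeat_protein(unit_len=50, n_units=4, sub_rate=0.0, seed=9)
        units = [sim.protein.residues[s:e] for s, e in sim.unit_intervals]
        assert build_consensus(units) == sim.ancestral_unit

    def test_needs_two_units(self):
        with pytest.raises(ValueError):
            build_consensus(["AAB"])


class TestIdentity:
    def test_identical_units_are_100(self):
        assert repeat_identity(["GAGS", "GAGS", "GAGS"]) == 100.0

    def test_three_quarters(self):
        assert repeat_identity(["AAAA", "AAAT"]) == 75.0

    def test_gap_only_columns_excluded(self):
        assert repeat_identity(["AA-", "AA-"]) == 100.0


class TestDiffClassification:
    def _codon_aln(self, rows):
        return MultipleAlignment.from_pairs(rows, alphabet="dna")

    def test_identical_unit_counts_nothing(self):
        aln = self._codon_aln([("u1", "GCTGCA"), ("u2", "GCTGCA")])
        d = classify_differences(aln, "GCTGCA")
        assert (d.nonsynonymous, d.synonymous) == (0, 0)

    def test_synonymous_and_nonsynonymous_single_sites(self):
        # consensus codon GCT (Ala): GCC stays Ala, ACT becomes Thr
        aln = self._codon_aln([("u1", "GCC"), ("u2", "ACT"), ("u3", "GCT")])
        d = classify_differences(aln, "GCT")
        assert (d.nonsynonymous, d.synonymous) == (1, 1)

    def test_totals_equal_hamming_distance(self):
        for seed in range(5):
            sim = sim_repeat_protein(unit_len=30, n_units=4, sub_rate=0.05, seed=seed)
            prot_rows = [
                (f"u{i}", sim.protein.residues[s:e])
                for i, (s, e) in enumerate(sim.unit_intervals)
            ]
            cds = {
                f"u{i}": BioSequence(f"u{i}", sim.dna.residues[3 * s : 3 * e], "dna")
                for i, (s, e) in enumerate(sim.unit_intervals)
            }
            codon_aln = backtranslate(MultipleAlignment.from_pairs(prot_rows), cds)
            consensus = consensus_dna_from_alignment(codon_aln)
            d = classify_differences(codon_aln, consensus)
            hamming = sum(
                1
                for _, row in codon_aln.rows
                for a, b in zip(row, consensus)
                if a != b and a != "-" and b != "-"
            )
            assert d.total == hamming

    def test_frame_violation_rejected(self):
        aln = self._codon_aln([("u1", "GCTG"), ("u2", "GCTA")])
        with pytest.raises(ValueError, match="multiple of 3"):
            classify_differences(aln)


class TestSubrepeats:
    def test_perfect_doubling_found_at_midpoint(self):
        off, ident = detect_subrepeats("ARCNEARCNE")
        assert off == 5
        assert ident == 100.0

    def test_random_consensus_has_low_subrepeat_identity(self, rng):
        seq = "".join(rng.choice(list(AA), size=360))
        _, ident = detect_subrepeats(seq)
        assert ident < 30.0


class TestResidueRuns:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAASSG", [("A", 0, 3), ("S", 3, 2)]),
            ("ABAB", []),
        ],
    )
    def test_examples(self, seq, expected):
        assert single_residue_runs(seq) == expected

    def test_planted_poly_alanine_run(self):
        seq = "GS" * 4 + "A" * 7 + "GS" * 4
        assert ("A", 8, 7) in single_residue_runs(seq)
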