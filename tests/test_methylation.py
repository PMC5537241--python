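"""Bisulfite alignment, context classification, normalized calling, summaries."""

import math

import numpy as np
import pytest

from satmethyl import (
    BisulfiteRead,
    MonomerAlignment,
    SeqRecord,
    build_consensus,
    call_methylation,
    classify_context,
    correlate_tracks,
    estimate_conversion_efficiency,
    sliding_window_methylation,
    summarize_by_context,
)
from satmethyl.methylation import ReadRejected, bisulfite_align
from satmethyl.seqio import reverse_complement


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,expected",
        [
            ("ACGA", 2, "CG"),
            ("CAGT", 1, "CHG"),
            ("CATT", 1, "CHH"),
            ("ACGA", 1, "non_C"),
            ("CCGG", 1, "CHG"),  # C C G: H=C, then G
            ("CCGG", 2, "CG"),
        ],
    )
    def test_definitions(self, seq, pos, expected):
        assert classify_context(seq, pos, circular=False) == expected

    def test_circular_wraparound(self):
        # last base C, first base G: CG across the tandem junction
        seq = "GAAAATC"
        assert classify_context(seq, 7, circular=True) == "CG"
        # oracle: same call on the doubled string without wraparound
        assert classify_context(seq + seq, 7, circular=False) == "CG"

    def test_linear_end_unresolved(self):
        assert classify_context("AAC", 3, circular=False) == "CHH_unresolved"

    def test_n_successor_unresolved(self):
        assert classify_context("CNAA", 1, circular=False) == "CHH_unresolved"

    def test_context_counts_conserved_circular(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 200))
        counts = {"CG": 0, "CHG": 0, "CHH": 0, "non_C": 0}
        for pos in range(1, 201):
            counts[classify_context(seq, pos, circular=True)] += 1
        assert counts["CG"] + counts["CHG"] + counts["CHH"] == seq.count("C")


def _consensus_of(seq):
    return build_consensus(
        MonomerAlignment((SeqRecord("a", seq), SeqRecord("b", seq)))
    )


class TestBisulfiteAlign:
    REF = "ATTCGGATCCAATGCGTACCATGGATTACGGATTTCCAGTAGGATCAGGCATTACGGATCCAT" * 2

    def test_fully_converted_read_identity_mapping(self):
        read = BisulfiteRead("r", self.REF.replace("C", "T"), "direct")
        mapping = bisulfite_align(read, self.REF)
        assert mapping == {i: i for i in range(1, len(self.REF) + 1)}

    def test_unconverted_read_identity_mapping(self):
        read = BisulfiteRead("r", self.REF, "direct")
        mapping = bisulfite_align(read, self.REF)
        assert mapping == {i: i for i in range(1, len(self.REF) + 1)}

    def test_internal_deletion_skips_one_coordinate(self):
        seq = self.REF[:60] + self.REF[61:]
        read = BisulfiteRead("r", seq.replace("C", "T"), "direct")
        mapping = bisulfite_align(read, self.REF)
        mapped = sorted(mapping.values())
        # exactly one reference coordinate is skipped, near the deletion
        assert len(mapped) == len(self.REF) - 1
        skipped = set(range(1, len(self.REF) + 1)) - set(mapped)
        assert len(skipped) == 1 and abs(skipped.pop() - 61) <= 3
        # mapping preserves order
        ordered = [mapping[q] for q in sorted(mapping)]
        assert ordered == sorted(ordered)

    def test_complementary_strand_maps_on_reverse_complement(self):
        read = BisulfiteRead(
            "r", reverse_complement(self.REF).replace("C", "T"), "complementary"
        )
        mapping = bisulfite_align(read, self.REF)
        assert mapping == {i: i for i in range(1, len(self.REF) + 1)}

    def test_primer_mask_excluded(self):
        read = BisulfiteRead("r", self.REF, "direct", primer_mask=((1, 10),))
        mapping = bisulfite_align(read, self.REF)
        assert min(mapping) == 11

    def test_short_read_rejected(self):
        with pytest.raises(ReadRejected, match="after masking"):
            bisulfite_align(BisulfiteRead("r", "ACGT" * 10, "direct"), self.REF)

    def test_low_identity_rejected(self):
        garbage = "G" * len(self.REF)
        with pytest.raises(ReadRejected, match="identity"):
            bisulfite_align(BisulfiteRead("r", garbage, "direct"), self.REF)


class TestCallMethylation:
    def test_all_c_native_column(self):
        # native all C at a position, 10 reads: 5 C, 5 T -> m = 0.5
        ref = "ATTCGGATCCAATGGGTACCATGGATTAGGGATTTCCAGTAGGATCAGGCATTAGGGATCCAT"
        native = MonomerAlignment((SeqRecord("a", ref), SeqRecord("b", ref)))
        cons = build_consensus(native)
        pos = ref.index("CG") + 1  # a CG-context cytosine
        reads = []
        for i in range(10):
            seq = list(ref.replace("C", "T"))
            if i < 5:
                seq[pos - 1] = "C"
            reads.append(BisulfiteRead(f"r{i}", "".join(seq), "direct"))
        calls = call_methylation(native, reads, cons)
        call = next(
            c for c in calls if c.strand == "direct" and c.position == pos
        )
        assert call.native_CT_fraction == 1.0
        assert call.m_normalized == pytest.approx(0.5)
        assert call.context == "CG"

    def test_mutation_bias_normalization_variants(self):
        # native column 80% C / 20% T; 40% of reads retain C.
        # printed formula: 0.40 / (0.8 + 0.2) = 0.40; C-only: 0.40 / 0.8 = 0.50
        base = "ATTGGGATGGAATGGGTAGGATGGATTAGGGATTTGGAGTAGGATGAGGGATTAGGGATGGAT"
        pos = 4
        natives = []
        for i in range(10):
            seq = list(base)
            seq[pos - 1] = "C" if i < 8 else "T"
            natives.append(SeqRecord(f"n{i}", "".join(seq)))
        native = MonomerAlignment(tuple(natives))
        cons = build_consensus(native)
        reads = []
        for i in range(10):
            seq = list(base.replace("C", "T"))
            seq[pos - 1] = "C" if i < 4 else "T"
            reads.append(BisulfiteRead(f"r{i}", "".join(seq), "direct"))
        for norm, expected in (("ct", 0.40), ("c_only", 0.50)):
            calls = call_methylation(native, reads, cons, normalization=norm)
            call = next(
                c for c in calls if c.strand == "direct" and c.position == pos
            )
            assert call.m_normalized == pytest.approx(expected)

    def test_duplicating_reads_leaves_calls_unchanged(self, methylated_dataset):
        _, monomers, _, _, reads, cons = methylated_dataset
        subset = reads[:6]
        calls1 = call_methylation(monomers, subset, cons)
        calls2 = call_methylation(monomers, subset * 2, cons)
        m1 = {(c.position, c.strand): c.m_normalized for c in calls1}
        m2 = {(c.position, c.strand): c.m_normalized for c in calls2}
        assert m1.keys() == m2.keys()
        for key, v in m1.items():
            assert m2[key] == pytest.approx(v, nan_ok=True)

    def test_zero_coverage_positions_flagged(self):
        ref = "ATTCGGATCCAATGGGTACCATGGATTAGGGATTTCCAGTAGGATCAGGCATTAGGGATCCAT"
        native = MonomerAlignment((SeqRecord("a", ref), SeqRecord("b", ref)))
        cons = build_consensus(native)
        calls = call_methylation(native, [], cons)
        assert calls and all(c.n_reads == 0 and math.isnan(c.m_normalized) for c in calls)


class TestSummaries:
    def test_fully_converted_reads_all_zero(self):
        ref = "ATTCGGATCCAATGGGTACCATGGATTAGGGATTTCCAGTAGGATCAGGCATTAGGGATCCAT"
        native = MonomerAlignment((SeqRecord("a", ref), SeqRecord("b", ref)))
        cons = build_consensus(native)
        reads = [
            BisulfiteRead(f"d{i}", ref.replace("C", "T"), "direct") for i in range(3)
        ] + [
            BisulfiteRead(
                f"c{i}", reverse_complement(ref).replace("C", "T"), "complementary"
            )
            for i in range(3)
        ]
        calls = call_methylation(native, reads, cons)
        summary = summarize_by_context(calls)
        table = summary.table.dropna(how="all")
        assert (table.fillna(0.0) == 0.0).all().all()

    def test_all_c_row_is_weighted_mean(self, methylated_dataset):
        _, monomers, _, _, reads, cons = methylated_dataset
        calls = call_methylation(monomers, reads, cons)
        s = summarize_by_context(calls)
        for col in s.table.columns:
            ctx = s.table.loc[["CG", "CHG", "CHH"], col]
            w = s.weights.loc[["CG", "CHG", "CHH"], col]
            assert s.table.loc["All C", col] == pytest.approx(
                (ctx * w).sum() / w.sum()
            )

    def test_strand_symmetric_dataset_gives_similar_strand_summaries(self):
        from satmethyl import (
            FamilyConfig,
            MethylationConfig,
            assign_methylation,
            generate_family,
            make_reads,
        )

        cfg = FamilyConfig(seed=5, per_site_substitution_prob=0.005, indel_prob=0.0)
        _, monomers = generate_family(cfg)
        mcfg = MethylationConfig(
            seed=6,
            conversion_efficiency=1.0,
            n_reads_direct=150,
            n_reads_complementary=150,
        )
        maps = assign_methylation(monomers, mcfg)
        reads = make_reads(monomers, maps, mcfg)
        cons = build_consensus(monomers)
        calls = call_methylation(monomers, reads, cons)
        s = summarize_by_context(calls).table
        d, c = s.loc["All C", "direct"], s.loc["All C", "complementary"]
        assert d == pytest.approx(c, abs=0.02)


class TestConversionEfficiency:
    REF = SeqRecord(
        "ref",
        "ATTCGGATCCAATGCGTACCATGGATTACGGATTTCCAGTAGGATCAGGCATTACGGATCCAT" * 2,
    )

    def test_complete_conversion(self):
        reads = [
            BisulfiteRead("r1", self.REF.sequence.replace("C", "T"), "direct")
        ]
        assert estimate_conversion_efficiency(reads, self.REF) == 1.0

    def test_partial_conversion_arithmetic(self):
        seq = list(self.REF.sequence.replace("C", "T"))
        c_positions = [i for i, b in enumerate(self.REF.sequence) if b == "C"]
        seq[c_positions[0]] = "C"  # one failure
        reads = [BisulfiteRead("r1", "".join(seq), "direct")]
        n_c = len(c_positions)
        assert estimate_conversion_efficiency(reads, self.REF) == pytest.approx(
            (n_c - 1) / n_c
        )

    def test_no_covered_cytosines_errors(self):
        ref = SeqRecord("ref", "ATGGATTAGGAT" * 10)
        read = BisulfiteRead("r1", ref.sequence, "direct")
        with pytest.raises(ValueError, match="cover no reference cytosines"):
            estimate_conversion_efficiency([read], ref)


class TestTracksAndCorrelation:
    def test_uniform_methylation_flat_track(self):
        ref = "ATTCGGATCCAATGGGTACCATGGATTAGGGATTTCCAGTAGGATCAGGCATTAGGGATCCAT"
        native = MonomerAlignment((SeqRecord("a", ref), SeqRecord("b", ref)))
        cons = build_consensus(native)
        # every C retained in half the reads -> m = 0.5 at every C position
        reads = [
            BisulfiteRead(f"r{i}", ref if i < 5 else ref.replace("C", "T"), "direct")
            for i in range(10)
        ]
        calls = call_methylation(native, reads, cons)
        track = sliding_window_methylation(calls, strand="direct", width=cons.width)
        vals = track.finite_values
        assert vals == pytest.approx(np.full(len(vals), 0.5))

    def test_single_methylated_position_window_support(self):
        ref = ("ATTGGGATGGAATGGGTAGGATGGATTAGGGATTTGGAGTAGGATGAGGGATTAGGGATGGAT"
               "ATTGGGATGGAATGGGTAGGATGGATTAGGGATTTGGAGTAGGATGAGGGATTAGGGATGGCT")
        assert ref.count("C") == 1
        pos = ref.index("C") + 1  # lone C near the right end
        native = MonomerAlignment((SeqRecord("a", ref), SeqRecord("b", ref)))
        cons = build_consensus(native)
        reads = [BisulfiteRead(f"r{i}", ref, "direct") for i in range(4)]
        calls = call_methylation(native, reads, cons)
        track = sliding_window_methylation(calls, strand="direct", width=cons.width)
        for start, value in zip(track.starts, track.values):
            if start <= pos <= start + track.window_width - 1:
                assert value == pytest.approx(1.0)
            else:
                assert math.isnan(value)

    def test_spearman_antitone_and_identity(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = correlate_tracks(x, list(reversed(x)))
        assert rho == pytest.approx(-1.0)
        rho, _ = correlate_tracks(x, x)
        assert rho == pytest.approx(1.0)

    def test_constant_series_undefined(self):
        rho, p = correlate_tracks([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert math.isnan(rho) and math.isnan(p)

    def test_permutation_p_close_to_t(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho_t, p_t = correlate_tracks(x, y, method="t")
        rho_p, p_p = correlate_tracks(
            x, y, method="permutation", n_permutations=4000, seed=1
        )
        assert rho_t == rho_p
        assert p_p == pytest.approx(p_t, abs=0.02)
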