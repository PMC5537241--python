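"""Synthetic family / methylation / bisulfite generators and their statistics."""

import json

import numpy as np
import pytest

from satmethyl import (
    FamilyConfig,
    MethylationConfig,
    assign_methylation,
    bisulfite_convert,
    classify_context,
    gc_content,
    generate_family,
    make_dataset,
    nucleotide_diversity,
    tandem_array,
)
from satmethyl.seqio import reverse_complement


class TestGenerateFamily:
    def test_deterministic_under_seed(self):
        a1, m1 = generate_family(FamilyConfig(seed=42))
        a2, m2 = generate_family(FamilyConfig(seed=42))
        assert a1.sequence == a2.sequence
        assert [r.sequence for r in m1] == [r.sequence for r in m2]

    def test_zero_substitution_identical_monomers(self):
        cfg = FamilyConfig(seed=1, per_site_substitution_prob=0.0, indel_prob=0.0)
        ancestral, monomers = generate_family(cfg)
        assert all(r.sequence == ancestral.sequence for r in monomers)
        assert nucleotide_diversity(monomers) == 0.0

    def test_pi_matches_closed_form_expectation(self):
        # two independent branches at rate p: expected pairwise divergence
        # 2p(1-p) + (2/3)p^2 (coincident different hits also differ w.p. 2/3)
        p = 0.015
        expected = 2 * p * (1 - p) + (2 / 3) * p * p
        pis = []
        for seed in range(6):
            cfg = FamilyConfig(
                seed=seed, per_site_substitution_prob=p, indel_prob=0.0,
                n_monomers={"SSU": 39},
            )
            _, monomers = generate_family(cfg)
            pis.append(nucleotide_diversity(monomers))
        # Monte-Carlo SE of the mean over 6 x 315-site families is ~1e-3
        assert np.mean(pis) == pytest.approx(expected, abs=3e-3)

    def test_default_summary_statistics_in_study_range(self, default_family):
        _, _, monomers = default_family
        assert monomers.width == 315
        assert len(monomers) == 39
        assert nucleotide_diversity(monomers) == pytest.approx(0.0294, abs=0.005)
        assert gc_content(list(monomers)) == pytest.approx(0.4405, abs=0.03)

    def test_conserved_blocks_lower_local_diversity(self):
        cfg = FamilyConfig(
            seed=3, conserved_blocks=((100, 160),), conserved_factor=0.02,
            indel_prob=0.0,
        )
        _, monomers = generate_family(cfg)
        inside, outside = [], []
        from satmethyl import sliding_window_pi

        track = sliding_window_pi(monomers)
        for start, value in zip(track.starts, track.values):
            (inside if 100 <= start and start + 9 <= 160 else outside).append(value)
        assert np.mean(inside) < 0.25 * np.mean(outside)

    def test_per_species_rates(self):
        cfg = FamilyConfig(
            seed=9,
            n_monomers={"SSO": 21, "SSU": 39},
            per_site_substitution_prob={"SSU": 0.015, "SSO": 0.017},
            indel_prob=0.0,
        )
        _, monomers = generate_family(cfg)
        assert len(monomers.subset_species("SSO")) == 21
        assert len(monomers.subset_species("SSU")) == 39


class TestAssignMethylation:
    def test_zero_rates_empty_maps(self, default_family):
        _, _, monomers = default_family
        maps = assign_methylation(
            monomers, MethylationConfig(seed=1, rates={"CG": 0, "CHG": 0, "CHH": 0})
        )
        assert all(len(m) == 0 for m in maps.values())

    def test_cg_rate_one_methylates_every_cg(self, default_family):
        _, _, monomers = default_family
        mcfg = MethylationConfig(seed=1, rates={"CG": 1.0, "CHG": 0.0, "CHH": 0.0})
        maps = assign_methylation(monomers, mcfg)
        rec = monomers.records[0]
        s = rec.ungapped()
        expected = {
            (pos, "direct")
            for pos in range(1, len(s) + 1)
            if classify_context(s, pos) == "CG"
        }
        direct_marks = {pm for pm in maps[rec.id] if pm[1] == "direct"}
        assert direct_marks == expected

    def test_empirical_rates_within_ci(self):
        cfg = FamilyConfig(seed=2, per_site_substitution_prob=0.0, indel_prob=0.0,
                           n_monomers={"SSU": 1000})
        _, monomers = generate_family(cfg)
        mcfg = MethylationConfig(seed=7)
        maps = assign_methylation(monomers, mcfg)
        s = monomers.records[0].ungapped()
        n = len(s)
        opportunities = {"CG": 0, "CHG": 0, "CHH": 0}
        for strand_seq in (s, reverse_complement(s)):
            for pos in range(1, n + 1):
                ctx = classify_context(strand_seq, pos)
                if ctx in opportunities:
                    opportunities[ctx] += 1
        events = {"CG": 0, "CHG": 0, "CHH": 0}
        for rec in monomers:
            for pos, strand in maps[rec.id]:
                seq = s if strand == "direct" else reverse_complement(s)
                local = pos if strand == "direct" else n - pos + 1
                events[classify_context(seq, local)] += 1
        for ctx, rate in mcfg.rates.items():
            n_draws = opportunities[ctx] * 1000
            se = (rate * (1 - rate) / n_draws) ** 0.5
            assert events[ctx] / n_draws == pytest.approx(rate, abs=4 * se)


class TestBisulfiteConvert:
    def test_full_efficiency_no_methylation_removes_all_c(self, default_family):
        _, ancestral, _ = default_family
        rng = np.random.default_rng(0)
        read = bisulfite_convert(ancestral, frozenset(), 1.0, "direct", rng)
        assert "C" not in read.sequence

    def test_methylated_cytosines_protected(self, default_family):
        _, ancestral, _ = default_family
        marks = frozenset(
            (pos, "direct")
            for pos, b in enumerate(ancestral.sequence, start=1)
            if b == "C"
        )
        rng = np.random.default_rng(0)
        read = bisulfite_convert(ancestral, marks, 1.0, "direct", rng)
        assert read.sequence == ancestral.sequence

    def test_complementary_read_is_converted_reverse_complement(self, default_family):
        _, ancestral, _ = default_family
        rng = np.random.default_rng(0)
        read = bisulfite_convert(ancestral, frozenset(), 1.0, "complementary", rng)
        assert read.sequence == reverse_complement(ancestral.sequence).replace("C", "T")

    def test_retention_matches_efficiency(self):
        cfg = FamilyConfig(seed=5, per_site_substitution_prob=0.0, indel_prob=0.0,
                           n_monomers={"SSU": 100})
        ancestral, monomers = generate_family(cfg)
        rng = np.random.default_rng(11)
        retained = total = 0
        for rec in monomers:
            read = bisulfite_convert(rec, frozenset(), 0.987, "direct", rng)
            for orig, got in zip(rec.sequence, read.sequence):
                if orig == "C":
                    total += 1
                    retained += got == "C"
        se = (0.013 * 0.987 / total) ** 0.5
        assert retained / total == pytest.approx(0.013, abs=4 * se)


class TestMakeDataset:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = FamilyConfig(seed=17)
        mcfg = MethylationConfig(seed=18)
        p1 = make_dataset(cfg, mcfg, tmp_path / "a")
        p2 = make_dataset(cfg, mcfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_truth_file_consistent_with_fasta(self, tmp_path):
        paths = make_dataset(FamilyConfig(seed=4), MethylationConfig(seed=5), tmp_path)
        truth = json.loads(paths["truth"].read_text())
        from satmethyl import read_fasta

        native = read_fasta(paths["native"])
        assert set(truth["methylation_maps"]) == {r.id for r in native}
        reads = read_fasta(paths["bisulfite"])
        assert len(reads) == 33 + 26  # study-sized clone counts
        sheet = paths["sample_sheet"].read_text().splitlines()
        assert sheet[0].split("\t") == ["id", "species", "strand", "fragment_class"]

    def test_tandem_array_concatenates_and_shifts_marks(self, default_family):
        _, _, monomers = default_family
        maps = {r.id: frozenset() for r in monomers}
        first = monomers.records[0]
        maps[monomers.records[1].id] = frozenset(
            {(pos, "direct") for pos, b in
             enumerate(monomers.records[1].ungapped(), 1) if b == "C"}
        )
        arr = tandem_array(monomers, maps)
        offset = len(first.ungapped())
        for pos, strand in arr.methylation_map:
            assert arr.sequence[pos - 1] == "C"
            assert pos > offset
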