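"""Genome scanning: planted-site recovery, strand symmetry, segmentation."""

import numpy as np
import pytest

from triplexscan import (
    GenomeSequence,
    ScoreParameters,
    find_polypurine_runs,
    random_genome,
    random_mirnas,
    reverse_complement,
    scan_sequence,
    segment_genome,
)
from triplexscan.pairing import BindingMode, Orientation
from triplexscan.scan import site_alignment
from triplexscan.scoring import binding_energy, heuristic_score
from triplexscan.simulate import default_planting_plan, perfect_target, plant_genome

RH = BindingMode.REVERSE_HOOGSTEEN
ANTI = Orientation.ANTIPARALLEL


@pytest.fixture(scope="module")
def planted_scan():
    mirnas = random_mirnas(4, seed=202, purine_fraction=0.9)
    plan = default_planting_plan(mirnas, 40_000, seed=203)
    genome, truth = plant_genome(plan, mirnas)
    sites = scan_sequence(genome, mirnas, modes=[RH], orientations=[ANTI])
    return genome, mirnas, truth, sites


class TestPolypurineRuns:
    def test_forward_run_by_inspection(self):
        assert find_polypurine_runs("CCGGGGGGGCC", 7) == [(2, 9, "+")]

    def test_alternating_pur_pyr_has_no_run(self):
        assert find_polypurine_runs("ACACACAC", 7) == []

    def test_pyrimidine_run_reports_minus_strand(self):
        runs = find_polypurine_runs("GGTTTTTTTTGG", 7)
        assert runs == [(2, 10, "-")]

    def test_printed_hairpin_strand_matches_one_pass_oracle(self, printed):
        seq = printed["hairpin_purine_24"]
        # brute force: every window position checked base by base
        def oracle(seq, min_len, charset):
            out, i = [], 0
            while i < len(seq):
                if seq[i] in charset:
                    j = i
                    while j < len(seq) and seq[j] in charset:
                        j += 1
                    if j - i >= min_len:
                        out.append((i, j))
                    i = j
                else:
                    i += 1
            return out
        for min_len in (3, 5, 7):
            got = find_polypurine_runs(seq, min_len)
            assert [(s, e) for s, e, st in got if st == "+"] == oracle(seq, min_len, "AG")
            assert [(s, e) for s, e, st in got if st == "-"] == oracle(seq, min_len, "CT")


class TestSegmentPlan:
    def test_simple_arithmetic(self):
        plan = segment_genome(GenomeSequence("g", "A" * 100), 50, 25)
        assert plan.segments == [(0, 50), (25, 75), (50, 100)]

    def test_covers_and_overlaps(self):
        g = GenomeSequence("g", "A" * 1013)
        plan = segment_genome(g, 200, 30)
        assert plan.segments[0][0] == 0 and plan.segments[-1][1] == 1013
        for (s1, e1), (s2, e2) in zip(plan.segments, plan.segments[1:]):
            assert e1 - s2 == 30

    def test_bad_parameters_rejected(self):
        g = GenomeSequence("g", "A" * 100)
        with pytest.raises(ValueError):
            segment_genome(g, 25, 25)


class TestRandomGenome:
    def test_same_seed_reproduces(self):
        assert random_genome(500, 42).sequence == random_genome(500, 42).sequence

    def test_single_base(self):
        assert random_genome(1, 0).sequence in "ACGT"

    def test_base_frequencies_uniform(self):
        g = random_genome(400_000, 7)
        for b in "ACGT":
            assert abs(g.sequence.count(b) / len(g) - 0.25) < 0.005


class TestScan:
    def test_planted_targets_recovered_exactly(self, planted_scan):
        genome, mirnas, truth, sites = planted_scan
        found = {(s.start, s.end, s.mirna_id): s for s in sites}
        for row in truth.itertuples():
            site = found[(row.start, row.end, row.mirna_id)]
            assert site.n_units == row.expected_n_units
            assert site.strand == row.strand

    def test_no_overlapping_reports_within_family(self, planted_scan):
        _, _, _, sites = planted_scan
        by_family = {}
        for s in sites:
            by_family.setdefault(s.family(), []).append(s)
        for fam_sites in by_family.values():
            fam_sites.sort(key=lambda s: s.start)
            for a, b in zip(fam_sites, fam_sites[1:]):
                assert a.end <= b.start

    def test_every_site_recomputes(self, planted_scan):
        genome, mirnas, _, sites = planted_scan
        for s in sites[:200]:
            aln = site_alignment(s, genome, mirnas)
            assert aln.n_units == s.n_units
            assert heuristic_score(aln) == s.score
            assert binding_energy(aln) == pytest.approx(s.energy, abs=1e-9)

    def test_pyrimidine_forward_strand_reports_minus(self):
        # purine run lives on the reverse strand of a CT-only sequence
        genome = GenomeSequence("g", "CT" * 40)
        mirnas = {"m": "AGAGAGAGAGAGAGAGAGAGA"}
        sites = scan_sequence(genome, mirnas, modes=[RH], orientations=[ANTI])
        assert sites and all(s.strand == "-" for s in sites)

    def test_strand_symmetry(self):
        mirnas = random_mirnas(2, seed=17, purine_fraction=0.85)
        plan = default_planting_plan(mirnas, 5_000, seed=18)
        genome, _ = plant_genome(plan, mirnas)
        mirror = GenomeSequence("g", reverse_complement(genome.sequence))
        # report_all: suppression keeps one of several tied overlapping
        # reports, which is not itself a mirror-symmetric choice
        fwd = scan_sequence(genome, mirnas, modes=[RH], orientations=[ANTI], report_all=True)
        rev = scan_sequence(mirror, mirnas, modes=[RH], orientations=[ANTI], report_all=True)
        L = len(genome)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (L - s.end, L - s.start, flip[s.strand], s.mirna_id, s.n_units)
            for s in rev
        )
        assert mirrored == sorted(
            (s.start, s.end, s.strand, s.mirna_id, s.n_units) for s in fwd
        )

    def test_too_short_genome_yields_nothing(self):
        sites = scan_sequence(
            GenomeSequence("g", "GGGGGG"), {"m": "GGG"}, modes=[RH], orientations=[ANTI]
        )
        assert sites == []

    def test_mirna_longer_than_genome_skipped_with_warning(self, caplog):
        with pytest.raises(ValueError):
            # the only miRNA is skipped -> effectively empty set downstream,
            # but an explicit empty input is the error case
            scan_sequence(GenomeSequence("g", "GGGG"), {}, modes=[RH])
        with caplog.at_level("WARNING"):
            sites = scan_sequence(
                GenomeSequence("g", "G" * 10),
                {"long": "G" * 50, "ok": "G" * 8},
                params=ScoreParameters(min_score=140.0),
                modes=[RH],
                orientations=[ANTI],
            )
        assert "skipped" in caplog.text
        assert all(s.mirna_id == "ok" for s in sites)

    def test_plant_at_position_zero(self):
        mirnas = {"m": "GAGGAGAAGGAGGAGAAGGAGG"}
        target = perfect_target(mirnas["m"])
        from triplexscan.simulate import PlantingPlan

        genome, truth = plant_genome(
            PlantingPlan(2_000, [("m", target, 0, "+")], seed=5), mirnas
        )
        sites = scan_sequence(genome, mirnas, modes=[RH], orientations=[ANTI])
        assert any(s.start == 0 and s.end == len(target) for s in sites)


class TestSegmentedScan:
    def test_segment_union_equals_whole_scan(self, planted_scan):
        genome, mirnas, _, whole = planted_scan
        seg = scan_sequence(
            genome, mirnas, modes=[RH], orientations=[ANTI],
            segment_length=7_000, overlap=64,
        )
        assert sorted(s.key() for s in seg) == sorted(s.key() for s in whole)

    def test_insufficient_overlap_rejected(self, planted_scan):
        genome, mirnas, _, _ = planted_scan
        with pytest.raises(ValueError, match="overlap"):
            scan_sequence(
                genome, mirnas, modes=[RH], orientations=[ANTI],
                segment_length=5_000, overlap=3,
            )
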