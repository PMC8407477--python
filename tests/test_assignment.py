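"""T1/T2/T3 rules: boundaries, literal truth tables, brute-force equivalence."""

import numpy as np
import pytest

from _oracles import brute_force_assign
from strainsift.alignment import AlignmentRecord
from strainsift.assignment import (
    assign_sample,
    classify_read,
    filter_background,
    resolve_t3,
    validity_filter,
)
from strainsift.synthetic import (
    StrainGenome,
    generate_strain_panel,
    sample_community,
    simulate_reads,
)


def rec(genome="G", start=0, length=100, nmm=0, strand="+", read="r"):
    return AlignmentRecord(read_id=read, genome_id=genome, start=start,
                           aligned_length=length, n_mismatches=nmm, strand=strand)


class TestValidityFilter:
    @pytest.mark.parametrize("nmm,length,expected", [
        (5, 100, False),  # boundary: 5 per 100 is invalid
        (4, 100, True),
        (0, 100, True),
        (3, 50, False),   # 0.06 >= 0.05
        (2, 50, True),    # 0.04 < 0.05
    ])
    def test_boundaries(self, nmm, length, expected):
        assert validity_filter(rec(nmm=nmm, length=length)) is expected

    def test_zero_length_rejected(self):
        bad = rec(nmm=0, length=1)
        object.__setattr__(bad, "aligned_length", 0)
        with pytest.raises(ValueError):
            validity_filter(bad)


class TestFilterBackground:
    def test_read_with_valid_background_hit_removed(self):
        kept = filter_background(["r1", "r2"], [rec(read="r1", nmm=1)])
        assert kept == ["r2"]

    def test_invalid_background_hit_does_not_remove(self):
        kept = filter_background(["r1"], [rec(read="r1", nmm=5)])
        assert kept == ["r1"]

    def test_empty_background_is_identity(self):
        assert filter_background(["r1", "r2"], []) == ["r1", "r2"]


class TestClassifyRead:
    def test_unique_best_is_t1_others_t2(self):
        als = [rec(genome="G", nmm=1), rec(genome="H", nmm=3)]
        assert classify_read("r", als, "G") == "T1"
        assert classify_read("r", als, "H") == "T2"

    def test_tied_best_is_t3_for_both(self):
        als = [rec(genome="G", nmm=2), rec(genome="H", nmm=2)]
        assert classify_read("r", als, "G") == "T3"
        assert classify_read("r", als, "H") == "T3"

    def test_no_alignment_to_g_but_elsewhere_is_t2(self):
        assert classify_read("r", [rec(genome="H", nmm=1)], "G") == "T2"

    def test_no_valid_alignment_anywhere_is_none(self):
        assert classify_read("r", [rec(genome="H", nmm=5)], "G") == "none"


class TestResolveT3:
    """The four-case truth table of the conditional T3 assignment rule."""

    def test_mismatched_t3_overlapping_better_t1_rejected(self):
        assert resolve_t3(rec(start=100, nmm=2), [rec(start=150, nmm=1)]) is False

    def test_perfect_t3_always_assigned(self):
        assert resolve_t3(rec(start=100, nmm=0), [rec(start=150, nmm=1)]) is True

    def test_mismatched_t3_without_overlap_assigned(self):
        assert resolve_t3(rec(start=100, nmm=2), [rec(start=300, nmm=0)]) is True

    def test_mismatched_t3_overlapping_worse_t1_assigned(self):
        assert resolve_t3(rec(start=100, nmm=2), [rec(start=150, nmm=3)]) is True

    def test_exhaustive_case_enumeration(self):
        # every combination of overlap in {0, 1, 50, 100} shared bases,
        # t3 mismatches in 0..4, t1 mismatches in 0..4
        for shared in (0, 1, 50, 100):
            t1_start = 100 + (100 - shared)
            for t3_nmm in range(5):
                for t1_nmm in range(5):
                    expected = not (
                        t3_nmm > 0 and shared >= 1 and t1_nmm < t3_nmm
                    )
                    got = resolve_t3(
                        rec(start=100, nmm=t3_nmm),
                        [rec(start=t1_start, nmm=t1_nmm)],
                    )
                    assert got is expected, (shared, t3_nmm, t1_nmm)

    def test_t1_on_other_genome_ignored(self):
        other = rec(genome="H", start=100, nmm=0)
        assert resolve_t3(rec(genome="G", start=100, nmm=2), [other]) is True


class TestAssignSample:
    def test_single_genome_all_reads_t1(self):
        genome = generate_strain_panel(2000, 1, 0.0, seed=5)[0]
        comp_genome = {genome.id: genome}
        reads = [(f"r{i}", genome.sequence[i * 50 : i * 50 + 100]) for i in range(20)]
        table = assign_sample(reads, [genome])
        assigned = table.assignments[genome.id]
        assert len(assigned) == 20
        assert all(a.label == "T1" for a in assigned)

    def test_identical_genomes_share_every_read_as_t3(self):
        g1 = generate_strain_panel(2000, 1, 0.0, seed=6, id_prefix="a")[0]
        g2 = StrainGenome(id="b000", sequence=g1.sequence)
        reads = [(f"r{i}", g1.sequence[i * 40 : i * 40 + 100]) for i in range(10)]
        table = assign_sample(reads, [g1, g2])
        for gid in (g1.id, g2.id):
            assigned = table.assignments[gid]
            assert {a.read_id for a in assigned} == {f"r{i}" for i in range(10)}
            assert all(a.label == "T3" for a in assigned)

    def test_read_from_divergent_site_is_t1_on_origin_t2_elsewhere(self):
        panel = generate_strain_panel(2000, 2, 0.03, seed=7)
        a, b = panel
        # pick a window where the two strains differ
        start = next(
            s for s in range(0, 1900, 10)
            if a.sequence[s : s + 100] != b.sequence[s : s + 100]
        )
        table = assign_sample([("r", a.sequence[start : start + 100])], panel)
        assert [x.label for x in table.assignments[a.id]] == ["T1"]
        assert table.assignments[b.id] == []

    def test_background_genome_never_increases_assignments(self):
        focal = generate_strain_panel(2000, 2, 0.02, seed=8)
        background = generate_strain_panel(2000, 1, 0.0, seed=9, id_prefix="bg",
                                           is_focal=False)
        genomes = {g.id: g for g in focal + background}
        comp = sample_community(focal, background, seed=10)
        reads, _ = simulate_reads(comp, genomes, 500, seed=11)
        without = assign_sample(reads, focal)
        with_bg = assign_sample(reads, focal, background)
        for gid in (g.id for g in focal):
            set_without = {a.read_id for a in without.assignments[gid]}
            set_with = {a.read_id for a in with_bg.assignments[gid]}
            assert set_with <= set_without

    def test_assignment_is_deterministic(self, small_panel, background_panel):
        comp = sample_community(small_panel, background_panel, seed=1)
        genomes = {g.id: g for g in list(small_panel) + list(background_panel)}
        reads, _ = simulate_reads(comp, genomes, 300, seed=2)
        t1 = assign_sample(reads, small_panel, background_panel)
        t2 = assign_sample(reads, small_panel, background_panel)
        assert t1.key_set() == t2.key_set()

    def test_no_assigned_alignment_violates_validity(self, small_panel):
        comp_reads = [
            (f"r{i}", small_panel[0].sequence[i * 30 : i * 30 + 100])
            for i in range(30)
        ]
        table = assign_sample(comp_reads, small_panel)
        for assigned in table.assignments.values():
            for a in assigned:
                assert a.alignment.n_mismatches / a.alignment.aligned_length < 0.05


class TestBruteForceEquivalence:
    """Pipeline output must equal a literal rule-by-rule reimplementation."""

    @pytest.mark.parametrize("seed", range(8))
    def test_randomized_micro_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_focal = int(rng.integers(2, 5))
        length = int(rng.integers(1000, 2000))
        focal = generate_strain_panel(length, n_focal, float(rng.uniform(0.005, 0.04)),
                                      seed=seed)
        background = generate_strain_panel(
            length, 1, 0.0, seed=1000 + seed, id_prefix="bg", is_focal=False
        )
        genomes = {g.id: g for g in focal + background}
        comp = sample_community(focal, background, seed=seed)
        sim_reads, _ = simulate_reads(
            comp, genomes, 120, substitution_rate=float(rng.uniform(0.0, 0.03)),
            seed=2000 + seed,
        )
        reads = [(r.read_id, r.sequence) for r in sim_reads]
        expected = brute_force_assign(reads, focal, background)
        got = assign_sample(sim_reads, focal, background).key_set()
        assert got == expected
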