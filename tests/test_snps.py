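"""SNP caller thresholds, intersection, prevalence filter, densities."""

import numpy as np
import pandas as pd
import pytest

from _oracles import bh_qvalues
from strainsift.alignment import map_reads
from strainsift.io import read_vcf, write_vcf
from strainsift.profiling import StrainProfileMatrix
from strainsift.snps import (
    Pileup,
    SNPCall,
    call_snps,
    density_group_test,
    downsample_reads,
    intersect_calls,
    prevalence_filter,
    snp_density_per_sample,
)
from strainsift.synthetic import StrainGenome, generate_strain_panel


def pileup_from_counts(ref_seq, column_counts):
    """Pileup with explicit (position -> {base: count}) overrides; other
    positions get clean reference-only coverage 0."""
    from strainsift._seq import BASES, encode

    ref = encode(ref_seq)
    counts = np.zeros((len(ref_seq), 4), dtype=np.int64)
    for pos, per_base in column_counts.items():
        for base, c in per_base.items():
            counts[pos, BASES.index(base)] = c
    return Pileup(genome_id="g", ref_codes=ref, counts=counts)


class TestCallSnps:
    def test_depth_below_minimum_not_called(self):
        pile = pileup_from_counts("AAAA", {1: {"A": 5, "C": 4}})  # depth 9
        assert call_snps(pile) == []

    def test_alt_reads_below_minimum_not_called(self):
        pile = pileup_from_counts("AAAA", {1: {"A": 7, "C": 3}})  # depth 10, alt 3
        assert call_snps(pile) == []

    def test_boundaries_met_inclusively_called(self):
        pile = pileup_from_counts("AAAA", {1: {"A": 16, "C": 4}})  # 4/20 = 0.2
        calls = call_snps(pile)
        assert len(calls) == 1
        c = calls[0]
        assert (c.position, c.ref_base, c.alt_base) == (1, "A", "C")
        assert (c.depth, c.alt_count) == (20, 4)
        assert c.alt_frequency == pytest.approx(0.2)

    def test_frequency_below_minimum_not_called(self):
        pile = pileup_from_counts("AAAA", {1: {"A": 17, "C": 4}})  # 4/21 < 0.2
        assert call_snps(pile) == []

    def test_reference_identical_pileup_yields_no_calls(self):
        genome = generate_strain_panel(1000, 1, 0.0, seed=3)[0]
        reads = [(f"r{i}", genome.sequence[s : s + 100])
                 for i, s in enumerate(range(0, 900, 20))]
        alignments = [a for a in map_reads(reads, genome) if a.n_mismatches == 0]
        pile = Pileup.from_alignments(genome, alignments, dict(reads))
        assert call_snps(pile) == []

    def test_low_quality_bases_excluded_from_pileup(self):
        genome = StrainGenome(id="g", sequence="A" * 120)
        reads = {f"r{i}": "C" * 100 for i in range(12)}
        from strainsift.alignment import AlignmentRecord
        alignments = [AlignmentRecord(r, "g", 0, 100, 100, "+") for r in reads]
        quals = {r: "!" * 100 for r in reads}  # Phred 0 < 15
        pile = Pileup.from_alignments(genome, alignments, reads, quals)
        assert pile.depth.max() == 0
        assert call_snps(pile) == []

    def test_planted_differences_recovered(self):
        # strain B = reference A with fixed substitutions; error-free reads
        # from B at ~20x must recover the planted sites where depth >= 10
        ref = generate_strain_panel(2000, 1, 0.0, seed=8)[0]
        rng = np.random.default_rng(9)
        planted = sorted(rng.choice(2000, size=25, replace=False).tolist())
        alt = list(ref.sequence)
        for p in planted:
            alt[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[alt[p]]
        alt_seq = "".join(alt)
        reads = {}
        starts = rng.integers(0, 1900, size=400)
        for i, s in enumerate(starts):
            reads[f"r{i}"] = alt_seq[s : s + 100]
        # pile reads up at their true positions (error-free, ungapped)
        from strainsift.alignment import AlignmentRecord
        alignments = [AlignmentRecord(f"r{i}", ref.id, int(s), 100, 0, "+")
                      for i, s in enumerate(starts)]
        pile = Pileup.from_alignments(ref, alignments, reads)
        calls = {c.position for c in call_snps(pile)}
        detectable = [p for p in planted if pile.depth[p] >= 10]
        assert detectable, "fixture must cover planted sites"
        recovered = sum(p in calls for p in detectable)
        assert recovered >= 0.95 * len(detectable)
        assert not (calls - set(planted))  # no false positives without errors


class TestIntersectCalls:
    def c(self, pos, alt="C", depth=20, alt_count=5):
        return SNPCall("g", pos, "A", alt, depth, alt_count, alt_count / depth)

    def test_identical_sets(self):
        a = [self.c(1), self.c(2)]
        assert intersect_calls(a, list(a)) == a

    def test_disjoint_sets(self):
        assert intersect_calls([self.c(1)], [self.c(2)]) == []

    def test_single_shared_position_fields_from_first(self):
        a = [self.c(1, depth=30), self.c(2), self.c(3), self.c(4), self.c(5)]
        b = [self.c(3, depth=99), self.c(7), self.c(8)]
        out = intersect_calls(a, b)
        assert [x.position for x in out] == [3]
        assert out[0].depth == 20  # from calls_a

    def test_mismatched_alt_not_intersected(self):
        assert intersect_calls([self.c(1, alt="C")], [self.c(1, alt="G")]) == []


def profile_with_qualifying_counts(n_qual_a, n_qual_b, coverage=0.45, depth=12.0,
                                   n_samples=25):
    samples = [f"A{i}" for i in range(n_samples)] + [f"B{i}" for i in range(n_samples)]
    groups = pd.Series(["A"] * n_samples + ["B"] * n_samples, index=samples)
    cov = pd.Series(0.0, index=samples)
    dep = pd.Series(0.0, index=samples)
    cov.iloc[:n_qual_a] = coverage
    dep.iloc[:n_qual_a] = depth
    cov.iloc[n_samples : n_samples + n_qual_b] = coverage
    dep.iloc[n_samples : n_samples + n_qual_b] = depth
    coverage_m = pd.DataFrame({"s1": cov})
    depth_m = pd.DataFrame({"s1": dep})
    return StrainProfileMatrix(coverage=coverage_m, depth=depth_m,
                               abundance=coverage_m * 0.0, groups=groups)


class TestPrevalenceFilter:
    def test_qualifying_in_both_groups_retained(self):
        prof = profile_with_qualifying_counts(21, 21)
        assert prevalence_filter(prof) == ["s1"]

    def test_failing_one_group_dropped(self):
        prof = profile_with_qualifying_counts(21, 19)
        assert prevalence_filter(prof) == []

    def test_exact_threshold_values_dropped_strict(self):
        prof = profile_with_qualifying_counts(25, 25, coverage=0.40)
        assert prevalence_filter(prof) == []
        prof = profile_with_qualifying_counts(25, 25, depth=10.0)
        assert prevalence_filter(prof) == []

    def test_monotone_in_thresholds(self):
        prof = profile_with_qualifying_counts(22, 22, coverage=0.5, depth=12.0)
        base = set(prevalence_filter(prof))
        for kwargs in ({"min_coverage": 0.6}, {"min_depth": 15},
                       {"min_samples_per_group": 23}):
            assert set(prevalence_filter(prof, **kwargs)) <= base

    def test_missing_groups_rejected(self):
        prof = profile_with_qualifying_counts(21, 21)
        prof.groups = None
        with pytest.raises(ValueError):
            prevalence_filter(prof)


class TestSnpDensity:
    def test_density_arithmetic(self):
        assert snp_density_per_sample(0, 5000) == 0.0
        assert snp_density_per_sample(10, 10_000) == pytest.approx(1.0)

    def test_zero_covered_length_rejected(self):
        with pytest.raises(ValueError):
            snp_density_per_sample(3, 0)

    def test_density_from_called_fixture(self):
        pile = pileup_from_counts("A" * 100, {
            i: {"A": 16, "C": 4} for i in range(0, 100, 10)
        })
        calls = call_snps(pile)
        covered = pile.callable_length(min_depth=10)
        assert covered == 10
        assert snp_density_per_sample(len(calls), covered) == pytest.approx(
            1000.0 * len(calls) / covered
        )


class TestDensityGroupTest:
    def densities(self, x, y, strain="s1"):
        idx = [f"A{i}" for i in range(len(x))] + [f"B{i}" for i in range(len(y))]
        groups = pd.Series(["A"] * len(x) + ["B"] * len(y), index=idx)
        return pd.DataFrame({strain: list(x) + list(y)}, index=idx), groups

    def test_identical_distributions(self):
        d, g = self.densities([1, 2, 3, 4], [1, 2, 3, 4])
        out = density_group_test(d, g)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert out.loc[0, "q_value"] == pytest.approx(1.0)

    def test_single_strain_q_equals_p(self):
        d, g = self.densities([1, 2, 3], [2, 3, 4])
        out = density_group_test(d, g)
        assert out.loc[0, "q_value"] == pytest.approx(out.loc[0, "p_value"])

    def test_bh_matches_hand_computation(self):
        p = [0.01, 0.02, 0.03]
        assert bh_qvalues(p) == pytest.approx([0.03, 0.03, 0.03])
        from statsmodels.stats.multitest import multipletests
        assert multipletests(p, method="fdr_bh")[1] == pytest.approx([0.03, 0.03, 0.03])

    def test_type_i_error_rate_under_null(self):
        rng = np.random.default_rng(12)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            d, g = self.densities(rng.normal(0, 1, 15), rng.normal(0, 1, 15))
            out = density_group_test(d, g)
            hits += out.loc[0, "p_value"] < 0.05
        assert 0.02 <= hits / n_sims <= 0.09

    def test_single_group_rejected(self):
        d, g = self.densities([1, 2], [])
        g[:] = "A"
        with pytest.raises(ValueError):
            density_group_test(d, g)

    def test_storey_option_runs(self):
        rng = np.random.default_rng(3)
        idx = [f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)]
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=idx)
        d = pd.DataFrame(rng.uniform(0, 5, size=(20, 6)),
                         index=idx, columns=[f"s{i}" for i in range(6)])
        out = density_group_test(d, groups, fdr_method="storey")
        assert (out["q_value"] >= 0).all() and (out["q_value"] <= 1).all()


class TestDownsample:
    def make(self, counts):
        return {f"s{i}": [f"s{i}:r{j}" for j in range(c)]
                for i, c in enumerate(counts)}

    def test_below_threshold_unchanged(self):
        reads = self.make([10, 12, 40])
        out = downsample_reads(reads, outlier_threshold=30, seed=1)
        assert out["s0"] == reads["s0"]
        assert out["s1"] == reads["s1"]

    def test_flagged_sample_hits_target_mean_exactly(self):
        reads = self.make([10, 12, 40])  # mean ~ 20.67 -> 21
        out = downsample_reads(reads, outlier_threshold=30, seed=1)
        assert len(out["s2"]) == round((10 + 12 + 40) / 3)
        assert set(out["s2"]) <= set(reads["s2"])

    def test_seed_determinism(self):
        reads = self.make([10, 12, 40])
        a = downsample_reads(reads, 30, seed=5)
        b = downsample_reads(reads, 30, seed=5)
        assert a == b

    def test_inconsistent_threshold_raises(self):
        reads = self.make([100, 100, 5])  # mean 68 > flagged sample's... pick threshold 4
        with pytest.raises(RuntimeError):
            downsample_reads(reads, outlier_threshold=4, seed=1)


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path):
        calls = [
            SNPCall("g1", 5, "A", "C", 20, 5, 0.25),
            SNPCall("g1", 50, "T", "G", 12, 4, 4 / 12),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(calls, {"g1": 1000}, path)
        back = read_vcf(path)
        assert [(c.genome_id, c.position, c.ref_base, c.alt_base, c.depth,
                 c.alt_count) for c in back] == [
            (c.genome_id, c.position, c.ref_base, c.alt_base, c.depth,
             c.alt_count) for c in calls]
        for got, exp in zip(back, calls):
            assert got.alt_frequency == pytest.approx(exp.alt_frequency, abs=1e-5)
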