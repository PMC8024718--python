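"""Harmonization, baselines, calling, burden: examples plus per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnahet.harmonize import (
    CallMatrix,
    call_aberrations,
    cna_burden,
    cohort_cna_frequency,
    gene_level_calls,
    harmonize,
    lesion_baseline,
    ploidy_stats,
    weighted_median,
)
from cnahet.io_formats import GeneInterval, GenomicSegment
from conftest import (
    oracle_baseline,
    oracle_calls_and_burden,
    per_base_values,
    profile,
    random_mini_profiles,
)


class TestHarmonize:
    def test_single_lesion_is_identity(self):
        m = harmonize([profile("A", [("1", 0, 100, 2.0)])])
        assert m.n_regions == 1
        assert (m.starts[0], m.ends[0]) == (0, 100)
        assert m.values[0, 0] == 2.0

    def test_union_breakpoints_two_lesions(self):
        a = profile("A", [("1", 0, 100, 2.0)])
        b = profile("B", [("1", 0, 60, 2.0), ("1", 60, 100, 4.0)])
        m = harmonize([a, b])
        assert m.starts.tolist() == [0, 60]
        assert m.ends.tolist() == [60, 100]
        assert m.values[:, 0].tolist() == [2.0, 2.0]
        assert m.values[:, 1].tolist() == [2.0, 4.0]

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ValueError):
            harmonize([])

    def test_idempotent(self, rng):
        profiles = random_mini_profiles(rng, 4)
        m1 = harmonize(profiles)
        # rebuild profiles from the harmonized matrix and harmonize again
        rebuilt = []
        for j, lesion in enumerate(m1.lesion_ids):
            segs = [
                (m1.chromosomes[i], int(m1.starts[i]), int(m1.ends[i]), m1.values[i, j])
                for i in range(m1.n_regions)
                if not np.isnan(m1.values[i, j])
            ]
            rebuilt.append(profile(lesion, segs, patient_id=m1.patient_ids[j]))
        m2 = harmonize(rebuilt)
        assert m2.starts.tolist() == m1.starts.tolist()
        assert m2.ends.tolist() == m1.ends.tolist()
        assert np.array_equal(m2.values, m1.values, equal_nan=True)

    def test_footprint_length_preserved_per_lesion(self, rng):
        profiles = random_mini_profiles(rng, 3)
        m = harmonize(profiles)
        lengths = m.lengths
        for j, prof in enumerate(profiles):
            covered = lengths[~np.isnan(m.values[:, j])].sum()
            assert covered == prof.covered_length

    def test_matches_per_base_oracle_on_random_cohorts(self, rng):
        chroms, clen = ["1", "2"], 120
        for _ in range(50):
            n = int(rng.integers(2, 6))
            profiles = random_mini_profiles(rng, n, chrom_len=clen)
            m = harmonize(profiles)
            for j, prof in enumerate(profiles):
                base = per_base_values(prof, chroms, clen)
                for i in range(m.n_regions):
                    window = base[m.chromosomes[i]][m.starts[i] : m.ends[i]]
                    v = m.values[i, j]
                    if np.isnan(v):
                        assert np.all(np.isnan(window))
                    else:
                        assert np.all(window == v)


class TestBaseline:
    def test_constant_genome(self):
        assert lesion_baseline(profile("A", [("1", 0, 100, 2.0)])) == 2.0

    def test_length_weighted_median_ignores_short_segment(self):
        p = profile("A", [("1", 0, 90, 2.0), ("1", 90, 100, 4.0)])
        assert lesion_baseline(p) == 2.0

    def test_matches_unit_expansion_oracle(self, rng):
        for _ in range(30):
            (p,) = random_mini_profiles(rng, 1, gap_probability=0.3)
            assert lesion_baseline(p) == pytest.approx(
                oracle_baseline(p, ["1", "2"], 120)
            )

    @given(
        st.lists(
            st.tuples(st.floats(0, 8), st.integers(1, 50)), min_size=1, max_size=8
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_weighted_median_equals_expanded_median(self, pairs):
        values = np.array([v for v, _ in pairs])
        weights = np.array([w for _, w in pairs], dtype=float)
        expanded = np.repeat(values, [int(w) for w in weights])
        assert weighted_median(values, weights) == pytest.approx(np.median(expanded))


class TestCalling:
    def test_all_values_at_baseline_are_neutral(self):
        m = harmonize([profile("A", [("1", 0, 100, 2.0)])])
        calls = call_aberrations(m)
        assert np.all(calls.calls == 0)

    def test_closed_threshold_arithmetic(self):
        # one long baseline segment plus short probes at 3.2 and 1.05
        p = profile(
            "A",
            [("1", 0, 1000, 2.0), ("1", 1000, 1010, 3.2), ("1", 1010, 1020, 1.05)],
        )
        calls = call_aberrations(harmonize([p]))
        assert calls.baselines[0] == 2.0
        by_start = dict(zip(calls.starts.tolist(), calls.calls[:, 0].tolist()))
        assert by_start[1000] == 1.0  # 1.2 >= 1
        assert by_start[1010] == 0.0  # -0.95 > -1
        assert by_start[0] == 0.0

    def test_exact_one_copy_gain_is_called(self):
        p = profile("A", [("1", 0, 1000, 2.0), ("1", 1000, 1010, 3.0)])
        calls = call_aberrations(harmonize([p]))
        assert calls.calls[calls.starts.tolist().index(1000), 0] == 1.0

    def test_threshold_validation(self):
        m = harmonize([profile("A", [("1", 0, 100, 2.0)])])
        with pytest.raises(ValueError):
            call_aberrations(m, gain_threshold=0)
        with pytest.raises(ValueError):
            call_aberrations(m, loss_threshold=0.5)

    def test_gain_calls_monotone_in_threshold(self, rng):
        profiles = random_mini_profiles(rng, 4)
        m = harmonize(profiles)
        counts = []
        for thr in (0.5, 1.0, 1.5, 2.0):
            calls = call_aberrations(m, gain_threshold=thr)
            counts.append(int(np.nansum(calls.calls == 1.0)))
        assert counts == sorted(counts, reverse=True)

    def test_matches_per_base_oracle(self, rng):
        chroms, clen = ["1", "2"], 120
        for _ in range(20):
            profiles = random_mini_profiles(rng, int(rng.integers(2, 5)))
            calls = call_aberrations(harmonize(profiles))
            oracle_calls, _ = oracle_calls_and_burden(profiles, chroms, clen)
            for j, prof in enumerate(profiles):
                for i in range(len(calls.starts)):
                    window = oracle_calls[prof.lesion_id][calls.chromosomes[i]][
                        calls.starts[i] : calls.ends[i]
                    ]
                    v = calls.calls[i, j]
                    if np.isnan(v):
                        assert np.all(np.isnan(window))
                    else:
                        assert np.all(window == v)


class TestBurden:
    def test_all_neutral_lesion_is_zero(self):
        calls = call_aberrations(harmonize([profile("A", [("1", 0, 100, 2.0)])]))
        assert cna_burden(calls).per_lesion["A"] == 0.0

    def test_half_genome_gained_is_fifty_percent(self):
        # baseline anchored by a dominant neutral stretch, then exactly
        # half of a second lesion-free slice gained
        p = profile("A", [("1", 0, 300, 2.0), ("2", 0, 300, 4.0), ("3", 0, 600, 2.0)])
        calls = call_aberrations(harmonize([p]))
        # 300 of 1200 bp aberrant = 25%; symmetry check on a direct call matrix
        assert cna_burden(calls).per_lesion["A"] == pytest.approx(25.0)
        half = CallMatrix(
            chromosomes=np.array(["1", "1"], dtype=object),
            starts=np.array([0, 100]),
            ends=np.array([100, 200]),
            calls=np.array([[1.0], [0.0]]),
            baselines=np.array([2.0]),
            gain_threshold=1.0,
            loss_threshold=-1.0,
            lesion_ids=["A"],
            patient_ids=["P"],
        )
        assert cna_burden(half).per_lesion["A"] == pytest.approx(50.0)

    def test_per_patient_is_mean_over_lesions(self):
        a = profile("A", [("1", 0, 300, 2.0), ("2", 0, 100, 4.0)], patient_id="P")
        b = profile("B", [("1", 0, 300, 2.0), ("2", 0, 100, 2.0)], patient_id="P")
        calls = call_aberrations(harmonize([a, b]))
        # lesion A: 100/400 bp aberrant = 25%, lesion B: 0% -> patient 12.5%
        assert cna_burden(calls).per_patient["P"] == pytest.approx(12.5)

    def test_subdivision_invariance(self, rng):
        """Splitting any input segment must not change baseline/calls/burden."""
        for _ in range(10):
            profiles = random_mini_profiles(rng, 3)
            split = []
            for prof in profiles:
                segs = []
                for s in prof.segments:
                    if s.length >= 2 and rng.random() < 0.7:
                        mid = int(rng.integers(s.start + 1, s.end))
                        segs += [
                            (s.chromosome, s.start, mid, s.copy_number),
                            (s.chromosome, mid, s.end, s.copy_number),
                        ]
                    else:
                        segs.append((s.chromosome, s.start, s.end, s.copy_number))
                split.append(profile(prof.lesion_id, segs, patient_id=prof.patient_id))
            b0 = cna_burden(call_aberrations(harmonize(profiles)))
            b1 = cna_burden(call_aberrations(harmonize(split)))
            for lesion in b0.per_lesion.index:
                assert b0.per_lesion[lesion] == pytest.approx(b1.per_lesion[lesion])
            for prof, sp in zip(profiles, split):
                assert lesion_baseline(prof) == lesion_baseline(sp)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(20):
            profiles = random_mini_profiles(rng, int(rng.integers(2, 5)))
            burden = cna_burden(call_aberrations(harmonize(profiles)))
            _, oracle = oracle_calls_and_burden(profiles, ["1", "2"], 120)
            for lesion, expected in oracle.items():
                assert burden.per_lesion[lesion] == pytest.approx(expected)


class TestPloidyStats:
    @pytest.mark.parametrize(
        "ploidies, expected",
        [((2, 2, 2), (2, 0)), ((2, 3.4), (2.7, 1.4)), ((3.1,), (3.1, 0))],
    )
    def test_median_and_range(self, ploidies, expected):
        med, rng_ = ploidy_stats(ploidies)
        assert med == pytest.approx(expected[0])
        assert rng_ == pytest.approx(expected[1])


class TestGeneLevelCalls:
    def _calls(self):
        # patient P: lesion A gains [100, 200); lesion B neutral there
        a = profile(
            "A", [("1", 0, 100, 2.0), ("1", 100, 200, 4.0), ("1", 200, 1000, 2.0)],
            patient_id="P",
        )
        b = profile("B", [("1", 0, 1000, 2.0)], patient_id="P")
        return call_aberrations(harmonize([a, b]))

    def test_gene_takes_largest_overlap_region(self):
        calls = self._calls()
        # gene spans [140, 240): 60 bp in the gained region, 40 bp after -> +1
        gene = GeneInterval("G", "1", 140, 240)
        res = gene_level_calls(calls, [gene])
        assert res.calls.loc["G", "A"] == 1.0
        # gene spans [160, 260): 40 bp gained, 60 bp neutral -> 0
        res2 = gene_level_calls(calls, [GeneInterval("G", "1", 160, 260)])
        assert res2.calls.loc["G", "A"] == 0.0

    def test_heterogeneity_flag(self):
        calls = self._calls()
        inside = GeneInterval("IN", "1", 110, 150)
        outside = GeneInterval("OUT", "1", 300, 400)
        res = gene_level_calls(calls, [inside, outside])
        assert bool(res.heterogeneity.loc["IN", "P"]) is True  # +1 in A, 0 in B
        assert bool(res.heterogeneity.loc["OUT", "P"]) is False

    def test_gene_without_region_is_missing_with_warning(self, caplog):
        calls = self._calls()
        with caplog.at_level("WARNING"):
            res = gene_level_calls(calls, [GeneInterval("FAR", "9", 0, 10)])
        assert np.isnan(res.calls.loc["FAR", "A"])
        assert "no region" in caplog.text


class TestCohortFrequency:
    def test_any_lesion_rule_and_double_contribution(self):
        # patient P1: lesion A gained, lesion B lost in the same region
        a = profile("A", [("1", 0, 100, 4.0), ("2", 0, 900, 2.0)], patient_id="P1")
        b = profile("B", [("1", 0, 100, 1.0), ("2", 0, 900, 2.0)], patient_id="P1")
        calls = call_aberrations(harmonize([a, b]))
        freq = cohort_cna_frequency(calls)
        row = freq[(freq.chromosome == "1") & (freq.start == 0)].iloc[0]
        assert row.gain_frequency == 1.0  # gained in >= 1 lesion
        assert row.loss_frequency == 1.0  # lost in >= 1 lesion: both counted

    def test_unaberrant_cohort_is_zero_everywhere(self):
        a = profile("A", [("1", 0, 100, 2.0)], patient_id="P1")
        freq = cohort_cna_frequency(call_aberrations(harmonize([a])))
        assert (freq.gain_frequency == 0).all()
        assert (freq.loss_frequency == 0).all()
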