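"""Variant-calling cascade: candidates, the two filter stages, frequencies."""

import numpy as np
import pytest

from mycomut.calling import (CallerConfig, assess_frequencies, call_variants,
                             collect_candidates, coverage_windows,
                             stage1_filter, stage2_founder_filter)
from mycomut.simulate import simulate_line

from conftest import manual_sample, small_config

# depths 100..200 uniformly: window A (10-90%) = [110, 190],
# window B (15-85%) = [115, 185]
PAD = list(range(100, 201))


def make_samples(depth, alt):
    s = manual_sample([depth], [alt], extra_depths=PAD, sample_id="s1")
    founder = manual_sample([depth], [0], extra_depths=PAD,
                            sample_id="founder", length_m=0.0)
    return [s], founder


class TestCollectCandidates:
    def test_no_alt_reads_no_candidates(self):
        samples, founder = make_samples(140, 0)
        assert collect_candidates(samples, founder) == []

    def test_single_alt_read_is_minimal_trigger(self):
        samples, founder = make_samples(140, 1)
        cands = collect_candidates(samples, founder)
        assert len(cands) == 1
        c = cands[0]
        assert (c.position, c.ref_allele, c.alt_allele) == (0, "A", "C")
        assert c.founder_support == 0

    def test_multiple_alt_alleles_yield_separate_candidates(self):
        s = manual_sample([100], [10], extra_depths=PAD)
        t = s.table
        t.loc[0, "G"] = 5
        t.loc[0, "A"] = 85
        founder = manual_sample([100], [0], extra_depths=PAD,
                                sample_id="founder", length_m=0.0)
        cands = collect_candidates([s], founder)
        assert [(c.alt_allele) for c in cands] == ["C", "G"]

    def test_coordinate_mismatch_names_position(self):
        samples, founder = make_samples(140, 1)
        shifted = samples[0].table.copy()
        shifted["pos0"] = shifted["pos0"] + 1000
        bad = manual_sample([100], [0], extra_depths=PAD)
        bad.table = shifted
        with pytest.raises(ValueError, match="mismatch"):
            collect_candidates([bad], founder)

    def test_matches_brute_force_enumeration_on_simulation(self):
        """Candidate set equals a direct scan of the count tables."""
        cfg = small_config(seed=21, n_background_sites=300)
        _, samples = simulate_line(cfg)
        founder, derived = samples[0], samples[1:]
        cands = collect_candidates(derived, founder)
        got = {(c.position, c.alt_allele) for c in cands}

        expected = set()
        for s in derived:
            for _, row in s.table.iterrows():
                for b in "ACGT":
                    if b != row["ref"] and row[b] > 0:
                        expected.add((int(row["pos0"]), b))
                for allele, n in row["indels"].items():
                    if n > 0:
                        expected.add((int(row["pos0"]), allele))
        assert got == expected


class TestStage1:
    def test_frequency_above_30_in_window_a_passes(self):
        samples, founder = make_samples(140, 49)  # 0.35 at depth 140
        [c] = collect_candidates(samples, founder)
        assert stage1_filter(c, samples, CallerConfig())

    def test_exactly_30_percent_is_strictly_excluded(self):
        # depth 110 sits inside window A but outside window B, so the
        # >20% branch cannot rescue a frequency of exactly 0.30
        samples, founder = make_samples(110, 33)
        [c] = collect_candidates(samples, founder)
        assert not stage1_filter(c, samples, CallerConfig())

    def test_25_percent_in_window_b_passes(self):
        samples, founder = make_samples(120, 30)
        [c] = collect_candidates(samples, founder)
        assert stage1_filter(c, samples, CallerConfig())

    def test_low_frequency_fails(self):
        samples, founder = make_samples(140, 10)
        [c] = collect_candidates(samples, founder)
        assert not stage1_filter(c, samples, CallerConfig())

    def test_fraction_of_mean_mode(self):
        samples, founder = make_samples(140, 49)
        [c] = collect_candidates(samples, founder)
        cfg = CallerConfig(coverage_window_mode="fraction_of_mean",
                           cov_window_a=(50.0, 150.0),
                           cov_window_b=(60.0, 140.0))
        assert stage1_filter(c, samples, cfg)

    def test_empty_sample_errors(self):
        samples, founder = make_samples(140, 49)
        empty = manual_sample([], [], sample_id="empty")
        with pytest.raises(ValueError, match="no assayed"):
            coverage_windows([empty], CallerConfig())

    def test_monotone_in_thresholds_and_windows(self):
        """Raising thresholds or narrowing windows never adds passes."""
        cfg = small_config(seed=22)
        _, samples = simulate_line(cfg)
        founder, derived = samples[0], samples[1:]
        cands = collect_candidates(derived, founder)
        base = CallerConfig()
        passing = {
            (c.position, c.alt_allele)
            for c in cands if stage1_filter(c, derived, base)
        }
        assert passing  # the comparison is vacuous otherwise
        stricter = [
            CallerConfig(freq_threshold_a=0.45, freq_threshold_b=0.35),
            CallerConfig(cov_window_a=(25.0, 75.0), cov_window_b=(30.0, 70.0)),
            CallerConfig(freq_threshold_a=0.5, freq_threshold_b=0.4,
                         cov_window_a=(20.0, 80.0), cov_window_b=(25.0, 75.0)),
        ]
        for cfg2 in stricter:
            sub = {
                (c.position, c.alt_allele)
                for c in cands if stage1_filter(c, derived, cfg2)
            }
            assert sub <= passing


class TestStage2:
    @pytest.mark.parametrize("support,max_support,expected", [
        (0, 0, True),
        (1, 0, False),
        (0, 2, True),
        (2, 2, True),
        (3, 2, False),
    ])
    def test_founder_support_rule(self, support, max_support, expected):
        samples, founder = make_samples(140, 49)
        [c] = collect_candidates(samples, founder)
        c.founder_support = support
        cfg = CallerConfig(founder_max_support=max_support)
        assert stage2_founder_filter(c, cfg) is expected


class TestAssessFrequencies:
    def _paired(self, d1, a1, d2, a2):
        r1 = manual_sample([d1], [a1], sample_id="p1", replicate_id=1)
        r2 = manual_sample([d2], [a2], sample_id="p1", replicate_id=2)
        founder = manual_sample([100], [0], sample_id="founder", length_m=0.0)
        cands = collect_candidates([r1, r2], founder)
        return assess_frequencies(cands, [r1, r2])

    def test_replicate_mean(self):
        [call] = self._paired(100, 40, 100, 60)
        assert call.frequencies == [0.5]

    def test_single_replicate_plain_ratio(self):
        s = manual_sample([60], [30], sample_id="p1")
        founder = manual_sample([60], [0], sample_id="founder", length_m=0.0)
        cands = collect_candidates([s], founder)
        [call] = assess_frequencies(cands, [s])
        assert call.frequencies == [0.5]

    def test_zero_depth_replicate_dropped_from_mean(self):
        [call] = self._paired(0, 0, 100, 50)
        assert call.frequencies == [0.5]

    def test_all_zero_depth_is_missing_not_zero(self):
        from mycomut.calling import VariantCandidate
        r1 = manual_sample([0], [0], sample_id="p1", replicate_id=1)
        r2 = manual_sample([0], [0], sample_id="p1", replicate_id=2)
        cand = VariantCandidate(position=0, ref_allele="A", alt_allele="C",
                                depths=np.array([0, 0]),
                                alt_counts=np.array([0, 0]), founder_support=0)
        [call] = assess_frequencies([cand], [r1, r2])
        assert np.isnan(call.frequencies[0])

    def test_three_replicates_rejected(self):
        reps = [manual_sample([100], [10], sample_id="p1", replicate_id=r)
                for r in (1, 2, 3)]
        founder = manual_sample([100], [0], sample_id="founder", length_m=0.0)
        cands = collect_candidates(reps, founder)
        with pytest.raises(ValueError, match="more than two replicates"):
            assess_frequencies(cands, reps)


class TestReproducibility:
    def test_identical_input_identical_calls(self):
        cfg = small_config(seed=23)
        _, samples = simulate_line(cfg)
        founder, derived = samples[0], samples[1:]
        out1 = call_variants(derived, founder)
        out2 = call_variants(derived, founder)
        key = lambda calls: [(c.position, c.alt_allele, tuple(c.frequencies))
                             for c in calls[1]]
        assert key(out1) == key(out2)
        flags = lambda cands: [(c.pass_stage1, c.pass_stage2) for c in cands]
        assert flags(out1[0]) == flags(out2[0])
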