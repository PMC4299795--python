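"""Detector: LTR pair finding, TSD calling, domain scanning, chain scores,
completeness filtering and solo-LTR identification."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from paleoerv.detect import (DomainHit, LTRPair, ProvirusCall, TSD,
                             call_proviruses, detect_tsd, filter_complete,
                             find_ltr_pairs, find_solo_ltrs, scan_domains,
                             score_chain, snap_boundaries)
from paleoerv.simulate import (Degradation, GenomeBuild, InsertSpec,
                               SimulationConfig, build_provirus,
                               derive_solo_ltr, generate_background,
                               simulate_genome)
from tests.conftest import truth_near


class TestFindLTRPairs:
    def test_identical_pair_found_with_full_identity(self):
        build = simulate_genome(SimulationConfig(
            60_000, insert_specs=[InsertSpec("ERV1", 0.0)], seed=31))
        pairs = find_ltr_pairs(build)
        assert len(pairs) == 1
        assert pairs[0].identity == 1.0
        t = build.truth[0]
        assert abs(pairs[0].ltr5[0] - t.start) <= 2
        assert abs(pairs[0].ltr3[1] - t.end) <= 2

    def test_diverged_pair_identity_matches_expectation(self):
        build = simulate_genome(SimulationConfig(
            60_000, insert_specs=[InsertSpec("ERV1", 0.078)], seed=32))
        pairs = find_ltr_pairs(build)
        assert len(pairs) == 1
        # K2P d=0.078 -> expected identity ~ exp(-d) ~ 0.925, +- sampling
        assert abs(pairs[0].identity - 0.925) < 0.04

    def test_separation_beyond_range_not_reported(self):
        rng = np.random.default_rng(33)
        bg = generate_background(45_000, 0.5, rng)
        repeat = generate_background(300, 0.5, rng)
        g = bg[:5000] + repeat + bg[5000:25000] + repeat + bg[25000:]
        assert find_ltr_pairs({"s": g}) == []

    def test_empty_genome_empty_list(self):
        assert find_ltr_pairs({"s": generate_background(30_000, 0.5, 1)}) == []


class TestDetectTSD:
    @pytest.mark.parametrize("cls,expected", [
        ("ERV1", 4), ("ERV2", 6), ("ERV3", 5), ("ERV4", 5)])
    def test_planted_class_tsd_length(self, cls, expected):
        # a small family: the detector resolves single-element one-base
        # boundary ambiguity with family evidence
        specs = [InsertSpec(cls, 0.01, family=0) for _ in range(4)]
        build = simulate_genome(SimulationConfig(
            220_000, insert_specs=specs, seed=41))
        calls = call_proviruses(build)
        assert len(calls) == 4
        lengths = [c.tsd.length for c in calls if c.tsd]
        assert lengths.count(expected) >= 3
        for c in calls:
            t = truth_near(build, c)
            if c.tsd and c.tsd.length == expected:
                assert c.tsd.sequence == t.tsd_sequence

    def test_random_flanks_mostly_none(self):
        rng = np.random.default_rng(42)
        none_count = 0
        trials = 40
        for _ in range(trials):
            seq = generate_background(6000, 0.5, rng)
            pair = LTRPair("s", (1000, 1400), (4600, 5000), 1.0, 400)
            if detect_tsd({"s": seq}, pair) is None:
                none_count += 1
        # per trial P(no exact >=3-mer) >= 1 - 2*4^-3 ~ 0.97
        assert none_count >= trials - 5

    def test_pair_at_scaffold_edge_none(self):
        seq = generate_background(8000, 0.5, 5)
        pair = LTRPair("s", (0, 400), (7600, 8000), 1.0, 400)
        assert detect_tsd({"s": seq}, pair) is None


class TestScanDomains:
    def test_erv1_full_domain_set(self):
        pv = build_provirus(InsertSpec("ERV1", 0.0), seed=51)
        hits = {h.domain for h in scan_domains(pv.seq[pv.ltr5[1]:pv.ltr3[0]])}
        assert hits == {"gag_ca", "gag_zf", "pro", "RT", "RNaseH", "IN",
                        "GPY_F", "env"}

    def test_erv4_lacks_zf_gpyf_dutpase(self):
        pv = build_provirus(InsertSpec("ERV4", 0.0), seed=52)
        hits = {h.domain for h in scan_domains(pv.seq[pv.ltr5[1]:pv.ltr3[0]])}
        assert {"gag_zf", "GPY_F", "dUTPase"}.isdisjoint(hits)
        assert {"gag_ca", "pro", "RT", "RNaseH", "IN", "env"} <= hits

    def test_strand_symmetric(self):
        pv = build_provirus(InsertSpec("ERV2", 0.0), seed=53)
        internal = pv.seq[pv.ltr5[1]:pv.ltr3[0]]
        fwd = scan_domains(internal)
        rev = scan_domains(str(Seq(internal).reverse_complement()))
        assert {h.domain for h in fwd} == {h.domain for h in rev}
        n = len(internal)
        fwd_spans = {h.domain: (h.start, h.end) for h in fwd}
        for h in rev:
            s, e = fwd_spans[h.domain]
            assert (n - h.end, n - h.start) == (s, e)


class TestChainScore:
    def test_empty_chain_scores_zero(self):
        assert score_chain([], None, None) == 0

    def test_seven_perfect_motifs_ltr_tsd(self):
        hits = [DomainHit(d, 0, i * 100, i * 100 + 50, 100.0)
                for i, d in enumerate(
                    ["gag_ca", "pro", "RT", "RNaseH", "IN", "GPY_F", "env"])]
        pair = LTRPair("s", (0, 400), (7000, 7400), 1.0, 400)
        assert score_chain(hits, pair, TSD("ACGTA")) == 775

    def test_subthreshold_chain_excluded(self):
        build = simulate_genome(SimulationConfig(
            60_000, insert_specs=[InsertSpec("ERV4", 0.0)], seed=54))
        assert len(call_proviruses(build, cutoff=250)) == 1
        assert call_proviruses(build, cutoff=10_000) == []

    @given(st.floats(min_value=0, max_value=100))
    def test_adding_a_hit_never_decreases_score(self, extra_score):
        hits = [DomainHit("pro", 0, 0, 45, 80.0)]
        base = score_chain(hits, None, None)
        more = score_chain(hits + [DomainHit("env", 0, 100, 196, extra_score)],
                           None, None)
        assert more >= base


class TestCallProviruses:
    def test_all_planted_elements_called_at_matching_coordinates(
            self, mixed_build, mixed_calls):
        proviral = [t for t in mixed_build.truth if not t.is_solo]
        assert len(mixed_calls) == len(proviral)
        for c in mixed_calls:
            t = truth_near(mixed_build, c)
            assert abs(c.start - t.start) <= 10
            assert abs(c.end - t.end) <= 10

    def test_empty_genome_empty_calls(self):
        g = {"s": generate_background(40_000, 0.5, 2)}
        assert call_proviruses(g) == []

    def test_sensitivity_and_precision(self):
        specs = [InsertSpec(cls, d, Degradation(0.03), family=f % 3)
                 for f, (cls, d) in enumerate(
                     [("ERV1", 0.02), ("ERV1", 0.05), ("ERV2", 0.03),
                      ("ERV2", 0.06), ("ERV3", 0.04), ("ERV3", 0.02),
                      ("ERV4", 0.05), ("ERV4", 0.03), ("ERV1", 0.07),
                      ("ERV4", 0.04)])]
        build = simulate_genome(SimulationConfig(
            500_000, insert_specs=specs, seed=55))
        calls = call_proviruses(build)
        matched = 0
        for c in calls:
            t = truth_near(build, c)
            if abs(c.start - t.start) <= 10 and abs(c.end - t.end) <= 10:
                matched += 1
        assert matched / len(build.truth) >= 0.90  # sensitivity
        assert matched / len(calls) >= 0.90        # precision


class TestFilterComplete:
    def test_call_missing_env_excluded(self, mixed_calls):
        c = next(c for c in mixed_calls if c.complete)
        import copy
        broken = copy.deepcopy(c)
        broken.hits = [h for h in broken.hits if h.domain != "env"]
        assert filter_complete([broken]) == []

    def test_ambiguity_run_rule(self, mixed_calls):
        import copy
        original = next(c for c in mixed_calls if c.complete)
        c = copy.deepcopy(original)
        c.pol_aa = original.pol_aa[:50] + "X" * 6 + original.pol_aa[56:]
        assert filter_complete([c]) == []
        c.pol_aa = original.pol_aa[:50] + "X" * 5 + original.pol_aa[56:]
        assert filter_complete([c]) == [c]

    def test_subset_and_idempotent(self, mixed_calls):
        kept = filter_complete(mixed_calls)
        assert set(c.id for c in kept) <= set(c.id for c in mixed_calls)
        assert filter_complete(kept) == kept


class TestSoloLTRs:
    def test_derived_solos_found_and_provirus_ltrs_not_double_reported(self):
        specs = [InsertSpec("ERV2", 0.02)] + \
                [InsertSpec("ERV2", 0.02, solo=True) for _ in range(3)]
        build = simulate_genome(SimulationConfig(
            120_000, insert_specs=specs, seed=61))
        calls = call_proviruses(build)
        assert len(calls) == 1
        seq = build.scaffolds[calls[0].scaffold]
        library = {"ltr": seq[slice(*calls[0].pair.ltr5)]}
        solos = find_solo_ltrs(build, library, calls)
        assert len(solos) == 3
        for s in solos:
            assert s.end <= calls[0].start or s.start >= calls[0].end

    def test_empty_library_empty_result(self, mixed_build):
        assert find_solo_ltrs(mixed_build, {}, []) == []

    def test_solo_only_genome_detector_reports_no_proviruses(self):
        specs = [InsertSpec("ERV3", 0.02, solo=True, family=9)
                 for _ in range(4)]
        build = simulate_genome(SimulationConfig(
            120_000, insert_specs=specs, seed=62))
        assert call_proviruses(build) == []
        t = build.truth[0]
        library = {"ltr": build.scaffolds[t.scaffold][t.start:t.end]}
        assert len(find_solo_ltrs(build, library, [])) == 4


class TestStrandSymmetry:
    def test_reverse_complement_mirrors_call_set(self):
        specs = [InsertSpec("ERV1", 0.02), InsertSpec("ERV4", 0.03)]
        build = simulate_genome(SimulationConfig(
            120_000, insert_specs=specs, seed=63))
        fwd = call_proviruses(build)
        n = len(build.scaffolds["scaffold_1"])
        rc = {"scaffold_1": str(Seq(build.scaffolds["scaffold_1"])
                                .reverse_complement())}
        rev = call_proviruses(rc)
        assert len(fwd) == len(rev)
        fwd_spans = sorted((c.start, c.end) for c in fwd)
        rev_spans = sorted((n - e, n - s) for s, e in
                           ((c.start, c.end) for c in rev))
        for (fs, fe), (rs, re_) in zip(fwd_spans, rev_spans):
            assert abs(fs - rs) <= 10 and abs(fe - re_) <= 10
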