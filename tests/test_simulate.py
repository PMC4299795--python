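"""Simulator: background sequence, provirus construction, planting,
degradation, solo derivation, species pairs, and truth-ledger integrity."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

from paleoerv.motifs import CLASS_TABLE, ZF_REGEX
from paleoerv.simulate import (Degradation, InsertSpec, SimulationConfig,
                               SpeciesPairConfig, build_provirus, degrade,
                               derive_solo_ltr, excise, generate_background,
                               make_species_pair, mutate_k2p, plant,
                               simulate_genome)
from paleoerv.dating import k2p_distance, pairwise_ltr_align


def gc(seq):
    return (seq.count("G") + seq.count("C")) / len(seq)


class TestBackground:
    def test_deterministic_and_gc(self):
        a = generate_background(1000, 0.5, 7)
        b = generate_background(1000, 0.5, 7)
        assert a == b and len(a) == 1000
        assert abs(gc(a) - 0.5) < 0.05

    def test_degenerate_gc_zero_gives_at_only(self):
        assert set(generate_background(10, 0.0, 1)) <= {"A", "T"}

    def test_gc_concentration_large_sample(self):
        seq = generate_background(100_000, 0.44, 3)
        assert abs(gc(seq) - 0.44) < 0.01

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            generate_background(0, 0.5, 1)


class TestBuildProvirus:
    def test_erv4_zero_divergence_structure(self):
        pv = build_provirus(InsertSpec("ERV4", 0.0), seed=1)
        assert pv.seq[slice(*pv.ltr5)] == pv.seq[slice(*pv.ltr3)]
        gag = str(Seq(pv.seq[slice(*pv.domains["gag"])]).translate())
        assert not ZF_REGEX.search(gag)
        assert "env" in pv.domains
        pol = str(Seq(pv.seq[slice(*pv.domains["pol"])]).translate())
        assert pol.count("*") == 1 and pol.endswith("*")

    def test_erv3_dutpase_downstream_of_integrase(self):
        from paleoerv.detect import scan_domains
        pv = build_provirus(InsertSpec("ERV3", 0.0), seed=2)
        hits = {h.domain: h for h in
                scan_domains(pv.seq[pv.ltr5[1]:pv.ltr3[0]])}
        assert "dUTPase" in hits
        assert hits["dUTPase"].start >= hits["IN"].end

    def test_erv1_divergence_recovered_by_k2p(self):
        rng = np.random.default_rng(5)
        ds = []
        for i in range(12):
            pv = build_provirus(InsertSpec("ERV1", 0.078), seed=100 + i)
            aln = pairwise_ltr_align(pv.seq[slice(*pv.ltr5)],
                                     pv.seq[slice(*pv.ltr3)])
            ds.append(k2p_distance(aln).d)
        # binomial sampling error on a 400 bp LTR: sd ~ sqrt(d/L) ~ 0.014
        assert abs(np.mean(ds) - 0.078) < 3 * np.sqrt(0.078 / 400 / 12)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            InsertSpec("ERV9")

    def test_capture_exclusive_with_solo(self):
        with pytest.raises(ValueError):
            InsertSpec("ERV4", capture="between_pol_env", solo=True)


class TestPlant:
    def test_tsd_duplicated_per_class(self):
        for cls in CLASS_TABLE:
            t = CLASS_TABLE[cls].tsd_length
            bg = generate_background(5000, 0.5, 3)
            pv = "ACGT" * 300
            edited, start, end, tsd = plant(bg, pv, 2000, t)
            assert len(tsd) == t
            assert edited[start - t:start] == tsd
            assert edited[end:end + t] == tsd
            assert edited[start:end] == pv

    def test_plant_then_excise_roundtrip(self):
        bg = generate_background(5000, 0.5, 9)
        edited, start, end, tsd = plant(bg, "A" * 500, 1000, 5)
        assert excise(edited, start, end, 5) == bg

    def test_site_inside_existing_element_rejected(self):
        bg = generate_background(5000, 0.5, 3)
        with pytest.raises(ValueError):
            plant(bg, "A" * 100, 1500, 4, occupied=[(1000, 2000)])


class TestDegrade:
    def test_zero_rate_identity(self):
        seq = generate_background(2000, 0.5, 4)
        assert degrade(seq, 0.0, 0.0, seed=1) == seq

    def test_force_nonsense_creates_stop_in_pol(self):
        pv = build_provirus(InsertSpec("ERV2", 0.0), seed=3)
        out = degrade(pv.seq, 0.0, 0.0, force_nonsense=True, seed=8,
                      pol_span=pv.domains["pol"])
        pol = str(Seq(out[slice(*pv.domains["pol"])]).translate())
        assert "*" in pol[:-1]

    def test_substitution_rate_applied(self):
        seq = generate_background(10_000, 0.5, 4)
        out = degrade(seq, 0.05, seed=2)
        diff = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert 0.03 < diff < 0.07


class TestSoloLTR:
    def test_solo_length_and_tsd(self):
        spec = InsertSpec("ERV4", 0.02)
        build = simulate_genome(SimulationConfig(
            50_000, insert_specs=[spec], seed=5))
        t = build.truth[0]
        ltr_len = t.ltr5[1] - t.ltr5[0]
        full_len = t.end - t.start
        before = build.scaffolds[t.scaffold]
        derive_solo_ltr(build, t.element_id)
        after = build.scaffolds[t.scaffold]
        assert t.is_solo and t.ltr3 is None
        assert t.end - t.start == ltr_len
        # single LTR still flanked by the original 5 bp TSD
        assert after[t.start - 5:t.start] == t.tsd_sequence
        assert after[t.end:t.end + 5] == t.tsd_sequence
        assert len(before) - len(after) == full_len - ltr_len

    def test_already_solo_rejected(self):
        build = simulate_genome(SimulationConfig(
            50_000, insert_specs=[InsertSpec("ERV4", 0.02)], seed=5))
        derive_solo_ltr(build, build.truth[0].element_id)
        with pytest.raises(ValueError):
            derive_solo_ltr(build, build.truth[0].element_id)

    def test_downstream_coordinates_shift(self):
        specs = [InsertSpec("ERV1", 0.01), InsertSpec("ERV2", 0.01)]
        build = simulate_genome(SimulationConfig(
            120_000, insert_specs=specs, seed=6))
        first, second = sorted(build.truth, key=lambda t: t.start)
        seq_before = build.scaffolds[second.scaffold][second.start:second.end]
        derive_solo_ltr(build, first.element_id)
        assert build.scaffolds[second.scaffold][second.start:second.end] == seq_before


class TestWholeGenome:
    def test_fixed_seed_byte_identical(self):
        specs = [InsertSpec("ERV1", 0.05, Degradation(0.02, 0.001))]
        a = simulate_genome(SimulationConfig(60_000, insert_specs=specs, seed=11))
        b = simulate_genome(SimulationConfig(60_000, insert_specs=specs, seed=11))
        assert a.scaffolds == b.scaffolds
        assert [vars(x) for x in a.truth] == [vars(x) for x in b.truth]

    def test_truth_coordinates_index_the_fasta(self, mixed_build):
        for t in mixed_build.truth:
            seq = mixed_build.scaffolds[t.scaffold]
            # TSD copies flank the element
            tl = len(t.tsd_sequence)
            assert seq[t.start - tl:t.start] == t.tsd_sequence
            assert seq[t.end:t.end + tl] == t.tsd_sequence
            if not t.is_solo:
                s, e = t.domains["pol"]
                pol = str(Seq(seq[s:e]).translate())
                assert pol.endswith("*")

    def test_tsd_lengths_match_class_table(self, mixed_build):
        for t in mixed_build.truth:
            assert len(t.tsd_sequence) == CLASS_TABLE[t.class_label].tsd_length

    def test_ltr_divergence_unbiased(self):
        """Mean measured K2P divergence over >=50 replicate pairs is an
        unbiased estimate of the requested age divergence (paired t-test
        not rejecting at alpha=0.01)."""
        rng = np.random.default_rng(17)
        d_true = 0.05
        errs = []
        for _ in range(50):
            anc = generate_background(1500, 0.5, rng)
            l5 = mutate_k2p(anc, d_true / 2, rng)
            l3 = mutate_k2p(anc, d_true / 2, rng)
            d = k2p_distance(pairwise_ltr_align(l5, l3)).d
            errs.append(d - d_true)
        assert stats.ttest_1samp(errs, 0.0).pvalue > 0.01


class TestSpeciesPair:
    def test_shared_inserts_linked_in_truth(self):
        shared = [InsertSpec("ERV1", 0.02, family=0) for _ in range(6)]
        spa = [InsertSpec("ERV2", 0.02, family=1) for _ in range(2)]
        spb = [InsertSpec("ERV3", 0.02, family=2) for _ in range(2)]
        a, b = make_species_pair(SpeciesPairConfig(
            700_000, shared, spa, spb, flank_divergence=0.05, seed=9))
        links_a = [t for t in a.truth if t.ortholog_partner_id]
        assert len(links_a) == 6
        ids_b = {t.element_id for t in b.truth}
        assert all(t.ortholog_partner_id in ids_b for t in links_a)

    def test_zero_flank_divergence_identical_flanks(self):
        shared = [InsertSpec("ERV1", 0.0, family=0) for _ in range(2)]
        a, b = make_species_pair(SpeciesPairConfig(
            200_000, shared, [], [], flank_divergence=0.0, seed=4))
        ta = sorted([t for t in a.truth], key=lambda t: t.start)[0]
        tb = next(t for t in b.truth if t.element_id == ta.ortholog_partner_id)
        fa = a.scaffolds[ta.scaffold][ta.start - 500:ta.start]
        fb = b.scaffolds[tb.scaffold][tb.start - 500:tb.start]
        assert fa == fb

    def test_unalignable_divergence_rejected(self):
        with pytest.raises(ValueError):
            SpeciesPairConfig(200_000, [], [], [], flank_divergence=0.5)
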