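import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tc1scout.core_io import revcomp
from tc1scout.element_structure import check_excision_sites, layout_total_length
from tc1scout.errors import PlacementError, SpecError
from tc1scout.orf_tools import translate
from tc1scout.synthetic_genome import (
    ElementSpec,
    PlantPlan,
    TriadSpec,
    build_element,
    frameshift_insert,
    frameshift_sites,
    plant_elements,
    random_background,
    reference_for_plan,
)


class TestBuildElement:
    def test_op1_geometry_totals_5659(self, op1_spec):
        el, layout, triad = build_element(op1_spec, 1)
        assert len(el) == 5659
        assert layout_total_length(layout) == 5659
        assert layout.segment_lengths == (169, 245, 3468, 1608, 169)

    def test_ce1_geometry_totals_1570(self):
        spec = ElementSpec(26, 246, 1032, 240)
        el, layout, _ = build_element(spec, 2)
        assert len(el) == 1570

    def test_minimal_element(self):
        spec = ElementSpec(0, 0, 6, 0)
        el, layout, triad = build_element(spec, 0)
        assert len(el) == 6
        assert triad is None

    def test_tirs_are_exact_revcomps(self, small_spec):
        el, _, _ = build_element(small_spec, 3)
        L = small_spec.tir_len
        assert el[-L:] == revcomp(el[:L])

    def test_orf_translates_and_carries_triad(self, small_spec):
        el, _, triad = build_element(small_spec, 4)
        orf = el[110 : 110 + 1203]
        protein = translate(orf)
        assert len(protein) == 400
        assert protein[triad.d1_pos - 1] == "D"
        assert protein[triad.d2_pos - 1] == "D"
        assert protein[triad.last_pos - 1] == "E"
        assert triad.spacing == 40
        # decoy-free construction: the triad residues are the only D/E
        assert protein.count("D") == 2 and protein.count("E") == 1

    def test_triad_colliding_with_stop_rejected(self):
        with pytest.raises(SpecError):
            ElementSpec(10, 10, 99, 10, triad=TriadSpec(2, 10, "E", 34))

    def test_orf_len_not_multiple_of_three_rejected(self):
        with pytest.raises(SpecError):
            ElementSpec(10, 10, 100, 10)

    @given(
        tir=st.integers(0, 40), utr5=st.integers(0, 50),
        n_codons=st.integers(2, 60), utr3=st.integers(0, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_layout_sums_for_generated_specs(self, tir, utr5, n_codons, utr3, seed):
        spec = ElementSpec(tir, utr5, 3 * n_codons, utr3)
        el, layout, _ = build_element(spec, seed)
        assert layout_total_length(layout) == len(el) == spec.total_length


class TestRandomBackground:
    def test_seeded_determinism(self):
        a = random_background(1000, 0.5, 7)
        b = random_background(1000, 0.5, 7)
        assert a.seq == b.seq

    def test_gc_one_rejected(self):
        with pytest.raises(SpecError):
            random_background(100, 1.0, 0)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(SpecError):
            random_background(0, 0.5, 0)

    def test_empirical_gc_within_one_percent(self):
        g = random_background(100_000, 0.42, 11)
        gc = (g.seq.count("G") + g.seq.count("C")) / g.length
        assert abs(gc - 0.42) < 0.01


class TestPlantElements:
    def test_all_zero_plan_returns_background(self, small_spec):
        plan = PlantPlan(n_full=0, rng_seed=5)
        genome, truth = plant_elements(5000, small_spec, plan)
        assert truth == []
        assert genome.seq == random_background(
            5000, 0.42, random.Random(5).randrange(2**31)
        ).seq

    def test_deterministic_under_seed(self, small_spec, basic_plan):
        g1, t1 = plant_elements(20000, small_spec, basic_plan)
        g2, t2 = plant_elements(20000, small_spec, basic_plan)
        assert g1.seq == g2.seq
        assert [r.interval for r in t1] == [r.interval for r in t2]

    def test_full_copies_have_tsd_flanks(self, small_spec, basic_plan):
        genome, truth = plant_elements(20000, small_spec, basic_plan)
        assert len(truth) == 2
        for rec in truth:
            ok, f5, f3 = check_excision_sites(genome, rec.interval)
            assert ok, (f5, f3)
            assert f5 == revcomp(f3)

    def test_planted_sequences_match_reference(self, small_spec, basic_plan):
        ref, _, _ = reference_for_plan(small_spec, basic_plan)
        genome, truth = plant_elements(20000, small_spec, basic_plan)
        for rec in truth:
            assert rec.inserted_seq == ref
            start, end = rec.interval.start, rec.interval.end
            assert genome.seq[start - 1 : end] == ref

    def test_divergence_applied_to_second_copy(self, small_spec):
        plan = PlantPlan(n_full=2, copy_divergence=(10, (3,)), rng_seed=9)
        ref, _, _ = reference_for_plan(small_spec, plan)
        _, truth = plant_elements(20000, small_spec, plan)
        by_index = {r.copy_index: r for r in truth}
        assert by_index[0].inserted_seq == ref
        div = by_index[1].inserted_seq
        assert len(div) == len(ref) - 3
        assert div != ref

    def test_partial_copy_is_truncation(self, small_spec):
        plan = PlantPlan(n_full=0, n_partial=(0.5,), rng_seed=2)
        ref, _, _ = reference_for_plan(small_spec, plan)
        _, truth = plant_elements(20000, small_spec, plan)
        (rec,) = truth
        assert rec.kind == "partial"
        assert rec.inserted_seq in (ref[: len(rec.inserted_seq)], ref[-len(rec.inserted_seq):])
        assert abs(rec.retained_fraction - 0.5) < 0.01

    def test_solo_tir_is_tir_sequence(self, small_spec):
        plan = PlantPlan(n_full=0, n_solo_tir=1, rng_seed=2)
        ref, _, _ = reference_for_plan(small_spec, plan)
        _, truth = plant_elements(20000, small_spec, plan)
        (rec,) = truth
        assert rec.kind == "solo_tir"
        assert rec.inserted_seq == ref[: small_spec.tir_len]

    def test_insufficient_space_raises(self, small_spec):
        plan = PlantPlan(n_full=5, rng_seed=1)
        with pytest.raises(PlacementError):
            plant_elements(3000, small_spec, plan)

    def test_frameshifted_copy_is_longer(self, small_spec):
        ins = frameshift_insert(41)
        plan = PlantPlan(n_full=1, frameshift_insertions=((400, ins),), rng_seed=4)
        ref, _, _ = reference_for_plan(small_spec, plan)
        _, truth = plant_elements(20000, small_spec, plan)
        assert truth[0].frameshifted
        assert len(truth[0].inserted_seq) == len(ref) + 41


class TestFrameshiftInsert:
    def test_length_and_edges(self):
        ins = frameshift_insert(41)
        assert len(ins) == 41
        assert ins.startswith("TAG")
        assert ins.endswith("TAATGA")

    def test_all_frames_blocked(self):
        ins = frameshift_insert(41)
        stops = {"TAA", "TAG", "TGA"}
        for phase in range(3):
            assert any(ins[i : i + 3] in stops for i in range(phase, len(ins) - 2, 3))

    def test_sites_exist_for_small_spec(self, small_spec):
        ref, _, _ = reference_for_plan(small_spec, PlantPlan(rng_seed=0))
        sites = frameshift_sites(small_spec, ref)
        assert sites
        orf_start = small_spec.tir_len + small_spec.utr5_len
        assert all((p - 1 - orf_start) % 3 == 0 for p in sites)
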