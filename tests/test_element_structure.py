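import random

import pytest
from tc1scout.core_io import GenomeSequence, Interval, revcomp
from tc1scout.element_structure import (
    ElementLayout,
    TirPair,
    annotate_layout,
    check_excision_sites,
    detect_tirs,
    infer_insertion_interval,
    layout_total_length,
)
from tc1scout.errors import (
    AmbiguousBoundaryError,
    InsufficientFlankError,
    LayoutError,
    ValidationError,
)
from tc1scout.synthetic_genome import PlantPlan, build_element, plant_elements


def brute_force_tir(region: str, min_len: int, max_len: int, min_identity: float):
    """Independent oracle: try every prefix length, keep the longest passing."""
    n = len(region)
    best = None
    for L in range(min_len, min(max_len, n // 2) + 1):
        prefix, suffix = region[:L], region[n - L :]
        if "N" in prefix or "N" in suffix:
            continue
        rc = revcomp(suffix)
        ident = sum(a == b for a, b in zip(prefix, rc)) / L
        if ident >= min_identity:
            best = L
    return best


def _rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestDetectTirs:
    def test_exact_169_bp_tirs(self, op1_spec):
        el, _, _ = build_element(op1_spec, 1)
        pair = detect_tirs(el, min_identity=1.0)
        assert pair is not None
        assert pair.length == 169
        assert pair.identity == 1.0
        assert pair.tir5 == Interval("region", 1, 169)
        assert pair.tir3 == Interval("region", len(el) - 168, len(el))

    def test_four_bp_palindromic_anchor(self):
        rng = random.Random(0)
        region = "CAGT" + _rand_dna(rng, 100) + "ACTG"
        pair = detect_tirs(region, min_len=4, max_len=10)
        assert pair is not None and pair.length >= 4

    def test_absent_when_no_tir(self):
        rng = random.Random(1)
        for _ in range(5):
            region = _rand_dna(rng, 300)
            got = detect_tirs(region, min_len=12, max_len=60)
            oracle = brute_force_tir(region, 12, 60, 1.0)
            assert (got.length if got else None) == oracle

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_on_planted_regions(self, seed, small_spec):
        el, _, _ = build_element(small_spec, seed)
        got = detect_tirs(el, min_len=10, max_len=250)
        assert got is not None
        assert got.length == brute_force_tir(el, 10, 250, 1.0) == 50

    def test_n_windows_excluded(self):
        core = "ACGTACGTACGTACG"
        region = "NNNNNNNNNN" + core + revcomp("NNNNNNNNNN")
        assert detect_tirs(region, min_len=5, max_len=10, min_identity=1.0) is None

    def test_degenerate_identity_threshold(self):
        rng = random.Random(2)
        tir = _rand_dna(rng, 50)
        decayed = list(revcomp(tir))
        for i in rng.sample(range(50), 5):
            decayed[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[decayed[i]]
        region = tir + _rand_dna(rng, 200) + "".join(decayed)
        assert detect_tirs(region, min_identity=1.0) is None
        pair = detect_tirs(region, min_identity=0.8)
        assert pair is not None and pair.identity >= 0.8


class TestCheckExcisionSites:
    def test_printed_site_pattern(self):
        # flank5 TACA / flank3 TGTA around a CA...TG element with TA flanks
        g = GenomeSequence("g", "GGGTA" + "CAGGGGTG" + "TAGGG")
        ok, f5, f3 = check_excision_sites(g, Interval("g", 6, 13))
        assert ok and f5 == "TACA" and f3 == "TGTA"

    def test_tata_pattern(self):
        g = GenomeSequence("g", "GGGTA" + "TAGGGGTA" + "TAGGG")
        ok, f5, f3 = check_excision_sites(g, Interval("g", 6, 13))
        assert ok and f5 == "TATA" and f3 == "TATA"

    def test_symmetry_violation_fails(self):
        g = GenomeSequence("g", "GGGTA" + "CAGGGGAA" + "TTGGG")
        ok, f5, f3 = check_excision_sites(g, Interval("g", 6, 13))
        assert not ok

    def test_missing_tsd_fails(self):
        g = GenomeSequence("g", "GGGCC" + "CAGGGGTG" + "GGGGG")
        ok, _, _ = check_excision_sites(g, Interval("g", 6, 13))
        assert not ok

    def test_edge_element_raises(self):
        g = GenomeSequence("g", "CAGGGGTG")
        with pytest.raises(InsufficientFlankError):
            check_excision_sites(g, Interval("g", 1, 8))

    def test_in_silico_excision_restores_single_tsd(self, small_spec):
        genome, truth = plant_elements(20000, small_spec, PlantPlan(n_full=1, rng_seed=8))
        (rec,) = truth
        s, e = rec.interval.start, rec.interval.end
        excised = genome.seq[: s - 1] + genome.seq[e + 2 :]  # drop element + right TSD
        left = genome.seq[s - 3 : s - 1]
        assert left == "TA"
        assert excised[s - 3 : s - 1] == "TA"


class TestLayout:
    def test_op1_layout(self):
        layout = ElementLayout.from_segment_lengths(169, 245, 3468, 1608, 169)
        assert layout_total_length(layout) == 5659

    def test_mp1_layout(self):
        assert layout_total_length(
            ElementLayout.from_segment_lengths(141, 60, 1305, 41, 141)
        ) == 1688

    def test_degenerate_layout(self):
        assert layout_total_length(ElementLayout.from_segment_lengths(0, 0, 3, 0, 0)) == 3

    def test_segment_sum_invariant_enforced(self):
        with pytest.raises(ValidationError):
            ElementLayout(Interval("r", 1, 100), 10, 10, 60, 10, 11)

    def test_annotate_layout_on_planted_element(self, op1_spec):
        genome, truth = plant_elements(40000, op1_spec, PlantPlan(n_full=1, rng_seed=1))
        (rec,) = truth
        region = genome.seq[rec.interval.start - 1 : rec.interval.end]
        tir = detect_tirs(region)
        orf = Interval(genome.id, rec.interval.start + 414, rec.interval.start + 414 + 3467)
        layout = annotate_layout(genome, rec.interval, tir, orf)
        assert layout.segment_lengths == (169, 245, 3468, 1608, 169)
        assert layout.excision_ok
        assert layout_total_length(layout) == 5659

    def test_zero_tir_layout(self):
        # unknown TIRs are zero-length segments: 0 + 23 + 858 + 3 + 0 = 884
        g = GenomeSequence("g", "GGTA" + "G" * 884 + "TAGG")
        element = Interval("g", 5, 888)
        orf = Interval("g", 5 + 23, 5 + 23 + 857)
        layout = annotate_layout(g, element, None, orf)
        assert layout.segment_lengths == (0, 23, 858, 3, 0)
        assert layout_total_length(layout) == 884

    def test_element_equals_orf(self):
        g = GenomeSequence("g", "GG" + "A" * 30 + "GG")
        element = Interval("g", 3, 32)
        layout = annotate_layout(g, element, None, element)
        assert layout.segment_lengths == (0, 0, 30, 0, 0)

    def test_orf_outside_element_raises(self):
        g = GenomeSequence("g", "G" * 100)
        with pytest.raises(LayoutError):
            annotate_layout(g, Interval("g", 10, 50), None, Interval("g", 40, 60))


class TestTirPairInvariants:
    def test_rejects_overlapping_tirs(self):
        with pytest.raises(ValidationError):
            TirPair(Interval("r", 1, 50), Interval("r", 40, 89), 1.0)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValidationError):
            TirPair(Interval("r", 1, 50), Interval("r", 100, 139), 1.0)


def _homolog_groups(seg_len: int, seed: int, n_with=3, n_without=3):
    rng = random.Random(seed)
    left = _rand_dna(rng, 400)
    right = _rand_dna(rng, 400)
    seg = _rand_dna(rng, seg_len)
    # unique flanks: no alignment-equivalent slide of the gap
    while seg[0] == right[0]:
        seg = rng.choice("ACGT") + seg[1:]
    while seg[-1] == left[-1]:
        seg = seg[:-1] + rng.choice("ACGT")
    with_group = [left + seg + right for _ in range(n_with)]
    without_group = [left + right for _ in range(n_without)]
    return with_group, without_group, len(left) + 1, len(left) + seg_len


class TestInferInsertionInterval:
    def test_886_bp_segment_recovered(self):
        with_g, without_g, start, end = _homolog_groups(886, 0)
        call = infer_insertion_interval(with_g, without_g)
        assert (call.interval.start, call.interval.end) == (start, end)
        assert call.interval.length() == 886
        assert call.support_with == 3
        assert call.support_without == 3
        assert call.confident

    def test_segment_in_all_regions_is_ambiguous(self):
        with_g, _, _, _ = _homolog_groups(200, 1)
        with pytest.raises(AmbiguousBoundaryError):
            infer_insertion_interval(with_g, with_g)

    def test_single_bp_segment(self):
        with_g, without_g, start, end = _homolog_groups(1, 2)
        call = infer_insertion_interval(with_g, without_g)
        assert call.interval.length() == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            infer_insertion_interval([], ["ACGT"])

    @pytest.mark.parametrize("seed", range(5))
    def test_endpoints_exact_over_seeds(self, seed):
        with_g, without_g, start, end = _homolog_groups(300 + 17 * seed, seed + 10)
        call = infer_insertion_interval(with_g, without_g)
        assert (call.interval.start, call.interval.end) == (start, end)
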