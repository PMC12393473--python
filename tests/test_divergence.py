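import numpy as np
import pytest
from scipy import stats

from autopod.chain import ChainBlock, ChainMap
from autopod.divergence import (
    SISTER,
    TARGET,
    DivergenceConfig,
    SurveyedFragment,
    TrioContext,
    call_derived_positions,
    conservation_shift_test,
    map_fragment_to_trio,
    mask_and_fragment,
    run_divergence,
    sequence_identity,
    standardize_to_length,
)
from autopod.genome import Genome
from autopod.intervals import GenomicInterval, IntervalSet
from autopod.simulate import TrioSimulationParams, VariantCatalog, simulate_trio

LENGTHS = {"chr1": 1_000_000}


def context_from(trio, score_track=None):
    return TrioContext(
        target=trio.target,
        sister=trio.sister,
        outgroup=trio.outgroup,
        chain_to_sister=trio.chain_to_sister,
        chain_to_outgroup=trio.chain_to_outgroup,
        catalogs=trio.catalogs,
        blacklist=trio.blacklist,
        score_track=score_track,
    )


def grid_elements(positions, chrom_length, width=500):
    """Disjoint width-aligned windows covering every given position."""
    starts = sorted({(p // width) * width for p in positions})
    return IntervalSet(
        [
            GenomicInterval("chr1", s, s + width, name=f"w{s}")
            for s in starts
            if s + width <= chrom_length
        ],
        label="elements",
    )


class TestStandardize:
    def test_midpoint_arithmetic(self):
        out = standardize_to_length(GenomicInterval("chr1", 1000, 1200), 500, LENGTHS)
        assert (out.start, out.end) == (850, 1350)

    def test_already_standard_unchanged(self):
        iv = GenomicInterval("chr1", 2000, 2500, name="x")
        out = standardize_to_length(iv, 500, LENGTHS)
        assert (out.start, out.end, out.name) == (2000, 2500, "x")

    def test_rejected_near_chrom_start(self):
        assert standardize_to_length(GenomicInterval("chr1", 50, 150), 500, LENGTHS) is None

    def test_rejected_near_chrom_end(self):
        assert (
            standardize_to_length(
                GenomicInterval("chr1", 999_800, 999_900), 500, LENGTHS
            )
            is None
        )

    def test_unknown_chrom(self):
        with pytest.raises(KeyError):
            standardize_to_length(GenomicInterval("chrX", 1000, 1200), 500, LENGTHS)


class TestMaskAndFragment:
    def test_no_variants_no_blacklist_unchanged(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 500, name="e")])
        out = mask_and_fragment(s, {}, 0.05, None)
        assert out == s

    def test_central_snp_splits_500bp(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 500, name="e")])
        cat = VariantCatalog("h", (("chr1", 250, 0.3),))
        out = mask_and_fragment(s, {"h": cat}, 0.05, None)
        assert [(iv.start, iv.end) for iv in out] == [(0, 250), (251, 500)]
        assert [len(iv) for iv in out] == [250, 249]
        assert all(iv.name == "e" for iv in out)

    def test_maf_at_threshold_not_masked(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 500)])
        cat = VariantCatalog("h", (("chr1", 250, 0.05),))
        out = mask_and_fragment(s, {"h": cat}, 0.05, None)
        assert out == s

    def test_any_species_masks(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 10)])
        cats = {
            "a": VariantCatalog("a", (("chr1", 2, 0.2),)),
            "b": VariantCatalog("b", (("chr1", 7, 0.2),)),
        }
        out = mask_and_fragment(s, cats, 0.05, None)
        assert [(iv.start, iv.end) for iv in out] == [(0, 2), (3, 7), (8, 10)]

    def test_random_matches_per_base_oracle(self):
        rng = np.random.default_rng(1)
        s = IntervalSet(
            [
                GenomicInterval("chr1", int(p), int(p) + 200, name=f"e{i}")
                for i, p in enumerate(range(0, 5000, 500))
            ]
        )
        cats = {
            sp: VariantCatalog(
                sp,
                tuple(
                    ("chr1", int(p), float(m))
                    for p, m in zip(
                        rng.choice(5200, size=80, replace=False),
                        rng.uniform(0, 0.5, size=80),
                    )
                ),
            )
            for sp in ("a", "b")
        }
        blacklist = IntervalSet([GenomicInterval("chr1", 1000, 1100)])
        out = mask_and_fragment(s, cats, 0.05, blacklist)
        masked = np.zeros(5200, dtype=bool)
        for cat in cats.values():
            for _, p, m in cat.records:
                if m > 0.05:
                    masked[p] = True
        masked[1000:1100] = True
        kept = np.zeros(5200, dtype=bool)
        for iv in s:
            kept[iv.start : iv.end] = True
        expected = kept & ~masked
        got = np.zeros(5200, dtype=bool)
        for iv in out:
            got[iv.start : iv.end] = True
        assert got.tolist() == expected.tolist()


class TestSequenceIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 1.0), ("AAAA", "CCCC", 0.0), ("ACGT", "ACGA", 0.75)],
    )
    def test_basics(self, a, b, expected):
        assert sequence_identity(a, b) == pytest.approx(expected)

    def test_n_positions_excluded(self):
        assert sequence_identity("ANGT", "ACGT") == pytest.approx(1.0)
        assert sequence_identity("ANGT", "CCGT") == pytest.approx(2 / 3)

    def test_all_n_is_nan(self):
        assert np.isnan(sequence_identity("NN", "AC"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sequence_identity("ACG", "AC")


class TestCallDerived:
    def make(self, t, s, o, start=0):
        return SurveyedFragment(
            GenomicInterval("chr1", start, start + len(t)),
            target_seq=t, sister_seq=s, outgroup_seq=o,
            identity_to_sister=1.0, identity_to_outgroup=1.0,
            identity_sister_outgroup=1.0,
        )

    def test_single_planted_difference(self):
        sv = self.make("AAGT", "ACGT", "ACGT")
        assert call_derived_positions(sv, TARGET) == [1]
        assert call_derived_positions(sv, SISTER) == []

    def test_three_way_disagreement_uninformative(self):
        sv = self.make("AAGT", "AGGT", "ACGT")
        assert call_derived_positions(sv, TARGET) == []
        assert call_derived_positions(sv, SISTER) == []

    def test_n_blocks_calls(self):
        sv = self.make("AAGT", "ANGT", "ACGT")
        assert call_derived_positions(sv, TARGET) == []

    def test_offset_positions_absolute(self):
        sv = self.make("AAGT", "ACGT", "ACGT", start=100)
        assert call_derived_positions(sv, TARGET) == [101]

    def test_rejected_fragment_raises(self):
        sv = SurveyedFragment(GenomicInterval("chr1", 0, 4), rejection_reason="x")
        with pytest.raises(ValueError):
            call_derived_positions(sv)


class TestMapFragment:
    def test_identity_chains_map_to_self(self):
        trio = simulate_trio(TrioSimulationParams(chrom_length=2000, seed=1))
        sv = map_fragment_to_trio(GenomicInterval("chr1", 100, 300), context_from(trio))
        assert sv.accepted
        assert sv.target_seq == sv.sister_seq == sv.outgroup_seq
        assert sv.identity_to_sister == 1.0

    def test_chain_gap_rejects_with_reason(self):
        trio = simulate_trio(
            TrioSimulationParams(chrom_length=2000, indel_blocks=[(500, 100)], seed=1)
        )
        sv = map_fragment_to_trio(GenomicInterval("chr1", 450, 650), context_from(trio))
        assert not sv.accepted
        assert sv.rejection_reason.startswith("unmappable_sister:")

    def test_minus_strand_sequences_align(self):
        target = Genome({"chr1": "AACCGGTTAA"})
        # sister genome holds the reverse complement; chain is minus-strand
        sister = Genome({"chrS": "TTAACCGGTT"})
        chain = ChainMap([ChainBlock("chr1", 0, 10, "chrS", 0, 10, "-", 1)])
        ctx = TrioContext(
            target=target, sister=sister, outgroup=target,
            chain_to_sister=chain,
            chain_to_outgroup=ChainMap([ChainBlock("chr1", 0, 10, "chr1", 0, 10, "+", 1)]),
            catalogs={}, blacklist=IntervalSet(),
        )
        sv = map_fragment_to_trio(GenomicInterval("chr1", 2, 8), ctx)
        assert sv.accepted
        assert sv.sister_seq == sv.target_seq


class TestRunDivergence:
    def clean_trio(self, n_t=200, n_s=150, seed=11, length=1_000_000):
        return simulate_trio(
            TrioSimulationParams(
                chrom_length=length, n_target_fixed=n_t, n_sister_fixed=n_s, seed=seed
            )
        )

    def test_identical_genomes_zero_derived(self):
        trio = simulate_trio(TrioSimulationParams(chrom_length=10_000, seed=2))
        elements = grid_elements(range(0, 10_000, 1000), 10_000)
        reports = run_divergence({"s": elements}, context_from(trio))
        assert reports["s"][TARGET].derived_count == 0
        assert reports["s"][SISTER].derived_count == 0
        assert reports["s"][TARGET].bp_surveyed == elements.covered_bp()

    def test_planted_truth_recovered_exactly(self):
        trio = self.clean_trio()
        planted = trio.truth.target_fixed + trio.truth.sister_fixed
        elements = grid_elements(planted, 1_000_000)
        reports = run_divergence({"s": elements}, context_from(trio))
        assert reports["s"][TARGET].derived_count == 200
        assert reports["s"][SISTER].derived_count == 150
        assert sorted(p for _, p in reports["s"][TARGET].derived_positions) == sorted(
            trio.truth.target_fixed
        )

    def test_swapped_planted_counts_swap_columns(self):
        a = self.clean_trio(n_t=80, n_s=30, seed=5, length=200_000)
        b = self.clean_trio(n_t=30, n_s=80, seed=5, length=200_000)
        elems_a = grid_elements(a.truth.target_fixed + a.truth.sister_fixed, 200_000)
        elems_b = grid_elements(b.truth.target_fixed + b.truth.sister_fixed, 200_000)
        rep_a = run_divergence({"s": elems_a}, context_from(a))["s"]
        rep_b = run_divergence({"s": elems_b}, context_from(b))["s"]
        assert rep_a[TARGET].derived_count == rep_b[SISTER].derived_count == 80
        assert rep_a[SISTER].derived_count == rep_b[TARGET].derived_count == 30

    def test_monotone_masking(self):
        trio = self.clean_trio(n_t=50, n_s=40, seed=9, length=100_000)
        elements = grid_elements(trio.truth.target_fixed + trio.truth.sister_fixed, 100_000)
        base = run_divergence({"s": elements}, context_from(trio))["s"][TARGET]
        # mask 10 of the planted target positions plus some background
        masked_positions = trio.truth.target_fixed[:10] + (1, 2, 3)
        cat = VariantCatalog(
            "extra", tuple(("chr1", int(p), 0.3) for p in masked_positions)
        )
        ctx = context_from(trio)
        ctx.catalogs = {**dict(ctx.catalogs), "extra": cat}
        masked = run_divergence({"s": elements}, ctx)["s"][TARGET]
        assert masked.bp_surveyed < base.bp_surveyed
        assert masked.derived_count == base.derived_count - 10

    def test_min_identity_one_rejects_any_mismatch(self):
        trio = self.clean_trio(n_t=30, n_s=0, seed=13, length=50_000)
        elements = grid_elements(trio.truth.target_fixed, 50_000)
        config = DivergenceConfig(min_identity=1.0)
        rep = run_divergence({"s": elements}, context_from(trio), config)["s"][TARGET]
        assert rep.derived_count == 0
        assert rep.rejections["below_min_identity"] == len(elements)

    def test_gate_never_flips_calls(self):
        trio = self.clean_trio(n_t=60, n_s=50, seed=17, length=100_000)
        elements = grid_elements(trio.truth.target_fixed + trio.truth.sister_fixed, 100_000)
        lo = run_divergence(
            {"s": elements}, context_from(trio), DivergenceConfig(min_identity=1e-9)
        )["s"][TARGET]
        default = run_divergence({"s": elements}, context_from(trio))["s"][TARGET]
        assert lo.derived_count == default.derived_count
        assert lo.derived_positions == default.derived_positions

    def test_standardization_recenter_and_rejection(self):
        trio = simulate_trio(TrioSimulationParams(chrom_length=10_000, seed=3))
        elements = IntervalSet(
            [
                GenomicInterval("chr1", 100, 150, name="edge"),  # window exits chrom
                GenomicInterval("chr1", 5000, 5100, name="mid"),
            ]
        )
        rep = run_divergence({"s": elements}, context_from(trio))["s"][TARGET]
        assert rep.rejections["standardization_out_of_bounds"] == 1
        assert rep.bp_surveyed == 500

    def test_rate_and_invariants(self):
        trio = self.clean_trio(n_t=100, n_s=80, seed=23, length=300_000)
        elements = grid_elements(trio.truth.target_fixed + trio.truth.sister_fixed, 300_000)
        rep = run_divergence({"s": elements}, context_from(trio))["s"]
        for lineage in (TARGET, SISTER):
            r = rep[lineage]
            assert r.derived_count <= r.bp_surveyed
            assert 0.0 <= r.rate_per_bp <= 1.0
            assert r.rate_per_bp == r.derived_count / r.bp_surveyed

    def test_empty_elements_rate_undefined(self):
        trio = simulate_trio(TrioSimulationParams(chrom_length=5000, seed=4))
        rep = run_divergence({"s": IntervalSet()}, context_from(trio))["s"][TARGET]
        assert rep.bp_surveyed == 0 and rep.rate_per_bp is None

    def test_scores_collected_at_derived_positions(self):
        from autopod.simulate import simulate_score_track

        trio = self.clean_trio(n_t=40, n_s=30, seed=29, length=100_000)
        elements = grid_elements(trio.truth.target_fixed + trio.truth.sister_fixed, 100_000)
        track = simulate_score_track(
            trio.truth.target_fixed, shift=1.0, noise_sd=0.5, seed=1,
            background_positions=trio.truth.sister_fixed,
        )
        reports = run_divergence({"s": elements}, context_from(trio, track))["s"]
        assert len(reports[TARGET].scores) == reports[TARGET].derived_count
        assert all(v is not None for v in reports[TARGET].scores)


class TestConservationShift:
    def test_identical_lists_p_one(self):
        r = conservation_shift_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == pytest.approx(1.0)
        assert r.mean_a == r.mean_b

    def test_complete_separation_tiny_p(self):
        a = list(np.linspace(10, 11, 50))
        b = list(np.linspace(0, 1, 50))
        r = conservation_shift_test(a, b)
        assert r.p_value < 1e-15

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(31)
        a = rng.normal(1.0, 0.5, size=1000)
        b = rng.normal(0.0, 0.5, size=1000)
        r = conservation_shift_test(list(a), list(b))
        assert r.p_value < 0.01
        assert r.mean_a > r.mean_b

    def test_missing_excluded_and_counted(self):
        r = conservation_shift_test([1.0, None, 2.0], [0.5, float("nan"), 1.5])
        assert r.n_missing == 2
        assert r.n_a == 2 and r.n_b == 2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            conservation_shift_test([None], [1.0])


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            DivergenceConfig(min_identity=0.0)
        with pytest.raises(ValueError):
            DivergenceConfig(maf_threshold=0.5)
        with pytest.raises(ValueError):
            DivergenceConfig(identity_rule="xor")

    def test_or_rule_accepts_one_sided_identity(self):
        # target matches outgroup but not sister: "or" keeps, "and" drops
        target = Genome({"chr1": "A" * 400})
        sister = Genome({"chr1": "C" * 400})
        outgroup = Genome({"chr1": "A" * 400})
        identity = ChainMap([ChainBlock("chr1", 0, 400, "chr1", 0, 400, "+", 1)])
        ctx = TrioContext(
            target=target, sister=sister, outgroup=outgroup,
            chain_to_sister=identity, chain_to_outgroup=identity,
            catalogs={}, blacklist=IntervalSet(),
        )
        elements = IntervalSet([GenomicInterval("chr1", 0, 400)])
        cfg_and = DivergenceConfig(standard_length=400, identity_rule="and")
        cfg_or = DivergenceConfig(standard_length=400, identity_rule="or")
        rep_and = run_divergence({"s": elements}, ctx, cfg_and)["s"][TARGET]
        rep_or = run_divergence({"s": elements}, ctx, cfg_or)["s"][TARGET]
        assert rep_and.bp_surveyed == 0
        assert rep_or.bp_surveyed == 400
        # sister differs everywhere but outgroup agrees with target: no calls
        assert rep_or.derived_count == 0
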