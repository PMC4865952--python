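"""IBD run detection and HBD interval algebra."""
import pytest

from hbdscan.ibd import (
    IbdConfig,
    case_shared_hbd,
    exclude_control_overlap,
    intersect_regions,
    merge_regions,
    roh_runs,
    roh_runs_bruteforce,
    subtract_regions,
)
from hbdscan.types import ConfigurationError, Provenance

from conftest import HET, HOM, make_markers, random_marker_instance, region

MB = 1_000_000


class TestRohRuns:
    def test_forty_nine_snps_are_too_few_even_over_two_megabases(self):
        markers = make_markers([HOM] * 49, spacing=2 * MB // 48)
        assert roh_runs(markers, "S1") == []

    def test_fifty_snps_spanning_1_5_mb_form_one_run(self):
        markers = make_markers([HOM] * 50, spacing=1_500_000 // 49)
        runs = roh_runs(markers, "S1")
        assert len(runs) == 1
        assert runs[0].n_markers == 50
        assert runs[0].length >= MB
        assert runs[0].provenance is Provenance.IBD_RUN

    def test_fifty_snps_under_one_megabase_are_rejected(self):
        markers = make_markers([HOM] * 50, spacing=500_000 // 49)
        assert roh_runs(markers, "S1") == []

    def test_het_marker_breaks_a_run(self):
        zyg = [HOM] * 120
        zyg[60] = HET
        markers = make_markers(zyg, spacing=30_000)
        runs = roh_runs(markers, "S1")
        # both halves have 59-60 markers over ~1.8 Mb
        assert len(runs) == 2
        assert runs[0].end < markers[60].pos < runs[1].start

    def test_matches_bruteforce_on_random_instances(self, rng):
        cfg = IbdConfig(min_run_snps=10, min_run_bp=100_000)
        for _ in range(30):
            markers = random_marker_instance(rng, n_max=120)
            assert roh_runs(markers, "S1", cfg) == roh_runs_bruteforce(
                markers, "S1", cfg
            )


class TestIntervalAlgebra:
    def test_partial_overlap(self):
        a = [region(1 * MB, 3 * MB)]
        b = [region(2 * MB, 5 * MB)]
        out = intersect_regions(a, b)
        assert [(r.start, r.end) for r in out] == [(2 * MB, 3 * MB)]

    def test_disjoint_lists_intersect_to_nothing(self):
        assert intersect_regions([region(1, 10)], [region(20, 30)]) == []

    def test_self_intersection_is_identity(self):
        a = [region(1 * MB, 3 * MB), region(5 * MB, 6 * MB)]
        out = intersect_regions(a, a)
        assert [(r.start, r.end) for r in out] == [(r.start, r.end) for r in a]

    def test_unsorted_input_is_rejected(self):
        bad = [region(5 * MB, 6 * MB), region(1 * MB, 3 * MB)]
        with pytest.raises(ValueError):
            intersect_regions(bad, bad)

    def test_overlapping_input_is_rejected(self):
        bad = [region(1, 10), region(5, 20)]
        with pytest.raises(ValueError):
            intersect_regions(bad, [region(1, 5)])

    def test_subtract_splits_region(self):
        out = subtract_regions([region(1, 100)], [region(40, 60)])
        assert [(r.start, r.end) for r in out] == [(1, 39), (61, 100)]

    def test_merge_unions_overlapping_regions(self):
        out = merge_regions([region(1, 50), region(40, 80), region(90, 95)])
        assert [(r.start, r.end) for r in out] == [(1, 80), (90, 95)]


class TestCaseSharedHbd:
    def test_single_case_is_identity(self):
        regions = [region(1 * MB, 3 * MB, sample="case1")]
        out = case_shared_hbd({"case1": regions})
        assert [(r.start, r.end) for r in out] == [(1 * MB, 3 * MB)]
        assert out[0].provenance is Provenance.CASE_SHARED_HBD

    def test_four_cases_share_core_interval(self):
        per_case = {
            "c1": [region(1 * MB, 5 * MB)],
            "c2": [region(2 * MB, 6 * MB)],
            "c3": [region(1 * MB, 5 * MB)],
            "c4": [region(2 * MB, 7 * MB)],
        }
        out = case_shared_hbd(per_case)
        assert [(r.start, r.end) for r in out] == [(2 * MB, 5 * MB)]

    def test_case_order_is_irrelevant(self):
        per_case = {
            "a": [region(1 * MB, 5 * MB)],
            "b": [region(2 * MB, 6 * MB)],
        }
        flipped = {"b": per_case["b"], "a": per_case["a"]}
        assert case_shared_hbd(per_case) == case_shared_hbd(flipped)

    def test_fragments_below_floor_are_dropped(self):
        per_case = {
            "a": [region(1 * MB, int(1.5 * MB))],
            "b": [region(int(1.2 * MB), 3 * MB)],
        }
        assert case_shared_hbd(per_case) == []  # 300 kb fragment

    def test_no_cases_is_an_error(self):
        with pytest.raises(ConfigurationError):
            case_shared_hbd({})

    def test_output_contained_in_every_case(self, rng):
        for _ in range(20):
            per_case = {}
            for cid in ("a", "b", "c"):
                starts = sorted(rng.integers(1, 50 * MB, size=3))
                per_case[cid] = merge_regions(
                    [region(int(s), int(s + rng.integers(1, 10 * MB))) for s in starts]
                )
            out = case_shared_hbd(per_case, min_fragment_bp=1)
            for r in out:
                for regions in per_case.values():
                    assert any(
                        c.chrom == r.chrom and c.start <= r.start and c.end >= r.end
                        for c in regions
                    )


class TestControlExclusion:
    def test_subtraction_keeps_megabase_fragments(self):
        hbd = [region(1 * MB, 5 * MB, provenance=Provenance.CASE_SHARED_HBD)]
        control = {"ctrl": [region(2 * MB, int(2.5 * MB))]}
        out = exclude_control_overlap(hbd, control)
        assert [(r.start, r.end) for r in out] == [
            (1 * MB, 2 * MB - 1),
            (int(2.5 * MB) + 1, 5 * MB),
        ]
        assert all(r.length >= MB for r in out)
        assert all(r.provenance is Provenance.HBD_CONTROL_EXCLUDED for r in out)

    def test_full_control_coverage_empties_region(self):
        hbd = [region(1 * MB, 5 * MB, provenance=Provenance.CASE_SHARED_HBD)]
        assert exclude_control_overlap(hbd, {"k": [region(1, 10 * MB)]}) == []

    def test_no_controls_leaves_input_unchanged(self):
        hbd = [region(1 * MB, 5 * MB, provenance=Provenance.CASE_SHARED_HBD)]
        out = exclude_control_overlap(hbd, {})
        assert [(r.start, r.end) for r in out] == [(1 * MB, 5 * MB)]

    def test_discard_entirely_mode_drops_touched_regions(self):
        hbd = [
            region(1 * MB, 5 * MB, provenance=Provenance.CASE_SHARED_HBD),
            region(10 * MB, 12 * MB, provenance=Provenance.CASE_SHARED_HBD),
        ]
        control = {"ctrl": [region(2 * MB, int(2.5 * MB))]}
        out = exclude_control_overlap(hbd, control, discard_entirely=True)
        assert [(r.start, r.end) for r in out] == [(10 * MB, 12 * MB)]

    def test_output_never_overlaps_controls(self, rng):
        for _ in range(20):
            hbd = merge_regions(
                [
                    region(int(s), int(s + rng.integers(MB, 8 * MB)))
                    for s in sorted(rng.integers(1, 40 * MB, size=3))
                ],
                provenance=Provenance.CASE_SHARED_HBD,
            )
            controls = {
                "k": merge_regions(
                    [
                        region(int(s), int(s + rng.integers(1, 4 * MB)))
                        for s in sorted(rng.integers(1, 40 * MB, size=3))
                    ]
                )
            }
            out = exclude_control_overlap(hbd, controls, min_fragment_bp=1)
            for r in out:
                for c in controls["k"]:
                    assert not r.overlaps(c)
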