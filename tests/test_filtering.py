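"""The variant funnel: QC, consequence, frequency and sharing filters."""
import pytest

from hbdscan.filtering import (
    FilterConfig,
    case_control_filter,
    consequence_filter,
    frequency_filter,
    qc_filter,
)
from hbdscan.types import (
    ConfigurationError,
    Consequence,
    Individual,
    Pedigree,
    Role,
    SampleObservation,
    VariantCall,
    VariantClass,
)

from conftest import make_snp


def obs(depth, alt, quality=60, cn=None):
    return SampleObservation(depth, alt, quality, cn)


def snp_with(pos, observation, **kw):
    return VariantCall(
        chrom="1",
        pos=pos,
        ref="A",
        alt="C",
        vclass=VariantClass.SNP,
        consequence=Consequence.NONSYNONYMOUS,
        observations={"S1": observation},
        **kw,
    )


class TestQcFilter:
    def test_six_row_fixture_leaves_one_survivor(self):
        calls = [
            snp_with(10_000, obs(30, 30, quality=15)),
            snp_with(20_000, obs(3, 3)),
            snp_with(30_000, obs(600, 600)),
            snp_with(40_000, obs(30, 30)),
            snp_with(40_004, obs(30, 30)),  # 4 bp from its neighbour
            snp_with(50_000, obs(30, 30)),
        ]
        survivors = qc_filter(calls)
        assert [c.pos for c in survivors] == [50_000]

    def test_empty_input(self):
        assert qc_filter([]) == []

    def test_snps_exactly_five_bp_apart_are_both_kept(self):
        calls = [snp_with(100, obs(30, 30)), snp_with(105, obs(30, 30))]
        assert len(qc_filter(calls)) == 2

    def test_adjacency_rule_exempts_indels(self):
        indel = VariantCall(
            chrom="1",
            pos=103,
            ref="A",
            alt="AT",
            vclass=VariantClass.INDEL,
            consequence=Consequence.FRAMESHIFT,
            observations={"S1": obs(30, 30)},
        )
        calls = [snp_with(100, obs(30, 30)), indel]
        assert len(qc_filter(calls)) == 2

    def test_copy_number_above_two_is_dropped(self):
        calls = [snp_with(100, obs(30, 30, cn=3)), snp_with(200, obs(30, 30, cn=2))]
        assert [c.pos for c in qc_filter(calls)] == [200]

    def test_all_missing_call_is_dropped(self):
        calls = [snp_with(100, obs(0, 0))]
        assert qc_filter(calls) == []

    def test_unsorted_input_rejected(self):
        calls = [snp_with(200, obs(30, 30)), snp_with(100, obs(30, 30))]
        with pytest.raises(ValueError):
            qc_filter(calls)

    def test_qc_gates_apply_per_sample(self):
        call = VariantCall(
            chrom="1",
            pos=100,
            ref="A",
            alt="C",
            vclass=VariantClass.SNP,
            observations={"good": obs(30, 30), "bad": obs(30, 30, quality=10)},
        )
        assert qc_filter([call]) == []


class TestConsequenceAndFrequency:
    @pytest.mark.parametrize(
        "consequence,kept",
        [
            (Consequence.NONSYNONYMOUS, True),
            (Consequence.FRAMESHIFT, True),
            (Consequence.SPLICE_ACCEPTOR, True),
            (Consequence.SPLICE_DONOR, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.NONCODING, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_consequence_classes(self, consequence, kept):
        call = make_snp(100, consequence=consequence)
        assert (consequence_filter([call]) == [call]) is kept

    @pytest.mark.parametrize(
        "freq,kept",
        [
            (0.006, False),  # above 0.5%: common, removed
            (0.005, True),  # the boundary itself is not "high frequency"
            (0.0001, True),
            (None, True),  # novel variants are the search target
        ],
    )
    def test_frequency_threshold_is_exclusive(self, freq, kept):
        call = make_snp(100, pop_freq=freq)
        assert (frequency_filter([call]) == [call]) is kept

    def test_filters_commute_and_are_idempotent(self, rng):
        freqs = [None, 0.001, 0.005, 0.006, 0.2]
        calls = [
            make_snp(
                int(100 + 10 * i),
                consequence=list(Consequence)[int(rng.integers(len(Consequence)))],
                pop_freq=freqs[int(rng.integers(len(freqs)))],
            )
            for i in range(100)
        ]
        a = frequency_filter(consequence_filter(calls))
        b = consequence_filter(frequency_filter(calls))
        assert a == b
        assert consequence_filter(a) == a
        assert frequency_filter(a) == a

    def test_survivors_grow_with_looser_frequency_threshold(self):
        calls = [make_snp(100 + i, pop_freq=f) for i, f in enumerate([0.001, 0.01, 0.1])]
        counts = [
            len(frequency_filter(calls, FilterConfig(max_pop_freq=t)))
            for t in (0.0, 0.005, 0.05, 1.0)
        ]
        assert counts == sorted(counts)


def family(n_cases=4, n_controls=2):
    inds = [
        Individual(f"case{i}", None, None, affected=True, role=Role.CASE)
        for i in range(n_cases)
    ] + [
        Individual(f"ctrl{i}", None, None, affected=False, role=Role.CONTROL)
        for i in range(n_controls)
    ]
    return Pedigree(inds)


def call_with_genotypes(case_obs, control_obs):
    observations = {f"case{i}": o for i, o in enumerate(case_obs)}
    observations.update({f"ctrl{i}": o for i, o in enumerate(control_obs)})
    return VariantCall(
        chrom="1",
        pos=100,
        ref="A",
        alt="C",
        vclass=VariantClass.SNP,
        observations=observations,
    )


HOM_OBS = obs(80, 80)
HET_OBS = obs(80, 40)
REF_OBS = obs(80, 0)


class TestCaseControlFilter:
    def test_recessive_family_pattern_is_kept(self):
        ped = family()
        call = call_with_genotypes([HOM_OBS] * 4, [HET_OBS] * 2)
        assert case_control_filter([call], ped) == [call]

    def test_variant_missing_in_one_case_is_removed(self):
        ped = family()
        call = call_with_genotypes([HOM_OBS] * 3 + [REF_OBS], [HET_OBS] * 2)
        assert case_control_filter([call], ped) == []

    def test_all_het_cases_without_homozygote_are_removed(self):
        ped = family()
        call = call_with_genotypes([HET_OBS] * 4, [HET_OBS] * 2)
        assert case_control_filter([call], ped) == []

    def test_homozygous_control_is_removed(self):
        ped = family()
        call = call_with_genotypes([HOM_OBS] * 4, [HOM_OBS, HET_OBS])
        assert case_control_filter([call], ped) == []

    def test_strict_absence_rejects_carrier_controls(self):
        ped = family()
        call = call_with_genotypes([HOM_OBS] * 4, [HET_OBS] * 2)
        assert case_control_filter([call], ped, strict_absence=True) == []
        ref_controls = call_with_genotypes([HOM_OBS] * 4, [REF_OBS] * 2)
        assert case_control_filter([ref_controls], ped, strict_absence=True) == [
            ref_controls
        ]

    def test_pedigree_without_cases_is_an_error(self):
        ped = family(n_cases=0, n_controls=2)
        with pytest.raises(ConfigurationError):
            case_control_filter([], ped)


def test_each_filter_returns_subset(rng):
    calls = sorted(
        (
            make_snp(
                int(rng.integers(1, 10**6)),
                consequence=list(Consequence)[int(rng.integers(len(Consequence)))],
                pop_freq=None if rng.random() < 0.3 else float(rng.random() * 0.02),
                depth=int(rng.integers(1, 700)),
                alt=0,
                quality=int(rng.integers(0, 99)),
            )
            for _ in range(200)
        ),
        key=lambda c: c.sort_key,
    )
    ids = {id(c) for c in calls}
    for filtered in (
        qc_filter(calls),
        consequence_filter(calls),
        frequency_filter(calls),
    ):
        assert all(id(c) in ids for c in filtered)
        assert len(filtered) <= len(calls)
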