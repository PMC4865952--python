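"""Gene-drop generator: templates, conditioning, truth and determinism."""
import dataclasses

import numpy as np
import pytest

from hbdscan.mapping import classify_marker
from hbdscan.simulate import (
    SimConfig,
    assign_alleles,
    autozygous_fraction,
    build_pedigree,
    gene_drop,
    label_at,
    make_fixture_suite,
    required_risk_transmissions,
    simulate_dataset,
    true_case_shared_segments,
)
from hbdscan.types import (
    ConfigurationError,
    Individual,
    Pedigree,
    Role,
    Sex,
    Zygosity,
)

SMALL = SimConfig(
    n_chromosomes=2,
    chrom_length_bp=10_000_000,
    n_markers_per_chrom=300,
    causal_chrom="1",
    causal_pos=5_000_000,
    seed=7,
)


class TestTemplates:
    def test_single_cousin_template_shape(self):
        ped = build_pedigree("first_cousin_single")
        case = ped[ped.case_ids[0]]
        father, mother = ped.parents_of(case.iid)
        # the parents are first cousins: they share grandparents F1/F2
        gp_f = set(ped.parents_of(father))
        gp_m = set(ped.parents_of(mother))
        shared = {
            p
            for f in gp_f
            if f
            for p in ped.parents_of(f)
            if p
        } & {
            p
            for m in gp_m
            if m
            for p in ped.parents_of(m)
            if p
        }
        assert shared == {"F1", "F2"}

    def test_double_cousin_template_has_four_cases_two_controls(self):
        ped = build_pedigree("first_cousin_double")
        assert len(ped.case_ids) == 4
        assert len(ped.control_ids) == 2
        # controls are the parents of one of the cases
        assert set(ped.parents_of("P4")) == set(ped.control_ids)

    def test_unknown_template_rejected(self):
        with pytest.raises(ConfigurationError):
            build_pedigree("nonsense")

    def test_custom_template_passthrough(self):
        ped = Pedigree([Individual("x", None, None, Sex.MALE)])
        assert build_pedigree("custom", custom=ped) is ped


class TestGeneDrop:
    def test_zero_recombination_transmits_whole_parental_haplotypes(self):
        cfg = dataclasses.replace(SMALL, recomb_rate_per_mb=0.0)
        ped = build_pedigree("first_cousin_double")
        haps, _ = gene_drop(ped, cfg, np.random.default_rng(1))
        for iid, by_chrom in haps.items():
            for chrom, (h0, h1) in by_chrom.items():
                assert len(h0) == 1 and len(h1) == 1

    def test_founders_have_no_autozygous_tracts(self):
        ped = build_pedigree("first_cousin_double")
        _, truth = gene_drop(ped, SMALL, np.random.default_rng(2))
        for founder in ped.founders:
            assert truth.autozygous_tracts[founder.iid] == []

    def test_conditioning_makes_all_cases_homozygous_at_causal_locus(self):
        ped = build_pedigree("first_cousin_double")
        risk = ("F1", 0)
        for seed in range(5):
            haps, _ = gene_drop(ped, SMALL, np.random.default_rng(seed))
            for cid in ped.case_ids:
                h0, h1 = haps[cid][SMALL.causal_chrom]
                assert label_at(h0, SMALL.causal_pos) == risk
                assert label_at(h1, SMALL.causal_pos) == risk

    def test_required_transmissions_follow_descent_paths(self):
        ped = build_pedigree("first_cousin_double")
        req = required_risk_transmissions(ped, ped.case_ids, "F1")
        # both grandparental sibs and all four cousin parents must transmit
        assert ("A", "pat") in req and ("B", "pat") in req
        assert {("P1", "pat"), ("P1", "mat"), ("P4", "pat"), ("P4", "mat")} <= req

    def test_tracts_cover_causal_locus_in_cases(self):
        ped = build_pedigree("first_cousin_double")
        _, truth = gene_drop(ped, SMALL, np.random.default_rng(3))
        for cid in ped.case_ids:
            assert any(
                t.contains(SMALL.causal_chrom, SMALL.causal_pos)
                for t in truth.autozygous_tracts[cid]
            )

    def test_unconditioned_inbreeding_coefficient_near_one_sixteenth(self):
        """Small-replicate calibration; the full 2,000-drop check is in
        the acceptance suite."""
        cfg = dataclasses.replace(
            SMALL, pedigree_template="first_cousin_single", condition_on_causal=False
        )
        ped = build_pedigree("first_cousin_single")
        genome = cfg.n_chromosomes * cfg.chrom_length_bp
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(400):
            _, truth = gene_drop(ped, cfg, rng, condition_on_causal=False)
            fracs.append(autozygous_fraction(truth, "E1", genome))
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 1 / 16) < 4 * se


class TestAlleles:
    def test_genotypes_are_mendelian_consistent(self):
        ped = build_pedigree("first_cousin_double")
        rng = np.random.default_rng(5)
        haps, truth = gene_drop(ped, SMALL, rng)
        tables = assign_alleles(haps, ped, SMALL, rng, truth=truth)
        for ind in ped:
            if ind.is_founder:
                continue
            for chrom in SMALL.chromosomes:
                kid = tables.dosages[ind.iid][chrom]
                dad = tables.dosages[ind.father][chrom]
                mom = tables.dosages[ind.mother][chrom]
                # child dosage must be achievable from one allele per parent
                lo = (dad > 1).astype(int) + (mom > 1).astype(int)
                hi = (dad > 0).astype(int) + (mom > 0).astype(int)
                assert np.all(kid >= lo) and np.all(kid <= hi)

    def test_causal_homozygosity_matches_tract_truth(self):
        ped = build_pedigree("first_cousin_double")
        rng = np.random.default_rng(6)
        haps, truth = gene_drop(ped, SMALL, rng)
        tables = assign_alleles(haps, ped, SMALL, rng, truth=truth)
        chrom = SMALL.causal_chrom
        idx = int(np.searchsorted(tables.positions[chrom], SMALL.causal_pos))
        risk = tuple(SMALL.causal_founder)
        for ind in ped:
            h0, h1 = haps[ind.iid][chrom]
            both_risk = (
                label_at(h0, SMALL.causal_pos) == risk
                and label_at(h1, SMALL.causal_pos) == risk
            )
            assert (tables.dosages[ind.iid][chrom][idx] == 2) == both_risk

    def test_zero_maf_marker_is_homref_everywhere(self):
        cfg = dataclasses.replace(SMALL, maf_low=1e-12, maf_high=1e-9)
        ped = build_pedigree("first_cousin_double")
        rng = np.random.default_rng(7)
        haps, _ = gene_drop(ped, cfg, rng)
        tables = assign_alleles(haps, ped, cfg, rng)
        for chrom in cfg.chromosomes:
            for ind in ped:
                dos = tables.dosages[ind.iid][chrom]
                idx = int(np.searchsorted(tables.positions[chrom], cfg.causal_pos))
                mask = np.ones(dos.size, dtype=bool)
                if chrom == cfg.causal_chrom:
                    mask[idx] = False  # the planted allele is exempt
                assert np.all(dos[mask] == 0)


class TestReads:
    def test_het_sites_have_balanced_alt_fraction(self):
        rng = np.random.default_rng(8)
        depth = rng.poisson(80, size=10_000)
        alt = rng.binomial(depth, 0.5)
        assert abs((alt / depth).mean() - 0.5) < 0.01

    def test_zero_base_error_makes_hom_alt_reads_pure(self):
        cfg = dataclasses.replace(SMALL, base_error=0.0)
        ds = simulate_dataset(cfg)
        chrom, pos = cfg.causal_chrom, cfg.causal_pos
        causal = [c for c in ds.calls if c.chrom == chrom and c.pos == pos][0]
        for cid in ds.pedigree.case_ids:
            obs = causal.observations[cid]
            assert obs.alt_reads == obs.depth

    def test_noiseless_reads_classify_to_true_genotypes(self):
        cfg = dataclasses.replace(SMALL, base_error=0.0)
        ds = simulate_dataset(cfg)
        expect = {
            0: Zygosity.HOM_REF,
            1: Zygosity.HET,
            2: Zygosity.HOM_ALT,
        }
        checked = 0
        for call in ds.calls[:200]:
            idx = int(
                np.searchsorted(ds.tables.positions[call.chrom], call.pos)
            )
            for iid, obs in call.observations.items():
                z = classify_marker(obs.depth, obs.alt_reads)
                if z in (Zygosity.UNCLASSIFIED, Zygosity.AMBIGUOUS):
                    continue  # sampling noise, not a confident call
                assert z is expect[int(ds.tables.dosages[iid][call.chrom][idx])]
                checked += 1
        assert checked > 500

    def test_causal_variant_is_novel_and_protein_affecting(self):
        ds = simulate_dataset(SMALL)
        causal = [
            c
            for c in ds.calls
            if c.chrom == SMALL.causal_chrom and c.pos == SMALL.causal_pos
        ][0]
        assert causal.pop_freq is None
        assert causal.consequence.value == "NONSYNONYMOUS"


class TestDeterminismAndTruth:
    def test_same_seed_same_dataset(self):
        a = simulate_dataset(SMALL)
        b = simulate_dataset(SMALL)
        assert a.calls == b.calls
        assert a.truth.autozygous_tracts == b.truth.autozygous_tracts

    def test_fixture_suite_is_byte_identical_across_runs(self, tmp_path):
        m1 = make_fixture_suite(str(tmp_path / "one"), seed=42)
        m2 = make_fixture_suite(str(tmp_path / "two"), seed=42)
        assert m1 == m2
        m3 = make_fixture_suite(str(tmp_path / "three"), seed=43)
        assert m3 != m1

    def test_case_shared_truth_contains_causal_locus(self):
        ds = simulate_dataset(SMALL)
        shared = true_case_shared_segments(ds.truth, ds.pedigree.case_ids)
        assert any(
            s.contains(SMALL.causal_chrom, SMALL.causal_pos) for s in shared
        )
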