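"""Gene-drop simulation of consanguineous pedigrees with known autozygosity.

Founder haplotypes carry unique labels and are dropped through the pedigree
by simulated meioses (Poisson crossovers on a uniform genetic map, no
interference). An individual's autozygous tracts are the maximal intervals
where both inherited haplotypes carry the same founder-haplotype label —
the ground truth against which homozygosity mapping is scored.

A recessive causal variant is planted on one founder haplotype; for disease
templates the meioses on the descent paths from that haplotype to the
designated cases are conditioned (per-meiosis rejection sampling) so every
case is homozygous for the risk allele, emulating ascertainment of an
affected family. Unconditioned drops are used for inbreeding-coefficient
calibration.

Read counts are drawn per sample and site as depth ~ Poisson(mean_depth)
and alt_reads ~ Binomial(depth, p) with p = base_error, 0.5 or
1 - base_error for the three true genotypes.
"""
from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as hio
from .types import (
    ConfigurationError,
    Consequence,
    GenomicRegion,
    Individual,
    Pedigree,
    Provenance,
    Role,
    SampleObservation,
    Sex,
    VariantCall,
    VariantClass,
)

# one haplotype = list of (start, end, founder_hap_label) segments
HapLabel = Tuple[str, int]
Haplotype = List[Tuple[int, int, HapLabel]]
HaplotypePair = Tuple[Haplotype, Haplotype]

_DEFAULT_CONSEQUENCE_PROBS: Dict[Consequence, float] = {
    Consequence.NONCODING: 0.45,
    Consequence.SYNONYMOUS: 0.30,
    Consequence.NONSYNONYMOUS: 0.20,
    Consequence.SPLICE_ACCEPTOR: 0.01,
    Consequence.SPLICE_DONOR: 0.01,
    Consequence.OTHER: 0.03,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic consanguineous family.

    Defaults emulate the sequenced family: a pedigree with two first-cousin
    couples, four affected offspring and two genotyped carrier parents;
    autosomes of 50 Mb with 2,000 exome markers each; mean coverage 80x
    with 1% base error; a uniform 1 cM/Mb genetic map.
    """

    pedigree_template: str = "first_cousin_double"
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    n_markers_per_chrom: int = 2_000
    maf_low: float = 0.05
    maf_high: float = 0.50
    recomb_rate_per_mb: float = 0.01  # crossovers per Mb per meiosis
    causal_chrom: str = "1"
    causal_pos: int = 25_000_000
    causal_founder: HapLabel = ("F1", 0)
    mean_depth: float = 80.0
    base_error: float = 0.01
    read_quality: int = 60
    novel_fraction: float = 0.01
    consequence_probs: Dict[Consequence, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONSEQUENCE_PROBS)
    )
    condition_on_causal: bool = True
    seed: int = 0

    @property
    def chromosomes(self) -> List[str]:
        return [str(i) for i in range(1, self.n_chromosomes + 1)]

    def problems(self) -> List[str]:
        out = []
        for name in (
            "n_chromosomes",
            "chrom_length_bp",
            "n_markers_per_chrom",
            "mean_depth",
            "read_quality",
        ):
            if getattr(self, name) <= 0:
                out.append(f"{name} must be positive")
        if not 0 < self.maf_low < self.maf_high <= 0.5:
            out.append("require 0 < maf_low < maf_high <= 0.5")
        if not 0 <= self.base_error < 0.5:
            out.append("base_error must lie in [0, 0.5)")
        if self.recomb_rate_per_mb < 0:
            out.append("recomb_rate_per_mb must be >= 0")
        if not 1 <= self.causal_pos <= self.chrom_length_bp:
            out.append("causal_pos must lie within the chromosome")
        if self.causal_chrom not in self.chromosomes:
            out.append("causal_chrom must be one of the simulated chromosomes")
        if abs(sum(self.consequence_probs.values()) - 1.0) > 1e-9:
            out.append("consequence_probs must sum to 1")
        return out


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    autozygous_tracts: Dict[str, List[GenomicRegion]]
    causal_chrom: str
    causal_pos: int
    # filled by assign_alleles: per individual, per chromosome, dosage 0/1/2
    true_genotypes: Optional[Dict[str, Dict[str, np.ndarray]]] = None
    marker_positions: Optional[Dict[str, np.ndarray]] = None


@dataclass
class SimTables:
    """Marker annotations and true genotype dosages for one simulation."""

    positions: Dict[str, np.ndarray]
    mafs: Dict[str, np.ndarray]
    consequences: Dict[str, List[Consequence]]
    pop_freqs: Dict[str, List[Optional[float]]]
    dosages: Dict[str, Dict[str, np.ndarray]]  # iid -> chrom -> 0/1/2


@dataclass
class SimulatedDataset:
    config: SimConfig
    pedigree: Pedigree
    calls: List[VariantCall]
    truth: SimTruth
    tables: SimTables


# ---------------------------------------------------------------------------
# pedigree templates


def build_pedigree(
    template: str, custom: Optional[Pedigree] = None
) -> Pedigree:
    """Build a pedigree template.

    ``first_cousin_single``: one first-cousin couple with one offspring
    (inbreeding coefficient F = 1/16). ``first_cousin_double``: two
    first-cousin couples descending from the same grandparental sibship,
    with four designated affected offspring (three sibs plus one) and the
    second couple's parents as genotyped unaffected controls. ``custom``
    returns the supplied pedigree unchanged.
    """
    if template == "custom":
        if custom is None:
            raise ConfigurationError("custom template requires a pedigree")
        return custom
    if template == "first_cousin_single":
        inds = [
            Individual("F1", None, None, Sex.MALE),
            Individual("F2", None, None, Sex.FEMALE),
            Individual("U1", None, None, Sex.FEMALE),
            Individual("U2", None, None, Sex.MALE),
            Individual("A", "F1", "F2", Sex.MALE),
            Individual("B", "F1", "F2", Sex.FEMALE),
            Individual("C1", "A", "U1", Sex.MALE, False, Role.CONTROL),
            Individual("D1", "U2", "B", Sex.FEMALE, False, Role.CONTROL),
            Individual("E1", "C1", "D1", Sex.FEMALE, True, Role.CASE),
        ]
        return Pedigree(inds)
    if template == "first_cousin_double":
        inds = [
            Individual("F1", None, None, Sex.MALE),
            Individual("F2", None, None, Sex.FEMALE),
            Individual("U1", None, None, Sex.FEMALE),
            Individual("U2", None, None, Sex.MALE),
            Individual("A", "F1", "F2", Sex.MALE),
            Individual("B", "F1", "F2", Sex.FEMALE),
            Individual("C1", "A", "U1", Sex.MALE),
            Individual("C2", "A", "U1", Sex.FEMALE),
            Individual("D1", "U2", "B", Sex.FEMALE),
            Individual("D2", "U2", "B", Sex.MALE),
            # first cousin couple 1: three affected sibs
            Individual("P1", "C1", "D1", Sex.FEMALE, True, Role.CASE),
            Individual("P2", "C1", "D1", Sex.MALE, True, Role.CASE),
            Individual("P3", "C1", "D1", Sex.MALE, True, Role.CASE),
            # first cousin couple 2: one affected offspring, parents genotyped
            Individual("P4", "D2", "C2", Sex.MALE, True, Role.CASE),
        ]
        # the genotyped unaffected parents of P4 act as controls
        inds = [
            Individual(i.iid, i.father, i.mother, i.sex, i.affected, Role.CONTROL)
            if i.iid in ("C2", "D2")
            else i
            for i in inds
        ]
        return Pedigree(inds)
    raise ConfigurationError(f"unknown pedigree template: {template}")


# ---------------------------------------------------------------------------
# gene drop


def _slice_hap(hap: Haplotype, start: int, end: int) -> Haplotype:
    out: Haplotype = []
    for s, e, label in hap:
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), label))
    return out


def _merge_adjacent(hap: Haplotype) -> Haplotype:
    out: Haplotype = []
    for seg in hap:
        if out and out[-1][2] == seg[2] and out[-1][1] + 1 == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2])
        else:
            out.append(seg)
    return out


def label_at(hap: Haplotype, pos: int) -> HapLabel:
    for s, e, label in hap:
        if s <= pos <= e:
            return label
    raise ValueError(f"position {pos} not covered by haplotype")


def _meiosis(
    parent: HaplotypePair, length: int, rate_per_bp: float, rng: np.random.Generator
) -> Haplotype:
    """One transmitted haplotype: Poisson crossovers at uniform positions."""
    k = int(rng.poisson(rate_per_bp * length))
    if k > 0:
        cuts = sorted(set(int(x) for x in rng.integers(1, length, size=k)))
    else:
        cuts = []
    phase = int(rng.integers(2))
    child: Haplotype = []
    start = 1
    src = phase
    for cut in cuts + [length]:
        child.extend(_slice_hap(parent[src], start, cut))
        start = cut + 1
        src ^= 1
    return _merge_adjacent(child)


def _ancestor_paths(pedigree: Pedigree, start: str, target: str) -> List[List[str]]:
    """All parent-link paths from ``start`` up to ``target`` (inclusive)."""
    if start == target:
        return [[start]]
    paths: List[List[str]] = []
    for parent in pedigree.parents_of(start):
        if parent is None:
            continue
        for sub in _ancestor_paths(pedigree, parent, target):
            paths.append([start] + sub)
    return paths


def required_risk_transmissions(
    pedigree: Pedigree, case_ids: Sequence[str], risk_founder: str
) -> set:
    """Meioses that must transmit the risk haplotype at the causal locus.

    For every case, both parents must pass the risk allele down their unique
    descent chain from the risk founder; the returned set holds
    (child_id, 'pat'|'mat') pairs. Raises when a descent path is absent or
    ambiguous (templates have unique paths by construction).
    """
    required = set()
    for cid in case_ids:
        father, mother = pedigree.parents_of(cid)
        if father is None or mother is None:
            raise ConfigurationError(f"case {cid} must have both parents in pedigree")
        for side, parent in (("pat", father), ("mat", mother)):
            paths = _ancestor_paths(pedigree, parent, risk_founder)
            if len(paths) != 1:
                raise ConfigurationError(
                    f"need exactly one descent path from {parent} to {risk_founder}, "
                    f"found {len(paths)}"
                )
            required.add((cid, side))
            chain = paths[0]
            for child, ancestor in zip(chain, chain[1:]):
                f, m = pedigree.parents_of(child)
                required.add((child, "pat" if ancestor == f else "mat"))
    return required


def _autozygous_tracts(
    pair: HaplotypePair, chrom: str, iid: str
) -> List[GenomicRegion]:
    h0, h1 = pair
    bounds = sorted({s for s, _, _ in h0} | {s for s, _, _ in h1})
    tracts: List[Tuple[int, int]] = []
    ends0 = [e for _, e, _ in h0]
    ends1 = [e for _, e, _ in h1]
    i = j = 0
    for start in bounds:
        while h0[i][1] < start:
            i += 1
        while h1[j][1] < start:
            j += 1
        end = min(h0[i][1], h1[j][1])
        if h0[i][2] == h1[j][2]:
            if tracts and tracts[-1][1] + 1 >= start:
                tracts[-1] = (tracts[-1][0], max(tracts[-1][1], end))
            else:
                tracts.append((start, end))
    return [
        GenomicRegion(
            chrom=chrom,
            start=s,
            end=e,
            provenance=Provenance.TRUE_AUTOZYGOUS,
            sample=iid,
        )
        for s, e in tracts
    ]


def gene_drop(
    pedigree: Pedigree,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    *,
    condition_on_causal: Optional[bool] = None,
) -> Tuple[Dict[str, Dict[str, HaplotypePair]], SimTruth]:
    """Drop labelled founder haplotypes through the pedigree.

    Returns per-individual, per-chromosome haplotype pairs and the ground
    truth of autozygous tracts. With causal conditioning the required
    meioses are rejection-sampled until they transmit the risk haplotype at
    the causal position (exact, because the conditioning event factorises
    over meioses).
    """
    cfg = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    condition = (
        cfg.condition_on_causal if condition_on_causal is None else condition_on_causal
    )
    required: set = set()
    if condition and pedigree.case_ids:
        required = required_risk_transmissions(
            pedigree, pedigree.case_ids, cfg.causal_founder[0]
        )

    rate_per_bp = cfg.recomb_rate_per_mb / 1e6
    length = cfg.chrom_length_bp
    risk_label = tuple(cfg.causal_founder)

    haplotypes: Dict[str, Dict[str, HaplotypePair]] = {}
    order = pedigree.topological_order()
    for chrom in cfg.chromosomes:
        conditioned_chrom = chrom == cfg.causal_chrom
        for ind in order:
            slot = haplotypes.setdefault(ind.iid, {})
            if ind.is_founder:
                slot[chrom] = (
                    [(1, length, (ind.iid, 0))],
                    [(1, length, (ind.iid, 1))],
                )
                continue
            pair: List[Haplotype] = []
            for side, parent_id in (("pat", ind.father), ("mat", ind.mother)):
                parent_pair = haplotypes[parent_id][chrom]
                must_carry = conditioned_chrom and (ind.iid, side) in required
                for attempt in range(10_000):
                    hap = _meiosis(parent_pair, length, rate_per_bp, rng)
                    if not must_carry or label_at(hap, cfg.causal_pos) == risk_label:
                        break
                else:  # pragma: no cover - parent guaranteed to carry
                    raise RuntimeError("conditioned meiosis failed to converge")
                pair.append(hap)
            slot[chrom] = (pair[0], pair[1])

    tracts: Dict[str, List[GenomicRegion]] = {}
    for ind in pedigree:
        regions: List[GenomicRegion] = []
        for chrom in cfg.chromosomes:
            regions.extend(
                _autozygous_tracts(haplotypes[ind.iid][chrom], chrom, ind.iid)
            )
        regions.sort(key=lambda r: r.sort_key)
        tracts[ind.iid] = regions
    truth = SimTruth(
        autozygous_tracts=tracts,
        causal_chrom=cfg.causal_chrom,
        causal_pos=cfg.causal_pos,
    )
    return haplotypes, truth


def autozygous_fraction(truth: SimTruth, iid: str, genome_bp: int) -> float:
    """Fraction of the simulated genome autozygous in one individual."""
    return sum(r.length for r in truth.autozygous_tracts[iid]) / genome_bp


# ---------------------------------------------------------------------------
# allele assignment


def _labels_at_positions(hap: Haplotype, positions: np.ndarray) -> List[HapLabel]:
    ends = np.array([e for _, e, _ in hap], dtype=np.int64)
    labels = [label for _, _, label in hap]
    idx = np.searchsorted(ends, positions, side="left")
    return [labels[i] for i in idx]


def assign_alleles(
    haplotypes: Dict[str, Dict[str, HaplotypePair]],
    pedigree: Pedigree,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[SimTruth] = None,
) -> SimTables:
    """Draw founder-haplotype alleles and derive true genotype dosages.

    Marker positions are uniform per chromosome (sorted, deduplicated, the
    causal position force-included); each founder haplotype draws an
    alternate allele per marker with the marker's MAF; the risk allele sits
    on exactly the configured founder haplotype. Genotypes follow the
    haplotype labels, so they are Mendelian-consistent by construction.
    """
    cfg = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    founder_labels: List[HapLabel] = []
    for ind in pedigree:
        if ind.is_founder:
            founder_labels.extend([(ind.iid, 0), (ind.iid, 1)])
    label_index = {label: i for i, label in enumerate(founder_labels)}
    consequence_keys = sorted(cfg.consequence_probs, key=lambda c: c.value)
    consequence_p = np.array([cfg.consequence_probs[c] for c in consequence_keys])

    positions: Dict[str, np.ndarray] = {}
    mafs: Dict[str, np.ndarray] = {}
    consequences: Dict[str, List[Consequence]] = {}
    pop_freqs: Dict[str, List[Optional[float]]] = {}
    dosages: Dict[str, Dict[str, np.ndarray]] = {ind.iid: {} for ind in pedigree}

    for chrom in cfg.chromosomes:
        pos = np.unique(
            rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_markers_per_chrom)
        )
        if chrom == cfg.causal_chrom and cfg.causal_pos not in pos:
            pos = np.sort(np.append(pos, cfg.causal_pos))
        n = pos.size
        maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=n)
        # founder haplotype alleles: rows follow founder_labels order
        alleles = (rng.random((len(founder_labels), n)) < maf).astype(np.int8)
        csq_idx = rng.choice(len(consequence_keys), size=n, p=consequence_p)
        novel = rng.random(n) < cfg.novel_fraction

        causal_idx = None
        if chrom == cfg.causal_chrom:
            causal_idx = int(np.searchsorted(pos, cfg.causal_pos))
            alleles[:, causal_idx] = 0
            alleles[label_index[tuple(cfg.causal_founder)], causal_idx] = 1

        csq = [consequence_keys[i] for i in csq_idx]
        freq: List[Optional[float]] = [
            None if novel[j] else round(float(maf[j]), 4) for j in range(n)
        ]
        if causal_idx is not None:
            csq[causal_idx] = Consequence.NONSYNONYMOUS
            freq[causal_idx] = None

        positions[chrom] = pos
        mafs[chrom] = maf
        consequences[chrom] = csq
        pop_freqs[chrom] = freq

        for ind in pedigree:
            h0, h1 = haplotypes[ind.iid][chrom]
            l0 = _labels_at_positions(h0, pos)
            l1 = _labels_at_positions(h1, pos)
            i0 = np.array([label_index[l] for l in l0])
            i1 = np.array([label_index[l] for l in l1])
            dosages[ind.iid][chrom] = (
                alleles[i0, np.arange(n)] + alleles[i1, np.arange(n)]
            ).astype(np.int8)

    tables = SimTables(
        positions=positions,
        mafs=mafs,
        consequences=consequences,
        pop_freqs=pop_freqs,
        dosages=dosages,
    )
    if truth is not None:
        truth.true_genotypes = dosages
        truth.marker_positions = positions
    return tables


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    tables: SimTables,
    pedigree: Pedigree,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
    sequenced: Optional[Sequence[str]] = None,
) -> List[VariantCall]:
    """Draw read counts for the sequenced samples and emit VariantCalls.

    Sequenced samples default to every CASE and CONTROL individual. The
    planted causal variant carries no population frequency (novel); all
    sites are biallelic SNVs with fixed ref/alt letters.
    """
    cfg = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if sequenced is None:
        sequenced = [ind.iid for ind in pedigree if ind.role is not Role.UNUSED]
    sequenced = list(sequenced)

    p_by_dosage = np.array([cfg.base_error, 0.5, 1.0 - cfg.base_error])
    calls: List[VariantCall] = []
    for chrom in cfg.chromosomes:
        pos = tables.positions[chrom]
        n = pos.size
        depth = rng.poisson(cfg.mean_depth, size=(len(sequenced), n))
        dosage = np.stack([tables.dosages[iid][chrom] for iid in sequenced])
        alt = rng.binomial(depth, p_by_dosage[dosage])
        for j in range(n):
            observations = {}
            for i, iid in enumerate(sequenced):
                d = int(depth[i, j])
                observations[iid] = SampleObservation(
                    depth=d,
                    alt_reads=int(alt[i, j]),
                    quality=cfg.read_quality if d > 0 else 0,
                )
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=int(pos[j]),
                    ref="A",
                    alt="C",
                    vclass=VariantClass.SNP,
                    consequence=tables.consequences[chrom][j],
                    pop_freq=tables.pop_freqs[chrom][j],
                    observations=observations,
                )
            )
    calls.sort(key=lambda c: c.sort_key)
    return calls


def simulate_dataset(config: Optional[SimConfig] = None) -> SimulatedDataset:
    """Run the full generator: pedigree, gene drop, alleles, reads."""
    cfg = config or SimConfig()
    problems = cfg.problems()
    if problems:
        raise ConfigurationError("; ".join(problems))
    rng = np.random.default_rng(cfg.seed)
    pedigree = build_pedigree(cfg.pedigree_template)
    haplotypes, truth = gene_drop(pedigree, cfg, rng)
    tables = assign_alleles(haplotypes, pedigree, cfg, rng, truth=truth)
    calls = simulate_reads(tables, pedigree, cfg, rng)
    return SimulatedDataset(
        config=cfg, pedigree=pedigree, calls=calls, truth=truth, tables=tables
    )


def true_case_shared_segments(
    truth: SimTruth, case_ids: Sequence[str], min_length_bp: int = 0
) -> List[GenomicRegion]:
    """Intersection of the cases' true autozygous tracts (label-agnostic)."""
    from .ibd import intersect_regions

    case_ids = sorted(case_ids)
    shared = list(truth.autozygous_tracts[case_ids[0]])
    for cid in case_ids[1:]:
        a = [
            GenomicRegion(r.chrom, r.start, r.end, Provenance.TRUE_AUTOZYGOUS)
            for r in shared
        ]
        b = [
            GenomicRegion(r.chrom, r.start, r.end, Provenance.TRUE_AUTOZYGOUS)
            for r in truth.autozygous_tracts[cid]
        ]
        shared = intersect_regions(a, b, provenance=Provenance.TRUE_AUTOZYGOUS)
    return [r for r in shared if r.length >= min_length_bp]


# ---------------------------------------------------------------------------
# fixture suite


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def make_fixture_suite(out_dir: str, seed: int) -> Dict[str, str]:
    """Write the deterministic fixture files used across module tests.

    Produces the 6-row QC table, the 1200- and 600-marker homozygous-window
    tables, the family PED template, a small end-to-end simulated dataset
    (VCF + PED + truth BED + truth genotype TSV) and a checksum manifest.
    Identical seeds yield byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)

    def _obs(depth: int, alt: int, qual: int) -> Dict[str, SampleObservation]:
        return {"S1": SampleObservation(depth, alt, qual)}

    def _snp(pos: int, obs, chrom: str = "1") -> VariantCall:
        return VariantCall(
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="C",
            vclass=VariantClass.SNP,
            consequence=Consequence.NONSYNONYMOUS,
            observations=obs,
        )

    qc_rows = [
        _snp(10_000, _obs(30, 30, 15)),  # fails quality >= 20
        _snp(20_000, _obs(3, 3, 60)),  # fails depth >= 4
        _snp(30_000, _obs(600, 600, 60)),  # fails depth <= 500
        _snp(40_000, _obs(30, 30, 60)),  # adjacent pair, 4 bp apart
        _snp(40_004, _obs(30, 30, 60)),
        _snp(50_000, _obs(30, 30, 60)),  # the lone survivor
    ]
    hio.write_variant_table_tsv(qc_rows, os.path.join(out_dir, "qc6.tsv"), ["S1"])

    for count, name in ((1200, "markers_hom_1200.tsv"), (600, "markers_hom_600.tsv")):
        rows = [_snp(1 + 1000 * i, _obs(30, 30, 60)) for i in range(count)]
        hio.write_variant_table_tsv(rows, os.path.join(out_dir, name), ["S1"])

    ped = build_pedigree("first_cousin_double")
    hio.write_pedigree(ped, os.path.join(out_dir, "family.ped"))

    sim_cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=10_000_000,
        n_markers_per_chrom=400,
        causal_chrom="1",
        causal_pos=5_000_000,
        seed=seed,
    )
    dataset = simulate_dataset(sim_cfg)
    sequenced = [i.iid for i in dataset.pedigree if i.role is not Role.UNUSED]
    hio.write_variant_vcf(
        dataset.calls,
        os.path.join(out_dir, "sim.vcf"),
        sequenced,
        contig_lengths={c: sim_cfg.chrom_length_bp for c in sim_cfg.chromosomes},
    )
    hio.write_pedigree(dataset.pedigree, os.path.join(out_dir, "sim.ped"))
    truth_regions = [
        r for iid in sorted(dataset.truth.autozygous_tracts) for r in dataset.truth.autozygous_tracts[iid]
    ]
    hio.write_regions_bed(truth_regions, os.path.join(out_dir, "sim_truth_tracts.bed"))

    with open(os.path.join(out_dir, "sim_truth_genotypes.tsv"), "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(sequenced) + "\n")
        for chrom in sim_cfg.chromosomes:
            pos = dataset.tables.positions[chrom]
            for j in range(pos.size):
                row = [chrom, str(int(pos[j]))]
                row += [
                    str(int(dataset.tables.dosages[iid][chrom][j])) for iid in sequenced
                ]
                fh.write("\t".join(row) + "\n")

    names = [
        "qc6.tsv",
        "markers_hom_1200.tsv",
        "markers_hom_600.tsv",
        "family.ped",
        "sim.vcf",
        "sim.ped",
        "sim_truth_tracts.bed",
        "sim_truth_genotypes.tsv",
    ]
    manifest = {name: _sha256(os.path.join(out_dir, name)) for name in names}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
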