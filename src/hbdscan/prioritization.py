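"""Intersect filtered variants with HBD regions and check recessive segregation.

Only recessive alleles located inside a case-shared, control-excluded HBD
region and segregating as a strict autosomal-recessive trait (all cases
homozygous-alternate, no control homozygous-alternate, obligate carriers
heterozygous or missing) are emitted as candidates. Candidates are
position-sorted, never ranked: pathogenicity prediction and conservation
are out of scope and live in a free-text ``notes`` slot.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .mapping import WindowConfig, classify_marker
from .types import GenomicRegion, Pedigree, VariantCall, Zygosity


@dataclass
class CandidateVariant:
    """A prioritized recessive candidate with its HBD region and genotypes."""

    variant: VariantCall
    region: GenomicRegion
    genotypes: Dict[str, Zygosity] = field(default_factory=dict)
    segregation_ok: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.region.contains(self.variant.chrom, self.variant.pos):
            raise ValueError(
                f"variant {self.variant.chrom}:{self.variant.pos} lies outside its region"
            )


def _region_lookup(
    regions: Sequence[GenomicRegion],
) -> Dict[str, List[GenomicRegion]]:
    by_chrom: Dict[str, List[GenomicRegion]] = {}
    for r in sorted(regions, key=lambda r: r.sort_key):
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ValueError(f"regions on {chrom} must be non-overlapping")
    return by_chrom


def region_containing(
    regions: Sequence[GenomicRegion], chrom: str, pos: int
) -> Optional[GenomicRegion]:
    from bisect import bisect_right

    by_chrom = _region_lookup(regions)
    rs = by_chrom.get(chrom, [])
    starts = [r.start for r in rs]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and rs[i].contains(chrom, pos):
        return rs[i]
    return None


def variants_in_regions(
    calls: Sequence[VariantCall], regions: Sequence[GenomicRegion]
) -> List[VariantCall]:
    """Keep calls whose position falls inside a region (inclusive ends)."""
    from bisect import bisect_right

    by_chrom = _region_lookup(regions)
    starts = {c: [r.start for r in rs] for c, rs in by_chrom.items()}
    out = []
    for call in calls:
        rs = by_chrom.get(call.chrom)
        if not rs:
            continue
        i = bisect_right(starts[call.chrom], call.pos) - 1
        if i >= 0 and rs[i].contains(call.chrom, call.pos):
            out.append(call)
    return out


def genotype_calls(
    variant: VariantCall, config: Optional[WindowConfig] = None
) -> Dict[str, Zygosity]:
    """Read-fraction zygosity of every observed sample at this variant."""
    cfg = config or WindowConfig()
    return {
        iid: classify_marker(obs.depth, obs.alt_reads, cfg)
        for iid, obs in variant.observations.items()
    }


def check_ar_segregation(
    variant: VariantCall,
    pedigree: Pedigree,
    config: Optional[WindowConfig] = None,
    *,
    genotypes: Optional[Dict[str, Zygosity]] = None,
) -> bool:
    """Strict autosomal-recessive segregation under full penetrance.

    True iff every case is homozygous-alternate, no control is
    homozygous-alternate, and every genotyped obligate carrier (an
    unaffected parent of a case) is heterozygous or effectively missing
    (AMBIGUOUS/UNCLASSIFIED); a homozygous-reference obligate carrier
    contradicts the recessive model and rejects the variant.
    """
    geno = genotypes if genotypes is not None else genotype_calls(variant, config)
    case_ids = pedigree.case_ids
    if not case_ids:
        return False
    if not all(geno.get(cid) is Zygosity.HOM_ALT for cid in case_ids):
        return False
    if any(geno.get(kid) is Zygosity.HOM_ALT for kid in pedigree.control_ids):
        return False
    obligate = set()
    for cid in case_ids:
        for parent in pedigree.parents_of(cid):
            if parent is not None and not pedigree[parent].affected:
                obligate.add(parent)
    for iid in obligate:
        g = geno.get(iid)
        if g is None or g in (Zygosity.AMBIGUOUS, Zygosity.UNCLASSIFIED):
            continue  # ungenotyped or unclassifiable: treated as missing
        if g is not Zygosity.HET:
            return False
    return True


def prioritize(
    filtered_calls: Sequence[VariantCall],
    hbd_regions: Sequence[GenomicRegion],
    pedigree: Pedigree,
    config: Optional[WindowConfig] = None,
) -> List[CandidateVariant]:
    """Emit candidate variants: inside an HBD region and segregating.

    Deterministic and invariant to input order; output sorted by
    (chromosome, position). No scoring beyond the filters.
    """
    by_chrom = _region_lookup(hbd_regions)
    from bisect import bisect_right

    starts = {c: [r.start for r in rs] for c, rs in by_chrom.items()}
    candidates: List[CandidateVariant] = []
    for call in sorted(filtered_calls, key=lambda c: c.sort_key):
        rs = by_chrom.get(call.chrom)
        if not rs:
            continue
        i = bisect_right(starts[call.chrom], call.pos) - 1
        if i < 0 or not rs[i].contains(call.chrom, call.pos):
            continue
        geno = genotype_calls(call, config)
        if not check_ar_segregation(call, pedigree, config, genotypes=geno):
            continue
        candidates.append(
            CandidateVariant(
                variant=call, region=rs[i], genotypes=geno, segregation_ok=True
            )
        )
    return candidates
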