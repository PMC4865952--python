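"""Variant-level filters reducing raw calls to rare recessive candidates.

The funnel applies, in order: per-sample QC gates with an adjacent-SNP
spacing rule, a protein-consequence filter, a population-frequency filter
and a case/control sharing filter. Each filter returns a subset of its
input and is idempotent; the consequence and frequency filters commute.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence

from .mapping import WindowConfig, classify_marker
from .types import (
    ConfigurationError,
    Consequence,
    Pedigree,
    VariantCall,
    VariantClass,
    Zygosity,
)

logger = logging.getLogger(__name__)

RETAINED_CONSEQUENCES: FrozenSet[Consequence] = frozenset(
    {
        Consequence.NONSYNONYMOUS,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_ACCEPTOR,
        Consequence.SPLICE_DONOR,
    }
)


@dataclass
class FilterConfig:
    """Published QC and rarity thresholds for the variant funnel.

    Calls need consensus quality >=20 and depth between 4 and 500 in every
    genotyped sample, annotated copy number <=2, and SNPs closer than 5 bp
    to another retained SNP are removed (both members of the pair). Variants
    at population frequency above 0.5% are discarded; the boundary itself is
    kept, and unannotated (novel) variants always pass.
    """

    min_quality: int = 20
    min_depth: int = 4
    max_depth: int = 500
    max_copy_number: int = 2
    min_adjacent_distance_bp: int = 5
    max_pop_freq: float = 0.005
    retained_consequences: FrozenSet[Consequence] = RETAINED_CONSEQUENCES

    def problems(self) -> List[str]:
        out = []
        if self.min_depth > self.max_depth:
            out.append(
                f"min_depth must be <= max_depth, got {self.min_depth} > {self.max_depth}"
            )
        if not 0.0 <= self.max_pop_freq <= 1.0:
            out.append(f"max_pop_freq must lie in [0, 1], got {self.max_pop_freq}")
        if self.min_quality < 0:
            out.append("min_quality must be >= 0")
        if self.min_adjacent_distance_bp < 0:
            out.append("min_adjacent_distance_bp must be >= 0")
        return out


def _check_sorted(calls: Sequence[VariantCall]) -> None:
    for a, b in zip(calls, calls[1:]):
        if b.sort_key < a.sort_key:
            raise ValueError("variant calls must be sorted by (chrom, pos)")


def qc_filter(
    calls: Sequence[VariantCall],
    config: Optional[FilterConfig] = None,
    pedigree: Optional[Pedigree] = None,
) -> List[VariantCall]:
    """Apply per-sample QC gates and the adjacent-SNP spacing rule.

    A call is retained iff every genotyped sample with nonzero depth meets
    the quality, depth and copy-number gates (calls missing in all samples
    are dropped). Among retained SNPs, any SNP lying closer than
    ``min_adjacent_distance_bp`` to another retained SNP on the same
    chromosome is then removed — cluster-wise, both members of a too-close
    pair (split multi-allelic records share a position and therefore remove
    each other). Indels are exempt from the spacing rule.
    """
    cfg = config or FilterConfig()
    _check_sorted(calls)

    stage1: List[VariantCall] = []
    for call in calls:
        observed = [
            obs
            for iid, obs in call.observations.items()
            if obs.depth > 0 and (pedigree is None or iid in pedigree)
        ]
        if not observed:
            logger.debug("drop %s:%d: no genotyped sample", call.chrom, call.pos)
            continue
        ok = all(
            obs.quality >= cfg.min_quality
            and cfg.min_depth <= obs.depth <= cfg.max_depth
            and (obs.copy_number_flag is None or obs.copy_number_flag <= cfg.max_copy_number)
            for obs in observed
        )
        if ok:
            stage1.append(call)
        else:
            logger.debug("drop %s:%d: per-sample QC gate", call.chrom, call.pos)

    snp_positions: Dict[str, List[int]] = {}
    for call in stage1:
        if call.vclass is VariantClass.SNP:
            snp_positions.setdefault(call.chrom, []).append(call.pos)
    too_close: Dict[str, set] = {}
    for chrom, positions in snp_positions.items():
        bad = set()
        for a, b in zip(positions, positions[1:]):
            if b - a < cfg.min_adjacent_distance_bp:
                bad.add(a)
                bad.add(b)
        too_close[chrom] = bad

    out = []
    for call in stage1:
        if (
            call.vclass is VariantClass.SNP
            and call.pos in too_close.get(call.chrom, ())
        ):
            logger.debug("drop %s:%d: adjacent-SNP spacing", call.chrom, call.pos)
            continue
        out.append(call)
    return out


def consequence_filter(
    calls: Sequence[VariantCall], config: Optional[FilterConfig] = None
) -> List[VariantCall]:
    """Keep protein-affecting classes; drop synonymous and non-coding calls."""
    cfg = config or FilterConfig()
    return [c for c in calls if c.consequence in cfg.retained_consequences]


def frequency_filter(
    calls: Sequence[VariantCall], config: Optional[FilterConfig] = None
) -> List[VariantCall]:
    """Drop variants whose population frequency exceeds ``max_pop_freq``.

    ``pop_freq`` is the maximum across the annotated frequency databases;
    an absent value marks a novel variant, which is always retained. The
    threshold is exclusive: a frequency exactly at the boundary is kept.
    """
    cfg = config or FilterConfig()
    for c in calls:
        if c.pop_freq is not None and not 0.0 <= c.pop_freq <= 1.0:
            raise ValueError(
                f"pop_freq outside [0, 1] at {c.chrom}:{c.pos}: {c.pop_freq}"
            )
    return [c for c in calls if c.pop_freq is None or c.pop_freq <= cfg.max_pop_freq]


def case_control_filter(
    calls: Sequence[VariantCall],
    pedigree: Pedigree,
    zygosity_config: Optional[WindowConfig] = None,
    *,
    strict_absence: bool = False,
) -> List[VariantCall]:
    """Keep variants shared by all cases and recessively absent in controls.

    A sample *carries* the variant when its read-fraction genotype is HET or
    HOM_ALT. Retained calls are carried by every case, homozygous-alternate
    in at least one case, and homozygous-alternate in no control. With
    ``strict_absence`` controls may not carry the variant at all (the
    literal "absent in controls" reading); the default allows heterozygous
    carrier parents, the configuration an autosomal recessive family
    necessarily shows.
    """
    zcfg = zygosity_config or WindowConfig()
    case_ids = pedigree.case_ids
    control_ids = pedigree.control_ids
    if not case_ids:
        raise ConfigurationError("pedigree defines no CASE individuals")

    out: List[VariantCall] = []
    for call in calls:
        geno = {
            iid: classify_marker(obs.depth, obs.alt_reads, zcfg)
            for iid, obs in call.observations.items()
        }
        carries = {
            iid: geno.get(iid) in (Zygosity.HET, Zygosity.HOM_ALT)
            for iid in geno
        }
        if not all(carries.get(cid, False) for cid in case_ids):
            logger.debug("drop %s:%d: not shared by all cases", call.chrom, call.pos)
            continue
        if not any(geno.get(cid) is Zygosity.HOM_ALT for cid in case_ids):
            logger.debug("drop %s:%d: never homozygous in a case", call.chrom, call.pos)
            continue
        if any(geno.get(kid) is Zygosity.HOM_ALT for kid in control_ids):
            logger.debug("drop %s:%d: homozygous in a control", call.chrom, call.pos)
            continue
        if strict_absence and any(carries.get(kid, False) for kid in control_ids):
            logger.debug("drop %s:%d: carried by a control", call.chrom, call.pos)
            continue
        out.append(call)
    return out
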