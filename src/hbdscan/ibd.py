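"""Run-based IBD segment detection and HBD interval algebra.

A per-sample IBD run is a maximal stretch of consecutive homozygous markers
(no intervening heterozygous marker) holding at least ``min_run_snps``
markers and spanning at least ``min_run_bp``. Case-shared HBD regions are
the n-way interval intersection of all cases' homozygous stretches; control
exclusion subtracts the union of the controls' stretches.

All region lists are sorted and non-overlapping per chromosome; coordinates
are 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .mapping import HET_CODE, sample_track
from .types import (
    ConfigurationError,
    GenomicRegion,
    Marker,
    Provenance,
    chrom_sort_key,
)


@dataclass
class IbdConfig:
    """Run rule for IBD segments: >=50 consecutive homozygous SNPs, >=1 Mb."""

    min_run_snps: int = 50
    min_run_bp: int = 1_000_000

    def problems(self) -> List[str]:
        out = []
        if self.min_run_snps < 1:
            out.append(f"min_run_snps must be >= 1, got {self.min_run_snps}")
        if self.min_run_bp < 1:
            out.append(f"min_run_bp must be >= 1, got {self.min_run_bp}")
        return out


def roh_runs(
    markers: Sequence[Marker],
    sample_id: str,
    config: Optional[IbdConfig] = None,
) -> List[GenomicRegion]:
    """Detect run-based IBD segments for one sample.

    The sample's marker sequence (HOM/HET classes only) is scanned for
    maximal runs of consecutive homozygous markers; runs with fewer than
    ``min_run_snps`` markers or spanning less than ``min_run_bp`` are
    discarded.
    """
    cfg = config or IbdConfig()
    regions: List[GenomicRegion] = []
    track = sample_track(markers, sample_id)
    for chrom in sorted(track, key=chrom_sort_key):
        pos, codes = track[chrom]
        hom = codes != HET_CODE
        n = pos.size
        i = 0
        while i < n:
            if not hom[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and hom[j + 1]:
                j += 1
            count = j - i + 1
            span = int(pos[j] - pos[i] + 1)
            if count >= cfg.min_run_snps and span >= cfg.min_run_bp:
                regions.append(
                    GenomicRegion(
                        chrom=chrom,
                        start=int(pos[i]),
                        end=int(pos[j]),
                        provenance=Provenance.IBD_RUN,
                        n_markers=count,
                        sample=sample_id,
                    )
                )
            i = j + 1
    regions.sort(key=lambda r: r.sort_key)
    return regions


def roh_runs_bruteforce(
    markers: Sequence[Marker],
    sample_id: str,
    config: Optional[IbdConfig] = None,
) -> List[GenomicRegion]:
    """Quadratic oracle for :func:`roh_runs`: test every candidate interval.

    An interval [i, j] of the sample's marker sequence is a run iff it is
    all-homozygous, not extendable on either side, and meets both minima.
    """
    cfg = config or IbdConfig()
    out: List[GenomicRegion] = []
    track = sample_track(markers, sample_id)
    for chrom in sorted(track, key=chrom_sort_key):
        pos, codes = track[chrom]
        hom = [c != HET_CODE for c in codes]
        n = len(hom)
        for i in range(n):
            for j in range(i, n):
                if not all(hom[i : j + 1]):
                    continue
                if i > 0 and hom[i - 1]:
                    continue
                if j + 1 < n and hom[j + 1]:
                    continue
                count = j - i + 1
                span = int(pos[j] - pos[i] + 1)
                if count >= cfg.min_run_snps and span >= cfg.min_run_bp:
                    out.append(
                        GenomicRegion(
                            chrom=chrom,
                            start=int(pos[i]),
                            end=int(pos[j]),
                            provenance=Provenance.IBD_RUN,
                            n_markers=count,
                            sample=sample_id,
                        )
                    )
    out.sort(key=lambda r: r.sort_key)
    return out


def _validate(regions: Sequence[GenomicRegion], name: str) -> None:
    by_chrom: Dict[str, List[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        for a, b in zip(rs, rs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{name}: regions on {chrom} must be sorted and non-overlapping"
                )


def _intervals(regions: Sequence[GenomicRegion]) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        out.setdefault(r.chrom, []).append((r.start, r.end))
    return out


def _emit(
    intervals: Dict[str, List[Tuple[int, int]]],
    provenance: Provenance,
    min_fragment_bp: int = 0,
    sample: Optional[str] = None,
) -> List[GenomicRegion]:
    out = [
        GenomicRegion(chrom=c, start=s, end=e, provenance=provenance, sample=sample)
        for c, ivs in intervals.items()
        for s, e in ivs
        if e - s + 1 >= min_fragment_bp
    ]
    out.sort(key=lambda r: r.sort_key)
    return out


def intersect_regions(
    a: Sequence[GenomicRegion],
    b: Sequence[GenomicRegion],
    *,
    provenance: Optional[Provenance] = None,
) -> List[GenomicRegion]:
    """Standard interval intersection of two sorted, non-overlapping lists."""
    _validate(a, "a")
    _validate(b, "b")
    prov = provenance or (a[0].provenance if a else Provenance.CASE_SHARED_HBD)
    ia, ib = _intervals(a), _intervals(b)
    result: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in set(ia) & set(ib):
        xs, ys = ia[chrom], ib[chrom]
        i = j = 0
        merged: List[Tuple[int, int]] = []
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s <= e:
                merged.append((s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
        if merged:
            result[chrom] = merged
    return _emit(result, prov)


def merge_regions(
    regions: Sequence[GenomicRegion], *, provenance: Optional[Provenance] = None
) -> List[GenomicRegion]:
    """Union of possibly-overlapping regions, merged per chromosome."""
    prov = provenance or (regions[0].provenance if regions else Provenance.IBD_RUN)
    ivs = _intervals(regions)
    result: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, pairs in ivs.items():
        pairs.sort()
        merged: List[Tuple[int, int]] = []
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        result[chrom] = merged
    return _emit(result, prov)


def subtract_regions(
    a: Sequence[GenomicRegion],
    b: Sequence[GenomicRegion],
    *,
    provenance: Optional[Provenance] = None,
) -> List[GenomicRegion]:
    """Interval difference a \\ b for sorted, non-overlapping lists."""
    _validate(a, "a")
    _validate(b, "b")
    prov = provenance or (a[0].provenance if a else Provenance.HBD_CONTROL_EXCLUDED)
    ia, ib = _intervals(a), _intervals(b)
    result: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, xs in ia.items():
        ys = ib.get(chrom, [])
        out: List[Tuple[int, int]] = []
        for s, e in xs:
            cur = s
            for bs, be in ys:
                if be < cur or bs > e:
                    continue
                if bs > cur:
                    out.append((cur, bs - 1))
                cur = max(cur, be + 1)
                if cur > e:
                    break
            if cur <= e:
                out.append((cur, e))
        if out:
            result[chrom] = out
    return _emit(result, prov)


def case_shared_hbd(
    per_case_stretches: Dict[str, Sequence[GenomicRegion]],
    min_fragment_bp: int = 1_000_000,
) -> List[GenomicRegion]:
    """n-way intersection of all cases' homozygous stretches.

    Fragments shorter than ``min_fragment_bp`` are discarded. The result is
    allele-agnostic: co-location of homozygosity, not allele identity, which
    is enforced later at variant prioritization.
    """
    if not per_case_stretches:
        raise ConfigurationError("case_shared_hbd requires at least one case")
    case_ids = sorted(per_case_stretches)
    shared = list(per_case_stretches[case_ids[0]])
    _validate(shared, case_ids[0])
    for cid in case_ids[1:]:
        shared = intersect_regions(
            shared, per_case_stretches[cid], provenance=Provenance.CASE_SHARED_HBD
        )
    ivs = _intervals(shared)
    return _emit(ivs, Provenance.CASE_SHARED_HBD, min_fragment_bp=min_fragment_bp)


def exclude_control_overlap(
    hbd_regions: Sequence[GenomicRegion],
    per_control_stretches: Dict[str, Sequence[GenomicRegion]],
    min_fragment_bp: int = 1_000_000,
    *,
    discard_entirely: bool = False,
) -> List[GenomicRegion]:
    """Remove control homozygosity from case-shared HBD regions.

    By default the overlapping portion is subtracted and remaining fragments
    shorter than ``min_fragment_bp`` are discarded; with
    ``discard_entirely`` any region touching a control stretch is dropped
    whole (the literal no-overlap reading).
    """
    _validate(hbd_regions, "hbd_regions")
    controls: List[GenomicRegion] = []
    for cid in sorted(per_control_stretches):
        controls.extend(per_control_stretches[cid])
    if not controls:
        return _emit(
            _intervals(hbd_regions),
            Provenance.HBD_CONTROL_EXCLUDED,
            min_fragment_bp=0,
        )
    control_union = merge_regions(controls)
    if discard_entirely:
        kept = [
            r
            for r in hbd_regions
            if not any(r.overlaps(c) for c in control_union)
        ]
        return _emit(_intervals(kept), Provenance.HBD_CONTROL_EXCLUDED)
    remainder = subtract_regions(
        hbd_regions, control_union, provenance=Provenance.HBD_CONTROL_EXCLUDED
    )
    return _emit(
        _intervals(remainder),
        Provenance.HBD_CONTROL_EXCLUDED,
        min_fragment_bp=min_fragment_bp,
    )
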