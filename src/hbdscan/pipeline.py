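"""End-to-end orchestration: filter -> map -> HBD -> prioritize, with a report.

The run report records the per-stage funnel counts (raw calls through QC,
consequence, frequency and sharing filters down to candidates), the
per-case homozygous-stretch totals and the final candidate table, together
with the full effective configuration, software version and seed, so a run
is reproducible from its report alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from . import __version__
from .filtering import (
    FilterConfig,
    case_control_filter,
    consequence_filter,
    frequency_filter,
    qc_filter,
)
from .ibd import (
    IbdConfig,
    case_shared_hbd,
    exclude_control_overlap,
    intersect_regions,
    merge_regions,
    roh_runs,
)
from .io import write_candidates_tsv, write_regions_bed
from .mapping import WindowConfig, build_marker_map, homozygous_stretches
from .prioritization import prioritize
from .simulate import SimConfig, SimulatedDataset, simulate_dataset
from .types import (
    ConfigurationError,
    GenomicRegion,
    Marker,
    Pedigree,
    PipelineError,
    Provenance,
    VariantCall,
)

logger = logging.getLogger(__name__)

HBD_SOURCES = ("ibd_runs", "windows", "intersect", "union")


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Aggregates every stage configuration; the single home of thresholds."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    ibd: IbdConfig = field(default_factory=IbdConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    # which detector delineates per-sample homozygous stretches; the run rule
    # works at marker resolution, windows at window-span resolution
    hbd_source: str = "ibd_runs"
    strict_absence: bool = False
    discard_control_overlap_entirely: bool = False
    seed: int = 0

    def problems(self) -> List[str]:
        out = []
        out += [f"filter: {p}" for p in self.filter.problems()]
        out += [f"window: {p}" for p in self.window.problems()]
        out += [f"ibd: {p}" for p in self.ibd.problems()]
        out += [f"sim: {p}" for p in self.sim.problems()]
        if self.hbd_source not in HBD_SOURCES:
            out.append(f"hbd_source must be one of {HBD_SOURCES}")
        return out


def validate_config(config: PipelineConfig) -> List[str]:
    """Check all sub-config invariants; an empty list means valid."""
    return config.problems()


def config_to_dict(config: PipelineConfig) -> Dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {
                (k.value if hasattr(k, "value") else k): convert(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, frozenset):
            return sorted(v.value if hasattr(v, "value") else v for v in obj)
        if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
            return obj.value
        return obj

    return convert(config)


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run (no timestamps)."""

    seed: int
    version: str
    config: Dict
    counts: Dict[str, int]
    per_case_stretch_bp: Dict[str, int]
    hbd_regions: List[Dict]
    candidates: List[Dict]

    def check_funnel(self) -> None:
        order = [
            "variants_input",
            "variants_qc",
            "variants_consequence",
            "variants_frequency",
            "variants_case_control",
            "candidates",
        ]
        values = [self.counts[k] for k in order]
        for a, b, ka, kb in zip(values, values[1:], order, order[1:]):
            if b > a:
                raise PipelineError(f"funnel violated: {kb} ({b}) > {ka} ({a})")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _region_dict(r: GenomicRegion) -> Dict:
    return {
        "chrom": r.chrom,
        "start": r.start,
        "end": r.end,
        "length": r.length,
        "provenance": r.provenance.value,
        "n_markers": r.n_markers,
    }


def per_sample_stretches(
    markers: Sequence[Marker],
    sample_id: str,
    window_config: WindowConfig,
    ibd_config: IbdConfig,
    hbd_source: str,
) -> List[GenomicRegion]:
    """Delineate one sample's homozygous stretches with the chosen detector."""
    if hbd_source not in HBD_SOURCES:
        raise ConfigurationError(f"unknown hbd_source: {hbd_source}")
    windows = (
        homozygous_stretches(markers, sample_id, window_config)
        if hbd_source in ("windows", "intersect", "union")
        else []
    )
    runs = (
        roh_runs(markers, sample_id, ibd_config)
        if hbd_source in ("ibd_runs", "intersect", "union")
        else []
    )
    if hbd_source == "windows":
        return windows
    if hbd_source == "ibd_runs":
        return runs
    if hbd_source == "intersect":
        out = intersect_regions(
            windows, runs, provenance=Provenance.PER_SAMPLE_STRETCH
        )
        return [r for r in out if r.length >= window_config.min_stretch_bp]
    merged = merge_regions(
        list(windows) + list(runs), provenance=Provenance.PER_SAMPLE_STRETCH
    )
    return [
        GenomicRegion(
            r.chrom, r.start, r.end, Provenance.PER_SAMPLE_STRETCH, r.n_markers, sample_id
        )
        for r in merged
    ]


def run_pipeline(
    config: PipelineConfig,
    calls: Optional[Sequence[VariantCall]] = None,
    pedigree: Optional[Pedigree] = None,
    out_dir: Optional[str] = None,
) -> RunReport:
    """Execute the full discovery pipeline and return the run report.

    Without explicit inputs, a dataset is simulated from ``config.sim``.
    Writes BED/TSV artifacts and the JSON report when ``out_dir`` is given.
    Zero candidates is a successful outcome, not an error.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))

    if calls is None:
        try:
            dataset: SimulatedDataset = simulate_dataset(config.sim)
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        calls = dataset.calls
        pedigree = dataset.pedigree
    if pedigree is None:
        raise ConfigurationError("a pedigree is required")
    if not pedigree.case_ids:
        raise ConfigurationError("pedigree defines no CASE individuals")

    counts: Dict[str, int] = {"variants_input": len(calls)}

    try:
        qc = qc_filter(calls, config.filter, pedigree)
    except Exception as exc:
        raise StageError("qc_filter", exc) from exc
    counts["variants_qc"] = len(qc)

    try:
        markers = build_marker_map(qc, pedigree, config.window)
    except Exception as exc:
        raise StageError("marker_map", exc) from exc
    counts["markers"] = len(markers)

    try:
        per_case: Dict[str, List[GenomicRegion]] = {}
        per_control: Dict[str, List[GenomicRegion]] = {}
        for cid in pedigree.case_ids:
            per_case[cid] = per_sample_stretches(
                markers, cid, config.window, config.ibd, config.hbd_source
            )
        for kid in pedigree.control_ids:
            per_control[kid] = per_sample_stretches(
                markers, kid, config.window, config.ibd, config.hbd_source
            )
    except Exception as exc:
        raise StageError("stretches", exc) from exc
    stretch_bp = {
        iid: sum(r.length for r in regions)
        for iid, regions in {**per_case, **per_control}.items()
    }

    try:
        shared = case_shared_hbd(per_case, config.window.min_stretch_bp)
        hbd = exclude_control_overlap(
            shared,
            per_control,
            config.window.min_stretch_bp,
            discard_entirely=config.discard_control_overlap_entirely,
        )
    except Exception as exc:
        raise StageError("hbd", exc) from exc
    counts["case_shared_regions"] = len(shared)
    counts["hbd_regions"] = len(hbd)

    try:
        cons = consequence_filter(qc, config.filter)
        counts["variants_consequence"] = len(cons)
        freq = frequency_filter(cons, config.filter)
        counts["variants_frequency"] = len(freq)
        cc = case_control_filter(
            freq, pedigree, config.window, strict_absence=config.strict_absence
        )
        counts["variants_case_control"] = len(cc)
    except Exception as exc:
        raise StageError("variant_filters", exc) from exc

    try:
        candidates = prioritize(cc, hbd, pedigree, config.window)
    except Exception as exc:
        raise StageError("prioritize", exc) from exc
    counts["candidates"] = len(candidates)

    for stage, n in counts.items():
        logger.info("%s: %d", stage, n)

    report = RunReport(
        seed=config.seed,
        version=__version__,
        config=config_to_dict(config),
        counts=counts,
        per_case_stretch_bp=stretch_bp,
        hbd_regions=[_region_dict(r) for r in hbd],
        candidates=[
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "consequence": c.variant.consequence.value,
                "pop_freq": c.variant.pop_freq,
                "genotypes": {k: v.value for k, v in sorted(c.genotypes.items())},
            }
            for c in candidates
        ],
    )
    report.check_funnel()

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        stretches = [r for rs in per_case.values() for r in rs] + [
            r for rs in per_control.values() for r in rs
        ]
        write_regions_bed(stretches, os.path.join(out_dir, "stretches.bed"))
        write_regions_bed(list(shared) + list(hbd), os.path.join(out_dir, "hbd.bed"))
        write_candidates_tsv(
            candidates, os.path.join(out_dir, "candidates.tsv"), pedigree
        )
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
    return report
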