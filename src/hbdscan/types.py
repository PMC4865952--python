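"""Core domain types shared across the autozygosity-mapping pipeline.

Coordinates are 1-based and inclusive throughout the package, matching the
UCSC-style intervals printed in the clinical-genetics literature; BED export
converts to 0-based half-open at the boundary (see :mod:`hbdscan.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Tuple


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class LoadError(PipelineError):
    """A file could not be parsed into domain objects."""


class ConfigurationError(PipelineError):
    """Inputs are inconsistent with each other or with the configuration."""


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class Consequence(str, Enum):
    """Coarse functional consequence of a variant on the coding sequence."""

    NONSYNONYMOUS = "NONSYNONYMOUS"
    FRAMESHIFT = "FRAMESHIFT"
    SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"
    SPLICE_DONOR = "SPLICE_DONOR"
    SYNONYMOUS = "SYNONYMOUS"
    NONCODING = "NONCODING"
    OTHER = "OTHER"


class Zygosity(str, Enum):
    """Read-fraction based zygosity class of one sample at one site.

    UNCLASSIFIED means a depth gate failed; AMBIGUOUS means the alternate
    read fraction fell between the homozygous and heterozygous bands.
    """

    HOM_REF = "HOM_REF"
    HOM_ALT = "HOM_ALT"
    HET = "HET"
    AMBIGUOUS = "AMBIGUOUS"
    UNCLASSIFIED = "UNCLASSIFIED"


HOMOZYGOUS: Tuple[Zygosity, Zygosity] = (Zygosity.HOM_REF, Zygosity.HOM_ALT)


class Provenance(str, Enum):
    """Which pipeline stage produced a genomic region."""

    PER_SAMPLE_STRETCH = "PER_SAMPLE_STRETCH"
    IBD_RUN = "IBD_RUN"
    CASE_SHARED_HBD = "CASE_SHARED_HBD"
    HBD_CONTROL_EXCLUDED = "HBD_CONTROL_EXCLUDED"
    TRUE_AUTOZYGOUS = "TRUE_AUTOZYGOUS"


class Role(str, Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"
    UNUSED = "UNUSED"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M"}


def chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    """Natural chromosome ordering: numeric names first, others by name."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def is_autosome(chrom: str) -> bool:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return name.upper() not in _NON_AUTOSOMES


@dataclass(frozen=True)
class SampleObservation:
    """Read-level evidence for one sample at one variant site.

    ``depth`` is the total read count, ``alt_reads`` the reads supporting
    the alternate allele, ``quality`` the phred-like consensus quality of
    the call, and ``copy_number_flag`` an optional annotated copy number.
    A missing genotype is represented as ``depth == 0``, never imputed.
    """

    depth: int
    alt_reads: int
    quality: int = 0
    copy_number_flag: Optional[int] = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError(
                f"alt_reads must be in [0, depth]; got {self.alt_reads} with depth {self.depth}"
            )
        if self.quality < 0:
            raise ValueError(f"quality must be >= 0, got {self.quality}")


MISSING_OBSERVATION = SampleObservation(depth=0, alt_reads=0, quality=0)


@dataclass
class VariantCall:
    """One variant site (one alternate allele) with per-sample observations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: VariantClass
    consequence: Consequence = Consequence.OTHER
    pop_freq: Optional[float] = None
    observations: Dict[str, SampleObservation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.alt == self.ref:
            raise ValueError(f"alt must differ from ref at {self.chrom}:{self.pos}")
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq must lie in [0, 1], got {self.pop_freq}")

    @property
    def sort_key(self) -> Tuple[Tuple[int, int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Individual:
    iid: str
    father: Optional[str]
    mother: Optional[str]
    sex: Sex = Sex.UNKNOWN
    affected: bool = False
    role: Role = Role.UNUSED

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Individuals with parent links, affection status and analysis roles."""

    individuals: List[Individual]

    def __post_init__(self) -> None:
        ids = [ind.iid for ind in self.individuals]
        if len(ids) != len(set(ids)):
            raise LoadError("duplicate individual ids in pedigree")
        self._by_id = {ind.iid: ind for ind in self.individuals}
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._by_id:
                    raise LoadError(
                        f"individual {ind.iid} references unknown parent {parent}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: Dict[str, int] = {}  # 0 = visiting, 1 = done

        for start in self._by_id:
            if start in state:
                continue
            stack: List[Tuple[str, int]] = [(start, 0)]
            while stack:
                iid, phase = stack.pop()
                if phase == 0:
                    if state.get(iid) == 0:
                        raise LoadError("pedigree contains a parentage cycle")
                    if state.get(iid) == 1:
                        continue
                    state[iid] = 0
                    stack.append((iid, 1))
                    ind = self._by_id[iid]
                    for parent in (ind.father, ind.mother):
                        if parent is not None and state.get(parent) != 1:
                            stack.append((parent, 0))
                else:
                    state[iid] = 1

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def __iter__(self):
        return iter(self.individuals)

    @property
    def ids(self) -> List[str]:
        return [ind.iid for ind in self.individuals]

    @property
    def case_ids(self) -> List[str]:
        return [ind.iid for ind in self.individuals if ind.role is Role.CASE]

    @property
    def control_ids(self) -> List[str]:
        return [ind.iid for ind in self.individuals if ind.role is Role.CONTROL]

    @property
    def founders(self) -> List[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    def parents_of(self, iid: str) -> Tuple[Optional[str], Optional[str]]:
        ind = self._by_id[iid]
        return ind.father, ind.mother

    def topological_order(self) -> List[Individual]:
        """Individuals ordered so every parent precedes its children."""
        done: Dict[str, bool] = {}
        order: List[Individual] = []

        def visit(iid: str) -> None:
            if done.get(iid):
                return
            ind = self._by_id[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            done[iid] = True
            order.append(ind)

        for ind in self.individuals:
            visit(ind.iid)
        return order


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based, inclusive genomic interval with provenance.

    ``length`` is ``end - start + 1``. Region lists handled by the interval
    algebra are required to be sorted and non-overlapping within one
    (chromosome, provenance, sample) bucket.
    """

    chrom: str
    start: int
    end: int
    provenance: Provenance
    n_markers: int = 0
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start must be <= end, got {self.start} > {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    @property
    def sort_key(self) -> Tuple[Tuple[int, int, str], int, int]:
        return (chrom_sort_key(self.chrom), self.start, self.end)


@dataclass
class Marker:
    """An autosomal SNP site with a per-sample zygosity classification."""

    chrom: str
    pos: int
    zygosity: Dict[str, Zygosity] = field(default_factory=dict)

    @property
    def sort_key(self) -> Tuple[Tuple[int, int, str], int]:
        return (chrom_sort_key(self.chrom), self.pos)
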