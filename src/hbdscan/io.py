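"""Readers and writers for the formats the pipeline touches.

Variant tables come in as VCF v4.2 (FORMAT ``DP``/``AD``/``GQ``, INFO
``CSQCLASS``/``POPFREQ``/``CN``) or as a simple TSV dialect that sidesteps
VCF ambiguities for fixtures; pedigrees as 6-column PED with an optional
ROLE column; regions go out as BED3+ (internally 1-based inclusive, BED is
0-based half-open, so exported start = start - 1). All writers are
deterministic: the same objects produce byte-identical files.
"""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .types import (
    ConfigurationError,
    Consequence,
    GenomicRegion,
    Individual,
    LoadError,
    MISSING_OBSERVATION,
    Pedigree,
    Provenance,
    Role,
    SampleObservation,
    Sex,
    VariantCall,
    VariantClass,
    chrom_sort_key,
)

_TSV_FIXED_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vclass",
    "consequence",
    "pop_freq",
    "copy_number",
]


def _fmt_freq(freq: Optional[float]) -> str:
    return "." if freq is None else format(freq, "g")


def _infer_vclass(ref: str, alt: str) -> VariantClass:
    return VariantClass.SNP if len(ref) == 1 and len(alt) == 1 else VariantClass.INDEL


# ---------------------------------------------------------------------------
# variant tables


def write_variant_table_tsv(
    calls: Sequence[VariantCall], path: str, sample_ids: Optional[Sequence[str]] = None
) -> None:
    """Write calls in the TSV dialect; per-sample cells are depth:alt:quality."""
    if sample_ids is None:
        seen: List[str] = []
        for call in calls:
            for iid in call.observations:
                if iid not in seen:
                    seen.append(iid)
        sample_ids = sorted(seen)
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_FIXED_COLUMNS + list(sample_ids)) + "\n")
        for call in sorted(calls, key=lambda c: c.sort_key):
            cn = {
                obs.copy_number_flag
                for obs in call.observations.values()
                if obs.copy_number_flag is not None
            }
            row = [
                call.chrom,
                str(call.pos),
                call.ref,
                call.alt,
                call.vclass.value,
                call.consequence.value,
                _fmt_freq(call.pop_freq),
                str(sorted(cn)[0]) if cn else ".",
            ]
            for iid in sample_ids:
                obs = call.observations.get(iid)
                if obs is None or obs.depth == 0:
                    row.append(".")
                else:
                    row.append(f"{obs.depth}:{obs.alt_reads}:{obs.quality}")
            fh.write("\t".join(row) + "\n")


def _read_variant_table_tsv(path: str, pedigree: Optional[Pedigree]) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_FIXED_COLUMNS)] != _TSV_FIXED_COLUMNS:
            raise LoadError(f"{path}: line 1: unexpected TSV header")
        sample_ids = header[len(_TSV_FIXED_COLUMNS) :]
        if pedigree is not None:
            unknown = [s for s in sample_ids if s not in pedigree]
            if unknown:
                raise ConfigurationError(
                    f"samples absent from pedigree: {', '.join(unknown)}"
                )
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise LoadError(f"{path}: line {lineno}: wrong column count")
            try:
                cn = None if fields[7] == "." else int(fields[7])
                observations = {}
                for iid, cell in zip(sample_ids, fields[8:]):
                    if cell == ".":
                        observations[iid] = SampleObservation(0, 0, 0, cn)
                        continue
                    depth, alt_reads, quality = (int(x) for x in cell.split(":"))
                    observations[iid] = SampleObservation(depth, alt_reads, quality, cn)
                calls.append(
                    VariantCall(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        ref=fields[2],
                        alt=fields[3],
                        vclass=VariantClass(fields[4]),
                        consequence=Consequence(fields[5]),
                        pop_freq=None if fields[6] == "." else float(fields[6]),
                        observations=observations,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise LoadError(f"{path}: line {lineno}: {exc}") from exc
    calls.sort(key=lambda c: c.sort_key)
    return calls


def _info_get(rec, key):
    # pysam raises ValueError for INFO keys absent from the header
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _sample_get(sample, key):
    try:
        return sample.get(key)
    except (KeyError, ValueError):
        return None


def _read_vcf(path: str, pedigree: Optional[Pedigree]) -> List[VariantCall]:
    calls: List[VariantCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if pedigree is not None:
            unknown = [s for s in samples if s not in pedigree]
            if unknown:
                raise ConfigurationError(
                    f"samples absent from pedigree: {', '.join(unknown)}"
                )
        for record_no, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                csq = _info_get(rec, "CSQCLASS")
                freq = _info_get(rec, "POPFREQ")
                cn = _info_get(rec, "CN")
                for alt_index, alt in enumerate(alts):
                    observations: Dict[str, SampleObservation] = {}
                    for iid in samples:
                        s = rec.samples[iid]
                        ad = _sample_get(s, "AD")
                        dp = _sample_get(s, "DP")
                        alt_reads = 0
                        if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
                            alt_reads = int(ad[alt_index + 1])
                        if dp is None:
                            dp = sum(x for x in ad if x is not None) if ad else 0
                        gq = _sample_get(s, "GQ")
                        if gq is None:
                            gq = int(rec.qual) if rec.qual is not None else 0
                        depth = int(dp)
                        if depth == 0:
                            observations[iid] = MISSING_OBSERVATION
                        else:
                            observations[iid] = SampleObservation(
                                depth=depth,
                                alt_reads=min(alt_reads, depth),
                                quality=int(gq),
                                copy_number_flag=int(cn) if cn is not None else None,
                            )
                    calls.append(
                        VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=str(alt),
                            vclass=_infer_vclass(rec.ref, str(alt)),
                            consequence=Consequence(csq) if csq else Consequence.OTHER,
                            pop_freq=float(freq) if freq is not None else None,
                            observations=observations,
                        )
                    )
            except (ValueError, KeyError, TypeError) as exc:
                raise LoadError(f"{path}: record {record_no}: {exc}") from exc
    calls.sort(key=lambda c: c.sort_key)
    return calls


def read_variant_table(
    path: str, format: Optional[str] = None, pedigree: Optional[Pedigree] = None
) -> List[VariantCall]:
    """Read a variant table (VCF or TSV dialect) into sorted VariantCalls.

    Multi-allelic VCF records split into one call per alternate allele with
    the matching ``AD`` slot; missing per-sample data becomes a depth-0
    observation. Sample ids are checked against the pedigree when given.
    """
    if format is None:
        format = "vcf" if path.endswith(".vcf") or path.endswith(".vcf.gz") else "tsv"
    if format == "vcf":
        return _read_vcf(path, pedigree)
    if format == "tsv":
        return _read_variant_table_tsv(path, pedigree)
    raise ValueError(f"unknown variant table format: {format}")


def write_variant_vcf(
    calls: Sequence[VariantCall],
    path: str,
    sample_ids: Sequence[str],
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write biallelic calls as an uncompressed VCF v4.2 text file."""
    calls = sorted(calls, key=lambda c: c.sort_key)
    if contig_lengths is None:
        contig_lengths = {}
        for call in calls:
            contig_lengths[call.chrom] = max(
                contig_lengths.get(call.chrom, 0), call.pos
            )
    lines = ["##fileformat=VCFv4.2", "##source=hbdscan"]
    for chrom in sorted(contig_lengths, key=chrom_sort_key):
        lines.append(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>")
    lines += [
        '##INFO=<ID=CSQCLASS,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=POPFREQ,Number=1,Type=Float,Description="Max population allele frequency">',
        '##INFO=<ID=CN,Number=1,Type=Integer,Description="Annotated copy number">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    for call in calls:
        info = [f"CSQCLASS={call.consequence.value}"]
        if call.pop_freq is not None:
            info.append(f"POPFREQ={format(call.pop_freq, 'g')}")
        cn = {
            obs.copy_number_flag
            for obs in call.observations.values()
            if obs.copy_number_flag is not None
        }
        if cn:
            info.append(f"CN={sorted(cn)[0]}")
        row = [
            call.chrom,
            str(call.pos),
            ".",
            call.ref,
            call.alt,
            ".",
            ".",
            ";".join(info),
            "GQ:DP:AD",
        ]
        for iid in sample_ids:
            obs = call.observations.get(iid, MISSING_OBSERVATION)
            row.append(
                f"{obs.quality}:{obs.depth}:{obs.depth - obs.alt_reads},{obs.alt_reads}"
            )
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pedigrees

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


def read_pedigree(path: str) -> Pedigree:
    """Read a 6-column PED file with an optional seventh ROLE column.

    PED phenotype 2 maps to affected. Without a ROLE column, affected
    individuals default to CASE and unaffected ones to CONTROL.
    """
    import warnings

    individuals: List[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (6, 7):
                raise LoadError(f"{path}: line {lineno}: expected 6 or 7 columns")
            _fam, iid, father, mother, sex_code, pheno = fields[:6]
            sex = _SEX_FROM_PED.get(sex_code)
            if sex is None:
                if sex_code != "0":
                    warnings.warn(
                        f"{path}: line {lineno}: unknown sex code {sex_code!r}, "
                        "stored as unknown"
                    )
                sex = Sex.UNKNOWN
            affected = pheno == "2"
            if len(fields) == 7:
                try:
                    role = Role(fields[6].upper())
                except ValueError as exc:
                    raise LoadError(
                        f"{path}: line {lineno}: unknown role {fields[6]!r}"
                    ) from exc
            else:
                role = Role.CASE if affected else Role.CONTROL
            individuals.append(
                Individual(
                    iid=iid,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    sex=sex,
                    affected=affected,
                    role=role,
                )
            )
    try:
        return Pedigree(individuals)
    except LoadError as exc:
        raise LoadError(f"{path}: {exc}") from exc


def write_pedigree(pedigree: Pedigree, path: str, famid: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        famid,
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        _SEX_TO_PED[ind.sex],
                        "2" if ind.affected else "1",
                        ind.role.value,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# regions (BED3+2)

_BED_HEADER = "# hbdscan regions: chrom, start (0-based), end, provenance, n_markers, sample"


def write_regions_bed(regions: Sequence[GenomicRegion], path: str) -> None:
    """Write regions as BED3+ (0-based half-open: start-1, end)."""
    ordered = sorted(
        regions, key=lambda r: (r.sort_key, r.provenance.value, r.sample or "")
    )
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for r in ordered:
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start - 1),
                        str(r.end),
                        r.provenance.value,
                        str(r.n_markers),
                        r.sample or ".",
                    ]
                )
                + "\n"
            )


def read_regions_bed(path: str) -> List[GenomicRegion]:
    regions: List[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                regions.append(
                    GenomicRegion(
                        chrom=fields[0],
                        start=int(fields[1]) + 1,
                        end=int(fields[2]),
                        provenance=Provenance(fields[3])
                        if len(fields) > 3
                        else Provenance.PER_SAMPLE_STRETCH,
                        n_markers=int(fields[4]) if len(fields) > 4 else 0,
                        sample=None
                        if len(fields) < 6 or fields[5] == "."
                        else fields[5],
                    )
                )
            except ValueError as exc:
                raise LoadError(f"{path}: line {lineno}: {exc}") from exc
    regions.sort(key=lambda r: (r.sort_key, r.provenance.value, r.sample or ""))
    return regions


# ---------------------------------------------------------------------------
# candidate tables


def candidate_table_columns(pedigree: Pedigree) -> List[str]:
    return [
        "chrom",
        "pos",
        "ref",
        "alt",
        "vclass",
        "consequence",
        "pop_freq",
        "region_chrom",
        "region_start",
        "region_end",
        "region_provenance",
        "segregation_ok",
        "notes",
    ] + [f"gt_{iid}" for iid in pedigree.ids]


def write_candidates_tsv(candidates, path: str, pedigree: Pedigree) -> None:
    """One row per candidate with the genotype matrix across the pedigree."""
    columns = candidate_table_columns(pedigree)
    rows = []
    for cand in candidates:
        v = cand.variant
        row = [
            v.chrom,
            str(v.pos),
            v.ref,
            v.alt,
            v.vclass.value,
            v.consequence.value,
            _fmt_freq(v.pop_freq),
            cand.region.chrom,
            str(cand.region.start),
            str(cand.region.end),
            cand.region.provenance.value,
            "1" if cand.segregation_ok else "0",
            cand.notes or ".",
        ]
        for iid in pedigree.ids:
            g = cand.genotypes.get(iid)
            row.append(g.value if g is not None else ".")
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_candidates_tsv(path: str) -> Tuple[List[str], List[List[str]]]:
    """Read a candidate table back as (header, rows of strings)."""
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise LoadError(f"{path}: empty candidate table")
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:]]


def write_candidate_rows(header: List[str], rows: List[List[str]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
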