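import numpy as np
import pytest

from hbdscan.types import (
    Consequence,
    GenomicRegion,
    Individual,
    Marker,
    Pedigree,
    Provenance,
    Role,
    SampleObservation,
    Sex,
    VariantCall,
    VariantClass,
    Zygosity,
)

HOM = Zygosity.HOM_ALT
HET = Zygosity.HET


def make_snp(
    pos,
    chrom="1",
    depth=30,
    alt=30,
    quality=60,
    consequence=Consequence.NONSYNONYMOUS,
    pop_freq=None,
    samples=("S1",),
    vclass=VariantClass.SNP,
    copy_number=None,
):
    obs = {
        iid: SampleObservation(depth, alt, quality, copy_number) for iid in samples
    }
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="C" if vclass is VariantClass.SNP else "CT",
        vclass=vclass,
        consequence=consequence,
        pop_freq=pop_freq,
        observations=obs,
    )


def make_markers(zygosities, spacing=1000, chrom="1", sample="S1", start=1):
    """Markers at fixed spacing with the given per-sample zygosity classes."""
    return [
        Marker(chrom=chrom, pos=start + i * spacing, zygosity={sample: z})
        for i, z in enumerate(zygosities)
    ]


def region(start, end, chrom="1", provenance=Provenance.PER_SAMPLE_STRETCH, **kw):
    return GenomicRegion(chrom=chrom, start=start, end=end, provenance=provenance, **kw)


@pytest.fixture
def trio_pedigree():
    return Pedigree(
        [
            Individual("dad", None, None, Sex.MALE, False, Role.CONTROL),
            Individual("mom", None, None, Sex.FEMALE, False, Role.CONTROL),
            Individual("kid", "dad", "mom", Sex.MALE, True, Role.CASE),
        ]
    )


@pytest.fixture
def quartet_pedigree():
    """Two affected sibs, two unaffected genotyped parents."""
    return Pedigree(
        [
            Individual("dad", None, None, Sex.MALE, False, Role.CONTROL),
            Individual("mom", None, None, Sex.FEMALE, False, Role.CONTROL),
            Individual("sib1", "dad", "mom", Sex.MALE, True, Role.CASE),
            Individual("sib2", "dad", "mom", Sex.FEMALE, True, Role.CASE),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_marker_instance(rng, n_max=2000, window_size=None, het_prob=None):
    """A randomized single-sample marker instance for oracle comparisons."""
    n = int(rng.integers(10, n_max + 1))
    het_prob = float(rng.uniform(0.0, 0.5)) if het_prob is None else het_prob
    gaps = rng.choice(
        [500, 1_000, 25_000, 400_000, 600_000, 1_200_000],
        size=n - 1,
        p=[0.25, 0.3, 0.3, 0.1, 0.04, 0.01],
    )
    pos = np.concatenate(([1], 1 + np.cumsum(gaps)))
    zyg = [
        Zygosity.HET if rng.random() < het_prob else Zygosity.HOM_ALT for _ in range(n)
    ]
    return [
        Marker(chrom="1", pos=int(p), zygosity={"S1": z}) for p, z in zip(pos, zyg)
    ]
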