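# Methods

## Scope and model

`hbdscan` implements the discovery procedure used to map autosomal-recessive
disease genes in consanguineous families from exome variant calls: a
variant-level filtering funnel, read-fraction homozygosity mapping, a
case-shared / control-excluded HBD (homozygosity-by-descent) intersection,
and recessive-segregation prioritization. The underlying genetic model is
strict: one fully penetrant recessive allele, identical by descent from a
single founder haplotype, homozygous in every affected individual and in no
unaffected one. Compound heterozygosity, phenocopies, reduced penetrance and
X-linked inheritance are deliberately outside the model.

## Zygosity classification

Each sample at each site is classified from its alternate-read fraction
f = alt_reads / depth:

| class | rule | depth gate |
|---|---|---|
| HOM_ALT | f ≥ 0.95 | depth ≥ 5 |
| HOM_REF | f ≤ 0.05 | depth ≥ 5 |
| HET | 0.30 ≤ f ≤ 0.70 | depth ≥ 10 |
| AMBIGUOUS | anything else | — |
| UNCLASSIFIED | a depth gate failed | — |

Marker selection additionally requires depth ≥ 20; because that gate
subsumes the per-class gates, both are applied (disable
`apply_marker_selection_gate` for the per-class-gates-only reading). The
class bands overlap on paper (f < 0.30 is both "ambiguous" and, below 0.05,
homozygous-reference); precedence HOM > HET > AMBIGUOUS resolves this in
favour of the homozygous definition, which is the one homozygosity mapping
relies on. Both homozygous classes count as homozygous for stretch
detection: the mapping is allele-agnostic; allele identity is enforced later
at prioritization.

## Variant funnel

QC keeps a call iff **every** genotyped sample with nonzero depth has
consensus quality ≥ 20, depth in [4, 500] and annotated copy number ≤ 2
(absent counts as passing); a call missing in all samples is dropped. The
per-sample reading (rather than pooled) is the stricter and simpler of the
two possible interpretations. SNPs closer than 5 bp to another retained SNP
are then removed cluster-wise — both members of a too-close pair, since
keeping one would need an unstated tie-break; the 5 bp boundary itself is
allowed, and indels are exempt. Consequence filtering keeps exactly
{non-synonymous, frameshift, splice acceptor, splice donor}. The frequency
filter removes variants whose maximum annotated population frequency
exceeds 0.5% — strictly greater; 0.5% itself survives and unannotated
(novel) variants always survive.

Case/control sharing keeps variants carried (HET or HOM_ALT) by every case,
homozygous-alternate in at least one case and homozygous-alternate in no
control. "Absent in controls" is read as *absent as a homozygous recessive
genotype*: the parents of an affected homozygote are obligate heterozygous
carriers, so literal absence would reject every true variant in a
parents-as-controls design. The literal reading remains available as
`strict_absence=True`.

## Homozygous stretch delineation

Two detectors operate on each sample's marker sequence (HOM/HET markers
only; AMBIGUOUS and UNCLASSIFIED markers drop out of the sequence), per
chromosome:

* **Windows** — every window of exactly 500 consecutive markers (step 1,
  the maximal-sensitivity reading of "all qualified windows") qualifies
  when it contains ≤ 2 heterozygous markers and no adjacent-marker gap
  > 500 kb. Qualified windows are unioned over marker indices; each union
  spans from its first to its last marker position, and unions < 1 Mb are
  discarded. Windows never span chromosomes. Because a gap > 500 kb
  disqualifies every window containing it, such a gap also necessarily
  splits any coalesced union.
* **Runs** — maximal runs of consecutive homozygous markers with ≥ 50
  markers spanning ≥ 1 Mb.

Region boundaries are the positions of the first and last supporting
marker — never extended midway toward flanking markers — the simplest
defensible convention; detected boundaries therefore jitter around the true
recombination breakpoint by a few marker spacings (outward by the run of
chance homozygous-by-state markers beyond the breakpoint, geometric with
success probability equal to the local heterozygosity; inward by up to one
marker spacing).

Case-shared HBD regions are the n-way interval intersection of all cases'
stretches; fragments < 1 Mb are discarded. Control exclusion subtracts the
union of the controls' stretches and re-applies the 1 Mb floor (a
discard-entirely mode drops whole regions on any overlap). All interval
algebra operates on sorted, non-overlapping 1-based inclusive lists; BED
export converts to 0-based half-open coordinates.

**Which detector delineates the HBD regions** is configurable
(`hbd_source`: `ibd_runs`, `windows`, `intersect`, `union`). The default is
`ibd_runs`. The reason is resolution: the minimum detectable stretch of the
window detector is one full window, ≈ window_size × marker spacing. At
exome-scale marker densities of tens of kb this is many megabases — larger
than the expected case-shared autozygous segment of first-cousin offspring
(the intersection across n cases of per-case segments whose flanks decay
exponentially at ≈ 6 meioses per 100 cM each) — so requiring window support
for every case discards true regions wholesale, while the 50-SNP run rule
resolves segments of ≈ 1 Mb. The window detector remains valuable where
genotyping error is high (it tolerates two misclassified markers; a run
breaks at one) and is retained as a first-class stage and option.

## Prioritization

Filtered variants falling inside an HBD region (inclusive ends, binary
search) are kept when they segregate: every case HOM_ALT, no control
HOM_ALT, and every genotyped unaffected parent of a case HET — an
AMBIGUOUS/UNCLASSIFIED parent counts as missing, but a confidently
homozygous-reference parent contradicts obligate carriership and rejects
the variant. Candidates are emitted position-sorted and unranked:
pathogenicity prediction, conservation and literature triage are external
and recorded only in a free-text notes field.

## Synthetic data generator

The generator emulates the sequenced family design: pedigree templates with
first-cousin marriages (`first_cousin_single`: one couple, one offspring,
F = 1/16; `first_cousin_double`: two couples sharing a grandparental
sibship, four affected offspring, the second couple genotyped as unaffected
carrier controls), uniform genetic map, Poisson crossovers without
interference, and founder haplotypes carrying unique labels so autozygosity
is observable exactly (both labels equal). Defaults, chosen to mirror the
study conditions: 20 autosomes × 50 Mb, 2,000 markers per chromosome
(uniform positions), MAF ~ U(0.05, 0.5), 0.01 crossovers/Mb (1 cM/Mb),
mean depth 80× (the study's ≈ 75× average coverage rounded), base error
0.01, read quality 60 (comfortably above the QC gate so QC behaviour is
controlled by the tests that probe it), 1% of markers annotated as novel,
and a consequence mix of 45% non-coding / 30% synonymous / 20%
non-synonymous / 1% + 1% splice / 3% other — a coarse exome-like blend that
exercises every funnel branch.

The planted causal variant sits on one founder haplotype, is annotated
novel and non-synonymous, and the meioses on the descent paths to the
designated cases are conditioned by per-meiosis rejection sampling so all
cases are homozygous — the in-silico analogue of ascertaining an affected
family. The conditioning is exact because the event "this meiosis transmits
the risk haplotype at the causal position" factorises over independent
meioses. Calibration uses *unconditioned* drops: the mean autozygous genome
fraction of first-cousin offspring is checked against F = 1/16 within
3 Monte-Carlo standard errors (2,000 replicates).

What the generator does **not** emulate: indels (filter behaviour for
indels is covered by hand-built fixtures), exome-like marker clustering,
LD between markers, allele-frequency spectra tied to population databases
(the "novel" annotation is independent of the simulated family MAF),
mapping artefacts, or batch effects. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative model, not
robustness to every pathology of real exome data.

## Numerical and degenerate-input choices

* All thresholds compare inclusively exactly as printed (≥ 95%, ≥ 5 bp,
  ≤ 2 hets, > 0.5% removed).
* Chromosomes sort naturally (numeric first); `chr` prefixes are tolerated;
  X/Y/MT are excluded from markers.
* Split multi-allelic records share a position; the adjacency rule treats
  them as a zero-distance pair and removes both, which is consistent with
  treating clustered calls as suspect.
* Duplicate marker positions collapse to the first occurrence.
* Missing genotypes are depth-0 observations, never imputed; depth 0
  classifies as UNCLASSIFIED.
* Empty inputs flow through every stage: zero candidates is a successful
  run, and an empty region list writes a header-only BED.
* All randomness derives from a single integer seed through
  `numpy.random.default_rng`; equal seeds give byte-identical artifacts
  (reports carry no timestamps).

## Problem sizes used in validation

The oracle-equivalence check compares the sliding-window detector with an
exhaustive per-window enumeration on 200 randomized instances of up to
2,000 markers, alternating between the published 500-marker window and a
50-marker window so both dense and sparse qualification regimes occur.
The recovery study runs 50 replicates of the default double-cousin family
end to end; segment recovery is scored by ≥ 90% reciprocal overlap against
the true planted case-shared segments of ≥ 1.5 Mb. The calibration uses
2,000 gene drops. These sizes keep a full validation run in the
single-digit minutes on one CPU while leaving Monte-Carlo error well below
the margins being tested.

## Known limitations

* Strictly homozygous-by-descent model: no compound-heterozygous logic.
* Boundary precision of HBD regions is limited to a few marker spacings;
  short chance homozygous-by-state segments co-shared by all cases can
  enter the HBD list, and their boundaries carry the same jitter.
* A true homozygote can draw enough error reads to fall below the 95%
  rule (≈ Binomial tail at the site's depth), classify as AMBIGUOUS and
  drop out of the sharing filter — an irreducible miss mode of the
  published thresholds, visible as occasional sub-100% recovery.
* No genotype-likelihood or HMM-based ROH calling, no genetic-map (cM)
  lengths, no LD pruning, no relatedness (kinship) estimation.
* The run-based and window-based detectors assume marker order and
  positions are exact; structural variation is not modelled.
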