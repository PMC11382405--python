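# Methods

`karyofeat` implements three analysis stages used to characterize
chromosome-level genome assemblies and population genotype sets of water
buffalo (*Bubalus bubalis*), together with a synthetic-data forge that makes
every stage testable against planted truth. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish about real data.

## Coordinate conventions

All internal coordinates are 0-based half-open. The 1-based inclusive
conventions of RepeatMasker `.out` and nucmer `show-coords` are converted at
the parse/serialize boundary only, and converting to and from disk format is
the identity (property-tested). Soft-masking case in FASTA input is
discarded on read: repeat state enters the pipeline through the annotation
file, not through sequence case.

## Assembly gaps

A gap is a maximal run of `N` of length at least `min_run` (default 10).
Public assembly reports do not state the run length that defines a "gap", so
the default is a compromise: long enough not to count isolated ambiguous
bases, short enough to catch scaffold spacers. It is exposed as a flag
(`--gap-min-run`) because NCBI's own accounting may differ.

## Telomeres

Telomere signal is the count of non-overlapping exact occurrences of the
vertebrate hexamer TTAGGG *and* its reverse complement CCCTAA within the
terminal 20,000-bp window of each arm. One hexamer is one unit, so a unit
count of *u* corresponds to roughly 6*u* bp of telomeric array. An arm is
"kept" only if its unit count is strictly greater than `min_units`
(default 50). A chromosome with both arms kept is called sub-metacentric;
a kept q-arm with an empty p-arm is the acrocentric-like pattern seen in
bovid karyotypes; anything else is left undetermined. Both-strand counting
is configurable (`both_strands=False` restricts to the forward motif).

Interstitial telomeric arrays — a classic scaffold-misassembly signature —
are flagged by the same counter in sliding windows (window 20 kb, step
10 kb) over the chromosome interior, excluding one window length at each
end so genuine terminal telomeres do not flag. Overlapping flagged windows
are merged and the merged span recounted. The step and end-exclusion are
package choices: they recover a planted ~8-kb interior array as a single
merged flag in tests.

## Centromeres

Centromere localization uses Satellite/centr repeat annotations only.
Hits are kept when their identity to consensus, computed as
100 − %divergence from the annotation row (insertion/deletion percentages
ignored), is strictly greater than 60%. Kept hits on a chromosome are
grouped by single linkage: a hit joins the open cluster when the
end-to-start distance to the cluster is strictly less than 1 Mb (measured
against the running maximum end, so containment cannot split a cluster).
The cluster with the most repeat records on the chromosome is the
centromere candidate; ties break toward larger summed bp, then leftmost.
Summed bp is available as an alternative selector (`by="total_bp"`),
since "densest cluster" is ambiguous between record count and base count.
Clustering is order-independent, idempotent, and equal to a brute-force
transitive-closure oracle in tests.

Known satellite monomers (the 673-bp and 1,404-bp buffalo centromeric
units) are copy-counted by tiling a candidate region at the monomer period:
a seed tile within 10% Hamming distance of the monomer starts an array, and
tiling continues while tiles stay within tolerance; both strands are tried
once and the better array returned. This is deliberately *not* de novo
tandem-repeat discovery or higher-order-repeat decomposition — it counts
copies of a monomer you already know.

## Assembly-to-assembly divergence

SVs of 50–10,000 bp are classified purely from anchor-gap geometry between
consecutive unique alignment anchors (anchors under 10 kb on either
coordinate are discarded as non-unique; that threshold follows the
convention of anchor-based SV callers and is a flag). With `Gr` the
reference gap and `Gq` the query gap, the event size is `|Gq − Gr|` and the
six classes are: insertion (`Gr ≥ 0`, `Gq > Gr`), deletion (`Gq ≥ 0`,
`Gr > Gq`), tandem expansion (`Gr < 0 ≤ Gq`), tandem contraction
(`Gq < 0 ≤ Gr`), repeat expansion (both negative, `|Gr| > |Gq|`), repeat
contraction (both negative, `|Gq| > |Gr|`). Equal gaps yield no call.
Exchanging reference and query swaps insertion↔deletion and
expansion↔contraction exactly (property-tested on random anchor sets).

SNVs come from column-wise comparison of the gapless alignment each anchor
implies; anchors with unequal span lengths are skipped with a warning
(indel-bearing alignments must arrive split, which is how coords files
represent them). Sites inside a supplied repeat mask are flagged and
excluded from counts; columns involving `N` never count. Anchors that
re-visit a reference base (the overlapping anchors of tandem events)
would report the same substitution twice, so records are deduplicated on
(chromosome, position, alleles).

Divergence percent is `100 × (SNV count + SV bp) / genome length`, with the
chromosome-level reference assembly length as the denominator. Applied to
the published pairwise table for the swamp and river reference assemblies
(12,375,163 SNVs, 27,064,859 SV bp, 2.70 Gb) this gives 1.46%, the ~1.5%
swamp/river figure.

SV sharing across multiple query assemblies called against one reference
clusters records by transitive closure of a match relation: same type and
reciprocal overlap ≥ 0.5 on reference coordinates; insertions, which occupy
a reference point, match on identical breakpoint and size. Each cluster is
assigned to exactly one subset — the full set of assemblies it spans.

## Population stage

QC follows plink-like semantics in a fixed, reported order: autosome
restriction → biallelic restriction → sample call-rate (`mind`, keep when
missing fraction ≤ 0.1) → site call-rate (`geno`, ≤ 0.1) → pooled MAF floor
(≥ 0.01 by default, 0.05 for PCA-style pruning). The order matters for the
per-filter removal counts in the QC report and is part of the contract;
relaxing any threshold never decreases the number of kept sites.

Cross-population classification assigns each QC-passing site exactly one
class with precedence specific > shared > uninformative:

- *swamp-specific polymorphic*: swamp MAF > 0.2 and the frequency of the
  pooled minor allele in river < 0.01 ("fixed");
- *river-specific polymorphic*: the mirror condition;
- *shared*: MAF > 0.01 in both populations;
- *uninformative*: everything else.

The "fixed" test uses the frequency of the *pooled* minor allele in the
other population rather than that population's own MAF, so a site near 0.5
cannot flip its minor-allele label between populations. All inequalities
are strict, missing genotypes never enter allele counts, and the vectorized
classifier equals a per-site brute-force evaluation of the rule (tested).

Heterozygosity per kb is `1000 × (#0/1 calls) / callable_bp` per sample,
with a caller-supplied callable length (the published per-sample figures do
not state their denominator, so none is hard-coded; the CLI defaults to
1 Mb per 1000 sites purely to give a stable scale). Ti/Tv counts A↔G and
C↔T as transitions; it is 0 when all sites are transversions and undefined
(NaN) when there are no transversions. The MAF spectrum is binned at 0.01
over [0, 0.5] with the last bin closed, and the panel metrics (fraction of
sites under MAF 0.1, count and fraction over MAF 0.2) are the quantities
that expose ascertainment bias of an array panel evaluated outside its
discovery population.

## Synthetic data: what it emulates and what it does not

The forge builds assemblies from seeded random background at GC 0.42 and
overlays: terminal telomere arrays (p-arm written as CCCTAA on the forward
strand so the G-rich strand points outward), centromeric arrays tiled from
one seeded random monomer per requested length with 2% per-base tile
mutations, annotation-only decoy satellite clusters, N-gap runs, and
optional interior telomere arrays. Monomers are random sequences, not real
BTSAT consensus: detection only requires self-consistency, and using real
consensus would add an external sequence dependency without changing what
the tests show. Terminal windows are screened after construction so no
chance telomeric hexamer survives outside a planted array — planted unit
counts are therefore exact by design, which is what lets the tests assert
equality rather than tolerance.

The standard toy genome is five 2-Mb chromosomes (10 Mb total): three with
telomeres at both arms and 673-bp-monomer centromeres, two acrocentric-like
with 1,404-bp monomers, decoys placed more than 1 Mb from the centromeric
cluster, and 20 gaps overall. The q-arm telomere unit counts include 637
and 2,369, the extremes of the published per-chromosome range. The diverged
sister carries SNVs at rate 0.002 with transition probability 0.68 (chosen
so the simulated Ti/Tv is ≈ 2.12, the published genome-wide ratio) and 30
SVs — 10 insertions, 10 deletions, 10 tandem expansions — at fixed
positions in the feature-free mid-chromosome zone, 130 kb apart so every
implied anchor clears the 10-kb uniqueness filter, with sizes drawn in
[60, 9000]. Tandem expansions are planted as true duplications, so the
emitted anchors are sequence-consistent; tandem contractions are exercised
at the geometry level (hand-built anchors and the swap-antisymmetry
property) because a sequence-consistent contraction requires a
tandem-seeded reference.

The genotype forge samples Hardy–Weinberg diploid genotypes at drawn
frequencies: type-specific sites at MAF 0.25–0.5 in one population and
frequency 0 in the other, shared sites at 0.05–0.5 in both, 2% missingness.
The default mixture is 1,000 swamp-specific, 2,000 river-specific and
5,000 shared sites over 100+100 samples. These margins put the expected
misclassification from realized-frequency noise well under 1%. QC spoilers
(5% of the mixture size per site filter, plus one over-missing sample per
population) are constructed to fail exactly one filter each, deterministically
where the filter is deterministic, so the QC report's per-filter counts can
be checked for equality.

What passing these tests shows: the scanners, callers and classifiers
implement their stated rules exactly and recover planted features under
realistic sizes and noise. What they do not show: performance on real
alignment artifacts (spurious anchors, segmental duplications, alignment
trimming), real satellite higher-order structure, linkage disequilibrium,
or population structure — the forge plants none of these. The full-scale
published numbers (gap counts and telomere totals of the real assemblies,
41M-SNP cohort statistics) require the multi-gigabase accessions and are
out of desk scope; the package exercises the same code paths on the toy
scale instead.

## Problem sizes and determinism

The standard runs are sized for a single CPU: the 10-Mb toy genome with
~20k SNVs simulates and analyses in a few seconds, and the 9,600-site ×
202-sample genotype simulation in under a second. All randomness flows from
`numpy.random.default_rng` seeded from the caller; identical spec and seed
give byte-identical outputs, and the CLI logs its effective configuration
and input checksums so a run is a pure function of (inputs, flags, seed).
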