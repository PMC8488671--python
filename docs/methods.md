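# Methods

## Coverage model

An introgression line is a diploid mosaic: along each chromosome, runs
of genes are homozygous recurrent (recurrent-allele dosage *a* = 2),
heterozygous (*a* = 1) or homozygous donor (*a* = 0), with donor dosage
*b* = 2 − *a*. Whole-genome fragments mapped against the pooled
parental references land on the two species' copies of each syntenic
gene pair. Read mapping itself is abstracted into a single
**cross-mapping fraction** *f* ∈ [0, 0.5): a fragment from one
species' allele is counted on the homologous copy with probability
*f*. For a gene of length *L* bp, counts are Poisson with means

```
mu_recurrent = lambda · (L/1000) · (a(1−f) + b·f)
mu_donor     = lambda · (L/1000) · (b(1−f) + a·f)
```

where *lambda* is the per-allele-copy depth in fragments per kb
(default 100). The expected FPKM ratio R = FPKM_r/FPKM_d is then
(a(1−f)+bf)/(b(1−f)+af), independent of lambda and L. The default
*f* = 1/3 is the value at which the homozygous classes' expected
ratios are exactly 2 and 0.5 and the heterozygous ratio is 1; the
homozygous-recurrent value 2 follows from the model's symmetry with
the homozygous-donor 0.5. *f* must stay below 0.5 or the three classes
collapse onto ratio 1. An optional overdispersion parameter switches
the counts to gamma-Poisson (Var = mu + phi·mu²); the default is pure
Poisson, appropriate for genomic (not transcriptomic) DNA coverage.

Donor-only genes (e.g. tandem insertions absent from the recurrent
genome) have no homolog for their cross-mapped fraction to land on;
their mean is lambda·(L/1000)·b·(1−f) and the *f* share is treated as
unassigned. This is why `total_mapped` may exceed the column sum in
count tables read from disk, and why presence/absence — not a ratio —
is reported for unpaired genes (present when coverage reaches
`min_presence_count`, default 5 fragments).

## Synthetic genomes and progeny

`generate_parents` draws gene lengths from a shifted exponential
(minimum 300 bp, mean 2000 bp — the floor avoids degenerate FPKM
denominators, the mean is a typical genomic gene span for a small
crucifer genome) and intergenic gaps from an exponential (mean
2000 bp). The two genomes are collinear 1:1 orthologs sharing lengths
(near-isogenic homologs); configured insertions add a 2-gene
donor-only tandem between two conserved flank genes, mimicking a
transposed gene-pair presence/absence variant. The similarity table
gives true orthologs scores in [90, 100] and sprinkles off-target hits
in [20, 60], so reciprocal-best-hit pairing recovers the truth while
still being exercised against decoys.

`simulate_progeny` selfs a line with exactly one heterozygous segment.
Each plant receives two independent gametes; along each chromosome the
transmitted haplotype switches between adjacent walked positions with
the Haldane recombination fraction r = ½(1 − e^(−2d/100)) for map
distance d (no interference). Adjacent markers are
`recomb_cM_per_interval` apart (default 5 cM); the causal locus —
by default the bp midpoint of the heterozygous segment — splits its
marker interval proportionally by bp. The locus genotype is therefore
1:2:1 in expectation, and the phenotype is codominant additive:
DTF = mu + a_effect·(donor dose − 1) + N(0, sigma²), defaults mu = 60 d,
a_effect = 30 d, sigma = 3 d, giving class means near 30/60/90 days.
No dominance deviation is modelled. An optional censoring threshold
marks plants as "not flowered" (NF); the generator's default leaves
censoring off, but the analysis side always treats NF plants as the
extreme late phenotype while excluding them from DTF means.

What the generator does **not** emulate: read-level artefacts
(mapping-quality structure, GC bias, duplicated-region pile-ups),
segmental rearrangements beyond clean inversions, SNP/indel haplotype
structure, segregation distortion, and genotyping errors in marker
assays. Tests passing on this generator therefore demonstrate the
statistical machinery under its stated model, not robustness to every
artefact of real sequencing data.

## Synteny

Candidate orthologs are reciprocal best hits in the similarity table,
with deterministic tie-breaking toward the lexicographically smallest
partner id; duplicate rows with conflicting scores are an input error.
Chaining runs per chromosome pair in ordinal gene-rank space (robust
to gene-length heterogeneity and matching the gene-level resolution of
the genotyper): a dynamic program over anchors sorted by recurrent
rank, separately for forward and inverted orientations, where a
predecessor extends a chain when both ranks advance by at most
`max_gap` (default 5) at a cost of `gap_penalty` (default 1) per
skipped rank. The recurrence is exact because the gap constraint binds
only consecutive chain members; a brute-force subset enumeration
confirms this on small instances in the test suite. The best chain is
extracted, its anchors removed, and the process repeats until the best
remaining chain is shorter than `min_block_size` (default 3). Score
ties go to the chain with the smaller first recurrent rank, then to
the forward orientation, keeping output order-invariant in the input.

## Genotyping

FPKM uses the library's total assigned fragments N, so multiplying all
counts and N by a constant changes nothing. The ratio uses a
pseudocount (default 0.1 FPKM) in both numerator and denominator to
stabilise zero-coverage denominators; pairs with fewer than
`min_count` (default 10) combined raw fragments are AMBIGUOUS.
Thresholds default to √2 and 1/√2, the geometric midpoints between
the expected ratios 2/1/0.5 — symmetric in log space, so swapping the
two genomes' roles maps R to 1/R and mirrors the homozygous calls
exactly.

Segment calling drops AMBIGUOUS calls, smooths the remainder with a
centred majority-vote window (default 5; ties keep the original call;
windows truncate at chromosome ends), and takes maximal runs of equal
calls as segments. Runs shorter than `min_segment_genes` (default 3)
are absorbed when both flanking runs agree, otherwise reported as
ambiguous gaps. A hidden-Markov segmentation would use the ratio
likelihoods directly and is deliberately left out; the majority-vote
denoiser is transparent and sufficient at the coverage this design
targets (at lambda = 100/kb/copy the shortest genes, ~300 bp, carry
~30 fragments per copy and contribute an irreducible few-percent raw
error rate, which the smoothing removes except within one gene of a
true boundary).

## Mapping

The segregation statistic is the ordinary chi-square goodness-of-fit
against expected counts total·r_i/Σr (df = classes − 1 = 2 for
A/H/B), with an upper-tail p from the chi-square survival function
(regularized incomplete gamma). Marker association is one-way
fixed-effects ANOVA of DTF across genotype classes, computed from sums
of squares so that variance explained R² = SS_between/SS_total is
reported alongside F and p; Kruskal–Wallis is available as an option.
A marker is testable with ≥ 2 classes of ≥ 2 flowered plants;
Bonferroni correction multiplies by the number of testable markers.
The most-associated marker minimises p, with ties broken toward larger
R² and then the leftmost position.

Phenotype classification places thresholds at the midpoint of the two
parental control means ± k pooled SDs (default k = 1); plants inside
the closed band are AMBIGUOUS, NF plants are LATE. Because the
heterozygote mean sits exactly at the midpoint under the additive
model, a 1-SD band deliberately leaves most heterozygotes AMBIGUOUS —
and some leak through on either side. Interval localisation therefore
interprets the classes as **dose bounds**, not exact genotypes: LATE
implies at least one donor allele at the locus (H or B), EARLY at most
one (A or H). Each informative plant then allows the locus only in
inter-marker intervals where a flanking marker genotype satisfies its
bound (inside the plant's own breakpoint interval either allele is
possible); the candidate interval is the intersection across plants.
This reading keeps misclassified heterozygotes consistent on either
side while still letting homozygous recombinants trim the interval
marker by marker; an exact-genotype reading would produce spurious
empty intersections whenever a single heterozygote crosses the band.
An empty intersection is still possible (e.g. a LATE plant homozygous
recurrent at every marker) and raises an error naming the conflicting
plants, signalling phenotype/genotype inconsistency rather than a
numerical failure.

## Numerical and determinism choices

All randomness flows from one integer seed through named substreams
(seed, stage, sample), so per-sample counts do not depend on draw
order elsewhere and every pipeline artifact is byte-reproducible; the
manifest records sha256 checksums of inputs and outputs to make this
checkable. Coordinates are 1-based inclusive (GFF3) internally;
BED output converts to 0-based half-open. Strand is ignored in ratio
computation (coverage is strand-symmetric). Test problem sizes —
2000–3000 genes for ratio and recovery checks, 100–200 replicate
simulations of 150–200 progeny for mapping calibration — are chosen so
each statistical assertion has comfortable margin over its sampling
error while the full suite stays fast on a single CPU.

## Known limitations

* Coverage-only genotyping cannot see copy-number changes within a
  species or distinguish a deleted recurrent allele from a donor
  homozygote; it assumes the pooled-reference mapping behaves like the
  f-mixture.
* The chainer's greedy chain extraction partitions anchors optimally
  one chain at a time, not jointly; heavily rearranged regions could
  in principle be tiled differently by a joint optimiser.
* The interval logic assumes a single codominant locus; epistasis,
  incomplete penetrance or a second segregating locus will surface as
  conflicts or inflated intervals, not be modelled away.
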