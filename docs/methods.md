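# Methods

## The analysis in one paragraph

Each mosquito contributes three aligned *Vssc* amplicons (E6-8, E20-21,
E31-32) and ASPCR band calls at the standalone V410L and F1534C codons.
Unique region sequences become discovery-ordered haplotypes; a chromosome's
concatenated haplotypes and codons form its pattern sequence; unique patterns
get P-numbers.  The pattern set is then summarized three ways: allele
frequencies per collection, a statistical-parsimony genealogy network, and a
per-allele verdict on whether multi-mutation resistance alleles arose by
sequential mutation, a single crossover, or either.

## Genotyping and phasing

Sanger traces of heterozygotes superimpose the two alleles, so a diploid
region sequence is modelled as the site-wise IUPAC union of two haplotypes.
Phasing is comparison-based and exhaustive: catalogs hold at most a few dozen
haplotypes, so every unordered pair is tried and the sequence is resolved only
when exactly one pair reproduces it.  When a single catalog haplotype is
consistent with the trace, its complement is proposed as a new *inferred*
haplotype, retained only if observed in at least two individuals; genotypes
that relied on a dropped inferred haplotype revert to unresolved.  Phasing
consults only haplotypes already observed in the same population (a
global-catalog fallback sits behind `population_scoped_phasing=False`).
Heterozygosity across an indel has no single-column IUPAC rendering (the
traces frame-shift); such individuals are marked unresolved — resolving them
required cloning in the wet lab, which is not modelled.

ASPCR scoring maps band presence to SS/RS/RR; a reaction with no band raises
an error rather than defaulting to susceptible.

## Pattern assembly

A fully homozygous individual contributes one pattern twice.  An individual
heterozygous at exactly one component (one region or one codon) has a forced
phasing — no cross-region linkage is involved — and is resolved
unconditionally.  With two or more heterozygous components the 2^(k−1)
phasings are enumerated and accepted only if exactly one yields two patterns
both already seen in homozygotes of the same population; anything else is
excluded from pattern counts and logged.  Residual ambiguity is surfaced,
never imputed.

## Frequencies

Frequency = chromosome count / (2 × resolved individuals), rounded half away
from zero to two decimals (so 1/8 prints as 0.13 and 14/16 as 0.88); absent
alleles are omitted rather than printed as zero.  The table keeps both the
raw value and the printed string.

## Variation summary

A SNP is an alignment column with ≥ 2 distinct non-gap bases.  An indel event
is a maximal run of columns in which the same subset of haplotypes is gapped,
so one biological deletion spanning k columns counts once.  Exon columns are
classified synonymous/nonsynonymous by translating each variant codon against
the majority-consensus codon (multi-hit codons by direct translation
comparison); exon intervals in the region catalog are codon-framed from their
start, and a trailing partial codon is left unclassified.  E20-21 intron
lengths define the haplotype groups: 250 bp → A, 234 bp → B, anything else
(the 233-bp single-deletion variant) → other.

## Mutational steps and the parsimony network

The distance between two patterns is substitutions (both bases non-gap,
differing) plus indel events (maximal runs gapped in exactly one sequence);
columns gapped in both are shared history and free.  A substitutions-only
mode exists (`count_indels=False`) because hash-mark counts on a network
figure and "mutational steps" need not agree on indels; the default counts
them, consistent with the variation summary.

The network is built TCS-style: pattern pairs in increasing step order, ties
broken by P-number order (a determinism rule, no biological claim); a pair is
connected only when it joins two separate components, a d-step connection
becoming a chain of d−1 inferred intermediate nodes; pairs beyond the
connection limit stay apart, so the network may legitimately fall into
several components.

**Connection limit.**  The probability that a j-step connection is free of
homoplasy is computed from a uniform-placement multiple-hit model: j mutation
events land independently and uniformly on the L sites of the pattern, and
the connection is parsimonious when all land on distinct sites, giving
P(j) = Π_{i=1}^{j−1} (1 − i/L).  The limit is the largest j with
P(j) > threshold (default 0.95), floored at 1 since a lone step cannot be
homoplasious.  For L = 2098 and 0.95 this gives 15 steps.  The estimator is
deliberately isolated in one function (`parsimony_probability`) so a
differently calibrated statistical-parsimony estimator can be swapped in
without touching network construction; an exact-arithmetic oracle of the same
model lives in the test suite.

**Minimum origins.**  Sampled nodes carry fixed character states; inferred
intermediates are free.  With losses free, the number of gains of the derived
state under a full labelling equals the number of connected components of the
derived-labelled subgraph, and marking an intermediate derived can only merge
components or add an unforced origin.  The minimum over all assignments is
therefore the number of components containing a sampled derived node in the
subgraph induced by derived sampled nodes plus all free intermediates — a
closed form verified against exhaustive search over all intermediate
assignments on random graphs of ≤ 12 nodes.

## Scenario classification

For each allele with ≥ 2 resistance mutations:

* **Sequential evidence** — a sampled pattern exists whose mutation set is a
  strict subset of the focal allele and whose step distance to a focal
  pattern equals the number of mutations gained, i.e. every step on the path
  is a kdr codon change.  This is evaluated on the step matrix directly, so
  it does not depend on which connections the network realized.
* **Recombination evidence** — a focal pattern is a perfect single-crossover
  mosaic of two sampled parents: it matches the left parent at every
  informative site (column where the parents differ) left of the breakpoint
  and the right parent at every informative site right of it, with zero
  private differences (a mismatch-tolerance parameter exists, default 0,
  because the patterns are short and low-diversity) and at least one
  informative site per side.  The breakpoint is reported as the maximal
  compatible half-open column interval.  Candidate parents are restricted to
  patterns whose mutation sets are strict subsets of the child's: a parent
  already carrying the full allele explains nothing about its origin, and
  without this restriction a sibling pattern would make every allele
  "either".
* Verdicts: both kinds of evidence → *either*; one → *sequential* or
  *recombination*; neither → *unresolved*.  Only single crossovers are
  modelled; a double-crossover history surfaces as unresolved.

## Synthetic data generator

The generator is event-ledger based rather than a coalescent with
recombination: the claims under test concern the topology of a handful of
mutation and crossover events, and an explicit ledger makes the truth exact
(replaying it regenerates every emitted sequence byte-for-byte; all
randomness flows from one seed).  Region pools grow from a random ancestral
sequence: carrier subsets for each planted SNP/indel come from a random
coalescent-like branching over the backgrounds, exon changes are planted as
synonymous or nonsynonymous by codon-aware substitution, kdr variants copy a
background and overwrite catalog codons, and crossover children splice two
parent patterns at the start of E20-21 (strictly between the 410 and 1534
codons).  Diploid rendering emits IUPAC codes at substitution differences and
unreadable positions (`N`) across indel differences, which downstream phasing
correctly refuses to resolve.

The study-condition configuration (`study.py`, a synthetic stand-in for
the field collections) plants 26 collections / 192 individuals — at least 8
per collection, 4 in the four California ones — 33 patterns over 7 + 9 + 11
region haplotypes, the per-feature variation counts (1 synonymous exon-7 SNP,
37 SNPs + 12 indel events in introns 6+7; 3 synonymous exon-20 SNPs + S989P,
the two 1016 columns, 49 SNPs + 20 indel events in intron 20; 14 synonymous
exon-32 substitutions + Q1835R, 3 intron-31 SNPs), the intron-20 length
classes, and the genealogical topology described in the README.  Two
deliberate artifices keep the planted truth exact: intron-20 indel diversity
is arranged in length-compensating runs so every group-B haplotype stays at
234 bp while 20 distinct indel events segregate; and within each collection
co-segregating patterns differ by substitutions/codons only, so odd leftover
chromosomes pair into single-component heterozygotes that need no cloning.
Q1835R is carried as an annotation on its E31-32 haplotype and never enters
the allele label.

What passing round-trip tests therefore show: the pipeline inverts its own
generative model exactly under curated-Sanger assumptions (no base-call
error, no contamination, deletions only relative to the reference
alignment, infinite-sites mutations).  They do not show robustness to trace
noise, alignment error, or recurrent mutation — real-data caveats a user
should keep in mind.

## Numerical and design choices

* Rounding: half away from zero at two decimals, exact via `decimal`.
* Tie-breaks: network connections by (steps, P-number); consensus base by
  (non-gap, count, base).
* Non-catalog codons at kdr sites translate via the standard genetic code
  and warn, counting as resistant only if the residue matches a known
  resistance residue.  Sites with undocumented mutant codons (L982W, A1007G,
  I1011M/V) are translate-only.
* Degenerate inputs: empty FASTA warns; a failed ASPCR raises; zero resolved
  individuals omit the population from the frequency table; a single pattern
  yields a one-node network.
* Problem sizes: acceptance runs use 20 seeds of the compact configuration,
  500 + 500 crossover replicates at 600 bp with 8 informative sites, 1000
  random pairs for the distance oracle, and graphs ≤ 12 nodes for exhaustive
  origin counting — sizes chosen so the full suite completes in seconds
  while every combinatorial path is exercised.

## Known limitations

* Statistical phasing (EM, MCMC) is intentionally absent; the comparison
  rule mirrors the genotyping design and leaves residual ambiguity
  unresolved rather than imputed.
* The parsimony-probability model ignores rate heterogeneity among sites and
  lineage-specific rates; the limit should be read as a conventional
  cut-off, not a calibrated probability.
* Scenario verdicts are qualitative; with unknown mutation and recombination
  rates the method cannot weigh the two histories, only report which are
  consistent with the data.
* Double crossovers and gene conversion are out of scope.
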