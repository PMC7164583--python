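# kdrevo — evolution of *kdr* resistance alleles in *Aedes aegypti*

Pyrethroid insecticides target the voltage-sensitive sodium channel (VSSC) of
*Aedes aegypti*; point mutations in its gene (*Vssc*) cause knockdown
resistance (*kdr*), and resistance alleles frequently carry several mutations
at once (e.g. `410L+1016I+1534C`).  Whether such alleles arise by **sequential
accumulation** of mutations on one lineage or by **recombination** joining two
single-mutation alleles is the question this package addresses.  It is written
for molecular entomologists and population geneticists working with
Sanger-style amplicon panels.

The pipeline mirrors a three-amplicon genotyping design: two sequenced regions
near the gene ends (E6-8, ~482 bp; E31-32, 1029 bp), one spanning the mutation
cluster around residues 982–1016 (E20-21, ~581 bp with a 250/234 bp intron
length polymorphism), plus allele-specific PCR (ASPCR) calls for the V410L and
F1534C codons.  From these it computes, per individual chromosome, a
**pattern sequence**

```
E6-8 haplotype + 410 codon + E20-21 haplotype + 1534 codon + E31-32 haplotype
```

and analyses the set of unique patterns (P-numbers, assigned in discovery
order):

* **Haplotype catalogs and phasing** — unique region alleles are cataloged in
  discovery order; heterozygotes (IUPAC ambiguity codes in the trace) are
  phased by exhaustive comparison with haplotypes already observed in the same
  population; inferred haplotypes must be seen in more than one individual.
* **Allele frequencies** — per collection, chromosome counts over
  2 × resolved individuals, rounded half-away-from-zero to two decimals.
* **Variation summaries** — per exon/intron SNP counts,
  synonymous/nonsynonymous classification against the majority consensus, and
  indel *events* (a maximal shared gap run counts once).
* **Statistical-parsimony network** — patterns are connected in increasing
  mutational-step order (substitutions + indel events); a *d*-step connection
  is realized as *d−1* inferred intermediates; connections stop at the
  parsimony limit, the largest *j* with
  `P(j) = Π_{i<j} (1 − i/L) > 0.95` for pattern length *L*.
* **Minimum origins** — the minimum number of independent gains of a mutation
  (e.g. F1534C) over all state assignments to the inferred intermediates.
* **Scenario classification** — for each multi-mutation allele: *sequential*
  if a sampled pattern with a strict-subset allele lies exactly
  (#mutations gained) steps away; *recombination* if the pattern is a perfect
  single-crossover mosaic of two smaller-allele parents; *either* if both.

A fully tested synthetic-data generator plants region diversity, kdr mutation
events and single crossovers with an exact event ledger, and is the ground
truth for every pipeline stage.

## Worked example

Generate the bundled synthetic study conditions (26 collections, 192
mosquitoes) and run the pipeline:

```bash
kdrevo simulate --seed 1 --study --out inputs/
kdrevo run --inputs inputs/ --out bundle/
```

which prints:

```
33 patterns over 27 region haplotypes; connection limit 15 steps
  410L+1016I+1534C: sequential
  410L+1534C: either
  989P+1016G: sequential
```

Reading: the data contain 33 unique pattern sequences built from 7 + 9 + 11
region haplotypes.  The triple mutant `410L+1016I+1534C` sits two codon steps
from a `1534C` pattern (gains 1016I and 410L) with no crossover explanation —
sequential accumulation.  `410L+1534C` is one codon step from a `1534C`
pattern **and** a perfect mosaic of a `410L` and an independent `1534C`
pattern with the breakpoint between the 410 and 1534 codons — the data support
either history.  The same information, with frequencies per collection
(e.g. `1534C` at 0.31–0.88 across Asian collections, the triple mutant fixed
in one Colombian colony), is written to `bundle/*.tsv`, and the network to
`bundle/network.graphml` / `network.dot`.

The numbered scripts under `analysis/` run the same stages as a narrative
(`01_simulate_study.py` … `05_scenarios.py`), writing tables under
`results/`.

## Layout

```
src/kdrevo/        library: domain, genotyping, patterns, network,
                   inference, simulate, study, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. brute-force oracles and acceptance tests
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```

All file coordinates are 0-based half-open; residue numbers follow the
house-fly VSSC numbering convention and are labels, never coordinates.
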