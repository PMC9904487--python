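# haploseer

Deduce genotypes at loci of interest — QTLs, Mendelian trait loci, SSR
fingerprinting markers — from phased, haploblocked SNP-array data via
pedigree-aware haplotype sharing.

## The problem

Breeders and germplasm curators hold two kinds of genetic data that do not
talk to each other: historic locus-specific genotypes (SSR fingerprints,
trait-test alleles, database records) and modern genome-wide SNP-array
profiles. For clonally propagated fruit crops the SNP data are typically
curated into *haploblocks* — chromosome segments delimited by historic
recombination, each carrying a small set of observed multi-SNP haplotypes —
and phased into two parental homologs per individual. `haploseer` translates
between the two worlds: given a handful of individuals with historically
reported genotypes at a target locus (a *reference panel*), it deduces that
locus's genotype for every other SNP-genotyped individual in the
pedigree-connected germplasm.

## The method

1. **Placement.** The target locus is placed on the haploblock map by
   physical position: *within* one haploblock or *between* two adjacent
   ones. Its base *haplotype pattern* is the code (or code pair) of the
   anchoring haploblock(s).
2. **Allele assignment.** Each panel allele is anchored to a unique
   haplotype pattern: homozygotes first, then heterozygotes that share an
   allele and a flanking pattern with an assigned case, then pedigree links
   among panel individuals. If one pattern is claimed by two alleles, the
   window grows one haploblock at a time — nearest first, keeping the cM
   length upstream and downstream of the locus near-equal — until
   pattern → allele is a function. The earliest known ancestor carrying each
   pattern is recorded as its *ancestral source*.
3. **Deduction.** Every homolog of every individual is matched against the
   source patterns. A match traceable to the source through an unbroken
   chain of parent–child transmissions is accepted as **IBD**. An untraceable
   match is accepted as **IBS** only if the maximal run of identical
   haploblock codes around the locus is at least the *threshold*: the
   shortest extended shared haplotype observed for any IBD deduction in the
   run (with ties among sources broken by IBD first, then longest shared
   segment). Everything else is UNDEDUCED with an explicit reason
   (missing data, unknown pattern, below threshold).
4. **Validation.** Deduced genotypes are compared, as unordered allele
   pairs, with independently reported ones; mismatches are triaged with
   pedigree evidence — which relatives share a homolog across the locus and
   which validated allele rides it.

A ground-truthed simulator (founder haplotypes transmitted through
Poisson-crossover meioses, hidden alleles riding founder segments) makes
every stage testable without any external dataset.

## Worked example

```sh
python examples/01_simulate_and_deduce.py
```

```
simulated 498 individuals, panel of 62
allele map: 66 pattern->allele entries over a 1-haploblock window; 34 panel alleles unresolved (heterozygous founders with no informative relative)
homologs by mode: {'PANEL': 90, 'IBD': 593}
individuals with 2/1/0 deduced alleles: 249/185/64
precision against hidden truth: 683/683 = 1.000
```

498 individuals descend from 50 founders over 4 generations; the panel's 62
members anchor 66 pattern → allele entries. 593 homologs are deduced by IBD
tracing and 90 are the panel's own; 249 individuals get complete genotypes,
185 a single allele. Because founder haplotype codes are unique in this
simulation, every one of the 683 deduced alleles can be — and is — verified
against the simulator's hidden truth. The other examples walk through window
growth (`02`), the IBS length threshold (`03`), and validation/triage of a
deliberately corrupted report (`04`).

The same pipeline runs from the shell:

```sh
haploseer simulate --seed 4 --out-dir data/
haploseer run --map data/map.tsv --haplotypes data/haplotypes.tsv \
  --pedigree data/pedigree.tsv --panel data/panel.tsv \
  --reported data/reported.tsv --locus-name L1 --chrom chr1 \
  --pos 16000000 --out-dir out/
```

writing `allele_map.tsv`, `deductions.tsv`, `summary.tsv`, `validation.tsv`
and a `manifest.json` with input checksums.

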