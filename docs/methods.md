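# Methods

## Data model

The pipeline consumes four tab-separated tables (UTF-8, header row required,
`NA` or empty meaning missing/unknown — the dialect of typical
breeding-database exports):

- **haploblock map** — per chromosome, ordered haploblocks with 1-based
  inclusive physical intervals (bp) and genetic intervals (cM), optionally
  with member SNP ids. Rows may arrive unsorted; blocks are sorted by
  physical start on load, but a genuine physical overlap, or a genetic
  order contradicting the physical order, is rejected as a structural
  error rather than silently repaired.
- **phased haplotypes** — long format: one haplotype code per (individual,
  haploblock, homolog ∈ {1, 2}). Codes are opaque labels compared by exact
  equality. Unlisted cells are MISSING, and MISSING never compares equal to
  anything — including MISSING — so unobserved data can never count as
  evidence of identity.
- **pedigree** — individual, mother, father; unknown parents allowed.
  Placeholder individuals for unknown-but-recurrent parents (e.g.
  `UP_Delicious`-style names) are ordinary records that may carry inferred
  haplotypes and serve as ancestral sources. The parent graph must be
  acyclic; parents named but not listed are auto-created as founders.
- **reference panel** — individual, allele1, allele2 for the target locus;
  a blank allele2 is stored as UNREPORTED, in which case at most one
  homolog of that individual can ever be pinned from the panel.

## Locus placement and window growth

A locus interval intersecting a haploblock's physical interval is WITHIN it
(partial overlap counts — clean data never exercises the distinction);
otherwise it is BETWEEN the two physically adjacent blocks flanking its gap.
Loci before the first or after the last block are out of coverage: the
method needs flanking haplotypes on both sides. The base window is the
containing block (WITHIN) or the two flanks (BETWEEN).

Expansion adds exactly one haploblock per step. The side is chosen so the
post-expansion genetic lengths upstream and downstream of the locus are as
close to equal as possible; ties go to the physically nearer candidate
block, then to the left; at a chromosome end growth continues on the open
side. The locus's own cM position, which linkage maps never provide, is
interpolated linearly in bp — inside the containing block, or across the
gap between the left block's gen_end and the right block's gen_start. A
window's genetic span is gen_end of its last block minus gen_start of its
first; with this convention a window covering a whole chromosome has one
fixed span per chromosome, which is also how shared-segment lengths behave
(below).

## Allele assignment

Assignment runs at one global window shared by all panel entries:

1. homozygous panel individuals anchor their allele on both homolog
   patterns;
2. to fixpoint: a heterozygote whose homolog pattern is already assigned one
   of its alleles pins that allele there and its other allele on its other
   homolog; failing that, an informative parent — one sharing exactly one
   reported allele with the individual — whose pattern matches one homolog
   decides which homolog carries the shared allele;
3. if any pattern ends up claimed by two distinct alleles the window grows
   one block and matching restarts on the longer patterns. Termination:
   pattern → allele is a function, or the window cannot expand (remaining
   alleles are reported unresolved, never guessed).

Patterns containing MISSING codes are never used to merge or split allele
classes. Individuals are processed in sorted name order, so the map is
reproducible whenever several assignment orders would be valid. Every panel
allele is either mapped or listed as unresolved.

For each resolved pattern, all chain-maximal carriers — carriers none of
whose parents carry the pattern, reachable from the panel carrier through an
unbroken chain of pattern-carrying parents — are recorded as ancestral
sources. Per-source minimal discriminating windows (the smallest
balanced-growth window at which a source's pattern observably differs from
every other given source) are a separate diagnostic computation; sources
identical over the whole chromosome are reported indistinguishable.

## Sharing, IBD, and the IBS threshold

The extended shared segment between two homologs is the maximal contiguous
run of equal, non-MISSING codes containing the anchor window; its length is
gen_end of the last shared block minus gen_start of the first. MISSING
terminates extension by default (bridging up to N missing blocks is
available behind `bridge_missing`, default 0, because bridging unobserved
regions overstates sharing). If any anchor code is MISSING the comparison is
NOT-EVALUABLE, which is distinct from a negative result.

IBD tracing is a breadth-first search up the pedigree from the query
homolog, depth-capped at 10 generations to bound cost on dense pedigrees. A
chain qualifies when every member carries the anchor pattern on some homolog
and consecutive members are parent/child; the shortest qualifying chain is
returned. Only the anchor pattern must be preserved along the chain — not
the full extended segment — since recombination legitimately shortens the
flanks in each meiosis.

Deduction is two-pass: pass 1 accepts IBD only and derives the IBS
threshold as the minimum shared length among IBD deductions, global across
the loci processed together; pass 2 applies IBS at that threshold. With no
IBD deductions at all, a configurable default of 9.4 cM — the published
cross-crop minimum for this class of data — is used with a warning. Among
several matching sources the order of preference is: IBD reachable
(shortest pedigree path, then longest shared segment, then lexicographic
name), else longest shared segment via IBS. Panel individuals' own resolved
homologs are labelled PANEL so downstream statistics can exclude them.
Failure is always explicit: UNDEDUCED with reason MISSING_DATA,
UNIQUE_PATTERN, or BELOW_THRESHOLD.

## Validation and triage

Genotype comparison is an unordered multiset match per individual; a single
deduced allele contained in the reported pair is PARTIAL; individuals
lacking either side are UNTESTABLE. Accuracy is matched deduced alleles over
validatable deduced alleles. Triage emits evidence, not verdicts: for each
parent, sibling (≥1 shared named parent, half-sibs included) and offspring
of a mismatching individual it reports shared homolog runs across the
locus, their cM length, and the allele deduced on the shared homolog. The
judgment that a historic report (rather than the deduction) is wrong remains
with the user.

## Simulator

The generator emulates pedigree-connected clonal germplasm: founders with
two homologs each, later generations produced by random matings among all
earlier individuals, and a hidden target-locus allele riding on each founder
homolog. Defaults — chosen once as the study conditions for testing — are 50
founders, 4 generations of 56 matings × 2 offspring (~498 individuals), one
chromosome of 40 haploblocks uniformly tiling 80 cM / 32 Mb, 8 distinct
locus alleles with half the founders homozygous (so the homozygote-first
assignment step has anchors), a reference panel of all founders plus 12
first-generation offspring, and zero missing-data/corruption rates (tests
that exercise masking and mismatch handling raise them explicitly).

Meiosis draws the crossover count from Poisson(map length in Morgans), with
positions uniform on the cM axis and the starting homolog a fair coin. No
crossover interference is modelled; plain Poisson recombination is
sufficient to generate the segment-length variation the threshold rule
feeds on. Each haploblock inherits the code of the parental homolog active
at its genetic midpoint — haploblocks are historic-recombination units, so a
within-block crossover is resolved to one side — and the hidden allele
inherits with the haploblock anchoring the locus (the containing block, or
the nearest flank when the locus falls between blocks). This couples the
allele to the anchor-block code at every meiosis, which is what makes
deduction precision *exactly* 1.0 provable in UNIQUE founder mode: every
complete anchor pattern identifies one founder homolog, and the allele
always travels with it. In POOLED mode (codes drawn from a small pool per
haploblock) unrelated homologs collide by state, exercising window
expansion, the IBS path, and genuine IBS misassignment risk below the
threshold.

All randomness flows from one integer-seeded NumPy generator
(`default_rng`), and all iteration orders are sorted, so equal seeds give
byte-identical emitted files.

### What the simulator does not emulate

Real curated datasets have uneven haploblock sizes and genetic gaps,
genotyping and phasing errors inside haplotype codes, population structure
and assortative parent choice, and pedigree errors. Passing tests therefore
demonstrate the correctness of the deduction logic under the stated model,
not the field accuracy of any particular dataset; on real data, accuracy is
bounded by the upstream phasing/haploblocking quality and the density of
pedigree connections.

## Numerical and design choices

- Physical coordinates 1-based inclusive; genetic coordinates floating cM.
- Shared lengths and window spans use haploblock-span endpoints (first
  block's gen_start to last block's gen_end); outermost-SNP endpoints would
  differ only within the terminal blocks.
- Deduction processes individuals and candidate sources in deterministic
  sorted order; identical inputs give byte-identical output tables.
- The acceptance script scales its checks to desk size (~500-individual
  simulations, 10,000 meioses for the crossover calibration, ~1,000 random
  fixtures for oracle equivalence), chosen so the whole run completes in
  seconds while keeping every estimate's Monte-Carlo error far below the
  asserted tolerances.

## Known limitations

- Assignment resolves heterozygous panel individuals only through shared
  patterns or informative parents inside the panel; an isolated heterozygous
  founder with two never-seen patterns is reported unresolved (the honest
  outcome — its homolog-to-allele phase is genuinely unknowable from the
  given data).
- IBS deduction below-threshold candidates are rejected rather than scored;
  no probabilistic confidence model (e.g. segment-length likelihoods) is
  provided.
- One locus per run; multi-locus runs share a global threshold by
  construction but must be orchestrated by the caller.
- Unphased input is out of scope; phasing quality is assumed from upstream
  curation.
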