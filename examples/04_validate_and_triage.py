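"""Validate deduced genotypes against reports and triage a mismatch.

Deduced genotypes are compared (as unordered allele pairs) with an
independently reported table. Here one report is deliberately corrupted;
validation flags it, and triage gathers pedigree evidence: relatives that
share a homolog across the locus, how many cM they share, and which allele
rides that homolog. A long shared segment carrying the deduced allele argues
that the historic report — not the deduction — is wrong.
"""

from haploseer import (
    SimConfig,
    Status,
    assign_alleles,
    base_window,
    compare_genotypes,
    deduce_all,
    genotype_view,
    simulate_dataset,
    triage_mismatch,
)

ds = simulate_dataset(SimConfig(seed=1))
amap = assign_alleles(ds.panel, ds.haplotypes, ds.pedigree, ds.placement, ds.hb_map)
deds, _ = deduce_all(ds.haplotypes.individuals, amap, ds.haplotypes,
                     ds.pedigree, ds.hb_map, panel=ds.panel)

reported = {
    ind: tuple(sorted((ds.truth.allele[(ind, 1)], ds.truth.allele[(ind, 2)])))
    for ind in ds.haplotypes.individuals
}
clean = compare_genotypes(deds, reported)
print(f"clean truth-derived reports: accuracy = {clean.accuracy:.3f} over "
      f"{clean.n_validatable_alleles} validatable alleles")

victim = next(i for i in clean.individuals_with(Status.MATCH)
              if not ds.pedigree.is_founder(i))
reported[victim] = ("999", reported[victim][1])  # plant a wrong report
report = compare_genotypes(deds, reported)
print(f"after corrupting one report: MISMATCH rows = "
      f"{report.individuals_with(Status.MISMATCH)}")

window = base_window(ds.placement, ds.hb_map)
evidence = triage_mismatch(victim, deds, ds.pedigree, ds.haplotypes,
                           ds.hb_map, window, reported, report)
deduced = [a for a in genotype_view(deds)[victim] if a]
print(f"{victim}: deduced {deduced}, reported {list(reported[victim])}")
print(evidence.head(5).to_string(index=False))
support = evidence[evidence["relative_allele_on_homolog"].isin(deduced)]
print(f"{len(support)} relatives share a homolog carrying a deduced allele "
      "-> the historic report is the likely error")
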