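"""The IBS acceptance threshold: reject short identical-by-state matches.

Three germplasm homologs match an ancestral source's haplotype pattern at
the locus. One is pedigree-connected (IBD) and shares 30 cM — the shortest
IBD-shared segment, which becomes the threshold. Of the two unrelated (IBS)
candidates, the 50 cM match is accepted and the 20 cM match is rejected:
short state-identical segments are too likely to be coincidental.
"""

from haploseer import (
    HaplotypeSet,
    Pedigree,
    ReferencePanel,
    TargetLocus,
    assign_alleles,
    deduce_all,
    place_locus,
)
from haploseer.simulate import SimConfig, simulate_map

hb_map = simulate_map(SimConfig(n_haploblocks=10, cm_length=100.0))
blocks = hb_map.blocks("chr1")

hs = HaplotypeSet()


def put(ind, hom, codes):
    hs.add_individual(ind)
    for b, c in zip(blocks, codes):
        hs.set_code(ind, hom, b.id, c)


put("SRC", 1, ["s"] * 10)
put("SRC", 2, ["s"] * 10)
put("kidIBD", 1, ["s" if 3 <= i <= 5 else "k" for i in range(10)])
put("kidIBD", 2, ["x"] * 10)
put("ibs_long", 1, ["s" if 2 <= i <= 6 else "l" for i in range(10)])
put("ibs_long", 2, ["y"] * 10)
put("ibs_short", 1, ["s" if 4 <= i <= 5 else "m" for i in range(10)])
put("ibs_short", 2, ["z"] * 10)

pedigree = Pedigree({"SRC": (None, None), "kidIBD": ("SRC", None),
                     "ibs_long": (None, None), "ibs_short": (None, None)})
panel = ReferencePanel("L")
panel.add("SRC", "A", "A")

blk = blocks[4]
locus = TargetLocus("L", "chr1", (blk.phys_start + blk.phys_end) // 2,
                    (blk.phys_start + blk.phys_end) // 2)
placement = place_locus(locus, hb_map)
amap = assign_alleles(panel, hs, pedigree, placement, hb_map)
deds, _ = deduce_all(hs.individuals, amap, hs, pedigree, hb_map, panel=panel)

for d in sorted(deds, key=lambda d: (d.individual, d.homolog)):
    if d.individual == "SRC" or d.homolog == 2:
        continue
    shared = f"{d.shared_cm:.0f} cM" if d.shared_cm is not None else "-"
    outcome = d.allele or f"UNDEDUCED ({d.reason.value})"
    mode = d.mode.value if d.mode else "-"
    print(f"{d.individual:10s} shared {shared:>6s} mode {mode:>4s} -> {outcome}")
print("the 30 cM minimum IBD segment sets the threshold; only IBS matches "
      "at or above it are trusted")
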