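"""Place a target locus on a haploblock map and grow balanced windows.

The locus (here a QTL-style marker position on a chromosome-16-like map)
falls physically between two haploblocks, so its base haplotype pattern is
the pair of flanking haplotypes. When that pattern cannot separate alleles
or ancestral sources, the window is widened one haploblock at a time while
keeping the genetic length on both sides of the locus near-equal.
"""

from haploseer import (
    CannotExpandError,
    Haploblock,
    HaploblockMap,
    TargetLocus,
    base_window,
    expand_window,
    place_locus,
    window_span_cm,
)

BLOCKS = [  # id, phys_start, phys_end, gen_start, gen_end
    ("HB-16-1", 1, 500_000, 0.0, 10.0),
    ("HB-16-2", 600_000, 900_000, 10.0, 15.0),
    ("HB-16-2a", 1_000_000, 1_200_000, 20.0, 21.0),
    ("HB-16-3", 1_300_000, 1_600_000, 21.5, 22.0),
    ("HB-16-4", 1_700_000, 2_900_000, 22.5, 23.5),
    ("HB-16-5", 3_003_499, 3_132_772, 24.0, 24.6),
    ("HB-16-6", 3_304_530, 3_349_986, 24.9, 25.2),
    ("HB-16-7", 3_400_000, 3_600_000, 25.5, 25.8),
    ("HB-16-8", 3_700_000, 4_000_000, 26.0, 27.0),
    ("HB-16-9", 4_100_000, 4_500_000, 27.5, 28.6),
    ("HB-16-10", 5_000_000, 9_000_000, 30.0, 50.0),
    ("HB-16-11", 9_500_000, 12_000_000, 55.0, 68.2),
]
hb_map = HaploblockMap(
    Haploblock(id=i, chromosome="16", phys_start=ps, phys_end=pe,
               gen_start=gs, gen_end=ge)
    for i, ps, pe, gs, ge in BLOCKS
)

locus = TargetLocus(name="acidityQTL", chromosome="16",
                    phys_start=3_177_899, phys_end=3_177_899)
placement = place_locus(locus, hb_map)
print(f"{locus.name} at {locus.chromosome}:{locus.phys_start} -> "
      f"{placement.kind.value} {placement.anchor_hbs()}")

w = base_window(placement, hb_map)
print(f"base window {w.hb_ids[0]}..{w.hb_ids[-1]}: "
      f"{window_span_cm(w, hb_map):.1f} cM")
while True:
    try:
        w = expand_window(w, hb_map)
    except CannotExpandError:
        break
    print(f"  grew to {w.hb_ids[0]}..{w.hb_ids[-1]}: "
          f"{window_span_cm(w, hb_map):.1f} cM")
print("each step adds the haploblock that best rebalances the cM flanks; "
      "spans are gen_end(last) - gen_start(first)")
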