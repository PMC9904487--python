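"""Shared fixtures: hand-built maps and pedigrees, plus simulated datasets.

The chr16-style apple map is a *synthetic stand-in* for the published
haploblock map of apple chromosome 16: block names, the physical coordinates
of the two blocks flanking the acidity QTL, and the genetic-map anchors
(window spans of 1.8 and 8.6 cM, chromosome length 68.2 cM) follow the
printed values; everything else is invented but structurally valid.
"""

from __future__ import annotations

import pytest

from haploseer import (
    CannotExpandError,
    Haploblock,
    HaploblockMap,
    HaplotypeSet,
    Pedigree,
    SimConfig,
    TargetLocus,
    base_window,
    expand_window,
    simulate_dataset,
)


def expansion_chain(placement, hb_map, n_steps=None):
    """All windows reachable by repeated expansion, base window first."""
    w = base_window(placement, hb_map)
    chain = [w]
    while n_steps is None or len(chain) <= n_steps:
        try:
            w = expand_window(w, hb_map)
        except CannotExpandError:
            break
        chain.append(w)
    return chain


def make_uniform_map(
    n_blocks: int = 10,
    cm_per_block: float = 10.0,
    bp_per_block: int = 1_000_000,
    chromosome: str = "chrT",
    gap_bp: int = 0,
) -> HaploblockMap:
    blocks = []
    for i in range(n_blocks):
        start = i * bp_per_block + 1
        end = (i + 1) * bp_per_block - gap_bp
        blocks.append(
            Haploblock(
                id=f"HB-{chromosome}-{i + 1}",
                chromosome=chromosome,
                phys_start=start,
                phys_end=end,
                gen_start=i * cm_per_block,
                gen_end=(i + 1) * cm_per_block - (gap_bp / bp_per_block) * cm_per_block,
            )
        )
    return HaploblockMap(blocks)


@pytest.fixture
def uniform_map():
    return make_uniform_map()


# (id, phys_start, phys_end, gen_start, gen_end) — HB-16-5/HB-16-6 physical
# intervals are the published ones; genetic coordinates embed the published
# anchors: span(16-5..16-7) = 1.8, span(16-2a..16-9) = 8.6, total = 68.2.
CHR16_BLOCKS = [
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


def make_chr16_map() -> HaploblockMap:
    return HaploblockMap(
        Haploblock(id=i, chromosome="16", phys_start=ps, phys_end=pe,
                   gen_start=gs, gen_end=ge)
        for i, ps, pe, gs, ge in CHR16_BLOCKS
    )


@pytest.fixture
def chr16_map():
    return make_chr16_map()


@pytest.fixture
def ma_locus():
    # apple acidity QTL marker position on chromosome 16
    return TargetLocus(name="Ma", chromosome="16", phys_start=3_177_899, phys_end=3_177_899)


@pytest.fixture
def trio_pedigree():
    return Pedigree({
        "child": ("mother", "father"),
        "mother": (None, None),
        "father": (None, None),
    })


def set_homolog(hs: HaplotypeSet, individual: str, homolog: int,
                hb_map: HaploblockMap, chromosome: str, codes) -> None:
    """Assign a full code vector over one chromosome (None -> leave MISSING)."""
    hs.add_individual(individual)
    for blk, code in zip(hb_map.blocks(chromosome), codes):
        if code is not None:
            hs.set_code(individual, homolog, blk.id, str(code))


def make_threshold_fixture():
    """Hand-built dataset with a planted minimum IBD length of 30 cM.

    One ancestral source (homozygous allele A, codes 's' everywhere), one
    pedigree-connected child sharing exactly 3 blocks (30 cM) across the
    locus, and two unrelated founders matching the anchor pattern with
    shared runs of 50 cM (above the planted minimum) and 20 cM (below).
    """
    from haploseer import ReferencePanel, place_locus

    hb_map = make_uniform_map()  # 10 blocks x 10 cM
    hs = HaplotypeSet()
    set_homolog(hs, "SRC", 1, hb_map, "chrT", ["s"] * 10)
    set_homolog(hs, "SRC", 2, hb_map, "chrT", ["s"] * 10)
    kid1 = ["s" if 3 <= i <= 5 else "k" for i in range(10)]
    set_homolog(hs, "kidIBD", 1, hb_map, "chrT", kid1)
    set_homolog(hs, "kidIBD", 2, hb_map, "chrT", ["x"] * 10)
    long1 = ["s" if 2 <= i <= 6 else "l" for i in range(10)]
    set_homolog(hs, "ibs_long", 1, hb_map, "chrT", long1)
    set_homolog(hs, "ibs_long", 2, hb_map, "chrT", ["y"] * 10)
    short1 = ["s" if 4 <= i <= 5 else "m" for i in range(10)]
    set_homolog(hs, "ibs_short", 1, hb_map, "chrT", short1)
    set_homolog(hs, "ibs_short", 2, hb_map, "chrT", ["z"] * 10)

    pedigree = Pedigree({
        "SRC": (None, None),
        "kidIBD": ("SRC", None),
        "ibs_long": (None, None),
        "ibs_short": (None, None),
    })
    panel = ReferencePanel("L")
    panel.add("SRC", "A", "A")
    blk = hb_map.blocks("chrT")[4]
    bp = (blk.phys_start + blk.phys_end) // 2
    placement = place_locus(TargetLocus("L", "chrT", bp, bp), hb_map)
    return hb_map, hs, pedigree, panel, placement


@pytest.fixture(scope="session")
def unique_sim():
    """Default study conditions: UNIQUE founder codes, ~500 individuals."""
    return simulate_dataset(SimConfig(seed=20260925))


@pytest.fixture(scope="session")
def pooled_sim():
    """POOLED codes: IBS ambiguity, window expansion, threshold behavior."""
    return simulate_dataset(
        SimConfig(seed=20260925, founder_mode="POOLED", pool_size=4, gap_fraction=0.2)
    )
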