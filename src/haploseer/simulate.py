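"""Pedigreed, phased, haploblocked germplasm simulator with hidden locus alleles.

The generator emulates the kind of data the deduction method consumes: a
founder population whose chromosomes are tiled by haploblocks, several
generations of matings with Poisson-crossover meioses, a hidden allele at a
target locus riding on each founder homolog, a reference panel of
historically "reported" genotypes, and full transmission truth (who inherited
which founder segment through whom) so every pipeline stage can be checked
against ground truth without any external dataset.

Two founder-haplotype modes set the difficulty. UNIQUE gives every founder
homolog its own private code at every haploblock, so haplotype patterns are
unambiguous founder identifiers and deduction precision is provably perfect —
the clean acceptance surface. POOLED draws codes from a small shared pool per
haploblock, creating identity-by-state between unrelated homologs and thereby
exercising window expansion and the shared-length threshold.

The hidden allele travels with the haploblock that anchors the locus (its
containing block, or the nearest flanking block when the locus falls between
blocks); within-meiosis crossovers are resolved at haploblock genetic
midpoints, so a haploblock — and with it the allele — is always inherited
from a single parental homolog.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as hio
from .model import Haploblock, HaploblockMap, HaplotypeSet, Pedigree, ReferencePanel, TargetLocus
from .placement import Placement, PlacementKind, place_locus


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are probabilities in [0, 1]. Defaults describe a desk-scale
    pedigree-connected germplasm set: 50 founders, 4 generations of 56
    matings x 2 offspring (~498 individuals), one chromosome of 40
    haploblocks tiling 80 cM / 32 Mb, and 8 distinct locus alleles with
    half the founders homozygous so the homozygote-first assignment step
    has anchors.
    """

    seed: int = 0
    n_founders: int = 50
    n_generations: int = 4
    n_matings_per_generation: int = 56
    offspring_per_mating: int = 2
    chromosome: str = "chr1"
    n_haploblocks: int = 40
    cm_length: float = 80.0
    bp_length: int = 32_000_000
    gap_fraction: float = 0.0  # physical fraction of each tile left between blocks
    snps_per_block: int = 0
    founder_mode: str = "UNIQUE"  # or "POOLED"
    pool_size: int = 4  # codes per haploblock in POOLED mode
    locus_name: str = "L1"
    locus_bp: int | None = None  # default: chromosome midpoint
    n_locus_alleles: int = 8
    homozygous_founder_fraction: float = 0.5
    n_panel_descendants: int = 12
    missing_rate: float = 0.0
    corruption_rate: float = 0.0

    def __post_init__(self):
        for name in ("missing_rate", "corruption_rate", "homozygous_founder_fraction",
                     "gap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.founder_mode not in ("UNIQUE", "POOLED"):
            raise ValueError("founder_mode must be UNIQUE or POOLED")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the dataset.

    `allele` / `founder_origin` are keyed by (individual, homolog) where
    homolog 1 is maternal and 2 paternal; `chain` is the transmission path
    of the locus-anchoring segment from the individual up to its founder;
    `crossovers` records crossover cM positions per realized meiosis.
    """

    allele: dict[tuple[str, int], str] = field(default_factory=dict)
    founder_origin: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)
    chain: dict[tuple[str, int], tuple[str, ...]] = field(default_factory=dict)
    crossovers: dict[tuple[str, int], tuple[float, ...]] = field(default_factory=dict)
    anchor_hb: str = ""


def simulate_map(config: SimConfig) -> HaploblockMap:
    """Tile one chromosome with contiguous, non-overlapping haploblocks.

    Physical and genetic coordinates advance uniformly; with a nonzero
    gap_fraction each block occupies only the leading part of its tile,
    leaving ungenotyped gaps a locus can fall *between*.
    """
    n = config.n_haploblocks
    tile_bp = config.bp_length / n
    tile_cm = config.cm_length / n
    frac = 1.0 - config.gap_fraction
    blocks = []
    for i in range(n):
        phys_start = int(round(i * tile_bp)) + 1
        phys_end = int(round(i * tile_bp + frac * tile_bp))
        phys_end = max(phys_end, phys_start)
        snps = tuple(
            f"snp_{config.chromosome}_{i + 1}_{j + 1}" for j in range(config.snps_per_block)
        )
        blocks.append(
            Haploblock(
                id=f"HB-{config.chromosome}-{i + 1}",
                chromosome=config.chromosome,
                phys_start=phys_start,
                phys_end=phys_end,
                gen_start=round(i * tile_cm, 6),
                gen_end=round((i + frac) * tile_cm, 6),
                snp_ids=snps,
            )
        )
    return HaploblockMap(blocks)


def default_locus(config: SimConfig, hb_map: HaploblockMap) -> TargetLocus:
    bp = config.locus_bp if config.locus_bp is not None else config.bp_length // 2
    return TargetLocus(
        name=config.locus_name,
        chromosome=config.chromosome,
        phys_start=bp,
        phys_end=bp,
    )


def _anchor_block_index(placement: Placement, hb_map: HaploblockMap) -> int:
    """Index of the haploblock the hidden allele travels with."""
    blocks = hb_map.blocks(placement.locus.chromosome)
    ids = [b.id for b in blocks]
    if placement.kind is PlacementKind.WITHIN:
        return ids.index(placement.within_hb)
    left = hb_map[placement.left_hb]
    right = hb_map[placement.right_hb]
    mid = 0.5 * (placement.locus.phys_start + placement.locus.phys_end)
    if mid - left.phys_end <= right.phys_start - mid:
        return ids.index(placement.left_hb)
    return ids.index(placement.right_hb)


@dataclass
class _Homolog:
    codes: list  # haplotype code per haploblock, map order
    origins: list  # (founder, founder_homolog) per haploblock
    allele: str
    allele_origin: tuple[str, int]
    chain: tuple[str, ...]  # transmission path of the locus segment, child->founder


def simulate_meiosis(
    homolog1: _Homolog,
    homolog2: _Homolog,
    hb_map: HaploblockMap,
    chromosome: str,
    anchor_index: int,
    rng: np.random.Generator,
) -> tuple[_Homolog, tuple[float, ...]]:
    """One gamete: Poisson crossovers, uniform on the cM axis, no interference.

    The crossover count is Poisson with mean equal to the map length in
    Morgans; the starting homolog is a fair coin; each haploblock inherits
    the code of the parental homolog active at its genetic midpoint, and the
    hidden allele inherits with the anchor haploblock.
    """
    blocks = hb_map.blocks(chromosome)
    span_start = blocks[0].gen_start
    span_end = blocks[-1].gen_end
    length_m = (span_end - span_start) / 100.0
    n_xo = rng.poisson(length_m)
    positions = np.sort(rng.uniform(span_start, span_end, size=n_xo))
    start = int(rng.integers(0, 2))
    parents = (homolog1, homolog2)
    codes, origins = [], []
    active_at_anchor = start
    for i, b in enumerate(blocks):
        mid = 0.5 * (b.gen_start + b.gen_end)
        active = (start + int(np.searchsorted(positions, mid))) % 2
        codes.append(parents[active].codes[i])
        origins.append(parents[active].origins[i])
        if i == anchor_index:
            active_at_anchor = active
    src = parents[active_at_anchor]
    gamete = _Homolog(
        codes=codes,
        origins=origins,
        allele=src.allele,
        allele_origin=src.allele_origin,
        chain=src.chain,
    )
    return gamete, tuple(float(p) for p in positions)


@dataclass
class SimulatedDataset:
    config: SimConfig
    hb_map: HaploblockMap
    haplotypes: HaplotypeSet
    pedigree: Pedigree
    locus: TargetLocus
    placement: Placement
    panel: ReferencePanel
    reported: dict[str, tuple[str | None, str | None]]
    truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full ground-truthed dataset under one seed.

    Founders are created first; each later generation draws mating pairs
    from all earlier individuals. The reference panel is the founders plus a
    few first-generation descendants, with truth genotypes. The reported-
    genotype table is derived from truth with the configured corruption
    rate (one allele replaced per corrupted individual), and missing-data
    masking is applied last so truth stays Mendelian-consistent.
    """
    rng = np.random.default_rng(config.seed)
    hb_map = simulate_map(config)
    locus = default_locus(config, hb_map)
    placement = place_locus(locus, hb_map)
    anchor_index = _anchor_block_index(placement, hb_map)
    blocks = hb_map.blocks(config.chromosome)
    n_blocks = len(blocks)

    allele_labels = [f"A{i + 1}" for i in range(config.n_locus_alleles)]
    homologs: dict[tuple[str, int], _Homolog] = {}
    parents_of: dict[str, tuple[str | None, str | None]] = {}
    truth = SimTruth(anchor_hb=blocks[anchor_index].id)

    founders = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    n_homozygous = int(round(config.homozygous_founder_fraction * config.n_founders))
    for fi, name in enumerate(founders):
        parents_of[name] = (None, None)
        if fi < n_homozygous:
            a = rng.choice(allele_labels)
            alleles = (str(a), str(a))
        else:
            alleles = (
                str(rng.choice(allele_labels)),
                str(rng.choice(allele_labels)),
            )
        for hom in (1, 2):
            if config.founder_mode == "UNIQUE":
                codes = [f"{2 * fi + hom}"] * n_blocks
            else:
                codes = [
                    str(int(c))
                    for c in rng.integers(1, config.pool_size + 1, size=n_blocks)
                ]
            homologs[(name, hom)] = _Homolog(
                codes=codes,
                origins=[(name, hom)] * n_blocks,
                allele=alleles[hom - 1],
                allele_origin=(name, hom),
                chain=(name,),
            )

    generations = [founders]
    counter = 0
    for gen in range(1, config.n_generations + 1):
        pool = [ind for g in generations for ind in g]
        newgen = []
        for _ in range(config.n_matings_per_generation):
            i, j = rng.choice(len(pool), size=2, replace=False)
            mother, father = pool[int(i)], pool[int(j)]
            for _k in range(config.offspring_per_mating):
                counter += 1
                child = f"G{gen}_{counter:04d}"
                parents_of[child] = (mother, father)
                for hom, parent in ((1, mother), (2, father)):
                    gamete, xos = simulate_meiosis(
                        homologs[(parent, 1)],
                        homologs[(parent, 2)],
                        hb_map,
                        config.chromosome,
                        anchor_index,
                        rng,
                    )
                    gamete = replace(gamete, chain=(child,) + gamete.chain)
                    homologs[(child, hom)] = gamete
                    truth.crossovers[(child, hom)] = xos
                newgen.append(child)
        generations.append(newgen)

    pedigree = Pedigree(parents_of)
    all_individuals = [ind for g in generations for ind in g]

    for ind in all_individuals:
        for hom in (1, 2):
            h = homologs[(ind, hom)]
            truth.allele[(ind, hom)] = h.allele
            truth.founder_origin[(ind, hom)] = h.allele_origin
            truth.chain[(ind, hom)] = h.chain

    panel = ReferencePanel(locus_name=config.locus_name)
    gen1 = generations[1] if len(generations) > 1 else []
    panel_members = founders + gen1[: config.n_panel_descendants]
    for ind in panel_members:
        a1, a2 = sorted((truth.allele[(ind, 1)], truth.allele[(ind, 2)]))
        panel.add(ind, a1, a2)

    reported: dict[str, tuple[str | None, str | None]] = {}
    for ind in all_individuals:
        a1, a2 = sorted((truth.allele[(ind, 1)], truth.allele[(ind, 2)]))
        if config.corruption_rate > 0 and rng.random() < config.corruption_rate:
            wrong = str(rng.choice([a for a in allele_labels if a != a1]))
            a1 = wrong
            a1, a2 = sorted((a1, a2))
        reported[ind] = (a1, a2)

    haplotypes = HaplotypeSet()
    for ind in all_individuals:
        haplotypes.add_individual(ind)
        for hom in (1, 2):
            h = homologs[(ind, hom)]
            for b, code in zip(blocks, h.codes):
                if config.missing_rate > 0 and rng.random() < config.missing_rate:
                    continue
                haplotypes.set_code(ind, hom, b.id, code)

    return SimulatedDataset(
        config=config,
        hb_map=hb_map,
        haplotypes=haplotypes,
        pedigree=pedigree,
        locus=locus,
        placement=placement,
        panel=panel,
        reported=reported,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Emit all core file formats plus the truth table into a directory."""
    from .validation import write_reported_genotypes

    out = hio.ensure_dir(out_dir)
    paths = {
        "map": out / "map.tsv",
        "haplotypes": out / "haplotypes.tsv",
        "pedigree": out / "pedigree.tsv",
        "panel": out / "panel.tsv",
        "reported": out / "reported.tsv",
        "truth": out / "truth.tsv",
    }
    hio.write_haploblock_map(ds.hb_map, paths["map"])
    hio.write_phased_haplotypes(ds.haplotypes, paths["haplotypes"])
    hio.write_pedigree(ds.pedigree, paths["pedigree"])
    hio.write_reference_panel(ds.panel, paths["panel"])
    write_reported_genotypes(ds.reported, paths["reported"])
    import pandas as pd

    rows = [
        {
            "individual": ind,
            "homolog": hom,
            "allele": ds.truth.allele[(ind, hom)],
            "founder": ds.truth.founder_origin[(ind, hom)][0],
            "founder_homolog": ds.truth.founder_origin[(ind, hom)][1],
            "chain": ">".join(ds.truth.chain[(ind, hom)]),
        }
        for (ind, hom) in sorted(ds.truth.allele)
    ]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
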