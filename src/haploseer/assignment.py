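"""Associating reference-panel locus alleles with unique haplotype patterns.

Each allele of a target locus (a QTL functional allele, an SSR amplicon
length, ...) is anchored to the haplotype pattern — the ordered tuple of
haploblock codes over a window around the locus — of the homolog that
carries it in the reference panel. Assignment proceeds homozygotes-first,
then propagates through heterozygotes that share an allele and a flanking
pattern with an already-assigned case, then falls back on pedigree links
among panel individuals. When one pattern ends up claimed by two distinct
alleles the window is widened by one haploblock (nearest first, flanks kept
genetically balanced) and matching restarts on the longer patterns.
Afterwards, the earliest known ancestor carrying each pattern is recorded as
its ancestral source.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

from .model import HaploblockMap, HaplotypeSet, Pedigree, ReferencePanel, is_missing
from .placement import (
    CannotExpandError,
    Placement,
    Window,
    base_window,
    expand_window,
)
from .sharing import anchor_pattern

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HaplotypePattern:
    """Ordered haplotype codes over a window; MISSING cells allowed.

    Two patterns match only when their windows are identical and every code
    pair is equal and non-MISSING: unobserved codes are never evidence of
    identity.
    """

    window: Window
    codes: tuple

    def __post_init__(self):
        if len(self.codes) != len(self.window.hb_ids):
            raise ValueError("pattern length must equal window length")

    @property
    def is_complete(self) -> bool:
        return not any(is_missing(c) for c in self.codes)

    def matches(self, other: "HaplotypePattern") -> bool:
        if self.window.hb_ids != other.window.hb_ids:
            return False
        if not self.is_complete or not other.is_complete:
            return False
        return all(a == b for a, b in zip(self.codes, other.codes))


def pattern_of(
    individual: str, homolog: int, window: Window, haplotypes: HaplotypeSet
) -> HaplotypePattern:
    """The code vector of one homolog over the window (MISSING propagates)."""
    return HaplotypePattern(
        window=window, codes=anchor_pattern(individual, homolog, window, haplotypes)
    )


@dataclass(frozen=True)
class AlleleMapEntry:
    codes: tuple
    allele: str
    source: str
    source_homolog: int


@dataclass
class AlleleMap:
    """Final pattern -> allele function for one locus, with ancestral sources.

    Multiple patterns may carry the same allele (different ancestral
    sources), and one pattern may be listed under several sources, but no
    pattern maps to two distinct alleles. Panel alleles that could not be
    pinned to a homolog pattern are listed in `unresolved`.
    """

    locus_name: str
    window: Window
    entries: list[AlleleMapEntry] = field(default_factory=list)
    unresolved: list[tuple[str, str, str]] = field(default_factory=list)
    #: (individual, homolog) -> allele for panel homologs that were resolved
    panel_homolog_alleles: dict[tuple[str, int], str] = field(default_factory=dict)

    def allele_of(self, codes: Sequence) -> str | None:
        for e in self.entries:
            if len(e.codes) == len(codes) and all(
                (not is_missing(a)) and (not is_missing(b)) and a == b
                for a, b in zip(e.codes, codes)
            ):
                return e.allele
        return None

    def matching_entries(self, codes: Sequence) -> list[AlleleMapEntry]:
        if any(is_missing(c) for c in codes):
            return []
        return [
            e
            for e in self.entries
            if len(e.codes) == len(codes)
            and all(a == b for a, b in zip(e.codes, codes))
        ]

    @property
    def alleles(self) -> list[str]:
        return sorted({e.allele for e in self.entries})


class _Conflict(Exception):
    def __init__(self, codes, alleles):
        self.codes = codes
        self.alleles = alleles
        super().__init__(f"pattern {codes} claimed by alleles {sorted(alleles)}")


def _try_assign_at_window(
    panel: ReferencePanel,
    haplotypes: HaplotypeSet,
    pedigree: Pedigree,
    window: Window,
):
    """One matching pass at a fixed window.

    Returns (assigned: codes->allele, homolog_allele: (ind,hom)->allele).
    Raises _Conflict if some pattern is claimed by two distinct alleles.
    """
    usable: dict[str, dict[int, tuple]] = {}
    for ind in panel.individuals:
        if ind not in haplotypes:
            log.warning("panel individual %s has no haplotype data; skipped", ind)
            continue
        pats = {}
        for hom in (1, 2):
            codes = anchor_pattern(ind, hom, window, haplotypes)
            if not any(is_missing(c) for c in codes):
                pats[hom] = codes
        if not pats:
            log.warning(
                "panel individual %s has no complete pattern over the window; skipped",
                ind,
            )
            continue
        usable[ind] = pats

    assigned: dict[tuple, str] = {}
    homolog_allele: dict[tuple[str, int], str] = {}

    def put(codes: tuple, allele: str):
        prev = assigned.get(codes)
        if prev is not None and prev != allele:
            raise _Conflict(codes, {prev, allele})
        assigned[codes] = allele

    def resolve(ind: str, hom: int, allele: str):
        put(usable[ind][hom], allele)
        homolog_allele[(ind, hom)] = allele

    # step 1: homozygotes anchor their allele on both homolog patterns
    for ind in sorted(usable):
        if panel.is_homozygous(ind):
            a1, _ = panel.alleles_of(ind)
            for hom in usable[ind]:
                resolve(ind, hom, a1)

    # steps 2-3 to fixpoint: propagate through heterozygotes via shared
    # patterns, then via informative pedigree links among panel individuals
    changed = True
    while changed:
        changed = False
        for ind in sorted(usable):
            if panel.is_homozygous(ind):
                continue
            a1, a2 = panel.alleles_of(ind)
            geno = [a for a in (a1, a2) if a is not None]
            pats = usable[ind]
            unresolved_homs = [h for h in pats if (ind, h) not in homolog_allele]
            if not unresolved_homs:
                continue
            # step 2: a homolog whose pattern is already assigned an allele of
            # this genotype pins that allele; the other allele rides the
            # other homolog
            for hom in list(unresolved_homs):
                known = assigned.get(pats[hom])
                if known is not None and known in geno:
                    resolve(ind, hom, known)
                    other = [h for h in pats if h != hom]
                    if a2 is not None and other:
                        remaining = list(geno)
                        remaining.remove(known)
                        if remaining and (ind, other[0]) not in homolog_allele:
                            resolve(ind, other[0], remaining[0])
                    changed = True
            unresolved_homs = [h for h in pats if (ind, h) not in homolog_allele]
            if not unresolved_homs:
                continue
            # step 3: an informative parent (exactly one allele in common per
            # reported genotypes) whose pattern matches one homolog decides
            # which homolog carries the shared allele
            for parent in sorted(pedigree.named_parents(ind)) if ind in pedigree else []:
                if parent not in panel.genotypes:
                    continue
                p1, p2 = panel.alleles_of(parent)
                pgeno = {a for a in (p1, p2) if a is not None}
                shared = set(geno) & pgeno
                if len(shared) != 1:
                    continue
                shared_allele = next(iter(shared))
                parent_pats = usable.get(parent, {})
                for hom in list(unresolved_homs):
                    if any(
                        pats[hom] == pc for pc in parent_pats.values()
                    ):
                        resolve(ind, hom, shared_allele)
                        other = [h for h in pats if h != hom and (ind, h) not in homolog_allele]
                        if a2 is not None and other:
                            remaining = list(geno)
                            remaining.remove(shared_allele)
                            if remaining:
                                resolve(ind, other[0], remaining[0])
                        changed = True
                        unresolved_homs = [
                            h for h in pats if (ind, h) not in homolog_allele
                        ]
                        break
    return assigned, homolog_allele


def find_ancestral_source(
    codes: tuple,
    carrier: str,
    carrier_homolog: int,
    pedigree: Pedigree,
    haplotypes: HaplotypeSet,
    window: Window,
) -> tuple[str, int]:
    """Earliest known ancestor carrying the pattern, reachable by an unbroken
    chain of parent-to-child transmissions of that pattern from the carrier.

    Ties among equally ancestral candidates break lexicographically.
    """
    if any(is_missing(c) for c in codes):
        raise ValueError("cannot trace an incomplete pattern")

    def carrying(ind: str) -> list[int]:
        out = []
        for hom in (1, 2):
            c = anchor_pattern(ind, hom, window, haplotypes)
            if not any(is_missing(x) for x in c) and all(
                a == b for a, b in zip(c, codes)
            ):
                out.append(hom)
        return out

    if carrier_homolog not in carrying(carrier):
        raise KeyError(
            f"{carrier} homolog {carrier_homolog} does not carry the pattern"
        )
    ends = _chain_maximal_carriers(codes, carrier, pedigree, haplotypes, window)
    # prefer the deepest (most ancestral) chain end; among carriers at the
    # same depth the lexicographically first name wins
    maxdepth = max(d for _, _, d in ends)
    cands = sorted((name, hom) for name, hom, d in ends if d == maxdepth)
    name, hom = cands[0]
    if name == carrier:
        hom = carrier_homolog
    return (name, hom)


def _chain_maximal_carriers(
    codes: tuple,
    carrier: str,
    pedigree: Pedigree,
    haplotypes: HaplotypeSet,
    window: Window,
) -> list[tuple[str, int, int]]:
    """All (individual, homolog, depth) pattern carriers reachable upward from
    `carrier` through carrier-parents, whose own parents do not carry it."""

    def carrying(ind: str) -> list[int]:
        out = []
        for hom in (1, 2):
            c = anchor_pattern(ind, hom, window, haplotypes)
            if not any(is_missing(x) for x in c) and all(
                a == b for a, b in zip(c, codes)
            ):
                out.append(hom)
        return out

    results = []
    queue = deque([(carrier, 0)])
    depths = {carrier: 0}
    while queue:
        ind, depth = queue.popleft()
        parents = pedigree.named_parents(ind) if ind in pedigree else []
        carrier_parents = [p for p in parents if carrying(p)]
        if not carrier_parents:
            results.append((ind, carrying(ind)[0], depth))
            continue
        for p in carrier_parents:
            if p not in depths or depths[p] < depth + 1:
                depths[p] = depth + 1
                queue.append((p, depth + 1))
    # dedupe on (individual, homolog), keeping max depth
    best: dict[tuple[str, int], int] = {}
    for name, hom, d in results:
        key = (name, hom)
        if key not in best or d > best[key]:
            best[key] = d
    return [(name, hom, d) for (name, hom), d in best.items()]


def assign_alleles(
    panel: ReferencePanel,
    haplotypes: HaplotypeSet,
    pedigree: Pedigree,
    placement: Placement,
    hb_map: HaploblockMap,
) -> AlleleMap:
    """Run the allele-to-haplotype-pattern assignment loop.

    Starts at the base window (the containing haploblock, or the two blocks
    the locus lies between), assigns homozygotes first, propagates through
    heterozygotes and pedigree links, and widens the window one haploblock
    at a time whenever a pattern is claimed by two distinct alleles. One
    global window is shared by all entries; per-source minimal windows are a
    separate computation (`minimal_discriminating_window`).
    """
    window = base_window(placement, hb_map)
    while True:
        try:
            assigned, homolog_allele = _try_assign_at_window(
                panel, haplotypes, pedigree, window
            )
            break
        except _Conflict as c:
            try:
                window = expand_window(window, hb_map)
                log.info(
                    "pattern conflict (%s); widened window to %d haploblocks",
                    c,
                    len(window),
                )
            except CannotExpandError:
                log.warning(
                    "irreducible conflict at maximal window: %s", c
                )
                assigned, homolog_allele = {}, {}
                break

    amap = AlleleMap(locus_name=panel.locus_name, window=window)
    amap.panel_homolog_alleles = dict(homolog_allele)

    seen_entries = set()
    for (ind, hom), allele in sorted(homolog_allele.items()):
        codes = anchor_pattern(ind, hom, window, haplotypes)
        for name, shom, _depth in _chain_maximal_carriers(
            codes, ind, pedigree, haplotypes, window
        ):
            key = (codes, allele, name, shom)
            if key not in seen_entries:
                seen_entries.add(key)
                amap.entries.append(
                    AlleleMapEntry(
                        codes=codes, allele=allele, source=name, source_homolog=shom
                    )
                )

    # every panel allele is either mapped or reported unresolved
    for ind in panel.individuals:
        a1, a2 = panel.alleles_of(ind)
        resolved = [
            homolog_allele.get((ind, hom)) for hom in (1, 2)
        ]
        remaining = [a for a in (a1, a2) if a is not None]
        for r in resolved:
            if r in remaining:
                remaining.remove(r)
        for allele in remaining:
            reason = (
                "no haplotype data"
                if ind not in haplotypes
                else "homolog could not be determined"
            )
            amap.unresolved.append((ind, allele, reason))
    amap.entries.sort(key=lambda e: (e.allele, e.source, e.source_homolog))
    return amap


def minimal_discriminating_window(
    sources: Sequence[tuple[str, int]],
    hb_map: HaploblockMap,
    haplotypes: HaplotypeSet,
    placement: Placement,
) -> dict[tuple[str, int], Window | None]:
    """Smallest balanced-growth window separating each source from the rest.

    Follows the same symmetric expansion rule as assignment. A source is
    separated once, for every other source, some window haploblock shows
    observably different codes (MISSING never discriminates). Sources that
    remain identical over the whole chromosome are reported with None.
    """
    if len(sources) < 2:
        raise ValueError("need at least two sources to discriminate")
    result: dict[tuple[str, int], Window | None] = {}
    for me in sources:
        window = base_window(placement, hb_map)
        found = None
        while True:
            my = anchor_pattern(me[0], me[1], window, haplotypes)
            ok = True
            for other in sources:
                if other == me:
                    continue
                theirs = anchor_pattern(other[0], other[1], window, haplotypes)
                if not any(
                    (not is_missing(a)) and (not is_missing(b)) and a != b
                    for a, b in zip(my, theirs)
                ):
                    ok = False
                    break
            if ok:
                found = window
                break
            try:
                window = expand_window(window, hb_map)
            except CannotExpandError:
                break
        result[me] = found
    return result
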