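"""Extended shared-haplotype segments, pedigree IBD tracing, IBS threshold.

Two homologs that carry the same haplotype pattern over the locus anchor
window may be identical by descent (a documented chain of parent-child
transmissions connects them) or merely identical by state. Confidence in an
IBS match comes from the genetic length of the maximal contiguous run of
equal codes around the anchor: an IBS match is only accepted when that run is
at least as long as the shortest run ever observed for an IBD match, the
empirically derived threshold.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Sequence

from .model import HaploblockMap, HaplotypeSet, Pedigree, is_missing
from .placement import Window

log = logging.getLogger(__name__)

#: published cross-crop fallback for the IBS acceptance threshold, cM
DEFAULT_IBS_THRESHOLD_CM = 9.4


class _NotEvaluable:
    """Anchor codes are MISSING on a homolog: sharing cannot be judged."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "NOT_EVALUABLE"

    def __bool__(self):
        return False


NOT_EVALUABLE = _NotEvaluable()


@dataclass(frozen=True)
class SharedSegment:
    individual_a: str
    homolog_a: int
    individual_b: str
    homolog_b: int
    first_hb: str
    last_hb: str
    length_cm: float


@dataclass(frozen=True)
class IbdPath:
    """Chain of individuals from query to source, all carrying the anchor pattern.

    Consecutive members are parent/child; carrying_homolog[i] is the homolog
    on which chain[i] carries the pattern.
    """

    chain: tuple[str, ...]
    carrying_homologs: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.chain) - 1


def anchor_pattern(
    individual: str, homolog: int, window: Window, haplotypes: HaplotypeSet
) -> tuple:
    """Code tuple over the anchor window (may contain MISSING)."""
    return tuple(haplotypes.code(individual, homolog, hb) for hb in window.hb_ids)


def _pattern_complete(codes: Sequence) -> bool:
    return not any(is_missing(c) for c in codes)


def shared_run(
    a: str,
    hom_a: int,
    b: str,
    hom_b: int,
    anchor_window: Window,
    haplotypes: HaplotypeSet,
    hb_map: HaploblockMap,
    bridge_missing: int = 0,
):
    """Maximal contiguous run of equal codes around the anchor window.

    Returns NOT_EVALUABLE if either homolog has a MISSING code inside the
    anchor window, None if any anchor code differs, otherwise the maximal
    extension left and right where codes remain equal and non-MISSING.
    `bridge_missing` optionally allows skipping up to that many consecutive
    haploblocks where either code is MISSING, provided matching resumes
    beyond them; by default MISSING terminates extension.
    """
    codes_a = anchor_pattern(a, hom_a, anchor_window, haplotypes)
    codes_b = anchor_pattern(b, hom_b, anchor_window, haplotypes)
    if not _pattern_complete(codes_a) or not _pattern_complete(codes_b):
        return NOT_EVALUABLE
    if any(ca != cb for ca, cb in zip(codes_a, codes_b)):
        return None
    blocks = hb_map.blocks(anchor_window.chromosome)
    ids = [blk.id for blk in blocks]
    first = ids.index(anchor_window.hb_ids[0])
    last = ids.index(anchor_window.hb_ids[-1])

    def matches(i: int) -> bool | None:
        ca = haplotypes.code(a, hom_a, ids[i])
        cb = haplotypes.code(b, hom_b, ids[i])
        if is_missing(ca) or is_missing(cb):
            return None  # unobserved, bridgeable
        return ca == cb

    def extend(start: int, step: int) -> int:
        pos = start
        i = start + step
        gap = 0
        while 0 <= i < len(ids):
            m = matches(i)
            if m is True:
                pos = i
                gap = 0
            elif m is None and gap < bridge_missing:
                gap += 1
            else:
                break
            i += step
        return pos

    lo = extend(first, -1)
    hi = extend(last, +1)
    length = blocks[hi].gen_end - blocks[lo].gen_start
    return SharedSegment(
        individual_a=a,
        homolog_a=hom_a,
        individual_b=b,
        homolog_b=hom_b,
        first_hb=ids[lo],
        last_hb=ids[hi],
        length_cm=length,
    )


def _carrying_homologs(
    individual: str, window: Window, haplotypes: HaplotypeSet, pattern: tuple
) -> list[int]:
    out = []
    for hom in (1, 2):
        codes = anchor_pattern(individual, hom, window, haplotypes)
        if _pattern_complete(codes) and all(
            c == p for c, p in zip(codes, pattern)
        ):
            out.append(hom)
    return out


def ibd_path(
    individual: str,
    homolog: int,
    source: str,
    source_homolog: int,
    pedigree: Pedigree,
    haplotypes: HaplotypeSet,
    anchor_window: Window,
    max_generations: int = 10,
) -> IbdPath | None:
    """Shortest ancestor chain transmitting the anchor pattern, or None.

    Breadth-first search from the query individual up through parents; a
    chain qualifies when every member carries the query homolog's anchor
    pattern on some homolog and consecutive members are parent/child. Only
    the anchor-window pattern must be preserved along the chain, not the
    full extended segment — recombination is free to shorten the flanks.
    Depth-capped to bound cost on dense pedigrees.
    """
    if individual not in pedigree or source not in pedigree:
        return None
    pattern = anchor_pattern(individual, homolog, anchor_window, haplotypes)
    if not _pattern_complete(pattern):
        return None
    if not _carrying_homologs(source, anchor_window, haplotypes, pattern) and not (
        source == individual
    ):
        return None
    if individual == source:
        return IbdPath(chain=(individual,), carrying_homologs=(homolog,))
    queue = deque([(individual, (individual,), (homolog,))])
    seen = {individual}
    while queue:
        current, chain, homs = queue.popleft()
        if len(chain) - 1 >= max_generations:
            continue
        for parent in sorted(pedigree.named_parents(current)):
            if parent in seen:
                continue
            carrying = _carrying_homologs(parent, anchor_window, haplotypes, pattern)
            if not carrying:
                continue
            if parent == source:
                hom = (
                    source_homolog
                    if source_homolog in carrying
                    else carrying[0]
                )
                if source_homolog not in carrying:
                    continue
                return IbdPath(chain=chain + (parent,), carrying_homologs=homs + (hom,))
            seen.add(parent)
            queue.append((parent, chain + (parent,), homs + (carrying[0],)))
    return None


def compute_ibs_threshold(
    ibd_lengths_cm: Sequence[float],
    default: float = DEFAULT_IBS_THRESHOLD_CM,
) -> float:
    """Minimum shared-segment length among IBD-mode deductions, in cM.

    The threshold is global across all loci analyzed together. With no IBD
    entries the configured default is returned and a warning logged.
    """
    lengths = [x for x in ibd_lengths_cm if x is not None]
    if not lengths:
        log.warning(
            "no IBD-mode deductions available; falling back to default "
            "IBS threshold of %.1f cM",
            default,
        )
        return default
    return min(lengths)
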