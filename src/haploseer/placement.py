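"""Placing a target locus on the haploblock map and growing pattern windows.

A locus either falls *within* a haploblock (its physical interval intersects
the block's) or *between* two physically adjacent blocks. The haplotype
pattern used to tag its alleles starts from the block(s) of that placement
and grows outward one haploblock at a time, keeping the genetic length on the
two sides of the locus as balanced as possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .model import Haploblock, HaploblockMap, StructuralError, TargetLocus


class PlacementKind(Enum):
    WITHIN = "WITHIN"
    BETWEEN = "BETWEEN"


class OutOfCoverageError(ValueError):
    """Locus lies before the first or after the last haploblock.

    The deduction method needs flanking haplotypes on both sides, so loci
    outside the mapped span cannot be anchored.
    """


class CannotExpandError(ValueError):
    """The window already spans the whole chromosome."""


@dataclass(frozen=True)
class Placement:
    locus: TargetLocus
    kind: PlacementKind
    within_hb: str | None = None
    left_hb: str | None = None
    right_hb: str | None = None

    def anchor_hbs(self) -> tuple[str, ...]:
        if self.kind is PlacementKind.WITHIN:
            return (self.within_hb,)
        return (self.left_hb, self.right_hb)


@dataclass(frozen=True)
class Window:
    """A contiguous run of haploblocks containing the placement anchor."""

    chromosome: str
    hb_ids: tuple[str, ...]
    anchor: Placement

    def __len__(self) -> int:
        return len(self.hb_ids)

    def __contains__(self, hb_id: str) -> bool:
        return hb_id in self.hb_ids


def place_locus(locus: TargetLocus, hb_map: HaploblockMap) -> Placement:
    """Locate a locus relative to the haploblock map.

    WITHIN if the locus interval intersects any haploblock's physical
    interval (partial overlap counts); otherwise BETWEEN the two adjacent
    blocks flanking the gap it falls in.
    """
    blocks = hb_map.blocks(locus.chromosome)
    if not blocks:
        raise OutOfCoverageError(f"no haploblocks on chromosome {locus.chromosome}")
    for hb in blocks:
        if locus.phys_start <= hb.phys_end and locus.phys_end >= hb.phys_start:
            return Placement(locus=locus, kind=PlacementKind.WITHIN, within_hb=hb.id)
    if locus.phys_end < blocks[0].phys_start or locus.phys_start > blocks[-1].phys_end:
        raise OutOfCoverageError(
            f"locus {locus.name} at {locus.chromosome}:{locus.phys_start}-"
            f"{locus.phys_end} is outside the mapped span "
            f"[{blocks[0].phys_start}, {blocks[-1].phys_end}]"
        )
    for left, right in zip(blocks, blocks[1:]):
        if left.phys_end < locus.phys_start and locus.phys_end < right.phys_start:
            return Placement(
                locus=locus,
                kind=PlacementKind.BETWEEN,
                left_hb=left.id,
                right_hb=right.id,
            )
    raise StructuralError(
        f"locus {locus.name} spans a haploblock boundary gap ambiguously"
    )


def base_window(placement: Placement, hb_map: HaploblockMap) -> Window:
    """The starting pattern window: the containing block, or the two flanks."""
    return Window(
        chromosome=placement.locus.chromosome,
        hb_ids=placement.anchor_hbs(),
        anchor=placement,
    )


def locus_genetic_position(placement: Placement, hb_map: HaploblockMap) -> float:
    """Genetic position (cM) of the locus, interpolated linearly in bp.

    WITHIN: interpolated inside the containing haploblock; BETWEEN:
    interpolated across the gap, between the left block's gen_end and the
    right block's gen_start. The linkage map never assigns the locus its own
    cM position, so this interpolation defines the center used by the
    balanced window growth.
    """
    locus = placement.locus
    mid = 0.5 * (locus.phys_start + locus.phys_end)
    if placement.kind is PlacementKind.WITHIN:
        hb = hb_map[placement.within_hb]
        if hb.phys_end == hb.phys_start:
            return hb.gen_start
        frac = (mid - hb.phys_start) / (hb.phys_end - hb.phys_start)
        frac = min(max(frac, 0.0), 1.0)
        return hb.gen_start + frac * (hb.gen_end - hb.gen_start)
    left = hb_map[placement.left_hb]
    right = hb_map[placement.right_hb]
    if right.phys_start == left.phys_end:
        return left.gen_end
    frac = (mid - left.phys_end) / (right.phys_start - left.phys_end)
    frac = min(max(frac, 0.0), 1.0)
    return left.gen_end + frac * (right.gen_start - left.gen_end)


def _window_indices(window: Window, hb_map: HaploblockMap) -> tuple[int, int]:
    blocks = hb_map.blocks(window.chromosome)
    ids = [b.id for b in blocks]
    first = ids.index(window.hb_ids[0])
    last = ids.index(window.hb_ids[-1])
    return first, last


def expand_window(window: Window, hb_map: HaploblockMap) -> Window:
    """Grow the window by exactly one haploblock, keeping flanks balanced.

    The side to grow is the one whose post-expansion flanking genetic
    lengths (upstream vs downstream of the locus position) are closest to
    equal. Ties go to the physically nearer candidate block, then to the
    left. At a chromosome end, growth continues on the open side only.
    """
    blocks = hb_map.blocks(window.chromosome)
    first, last = _window_indices(window, hb_map)
    can_left = first > 0
    can_right = last < len(blocks) - 1
    if not can_left and not can_right:
        raise CannotExpandError(
            f"window already covers all of chromosome {window.chromosome}"
        )
    locus_cm = locus_genetic_position(window.anchor, hb_map)
    down = hb_map[window.hb_ids[-1]].gen_end - locus_cm  # downstream flank, cM

    def grown(side: str) -> Window:
        if side == "left":
            ids = (blocks[first - 1].id,) + window.hb_ids
        else:
            ids = window.hb_ids + (blocks[last + 1].id,)
        return Window(chromosome=window.chromosome, hb_ids=ids, anchor=window.anchor)

    if not can_left:
        return grown("right")
    if not can_right:
        return grown("left")
    up_left = locus_cm - blocks[first - 1].gen_start
    up_now = locus_cm - hb_map[window.hb_ids[0]].gen_start
    down_right = blocks[last + 1].gen_end - locus_cm
    imbalance_left = abs(up_left - down)
    imbalance_right = abs(up_now - down_right)
    if imbalance_left < imbalance_right:
        return grown("left")
    if imbalance_right < imbalance_left:
        return grown("right")
    locus_mid = 0.5 * (window.anchor.locus.phys_start + window.anchor.locus.phys_end)
    dist_left = locus_mid - blocks[first - 1].phys_end
    dist_right = blocks[last + 1].phys_start - locus_mid
    if dist_right < dist_left:
        return grown("right")
    return grown("left")


def window_span_cm(window: Window, hb_map: HaploblockMap) -> float:
    """Genetic span of the window: last block's gen_end minus first's gen_start."""
    if not window.hb_ids:
        raise ValueError("empty window")
    return hb_map[window.hb_ids[-1]].gen_end - hb_map[window.hb_ids[0]].gen_start
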