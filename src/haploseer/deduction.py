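"""Deducing locus genotypes for whole germplasm sets via IBD or thresholded IBS.

Every homolog of every individual is compared, over the final assignment
window, to the patterns of the allele map's ancestral sources. A match that
can be traced through the pedigree to the source is accepted as IBD; a match
that cannot is accepted as IBS only when the extended shared haplotype around
the locus is at least as long as the shortest segment observed for any IBD
deduction in the run (the empirically derived threshold). Everything else is
reported UNDEDUCED with a reason, never silently guessed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .assignment import AlleleMap
from .model import HaploblockMap, HaplotypeSet, Pedigree, ReferencePanel, is_missing
from .sharing import (
    DEFAULT_IBS_THRESHOLD_CM,
    NOT_EVALUABLE,
    anchor_pattern,
    compute_ibs_threshold,
    ibd_path,
    shared_run,
)

log = logging.getLogger(__name__)


class Mode(Enum):
    IBD = "IBD"
    IBS = "IBS"
    PANEL = "PANEL"


class UndeducedReason(Enum):
    UNIQUE_PATTERN = "UNIQUE_PATTERN"
    MISSING_DATA = "MISSING_DATA"
    BELOW_THRESHOLD = "BELOW_THRESHOLD"


@dataclass(frozen=True)
class HomologDeduction:
    individual: str
    homolog: int
    allele: str | None
    mode: Mode | None
    source: str | None
    source_homolog: int | None
    shared_cm: float | None
    first_hb: str | None
    last_hb: str | None
    reason: UndeducedReason | None

    @property
    def deduced(self) -> bool:
        return self.allele is not None


@dataclass
class DeductionSummary:
    locus_name: str
    n_individuals: int
    individuals_with_2: int
    individuals_with_1: int
    individuals_with_0: int
    homologs_by_mode: dict[str, int]
    undeduced_by_reason: dict[str, int]
    unassigned_patterns: list[tuple[tuple, int]] = field(default_factory=list)


def _candidate_matches(
    codes: tuple, allele_map: AlleleMap
) -> list:
    return allele_map.matching_entries(codes)


def deduce_homolog(
    individual: str,
    homolog: int,
    allele_map: AlleleMap,
    haplotypes: HaplotypeSet,
    pedigree: Pedigree,
    hb_map: HaploblockMap,
    threshold: float | None,
    panel: ReferencePanel | None = None,
    ibd_only: bool = False,
) -> HomologDeduction:
    """Deduce the locus allele on one homolog.

    Order of business: MISSING-contaminated pattern -> UNDEDUCED
    (MISSING_DATA); no allele-map match -> UNDEDUCED (UNIQUE_PATTERN); an
    IBD-traceable source wins (tie: shortest pedigree path, then longest
    shared segment, then lexicographic source name); otherwise the source
    with the longest extended shared haplotype is taken as IBS, accepted
    only at or above the threshold. A panel individual's own resolved
    homolog is labelled PANEL. With `ibd_only`, IBS candidates are reported
    as below-threshold regardless of length (used by the first pass that
    derives the threshold).
    """
    window = allele_map.window

    def undeduced(reason):
        return HomologDeduction(
            individual=individual,
            homolog=homolog,
            allele=None,
            mode=None,
            source=None,
            source_homolog=None,
            shared_cm=None,
            first_hb=None,
            last_hb=None,
            reason=reason,
        )

    if panel is not None and (individual, homolog) in allele_map.panel_homolog_alleles:
        allele = allele_map.panel_homolog_alleles[(individual, homolog)]
        return HomologDeduction(
            individual=individual,
            homolog=homolog,
            allele=allele,
            mode=Mode.PANEL,
            source=individual,
            source_homolog=homolog,
            shared_cm=None,
            first_hb=window.hb_ids[0],
            last_hb=window.hb_ids[-1],
            reason=None,
        )

    codes = anchor_pattern(individual, homolog, window, haplotypes)
    if any(is_missing(c) for c in codes):
        return undeduced(UndeducedReason.MISSING_DATA)
    entries = _candidate_matches(codes, allele_map)
    if not entries:
        return undeduced(UndeducedReason.UNIQUE_PATTERN)

    scored = []
    for e in entries:
        if e.source == individual:
            continue  # self-sharing is not evidence
        seg = shared_run(
            individual,
            homolog,
            e.source,
            e.source_homolog,
            window,
            haplotypes,
            hb_map,
        )
        if seg is NOT_EVALUABLE or seg is None:
            continue
        path = ibd_path(
            individual,
            homolog,
            e.source,
            e.source_homolog,
            pedigree,
            haplotypes,
            window,
        )
        scored.append((e, seg, path))
    if not scored:
        return undeduced(UndeducedReason.UNIQUE_PATTERN)

    ibd_candidates = [(e, s, p) for e, s, p in scored if p is not None]
    if ibd_candidates:
        e, seg, path = min(
            ibd_candidates, key=lambda t: (len(t[2]), -t[1].length_cm, t[0].source)
        )
        return HomologDeduction(
            individual=individual,
            homolog=homolog,
            allele=e.allele,
            mode=Mode.IBD,
            source=e.source,
            source_homolog=e.source_homolog,
            shared_cm=seg.length_cm,
            first_hb=seg.first_hb,
            last_hb=seg.last_hb,
            reason=None,
        )

    e, seg, _ = max(scored, key=lambda t: (t[1].length_cm, t[0].source))
    if ibd_only or threshold is None or seg.length_cm < threshold:
        return undeduced(UndeducedReason.BELOW_THRESHOLD)
    return HomologDeduction(
        individual=individual,
        homolog=homolog,
        allele=e.allele,
        mode=Mode.IBS,
        source=e.source,
        source_homolog=e.source_homolog,
        shared_cm=seg.length_cm,
        first_hb=seg.first_hb,
        last_hb=seg.last_hb,
        reason=None,
    )


def deduce_all(
    individuals: Iterable[str],
    allele_map: AlleleMap,
    haplotypes: HaplotypeSet,
    pedigree: Pedigree,
    hb_map: HaploblockMap,
    panel: ReferencePanel | None = None,
    threshold: float | None = None,
) -> tuple[list[HomologDeduction], DeductionSummary]:
    """Two-pass deduction over a germplasm set.

    Pass 1 accepts IBD matches only and derives the IBS threshold as the
    minimum IBD shared length (unless an explicit `threshold` override is
    given); pass 2 re-deduces everything applying IBS at that threshold.
    """
    individuals = sorted(individuals)
    if threshold is None:
        ibd_lengths = []
        for ind in individuals:
            for hom in (1, 2):
                d = deduce_homolog(
                    ind, hom, allele_map, haplotypes, pedigree, hb_map,
                    threshold=None, panel=panel, ibd_only=True,
                )
                if d.mode is Mode.IBD:
                    ibd_lengths.append(d.shared_cm)
        threshold = compute_ibs_threshold(ibd_lengths, DEFAULT_IBS_THRESHOLD_CM)
        log.info("derived IBS acceptance threshold: %.2f cM", threshold)

    rows = [
        deduce_homolog(
            ind, hom, allele_map, haplotypes, pedigree, hb_map,
            threshold=threshold, panel=panel,
        )
        for ind in individuals
        for hom in (1, 2)
    ]

    per_ind = Counter()
    for d in rows:
        if d.deduced:
            per_ind[d.individual] += 1
    n2 = sum(1 for i in individuals if per_ind.get(i, 0) == 2)
    n1 = sum(1 for i in individuals if per_ind.get(i, 0) == 1)
    n0 = len(individuals) - n2 - n1
    by_mode = Counter(d.mode.value for d in rows if d.mode is not None)
    by_reason = Counter(d.reason.value for d in rows if d.reason is not None)
    summary = DeductionSummary(
        locus_name=allele_map.locus_name,
        n_individuals=len(individuals),
        individuals_with_2=n2,
        individuals_with_1=n1,
        individuals_with_0=n0,
        homologs_by_mode=dict(by_mode),
        undeduced_by_reason=dict(by_reason),
        unassigned_patterns=unassigned_pattern_inventory(
            rows, haplotypes, allele_map.window
        ),
    )
    return rows, summary


def unassigned_pattern_inventory(
    deductions: Sequence[HomologDeduction],
    haplotypes: HaplotypeSet,
    window,
) -> list[tuple[tuple, int]]:
    """Distinct patterns among UNIQUE_PATTERN homologs with carrier counts.

    Sorted by descending multiplicity (then by codes) — the prioritization
    aid for deciding which unknown haplotypes to DNA-test next.
    """
    counts: Counter = Counter()
    for d in deductions:
        if d.reason is UndeducedReason.UNIQUE_PATTERN:
            codes = anchor_pattern(d.individual, d.homolog, window, haplotypes)
            if not any(is_missing(c) for c in codes):
                counts[codes] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def deductions_to_frame(
    deductions: Sequence[HomologDeduction], locus_name: str
) -> pd.DataFrame:
    """Homolog-level output table (the canonical representation)."""
    return pd.DataFrame(
        [
            {
                "individual": d.individual,
                "locus": locus_name,
                "homolog": d.homolog,
                "allele": d.allele or "",
                "mode": d.mode.value if d.mode else "",
                "source": d.source or "",
                "shared_cM": "" if d.shared_cm is None else round(d.shared_cm, 4),
                "window_first_hb": d.first_hb or "",
                "window_last_hb": d.last_hb or "",
                "reason": d.reason.value if d.reason else "",
            }
            for d in deductions
        ]
    )


def genotype_view(deductions: Sequence[HomologDeduction]) -> dict[str, tuple]:
    """Cultivar-level pivot: individual -> unordered deduced allele pair.

    Single-allele results carry None in the second slot (rendered
    "allele / -" in reports).
    """
    out: dict[str, list] = {}
    for d in deductions:
        out.setdefault(d.individual, [None, None])[d.homolog - 1] = d.allele
    view = {}
    for ind, (a1, a2) in out.items():
        alleles = sorted(a for a in (a1, a2) if a is not None)
        if len(alleles) == 2:
            view[ind] = (alleles[0], alleles[1])
        elif len(alleles) == 1:
            view[ind] = (alleles[0], None)
        else:
            view[ind] = (None, None)
    return view
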