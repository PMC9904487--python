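"""Comparing deduced genotypes to independently reported ones.

Reported genotypes (historic SSR scores, database records, de novo
genotyping) are unordered allele pairs, possibly with the second allele
absent. Comparison is therefore an unordered multiset match per individual;
mismatches are then triaged with pedigree evidence — which relatives share a
homolog across the locus, and which validated allele rides that homolog —
because a reported genotype contradicted by chromosome-scale haplotype
sharing with validated relatives is more likely a historic scoring error
than a double recombination at the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .deduction import HomologDeduction
from .model import HaploblockMap, HaplotypeSet, Pedigree
from .sharing import NOT_EVALUABLE, shared_run


class Status(Enum):
    MATCH = "MATCH"
    PARTIAL = "PARTIAL"
    MISMATCH = "MISMATCH"
    UNTESTABLE = "UNTESTABLE"


@dataclass
class ValidationReport:
    rows: pd.DataFrame
    accuracy: float  # matched deduced alleles / validatable deduced alleles
    n_matched_alleles: int
    n_validatable_alleles: int

    def status_of(self, individual: str) -> Status:
        r = self.rows[self.rows["individual"] == individual]
        if r.empty:
            raise KeyError(individual)
        return Status(r.iloc[0]["status"])

    def individuals_with(self, status: Status) -> list[str]:
        return sorted(self.rows[self.rows["status"] == status.value]["individual"])


def _deduced_genotypes(
    deductions: Sequence[HomologDeduction],
) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for d in deductions:
        out.setdefault(d.individual, [])
        if d.allele is not None:
            out[d.individual].append(d.allele)
    return out


def compare_genotypes(
    deductions: Sequence[HomologDeduction],
    reported: Mapping[str, tuple[str | None, str | None]],
) -> ValidationReport:
    """Unordered comparison of deduced vs reported genotypes.

    Statuses partition the individuals appearing in either table:
    MATCH — every deduced allele pairs off against the reported pair and
    both alleles were deduced and reported; PARTIAL — fewer than two alleles
    on one side, but everything comparable agrees; MISMATCH — at least one
    deduced allele has no counterpart in the reported genotype (or vice
    versa when both sides are complete); UNTESTABLE — deduction or report
    absent. Accuracy = matched deduced alleles / validatable deduced
    alleles, over individuals with both a deduction and a report.
    """
    deduced = _deduced_genotypes(deductions)
    rows = []
    matched_total = 0
    validatable_total = 0
    for ind in sorted(set(deduced) | set(reported)):
        ded = sorted(deduced.get(ind, []))
        rep = sorted(a for a in reported.get(ind, (None, None)) if a)
        if not ded or not rep:
            status = Status.UNTESTABLE
        else:
            rem = list(rep)
            matched = 0
            for a in ded:
                if a in rem:
                    rem.remove(a)
                    matched += 1
            validatable_total += len(ded)
            matched_total += matched
            if matched < len(ded) or (len(ded) == 2 and len(rep) == 2 and rem):
                status = Status.MISMATCH
            elif len(ded) == 2 and len(rep) == 2:
                status = Status.MATCH
            else:
                status = Status.PARTIAL
        rows.append(
            {
                "individual": ind,
                "deduced": "/".join(ded) if ded else "-",
                "reported": "/".join(rep) if rep else "-",
                "status": status.value,
            }
        )
    df = pd.DataFrame(rows, columns=["individual", "deduced", "reported", "status"])
    accuracy = matched_total / validatable_total if validatable_total else float("nan")
    return ValidationReport(
        rows=df,
        accuracy=accuracy,
        n_matched_alleles=matched_total,
        n_validatable_alleles=validatable_total,
    )


def triage_mismatch(
    individual: str,
    deductions: Sequence[HomologDeduction],
    pedigree: Pedigree,
    haplotypes: HaplotypeSet,
    hb_map: HaploblockMap,
    anchor_window,
    validated_reports: Mapping[str, tuple[str | None, str | None]],
    report: ValidationReport | None = None,
) -> pd.DataFrame:
    """Pedigree evidence table for one mismatching individual.

    For every parent, sibling (sharing >= 1 named parent, half-sibs
    included) and offspring, and every homolog pair, reports whether a
    homolog is shared across the locus, the shared cM, the relative's
    deduced allele on the shared homolog, and the relative's reported
    genotype. Evidence only — the likely-reporting-error verdict is the
    user's call.
    """
    if report is not None and report.status_of(individual) is not Status.MISMATCH:
        raise ValueError(f"{individual} is not a MISMATCH case")
    by_key = {(d.individual, d.homolog): d for d in deductions}
    relatives: list[tuple[str, str]] = []
    if individual in pedigree:
        relatives += [(p, "parent") for p in pedigree.named_parents(individual)]
        relatives += [(s, "sibling") for s in pedigree.siblings(individual)]
        relatives += [(c, "offspring") for c in pedigree.children(individual)]
    rows = []
    for rel, relation in relatives:
        if rel not in haplotypes:
            continue
        for my_hom in (1, 2):
            for rel_hom in (1, 2):
                seg = shared_run(
                    individual, my_hom, rel, rel_hom, anchor_window, haplotypes, hb_map
                )
                if seg is None or seg is NOT_EVALUABLE:
                    continue
                rel_ded = by_key.get((rel, rel_hom))
                rep = validated_reports.get(rel)
                rows.append(
                    {
                        "relative": rel,
                        "relation": relation,
                        "own_homolog": my_hom,
                        "relative_homolog": rel_hom,
                        "shared_cM": round(seg.length_cm, 4),
                        "shared_first_hb": seg.first_hb,
                        "shared_last_hb": seg.last_hb,
                        "relative_allele_on_homolog": (
                            rel_ded.allele if rel_ded and rel_ded.allele else ""
                        ),
                        "relative_reported": (
                            "/".join(a for a in rep if a) if rep else ""
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "relative",
            "relation",
            "own_homolog",
            "relative_homolog",
            "shared_cM",
            "shared_first_hb",
            "shared_last_hb",
            "relative_allele_on_homolog",
            "relative_reported",
        ],
    ).sort_values(["shared_cM"], ascending=False, ignore_index=True)


def load_reported_genotypes(path) -> dict[str, tuple[str | None, str | None]]:
    """Read a reported-genotype TSV (individual, allele1, allele2)."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=["", "NA"]
    )
    out = {}
    for row in df.itertuples(index=False):
        a1 = row.allele1 if isinstance(row.allele1, str) and row.allele1 else None
        a2 = row.allele2 if isinstance(row.allele2, str) and row.allele2 else None
        out[row.individual] = (a1, a2)
    return out


def write_reported_genotypes(
    reported: Mapping[str, tuple[str | None, str | None]], path
) -> None:
    rows = [
        {"individual": ind, "allele1": a1 or "", "allele2": a2 or ""}
        for ind, (a1, a2) in sorted(reported.items())
    ]
    pd.DataFrame(rows, columns=["individual", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )
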