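"""Tab-separated readers and writers for the haplotype-sharing pipeline.

Dialect: UTF-8, tab-separated, header row required; "NA" and the empty string
both denote missing/unknown. This matches typical breeding-database exports
(PediHaplotyper / FlexQTL style long tables).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .model import (
    UNREPORTED,
    FormatError,
    Haploblock,
    HaploblockMap,
    HaplotypeSet,
    Pedigree,
    ReferencePanel,
    ReferenceError_,
)

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=_NA_VALUES
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def load_haploblock_map(path) -> HaploblockMap:
    """Read a haploblock map table and validate its coordinate structure.

    Columns: chromosome, haploblock, phys_start, phys_end, gen_start,
    gen_end, optionally snp_ids (";"-joined) and n_snps. Rows may arrive in
    any order; blocks are sorted by physical start, but a genuine physical
    overlap or a genetic/physical order contradiction is a structural error.
    """
    df = _read_tsv(
        path,
        ["chromosome", "haploblock", "phys_start", "phys_end", "gen_start", "gen_end"],
    )
    blocks = []
    for row in df.itertuples(index=False):
        snp_ids: tuple[str, ...] = ()
        if "snp_ids" in df.columns and isinstance(row.snp_ids, str) and row.snp_ids:
            snp_ids = tuple(row.snp_ids.split(";"))
        try:
            blocks.append(
                Haploblock(
                    id=row.haploblock,
                    chromosome=row.chromosome,
                    phys_start=int(row.phys_start),
                    phys_end=int(row.phys_end),
                    gen_start=float(row.gen_start),
                    gen_end=float(row.gen_end),
                    snp_ids=snp_ids,
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"{path}: bad coordinates in row {row!r}: {exc}") from exc
    hb_map = HaploblockMap(blocks)
    for chrom, (n_hb, n_snp) in sorted(hb_map.counts().items()):
        log.info("chromosome %s: %d haploblocks, %d SNPs", chrom, n_hb, n_snp)
    return hb_map


def write_haploblock_map(hb_map: HaploblockMap, path) -> None:
    rows = [
        {
            "chromosome": hb.chromosome,
            "haploblock": hb.id,
            "phys_start": hb.phys_start,
            "phys_end": hb.phys_end,
            "gen_start": hb.gen_start,
            "gen_end": hb.gen_end,
            "n_snps": hb.n_snps,
            "snp_ids": ";".join(hb.snp_ids),
        }
        for hb in hb_map
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_phased_haplotypes(path, hb_map: HaploblockMap) -> HaplotypeSet:
    """Read a long-format phased-haplotype table against a validated map.

    Columns: individual, haploblock, homolog, code. Unlisted
    (individual, haploblock, homolog) cells are MISSING; rows with a missing
    code field are treated as explicit MISSING cells and skipped.
    """
    df = _read_tsv(path, ["individual", "haploblock", "homolog", "code"])
    hs = HaplotypeSet()
    for row in df.itertuples(index=False):
        if row.haploblock not in hb_map:
            raise ReferenceError_(
                f"{path}: haploblock {row.haploblock!r} not present in map"
            )
        try:
            hom = int(row.homolog)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: homolog {row.homolog!r} is not an integer")
        if hom not in (1, 2):
            raise FormatError(f"{path}: homolog must be 1 or 2, got {hom}")
        hs.add_individual(row.individual)
        if isinstance(row.code, str) and row.code:
            hs.set_code(row.individual, hom, row.haploblock, row.code)
    return hs


def write_phased_haplotypes(hs: HaplotypeSet, path) -> None:
    rows = [
        {"individual": ind, "haploblock": hb, "homolog": hom, "code": code}
        for (ind, hom, hb), code in sorted(hs.items())
    ]
    pd.DataFrame(rows, columns=["individual", "haploblock", "homolog", "code"]).to_csv(
        path, sep="\t", index=False
    )


def load_pedigree(path) -> Pedigree:
    """Read a pedigree table (individual, mother, father; NA/empty = unknown).

    Parents named but not listed as individuals are auto-created as founders.
    """
    df = _read_tsv(path, ["individual", "mother", "father"])
    parents = {}
    for row in df.itertuples(index=False):
        mother = row.mother if isinstance(row.mother, str) and row.mother else None
        father = row.father if isinstance(row.father, str) and row.father else None
        parents[row.individual] = (mother, father)
    return Pedigree(parents)


def write_pedigree(ped: Pedigree, path) -> None:
    rows = []
    for ind in ped.individuals:
        mother, father = ped.parents(ind)
        rows.append(
            {"individual": ind, "mother": mother or "NA", "father": father or "NA"}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference_panel(path, locus_name: str) -> ReferencePanel:
    """Read reported locus genotypes (individual, allele1, allele2).

    A blank allele2 is stored as UNREPORTED: only one homolog of that
    individual will ever be assignable from the panel.
    """
    df = _read_tsv(path, ["individual", "allele1", "allele2"])
    panel = ReferencePanel(locus_name=locus_name)
    for row in df.itertuples(index=False):
        a2 = row.allele2 if isinstance(row.allele2, str) and row.allele2 else UNREPORTED
        panel.add(row.individual, row.allele1, a2)
    return panel


def write_reference_panel(panel: ReferencePanel, path) -> None:
    rows = []
    for ind in panel.individuals:
        a1, a2 = panel.alleles_of(ind)
        rows.append({"individual": ind, "allele1": a1, "allele2": a2 or ""})
    pd.DataFrame(rows, columns=["individual", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
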