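"""End-to-end pipeline (locate -> assign -> deduce -> validate) with manifest.

Runs the stages in order on file inputs, writes all artifact TSVs and a JSON
run manifest recording input checksums, parameters and the tool version so a
run is reproducible and auditable. UNDEDUCED outcomes are ordinary results;
only structural problems (missing files, invalid inputs) raise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .assignment import assign_alleles
from .deduction import deduce_all, deductions_to_frame
from .io import (
    ensure_dir,
    load_haploblock_map,
    load_pedigree,
    load_phased_haplotypes,
    load_reference_panel,
)
from .model import TargetLocus
from .placement import base_window, place_locus
from .validation import (
    Status,
    compare_genotypes,
    load_reported_genotypes,
    triage_mismatch,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    map_path: str
    haplotypes_path: str
    pedigree_path: str
    panel_path: str
    locus_name: str
    chromosome: str
    pos_start: int
    pos_end: int | None = None
    reported_path: str | None = None
    threshold: float | None = None  # None -> derive from IBD minimum
    bridge_missing: int = 0
    out_dir: str = "out"
    triage: bool = False

    def validate(self) -> None:
        errors = []
        for attr in ("map_path", "haplotypes_path", "pedigree_path", "panel_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                errors.append(f"{attr}: file not found: {p}")
        if self.threshold is not None and self.threshold < 0:
            errors.append(f"threshold must be >= 0, got {self.threshold}")
        if errors:
            raise ValueError("; ".join(errors))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full deduction pipeline; returns the manifest dict."""
    config.validate()
    out = ensure_dir(config.out_dir)

    log.info("[load] reading inputs")
    hb_map = load_haploblock_map(config.map_path)
    haplotypes = load_phased_haplotypes(config.haplotypes_path, hb_map)
    pedigree = load_pedigree(config.pedigree_path)
    panel = load_reference_panel(config.panel_path, config.locus_name)

    log.info("[locate] placing locus %s", config.locus_name)
    locus = TargetLocus(
        name=config.locus_name,
        chromosome=config.chromosome,
        phys_start=config.pos_start,
        phys_end=config.pos_end if config.pos_end is not None else config.pos_start,
    )
    placement = place_locus(locus, hb_map)

    log.info("[assign] associating panel alleles with haplotype patterns")
    amap = assign_alleles(panel, haplotypes, pedigree, placement, hb_map)
    amap_rows = [
        {
            "pattern": ";".join(str(c) for c in e.codes),
            "window_first_hb": amap.window.hb_ids[0],
            "window_last_hb": amap.window.hb_ids[-1],
            "allele": e.allele,
            "source": e.source,
            "source_homolog": e.source_homolog,
        }
        for e in amap.entries
    ]
    pd.DataFrame(
        amap_rows,
        columns=[
            "pattern", "window_first_hb", "window_last_hb",
            "allele", "source", "source_homolog",
        ],
    ).to_csv(out / "allele_map.tsv", sep="\t", index=False)

    log.info("[deduce] deducing genotypes for %d individuals", len(haplotypes.individuals))
    deds, summary = deduce_all(
        haplotypes.individuals, amap, haplotypes, pedigree, hb_map,
        panel=panel, threshold=config.threshold,
    )
    deductions_to_frame(deds, config.locus_name).to_csv(
        out / "deductions.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "locus": summary.locus_name,
                "n_individuals": summary.n_individuals,
                "individuals_with_2": summary.individuals_with_2,
                "individuals_with_1": summary.individuals_with_1,
                "individuals_with_0": summary.individuals_with_0,
                **{f"mode_{k}": v for k, v in sorted(summary.homologs_by_mode.items())},
                **{f"reason_{k}": v for k, v in sorted(summary.undeduced_by_reason.items())},
            }
        ]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)

    validation_accuracy = None
    if config.reported_path:
        log.info("[validate] comparing against reported genotypes")
        reported = load_reported_genotypes(config.reported_path)
        report = compare_genotypes(deds, reported)
        report.rows.to_csv(out / "validation.tsv", sep="\t", index=False)
        validation_accuracy = report.accuracy
        if config.triage:
            window = base_window(placement, hb_map)
            for ind in report.individuals_with(Status.MISMATCH):
                ev = triage_mismatch(
                    ind, deds, pedigree, haplotypes, hb_map, window, reported, report
                )
                safe = ind.replace("/", "_").replace(" ", "_")
                ev.to_csv(out / f"triage_{safe}.tsv", sep="\t", index=False)

    manifest = {
        "tool": "haploseer",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in {
                "map": config.map_path,
                "haplotypes": config.haplotypes_path,
                "pedigree": config.pedigree_path,
                "panel": config.panel_path,
                **({"reported": config.reported_path} if config.reported_path else {}),
            }.items()
        },
        "placement": {
            "kind": placement.kind.value,
            "anchor_hbs": list(placement.anchor_hbs()),
        },
        "final_window": list(amap.window.hb_ids),
        "validation_accuracy": validation_accuracy,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
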