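"""Allele-to-haplotype-pattern assignment and ancestral-source tracing."""

from __future__ import annotations

import numpy as np
import pytest

from haploseer import (
    MISSING,
    HaplotypeSet,
    Pedigree,
    ReferencePanel,
    TargetLocus,
    assign_alleles,
    base_window,
    find_ancestral_source,
    minimal_discriminating_window,
    pattern_of,
    place_locus,
)
from haploseer.sharing import anchor_pattern

from conftest import expansion_chain, make_uniform_map, set_homolog


def mid_locus(hb_map, chromosome="chrT", block_index=None):
    blocks = hb_map.blocks(chromosome)
    i = len(blocks) // 2 if block_index is None else block_index
    blk = blocks[i]
    bp = (blk.phys_start + blk.phys_end) // 2
    return place_locus(TargetLocus("L", chromosome, bp, bp), hb_map)


class TestHaplotypePattern:
    def test_missing_blocks_matching(self, uniform_map):
        hs = HaplotypeSet()
        set_homolog(hs, "a", 1, uniform_map, "chrT", ["1"] * 10)
        set_homolog(hs, "b", 1, uniform_map, "chrT", ["1"] * 9 + [None])
        placement = mid_locus(uniform_map, block_index=9)
        w = base_window(placement, uniform_map)
        pa = pattern_of("a", 1, w, hs)
        pb = pattern_of("b", 1, w, hs)
        assert pa.matches(pa)
        assert not pb.matches(pb)  # MISSING never equals anything
        assert not pa.matches(pb) and not pb.matches(pa)

    def test_all_missing_pattern_unusable(self, uniform_map):
        hs = HaplotypeSet()
        hs.add_individual("ghost")
        w = base_window(mid_locus(uniform_map), uniform_map)
        p = pattern_of("ghost", 1, w, hs)
        assert not p.is_complete
        assert all(c is MISSING for c in p.codes)

    def test_equality_depends_on_window_identity(self, uniform_map):
        hs = HaplotypeSet()
        set_homolog(hs, "a", 1, uniform_map, "chrT", ["1"] * 10)
        w1 = base_window(mid_locus(uniform_map, block_index=4), uniform_map)
        w2 = base_window(mid_locus(uniform_map, block_index=5), uniform_map)
        assert not pattern_of("a", 1, w1, hs).matches(pattern_of("a", 1, w2, hs))


class TestAssignAlleles:
    def test_homozygote_forces_base_assignment(self, uniform_map):
        """AA with patterns (p,p) plus AB with (p,q) pins A<->p and B<->q."""
        hs = HaplotypeSet()
        set_homolog(hs, "hom", 1, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "hom", 2, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "het", 1, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "het", 2, uniform_map, "chrT", ["q"] * 10)
        panel = ReferencePanel("L")
        panel.add("hom", "A", "A")
        panel.add("het", "A", "B")
        ped = Pedigree({"hom": (None, None), "het": (None, None)})
        placement = mid_locus(uniform_map)
        amap = assign_alleles(panel, hs, ped, placement, uniform_map)
        assert len(amap.window) == 1  # no conflict, no expansion
        by_pattern = {e.codes[0]: e.allele for e in amap.entries}
        assert by_pattern == {"p": "A", "q": "B"}
        assert amap.unresolved == []

    def test_conflicting_pattern_triggers_window_expansion(self, uniform_map):
        """Two alleles on the same base pattern separate after expansion."""
        hs = HaplotypeSet()
        for hom in (1, 2):
            set_homolog(hs, "X", hom, uniform_map, "chrT", list("1111111111"))
            set_homolog(hs, "Y", hom, uniform_map, "chrT", list("2221112222"))
        panel = ReferencePanel("L")
        panel.add("X", "A", "A")
        panel.add("Y", "B", "B")
        ped = Pedigree({"X": (None, None), "Y": (None, None)})
        placement = mid_locus(uniform_map)  # within block index 5
        amap = assign_alleles(panel, hs, ped, placement, uniform_map)
        assert len(amap.window) > 1
        assert amap.allele_of(anchor_pattern("X", 1, amap.window, hs)) == "A"
        assert amap.allele_of(anchor_pattern("Y", 1, amap.window, hs)) == "B"
        assert amap.unresolved == []
        # pattern -> allele is a function
        seen = {}
        for e in amap.entries:
            assert seen.setdefault(e.codes, e.allele) == e.allele

    def test_pedigree_resolves_heterozygote_homolog(self, uniform_map):
        """With no homozygote anchor for one allele, an informative parent
        decides which homolog carries the shared allele."""
        hs = HaplotypeSet()
        set_homolog(hs, "parent", 1, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "parent", 2, uniform_map, "chrT", ["r"] * 10)
        set_homolog(hs, "kid", 1, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "kid", 2, uniform_map, "chrT", ["q"] * 10)
        panel = ReferencePanel("L")
        panel.add("parent", "A", "C")  # heterozygous: no homozygote anchor
        panel.add("kid", "A", "B")  # shares exactly allele A with parent
        ped = Pedigree({"kid": ("parent", None), "parent": (None, None)})
        placement = mid_locus(uniform_map)
        amap = assign_alleles(panel, hs, ped, placement, uniform_map)
        assert amap.panel_homolog_alleles[("kid", 1)] == "A"
        assert amap.panel_homolog_alleles[("kid", 2)] == "B"
        # and propagation then resolves the parent's other homolog
        assert amap.panel_homolog_alleles[("parent", 1)] == "A"
        assert amap.panel_homolog_alleles[("parent", 2)] == "C"

    def test_simulated_panel_recovers_truth(self, unique_sim):
        ds = unique_sim
        amap = assign_alleles(ds.panel, ds.haplotypes, ds.pedigree,
                              ds.placement, ds.hb_map)
        for (ind, hom), allele in amap.panel_homolog_alleles.items():
            assert allele == ds.truth.allele[(ind, hom)]
        # conservation: every panel allele mapped or listed unresolved
        for ind in ds.panel.individuals:
            a1, a2 = ds.panel.alleles_of(ind)
            resolved = [amap.panel_homolog_alleles.get((ind, h)) for h in (1, 2)]
            listed = [a for i, a, _ in amap.unresolved if i == ind]
            remaining = [a for a in (a1, a2) if a is not None]
            for r in resolved:
                if r in remaining:
                    remaining.remove(r)
            assert sorted(remaining) == sorted(listed)

    def test_idempotent_on_own_sources(self, unique_sim):
        """Re-running assignment with the resolved panel reproduces the map."""
        ds = unique_sim
        amap = assign_alleles(ds.panel, ds.haplotypes, ds.pedigree,
                              ds.placement, ds.hb_map)
        panel2 = ReferencePanel(ds.panel.locus_name)
        resolved_inds = sorted({i for (i, _h) in amap.panel_homolog_alleles})
        for ind in resolved_inds:
            h1 = amap.panel_homolog_alleles.get((ind, 1))
            h2 = amap.panel_homolog_alleles.get((ind, 2))
            if h1 and h2:
                panel2.add(ind, *sorted((h1, h2)))
        amap2 = assign_alleles(panel2, ds.haplotypes, ds.pedigree,
                               ds.placement, ds.hb_map)
        assert amap2.window.hb_ids == amap.window.hb_ids
        map1 = {(e.codes, e.allele) for e in amap.entries}
        map2 = {(e.codes, e.allele) for e in amap2.entries}
        assert map2 <= map1  # no new or contradictory associations

    def test_skips_panel_individual_without_data(self, uniform_map, caplog):
        import logging

        hs = HaplotypeSet()
        set_homolog(hs, "ok", 1, uniform_map, "chrT", ["p"] * 10)
        set_homolog(hs, "ok", 2, uniform_map, "chrT", ["p"] * 10)
        panel = ReferencePanel("L")
        panel.add("ok", "A", "A")
        panel.add("ghost", "B", "B")
        ped = Pedigree({"ok": (None, None), "ghost": (None, None)})
        with caplog.at_level(logging.WARNING):
            amap = assign_alleles(panel, hs, ped, mid_locus(uniform_map), uniform_map)
        assert "ghost" in caplog.text
        assert [a for i, a, _ in amap.unresolved if i == "ghost"] == ["B", "B"]


class TestAncestralSource:
    def test_founder_is_its_own_source(self, uniform_map):
        hs = HaplotypeSet()
        set_homolog(hs, "f", 1, uniform_map, "chrT", ["u"] * 10)
        ped = Pedigree({"f": (None, None)})
        w = base_window(mid_locus(uniform_map), uniform_map)
        codes = anchor_pattern("f", 1, w, hs)
        assert find_ancestral_source(codes, "f", 1, ped, hs, w) == ("f", 1)

    def test_simulated_transmission_traces_to_founder(self, unique_sim):
        ds = unique_sim
        w = base_window(ds.placement, ds.hb_map)
        non_founders = [i for i in ds.haplotypes.individuals
                        if not ds.pedigree.is_founder(i)]
        for ind in non_founders[:40]:
            for hom in (1, 2):
                codes = anchor_pattern(ind, hom, w, ds.haplotypes)
                src = find_ancestral_source(codes, ind, hom, ds.pedigree,
                                            ds.haplotypes, w)
                # UNIQUE founder codes: the pattern identifies its founder homolog
                assert src == ds.truth.founder_origin[(ind, hom)]


class TestMinimalDiscriminatingWindow:
    def test_base_window_suffices_when_sources_differ(self, uniform_map):
        hs = HaplotypeSet()
        set_homolog(hs, "s1", 1, uniform_map, "chrT", ["1"] * 10)
        set_homolog(hs, "s2", 1, uniform_map, "chrT", ["2"] * 10)
        placement = mid_locus(uniform_map)
        res = minimal_discriminating_window([("s1", 1), ("s2", 1)],
                                            uniform_map, hs, placement)
        assert len(res[("s1", 1)]) == 1 and len(res[("s2", 1)]) == 1

    def test_indistinguishable_sources_reported_none(self, uniform_map):
        hs = HaplotypeSet()
        set_homolog(hs, "s1", 1, uniform_map, "chrT", ["1"] * 10)
        set_homolog(hs, "s2", 1, uniform_map, "chrT", ["1"] * 10)
        placement = mid_locus(uniform_map)
        res = minimal_discriminating_window([("s1", 1), ("s2", 1)],
                                            uniform_map, hs, placement)
        assert res == {("s1", 1): None, ("s2", 1): None}

    def test_matches_exhaustive_enumeration(self, uniform_map):
        """Incremental search equals a scan over the full expansion chain."""
        rng = np.random.default_rng(17)
        placement = mid_locus(uniform_map)
        chain = expansion_chain(placement, uniform_map)
        anchor_idx = 5
        for _ in range(200):
            hs = HaplotypeSet()
            sources = []
            for s in range(3):
                codes = [str(c) for c in rng.integers(1, 3, size=10)]
                codes[anchor_idx] = "1"  # identical at the anchor block
                set_homolog(hs, f"s{s}", 1, uniform_map, "chrT", codes)
                sources.append((f"s{s}", 1))
            res = minimal_discriminating_window(sources, uniform_map, hs, placement)
            for me in sources:
                expected = None
                for w in chain:
                    mine = anchor_pattern(me[0], me[1], w, hs)
                    if all(
                        any(a != b for a, b in zip(
                            mine, anchor_pattern(o[0], o[1], w, hs)))
                        for o in sources if o != me
                    ):
                        expected = w.hb_ids
                        break
                got = res[me].hb_ids if res[me] is not None else None
                assert got == expected
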