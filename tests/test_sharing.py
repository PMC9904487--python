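"""Shared-segment search, IBD tracing, and the IBS threshold."""

from __future__ import annotations

import numpy as np
import pytest

from haploseer import (
    NOT_EVALUABLE,
    HaplotypeSet,
    Pedigree,
    TargetLocus,
    base_window,
    compute_ibs_threshold,
    ibd_path,
    place_locus,
    shared_run,
)

from conftest import make_uniform_map, set_homolog


def brute_force_shared_run(codes_a, codes_b, anchor_lo, anchor_hi):
    """Exhaustive search for the maximal equal, non-missing run containing
    the anchor index range. Returns (lo, hi) block indices or None."""
    n = len(codes_a)

    def block_ok(i):
        return (
            codes_a[i] is not None
            and codes_b[i] is not None
            and codes_a[i] == codes_b[i]
        )

    best = None
    for lo in range(0, anchor_lo + 1):
        for hi in range(anchor_hi, n):
            if all(block_ok(i) for i in range(lo, hi + 1)):
                if best is None or (hi - lo) > (best[1] - best[0]):
                    best = (lo, hi)
    return best


def build_pair(hb_map, codes_a, codes_b):
    hs = HaplotypeSet()
    set_homolog(hs, "a", 1, hb_map, "chrT", codes_a)
    set_homolog(hs, "b", 1, hb_map, "chrT", codes_b)
    return hs


@pytest.fixture
def anchor(uniform_map):
    # locus inside block 5 of 10 -> single-block anchor window at index 4
    blk = uniform_map.blocks("chrT")[4]
    p = place_locus(TargetLocus("L", "chrT", blk.phys_start + 5, blk.phys_start + 5),
                    uniform_map)
    return base_window(p, uniform_map)


class TestSharedRun:
    def test_identical_homologs_span_whole_chromosome(self, uniform_map, anchor):
        hs = build_pair(uniform_map, ["1"] * 10, ["1"] * 10)
        seg = shared_run("a", 1, "b", 1, anchor, hs, uniform_map)
        assert (seg.first_hb, seg.last_hb) == ("HB-chrT-1", "HB-chrT-10")
        assert seg.length_cm == pytest.approx(100.0)

    def test_anchor_difference_gives_none(self, uniform_map, anchor):
        codes_b = ["1"] * 10
        codes_b[4] = "2"
        hs = build_pair(uniform_map, ["1"] * 10, codes_b)
        assert shared_run("a", 1, "b", 1, anchor, hs, uniform_map) is None

    def test_missing_anchor_not_evaluable(self, uniform_map, anchor):
        codes_b = ["1"] * 10
        codes_b[4] = None
        hs = build_pair(uniform_map, ["1"] * 10, codes_b)
        assert shared_run("a", 1, "b", 1, anchor, hs, uniform_map) is NOT_EVALUABLE

    def test_missing_terminates_extension_by_default(self, uniform_map, anchor):
        codes_b = ["1"] * 10
        codes_b[6] = None
        hs = build_pair(uniform_map, ["1"] * 10, codes_b)
        seg = shared_run("a", 1, "b", 1, anchor, hs, uniform_map)
        assert seg.last_hb == "HB-chrT-6"

    def test_bridge_missing_skips_gap(self, uniform_map, anchor):
        codes_b = ["1"] * 10
        codes_b[6] = None
        hs = build_pair(uniform_map, ["1"] * 10, codes_b)
        seg = shared_run("a", 1, "b", 1, anchor, hs, uniform_map, bridge_missing=1)
        assert seg.last_hb == "HB-chrT-10"

    def test_symmetry_in_homolog_arguments(self, uniform_map, anchor):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ca = [str(c) for c in rng.integers(1, 3, size=10)]
            cb = [str(c) for c in rng.integers(1, 3, size=10)]
            cb[4] = ca[4]  # force anchor match
            hs = build_pair(uniform_map, ca, cb)
            s1 = shared_run("a", 1, "b", 1, anchor, hs, uniform_map)
            s2 = shared_run("b", 1, "a", 1, anchor, hs, uniform_map)
            assert (s1.first_hb, s1.last_hb, s1.length_cm) == (
                s2.first_hb, s2.last_hb, s2.length_cm
            )

    def test_matches_brute_force_on_random_fixtures(self, uniform_map, anchor):
        """The incremental extension equals exhaustive maximal-run search."""
        rng = np.random.default_rng(42)
        ids = [b.id for b in uniform_map.blocks("chrT")]
        for _ in range(300):
            ca = [str(c) if rng.random() > 0.15 else None
                  for c in rng.integers(1, 3, size=10)]
            cb = [str(c) if rng.random() > 0.15 else None
                  for c in rng.integers(1, 3, size=10)]
            hs = build_pair(uniform_map, ca, cb)
            seg = shared_run("a", 1, "b", 1, anchor, hs, uniform_map)
            if ca[4] is None or cb[4] is None:
                assert seg is NOT_EVALUABLE
                continue
            expected = brute_force_shared_run(ca, cb, 4, 4)
            if ca[4] != cb[4]:
                assert seg is None
                continue
            lo, hi = expected
            assert (seg.first_hb, seg.last_hb) == (ids[lo], ids[hi])

    def test_segment_always_contains_anchor(self, uniform_map, anchor):
        rng = np.random.default_rng(5)
        ids = [b.id for b in uniform_map.blocks("chrT")]
        for _ in range(100):
            ca = [str(c) for c in rng.integers(1, 4, size=10)]
            cb = list(ca)
            hs = build_pair(uniform_map, ca, cb)
            seg = shared_run("a", 1, "b", 1, anchor, hs, uniform_map)
            assert ids.index(seg.first_hb) <= 4 <= ids.index(seg.last_hb)


class TestIbdPath:
    def test_child_carrying_parental_homolog_is_one_link(self, uniform_map, anchor,
                                                         trio_pedigree):
        hs = HaplotypeSet()
        set_homolog(hs, "mother", 1, uniform_map, "chrT", ["9"] * 10)
        set_homolog(hs, "child", 1, uniform_map, "chrT", ["9"] * 10)
        path = ibd_path("child", 1, "mother", 1, trio_pedigree, hs, anchor)
        assert path.chain == ("child", "mother")
        assert len(path) == 1

    def test_broken_transmission_gives_none(self, uniform_map, anchor):
        ped = Pedigree({"gc": ("c", None), "c": ("gm", None), "gm": (None, None)})
        hs = HaplotypeSet()
        set_homolog(hs, "gm", 1, uniform_map, "chrT", ["9"] * 10)
        set_homolog(hs, "c", 1, uniform_map, "chrT", ["8"] * 10)  # did not inherit
        set_homolog(hs, "gc", 1, uniform_map, "chrT", ["9"] * 10)
        assert ibd_path("gc", 1, "gm", 1, ped, hs, anchor) is None

    def test_path_implies_shared_run(self, unique_sim):
        """Wherever a pedigree path exists, the two endpoint homologs share a
        segment over the anchor window."""
        ds = unique_sim
        from haploseer import base_window

        window = base_window(ds.placement, ds.hb_map)
        checked = 0
        for ind in ds.haplotypes.individuals[:80]:
            for hom in (1, 2):
                founder, fhom = ds.truth.founder_origin[(ind, hom)]
                if founder == ind:
                    continue
                path = ibd_path(ind, hom, founder, fhom, ds.pedigree,
                                ds.haplotypes, window)
                if path is None:
                    continue
                seg = shared_run(ind, hom, founder, fhom, window,
                                 ds.haplotypes, ds.hb_map)
                assert seg is not None and seg is not NOT_EVALUABLE
                checked += 1
        assert checked > 50

    def test_paths_match_simulated_transmission_chains(self, unique_sim):
        """Returned paths are shortest qualifying chains and agree with the
        simulator's true transmission chain when that chain is the unique
        shortest route."""
        ds = unique_sim
        from haploseer import base_window
        from haploseer.sharing import anchor_pattern

        window = base_window(ds.placement, ds.hb_map)

        def qualifying_chains(ind, pattern, target, maxlen):
            """All parent-chains ind->target of length <= maxlen whose members
            carry the pattern (exhaustive oracle)."""
            out = []

            def carrier(x):
                return any(
                    all(a == b for a, b in zip(
                        anchor_pattern(x, h, window, ds.haplotypes), pattern))
                    for h in (1, 2)
                )

            def walk(chain):
                cur = chain[-1]
                if cur == target:
                    out.append(tuple(chain))
                    return
                if len(chain) > maxlen:
                    return
                for p in ds.pedigree.named_parents(cur):
                    if carrier(p):
                        walk(chain + [p])

            walk([ind])
            return out

        n_equal = n_total = 0
        non_founders = [i for i in ds.haplotypes.individuals
                        if not ds.pedigree.is_founder(i)]
        for ind in non_founders[:60]:
            for hom in (1, 2):
                founder, fhom = ds.truth.founder_origin[(ind, hom)]
                if founder == ind:
                    continue
                pattern = anchor_pattern(ind, hom, window, ds.haplotypes)
                path = ibd_path(ind, hom, founder, fhom, ds.pedigree,
                                ds.haplotypes, window)
                truth_chain = ds.truth.chain[(ind, hom)]
                assert path is not None
                chains = qualifying_chains(ind, pattern, founder, len(truth_chain))
                assert tuple(path.chain) in chains
                shortest = min(len(c) for c in chains)
                assert len(path.chain) == shortest
                uniques = [c for c in chains if len(c) == shortest]
                n_total += 1
                if len(uniques) == 1 and len(truth_chain) == shortest:
                    assert path.chain == truth_chain
                    n_equal += 1
        assert n_total > 40 and n_equal > 0


class TestIbsThreshold:
    def test_exact_minimum(self):
        assert compute_ibs_threshold([12.0, 9.4, 68.2]) == 9.4
        assert compute_ibs_threshold([5.5]) == 5.5

    def test_default_when_no_ibd(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert compute_ibs_threshold([]) == 9.4
        assert "default" in caplog.text

    def test_planted_minimum_recovered(self):
        rng = np.random.default_rng(3)
        lengths = list(rng.uniform(10, 60, size=50)) + [7.25]
        assert compute_ibs_threshold(lengths) == 7.25
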