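"""Domain types for haploblock maps, phased haplotypes, pedigrees and panels.

The phased input data consist of one haplotype *code* per individual, homolog
(1 or 2) and haploblock. A haploblock is a chromosome segment delimited by
historic recombination events inside which array SNPs are combined into
multi-SNP haplotypes; the code identifies which of the observed multi-SNP
haplotypes an individual carries there. These codes, together with an ordered
haploblock map carrying both physical (bp) and genetic (cM) coordinates and a
pedigree with possibly-unknown parents, are everything the haplotype-sharing
deduction method needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx


class _Missing:
    """Sentinel for an unobserved haplotype code.

    MISSING never compares equal to anything, including itself: an unobserved
    code can never be used as evidence that two homologs match.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __eq__(self, other):  # noqa: D105
        return False

    def __ne__(self, other):
        return True

    def __hash__(self):
        return id(self)

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


MISSING = _Missing()

#: placeholder for an unknown pedigree parent
UNKNOWN = None

#: placeholder for an unreported second panel allele
UNREPORTED = None


def is_missing(code) -> bool:
    return code is MISSING


class StructuralError(ValueError):
    """Input violates a structural invariant (overlap, cycle, ordering...)."""


class FormatError(ValueError):
    """Input file does not follow the expected tabular dialect."""


class ReferenceError_(KeyError):
    """A record refers to an entity that does not exist."""


@dataclass(frozen=True)
class Haploblock:
    """One historic-recombination block with physical and genetic extent.

    Physical coordinates are 1-based inclusive base pairs; genetic coordinates
    are centimorgans on the chromosome's linkage map.
    """

    id: str
    chromosome: str
    phys_start: int
    phys_end: int
    gen_start: float
    gen_end: float
    snp_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.phys_start > self.phys_end:
            raise StructuralError(
                f"haploblock {self.id}: phys_start {self.phys_start} > phys_end {self.phys_end}"
            )
        if self.gen_start > self.gen_end:
            raise StructuralError(
                f"haploblock {self.id}: gen_start {self.gen_start} > gen_end {self.gen_end}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


class HaploblockMap:
    """Per-chromosome ordered, non-overlapping sequences of haploblocks.

    Blocks are sorted by physical start on construction; true physical
    overlaps and genetic-order violations are structural errors, never
    silently repaired.
    """

    def __init__(self, haploblocks: Iterable[Haploblock]):
        self._by_chrom: dict[str, list[Haploblock]] = {}
        self._by_id: dict[str, Haploblock] = {}
        for hb in haploblocks:
            if hb.id in self._by_id:
                raise StructuralError(f"duplicate haploblock id {hb.id}")
            self._by_id[hb.id] = hb
            self._by_chrom.setdefault(hb.chromosome, []).append(hb)
        for chrom, blocks in self._by_chrom.items():
            blocks.sort(key=lambda b: b.phys_start)
            for a, b in zip(blocks, blocks[1:]):
                if b.phys_start <= a.phys_end:
                    raise StructuralError(
                        f"haploblocks {a.id} and {b.id} overlap physically on {chrom}"
                    )
                if b.gen_start < a.gen_start:
                    raise StructuralError(
                        f"haploblocks {a.id} and {b.id} on {chrom}: genetic order "
                        "contradicts physical order"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def blocks(self, chromosome: str) -> list[Haploblock]:
        try:
            return list(self._by_chrom[chromosome])
        except KeyError:
            raise ReferenceError_(f"chromosome {chromosome!r} not in map") from None

    def __getitem__(self, hb_id: str) -> Haploblock:
        try:
            return self._by_id[hb_id]
        except KeyError:
            raise ReferenceError_(f"haploblock {hb_id!r} not in map") from None

    def __contains__(self, hb_id: str) -> bool:
        return hb_id in self._by_id

    def __iter__(self) -> Iterator[Haploblock]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def __len__(self) -> int:
        return len(self._by_id)

    def index_of(self, hb_id: str) -> int:
        """Position of a haploblock within its chromosome's ordered blocks."""
        hb = self[hb_id]
        for i, b in enumerate(self._by_chrom[hb.chromosome]):
            if b.id == hb_id:
                return i
        raise AssertionError("unreachable")

    def counts(self) -> dict[str, tuple[int, int]]:
        """Per-chromosome (n_haploblocks, n_snps)."""
        return {
            chrom: (len(blocks), sum(b.n_snps for b in blocks))
            for chrom, blocks in self._by_chrom.items()
        }

    def __eq__(self, other):
        if not isinstance(other, HaploblockMap):
            return NotImplemented
        return {c: self._by_chrom[c] for c in self._by_chrom} == {
            c: other._by_chrom[c] for c in other._by_chrom
        }


class HaplotypeSet:
    """Sparse mapping (individual, homolog in {1,2}, haploblock) -> code.

    Unlisted cells are MISSING. Codes are opaque labels compared by exact
    string equality.
    """

    def __init__(self, cells: Mapping[tuple[str, int, str], str] | None = None):
        self._cells: dict[tuple[str, int, str], str] = {}
        self._individuals: set[str] = set()
        if cells:
            for (ind, hom, hb), code in cells.items():
                self.set_code(ind, hom, hb, code)

    def set_code(self, individual: str, homolog: int, hb_id: str, code: str) -> None:
        if homolog not in (1, 2):
            raise FormatError(f"homolog must be 1 or 2, got {homolog!r}")
        self._cells[(individual, homolog, hb_id)] = str(code)
        self._individuals.add(individual)

    def code(self, individual: str, homolog: int, hb_id: str):
        """The haplotype code, or MISSING if the cell is unobserved."""
        return self._cells.get((individual, homolog, hb_id), MISSING)

    def add_individual(self, individual: str) -> None:
        self._individuals.add(individual)

    @property
    def individuals(self) -> list[str]:
        return sorted(self._individuals)

    def __contains__(self, individual: str) -> bool:
        return individual in self._individuals

    def __len__(self) -> int:
        return len(self._cells)

    def items(self):
        return self._cells.items()

    def __eq__(self, other):
        if not isinstance(other, HaplotypeSet):
            return NotImplemented
        return self._cells == other._cells and self._individuals == other._individuals


class Pedigree:
    """Acyclic parent links; both-parent-unknown individuals are founders.

    Placeholder individuals for unknown-but-distinct parents (breeding
    databases name them e.g. "UP_Delicious") are ordinary records and may
    carry haplotypes — they can be ancestral sources of alleles.
    """

    def __init__(self, parents: Mapping[str, tuple[str | None, str | None]]):
        self._parents: dict[str, tuple[str | None, str | None]] = {}
        for ind, (mother, father) in parents.items():
            self._parents[ind] = (mother, father)
        # auto-create founder records for named-but-unlisted parents
        for mother, father in list(self._parents.values()):
            for p in (mother, father):
                if p is not None and p not in self._parents:
                    self._parents[p] = (UNKNOWN, UNKNOWN)
        g = nx.DiGraph()
        g.add_nodes_from(self._parents)
        for ind, (mother, father) in self._parents.items():
            for p in (mother, father):
                if p is not None:
                    g.add_edge(p, ind)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise StructuralError(f"pedigree contains a cycle: {cycle}")
        self._graph = g

    @property
    def individuals(self) -> list[str]:
        return sorted(self._parents)

    def __contains__(self, individual: str) -> bool:
        return individual in self._parents

    def parents(self, individual: str) -> tuple[str | None, str | None]:
        try:
            return self._parents[individual]
        except KeyError:
            raise ReferenceError_(f"individual {individual!r} not in pedigree") from None

    def named_parents(self, individual: str) -> list[str]:
        return [p for p in self.parents(individual) if p is not None]

    def children(self, individual: str) -> list[str]:
        return sorted(self._graph.successors(individual))

    def is_founder(self, individual: str) -> bool:
        mother, father = self.parents(individual)
        return mother is None and father is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.is_founder(i)]

    def siblings(self, individual: str) -> list[str]:
        """Individuals sharing at least one named parent (half-sibs included)."""
        out = set()
        for p in self.named_parents(individual):
            out.update(self.children(p))
        out.discard(individual)
        return sorted(out)

    def topological_order(self) -> list[str]:
        """Founders-first ordering (parents always before children)."""
        return list(nx.topological_sort(self._graph))

    def __eq__(self, other):
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self._parents == other._parents


@dataclass(frozen=True)
class TargetLocus:
    """A locus of interest given by name and physical position/interval.

    Point loci (a single informative SNP or marker position) have
    phys_start == phys_end.
    """

    name: str
    chromosome: str
    phys_start: int
    phys_end: int

    def __post_init__(self):
        if self.phys_start > self.phys_end:
            raise StructuralError(
                f"locus {self.name}: phys_start {self.phys_start} > phys_end {self.phys_end}"
            )


@dataclass
class ReferencePanel:
    """Historically reported genotypes anchoring allele-to-haplotype assignment.

    allele2 may be UNREPORTED, in which case only one homolog of that
    individual can ever be assigned from the panel.
    """

    locus_name: str
    genotypes: dict[str, tuple[str, str | None]] = field(default_factory=dict)

    def add(self, individual: str, allele1: str, allele2: str | None) -> None:
        if individual in self.genotypes:
            raise FormatError(f"duplicate panel individual {individual!r}")
        if not allele1:
            raise FormatError(f"panel individual {individual!r} has empty allele1")
        self.genotypes[individual] = (allele1, allele2 if allele2 else UNREPORTED)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.genotypes)

    def alleles_of(self, individual: str) -> tuple[str, str | None]:
        return self.genotypes[individual]

    def is_homozygous(self, individual: str) -> bool:
        a1, a2 = self.genotypes[individual]
        return a2 is not None and a1 == a2

    def __len__(self) -> int:
        return len(self.genotypes)
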