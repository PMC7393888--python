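"""Alignment, annotation and dated-tree I/O plus the coordinate machinery.

Everything downstream (SNP calling, structural-event extraction, association
tests, rate estimation) operates on three objects built here:

* :class:`MultipleAlignment` — the gap-containing plastome alignment,
  uppercase over ``A C G T N -``.
* :class:`RegionMap` — the three-way genome partition (coding exon / intron /
  intergenic spacer) on the reference coordinate system, with per-gene exon
  structure, strand and codon phase.
* :class:`DatedTopology` — the fixed rooted seven-taxon tree with node ages
  in My: five ingroup taxa (two congeneric pairs plus a monotypic subfamily)
  and two successive family-level outgroups. Branch ranks (subfamily / genus
  / species) and the hierarchical outgroup scheme are derived from the
  topology itself.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = set("ACGTN-")
GAP = "-"

EXON = "exon"
INTRON = "intron"
SPACER = "spacer"

RANK_SUBFAMILY = "subfamily"
RANK_GENUS = "genus"
RANK_SPECIES = "species"
RANK_STEM = "stem"          # branch subtending the whole ingroup
RANK_OUTGROUP = "outgroup"  # outgroup-side branches
RANK_AMBIGUOUS = "ambiguous"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class MultipleAlignment:
    taxon_ids: list[str]
    rows: list[str]
    reference_taxon: str | None = None

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.rows):
            raise FormatError("taxon_ids and rows differ in length")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids in alignment")
        if not self.rows or not self.rows[0]:
            raise FormatError("empty alignment")
        n = len(self.rows[0])
        for tid, row in zip(self.taxon_ids, self.rows):
            if len(row) != n:
                raise FormatError(
                    f"ragged alignment: record '{tid}' has length {len(row)}, "
                    f"expected {n}"
                )
            bad = set(row) - ALPHABET
            if bad:
                col = next(i for i, c in enumerate(row) if c in bad)
                raise FormatError(
                    f"illegal character {row[col]!r} in record '{tid}' at column {col}"
                )
        if self.reference_taxon is not None and self.reference_taxon not in self.taxon_ids:
            raise FormatError(f"reference taxon '{self.reference_taxon}' not in alignment")
        self._index = {t: i for i, t in enumerate(self.taxon_ids)}

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def row(self, taxon: str) -> str:
        return self.rows[self._index[taxon]]

    def column(self, col: int) -> dict[str, str]:
        return {t: r[col] for t, r in zip(self.taxon_ids, self.rows)}


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path, reference_taxon: str | None = None) -> MultipleAlignment:
    """Read a FASTA multiple alignment; lowercase and U are normalized."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 3:
        raise FormatError(f"alignment needs >=3 records, got {len(records)}")
    taxa = [r.id for r in records]
    rows = [_normalize(str(r.seq)) for r in records]
    return MultipleAlignment(taxa, rows, reference_taxon=reference_taxon)


def write_alignment(aln: MultipleAlignment, path, wrap: int = 70) -> None:
    records = [
        SeqRecord(Seq(row), id=tid, description="")
        for tid, row in zip(aln.taxon_ids, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

@dataclass
class CoordinateMap:
    """Bijection between alignment columns and ungapped positions of one taxon.

    ``col_to_pos[c]`` is -1 at gap columns; ``pos_to_col`` has one entry per
    ungapped position.
    """

    taxon: str
    col_to_pos: np.ndarray
    pos_to_col: np.ndarray

    @property
    def ungapped_length(self) -> int:
        return len(self.pos_to_col)


def build_coordinate_map(aln: MultipleAlignment, taxon: str) -> CoordinateMap:
    if taxon not in aln.taxon_ids:
        raise KeyError(f"unknown taxon '{taxon}'")
    row = np.frombuffer(aln.row(taxon).encode(), dtype="S1")
    nongap = row != b"-"
    col_to_pos = np.full(aln.length, -1, dtype=np.int64)
    col_to_pos[nongap] = np.arange(int(nongap.sum()))
    pos_to_col = np.flatnonzero(nongap)
    if len(pos_to_col) == 0:
        logger.warning("taxon '%s' is all gaps; empty coordinate map", taxon)
    return CoordinateMap(taxon, col_to_pos, pos_to_col)


# ---------------------------------------------------------------------------
# Region map
# ---------------------------------------------------------------------------

@dataclass
class Interval:
    start: int
    end: int
    kind: str                    # exon | intron | spacer
    gene: str | None = None      # owning gene (exon/intron) or "left-right" for spacers
    phase: int = 0               # codon phase of `start` for exons of coding genes
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    name: str
    strand: str
    coding: bool
    exons: list[Interval] = field(default_factory=list)  # genomic order

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class RegionMap:
    intervals: list[Interval]
    genes: dict[str, Gene]
    reference_length: int

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        pos = 0
        for iv in ivs:
            if iv.start != pos:
                raise FormatError(
                    f"intervals not contiguous at {pos} (next starts {iv.start})"
                )
            if iv.end <= iv.start:
                raise FormatError(f"empty interval at {iv.start}")
            pos = iv.end
        if pos != self.reference_length:
            raise FormatError(
                f"intervals cover [0,{pos}) but reference length is {self.reference_length}"
            )
        self.intervals = ivs
        for g in self.genes.values():
            if g.coding and g.cds_length % 3 != 0:
                raise FormatError(
                    f"coding gene '{g.name}' has CDS length {g.cds_length}, "
                    "not a multiple of 3"
                )

    def length_by_kind(self) -> dict[str, int]:
        out = {EXON: 0, INTRON: 0, SPACER: 0}
        for iv in self.intervals:
            out[iv.kind] += len(iv)
        return out

    def interval_at(self, pos: int) -> Interval:
        lo, hi = 0, len(self.intervals)
        while lo < hi:
            mid = (lo + hi) // 2
            iv = self.intervals[mid]
            if pos < iv.start:
                hi = mid
            elif pos >= iv.end:
                lo = mid + 1
            else:
                return iv
        raise IndexError(f"position {pos} outside reference")


def _spacer_name(left: str | None, right: str | None) -> str:
    return f"{left or '5prime'}-{right or '3prime'}"


def region_map_from_genes(genes: list[Gene], reference_length: int) -> RegionMap:
    """Assemble the exon/intron/spacer partition from per-gene exon lists."""
    genes_sorted = sorted(genes, key=lambda g: g.start)
    intervals: list[Interval] = []
    pos = 0
    prev_gene: str | None = None
    for g in genes_sorted:
        if g.start < pos:
            raise FormatError(f"gene '{g.name}' overlaps a previous feature")
        if g.end > reference_length:
            raise FormatError(f"gene '{g.name}' extends beyond reference length")
        if g.start > pos:
            intervals.append(
                Interval(pos, g.start, SPACER, _spacer_name(prev_gene, g.name))
            )
        # exons plus derived introns (within-gene complement of the exons)
        exons = sorted(g.exons, key=lambda e: e.start)
        cds_before = 0
        total = sum(len(e) for e in exons)
        cur = g.start
        for e in exons:
            if e.start > cur:
                intervals.append(Interval(cur, e.start, INTRON, g.name, strand=g.strand))
            elif e.start < cur:
                raise FormatError(f"overlapping exons within gene '{g.name}'")
            if g.strand == "+":
                phase = cds_before % 3
            else:
                phase = (total - cds_before - len(e)) % 3  # phase of genomic start
            intervals.append(Interval(e.start, e.end, EXON, g.name, phase, g.strand))
            cds_before += len(e)
            cur = e.end
        pos = g.end
        prev_gene = g.name
    if pos < reference_length:
        intervals.append(Interval(pos, reference_length, SPACER, _spacer_name(prev_gene, None)))
    gdict = {g.name: Gene(g.name, g.strand, g.coding,
                          [iv for iv in intervals if iv.kind == EXON and iv.gene == g.name])
             for g in genes_sorted}
    return RegionMap(intervals, gdict, reference_length)


def read_annotation(path, reference_length: int) -> RegionMap:
    """Read a GFF3 annotation into a RegionMap.

    Expects ``gene`` features with ``CDS`` (or ``exon``) children; introns are
    derived as the within-gene complement of the exons, spacers fill the gaps
    between genes. A ``coding=false`` attribute on a gene marks it
    non-protein-coding (codon-phase validation skipped).
    """
    import gffutils

    with open(path) as fh:
        has_features = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_features:
        return region_map_from_genes([], reference_length)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True,
        force=True,
    )
    genes: list[Gene] = []
    for gf in db.features_of_type("gene"):
        name = gf.attributes.get("Name", [gf.id])[0]
        coding = gf.attributes.get("coding", ["true"])[0].lower() != "false"
        strand = gf.strand if gf.strand in "+-" else "+"
        exons = []
        children = list(db.children(gf, featuretype="CDS")) or list(
            db.children(gf, featuretype="exon")
        )
        if not children:
            children = [gf]
        for c in children:
            if c.end > reference_length:
                raise FormatError(
                    f"feature of gene '{name}' ends at {c.end}, beyond reference "
                    f"length {reference_length}"
                )
            exons.append(Interval(c.start - 1, c.end, EXON, name, strand=strand))
        genes.append(Gene(name, strand, coding, sorted(exons, key=lambda e: e.start)))
    return region_map_from_genes(genes, reference_length)


def write_annotation(regions: RegionMap, path, seqid: str = "reference") -> None:
    """Emit the gene/CDS features of a RegionMap as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {regions.reference_length}\n")
        for g in sorted(regions.genes.values(), key=lambda g: g.start):
            coding = "true" if g.coding else "false"
            fh.write(
                f"{seqid}\tplastmut\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.name};Name={g.name};coding={coding}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{seqid}\tplastmut\tCDS\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t"
                    f"{e.phase if g.coding else '.'}\t"
                    f"ID={g.name}.cds{i};Parent={g.name}\n"
                )


def project_regions(regions: RegionMap, cmap: CoordinateMap, aln_length: int) -> np.ndarray:
    """Label every alignment column with the index of its reference interval.

    Columns where the reference is gapped inherit the interval of the previous
    reference base (leading gap columns take the first interval). Returns an
    int array of interval indices into ``regions.intervals``.
    """
    if cmap.ungapped_length != regions.reference_length:
        raise FormatError(
            f"coordinate map has {cmap.ungapped_length} positions but region map "
            f"covers {regions.reference_length}"
        )
    iv_of_pos = np.empty(regions.reference_length, dtype=np.int64)
    for i, iv in enumerate(regions.intervals):
        iv_of_pos[iv.start:iv.end] = i
    labels = np.empty(aln_length, dtype=np.int64)
    cur = iv_of_pos[0] if regions.reference_length else 0
    for c in range(aln_length):
        p = cmap.col_to_pos[c]
        if p >= 0:
            cur = iv_of_pos[p]
        labels[c] = cur
    return labels


# ---------------------------------------------------------------------------
# Dated topology
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str
    age: float
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.tips())
        return out


class DatedTopology:
    """The fixed rooted dated tree with rank labels and outgroup scheme.

    Structure required: a five-taxon ingroup ``((a,b),(c,d)),e`` — two
    congeneric cherries forming one subfamily, plus taxon *e* as the second
    (monotypic) subfamily — and two outgroup taxa outside it, either as a
    clade or as a grade.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: dict[str, TreeNode] = {}
        self._register(root)
        self._validate_ages(root)
        self._identify_structure()

    # -- construction helpers ------------------------------------------------

    def _register(self, node: TreeNode) -> None:
        if node.name in self.nodes:
            raise FormatError(f"duplicate node name '{node.name}'")
        self.nodes[node.name] = node
        for c in node.children:
            c.parent = node
            self._register(c)

    def _validate_ages(self, node: TreeNode) -> None:
        for c in node.children:
            if not (c.age < node.age):
                raise FormatError(
                    f"child '{c.name}' age {c.age} not below parent "
                    f"'{node.name}' age {node.age}"
                )
            self._validate_ages(c)

    def _identify_structure(self) -> None:
        tips = self.root.tips()
        if len(tips) != 7:
            raise FormatError(f"expected 7 taxa (5 ingroup + 2 outgroups), got {len(tips)}")

        def is_cherry(n: TreeNode) -> bool:
            return len(n.children) == 2 and all(c.is_leaf for c in n.children)

        crown = None
        for node in self._preorder(self.root):
            if len(node.tips()) != 5 or len(node.children) != 2:
                continue
            a, b = node.children
            for core, idio in ((a, b), (b, a)):
                if idio.is_leaf and len(core.children) == 2 and all(
                    is_cherry(c) for c in core.children
                ):
                    crown = node
                    self.ingroup_crown = node
                    self.subfamily_core = core     # the two-genus subfamily crown
                    self.idiospermum = idio.name   # monotypic-subfamily terminal
                    break
            if crown:
                break
        if crown is None:
            raise FormatError(
                "topology does not contain the required ((a,b),(c,d)),e ingroup; "
                "outgroups required outside a five-taxon ingroup of two cherries "
                "plus one terminal"
            )
        self.ingroup_taxa = crown.tips()
        self.outgroup_taxa = [t for t in tips if t not in self.ingroup_taxa]
        if len(self.outgroup_taxa) != 2:
            raise FormatError("outgroups required: exactly 2 taxa outside the ingroup")
        self.cherries = list(self.subfamily_core.children)  # two genus crowns

        # Branch ranks, branch identified by its child node name.
        self.branch_rank: dict[str, str] = {}
        self.branch_side: dict[str, str] = {}
        for n in self._preorder(self.root):
            if n is self.root:
                continue
            self.branch_rank[n.name] = RANK_OUTGROUP
        self.branch_rank[crown.name] = RANK_STEM if crown is not self.root else RANK_STEM
        self.branch_rank[self.idiospermum] = RANK_SUBFAMILY
        self.branch_rank[self.subfamily_core.name] = RANK_SUBFAMILY
        for cherry in self.cherries:
            side = self._side_label(cherry)
            self.branch_rank[cherry.name] = RANK_GENUS
            self.branch_side[cherry.name] = side
            for tip in cherry.children:
                self.branch_rank[tip.name] = RANK_SPECIES
                self.branch_side[tip.name] = side
        if crown is self.root:
            raise FormatError("outgroups required: ingroup crown cannot be the root")

    @staticmethod
    def _side_label(cherry: TreeNode) -> str:
        a, b = (c.name for c in cherry.children)
        pre = ""
        for x, y in zip(a, b):
            if x != y:
                break
            pre += x
        pre = pre.rstrip("_- .")
        return pre if len(pre) >= 2 else f"{a}+{b}"

    # -- traversal / queries -------------------------------------------------

    def _preorder(self, node: TreeNode):
        yield node
        for c in node.children:
            yield from self._preorder(c)

    def preorder(self):
        return self._preorder(self.root)

    @property
    def taxa(self) -> list[str]:
        return self.root.tips()

    def clade_tips(self, branch: str) -> list[str]:
        return self.nodes[branch].tips()

    def branch_duration(self, branch: str) -> float:
        n = self.nodes[branch]
        return n.parent.age - n.age

    def ingroup_branches(self) -> list[str]:
        """Branches below (and including) the ingroup crown's children."""
        out = []
        for n in self._preorder(self.ingroup_crown):
            if n is not self.ingroup_crown:
                out.append(n.name)
        return out

    def additive_time(self) -> float:
        """Sum of ingroup branch durations (My), the structural-rate denominator."""
        return sum(self.branch_duration(b) for b in self.ingroup_branches())

    def sides(self) -> list[str]:
        return [self.branch_side[c.name] for c in self.cherries]

    def rank_outgroups(self, branch: str) -> list[str]:
        """Hierarchical outgroup taxa used to polarize a mutation on `branch`."""
        rank = self.branch_rank.get(branch)
        if rank == RANK_SUBFAMILY:
            return list(self.outgroup_taxa)
        if rank == RANK_GENUS:
            return [self.idiospermum]
        if rank == RANK_SPECIES:
            side = self.branch_side[branch]
            for cherry in self.cherries:
                if self.branch_side[cherry.name] != side:
                    return cherry.tips()
        return []


def _from_dendropy(tree: dendropy.Tree, ages: dict[str, float] | None) -> TreeNode:
    counter = [0]

    def conv(nd) -> TreeNode:
        if nd.is_leaf():
            return TreeNode(nd.taxon.label.replace(" ", "_"), 0.0)
        label = nd.label
        age = None
        if label is not None:
            try:
                age = float(label)
                label = None
            except ValueError:
                pass
        if label is None:
            counter[0] += 1
            label = f"node{counter[0]}"
        if ages and label in ages:
            age = ages[label]
        if age is None:
            raise FormatError(
                f"missing age for internal node '{label}': supply node ages as "
                "internal labels or in a companion TSV"
            )
        node = TreeNode(label, age)
        node.children = [conv(c) for c in nd.child_nodes()]
        return node

    root = tree.seed_node
    if len(root.child_nodes()) != 2:
        raise FormatError("tree must be rooted and fully resolved (binary root)")
    return conv(root)


def read_dated_tree(path, ages_tsv=None) -> DatedTopology:
    """Read a rooted Newick tree whose internal nodes carry ages in My.

    Ages may be given as internal node labels (numbers) or, for named nodes,
    in a two-column TSV ``node_id<TAB>age_My``.
    """
    ages = None
    if ages_tsv is not None:
        ages = {}
        with open(ages_tsv) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, val = line.split("\t")[:2]
                ages[name] = float(val)
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)
    root = _from_dendropy(tree, ages)
    return DatedTopology(root)


def write_dated_tree(topology: DatedTopology, path) -> None:
    def nw(n: TreeNode) -> str:
        if n.is_leaf:
            return n.name
        inner = ",".join(nw(c) for c in n.children)
        return f"({inner}){n.age:g}"

    with open(path, "w") as fh:
        fh.write(nw(topology.root) + ";\n")


def default_topology(
    ingroup_ages: tuple[float, float, float, float] = (108.8, 18.7, 7.6, 6.2),
    root_age: float = 140.0,
    outgroup_node_age: float = 120.0,
    taxa: dict[str, str] | None = None,
) -> DatedTopology:
    """The study topology: two congeneric cherries + monotypic subfamily,
    with a Magnoliaceae outgroup clade. Ages are (crown, core, cherryA, cherryB)."""
    t = taxa or {}
    ca, cb = t.get("cherryA", ("Calycanthus_chinensis", "Calycanthus_floridus"))
    na, nb = t.get("cherryB", ("Chimonanthus_nitens", "Chimonanthus_praecox"))
    idio = t.get("idiospermum", "Idiospermum_australiense")
    o1, o2 = t.get("outgroups", ("Liriodendron_tulipifera", "Magnolia_kwangsiensis"))
    a_crown, a_core, a_cha, a_chb = ingroup_ages
    root = TreeNode("root", root_age, [
        TreeNode("outgroup_crown", outgroup_node_age,
                 [TreeNode(o1, 0.0), TreeNode(o2, 0.0)]),
        TreeNode("ingroup_crown", a_crown, [
            TreeNode("core_crown", a_core, [
                TreeNode("cherryA_crown", a_cha,
                         [TreeNode(ca, 0.0), TreeNode(cb, 0.0)]),
                TreeNode("cherryB_crown", a_chb,
                         [TreeNode(na, 0.0), TreeNode(nb, 0.0)]),
            ]),
            TreeNode(idio, 0.0),
        ]),
    ])
    return DatedTopology(root)
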