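"""Nucleotide-substitution calling, polarization and classification.

A polymorphic alignment column becomes a :class:`SnpSite`. Biallelic sites
are placed on a branch of the fixed topology by small parsimony, assigned a
taxonomic rank (subfamily / genus / species), and polarized against the
hierarchical outgroups of that rank: the state shared with the rank's
outgroups is plesiomorphic (ancestral), the other state apomorphic (derived).
Sites are then classified by substitution type (transition / transversion,
12 directed classes pooled into 6 complementary-strand classes), genomic
region, and — for exonic sites — coding effect against the reference codon
context under the plastid genetic code (translation table 11).

dN/dS here is a raw event-count ratio (nonsynonymous count / synonymous
count), not a per-site-normalized estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from ._fitch import map_binary_character
from .genomic_io import (
    EXON, INTRON, SPACER,
    RANK_AMBIGUOUS, RANK_GENUS, RANK_SPECIES, RANK_SUBFAMILY,
    CoordinateMap, DatedTopology, MultipleAlignment, RegionMap,
    build_coordinate_map, project_regions,
)

logger = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

#: the six complementary-strand substitution pools of the directed spectrum
POOLED_CLASSES = (
    "A>G+T>C", "G>A+C>T",          # transitions
    "A>C+T>G", "C>A+G>T",          # common transversions
    "A>T+T>A", "G>C+C>G",          # rare transversions
)
DIRECTED_CLASSES = tuple(
    f"{a}>{d}" for a in "ACGT" for d in "ACGT" if a != d
)

_PLASTID_TABLE = CodonTable.unambiguous_dna_by_id[11]


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid, '*' for stop, None if untranslatable (N etc.)."""
    if codon in _PLASTID_TABLE.stop_codons:
        return "*"
    return _PLASTID_TABLE.forward_table.get(codon)


@dataclass
class SnpSite:
    column: int
    alleles: dict[str, str]                 # taxon -> base ('-'/'N' possible for outgroups)
    ingroup_alleles: tuple[str, ...] = ()
    allelism: str = "biallelic"             # biallelic | triallelic | quadallelic
    branch: str | None = None
    rank: str | None = None                 # subfamily | genus | species | ambiguous
    side: str | None = None                 # genus/species side label
    parallel: bool = False
    ancestral: str | None = None
    derived: str | None = None
    direction_known: bool = False
    ts_tv: str | None = None                # transition | transversion
    directed_class: str | None = None
    pooled_class: str | None = None
    region: str | None = None               # exon | intron | spacer
    gene: str | None = None
    coding_effect: str | None = None        # synonymous | nonsynonymous
    effect_note: str | None = None
    multi_snp_codon: bool = False
    codon_index: int | None = None

    @property
    def is_clean_biallelic(self) -> bool:
        """Biallelic, non-parallel, rank resolved — the Table-2 census class."""
        return (
            self.allelism == "biallelic"
            and not self.parallel
            and self.rank in (RANK_SUBFAMILY, RANK_GENUS, RANK_SPECIES)
        )


# ---------------------------------------------------------------------------
# Calling and branch mapping
# ---------------------------------------------------------------------------

def call_polymorphic_sites(
    aln: MultipleAlignment, topology: DatedTopology
) -> list[SnpSite]:
    """Every column with >=2 distinct bases among the ingroup taxa and no
    ingroup gap or N (gapped columns belong to structural events)."""
    missing = [t for t in topology.taxa if t not in aln.taxon_ids]
    if missing:
        raise ValueError(f"alignment lacks topology taxa: {missing}")
    ingroup = topology.ingroup_taxa
    mat = np.array(
        [np.frombuffer(aln.row(t).encode(), dtype="S1") for t in ingroup]
    )
    ok = ~((mat == b"-") | (mat == b"N")).any(axis=0)
    poly = (mat != mat[0]).any(axis=0)
    n_excluded = int((~ok & poly).sum())
    if n_excluded:
        logger.info("%d polymorphic columns excluded for ingroup gap/N", n_excluded)
    sites = []
    for col in np.flatnonzero(ok & poly):
        col = int(col)
        column = aln.column(col)
        states = sorted({column[t] for t in ingroup})
        allelism = {2: "biallelic", 3: "triallelic", 4: "quadallelic"}[len(states)]
        sites.append(
            SnpSite(column=col, alleles=column, ingroup_alleles=tuple(states),
                    allelism=allelism)
        )
    return sites


def map_to_branch(site: SnpSite, topology: DatedTopology) -> SnpSite:
    """Fitch placement of a biallelic site; fills branch, rank, side, parallel.

    Outgroup bases outside the two ingroup alleles (or gaps/N) carry no
    placement information and are scored as missing.
    """
    if site.allelism != "biallelic":
        return site
    alleles = set(site.ingroup_alleles)
    leaf_states: dict[str, str | None] = {}
    for t in topology.taxa:
        b = site.alleles[t]
        leaf_states[t] = b if b in alleles else None
    branch, rank, parallel = map_binary_character(topology, leaf_states)
    site.branch, site.rank, site.parallel = branch, rank, parallel
    if branch is not None:
        site.side = topology.branch_side.get(branch)
    return site


def infer_direction(site: SnpSite, topology: DatedTopology) -> SnpSite:
    """Polarize against the rank-appropriate outgroups (unanimity rule)."""
    if site.parallel or site.branch is None or site.allelism != "biallelic":
        return site
    outs = topology.rank_outgroups(site.branch)
    if not outs:
        return site
    obs = {site.alleles[t] for t in outs}
    alleles = set(site.ingroup_alleles)
    if len(obs) == 1 and (anc := obs.pop()) in alleles:
        site.ancestral = anc
        site.derived = next(a for a in site.ingroup_alleles if a != anc)
        site.direction_known = True
        cls = classify_substitution(site.ancestral, site.derived)
        site.ts_tv, site.directed_class, site.pooled_class = cls
    return site


def classify_substitution(ancestral: str, derived: str) -> tuple[str, str, str]:
    """(transition|transversion, directed class, complementary-strand pool)."""
    if ancestral == derived or {ancestral, derived} - set("ACGT"):
        raise ValueError(f"invalid substitution {ancestral}->{derived}")
    ts = (
        "transition"
        if {ancestral, derived} <= PURINES or {ancestral, derived} <= PYRIMIDINES
        else "transversion"
    )
    directed = f"{ancestral}>{derived}"
    comp = f"{COMPLEMENT[ancestral]}>{COMPLEMENT[derived]}"
    pooled = next(p for p in POOLED_CLASSES if directed in p.split("+"))
    assert comp in pooled.split("+") or directed in pooled.split("+")
    return ts, directed, pooled


# ---------------------------------------------------------------------------
# Region and coding effect
# ---------------------------------------------------------------------------

class CodingContext:
    """Codon arithmetic on the reference: maps a reference position inside a
    coding gene to its codon (coding-strand orientation) and back."""

    def __init__(self, regions: RegionMap, reference_seq_ungapped: str):
        self.regions = regions
        self.ref = reference_seq_ungapped

    def _gene_exons(self, gene: str):
        g = self.regions.genes[gene]
        exons = g.exons
        cum = [0]
        for e in exons:
            cum.append(cum[-1] + len(e))
        return g, exons, cum

    def cds_offset(self, gene: str, refpos: int) -> int:
        g, exons, cum = self._gene_exons(gene)
        for i, e in enumerate(exons):
            if e.start <= refpos < e.end:
                genomic_off = cum[i] + (refpos - e.start)
                return genomic_off if g.strand == "+" else g.cds_length - 1 - genomic_off
        raise ValueError(f"position {refpos} not exonic in gene '{gene}'")

    def refpos_of_offset(self, gene: str, off: int) -> int:
        g, exons, cum = self._gene_exons(gene)
        genomic_off = off if g.strand == "+" else g.cds_length - 1 - off
        for i, e in enumerate(exons):
            if cum[i] <= genomic_off < cum[i + 1]:
                return e.start + (genomic_off - cum[i])
        raise ValueError(f"offset {off} outside CDS of '{gene}'")

    def codon_at(self, gene: str, refpos: int) -> tuple[str, int, int]:
        """(codon on coding strand, position within codon, codon index)."""
        g = self.regions.genes[gene]
        off = self.cds_offset(gene, refpos)
        ci, within = divmod(off, 3)
        bases = []
        for k in range(3):
            p = self.refpos_of_offset(gene, 3 * ci + k)
            b = self.ref[p]
            bases.append(b if g.strand == "+" else COMPLEMENT.get(b, "N"))
        return "".join(bases), within, ci

    def strand(self, gene: str) -> str:
        return self.regions.genes[gene].strand


def annotate_regions(
    sites: list[SnpSite], regions: RegionMap, labels: np.ndarray
) -> list[SnpSite]:
    for s in sites:
        iv = regions.intervals[labels[s.column]]
        s.region = iv.kind
        s.gene = iv.gene
    return sites


def classify_coding_effect(
    site: SnpSite,
    regions: RegionMap,
    aln: MultipleAlignment,
    cmap: CoordinateMap,
    context: CodingContext | None = None,
) -> SnpSite:
    """Synonymous/nonsynonymous call for a direction-known exonic site.

    The ancestral codon is the reference codon context with the ancestral
    base placed at the site (strand-aware); the derived codon substitutes the
    derived base. Amino acids are compared under translation table 11.
    """
    if site.region != EXON or not site.direction_known:
        return site
    gene = regions.genes.get(site.gene)
    if gene is None or not gene.coding:
        site.effect_note = "non-coding gene"
        return site
    refpos = int(cmap.col_to_pos[site.column])
    if refpos < 0:
        site.effect_note = "reference gapped at site"
        logger.debug("column %d: %s", site.column, site.effect_note)
        return site
    if context is None:
        ref_seq = aln.row(cmap.taxon).replace("-", "")
        context = CodingContext(regions, ref_seq)
    codon, within, ci = context.codon_at(site.gene, refpos)
    if "N" in codon or "-" in codon:
        site.effect_note = "codon interrupted"
        return site
    anc_b = site.ancestral if gene.strand == "+" else COMPLEMENT[site.ancestral]
    der_b = site.derived if gene.strand == "+" else COMPLEMENT[site.derived]
    anc_codon = codon[:within] + anc_b + codon[within + 1:]
    der_codon = codon[:within] + der_b + codon[within + 1:]
    aa_a, aa_d = translate_codon(anc_codon), translate_codon(der_codon)
    if aa_a is None or aa_d is None:
        site.effect_note = "untranslatable codon"
        return site
    site.coding_effect = "synonymous" if aa_a == aa_d else "nonsynonymous"
    site.codon_index = ci
    return site


def flag_multi_snp_codons(sites: list[SnpSite]) -> None:
    seen: dict[tuple[str, int], int] = {}
    for s in sites:
        if s.codon_index is not None:
            key = (s.gene, s.codon_index)
            seen[key] = seen.get(key, 0) + 1
    for s in sites:
        if s.codon_index is not None and seen[(s.gene, s.codon_index)] > 1:
            s.multi_snp_codon = True


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _ratio(a: int, b: int) -> float | None:
    return None if b == 0 else round(a / b, 2)


def spectrum(sites: list[SnpSite], by: str | None = None) -> pd.DataFrame:
    """Directed 12-class and pooled 6-class counts over direction-known sites.

    ``by='rank'`` stratifies; default is one pooled stratum ('all')."""
    rows = {}
    for s in sites:
        if not s.direction_known or not s.is_clean_biallelic:
            continue
        stratum = s.rank if by == "rank" else "all"
        d = rows.setdefault(stratum, {c: 0 for c in DIRECTED_CLASSES})
        d[s.directed_class] += 1
    out = pd.DataFrame(rows).T.reindex(columns=list(DIRECTED_CLASSES)).fillna(0).astype(int)
    for pool in POOLED_CLASSES:
        a, b = pool.split("+")
        out[pool] = out[a] + out[b]
    out["total"] = out[list(DIRECTED_CLASSES)].sum(axis=1)
    return out


def summarize_rank_region(
    sites: list[SnpSite], regions: RegionMap, topology: DatedTopology
) -> pd.DataFrame:
    """Rank x region census of the clean biallelic sites (the Table-2 shape).

    Columns: subfamily, genus (both stems pooled), one per species side, total.
    Rows: counts and percents per region, nonsyn/syn counts and their count
    ratio dN/dS for the coding region.
    """
    sides = topology.sides()
    strata = [RANK_SUBFAMILY, RANK_GENUS] + [f"species_{s}" for s in sides] + ["total"]
    lengths = regions.length_by_kind()
    total_len = regions.reference_length

    def stratum_of(s: SnpSite) -> str | None:
        if not s.is_clean_biallelic:
            return None
        if s.rank == RANK_SPECIES:
            return f"species_{s.side}"
        return s.rank

    counts: dict[str, dict[str, int]] = {
        st: {"total": 0, EXON: 0, INTRON: 0, SPACER: 0, "nonsyn": 0, "syn": 0}
        for st in strata
    }
    for s in sites:
        st = stratum_of(s)
        if st is None:
            continue
        for key in (st, "total"):
            c = counts[key]
            c["total"] += 1
            if s.region in (EXON, INTRON, SPACER):
                c[s.region] += 1
            if s.coding_effect == "nonsynonymous":
                c["nonsyn"] += 1
            elif s.coding_effect == "synonymous":
                c["syn"] += 1

    rows = []
    for st in strata:
        c = counts[st]
        rows.append({
            "stratum": st,
            "total_substitutions": c["total"],
            "total_percent": round(100 * c["total"] / total_len, 2),
            "coding": c[EXON],
            "coding_percent": round(100 * c[EXON] / lengths[EXON], 2) if lengths[EXON] else None,
            "nonsynonymous": c["nonsyn"],
            "synonymous": c["syn"],
            "dn_ds": _ratio(c["nonsyn"], c["syn"]),
            "intron": c[INTRON],
            "intron_percent": round(100 * c[INTRON] / lengths[INTRON], 2) if lengths[INTRON] else None,
            "spacer": c[SPACER],
            "spacer_percent": round(100 * c[SPACER] / lengths[SPACER], 2) if lengths[SPACER] else None,
        })
    df = pd.DataFrame(rows).set_index("stratum")
    df.attrs["analyzed_length"] = total_len
    df.attrs["region_lengths"] = lengths
    return df


DEFAULT_GENE_GROUPS = ("atp", "ndh", "pet", "psa", "psb", "rpl", "rpo", "rps")


def summarize_gene_groups(
    sites: list[SnpSite], grouping=None
) -> pd.DataFrame:
    """Per functional gene group: Ts/Tv and dN/dS count ratios (Fig.-4 shape).

    ``grouping`` maps gene name -> group label; default groups genes by the
    conventional name prefixes. Unmatched genes land in 'other'.
    """
    def group_of(gene: str) -> str:
        if grouping is not None:
            return grouping.get(gene, "other")
        gl = gene.lower()
        for p in DEFAULT_GENE_GROUPS:
            if gl.startswith(p):
                return p
        return "other"

    agg: dict[str, dict[str, int]] = {}
    for s in sites:
        if s.region != EXON or not s.direction_known or not s.is_clean_biallelic:
            continue
        g = agg.setdefault(group_of(s.gene), {"ts": 0, "tv": 0, "dn": 0, "ds": 0})
        if s.ts_tv == "transition":
            g["ts"] += 1
        elif s.ts_tv == "transversion":
            g["tv"] += 1
        if s.coding_effect == "nonsynonymous":
            g["dn"] += 1
        elif s.coding_effect == "synonymous":
            g["ds"] += 1
    rows = []
    for grp in sorted(agg):
        g = agg[grp]
        rows.append({
            "group": grp, **g,
            "ts_tv": _ratio(g["ts"], g["tv"]),
            "dn_ds": _ratio(g["dn"], g["ds"]),
        })
    return pd.DataFrame(rows, columns=["group", "ts", "tv", "dn", "ds", "ts_tv", "dn_ds"])


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float
    expected: list[float] = field(default_factory=list)
    low_expected: bool = False


def test_substitution_bias(counts, expected_probs=None) -> GTestResult:
    """Likelihood-ratio G test of observed class counts against expected
    proportions (uniform unless given). G = 2 * sum O * ln(O/E), df = k - 1."""
    obs = [int(c) for c in counts]
    n = sum(obs)
    if n <= 0:
        raise ValueError("total count must be positive")
    k = len(obs)
    probs = expected_probs or [1 / k] * k
    exp = [n * p for p in probs]
    g = 2.0 * sum(o * math.log(o / e) for o, e in zip(obs, exp) if o > 0)
    df = k - 1
    p = float(stats.chi2.sf(g, df))
    low = any(e < 1 for e in exp)
    if low:
        logger.warning("expected count < 1 in G test; exact multinomial advised")
    return GTestResult(g=g, df=df, p_value=p, expected=exp, low_expected=low)


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

def codon_usage(
    aln: MultipleAlignment,
    regions: RegionMap,
    taxon: str,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Codon frequencies and amino-acid composition of one taxon's coding genes.

    Gene sequences are read strand-aware from the exon-labeled alignment
    columns after degapping; genes whose degapped length is not a multiple of
    3 are skipped with a log message, codons containing N are counted but
    marked untranslatable.
    """
    if labels is None:
        cmap = build_coordinate_map(aln, aln.reference_taxon)
        labels = project_regions(regions, cmap, aln.length)
    iv_index = {id(iv): i for i, iv in enumerate(regions.intervals)}
    row = aln.row(taxon)
    counts: dict[str, int] = {}
    n_untranslatable = 0
    for g in regions.genes.values():
        if not g.coding:
            continue
        exon_ids = {iv_index[id(e)] for e in g.exons}
        cols = np.flatnonzero(np.isin(labels, list(exon_ids)))
        seq = "".join(row[c] for c in cols if row[c] != "-")
        if g.strand == "-":
            seq = "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))
        if len(seq) % 3 != 0:
            logger.info("gene '%s' in %s: degapped length %d not /3; skipped",
                        g.name, taxon, len(seq))
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if "N" in codon:
                n_untranslatable += 1
                continue
            counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    rows = []
    for codon in sorted(counts):
        aa = translate_codon(codon) or "?"
        rows.append({"codon": codon, "amino_acid": aa, "count": counts[codon],
                     "percent": round(100 * counts[codon] / total, 2)})
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "percent"])
    df.attrs["n_untranslatable"] = n_untranslatable
    df.attrs["total_codons"] = total
    return df


def amino_acid_composition(usage: pd.DataFrame) -> pd.DataFrame:
    aa = usage.groupby("amino_acid")[["count"]].sum().reset_index()
    total = aa["count"].sum()
    aa["percent"] = (100 * aa["count"] / total).round(2)
    return aa


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def analyze_snps(
    aln: MultipleAlignment,
    regions: RegionMap,
    topology: DatedTopology,
) -> list[SnpSite]:
    """Call, map, polarize and classify every polymorphic site."""
    cmap = build_coordinate_map(aln, aln.reference_taxon)
    labels = project_regions(regions, cmap, aln.length)
    ref_seq = aln.row(aln.reference_taxon).replace("-", "")
    context = CodingContext(regions, ref_seq)
    sites = call_polymorphic_sites(aln, topology)
    for s in sites:
        map_to_branch(s, topology)
        infer_direction(s, topology)
    annotate_regions(sites, regions, labels)
    for s in sites:
        classify_coding_effect(s, regions, aln, cmap, context)
    flag_multi_snp_codons(sites)
    return sites
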