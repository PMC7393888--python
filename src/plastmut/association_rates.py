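"""Association of structural mutations with nucleotide substitutions, and
per-site mutation-rate estimation.

The association statistic compares pairwise genetic distance (uncorrected
p-distance by default; optional Jukes-Cantor correction) over annotation
units (a gene's exon set, an intron, a spacer) that contain at least one
structural event distinguishing the pair (gdS) against units with none
(gdN). Rates follow mu = m / (n * T): m observed mutations over n sites
since divergence time T, with a Poisson standard error sqrt(m) / (n * T);
structural rates divide by the additive time (sum of ingroup branch
durations) instead of a single node age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import (
    EXON, DatedTopology, MultipleAlignment, RegionMap,
)
from .structural_analysis import StructuralEvent
from .snp_analysis import SnpSite

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Genetic distance
# ---------------------------------------------------------------------------

def p_distance(
    aln: MultipleAlignment,
    taxon_a: str,
    taxon_b: str,
    columns=None,
    jukes_cantor: bool = False,
) -> float | None:
    """Mismatches / compared columns, excluding columns gapped or N in either
    taxon. None (with a log message) when nothing is comparable."""
    ra = np.frombuffer(aln.row(taxon_a).encode(), dtype="S1")
    rb = np.frombuffer(aln.row(taxon_b).encode(), dtype="S1")
    if columns is not None:
        idx = np.asarray(sorted(columns), dtype=np.int64)
        ra, rb = ra[idx], rb[idx]
    ok = ~(
        (ra == b"-") | (rb == b"-") | (ra == b"N") | (rb == b"N")
    )
    n = int(ok.sum())
    if n == 0:
        logger.info("p_distance(%s,%s): zero comparable columns", taxon_a, taxon_b)
        return None
    p = float((ra[ok] != rb[ok]).sum()) / n
    if jukes_cantor:
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)
    return p


# ---------------------------------------------------------------------------
# Structural/nucleotide association (Table-5 shape)
# ---------------------------------------------------------------------------

@dataclass
class AssociationRow:
    taxon_a: str
    taxon_b: str
    level: str
    n_substitutions: int
    n_structural: int
    n_over_s: float | None
    gd: dict  # partition -> (gdS, gdN, ratio)


def _units(regions: RegionMap, labels: np.ndarray):
    """Annotation units as (name, partition-kind, column-index-array)."""
    units = []
    by_iv: dict[int, list[int]] = {}
    for i in range(len(regions.intervals)):
        by_iv[i] = []
    for c, lab in enumerate(labels):
        by_iv[int(lab)].append(c)
    # one unit per gene (all exon columns), per intron, per spacer
    gene_cols: dict[str, list[int]] = {}
    for i, iv in enumerate(regions.intervals):
        cols = by_iv[i]
        if iv.kind == EXON:
            gene_cols.setdefault(iv.gene, []).extend(cols)
        else:
            units.append((f"{iv.kind}:{iv.gene}:{iv.start}", iv.kind,
                          np.array(cols, dtype=np.int64)))
    for gene, cols in gene_cols.items():
        units.append((f"gene:{gene}", EXON, np.array(sorted(cols), dtype=np.int64)))
    return units


def default_pairs(topology: DatedTopology) -> list[tuple[str, str, str]]:
    """The study's comparison scheme: the lone-subfamily taxon against each
    core taxon (subfamily level), cross-genus pairs (genus), within-cherry
    pairs (species)."""
    cherry_a, cherry_b = (c.tips() for c in topology.cherries)
    idio = topology.idiospermum
    pairs = [(idio, t, "subfamily") for t in cherry_a + cherry_b]
    pairs += [(a, b, "genus") for a in cherry_a for b in cherry_b]
    pairs += [(cherry_a[0], cherry_a[1], "species"),
              (cherry_b[0], cherry_b[1], "species")]
    return pairs


def associate(
    sites: list[SnpSite],
    events: list[StructuralEvent],
    regions: RegionMap,
    aln: MultipleAlignment,
    topology: DatedTopology,
    labels: np.ndarray,
    pairs: list[tuple[str, str, str]] | None = None,
    jukes_cantor: bool = False,
) -> pd.DataFrame:
    """gdS/gdN association rows for each comparison pair and partition.

    A unit is "with structural mutation" for a pair when at least one
    structural event whose carriers separate the pair starts inside it.
    Partitions: whole, noncoding (introns + spacers), coding (gene units).
    """
    pairs = pairs if pairs is not None else default_pairs(topology)
    units = _units(regions, labels)
    # unit index of each event 5'-start column
    starts = {}
    for ui, (_, _, cols) in enumerate(units):
        for c in cols:
            starts[int(c)] = ui
    rows = []
    for a, b, level in pairs:
        def separates(carriers) -> bool:
            return (a in carriers) != (b in carriers)

        n_sub = sum(
            1 for s in sites
            if s.alleles[a] != s.alleles[b]
            and s.alleles[a] in "ACGT" and s.alleles[b] in "ACGT"
        )
        ev_sep = [e for e in events if separates(e.carriers or e.gapped_taxa)]
        s_units = {starts[e.columns[0]] for e in ev_sep if e.columns[0] in starts}
        row: dict[str, object] = {
            "taxon_a": a, "taxon_b": b, "level": level,
            "N": n_sub, "S": len(ev_sep),
            "N_over_S": round(n_sub / len(ev_sep), 2) if ev_sep else None,
        }
        for part, kinds in (
            ("whole", None), ("noncoding", {"intron", "spacer"}), ("coding", {EXON})
        ):
            with_cols: list[np.ndarray] = []
            without_cols: list[np.ndarray] = []
            for ui, (_, kind, cols) in enumerate(units):
                if kinds is not None and kind not in kinds:
                    continue
                (with_cols if ui in s_units else without_cols).append(cols)
            gds = p_distance(aln, a, b, np.concatenate(with_cols),
                             jukes_cantor) if with_cols else None
            gdn = p_distance(aln, a, b, np.concatenate(without_cols),
                             jukes_cantor) if without_cols else None
            row[f"gdS_{part}"] = None if gds is None else round(gds, 4)
            row[f"gdN_{part}"] = None if gdn is None else round(gdn, 4)
            row[f"gdS_gdN_{part}"] = (
                round(gds / gdn, 2) if gds is not None and gdn else None
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass
class RateEstimate:
    m: int          # observed mutation count
    n: int          # sites (bp)
    t_years: float  # time denominator in years
    mu: float       # per site per year
    se: float       # Poisson standard error, per site per year


def estimate_substitution_rate(m: int, n: int, t_years: float) -> RateEstimate:
    """mu = m / (n * T); SE treats m as Poisson: sqrt(m) / (n * T)."""
    if n <= 0 or t_years <= 0:
        raise ValueError("n and T must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    denom = n * t_years
    return RateEstimate(m=m, n=n, t_years=t_years,
                        mu=m / denom, se=math.sqrt(m) / denom)


def additive_time(topology: DatedTopology) -> float:
    """Total ingroup branch time in My (terminals contribute their full
    subtending branches)."""
    return topology.additive_time()


def estimate_structural_rate(
    event_count: int, n: int, additive_time_years: float
) -> RateEstimate:
    """Structural-mutation rate over the additive branch time."""
    return estimate_substitution_rate(event_count, n, additive_time_years)


def direction_bias_test(a: int, b: int) -> float:
    """Two-sided exact probability of an a:b direction split against 1:1."""
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("need non-negative counts with a positive total")
    return float(stats.binomtest(a, a + b, 0.5, alternative="two-sided").pvalue)


def stem_loop_correlation(inversions: list[StructuralEvent]) -> tuple[float, float] | None:
    """Pearson correlation of loop vs stem lengths with its t-test p-value;
    None for <3 inversions or zero variance."""
    pts = [(e.loop_length, e.stem_length) for e in inversions
           if e.loop_length is not None and e.stem_length is not None]
    if len(pts) < 3:
        return None
    loops, stems = zip(*pts)
    if len(set(loops)) == 1 or len(set(stems)) == 1:
        logger.info("stem/loop correlation undefined: zero variance")
        return None
    r, p = stats.pearsonr(loops, stems)
    return float(r), float(p)


def rank_rate_table(
    summary: pd.DataFrame,
    topology: DatedTopology,
    analyzed_length: int,
) -> pd.DataFrame:
    """Substitution-rate rows per taxonomic rank from a rank x region summary.

    T per rank is the age of the corresponding node (crown for subfamily,
    core crown for genus, cherry crowns for species)."""
    ages = {
        "subfamily": topology.ingroup_crown.age,
        "genus": topology.subfamily_core.age,
    }
    for cherry in topology.cherries:
        side = topology.branch_side[cherry.name]
        ages[f"species_{side}"] = cherry.age
    rows = []
    for stratum, t_my in ages.items():
        if stratum not in summary.index:
            continue
        m = int(summary.loc[stratum, "total_substitutions"])
        est = estimate_substitution_rate(m, analyzed_length, t_my * 1e6)
        rows.append({"rank": stratum, "m": m, "n": analyzed_length,
                     "T_My": t_my, "mu": est.mu, "se": est.se})
    return pd.DataFrame(rows)
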