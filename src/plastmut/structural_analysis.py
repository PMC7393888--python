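"""Structural-mutation extraction and classification.

Four event categories are recognized in a plastome alignment:

* **indel** — inserted/deleted sequence with no tandem-duplication or
  microsatellite structure;
* **repeat** — an insertion/deletion whose segment exactly duplicates the
  immediately adjacent upstream or downstream sequence (tandem duplication);
* **microsatellite** — copy-number slippage at a short (1–3 bp motif) repeat
  run;
* **inversion** — a short reverse-complemented segment (loop) flanked by an
  inverted-repeat pair (stem), i.e. a stem-loop flip.

Indel-like events are carved out of maximal runs of identical gap pattern;
inversions leave no gaps and are found by a reverse-complement scan between
taxa. Classification precedence is microsatellite > repeat > indel. Events
are placed on branches with the same small-parsimony mapping as SNPs
(binary gapped/ungapped, or orientation, character) and polarized by the
rank-appropriate outgroups: outgroups carrying the segment imply a deletion
in the carriers, outgroups lacking it an insertion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._fitch import map_binary_character, sankoff_min_changes
from .genomic_io import (
    EXON, INTRON, SPACER,
    RANK_AMBIGUOUS, RANK_GENUS, RANK_OUTGROUP, RANK_SPECIES, RANK_STEM,
    RANK_SUBFAMILY,
    DatedTopology, MultipleAlignment, RegionMap,
)
from .snp_analysis import COMPLEMENT

logger = logging.getLogger(__name__)

INDEL = "indel"
REPEAT = "repeat"
MICROSATELLITE = "microsatellite"
INVERSION = "inversion"

INSERTION = "insertion"
DELETION = "deletion"
UNCERTAIN = "uncertain"

#: indel size classes; the 50 bp boundary resolved as 1-10 / 11-50 / 51-100 / >100
INDEL_SIZE_CLASSES = (("1-10", 1, 10), ("11-50", 11, 50),
                      ("51-100", 51, 100), (">100", 101, None))


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))


@dataclass
class StructuralEvent:
    category: str                       # indel | repeat | microsatellite | inversion
    columns: tuple[int, int]            # half-open alignment span
    length: int                         # event length in bp (loop length for inversions)
    carriers: tuple[str, ...] = ()      # taxa bearing the derived state
    gapped_taxa: tuple[str, ...] = ()   # taxa gapped over the span (indel-like only)
    branch: str | None = None
    rank: str | None = None
    side: str | None = None
    parallel: bool = False
    direction: str = UNCERTAIN          # insertion | deletion | uncertain (indel-like)
    location: str | None = None         # exon | intron | spacer
    locus: str | None = None            # gene name or "left-right" spacer name
    span_boundary: bool = False
    motif: str | None = None            # microsatellites
    loop_length: int | None = None      # inversions
    stem_length: int | None = None      # inversions
    flag: str | None = None

    @property
    def ranked(self) -> bool:
        return self.rank in (RANK_SUBFAMILY, RANK_GENUS, RANK_SPECIES)


# ---------------------------------------------------------------------------
# Gap-pattern extraction
# ---------------------------------------------------------------------------

def extract_gap_events(
    aln: MultipleAlignment, topology: DatedTopology
) -> list[StructuralEvent]:
    """Maximal runs of identical gap pattern become one candidate event each.

    The gap pattern of a column is the set of taxa gapped there; overlapping
    or nested gap structures therefore split at every pattern boundary. Each
    candidate is branch-mapped on the binary gapped/ungapped character;
    carriers are the tips below the mapped branch (the clade bearing the
    derived state), falling back to the gapped set when the mapping is
    ambiguous.
    """
    taxa = [t for t in topology.taxa if t in aln.taxon_ids]
    mat = np.array([np.frombuffer(aln.row(t).encode(), dtype="S1") for t in taxa])
    gap = mat == b"-"
    any_gap = gap.any(axis=0)
    events: list[StructuralEvent] = []
    col = 0
    L = aln.length
    while col < L:
        if not any_gap[col]:
            col += 1
            continue
        pattern = gap[:, col]
        end = col + 1
        while end < L and any_gap[end] and (gap[:, end] == pattern).all():
            end += 1
        gapped = tuple(t for t, g in zip(taxa, pattern) if g)
        ev = StructuralEvent(
            category=INDEL, columns=(col, end), length=end - col,
            gapped_taxa=gapped,
        )
        if len(gapped) == len(taxa):
            ev.flag = "all-gap column run"
            ev.rank = RANK_AMBIGUOUS
        else:
            leaf_states = {t: ("1" if g else "0") for t, g in zip(taxa, pattern)}
            branch, rank, parallel = map_binary_character(topology, leaf_states)
            ev.branch, ev.rank, ev.parallel = branch, rank, parallel
            if branch is not None:
                ev.carriers = tuple(topology.clade_tips(branch))
                ev.side = topology.branch_side.get(branch)
            else:
                ev.carriers = gapped
        events.append(ev)
        col = end
    return events


# ---------------------------------------------------------------------------
# Classification cascade
# ---------------------------------------------------------------------------

def _segment_taxon(event: StructuralEvent, aln: MultipleAlignment) -> str | None:
    """A taxon holding the segment (ungapped over the span); reference first."""
    s, e = event.columns
    preferred = [aln.reference_taxon] if aln.reference_taxon else []
    for t in preferred + aln.taxon_ids:
        if t is None or t in event.gapped_taxa:
            continue
        seg = aln.row(t)[s:e]
        if "-" not in seg and "N" not in seg:
            return t
    return None


def _motif_run_length(seq: str, start: int, end: int, motif: str) -> tuple[int, int]:
    """Extend the motif run covering seq[start:end] left and right, in whole
    phase; returns (run_start, run_end) in `seq` coordinates."""
    m = len(motif)
    a = start
    while a - 1 >= 0 and seq[a - 1] == motif[(a - 1 - start) % m]:
        a -= 1
    b = end
    while b < len(seq) and seq[b] == motif[(b - start) % m]:
        b += 1
    return a, b


def classify_structural(
    event: StructuralEvent, aln: MultipleAlignment,
    mono_min_run: int = 8, multi_min_copies: int = 3,
) -> StructuralEvent:
    """Decide microsatellite > repeat > indel for one gap-run candidate.

    (1) microsatellite: the segment is >=1 whole copies of a 1-3 bp motif and
    the run in the longer allele (segment plus flanks) totals >= `mono_min_run`
    bp for mononucleotide motifs or >= `multi_min_copies` copies for di/tri;
    (2) repeat: the segment exactly duplicates the immediately adjacent
    upstream or downstream sequence of equal length; (3) otherwise indel.
    """
    taxon = _segment_taxon(event, aln)
    if taxon is None:
        event.category = INDEL
        event.flag = "segment unresolvable (flank all-gap)"
        return event
    s, e = event.columns
    row = aln.row(taxon)
    seg = row[s:e].replace("-", "")
    event.length = len(seg)
    # position of the segment within the taxon's ungapped sequence
    degapped = row.replace("-", "")
    pos = sum(1 for c in row[:s] if c != "-")
    # (1) microsatellite
    for m in (1, 2, 3):
        if len(seg) % m != 0 or len(seg) == 0:
            continue
        motif = seg[:m]
        if seg != motif * (len(seg) // m):
            continue
        if m > 1 and len(set(motif)) == 1:
            continue  # degenerate motif already handled at m=1
        a, b = _motif_run_length(degapped, pos, pos + len(seg), motif)
        run_bp = b - a
        if (m == 1 and run_bp >= mono_min_run) or (
            m > 1 and run_bp // m >= multi_min_copies
        ):
            event.category = MICROSATELLITE
            event.motif = motif
            return event
    # (2) tandem repeat
    L = len(seg)
    up = degapped[pos - L:pos] if pos - L >= 0 else ""
    down = degapped[pos + L:pos + 2 * L]
    if L > 0 and (up == seg or down == seg):
        event.category = REPEAT
        return event
    event.category = INDEL
    return event


def infer_structural_direction(
    event: StructuralEvent, topology: DatedTopology, aln: MultipleAlignment
) -> StructuralEvent:
    """Insertion/deletion polarity from the rank-appropriate outgroups.

    Outgroups all holding the segment (fully ungapped over the span) make the
    derived state 'absent'; all lacking it (fully gapped) make it 'present'.
    Disagreement, partial gaps, or an unranked event leave it uncertain.
    """
    if event.branch is None or not event.ranked:
        event.direction = UNCERTAIN
        return event
    outs = topology.rank_outgroups(event.branch)
    s, e = event.columns
    state = set()
    for t in outs:
        seg = aln.row(t)[s:e]
        if all(c == "-" for c in seg):
            state.add("absent")
        elif "-" not in seg:
            state.add("present")
        else:
            state.add("partial")
    carriers_gapped = all(t in event.gapped_taxa for t in event.carriers)
    if state == {"present"}:
        event.direction = DELETION if carriers_gapped else UNCERTAIN
    elif state == {"absent"}:
        event.direction = INSERTION if not carriers_gapped else UNCERTAIN
    else:
        event.direction = UNCERTAIN
    return event


# ---------------------------------------------------------------------------
# Inversion detection
# ---------------------------------------------------------------------------

def _pair_candidate_spans(
    ra: str, rb: str, min_total: int, max_total: int
) -> list[tuple[int, int]]:
    """Maximal reverse-complement-equal column spans between two aligned rows.

    A span [s, e) qualifies when both rows are clean (A/C/G/T) over it,
    ra[s:e] == revcomp(rb[s:e]), and the rows disagree somewhere inside.
    Mismatch positions inside such a span are symmetric about its center, so
    every span is anchored by a mirror pair of mismatches: candidate centers
    are enumerated from nearby mismatch pairs and expanded outward to
    maximality (capped at `max_total` columns). The span includes the stems:
    the left stem is the reverse complement of the right one, so the
    equality extends through both.
    """
    n = len(ra)
    comp = COMPLEMENT
    clean = [ra[i] in "ACGT" and rb[i] in "ACGT" for i in range(n)]
    mism = [i for i in range(n) if clean[i] and ra[i] != rb[i]]
    spans: set[tuple[int, int]] = set()
    for idx, m1 in enumerate(mism):
        for m2 in mism[idx:]:
            if m2 - m1 > max_total - 2:
                break
            M = m1 + m2 + 1  # span endpoints satisfy s + e == M
            i = (M - 1) // 2
            best = None
            while i >= 0:
                j = M - 1 - i
                if j >= n or M - 2 * i > max_total:
                    break
                if not (clean[i] and clean[j]):
                    break
                if ra[i] != comp[rb[j]] or ra[j] != comp[rb[i]]:
                    break
                if i <= m1:
                    best = i
                i -= 1
            if best is not None and M - 2 * best >= min_total:
                spans.add((best, M - best))
    # drop spans nested inside another reported span
    out = [s for s in spans
           if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)]
    return sorted(out)


def _decompose_stem_loop(sa: str, sb: str) -> tuple[int, int]:
    """Split a reverse-complement-equal span into (stem, loop): the stem is
    the edge run where the two orientations still agree (symmetric by
    construction), the loop the remainder."""
    s = 0
    while s < len(sa) // 2 and sa[s] == sb[s]:
        s += 1
    return s, len(sa) - 2 * s


def detect_inversions(
    aln: MultipleAlignment,
    topology: DatedTopology,
    min_stem: int = 7,
    max_loop: int = 100,
    max_stem: int = 60,
) -> list[StructuralEvent]:
    """Stem-loop inversions: spans where one taxon's sequence is the reverse
    complement of another's, flanked by an inverted-repeat pair of >=
    `min_stem` bp, with loop length in [2, `max_loop`].

    Orientation polarity comes from the rank outgroups when they agree; a
    convergent inversion (minimal reconstruction with several independent
    flips) is reported once per carrying branch, not merged.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    taxa = [t for t in topology.taxa if t in aln.taxon_ids]
    rows = {t: aln.row(t) for t in taxa}
    max_total = max_loop + 2 * max_stem
    min_total = 2 + 2 * min_stem
    spans: set[tuple[int, int]] = set()
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1:]:
            spans.update(
                _pair_candidate_spans(rows[ta], rows[tb], min_total, max_total)
            )
    events: list[StructuralEvent] = []
    for (s, e) in sorted(spans):
        # group taxa by orientation over the span
        variants: dict[str, list[str]] = {}
        for t in taxa:
            seg = rows[t][s:e]
            if "-" in seg or "N" in seg:
                continue
            variants.setdefault(seg, []).append(t)
        pair = None
        for seg in variants:
            rc = revcomp(seg)
            if rc != seg and rc in variants:
                pair = (seg, rc)
                break
        if pair is None:
            continue
        sa, sb = pair
        stem, loop = _decompose_stem_loop(sa, sb)
        if stem < min_stem or loop < 2 or loop > max_loop:
            continue
        group_a, group_b = variants[sa], variants[sb]
        # ancestral orientation from the two family-level outgroups
        anc = None
        out_states = {t: ("A" if t in group_a else "B" if t in group_b else None)
                      for t in topology.outgroup_taxa}
        vals = set(v for v in out_states.values() if v)
        if len(vals) == 1 and None not in out_states.values():
            anc = vals.pop()
        leaf_states = {
            t: ("A" if t in group_a else "B" if t in group_b else None)
            for t in taxa
        }
        best, recons = sankoff_min_changes(topology, leaf_states, ("A", "B"))
        if anc is not None:
            derived = "B" if anc == "A" else "A"
            recons = {
                r for r in recons
                if all(state == derived for _, state in r)
            } or recons
        recon = sorted(recons, key=lambda r: sorted(r))[0]
        for branch, state in sorted(recon):
            ev = StructuralEvent(
                category=INVERSION, columns=(s + stem, e - stem), length=loop,
                carriers=tuple(topology.clade_tips(branch)),
                branch=branch, rank=topology.branch_rank[branch],
                side=topology.branch_side.get(branch),
                parallel=len(recon) > 1,
                direction=UNCERTAIN,
                loop_length=loop, stem_length=stem,
            )
            if anc is not None:
                ev.flag = "orientation polarized by outgroups"
            events.append(ev)
    # the same loop may surface from spans with slightly different stem
    # extents (pair-dependent flank agreement): keep the longest-stem call
    best: dict[tuple, StructuralEvent] = {}
    for ev in events:
        key = (ev.columns, ev.branch)
        if key not in best or (ev.stem_length or 0) > (best[key].stem_length or 0):
            best[key] = ev
    return sorted(best.values(), key=lambda e: (e.columns, e.branch or ""))


# ---------------------------------------------------------------------------
# Location and summaries
# ---------------------------------------------------------------------------

def locate_event(
    event: StructuralEvent, regions: RegionMap, labels: np.ndarray
) -> StructuralEvent:
    """Region at the event's 5'-most column; boundary-spanning events keep the
    5' label and are flagged."""
    s, e = event.columns
    iv = regions.intervals[labels[s]]
    event.location = iv.kind
    event.locus = iv.gene
    if labels[e - 1] != labels[s]:
        event.span_boundary = True
    return event


def _size_class(length: int) -> str:
    for name, lo, hi in INDEL_SIZE_CLASSES:
        if length >= lo and (hi is None or length <= hi):
            return name
    return INDEL_SIZE_CLASSES[0][0]


def summarize_structural(
    events: list[StructuralEvent], topology: DatedTopology | None = None
) -> pd.DataFrame:
    """Per-rank category counts with size, location and direction breakdowns
    (the Table-3 shape), plus an exact binomial test of direction bias."""
    sides = topology.sides() if topology else []
    strata = [RANK_SUBFAMILY, RANK_GENUS] + [f"species_{s}" for s in sides] \
        + ["other", "total"]

    def stratum_of(ev: StructuralEvent) -> str:
        if not ev.ranked:
            return "other"
        if ev.rank == RANK_SPECIES and ev.side and f"species_{ev.side}" in strata:
            return f"species_{ev.side}"
        if ev.rank == RANK_GENUS:
            return RANK_GENUS
        if ev.rank == RANK_SUBFAMILY:
            return RANK_SUBFAMILY
        return "other"

    rows = []
    for cat in (INDEL, REPEAT, MICROSATELLITE, INVERSION):
        evs = [e for e in events if e.category == cat]
        row: dict[str, object] = {"category": cat}
        for st in strata[:-1]:
            row[st] = sum(1 for e in evs if stratum_of(e) == st)
        row["total"] = len(evs)
        if cat == INDEL:
            for name, *_ in INDEL_SIZE_CLASSES:
                row[f"size_{name}"] = sum(1 for e in evs if _size_class(e.length) == name)
        if cat in (INDEL, REPEAT, MICROSATELLITE):
            for loc in (EXON, INTRON, SPACER):
                row[f"loc_{loc}"] = sum(1 for e in evs if e.location == loc)
            ins = sum(1 for e in evs if e.direction == INSERTION)
            dele = sum(1 for e in evs if e.direction == DELETION)
            unc = sum(1 for e in evs if e.direction == UNCERTAIN)
            row.update(insertion=ins, deletion=dele, uncertain=unc)
            if ins + dele > 0:
                row["direction_bias_p"] = direction_bias_p(ins, dele)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("category")
    return df


def direction_bias_p(a: int, b: int) -> float:
    """Two-sided exact binomial probability of an a:b split against 1:1."""
    return float(stats.binomtest(a, a + b, 0.5, alternative="two-sided").pvalue)


def inversion_table(events: list[StructuralEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        if e.category != INVERSION:
            continue
        rows.append({
            "columns_start": e.columns[0] + 1, "columns_end": e.columns[1],
            "location": e.location, "locus": e.locus,
            "loop": e.loop_length, "stem": e.stem_length,
            "rank": e.rank, "branch": e.branch,
            "carriers": ",".join(e.carriers), "parallel": e.parallel,
        })
    return pd.DataFrame(rows, columns=[
        "columns_start", "columns_end", "location", "locus", "loop", "stem",
        "rank", "branch", "carriers", "parallel",
    ])


# ---------------------------------------------------------------------------
# Pipeline convenience
# ---------------------------------------------------------------------------

def analyze_structural(
    aln: MultipleAlignment,
    regions: RegionMap,
    topology: DatedTopology,
    labels: np.ndarray,
    min_stem: int = 7,
    max_loop: int = 100,
) -> list[StructuralEvent]:
    """Extract, classify, polarize and locate all structural events."""
    events = extract_gap_events(aln, topology)
    for ev in events:
        classify_structural(ev, aln)
        infer_structural_direction(ev, topology, aln)
        locate_event(ev, regions, labels)
    invs = detect_inversions(aln, topology, min_stem=min_stem, max_loop=max_loop)
    for ev in invs:
        locate_event(ev, regions, labels)
    return events + invs
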