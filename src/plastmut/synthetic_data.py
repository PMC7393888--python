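"""Plastome-like sequence evolution on the fixed dated topology, with a
complete ground-truth event log.

The generator plants an annotated root genome — protein-coding genes (ATG …
stop, optionally split by one intron), intergenic spacers, microsatellite
runs, exact tandem duplications and inverted-repeat stem-loop substrates —
and evolves it along every branch of the seven-taxon dated tree under
Poisson event processes:

* substitutions drawn from a 12-class directed weight matrix (defaults give
  a transition bias of ~1.6 and depressed A<->T / G<->C pools);
* indels with deletion:insertion odds 8.5 and a size mix dominated by
  1-10 bp events;
* tandem-repeat copy gains (85%) and losses (15%);
* microsatellite slippage (copy-number changes at planted runs);
* stem-loop inversions (reverse-complementing a planted loop).

The true alignment is emitted directly from the event bookkeeping — every
residue carries a persistent column identity — so downstream callers are
tested against calling error only, never alignment error. Structural events
are restricted to non-exonic sequence and substitutions avoid the planted
substrate spans; both choices keep the generator's category labels
consistent with the classifier definitions (see docs/methods.md).

Determinism: identical (config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .genomic_io import (
    EXON, INTRON, SPACER,
    DatedTopology, Gene, Interval, MultipleAlignment, RegionMap,
    default_topology, region_map_from_genes,
)
from .snp_analysis import COMPLEMENT, SnpSite
from .structural_analysis import (
    DELETION, INDEL, INSERTION, INVERSION, MICROSATELLITE, REPEAT,
    StructuralEvent, revcomp,
)

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: directed substitution weights w[ancestral][derived]; complementary-strand
#: symmetric, transition-biased, with rare A<->T and G<->C transversions
DEFAULT_SUBSTITUTION_WEIGHTS = {
    "A": {"C": 3.4, "G": 6.0, "T": 0.35},
    "C": {"A": 3.4, "G": 0.9, "T": 6.0},
    "G": {"A": 6.0, "C": 0.9, "T": 3.4},
    "T": {"A": 0.35, "C": 6.0, "G": 3.4},
}

INDEL_SIZE_MIX = (  # (probability, low, high), sizes in bp
    (0.76, 1, 10), (0.14, 11, 50), (0.06, 51, 100), (0.04, 101, 200),
)
REPEAT_LENGTH_MIX = {3: 0.034, 4: 0.239, 5: 0.444, 6: 0.180, 7: 0.017,
                     9: 0.026, 10: 0.026, 12: 0.034}
MICROSAT_MOTIF_MIX = (  # (probability, kind)
    (0.75, "mono_at"), (0.10, "mono_cg"), (0.10, "di"), (0.05, "tri"),
)


@dataclass
class SimulationConfig:
    """Study-condition defaults: genome composition per the sequenced
    plastomes (GC 0.39; coding/intron/spacer roughly 0.53/0.11/0.33 of the
    analyzed length), substitution rate matching the subfamily-rank estimate
    (0.14e-9 per site per year = 1.4e-4 per site per My), structural rates
    matching the observed event censuses over the additive tree time, and
    the observed direction biases."""

    genome_length: int = 20_000
    coding_fraction: float = 0.53
    intron_fraction: float = 0.11
    gc_content: float = 0.39
    substitution_rate: float = 1.4e-4          # events / site / My
    substitution_weights: dict = field(
        default_factory=lambda: {a: dict(d) for a, d in
                                 DEFAULT_SUBSTITUTION_WEIGHTS.items()})
    indel_rate: float = 5.5e-6                 # events / site / My
    deletion_insertion_odds: float = 8.5
    repeat_rate: float = 3.5e-6                # events / site / My
    repeat_gain_fraction: float = 0.85
    microsat_loci_per_kb: float = 1.0          # planted locus density
    microsat_slippage_rate: float = 1e-3       # events / locus / My
    inversion_substrates_per_kb: float = 1.0
    inversion_rate: float = 2.5e-4             # events / substrate / My
    tandem_dups_per_kb: float = 0.5            # planted repeat-loss substrates
    hotspot_fraction: float = 0.0              # fraction of units upweighted
    hotspot_multiplier: float = 1.0

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if not 0 <= self.coding_fraction <= 1 or not 0 <= self.intron_fraction <= 1:
            raise ValueError("fractions must lie in [0,1]")
        if self.coding_fraction + self.intron_fraction > 1:
            raise ValueError("coding + intron fractions exceed 1")
        for r in (self.substitution_rate, self.indel_rate, self.repeat_rate,
                  self.microsat_slippage_rate, self.inversion_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        cfg = cls(**json.loads(text))
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Truth log
# ---------------------------------------------------------------------------

@dataclass
class TruthEvent:
    branch: str
    kind: str                       # substitution | indel | repeat | microsatellite | inversion
    direction: str | None = None    # insertion | deletion (indel-like kinds)
    ids: tuple[int, ...] = ()       # residue identities involved
    inserted_chars: str | None = None
    anchor_id: int | None = None
    ancestral: str | None = None    # substitutions
    derived: str | None = None
    motif: str | None = None
    columns: tuple[int, int] | None = None  # filled at finalize
    carriers: tuple[str, ...] = ()


@dataclass
class TruthLog:
    events: list[TruthEvent] = field(default_factory=list)

    def substitutions(self) -> list[TruthEvent]:
        return [e for e in self.events if e.kind == "substitution"]

    def structural(self) -> list[TruthEvent]:
        return [e for e in self.events if e.kind != "substitution"]

    def finalize(self, column_of: dict[int, int], topology: DatedTopology) -> None:
        for e in self.events:
            cols = [column_of[i] for i in e.ids if i in column_of]
            if cols:
                e.columns = (min(cols), max(cols) + 1)
            e.carriers = tuple(topology.clade_tips(e.branch))


# ---------------------------------------------------------------------------
# Root genome generation
# ---------------------------------------------------------------------------

@dataclass
class Substrate:
    kind: str                # microsatellite | tandem_dup | inversion
    ids: tuple[int, ...]     # root residue ids of the whole substrate
    motif: str | None = None
    copy_len: int = 0        # tandem dup copy length
    stem: int = 0
    loop_ids: tuple[int, ...] = ()


def _random_bases(rng, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


_STOPS = ("TAA", "TAG", "TGA")


def _random_cds(rng, n_codons: int, gc: float) -> str:
    out = ["ATG"]
    while len(out) < n_codons - 1:
        c = _random_bases(rng, 3, gc)
        if c not in _STOPS:
            out.append(c)
    out.append(_STOPS[rng.integers(3)])
    return "".join(out)


def generate_root(
    config: SimulationConfig, seed: int
) -> tuple[str, RegionMap, list[Substrate]]:
    """Build the root sequence, its region map, and the planted substrates.

    Layout alternates spacer / gene (40% of genes carry one intron); mean
    element lengths are chosen so realized coding/intron/spacer fractions
    approximate the configured ones. Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    L = config.genome_length
    fc, fi = config.coding_fraction, config.intron_fraction
    fs = 1 - fc - fi
    gene_mean = 750
    intron_mean = (gene_mean * fi / fc / 0.4) if fc > 0 else 0
    spacer_mean = gene_mean * fs / fc if fc > 0 else L
    prefixes = ("atp", "ndh", "pet", "psa", "psb", "rpl", "rpo", "rps")

    parts: list[tuple[str, str, dict]] = []  # (kind, seq, meta)
    pos = 0
    gi = 0
    while pos < L:
        sp = int(max(40, rng.normal(spacer_mean, spacer_mean / 3))) if fc > 0 else L
        sp = min(sp, L - pos)
        parts.append((SPACER, _random_bases(rng, sp, config.gc_content), {}))
        pos += sp
        if pos >= L or fc == 0:
            break
        n_codons = int(rng.integers(80, 400))
        cds = _random_cds(rng, n_codons, config.gc_content)
        if pos + len(cds) + 200 > L:
            rest = L - pos
            if rest > 0:
                parts.append((SPACER, _random_bases(rng, rest, config.gc_content), {}))
            pos = L
            break
        gi += 1
        name = f"{prefixes[(gi - 1) % len(prefixes)]}{gi:02d}"
        strand = "+" if rng.random() < 0.5 else "-"
        meta = {"name": name, "strand": strand}
        if intron_mean > 0 and rng.random() < 0.4:
            ilen = int(max(60, rng.normal(intron_mean, intron_mean / 4)))
            cut = int(rng.integers(30, len(cds) - 30))
            meta["intron"] = (cut, ilen)
            seq = cds[:cut] + _random_bases(rng, ilen, config.gc_content) + cds[cut:]
        else:
            seq = cds
        if strand == "-":
            seq = revcomp(seq)
            if "intron" in meta:
                cut, ilen = meta["intron"]
                meta["intron"] = (len(cds) - cut, ilen)
        parts.append(("gene", seq, meta))
        pos += len(seq)

    seq_chars = list("".join(s for _, s, _ in parts))
    genome_len = len(seq_chars)

    # assemble genes / region map
    genes: list[Gene] = []
    cursor = 0
    for kind, s, meta in parts:
        if kind == "gene":
            g0, g1 = cursor, cursor + len(s)
            if "intron" in meta:
                cut, ilen = meta["intron"]
                exons = [Interval(g0, g0 + cut, EXON, meta["name"]),
                         Interval(g0 + cut + ilen, g1, EXON, meta["name"])]
            else:
                exons = [Interval(g0, g1, EXON, meta["name"])]
            genes.append(Gene(meta["name"], meta["strand"], True, exons))
        cursor += len(s)
    regions = region_map_from_genes(genes, genome_len)

    # plant substrates inside spacers
    substrates: list[Substrate] = []
    spacers = [iv for iv in regions.intervals if iv.kind == SPACER and len(iv) > 120]
    taken: list[tuple[int, int]] = []

    def place(span_len: int) -> int | None:
        for _ in range(60):
            iv = spacers[rng.integers(len(spacers))]
            if len(iv) < span_len + 20:
                continue
            start = int(rng.integers(iv.start + 10, iv.end - 10 - span_len))
            if all(start + span_len + 2 <= a or start >= b + 2 for a, b in taken):
                taken.append((start, start + span_len))
                return start
        return None

    n_ms = round(config.microsat_loci_per_kb * genome_len / 1000)
    for _ in range(n_ms):
        p, kind = _weighted_choice(rng, MICROSAT_MOTIF_MIX)
        if kind == "mono_at":
            motif = "A" if rng.random() < 0.5 else "T"
            run = motif * int(rng.integers(10, 15))
        elif kind == "mono_cg":
            motif = "C" if rng.random() < 0.5 else "G"
            run = motif * int(rng.integers(10, 15))
        elif kind == "di":
            motif = _distinct_motif(rng, 2)
            run = motif * int(rng.integers(4, 7))
        else:
            motif = _distinct_motif(rng, 3)
            run = motif * int(rng.integers(3, 6))
        start = place(len(run))
        if start is None:
            continue
        seq_chars[start:start + len(run)] = run
        # break the run at its borders so planted copy number is exact
        seq_chars[start - 1] = _not_base(rng, motif[-1])
        seq_chars[start + len(run)] = _not_base(rng, motif[0])
        substrates.append(Substrate(MICROSATELLITE,
                                    tuple(range(start, start + len(run))),
                                    motif=motif))

    n_dup = round(config.tandem_dups_per_kb * genome_len / 1000)
    for _ in range(n_dup):
        clen = int(rng.integers(4, 9))
        copy = _nonperiodic_segment(rng, clen, config.gc_content)
        start = place(2 * clen)
        if start is None:
            continue
        seq_chars[start:start + 2 * clen] = copy + copy
        seq_chars[start - 1] = _not_base(rng, copy[-1])
        seq_chars[start + 2 * clen] = _not_base(rng, copy[0])
        substrates.append(Substrate("tandem_dup",
                                    tuple(range(start, start + 2 * clen)),
                                    copy_len=clen))

    n_inv = round(config.inversion_substrates_per_kb * genome_len / 1000)
    for _ in range(n_inv):
        stem = int(rng.integers(7, 19))
        loop = int(rng.integers(4, 41))
        sseq = _nonperiodic_segment(rng, stem, config.gc_content)
        lseq = _random_bases(rng, loop, config.gc_content)
        while lseq[0] == COMPLEMENT[lseq[-1]] or lseq == revcomp(lseq):
            lseq = _random_bases(rng, loop, config.gc_content)
        total = 2 * stem + loop
        start = place(total)
        if start is None:
            continue
        seq_chars[start:start + total] = sseq + lseq + revcomp(sseq)
        ids = tuple(range(start, start + total))
        substrates.append(Substrate(INVERSION, ids, stem=stem,
                                    loop_ids=ids[stem:stem + loop]))

    return "".join(seq_chars), regions, substrates


def _weighted_choice(rng, mix):
    probs = np.array([row[0] for row in mix])
    i = rng.choice(len(mix), p=probs / probs.sum())
    return mix[i]


def _distinct_motif(rng, n: int) -> str:
    while True:
        m = _random_bases(rng, n, 0.5)
        if len(set(m)) > 1:
            return m


def _not_base(rng, avoid: str) -> str:
    choices = [b for b in BASES if b != avoid]
    return choices[rng.integers(len(choices))]


def _nonperiodic_segment(rng, n: int, gc: float) -> str:
    while True:
        s = _random_bases(rng, n, gc)
        if not _is_motif_repeat(s):
            return s


def _is_motif_repeat(seg: str) -> bool:
    for m in (1, 2, 3):
        if len(seg) >= m and len(seg) % m == 0 and seg == seg[:m] * (len(seg) // m):
            return True
    return False


# ---------------------------------------------------------------------------
# Evolution along the tree
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("ids", "chars", "used", "avail")

    def __init__(self, ids, chars, used, avail):
        self.ids: list[int] = ids
        self.chars: dict[int, str] = chars
        self.used: set[int] = used
        self.avail: set[int] = avail  # substrate indices still intact/unused

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.ids), dict(self.chars), set(self.used),
                        set(self.avail))


def _apply_deletion(lin: _Lineage, ids: tuple[int, ...]) -> None:
    i = lin.ids.index(ids[0])
    if lin.ids[i:i + len(ids)] != list(ids):
        raise RuntimeError("deletion span not contiguous")
    del lin.ids[i:i + len(ids)]


def _apply_insertion(lin: _Lineage, anchor: int | None, ids: tuple[int, ...],
                     chars: str) -> None:
    i = 0 if anchor is None else lin.ids.index(anchor) + 1
    lin.ids[i:i] = list(ids)
    for rid, c in zip(ids, chars):
        lin.chars[rid] = c


def _apply_inversion(lin: _Lineage, loop_ids: tuple[int, ...]) -> None:
    old = [lin.chars[i] for i in loop_ids]
    for rid, c in zip(loop_ids, reversed(old)):
        lin.chars[rid] = COMPLEMENT[c]


def _apply_substitution(lin: _Lineage, rid: int, derived: str) -> None:
    lin.chars[rid] = derived


@dataclass
class SimulationResult:
    alignment: MultipleAlignment
    regions: RegionMap            # on the reference taxon's coordinates
    topology: DatedTopology
    truth: TruthLog
    root_sequence: str
    root_regions: RegionMap
    config: SimulationConfig
    hotspot_units: set[int] = field(default_factory=set)


def evolve(
    root_seq: str,
    root_regions: RegionMap,
    topology: DatedTopology,
    config: SimulationConfig,
    seed: int,
    substrates: list[Substrate] | None = None,
) -> SimulationResult:
    """Evolve the root along every branch; returns the true alignment plus
    the complete event log. ``seed`` drives all randomness."""
    rng = np.random.default_rng(seed)
    substrates = substrates or []
    L0 = len(root_seq)

    # residue id -> root annotation unit (interval index); inherited on insert
    unit_of: dict[int, int] = {}
    for i, iv in enumerate(root_regions.intervals):
        for p in range(iv.start, iv.end):
            unit_of[p] = i
    exon_units = {i for i, iv in enumerate(root_regions.intervals) if iv.kind == EXON}
    n_units = len(root_regions.intervals)
    mult = np.ones(n_units)
    hotspot_units: set[int] = set()
    if config.hotspot_fraction > 0 and config.hotspot_multiplier != 1.0:
        # hotspots are drawn from the units that can also receive structural
        # events (non-exonic), so high substitution rate and structural
        # placement are coupled in the same units
        noncoding = [u for u in range(n_units) if u not in exon_units]
        k = max(1, round(config.hotspot_fraction * len(noncoding)))
        pick = rng.choice(len(noncoding), size=k, replace=False)
        hotspot_units = {noncoding[int(i)] for i in pick}
        for u in hotspot_units:
            mult[u] = config.hotspot_multiplier

    substrate_ids: set[int] = set()
    for sub in substrates:
        substrate_ids.update(sub.ids)

    next_id = [L0]
    insertion_journal: list[tuple[int | None, tuple[int, ...]]] = []
    truth = TruthLog()

    def fresh_ids(n: int) -> tuple[int, ...]:
        ids = tuple(range(next_id[0], next_id[0] + n))
        next_id[0] += n
        return ids

    root_lin = _Lineage(list(range(L0)), {i: c for i, c in enumerate(root_seq)},
                        set(), set(range(len(substrates))))

    tip_states: dict[str, _Lineage] = {}

    def struct_ok(lin: _Lineage, span_ids: list[int], margin_ids: list[int]) -> bool:
        for rid in span_ids:
            if rid in lin.used or rid in substrate_ids or unit_of[rid] in exon_units:
                return False
        for rid in margin_ids:
            if rid in lin.used:
                return False
        return True

    def do_branch(node_name: str, lin: _Lineage, dur: float) -> None:
        Lc = len(lin.ids)
        idx_of = {rid: i for i, rid in enumerate(lin.ids)}
        w_struct = np.array(
            [0.0 if (lin.ids[i] in substrate_ids or unit_of[lin.ids[i]] in exon_units)
             else mult[unit_of[lin.ids[i]]] for i in range(Lc)]
        )
        if w_struct.sum() > 0:
            p_struct = w_struct / w_struct.sum()
        else:
            p_struct = None

        def draw_pos() -> int:
            return int(rng.choice(Lc, p=p_struct))

        tasks = (
            [("indel", None)] * rng.poisson(config.indel_rate * Lc * dur)
            + [("repeat", None)] * rng.poisson(config.repeat_rate * Lc * dur)
            + [("microsat", None)] * rng.poisson(
                config.microsat_slippage_rate * len(lin.avail) * dur)
            + [("inversion", None)] * rng.poisson(
                config.inversion_rate
                * sum(1 for s in lin.avail if substrates[s].kind == INVERSION)
                * dur)
        )
        rng.shuffle(tasks)
        for kind, _ in tasks:
            if p_struct is None:
                break
            if kind == "indel":
                _do_indel(node_name, lin, draw_pos)
            elif kind == "repeat":
                _do_repeat(node_name, lin, draw_pos)
            elif kind == "microsat":
                _do_microsat(node_name, lin)
            elif kind == "inversion":
                _do_inversion(node_name, lin)

        # substitutions on the post-structural sequence
        n_sub = rng.poisson(config.substitution_rate * len(lin.ids) * dur)
        if n_sub:
            w = np.array([0.0 if rid in substrate_ids else mult[unit_of[rid]]
                          for rid in lin.ids])
            w_sum = w.sum()
            if w_sum > 0:
                picks = rng.choice(len(lin.ids), size=n_sub, p=w / w_sum)
                wm = config.substitution_weights
                for i in picks:
                    rid = lin.ids[int(i)]
                    a = lin.chars[rid]
                    if a not in wm:
                        continue
                    row = wm[a]
                    ds = list(row)
                    pr = np.array([row[d] for d in ds])
                    d = ds[int(rng.choice(len(ds), p=pr / pr.sum()))]
                    _apply_substitution(lin, rid, d)
                    truth.events.append(TruthEvent(
                        branch=node_name, kind="substitution", ids=(rid,),
                        ancestral=a, derived=d))

    # -- event constructors --------------------------------------------------

    def _sample_indel_len() -> int:
        p, lo, hi = _weighted_choice(rng, INDEL_SIZE_MIX)
        return int(rng.integers(lo, hi + 1))

    def _mimics_structure(left: str, seg: str, right: str) -> bool:
        """Would an indel of `seg` between `left` and `right` classify as a
        tandem repeat or microsatellite under the caller's cascade?"""
        k = len(seg)
        if k and (left[-k:] == seg or right[:k] == seg):
            return True
        for m in (1, 2, 3):
            if k == 0 or k % m or seg != seg[:m] * (k // m):
                continue
            motif = seg[:m]
            ext_l = 0
            while ext_l < len(left) and left[-1 - ext_l] == motif[(-1 - ext_l) % m]:
                ext_l += 1
            ext_r = 0
            while ext_r < len(right) and right[ext_r] == motif[ext_r % m]:
                ext_r += 1
            run = k + ext_l + ext_r
            if (m == 1 and run >= 8) or (m > 1 and run // m >= 3):
                return True
        return False

    def _context(lin: _Lineage, lo: int, hi: int) -> str:
        lo, hi = max(0, lo), min(len(lin.ids), hi)
        return "".join(lin.chars[lin.ids[j]] for j in range(lo, hi))

    def _do_indel(branch: str, lin: _Lineage, draw_pos) -> None:
        odds = config.deletion_insertion_odds
        for _ in range(50):
            deletion = rng.random() < odds / (1 + odds)
            length = _sample_indel_len()
            if deletion:
                if len(lin.ids) <= length + 2:
                    continue
                i = draw_pos()
                if i + length >= len(lin.ids):
                    continue
                span = lin.ids[i:i + length]
                margin = [lin.ids[j] for j in (i - 1, i + length) if 0 <= j < len(lin.ids)]
                if not struct_ok(lin, span, margin):
                    continue
                seg = "".join(lin.chars[r] for r in span)
                if _mimics_structure(_context(lin, i - 24, i), seg,
                                     _context(lin, i + length, i + length + 24)):
                    continue
                _apply_deletion(lin, tuple(span))
                lin.used.update(span + margin)
                truth.events.append(TruthEvent(
                    branch=branch, kind=INDEL, direction=DELETION,
                    ids=tuple(span)))
                return
            else:
                i = draw_pos()
                if i < 1 or i + 1 >= len(lin.ids):
                    continue
                anchor = lin.ids[i]
                nxt = lin.ids[i + 1]
                if not struct_ok(lin, [anchor, nxt], []):
                    continue
                seg = _random_bases(rng, length, config.gc_content)
                if _mimics_structure(_context(lin, i - 23, i + 1), seg,
                                     _context(lin, i + 1, i + 25)):
                    continue
                ids = fresh_ids(length)
                _apply_insertion(lin, anchor, ids, seg)
                for rid in ids:
                    unit_of[rid] = unit_of[anchor]
                insertion_journal.append((anchor, ids))
                lin.used.update(ids)
                lin.used.update((anchor, nxt))
                truth.events.append(TruthEvent(
                    branch=branch, kind=INDEL, direction=INSERTION,
                    ids=ids, inserted_chars=seg, anchor_id=anchor))
                return

    def _sample_repeat_len() -> int:
        ls = list(REPEAT_LENGTH_MIX)
        pr = np.array([REPEAT_LENGTH_MIX[l] for l in ls])
        return int(ls[int(rng.choice(len(ls), p=pr / pr.sum()))])

    def _do_repeat(branch: str, lin: _Lineage, draw_pos) -> None:
        gain = rng.random() < config.repeat_gain_fraction
        if not gain:
            cands = [s for s in lin.avail
                     if substrates[s].kind == "tandem_dup"
                     and all(r in lin.chars for r in substrates[s].ids)
                     and set(substrates[s].ids) <= set(lin.ids)
                     and not (set(substrates[s].ids) & lin.used)]
            if cands:
                si = sorted(cands)[int(rng.integers(len(cands)))]
                sub = substrates[si]
                clen = sub.copy_len
                second = sub.ids[clen:]
                _apply_deletion(lin, tuple(second))
                lin.avail.discard(si)
                lin.used.update(sub.ids)
                truth.events.append(TruthEvent(
                    branch=branch, kind=REPEAT, direction=DELETION,
                    ids=tuple(second)))
                return
            gain = True  # no intact substrate left: fall back to a gain
        for _ in range(50):
            length = _sample_repeat_len()
            i = draw_pos()
            if i + length + 1 >= len(lin.ids):
                continue
            span = lin.ids[i:i + length]
            margin = [lin.ids[j] for j in (i - 1, i + length) if 0 <= j < len(lin.ids)]
            if not struct_ok(lin, span, margin):
                continue
            seg = "".join(lin.chars[r] for r in span)
            if _is_motif_repeat(seg):
                continue
            up = "".join(lin.chars[r] for r in lin.ids[max(0, i - length):i])
            if up == seg:
                continue  # would create a triplication of an existing pair
            ids = fresh_ids(length)
            anchor = span[-1]
            _apply_insertion(lin, anchor, ids, seg)
            for rid in ids:
                unit_of[rid] = unit_of[anchor]
            insertion_journal.append((anchor, ids))
            lin.used.update(ids)
            lin.used.update(span + margin)
            substrate_ids.update(ids)
            substrate_ids.update(span)
            truth.events.append(TruthEvent(
                branch=branch, kind=REPEAT, direction=INSERTION,
                ids=ids, inserted_chars=seg, anchor_id=anchor))
            return

    def _do_microsat(branch: str, lin: _Lineage) -> None:
        cands = [s for s in lin.avail
                 if substrates[s].kind == MICROSATELLITE
                 and set(substrates[s].ids) <= set(lin.ids)
                 and not (set(substrates[s].ids) & lin.used)]
        if not cands:
            return
        si = sorted(cands)[int(rng.integers(len(cands)))]
        sub = substrates[si]
        motif = sub.motif
        m = len(motif)
        copies = len(sub.ids) // m
        k = int(rng.integers(1, 3))  # 1-2 copies gained or lost
        insertion = rng.random() < 0.5
        lin.avail.discard(si)
        lin.used.update(sub.ids)
        if insertion:
            first = sub.ids[0]
            i = lin.ids.index(first)
            anchor = lin.ids[i - 1] if i > 0 else None
            seg = motif * k
            ids = fresh_ids(len(seg))
            _apply_insertion(lin, anchor, ids, seg)
            ref_unit = unit_of[first]
            for rid in ids:
                unit_of[rid] = ref_unit
            insertion_journal.append((anchor, ids))
            lin.used.update(ids)
            substrate_ids.update(ids)
            truth.events.append(TruthEvent(
                branch=branch, kind=MICROSATELLITE, direction=INSERTION,
                ids=ids, inserted_chars=seg, anchor_id=anchor, motif=motif))
        else:
            k = min(k, copies - 1)
            if k < 1:
                return
            # remove copies from either end of the run
            span = sub.ids[-k * m:] if rng.random() < 0.5 else sub.ids[:k * m]
            _apply_deletion(lin, tuple(span))
            truth.events.append(TruthEvent(
                branch=branch, kind=MICROSATELLITE, direction=DELETION,
                ids=tuple(span), motif=motif))

    def _do_inversion(branch: str, lin: _Lineage) -> None:
        cands = [s for s in lin.avail
                 if substrates[s].kind == INVERSION
                 and set(substrates[s].ids) <= set(lin.ids)
                 and not (set(substrates[s].ids) & lin.used)]
        if not cands:
            return
        si = sorted(cands)[int(rng.integers(len(cands)))]
        sub = substrates[si]
        _apply_inversion(lin, sub.loop_ids)
        lin.avail.discard(si)
        lin.used.update(sub.ids)
        truth.events.append(TruthEvent(
            branch=branch, kind=INVERSION, ids=sub.loop_ids))

    # -- walk the tree -------------------------------------------------------

    def walk(node, lin: _Lineage) -> None:
        for child in node.children:
            clin = lin.copy()
            do_branch(child.name, clin, node.age - child.age)
            if child.is_leaf:
                tip_states[child.name] = clin
            else:
                walk(child, clin)

    walk(topology.root, root_lin)

    # -- emit the true alignment ---------------------------------------------
    master = list(range(L0))
    for anchor, ids in insertion_journal:
        i = 0 if anchor is None else master.index(anchor) + 1
        master[i:i] = list(ids)
    column_of = {rid: c for c, rid in enumerate(master)}

    order = _alignment_order(topology)
    rows = []
    for t in order:
        lin = tip_states[t]
        row = ["-"] * len(master)
        for rid in lin.ids:
            row[column_of[rid]] = lin.chars[rid]
        rows.append("".join(row))
    reference = order[0]
    aln = MultipleAlignment(order, rows, reference_taxon=reference)

    truth.finalize(column_of, topology)
    ref_regions = _reference_regions(tip_states[reference].ids, unit_of,
                                     root_regions)
    return SimulationResult(
        alignment=aln, regions=ref_regions, topology=topology, truth=truth,
        root_sequence=root_seq, root_regions=root_regions, config=config,
        hotspot_units=hotspot_units,
    )


def _alignment_order(topology: DatedTopology) -> list[str]:
    order = []
    for cherry in topology.cherries:
        order.extend(cherry.tips())
    order.append(topology.idiospermum)
    order.extend(topology.outgroup_taxa)
    return order


def _reference_regions(
    ref_ids: list[int], unit_of: dict[int, int], root_regions: RegionMap
) -> RegionMap:
    """Rebuild the region map on the reference tip's own coordinates.

    Exons are never hit by structural events, so every root exon survives
    intact; intron and spacer lengths shift with the reference's indels."""
    genes: dict[str, Gene] = {}
    root_ivs = root_regions.intervals
    exon_runs: dict[tuple[str, int], list[int]] = {}
    for pos, rid in enumerate(ref_ids):
        iv = root_ivs[unit_of[rid]]
        if iv.kind == EXON:
            exon_runs.setdefault((iv.gene, unit_of[rid]), []).append(pos)
    gene_exons: dict[str, list[Interval]] = {}
    for (gene, _), positions in sorted(exon_runs.items(), key=lambda kv: kv[1][0]):
        s, e = positions[0], positions[-1] + 1
        if e - s != len(positions):
            raise RuntimeError(f"exon of '{gene}' fragmented in reference")
        gene_exons.setdefault(gene, []).append(Interval(s, e, EXON, gene))
    out = []
    for gene, exons in gene_exons.items():
        g0 = root_regions.genes[gene]
        out.append(Gene(gene, g0.strand, g0.coding,
                        sorted(exons, key=lambda iv: iv.start)))
    return region_map_from_genes(out, len(ref_ids))


def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int = 0,
    topology: DatedTopology | None = None,
) -> SimulationResult:
    """generate_root + evolve with derived sub-seeds (all from `seed`)."""
    config = config or SimulationConfig()
    topology = topology or default_topology()
    ss = np.random.SeedSequence(seed)
    s_root, s_evo = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    root_seq, root_regions, substrates = generate_root(config, s_root)
    return evolve(root_seq, root_regions, topology, config, s_evo, substrates)


# ---------------------------------------------------------------------------
# Truth replay (log completeness check)
# ---------------------------------------------------------------------------

def replay(
    truth: TruthLog, root_seq: str, topology: DatedTopology
) -> dict[str, str]:
    """Re-derive every tip's ungapped sequence purely from the event log.

    The log is replayed branch by branch along the tree; agreement with the
    alignment rows is the strongest internal-consistency check of the
    simulator's bookkeeping."""
    by_branch: dict[str, list[TruthEvent]] = {}
    for e in truth.events:
        by_branch.setdefault(e.branch, []).append(e)
    tips: dict[str, str] = {}

    def walk(node, lin: _Lineage) -> None:
        for child in node.children:
            clin = lin.copy()
            for e in by_branch.get(child.name, []):
                if e.kind == "substitution":
                    _apply_substitution(clin, e.ids[0], e.derived)
                elif e.kind == INVERSION:
                    _apply_inversion(clin, e.ids)
                elif e.direction == DELETION:
                    _apply_deletion(clin, e.ids)
                else:
                    _apply_insertion(clin, e.anchor_id, e.ids, e.inserted_chars)
            if child.is_leaf:
                tips[child.name] = "".join(clin.chars[r] for r in clin.ids)
            else:
                walk(child, clin)

    root_lin = _Lineage(list(range(len(root_seq))),
                        {i: c for i, c in enumerate(root_seq)}, set(), set())
    walk(topology.root, root_lin)
    return tips


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def score_recovery(
    truth: TruthLog,
    called_events: list[StructuralEvent],
    called_sites: list[SnpSite] | None = None,
    topology: DatedTopology | None = None,
) -> dict:
    """Per-category precision/recall (reciprocal span overlap >= 50%, same
    category), direction accuracy over direction-known calls, and — when SNP
    calls are supplied — rank and ancestral-state accuracy against the log."""
    cats = (INDEL, REPEAT, MICROSATELLITE, INVERSION)
    out: dict = {}
    matched_pairs: list[tuple[TruthEvent, StructuralEvent]] = []
    for cat in cats:
        tr = [e for e in truth.structural() if e.kind == cat and e.columns]
        ca = [e for e in called_events if e.category == cat]
        used: set[int] = set()
        hits = 0
        for te in tr:
            best = None
            for j, ce in enumerate(ca):
                if j in used:
                    continue
                ov = _overlap(te.columns, ce.columns)
                ta = te.columns[1] - te.columns[0]
                cb = ce.columns[1] - ce.columns[0]
                if ov >= 0.5 * ta and ov >= 0.5 * cb:
                    best = j
                    break
            if best is not None:
                used.add(best)
                hits += 1
                matched_pairs.append((te, ca[best]))
        out[f"{cat}_recall"] = hits / len(tr) if tr else None
        out[f"{cat}_precision"] = hits / len(ca) if ca else None
        out[f"{cat}_n_truth"] = len(tr)
        out[f"{cat}_n_called"] = len(ca)

    dir_pairs = [
        (te, ce) for te, ce in matched_pairs
        if te.direction is not None and ce.direction != "uncertain"
    ]
    out["direction_n"] = len(dir_pairs)
    out["direction_accuracy"] = (
        sum(te.direction == ce.direction for te, ce in dir_pairs) / len(dir_pairs)
        if dir_pairs else None
    )

    if called_sites is not None and topology is not None:
        sub_by_col: dict[int, list[TruthEvent]] = {}
        ingroup = set(topology.ingroup_taxa)
        for e in truth.substitutions():
            if e.columns and set(e.carriers) & ingroup:
                sub_by_col.setdefault(e.columns[0], []).append(e)
        n = rank_ok = anc_ok = 0
        for s in called_sites:
            if not (s.is_clean_biallelic and s.direction_known):
                continue
            tr = sub_by_col.get(s.column, [])
            tr = [t for t in tr if set(t.carriers) <= ingroup]
            if len(tr) != 1:
                continue
            te = tr[0]
            n += 1
            rank_ok += (s.branch == te.branch)
            anc_ok += (s.ancestral == te.ancestral)
        out["snp_n_scored"] = n
        out["snp_rank_accuracy"] = rank_ok / n if n else None
        out["snp_ancestral_accuracy"] = anc_ok / n if n else None
    return out


def expected_pooled_proportions(
    config: SimulationConfig,
    root_seq: str,
    topology: DatedTopology | None = None,
) -> dict[str, float]:
    """Pooled 6-class substitution proportions implied by the weight matrix
    and the root base composition.

    Without a topology this is the single-event expectation (site drawn
    uniformly, derived state from the ancestral base's weight row). With a
    topology the expectation accounts for multiple hits within a branch: the
    per-site process is a Markov jump chain with uniform jump rate r (the
    substitution rate) and jump matrix J[a][d] = w_ad / sum_d w_ad, so the
    branch-endpoint pair distribution is pi_a * expm(r t (J - I))[a, d];
    off-diagonal mass is summed over the ingroup rank branches, which is
    what an outgroup-polarized census observes."""
    from scipy.linalg import expm
    from .snp_analysis import POOLED_CLASSES

    n = len(root_seq)
    pi = np.array([root_seq.count(b) / n for b in BASES])
    W = np.array([[config.substitution_weights[a].get(d, 0.0) for d in BASES]
                  for a in BASES])
    J = W / W.sum(axis=1, keepdims=True)
    directed = np.zeros((4, 4))
    if topology is None:
        directed = pi[:, None] * J
    else:
        r = config.substitution_rate
        for b in topology.ingroup_branches():
            t = topology.branch_duration(b)
            P = expm(r * t * (J - np.eye(4)))
            directed += pi[:, None] * P
    np.fill_diagonal(directed, 0.0)
    directed /= directed.sum()
    idx = {b: i for i, b in enumerate(BASES)}
    pooled = {}
    for pool in POOLED_CLASSES:
        x, y = pool.split("+")
        pooled[pool] = float(directed[idx[x[0]], idx[x[2]]]
                             + directed[idx[y[0]], idx[y[2]]])
    return pooled
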