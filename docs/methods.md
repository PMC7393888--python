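# Methods

## The analysis model

`plastmut` treats a plastome alignment of five ingroup taxa and two
family-level outgroups as a census of mutation events on a fixed, dated,
fully resolved topology `(((a,b),(c,d)),e)` + two outgroups: two congeneric
species pairs ("cherries") forming one subfamily, a monotypic sister
subfamily, and two successive outgroups (accepted either as a clade or as a
grade). Branches carry taxonomic ranks: the monotypic-subfamily terminal
and the stem of the two-genus subfamily are *subfamily*-rank branches, the
two genus stems *genus*-rank, and the four cherry terminals *species*-rank.
The analysis assumes the topology is known a priori and is not re-estimated
from the data — the point of the design is that mutation directions are
read off a phylogeny that is independent of the alignment being analyzed.

### Nucleotide sites

A column is polymorphic when ≥ 2 distinct bases occur among the five
ingroup taxa. Columns where any ingroup taxon has a gap or N are excluded
from SNP calling (gaps belong to the structural census; this keeps the two
censuses disjoint). Outgroup gaps/Ns only block polarization, not calling.
Allelism (biallelic / triallelic / quadallelic) is recorded over ingroup
states; triallelic and parallel sites are counted but excluded from
direction, spectrum and dN/dS summaries.

Branch placement uses Sankoff small parsimony over the observed states,
with exhaustive enumeration of minimal reconstructions. An outgroup base
that is not one of the two ingroup alleles is scored as missing: it carries
no information about where the ingroup change happened, and treating it as
a real state would inflate the change count into a spurious parallel call.
A site maps to a branch only when exactly one minimal single-change
placement exists; ties give rank `ambiguous`, and a Fitch minimum ≥ 2 flags
a parallel mutation. Note that "biallelic" in the rank × region census
means *clean* biallelic: two-state columns that are parallel are a separate
class (a two-state column produced by convergence is still excluded).

Polarization is hierarchical: subfamily-rank sites are read against both
family outgroups, genus-rank sites against the monotypic subfamily,
species-rank sites against the two taxa of the sister genus. The direction
is accepted only when all rank-outgroup taxa unanimously carry one of the
two ingroup alleles; that allele is ancestral. This unanimity rule is the
package's operational definition of "inferable direction".

Substitutions are classified into the 12 directed classes and pooled into
6 complementary-strand classes (two transition pools, four transversion
pools). Class-bias significance uses the likelihood-ratio G statistic
`G = 2 Σ O ln(O/E)` with uniform expected proportions by default and a
chi-square tail on k−1 degrees of freedom; expected counts < 1 set a
warning flag recommending an exact multinomial test.

Coding effect: the ancestral codon is the *reference* codon context with
the ancestral base substituted at the site (strand-aware; minus-strand
genes are complemented through the coordinate map), the derived codon
swaps in the derived base, and the two are translated under the plastid
genetic code (table 11). Each SNP is evaluated independently against the
ancestral context; codons carrying more than one SNP are flagged. dN/dS is
the raw event-count ratio dN/dS = (#nonsynonymous)/(#synonymous), undefined
when dS = 0 — deliberately not a per-site-normalized estimate, because the
downstream tables are count censuses.

### Structural events

Maximal runs of identical gap pattern (the same set of taxa gapped over
contiguous columns) are one candidate event each; nested or overlapping
gap structures therefore split at pattern boundaries. The binary
gapped/ungapped character is branch-mapped exactly like a SNP; carriers are
the tips below the mapped branch. Classification cascade (precedence
microsatellite > repeat > indel):

1. **microsatellite** — the segment is ≥ 1 whole copies of a 1–3 bp motif
   and the motif run in the longer allele (segment plus flanks) totals
   ≥ 8 bp for mononucleotide motifs or ≥ 3 copies for di-/trinucleotide
   motifs (conventional cpSSR minima; both thresholds are parameters);
2. **repeat** — the segment exactly duplicates the immediately adjacent
   upstream or downstream flank of equal length (tandem duplication);
3. **indel** — everything else.

Direction: if all rank-outgroup taxa hold the segment (fully ungapped over
the span) the derived state is absence → deletion in the carriers; if all
lack it → insertion; disagreement, partial gaps, or an unranked event →
uncertain. Direction is a report field, never a filter.

Indel size classes are 1–10 / 11–50 / 51–100 / > 100 bp, with the published
bins' ambiguous boundary at 50 resolved as 11–50 / 51–100. Direction bias
is tested with the two-sided exact binomial probability of the
insertion:deletion split against 1:1 (the exact-test arithmetic behind a
2-category Fisher test).

### Inversions

A stem-loop inversion appears in an alignment as a span where one taxon's
sequence is the reverse complement of another's, flanked by an
inverted-repeat pair. Because the left stem is the reverse complement of
the right one, the reverse-complement equality extends through the stems:
the scanner therefore looks for maximal reverse-complement-equal spans
between taxon pairs. Inside such a span, row mismatches are symmetric
about its center, so every span is anchored by a mirror pair of
mismatches; the scanner enumerates candidate centers from nearby mismatch
pairs and expands outward to maximality (equivalent to, and tested
against, an exhaustive substring scan). The span is decomposed into stem
(the edge run where the two orientations still agree) and loop (the rest);
events require stem ≥ `min_stem` (default 7 bp, the smallest published
stem), loop between 2 and `max_loop` (default 100 bp, above the largest
published loop of 92 bp). Orientation polarity comes from the family
outgroups when they agree; a convergent inversion is reported once per
carrying branch in the minimal reconstruction, never merged, since the
published inversions include two shared by non-sister taxa. Inversions are
"non-directional": uncertain polarity never drops an event.

### Association of structural and nucleotide mutation

For each comparison pair, annotation units (one unit per gene's exon set,
per intron, per spacer) are split into those containing at least one
structural event whose carriers separate the pair ("with S", by the
event's 5′-most column) and the rest. gdS and gdN are p-distances
(mismatches / compared columns, excluding columns gapped or N in either
taxon) over the concatenated columns of each class, for the whole genome
and for the noncoding and coding partitions. Uncorrected p-distance is the
deliberate choice: the observed distances are < 0.04, where model
correction is negligible, and p-distance is exactly testable; a
Jukes–Cantor hook exists. Units rather than fixed windows anchor "regions
with structural mutations" because units are reproducible and
annotation-anchored; the unit definition is the package's own, since no
precise extent is published.

### Rates

`mu = m/(nT)` per site per year, with ages supplied in My and converted to
years in exactly one place. The published variance formula for this
estimator is self-referential as printed; the package uses the Poisson
standard error `sqrt(m)/(nT)` as its interpretation. Substitution rates
use the rank's node age as T — note this divides the mutations of *both*
branches at that rank by a single divergence time, which is the census
convention, so rank rates are not per-branch rates. Structural rates
divide by the additive time: the sum of ingroup branch durations (250.1 My
for the study ages 108.8/18.7/7.6/6.2). Only the subfamily-rank published
rate is exactly recoverable from published inputs (m = 1996, n = 130,345,
T = 108.8 My → 0.14e-9); the genus- and species-rank published values do
not follow from the published counts and ages, so the package reports its
own values and treats the published rank-rate mean (0.25e-9) purely as
arithmetic on the printed rates.

## The simulator

The synthetic-data module is first-class code that defines the study
conditions. `generate_root` plants an annotated root genome: protein-coding
genes (ATG…stop, 40% split by one intron), intergenic spacers, and — inside
spacers — microsatellite runs, exact tandem duplications (repeat-loss
substrates) and inverted-repeat stem-loop cassettes (inversion substrates).
`evolve` draws Poisson event counts per branch (expectation rate × length ×
branch duration in My) and applies them; every residue carries a persistent
column identity, so the emitted alignment is the *true* alignment and
caller tests measure calling error only, never alignment error. The truth
log records every event with enough detail that `replay` reproduces every
tip sequence from the root exactly — the strongest internal-consistency
check, asserted in the suite.

Default parameters and where they come from:

| parameter | default | anchor |
|---|---|---|
| genome_length | 20,000 bp | scaled-down plastome (single-copy representation) |
| coding/intron/spacer fractions | 0.53/0.11/0.33 | the analyzed-length partition of the study genomes |
| GC content | 0.39 | the sequenced genomes' GC |
| substitution_rate | 1.4e-4 /site/My | the subfamily-rank rate 0.14e-9 /site/yr |
| 12-class weights | Ts 6.0, common Tv 3.4, A<->T 0.35, G<->C 0.9 | reproduce Ts/Tv ≈ 1.6 and the depressed A<->T (~2.8%) and G<->C (~3.6%) pools |
| indel_rate | 5.5e-6 /site/My | 178 indels / (130,345 bp × 250.1 My) |
| deletion:insertion odds | 8.5 | the observed deletion bias |
| repeat_rate | 3.5e-6 /site/My | 116 repeats over the same denominator |
| repeat gain fraction | 0.85 | 85.3% insertion-direction repeats |
| microsat loci | 1.0 /kb | 129 loci / 130 kb |
| microsat slippage | 1e-3 /locus/My; ±1–2 copies, 50:50 | non-directional slippage |
| inversion substrates | 1.0 /kb; events 2.5e-4 /substrate/My | ≈ 2 inversions per 20 kb genome, matching 13 / 130 kb with rare convergence |
| node ages | 108.8/18.7/7.6/6.2 My (root 140, outgroup crown 120) | the dated topology; undated outgroup nodes get the calibration bound (140) and an intermediate value |

Generator hygiene, chosen so the generator's labels agree with the
classifier's deterministic definitions: structural events are placed only
in non-exonic sequence (the real censuses are overwhelmingly noncoding and
this keeps the reference annotation's codon structure valid); substitutions
avoid the planted substrate spans (~2–3% of the genome) so motif runs,
duplicate copies and stem-loop orientations stay exact; indel segments are
redrawn if they would mimic a tandem duplication or extend a
microsatellite run past the calling threshold; one structural event per
substrate per lineage. Hotspot mode multiplies both the substitution and
the structural placement weight of a fraction of *noncoding* units
(hotspots must be in units that can receive structural events, otherwise
the association question is ill-posed).

What the simulator does not emulate: alignment error (by design), the
quadripartite LSC/IR/SSC architecture and IR-copy duplication, tRNA/rRNA
genes, rate heterogeneity across sites (beyond the optional hotspot
units), GC-content differences between coding and noncoding sequence, and
selection (coding effects are neutral). Passing recovery tests therefore
demonstrate that the callers and classifiers are correct on correctly
aligned data under realistic event densities — not that they are robust to
alignment artifacts or IR double-counting, which real analyses must handle
upstream (the package requires a single-copy representation of the
genome).

## Expected spectrum under multiple hits

The recovery suite compares the called pooled spectrum with the generating
weights. A site's observed (ancestral, derived) pair is the endpoint of a
Markov jump chain along its branch — with uniform per-site jump rate r and
jump matrix J[a][d] = w_ad / Σ_d w_ad — not a single draw, so the expected
class proportions are computed from `expm(r t (J − I))` per ingroup rank
branch, weighted by base composition, with off-diagonal mass normalized.
At the default rate the correction mainly re-inflates the rare A<->T pool,
which multi-step paths reach disproportionately often.

## Numerical and reporting conventions

Coordinates are 0-based half-open internally; GFF3 is converted at the
boundary and all reports print 1-based inclusive positions. Percents and
ratios print to 2 dp, rates to 2 significant figures in scientific
notation. Columns containing N in any ingroup taxon are excluded from SNP
calling and p-distance denominators with a logged count. Boundary-spanning
structural events take the region of their 5′-most column and are flagged.
Ties among minimal parsimony placements are never broken silently — they
become `ambiguous`. All randomness flows from a single seed through
`numpy.random.Generator`; analysis stages are seed-free and rerun
byte-identically.

## Problem sizes used by the test suite

Recovery checks run five 20 kb simulations under the default (study)
conditions, pooling roughly 3,000 polarized substitutions and 600
structural events; association checks run twenty 10 kb replicates each for
independent and hotspot placement; oracle equivalences run on all 126
binary patterns of the 7-taxon tree, 2 kb inversion fixtures, and 100
random exonic SNPs per strand. These sizes are the package's chosen
validation conditions: large enough that binomial noise sits well inside
the asserted tolerances (3 SE), small enough to keep the whole suite in
tens of seconds.

## Known limitations

* Parsimony branch mapping cannot see convergent events that minimal
  reconstructions explain with fewer changes (e.g. both outgroups flipping
  the same stem-loop makes the inverted orientation look ancestral); such
  events are genuinely unidentifiable from the data and appear as misses
  in recovery scoring at high convergence densities.
* The subfamily-rank census mixes two branches over one divergence time
  (see Rates); comparisons of rank rates are therefore census conventions,
  not per-branch rate estimates.
* Repeat losses require an intact pre-existing duplication; the simulator
  falls back to a gain when none remains, so realized gain:loss odds can
  sit slightly above the configured value at high repeat rates.
* gdS/gdN inherits the unit definition; very small units with few
  comparable columns produce noisy per-unit distances, which is why the
  association is reported over concatenated columns, not averaged per
  unit.
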