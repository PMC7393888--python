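"""SNP calling, branch mapping, polarization and classification."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from oracles import brute_force_branch_call, whole_gene_effect
from plastmut.genomic_io import (
    EXON, Gene, Interval, MultipleAlignment, build_coordinate_map,
    project_regions, region_map_from_genes,
)
from plastmut.snp_analysis import (
    DIRECTED_CLASSES, POOLED_CLASSES, CodingContext, SnpSite,
    analyze_snps, call_polymorphic_sites, classify_coding_effect,
    classify_substitution, codon_usage, amino_acid_composition,
    infer_direction, map_to_branch, spectrum, summarize_gene_groups,
    summarize_rank_region,
)
from plastmut.snp_analysis import test_substitution_bias as g_test_bias

TAXA = ["Calycanthus_chinensis", "Calycanthus_floridus",
        "Chimonanthus_nitens", "Chimonanthus_praecox",
        "Idiospermum_australiense",
        "Liriodendron_tulipifera", "Magnolia_kwangsiensis"]


def aln_from_columns(cols, reference=TAXA[0]):
    """Build a 7-taxon alignment from per-column taxon->base strings."""
    rows = ["".join(c[i] for c in cols) for i in range(len(TAXA))]
    return MultipleAlignment(list(TAXA), rows, reference_taxon=reference)


def one_column_site(bases, topology):
    """bases: 7 chars in TAXA order; returns the called site (or None)."""
    pad = "A" * 7  # monomorphic guard columns
    aln = aln_from_columns([pad, bases, pad])
    sites = call_polymorphic_sites(aln, topology)
    return sites[0] if sites else None


class TestCalling:
    def test_biallelic_column(self, topology):
        s = one_column_site("AAAGGGG", topology)
        assert s is not None and s.allelism == "biallelic"
        assert s.ingroup_alleles == ("A", "G")

    def test_triallelic_column(self, topology):
        s = one_column_site("AACGGGG", topology)
        assert s.allelism == "triallelic"

    def test_ingroup_gap_excludes_column(self, topology):
        assert one_column_site("AA-GGGG", topology) is None

    def test_ingroup_n_excludes_column(self, topology):
        assert one_column_site("AANGGGG", topology) is None

    def test_outgroup_gap_does_not_exclude(self, topology):
        s = one_column_site("AAAGG-G", topology)
        assert s is not None

    def test_degenerate_monomorphic_alignment(self, topology):
        aln = aln_from_columns(["AAAAAAA", "CCCCCCC"])
        assert call_polymorphic_sites(aln, topology) == []

    def test_allelism_conservation(self, sim, sim_analysis):
        sites = sim_analysis["sites"]
        by = {"biallelic": 0, "triallelic": 0, "quadallelic": 0}
        for s in sites:
            by[s.allelism] += 1
        assert sum(by.values()) == len(sites)


class TestBranchMapping:
    def test_forced_single_change_subfamily(self, topology):
        # all four core taxa A, Idiospermum and both outgroups G
        s = one_column_site("AAAAGGG", topology)
        map_to_branch(s, topology)
        assert s.rank == "subfamily" and not s.parallel
        assert s.branch == "core_crown"

    def test_parallel_two_gains(self, topology):
        # C. chinensis and Ch. nitens share T independently
        s = one_column_site("TCTCCCC", topology)
        map_to_branch(s, topology)
        assert s.parallel and s.rank == "ambiguous"

    def test_outgroup_third_allele_is_uninformative(self, topology):
        # outgroups carry C, not among the ingroup alleles {A,G}
        s = one_column_site("GAAAACC", topology)
        map_to_branch(s, topology)
        assert not s.parallel and s.rank == "species"
        assert s.branch == "Calycanthus_chinensis"

    def test_agrees_with_exhaustive_enumeration(self, topology):
        # every informative binary ingroup pattern, outgroups fixed ancestral
        for mask in range(1, 2 ** 5 - 1):
            bases = ["G" if mask >> i & 1 else "A" for i in range(5)] + ["A", "A"]
            s = one_column_site("".join(bases), topology)
            map_to_branch(s, topology)
            leaf_states = {t: b for t, b in zip(TAXA, bases)}
            branch, parallel = brute_force_branch_call(
                topology, leaf_states, ("A", "G"))
            assert (s.branch, s.parallel) == (branch, parallel), bases


class TestDirection:
    def test_species_rank_polarized_by_sister_genus(self, topology):
        s = one_column_site("GAAAAAA", topology)
        map_to_branch(s, topology)
        infer_direction(s, topology)
        assert s.rank == "species" and s.direction_known
        assert (s.ancestral, s.derived) == ("A", "G")

    def test_rank_outgroups_disagree_uncertain(self, topology):
        # subfamily-rank split; the two family outgroups read C vs A
        s = one_column_site("AAAAGCA", topology)
        map_to_branch(s, topology)
        infer_direction(s, topology)
        assert s.rank == "subfamily" and not s.direction_known

    def test_outgroup_gap_uncertain(self, topology):
        s = one_column_site("AAAAG--", topology)
        map_to_branch(s, topology)
        infer_direction(s, topology)
        assert not s.direction_known

    def test_simulated_direction_accuracy(self, sim, sim_analysis, topology):
        from plastmut.synthetic_data import score_recovery
        m = score_recovery(sim.truth, sim_analysis["events"],
                           sim_analysis["sites"], sim.topology)
        assert m["snp_n_scored"] > 300
        assert m["snp_ancestral_accuracy"] >= 0.95


class TestClassifySubstitution:
    def test_transition_example(self):
        assert classify_substitution("A", "G") == (
            "transition", "A>G", "A>G+T>C")

    def test_transversion_example(self):
        assert classify_substitution("C", "A") == (
            "transversion", "C>A", "C>A+G>T")

    def test_exhaustive_four_transitions_eight_transversions(self):
        kinds = [classify_substitution(a, d)[0]
                 for a in "ACGT" for d in "ACGT" if a != d]
        assert kinds.count("transition") == 4
        assert kinds.count("transversion") == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")

    def test_pooling_preserves_totals(self, sim_analysis):
        sp = spectrum(sim_analysis["sites"]).loc["all"]
        assert sum(sp[c] for c in DIRECTED_CLASSES) == sp["total"]
        assert sum(sp[p] for p in POOLED_CLASSES) == sp["total"]


def make_coding_fixture(strand="+"):
    """One 12-codon gene at positions 10..46 on a 60 bp reference."""
    rng = random.Random(7)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < 11:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    if strand == "-":
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        body = "".join(comp[b] for b in reversed(cds))
    else:
        body = cds
    ref = "A" * 10 + body + "C" * 14
    gene = Gene("g1", strand, True, [Interval(10, 46, EXON, "g1")])
    rm = region_map_from_genes([gene], 60)
    rows = [ref] * 7
    aln = MultipleAlignment(list(TAXA), rows, reference_taxon=TAXA[0])
    return aln, rm, cds


class TestCodingEffect:
    def test_third_position_synonymous(self, topology):
        # codon ATT -> ATC is Ile -> Ile
        ref = "ATTATTATT" + "A" * 21
        gene = Gene("g", "+", True, [Interval(0, 9, EXON, "g")])
        rm = region_map_from_genes([gene], 30)
        aln = MultipleAlignment(list(TAXA), [ref] * 7, reference_taxon=TAXA[0])
        cmap = build_coordinate_map(aln, TAXA[0])
        s = SnpSite(column=2, alleles={t: "T" for t in TAXA},
                    ingroup_alleles=("C", "T"), region=EXON, gene="g",
                    ancestral="T", derived="C", direction_known=True)
        classify_coding_effect(s, rm, aln, cmap)
        assert s.coding_effect == "synonymous"

    def test_first_position_nonsynonymous(self, topology):
        ref = "ATTATTATT" + "A" * 21
        gene = Gene("g", "+", True, [Interval(0, 9, EXON, "g")])
        rm = region_map_from_genes([gene], 30)
        aln = MultipleAlignment(list(TAXA), [ref] * 7, reference_taxon=TAXA[0])
        cmap = build_coordinate_map(aln, TAXA[0])
        s = SnpSite(column=0, alleles={t: "A" for t in TAXA},
                    ingroup_alleles=("A", "C"), region=EXON, gene="g",
                    ancestral="A", derived="C", direction_known=True)
        classify_coding_effect(s, rm, aln, cmap)
        assert s.coding_effect == "nonsynonymous"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_whole_gene_translation(self, strand):
        rng = random.Random(11)
        aln, rm, cds = make_coding_fixture(strand)
        cmap = build_coordinate_map(aln, TAXA[0])
        ref = aln.row(TAXA[0])
        ctx = CodingContext(rm, ref)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for _ in range(100):
            col = rng.randrange(10, 46)
            anc = ref[col]
            der = rng.choice([b for b in "ACGT" if b != anc])
            s = SnpSite(column=col, alleles={t: anc for t in TAXA},
                        ingroup_alleles=tuple(sorted((anc, der))),
                        region=EXON, gene="g1", ancestral=anc, derived=der,
                        direction_known=True)
            classify_coding_effect(s, rm, aln, cmap, ctx)
            off = ctx.cds_offset("g1", col)
            a, d = (anc, der) if strand == "+" else (comp[anc], comp[der])
            expected = whole_gene_effect(cds, off, a, d)
            assert s.coding_effect == expected, (col, anc, der)


class TestSummaries:
    def _sites(self):
        sites = []
        for i in range(53):
            sites.append(SnpSite(column=i, alleles={}, allelism="biallelic",
                                 rank="genus", branch="cherryA_crown",
                                 region=EXON, coding_effect="nonsynonymous"))
        for i in range(65):
            sites.append(SnpSite(column=100 + i, alleles={}, allelism="biallelic",
                                 rank="genus", branch="cherryA_crown",
                                 region=EXON, coding_effect="synonymous"))
        return sites

    def test_dn_ds_count_ratio(self, topology):
        rm = region_map_from_genes([], 130345)
        df = summarize_rank_region(self._sites(), rm, topology)
        assert df.loc["genus", "dn_ds"] == pytest.approx(0.82)

    def test_site_density_percent(self, topology):
        rm = region_map_from_genes([], 130345)
        sites = [SnpSite(column=i, alleles={}, allelism="biallelic",
                         rank="subfamily", branch="core_crown",
                         region="spacer") for i in range(1996)]
        df = summarize_rank_region(sites, rm, topology)
        assert df.loc["subfamily", "total_percent"] == pytest.approx(1.53)

    def test_empty_site_list_all_zero(self, topology):
        rm = region_map_from_genes([], 1000)
        df = summarize_rank_region([], rm, topology)
        assert (df["total_substitutions"] == 0).all()
        import pandas as pd
        assert pd.isna(df.loc["total", "dn_ds"])  # undefined, not a number

    def test_gene_group_ratios(self):
        sites = []
        for i in range(6):
            sites.append(SnpSite(column=i, alleles={}, allelism="biallelic",
                                 rank="genus", branch="cherryA_crown",
                                 region=EXON, gene="psb01",
                                 direction_known=True, ts_tv="transition"))
        for i in range(2):
            sites.append(SnpSite(column=10 + i, alleles={}, allelism="biallelic",
                                 rank="genus", branch="cherryA_crown",
                                 region=EXON, gene="psb01",
                                 direction_known=True, ts_tv="transversion"))
        df = summarize_gene_groups(sites).set_index("group")
        assert df.loc["psb", "ts_tv"] == pytest.approx(3.0)
        assert df.loc["psb", "dn_ds"] is None  # zero synonymous: undefined

    def test_gene_groups_match_recount(self, sim_analysis):
        sites = sim_analysis["sites"]
        df = summarize_gene_groups(sites).set_index("group")
        for grp in df.index:
            ts = sum(1 for s in sites
                     if s.region == EXON and s.direction_known
                     and s.is_clean_biallelic and s.ts_tv == "transition"
                     and s.gene.lower().startswith(grp))
            assert df.loc[grp, "ts"] == ts


class TestGTest:
    def test_uniform_counts_null(self):
        r = g_test_bias([10, 10, 10, 10])
        assert r.g == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_single_nonzero_cell_closed_form(self):
        r = g_test_bias([100, 0, 0, 0])
        assert r.g == pytest.approx(2 * 100 * math.log(4))
        assert r.df == 3

    def test_matches_direct_likelihood_computation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(1, 200, size=6)
            r = g_test_bias(counts.tolist())
            g2, p2 = stats.power_divergence(counts, lambda_="log-likelihood")
            assert r.g == pytest.approx(float(g2))
            assert r.p_value == pytest.approx(float(p2))

    def test_low_expected_flagged(self):
        r = g_test_bias([3, 1, 0, 0, 0, 0])
        assert r.low_expected


class TestCodonUsage:
    def _fixture(self):
        ref = "ATGATTTAA" + "C" * 21
        gene = Gene("g", "+", True, [Interval(0, 9, EXON, "g")])
        rm = region_map_from_genes([gene], 30)
        aln = MultipleAlignment(list(TAXA), [ref] * 7, reference_taxon=TAXA[0])
        return aln, rm

    def test_simple_gene_counts(self):
        aln, rm = self._fixture()
        df = codon_usage(aln, rm, TAXA[0])
        got = dict(zip(df["codon"], df["count"]))
        assert got == {"ATG": 1, "ATT": 1, "TAA": 1}
        assert all(abs(p - 33.33) < 0.01 for p in df["percent"])

    def test_percent_normalization_and_aa_aggregation(self, sim, sim_analysis):
        df = codon_usage(sim.alignment, sim.regions,
                         sim.alignment.reference_taxon, sim_analysis["labels"])
        assert df["percent"].sum() == pytest.approx(100, abs=0.05)
        aa = amino_acid_composition(df)
        assert aa["percent"].sum() == pytest.approx(100, abs=0.05)
        leu = aa.set_index("amino_acid").loc["L", "count"]
        assert leu == df[df["amino_acid"] == "L"]["count"].sum()
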