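"""CDS assembly, codon counting, RSCU, classification, start/stop audit."""

import pytest

from mitochar.codons import (
    SYNONYMOUS_FAMILIES,
    classify_codons,
    codon_counts,
    extract_cds,
    rscu,
    start_stop_audit,
)
from mitochar.model import AnnotationSet, CircularGenome, GeneFeature, Segment, revcomp


def _genome(seq):
    return CircularGenome("toy", seq)


def _feature(strand, segments, name="g", category="PCG"):
    return GeneFeature(name, category, strand, [Segment(s, e) for s, e in segments])


class TestExtractCds:
    def test_forward_single_segment_direct_slice(self):
        g = _genome("ATGAAATTTCCC")
        assert extract_cds(g, _feature("J", [(1, 6)])) == "ATGAAA"

    def test_reverse_strand_is_reverse_complement(self):
        g = _genome("TTACAT" + "G" * 10)
        assert extract_cds(g, _feature("N", [(1, 6)])) == "ATGTAA"

    def test_trans_spliced_reverse_gene_recovers_planted_cds(self, sim_circle1):
        genome, ann, truth = sim_circle1
        multi_n = [
            (f, t)
            for f, t in zip(ann.features, truth.planted_genes)
            if f.strand == "N" and len(f.segments) > 1
        ]
        assert multi_n, "template should plant a trans-spliced N-strand gene"
        for feature, planted in multi_n:
            assert extract_cds(genome, feature) == planted.coding_sequence

    def test_segment_beyond_genome_bounds_is_an_error(self):
        g = _genome("ACGTACGT")
        with pytest.raises(Exception, match="exceeds"):
            extract_cds(g, _feature("J", [(5, 20)]))

    def test_strand_symmetry_of_codon_counts(self):
        # the same gene planted forward, or as its reverse complement on
        # the other strand, yields identical codon counts
        cds = "ATGGCTTTAGAATTTTGCCACTAA"
        fwd = _genome(cds + "ACGT")
        rev = _genome(revcomp(cds) + "ACGT")
        n = len(cds)
        counts_fwd = codon_counts([extract_cds(fwd, _feature("J", [(1, n)]))]).counts
        counts_rev = codon_counts([extract_cds(rev, _feature("N", [(1, n)]))]).counts
        assert counts_fwd == counts_rev


class TestCodonCounts:
    def test_minimal_cds(self):
        table = codon_counts(["ATGTAA"])
        assert table.counts["ATG"] == 1
        assert table.counts["TAA"] == 1
        assert table.total_codons == 2

    def test_trailing_partial_codon_dropped_and_accounted(self):
        table = codon_counts(["ATGAAAT"])
        assert table.total_codons == 2
        assert table.dropped_nt == 1
        assert 3 * table.total_codons + table.dropped_nt == 7

    def test_ambiguous_codons_excluded_but_tallied(self):
        table = codon_counts(["ATGNNNTAA"])
        assert table.total_codons == 2
        assert table.ambiguous_codons == 1

    def test_simulated_pool_frequencies_match_profile(self, sim_circle2):
        genome, ann, truth = sim_circle2
        # only codons between the forced init and term are profile draws
        pool = [
            g.coding_sequence[3:-3] for g in truth.planted_genes
            if g.category in ("PCG", "other")
        ]
        table = codon_counts(pool)
        from scipy import stats

        codons_list = [c for c in table.counts if truth.codon_profile.get(c)]
        observed = [table.counts[c] for c in codons_list]
        total = sum(observed)
        probs = [truth.codon_profile[c] for c in codons_list]
        expected = [total * p / sum(probs) for p in probs]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert total > 800
        # 99.9% chi-square band for the multinomial draw
        assert chi2 < stats.chi2.ppf(0.999, df=len(codons_list) - 1)


class TestRSCU:
    def test_hand_arithmetic_for_phe_family(self):
        table = codon_counts(["TTT"] * 3 + ["TTC"])
        rscu(table)
        assert table.rscu["TTT"] == pytest.approx(1.5)
        assert table.rscu["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self):
        table = codon_counts(list(SYNONYMOUS_FAMILIES["L"]))  # one of each Leu codon
        rscu(table)
        for codon in SYNONYMOUS_FAMILIES["L"]:
            assert table.rscu[codon] == pytest.approx(1.0)

    def test_single_codon_families_pin_to_one(self):
        table = codon_counts(["ATGTGGTGG"])
        rscu(table)
        assert table.rscu["ATG"] == 1.0
        assert table.rscu["TGG"] == 1.0

    def test_unobserved_family_is_blank_not_zero(self):
        table = codon_counts(["ATG"])
        rscu(table)
        assert table.rscu["CAT"] is None  # no His observed

    def test_family_normalization_sums_to_family_size(self, sim_circle2):
        genome, ann, truth = sim_circle2
        pool = [
            g.coding_sequence for g in truth.planted_genes
            if g.category in ("PCG", "other")
        ]
        table = rscu(codon_counts(pool))
        for aa, family in SYNONYMOUS_FAMILIES.items():
            values = [table.rscu[c] for c in family]
            if all(v is not None for v in values):
                assert sum(values) == pytest.approx(len(family))

    def test_stop_family_included_by_default_excluded_on_request(self):
        table = codon_counts(["ATGTAA", "ATGTAA", "ATGTGA"])
        rscu(table)
        assert table.rscu["TAA"] == pytest.approx(2.0)
        rscu(table, include_stops=False)
        assert "TAA" not in table.rscu

    def test_monotonicity_in_own_count(self):
        lo = rscu(codon_counts(["TTT"] * 2 + ["TTC"] * 2))
        hi = rscu(codon_counts(["TTT"] * 3 + ["TTC"] * 2))
        assert hi.rscu["TTT"] > lo.rscu["TTT"]
        assert hi.rscu["TTC"] <= lo.rscu["TTC"]


class TestClassification:
    def test_threshold_classes(self):
        table = codon_counts(["TTT"] * 3 + ["TTC"])
        classify_codons(table)
        assert table.classification["TTT"] == "optimal"
        assert table.classification["TTC"] == "non_optimal"

    def test_met_and_trp_have_no_preference(self):
        table = codon_counts(["ATGTGGATG"])
        classify_codons(table)
        assert table.classification["ATG"] == "no_preference"
        assert table.classification["TGG"] == "no_preference"

    def test_balanced_family_all_no_preference(self):
        table = codon_counts(["TTTTTC"])
        classify_codons(table)
        assert table.classification["TTT"] == "no_preference"
        assert table.classification["TTC"] == "no_preference"


class TestStartStopAudit:
    def test_planted_codons_recovered(self, sim_circle1):
        genome, ann, truth = sim_circle1
        audit = start_stop_audit(genome, ann, categories=("PCG", "other"))
        expected = {
            g.name: (g.init_codon, g.term_codon)
            for g in truth.planted_genes
            if g.category in ("PCG", "other")
        }
        for _, row in audit.iterrows():
            init, term = expected[row["gene"]]
            assert row["init_codon"] == init
            assert row["term_codon"] == term

    def test_acg_start_is_noncanonical(self):
        g = _genome("ACGAAATGA")
        audit = start_stop_audit(g, AnnotationSet("t", [_feature("J", [(1, 9)])]))
        row = audit.iloc[0]
        assert row["init_codon"] == "ACG"
        assert not bool(row["is_canonical_start"])

    def test_short_cds_flagged_not_audited(self):
        g = _genome("ATGCA")
        audit = start_stop_audit(g, AnnotationSet("t", [_feature("J", [(1, 5)])]))
        assert audit.iloc[0]["flag"] == "too_short"

    def test_declared_mismatch_reported(self):
        g = _genome("ATGAAATGA")
        f = _feature("J", [(1, 9)])
        f.declared_init_codon = "ACG"
        audit = start_stop_audit(g, AnnotationSet("t", [f]))
        assert not bool(audit.iloc[0]["init_matches_declared"])
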