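"""Perfect SSR and minisatellite detection, checked against a brute-force
enumerator and planted ground truth."""

import numpy as np
import pytest

from mitochar.model import CircularGenome, revcomp
from mitochar.repeats import (
    canonical_motif,
    find_ssrs,
    find_tandem_repeats,
    repeat_fraction,
    resolve_overlaps,
)


def _min_dividing_period(unit):
    k = len(unit)
    for p in range(1, k):
        if k % p == 0 and unit == unit[:p] * (k // p):
            return p
    return k


def brute_force_ssrs(seq, thresholds):
    """Independent oracle: O(n*k) literal enumeration of maximal perfect
    runs on a linear sequence."""
    n = len(seq)
    found = set()
    for k, thr in thresholds.items():
        for start in range(n - k):
            # maximality on the left
            if start > 0 and start - 1 + k < n and seq[start - 1] == seq[start - 1 + k]:
                continue
            m = k
            while start + m < n and seq[start + m] == seq[start + m - k]:
                m += 1
            copies = m // k
            unit = seq[start : start + k]
            if copies >= thr and _min_dividing_period(unit) == k:
                found.add((canonical_motif(unit), k, copies, start + 1))
    return found


def _random_genome(length, seed, circular=True):
    rng = np.random.default_rng(seed)
    return CircularGenome(
        "rand", "".join(rng.choice(list("ACGT"), size=length)), circular
    )


class TestFindSSRs:
    def test_matches_brute_force_on_random_background(self):
        genome = _random_genome(5_000, seed=3, circular=False)
        loose = {1: 5, 2: 3, 3: 3, 4: 2, 5: 2, 6: 2}  # low thresholds: many hits
        records = find_ssrs(genome, loose)
        got = {(r.motif, r.unit_len, r.copies, r.start) for r in records}
        assert got == brute_force_ssrs(genome.sequence, loose)
        assert len(got) > 30

    def test_run_below_threshold_not_reported(self):
        genome = CircularGenome("t", "ACGTC" + "G" * 5 + "ATCAT" * 4, circular=False)
        assert all(r.motif != "G" for r in find_ssrs(genome))

    def test_planted_dinucleotide_exact_coordinates(self, sim_circle1):
        genome, ann, truth = sim_circle1
        found = {(r.motif, r.copies, r.start, r.start - 1 + r.span) for r in find_ssrs(genome)}
        for planted in truth.planted_repeats:
            if planted.unit_len <= 6:
                assert (
                    planted.motif,
                    planted.copies,
                    planted.start,
                    planted.end,
                ) in found

    def test_planted_in_gene_repeat_annotated_with_host_gene(self, sim_circle1):
        genome, ann, truth = sim_circle1
        records = find_ssrs(genome, annotations=ann)
        mono = [r for r in records if r.motif == "T" and r.copies == 10]
        assert mono and mono[0].in_gene == "orf309"

    def test_origin_spanning_repeat_found_once_with_wrap_flag(self):
        base = _random_genome(600, seed=9)
        seq = base.sequence[:250] + "AT" * 8 + base.sequence[250:]
        # guard flanks so the run is exactly (AT)8
        seq = seq[:249] + "C" + seq[250:]
        seq = seq[: 250 + 16] + "C" + seq[250 + 17 :]
        rotated = CircularGenome("rot", seq[258:] + seq[:258])
        hits = [r for r in find_ssrs(rotated) if r.motif == "AT"]
        assert len(hits) == 1
        assert hits[0].wraps_origin
        assert hits[0].copies == 8

    def test_rotation_invariance_of_census_multiset(self, sim_circle1):
        genome, _, _ = sim_circle1
        census = lambda g: sorted(
            (r.motif, r.unit_len, r.copies) for r in find_ssrs(g)
        )
        assert census(genome) == census(genome.rotated(genome.length // 3))

    def test_reverse_complement_pairing(self, sim_circle1):
        genome, _, _ = sim_circle1
        fwd = find_ssrs(genome)
        rev = find_ssrs(CircularGenome("rc", revcomp(genome.sequence)))
        expected = sorted(
            (canonical_motif(revcomp(r.unit)), r.copies) for r in fwd
        )
        assert expected == sorted((r.motif, r.copies) for r in rev)

    def test_compound_tagging_of_adjacent_runs(self):
        seq = "C" + "A" * 12 + "GG" + "AT" * 7 + "C" * 30
        genome = CircularGenome("t", seq, circular=False)
        records = find_ssrs(genome)
        groups = {r.motif: r.compound_group for r in records}
        assert groups["A"] == groups["AT"] is not None


class TestCanonicalMotif:
    @pytest.mark.parametrize(
        "unit, expected",
        [("TA", "AT"), ("AT", "AT"), ("GAT", "ATG"), ("A", "A")],
    )
    def test_least_rotation(self, unit, expected):
        assert canonical_motif(unit) == expected


class TestTandemRepeats:
    def test_short_total_span_not_reported(self):
        genome = CircularGenome("t", "ATTTCGGC" * 50, circular=False)
        # period 8 is below min_unit anyway; plant a 7bp unit x3 = 21 < 24
        g2 = CircularGenome("t", "GATTACA" * 3 + "C" + "ACGT" * 30, circular=False)
        assert find_tandem_repeats(g2) == []

    def test_planted_minisatellite_recovered(self, sim_circle2):
        genome, _, truth = sim_circle2
        mini = find_tandem_repeats(genome)
        planted = [r for r in truth.planted_repeats if r.unit_len > 6]
        assert planted
        found = {(r.motif, r.unit_len, r.copies, r.start) for r in mini}
        for p in planted:
            assert (p.motif, p.unit_len, p.copies, p.start) in found

    def test_no_exact_period_gives_empty_list(self):
        genome = _random_genome(2_000, seed=17, circular=False)
        # random 2 kb essentially never carries a perfect >=24 bp duplication
        assert find_tandem_repeats(genome) == []

    def test_min_unit_must_exceed_ssr_range(self):
        with pytest.raises(ValueError):
            find_tandem_repeats(_random_genome(100, 0), min_unit=4)


class TestRepeatFraction:
    def test_published_footprint_over_both_circles(self):
        from mitochar.repeats import SSRRecord

        record = SSRRecord("A", "A", 1, 579, 1, 579)  # printed total footprint
        out = repeat_fraction([record], 414_980)
        assert out["repeat_bp"] == 579
        assert round(out["percent"], 2) == 0.14

    def test_no_repeats_is_zero(self):
        assert repeat_fraction([], 1000) == {"repeat_bp": 0, "percent": 0.0}

    def test_simulated_fraction_matches_truth_exactly(self, sim_circle1):
        genome, _, truth = sim_circle1
        records = find_ssrs(genome) + find_tandem_repeats(genome)
        records = resolve_overlaps(records, genome.length)
        truth_bp = sum(r.span for r in truth.planted_repeats)
        out = repeat_fraction(records, genome.length)
        # background of this small circle carries no chance runs at the
        # default thresholds, so detection equals the planted footprint
        assert out["repeat_bp"] == truth_bp

    def test_zero_genome_length_is_error(self):
        with pytest.raises(ValueError):
            repeat_fraction([], 0)
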