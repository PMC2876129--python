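"""Permutation null, p-values, specificity, and GO enrichment."""

from math import comb

import numpy as np
import pytest

from tmmotif.motifs import parse_prosite, scan_database
from tmmotif.stats import (
    PermutationNull,
    build_motif_report,
    classify_abundance,
    classify_specificity,
    empirical_pvalue,
    false_positive_rate,
    go_enrichment,
    motif_pvalue,
    odds_ratio,
    permutation_null,
    tm_specificity_p,
)


class TestPermutationNull:
    def test_shuffle_invariant_database(self):
        db = [(f"s{i}", "AAAAA") for i in range(4)]
        m = parse_prosite("A")
        null = permutation_null(m, db, n_perm=5, seed=0)
        n_m, _ = scan_database(m, db)
        assert np.all(null.counts == n_m)

    def test_deterministic_given_seed(self):
        db = [("s1", "APLGWKAPL"), ("s2", "GGAPLWWKY")]
        m = parse_prosite("A-P-L")
        n1 = permutation_null(m, db, n_perm=10, seed=5)
        n2 = permutation_null(m, db, n_perm=10, seed=5)
        assert np.all(n1.counts == n2.counts)

    def test_null_mean_matches_iid_closed_form(self):
        """Composition-preserving shuffles approximate the i.i.d. expectation
        sum_s (L_s - 2) * p_A p_P p_L for the 3-mer APL."""
        rng = np.random.default_rng(2)
        db = []
        expect = 0.0
        for i in range(40):
            seq = "".join(rng.choice(list("APLG"), size=60))
            db.append((f"s{i}", seq))
            pa, pp, pl = (seq.count(c) / 60 for c in "APL")
            expect += (60 - 2) * pa * pp * pl
        null = permutation_null(parse_prosite("A-P-L"), db, n_perm=100, seed=3)
        se = null.sd / np.sqrt(null.n_perm)
        assert abs(null.mean - expect) <= 3 * se

    def test_composition_preserved(self):
        # shuffling cannot change single-letter counts
        db = [("s1", "AAPL")]
        null = permutation_null(parse_prosite("A"), db, n_perm=6, seed=1)
        assert np.all(null.counts == 2)


class TestPValues:
    def test_at_mean_half(self):
        null = PermutationNull(np.array([8.0, 12.0]), 10.0, 2.0, 2, 0)
        assert motif_pvalue(10, null) == pytest.approx(0.5)

    def test_far_tail(self):
        null = PermutationNull(np.array([8.0, 12.0]), 10.0, 2.0, 2, 0)
        assert motif_pvalue(10 + 10 * 2, null) < 1e-15

    def test_z2_standard_table(self):
        null = PermutationNull(np.array([8.0, 12.0]), 10.0, 2.0, 2, 0)
        assert motif_pvalue(14, null) == pytest.approx(0.02275, abs=2e-5)

    def test_degenerate_sd(self):
        null = PermutationNull(np.array([5.0, 5.0]), 5.0, 0.0, 2, 0)
        assert motif_pvalue(5, null) == 1.0
        assert motif_pvalue(6, null) == 0.0

    def test_empirical_pvalue_bounds(self):
        null = PermutationNull(np.arange(10.0), 4.5, 3.0, 10, 0)
        assert 0 < empirical_pvalue(100, null) <= 1
        assert empirical_pvalue(0, null) == 1.0


class TestOddsAndRates:
    def test_odds_ratio_values(self):
        assert odds_ratio(5, 5.0) == 1.0
        assert odds_ratio(20, 5.0) == 4.0
        assert np.isnan(odds_ratio(5, 0.0))

    def test_odds_consistency_with_mean(self):
        null = PermutationNull(np.array([4.0, 6.0]), 5.0, 1.0, 2, 0)
        assert (odds_ratio(7, null.mean) > 1) == (7 > null.mean)

    def test_clc_motif_bookkeeping(self):
        # 23 TM occurrences, none globular: 0% false positives, high specificity
        assert false_positive_rate(0, 23) == 0.0
        assert classify_specificity(0.0) == "high"

    def test_even_split_low_specificity(self):
        assert false_positive_rate(10, 10) == 0.5
        assert classify_specificity(0.5) == "low"

    @pytest.mark.parametrize(
        "n_m,expected", [(99, "low"), (100, "medium"), (181, "medium"), (500, "medium"), (501, "high")]
    )
    def test_abundance_classes(self, n_m, expected):
        assert classify_abundance(n_m) == expected

    def test_undefined_rate(self):
        assert np.isnan(false_positive_rate(0, 0))


class TestTMSpecificity:
    def test_all_carriers_tm_closed_form(self):
        # P(all 5 carriers TM | 5 TM + 5 GLOB universe) = C(5,5)/C(10,5)
        assert tm_specificity_p(5, 5, 0, 5) == pytest.approx(1 / 252)

    def test_proportional_split_not_significant(self):
        p = tm_specificity_p(3, 30, 3, 30)
        assert 0.4 <= p <= 1.0

    def test_zero_carriers(self):
        assert tm_specificity_p(0, 10, 0, 10) == 1.0

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            tm_specificity_p(6, 5, 0, 5)


def exhaustive_hypergeom_tail(big_g, big_c, n, k):
    """Enumerate all C(G, n) draws and count those with >= k category members."""
    import itertools

    members = set(range(big_c))
    hits = total = 0
    for draw in itertools.combinations(range(big_g), n):
        total += 1
        if len(members & set(draw)) >= k:
            hits += 1
    return hits / total


class TestGOEnrichment:
    def test_closed_form_example(self):
        go = [(f"s{i}", "GO:X") for i in range(5)]
        db_ids = {f"s{i}" for i in range(10)}
        hit_ids = {f"s{i}" for i in range(5)}
        recs = go_enrichment(hit_ids, db_ids, go, n_categories=1)
        assert recs[0].p == pytest.approx(1 / 252)
        assert recs[0].coverage == 1.0

    def test_zero_hits_term(self):
        go = [("s0", "GO:X")]
        recs = go_enrichment(set(), {"s0", "s1"}, go)
        assert recs[0].p == 1.0 and recs[0].coverage == 0.0

    def test_bonferroni_reference_threshold(self):
        # alpha=0.01 over the 24287-category reference: 1e-5 is NOT significant
        go = [(f"s{i}", "GO:X") for i in range(5)] + [("s9", "GO:Y")]
        db_ids = {f"s{i}" for i in range(10)}
        hit_ids = {f"s{i}" for i in range(5)}
        recs = go_enrichment(hit_ids, db_ids, go, alpha=0.01, n_categories=24287)
        rec = next(r for r in recs if r.term == "GO:X")
        assert rec.p == pytest.approx(1 / 252)  # ~4e-3 > 0.01/24287
        assert not rec.significant

    @pytest.mark.parametrize(
        "big_g,big_c,n,k",
        [(10, 5, 5, 5), (8, 3, 4, 2), (12, 6, 5, 3), (9, 4, 3, 0), (7, 2, 5, 1)],
    )
    def test_tail_equals_exhaustive_enumeration(self, big_g, big_c, n, k):
        go = [(f"s{i}", "GO:T") for i in range(big_c)]
        db_ids = {f"s{i}" for i in range(big_g)}
        hit_ids = {f"s{i}" for i in range(n)} if k else {f"s{i}" for i in range(big_c, big_c + n)}
        recs = go_enrichment(hit_ids, db_ids, go)
        observed_k = recs[0].k
        assert recs[0].p == pytest.approx(
            exhaustive_hypergeom_tail(big_g, big_c, n, observed_k), abs=1e-12
        )

    def test_hit_ids_subset_enforced(self):
        with pytest.raises(ValueError):
            go_enrichment({"zz"}, {"s0"}, [("s0", "GO:X")])


class TestReportPower:
    def test_planted_motif_significant_and_specific(self):
        """30% TM planting, 0% globular: p_perm < 0.05 and fp_rate = 0."""
        from tmmotif.synth import PlantedMotif, SynthSpec, make_sequence_db

        spec = SynthSpec(seed=8, n_tm=40, n_glob=40,
                         planted=[PlantedMotif("L-W-S-I-P-L-G", 0.3, 0.0)])
        tm, glob, truth, go = make_sequence_db(spec)
        rep = build_motif_report(parse_prosite("L-W-S-I-P-L-G"), tm, glob, go, n_perm=100, seed=8)
        assert rep.p_perm < 0.05
        assert rep.fp_rate == 0.0
        assert rep.n_m >= len([t for t in truth if t["partition"] == "tm"])
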