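"""Prosite-dialect parsing, induction, scanning, and redundancy grouping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmmotif.motifs import (
    AA20,
    group_redundant,
    induce_pattern,
    motif_to_string,
    parse_prosite,
    read_motif_library,
    scan_database,
    scan_sequence,
)

PAPER_STYLE_PATTERNS = [
    "A-[AS]-[FIV]-[NR]-A-P-L-[AT]-G",
    "[WY]-x(2)-Y-P-P-L",
    "L-x-S-I-[GP]",
    "{DT}-A-x(1,3)-[ILV]",
]


class TestParse:
    def test_nine_symbol_pattern(self):
        m = parse_prosite("A-[AS]-[FIV]-[NR]-A-P-L-[AT]-G")
        assert [len(s.residues) for s in m.symbols] == [1, 2, 3, 2, 1, 1, 1, 2, 1]

    def test_wildcard_repeat(self):
        m = parse_prosite("x(2)")
        assert len(m.symbols) == 1
        s = m.symbols[0]
        assert s.kind == "wildcard" and (s.repeat_min, s.repeat_max) == (2, 2)
        assert m.min_length == 2

    def test_exclusion_set(self):
        m = parse_prosite("{DT}")
        assert m.symbols[0].kind == "exclusion"
        assert len(m.symbols[0].residues) == 18
        assert not {"D", "T"} & m.symbols[0].residues

    @pytest.mark.parametrize("bad", ["A-[", "[]-A", "A-x(3,1)", "A--G", "A-[B]"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_prosite(bad)

    @pytest.mark.parametrize("pattern", PAPER_STYLE_PATTERNS)
    def test_roundtrip_idempotence(self, pattern):
        once = motif_to_string(parse_prosite(pattern))
        assert motif_to_string(parse_prosite(once)) == once


class TestScan:
    def test_wyxxyppl_example(self):
        hits = scan_sequence(parse_prosite("[WY]-x(2)-Y-P-P-L"), "AWGAYPPLK")
        assert [h.start for h in hits] == [1]

    def test_empty_sequence(self):
        assert scan_sequence(parse_prosite("A-P-L"), "") == []

    def test_repeated_motif(self):
        hits = scan_sequence(parse_prosite("A-P-L"), "APLAPL")
        assert [h.start for h in hits] == [0, 3]

    def test_overlapping_hits_reported(self):
        hits = scan_sequence(parse_prosite("A-x-A"), "AAAAA")
        assert [h.start for h in hits] == [0, 1, 2]

    def test_case_insensitive_and_nonstandard_never_match(self):
        m = parse_prosite("[AS]-P")
        assert [h.start for h in scan_sequence(m, "apx")] == [0]
        assert scan_sequence(parse_prosite("x-x"), "BZ") == []  # wildcard is 20 letters only

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_agrees_with_naive_matcher(self, seed):
        """Oracle equivalence: brute-force instance matching at every start."""
        rng = np.random.default_rng(seed)
        pattern = "-".join(
            rng.choice(
                ["A", "L", "[AG]", "[LS]", "x", "x(1,2)", "{P}"],
                size=rng.integers(2, 5),
                p=[0.25, 0.25, 0.15, 0.15, 0.1, 0.05, 0.05],
            )
        )
        m = parse_prosite(pattern)
        seq = "".join(rng.choice(list("ALGSP"), size=12))
        starts = {h.start for h in scan_sequence(m, seq)}

        choices = [range(s.repeat_min, s.repeat_max + 1) for s in m.symbols]
        naive = set()
        for combo in itertools.product(*choices):
            sets = []
            for s, reps in zip(m.symbols, combo):
                sets.extend([s.residues] * reps)
            for start in range(len(seq) - len(sets) + 1):
                if all(seq[start + i] in sets[i] for i in range(len(sets))):
                    naive.add(start)
        assert starts == naive


class TestInduce:
    def test_unanimous(self):
        m = induce_pattern(["APL", "APL", "APL"])
        assert motif_to_string(m) == "A-P-L"

    def test_80_percent_coverage_contract(self):
        seqs = ["APL", "SPL", "APL", "APL", "APV"]
        m = induce_pattern(seqs, 0.8)
        assert m is not None
        matched = sum(1 for s in seqs if scan_sequence(m, s))
        assert matched >= 0.8 * len(seqs)

    def test_unrelated_sequences_give_none(self):
        # every column carries 5 distinct residues, exceeding max_set_size 4
        rng = np.random.default_rng(0)
        cols = [rng.choice(list(AA20), size=5, replace=False) for _ in range(6)]
        seqs = ["".join(cols[j][i] for j in range(6)) for i in range(5)]
        assert induce_pattern(seqs, 0.8, max_set_size=4) is None

    def test_mixed_lengths_error(self):
        with pytest.raises(ValueError):
            induce_pattern(["APL", "APLG"])

    @pytest.mark.parametrize("fraction", [0.8, 1.0])
    def test_postcondition_on_noisy_families(self, fraction):
        rng = np.random.default_rng(42)
        base = "LWSIPLG"
        seqs = []
        for _ in range(10):
            s = list(base)
            if rng.random() < 0.4:  # mutate one position
                pos = int(rng.integers(0, len(base)))
                s[pos] = str(rng.choice(list(AA20)))
            seqs.append("".join(s))
        m = induce_pattern(seqs, fraction)
        assert m is not None
        matched = sum(1 for s in seqs if scan_sequence(m, s))
        assert matched >= fraction * len(seqs)


class TestScanDatabase:
    def test_planted_once_per_sequence(self):
        rng = np.random.default_rng(7)
        db = []
        for i in range(23):
            seq = list(rng.choice(list("GAVE"), size=30))
            pos = int(rng.integers(0, 30 - 3))
            seq[pos : pos + 3] = list("WPW")
            db.append((f"s{i}", "".join(seq)))
        n, ids = scan_database(parse_prosite("W-P-W"), db)
        assert n >= 23
        assert len(ids) == 23

    def test_empty_db(self):
        assert scan_database(parse_prosite("A-P-L"), []) == (0, set())

    def test_two_hits_one_sequence(self):
        n, ids = scan_database(parse_prosite("A-P-L"), [("s1", "APLGGAPL")])
        assert n == 2 and ids == {"s1"}


class TestGroupRedundant:
    DB = [("a", "APLWWW"), ("b", "APLYYY"), ("c", "KKKAPL"), ("d", "GGGGGG")]

    def test_identical_hit_sets_one_group(self):
        m1 = parse_prosite("A-P-L")
        m2 = parse_prosite("A-P")
        groups = group_redundant([m1, m2], self.DB)
        assert len(groups) == 1
        assert len(groups[0].motifs) == 2

    def test_disjoint_hit_sets_separate(self):
        groups = group_redundant([parse_prosite("W-W-W"), parse_prosite("Y-Y-Y")], self.DB)
        assert len(groups) == 2

    def test_transitive_chain_closure(self):
        # A hits {a,b,c}; B hits {a,b}; C hits {b}; A~B (2/2 wait, by min): use crafted db
        db = [("s1", "AAA CCC".replace(" ", "")), ("s2", "AAACCC"), ("s3", "CCCGGG")]
        a = parse_prosite("A-A-A")  # hits s1, s2
        b = parse_prosite("C-C-C")  # hits s1, s2, s3
        c = parse_prosite("G-G-G")  # hits s3
        groups = group_redundant([a, b, c], db)
        # overlap(a,b) = 2/2 = 1 > .8; overlap(b,c) = 1/1 = 1 > .8; a,c overlap 0
        assert len(groups) == 1 and len(groups[0].motifs) == 3

    def test_zero_hit_motif_flagged(self):
        with pytest.warns(UserWarning, match="zero hits"):
            groups = group_redundant([parse_prosite("W-W-W-W-W")], self.DB)
        assert groups[0].zero_hits


def test_read_motif_library_with_id_prefix():
    lib = read_motif_library("PS00001; A-P-L\n# comment\n[WY]-x(2)-Y-P-P-L\n")
    assert [motif_to_string(m) for m in lib] == ["A-P-L", "[WY]-x(2)-Y-P-P-L"]
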