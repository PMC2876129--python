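"""Prosite-dialect motifs: parsing, induction from clusters, scanning, grouping.

The dialect covers single residues (``A``), residue sets (``[AS]``),
exclusion sets (``{DT}`` = any residue except D or T), the wildcard ``x``,
and repetition counts or ranges in parentheses (``x(3)``, ``x(1,3)``), with
symbols joined by ``-``.

Pattern induction from a cluster of equal-length fragment sequences is
positional (the fragments are fixed-length windows, so they are inherently
aligned): per-column residue sets are trimmed greedily, rarest residue first,
as long as the motif still matches the required fraction of the members;
columns that stay too diverse become wildcards.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)


@dataclass(frozen=True)
class MotifSymbol:
    """One pattern position: kind, allowed residues, and a repeat range."""

    kind: str  # single | set | exclusion | wildcard
    residues: frozenset[str]
    repeat_min: int = 1
    repeat_max: int = 1
    excluded: frozenset[str] = frozenset()  # populated for exclusion symbols

    def __post_init__(self) -> None:
        if self.kind not in {"single", "set", "exclusion", "wildcard"}:
            raise ValueError(f"bad symbol kind {self.kind}")
        if self.repeat_min < 1 or self.repeat_min > self.repeat_max:
            raise ValueError("bad repeat range")
        if self.kind == "single" and len(self.residues) != 1:
            raise ValueError("single symbol needs exactly one residue")
        if self.kind == "set" and not 2 <= len(self.residues) <= 19:
            raise ValueError("set symbol needs 2-19 residues")
        if self.kind == "wildcard" and self.residues != AA_SET:
            raise ValueError("wildcard must allow all 20 residues")
        if not self.residues or not self.residues <= AA_SET:
            raise ValueError("residue set must be a non-empty subset of the 20 letters")


@dataclass
class RegexMotif:
    """An ordered list of Prosite-dialect symbols."""

    symbols: list[MotifSymbol]
    source: str = ""

    def __str__(self) -> str:
        return motif_to_string(self)

    @property
    def min_length(self) -> int:
        return sum(s.repeat_min for s in self.symbols)

    def to_regex(self) -> str:
        parts = []
        for s in self.symbols:
            if s.kind == "single":
                body = next(iter(s.residues))
            else:
                body = "[" + "".join(sorted(s.residues)) + "]"
            if (s.repeat_min, s.repeat_max) == (1, 1):
                parts.append(body)
            elif s.repeat_min == s.repeat_max:
                parts.append(f"{body}{{{s.repeat_min}}}")
            else:
                parts.append(f"{body}{{{s.repeat_min},{s.repeat_max}}}")
        return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int
    span: str


_TOKEN_RE = re.compile(
    r"(?P<body>x|[A-Z]|\[[A-Z]+\]|\{[A-Z]+\})(?:\((?P<rmin>\d+)(?:,(?P<rmax>\d+))?\))?$"
)


def parse_prosite(pattern: str) -> RegexMotif:
    """Parse a Prosite-dialect pattern string into a RegexMotif.

    Raises ValueError naming the offending token position on unbalanced
    brackets, empty sets, or inverted repeat ranges.
    """
    text = pattern.strip().rstrip(".")
    if not text:
        raise ValueError("empty pattern")
    symbols: list[MotifSymbol] = []
    for pos, token in enumerate(text.split("-")):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValueError(f"pattern {pattern!r}: bad symbol {token!r} at position {pos}")
        body = m.group("body")
        rmin = int(m.group("rmin")) if m.group("rmin") else 1
        rmax = int(m.group("rmax")) if m.group("rmax") else rmin
        if rmin > rmax:
            raise ValueError(f"pattern {pattern!r}: repeat range ({rmin},{rmax}) at position {pos}")
        if body == "x":
            sym = MotifSymbol("wildcard", AA_SET, rmin, rmax)
        elif body.startswith("["):
            residues = frozenset(body[1:-1])
            if not residues:
                raise ValueError(f"pattern {pattern!r}: empty set at position {pos}")
            if not residues <= AA_SET:
                raise ValueError(f"pattern {pattern!r}: non-standard residue at position {pos}")
            kind = "single" if len(residues) == 1 else "set"
            sym = MotifSymbol(kind, residues, rmin, rmax)
        elif body.startswith("{"):
            excluded = frozenset(body[1:-1])
            if not excluded or not excluded <= AA_SET:
                raise ValueError(f"pattern {pattern!r}: bad exclusion at position {pos}")
            sym = MotifSymbol("exclusion", AA_SET - excluded, rmin, rmax, excluded=excluded)
        else:
            if body not in AA_SET:
                raise ValueError(f"pattern {pattern!r}: unknown residue {body!r} at position {pos}")
            sym = MotifSymbol("single", frozenset(body), rmin, rmax)
        symbols.append(sym)
    return RegexMotif(symbols, source=pattern.strip())


def motif_to_string(m: RegexMotif) -> str:
    parts = []
    for s in m.symbols:
        if s.kind == "wildcard":
            body = "x"
        elif s.kind == "exclusion":
            body = "{" + "".join(sorted(s.excluded)) + "}"
        elif s.kind == "single":
            body = next(iter(s.residues))
        else:
            body = "[" + "".join(sorted(s.residues)) + "]"
        if (s.repeat_min, s.repeat_max) == (1, 1):
            parts.append(body)
        elif s.repeat_min == s.repeat_max:
            parts.append(f"{body}({s.repeat_min})")
        else:
            parts.append(f"{body}({s.repeat_min},{s.repeat_max})")
    return "-".join(parts)


def scan_sequence(m: RegexMotif, seq: str) -> list[MotifHit]:
    """All match start positions (overlaps allowed, one hit per start)."""
    seq = seq.upper()
    if not seq:
        return []
    # lookahead yields every start; the inner group is the (greedy) matched span
    rx = re.compile(f"(?=({m.to_regex()}))")
    return [MotifHit("", mt.start(), mt.group(1)) for mt in rx.finditer(seq)]


def scan_database(
    m: RegexMotif, db: list[tuple[str, str]]
) -> tuple[int, set[str]]:
    """Total hit count N_M and the set of sequence ids with at least one hit."""
    total = 0
    ids: set[str] = set()
    for seq_id, seq in db:
        hits = scan_sequence(m, seq)
        if hits:
            total += len(hits)
            ids.add(seq_id)
    return total, ids


def _matches_fraction(m: RegexMotif, seqs: list[str]) -> float:
    return sum(1 for s in seqs if scan_sequence(m, s)) / len(seqs)


def induce_pattern(
    seqs: list[str],
    min_match_fraction: float = 0.8,
    max_set_size: int = 4,
) -> RegexMotif | None:
    """Induce a Prosite-dialect motif from equal-length fragment sequences.

    Builds per-column residue sets, greedily drops the rarest residues while
    the motif still matches at least ``min_match_fraction`` of the inputs,
    and turns columns with more than ``max_set_size`` distinct residues into
    wildcards.  Returns None when only the all-wildcard pattern remains.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    seqs = [s.upper() for s in seqs]

    columns: list[Counter] = [Counter(s[i] for s in seqs) for i in range(length)]
    # a column too diverse on the FULL observed set is a wildcard for good;
    # coverage-based trimming below only sharpens the remaining columns
    wildcard = [len(frozenset(c) & AA_SET) > max_set_size or not frozenset(c) & AA_SET
                for c in columns]

    def build(colsets: list[frozenset[str]]) -> RegexMotif:
        symbols = []
        for i, cs in enumerate(colsets):
            if wildcard[i]:
                symbols.append(MotifSymbol("wildcard", AA_SET))
            elif len(cs) == 1:
                symbols.append(MotifSymbol("single", cs))
            else:
                symbols.append(MotifSymbol("set", cs))
        return RegexMotif(symbols)

    colsets = [frozenset(c) & AA_SET or AA_SET for c in columns]
    # trim rare residues column by column while coverage allows
    for i, counter in enumerate(columns):
        if wildcard[i]:
            continue
        for res, _cnt in sorted(counter.items(), key=lambda kv: (kv[1], kv[0])):
            if len(colsets[i]) <= 1:
                break
            trial = list(colsets)
            trial[i] = colsets[i] - {res}
            if not trial[i]:
                continue
            if _matches_fraction(build(trial), seqs) >= min_match_fraction:
                colsets = trial
    motif = build(colsets)
    if all(s.kind == "wildcard" for s in motif.symbols):
        return None
    if _matches_fraction(motif, seqs) < min_match_fraction:
        return None
    return motif


@dataclass
class MotifGroup:
    """Motifs judged redundant by hit-set overlap; representative has most hits."""

    motifs: list[RegexMotif]
    representative: RegexMotif
    zero_hits: bool = False


def group_redundant(
    motifs: list[RegexMotif],
    db: list[tuple[str, str]],
    overlap_threshold: float = 0.8,
) -> list[MotifGroup]:
    """Group motifs whose hit-sequence sets overlap above the threshold.

    Overlap between two motifs is |A n B| / min(|A|, |B|) over their hit-id
    sets; motifs joined by above-threshold edges form connected components.
    Motifs with no hits each form their own flagged group.
    """
    scans = [scan_database(m, db) for m in motifs]
    g = nx.Graph()
    g.add_nodes_from(range(len(motifs)))
    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            a, b = scans[i][1], scans[j][1]
            if not a or not b:
                continue
            overlap = len(a & b) / min(len(a), len(b))
            if overlap > overlap_threshold:
                g.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        zero = all(scans[i][0] == 0 for i in comp)
        if zero:
            for i in comp:
                groups.append(MotifGroup([motifs[i]], motifs[i], zero_hits=True))
            continue
        rep = max(comp, key=lambda i: (scans[i][0], -i))
        groups.append(MotifGroup([motifs[i] for i in comp], motifs[rep]))
    if any(s[0] == 0 for s in scans):
        warnings.warn("some motifs had zero hits and form their own groups")
    return sorted(groups, key=lambda gr: str(gr.representative))


def read_motif_library(text: str) -> list[RegexMotif]:
    """One Prosite-dialect pattern per line; optional 'PSxxxxx;' id prefix."""
    motifs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ";" in line:
            prefix, rest = line.split(";", 1)
            if re.fullmatch(r"PS\w+", prefix.strip()):
                line = rest.strip()
        motifs.append(parse_prosite(line))
    return motifs
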