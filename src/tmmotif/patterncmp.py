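"""Regex-vs-regex similarity, novelty filtering, and the randomized null model.

Two patterns are compared by expanding each repetition range into fixed-length
*instances* (lists of per-position residue sets), sliding the shorter instance
along the longer, and scoring every same-length overlap.  A position pair
scores ``|s1 n s2| / (|s1| * |s2|)`` and a segment scores the mean of its
position scores, so a perfect single-letter match scores 1 and two wildcards
score 20/400 = 0.05.  The best score over all offsets and instance pairs is
the pattern similarity; a motif whose best score against a pattern library
reaches the cutoff (default 0.86) is *known*, otherwise *novel*.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from tmmotif.motifs import AA_SET, MotifSymbol, RegexMotif

PatternInstance = tuple[frozenset, ...]


@dataclass
class ComparisonResult:
    best_score: float
    best_offset: int
    best_pair: tuple[int, int]  # (instance index in m1, instance index in m2)
    approximate: bool = False
    verdict: str | None = None


def expand_instances(m: RegexMotif, max_instances: int = 512) -> tuple[list[PatternInstance], bool]:
    """Cartesian expansion of repetition ranges into fixed-length instances.

    Enumeration is deterministic, smallest repetition counts first; when the
    expansion exceeds ``max_instances`` it is truncated with a warning and the
    second return value flags the result approximate.
    """
    choices = [range(s.repeat_min, s.repeat_max + 1) for s in m.symbols]
    instances: list[PatternInstance] = []
    truncated = False
    for combo in sorted(itertools.product(*choices), key=lambda c: (sum(c), c)):
        if len(instances) >= max_instances:
            truncated = True
            warnings.warn(f"pattern {m}: instance expansion truncated at {max_instances}")
            break
        inst: list[frozenset] = []
        for sym, reps in zip(m.symbols, combo):
            inst.extend([sym.residues] * reps)
        instances.append(tuple(inst))
    return instances, truncated


def pair_score(s1: frozenset, s2: frozenset) -> float:
    """Shared residues over the product of set sizes, in [0, 1]."""
    if not s1 or not s2:
        raise ValueError("empty residue set")
    return len(s1 & s2) / (len(s1) * len(s2))


def segment_score(i1: PatternInstance, i2: PatternInstance) -> float:
    """Mean pair score over the positions of two equal-length instances."""
    if len(i1) != len(i2):
        raise ValueError("instances must have equal length")
    if not i1:
        raise ValueError("empty instance")
    return sum(pair_score(a, b) for a, b in zip(i1, i2)) / len(i1)


def compare_patterns(
    m1: RegexMotif,
    m2: RegexMotif,
    max_instances: int = 512,
    min_overlap: int | None = None,
) -> ComparisonResult:
    """Best alignment score between two patterns over all instance pairs.

    For each pair of instances the shorter one is slid along the longer and
    every full-length placement of the shorter is scored; ``min_overlap``
    (default: the shorter length, i.e. containment) relaxes to partial
    overlaps of at least that many positions, scored over the overlap only.
    """
    inst1, t1 = expand_instances(m1, max_instances)
    inst2, t2 = expand_instances(m2, max_instances)
    best = ComparisonResult(0.0, 0, (0, 0), approximate=t1 or t2)
    for a, ia in enumerate(inst1):
        for b, ib in enumerate(inst2):
            short, long_ = (ia, ib) if len(ia) <= len(ib) else (ib, ia)
            ls, ll = len(short), len(long_)
            ov = min_overlap if min_overlap is not None else ls
            ov = min(ov, ls)
            for off in range(-(ls - ov), ll - ov + 1):
                lo = max(0, off)
                hi = min(ll, off + ls)
                seg_long = long_[lo:hi]
                seg_short = short[lo - off : hi - off]
                score = segment_score(seg_short, seg_long)
                if score > best.best_score:
                    best = ComparisonResult(score, off, (a, b), approximate=t1 or t2)
    return best


def novelty_filter(
    motifs: list[RegexMotif],
    library: list[RegexMotif],
    cutoff: float = 0.86,
    max_instances: int = 512,
) -> list[ComparisonResult]:
    """Known/novel verdict per motif against a pattern library.

    A motif is known when its best comparison score over the library reaches
    ``cutoff``; an empty library makes every motif novel (with a warning).
    """
    if not library:
        warnings.warn("empty pattern library: all motifs reported novel")
        return [ComparisonResult(0.0, 0, (0, 0), verdict="novel") for _ in motifs]
    out = []
    for m in motifs:
        best = ComparisonResult(0.0, 0, (0, 0))
        for pat in library:
            res = compare_patterns(m, pat, max_instances)
            if res.best_score > best.best_score:
                best = res
        best.verdict = "known" if best.best_score >= cutoff else "novel"
        out.append(best)
    return out


@dataclass
class RandomModelSummary:
    observed_best: list[float]
    null_best: list[float]
    quantile_level: float
    null_quantile: float


def shuffle_pattern(m: RegexMotif, rng: np.random.Generator) -> RegexMotif:
    """Permute the order of a pattern's symbols (residue sets preserved)."""
    idx = rng.permutation(len(m.symbols))
    return RegexMotif([m.symbols[i] for i in idx], source=f"shuffled({m.source})")


def random_model_cutoff(
    motifs: list[RegexMotif],
    library: list[RegexMotif],
    n_shuffles: int = 10,
    seed: int = 0,
    quantile: float = 0.95,
    max_instances: int = 128,
) -> RandomModelSummary:
    """Observed vs column-shuffled-library best-score distributions.

    The null is built by comparing each motif against ``n_shuffles``
    symbol-order permutations of every library pattern; the score at the
    requested null quantile supports cutoff selection.
    """
    rng = np.random.default_rng(seed)
    observed = [
        max((compare_patterns(m, p, max_instances).best_score for p in library), default=0.0)
        for m in motifs
    ]
    null: list[float] = []
    for _ in range(n_shuffles):
        shuffled = [shuffle_pattern(p, rng) for p in library]
        for m in motifs:
            null.append(
                max((compare_patterns(m, p, max_instances).best_score for p in shuffled), default=0.0)
            )
    q = float(np.quantile(null, quantile)) if null else 0.0
    return RandomModelSummary(observed, null, quantile, q)
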