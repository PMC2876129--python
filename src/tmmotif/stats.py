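"""Motif statistics: permutation null, specificity, and GO enrichment.

Overrepresentation in the transmembrane database is measured against a null
built by shuffling the residues within each database sequence (lengths and
compositions preserved) 100 times and fitting a normal distribution to the
per-permutation occurrence counts; the p-value of an observed count N_M is
the upper normal tail.  Specificity against a globular database uses the
false positive rate N_GLOB / (N_GLOB + N_M) and an upper-tail hypergeometric
p-value on the TM/globular split of motif-carrying sequences (significant
below 2e-6).  GO enrichment is the standard hypergeometric test with
Bonferroni correction (alpha = 0.01 over the number of GO categories;
the reference count 24287 can be supplied to reproduce that threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom, norm

from tmmotif.motifs import RegexMotif, scan_database

HYPERGEOM_SIGNIFICANCE = 2e-6
GO_N_CATEGORIES_REFERENCE = 24287


@dataclass
class PermutationNull:
    """Null occurrence distribution from within-sequence residue shuffles."""

    counts: np.ndarray
    mean: float
    sd: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("need at least 2 permutations")
        if self.sd < 0:
            raise ValueError("negative sd")


def permutation_null(
    m: RegexMotif,
    db: list[tuple[str, str]],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationNull:
    """Hit counts of a motif over n_perm within-sequence shuffles of the db."""
    if not db:
        raise ValueError("empty database")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm)
    seq_arrays = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in db]
    for k in range(n_perm):
        shuffled = []
        for i, arr in enumerate(seq_arrays):
            perm = rng.permutation(arr)
            shuffled.append((db[i][0], perm.tobytes().decode()))
        counts[k], _ = scan_database(m, shuffled)
    return PermutationNull(
        counts=counts,
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)),
        n_perm=n_perm,
        seed=seed,
    )


def motif_pvalue(n_m: int, null: PermutationNull) -> float:
    """Upper-tail normal probability of observing N_M or more occurrences."""
    if null.sd == 0.0:
        return 1.0 if n_m <= null.mean else 0.0
    return float(norm.sf(n_m, loc=null.mean, scale=null.sd))


def empirical_pvalue(n_m: int, null: PermutationNull) -> float:
    """Exact empirical tail with the add-one correction."""
    return float((np.sum(null.counts >= n_m) + 1) / (null.n_perm + 1))


def odds_ratio(n_m: int, expectation: float) -> float:
    """Observed occurrences over the null expectation."""
    if expectation <= 0:
        return float("nan")
    return n_m / expectation


def false_positive_rate(n_glob: int, n_m: int) -> float:
    """Fraction of a motif's occurrences that fall in globular sequences."""
    if n_glob + n_m == 0:
        return float("nan")
    return n_glob / (n_glob + n_m)


def classify_specificity(fp_rate: float) -> str:
    """<=10% high, (10%, 40%] medium, >40% low."""
    if np.isnan(fp_rate):
        return "undefined"
    if fp_rate <= 0.10:
        return "high"
    if fp_rate <= 0.40:
        return "medium"
    return "low"


def classify_abundance(n_m: int) -> str:
    """<100 occurrences low, 100-500 medium, >500 high."""
    if n_m < 100:
        return "low"
    if n_m <= 500:
        return "medium"
    return "high"


def tm_specificity_p(
    n_tm_hit: int, n_tm_total: int, n_glob_hit: int, n_glob_total: int
) -> float:
    """Upper-tail hypergeometric p for the TM share of motif-carrying sequences.

    Drawing ``n_tm_hit + n_glob_hit`` carriers from a universe of
    ``n_tm_total`` TM plus ``n_glob_total`` globular sequences, the p-value is
    the probability of at least ``n_tm_hit`` TM sequences among the carriers.
    """
    if n_tm_hit > n_tm_total or n_glob_hit > n_glob_total:
        raise ValueError("hit counts exceed totals")
    draws = n_tm_hit + n_glob_hit
    if draws == 0:
        return 1.0
    universe = n_tm_total + n_glob_total
    return float(hypergeom.sf(n_tm_hit - 1, universe, n_tm_total, draws))


@dataclass
class GoRecord:
    term: str
    k: int  # motif-carrying sequences annotated with the term
    n: int  # motif-carrying sequences
    big_c: int  # database sequences annotated with the term
    big_g: int  # database sequences
    p: float
    coverage: float
    significant: bool


def go_enrichment(
    hit_ids: set[str],
    db_ids: set[str],
    go_annotations: list[tuple[str, str]],
    alpha: float = 0.01,
    n_categories: int | None = None,
) -> list[GoRecord]:
    """Hypergeometric GO-term enrichment of motif-carrying sequences.

    ``go_annotations`` is a (sequence_id, term_id) table.  For each term with
    at least one annotated database sequence, the upper-tail hypergeometric
    probability of observing at least k annotated sequences among the n
    carriers is computed; a term is significant below ``alpha / n_categories``
    (Bonferroni; ``n_categories`` defaults to the number of distinct terms).
    """
    if not hit_ids <= db_ids:
        raise ValueError("hit_ids must be a subset of db_ids")
    term_members: dict[str, set[str]] = {}
    for seq_id, term in go_annotations:
        if seq_id in db_ids:
            term_members.setdefault(term, set()).add(seq_id)
    if n_categories is None:
        n_categories = max(len({t for _, t in go_annotations}), 1)
    threshold = alpha / n_categories
    big_g = len(db_ids)
    n = len(hit_ids)
    records = []
    for term in sorted(term_members):
        members = term_members[term]
        big_c = len(members)
        if big_c == 0:
            continue
        k = len(members & hit_ids)
        p = float(hypergeom.sf(k - 1, big_g, big_c, n)) if n else 1.0
        coverage = k / n if n else 0.0
        records.append(GoRecord(term, k, n, big_c, big_g, p, coverage, p < threshold))
    return records


@dataclass
class MotifReport:
    """Full statistical dossier for one motif."""

    motif: RegexMotif
    n_m: int = 0
    n_glob: int = 0
    p_perm: float = 1.0
    p_empirical: float = 1.0
    odds: float = float("nan")
    fp_rate: float = float("nan")
    specificity_p: float = 1.0
    abundance_class: str = "low"
    specificity_class: str = "undefined"
    go_records: list[GoRecord] = field(default_factory=list)
    novelty: str | None = None
    hit_ids: set[str] = field(default_factory=set)


def build_motif_report(
    motif: RegexMotif,
    tm_db: list[tuple[str, str]],
    glob_db: list[tuple[str, str]],
    go_annotations: list[tuple[str, str]] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.01,
    n_categories: int | None = None,
) -> MotifReport:
    """Run the whole statistics pipeline for one motif."""
    n_m, tm_ids = scan_database(motif, tm_db)
    n_glob, glob_ids = scan_database(motif, glob_db)
    null = permutation_null(motif, tm_db, n_perm=n_perm, seed=seed)
    fp = false_positive_rate(n_glob, n_m)
    report = MotifReport(
        motif=motif,
        n_m=n_m,
        n_glob=n_glob,
        p_perm=motif_pvalue(n_m, null),
        p_empirical=empirical_pvalue(n_m, null),
        odds=odds_ratio(n_m, null.mean),
        fp_rate=fp,
        specificity_p=tm_specificity_p(len(tm_ids), len(tm_db), len(glob_ids), len(glob_db)),
        abundance_class=classify_abundance(n_m),
        specificity_class=classify_specificity(fp),
        hit_ids=tm_ids,
    )
    if go_annotations is not None:
        db_ids = {i for i, _ in tm_db}
        report.go_records = go_enrichment(
            tm_ids, db_ids, go_annotations, alpha=alpha, n_categories=n_categories
        )
    return report
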