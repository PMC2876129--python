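"""Membrane-protein identification from motif-hit counts.

A sequence carrying more than ``hit_threshold`` (default 5) distinct
high-confidence motifs -- motifs whose false positive rate is below
``max_fp_rate`` (default 40%) -- is predicted to be a transmembrane protein.
The rule abstains otherwise: coverage of the motif library is limited, so a
sequence below the threshold gets no call rather than a "globular" label.
"""

from __future__ import annotations

from dataclasses import dataclass

from tmmotif.motifs import scan_sequence
from tmmotif.stats import MotifReport

TM = "TM"
NO_CALL = "no-call"


@dataclass
class ClassifierConfig:
    max_fp_rate: float = 0.40
    hit_threshold: int = 5

    def __post_init__(self) -> None:
        if self.hit_threshold < 1:
            raise ValueError("hit_threshold must be >= 1")


def count_distinct_hits(
    seq: str, library: list[MotifReport], cfg: ClassifierConfig | None = None
) -> int:
    """Number of distinct high-confidence motifs with at least one hit."""
    cfg = cfg or ClassifierConfig()
    count = 0
    for report in library:
        if not report.fp_rate < cfg.max_fp_rate:  # NaN fp_rate never passes
            continue
        if scan_sequence(report.motif, seq):
            count += 1
    return count


def predict_tm(
    seq: str, library: list[MotifReport], cfg: ClassifierConfig | None = None
) -> str:
    """TM when the distinct-hit count strictly exceeds the threshold, else no-call."""
    cfg = cfg or ClassifierConfig()
    return TM if count_distinct_hits(seq, library, cfg) > cfg.hit_threshold else NO_CALL
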