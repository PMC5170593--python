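"""Paired-end FASTQ quality filtering.

Five rules, applied in order, with a pair removed by the first rule that
fires:

1. N rule — remove the pair if either mate has strictly more than 5% N bases.
2. Mean-quality rule — remove the pair if either mate's mean Phred quality is
   strictly below 20, computed on the untrimmed read.
3. 3' trimming — per mate, remove the maximal 3'-terminal run of bases with
   quality strictly below 13; trimming stops at the first base (from the 3'
   end) with quality >= 13.
4. Length rule — after trimming, remove the pair if either mate is strictly
   shorter than 40 bases.
5. Deduplication — among pairs whose trimmed mate sequences are identical,
   keep only the first-encountered pair.

All thresholds live in :class:`QCThresholds` and all comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .models import ReadPair

RULE_ORDER = ("n_rich", "low_mean_q", "too_short_after_trim", "duplicate")


@dataclass
class QCThresholds:
    max_n_fraction: float = 0.05
    min_mean_quality: float = 20.0
    trim_quality_floor: int = 13
    min_length_after_trim: int = 40

    def __post_init__(self) -> None:
        if not 0 < self.max_n_fraction <= 1:
            raise ValueError("max_n_fraction must be in (0, 1]")
        if self.min_mean_quality <= 0 or self.trim_quality_floor <= 0:
            raise ValueError("quality thresholds must be positive")
        if self.min_length_after_trim <= 0:
            raise ValueError("min_length_after_trim must be positive")


@dataclass
class QCReport:
    pairs_in: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in RULE_ORDER}
    )
    pairs_retained: int = 0
    bases_trimmed: int = 0

    def check(self) -> None:
        if self.pairs_in != self.pairs_retained + sum(self.removed.values()):
            raise AssertionError("QC report counts do not conserve pairs")


def _check_pair(pair: ReadPair) -> None:
    for seq, _ in pair.mates:
        if len(seq) == 0:
            raise ValueError(f"{pair.pair_id}: zero-length mate")


def n_fraction_rule(pair: ReadPair, t: QCThresholds) -> bool:
    """True = keep. Removes the pair if either mate is >max_n_fraction N."""
    _check_pair(pair)
    for seq, _ in pair.mates:
        if seq.count("N") / len(seq) > t.max_n_fraction:
            return False
    return True


def mean_quality_rule(pair: ReadPair, t: QCThresholds) -> bool:
    """True = keep. Mean quality is computed on the untrimmed read."""
    _check_pair(pair)
    for _, quals in pair.mates:
        if sum(quals) / len(quals) < t.min_mean_quality:
            return False
    return True


def trim_three_prime(
    seq: str, quals: tuple[int, ...], t: QCThresholds
) -> tuple[str, tuple[int, ...]]:
    """Drop the maximal 3'-terminal run of bases below the quality floor."""
    end = len(quals)
    while end > 0 and quals[end - 1] < t.trim_quality_floor:
        end -= 1
    return seq[:end], quals[:end]


def length_rule(pair: ReadPair, t: QCThresholds) -> bool:
    """True = keep. Applied after trimming."""
    for seq, _ in pair.mates:
        if len(seq) < t.min_length_after_trim:
            return False
    return True


def process_pairs(
    pairs: Iterable[ReadPair], t: QCThresholds | None = None
) -> tuple[list[ReadPair], QCReport, dict[str, str]]:
    """Run the full rule cascade over a pair stream.

    Returns (retained pairs, report, removal reason per removed pair id).
    """
    t = t or QCThresholds()
    report = QCReport()
    removed_reason: dict[str, str] = {}
    retained: list[ReadPair] = []
    seen: dict[tuple[str, str], str] = {}
    for pair in pairs:
        report.pairs_in += 1
        if not n_fraction_rule(pair, t):
            report.removed["n_rich"] += 1
            removed_reason[pair.pair_id] = "n_rich"
            continue
        if not mean_quality_rule(pair, t):
            report.removed["low_mean_q"] += 1
            removed_reason[pair.pair_id] = "low_mean_q"
            continue
        seq1, qual1 = trim_three_prime(pair.seq1, pair.qual1, t)
        seq2, qual2 = trim_three_prime(pair.seq2, pair.qual2, t)
        report.bases_trimmed += (len(pair.seq1) - len(seq1)) + (len(pair.seq2) - len(seq2))
        trimmed = ReadPair(pair.pair_id, seq1, qual1, seq2, qual2)
        if not length_rule(trimmed, t):
            report.removed["too_short_after_trim"] += 1
            removed_reason[pair.pair_id] = "too_short_after_trim"
            continue
        key = (seq1, seq2)
        if key in seen:
            report.removed["duplicate"] += 1
            removed_reason[pair.pair_id] = "duplicate"
            continue
        seen[key] = pair.pair_id
        retained.append(trimmed)
        report.pairs_retained += 1
    report.check()
    return retained, report, removed_reason


def run_read_qc(
    fastq_in: tuple[str, str],
    fastq_out: tuple[str, str],
    t: QCThresholds | None = None,
) -> QCReport:
    """File-level entry point: filter a FASTQ pair and write the survivors."""
    from .io import iter_fastq_pairs, write_fastq_pair

    retained, report, _ = process_pairs(iter_fastq_pairs(*fastq_in), t)
    write_fastq_pair(retained, *fastq_out)
    return report


def report_frame(report: QCReport):
    """Report as a tidy one-row table (for the TSV the CLI writes)."""
    import pandas as pd

    row = {"pairs_in": report.pairs_in}
    row.update({f"removed_{k}": v for k, v in report.removed.items()})
    row["pairs_retained"] = report.pairs_retained
    row["bases_trimmed"] = report.bases_trimmed
    return pd.DataFrame([row])
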