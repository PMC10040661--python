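"""Read, transcript and contig quality filters, including contamination screening.

The read filter drops a read when any of these holds:

* more than ``max_consecutive_n`` consecutive ``N`` calls (default 3);
* more than ``max_low_q_bases`` bases at PHRED <= ``low_q`` (defaults 3 and 20);
* median PHRED below ``min_median_q`` (default 20);
* length below 50 bp for paired-end or 25 bp for mate-pair libraries.

Note the median rule is implied by the low-quality-base count for any read of
eight or more bases (a sub-20 median forces at least half the bases to Q<20),
so in practice it only bites on degenerate short inputs; it is checked anyway
so the rule set matches its statement.

The contamination screen unions the passing hit intervals of a contig
(overlaps counted once) and flags the contig when that union covers more
than ``max_fraction`` of its length.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass

from .core import ContigHitSet, ReadRecord

MIN_READ_LEN = {"paired_end": 50, "mate_pair": 25}

_N_RUN = re.compile(r"[Nn]+")


@dataclass(frozen=True)
class ReadFilterConfig:
    max_consecutive_n: int = 3
    max_low_q_bases: int = 3
    low_q: int = 20
    min_median_q: float = 20.0
    min_len: dict | None = None  # per library class; defaults to MIN_READ_LEN

    def min_len_for(self, library_class: str) -> int:
        table = self.min_len or MIN_READ_LEN
        return table[library_class]


def read_failure_reason(
    read: ReadRecord, cfg: ReadFilterConfig = ReadFilterConfig()
) -> str | None:
    """Why a read fails, or None if it passes.

    Reasons are checked in the order the rules are stated: consecutive Ns,
    low-quality base count, median quality, length. Empty reads fail on
    length.
    """
    if len(read.sequence) == 0:
        return "length"
    runs = _N_RUN.findall(read.sequence)
    if runs and max(len(r) for r in runs) > cfg.max_consecutive_n:
        return "consecutive_n"
    n_low = sum(1 for q in read.qualities if q <= cfg.low_q)
    if n_low > cfg.max_low_q_bases:
        return "low_quality_bases"
    if statistics.median(read.qualities) < cfg.min_median_q:
        return "low_median_quality"
    if len(read.sequence) < cfg.min_len_for(read.library_class):
        return "length"
    return None


def filter_reads(
    reads,
    cfg: ReadFilterConfig = ReadFilterConfig(),
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Split reads into (kept, discarded-with-reason)."""
    kept: list[ReadRecord] = []
    discarded: list[tuple[ReadRecord, str]] = []
    for read in reads:
        reason = read_failure_reason(read, cfg)
        if reason is None:
            kept.append(read)
        else:
            discarded.append((read, reason))
    return kept, discarded


def filter_transcripts(seqs, min_len: int = 241):
    """Keep transcript sequences of length >= min_len.

    ``seqs`` is an iterable of (id, sequence) pairs or objects with
    ``len()``-able sequences (Bio.SeqRecord works).
    """
    return [s for s in seqs if _seq_len(s) >= min_len]


def filter_contigs_by_length(contigs, min_len: int = 1001):
    """Keep contigs of length >= min_len (default: strictly over 1,000 bp)."""
    return [c for c in contigs if _seq_len(c) >= min_len]


def _seq_len(item) -> int:
    if isinstance(item, tuple):
        return len(item[1])
    try:
        return len(item.seq)
    except AttributeError:
        return len(item)


@dataclass(frozen=True)
class ContaminationConfig:
    max_evalue: float = 1e-8  # strict: evalue must be below this
    min_hit_len: int = 100  # strict: hit length must exceed this
    min_identity: float = 70.0  # strict: identity must exceed this
    max_fraction: float = 0.25  # strict: union fraction must exceed this


def union_length(intervals) -> int:
    """Total bases covered by a set of 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    total = 0
    cur_start: int | None = None
    cur_end = 0
    for start, end in ivs:
        if cur_start is None or start > cur_end + 1:
            if cur_start is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_start is not None:
        total += cur_end - cur_start + 1
    return total


def contamination_filter(
    hitset: ContigHitSet, cfg: ContaminationConfig = ContaminationConfig()
) -> tuple[str, float]:
    """Classify a contig as ``contaminant`` or ``clean``.

    Hits are first gated per hit (evalue < max_evalue, hit length >
    min_hit_len, identity > min_identity); survivors are unioned on the
    contig and the contig is a contaminant iff the covered fraction of its
    length exceeds ``max_fraction``. Returns (verdict, covered fraction).
    """
    passing = [
        (start, end)
        for start, end, ident, evalue in hitset.hits
        if evalue < cfg.max_evalue
        and (end - start + 1) > cfg.min_hit_len
        and ident > cfg.min_identity
    ]
    fraction = union_length(passing) / hitset.contig_len if passing else 0.0
    verdict = "contaminant" if fraction > cfg.max_fraction else "clean"
    return verdict, fraction
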