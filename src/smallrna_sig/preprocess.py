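"""Raw FASTQ -> clean reads -> collapsed tags.

Clean reads are obtained by trimming the 3' (and optionally 5') adapter,
then removing contaminants, too-short/too-long reads (the library is
gel-selected to 18-40 nt) and low-quality reads.  Identical clean reads are
collapsed into tags carrying a copy number, the unit all downstream
quantification operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import FastqRead
from .util import mean_phred


@dataclass(frozen=True)
class TrimmedRead:
    read: FastqRead
    adapter3_found: bool = False
    adapter5_found: bool = False


@dataclass
class PreprocessStats:
    """Read-ledger: raw = clean + contaminant + length + quality rejections."""

    raw: int = 0
    adapter_trimmed: int = 0
    contaminant_rejected: int = 0
    length_rejected: int = 0
    quality_rejected: int = 0
    clean: int = 0

    def balances(self) -> bool:
        return self.raw == (
            self.clean
            + self.contaminant_rejected
            + self.length_rejected
            + self.quality_rejected
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "raw": self.raw,
            "adapter_trimmed": self.adapter_trimmed,
            "contaminant_rejected": self.contaminant_rejected,
            "length_rejected": self.length_rejected,
            "quality_rejected": self.quality_rejected,
            "clean": self.clean,
        }


@dataclass
class CleanReadSet:
    reads: list[FastqRead]
    stats: PreprocessStats


@dataclass(frozen=True)
class Tag:
    """A distinct clean-read sequence with its copy number."""

    sequence: str
    count: int
    rank: int = 0

    @property
    def id(self) -> str:
        return f"t{self.rank}_x{self.count}"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be positive")


def find_adapter3(seq: str, adapter: str, min_overlap: int = 6,
                  max_mismatch_rate: float = 0.1) -> int | None:
    """Start of the best semi-global 3' adapter match, or None.

    Everything from the returned index to the read end is adapter.  The
    adapter may begin anywhere in the read and run off its 3' end.  Score is
    matches − 3·mismatches over the overlap; the best score wins, ties going
    to the leftmost (most conservative) trim.
    """
    n, m = len(seq), len(adapter)
    if m == 0:
        raise ValueError("3' adapter must be non-empty")
    # A leftmost full exact occurrence cannot be out-scored by any other
    # candidate (score <= m with equality only for full exact matches).
    idx = seq.find(adapter)
    if idx >= 0:
        return idx
    best_i, best_score = None, None
    for i in range(0, n - min_overlap + 1):
        ov = min(m, n - i)
        allowed = int(max_mismatch_rate * ov)
        mism = 0
        window = seq[i : i + ov]
        for a, b in zip(window, adapter):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism > allowed:
            continue
        score = (ov - mism) - 3 * mism
        if best_score is None or score > best_score:
            best_i, best_score = i, score
    return best_i


def find_adapter5(seq: str, adapter: str, min_overlap: int = 6,
                  max_mismatch_rate: float = 0.1) -> int | None:
    """Length of a 5' adapter suffix aligned to the read prefix, or None."""
    n, m = len(seq), len(adapter)
    for ov in range(min(m, n), min_overlap - 1, -1):
        mism = sum(1 for a, b in zip(seq[:ov], adapter[m - ov :]) if a != b)
        if mism <= max_mismatch_rate * ov:
            return ov
    return None


def trim_adapters(
    reads: Iterable[FastqRead],
    adapter3: str,
    adapter5: str = "",
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> list[TrimmedRead]:
    """Remove adapter sequence from each read; untrimmable reads pass through.

    The 3' adapter and everything downstream of it are removed.  If a 5'
    adapter is configured, a matching read prefix is removed as well (whether
    such reads are instead discarded is decided in :func:`filter_clean`).
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    out: list[TrimmedRead] = []
    for read in reads:
        seq, qual = read.seq, read.qual
        found3 = found5 = False
        i3 = find_adapter3(seq, adapter3, min_overlap, max_mismatch_rate)
        if i3 is not None:
            seq, qual = seq[:i3], qual[:i3]
            found3 = True
        if adapter5:
            ov = find_adapter5(seq, adapter5, min_overlap, max_mismatch_rate)
            if ov is not None:
                seq, qual = seq[ov:], qual[ov:]
                found5 = True
        out.append(TrimmedRead(FastqRead(read.id, seq, qual), found3, found5))
    return out


def filter_clean(
    trimmed: Sequence[TrimmedRead],
    min_len: int = 18,
    max_len: int = 40,
    min_mean_quality: float = 20.0,
    contaminants: Sequence[str] = (),
    discard_adapter5: bool = False,
) -> CleanReadSet:
    """Apply the clean-read filters and keep the ledger balanced.

    Retains reads of length in [min_len, max_len] with no ambiguous base and
    mean Phred >= min_mean_quality.  ``contaminants`` is an optional list of
    sequences screened by exact substring match; with ``discard_adapter5``
    reads that carried a 5' adapter are treated as contaminants rather than
    kept trimmed.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    stats = PreprocessStats()
    kept: list[FastqRead] = []
    for tr in trimmed:
        stats.raw += 1
        if tr.adapter3_found or tr.adapter5_found:
            stats.adapter_trimmed += 1
        seq = tr.read.seq
        if (discard_adapter5 and tr.adapter5_found) or any(
            c in seq for c in contaminants if c
        ):
            stats.contaminant_rejected += 1
            continue
        if not (min_len <= len(seq) <= max_len):
            stats.length_rejected += 1
            continue
        if "N" in seq or mean_phred(tr.read.qual) < min_mean_quality:
            stats.quality_rejected += 1
            continue
        stats.clean += 1
        kept.append(tr.read)
    assert stats.balances()
    return CleanReadSet(reads=kept, stats=stats)


def collapse_reads(clean: CleanReadSet | Sequence[FastqRead]) -> list[Tag]:
    """Collapse identical clean reads into tags.

    Tags are ordered by descending count, then lexicographic sequence, and
    numbered from 1 in that order.  Sum of tag counts equals the clean-read
    count (the collapse is lossless).
    """
    reads = clean.reads if isinstance(clean, CleanReadSet) else clean
    counts: dict[str, int] = {}
    for read in reads:
        counts[read.seq] = counts.get(read.seq, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [Tag(seq, n, rank=i + 1) for i, (seq, n) in enumerate(ordered)]


def preprocess_reads(
    reads: Iterable[FastqRead],
    adapter3: str,
    adapter5: str = "",
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_len: int = 18,
    max_len: int = 40,
    min_mean_quality: float = 20.0,
    contaminants: Sequence[str] = (),
    discard_adapter5: bool = False,
) -> tuple[list[Tag], CleanReadSet]:
    """Convenience wrapper: trim, filter and collapse in one call."""
    trimmed = trim_adapters(reads, adapter3, adapter5, min_overlap, max_mismatch_rate)
    clean = filter_clean(trimmed, min_len, max_len, min_mean_quality,
                         contaminants, discard_adapter5)
    return collapse_reads(clean), clean
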