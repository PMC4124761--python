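"""Exact, exhaustive, double-stranded genome matching of tags.

Only perfect matches are retained, so mapping reduces to exact substring
search.  A k-mer hash over the forward genome seeds lookups; the reverse
strand is handled by querying the reverse complement of each tag, so a hit
``(chrom, start, '-')`` means the genome substring at ``[start, start+len)``
equals the reverse complement of the tag.  All occurrences are reported —
multi-mapping must be preserved because the weighted quantification divides
each tag's count by its number of hits.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .preprocess import Tag
from .util import percentage, revcomp


class Hit(NamedTuple):
    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class HitSet:
    """All perfect-match genomic occurrences of one tag."""

    tag: Tag
    hits: tuple[Hit, ...]

    @property
    def n_hits(self) -> int:
        return len(self.hits)


class MatchIndex:
    """k-mer seeded exact-substring lookup over a genome.

    Supports queries of length >= k (default 18, the shortest retained
    read).  Positions containing N are never indexed and never match.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 18):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("cannot index an empty genome")
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        bad = {
            c for seq in self.genome.values() for c in set(seq) if c not in "ACGTN"
        }
        if bad:
            raise ValueError(f"genome contains non-ACGTN characters: {sorted(bad)}")
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._seeds[kmer].append((chrom, i))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        seed = query[: self.k]
        out = []
        for chrom, i in self._seeds.get(seed, ()):
            window = self.genome[chrom][i : i + len(query)]
            if window == query:  # N in genome never equals an ACGT base of query
                out.append((chrom, i))
        return out

    def query(self, sequence: str) -> list[Hit]:
        """All perfect-match occurrences of ``sequence`` on both strands."""
        sequence = sequence.upper()
        if len(sequence) < self.k:
            raise ValueError(
                f"query length {len(sequence)} below index support (k={self.k})"
            )
        if "N" in sequence:
            return []
        hits = [Hit(c, i, "+") for c, i in self._occurrences(sequence)]
        hits += [Hit(c, i, "-") for c, i in self._occurrences(revcomp(sequence))]
        return sorted(hits)


def build_index(genome: Mapping[str, str], k: int = 18) -> MatchIndex:
    return MatchIndex(genome, k=k)


def match_tags(index: MatchIndex, tags: Iterable[Tag]) -> list[HitSet]:
    """Map tags; tags with no perfect match are omitted from the result."""
    out = []
    for tag in tags:
        hits = index.query(tag.sequence)
        if hits:
            out.append(HitSet(tag=tag, hits=tuple(hits)))
    return out


@dataclass(frozen=True)
class MappingSummary:
    """One row of a sequencing-summary table (clean reads / mapped / %)."""

    total_clean: int
    mapped: int

    @property
    def percentage(self) -> float:
        return percentage(self.mapped, self.total_clean)

    def __post_init__(self) -> None:
        if not 0 <= self.mapped <= self.total_clean:
            raise ValueError("mapped count must lie in [0, total_clean]")
        if self.total_clean == 0:
            raise ValueError("mapping percentage undefined for zero clean reads")


def summarize_mapping(tags: Sequence[Tag], hitsets: Sequence[HitSet]) -> MappingSummary:
    """Clean-read mapping summary: a read is mapped iff its tag has a hit."""
    mapped_seqs = {hs.tag.sequence for hs in hitsets}
    total = sum(t.count for t in tags)
    mapped = sum(t.count for t in tags if t.sequence in mapped_seqs)
    return MappingSummary(total_clean=total, mapped=mapped)
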