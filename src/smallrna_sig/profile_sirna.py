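"""Endo-siRNA screening and weighted expression-by-length profiles.

Candidate endo-siRNAs must satisfy three criteria: length 18-23 nt, a
perfect genome match, and repeat-derived origin.  Because the annotation
hierarchy places endo-siRNA last, a tag already claimed by a higher-priority
class (miRNA, structural RNA, piRNA) is excluded even when it meets all
three criteria.  Expression is summarized per read length as weighted tag
totals scaled to "tag count per 10 million" over the sample's genome-mapped
read total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .annotate import ClassifiedTag, RepeatTrack, UNANNOTATED


@dataclass(frozen=True)
class EndoSiRNACall:
    """Per-tag screening outcome with each criterion recorded separately."""

    tag_id: str
    sequence: str
    count: int
    length: int
    n_hits: int
    repeat_families: tuple[str, ...]
    pass_length: bool
    pass_mapped: bool
    pass_repeat: bool
    pass_hierarchy: bool

    @property
    def passed(self) -> bool:
        return (self.pass_length and self.pass_mapped and self.pass_repeat
                and self.pass_hierarchy)

    @property
    def weight(self) -> float:
        return self.count / self.n_hits if self.n_hits else 0.0


def screen_endo_sirna(
    classified: Sequence[ClassifiedTag],
    repeats: RepeatTrack,
    min_len: int = 18,
    max_len: int = 23,
    repeat_overlap_frac: float = 0.5,
) -> list[EndoSiRNACall]:
    """Screen mapped tags against the endo-siRNA criteria.

    "Repeat-derived" means at least one genomic hit is overlapped by a
    repeat interval over >= ``repeat_overlap_frac`` of the tag length.  The
    hierarchy criterion passes only for tags no annotation track claimed.
    """
    calls: list[EndoSiRNACall] = []
    for ct in classified:
        length = ct.length
        fams: set[str] = set()
        pass_repeat = False
        for hit in ct.hitset.hits:
            for fam, ov in repeats.overlap(hit.chrom, hit.start, hit.start + length):
                if ov >= repeat_overlap_frac * length:
                    fams.add(fam)
                    pass_repeat = True
        calls.append(
            EndoSiRNACall(
                tag_id=ct.tag.id,
                sequence=ct.tag.sequence,
                count=ct.count,
                length=length,
                n_hits=ct.hitset.n_hits,
                repeat_families=tuple(sorted(fams)),
                pass_length=min_len <= length <= max_len,
                pass_mapped=ct.hitset.n_hits >= 1,
                pass_repeat=pass_repeat,
                pass_hierarchy=ct.class_label == UNANNOTATED,
            )
        )
    return calls


def sirna_length_profile(
    calls: Sequence[EndoSiRNACall],
    total_mapped_reads: int,
    min_len: int = 18,
    max_len: int = 23,
    scale: float = 1e7,
) -> pd.Series:
    """Weighted endo-siRNA signal per length, as tag count per 10 million.

    Only passing calls contribute; each adds its weighted count w = count /
    n_hits at its length (multi-mappers are down-weighted), scaled by
    ``scale / total_mapped_reads``.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    profile = pd.Series(0.0, index=range(min_len, max_len + 1), name="tags_per_10M")
    factor = scale / total_mapped_reads
    for call in calls:
        if call.passed and min_len <= call.length <= max_len:
            profile[call.length] += call.weight * factor
    return profile


def calls_to_frame(calls: Sequence[EndoSiRNACall]) -> pd.DataFrame:
    """Screening results as a table with per-criterion booleans."""
    return pd.DataFrame(
        [
            {
                "tag": c.tag_id,
                "sequence": c.sequence,
                "count": c.count,
                "length": c.length,
                "n_hits": c.n_hits,
                "repeat_families": ",".join(c.repeat_families),
                "pass_length": c.pass_length,
                "pass_mapped": c.pass_mapped,
                "pass_repeat": c.pass_repeat,
                "pass_hierarchy": c.pass_hierarchy,
                "passed": c.passed,
            }
            for c in calls
        ]
    )
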