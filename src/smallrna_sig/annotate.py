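"""Hierarchical annotation of mapped tags into small-RNA classes.

Each mapped tag is assigned the highest-priority class overlapped by any of
its genomic hits, under the fixed ordering used for small-RNA libraries:

    miRNA  >  rRNA/snoRNA/tRNA/scRNA/snRNA  >  piRNA  >  endo-siRNA

miRNA and the structural classes require same-strand overlap; piRNA cluster
overlap can optionally be strand-agnostic (clusters are single-strand
annotations, but both strands are profiled downstream).  endo-siRNA is not a
track: tags left unannotated here are screened by rule in
:mod:`smallrna_sig.profile_sirna`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_match import Hit, HitSet
from .io import read_bed6, read_gff3
from .preprocess import Tag

#: Annotation priority, highest first.  Classes within one tier share a rank.
CLASS_TIERS: tuple[tuple[str, ...], ...] = (
    ("miRNA",),
    ("rRNA", "snoRNA", "tRNA", "scRNA", "snRNA"),
    ("piRNA",),
)

STRUCTURAL_CLASSES = CLASS_TIERS[1]
KNOWN_CLASSES = tuple(c for tier in CLASS_TIERS for c in tier)

UNANNOTATED = "unannotated"
ENDO_SIRNA = "endo_siRNA"


@dataclass(frozen=True)
class Locus:
    """A genomic annotation interval, 0-based half-open."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    #: for mature miRNAs, the hairpin locus id
    parent: str | None = None
    #: 'hairpin' or 'mature' for miRNA loci, '' otherwise
    subtype: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


class AnnotationSet:
    """Per-class interval collections queryable by (chrom, interval, strand)."""

    def __init__(self, loci: Iterable[Locus] = ()):
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self.loci: dict[str, Locus] = {}
        for locus in loci:
            self.add(locus)

    def add(self, locus: Locus) -> None:
        if locus.feature_class not in KNOWN_CLASSES:
            raise ValueError(f"unknown annotation class {locus.feature_class!r}")
        if locus.locus_id in self.loci:
            raise ValueError(f"duplicate locus id {locus.locus_id!r}")
        if locus.end <= locus.start:
            raise ValueError(f"empty interval for locus {locus.locus_id!r}")
        self.loci[locus.locus_id] = locus
        self._trees[(locus.feature_class, locus.chrom)][locus.start : locus.end] = locus

    def __len__(self) -> int:
        return len(self.loci)

    def classes(self) -> set[str]:
        return {l.feature_class for l in self.loci.values()}

    def by_class(self, feature_class: str) -> list[Locus]:
        return [l for l in self.loci.values() if l.feature_class == feature_class]

    def query(self, feature_class: str, chrom: str, start: int, end: int) -> list[Locus]:
        """Loci of one class overlapping [start, end) on chrom (any strand)."""
        tree = self._trees.get((feature_class, chrom))
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda l: l.locus_id)


class RepeatTrack:
    """Repeat intervals with family labels (e.g. ERV1/ERV2/ERV3/LINE/SINE)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str, str]] = ()):
        # (chrom, start, end, family, strand)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.intervals: list[tuple[str, int, int, str, str]] = []
        for chrom, start, end, family, strand in intervals:
            self.add(chrom, start, end, family, strand)

    def add(self, chrom: str, start: int, end: int, family: str, strand: str = "+") -> None:
        if end <= start:
            raise ValueError("empty repeat interval")
        self.intervals.append((chrom, start, end, family, strand))
        self._trees[chrom][start:end] = (family, start, end)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def families(self) -> set[str]:
        return {fam for _, _, _, fam, _ in self.intervals}

    def overlap(self, chrom: str, start: int, end: int) -> list[tuple[str, int]]:
        """(family, overlap length) for every repeat overlapping the query."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start, end):
            fam, s, e = iv.data
            out.append((fam, min(end, e) - max(start, s)))
        return out

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatTrack":
        df = read_bed6(path)
        track = cls()
        for row in df.itertuples(index=False):
            track.add(row.chrom, row.start, row.end, row.name, row.strand)
        return track

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals,
                            columns=["chrom", "start", "end", "family", "strand"])


def load_annotations(gff_paths: Mapping[str, str | Path]) -> AnnotationSet:
    """Build an :class:`AnnotationSet` from per-class GFF3 files.

    The GFF3 ``type`` column carries the class (``miRNA_hairpin`` and
    ``miRNA_mature`` both map to class miRNA); the ``ID`` attribute is the
    locus id.  Coordinates are converted from 1-based inclusive to 0-based
    half-open on read.
    """
    ann = AnnotationSet()
    for cls_name, path in gff_paths.items():
        if cls_name not in KNOWN_CLASSES:
            raise ValueError(f"unknown annotation class {cls_name!r} for {path}")
        df = read_gff3(path)
        for i, row in enumerate(df.itertuples(index=False)):
            if row.ID is None:
                raise ValueError(f"{path}: record {i + 1} lacks an ID attribute")
            subtype = ""
            if cls_name == "miRNA":
                subtype = "mature" if "mature" in str(row.type) else "hairpin"
            ann.add(
                Locus(
                    locus_id=row.ID,
                    chrom=row.seqid,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    feature_class=cls_name,
                    parent=row.Parent,
                    subtype=subtype,
                )
            )
    return ann


@dataclass
class ClassifiedTag:
    """A mapped tag with its class assignment and the hit that decided it."""

    tag: Tag
    hitset: HitSet
    class_label: str
    assigned_locus: str | None = None
    assigned_hit: Hit | None = None
    overlapped_loci: tuple[str, ...] = ()

    @property
    def count(self) -> int:
        return self.tag.count

    @property
    def length(self) -> int:
        return len(self.tag.sequence)


def _strand_ok(hit_strand: str, locus_strand: str, feature_class: str,
               pirna_strand_agnostic: bool) -> bool:
    if feature_class == "piRNA" and pirna_strand_agnostic:
        return True
    return hit_strand == locus_strand


def classify_tag(
    hitset: HitSet,
    ann: AnnotationSet,
    min_overlap_frac: float = 0.8,
    pirna_strand_agnostic: bool = False,
) -> ClassifiedTag:
    """Assign a mapped tag to its highest-priority overlapping class.

    Classes are evaluated tier by tier; within the winning tier the locus
    with the largest overlap wins, ties broken by lexicographic locus id.
    A tag whose hits overlap no track at the required fraction is labelled
    ``unannotated`` (the endo-siRNA screen may claim it later).
    """
    if hitset.n_hits == 0:
        raise ValueError("cannot classify a tag with no genomic hits")
    tag_len = len(hitset.tag.sequence)
    min_overlap = min_overlap_frac * tag_len

    for tier in CLASS_TIERS:
        # (−overlap, locus_id) ordering makes the tie-break order-free
        best: tuple[float, str, Locus, Hit] | None = None
        overlapped: set[str] = set()
        for hit in hitset.hits:
            h_start, h_end = hit.start, hit.start + tag_len
            for cls_name in tier:
                for locus in ann.query(cls_name, hit.chrom, h_start, h_end):
                    ov = min(h_end, locus.end) - max(h_start, locus.start)
                    if ov < min_overlap:
                        continue
                    if not _strand_ok(hit.strand, locus.strand, cls_name,
                                      pirna_strand_agnostic):
                        continue
                    overlapped.add(locus.locus_id)
                    key = (-ov, locus.locus_id)
                    if best is None or key < (-best[0], best[1]):
                        best = (ov, locus.locus_id, locus, hit)
        if best is not None:
            _, _, locus, hit = best
            return ClassifiedTag(
                tag=hitset.tag,
                hitset=hitset,
                class_label=locus.feature_class,
                assigned_locus=locus.locus_id,
                assigned_hit=hit,
                overlapped_loci=tuple(sorted(overlapped)),
            )
    return ClassifiedTag(tag=hitset.tag, hitset=hitset, class_label=UNANNOTATED)


def classify_tags(
    hitsets: Iterable[HitSet],
    ann: AnnotationSet,
    min_overlap_frac: float = 0.8,
    pirna_strand_agnostic: bool = False,
) -> list[ClassifiedTag]:
    return [
        classify_tag(hs, ann, min_overlap_frac, pirna_strand_agnostic)
        for hs in hitsets
    ]


def class_composition(classified: Sequence[ClassifiedTag]) -> pd.DataFrame:
    """Per-class read counts and fractions of annotated reads.

    Returns one row per class present, with columns ``reads`` (absolute
    annotated read counts) and ``fraction`` (of annotated reads, summing to
    1), plus an ``unannotated`` row whose fraction is NaN.
    """
    counts: dict[str, int] = defaultdict(int)
    for ct in classified:
        counts[ct.class_label] += ct.count
    unann = counts.pop(UNANNOTATED, 0)
    total_annotated = sum(counts.values())
    rows = [
        {
            "class": cls_name,
            "reads": n,
            "fraction": (n / total_annotated) if total_annotated else float("nan"),
        }
        for cls_name, n in sorted(counts.items(), key=lambda kv: -kv[1])
    ]
    rows.append({"class": UNANNOTATED, "reads": unann, "fraction": float("nan")})
    return pd.DataFrame(rows, columns=["class", "reads", "fraction"])


def length_distribution(
    tagged: Sequence[ClassifiedTag] | Sequence[Tag],
    min_len: int = 18,
    max_len: int = 40,
    weighted: bool = False,
) -> pd.Series:
    """Read totals per length over [min_len, max_len].

    With ``weighted=True`` each tag contributes count/#hits per hit summed
    over hits — which equals its count — so the flag only matters when the
    caller pre-filters hits; it is kept for symmetry with the weighted
    profiles.
    """
    totals = pd.Series(0.0, index=range(min_len, max_len + 1), name="reads")
    for item in tagged:
        tag = item.tag if isinstance(item, ClassifiedTag) else item
        n = len(tag.sequence)
        if min_len <= n <= max_len:
            totals[n] += tag.count
    return totals
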