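"""Mature-miRNA quantification, normalization, signature calls, clustering.

miRNA-classified tags are counted per mature miRNA, normalized to reads per
million (RPM) within each sample, thresholded at RPM >= 1 to call
expression, and screened for cell-type signatures: a mature miRNA is
focal-sample specific when it is expressed in the focal sample and at least
``fold``-fold higher than in *every* other sample.  Samples are clustered
hierarchically on the log2-RPM layer with correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .annotate import AnnotationSet, ClassifiedTag

HAIRPIN_BUCKET_PREFIX = "hairpin:"


def count_mature(
    classified: Sequence[ClassifiedTag],
    ann: AnnotationSet,
    min_overlap_frac: float = 0.8,
) -> tuple[pd.Series, list[str]]:
    """Raw counts per mature miRNA for one sample.

    A miRNA-classified tag contributes its full count to each distinct
    mature interval its assigning hit overlaps at ``min_overlap_frac`` of
    the tag length.  Tags whose assigning hit overlaps only the hairpin are
    counted into a flagged ``hairpin:<id>`` bucket.

    Returns the count series (indexed by every mature locus in the
    annotation, zero-filled) and the list of hairpin-only bucket ids.
    """
    matures = sorted(
        l.locus_id for l in ann.loci.values()
        if l.feature_class == "miRNA" and l.subtype == "mature"
    )
    counts: dict[str, int] = {m: 0 for m in matures}
    flagged: list[str] = []
    for ct in classified:
        if ct.class_label != "miRNA" or ct.assigned_hit is None:
            continue
        tag_len = ct.length
        hit = ct.assigned_hit
        h_start, h_end = hit.start, hit.start + tag_len
        assigned = []
        for locus in ann.query("miRNA", hit.chrom, h_start, h_end):
            if locus.subtype != "mature" or locus.strand != hit.strand:
                continue
            ov = min(h_end, locus.end) - max(h_start, locus.start)
            if ov >= min_overlap_frac * tag_len:
                assigned.append(locus.locus_id)
        if assigned:
            for m in set(assigned):
                counts[m] = counts.get(m, 0) + ct.count
        else:
            bucket = HAIRPIN_BUCKET_PREFIX + (ct.assigned_locus or "unknown")
            counts[bucket] = counts.get(bucket, 0) + ct.count
            flagged.append(bucket)
    return pd.Series(counts, name="count").sort_index(), sorted(set(flagged))


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with RPM and log2 layers.

    ``library_sizes`` are the per-sample normalization denominators; the
    default builder uses the per-sample miRNA-annotated total (so each RPM
    column sums to 1e6), with any externally supplied denominator (e.g.
    total genome-mapped reads) accepted instead.
    """

    raw: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.raw = self.raw.fillna(0)
        self.library_sizes = self.library_sizes.reindex(self.raw.columns)
        if (self.library_sizes <= 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be positive for every sample")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, pd.Series] | pd.DataFrame,
        library_sizes: Mapping[str, float] | None = None,
    ) -> "ExpressionMatrix":
        raw = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(dict(counts))
        raw = raw.fillna(0)
        if library_sizes is None:
            sizes = raw.sum(axis=0)
        else:
            sizes = pd.Series(dict(library_sizes), dtype=float)
        return cls(raw=raw, library_sizes=sizes)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def rpm(self) -> pd.DataFrame:
        return self.raw * 1e6 / self.library_sizes

    def log2_rpm(self, pseudocount: float = 0.0) -> pd.DataFrame:
        """log2(RPM + pseudocount); NaN where the argument is zero.

        With the default pseudocount of 0 the layer is defined only for
        non-zero RPM — the RPM >= 1 expression filter is expected to precede
        any use of this layer.  Clustering uses pseudocount 1.
        """
        shifted = self.rpm() + pseudocount
        with np.errstate(divide="ignore"):
            out = np.log2(shifted.where(shifted > 0))
        return out


def rpm_normalize(
    counts: Mapping[str, pd.Series] | pd.DataFrame,
    library_sizes: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    return ExpressionMatrix.from_counts(counts, library_sizes)


def call_expressed(rpm: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean expression mask: RPM >= threshold."""
    return rpm >= threshold


@dataclass
class SignatureResult:
    """miRNAs specifically highly expressed in the focal sample."""

    focal: str
    others: tuple[str, ...]
    fold: float
    table: pd.DataFrame  # columns: focal RPM + fold_vs_<other> per other

    @property
    def mirnas(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _fold_ratio(focal: np.ndarray, other: np.ndarray, epsilon: float) -> np.ndarray:
    # zero-guard: only a zero denominator is replaced by epsilon, so finite
    # ratios (including exact boundary cases like 10/5) are untouched
    denom = np.where(other > 0, other, epsilon)
    return focal / denom


def call_signature(
    matrix: ExpressionMatrix,
    focal: str,
    others: Sequence[str] | None = None,
    fold: float = 2.0,
    epsilon: float = 0.5,
    expressed_threshold: float = 1.0,
    vs: str = "each",
) -> SignatureResult:
    """Signature miRNAs of the focal sample at a fold-change threshold.

    A mature miRNA qualifies when its focal RPM is at or above
    ``expressed_threshold`` and its fold change against every other sample
    (``vs='each'``, the default) or against their mean (``vs='mean'``) is at
    least ``fold``.  Zero RPM in a comparison sample is guarded by
    ``epsilon``.  Rows are sorted by descending focal RPM.
    """
    rpm = matrix.rpm()
    if others is None:
        others = [s for s in rpm.columns if s != focal]
    others = list(others)
    if focal in others:
        raise ValueError("focal sample cannot be among the comparison samples")
    if not others:
        raise ValueError("at least one comparison sample is required")
    if fold < 1:
        raise ValueError("fold threshold must be >= 1")

    focal_rpm = rpm[focal].to_numpy()
    mask = focal_rpm >= expressed_threshold
    folds = {}
    if vs == "mean":
        mean_other = rpm[others].mean(axis=1).to_numpy()
        ratio = _fold_ratio(focal_rpm, mean_other, epsilon)
        mask &= ratio >= fold
        folds["fold_vs_mean"] = ratio
    elif vs == "each":
        for s in others:
            ratio = _fold_ratio(focal_rpm, rpm[s].to_numpy(), epsilon)
            mask &= ratio >= fold
            folds[f"fold_vs_{s}"] = ratio
    else:
        raise ValueError("vs must be 'each' or 'mean'")

    table = pd.DataFrame({"focal_rpm": focal_rpm, **folds}, index=rpm.index)
    table = table[mask].sort_values("focal_rpm", ascending=False)
    return SignatureResult(focal=focal, others=tuple(others), fold=fold, table=table)


@dataclass
class SampleClustering:
    """Average-linkage hierarchy over samples in correlation distance."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy hierarchical-clustering encoding

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Merge history as (left members, right members, height)."""
        clusters: dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        out = []
        n = len(self.labels)
        for step, (a, b, height, _) in enumerate(self.linkage_matrix):
            left, right = clusters[int(a)], clusters[int(b)]
            out.append((left, right, float(height)))
            clusters[n + step] = left | right
        return out


def cluster_samples(
    log2_expr: pd.DataFrame,
    min_expressed_samples: int = 1,
    expressed_mask: pd.DataFrame | None = None,
) -> SampleClustering:
    """Cluster samples on log2 expression, correlation distance, average link.

    ``expressed_mask`` (e.g. from :func:`call_expressed`) restricts the
    feature set to miRNAs expressed in at least ``min_expressed_samples``
    samples before computing distances.
    """
    if log2_expr.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    data = log2_expr
    if expressed_mask is not None:
        keep = expressed_mask.sum(axis=1) >= min_expressed_samples
        data = data.loc[keep]
    values = data.to_numpy(dtype=float)
    values = values[~np.isnan(values).any(axis=1)]
    if values.shape[0] < 2:
        raise ValueError("not enough finite features to cluster on")
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrize fp noise
    z = linkage(squareform(dist, checks=False), method="average")
    return SampleClustering(labels=tuple(log2_expr.columns), linkage_matrix=z)
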