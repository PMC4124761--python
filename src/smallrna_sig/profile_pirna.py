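"""Weighted piRNA quantification: multi-mapper weights, strand-resolved
genome-wide distribution, and repeat-family enrichment.

piRNAs are repeat-derived and heavily multi-mapping, so each tag's count is
spread over its genomic hits as a per-hit weight w = count / n_hits
("weighted reads").  The weight is conserved exactly: summed over a tag's
hits it returns the tag's count, so total weighted signal equals the piRNA
read count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotate import ClassifiedTag, RepeatTrack
from .genome_match import Hit


@dataclass(frozen=True)
class WeightedTag:
    """A tag with its per-hit weight w = count / n_hits."""

    tag_id: str
    sequence: str
    count: int
    hits: tuple[Hit, ...]
    class_label: str

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def weight(self) -> float:
        return self.count / self.n_hits


def weight_tags(
    classified: Sequence[ClassifiedTag],
    classes: Iterable[str] = ("piRNA",),
) -> list[WeightedTag]:
    """Per-hit weighted tags for the selected classes.

    Every input tag must be mapped (n_hits >= 1); the conservation
    sum(weight * n_hits) == sum(count) holds exactly up to float error.
    """
    wanted = set(classes)
    out: list[WeightedTag] = []
    for ct in classified:
        if ct.class_label not in wanted:
            continue
        if ct.hitset.n_hits == 0:
            raise ValueError(f"tag {ct.tag.id} has no hits; filter unmapped tags first")
        out.append(
            WeightedTag(
                tag_id=ct.tag.id,
                sequence=ct.tag.sequence,
                count=ct.count,
                hits=ct.hitset.hits,
                class_label=ct.class_label,
            )
        )
    return out


def five_prime_position(hit: Hit, length: int) -> int:
    """5' end of a hit: start on '+', last base on '-'."""
    return hit.start if hit.strand == "+" else hit.start + length - 1


@dataclass
class StrandBinProfile:
    """Summed per-hit weights per (chrom, bin, strand), plus a weighted-RPM layer."""

    bin_size: int
    table: pd.DataFrame  # chrom, bin_start, strand, weight, weighted_rpm
    library_size: float

    def total_weight(self) -> float:
        return float(self.table["weight"].sum())


def genome_distribution(
    weighted: Sequence[WeightedTag],
    bin_size: int,
    library_size: float | None = None,
) -> StrandBinProfile:
    """Strand-resolved binned genome distribution of weighted signal.

    Each hit contributes its tag's weight to the bin containing its 5' end,
    keyed by strand.  ``weighted_rpm`` scales weights by 1e6/library_size
    (library_size defaults to the total weighted signal itself).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    acc: dict[tuple[str, int, str], float] = defaultdict(float)
    for wt in weighted:
        w = wt.weight
        length = len(wt.sequence)
        for hit in wt.hits:
            pos = five_prime_position(hit, length)
            acc[(hit.chrom, (pos // bin_size) * bin_size, hit.strand)] += w
    rows = [
        {"chrom": c, "bin_start": b, "strand": s, "weight": w}
        for (c, b, s), w in sorted(acc.items())
    ]
    table = pd.DataFrame(rows, columns=["chrom", "bin_start", "strand", "weight"])
    if library_size is None:
        library_size = float(table["weight"].sum()) or 1.0
    table["weighted_rpm"] = table["weight"] * 1e6 / library_size
    return StrandBinProfile(bin_size=bin_size, table=table, library_size=library_size)


def _family_weights(
    weighted: Sequence[WeightedTag], repeats: RepeatTrack
) -> tuple[dict[str, float], float]:
    """Per-family weighted signal and the total weighted signal.

    A hit contributes its weight to every family it overlaps (by >= 1 bp),
    so family totals are not additive across families; the total is the
    plain weighted read count.
    """
    per_family: dict[str, float] = defaultdict(float)
    total = 0.0
    for wt in weighted:
        w = wt.weight
        length = len(wt.sequence)
        for hit in wt.hits:
            total += w
            fams = {fam for fam, ov in repeats.overlap(hit.chrom, hit.start,
                                                       hit.start + length)}
            for fam in fams:
                per_family[fam] += w
    return dict(per_family), total


def repeat_enrichment(
    weighted_by_sample: Mapping[str, Sequence[WeightedTag]],
    repeats: RepeatTrack,
    sample_pair: tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeat-family enrichment between two samples.

    For each family, the weighted in-family vs out-of-family counts of the
    two samples (rounded to integers) form a 2x2 table tested with Fisher's
    exact test; p-values are Benjamini-Hochberg corrected across families.
    Returns one row per family with fractions, odds ratio, p, q and an
    ``enriched`` flag (q < alpha).
    """
    a, b = sample_pair
    fam_a, tot_a = _family_weights(weighted_by_sample[a], repeats)
    fam_b, tot_b = _family_weights(weighted_by_sample[b], repeats)
    families = sorted(repeats.families)
    if not families:
        return pd.DataFrame(
            columns=["family", f"fraction_{a}", f"fraction_{b}",
                     "odds_ratio", "p_value", "q_value", "enriched"]
        )
    rows = []
    for fam in families:
        in_a = fam_a.get(fam, 0.0)
        in_b = fam_b.get(fam, 0.0)
        table = np.array(
            [
                [round(in_a), round(max(tot_a - in_a, 0.0))],
                [round(in_b), round(max(tot_b - in_b, 0.0))],
            ],
            dtype=np.int64,
        )
        odds, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "family": fam,
                f"fraction_{a}": in_a / tot_a if tot_a else 0.0,
                f"fraction_{b}": in_b / tot_b if tot_b else 0.0,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(out["p_value"], method="fdr_bh")
    out["q_value"] = qvals
    out["enriched"] = out["q_value"] < alpha
    return out
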