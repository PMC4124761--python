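"""Pipeline orchestration: sample sheet in, summary artifacts out.

Runs preprocess -> match -> annotate -> class profiles for every sample in
the sheet, then the cross-sample analyses (expression matrix, signatures,
clustering, strand-resolved piRNA distributions, repeat enrichment,
endo-siRNA profiles) and writes the summary table, per-class TSVs and
figures.  Every number in the report is recomputed from stage outputs — the
report layer adds no arithmetic of its own beyond formatting.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram
from scipy.stats import spearmanr

from . import annotate as ann_mod
from . import profile_mirna, profile_pirna, profile_sirna
from .annotate import ENDO_SIRNA, UNANNOTATED, RepeatTrack, load_annotations
from .config import PipelineConfig
from .genome_match import MatchIndex, match_tags, summarize_mapping
from .io import read_fasta, read_fastq
from .preprocess import preprocess_reads


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and sample it occurred in."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample
        self.cause = cause


@dataclass
class SampleSheet:
    """Rows of (sample label, FASTQ path, cell-type tag)."""

    rows: pd.DataFrame

    REQUIRED = ("sample", "fastq", "cell_type")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.rows.columns)
        if missing:
            raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
        if self.rows["sample"].duplicated().any():
            raise ValueError("sample labels must be unique")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def samples(self) -> list[str]:
        return list(self.rows["sample"])

    def fastq_of(self, sample: str) -> Path:
        row = self.rows[self.rows["sample"] == sample].iloc[0]
        return Path(row["fastq"])


@dataclass
class SampleResult:
    """Everything one sample contributes to the cross-sample stage."""

    label: str
    stats: dict[str, int]
    summary_total: int
    summary_mapped: int
    classified: list  # ClassifiedTag, with endo-siRNA reassignment applied
    sirna_calls: list
    composition: pd.DataFrame
    length_hist: pd.Series
    mirna_counts: pd.Series


@dataclass
class RunReport:
    outdir: Path
    mapping_summary: pd.DataFrame
    compositions: dict[str, pd.DataFrame]
    length_histograms: dict[str, pd.Series]
    signature: profile_mirna.SignatureResult | None
    clustering: profile_mirna.SampleClustering | None
    trends: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _process_sample(
    label: str,
    fastq: Path,
    index: MatchIndex,
    annset,
    repeats: RepeatTrack,
    cfg: PipelineConfig,
) -> SampleResult:
    pp = cfg.preprocess
    try:
        reads = list(read_fastq(fastq))
    except Exception as err:  # malformed FASTQ and friends
        raise PipelineError("preprocess", label, err) from err
    tags, clean = preprocess_reads(
        reads,
        adapter3=pp.adapter3,
        adapter5=pp.adapter5,
        min_overlap=pp.min_overlap,
        max_mismatch_rate=pp.max_mismatch_rate,
        min_len=pp.min_len,
        max_len=pp.max_len,
        min_mean_quality=pp.min_mean_quality,
        contaminants=pp.contaminants,
        discard_adapter5=pp.discard_adapter5,
    )
    try:
        hitsets = match_tags(index, tags)
        summary = summarize_mapping(tags, hitsets)
    except Exception as err:
        raise PipelineError("match", label, err) from err
    try:
        classified = ann_mod.classify_tags(
            hitsets, annset,
            min_overlap_frac=cfg.annotate.min_overlap_frac,
            pirna_strand_agnostic=cfg.annotate.pirna_strand_agnostic,
        )
        sirna_calls = profile_sirna.screen_endo_sirna(
            classified, repeats,
            min_len=cfg.sirna.min_len,
            max_len=cfg.sirna.max_len,
            repeat_overlap_frac=cfg.sirna.repeat_overlap_frac,
        )
        passing = {c.tag_id for c in sirna_calls if c.passed}
        for ct in classified:
            if ct.class_label == UNANNOTATED and ct.tag.id in passing:
                ct.class_label = ENDO_SIRNA
        composition = ann_mod.class_composition(classified)
        length_hist = ann_mod.length_distribution(
            classified, min_len=pp.min_len, max_len=pp.max_len
        )
        mirna_counts, _ = profile_mirna.count_mature(
            classified, annset, min_overlap_frac=cfg.annotate.min_overlap_frac
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError("annotate", label, err) from err
    return SampleResult(
        label=label,
        stats=clean.stats.as_dict(),
        summary_total=summary.total_clean,
        summary_mapped=summary.mapped,
        classified=classified,
        sirna_calls=sirna_calls,
        composition=composition,
        length_hist=length_hist,
        mirna_counts=mirna_counts,
    )


def class_trend_summary(
    compositions: Mapping[str, pd.DataFrame],
    order: Sequence[str],
) -> dict[str, str]:
    """Monotonic-trend labels per class along a declared sample order.

    Labels are 'increasing', 'declining' or 'flat' from the sign of the
    Spearman correlation between the declared order and the class fraction
    of annotated reads.  Purely descriptive: no significance test is
    attempted at 3-5 samples.
    """
    order = list(order)
    if len(order) < 2:
        raise ValueError("trend summary needs at least two ordered samples")
    missing = [s for s in order if s not in compositions]
    if missing:
        raise ValueError(f"ordered samples missing from compositions: {missing}")
    classes: set[str] = set()
    for comp in compositions.values():
        classes |= set(comp.loc[comp["class"] != UNANNOTATED, "class"])
    trends: dict[str, str] = {}
    for cls_name in sorted(classes):
        fracs = []
        for s in order:
            comp = compositions[s]
            row = comp[comp["class"] == cls_name]
            fracs.append(float(row["fraction"].iloc[0]) if len(row) else 0.0)
        if len(set(fracs)) == 1:
            trends[cls_name] = "flat"
            continue
        rho = spearmanr(range(len(order)), fracs).statistic
        if np.isnan(rho) or rho == 0:
            trends[cls_name] = "flat"
        elif rho > 0:
            trends[cls_name] = "increasing"
        else:
            trends[cls_name] = "declining"
    return trends


def run_pipeline(
    samplesheet: SampleSheet | str | Path,
    config: PipelineConfig,
    outdir: str | Path,
    genome_fasta: str | Path,
    track_paths: Mapping[str, str | Path],
    repeats_bed: str | Path | None = None,
    make_figures: bool = True,
) -> RunReport:
    """Run the full pipeline over a sample sheet and emit report artifacts."""
    if not isinstance(samplesheet, SampleSheet):
        samplesheet = SampleSheet.from_tsv(samplesheet)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: dict = {"config": config.to_dict(), "stages": {}, "inputs": {}}

    genome = read_fasta(genome_fasta)
    index = MatchIndex(genome, k=config.index_k)
    existing = {c: p for c, p in track_paths.items() if Path(p).exists()}
    annset = load_annotations(existing)
    repeats = RepeatTrack.from_bed(repeats_bed) if repeats_bed else RepeatTrack()
    log["inputs"]["genome"] = _sha256(Path(genome_fasta))
    log["stages"]["index"] = round(time.time() - t0, 3)

    results: dict[str, SampleResult] = {}
    for label in samplesheet.samples:
        t1 = time.time()
        fastq = samplesheet.fastq_of(label)
        log["inputs"][label] = _sha256(fastq)
        results[label] = _process_sample(label, fastq, index, annset, repeats, config)
        log["stages"][label] = round(time.time() - t1, 3)

    paths: dict[str, Path] = {}

    # Table-1-style mapping summary
    summary = pd.DataFrame(
        {
            "sample": list(results),
            "total_clean_reads": [r.summary_total for r in results.values()],
            "mapped_to_genome": [r.summary_mapped for r in results.values()],
            "percentage": [
                summarize_mapping_percentage(r.summary_total, r.summary_mapped)
                for r in results.values()
            ],
        }
    )
    paths["mapping_summary"] = outdir / "mapping_summary.tsv"
    summary.to_csv(paths["mapping_summary"], sep="\t", index=False)

    # per-sample stage tables
    for label, res in results.items():
        sdir = outdir / label
        sdir.mkdir(exist_ok=True)
        pd.DataFrame([res.stats]).to_csv(sdir / "preprocess_stats.tsv",
                                         sep="\t", index=False)
        res.composition.to_csv(sdir / "composition.tsv", sep="\t", index=False)
        res.length_hist.rename_axis("length").to_frame().to_csv(
            sdir / "length_histogram.tsv", sep="\t")
        classified_frame(res.classified).to_csv(sdir / "classified.tsv",
                                                sep="\t", index=False)
        profile_sirna.calls_to_frame(res.sirna_calls).to_csv(
            sdir / "sirna_screen.tsv", sep="\t", index=False)

    # miRNA expression matrix, signatures, clustering
    counts = {label: res.mirna_counts for label, res in results.items()}
    lib_sizes = None
    if config.mirna.rpm_denominator == "genome_mapped":
        lib_sizes = {label: res.summary_mapped for label, res in results.items()}
    matrix = profile_mirna.ExpressionMatrix.from_counts(counts, lib_sizes)
    paths["mirna_rpm"] = outdir / "mirna_rpm.tsv"
    matrix.rpm().to_csv(paths["mirna_rpm"], sep="\t")

    signature = None
    if config.mirna.focal_sample in results and len(results) >= 2:
        signature = profile_mirna.call_signature(
            matrix,
            focal=config.mirna.focal_sample,
            fold=config.mirna.fold,
            epsilon=config.mirna.epsilon,
            expressed_threshold=config.mirna.expressed_rpm,
            vs=config.mirna.vs,
        )
        paths["signature"] = outdir / f"signature_{signature.focal}.tsv"
        signature.table.to_csv(paths["signature"], sep="\t")

    clustering = None
    if len(results) >= 2:
        log2 = matrix.log2_rpm(pseudocount=config.mirna.cluster_pseudocount)
        mask = profile_mirna.call_expressed(matrix.rpm(), config.mirna.expressed_rpm)
        clustering = profile_mirna.cluster_samples(log2, expressed_mask=mask)

    # weighted piRNA layer
    pirna_totals: dict[str, float] = {}
    weighted_by_sample = {}
    for label, res in results.items():
        weighted = profile_pirna.weight_tags(res.classified, classes=("piRNA",))
        weighted_by_sample[label] = weighted
        profile = profile_pirna.genome_distribution(
            weighted, bin_size=config.pirna.bin_size,
            library_size=res.summary_mapped or None,
        )
        pirna_totals[label] = profile.total_weight()
        profile.table.to_csv(outdir / label / "pirna_bins.tsv", sep="\t", index=False)
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            sub = profile.table[profile.table["strand"] == strand]
            bg = sub.assign(end=sub["bin_start"] + config.pirna.bin_size)
            bg[["chrom", "bin_start", "end", "weighted_rpm"]].to_csv(
                outdir / label / f"pirna_{suffix}.bedGraph",
                sep="\t", header=False, index=False)

    enrichment = None
    if len(repeats) and len(results) >= 2:
        pair = _enrichment_pair(config, list(results))
        enrichment = profile_pirna.repeat_enrichment(
            weighted_by_sample, repeats, pair, alpha=config.pirna.enrichment_alpha)
        paths["repeat_enrichment"] = outdir / "repeat_enrichment.tsv"
        enrichment.to_csv(paths["repeat_enrichment"], sep="\t", index=False)

    # endo-siRNA length profiles
    sirna_profiles = {}
    for label, res in results.items():
        if res.summary_mapped:
            sirna_profiles[label] = profile_sirna.sirna_length_profile(
                res.sirna_calls, res.summary_mapped,
                min_len=config.sirna.min_len, max_len=config.sirna.max_len)
    if sirna_profiles:
        paths["sirna_profiles"] = outdir / "sirna_length_profiles.tsv"
        pd.DataFrame(sirna_profiles).rename_axis("length").to_csv(
            paths["sirna_profiles"], sep="\t")

    # developmental trends
    compositions = {label: res.composition for label, res in results.items()}
    order = [s for s in config.sample_order if s in compositions]
    trends = class_trend_summary(compositions, order) if len(order) >= 2 else {}
    if trends:
        paths["trends"] = outdir / "class_trends.tsv"
        pd.Series(trends, name="trend").rename_axis("class").to_csv(
            paths["trends"], sep="\t")

    if make_figures:
        _figures(outdir, results, clustering, matrix, sirna_profiles,
                 weighted_by_sample, pirna_totals, config, paths)

    log["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "run_log.json", "w") as handle:
        json.dump(log, handle, indent=2, default=str)

    return RunReport(
        outdir=outdir,
        mapping_summary=summary,
        compositions=compositions,
        length_histograms={l: r.length_hist for l, r in results.items()},
        signature=signature,
        clustering=clustering,
        trends=trends,
        paths=paths,
    )


def summarize_mapping_percentage(total: int, mapped: int) -> float:
    from .genome_match import MappingSummary

    return MappingSummary(total_clean=total, mapped=mapped).percentage


def _enrichment_pair(config: PipelineConfig, samples: list[str]) -> tuple[str, str]:
    ordered = [s for s in config.sample_order if s in samples]
    if len(ordered) >= 2:
        return ordered[-1], ordered[0]  # latest vs earliest developmental stage
    return samples[0], samples[1]


def classified_frame(classified) -> pd.DataFrame:
    rows = []
    for ct in classified:
        hit = ct.assigned_hit
        rows.append(
            {
                "tag": ct.tag.id,
                "sequence": ct.tag.sequence,
                "count": ct.count,
                "length": ct.length,
                "n_hits": ct.hitset.n_hits,
                "class": ct.class_label,
                "locus": ct.assigned_locus or "",
                "chrom": hit.chrom if hit else "",
                "start": hit.start if hit else -1,
                "strand": hit.strand if hit else "",
            }
        )
    return pd.DataFrame(rows)


def _figures(outdir, results, clustering, matrix, sirna_profiles,
             weighted_by_sample, pirna_totals, config, paths) -> None:
    # length-distribution curves
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, res in results.items():
        hist = res.length_hist
        total = hist.sum() or 1.0
        ax.plot(hist.index, hist / total, marker="o", ms=3, label=label)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("fraction of mapped reads")
    ax.legend()
    fig.savefig(outdir / "fig_length_distribution.png", dpi=120)
    plt.close(fig)

    # class composition bars
    comp = pd.DataFrame(
        {
            label: res.composition.set_index("class")["fraction"]
            for label, res in results.items()
        }
    ).drop(index=UNANNOTATED, errors="ignore").fillna(0)
    fig, ax = plt.subplots(figsize=(7, 4))
    comp.T.plot.bar(stacked=True, ax=ax, width=0.8)
    ax.set_ylabel("fraction of annotated reads")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(outdir / "fig_composition.png", dpi=120)
    plt.close(fig)

    # sample dendrogram + expression heat map
    if clustering is not None:
        fig, (ax1, ax2) = plt.subplots(
            1, 2, figsize=(9, 4), gridspec_kw={"width_ratios": [1, 2]})
        dn = dendrogram(clustering.linkage_matrix, labels=list(clustering.labels),
                        ax=ax1, orientation="left")
        log2 = matrix.log2_rpm(pseudocount=config.mirna.cluster_pseudocount)
        order = dn["ivl"]
        im = ax2.imshow(log2[order].to_numpy(), aspect="auto", cmap="viridis")
        ax2.set_xticks(range(len(order)), order)
        ax2.set_yticks([])
        fig.colorbar(im, ax=ax2, label="log2 RPM")
        fig.tight_layout()
        fig.savefig(outdir / "fig_mirna_clustering.png", dpi=120)
        plt.close(fig)

    # strand-resolved piRNA distribution (samples above the plot floor)
    floor = config.pirna.plot_floor_fraction * max(pirna_totals.values(), default=0)
    shown = [l for l, t in pirna_totals.items() if t >= floor and t > 0]
    if shown:
        fig, axes = plt.subplots(len(shown), 1, figsize=(8, 1.8 * len(shown)),
                                 sharex=True, squeeze=False)
        for ax, label in zip(axes.ravel(), shown):
            table = pd.read_csv(outdir / label / "pirna_bins.tsv", sep="\t")
            for strand, color, sign in (("+", "tab:red", 1), ("-", "tab:blue", -1)):
                sub = table[table["strand"] == strand]
                ax.bar(sub["bin_start"], sign * sub["weighted_rpm"],
                       width=config.pirna.bin_size, color=color)
            ax.set_ylabel(label, fontsize=8)
        axes.ravel()[-1].set_xlabel("genome position (concatenated bins)")
        fig.tight_layout()
        fig.savefig(outdir / "fig_pirna_distribution.png", dpi=120)
        plt.close(fig)

    # endo-siRNA expression by length
    if sirna_profiles:
        fig, ax = plt.subplots(figsize=(6, 4))
        for label, prof in sirna_profiles.items():
            ax.plot(prof.index, prof.values, marker="o", label=label)
        ax.set_xlabel("read length (nt)")
        ax.set_ylabel("weighted tags per 10 million mapped")
        ax.legend()
        fig.savefig(outdir / "fig_sirna_length.png", dpi=120)
        plt.close(fig)

    # class trends along the declared order
    order = [s for s in config.sample_order if s in results]
    if len(order) >= 2:
        fig, ax = plt.subplots(figsize=(6, 4))
        for cls_name in ("miRNA", "piRNA", ENDO_SIRNA):
            fracs = []
            for s in order:
                comp_s = results[s].composition
                row = comp_s[comp_s["class"] == cls_name]
                fracs.append(float(row["fraction"].iloc[0]) if len(row) else 0.0)
            ax.plot(order, fracs, marker="o", label=cls_name)
        ax.set_ylabel("fraction of annotated reads")
        ax.legend()
        fig.savefig(outdir / "fig_class_trends.png", dpi=120)
        plt.close(fig)
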