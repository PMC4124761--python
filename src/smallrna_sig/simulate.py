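"""Synthetic small-RNA-seq data with per-read ground truth.

Builds a toy genome carrying disjoint annotation tracks (miRNA hairpins with
nested matures, structural RNAs, single-strand piRNA clusters hosted in
ERV-family repeats, standalone repeats that source endo-siRNAs) and emits
per-cell-type FASTQ read sets whose class mixture, per-class read-length
distributions, strand rules and error process are fully configurable.  Every
emitted read is recorded in a truth table (class, source locus, strand,
insert length), so downstream preprocessing, mapping, annotation and
quantification can be scored exactly.

Disjointness is enforced at the k-mer level: a build is rejected and
retried unless no 18-mer (canonically, up to reverse complement) occurs in
two different track groups or in both a track and the background.  This
makes perfect-match classification of error-free reads unambiguous, which
is what lets recovery tests demand 100% accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationSet, Locus, RepeatTrack
from .io import FastqRead, write_bed6, write_fasta, write_fastq, write_gff3
from .util import revcomp

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

STRUCTURAL_SIM_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "scRNA")
SIM_CLASSES = ("miRNA",) + STRUCTURAL_SIM_CLASSES + ("piRNA", "siRNA", "other")

# Per-class read-length models (insert length before adapter), chosen to
# reproduce the canonical library shapes: miRNA peaked at 22-23 nt, piRNA at
# 27-30 nt, endo-siRNA at 21-22 nt, structural-RNA degradation fragments
# broad, background including sub-18 inserts so the length filter fires.
MIRNA_LENGTHS = {20: 0.05, 21: 0.15, 22: 0.40, 23: 0.28, 24: 0.09, 25: 0.03}
PIRNA_LENGTHS = {26: 0.08, 27: 0.18, 28: 0.26, 29: 0.22, 30: 0.14, 31: 0.08, 32: 0.04}
SIRNA_LENGTHS = {18: 0.04, 19: 0.08, 20: 0.16, 21: 0.32, 22: 0.28, 23: 0.12}
STRUCT_LENGTHS = {n: (1.0 if n <= 30 else 0.5) for n in range(18, 36)}
OTHER_LENGTHS = {15: 0.02, 16: 0.02, 17: 0.02, **{n: 0.94 / 19 for n in range(18, 37)}}

DEFAULT_LENGTH_MODELS: dict[str, dict[int, float]] = {
    "miRNA": MIRNA_LENGTHS,
    "piRNA": PIRNA_LENGTHS,
    "siRNA": SIRNA_LENGTHS,
    "other": OTHER_LENGTHS,
    **{c: STRUCT_LENGTHS for c in STRUCTURAL_SIM_CLASSES},
}

REPEAT_FAMILIES = ("LINE", "SINE")
ERV_FAMILIES = ("ERV1", "ERV2", "ERV3")


class GenomeTooSmallError(ValueError):
    """Raised when loci cannot be placed after bounded retries."""


class SimulationConfigError(ValueError):
    """Raised for unsatisfiable simulation requests."""


@dataclass(frozen=True)
class GenomeSpec:
    """Locus counts and sizes for the toy genome."""

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 100_000, "chr2": 60_000}
    )
    n_mirna: int = 30
    hairpin_len: int = 80
    mature_len: int = 22
    n_rrna: int = 6
    rrna_len: int = 120
    n_trna: int = 6
    trna_len: int = 75
    n_snorna: int = 4
    snorna_len: int = 90
    n_snrna: int = 3
    snrna_len: int = 150
    n_scrna: int = 0
    scrna_len: int = 120
    n_pirna_clusters: int = 6
    pirna_cluster_len: tuple[int, int] = (1500, 3000)
    n_repeats: int = 20
    repeat_len: tuple[int, int] = (300, 900)
    #: probability that a piRNA cluster is hosted inside an ERV1/2/3 repeat
    p_pirna_in_erv: float = 0.7
    #: clearance between placed intervals; must exceed the matcher k-mer size
    margin: int = 60
    max_build_attempts: int = 15

    def structural_plan(self) -> list[tuple[str, int, int]]:
        return [
            ("rRNA", self.n_rrna, self.rrna_len),
            ("tRNA", self.n_trna, self.trna_len),
            ("snoRNA", self.n_snorna, self.snorna_len),
            ("snRNA", self.n_snrna, self.snrna_len),
            ("scRNA", self.n_scrna, self.scrna_len),
        ]


@dataclass
class GenomeBundle:
    """Toy genome plus its annotation tracks and ground-truth geometry."""

    genome: dict[str, str]
    tracks: AnnotationSet
    repeats: RepeatTrack
    #: standalone repeats (endo-siRNA source), as loci with ids
    sirna_sources: list[Locus]
    #: unannotated intervals used for background ("other") reads
    background: list[tuple[str, int, int]]
    spec: GenomeSpec
    seed: int

    def classes_with_loci(self) -> set[str]:
        present = self.tracks.classes()
        if self.sirna_sources:
            present.add("siRNA")
        if self.background:
            present.add("other")
        return present


@dataclass
class CellTypeProfile:
    """Sampling profile for one cell-type library."""

    label: str
    class_mix: Mapping[str, float]
    length_models: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MODELS)
    )
    #: per-class mapping locus_id -> sampling weight; absent -> uniform
    expression_weights: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = ""
    error_rate: float = 0.0
    machine_read_len: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        mix = dict(self.class_mix)
        if any(p < 0 for p in mix.values()):
            raise SimulationConfigError("class proportions must be non-negative")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(f"class proportions sum to {total}, not 1")
        unknown = set(mix) - set(SIM_CLASSES)
        if unknown:
            raise SimulationConfigError(f"unknown simulation classes: {sorted(unknown)}")
        if not 0 <= self.error_rate < 1:
            raise SimulationConfigError("error_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# genome construction


class _Placer:
    """Non-overlapping interval allocator with a clearance margin."""

    def __init__(self, chrom_lengths: Mapping[str, int], margin: int,
                 rng: np.random.Generator):
        self.lengths = dict(chrom_lengths)
        self.margin = margin
        self.rng = rng
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in self.lengths}
        self.chroms = sorted(self.lengths)
        total = sum(self.lengths.values())
        self.probs = np.array([self.lengths[c] / total for c in self.chroms])

    def place(self, length: int, tries: int = 300) -> tuple[str, int]:
        for _ in range(tries):
            chrom = self.chroms[self.rng.choice(len(self.chroms), p=self.probs)]
            hi = self.lengths[chrom] - length
            if hi <= 0:
                continue
            start = int(self.rng.integers(0, hi + 1))
            lo, hi2 = start - self.margin, start + length + self.margin
            if all(e <= lo or s >= hi2 for s, e in self.occupied[chrom]):
                self.occupied[chrom].append((start, start + length))
                return chrom, start
        raise GenomeTooSmallError(
            f"could not place a {length} bp locus after {tries} tries; "
            "genome too small for the requested locus plan"
        )


def _random_genome(chrom_lengths: Mapping[str, int],
                   rng: np.random.Generator) -> dict[str, str]:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return {
        chrom: b"".join(bases[rng.integers(0, 4, size=length)]).decode()
        for chrom, length in sorted(chrom_lengths.items())
    }


def _kmer_groups_ok(genome: Mapping[str, str], regions: Sequence[tuple[str, int, int, int]],
                    k: int = 18) -> bool:
    """True iff no canonical k-mer occurs in two different region groups.

    ``regions`` are (chrom, start, end, group) with positive integer groups;
    genome windows not fully inside a region belong to group 0 (background).
    Group uniformity over a window follows from endpoints because placed
    intervals are separated by a margin wider than k.
    """
    labels = {c: np.zeros(len(s), dtype=np.int32) for c, s in genome.items()}
    for chrom, start, end, group in regions:
        labels[chrom][start:end] = group
    seen: dict[str, int] = {}
    for chrom, seq in genome.items():
        lab = labels[chrom]
        for i in range(len(seq) - k + 1):
            group = int(lab[i]) if lab[i] == lab[i + k - 1] else 0
            w = seq[i : i + k]
            canon = min(w, revcomp(w))
            prev = seen.get(canon)
            if prev is None:
                seen[canon] = group
            elif prev != group:
                return False
    return True


def build_toy_genome(spec: GenomeSpec | None = None, seed: int = 0) -> GenomeBundle:
    """Generate a toy genome whose annotation tracks are mutually disjoint.

    piRNA clusters are hosted inside ERV1/ERV2/ERV3 repeat intervals with
    probability ``spec.p_pirna_in_erv``; standalone LINE/SINE repeats source
    endo-siRNAs.  The build is retried with fresh sequence if any 18-mer is
    shared between track groups (see module docstring).
    """
    spec = spec or GenomeSpec()
    last_err: Exception | None = None
    for attempt in range(spec.max_build_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        try:
            bundle = _build_once(spec, rng, seed)
        except GenomeTooSmallError as err:
            last_err = err
            continue
        if bundle is not None:
            return bundle
    if last_err is not None:
        raise last_err
    raise GenomeTooSmallError(
        "k-mer disjointness between annotation tracks could not be achieved; "
        "enlarge the genome or reduce the locus plan"
    )


def _build_once(spec: GenomeSpec, rng: np.random.Generator,
                seed: int) -> GenomeBundle | None:
    genome = _random_genome(spec.chrom_lengths, rng)
    placer = _Placer(spec.chrom_lengths, spec.margin, rng)
    loci: list[Locus] = []
    repeats = RepeatTrack()
    sirna_sources: list[Locus] = []
    regions: list[tuple[str, int, int, int]] = []
    group_ids = {"miRNA": 1, "rRNA": 2, "tRNA": 3, "snoRNA": 4, "snRNA": 5,
                 "scRNA": 6, "piRNA": 7, "repeat": 8}

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # miRNA hairpins with 1-2 nested matures
    for i in range(spec.n_mirna):
        chrom, start = placer.place(spec.hairpin_len)
        st = strand()
        hid = f"mir{i + 1:04d}"
        loci.append(Locus(hid, chrom, start, start + spec.hairpin_len, st,
                          "miRNA", subtype="hairpin"))
        regions.append((chrom, start, start + spec.hairpin_len, group_ids["miRNA"]))
        arms = ["5p"] if rng.random() < 0.5 else ["5p", "3p"]
        for arm in arms:
            if arm == "5p":
                m_start = start + 8
            else:
                m_start = start + spec.hairpin_len - 8 - spec.mature_len
            loci.append(Locus(f"{hid}-{arm}", chrom, m_start,
                              m_start + spec.mature_len, st, "miRNA",
                              parent=hid, subtype="mature"))

    # structural RNAs
    for cls_name, n, length in spec.structural_plan():
        for i in range(n):
            chrom, start = placer.place(length)
            loci.append(Locus(f"{cls_name.lower()}{i + 1:03d}", chrom, start,
                              start + length, strand(), cls_name))
            regions.append((chrom, start, start + length, group_ids[cls_name]))

    # piRNA clusters, single-strand, optionally hosted in an ERV repeat
    for i in range(spec.n_pirna_clusters):
        lo, hi = spec.pirna_cluster_len
        length = int(rng.integers(lo, hi + 1))
        chrom, start = placer.place(length)
        st = strand()
        cid = f"picluster{i + 1:02d}"
        loci.append(Locus(cid, chrom, start, start + length, st, "piRNA"))
        regions.append((chrom, start, start + length, group_ids["piRNA"]))
        if rng.random() < spec.p_pirna_in_erv:
            family = ERV_FAMILIES[int(rng.integers(0, len(ERV_FAMILIES)))]
            repeats.add(chrom, start, start + length, family, st)

    # standalone repeats: endo-siRNA source material
    for i in range(spec.n_repeats):
        lo, hi = spec.repeat_len
        length = int(rng.integers(lo, hi + 1))
        chrom, start = placer.place(length)
        st = strand()
        family = REPEAT_FAMILIES[int(rng.integers(0, len(REPEAT_FAMILIES)))]
        rid = f"rep{i + 1:03d}"
        repeats.add(chrom, start, start + length, family, st)
        # kept outside the AnnotationSet: repeats are not an annotation
        # class, only ground-truth source material for endo-siRNA reads
        sirna_sources.append(Locus(rid, chrom, start, start + length, st,
                                   "repeat", subtype="repeat"))
        regions.append((chrom, start, start + length, group_ids["repeat"]))

    if regions and not _kmer_groups_ok(genome, regions):
        return None

    # background: margin-shrunk gaps between placed intervals
    background: list[tuple[str, int, int]] = []
    pad = spec.margin // 2
    for chrom in sorted(spec.chrom_lengths):
        ivs = sorted(placer.occupied[chrom])
        pos = 0
        for s, e in ivs + [(spec.chrom_lengths[chrom], spec.chrom_lengths[chrom])]:
            lo, hi = pos + pad, s - pad
            if hi - lo >= 60:
                background.append((chrom, lo, hi))
            pos = e
    return GenomeBundle(
        genome=genome,
        tracks=AnnotationSet(loci),
        repeats=repeats,
        sirna_sources=sirna_sources,
        background=background,
        spec=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# read sampling


def _sample_length(model: Mapping[int, float], rng: np.random.Generator,
                   max_len: int | None = None) -> int:
    lengths = sorted(model)
    probs = np.array([model[n] for n in lengths], dtype=float)
    probs /= probs.sum()
    if max_len is not None:
        keep = [j for j, n in enumerate(lengths) if n <= max_len]
        if not keep:
            return max_len
        lengths = [lengths[j] for j in keep]
        probs = probs[keep]
        probs /= probs.sum()
    return int(lengths[rng.choice(len(lengths), p=probs)])


def _weighted_choice(ids: Sequence[str], weights: Mapping[str, float] | None,
                     rng: np.random.Generator) -> int:
    if not weights:
        return int(rng.integers(0, len(ids)))
    w = np.array([float(weights.get(i, 0.0)) for i in ids])
    if w.sum() <= 0:
        return int(rng.integers(0, len(ids)))
    return int(rng.choice(len(ids), p=w / w.sum()))


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if error_rate <= 0:
        return seq, 0
    out = list(seq)
    n_err = 0
    for j in range(len(out)):
        if rng.random() < error_rate:
            choices = [b for b in "ACGT" if b != out[j]]
            out[j] = choices[int(rng.integers(0, 3))]
            n_err += 1
    return "".join(out), n_err


TRUTH_COLUMNS = ["read_id", "true_class", "locus_id", "chrom", "start", "end",
                 "strand", "insert_len", "n_errors"]


def simulate_sample(
    bundle: GenomeBundle,
    profile: CellTypeProfile,
    n_reads: int,
    seed: int | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Emit one library of raw reads plus its ground-truth table.

    Class counts follow a multinomial draw of the profile's class mixture.
    Each read is an error-mutated subsequence of a sampled locus with the 3'
    adapter appended and the result truncated to the machine read length
    (the adapter is read through, as in real small-RNA libraries).  piRNA
    reads are emitted from the cluster's annotated strand only.
    """
    if n_reads < 0:
        raise SimulationConfigError("n_reads must be non-negative")
    rng = np.random.default_rng(seed if seed is not None else profile.seed)
    mix_classes = sorted(c for c, p in profile.class_mix.items() if p > 0)
    available = bundle.classes_with_loci()
    missing = [c for c in mix_classes if c not in available]
    if missing:
        raise SimulationConfigError(
            f"profile requests classes with zero loci in the genome: {missing}"
        )

    matures = sorted(
        (l for l in bundle.tracks.loci.values()
         if l.feature_class == "miRNA" and l.subtype == "mature"),
        key=lambda l: l.locus_id,
    )
    per_class_loci: dict[str, list[Locus]] = {
        "miRNA": matures,
        "piRNA": sorted(bundle.tracks.by_class("piRNA"), key=lambda l: l.locus_id),
        "siRNA": sorted(bundle.sirna_sources, key=lambda l: l.locus_id),
    }
    for cls_name in STRUCTURAL_SIM_CLASSES:
        per_class_loci[cls_name] = sorted(bundle.tracks.by_class(cls_name),
                                          key=lambda l: l.locus_id)

    probs = np.array([profile.class_mix[c] for c in mix_classes])
    counts = rng.multinomial(n_reads, probs) if n_reads else np.zeros(len(mix_classes), int)

    reads: list[FastqRead] = []
    truth_rows: list[tuple] = []
    read_no = 0
    for cls_name, n_cls in zip(mix_classes, counts):
        model = profile.length_models.get(cls_name, DEFAULT_LENGTH_MODELS[cls_name])
        weights = profile.expression_weights.get(cls_name)
        for _ in range(int(n_cls)):
            read_no += 1
            rid = f"{profile.label}_{read_no:07d}"
            if cls_name == "other":
                chrom, lo, hi = bundle.background[
                    int(rng.integers(0, len(bundle.background)))
                ]
                length = _sample_length(model, rng, hi - lo)
                start = int(rng.integers(lo, hi - length + 1))
                st = "+" if rng.random() < 0.5 else "-"
                locus_id = "background"
            elif cls_name == "miRNA":
                loci = per_class_loci["miRNA"]
                locus = loci[_weighted_choice([l.locus_id for l in loci], weights, rng)]
                length = _sample_length(model, rng)
                start = locus.start + int(rng.integers(-2, 3))
                hairpin = bundle.tracks.loci[locus.parent]
                start = max(hairpin.start, min(start, hairpin.end - length))
                chrom, st, locus_id = locus.chrom, locus.strand, locus.locus_id
            else:
                loci = per_class_loci[cls_name]
                locus = loci[_weighted_choice([l.locus_id for l in loci], weights, rng)]
                length = _sample_length(model, rng, locus.length)
                start = locus.start + int(rng.integers(0, locus.length - length + 1))
                chrom = locus.chrom
                locus_id = locus.locus_id
                if cls_name == "piRNA":
                    st = locus.strand  # clusters emit from one strand only
                elif cls_name == "siRNA":
                    st = "+" if rng.random() < 0.5 else "-"
                else:
                    st = locus.strand
            insert = bundle.genome[chrom][start : start + length]
            if st == "-":
                insert = revcomp(insert)
            insert, n_err = _mutate(insert, profile.error_rate, rng)
            raw = profile.adapter5 + insert + profile.adapter3
            raw = raw[: profile.machine_read_len]
            truth_cls = cls_name
            truth_rows.append((rid, truth_cls, locus_id, chrom, start,
                               start + length, st, length, n_err))
            reads.append(FastqRead(rid, raw, "I" * len(raw)))
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# default cell-type profiles

# Qualitative contrasts encoded: miRNA ~60% of annotated reads in all
# libraries except developing germ cells, where piRNA is the modal class;
# piRNA abundance ordered GC > SSC > ESC > ST > MSC; endo-siRNA abundance
# ordered ESC > SSC > ST > MSC > GC; miRNA declining and piRNA increasing
# along the ESC -> SSC -> GC developmental order.
DEFAULT_CLASS_MIXES: dict[str, dict[str, float]] = {
    "ESC": {"miRNA": 0.60, "piRNA": 0.06, "siRNA": 0.14, "rRNA": 0.06,
            "tRNA": 0.04, "snoRNA": 0.02, "snRNA": 0.02, "other": 0.06},
    "SSC": {"miRNA": 0.55, "piRNA": 0.16, "siRNA": 0.10, "rRNA": 0.05,
            "tRNA": 0.04, "snoRNA": 0.02, "snRNA": 0.02, "other": 0.06},
    "GC": {"miRNA": 0.18, "piRNA": 0.55, "siRNA": 0.03, "rRNA": 0.08,
           "tRNA": 0.06, "snoRNA": 0.02, "snRNA": 0.02, "other": 0.06},
    "ST": {"miRNA": 0.58, "piRNA": 0.05, "siRNA": 0.06, "rRNA": 0.11,
           "tRNA": 0.08, "snoRNA": 0.03, "snRNA": 0.03, "other": 0.06},
    "MSC": {"miRNA": 0.62, "piRNA": 0.015, "siRNA": 0.05, "rRNA": 0.115,
            "tRNA": 0.08, "snoRNA": 0.03, "snRNA": 0.03, "other": 0.06},
}

#: developmental ordering used for trend summaries
DEVELOPMENTAL_ORDER = ("ESC", "SSC", "GC")


def default_profiles(bundle: GenomeBundle, seed: int = 0,
                     error_rate: float = 0.0) -> dict[str, CellTypeProfile]:
    """The five bundled cell-type profiles (ESC/SSC/GC/ST/MSC-like).

    miRNA expression weights follow two latent programs — a pluripotent/
    germline program shared (with noise) by the ESC- and SSC-like profiles
    and a somatic program shared by the ST- and MSC-like profiles, with the
    GC-like profile drawing its own — so that sample clustering on the
    miRNA expression matrix reproduces the expected {ESC,SSC} / {ST,MSC}
    grouping.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 977]))
    matures = sorted(
        l.locus_id
        for l in bundle.tracks.loci.values()
        if l.feature_class == "miRNA" and l.subtype == "mature"
    )
    n = len(matures)
    program_pluri = rng.lognormal(0.0, 1.2, n)
    program_somatic = rng.lognormal(0.0, 1.2, n)
    program_gc = rng.lognormal(0.0, 1.2, n)
    programs = {
        "ESC": program_pluri,
        "SSC": program_pluri,
        "ST": program_somatic,
        "MSC": program_somatic,
        "GC": program_gc,
    }
    profiles: dict[str, CellTypeProfile] = {}
    for i, (label, mix) in enumerate(DEFAULT_CLASS_MIXES.items()):
        noise = rng.lognormal(0.0, 0.25, n)
        weights = {m: float(w) for m, w in zip(matures, programs[label] * noise)}
        profiles[label] = CellTypeProfile(
            label=label,
            class_mix=mix,
            expression_weights={"miRNA": weights},
            error_rate=error_rate,
            seed=seed * 131 + i,
        )
    return profiles


# ---------------------------------------------------------------------------
# on-disk artifacts


def bundle_track_paths(outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    classes = ("miRNA", "rRNA", "tRNA", "snoRNA", "snRNA", "scRNA", "piRNA")
    return {c: outdir / f"{c.lower()}.gff3" for c in classes}


def write_bundle(bundle: GenomeBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, per-class GFF3 tracks and the repeat BED6 track."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {"genome": outdir / "genome.fa"}
    write_fasta(bundle.genome, paths["genome"])
    track_paths = bundle_track_paths(outdir)
    for cls_name, path in track_paths.items():
        records = []
        for locus in sorted(bundle.tracks.by_class(cls_name),
                            key=lambda l: (l.chrom, l.start, l.locus_id)):
            ftype = cls_name
            if cls_name == "miRNA":
                ftype = f"miRNA_{locus.subtype}"
            records.append({
                "seqid": locus.chrom, "type": ftype, "start": locus.start,
                "end": locus.end, "strand": locus.strand, "id": locus.locus_id,
                "parent": locus.parent,
            })
        write_gff3(records, path)
        paths[cls_name] = path
    rep = bundle.repeats.to_frame()
    rep = rep.rename(columns={"family": "name"})
    rep["score"] = 0
    paths["repeats"] = outdir / "repeats.bed"
    write_bed6(rep, paths["repeats"])
    return paths


def write_sample(reads: Sequence[FastqRead], truth: pd.DataFrame, label: str,
                 outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq = outdir / f"{label}.fastq.gz"
    truth_path = outdir / f"{label}.truth.tsv"
    write_fastq(reads, fastq)
    truth.to_csv(truth_path, sep="\t", index=False)
    return fastq, truth_path
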