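# smallrna-sig

Small RNA-seq profiling with hierarchical noncoding-RNA annotation, for
researchers comparing small-RNA populations — miRNAs, piRNAs, endogenous
siRNAs, and structural-RNA fragments — across cell types, e.g. along the
mouse spermatogenesis lineage (embryonic stem cells → spermatogonial stem
cells → developing germ cells, alongside Sertoli and mesenchymal stem
cells).

## What it computes

Starting from raw single-end small-RNA FASTQ files, a reference genome
(FASTA) and per-class annotation tracks (GFF3/BED), the pipeline:

1. **Preprocesses** reads into *clean reads*: 3′ (optionally 5′) adapter
   trimming, removal of contaminants, reads shorter than 18 nt or longer
   than 40 nt (the gel size-selection window), and low-quality reads;
   identical clean reads are collapsed into **tags** `(sequence, count)`.
2. **Maps** each tag to the genome keeping **perfect matches only**, on both
   strands, reporting *all* occurrences (multi-mapping is preserved), and
   summarizes per-sample totals as `total clean / mapped / %`.
3. **Annotates** each mapped tag with the fixed priority order

   `miRNA > rRNA/snoRNA/tRNA/scRNA/snRNA > piRNA > endo-siRNA`

   by genomic interval overlap (a tag takes the highest-priority class any
   of its hits overlaps), and reports class composition and read-length
   distributions (miRNA-dominated libraries peak at 22–23 nt,
   piRNA-dominated ones at 27–30 nt).
4. **Quantifies each class in its own terms:**
   - *miRNA*: mature-miRNA counts → RPM within each sample
     (`RPM = 10⁶·count/library`), expression called at RPM ≥ 1, cell-type
     **signature** miRNAs called at ≥ *f*-fold change (default 2) versus
     *every* other sample, and samples clustered hierarchically on log2-RPM
     (correlation distance, average linkage).
   - *piRNA*: multi-mapping-aware **weighted reads** ω = #Reads/#Hits per
     tag; strand-resolved binned genome-wide distributions (piRNA clusters
     are single-strand) and repeat-family (ERV1/2/3, LINE, SINE) enrichment
     between samples via Fisher's exact test with Benjamini–Hochberg
     correction.
   - *endo-siRNA*: three-criterion screen — length 18–23 nt, perfect genome
     match, repeat-derived — applied after the annotation hierarchy, with
     weighted expression-by-length profiles scaled to tag count per 10
     million mapped reads.

A bundled **simulator** generates toy genomes with disjoint annotation
tracks and five cell-type libraries with per-read ground truth, so the full
pipeline is testable end to end without external data.

## Worked example

```python
import pandas as pd
import smallrna_sig as srs
from smallrna_sig.config import PipelineConfig
from smallrna_sig.report import run_pipeline
from smallrna_sig.simulate import bundle_track_paths, write_bundle, write_sample

bundle = srs.build_toy_genome(seed=1)                 # 160 kb toy genome
write_bundle(bundle, "data")                          # FASTA + GFF3 + BED
rows = []
for label, profile in srs.default_profiles(bundle, seed=1).items():
    reads, truth = srs.simulate_sample(bundle, profile, 20_000)
    fastq, _ = write_sample(reads, truth, label, "data")
    rows.append({"sample": label, "fastq": str(fastq), "cell_type": label})
pd.DataFrame(rows).to_csv("data/samplesheet.tsv", sep="\t", index=False)

report = run_pipeline(
    "data/samplesheet.tsv", PipelineConfig(), "run",
    genome_fasta="data/genome.fa",
    track_paths=bundle_track_paths("data"),
    repeats_bed="data/repeats.bed",
)
print(report.mapping_summary.to_string(index=False))
print(report.trends)
```

prints

```
sample  total_clean_reads  mapped_to_genome  percentage
   ESC              19925             19925       100.0
   SSC              19934             19934       100.0
    GC              19931             19931       100.0
    ST              19936             19936       100.0
   MSC              19932             19932       100.0
{'endo_siRNA': 'declining', 'miRNA': 'declining', 'piRNA': 'increasing', ...}
```

Every error-free simulated read survives cleaning and maps perfectly, hence
the 100% column; with a non-zero substitution error rate the mapped
percentage drops into the realistic 75–80% range because mismatched reads
are discarded by the perfect-match rule.  `report.signature.table` lists
the miRNAs specifically high in the focal sample with their fold change
against each other sample, e.g.

```
            focal_rpm  fold_vs_ESC  fold_vs_GC  fold_vs_ST  fold_vs_MSC
mir0029-3p   44532.59         2.07        2.05        2.33         2.44
mir0008-5p   15144.69         2.04        5.44       11.14         6.23
```

and `report.trends` labels each class's direction along the declared
developmental order — miRNA and endo-siRNA declining while piRNA increases,
the canonical small-RNA transition during spermatogenesis.

The same stages are available from the shell:

```bash
smallrna-sig simulate --outdir data --seed 1 --n-reads 20000
smallrna-sig preprocess --fastq data/ESC.fastq.gz --adapter3 TGGAATTCTCGGGTGCCAAGG \
    --out tags.fa --stats stats.tsv
smallrna-sig match --genome data/genome.fa --tags tags.fa --out hits.tsv --summary summary.tsv
smallrna-sig run --samplesheet data/samplesheet.tsv --genome data/genome.fa \
    --tracks tracks.yaml --outdir run
```

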