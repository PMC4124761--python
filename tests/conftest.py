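"""Shared fixtures: one toy genome and five small simulated libraries.

Session-scoped because genome construction enforces k-mer disjointness
between annotation tracks (a retry loop) and sample processing runs the
full preprocess/match/annotate chain; everything downstream reuses them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import smallrna_sig as srs
from smallrna_sig.annotate import ENDO_SIRNA, UNANNOTATED
from smallrna_sig.util import revcomp

SEED = 11
N_READS = 10_000

#: simulator truth label -> label the pipeline should assign to the tag
TRUTH_TO_PIPELINE = {
    "miRNA": "miRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "scRNA": "scRNA",
    "piRNA": "piRNA",
    "siRNA": ENDO_SIRNA,
    "other": UNANNOTATED,
}


@pytest.fixture(scope="session")
def bundle():
    return srs.build_toy_genome(seed=SEED)


@pytest.fixture(scope="session")
def profiles(bundle):
    return srs.default_profiles(bundle, seed=SEED)


@pytest.fixture(scope="session")
def index(bundle):
    return srs.MatchIndex(bundle.genome)


@dataclass
class ProcessedSample:
    label: str
    reads: list
    truth: object
    tags: list
    clean: object
    hitsets: list
    summary: object
    classified: list
    sirna_calls: list


def _process(label, bundle, profiles, index, n_reads=N_READS):
    profile = profiles[label]
    reads, truth = srs.simulate_sample(bundle, profile, n_reads)
    tags, clean = srs.preprocess_reads(reads, adapter3=profile.adapter3)
    hitsets = srs.match_tags(index, tags)
    summary = srs.summarize_mapping(tags, hitsets)
    classified = srs.classify_tags(hitsets, bundle.tracks)
    calls = srs.screen_endo_sirna(classified, bundle.repeats)
    passing = {c.tag_id for c in calls if c.passed}
    for ct in classified:
        if ct.class_label == UNANNOTATED and ct.tag.id in passing:
            ct.class_label = ENDO_SIRNA
    return ProcessedSample(label, reads, truth, tags, clean, hitsets, summary,
                           classified, calls)


@pytest.fixture(scope="session")
def processed(bundle, profiles, index):
    """All five cell-type libraries run through the full chain."""
    return {
        label: _process(label, bundle, profiles, index)
        for label in ("ESC", "SSC", "GC", "ST", "MSC")
    }


@pytest.fixture(scope="session")
def esc(processed):
    return processed["ESC"]


@pytest.fixture(scope="session")
def gc(processed):
    return processed["GC"]


def expected_classes_by_sequence(bundle, truth) -> dict[str, set[str]]:
    """Map each error-free insert sequence to its acceptable pipeline labels."""
    out: dict[str, set[str]] = {}
    for row in truth.itertuples():
        if row.n_errors:
            continue
        sub = bundle.genome[row.chrom][row.start : row.end]
        seq = revcomp(sub) if row.strand == "-" else sub
        out.setdefault(seq, set()).add(TRUTH_TO_PIPELINE[row.true_class])
    return out
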