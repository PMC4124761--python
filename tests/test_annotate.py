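"""Hierarchical classification: priority order, conventions, conservation."""

import random

import pytest

import smallrna_sig as srs
from conftest import TRUTH_TO_PIPELINE, expected_classes_by_sequence
from smallrna_sig.annotate import (
    UNANNOTATED,
    AnnotationSet,
    Locus,
    class_composition,
    classify_tag,
    classify_tags,
    length_distribution,
    load_annotations,
)
from smallrna_sig.genome_match import Hit, HitSet
from smallrna_sig.preprocess import Tag
from smallrna_sig.simulate import bundle_track_paths, write_bundle


def make_hitset(seq="A" * 22, count=1, hits=(("chr1", 100, "+"),)):
    return HitSet(tag=Tag(seq, count, rank=1),
                  hits=tuple(Hit(*h) for h in hits))


class TestLoadAnnotations:
    def test_empty_files_give_empty_set(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        ann = load_annotations({"miRNA": p})
        assert len(ann) == 0
        ct = classify_tag(make_hitset(), ann)
        assert ct.class_label == UNANNOTATED

    def test_roundtrip_through_gff(self, bundle, tmp_path):
        """Every simulated locus is retrievable after write + reload."""
        write_bundle(bundle, tmp_path)
        paths = {c: p for c, p in bundle_track_paths(tmp_path).items()
                 if p.exists()}
        ann = load_annotations(paths)
        assert set(ann.loci) == set(bundle.tracks.loci)
        for lid, locus in bundle.tracks.loci.items():
            got = ann.loci[lid]
            assert (got.chrom, got.start, got.end, got.strand,
                    got.feature_class) == (locus.chrom, locus.start, locus.end,
                                           locus.strand, locus.feature_class)
            hits = ann.query(locus.feature_class, locus.chrom,
                             locus.start, locus.end)
            assert lid in [l.locus_id for l in hits]

    def test_gff_one_based_inclusive_converted(self, tmp_path):
        p = tmp_path / "t.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\tx\trRNA\t101\t122\t.\t+\t.\tID=r1\n")
        ann = load_annotations({"rRNA": p})
        assert (ann.loci["r1"].start, ann.loci["r1"].end) == (100, 122)

    def test_malformed_gff_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\tx\trRNA\tnot_a_number\t50\t.\t+\t.\tID=r1\n")
        with pytest.raises(ValueError, match="bad.gff3"):
            load_annotations({"rRNA": p})

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "t.gff3"
        p.write_text("##gff-version 3\n")
        with pytest.raises(ValueError, match="unknown annotation class"):
            load_annotations({"lncRNA": p})


class TestPriority:
    @pytest.fixture()
    def nested_ann(self):
        # a mature miRNA and a structural RNA both inside a piRNA cluster
        return AnnotationSet([
            Locus("pic1", "chr1", 0, 5_000, "+", "piRNA"),
            Locus("mir1-5p", "chr1", 100, 122, "+", "miRNA", subtype="mature"),
            Locus("trna1", "chr1", 2_000, 2_075, "+", "tRNA"),
        ])

    def test_mirna_beats_pirna(self, nested_ann):
        ct = classify_tag(make_hitset(hits=(("chr1", 100, "+"),)), nested_ann)
        assert ct.class_label == "miRNA"
        assert ct.assigned_locus == "mir1-5p"

    def test_structural_beats_pirna(self, nested_ann):
        ct = classify_tag(make_hitset(hits=(("chr1", 2_010, "+"),)), nested_ann)
        assert ct.class_label == "tRNA"

    def test_pirna_when_nothing_better(self, nested_ann):
        ct = classify_tag(make_hitset(hits=(("chr1", 3_000, "+"),)), nested_ann)
        assert ct.class_label == "piRNA"

    def test_best_class_across_all_hits(self, nested_ann):
        # one hit in the cluster, one in the mature miRNA: miRNA wins
        ct = classify_tag(
            make_hitset(hits=(("chr1", 3_000, "+"), ("chr1", 100, "+"))),
            nested_ann)
        assert ct.class_label == "miRNA"
        assert ct.assigned_hit == Hit("chr1", 100, "+")

    def test_strand_rule_for_mirna(self, nested_ann):
        ct = classify_tag(make_hitset(hits=(("chr1", 100, "-"),)), nested_ann)
        # wrong strand for the mature; cluster is + only too
        assert ct.class_label == UNANNOTATED

    def test_pirna_strand_agnostic_switch(self, nested_ann):
        hs = make_hitset(hits=(("chr1", 3_000, "-"),))
        assert classify_tag(hs, nested_ann).class_label == UNANNOTATED
        assert classify_tag(hs, nested_ann,
                            pirna_strand_agnostic=True).class_label == "piRNA"

    def test_min_overlap_fraction_enforced(self, nested_ann):
        # 22 nt tag overlapping the mature by 11 nt only: below 0.8 fraction
        ct = classify_tag(make_hitset(hits=(("chr1", 111, "+"),)), nested_ann)
        assert ct.class_label == "piRNA"

    def test_unannotated_when_no_overlap(self):
        ann = AnnotationSet([Locus("r1", "chr1", 0, 100, "+", "rRNA")])
        ct = classify_tag(make_hitset(seq="A" * 30,
                                      hits=(("chr1", 5_000, "+"),)), ann)
        assert ct.class_label == UNANNOTATED

    def test_zero_hit_tag_rejected(self):
        ann = AnnotationSet()
        with pytest.raises(ValueError):
            classify_tag(HitSet(tag=Tag("A" * 22, 1, 1), hits=()), ann)


class TestSimulationRecovery:
    def test_classification_matches_truth_exactly(self, bundle, processed):
        for sample in processed.values():
            expected = expected_classes_by_sequence(bundle, sample.truth)
            for ct in sample.classified:
                assert ct.class_label in expected[ct.tag.sequence]

    def test_priority_soundness_recheck(self, bundle, gc):
        """No tag sits in a class when a higher tier also overlaps it."""
        from smallrna_sig.annotate import CLASS_TIERS

        tier_of = {c: i for i, tier in enumerate(CLASS_TIERS) for c in tier}
        for ct in gc.classified[:2000]:
            if ct.class_label not in tier_of:
                continue
            rank = tier_of[ct.class_label]
            for hit in ct.hitset.hits:
                lo, hi = hit.start, hit.start + ct.length
                for tier in CLASS_TIERS[:rank]:
                    for cls_name in tier:
                        for locus in bundle.tracks.query(cls_name, hit.chrom, lo, hi):
                            ov = min(hi, locus.end) - max(lo, locus.start)
                            assert not (ov >= 0.8 * ct.length
                                        and locus.strand == hit.strand)

    def test_input_order_never_changes_labels(self, bundle, esc):
        subset = esc.hitsets[:300]
        base = {hs.tag.sequence: classify_tag(hs, bundle.tracks).class_label
                for hs in subset}
        shuffled = list(subset)
        random.Random(5).shuffle(shuffled)
        for hs in shuffled:
            assert classify_tag(hs, bundle.tracks).class_label == base[hs.tag.sequence]

    def test_conservation_annotated_plus_unannotated(self, esc):
        comp = class_composition(esc.classified)
        assert comp["reads"].sum() == esc.summary.mapped


class TestComposition:
    def test_single_class_fraction_one(self):
        ann = AnnotationSet([Locus("r1", "chr1", 0, 100, "+", "rRNA")])
        cts = classify_tags([make_hitset(hits=(("chr1", 10, "+"),))], ann)
        comp = class_composition(cts)
        assert comp.set_index("class").loc["rRNA", "fraction"] == 1.0

    def test_fraction_arithmetic(self):
        ann = AnnotationSet([
            Locus("m1", "chr1", 0, 100, "+", "miRNA", subtype="mature"),
            Locus("p1", "chr1", 200, 400, "+", "piRNA"),
            Locus("r1", "chr1", 500, 700, "+", "rRNA"),
        ])
        cts = classify_tags(
            [make_hitset(count=600, hits=(("chr1", 10, "+"),)),
             make_hitset(count=300, hits=(("chr1", 250, "+"),)),
             make_hitset(count=100, hits=(("chr1", 550, "+"),))],
            ann)
        comp = class_composition(cts).set_index("class")
        assert comp.loc["miRNA", "fraction"] == pytest.approx(0.6)
        assert comp.loc["piRNA", "fraction"] == pytest.approx(0.3)
        assert comp.loc["rRNA", "fraction"] == pytest.approx(0.1)

    def test_pirna_modal_in_germ_cell_profile(self, gc):
        comp = class_composition(gc.classified)
        annotated = comp[comp["class"] != UNANNOTATED]
        assert annotated.iloc[0]["class"] == "piRNA"


class TestLengthDistribution:
    def test_single_tag(self):
        tags = [Tag("A" * 22, 5, 1)]
        dist = length_distribution(tags)
        assert dist[22] == 5 and dist.drop(22).sum() == 0

    def test_mirna_dominated_peaks_at_22_23(self, esc):
        mirna = [ct for ct in esc.classified if ct.class_label == "miRNA"]
        dist = length_distribution(mirna)
        assert dist.idxmax() in (22, 23)

    def test_pirna_dominated_peaks_at_27_30(self, gc):
        dist = length_distribution(gc.classified)
        assert dist.idxmax() in (27, 28, 29, 30)

    def test_normalized_density_sums_to_one(self, esc):
        dist = length_distribution(esc.classified)
        assert (dist / dist.sum()).sum() == pytest.approx(1.0)
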