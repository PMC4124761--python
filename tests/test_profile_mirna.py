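"""miRNA quantification: counting, RPM, expression calls, signatures,
sample clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from smallrna_sig.annotate import AnnotationSet, ClassifiedTag, Locus
from smallrna_sig.genome_match import Hit, HitSet
from smallrna_sig.preprocess import Tag
from smallrna_sig.profile_mirna import (
    ExpressionMatrix,
    call_expressed,
    call_signature,
    cluster_samples,
    count_mature,
)


def mirna_tag(seq_len, count, chrom, start, strand="+", rank=1):
    tag = Tag("A" * seq_len, count, rank)
    hit = Hit(chrom, start, strand)
    return ClassifiedTag(tag=tag, hitset=HitSet(tag, (hit,)),
                         class_label="miRNA", assigned_locus="mir1",
                         assigned_hit=hit)


@pytest.fixture()
def one_mirna_ann():
    return AnnotationSet([
        Locus("mir1", "chr1", 100, 180, "+", "miRNA", subtype="hairpin"),
        Locus("mir1-5p", "chr1", 108, 130, "+", "miRNA",
              parent="mir1", subtype="mature"),
    ])


class TestCountMature:
    def test_no_mirna_tags_all_zero(self, one_mirna_ann):
        counts, flagged = count_mature([], one_mirna_ann)
        assert counts["mir1-5p"] == 0 and flagged == []

    def test_counts_aggregate_over_tags(self, one_mirna_ann):
        tags = [mirna_tag(22, 5, "chr1", 108, rank=1),
                mirna_tag(22, 2, "chr1", 108, rank=2),
                mirna_tag(22, 1, "chr1", 109, rank=3)]
        counts, _ = count_mature(tags, one_mirna_ann)
        assert counts["mir1-5p"] == 8

    def test_hairpin_only_overlap_flagged(self, one_mirna_ann):
        tags = [mirna_tag(22, 3, "chr1", 150)]  # inside hairpin, off mature
        counts, flagged = count_mature(tags, one_mirna_ann)
        assert counts["hairpin:mir1"] == 3
        assert flagged == ["hairpin:mir1"]
        assert counts["mir1-5p"] == 0

    def test_simulation_recovers_configured_weights(self, bundle, profiles, esc):
        """Sampling weights and recovered counts agree in rank order."""
        counts, _ = count_mature(esc.classified, bundle.tracks)
        weights = profiles["ESC"].expression_weights["miRNA"]
        shared = [m for m in weights if counts.get(m, 0) >= 0]
        rho = spearmanr([weights[m] for m in shared],
                        [counts[m] for m in shared]).statistic
        assert rho >= 0.9


class TestExpressionMatrix:
    def test_rpm_basic_and_conservation(self):
        raw = pd.DataFrame({"s1": [100, 0], "s2": [50, 50]},
                           index=["a", "b"])
        m = ExpressionMatrix.from_counts(raw, {"s1": 1_000_000, "s2": 100})
        assert m.rpm().loc["a", "s1"] == 100.0
        # under the library-total denominator each column sums to 1e6
        m2 = ExpressionMatrix.from_counts(raw)
        assert np.allclose(m2.rpm().sum(axis=0), 1e6)

    def test_log2_undefined_at_zero_by_default(self):
        raw = pd.DataFrame({"s1": [10, 0]}, index=["a", "b"])
        m = ExpressionMatrix.from_counts(raw)
        log2 = m.log2_rpm()
        assert np.isfinite(log2.loc["a", "s1"])
        assert np.isnan(log2.loc["b", "s1"])

    def test_zero_library_size_rejected(self):
        raw = pd.DataFrame({"s1": [0]}, index=["a"])
        with pytest.raises(ValueError):
            ExpressionMatrix(raw=raw, library_sizes=pd.Series({"s1": 0.0}))


class TestCallExpressed:
    def test_boundary_at_one_rpm(self):
        rpm = pd.DataFrame({"s": [1.0, 0.99, 0.0]}, index=["a", "b", "c"])
        mask = call_expressed(rpm)
        assert mask["s"].tolist() == [True, False, False]


def matrix_from_rpm(rpm: pd.DataFrame) -> ExpressionMatrix:
    """Counts equal to desired RPM with library size 1e6 per sample."""
    sizes = {s: 1e6 for s in rpm.columns}
    return ExpressionMatrix(raw=rpm.copy(), library_sizes=pd.Series(sizes))


class TestCallSignature:
    def test_exact_twofold_boundary_included(self):
        rpm = pd.DataFrame(
            {"F": [10.0], "a": [5.0], "b": [5.0], "c": [5.0], "d": [5.0]},
            index=["m1"])
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2)
        assert res.mirnas == ["m1"]

    def test_single_high_other_excludes(self):
        rpm = pd.DataFrame(
            {"F": [10.0], "a": [5.0], "b": [5.0], "c": [6.0], "d": [5.0]},
            index=["m1"])
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2)
        assert res.mirnas == []

    def test_unexpressed_focal_never_called(self):
        rpm = pd.DataFrame({"F": [0.5], "a": [0.1]}, index=["m1"])
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2)
        assert res.mirnas == []

    def test_zero_guard_on_absent_others(self):
        rpm = pd.DataFrame({"F": [10.0], "a": [0.0]}, index=["m1"])
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2, epsilon=0.5)
        assert res.mirnas == ["m1"]

    def test_focal_among_others_rejected(self):
        rpm = pd.DataFrame({"F": [1.0], "a": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            call_signature(matrix_from_rpm(rpm), "F", others=["F", "a"])

    def test_no_comparison_samples_rejected(self):
        rpm = pd.DataFrame({"F": [1.0]}, index=["m1"])
        with pytest.raises(ValueError):
            call_signature(matrix_from_rpm(rpm), "F")

    def _planted_matrix(self, n_mirna=200, n_planted=20, seed=0):
        rng = np.random.default_rng(seed)
        samples = ["F", "a", "b", "c", "d"]
        base = rng.uniform(2, 50, size=(n_mirna, len(samples)))
        rpm = pd.DataFrame(base, columns=samples,
                           index=[f"m{i:03d}" for i in range(n_mirna)])
        planted = rpm.index[:n_planted]
        # focal at >= 4x the best competitor for planted rows;
        # everything else held within 2x of the focal value
        rpm.loc[:, "F"] = rpm[["a", "b", "c", "d"]].max(axis=1) * 1.2
        rpm.loc[planted, "F"] = rpm.loc[planted, ["a", "b", "c", "d"]].max(
            axis=1) * 4.5
        return rpm, set(planted)

    def test_planted_signature_recovered_exactly(self):
        rpm, planted = self._planted_matrix()
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2)
        assert set(res.mirnas) == planted  # no false positives either

    def test_signature_set_shrinks_with_fold(self):
        rpm, _ = self._planted_matrix()
        m = matrix_from_rpm(rpm)
        sizes = [len(call_signature(m, "F", fold=f)) for f in (1.5, 2, 4)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_invariant_to_sample_depth_scaling(self):
        rpm, _ = self._planted_matrix(seed=3)
        raw = rpm.copy()
        m1 = ExpressionMatrix.from_counts(raw)
        scaled = raw.copy()
        scaled["a"] = scaled["a"] * 7.0  # same sample, deeper sequencing
        m2 = ExpressionMatrix.from_counts(scaled)
        r1 = call_signature(m1, "F", fold=2)
        r2 = call_signature(m2, "F", fold=2)
        assert r1.mirnas == r2.mirnas

    def test_results_sorted_by_focal_rpm(self):
        rpm, _ = self._planted_matrix(seed=4)
        res = call_signature(matrix_from_rpm(rpm), "F", fold=2)
        vals = res.table["focal_rpm"].to_numpy()
        assert (np.diff(vals) <= 0).all()

    def test_vs_mean_mode(self):
        rpm = pd.DataFrame({"F": [10.0], "a": [2.0], "b": [12.0]}, index=["m1"])
        each = call_signature(matrix_from_rpm(rpm), "F", fold=2, vs="each")
        mean = call_signature(matrix_from_rpm(rpm), "F", fold=2, vs="mean")
        assert each.mirnas == [] and mean.mirnas == []
        rpm2 = pd.DataFrame({"F": [16.0], "a": [2.0], "b": [12.0]}, index=["m1"])
        assert call_signature(matrix_from_rpm(rpm2), "F", fold=2,
                              vs="mean").mirnas == ["m1"]


class TestClusterSamples:
    def test_identical_samples_merge_at_zero_height(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"A": x, "B": x, "C": rng.normal(size=50)})
        clustering = cluster_samples(df)
        (left, right, height) = clustering.merges()[0]
        assert {frozenset(left), frozenset(right)} == {frozenset({"A"}),
                                                       frozenset({"B"})}
        assert height == pytest.approx(0.0, abs=1e-12)

    def test_constructed_geometry_pairs_first(self):
        rng = np.random.default_rng(1)
        pa = rng.normal(size=80)
        pb = rng.normal(size=80)
        df = pd.DataFrame({
            "A": pa + rng.normal(0, 0.05, 80),
            "B": pa + rng.normal(0, 0.05, 80),
            "C": pb + rng.normal(0, 0.05, 80),
            "D": pb + rng.normal(0, 0.05, 80),
            "E": rng.normal(size=80),
        })
        merges = cluster_samples(df).merges()
        first_two = {left | right for left, right, _ in merges[:2]}
        assert first_two == {frozenset({"A", "B"}), frozenset({"C", "D"})}

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            cluster_samples(pd.DataFrame({"A": [1.0, 2.0]}))

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("ABCD"))
        z1 = cluster_samples(df).linkage_matrix
        z2 = cluster_samples(df).linkage_matrix
        assert np.array_equal(z1, z2)
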