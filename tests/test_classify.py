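"""Detection-frequency filters, ratio marks and the classification rules.

Scenarios are built on a fixed 3-tree design grid (10 sampling days x 2
replicates per tree; 10 pre-exposure and 10 post-exposure samples per tree)
so detection frequencies are exact round fractions.
"""

import pandas as pd
import pytest

from trunkvoc.classify import (
    POST_PHASES,
    PRE_PHASES,
    EmissionContext,
    RatioMark,
    TreeRoles,
    classify_all,
    classify_compound,
    constitutive_set,
    detection_frequency,
    phase_mean_rate,
    ratio_with_marks,
    retention_filter,
)

ROLES = TreeRoles()
DAYS = [0, 4, 8, 10, 15, 25, 40, 60, 90, 120]  # 5 pre-, 5 post-exposure days


def make_ctx(detections):
    """detections: iterable of (compound, tree, day, replicate, rate)."""
    design = pd.DataFrame(
        [
            {
                "sample_id": f"{t}-{d}-{r}", "tree_id": t, "day": d, "replicate": r,
                "bark_area_dm2": 2.0, "duration_h": 1.5, "flow_ml_min": 30.0,
                "is_background": False, "location": "outside",
            }
            for t in ROLES.all for d in DAYS for r in (1, 2)
        ]
    )
    emissions = pd.DataFrame(
        [
            {"compound": c, "tree_id": t, "day": d, "replicate": r,
             "rate": rate, "unit": "ng_per_dm2_h"}
            for c, t, d, r, rate in detections
        ],
        columns=["compound", "tree_id", "day", "replicate", "rate", "unit"],
    )
    return EmissionContext(emissions, design)


def everywhere(compound, rate=1.0, trees=ROLES.all, days=DAYS):
    return [(compound, t, d, r, rate) for t in trees for d in days for r in (1, 2)]


PRE_DAYS = [d for d in DAYS if d <= 19]
POST_DAYS = [d for d in DAYS if d >= 20]


class TestDetectionFrequency:
    def test_full_and_zero(self):
        ctx = make_ctx(everywhere("x"))
        assert detection_frequency(ctx, "x", ROLES.all, {1, 2, 3}) == 100.0
        assert detection_frequency(ctx, "absent", ["ApI"], {3}) == 0.0

    def test_fraction_arithmetic_with_duplicates(self):
        # detected in 3 of 10 ApI post samples -> 30%
        det = [("x", "ApI", 25, 1, 1.0), ("x", "ApI", 25, 2, 1.0),
               ("x", "ApI", 40, 1, 1.0)]
        ctx = make_ctx(det)
        assert detection_frequency(ctx, "x", ["ApI"], POST_PHASES) == pytest.approx(30.0)

    def test_empty_scope_is_error(self):
        ctx = make_ctx(everywhere("x"))
        with pytest.raises(ValueError):
            detection_frequency(ctx, "x", ["nonexistent"], {1})


class TestRetentionFilter:
    def test_inclusive_at_threshold(self):
        # 6 of 60 pooled samples = exactly 10%
        det = [("edge", "ApI", d, r, 1.0) for d in (25, 40, 60) for r in (1, 2)]
        det += everywhere("common")
        ctx = make_ctx(det)
        assert set(retention_filter(ctx, 10.0)) == {"common", "edge"}

    def test_below_threshold_dropped(self):
        det = [("rare", "ApI", 25, 1, 1.0)] + everywhere("common")
        ctx = make_ctx(det)
        assert set(retention_filter(ctx, 10.0)) == {"common"}

    def test_monotone_in_threshold(self):
        det = everywhere("a") + [("b", "ApI", d, r, 1.0)
                                 for d in DAYS[:5] for r in (1, 2)]
        ctx = make_ctx(det)
        sizes = [len(retention_filter(ctx, t)) for t in (5, 20, 50, 90)]
        assert sizes == sorted(sizes, reverse=True)


class TestConstitutiveSet:
    def test_requires_every_tree(self):
        # 100% at ApC/ApI but only 40% of pre samples at ApN
        det = everywhere("x", trees=["ApC", "ApI"])
        det += [("x", "ApN", d, r, 1.0) for d in [0, 4] for r in (1, 2)]
        ctx = make_ctx(det)
        assert constitutive_set(ctx, ["x"], ROLES) == set()
        # pooled counting rescues it: 24 of 30 pre samples = 80%
        assert constitutive_set(ctx, ["x"], ROLES, pooled=True) == {"x"}

    def test_inclusive_at_fifty_percent(self):
        # exactly 5 of 10 pre samples per tree
        det = [("x", t, d, r, 1.0) for t in ROLES.all
               for d, r in [(0, 1), (0, 2), (4, 1), (4, 2), (8, 1)]]
        ctx = make_ctx(det)
        assert constitutive_set(ctx, ["x"], ROLES) == {"x"}

    def test_monotone_in_threshold(self):
        det = everywhere("x")
        det += [("y", t, d, r, 1.0) for t in ROLES.all
                for d in PRE_DAYS[:3] for r in (1, 2)]
        ctx = make_ctx(det)
        for lo, hi in [(30, 60), (50, 90)]:
            assert constitutive_set(ctx, ["x", "y"], ROLES, hi) <= constitutive_set(
                ctx, ["x", "y"], ROLES, lo
            )


class TestPhaseMeanRate:
    def test_mean_of_detected(self):
        det = [("x", "ApI", 25, 1, 2.0), ("x", "ApI", 25, 2, 4.0)]
        det += [("x", "ApI", d, r, 1.0) for d in (40, 60, 90, 120) for r in (1, 2)]
        ctx = make_ctx(det)
        assert phase_mean_rate(ctx, "x", "ApI", POST_PHASES) == pytest.approx(1.4)

    def test_sparse_scope_undefined(self):
        det = [("x", "ApI", 25, 1, 5.0)]  # 1 of 10 = 10% < 20%
        ctx = make_ctx(det)
        assert phase_mean_rate(ctx, "x", "ApI", POST_PHASES) is None

    def test_exactly_twenty_percent_defined(self):
        det = [("x", "ApI", 25, 1, 3.0), ("x", "ApI", 25, 2, 5.0)]  # 2/10
        ctx = make_ctx(det)
        assert phase_mean_rate(ctx, "x", "ApI", POST_PHASES) == pytest.approx(4.0)


class TestRatioMarks:
    def test_numeric(self):
        m = ratio_with_marks(8.0, 2.0)
        assert (m.kind, m.value) == ("numeric", 4.0)
        assert m.satisfies_twofold()

    def test_sparse_comparison_renders_gt(self):
        m = ratio_with_marks(8.0, None)
        assert m.kind == "sparse" and m.render() == ">"

    def test_exclusive_renders_tree_label(self):
        m = ratio_with_marks(8.0, None, numerator_exclusive=True, numerator_label="ApI")
        assert m.kind == "exclusive" and m.render() == "ApI"

    def test_intra_tree_de_novo_renders_alb(self):
        m = ratio_with_marks(8.0, None, intra_tree=True)
        assert m.kind == "de_novo" and m.render() == "ALB"

    def test_both_undefined_is_error(self):
        with pytest.raises(ValueError):
            ratio_with_marks(None, None)

    def test_numeric_below_two_not_satisfied(self):
        assert not ratio_with_marks(3.0, 2.0).satisfies_twofold()
        assert ratio_with_marks(4.0, 2.0).satisfies_twofold()  # inclusive


def classify_one(detections, compound, **kw):
    ctx = make_ctx(detections)
    retained = retention_filter(ctx, 10.0)
    core = constitutive_set(ctx, retained, ROLES)
    return classify_compound(ctx, compound, ROLES, core, **kw)


class TestClassification:
    def test_de_novo_infested_only_is_hipv(self):
        det = [("x", "ApI", d, r, 3.0) for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "hipv" and res.rule == "hipv_de_novo"

    def test_boundary_twofold_inclusive_is_hipv(self):
        """post/pre = ApI/ApN = ApI/ApC = exactly 2.0 still counts."""
        det = [("x", "ApI", d, r, 1.0) for d in PRE_DAYS for r in (1, 2)]
        det += [("x", "ApI", d, r, 2.0) for d in POST_DAYS for r in (1, 2)]
        det += [("x", t, d, r, 1.0) for t in ("ApN", "ApC")
                for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "hipv" and res.rule == "hipv_twofold"

    def test_comparable_increase_both_trees_is_stress(self):
        """3.0-fold and 3.1-fold increases (ratio 0.97, inside band)."""
        det = []
        for tree, post_rate in (("ApI", 3.0), ("ApN", 3.1)):
            det += [("x", tree, d, r, 1.0) for d in PRE_DAYS for r in (1, 2)]
            det += [("x", tree, d, r, post_rate) for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "stress_induced"

    def test_disparate_increases_not_stress(self):
        """10-fold vs 2.5-fold is outside the factor-2 comparability band."""
        det = []
        for tree, post_rate in (("ApI", 10.0), ("ApN", 2.5)):
            det += [("x", tree, d, r, 1.0) for d in PRE_DAYS for r in (1, 2)]
            det += [("x", tree, d, r, post_rate) for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "hipv"

    def test_neighbor_rule_mirrors_hipv(self):
        det = [("x", "ApN", d, r, 3.0) for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "neighbor_induced" and res.rule == "neighbor_de_novo"

    def test_constitutive_primary_with_induced_secondary(self):
        det = everywhere("x", rate=1.0, days=PRE_DAYS)
        det += [("x", t, d, r, 1.0) for t in ("ApN", "ApC")
                for d in POST_DAYS for r in (1, 2)]
        det += [("x", "ApI", d, r, 5.0) for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "constitutive"
        assert res.secondary == "hipv"

    def test_de_novo_in_every_tree_counts_as_stress(self):
        """Comparable de-novo appearance in both stressed trees fires the
        stress rule (the rule does not consult the control tree)."""
        det = [("x", t, d, r, 1.0) for t in ROLES.all
               for d in POST_DAYS for r in (1, 2)]
        res = classify_one(det, "x")
        assert res.label == "stress_induced"

    def test_flat_sparse_compound_unclassified(self):
        """Detected below the constitutive threshold with ~unit ratios:
        no rule fires."""
        det = [("x", t, d, r, 1.0) for t in ROLES.all
               for d in PRE_DAYS[:2] for r in (1, 2)]  # 40% pre DF
        det += [("x", t, d, r, 1.0) for t in ROLES.all
                for d in POST_DAYS[:2] for r in (1, 2)]  # 40% post DF
        res = classify_one(det, "x")
        assert res.label == "unclassified"


class TestPartitionInvariant:
    def test_primary_labels_partition_retained_set(self, run_bundle):
        """Every retained compound gets exactly one primary label."""
        cls = run_bundle["bundle"]["classification"]
        assert cls["compound"].is_unique
        assert set(cls["label"]) <= {
            "constitutive", "hipv", "neighbor_induced", "stress_induced",
            "unclassified",
        }

    def test_df_values_recomputable_exactly(self, run_bundle):
        """DF columns equal brute-force recounts from the emission table."""
        bundle = run_bundle["bundle"]
        cfg = run_bundle["cfg"]
        design = pd.read_csv(cfg.design)
        ctx = EmissionContext(bundle["emissions"], design)
        cls = bundle["classification"].set_index("compound")
        for compound in cls.index[:10]:
            for tree in ROLES.all:
                expected = detection_frequency(ctx, compound, [tree], PRE_PHASES)
                assert cls.loc[compound, f"df_{tree}_pre"] == pytest.approx(expected)
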