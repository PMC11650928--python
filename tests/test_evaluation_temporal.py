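import math

import numpy as np
import pytest

from patchid.backbones import BackboneSpec, FunctionBackbone
from patchid.ensemble_fusion import EnsembleModel, INDEX_ORDER, collect_indices, final_similarity
from patchid.evaluation_temporal import (
    EvaluationReport,
    ImagePair,
    SharkGroup,
    confusion_metrics,
    image_based_eval,
    roc_auc,
    report_from_scores,
    shark_based_eval,
    temporal_analysis,
)
from patchid.exceptions import ConfigError
from patchid.patch_pipeline import Patch
from patchid.similarity_net import PatchModel, SimilarityHead


class TestConfusionMetrics:
    def test_hand_count(self):
        acc, prec, mae = confusion_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert (acc, prec, mae) == (0.75, 0.5, 0.25)

    def test_all_correct(self):
        acc, prec, mae = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert (acc, prec, mae) == (1.0, 1.0, 0.0)

    def test_no_positive_predictions(self):
        acc, prec, mae = confusion_metrics([0, 0, 0], [1, 0, 0])
        assert math.isnan(prec)
        assert acc == pytest.approx(2 / 3)
        assert mae == pytest.approx(1 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ConfigError):
            confusion_metrics([1, 0], [1])

    def test_accuracy_plus_mae_is_one(self, rng):
        for _ in range(20):
            d = rng.integers(0, 2, 30).tolist()
            y = rng.integers(0, 2, 30).tolist()
            acc, _, mae = confusion_metrics(d, y)
            assert acc + mae == 1.0


def _concordance_auc(scores, labels):
    """O(n^2) oracle: P(pos > neg) + 0.5 P(pos == neg)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_concordance_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(5, 200))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            _, auc = roc_auc(scores.tolist(), labels.tolist())
            assert auc == pytest.approx(_concordance_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_roc_endpoints(self, rng):
        points, _ = roc_auc(rng.random(30).tolist(), ([0, 1] * 15))
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)


# ---------------------------------------------------------------------------
# analytic twin-model stubs: shark k renders constant pixel level k/9; the
# head computes s ~ 1 iff the two embeddings are equal
# ---------------------------------------------------------------------------


def _difference_model(ptype):
    spec = BackboneSpec("stub", 4, (0.0, 1.0), 1, "random_frozen_test")
    bb = FunctionBackbone(spec, lambda x: x.mean(axis=(1, 2, 3))[:, None, None, None])
    head = SimilarityHead(
        W1=np.array([[60.0, -60.0], [-60.0, 60.0]]),
        b1=np.zeros(2),
        W2=np.array([[-40.0], [-40.0]]),
        b2=np.array([6.0]),
    )
    return PatchModel(patch_type=ptype, backbone=bb, head=head)


def _identity_ensemble():
    class _Head(object):
        def predict(self, X):
            return np.atleast_2d(X)[:, 0] - 0.5

    return EnsembleModel(base_score=0.5, trees=[_Head()], tree_weights=[1.0], fitted=True)


def _image(shark_idx, image_id):
    level = shark_idx / 9.0 * 255.0
    return {
        t: Patch(t, np.full((4, 4, 3), level, dtype=np.float32), image_id, f"S{shark_idx}")
        for t in INDEX_ORDER
    }


@pytest.fixture
def models():
    return {t: _difference_model(t) for t in INDEX_ORDER}


@pytest.fixture
def ensemble():
    return _identity_ensemble()


class TestImageBasedEval:
    def test_analytic_stub_is_perfect(self, models, ensemble):
        pairs = [
            ImagePair(_image(1, "a1"), _image(1, "a2"), 1),
            ImagePair(_image(1, "a1"), _image(2, "b1"), 0),
            ImagePair(_image(2, "b1"), _image(2, "b2"), 1),
            ImagePair(_image(3, "c1"), _image(1, "a1"), 0),
        ]
        report = image_based_eval(models, ensemble, pairs)
        assert report.accuracy == 1.0
        assert report.mae == 0.0
        assert report.precision == 1.0

    def test_accuracy_plus_mae_identity(self, models, ensemble, rng):
        pairs = []
        for i in range(12):
            a, b = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            if a == b:
                pairs.append(ImagePair(_image(a, f"x{i}"), _image(a, f"y{i}"), 1))
            else:
                pairs.append(ImagePair(_image(a, f"x{i}"), _image(b, f"y{i}"), 0))
        report = image_based_eval(models, ensemble, pairs)
        assert report.accuracy + report.mae == 1.0

    def test_order_invariance(self, models, ensemble):
        pairs = [
            ImagePair(_image(1, "a1"), _image(2, "b1"), 0),
            ImagePair(_image(1, "a1"), _image(1, "a2"), 1),
            ImagePair(_image(3, "c1"), _image(3, "c2"), 1),
        ]
        r1 = image_based_eval(models, ensemble, pairs)
        r2 = image_based_eval(models, ensemble, pairs[::-1])
        assert sorted(r1.scores) == sorted(r2.scores)
        assert r1.accuracy == r2.accuracy

    def test_empty_rejected(self, models, ensemble):
        with pytest.raises(ConfigError):
            image_based_eval(models, ensemble, [])


class TestSharkBasedEval:
    def test_k1_times_k2_averaging_oracle(self, models, ensemble):
        g1 = SharkGroup("S1", tuple(_image(1, f"a{i}") for i in range(2)))
        g2 = SharkGroup("S2", tuple(_image(2, f"b{i}") for i in range(3)))
        report = shark_based_eval(models, ensemble, [g1, g2])
        # brute-force oracle: all 2x3 = 6 ordered cross pairs, averaged
        vals = [
            final_similarity(ensemble, collect_indices(models, pa, pb))
            for pa in g1.images
            for pb in g2.images
        ]
        assert len(vals) == 6
        # report contains the negative group pair score plus two halvings
        assert report.scores[0] == pytest.approx(float(np.mean(vals)), abs=1e-12)

    def test_singleton_groups_reduce_to_image_based(self, models, ensemble):
        groups = [SharkGroup(f"S{k}", (_image(k, f"i{k}"),)) for k in (1, 2, 3)]
        shark_rep = shark_based_eval(models, ensemble, groups)
        pairs = [
            ImagePair(groups[i].images[0], groups[j].images[0], 0)
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        image_rep = image_based_eval(models, ensemble, pairs)
        assert shark_rep.scores == pytest.approx(image_rep.scores, abs=1e-15)

    def test_group_score_within_min_max(self, models, ensemble, rng):
        g1 = SharkGroup("S1", tuple(_image(1, f"a{i}") for i in range(3)))
        g2 = SharkGroup("S2", tuple(_image(2, f"b{i}") for i in range(2)))
        vals = [
            final_similarity(ensemble, collect_indices(models, pa, pb))
            for pa in g1.images
            for pb in g2.images
        ]
        report = shark_based_eval(models, ensemble, [g1, g2])
        assert min(vals) - 1e-12 <= report.scores[0] <= max(vals) + 1e-12

    def test_needs_two_groups(self, models, ensemble):
        with pytest.raises(ConfigError):
            shark_based_eval(models, ensemble, [SharkGroup("S1", (_image(1, "a"),))])

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            SharkGroup("S1", ())


class TestTemporalAnalysis:
    def test_baseline_against_itself(self, models, ensemble):
        baseline = SharkGroup("S1", tuple(_image(1, f"b{i}") for i in range(2)))
        curve, verdict = temporal_analysis(
            models, ensemble, baseline, {"T0": list(baseline.images)}
        )
        # identical images: the pseudo-marker equals the self-similarity score
        assert curve[0][1] > 0.5
        assert verdict == "stable"

    def test_marker_numeric_ordering(self, models, ensemble):
        baseline = SharkGroup("S1", (_image(1, "b0"),))
        curve, _ = temporal_analysis(
            models, ensemble, baseline,
            {"T10": [_image(1, "t10")], "T2": [_image(1, "t2")]},
        )
        assert [m for m, _ in curve] == ["T2", "T10"]

    def test_unstable_when_pattern_changes(self, models, ensemble):
        baseline = SharkGroup("S1", (_image(1, "b0"),))
        curve, verdict = temporal_analysis(
            models, ensemble, baseline,
            {"T1": [_image(1, "t1")], "T2": [_image(5, "t2")]},  # T2 diverged
        )
        assert verdict == "unstable"
        values = dict(curve)
        assert values["T1"] > 0.5 and values["T2"] < 0.5

    def test_bad_marker_rejected(self, models, ensemble):
        baseline = SharkGroup("S1", (_image(1, "b0"),))
        with pytest.raises(Exception):
            temporal_analysis(models, ensemble, baseline, {"week3": [_image(1, "x")]})

    def test_no_markers_rejected(self, models, ensemble):
        baseline = SharkGroup("S1", (_image(1, "b0"),))
        with pytest.raises(ConfigError):
            temporal_analysis(models, ensemble, baseline, {})


class TestReportProperties:
    def test_accuracy_plus_mae_always_one(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 50))
            scores = rng.random(n).tolist()
            labels = rng.integers(0, 2, n).tolist()
            rep = report_from_scores(scores, labels)
            assert rep.accuracy + rep.mae == 1.0

    def test_label_permutation_null(self, rng):
        n = 600
        scores = rng.random(n)
        labels = rng.permutation([1] * (n // 2) + [0] * (n // 2))
        _, auc = roc_auc(scores.tolist(), labels.tolist())
        assert 0.4 <= auc <= 0.6
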