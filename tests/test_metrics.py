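"""Confusion metrics, published-grid reconstruction, curves, agreement."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ckdphen.metrics import (
    ConfusionMatrix,
    agreement_report,
    classification_metrics,
    cohens_kappa,
    pr_and_auc,
    proportion_ci,
    reconstruct_matrix_from_rates,
    roc_and_auc,
)

# published rule-based classifier grid on a 29 CKD / 133 non-CKD review
# cohort: (sens, spec) inputs and the printed (ppv, npv, f1, acc) cells
RULE_GRID = {
    "egfr_index": (0.793, 0.962, 0.821, 0.955, 0.807, 0.932),
    "discharge_summary": (0.862, 0.684, 0.373, 0.958, 0.521, 0.716),
    "icd10_codes": (0.931, 0.872, 0.614, 0.983, 0.740, 0.883),
}
N_POS, N_NEG = 29, 133


def auroc_pairwise_oracle(scores, labels):
    """O(n^2) Mann-Whitney count: P(pos > neg) with ties counted 1/2."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_threshold_oracle(scores, labels):
    """Step-wise area by explicit threshold enumeration (descending)."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    total_pos = y.sum()
    area = 0.0
    prev_recall = 0.0
    i = 0
    n = len(s)
    tp = fp = 0
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            tp += y[j]
            fp += not y[j]
            j += 1
        recall = tp / total_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestConfusionMatrix:
    def test_perfect_and_inverted(self):
        truth = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        cm = ConfusionMatrix.from_labels(truth, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (5, 0, 0, 5)
        cm = ConfusionMatrix.from_labels(~truth, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 5, 5, 0)

    def test_hand_counted_cells(self):
        pred = np.array([1, 1, 0, 0, 1, 0, 1, 0], dtype=bool)
        true = np.array([1, 0, 1, 0, 1, 1, 0, 0], dtype=bool)
        cm = ConfusionMatrix.from_labels(pred, true)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 2, 2, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ConfusionMatrix.from_labels([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix.from_labels([1, 2], [1, 0])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)


class TestClassificationMetrics:
    def test_published_egfr_row(self):
        ms = classification_metrics(ConfusionMatrix(23, 5, 6, 128))
        assert round(ms["ppv"], 3) == 0.821
        assert round(ms["npv"], 3) == 0.955
        assert round(ms["f1"], 3) == 0.807
        assert round(ms["accuracy"], 3) == 0.932

    def test_published_icd_row(self):
        ms = classification_metrics(ConfusionMatrix(27, 17, 2, 116))
        assert round(ms["ppv"], 3) == 0.614
        assert round(ms["f1"], 3) == 0.740
        assert round(ms["accuracy"], 3) == 0.883

    def test_degenerate_all_negative_flags_undefined(self):
        ms = classification_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert {"sensitivity", "ppv", "f1"} <= ms.undefined
        assert np.isnan(ms["sensitivity"])
        assert ms["specificity"] == 1.0 and ms["accuracy"] == 1.0

    def test_f1_identity_on_random_matrices(self, rng):
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 60, 4)
            if tp + fp + fn + tn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(fp), int(fn), int(tn))
            ms = classification_metrics(cm)
            if {"ppv", "sensitivity", "f1"} & ms.undefined:
                continue
            p, s = ms["ppv"], ms["sensitivity"]
            if p + s == 0:
                continue
            assert ms["f1"] == pytest.approx(2 * p * s / (p + s))

    def test_ci_bounds_bracket_point(self):
        ms = classification_metrics(ConfusionMatrix(23, 5, 6, 128))
        for m in ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy"):
            assert ms.ci_low[m] <= ms[m] <= ms.ci_high[m]


class TestReconstruction:
    @pytest.mark.parametrize(
        "sens,spec,cells",
        [
            (0.793, 0.962, (23, 5, 6, 128)),
            (0.862, 0.684, (25, 42, 4, 91)),
            (0.931, 0.872, (27, 17, 2, 116)),
        ],
    )
    def test_published_rows(self, sens, spec, cells):
        cm = reconstruct_matrix_from_rates(sens, spec, N_POS, N_NEG)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == cells

    def test_perfect_rates(self):
        cm = reconstruct_matrix_from_rates(1.0, 1.0, 10, 10)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 0, 0, 10)

    def test_full_grid_reproduced_to_three_decimals(self):
        for sens, spec, ppv, npv, f1, acc in RULE_GRID.values():
            cm = reconstruct_matrix_from_rates(sens, spec, N_POS, N_NEG)
            ms = classification_metrics(cm)
            assert round(ms["sensitivity"], 3) == sens
            assert round(ms["specificity"], 3) == spec
            assert round(ms["ppv"], 3) == ppv
            assert round(ms["npv"], 3) == npv
            assert round(ms["f1"], 3) == f1
            assert round(ms["accuracy"], 3) == acc

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            reconstruct_matrix_from_rates(1.2, 0.5, 10, 10)
        with pytest.raises(ValueError):
            reconstruct_matrix_from_rates(0.5, 0.5, 0, 10)


class TestProportionCi:
    def test_zero_numerator_low_is_zero(self):
        lo, hi = proportion_ci(0, 50)
        assert lo == 0.0 and 0.0 < hi < 0.15

    def test_wilson_closed_form(self):
        # hand evaluation of the Wilson score interval for 50/100 at z=1.96
        lo, hi = proportion_ci(50, 100)
        z = 1.959963984540054
        centre = (0.5 + z**2 / 200) / (1 + z**2 / 100)
        half = (z / (1 + z**2 / 100)) * np.sqrt(0.25 / 100 + z**2 / 40000)
        assert lo == pytest.approx(centre - half, abs=1e-9)
        assert hi == pytest.approx(centre + half, abs=1e-9)
        assert lo + hi == pytest.approx(2 * centre)

    def test_width_shrinks_with_n(self):
        lo1, hi1 = proportion_ci(50, 100)
        lo2, hi2 = proportion_ci(500, 1000)
        assert hi2 - lo2 < hi1 - lo1

    def test_clopper_pearson_option(self):
        lo, hi = proportion_ci(5, 10, method="clopper-pearson")
        assert 0 < lo < 0.5 < hi < 1

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 0)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1], dtype=bool)
        assert roc_and_auc(scores, labels).auroc == 1.0

    def test_null_scores_near_half(self, rng):
        scores = rng.uniform(size=2000)
        labels = rng.uniform(size=2000) < 0.3
        assert abs(roc_and_auc(scores, labels).auroc - 0.5) < 0.03

    def test_hand_example_matches_pairwise_oracle(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0], dtype=bool)
        cs = roc_and_auc(scores, labels)
        assert cs.auroc == pytest.approx(auroc_pairwise_oracle(scores, labels))

    def test_random_instances_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 120))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                continue
            cs = roc_and_auc(scores, labels)
            assert cs.auroc == pytest.approx(
                auroc_pairwise_oracle(scores, labels), abs=1e-12
            )
            assert cs.auroc_ci[0] <= cs.auroc <= cs.auroc_ci[1]

    def test_roc_endpoints(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1], dtype=bool)
        pts = roc_and_auc(scores, labels).roc_points
        assert (pts.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (pts.iloc[-1][["fpr", "tpr"]] == 1).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc([0.1, 0.9], [1, 1])


class TestPr:
    def test_perfect_classifier(self):
        cs = pr_and_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], bootstrap=0)
        assert cs.auprc == 1.0

    def test_uninformative_scores_near_prevalence(self, rng):
        scores = rng.uniform(size=2000)
        labels = rng.uniform(size=2000) < 0.25
        cs = pr_and_auc(scores, labels, bootstrap=0)
        assert abs(cs.auprc - labels.mean()) < 0.05

    def test_hand_example_matches_threshold_oracle(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.6, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0], dtype=bool)
        cs = pr_and_auc(scores, labels, bootstrap=0)
        assert cs.auprc == pytest.approx(auprc_threshold_oracle(scores, labels))

    def test_random_instances_match_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 100))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.uniform(size=n) < 0.4
            if labels.all() or not labels.any():
                continue
            cs = pr_and_auc(scores, labels, bootstrap=0)
            assert cs.auprc == pytest.approx(
                auprc_threshold_oracle(scores, labels), abs=1e-12
            )

    def test_bootstrap_ci_brackets_point(self, rng):
        scores = rng.uniform(size=300)
        labels = (scores + rng.normal(0, 0.3, 300)) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        cs = pr_and_auc(scores, labels, bootstrap=200, seed=1)
        assert cs.auprc_ci[0] <= cs.auprc <= cs.auprc_ci[1]

    def test_permutation_invariance(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.uniform(size=50) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        perm = rng.permutation(50)
        a = pr_and_auc(scores, labels, bootstrap=0).auprc
        b = pr_and_auc(scores[perm], labels[perm], bootstrap=0).auprc
        assert a == pytest.approx(b)


class TestKappa:
    def test_identical_labels(self):
        assert cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_hand_example_zero(self):
        assert cohens_kappa([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_complete_disagreement_balanced(self):
        assert cohens_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1.0)

    def test_degenerate_marginals_nan(self):
        assert np.isnan(cohens_kappa([1, 1, 1], [1, 1, 1]))

    def test_matches_sklearn_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            a = rng.uniform(size=n) < 0.5
            b = rng.uniform(size=n) < 0.5
            ours = cohens_kappa(a, b)
            theirs = cohen_kappa_score(a, b)
            if np.isnan(ours) or np.isnan(theirs):
                continue
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 0], [1])


class TestAgreementReport:
    def test_identical_sets(self):
        a = pd.Series([True, False, True], index=["x", "y", "z"])
        rep = agreement_report(a, a)
        assert rep.accuracy == 1.0 and rep.kappa == 1.0 and rep.n_overlap == 3

    def test_overlap_only(self):
        a = pd.Series([True, False], index=["x", "y"])
        b = pd.Series([True, True, False], index=["x", "q", "r"])
        rep = agreement_report(a, b)
        assert rep.n_overlap == 1

    def test_disjoint_sets_rejected(self):
        a = pd.Series([True], index=["x"])
        b = pd.Series([True], index=["y"])
        with pytest.raises(ValueError):
            agreement_report(a, b)
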