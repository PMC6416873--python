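"""Compound covariate subtype prediction: posterior math, panel selection,
decision tree, cross-validation without selection leakage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from diffgc import (BCCPClassifier, SubtypePredictor, ValidationError, loocv,
                    select_subtype_genes, sens_spec_curve)
from diffgc.bccp import confusion_and_rates


def make_xy(strong_fixture, strong_normalized):
    X = strong_normalized.to_samples()
    y = strong_fixture.truth.set_index("sample_id")["subtype"]
    return X, y


class TestPanelSelection:
    def test_planted_panels_recovered_without_contamination(
            self, strong_fixture, strong_normalized):
        X, y = make_xy(strong_fixture, strong_normalized)
        panels = select_subtype_genes(X, y)
        for s, panel in panels.items():
            planted = set(strong_fixture.signature_genes[s])
            assert len(planted & set(panel.genes)) / len(planted) >= 0.9
            contamination = len(set(panel.genes) - planted) / max(len(panel.genes), 1)
            assert contamination < 0.05

    def test_null_data_gives_nearly_empty_panels(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 2000)))
        y = pd.Series(np.repeat(["EBV", "MSI", "GS", "CIN"], 10))
        panels = select_subtype_genes(X, y, alpha=0.001)
        # chance of one gene passing all three 0.001 tests is ~alpha^3-scale
        assert sum(len(p.genes) for p in panels.values()) <= 3

    def test_top_n_truncation_in_rank_order(self, strong_fixture,
                                            strong_normalized):
        X, y = make_xy(strong_fixture, strong_normalized)
        full = select_subtype_genes(X, y, top_n=200)["MSI"]
        small = select_subtype_genes(X, y, top_n=10)["MSI"]
        assert len(small.genes) == 10
        assert small.genes == full.genes[:10]

    def test_small_subtype_rejected(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(7, 10)))
        y = pd.Series(["EBV", "EBV", "MSI", "MSI", "GS", "GS", "CIN"])
        with pytest.raises(ValidationError):
            select_subtype_genes(X, y)


class TestBCCPClassifier:
    def test_symmetric_classes_give_symmetric_score_means(self):
        rng = np.random.default_rng(2)
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]]) + rng.normal(0, 0.01, (4, 1))
        y = [False, False, True, True]
        model = BCCPClassifier().fit(X, y)
        # scores scale with the training t-statistic, so symmetry is relative
        assert model.mu_pos_ == pytest.approx(-model.mu_neg_, rel=0.05)

    def test_posterior_half_at_midpoint(self):
        model = BCCPClassifier()
        model.weights_ = np.array([1.0])
        model.mu_pos_, model.mu_neg_, model.sigma_ = 2.0, 4.0, 1.0
        model.classes_ = np.array([False, True])
        assert model.posterior([[3.0]])[0] == pytest.approx(0.5, abs=1e-12)

    def test_posterior_matches_normal_density_oracle_at_six_sigma(self):
        """c = mu+ with mu- = mu+ + 6*sigma, equal priors:
        posterior = phi(0) / (phi(0) + phi(6)) ~ 1 - 1.52e-8."""
        model = BCCPClassifier()
        model.weights_ = np.array([1.0])
        model.mu_pos_, model.mu_neg_, model.sigma_ = 0.0, 6.0, 1.0
        model.classes_ = np.array([False, True])
        expected = sps.norm.pdf(0) / (sps.norm.pdf(0) + sps.norm.pdf(6))
        post = model.posterior([[0.0]])[0]
        assert post == pytest.approx(expected, abs=1e-15)
        assert post == pytest.approx(1 - 1.523e-8, abs=1e-11)

    def test_degenerate_priors_override_data(self):
        model = BCCPClassifier(priors=(1.0, 0.0))
        model.weights_ = np.array([1.0])
        model.mu_pos_, model.mu_neg_, model.sigma_ = 0.0, 5.0, 1.0
        model.classes_ = np.array([False, True])
        assert model.posterior([[100.0]])[0] == 1.0

    def test_label_swap_maps_posterior_to_complement(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        y = np.repeat([True, False], 10)
        test = rng.normal(size=(7, 5))
        p_pos = BCCPClassifier().fit(X, y).posterior(test)
        p_neg = BCCPClassifier().fit(X, ~y).posterior(test)
        assert np.allclose(p_pos, 1 - p_neg, atol=1e-9)

    def test_posterior_monotone_in_score(self):
        model = BCCPClassifier()
        model.weights_ = np.array([1.0])
        model.mu_pos_, model.mu_neg_, model.sigma_ = 3.0, -1.0, 1.5
        model.classes_ = np.array([False, True])
        grid = np.linspace(-10, 10, 101).reshape(-1, 1)
        post = model.posterior(grid)
        assert (np.diff(post) > 0).all()
        assert ((post > 0) & (post < 1)).all()

    def test_zero_score_variance_rejected(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        with pytest.raises(ValidationError):
            BCCPClassifier().fit(X, [True, True, False, False])


class TestDecisionTree:
    def make_predictor(self, strong_fixture, strong_normalized):
        X = strong_normalized.to_samples()
        y = strong_fixture.truth.set_index("sample_id")["subtype"]
        return SubtypePredictor().fit(X, y), X, y

    def test_first_node_stop_and_fall_through(self, strong_fixture,
                                              strong_normalized):
        model, X, y = self.make_predictor(strong_fixture, strong_normalized)
        calls = model.predict_calls(X)
        ebv = calls[y == "EBV"]
        assert (ebv["label"] == "EBV").all()
        assert (ebv["tree_path"] == "EBV").all()  # stopped at node 1
        cin = calls[y == "CIN"]
        assert (cin["label"] == "CIN").all()
        assert (cin["tree_path"] == "EBV->MSI->GS").all()  # full fall-through

    def test_every_sample_gets_exactly_one_label(self, strong_fixture,
                                                 strong_normalized):
        model, X, _ = self.make_predictor(strong_fixture, strong_normalized)
        labels = model.predict(X)
        assert len(labels) == len(X)
        assert set(labels) <= {"EBV", "MSI", "GS", "CIN"}

    def test_invalid_node_order_rejected(self, strong_fixture,
                                         strong_normalized):
        X = strong_normalized.to_samples()
        y = strong_fixture.truth.set_index("sample_id")["subtype"]
        with pytest.raises(ValidationError):
            SubtypePredictor(node_order=("EBV", "EBV", "MSI")).fit(X, y)
        with pytest.raises(ValidationError):
            SubtypePredictor(node_order=("EBV", "MSI", "GS", "CIN")).fit(X, y)

    def test_estimator_is_clonable(self):
        from sklearn.base import clone
        clone(SubtypePredictor(alpha=0.01, top_n=50))


class TestCrossValidation:
    def test_forced_separation_toy_reaches_perfect_accuracy(self):
        """Separable one-informative-gene toy, two classes: LOOCV = 1.0."""
        rng = np.random.default_rng(4)
        X = pd.DataFrame({
            "g1": np.r_[rng.normal(0, 0.1, 4), rng.normal(5, 0.1, 4)],
            "g2": rng.normal(size=8), "g3": rng.normal(size=8)})
        y = pd.Series(["A"] * 4 + ["B"] * 4)
        result = loocv(X, y, alpha=0.05, top_n=1, node_order=("A",),
                       standardize=False)
        assert result["accuracy"] == 1.0

    def test_effectless_subtype_drops_to_chance_sensitivity(self):
        """Remove one subtype's signature by nulling its genes: its LOOCV
        sensitivity collapses while the others stay high."""
        from diffgc import SimulationConfig, normalize_rnaseq, simulate_cohorts
        fx = simulate_cohorts(SimulationConfig(
            n_genes=1000, n_signature_genes_per_subtype=100,
            cohorts={"a": {s: 10 for s in ("EBV", "MSI", "GS", "CIN")}}, seed=6))
        norm = normalize_rnaseq(fx.expression)
        data = norm.data.copy()
        # erase the GS signature: replace those rows with pure noise
        rng = np.random.default_rng(0)
        gs_genes = fx.signature_genes["GS"]
        data.loc[gs_genes] = rng.normal(size=(len(gs_genes), data.shape[1]))
        X = data.T
        y = fx.truth.set_index("sample_id")["subtype"]
        result = loocv(X, y, alpha=0.001, top_n=100)
        assert result["rates"]["GS"]["sensitivity"] <= 0.5
        for s in ("EBV", "MSI"):
            assert result["rates"][s]["sensitivity"] >= 0.8

    def test_confusion_matrix_shape_and_accuracy(self):
        result = confusion_and_rates(np.array(["EBV", "MSI", "MSI"]),
                                     np.array(["EBV", "MSI", "GS"]),
                                     subtypes=("EBV", "MSI", "GS", "CIN"))
        assert result["confusion"].to_numpy().sum() == 3
        assert result["accuracy"] == pytest.approx(2 / 3)
        assert result["rates"]["MSI"]["sensitivity"] == pytest.approx(0.5)


class TestSensSpecCurve:
    def test_threshold_extremes(self):
        posteriors = np.array([0.1, 0.4, 0.6, 0.9])
        truth = np.array([False, False, True, True])
        curve = sens_spec_curve(posteriors, truth, thresholds=[0.0, 1.0 + 1e-9])
        assert curve.iloc[0]["sensitivity"] == 1.0
        assert curve.iloc[1]["sensitivity"] == 0.0
        assert curve.iloc[1]["specificity"] == 1.0

    def test_matches_brute_force_count_oracle(self):
        rng = np.random.default_rng(7)
        posteriors = rng.random(50)
        truth = rng.random(50) < 0.4
        thresholds = np.linspace(0, 1, 11)
        curve = sens_spec_curve(posteriors, truth, thresholds)
        for _, row in curve.iterrows():
            thr = row["threshold"]
            tp = sum(1 for p, t in zip(posteriors, truth) if t and p >= thr)
            tn = sum(1 for p, t in zip(posteriors, truth) if not t and p < thr)
            assert row["sensitivity"] == pytest.approx(tp / truth.sum())
            assert row["specificity"] == pytest.approx(tn / (~truth).sum())

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        curve = sens_spec_curve(rng.random(30), rng.random(30) < 0.5)
        assert (np.diff(curve["sensitivity"]) <= 1e-12).all()
        assert (np.diff(curve["specificity"]) >= -1e-12).all()

    def test_empty_truth_class_rejected(self):
        with pytest.raises(ValidationError):
            sens_spec_curve([0.5], [False])
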