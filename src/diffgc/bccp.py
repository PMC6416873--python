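"""Bayesian compound covariate prediction of the four gastric cancer
molecular subtypes (EBV, MSI, GS, CIN).

The pipeline has three layers:

1. **Subtype-specific gene panels** — for each subtype, genes whose
   two-sample t-test against *each* of the other three subtypes is
   individually significant (p < alpha) with a consistent sign of t; the
   top ``top_n`` candidates are kept, ranked by the maximum of the three
   pairwise p-values (most uniformly significant first), ties by
   descending mean |t| then gene ID.

2. **One-vs-rest Bayesian compound covariate predictor (BCCP)** — each
   sample is reduced to a compound covariate score
   ``c_j = sum_i t_i * x_ij`` over the panel, weighted by the training-set
   t-statistics. Class-conditional densities of c are Gaussian with
   class-specific means and a pooled within-class standard deviation; the
   posterior follows from Bayes' rule with configurable priors
   (default 1/2, 1/2).

3. **Decision-tree composition** — one-vs-rest nodes are evaluated in
   order (default EBV -> MSI -> GS); the first node whose posterior reaches
   the acceptance threshold labels the sample, and samples that fall
   through every node receive the terminal remainder label (CIN).

Cross-validation (:func:`loocv`) repeats gene selection *and* model
fitting inside every fold, so no information leaks from the held-out
sample into the feature panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .containers import SUBTYPES, ValidationError
from .diffexpr import pooled_ttest

DEFAULT_NODE_ORDER = ("EBV", "MSI", "GS")


# ---------------------------------------------------------------------------
# gene panels

@dataclass
class SubtypeGenePanel:
    """Genes specific to one subtype, with their pairwise test statistics."""

    subtype: str
    genes: list[str]
    records: pd.DataFrame  # per-gene t/p vs each other subtype + ranking keys


def select_subtype_genes(X: pd.DataFrame, y: pd.Series | np.ndarray,
                         alpha: float = 0.001, top_n: int = 200,
                         require_consistent_sign: bool = True
                         ) -> dict[str, SubtypeGenePanel]:
    """Select subtype-specific gene panels from samples-x-genes data.

    A gene enters subtype s's panel iff its t-test of s vs each other
    subtype individually has p < alpha (and, by default, the same sign of
    t in all three comparisons). Panels are truncated to ``top_n`` by
    ascending max pairwise p, ties by descending mean |t|, then gene ID.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), index=X.index)
    subtypes = sorted(y.unique())
    for s in subtypes:
        if (y == s).sum() < 2:
            raise ValidationError(f"subtype {s} has < 2 samples")
    values = X.to_numpy(dtype=float).T  # genes x samples
    genes = np.asarray(X.columns)
    masks = {s: (y == s).to_numpy() for s in subtypes}

    panels: dict[str, SubtypeGenePanel] = {}
    for s in subtypes:
        others = [o for o in subtypes if o != s]
        t_cols, p_cols = {}, {}
        for o in others:
            t, p = pooled_ttest(values[:, masks[s]], values[:, masks[o]])
            t_cols[o], p_cols[o] = t, p
        t_mat = np.column_stack([t_cols[o] for o in others])
        p_mat = np.column_stack([p_cols[o] for o in others])
        significant = (p_mat < alpha).all(axis=1)
        if require_consistent_sign:
            signs = np.sign(t_mat)
            significant &= (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
        idx = np.flatnonzero(significant)
        records = pd.DataFrame({
            **{f"t_vs_{o}": t_cols[o][idx] for o in others},
            **{f"p_vs_{o}": p_cols[o][idx] for o in others},
            "max_p": p_mat[idx].max(axis=1),
            "mean_abs_t": np.abs(t_mat[idx]).mean(axis=1),
        }, index=genes[idx])
        records.index.name = "gene_id"
        order = sorted(records.index,
                       key=lambda g: (records.at[g, "max_p"],
                                      -records.at[g, "mean_abs_t"], str(g)))
        records = records.loc[order].head(top_n)
        panels[s] = SubtypeGenePanel(subtype=s, genes=list(records.index),
                                     records=records)
    return panels


# ---------------------------------------------------------------------------
# one-vs-rest BCCP

class BCCPClassifier(ClassifierMixin, BaseEstimator):
    """Binary Bayesian compound covariate predictor.

    Fit on samples-x-genes data already restricted to a gene panel; ``y``
    is binary with 1 (or True) marking the positive class.

    Attributes
    ----------
    weights_ : per-gene training t-statistics (positive vs rest).
    mu_pos_, mu_neg_ : class-conditional means of the compound score.
    sigma_ : pooled within-class standard deviation of the score.
    """

    def __init__(self, priors: tuple[float, float] = (0.5, 0.5)):
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(bool)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValidationError("panel must be nonempty")
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos < 2 or n_neg < 2:
            raise ValidationError("both classes need >= 2 samples")
        if not np.isclose(sum(self.priors), 1.0):
            raise ValidationError("priors must sum to 1")
        t, _ = pooled_ttest(X[y].T, X[~y].T)
        self.weights_ = t
        scores = X @ t
        pos, neg = scores[y], scores[~y]
        self.mu_pos_ = float(pos.mean())
        self.mu_neg_ = float(neg.mean())
        pooled_var = (((n_pos - 1) * pos.var(ddof=1) + (n_neg - 1) * neg.var(ddof=1))
                      / (n_pos + n_neg - 2))
        self.sigma_ = float(np.sqrt(pooled_var))
        if self.sigma_ == 0:
            raise ValidationError("pooled sd of compound scores is zero")
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "weights_")
        return np.asarray(X, dtype=float) @ self.weights_

    def predict_proba(self, X):
        """Columns ordered as ``classes_`` ([negative, positive])."""
        c = self.decision_function(X)
        prior_pos, prior_neg = self.priors[0], self.priors[1]
        # priors stored (positive, negative); degenerate priors short-circuit
        if prior_pos in (0.0, 1.0):
            p_pos = np.full_like(c, prior_pos, dtype=float)
        else:
            log_pos = np.log(prior_pos) + sps.norm.logpdf(c, self.mu_pos_, self.sigma_)
            log_neg = np.log(prior_neg) + sps.norm.logpdf(c, self.mu_neg_, self.sigma_)
            m = np.maximum(log_pos, log_neg)
            p_pos = np.exp(log_pos - m) / (np.exp(log_pos - m) + np.exp(log_neg - m))
        return np.column_stack([1 - p_pos, p_pos])

    def posterior(self, X):
        """Positive-class posterior probability."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.posterior(X) >= 0.5


# ---------------------------------------------------------------------------
# multiclass composition

class SubtypePredictor(ClassifierMixin, BaseEstimator):
    """Four-subtype classifier: gene panels + one-vs-rest BCCPs + decision tree.

    Parameters
    ----------
    alpha, top_n:
        Panel selection threshold and size.
    node_order:
        Ordered one-vs-rest nodes; the one subtype absent from the order is
        the terminal remainder label.
    threshold:
        Node acceptance posterior (default 0.5).
    standardize:
        Z-standardize genes against frozen training means/sds before
        selection and scoring (recommended when train and test come from
        different normalization batches).
    """

    def __init__(self, alpha: float = 0.001, top_n: int = 200,
                 node_order: tuple[str, ...] = DEFAULT_NODE_ORDER,
                 threshold: float = 0.5,
                 priors: tuple[float, float] = (0.5, 0.5),
                 require_consistent_sign: bool = True,
                 standardize: bool = True):
        self.alpha = alpha
        self.top_n = top_n
        self.node_order = node_order
        self.threshold = threshold
        self.priors = priors
        self.require_consistent_sign = require_consistent_sign
        self.standardize = standardize

    def _validate_nodes(self, subtypes: list[str]) -> str:
        order = list(self.node_order)
        if len(set(order)) != len(order) or not set(order) <= set(subtypes):
            raise ValidationError(
                f"node_order {order} is not a permutation-prefix of {subtypes}")
        remainder = [s for s in subtypes if s not in order]
        if len(remainder) != 1:
            raise ValidationError(
                "node_order must leave exactly one terminal remainder subtype")
        return remainder[0]

    def fit(self, X, y):
        from .normalize import GeneStandardizer

        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y), index=X.index)
        subtypes = sorted(y.unique())
        self.remainder_ = self._validate_nodes(subtypes)
        if self.standardize:
            self.scaler_ = GeneStandardizer().fit(X.to_numpy(dtype=float))
            X = pd.DataFrame(self.scaler_.transform(X.to_numpy(dtype=float)),
                             index=X.index, columns=X.columns)
        else:
            self.scaler_ = None
        self.panels_ = select_subtype_genes(
            X, y, alpha=self.alpha, top_n=self.top_n,
            require_consistent_sign=self.require_consistent_sign)
        self.models_ = {}
        self.feature_names_in_ = np.asarray(X.columns)
        for s in subtypes:
            genes = self.panels_[s].genes
            if not genes:
                self.models_[s] = None  # empty panel: node never accepts
                continue
            self.models_[s] = BCCPClassifier(priors=self.priors).fit(
                X[genes].to_numpy(), (y == s).to_numpy())
        self.classes_ = np.asarray(subtypes)
        return self

    def _prepare(self, X) -> pd.DataFrame:
        check_is_fitted(self, "models_")
        X = pd.DataFrame(X)
        missing = set(self.feature_names_in_) - set(X.columns)
        if missing:
            raise ValidationError(f"missing genes in test data: {sorted(missing)[:5]}")
        X = X[list(self.feature_names_in_)]
        if self.scaler_ is not None:
            X = pd.DataFrame(self.scaler_.transform(X.to_numpy(dtype=float)),
                             index=X.index, columns=X.columns)
        return X

    def node_posteriors(self, X) -> pd.DataFrame:
        """One-vs-rest posterior of every fitted node (all four subtypes)."""
        X = self._prepare(X)
        out = {}
        for s, model in self.models_.items():
            if model is None:
                out[s] = np.zeros(len(X))
            else:
                out[s] = model.posterior(X[self.panels_[s].genes].to_numpy())
        return pd.DataFrame(out, index=X.index)

    def predict_calls(self, X) -> pd.DataFrame:
        """Per-sample decision-tree traversal: visited posteriors, path, label."""
        posteriors = self.node_posteriors(X)
        labels, paths = [], []
        for _, row in posteriors.iterrows():
            path = []
            label = self.remainder_
            for s in self.node_order:
                path.append(s)
                if row[s] >= self.threshold:
                    label = s
                    break
            labels.append(label)
            paths.append("->".join(path))
        calls = posteriors.copy()
        calls.columns = [f"posterior_{s}" for s in calls.columns]
        calls["label"] = labels
        calls["tree_path"] = paths
        return calls

    def predict(self, X) -> np.ndarray:
        return self.predict_calls(X)["label"].to_numpy()


# ---------------------------------------------------------------------------
# evaluation

def confusion_and_rates(y_true, y_pred, subtypes=SUBTYPES) -> dict:
    """Confusion matrix plus per-subtype sensitivity/specificity and accuracy."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    confusion = pd.DataFrame(0, index=list(subtypes), columns=list(subtypes))
    for t, p in zip(y_true, y_pred):
        confusion.at[t, p] += 1
    rates = {}
    for s in subtypes:
        is_s = y_true == s
        pred_s = y_pred == s
        sens = float((pred_s & is_s).sum() / is_s.sum()) if is_s.any() else np.nan
        spec = float((~pred_s & ~is_s).sum() / (~is_s).sum()) if (~is_s).any() else np.nan
        rates[s] = {"sensitivity": sens, "specificity": spec}
    accuracy = float((y_true == y_pred).mean())
    return {"confusion": confusion, "rates": rates, "accuracy": accuracy}


def loocv(X, y, alpha: float = 0.001, top_n: int = 200,
          node_order: tuple[str, ...] = DEFAULT_NODE_ORDER,
          threshold: float = 0.5, standardize: bool = True) -> dict:
    """Leave-one-out cross-validation with in-fold gene re-selection.

    Gene selection and model fitting are repeated on each fold's training
    portion only, so the held-out sample never influences its own feature
    panel (the key guard against selection leakage).
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), index=X.index)
    for s, n in y.value_counts().items():
        if n < 3:
            raise ValidationError(f"subtype {s} needs >= 3 samples for LOOCV")
    predictions = []
    for i in range(len(X)):
        train = np.ones(len(X), dtype=bool)
        train[i] = False
        model = SubtypePredictor(alpha=alpha, top_n=top_n, node_order=node_order,
                                 threshold=threshold, standardize=standardize)
        model.fit(X.iloc[train], y.iloc[train])
        predictions.append(model.predict(X.iloc[[i]])[0])
    result = confusion_and_rates(y.to_numpy(), np.asarray(predictions),
                                 subtypes=sorted(y.unique()))
    result["predictions"] = pd.Series(predictions, index=X.index, name="predicted")
    return result


def sens_spec_curve(posteriors, truth, thresholds=None) -> pd.DataFrame:
    """Sensitivity/specificity of a one-vs-rest posterior across thresholds.

    ``truth`` is a boolean vector of positive-class membership. Sensitivity
    is non-increasing and specificity non-decreasing in the threshold.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if not truth.any():
        raise ValidationError("empty positive truth class")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    rows = []
    for thr in thresholds:
        called = posteriors >= thr
        sens = float((called & truth).sum() / truth.sum())
        spec = float((~called & ~truth).sum() / (~truth).sum()) if (~truth).any() else np.nan
        rows.append({"threshold": float(thr), "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
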