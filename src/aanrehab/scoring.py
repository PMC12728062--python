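"""Stacked regression scoring and the online inference chain.

Training: per-task random-forest and RBF support-vector regressors are
stacked under a linear ridge meta-learner fed with out-of-fold base
predictions plus optional context variables, under subject-grouped
cross-validation (no identity leakage between folds). The meta-learner is
fitted by iteratively reweighted least squares against a weighted Huber
objective, which also serves as the model-selection criterion.

Inference: fused per-task predictions are standardized and mapped through a
monotone linear-sigmoid composite S = sigma(a * sum_m alpha_m z_m + b) in
[0, 1], optionally aligned to the individualized baseline-to-healthy
reference score via isotonic regression or Platt scaling, exponentially
smoothed, bias-corrected at session level, and accompanied by an uncertainty
estimate built from random-forest ensemble spread and the residual history.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import Ridge
from sklearn.model_selection import GroupKFold, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted

DEFAULT_TASKS = ("fma_proxy", "arat_proxy", "romn", "sparc")
#: Clinical-relevance task weights for the Huber objective.
DEFAULT_TASK_WEIGHTS = {"fma_proxy": 0.4, "arat_proxy": 0.3, "romn": 0.2,
                        "sparc": 0.1}
QUALITY_TAU = 0.9


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def huber(r, delta: float = 1.0):
    """Huber penalty H_delta(r): quadratic inside |r| <= delta, linear outside."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r <= delta, 0.5 * r**2, delta * (r - 0.5 * delta))


def weighted_huber(residuals, task_weights=None, delta: float = 1.0) -> float:
    """Weighted Huber loss summed over samples and tasks.

    ``residuals`` has shape (n_samples, n_tasks); ``task_weights`` is a
    per-task weight vector (defaults to uniform).
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    w = (np.ones(r.shape[1]) if task_weights is None
         else np.asarray(task_weights, dtype=float))
    return float(np.sum(huber(r, delta) * w))


# ---------------------------------------------------------------------------
# Stacked model
# ---------------------------------------------------------------------------


class StackedScoreRegressor(BaseEstimator, RegressorMixin):
    """Multi-task stacked regressor: RF + SVR base learners, ridge meta-learner.

    For each task (column of Y), a random forest (200 trees, depth 8, min
    leaf 5) and an RBF SVR (gamma=0.01, C=10, epsilon=0.1) are fitted; a
    ridge meta-learner (alpha=0.5) combines their out-of-fold predictions,
    plus optional context columns, into the fused task prediction. Fitting
    weights the meta-learner by a Huber IRLS scheme (delta on standardized
    residuals) times per-window quality weights.

    Cross-validation is grouped by subject when ``groups`` is passed to
    :meth:`fit`; a split in which any group appears on both sides raises.

    Attributes (after fit)
    ----------------------
    rf_models_, svr_models_ : per-task fitted base learners
    meta_models_ : per-task fitted ridge meta-learners
    oof_predictions_ : out-of-fold fused predictions used for stacking
    z_mean_, z_std_ : per-task standardization of fused predictions
    """

    def __init__(
        self,
        task_names=DEFAULT_TASKS,
        task_weights=None,
        rf_n_estimators: int = 200,
        rf_max_depth: int = 8,
        rf_min_samples_leaf: int = 5,
        svr_gamma: float = 0.01,
        svr_c: float = 10.0,
        svr_epsilon: float = 0.1,
        ridge_alpha: float = 0.5,
        huber_delta: float = 1.0,
        n_splits: int = 5,
        random_state: int = 0,
    ):
        self.task_names = task_names
        self.task_weights = task_weights
        self.rf_n_estimators = rf_n_estimators
        self.rf_max_depth = rf_max_depth
        self.rf_min_samples_leaf = rf_min_samples_leaf
        self.svr_gamma = svr_gamma
        self.svr_c = svr_c
        self.svr_epsilon = svr_epsilon
        self.ridge_alpha = ridge_alpha
        self.huber_delta = huber_delta
        self.n_splits = n_splits
        self.random_state = random_state

    # -- construction -------------------------------------------------------

    def _make_rf(self):
        return RandomForestRegressor(
            n_estimators=self.rf_n_estimators,
            max_depth=self.rf_max_depth,
            min_samples_leaf=self.rf_min_samples_leaf,
            random_state=self.random_state,
            n_jobs=1,
        )

    def _make_svr(self):
        return SVR(kernel="rbf", gamma=self.svr_gamma, C=self.svr_c,
                   epsilon=self.svr_epsilon)

    @staticmethod
    def _check_splits(splits, groups):
        """Leakage guard: no group may appear in both sides of any split."""
        for train, val in splits:
            if groups is not None:
                shared = set(np.asarray(groups)[train]) & set(
                    np.asarray(groups)[val]
                )
                if shared:
                    raise ValueError(
                        f"subject leakage: groups {sorted(shared)} present in "
                        "both train and validation folds"
                    )
            yield train, val

    def fit(self, X, Y, groups=None, sample_weight=None, context=None, cv=None):
        """Fit base learners, then the meta-learner on out-of-fold predictions.

        Parameters
        ----------
        X : (n, p) feature matrix
        Y : (n, M) multi-task labels (1-D allowed for a single task)
        groups : subject identifiers for grouped cross-validation
        sample_weight : per-window weights; windows with quality Q below the
            threshold tau should be passed weight Q/tau
        context : optional (n, k) context columns for the meta-learner
        cv : explicit list of (train_idx, val_idx) splits; validated against
            ``groups`` for leakage
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, n_tasks = Y.shape
        self.n_tasks_ = n_tasks
        context = None if context is None else np.asarray(context, dtype=float)
        sample_weight = (np.ones(n) if sample_weight is None
                         else np.asarray(sample_weight, dtype=float))

        if cv is None:
            if groups is not None:
                n_groups = len(set(np.asarray(groups).tolist()))
                splitter = GroupKFold(n_splits=min(self.n_splits, n_groups))
                cv = list(splitter.split(X, Y[:, 0], groups))
            else:
                splitter = KFold(n_splits=self.n_splits, shuffle=True,
                                 random_state=self.random_state)
                cv = list(splitter.split(X))
        cv = list(self._check_splits(cv, groups))

        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)

        oof_base = np.full((n, n_tasks, 2), np.nan)
        for train, val in cv:
            for m in range(n_tasks):
                rf = self._make_rf().fit(X[train], Y[train, m],
                                         sample_weight=sample_weight[train])
                svr = self._make_svr().fit(Xs[train], Y[train, m],
                                           sample_weight=sample_weight[train])
                oof_base[val, m, 0] = rf.predict(X[val])
                oof_base[val, m, 1] = svr.predict(Xs[val])
        seen = ~np.isnan(oof_base[:, 0, 0])

        self.rf_models_, self.svr_models_, self.meta_models_ = [], [], []
        oof_fused = np.full((n, n_tasks), np.nan)
        for m in range(n_tasks):
            rf = self._make_rf().fit(X, Y[:, m], sample_weight=sample_weight)
            svr = self._make_svr().fit(Xs, Y[:, m], sample_weight=sample_weight)
            self.rf_models_.append(rf)
            self.svr_models_.append(svr)
            Z = self._meta_inputs(oof_base[seen, m, 0], oof_base[seen, m, 1],
                                  None if context is None else context[seen])
            meta = self._fit_meta_irls(Z, Y[seen, m], sample_weight[seen])
            self.meta_models_.append(meta)
            oof_fused[seen, m] = meta.predict(Z)

        self.oof_predictions_ = oof_fused
        fused = oof_fused[seen]
        self.z_mean_ = fused.mean(axis=0)
        self.z_std_ = np.where(fused.std(axis=0) > 0, fused.std(axis=0), 1.0)
        self.n_features_in_ = X.shape[1]
        self.n_context_ = 0 if context is None else context.shape[1]
        return self

    @staticmethod
    def _meta_inputs(yhat_rf, yhat_svr, context):
        cols = [np.asarray(yhat_rf)[:, None], np.asarray(yhat_svr)[:, None]]
        if context is not None:
            cols.append(np.atleast_2d(context))
        return np.hstack(cols)

    def _fit_meta_irls(self, Z, y, base_weight, n_iter: int = 3):
        """Ridge meta-learner via Huber IRLS on standardized residuals."""
        meta = Ridge(alpha=self.ridge_alpha)
        w = base_weight.copy()
        scale = max(np.std(y), 1e-12)
        for _ in range(n_iter):
            meta.fit(Z, y, sample_weight=w)
            r = np.abs(y - meta.predict(Z)) / scale
            huber_w = np.where(r <= self.huber_delta, 1.0,
                               self.huber_delta / np.maximum(r, 1e-12))
            w = base_weight * huber_w
        return meta

    # -- inference -----------------------------------------------------------

    def _rf_predict(self, m, X):
        """Forest prediction with a direct-tree fast path for small batches.

        sklearn's ``RandomForestRegressor.predict`` loops trees with per-call
        validation overhead that dominates single-window online inference;
        averaging ``tree_.predict`` outputs is numerically identical.
        """
        rf = self.rf_models_[m]
        if X.shape[0] > 32:
            return rf.predict(X)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        acc = np.zeros(X.shape[0])
        for est in rf.estimators_:
            acc += np.asarray(est.tree_.predict(X32)).reshape(X.shape[0], -1)[:, 0]
        return acc / len(rf.estimators_)

    def predict(self, X, context=None):
        """Fused per-task predictions, shape (n, n_tasks)."""
        check_is_fitted(self, "meta_models_")
        X = np.asarray(X, dtype=float)
        Xs = self.scaler_.transform(X)
        context = None if context is None else np.asarray(context, dtype=float)
        out = np.empty((X.shape[0], self.n_tasks_))
        for m in range(self.n_tasks_):
            Z = self._meta_inputs(self._rf_predict(m, X),
                                  self.svr_models_[m].predict(Xs),
                                  context)
            out[:, m] = self.meta_models_[m].predict(Z)
        return out

    def standardize(self, Y_hat):
        """Map fused task predictions to dimensionless components z_m."""
        check_is_fitted(self, "z_mean_")
        return (np.asarray(Y_hat, dtype=float) - self.z_mean_) / self.z_std_

    def tree_score_std(self, X, alphas=None, a: float = 1.0, b: float = 0.0,
                       context=None, n_tree_sample: int = 50):
        """Ensemble spread of the composite score across random-forest trees.

        Each tree of each task forest produces a task prediction; propagating
        per-tree predictions through standardization and the composite map
        yields a distribution of scores whose standard deviation is the
        model-variance part of the uncertainty, already on the score scale.
        A subsample of ``n_tree_sample`` trees keeps the online path cheap.
        """
        check_is_fitted(self, "rf_models_")
        X32 = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        if X32.ndim == 1:
            X32 = X32[None, :]
        alphas = _check_alphas(alphas, self.n_tasks_)
        n_trees = min(len(rf.estimators_) for rf in self.rf_models_)
        step = max(1, n_trees // max(1, min(n_tree_sample, n_trees)))
        idx = range(0, n_trees, step)
        scores = np.empty((X32.shape[0], len(idx)))
        for j, t in enumerate(idx):
            Y_t = np.column_stack(
                [np.asarray(
                    self.rf_models_[m].estimators_[t].tree_.predict(X32)
                 ).reshape(X32.shape[0], -1)[:, 0]
                 for m in range(self.n_tasks_)]
            )
            z = self.standardize(Y_t)
            scores[:, j] = np.atleast_1d(composite_score(z, alphas, a=a, b=b))
        return scores.std(axis=1)

    def score(self, X, Y, context=None):
        """Mean coefficient of determination across tasks."""
        from sklearn.metrics import r2_score

        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Y_hat = self.predict(X, context=context)
        return float(np.mean([r2_score(Y[:, m], Y_hat[:, m])
                              for m in range(Y.shape[1])]))


# ---------------------------------------------------------------------------
# Composite score and reference mapping
# ---------------------------------------------------------------------------


def _check_alphas(alphas, n_tasks):
    if alphas is None:
        return np.full(n_tasks, 1.0 / n_tasks)
    alphas = np.asarray(alphas, dtype=float)
    if (alphas < 0).any():
        raise ValueError("task coefficients alpha_m must be non-negative")
    if not np.isclose(alphas.sum(), 1.0):
        raise ValueError("task coefficients alpha_m must sum to 1")
    return alphas


def composite_score(z, alphas=None, a: float = 1.0, b: float = 0.0):
    """Monotone linear-sigmoid composite S = sigma(a * sum_m alpha_m z_m + b).

    ``z`` holds standardized task components, shape (n, M) or (M,);
    ``alphas`` are non-negative task coefficients summing to 1 (default
    equal). Returns scores in (0, 1), monotone increasing in every component
    when a > 0.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    alphas = _check_alphas(alphas, z.shape[1])
    s = _sigmoid(a * z @ alphas + b)
    return s if s.size > 1 else float(s[0])


def fit_composite_calibration(z, target, alphas=None):
    """Fit the composite calibration parameters (a, b) to reference scores.

    Least-squares fit of sigma(a * g + b) to ``target`` in [0, 1], where
    g = sum_m alpha_m z_m. Returns (a, b) with a constrained positive so the
    composite stays monotone.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    alphas = _check_alphas(alphas, z.shape[1])
    g = z @ alphas
    target = np.clip(np.asarray(target, dtype=float), 1e-4, 1 - 1e-4)

    def resid(p):
        return _sigmoid(p[0] * g + p[1]) - target

    sol = least_squares(resid, x0=np.array([1.0, 0.0]),
                        bounds=([1e-6, -np.inf], [np.inf, np.inf]))
    return float(sol.x[0]), float(sol.x[1])


def reference_score(y_hat, mu_0: float, mu_ref: float):
    """Individualized baseline-to-healthy reference score.

    S_ref = clip((y_hat - mu_0) / (mu_ref - mu_0), 0, 1), where mu_0 is the
    calibration-period expectation and mu_ref the healthy-reference
    expectation of the predicted quantity.
    """
    if mu_ref == mu_0:
        raise ValueError("mu_ref must differ from mu_0")
    s = (np.asarray(y_hat, dtype=float) - mu_0) / (mu_ref - mu_0)
    s = np.clip(s, 0.0, 1.0)
    return s if s.size > 1 else float(s)


# ---------------------------------------------------------------------------
# Calibration between S and S_ref
# ---------------------------------------------------------------------------


class ScoreCalibrator:
    """Aligns composite scores with reference scores (isotonic or Platt).

    ``mode="isotonic"`` fits a monotone non-decreasing step map;
    ``mode="platt"`` fits a two-parameter sigmoid sigma(a s + b). Constant
    inputs degrade to the identity map with a warning.
    """

    def __init__(self, mode: str = "isotonic"):
        if mode not in ("isotonic", "platt"):
            raise ValueError(f"unknown calibration mode {mode!r}")
        self.mode = mode
        self.identity_ = False

    def fit(self, s, s_ref):
        s = np.asarray(s, dtype=float)
        s_ref = np.asarray(s_ref, dtype=float)
        if s.size < 20:
            raise ValueError("calibration requires at least 20 pairs")
        if np.std(s) == 0 or np.std(s_ref) == 0:
            warnings.warn("constant calibration inputs: using identity map",
                          stacklevel=2)
            self.identity_ = True
            return self
        if self.mode == "isotonic":
            self.iso_ = IsotonicRegression(y_min=0.0, y_max=1.0,
                                           out_of_bounds="clip").fit(s, s_ref)
        else:
            target = np.clip(s_ref, 1e-4, 1 - 1e-4)

            def resid(p):
                return _sigmoid(p[0] * s + p[1]) - target

            sol = least_squares(resid, x0=np.array([1.0, 0.0]))
            self.a_, self.b_ = float(sol.x[0]), float(sol.x[1])
        return self

    def predict(self, s):
        s = np.asarray(s, dtype=float)
        if self.identity_:
            out = np.clip(s, 0.0, 1.0)
        elif self.mode == "isotonic":
            out = self.iso_.predict(s)
        else:
            out = _sigmoid(self.a_ * s + self.b_)
        return out if out.size > 1 else float(out)


# ---------------------------------------------------------------------------
# Online chain: smoothing, bias, uncertainty
# ---------------------------------------------------------------------------


class ScoreSmoother:
    """Exponential smoothing S~_t = lambda S_t + (1 - lambda) S~_{t-1}.

    Initialized at the first observation; lambda in (0, 1].
    """

    def __init__(self, lam: float = 0.3):
        if not 0.0 < lam <= 1.0:
            raise ValueError("smoothing rate lambda must lie in (0, 1]")
        self.lam = lam
        self.state: float | None = None

    def update(self, s: float) -> float:
        self.state = s if self.state is None else (
            self.lam * s + (1.0 - self.lam) * self.state
        )
        return self.state

    def reset(self):
        self.state = None


def smooth_series(s, lam: float = 0.3) -> np.ndarray:
    """Vectorized exponential smoothing of a score series."""
    sm = ScoreSmoother(lam)
    return np.array([sm.update(v) for v in np.asarray(s, dtype=float)])


def bias_correct(b_t: float, session_target_mean: float,
                 session_pred_mean: float, eta: float = 0.1) -> float:
    """Session-level fusion-bias update b_{t+1} = b_t + eta (S_bar - S_hat_bar).

    Only this bias term adapts online; the base and meta learners stay fixed.
    ``eta`` must lie in (0, 1).
    """
    if not 0.0 < eta < 1.0:
        raise ValueError("bias learning rate eta must lie in (0, 1)")
    return b_t + eta * (session_target_mean - session_pred_mean)


class ResidualEMA:
    """Exponential moving average of squared residuals (SVR residual history)."""

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha
        self.state: float | None = None

    def update(self, residual: float) -> float:
        sq = float(residual) ** 2
        self.state = sq if self.state is None else (
            self.alpha * sq + (1.0 - self.alpha) * self.state
        )
        return self.state


def uncertainty(model: StackedScoreRegressor, X, residual_ema: ResidualEMA | None = None,
                alphas=None, a: float = 1.0, b: float = 0.0, context=None,
                w_tree: float = 0.5, w_resid: float = 0.5):
    """Score uncertainty from forest ensemble spread and residual history.

    sigma_t = sqrt(w_tree * Var_trees + w_resid * EMA(residual^2)); with no
    residual history the tree-variance term alone is used (weights renorm).
    """
    tree_sd = model.tree_score_std(X, alphas=alphas, a=a, b=b, context=context)
    if residual_ema is None or residual_ema.state is None:
        return tree_sd if tree_sd.size > 1 else float(tree_sd[0])
    var = w_tree * tree_sd**2 + w_resid * residual_ema.state
    out = np.sqrt(var / (w_tree + w_resid))
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Intent classification
# ---------------------------------------------------------------------------


class IntentClassifier(BaseEstimator, ClassifierMixin):
    """Binary movement-intent classifier with a linear decision function.

    f(x) = w^T x + b; f > 0 -> "active", f <= 0 -> "rest" (boundary ties
    resolve conservatively to rest). Weights can be supplied directly or
    learned with a linear-kernel SVM.
    """

    classes_ = np.array(["rest", "active"])

    def __init__(self, w=None, b: float = 0.0, c: float = 1.0):
        self.w = w
        self.b = b
        self.c = c

    def fit(self, X, y, active_label: str = "active"):
        y = np.asarray(y)
        if len(set(y.tolist())) < 2:
            raise ValueError("intent training requires both classes")
        svm = SVC(kernel="linear", C=self.c).fit(np.asarray(X, dtype=float), y)
        self.w_ = svm.coef_.ravel()
        self.b_ = float(svm.intercept_[0])
        # orient the margin so f > 0 always means "active"
        if str(svm.classes_[1]) != active_label:
            self.w_, self.b_ = -self.w_, -self.b_
        return self

    def _coefs(self):
        if self.w is not None:
            return np.asarray(self.w, dtype=float), float(self.b)
        check_is_fitted(self, "w_")
        return self.w_, self.b_

    def decision_function(self, X):
        w, b = self._coefs()
        return np.atleast_2d(np.asarray(X, dtype=float)) @ w + b

    def predict(self, X):
        margin = self.decision_function(X)
        return np.where(margin > 0, "active", "rest")


# ---------------------------------------------------------------------------
# Serving bundle
# ---------------------------------------------------------------------------


def feature_hash(feature_names) -> str:
    return hashlib.sha256(",".join(feature_names).encode()).hexdigest()[:16]


@dataclass
class ModelBundle:
    """Everything the online scorer needs: model, composite map, references.

    ``predict_score`` runs the full inference chain for a feature matrix:
    fused task predictions -> standardization -> composite sigmoid ->
    optional isotonic/Platt alignment, plus the online fusion bias.
    """

    model: StackedScoreRegressor
    feature_names: list[str]
    alphas: np.ndarray
    a: float = 1.0
    b: float = 0.0
    mu_0: float = 0.0
    mu_ref: float = 1.0
    calibrator: ScoreCalibrator | None = None
    bias: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.alphas = _check_alphas(self.alphas, len(self.alphas))

    @property
    def hash(self) -> str:
        return feature_hash(self.feature_names)

    def check_features(self, feature_names):
        if feature_hash(feature_names) != self.hash:
            raise ValueError(
                "feature-list hash mismatch between training and serving"
            )

    def predict_tasks(self, X, context=None):
        return self.model.predict(X, context=context)

    def predict_score(self, X, context=None):
        """Instantaneous composite scores S_t in [0, 1] for feature rows.

        The control-path score: sigma(a sum_m alpha_m z_m + b + bias),
        clipped to [0, 1]. The isotonic/Platt calibrator (alignment with the
        clinical reference mapping) is applied by
        :meth:`predict_calibrated_reference`, not here.
        """
        z = self.model.standardize(self.predict_tasks(X, context=context))
        s = np.atleast_1d(composite_score(z, self.alphas, a=self.a,
                                          b=self.b + self.bias))
        s = np.clip(s, 0.0, 1.0)
        return s if s.size > 1 else float(s[0])

    def predict_reference(self, X, context=None, task: int = 0,
                          mu_0: float | None = None):
        """Reference scores of the primary task via the baseline/healthy map."""
        y = self.predict_tasks(X, context=context)[:, task]
        return reference_score(y, self.mu_0 if mu_0 is None else mu_0,
                               self.mu_ref)

    def predict_calibrated_reference(self, X, context=None):
        """Composite scores aligned to the clinical reference scale."""
        if self.calibrator is None:
            raise ValueError("bundle was built without a calibrator")
        s = np.atleast_1d(self.predict_score(X, context=context))
        out = np.atleast_1d(self.calibrator.predict(s))
        return out if out.size > 1 else float(out[0])

    def uncertainty(self, X, residual_ema=None, context=None):
        return uncertainty(self.model, X, residual_ema=residual_ema,
                           alphas=self.alphas, a=self.a, b=self.b,
                           context=context)

    # -- persistence ---------------------------------------------------------

    def save(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "feature_names": list(self.feature_names),
            "feature_hash": self.hash,
            "alphas": list(map(float, self.alphas)),
            "a": self.a,
            "b": self.b,
            "mu_0": self.mu_0,
            "mu_ref": self.mu_ref,
            "bias": self.bias,
            "task_names": list(self.model.task_names),
            "metadata": self.metadata,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
        joblib.dump({"model": self.model, "calibrator": self.calibrator},
                    directory / "learners.joblib")

    @classmethod
    def load(cls, directory):
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        learners = joblib.load(directory / "learners.joblib")
        bundle = cls(
            model=learners["model"],
            feature_names=meta["feature_names"],
            alphas=np.asarray(meta["alphas"]),
            a=meta["a"], b=meta["b"], mu_0=meta["mu_0"], mu_ref=meta["mu_ref"],
            calibrator=learners["calibrator"], bias=meta["bias"],
            metadata=meta.get("metadata", {}),
        )
        if bundle.hash != meta["feature_hash"]:
            raise ValueError("stored feature hash does not match feature list")
        return bundle
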