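"""Suitability models: GLM, boosted trees, surface range envelope, MaxEnt-like.

Each algorithm is a scikit-learn-style estimator with the identical contract:

    model.fit(X, y, sample_weight=None)   # X: DataFrame/array, y: 0/1
    model.predict(X) -> suitability in [0, 1]

so that any of them (or an AUC-weighted ensemble of all of them, see
:mod:`viperarisk.evaluation`) can drive the downstream thresholding and
projection stages interchangeably.  ``predict_model`` lifts a fitted
estimator onto a predictor stack, producing a suitability raster with nodata
propagated.

The four algorithms span the classic model families of habitat-suitability
work: a parametric regression with quadratic response curves (GLM), a
machine-learning tree ensemble (GBM), a climatic envelope (SRE/BIOCLIM), and
a penalised feature-rich presence–background regression equivalent to the
maximum-entropy formulation (MaxEnt-like).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, FittingError
from .raster import PredictorStack, RasterGrid

ALGORITHMS = ("GLM", "GBM", "SRE", "MAXENT")


def _as_frame(X, names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def _check_fit_inputs(X: pd.DataFrame, y, sample_weight):
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise FittingError("labels must contain both classes 0 and 1")
    if len(X) != len(y):
        raise FittingError("X and y lengths differ")
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
    if np.any(w <= 0):
        raise FittingError("sample weights must be positive")
    return y, w


class _SuitabilityModel(BaseEstimator):
    """Shared plumbing: predictor bookkeeping + standardisation constants."""

    algorithm: str = "?"

    def _store_training_meta(self, X: pd.DataFrame) -> None:
        self.predictor_names_ = list(X.columns)
        self.mean_ = X.mean().to_numpy(dtype=float)
        self.scale_ = X.std(ddof=0).replace(0, 1.0).to_numpy(dtype=float)

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        Z = X[self.predictor_names_].to_numpy(dtype=float)
        return (Z - self.mean_) / self.scale_


class GlmSuitability(_SuitabilityModel):
    """Weighted binomial GLM with quadratic terms and stepwise-AIC selection.

    The candidate basis is {x_j, x_j²} over standardised predictors.  Search
    starts from the full model and repeatedly applies the single add/drop move
    that lowers AIC the most (ties favour the smaller model), so the selected
    model's AIC never exceeds the full model's.
    """

    algorithm = "GLM"

    def __init__(self, max_iter: int = 100):
        self.max_iter = max_iter

    def _design(self, Z: np.ndarray, terms: list[tuple[int, int]]) -> np.ndarray:
        cols = [np.ones(len(Z))]
        cols += [Z[:, j] ** p for j, p in terms]
        return np.column_stack(cols)

    def fit(self, X, y, sample_weight=None):
        X = _as_frame(X)
        y, w = _check_fit_inputs(X, y, sample_weight)
        self._store_training_meta(X)
        Z = self._standardize(X)
        p = Z.shape[1]
        all_terms = [(j, 1) for j in range(p)] + [(j, 2) for j in range(p)]

        def fit_terms(terms):
            D = self._design(Z, terms)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = sm.GLM(y, D, family=sm.families.Binomial(),
                                 freq_weights=w).fit(maxiter=self.max_iter)
                    res.aic  # force lazy evaluation while warnings are muted
                except Exception as exc:  # pragma: no cover - singular designs
                    raise FittingError(f"GLM failed to converge: {exc}") from exc
            return res

        current = list(all_terms)
        res = fit_terms(current)
        best_aic = res.aic
        self.full_aic_ = float(best_aic)
        improved = True
        while improved:
            improved = False
            candidates: list[tuple[float, int, list]] = []
            for t in current:  # drops
                trial = [u for u in current if u != t]
                candidates.append((fit_terms(trial).aic, len(trial), trial))
            for t in all_terms:  # re-adds
                if t not in current:
                    trial = current + [t]
                    candidates.append((fit_terms(trial).aic, len(trial), trial))
            if not candidates:
                break
            cand_aic, _, cand_terms = min(candidates, key=lambda c: (round(c[0], 10), c[1]))
            if cand_aic < best_aic - 1e-9:
                current, best_aic = cand_terms, cand_aic
                res = fit_terms(current)
                improved = True
        self.terms_ = current
        self.coef_ = np.asarray(res.params, dtype=float)
        self.aic_ = float(best_aic)
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X, getattr(self, "predictor_names_", None))
        Z = self._standardize(X)
        eta = self._design(Z, self.terms_) @ self.coef_
        return expit(eta)


class GbmSuitability(_SuitabilityModel):
    """Stochastic gradient-boosted classification trees (Bernoulli loss).

    Defaults follow standard practice for presence–background boosting: up to
    2500 trees, learning rate 0.001, bag fraction 0.5.
    """

    algorithm = "GBM"

    def __init__(self, n_trees: int = 2500, learning_rate: float = 0.001,
                 bag_fraction: float = 0.5, max_depth: int = 3,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.learning_rate = learning_rate
        self.bag_fraction = bag_fraction
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = _as_frame(X)
        y, w = _check_fit_inputs(X, y, sample_weight)
        self._store_training_meta(X)
        self.booster_ = GradientBoostingClassifier(
            n_estimators=self.n_trees,
            learning_rate=self.learning_rate,
            subsample=self.bag_fraction,
            max_depth=self.max_depth,
            random_state=self.random_state,
        )
        try:
            self.booster_.fit(X.to_numpy(dtype=float), y, sample_weight=w)
        except Exception as exc:
            raise FittingError(f"GBM failed: {exc}") from exc
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X, getattr(self, "predictor_names_", None))
        proba = self.booster_.predict_proba(
            X[self.predictor_names_].to_numpy(dtype=float))[:, 1]
        return np.clip(proba, 0.0, 1.0)


class SreSuitability(_SuitabilityModel):
    """Surface range envelope (BIOCLIM): rectangular presence envelope.

    Per predictor, bounds are the [q/2, 1 − q/2] linear-interpolation
    quantiles of the *presence* values, with ``q = trim_quantile`` the total
    trimmed mass (split across both tails).  Prediction is binary: 1 iff
    every predictor lies within its bounds.
    """

    algorithm = "SRE"

    def __init__(self, trim_quantile: float = 0.05):
        self.trim_quantile = trim_quantile

    def fit(self, X, y, sample_weight=None):
        if not 0 <= self.trim_quantile < 1:
            raise ConfigurationError("trim_quantile must be in [0, 1)")
        X = _as_frame(X)
        y, _ = _check_fit_inputs(X, y, sample_weight)
        if int((y == 1).sum()) < 2:
            raise FittingError("SRE needs at least two presence rows")
        self._store_training_meta(X)
        P = X.loc[np.asarray(y) == 1].to_numpy(dtype=float)
        half = self.trim_quantile / 2.0
        self.lower_ = np.quantile(P, half, axis=0, method="linear")
        self.upper_ = np.quantile(P, 1 - half, axis=0, method="linear")
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X, getattr(self, "predictor_names_", None))
        V = X[self.predictor_names_].to_numpy(dtype=float)
        inside = (V >= self.lower_) & (V <= self.upper_)
        return inside.all(axis=1).astype(float)

    @property
    def bounds_(self) -> dict[str, tuple[float, float]]:
        return {n: (float(l), float(u)) for n, l, u in
                zip(self.predictor_names_, self.lower_, self.upper_)}


def _hinge_features(Z: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Forward and reverse hinges at per-predictor knots; outputs in [0, 1]."""
    feats = []
    for j in range(Z.shape[1]):
        z = Z[:, j]
        for k in knots[j]:
            feats.append(np.maximum(z - k, 0.0))
            feats.append(np.maximum(k - z, 0.0))
    return np.column_stack(feats) if feats else np.empty((len(Z), 0))


class MaxentSuitability(_SuitabilityModel):
    """L1-penalised presence–background logistic model over rich features.

    Features over standardised predictors: linear, quadratic, all pairwise
    products, and forward/reverse hinges at ``n_knots`` per-predictor
    quantile knots (optionally step/threshold indicators).  This penalised
    logistic formulation is the standard equivalent of the maximum-entropy
    estimator for presence–background data; ``reg_multiplier`` scales the
    penalty (1.0 = default regularisation) and the solver is capped at
    ``max_iterations``.
    """

    algorithm = "MAXENT"

    def __init__(self, max_iterations: int = 200, n_knots: int = 5,
                 reg_multiplier: float = 1.0, use_threshold_features: bool = False):
        self.max_iterations = max_iterations
        self.n_knots = n_knots
        self.reg_multiplier = reg_multiplier
        self.use_threshold_features = use_threshold_features

    def _features(self, Z: np.ndarray) -> np.ndarray:
        cols = [Z, Z**2]
        prods = [Z[:, [a]] * Z[:, [b]]
                 for a, b in combinations(range(Z.shape[1]), 2)]
        if prods:
            cols.append(np.column_stack(prods))
        cols.append(_hinge_features(Z, self.knots_))
        if self.use_threshold_features:
            thr = []
            for j in range(Z.shape[1]):
                for k in self.knots_[j]:
                    thr.append((Z[:, j] > k).astype(float))
            cols.append(np.column_stack(thr))
        return np.column_stack(cols)

    def fit(self, X, y, sample_weight=None):
        X = _as_frame(X)
        y, w = _check_fit_inputs(X, y, sample_weight)
        self._store_training_meta(X)
        Z = self._standardize(X)
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        self.knots_ = np.quantile(Z, qs, axis=0).T  # (p, n_knots)
        F = self._features(Z)
        self.feature_scale_ = np.where(F.std(axis=0) == 0, 1.0, F.std(axis=0))
        F = F / self.feature_scale_
        # large intercept_scaling ≈ unpenalised intercept, as in the
        # maximum-entropy formulation where the normaliser is free
        self.clf_ = LogisticRegression(
            penalty="l1", C=1.0 / self.reg_multiplier, solver="liblinear",
            max_iter=self.max_iterations, intercept_scaling=100.0,
            random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.clf_.fit(F, y, sample_weight=w)
            except Exception as exc:
                raise FittingError(f"MAXENT failed: {exc}") from exc
        self.n_active_features_ = int(np.sum(self.clf_.coef_ != 0))
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_frame(X, getattr(self, "predictor_names_", None))
        Z = self._standardize(X)
        F = self._features(Z) / self.feature_scale_
        return self.clf_.predict_proba(F)[:, 1]


def make_model(algorithm: str, seed: int = 0, **kwargs) -> _SuitabilityModel:
    """Factory: algorithm name → fresh unfitted estimator."""
    alg = algorithm.upper()
    if alg == "GLM":
        return GlmSuitability(**kwargs)
    if alg == "GBM":
        return GbmSuitability(random_state=seed, **kwargs)
    if alg == "SRE":
        return SreSuitability(**kwargs)
    if alg == "MAXENT":
        return MaxentSuitability(**kwargs)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def default_models(seed: int = 0) -> dict[str, _SuitabilityModel]:
    """The standard four-model battery keyed by algorithm name."""
    return {alg: make_model(alg, seed=seed) for alg in ALGORITHMS}


def clone_model(model: _SuitabilityModel) -> _SuitabilityModel:
    return clone(model)


def serialize_model(model: _SuitabilityModel, blob_dir=None) -> dict:
    """Fitted model → JSON-able manifest dict.

    GLM, SRE and MaxEnt-like payloads are plain numbers; the boosted-tree
    model stores its estimator as a joblib blob in ``blob_dir`` (required for
    GBM) and records the file name.
    """
    base = {
        "algorithm": model.algorithm,
        "settings": model.get_params(),
        "predictor_names": model.predictor_names_,
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
    }
    if isinstance(model, GlmSuitability):
        base["payload"] = {"terms": [list(t) for t in model.terms_],
                           "coef": model.coef_.tolist(), "aic": model.aic_}
    elif isinstance(model, SreSuitability):
        base["payload"] = {"lower": model.lower_.tolist(),
                           "upper": model.upper_.tolist()}
    elif isinstance(model, MaxentSuitability):
        base["payload"] = {
            "knots": model.knots_.tolist(),
            "feature_scale": model.feature_scale_.tolist(),
            "coef": model.clf_.coef_.ravel().tolist(),
            "intercept": float(model.clf_.intercept_[0]),
        }
    elif isinstance(model, GbmSuitability):
        import joblib

        if blob_dir is None:
            raise ConfigurationError("GBM serialization needs a blob_dir")
        from pathlib import Path

        blob = Path(blob_dir) / "gbm_booster.joblib"
        joblib.dump(model.booster_, blob)
        base["payload"] = {"blob": blob.name}
    else:
        raise ConfigurationError(f"cannot serialize {type(model).__name__}")
    return base


def deserialize_model(manifest: dict, blob_dir=None) -> _SuitabilityModel:
    """Inverse of :func:`serialize_model`."""
    model = make_model(manifest["algorithm"])
    model.set_params(**manifest["settings"])
    model.predictor_names_ = list(manifest["predictor_names"])
    model.mean_ = np.asarray(manifest["mean"], dtype=float)
    model.scale_ = np.asarray(manifest["scale"], dtype=float)
    payload = manifest["payload"]
    if isinstance(model, GlmSuitability):
        model.terms_ = [tuple(t) for t in payload["terms"]]
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.aic_ = payload["aic"]
    elif isinstance(model, SreSuitability):
        model.lower_ = np.asarray(payload["lower"], dtype=float)
        model.upper_ = np.asarray(payload["upper"], dtype=float)
    elif isinstance(model, MaxentSuitability):
        model.knots_ = np.asarray(payload["knots"], dtype=float)
        model.feature_scale_ = np.asarray(payload["feature_scale"], dtype=float)
        clf = LogisticRegression()
        clf.classes_ = np.array([0, 1])
        clf.coef_ = np.asarray([payload["coef"]], dtype=float)
        clf.intercept_ = np.asarray([payload["intercept"]], dtype=float)
        model.clf_ = clf
    elif isinstance(model, GbmSuitability):
        import joblib

        if blob_dir is None:
            raise ConfigurationError("GBM deserialization needs a blob_dir")
        from pathlib import Path

        model.booster_ = joblib.load(Path(blob_dir) / payload["blob"])
    return model


def predict_model(model, stack: PredictorStack) -> RasterGrid:
    """Predict a fitted model over every valid cell of a stack.

    Returns a suitability raster in [0, 1]; nodata cells stay masked.  The
    standardisation constants stored at fit time are reused, so projecting
    onto a future stack keeps the training scale.
    """
    names = list(model.predictor_names_)
    missing = [n for n in names if n not in stack]
    if missing:
        raise ConfigurationError(f"stack lacks model predictors {missing}")
    ref = stack.reference
    valid = ~stack.nodata_mask
    X = pd.DataFrame({n: stack[n].values[valid] for n in names})
    preds = np.clip(model.predict(X), 0.0, 1.0)
    out_vals = np.zeros(ref.shape)
    out_vals[valid] = preds
    return RasterGrid(out_vals, ref.origin_lon, ref.origin_lat, ref.cell_size,
                      stack.nodata_mask.copy())
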