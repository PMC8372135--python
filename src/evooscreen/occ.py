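"""One-class classifiers for EVOO authentication.

All five algorithms share one contract: fit on EVOO feature vectors only,
then emit a nonnegative *class distance* for any query vector — larger
means less EVOO-like.  The algorithms are

* SIMCA — PCA of the target class with the combined normalized distance
  d = sqrt((q/q0)^2 + (h/h0)^2), where q is the orthogonal (residual)
  distance, h the Hotelling score leverage, and q0, h0 their training
  means;
* PCA residual — the raw Q statistic (squared residual norm);
* kNN — mean Euclidean distance to the k nearest training vectors;
* Mahalanobis — with shrinkage of the covariance toward a scaled
  identity, required because spectra have far more wavelengths than there
  are EVOO training samples;
* one-class SVM — RBF kernel, "automatic" bandwidth via the median
  heuristic, reporting the decision-function deficit so that in-class
  points score exactly zero.

Hyperparameters (number of components, number of neighbours) are chosen
by an inner five-fold cross-validation grouped by sample, so that all
replicate measurements of one oil stay in one fold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist
from sklearn.svm import OneClassSVM

from .errors import ConditioningError, ConfigError, SplitError
from .preprocess import PreprocessSpec
from .spectra import Sensor


class Algorithm(str, enum.Enum):
    SIMCA = "SIMCA"
    KNN = "KNN"
    PCA_RESIDUAL = "PCA_RESIDUAL"
    MAHALANOBIS = "MAHALANOBIS"
    OCSVM_RBF = "OCSVM_RBF"


#: inner-CV hyperparameter candidates, in increasing complexity order
#: (the tie-break prefers the earlier, i.e. simpler, candidate)
DEFAULT_CANDIDATES: dict[Algorithm, list[dict]] = {
    Algorithm.SIMCA: [{"n_components": k} for k in (1, 2, 3, 5)],
    Algorithm.PCA_RESIDUAL: [{"n_components": k} for k in (1, 2, 3, 5)],
    Algorithm.KNN: [{"k_neighbors": k} for k in (1, 3, 5)],
    Algorithm.MAHALANOBIS: [{"regularization": 1e-3}],
    Algorithm.OCSVM_RBF: [{"nu": 0.1, "gamma": "auto"}],
}


def _center_scale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return mean, sd


class _PCABase:
    """Shared mean-centred PCA machinery (no scaling: SNV-type
    preprocessing already normalizes rows)."""

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ConfigError("n_components must be >= 1")
        self.n_components = n_components

    def _fit_pca(self, X: np.ndarray) -> None:
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ConfigError(
                f"n_components={self.n_components} exceeds min(n-1, p)="
                f"{min(n - 1, p)}"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.loadings_ = Vt[: self.n_components].T            # p x a
        T = Xc @ self.loadings_
        self.score_var_ = T.var(axis=0, ddof=1)
        self.score_var_ = np.where(self.score_var_ > 1e-30,
                                   self.score_var_, 1.0)
        # absolute floor for "numerically zero" residuals, tied to the
        # overall scale of the training cloud
        self._q_eps = 1e-12 * max(float((Xc * Xc).sum(axis=1).mean()), 1e-30)
        self._train_qh = self._qh(X)

    def _qh(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Xc = np.atleast_2d(np.asarray(X, dtype=float)) - self.mean_
        T = Xc @ self.loadings_
        resid = Xc - T @ self.loadings_.T
        q = (resid * resid).sum(axis=1)
        h = (T * T / self.score_var_).sum(axis=1)
        return q, h


class SimcaModel(_PCABase):
    """Soft independent modelling of class analogies (one class)."""

    def fit(self, X: np.ndarray) -> "SimcaModel":
        self._fit_pca(np.asarray(X, dtype=float))
        q, h = self._train_qh
        self.q0_ = float(q.mean())
        self.h0_ = float(h.mean())
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        q, h = self._qh(X)
        if self.q0_ > self._q_eps:
            qterm = q / self.q0_
        else:
            # training residuals are numerically zero: any residual beyond
            # round-off is decisively out of the model plane
            qterm = np.where(q <= self._q_eps, 0.0, q / self._q_eps)
        hterm = h / self.h0_ if self.h0_ > 1e-30 else np.zeros_like(h)
        return np.sqrt(qterm ** 2 + hterm ** 2)


class PcaResidualModel(_PCABase):
    """Q-residual distance: squared norm of the part of x outside the
    retained principal-component subspace."""

    def fit(self, X: np.ndarray) -> "PcaResidualModel":
        self._fit_pca(np.asarray(X, dtype=float))
        self.q0_ = float(self._train_qh[0].mean())
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        return self._qh(X)[0]

    def cv_distance(self, X: np.ndarray) -> np.ndarray:
        # scale-aware objective for component selection: raw Q shrinks
        # monotonically with more components, so CV compares it to the
        # training-fold mean instead
        q = self._qh(X)[0]
        if self.q0_ > self._q_eps:
            return q / self.q0_
        return np.where(q <= self._q_eps, 0.0, q / self._q_eps)


class KnnModel:
    """Mean Euclidean distance to the k nearest EVOO training vectors."""

    def __init__(self, k_neighbors: int):
        if k_neighbors < 1:
            raise ConfigError("k_neighbors must be >= 1")
        self.k_neighbors = k_neighbors

    def fit(self, X: np.ndarray) -> "KnnModel":
        X = np.asarray(X, dtype=float)
        if self.k_neighbors > X.shape[0]:
            raise ConfigError("k_neighbors exceeds the training size")
        self.train_ = X
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        D = cdist(np.atleast_2d(X), self.train_)
        k = self.k_neighbors
        nearest = np.partition(D, k - 1, axis=1)[:, :k]
        return nearest.mean(axis=1)


class MahalanobisModel:
    """Mahalanobis distance with shrinkage Sigma + lam*tr(Sigma)/p * I.

    ``standardize`` (default on) divides features by their training
    standard deviation first, purely for numerical conditioning.
    """

    def __init__(self, regularization: float = 1e-3, standardize: bool = True):
        if regularization < 0:
            raise ConfigError("regularization must be >= 0")
        self.regularization = regularization
        self.standardize = standardize

    def fit(self, X: np.ndarray) -> "MahalanobisModel":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ConfigError("need at least 2 training vectors")
        if self.standardize:
            self.mu_, self.sd_ = _center_scale(X)
            X = (X - self.mu_) / self.sd_
            self.center_ = np.zeros(X.shape[1])
        else:
            self.mu_, self.sd_ = None, None
            self.center_ = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        p = cov.shape[0]
        lam = self.regularization * np.trace(cov) / p
        cov_shrunk = cov + lam * np.eye(p)
        try:
            self._chol = cho_factor(cov_shrunk)
        except np.linalg.LinAlgError as exc:
            raise ConditioningError(
                "covariance singular even after shrinkage"
            ) from exc
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardize:
            X = (X - self.mu_) / self.sd_
        V = X - self.center_
        sol = cho_solve(self._chol, V.T)
        d2 = (V.T * sol).sum(axis=0)
        return np.sqrt(np.maximum(d2, 0.0))


class OcsvmModel:
    """One-class SVM with RBF kernel.

    gamma="auto" uses the median heuristic gamma = 1/(2 sigma^2) with
    sigma^2 the median squared pairwise training distance.  The reported
    distance is max(0, rho - f(x)), the deficit of the decision function,
    so points inside the learned boundary score exactly 0.
    """

    def __init__(self, nu: float = 0.1, gamma: float | str = "auto",
                 standardize: bool = True):
        if not 0.0 < nu < 1.0:
            raise ConfigError("nu must lie in (0, 1)")
        if gamma != "auto" and (not np.isscalar(gamma) or gamma <= 0):
            raise ConfigError("gamma must be positive or 'auto'")
        self.nu = nu
        self.gamma = gamma
        self.standardize = standardize

    def fit(self, X: np.ndarray) -> "OcsvmModel":
        X = np.asarray(X, dtype=float)
        if self.standardize:
            self.mu_, self.sd_ = _center_scale(X)
            X = (X - self.mu_) / self.sd_
        if self.gamma == "auto":
            sq = pdist(X, "sqeuclidean")
            med = float(np.median(sq)) if sq.size else 0.0
            if med <= 0:
                raise ConditioningError(
                    "degenerate kernel: all training points identical"
                )
            gamma = 1.0 / (2.0 * med)
        else:
            gamma = float(self.gamma)
        self.gamma_ = gamma
        self._svm = OneClassSVM(kernel="rbf", nu=self.nu, gamma=gamma).fit(X)
        return self

    def distance(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardize:
            X = (X - self.mu_) / self.sd_
        return np.maximum(0.0, -self._svm.decision_function(X))


_ESTIMATORS = {
    Algorithm.SIMCA: SimcaModel,
    Algorithm.KNN: KnnModel,
    Algorithm.PCA_RESIDUAL: PcaResidualModel,
    Algorithm.MAHALANOBIS: MahalanobisModel,
    Algorithm.OCSVM_RBF: OcsvmModel,
}


def make_estimator(algorithm: Algorithm, **hyperparams):
    return _ESTIMATORS[Algorithm(algorithm)](**hyperparams)


# thin functional wrappers over the estimator classes --------------------

def fit_simca(train: np.ndarray, n_components: int) -> SimcaModel:
    return SimcaModel(n_components).fit(train)


def simca_distance(model: SimcaModel, x: np.ndarray) -> float:
    return float(model.distance(np.atleast_2d(x))[0])


def fit_knn_occ(train: np.ndarray, k_neighbors: int) -> KnnModel:
    return KnnModel(k_neighbors).fit(train)


def knn_distance(model: KnnModel, x: np.ndarray) -> float:
    return float(model.distance(np.atleast_2d(x))[0])


def fit_pca_residual(train: np.ndarray, n_components: int) -> PcaResidualModel:
    return PcaResidualModel(n_components).fit(train)


def q_residual(model: PcaResidualModel, x: np.ndarray) -> float:
    return float(model.distance(np.atleast_2d(x))[0])


def fit_mahalanobis(train: np.ndarray, regularization: float = 1e-3,
                    standardize: bool = True) -> MahalanobisModel:
    return MahalanobisModel(regularization, standardize).fit(train)


def maha_distance(model: MahalanobisModel, x: np.ndarray) -> float:
    return float(model.distance(np.atleast_2d(x))[0])


def fit_ocsvm(train: np.ndarray, nu: float = 0.1,
              gamma: float | str = "auto") -> OcsvmModel:
    return OcsvmModel(nu, gamma).fit(train)


def ocsvm_distance(model: OcsvmModel, x: np.ndarray) -> float:
    return float(model.distance(np.atleast_2d(x))[0])


# ---------------------------------------------------------------------------
# model spec / trained model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OCCModelSpec:
    """A (sensor, preprocessing chain, algorithm) grid point."""

    sensor: Sensor
    preprocess: PreprocessSpec
    algorithm: Algorithm

    @property
    def key(self) -> str:
        return f"{self.sensor.value}:{self.preprocess.key}:{self.algorithm.value}"

    @classmethod
    def from_key(cls, key: str) -> "OCCModelSpec":
        sensor, pp, algo = key.split(":")
        return cls(Sensor(sensor), PreprocessSpec.from_key(pp), Algorithm(algo))


@dataclass
class TrainedOCCModel:
    """A fitted grid point plus its cross-validated distance calibration."""

    spec: OCCModelSpec
    estimator: object
    hyperparams: dict
    calibration_distances: np.ndarray     # grouped-CV per-sample distances
    calibration_sample_ids: list[str]
    threshold: float

    @property
    def calibration_summary(self) -> dict:
        d = self.calibration_distances
        return {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            "q50": float(np.quantile(d, 0.5)),
            "q95": float(np.quantile(d, 0.95)),
            "max": float(np.max(d)),
        }

    def distance(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.distance(X)


def _grouped_folds(sample_ids: np.ndarray, n_folds: int,
                   seed: int) -> list[np.ndarray]:
    """Partition unique sample ids into n_folds seeded folds; returns row
    masks.  All measurements of one sample land in one fold."""
    unique = np.unique(sample_ids)
    if unique.size < n_folds:
        raise SplitError(
            f"grouped CV needs >= {n_folds} distinct samples, got {unique.size}"
        )
    order = np.random.default_rng(seed).permutation(unique)
    return [np.isin(sample_ids, part)
            for part in np.array_split(order, n_folds)]


def _cv_distance(estimator, X: np.ndarray) -> np.ndarray:
    fn = getattr(estimator, "cv_distance", None)
    return fn(X) if fn is not None else estimator.distance(X)


def inner_cv_select(
    algorithm: Algorithm,
    X: np.ndarray,
    sample_ids: np.ndarray,
    candidate_grid: list[dict] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> dict:
    """Five-fold grouped CV hyperparameter selection.

    Picks the candidate minimizing the mean held-out EVOO class distance;
    exact ties go to the earlier (simpler) candidate.  A single candidate
    is returned unchanged without fitting.
    """
    algorithm = Algorithm(algorithm)
    candidates = candidate_grid or DEFAULT_CANDIDATES[algorithm]
    if len(candidates) == 1:
        return dict(candidates[0])
    folds = _grouped_folds(np.asarray(sample_ids), n_folds, seed)
    scores = []
    for cand in candidates:
        fold_means = []
        for mask in folds:
            if mask.all() or not mask.any():
                continue
            try:
                est = make_estimator(algorithm, **cand).fit(X[~mask])
            except ConfigError:
                fold_means.append(np.inf)
                continue
            fold_means.append(float(np.mean(_cv_distance(est, X[mask]))))
        scores.append(float(np.mean(fold_means)))
    best = int(np.argmin(scores))      # argmin is stable: first minimum wins
    return dict(candidates[best])


def cross_validated_distances(
    algorithm: Algorithm,
    hyperparams: dict,
    X: np.ndarray,
    sample_ids: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Held-out distance for every training measurement, from grouped CV
    with the chosen hyperparameters (never resubstitution)."""
    folds = _grouped_folds(np.asarray(sample_ids), n_folds, seed)
    out = np.empty(X.shape[0])
    for mask in folds:
        est = make_estimator(algorithm, **hyperparams).fit(X[~mask])
        out[mask] = est.distance(X[mask])
    return out


def train_occ_model(
    spec: OCCModelSpec,
    X: np.ndarray,
    sample_ids: np.ndarray,
    candidate_grid: list[dict] | None = None,
    seed: int = 0,
) -> TrainedOCCModel:
    """Full training of one grid point on EVOO features.

    Runs the inner CV, refits on all rows, and calibrates per-sample
    distances from grouped five-fold CV.  The initial threshold is the
    no-false-negative rule: just above the largest calibrated per-sample
    distance (scenario tuning may overwrite it later).
    """
    sample_ids = np.asarray(sample_ids)
    hyper = inner_cv_select(spec.algorithm, X, sample_ids, candidate_grid,
                            seed=seed)
    est = make_estimator(spec.algorithm, **hyper).fit(X)
    per_meas = cross_validated_distances(
        spec.algorithm, hyper, X, sample_ids, seed=seed
    )
    ids = []
    per_sample = []
    for sid in np.unique(sample_ids):
        ids.append(str(sid))
        per_sample.append(float(per_meas[sample_ids == sid].mean()))
    per_sample = np.asarray(per_sample)
    threshold = max(float(per_sample.max()) * (1.0 + 1e-6), 1e-12)
    return TrainedOCCModel(spec, est, hyper, per_sample, ids, threshold)


__all__ = [
    "Algorithm", "OCCModelSpec", "TrainedOCCModel", "DEFAULT_CANDIDATES",
    "SimcaModel", "KnnModel", "PcaResidualModel", "MahalanobisModel",
    "OcsvmModel", "make_estimator", "inner_cv_select",
    "cross_validated_distances", "train_occ_model",
    "fit_simca", "simca_distance", "fit_knn_occ", "knn_distance",
    "fit_pca_residual", "q_residual", "fit_mahalanobis", "maha_distance",
    "fit_ocsvm", "ocsvm_distance",
]
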