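"""The logistic scoring function and its parametrisation.

A candidate binding window R is scored linearly on its three local biases,

    S_F(R) = lambda1 * delta_id + lambda2 * delta_a + lambda3 * delta_h + gamma,

and the probability that the region folds upon binding (disorder-to-order
transition) is the logistic transform

    p_DO(R) = exp(S_F) / (1 + exp(S_F)).

The coefficients are estimated by maximum likelihood on labelled regions:
1 for regions that fold upon binding in every known complex, 0 for regions
that remain disordered in every complex. Context-dependent regions are
excluded from training. Fitting is Newton/IRLS with analytic standard
errors; complete separation is detected and handled by a small ridge with a
warning, since the unpenalised MLE then diverges.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
from scipy.special import expit

from .features import BiasFeatures, FeatureConfig
from .io import read_model_json, write_model_json

MAX_ITER = 100
LL_TOL = 1e-8
RIDGE_DEFAULT = 1e-4


class FitError(ValueError):
    """Fitting cannot proceed (degenerate input)."""


class ConfigMismatchError(ValueError):
    """Model parameters and features were produced under different configs."""


class SeparationWarning(UserWarning):
    """Complete separation detected; ridge fallback engaged."""


@dataclass(frozen=True)
class ModelParams:
    """Logistic coefficients for (delta_id, delta_a, delta_h) plus intercept.

    ``feature_config`` records how the features the model was trained on
    were computed, so parameters and features can never be silently mixed.
    """

    lambda1: float
    lambda2: float
    lambda3: float
    gamma: float
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    provenance: dict = field(default_factory=dict)

    def coefficients(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])

    def to_dict(self) -> dict:
        return {
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "gamma": self.gamma,
            "feature_config": self.feature_config.to_dict(),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            lambda1=float(d["lambda1"]),
            lambda2=float(d["lambda2"]),
            lambda3=float(d["lambda3"]),
            gamma=float(d["gamma"]),
            feature_config=FeatureConfig.from_dict(d.get("feature_config", {})),
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        write_model_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(read_model_json(path))


@dataclass(frozen=True)
class TrainingExample:
    """One labelled region: features plus a binary transition label.

    label 1 = disorder-to-order region, 0 = disorder-to-disorder region.
    One example per region (not per residue). Context-dependent regions are
    never used for training.
    """

    features: BiasFeatures
    label: int
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def score_region(
    features: BiasFeatures,
    params: ModelParams,
    *,
    feature_config: FeatureConfig | None = None,
) -> float:
    """Linear score S_F of one window.

    If the caller supplies the configuration its features were computed
    under, it is checked against the model's.
    """
    if feature_config is not None and feature_config != params.feature_config:
        raise ConfigMismatchError(
            "feature configuration does not match the one the model was "
            f"trained with: {feature_config} vs {params.feature_config}"
        )
    return float(
        params.lambda1 * features.delta_id
        + params.lambda2 * features.delta_a
        + params.lambda3 * features.delta_h
        + params.gamma
    )


def pdo_from_score(s: float | np.ndarray) -> float | np.ndarray:
    """Disorder-to-order probability p_DO = logistic(S_F), overflow-safe."""
    out = expit(s)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def _design_matrix(examples: list[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array(
        [
            [e.features.delta_id, e.features.delta_a, e.features.delta_h, 1.0]
            for e in examples
        ]
    )
    y = np.array([e.label for e in examples], dtype=float)
    return X, y


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1+e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Newton/IRLS for logistic regression. Returns
    (beta, covariance, log-likelihood, converged, iterations)."""
    n, p = X.shape
    beta = np.zeros(p)
    ll_old = _log_likelihood(X, y, beta) - 0.5 * ridge * beta @ beta
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1.0 - mu)
        hessian = (X * w[:, None]).T @ X + ridge * np.eye(p)
        grad = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(hessian, grad)
        except np.linalg.LinAlgError as exc:  # singular information matrix
            raise FitError(f"information matrix singular at iteration {it}") from exc
        beta = beta + step
        ll = _log_likelihood(X, y, beta) - 0.5 * ridge * beta @ beta
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    mu = expit(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X + ridge * np.eye(X.shape[1])
    cov = np.linalg.inv(info)
    return beta, cov, _log_likelihood(X, y, beta), converged, it


def _separated(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> bool:
    """Complete separation: the current direction classifies perfectly and
    the likelihood is still climbing (coefficients diverging)."""
    eta = X @ beta
    perfect = np.all((eta > 0) == (y == 1)) and np.all(eta != 0)
    return bool(perfect and np.abs(beta).max() > 15.0)


@dataclass(frozen=True)
class FitDiagnostics:
    log_likelihood: float
    converged: bool
    iterations: int
    standard_errors: np.ndarray
    covariance: np.ndarray
    ridge: float
    separation_detected: bool
    n_examples: int
    n_positive: int


def fit_logistic_design(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = 0.0,
    tol: float = LL_TOL,
    max_iter: int = MAX_ITER,
    min_per_class: int = 10,
) -> tuple[np.ndarray, FitDiagnostics]:
    """Maximum-likelihood logistic fit on an arbitrary design matrix.

    Plain Newton/IRLS; convergence when the log-likelihood changes by less
    than ``tol`` or after ``max_iter`` iterations. On complete separation
    (where the MLE diverges) a small ridge (1e-4) is engaged automatically
    with a :class:`SeparationWarning`. Standard errors come from the
    inverse observed information at the optimum.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise FitError("non-finite feature values in training examples")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise FitError(
            "both disorder-to-order (1) and disorder-to-disorder (0) labels "
            f"are required; got {n_pos} positive / {n_neg} negative"
        )
    if min(n_pos, n_neg) < min_per_class:
        raise FitError(
            f"need at least {min_per_class} examples per class; got "
            f"{n_pos} positive / {n_neg} negative"
        )

    separation = False
    beta, cov, ll, converged, it = _irls(X, y, ridge, tol, max_iter)
    if ridge == 0.0 and _separated(X, y, beta):
        separation = True
        warnings.warn(
            "complete separation detected: the unpenalised MLE diverges; "
            f"refitting with ridge={RIDGE_DEFAULT}",
            SeparationWarning,
            stacklevel=2,
        )
        ridge = RIDGE_DEFAULT
        beta, cov, ll, converged, it = _irls(X, y, ridge, tol, max_iter)
    if not converged and not separation:
        raise FitError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll:.6g}); inspect features for scaling "
            "problems or near-separation"
        )
    diag = FitDiagnostics(
        log_likelihood=ll,
        converged=converged,
        iterations=it,
        standard_errors=np.sqrt(np.diag(cov)),
        covariance=cov,
        ridge=ridge,
        separation_detected=separation,
        n_examples=len(y),
        n_positive=n_pos,
    )
    return beta, diag


def fit_params(
    examples: list[TrainingExample],
    *,
    feature_config: FeatureConfig = FeatureConfig(),
    ridge: float = 0.0,
    tol: float = LL_TOL,
    max_iter: int = MAX_ITER,
    min_per_class: int = 10,
    provenance: dict | None = None,
) -> tuple[ModelParams, FitDiagnostics]:
    """Maximum-likelihood fit of the scoring coefficients on labelled
    regions; see :func:`fit_logistic_design` for the numerical contract."""
    X, y = _design_matrix(examples)
    beta, diag = fit_logistic_design(
        X, y, ridge=ridge, tol=tol, max_iter=max_iter, min_per_class=min_per_class
    )

    prov = dict(provenance or {})
    prov.setdefault("date", date.today().isoformat())
    prov.setdefault("training_set_hash", _examples_hash(examples))
    prov.setdefault("n_examples", len(examples))
    params = ModelParams(
        lambda1=float(beta[0]),
        lambda2=float(beta[1]),
        lambda3=float(beta[2]),
        gamma=float(beta[3]),
        feature_config=feature_config,
        provenance=prov,
    )
    return params, diag


def _examples_hash(examples: list[TrainingExample]) -> str:
    h = hashlib.sha256()
    for e in examples:
        h.update(
            f"{e.features.delta_id:.12g},{e.features.delta_a:.12g},"
            f"{e.features.delta_h:.12g},{e.label};".encode()
        )
    return h.hexdigest()[:16]


def default_params() -> ModelParams:
    """The packaged default model.

    Fitted on synthetic labelled regions (see the model file's provenance
    block); it exercises the full pipeline but is **non-canonical** — for
    benchmark-quality predictions train on curated regions with external
    disorder scores and load that model instead.
    """
    path = Path(__file__).parent / "data" / "default_model.json"
    return ModelParams.load(path)
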