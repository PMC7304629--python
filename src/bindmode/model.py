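"""Model/Results interface over the logistic scoring core.

:class:`BindingModeModel` is constructed from labelled region features
(directly, from :class:`~bindmode.scoring.TrainingExample` lists, or from a
DataFrame); ``fit()`` returns a :class:`BindingModeResults` carrying the
estimated coefficients, their standard errors and confidence intervals,
fit diagnostics and a ``summary()`` table. Prediction — window scores,
per-residue profiles, landscape classes — hangs off the results object.

    >>> model = BindingModeModel.from_examples(examples)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> profiles = res.profile(seq, disorder_profile)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .disorder import builtin_disorder
from .entropy import DEFAULT_THRESHOLDS, LandscapeThresholds
from .features import BiasFeatures, FeatureConfig
from .io import DisorderProfile, ProteinSequence
from .profiler import ResidueBindingProfile, profile_sequence
from .scoring import (
    FitDiagnostics,
    ModelParams,
    TrainingExample,
    fit_params,
    pdo_from_score,
    score_region,
)

PARAM_NAMES = ("lambda1", "lambda2", "lambda3", "gamma")
FEATURE_NAMES = ("delta_id", "delta_a", "delta_h")


class BindingModeModel:
    """Logistic model of disorder-to-order transition on region biases.

    Parameters
    ----------
    examples : list of TrainingExample
        One labelled region per example (label 1 = folds upon binding,
        0 = stays disordered).
    feature_config : FeatureConfig
        How the features were computed; recorded in the fitted parameters.
    """

    def __init__(
        self,
        examples: list[TrainingExample],
        feature_config: FeatureConfig = FeatureConfig(),
    ) -> None:
        self.examples = list(examples)
        self.feature_config = feature_config

    @classmethod
    def from_examples(
        cls, examples, feature_config: FeatureConfig = FeatureConfig()
    ) -> "BindingModeModel":
        return cls(examples, feature_config)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        feature_config: FeatureConfig = FeatureConfig(),
    ) -> "BindingModeModel":
        """Build from a DataFrame with delta_id/delta_a/delta_h/label columns."""
        missing = {*FEATURE_NAMES, label_col} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        examples = [
            TrainingExample(
                features=BiasFeatures(
                    delta_id=float(row.delta_id),
                    delta_a=float(row.delta_a),
                    delta_h=float(row.delta_h),
                ),
                label=int(getattr(row, label_col)),
                region_id=str(getattr(row, "region_id", row.Index)),
            )
            for row in df.itertuples()
        ]
        return cls(examples, feature_config)

    @property
    def nobs(self) -> int:
        return len(self.examples)

    def fit(
        self,
        *,
        ridge: float = 0.0,
        tol: float = 1e-8,
        max_iter: int = 100,
        min_per_class: int = 10,
    ) -> "BindingModeResults":
        params, diag = fit_params(
            self.examples,
            feature_config=self.feature_config,
            ridge=ridge,
            tol=tol,
            max_iter=max_iter,
            min_per_class=min_per_class,
        )
        return BindingModeResults(model=self, params=params, diagnostics=diag)


@dataclass(frozen=True)
class BindingModeResults:
    """Fitted binding-mode model: estimates, uncertainty, prediction."""

    model: BindingModeModel | None
    params: ModelParams
    diagnostics: FitDiagnostics | None = None

    @classmethod
    def from_params(cls, params: ModelParams) -> "BindingModeResults":
        """Wrap externally trained parameters (e.g. a loaded model file)."""
        return cls(model=None, params=params, diagnostics=None)

    # --- estimates -----------------------------------------------------

    @property
    def coefficients(self) -> np.ndarray:
        p = self.params
        return np.array([p.lambda1, p.lambda2, p.lambda3, p.gamma])

    @property
    def bse(self) -> np.ndarray:
        if self.diagnostics is None:
            raise ValueError("no fit diagnostics: results wrap external parameters")
        return self.diagnostics.standard_errors

    @property
    def llf(self) -> float:
        if self.diagnostics is None:
            raise ValueError("no fit diagnostics: results wrap external parameters")
        return self.diagnostics.log_likelihood

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald (asymptotic normal) confidence intervals, one row per
        coefficient in (lambda1, lambda2, lambda3, gamma) order."""
        z = norm.ppf(1 - alpha / 2)
        est = self.coefficients
        se = self.bse
        return np.column_stack([est - z * se, est + z * se])

    def summary(self) -> str:
        """Human-readable coefficient table with SEs, z and 95% CI."""
        lines = [
            "Binding-mode logistic model",
            "=" * 62,
        ]
        if self.diagnostics is not None:
            d = self.diagnostics
            lines += [
                f"N regions: {d.n_examples}   folds-on-binding: {d.n_positive}"
                f"   log-likelihood: {d.log_likelihood:.4f}",
                f"converged: {d.converged} in {d.iterations} iterations"
                + (f"   (ridge {d.ridge:g}, separation)" if d.separation_detected else ""),
                "-" * 62,
                f"{'':>10}{'coef':>10}{'std err':>10}{'z':>8}{'[0.025':>12}{'0.975]':>10}",
            ]
            ci = self.conf_int()
            for name, est, se, (lo, hi) in zip(
                PARAM_NAMES, self.coefficients, self.bse, ci
            ):
                z = est / se if se > 0 else np.nan
                lines.append(
                    f"{name:>10}{est:>10.4f}{se:>10.4f}{z:>8.2f}{lo:>12.4f}{hi:>10.4f}"
                )
        else:
            lines.append("(externally supplied parameters; no fit diagnostics)")
            for name, est in zip(PARAM_NAMES, self.coefficients):
                lines.append(f"{name:>10}{est:>10.4f}")
        lines.append("=" * 62)
        lines.append(
            f"composition statistic: {self.params.feature_config.composition_statistic}"
            f"   flanks: {self.params.feature_config.flank_len}"
            f"   windows: {self.params.feature_config.min_len}-"
            f"{self.params.feature_config.max_len}"
        )
        return "\n".join(lines)

    # --- prediction ----------------------------------------------------

    def predict(self, features: BiasFeatures) -> float:
        """p_DO for one window's features under the fitted coefficients."""
        return float(pdo_from_score(score_region(features, self.params)))

    def profile(
        self,
        seq: ProteinSequence,
        disorder: DisorderProfile | None = None,
        thresholds: LandscapeThresholds = DEFAULT_THRESHOLDS,
        *,
        allow_id_mismatch: bool = False,
    ) -> list[ResidueBindingProfile]:
        """Per-residue binding-mode profiles for a sequence.

        With ``disorder=None`` the built-in charge/hydropathy fallback
        supplies the disorder scores.
        """
        if disorder is None:
            disorder = builtin_disorder(seq)
        return profile_sequence(
            seq,
            disorder,
            self.params,
            thresholds,
            allow_id_mismatch=allow_id_mismatch,
        )

    def profile_frame(self, seq, disorder=None, **kwargs) -> pd.DataFrame:
        """:meth:`profile` as a tidy DataFrame."""
        rows = self.profile(seq, disorder, **kwargs)
        return pd.DataFrame(
            {
                "sequence_id": [r.sequence_id for r in rows],
                "position": [r.position for r in rows],
                "residue": [r.residue for r in rows],
                "n_windows": [r.n_windows for r in rows],
                "p_do": [r.p_do for r in rows],
                "p_dd": [r.p_dd for r in rows],
                "entropy_bits": [r.entropy_bits for r in rows],
                "landscape_class": [r.landscape_class for r in rows],
            }
        )

    def save(self, path) -> None:
        self.params.save(path)
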