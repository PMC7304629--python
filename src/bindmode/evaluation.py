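"""Performance statistics: ROC/AUC, Mann-Whitney tests, and the bivariate
(p_DD, entropy) discrimination harness.

AUC is computed through its rank identity: the Mann-Whitney U statistic
divided by n1*n2, with ties contributing 1/2. This equals the trapezoidal
area under the ROC curve over all thresholds and is invariant under any
strictly increasing transform of the scores.

The benchmark harness compares residue populations (e.g. entropy of
disorder-to-order vs context-dependent residues) exactly as one would when
evaluating against curated region datasets; residue-level pooling across
proteins is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .scoring import (
    FitDiagnostics,
    ModelParams,
    fit_logistic_design,
    pdo_from_score,
)

EXACT_P_MAX_PRODUCT = 400


def roc_auc(positives, negatives) -> float:
    """Area under the ROC curve for separating two score samples.

    Equals U / (n1*n2) with midrank tie handling: the probability that a
    random positive outscores a random negative, ties counted half.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U and two-sided p-value for two score samples.

    Exact p for small samples (n1*n2 <= 400 with no ties), normal
    approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size * b.size <= EXACT_P_MAX_PRODUCT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BivariateResult:
    """Fitted two-feature logistic discriminator and its AUC."""

    params: ModelParams
    diagnostics: FitDiagnostics
    auc: float
    fitted_probabilities: np.ndarray


def bivariate_discrimination(pairs, labels) -> BivariateResult:
    """Discriminate two residue classes from (p_DD, entropy) jointly.

    Fits a logistic classifier on the two features (third coefficient
    pinned to a zero feature) and reports the AUC of its fitted
    probabilities. This is the harness used to ask whether bound-state
    disorder and binding-mode diversity together separate context-dependent
    residues from single-mode ones.
    """
    pairs = np.asarray(pairs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (p_dd, entropy)")
    if pairs.shape[0] != labels.size:
        raise ValueError("pairs and labels must have equal length")
    X = np.column_stack([pairs, np.ones(len(labels))])
    beta, diag = fit_logistic_design(X, labels.astype(float), min_per_class=2)
    params = ModelParams(
        lambda1=float(beta[0]),
        lambda2=float(beta[1]),
        lambda3=0.0,
        gamma=float(beta[2]),
        provenance={"features": "(p_dd, entropy_bits)"},
    )
    probs = np.asarray(pdo_from_score(X @ beta))
    auc = roc_auc(probs[labels == 1], probs[labels == 0])
    return BivariateResult(
        params=params, diagnostics=diag, auc=auc, fitted_probabilities=probs
    )


def class_comparisons(
    table: pd.DataFrame,
    value_col: str,
    class_col: str = "label",
) -> pd.DataFrame:
    """Pairwise AUC and Mann-Whitney p for every pair of residue classes.

    ``table`` pools residues across proteins; one row per residue with its
    score (entropy or p_DD) and its region label (e.g. DOR/CDR/DDR/DBR).
    Returns one row per ordered class pair with n's, AUC and two-sided p.
    """
    classes = sorted(table[class_col].dropna().unique())
    rows = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            va = table.loc[table[class_col] == ca, value_col].dropna().to_numpy()
            vb = table.loc[table[class_col] == cb, value_col].dropna().to_numpy()
            if va.size == 0 or vb.size == 0:
                continue
            u, p = mann_whitney(va, vb)
            rows.append(
                {
                    "class_a": ca,
                    "class_b": cb,
                    "n_a": va.size,
                    "n_b": vb.size,
                    "value": value_col,
                    "auc_a_vs_b": roc_auc(va, vb),
                    "mannwhitney_u": u,
                    "p_two_sided": p,
                }
            )
    return pd.DataFrame(rows)
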