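"""Group-level tests, multiple-comparison corrections, and QDA classification.

The clinical protocol: a two-feature quadratic discriminant (peak alpha
ratio, mask density) is trained on the training split and evaluated on the
held-out validation split, reporting sensitivity (ASD recall) and
specificity (control recall).  Asperger's subjects are excluded from the
classifier when the protocol flag is set, mirroring the study design.
Because the source study never names its group test, every reported p-value
carries the name of the test that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

from .networks import bh_fdr


@dataclass
class SubjectFeatures:
    subject_id: str
    group: str
    subtype: str = "none"
    split: str = "training"
    peak_alpha_ratio: float = np.nan
    mean_density: float = np.nan
    mask_density: float = np.nan
    intersection_mask_density: float = np.nan


def group_difference_test(
    values_a, values_b, test: str = "rank_sum", alternative: str = "two_sided"
) -> tuple[float, str]:
    """p-value for a difference between two groups; returns (p, test_name).

    test: 'rank_sum' (Wilcoxon rank-sum / Mann-Whitney) or 'welch_t'.
    alternative: 'two_sided', 'A_less' (group A stochastically smaller) or
    'A_greater'.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    alt = {"two_sided": "two-sided", "A_less": "less", "A_greater": "greater"}[alternative]
    if test == "rank_sum":
        p = stats.mannwhitneyu(a, b, alternative=alt).pvalue
        name = f"rank_sum ({alternative})"
    elif test == "welch_t":
        p = stats.ttest_ind(a, b, equal_var=False, alternative=alt).pvalue
        name = f"welch_t ({alternative})"
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(p), name


def multiple_comparison_adjust(pvalues, method: str, alpha: float = 0.05):
    """Bonferroni threshold or BH-FDR decisions.

    'bonferroni' returns (threshold, decisions) with threshold = alpha/m;
    'bh_fdr' returns (None, decisions) from the linear step-up.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if method == "bonferroni":
        threshold = alpha / p.size
        return threshold, p <= threshold
    if method == "bh_fdr":
        return None, bh_fdr(p, q=alpha)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class QdaModel:
    """Per-class Gaussian densities with class-specific covariances."""

    classes: tuple[str, ...]
    means: dict                      # class -> mean vector
    covariances: dict                # class -> covariance matrix
    priors: dict                     # class -> prior probability
    feature_names: tuple[str, ...] = ()
    _sk: QuadraticDiscriminantAnalysis | None = None


def qda_train(
    features: np.ndarray,
    labels,
    priors: str = "equal",
    feature_names: tuple[str, ...] = (),
    reg_param: float = 0.0,
) -> QdaModel:
    """Fit a quadratic discriminant (per-class multivariate normal).

    priors: 'equal' (default, conservative for unbalanced groups) or
    'empirical' (class frequencies).  A singular class covariance triggers
    ridge regularization via ``reg_param``.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
    pri = None if priors == "empirical" else np.full(len(classes), 1.0 / len(classes))
    sk = QuadraticDiscriminantAnalysis(
        priors=pri, store_covariance=True, reg_param=reg_param
    )
    try:
        sk.fit(X, y)
        _ = [np.linalg.cholesky(c) for c in sk.covariance_]
    except np.linalg.LinAlgError:
        # singular class covariance (e.g. a feature constant within a class):
        # refit with a ridge large enough to clear the rank tolerance
        ridge = max(reg_param, 1e-3)
        import logging

        logging.getLogger(__name__).warning(
            "singular class covariance; applying ridge reg_param=%g", ridge)
        sk = QuadraticDiscriminantAnalysis(
            priors=pri, store_covariance=True, reg_param=ridge
        )
        sk.fit(X, y)
    cls = tuple(sk.classes_.tolist())
    return QdaModel(
        classes=cls,
        means={c: sk.means_[i] for i, c in enumerate(cls)},
        covariances={c: sk.covariance_[i] for i, c in enumerate(cls)},
        priors={c: sk.priors_[i] for i, c in enumerate(cls)},
        feature_names=tuple(feature_names),
        _sk=sk,
    )


def qda_predict(model: QdaModel, features: np.ndarray) -> np.ndarray:
    """Maximum-posterior class labels under the fitted per-class Gaussians."""
    return model._sk.predict(np.asarray(features, float))


@dataclass
class ClassificationMetrics:
    sensitivity: float          # TP / (TP + FN), positive class = ASD
    specificity: float          # TN / (TN + FP)
    tp: int
    fn: int
    tn: int
    fp: int

    def rounded_percent(self) -> tuple[int, int]:
        return round(100 * self.sensitivity), round(100 * self.specificity)


def classification_metrics(predicted, truth, positive: str = "ASD") -> ClassificationMetrics:
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    pos = true == positive
    if not pos.any() or pos.all():
        raise ValueError("a truth class is empty; metrics undefined")
    tp = int((pred[pos] == positive).sum())
    fn = int(pos.sum()) - tp
    tn = int((pred[~pos] != positive).sum())
    fp = int((~pos).sum()) - tn
    return ClassificationMetrics(
        sensitivity=tp / (tp + fn), specificity=tn / (tn + fp),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )
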