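"""Discrimination metrics and paired AUC comparison.

AUC is the Mann-Whitney statistic (ties count one half). Confidence
intervals and the paired comparison of two correlated AUCs use the DeLong
placement-value method with a normal approximation — the standard approach
for models evaluated on the same admissions. AUPR is the step-wise average
precision. A single-pixel perturbation experiment probes robustness of a
trained image classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("need both classes present")
    return y


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC with half-credit ties."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    m = int(y.sum())
    n = len(y) - m
    return float((r[y == 1].sum() - m * (m + 1) / 2) / (m * n))


def _placements(labels: np.ndarray, scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values (V10 for positives, V01 for negatives)."""
    y = labels
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = rankdata(np.concatenate([pos, neg]))
    pos_r = rankdata(pos)
    neg_r = rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_variance(labels, score_list: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance matrix for k score vectors."""
    y = _check_binary(labels)
    k = len(score_list)
    v10s, v01s, aucs = [], [], []
    for s in score_list:
        v10, v01, a = _placements(y, np.asarray(s, dtype=float))
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(a)
    m, n = len(v10s[0]), len(v01s[0])
    S10 = np.cov(np.stack(v10s), ddof=1) if m > 1 else np.zeros((k, k))
    S01 = np.cov(np.stack(v01s), ddof=1) if n > 1 else np.zeros((k, k))
    S10 = np.atleast_2d(S10)
    S01 = np.atleast_2d(S01)
    return np.array(aucs), S10 / m + S01 / n


def delong_ci(labels, scores, alpha: float = 0.05) -> Tuple[float, float]:
    """DeLong normal-approximation CI for one AUC, clipped to [0, 1]."""
    y = _check_binary(labels)
    if y.sum() < 10 or (1 - y).sum() < 10:
        raise ValueError("need at least 10 observations per class for a CI")
    aucs, var = delong_variance(y, [scores])
    se = float(np.sqrt(max(var[0, 0], 0.0)))
    if se == 0.0:
        import warnings
        warnings.warn("degenerate DeLong variance; returning widest clip")
        return (0.0, 1.0)
    z = norm.ppf(1 - alpha / 2)
    return (float(np.clip(aucs[0] - z * se, 0, 1)),
            float(np.clip(aucs[0] + z * se, 0, 1)))


def compare_auc(labels, scores_a, scores_b) -> Tuple[float, float]:
    """Paired DeLong test: (AUC_a - AUC_b, two-sided p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same admissions")
    aucs, S = delong_variance(labels, [a, b])
    delta = float(aucs[0] - aucs[1])
    var = float(S[0, 0] + S[1, 1] - 2 * S[0, 1])
    if var <= 0:
        return delta, 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / np.sqrt(var)
    return delta, float(2 * norm.sf(abs(z)))


def average_precision(labels, scores) -> float:
    """Step-wise area under the precision-recall curve."""
    y = _check_binary(labels)
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


@dataclass
class EvalReport:
    """Discrimination summary for one model on one evaluation set."""

    name: str
    auc: float
    auc_ci_95: Tuple[float, float]
    aupr: float
    n: int
    comparisons: List[Dict] = field(default_factory=list)

    def __post_init__(self):
        lo, hi = self.auc_ci_95
        assert lo - 1e-9 <= self.auc <= hi + 1e-9

    def to_dict(self) -> Dict:
        return {
            "name": self.name,
            "auc": round(self.auc, 6),
            "auc_ci_95": [round(self.auc_ci_95[0], 6), round(self.auc_ci_95[1], 6)],
            "aupr": round(self.aupr, 6),
            "n": self.n,
            "comparisons": self.comparisons,
        }


def evaluate_scores(name: str, labels, scores,
                    others: Optional[Dict[str, np.ndarray]] = None) -> EvalReport:
    """Full report: AUC with CI, AUPR, paired DeLong tests vs other models."""
    y = _check_binary(labels)
    try:
        ci = delong_ci(y, scores)
    except ValueError:
        import warnings
        warnings.warn(f"{name}: too few events for a DeLong CI; reporting [0, 1]")
        ci = (0.0, 1.0)
    report = EvalReport(
        name=name,
        auc=roc_auc(y, scores),
        auc_ci_95=ci,
        aupr=average_precision(y, scores),
        n=len(y),
    )
    for other_name, other_scores in (others or {}).items():
        delta, p = compare_auc(y, scores, other_scores)
        report.comparisons.append(
            {"other": other_name, "delta_auc": round(delta, 6), "p_value": round(p, 8)})
    return report


def pixel_perturbation_test(model, images: np.ndarray, labels,
                            seed: int = 0) -> Tuple[float, float]:
    """Zero one uniformly random pixel per image; AUC before vs after."""
    rng = np.random.default_rng(seed)
    y = _check_binary(labels)
    before = roc_auc(y, model.predict_proba(images))
    perturbed = np.array(images, dtype=np.float32, copy=True)
    n, V, T = perturbed.shape
    rows = rng.integers(0, V, size=n)
    cols = rng.integers(0, T, size=n)
    perturbed[np.arange(n), rows, cols] = 0.0
    after = roc_auc(y, model.predict_proba(perturbed))
    return float(before), float(after)
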