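"""Linear predictor score (LPS) Bayesian classifier.

Each gene contributes its expression weighted by the two-sample t statistic
between the positive and negative training class:

    LPS(x) = sum_j a_j * x_j

Class-conditional Gaussians are fitted to the training scores and the
posterior probability of the positive class for a new sample is

    P(pos | s) = phi(s; mu1, sd1) / (phi(s; mu1, sd1) + phi(s; mu0, sd0))

with a three-way call: positive above ``p_hi`` (default 0.9), negative
below ``p_lo`` (default 0.1), not-attributed (NA) in between.  A compact
predictor subset is refined from candidate genes by greedy forward
inclusion in |a_j| order scored by leave-one-out assignment quality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = ["LPSModel", "fit_lps", "lps_score", "posterior_wm", "classify", "refine_predictor"]


@dataclass
class LPSModel:
    """Per-gene t-statistic coefficients plus class-conditional Gaussians
    over the training LPS scores."""

    genes: list[str]
    coefficients: np.ndarray
    class1_mean: float
    class1_sd: float
    class0_mean: float
    class0_sd: float
    p_hi: float = 0.9
    p_lo: float = 0.1
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.class1_sd <= 0 or self.class0_sd <= 0:
            raise ValueError("class-conditional sds must be positive")
        if not 0 <= self.p_lo < self.p_hi <= 1:
            raise ValueError("need 0 <= p_lo < p_hi <= 1")

    def to_json(self, path: Path | str) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "genes": self.genes,
                    "coefficients": self.coefficients.tolist(),
                    "class1_mean": self.class1_mean,
                    "class1_sd": self.class1_sd,
                    "class0_mean": self.class0_mean,
                    "class0_sd": self.class0_sd,
                    "p_hi": self.p_hi,
                    "p_lo": self.p_lo,
                    "positive_class": self.positive_class,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: Path | str) -> "LPSModel":
        d = json.loads(Path(path).read_text())
        d["coefficients"] = np.asarray(d["coefficients"], dtype=float)
        return cls(**d)


def _t_coefficients(x1: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Two-sample pooled t statistic per gene (rows); zero-variance genes
    get coefficient 0 with a warning."""
    n1, n0 = x1.shape[1], x0.shape[1]
    dof = n1 + n0 - 2
    s2 = (x1.var(axis=1, ddof=1) * (n1 - 1) + x0.var(axis=1, ddof=1) * (n0 - 1)) / dof
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    diff = x1.mean(axis=1) - x0.mean(axis=1)
    coef = np.zeros_like(diff)
    nz = se > 0
    if (~nz).any():
        warnings.warn(f"{int((~nz).sum())} gene(s) with zero pooled variance; coefficient 0")
    coef[nz] = diff[nz] / se[nz]
    return coef


def fit_lps(
    matrix: ExpressionMatrix,
    labels: Mapping[str, bool] | pd.Series,
    genes: Sequence[str],
    p_hi: float = 0.9,
    p_lo: float = 0.1,
    positive_class: str = "positive",
) -> LPSModel:
    """Fit an LPS model; ``labels`` maps sample id -> is-positive."""
    genes = list(genes)
    sub = matrix.subset_genes(genes)
    lab = pd.Series(labels).loc[sub.sample_ids].astype(bool)
    pos = sub.values.loc[:, lab[lab].index].to_numpy(float)
    neg = sub.values.loc[:, lab[~lab].index].to_numpy(float)
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    coef = _t_coefficients(pos, neg)
    scores_pos = coef @ pos
    scores_neg = coef @ neg
    return LPSModel(
        genes=genes,
        coefficients=coef,
        class1_mean=float(scores_pos.mean()),
        class1_sd=float(scores_pos.std(ddof=1)),
        class0_mean=float(scores_neg.mean()),
        class0_sd=float(scores_neg.std(ddof=1)),
        p_hi=p_hi,
        p_lo=p_lo,
        positive_class=positive_class,
    )


def lps_score(model: LPSModel, sample_profile: Mapping[str, float] | pd.Series) -> float:
    """Weighted expression sum over the model's genes (model gene order)."""
    profile = pd.Series(sample_profile)
    missing = [g for g in model.genes if g not in profile.index]
    if missing:
        raise KeyError(f"profile missing model genes: {missing[:5]}")
    x = profile.loc[model.genes].to_numpy(float)
    return float(model.coefficients @ x)


def posterior_wm(model: LPSModel, score: float) -> float:
    """Posterior probability of the positive class at the given score."""
    l1 = stats.norm.logpdf(score, model.class1_mean, model.class1_sd)
    l0 = stats.norm.logpdf(score, model.class0_mean, model.class0_sd)
    # stable logistic of the log-density difference
    d = np.clip(l0 - l1, -700.0, 700.0)
    return float(1.0 / (1.0 + np.exp(d)))


def classify(model: LPSModel, sample_profile: Mapping[str, float] | pd.Series) -> str:
    """Three-way call: positive-class name, 'nonWM'-style negative, or 'NA'."""
    post = posterior_wm(model, lps_score(model, sample_profile))
    if post >= model.p_hi:
        return "WM"
    if post <= model.p_lo:
        return "nonWM"
    return "NA"


def predict_table(model: LPSModel, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample LPS score, posterior and call."""
    rows = []
    for s in matrix.sample_ids:
        score = lps_score(model, matrix.values[s])
        post = posterior_wm(model, score)
        call = "WM" if post >= model.p_hi else ("nonWM" if post <= model.p_lo else "NA")
        rows.append({"sample_id": s, "lps": score, "posterior": post, "call": call})
    return pd.DataFrame(rows)


def _loo_score(
    matrix: ExpressionMatrix,
    lab: pd.Series,
    genes: list[str],
    p_hi: float,
    p_lo: float,
) -> int:
    """Leave-one-out assignment quality: +1 correct, 0 NA, -1 wrong."""
    total = 0
    samples = matrix.sample_ids
    for s in samples:
        keep = [t for t in samples if t != s]
        sub = ExpressionMatrix(
            matrix.values[keep], matrix.species,
            {t: matrix.class_of_sample.get(t, "") for t in keep} if matrix.class_of_sample else {},
        )
        try:
            m = fit_lps(sub, lab.loc[keep], genes, p_hi=p_hi, p_lo=p_lo)
        except ValueError:  # a class emptied below 2 samples
            return -len(samples)
        call = classify(m, matrix.values[s])
        truth = "WM" if lab.loc[s] else "nonWM"
        total += 1 if call == truth else (0 if call == "NA" else -1)
    return total


def refine_predictor(
    matrix: ExpressionMatrix,
    labels: Mapping[str, bool] | pd.Series,
    candidate_genes: Sequence[str],
    max_genes: int = 50,
    p_hi: float = 0.9,
    p_lo: float = 0.1,
) -> tuple[list[str], LPSModel]:
    """Greedy forward selection of a compact predictor gene set.

    Candidates are ranked by |a_j| on the full data; prefixes in rank order
    are scored by leave-one-out assignment quality and the best prefix
    (ties -> fewer genes) is refitted on all samples and returned, together
    with its up/down split in the model coefficients.
    """
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise ValueError("empty candidate gene list")
    lab = pd.Series(labels).astype(bool)
    full = fit_lps(matrix, lab, candidate_genes, p_hi=p_hi, p_lo=p_lo)
    order = np.argsort(-np.abs(full.coefficients), kind="stable")
    ranked = [candidate_genes[i] for i in order]
    best_genes, best_score = None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n in range(1, min(len(ranked), max_genes) + 1):
            score = _loo_score(matrix, lab, ranked[:n], p_hi, p_lo)
            if score > best_score:
                best_genes, best_score = ranked[:n], score
    model = fit_lps(matrix, lab, best_genes, p_hi=p_hi, p_lo=p_lo)
    return best_genes, model
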