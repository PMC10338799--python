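"""Review-score mapping and the logistic contour-quality filter.

Reviewers score each generated contour on two 1-5 scales: clinical
usability (CSC) and realism (RSC).  The scales band into three editing
levels — 0 (no edits, both scores 5), 1 (minor edits, both in 3-4),
2 (major edits, both in 1-2).  The auto-filter is a logistic regression
predicting minor-vs-major editing from the variation constant C and the
distance metrics, fitted on an 80:20 subject-grouped split and selected by
held-out AUC across a small model family:

    M1 = {C};  M2 = {C, surface_dsc};  M3 = {C, surface_dsc, hd95}

with ``+I`` variants adding all pairwise interaction products.

Also provided: rank-based AUC, Cohen's kappa, and the linear-to-linear
(ordinal chi-square) association test M^2 = (N-1) r^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .errors import SingleClassTrainingError

__all__ = [
    "FORMULAS",
    "FilterModel",
    "editing_level",
    "consensus_level",
    "fit_filter",
    "auc",
    "apply_filter",
    "cohen_kappa",
    "linear_to_linear_test",
    "LinearTrendResult",
]

FORMULAS = {
    "M1": ("C",),
    "M2": ("C", "surface_dsc"),
    "M3": ("C", "surface_dsc", "hd95"),
}


def _band(score: int) -> int:
    """Map one 1-5 review score to its editing band (0, 1 or 2)."""
    if score == 5:
        return 0
    if score in (3, 4):
        return 1
    if score in (1, 2):
        return 2
    raise ValueError(f"score must be an integer in 1..5, got {score!r}")


def editing_level(csc: int, rsc: int, on_discordant: str = "worse") -> int:
    """Editing level (0 none / 1 minor / 2 major) from a CSC, RSC score pair.

    Score pairs whose two scores fall in different bands (e.g. CSC=5,
    RSC=3) are "discordant"; by default the worse (higher) level is
    assigned, the conservative choice for clinical use.  Pass
    ``on_discordant="error"`` to raise instead.
    """
    for s in (csc, rsc):
        if not float(s).is_integer() or not 1 <= s <= 5:
            raise ValueError(f"scores must be integers in 1..5, got ({csc}, {rsc})")
    b1, b2 = _band(int(csc)), _band(int(rsc))
    if b1 == b2:
        return b1
    if on_discordant == "error":
        raise ValueError(f"discordant score pair ({csc}, {rsc})")
    if on_discordant != "worse":
        raise ValueError("on_discordant must be 'worse' or 'error'")
    return max(b1, b2)


def consensus_level(reviews, on_discordant: str = "worse") -> int:
    """Joint editing level from several reviewers' (csc, rsc) pairs.

    CSC and RSC are averaged across reviewers, rounded half-up, and the
    banding applied to the rounded averages.
    """
    reviews = list(reviews)
    if not reviews:
        raise ValueError("need at least one review")
    csc = float(np.mean([r[0] for r in reviews]))
    rsc = float(np.mean([r[1] for r in reviews]))
    half_up = lambda v: int(np.floor(v + 0.5))
    return editing_level(half_up(csc), half_up(rsc), on_discordant=on_discordant)


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling.

    Probability that a randomly chosen positive outranks a randomly chosen
    negative; 1.0 for perfect ranking, 0.0 for perfectly reversed.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cohen_kappa(ratings_a, ratings_b, weighted: bool = False) -> float:
    """Cohen's kappa chance-corrected agreement between two raters.

    Unweighted by default; ``weighted=True`` uses linear weights for
    ordinal levels.
    """
    return float(
        cohen_kappa_score(ratings_a, ratings_b, weights="linear" if weighted else None)
    )


@dataclass
class LinearTrendResult:
    statistic: float
    pvalue: float
    correlation: float
    n: int


def linear_to_linear_test(
    table, row_scores=None, col_scores=None
) -> LinearTrendResult:
    """Linear-to-linear (ordinal chi-square) association test on a count table.

    Rows and columns carry ordered scores (defaults: 0, 1, 2, ...).  The
    statistic is M^2 = (N - 1) * r^2 where r is the Pearson correlation of
    the row/column scores over the N individual records implied by the
    counts; the p-value comes from chi-square with 1 df.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    u = np.asarray(row_scores if row_scores is not None else np.arange(table.shape[0]), float)
    v = np.asarray(col_scores if col_scores is not None else np.arange(table.shape[1]), float)
    n = table.sum()
    if n <= 1:
        raise ValueError("need more than one record")
    pu = table.sum(axis=1) / n
    pv = table.sum(axis=0) / n
    mu_u, mu_v = pu @ u, pv @ v
    cov = (table / n * np.outer(u - mu_u, v - mu_v)).sum()
    var_u = pu @ (u - mu_u) ** 2
    var_v = pv @ (v - mu_v) ** 2
    if var_u == 0 or var_v == 0:
        raise ValueError("degenerate table: a margin is concentrated on one level")
    r = cov / np.sqrt(var_u * var_v)
    m2 = (n - 1) * r**2
    return LinearTrendResult(
        statistic=float(m2), pvalue=float(chi2.sf(m2, 1)),
        correlation=float(r), n=int(n),
    )


@dataclass
class FilterModel:
    """A fitted minor-vs-major logistic filter.

    ``terms`` lists covariate names in design order (interaction terms are
    ``"a:b"`` products); ``coef`` maps term -> coefficient.  The positive
    class is minor editing (level 1).
    """

    formula_id: str
    terms: tuple
    intercept: float
    coef: dict
    cutoff: float = 0.5
    regularized: bool = False
    fitted: bool = True
    stderr: dict | None = None

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                cols.append(np.asarray(df[a], float) * np.asarray(df[b], float))
            else:
                cols.append(np.asarray(df[t], float))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        """Probability of the minor-editing class for each row."""
        x = self._design(df)
        beta = np.array([self.coef[t] for t in self.terms])
        return expit(self.intercept + x @ beta)

    def to_json(self, path=None) -> str:
        payload = {
            "formula_id": self.formula_id,
            "terms": list(self.terms),
            "intercept": self.intercept,
            "coef": self.coef,
            "cutoff": self.cutoff,
            "regularized": self.regularized,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FilterModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            formula_id=payload["formula_id"],
            terms=tuple(payload["terms"]),
            intercept=float(payload["intercept"]),
            coef={k: float(v) for k, v in payload["coef"].items()},
            cutoff=float(payload.get("cutoff", 0.5)),
            regularized=bool(payload.get("regularized", False)),
        )


def _formula_terms(formula: str) -> tuple[str, tuple]:
    base_id = formula.replace("+I", "")
    if base_id not in FORMULAS:
        raise ValueError(f"unknown formula {formula!r}; use M1, M2, M2+I, M3, M3+I")
    terms = list(FORMULAS[base_id])
    if formula.endswith("+I"):
        terms += [f"{a}:{b}" for a, b in combinations(FORMULAS[base_id], 2)]
    return formula, tuple(terms)


def grouped_split(subjects, test_fraction: float, seed: int):
    """Deterministic subject-grouped train/test membership masks."""
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(uniq)
    n_test = max(1, int(round(test_fraction * len(uniq))))
    if n_test >= len(uniq):
        n_test = len(uniq) - 1
    test_subjects = set(perm[:n_test].tolist())
    test = np.array([s in test_subjects for s in subjects])
    return ~test, test


def fit_filter(
    records: pd.DataFrame,
    formula: str = "M2",
    split_seed: int = 0,
    test_fraction: float = 0.2,
    cutoff: float = 0.5,
) -> tuple[FilterModel, float]:
    """Fit a minor-vs-major logistic filter and score it on held-out data.

    ``records`` needs columns ``subject``, ``level`` (1 minor / 2 major;
    level-0 rows are dropped with a warning) and the formula's covariates.
    The 80:20 split is grouped by subject so no subject spans both halves.
    Maximum-likelihood fit via statsmodels; on (quasi-)separation a small
    ridge penalty is used instead and flagged on the returned model.

    Returns ``(model, held_out_auc)``.
    """
    formula_id, terms = _formula_terms(formula)
    df = records.copy()
    if (df["level"] == 0).any():
        warnings.warn("dropping level-0 (no-edit) records from filter fitting")
        df = df[df["level"] != 0]
    if not df["level"].isin([1, 2]).all():
        raise ValueError("level must be 1 (minor) or 2 (major)")
    y = (df["level"] == 1).to_numpy(float)

    train, test = grouped_split(df["subject"].to_numpy(), test_fraction, split_seed)
    if len(np.unique(y[train])) < 2:
        raise SingleClassTrainingError("training portion contains a single class")

    proto = FilterModel(formula_id, terms, 0.0, {t: 0.0 for t in terms})
    x = proto._design(df)
    x_const = sm.add_constant(x, has_constant="add")

    regularized = False
    params = stderr = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y[train], x_const[train]).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(np.abs(res.params) < 1e3):
                params, stderr = res.params, res.bse
        except Exception:
            params = None
    if params is None:  # separation or divergence -> ridge fallback
        res = sm.Logit(y[train], x_const[train]).fit_regularized(
            method="l1", alpha=1.0, L1_wt=0.0, disp=0, maxiter=500
        )
        params, stderr, regularized = np.asarray(res.params), None, True
        warnings.warn("logistic fit did not converge; using ridge-penalized fit")

    model = FilterModel(
        formula_id=formula_id,
        terms=terms,
        intercept=float(params[0]),
        coef={t: float(params[1 + i]) for i, t in enumerate(terms)},
        cutoff=cutoff,
        regularized=regularized,
        stderr=None if stderr is None else {
            "const": float(stderr[0]),
            **{t: float(stderr[1 + i]) for i, t in enumerate(terms)},
        },
    )
    p_test = model.predict_proba(df[test])
    if len(np.unique(y[test])) < 2:
        held_out = float("nan")
    else:
        held_out = auc(p_test, y[test])
    return model, held_out


def apply_filter(model: FilterModel, features: pd.DataFrame, cutoff: float | None = None):
    """Predict minor-editing probability and accept/reject per row.

    Returns a copy of ``features`` with ``p_minor`` and ``accepted`` columns
    (accepted when p_minor >= cutoff).
    """
    cutoff = model.cutoff if cutoff is None else cutoff
    out = features.copy()
    p = model.predict_proba(features)
    out["p_minor"] = p
    out["accepted"] = p >= cutoff
    return out
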