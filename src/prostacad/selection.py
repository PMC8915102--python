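"""Feature fusion and bi-directional stepwise selection.

The four blocks — functional (ADC-CDF, 122), texture (58), shape (85) and
the scalar PSA biomarker — concatenate into a 266-wide combined table.  The
reduction step is classic bi-directional stepwise selection against a
binary-diagnosis logistic regression: starting from the empty set, the
forward step adds the candidate with the smallest likelihood-ratio entry
p-value if it clears the significance threshold, the backward step then
drops any included feature whose removal p-value exceeds the same
threshold, and the two alternate until a full pass changes nothing.  Two
thresholds are conventional: 0.05 (strict) and 0.1 (permissive, admits more
features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .features import FeatureTable

__all__ = ["SelectionResult", "StepRecord", "integrate_features", "stepwise_select"]


def integrate_features(
    functional: FeatureTable,
    texture: FeatureTable,
    shape: FeatureTable,
    psa: Mapping[str, float] | pd.Series,
) -> FeatureTable:
    """Column-wise fusion functional | texture | shape | PSA (266 by default).

    All blocks must cover the identical case set; rows are canonically
    sorted by case_id so input ordering is irrelevant.
    """
    blocks = [functional.sort_cases(), texture.sort_cases(), shape.sort_cases()]
    ids = blocks[0].case_ids
    for blk, name in zip(blocks[1:], ("texture", "shape")):
        if blk.case_ids != ids:
            offenders = sorted(set(blk.case_ids) ^ set(ids))
            raise ValueError(f"case mismatch in {name} block: {offenders}")
    if isinstance(psa, pd.Series):
        psa = psa.to_dict()
    missing = [cid for cid in ids if cid not in psa]
    if missing:
        raise ValueError(f"case mismatch in psa block: {missing}")
    for a, b in zip(blocks[:-1], blocks[1:]):
        if not np.array_equal(a.labels, b.labels):
            raise ValueError("label mismatch across feature blocks")
    psa_col = np.array([[float(psa[cid])] for cid in ids])
    return FeatureTable(
        case_ids=list(ids),
        feature_names=(
            blocks[0].feature_names + blocks[1].feature_names
            + blocks[2].feature_names + ["psa"]
        ),
        matrix=np.hstack([b.matrix for b in blocks] + [psa_col]),
        labels=blocks[0].labels.copy(),
        provenance=(
            blocks[0].provenance + blocks[1].provenance
            + blocks[2].provenance + ["psa"]
        ),
    )


@dataclass
class StepRecord:
    step: int
    action: str  # "add" | "remove"
    feature: str
    p_value: float
    penalized: bool = False  # fallback likelihood used (separation/singularity)


@dataclass
class SelectionResult:
    selected_names: list[str]
    trace: list[StepRecord] = field(default_factory=list)
    threshold: float = 0.05


# ---------------------------------------------------------------------------
# logistic likelihoods

_RIDGE = 1e-6


def _penalized_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood at the ridge-penalized logistic optimum.

    Used when the plain Newton fit fails (perfect separation or a singular
    Hessian from collinear columns); the tiny penalty keeps the optimum
    finite while leaving well-posed fits essentially unchanged.
    """

    def negloglik(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ beta
        # log(1 + exp(eta)) stably
        log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
        nll = float(log1pexp.sum() - y @ eta) + 0.5 * _RIDGE * beta[1:] @ beta[1:]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        grad = X.T @ (p - y)
        grad[1:] += _RIDGE * beta[1:]
        return nll, grad

    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(negloglik, beta0, jac=True, method="L-BFGS-B")
    eta = X @ res.x
    log1pexp = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
    return float(y @ eta - log1pexp.sum())


def _loglik(X: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Maximized logistic log-likelihood; flags penalized fallback."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            llf = float(res.llf)
            if np.isfinite(llf) and res.mle_retvals.get("converged", False):
                return llf, False
        except Exception:
            pass
    return _penalized_loglik(X, y), True


def _lr_pvalue(ll_full: float, ll_reduced: float) -> float:
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    return float(stats.chi2.sf(stat, df=1))


def stepwise_select(
    table: FeatureTable,
    threshold: float,
    max_steps: int | None = None,
) -> SelectionResult:
    """Bi-directional stepwise selection on a labeled feature table.

    Features are z-scored internally (zero-variance columns are kept but
    carry no information, so they are never selected at thresholds < 1).
    Entry and removal both use the likelihood-ratio test between nested
    logistic models at significance ``threshold``; ties on p-values break
    toward the lowest column index, making the procedure deterministic.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    y = table.labels.astype(float)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 cases per class")
    X = table.matrix
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    n, p = Z.shape
    if max_steps is None:
        max_steps = 2 * p

    const = np.ones((n, 1))

    def design(cols: Sequence[int]) -> np.ndarray:
        return np.hstack([const, Z[:, list(cols)]]) if cols else const

    selected: list[int] = []
    trace: list[StepRecord] = []
    step = 0
    while step < max_steps:
        changed = False
        # forward step: smallest entry p-value
        ll0, _ = _loglik(design(selected), y)
        best_p, best_j, best_flag = np.inf, -1, False
        for j in range(p):
            if j in selected:
                continue
            ll1, flag = _loglik(design(selected + [j]), y)
            pv = _lr_pvalue(ll1, ll0)
            if pv < best_p - 1e-15:  # strict improvement; ties keep lowest index
                best_p, best_j, best_flag = pv, j, flag
        if best_j >= 0 and best_p <= threshold:
            selected.append(best_j)
            step += 1
            trace.append(
                StepRecord(step, "add", table.feature_names[best_j], best_p, best_flag)
            )
            changed = True
        # backward steps: drop the worst included feature while above threshold
        while selected and step < max_steps:
            ll_full, _ = _loglik(design(selected), y)
            worst_p, worst_k, worst_flag = -np.inf, -1, False
            for k in selected:
                reduced = [c for c in selected if c != k]
                ll_red, flag = _loglik(design(reduced), y)
                pv = _lr_pvalue(ll_full, ll_red)
                if pv > worst_p + 1e-15 or (
                    pv >= worst_p - 1e-15 and (worst_k < 0 or k < worst_k)
                ):
                    worst_p, worst_k, worst_flag = pv, k, flag
            if worst_k >= 0 and worst_p > threshold:
                selected.remove(worst_k)
                step += 1
                trace.append(
                    StepRecord(
                        step, "remove", table.feature_names[worst_k], worst_p, worst_flag
                    )
                )
                changed = True
            else:
                break
        if not changed:
            break
    return SelectionResult(
        selected_names=[table.feature_names[j] for j in selected],
        trace=trace,
        threshold=threshold,
    )
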