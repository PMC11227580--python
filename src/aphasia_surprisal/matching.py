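"""Nearest-neighbour propensity-score matching of aphasia and control groups.

The propensity score is the fitted probability of aphasia-group membership
given the covariates the study balances on (age, numeric; sex, indicator),
estimated by maximum-likelihood probit regression.  Treated units are matched
1:1 to controls greedily, without replacement, in descending propensity
order, each pair minimizing the absolute score difference among the controls
still available.  Balance is reported as the standardized mean difference
(SMD) of each covariate before and after matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

logger = logging.getLogger(__name__)

SCORE_CLIP = 1e-6


@dataclass(frozen=True)
class PropensityFit:
    """Probit coefficients and fitted scores, clipped inside (0, 1)."""

    coefficients: pd.Series | None
    scores: pd.Series
    method: str  # "probit" or "covariate-distance"
    converged: bool
    std_errors: pd.Series | None = None


@dataclass(frozen=True)
class MatchResult:
    pairs: pd.DataFrame  # treated_id, control_id, score_t, score_c
    unmatched: list[str]
    fit: PropensityFit


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: categorical columns become 0/1 indicators."""
    X = pd.get_dummies(covariates, drop_first=True).astype(float)
    return X


def fit_propensity(
    covariates: pd.DataFrame,
    treatment: pd.Series,
    maxiter: int = 100,
    gtol: float = 1e-8,
) -> PropensityFit:
    """ML probit fit of treatment on covariates.

    Under perfect separation (or non-convergence) the fit falls back, with a
    warning, to a covariate-distance score: one minus the min-max scaled
    Euclidean distance to the treated centroid in standardized covariate
    space — monotone in similarity to the treated arm, so greedy matching
    still behaves sensibly.
    """
    t = np.asarray(treatment).astype(float)
    if (t == 1).sum() < 2 or (t == 0).sum() < 2:
        raise ValueError("need at least 2 units per arm")
    X = _design(covariates)
    exog = sm.add_constant(X)
    try:
        import warnings as _warnings

        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Probit(t, exog).fit(
                method="newton", maxiter=maxiter, tol=gtol, disp=0
            )
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged or not np.isfinite(res.params).all():
            raise PerfectSeparationError("probit did not converge")
        scores = pd.Series(res.predict(exog), index=covariates.index)
        scores = scores.clip(SCORE_CLIP, 1 - SCORE_CLIP)
        return PropensityFit(
            coefficients=pd.Series(res.params.values, index=exog.columns),
            scores=scores,
            method="probit",
            converged=True,
            std_errors=pd.Series(res.bse.values, index=exog.columns),
        )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        logger.warning(
            "probit fit failed (separation or singular design); "
            "falling back to covariate-distance scores"
        )
        Z = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
        centroid = Z[t == 1].mean()
        dist = np.sqrt(((Z - centroid) ** 2).sum(axis=1))
        rng = dist.max() - dist.min()
        sim = 1.0 - (dist - dist.min()) / (rng if rng > 0 else 1.0)
        scores = sim.clip(SCORE_CLIP, 1 - SCORE_CLIP)
        return PropensityFit(
            coefficients=None, scores=scores, method="covariate-distance",
            converged=False,
        )


def nearest_match(
    scores: pd.Series, treated_ids: list[str], control_ids: list[str]
) -> tuple[list[tuple[str, str]], list[str]]:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Treated units are processed in descending score order; each takes the
    remaining control with the closest score.  When controls are outnumbered
    the smaller arm does the selecting (each control takes the nearest
    treated unit), so the retained treated subset resembles the control pool
    rather than its own extreme.  Returns (pairs, unmatched); pairs are
    always reported as (treated, control).
    """
    if not treated_ids or not control_ids:
        raise ValueError("both arms must be non-empty")
    swap = len(control_ids) < len(treated_ids)
    selectors, pool = (
        (control_ids, treated_ids) if swap else (treated_ids, control_ids)
    )
    order = sorted(selectors, key=lambda i: -scores[i])
    available = set(pool)
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for s_id in order:
        if not available:
            unmatched.append(s_id)
            continue
        p_id = min(available, key=lambda c: (abs(scores[c] - scores[s_id]), str(c)))
        available.discard(p_id)
        pairs.append((p_id, s_id) if swap else (s_id, p_id))
    unmatched.extend(sorted(available, key=str))
    if unmatched:
        logger.info("%d units left unmatched", len(unmatched))
    return pairs, unmatched


def standardized_mean_difference(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """SMD with the pooled (unweighted average of variances) denominator."""
    x_t, x_c = np.asarray(x_t, float), np.asarray(x_c, float)
    pooled = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / pooled)


def balance_report(
    covariates: pd.DataFrame, treatment: pd.Series, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Covariate means and SMD before and after matching, one row per covariate."""
    X = _design(covariates)
    t = np.asarray(treatment).astype(bool)
    t_ids = [a for a, _ in pairs]
    c_ids = [b for _, b in pairs]
    rows = []
    for col in X.columns:
        pre_t, pre_c = X.loc[t, col].values, X.loc[~t, col].values
        post_t, post_c = X.loc[t_ids, col].values, X.loc[c_ids, col].values
        rows.append(
            {
                "covariate": col,
                "mean_treated_pre": pre_t.mean(),
                "mean_control_pre": pre_c.mean(),
                "smd_pre": standardized_mean_difference(pre_t, pre_c),
                "mean_treated_post": post_t.mean(),
                "mean_control_post": post_c.mean(),
                "smd_post": standardized_mean_difference(post_t, post_c),
            }
        )
    return pd.DataFrame(rows)


def match_groups(
    manifest: pd.DataFrame, covariate_columns: tuple[str, ...] = ("age", "sex")
) -> MatchResult:
    """Propensity-match aphasia participants to controls on the manifest.

    Returns the pairs table, unmatched ids, and the underlying fit.  When the
    treated arm outnumbers the controls the smaller arm limits the number of
    pairs, mirroring 1:1 matching without replacement.
    """
    df = manifest.set_index("participant_id")
    treatment = (df["group"] == "aphasia").astype(int)
    fit = fit_propensity(df[list(covariate_columns)], treatment)
    treated = list(df.index[treatment == 1])
    controls = list(df.index[treatment == 0])
    pairs, unmatched = nearest_match(fit.scores, treated, controls)
    pairs_df = pd.DataFrame(
        [
            {
                "treated_id": t,
                "control_id": c,
                "score_t": fit.scores[t],
                "score_c": fit.scores[c],
            }
            for t, c in pairs
        ]
    )
    return MatchResult(pairs=pairs_df, unmatched=unmatched, fit=fit)
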