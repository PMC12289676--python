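"""Herb-dose effect modeling (SPRA).

The botanicals-effect relationship is modeled on per-run response means
with a sparse polynomial in the herb doses: linear terms (main effects),
quadratic terms (nonlinear effects) and pairwise interactions.  With six
herbs the full term set has 6 + 6 + 15 = 27 columns against only 7 design
runs, so selection proceeds in two stages:

1. LASSO screening with cross-validated penalty keeps a candidate subset;
2. bidirectional stepwise refinement minimizes AIC over single-term
   additions (restricted to the LASSO survivors) and deletions, starting
   from the survivor model.

The final OLS fit supplies raw and standardized coefficients, per-term
p-values, R-squared and the overall F-test p-value.  Standardized
coefficients carry the sign/magnitude semantics used for radar-chart
display: positive means the term raises the response.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LassoCV

from .design import DoseMatrix
from .scoring import zscore

__all__ = [
    "TermSet",
    "EffectModel",
    "SpraConfig",
    "poly_term_names",
    "expand_poly_terms",
    "run_means",
    "lasso_screen",
    "stepwise_refine",
    "fit_spra",
    "RankError",
]

log = logging.getLogger(__name__)


class RankError(ValueError):
    """Selected design matrix is rank deficient."""


@dataclass(frozen=True)
class TermSet:
    """Ordered polynomial terms over herb labels: linear, quadratic, pairwise."""

    herbs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.herbs)) != len(self.herbs):
            raise ValueError("duplicate herb names")
        if len(self.herbs) < 2:
            raise ValueError("need at least 2 herbs for interaction terms")

    @property
    def names(self) -> list[str]:
        lin = list(self.herbs)
        quad = [f"{h}^2" for h in self.herbs]
        inter = [f"{a}*{b}" for a, b in itertools.combinations(self.herbs, 2)]
        return lin + quad + inter


def poly_term_names(herbs: tuple[str, ...]) -> list[str]:
    """Full polynomial term list (linear, quadratic, interactions) in order."""
    return TermSet(tuple(herbs)).names


def expand_poly_terms(
    doses: DoseMatrix | pd.DataFrame, standardize_doses: bool = True
) -> pd.DataFrame:
    """Expand herb doses into the polynomial term design matrix.

    Doses are Z-scored per herb first (unless disabled), then the term
    columns are computed from the (standardized) doses.  Column order:
    linear, quadratic, interactions (pairs in herb order).
    """
    if isinstance(doses, DoseMatrix):
        df = doses.to_frame().set_index("run")
    else:
        df = doses.set_index("run") if "run" in doses.columns else doses.copy()
    herbs = tuple(df.columns)
    ts = TermSet(herbs)
    d = df.to_numpy(float)
    if standardize_doses:
        d = np.column_stack([zscore(d[:, j]) for j in range(d.shape[1])])
    cols = {}
    for j, h in enumerate(herbs):
        cols[h] = d[:, j]
    for j, h in enumerate(herbs):
        cols[f"{h}^2"] = d[:, j] ** 2
    for (ja, a), (jb, b) in itertools.combinations(enumerate(herbs), 2):
        cols[f"{a}*{b}"] = d[:, ja] * d[:, jb]
    return pd.DataFrame(cols, index=df.index)[ts.names]


def run_means(
    animals: pd.DataFrame, response: str, runs: list[str] | None = None
) -> pd.Series:
    """Per-run mean of a response column, in the given run order.

    Defaults to the uniform-design runs (labels starting with 'UD') in the
    order they appear.
    """
    if "run" not in animals.columns:
        raise KeyError("animal table needs a 'run' column")
    if runs is None:
        seen = animals["run"].dropna()
        runs = sorted(
            {r for r in seen if str(r).startswith("UD")},
            key=lambda r: (len(str(r)), str(r)),
        )
    means = animals.groupby("run")[response].mean()
    missing = [r for r in runs if r not in means.index]
    if missing:
        raise ValueError(f"runs with no animals: {missing}")
    return means.reindex(runs)


def lasso_screen(
    X: pd.DataFrame,
    y: np.ndarray,
    cv: int | None = None,
    seed: int = 0,
) -> list[str]:
    """LASSO screening: term names with nonzero coefficient at the CV-optimal penalty.

    Columns of X are assumed standardized.  With fewer observations than
    the requested folds, leave-one-out CV is used instead (logged).
    """
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("LASSO screening needs at least 3 observations")
    folds = cv or n
    if n < folds:
        log.info("n=%d < %d folds; falling back to leave-one-out CV", n, folds)
        folds = n
    if np.ptp(y) == 0:
        return []
    model = LassoCV(cv=folds, random_state=seed, max_iter=50000)
    with np.errstate(all="ignore"):
        model.fit(X.to_numpy(float), y)
    return [c for c, b in zip(X.columns, model.coef_) if b != 0.0]


def _ols_aic(X: np.ndarray, y: np.ndarray) -> float:
    """Stepwise AIC in the R extractAIC convention: n log(RSS/n) + 2 edf."""
    n = len(y)
    if X.shape[1] == 0:
        rss = float(((y - y.mean()) ** 2).sum())
        k = 1
    else:
        Z = np.column_stack([np.ones(n), X])
        beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        rss = float(((y - Z @ beta) ** 2).sum())
        k = Z.shape[1]
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


@dataclass(frozen=True)
class EffectModel:
    """A fitted sparse polynomial dose-effect model."""

    response: str
    terms: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    std_coefficients: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    model_pvalue: float
    n_obs: int
    aic: float = float("nan")
    herbs: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "coefficient": [self.coefficients[t] for t in self.terms],
                "std_coefficient": [self.std_coefficients[t] for t in self.terms],
                "p_value": [self.pvalues[t] for t in self.terms],
            }
        )

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "terms": list(self.terms),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "std_coefficients": self.std_coefficients,
            "p_values": self.pvalues,
            "r_squared": self.r_squared,
            "model_p_value": self.model_pvalue,
            "n_obs": self.n_obs,
            "aic": self.aic,
        }


def _final_fit(
    X: pd.DataFrame, y: np.ndarray, terms: list[str], response: str
) -> EffectModel:
    n = len(y)
    y = np.asarray(y, float)
    sd_y = y.std(ddof=1) if n > 1 else 0.0
    if not terms:
        return EffectModel(
            response=response, terms=(), intercept=float(y.mean()),
            coefficients={}, std_coefficients={}, pvalues={},
            r_squared=0.0, model_pvalue=1.0, n_obs=n,
            aic=_ols_aic(np.empty((n, 0)), y),
        )
    Xs = X[terms].to_numpy(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), Xs])) < len(terms) + 1:
        raise RankError(f"singular design for terms {terms}")
    fit = sm.OLS(y, sm.add_constant(Xs)).fit()
    coefs = dict(zip(terms, fit.params[1:]))
    sds = {t: X[t].std(ddof=1) for t in terms}
    std_coefs = {
        t: coefs[t] * sds[t] / sd_y if sd_y > 0 else 0.0 for t in terms
    }
    return EffectModel(
        response=response,
        terms=tuple(terms),
        intercept=float(fit.params[0]),
        coefficients=coefs,
        std_coefficients=std_coefs,
        pvalues=dict(zip(terms, fit.pvalues[1:])),
        r_squared=float(fit.rsquared),
        model_pvalue=float(fit.f_pvalue) if not np.isnan(fit.f_pvalue) else 1.0,
        n_obs=n,
        aic=_ols_aic(Xs, y),
    )


def stepwise_refine(
    X: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str] | None = None,
    response: str = "y",
    max_terms: int | None = None,
    max_iter: int = 50,
) -> EffectModel:
    """Bidirectional stepwise AIC refinement.

    Starts from the candidate model (the LASSO survivors), then repeatedly
    applies the best single-term addition (restricted to candidates) or
    deletion (unrestricted) that lowers AIC, stopping at a local minimum.
    Ties prefer deletion, then term order.  The selected-term count is
    capped at n - 2 so p-values retain residual degrees of freedom.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n <= 2:
        raise ValueError("stepwise refinement needs n > 2")
    cap = min(max_terms if max_terms is not None else n - 2, n - 2)
    if candidates is None:
        candidates = list(X.columns)
    order = {t: i for i, t in enumerate(X.columns)}
    current = list(candidates) if len(candidates) <= cap else []
    current_aic = _ols_aic(X[current].to_numpy(float), y)
    for _ in range(max_iter):
        moves: list[tuple[float, int, int, str, str]] = []
        for t in current:  # deletions (unrestricted)
            trial = [u for u in current if u != t]
            aic = _ols_aic(X[trial].to_numpy(float), y)
            moves.append((aic, 0, order[t], "del", t))
        if len(current) < cap:
            for t in candidates:  # additions restricted to survivors
                if t in current:
                    continue
                trial = current + [t]
                aic = _ols_aic(X[trial].to_numpy(float), y)
                moves.append((aic, 1, order[t], "add", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best = moves[0]
        if best[0] < current_aic - 1e-10:
            if best[3] == "del":
                current.remove(best[4])
            else:
                current.append(best[4])
            current_aic = best[0]
        else:
            break
    else:
        raise RuntimeError(f"stepwise search did not settle in {max_iter} iterations")
    current.sort(key=order.get)
    return _final_fit(X, y, current, response)


@dataclass(frozen=True)
class SpraConfig:
    """SPRA settings: seeding, standardization and selection controls."""

    seed: int = 0
    standardize_doses: bool = True
    standardize_terms: bool = True
    use_lasso: bool = True
    cv: int | None = None  # None -> leave-one-out
    max_terms: int | None = None  # None -> n - 2
    runs: tuple[str, ...] | None = None


def fit_spra(
    doses: DoseMatrix | pd.DataFrame,
    animals: pd.DataFrame,
    response: str,
    config: SpraConfig = SpraConfig(),
) -> EffectModel:
    """Full SPRA pipeline for one response.

    Per-run response means -> polynomial term expansion over (Z-scored)
    doses -> Z-scoring of term columns -> LASSO screening -> bidirectional
    stepwise AIC refinement.
    """
    X_raw = expand_poly_terms(doses, standardize_doses=config.standardize_doses)
    runs = list(config.runs) if config.runs else list(X_raw.index)
    y = run_means(animals, response, runs=runs).to_numpy(float)
    X = X_raw.loc[runs]
    if config.standardize_terms:
        keep = {}
        for c in X.columns:
            col = X[c].to_numpy(float)
            if col.std(ddof=1) > 0:
                keep[c] = zscore(col)
            else:
                log.info("dropping constant term column %s", c)
        X = pd.DataFrame(keep, index=X.index)
    if config.use_lasso:
        candidates = lasso_screen(X, y, cv=config.cv, seed=config.seed)
    else:
        candidates = list(X.columns)
    return stepwise_refine(
        X, y, candidates=candidates, response=response, max_terms=config.max_terms
    )
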