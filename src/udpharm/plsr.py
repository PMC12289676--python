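"""NIPALS partial least squares regression with VIP screening.

PLSR extracts latent components t_a = X w_a that maximize covariance with
the response block, deflating X and Y after each component.  The number of
components is chosen as the smallest A whose cumulative explained
Y-variance exceeds a threshold (0.80 by default).  Predictor relevance is
summarized by Variable Importance in Projection:

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a )

with SS_a the Y-variance explained by component a; predictors with
VIP > 1 are flagged as significant contributors.  Both blocks are
autoscaled (mean 0, sample SD 1) before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import DegenerateColumnError

__all__ = [
    "PlsrFit",
    "nipals_plsr",
    "select_ncomp",
    "vip",
    "screen_vip",
    "ConvergenceError",
]

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """NIPALS inner loop failed to converge."""


@dataclass(frozen=True)
class PlsrFit:
    """A fitted NIPALS PLSR model on autoscaled blocks.

    ``coef`` maps autoscaled X to autoscaled Y; ``explained_y_variance``
    gives the fraction of (autoscaled) Y sum of squares captured by each
    component.
    """

    x_weights: np.ndarray  # p x A, unit-norm columns
    x_loadings: np.ndarray  # p x A
    x_scores: np.ndarray  # n x A, mutually orthogonal
    y_loadings: np.ndarray  # m x A
    coef: np.ndarray  # p x m, autoscaled scale
    explained_y_variance: np.ndarray  # length A
    ncomp: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    x_names: tuple[str, ...]
    y_names: tuple[str, ...]

    def predict(self, X) -> np.ndarray:
        """Predict responses on the original (unscaled) measurement scale."""
        Xs = (np.asarray(X, float) - self.x_mean) / self.x_sd
        return Xs @ self.coef * self.y_sd + self.y_mean


def _autoscale(M: np.ndarray, names: tuple[str, ...], block: str):
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise DegenerateColumnError(
            f"zero-variance {block} column(s): {[names[j] for j in bad]}"
        )
    return (M - mean) / sd, mean, sd


def nipals_plsr(
    X,
    Y,
    ncomp: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PlsrFit:
    """Fit PLSR by NIPALS with the given number of components.

    X (n x p) and Y (n x m) are autoscaled internally.  Per component the
    inner loop alternates w, t, q, u until the score vector changes by
    less than ``tol``; X and Y are then deflated by the rank-one
    approximations.  Components whose score norm underflows (X block
    exhausted) end the extraction early with a logged warning.
    """
    x_names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{j + 1}" for j in range(np.asarray(X).shape[1])
    )
    y_names = tuple(Y.columns) if isinstance(Y, pd.DataFrame) else tuple(
        f"y{k + 1}" for k in range(np.atleast_2d(np.asarray(Y).T).shape[0])
    )
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if n < 2:
        raise ValueError("PLSR needs at least 2 samples")
    if not 1 <= ncomp <= min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    Xs, x_mean, x_sd = _autoscale(X, x_names, "X")
    Ys, y_mean, y_sd = _autoscale(Y, y_names, "Y")
    ss_y_total = float((Ys**2).sum())

    ss_x_total = float((Xs**2).sum())
    Xr, Yr = Xs.copy(), Ys.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    Q = np.zeros((m, ncomp))
    ssy = np.zeros(ncomp)
    a_done = 0
    for a in range(ncomp):
        if float((Xr**2).sum()) < 1e-12 * ss_x_total:
            log.warning("X block exhausted after %d component(s)", a)
            break
        # start u from the Y column with the largest residual variance
        u = Yr[:, int(np.argmax((Yr**2).sum(axis=0)))].copy()
        if float((u**2).sum()) < 1e-24:
            log.warning("Y block exhausted after %d component(s)", a)
            break
        t_old = np.zeros(n)
        exhausted = False
        for it in range(max_iter):
            w = Xr.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-12 * np.sqrt(ss_x_total):
                if a > 0:  # X carries no further covariance with Y
                    exhausted = True
                    break
                raise ConvergenceError(
                    f"degenerate weight vector at component {a + 1}"
                )
            w /= nw
            t = Xr @ w
            q = Yr.T @ t / float(t @ t)
            u = Yr @ q / float(q @ q) if float(q @ q) > 0 else t
            if np.linalg.norm(t - t_old) < tol:
                break
            t_old = t
        else:
            raise ConvergenceError(
                f"NIPALS did not converge in {max_iter} iterations "
                f"at component {a + 1}"
            )
        if exhausted:
            log.warning("X-Y covariance exhausted after %d component(s)", a)
            break
        tt = float(t @ t)
        p_a = Xr.T @ t / tt
        q_a = Yr.T @ t / tt
        Xr = Xr - np.outer(t, p_a)
        Yr = Yr - np.outer(t, q_a)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_a, t, q_a
        ssy[a] = tt * float(q_a @ q_a) / ss_y_total
        a_done = a + 1
    if a_done == 0:
        raise ConvergenceError("no PLSR component could be extracted")
    W, P, T, Q, ssy = W[:, :a_done], P[:, :a_done], T[:, :a_done], Q[:, :a_done], ssy[:a_done]
    coef = W @ np.linalg.solve(P.T @ W, Q.T)
    return PlsrFit(
        x_weights=W, x_loadings=P, x_scores=T, y_loadings=Q, coef=coef,
        explained_y_variance=ssy, ncomp=a_done,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        x_names=x_names, y_names=y_names,
    )


def select_ncomp(
    X, Y, threshold: float = 0.80, max_comp: int | None = None
) -> int:
    """Smallest component count whose cumulative explained Y-variance exceeds
    ``threshold``; returns ``max_comp`` with a warning if never exceeded."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n, p = np.asarray(X, float).shape
    cap = min(n - 1, p) if max_comp is None else min(max_comp, n - 1, p)
    best_a, cum_at_best = 1, 0.0
    for a in range(1, cap + 1):
        try:
            fit = nipals_plsr(X, Y, ncomp=a)
        except ConvergenceError:
            log.warning("component %d did not converge; stopping at %d", a, best_a)
            break
        cum = float(fit.explained_y_variance.sum())
        best_a, cum_at_best = fit.ncomp, cum
        if cum > threshold:
            return fit.ncomp
        if fit.ncomp < a:  # block exhausted before reaching a components
            break
    log.warning(
        "cumulative explained Y-variance %.3f never exceeded %.2f; using %d",
        cum_at_best, threshold, best_a,
    )
    return best_a


def vip(fit: PlsrFit) -> np.ndarray:
    """Variable Importance in Projection for every predictor.

    Mean of squared VIPs is 1 by construction (sum VIP_j^2 = p).
    """
    ss = fit.explained_y_variance
    total = ss.sum()
    if total <= 0:
        raise ValueError("zero explained Y-variance: VIP undefined")
    p = fit.x_weights.shape[0]
    wnorm2 = (fit.x_weights**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (fit.x_weights**2) / wnorm2  # p x A, columns sum to 1
    return np.sqrt(p * (contrib @ ss) / total)


def screen_vip(fit: PlsrFit, threshold: float = 1.0) -> list[str]:
    """Predictor names with VIP strictly above ``threshold``, descending VIP."""
    scores = vip(fit)
    order = np.argsort(-scores, kind="stable")
    return [fit.x_names[j] for j in order if scores[j] > threshold]
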