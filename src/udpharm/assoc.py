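"""Spearman rank-correlation matrices (liver vs gastric indicator heatmaps)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["CorMatrix", "spearman_matrix"]


@dataclass(frozen=True)
class CorMatrix:
    """Pairwise Spearman rho and p-values between two variable sets."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    p_adj: pd.DataFrame | None = None

    def to_long(self) -> pd.DataFrame:
        rows = []
        for r in self.rho.index:
            for c in self.rho.columns:
                rows.append(
                    {
                        "var1": r,
                        "var2": c,
                        "rho": self.rho.loc[r, c],
                        "p": self.p.loc[r, c],
                        "p_adj": (
                            self.p_adj.loc[r, c] if self.p_adj is not None else np.nan
                        ),
                        "n": self.n.loc[r, c],
                    }
                )
        return pd.DataFrame(rows)


def spearman_matrix(
    table: pd.DataFrame,
    rows: list[str],
    cols: list[str],
    adjust: str | None = None,
) -> CorMatrix:
    """Spearman correlations between two variable lists, pairwise complete.

    rho uses average ranks for ties; p comes from the t approximation with
    n - 2 df.  Constant variables yield NaN cells (flagged missing, not an
    error).  ``adjust='bh'`` adds Benjamini-Hochberg adjusted p-values
    across the whole matrix.
    """
    rho = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    pmat = pd.DataFrame(np.nan, index=rows, columns=cols, dtype=float)
    nmat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for r in rows:
        for c in cols:
            xs, ys = table[r], table[c]
            ok = xs.notna() & ys.notna()
            n = int(ok.sum())
            nmat.loc[r, c] = n
            if n < 4:
                continue
            x, y = xs[ok].to_numpy(float), ys[ok].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # undefined correlation: left as NaN
            res = stats.spearmanr(x, y)
            rho.loc[r, c] = res.statistic
            pmat.loc[r, c] = res.pvalue
    p_adj = None
    if adjust == "bh":
        flat = pmat.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p_adj = pd.DataFrame(adj.reshape(pmat.shape), index=rows, columns=cols)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return CorMatrix(rho=rho, p=pmat, n=nmat, p_adj=p_adj)
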