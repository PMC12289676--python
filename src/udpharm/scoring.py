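"""Efficacy scoring: macroscopic ulcer index, entropy-weight composites.

Two pieces of machinery live here.

*Ulcer index* (UI): each hemorrhagic lesion is scored 0-5 by length band
(punctate lesions score 1; <2 mm scores 2; 2-3 mm scores 3; 3-4 mm scores
4; >4 mm scores 5), the score doubles when the erosion width exceeds 1 mm,
and the UI is the sum over lesions.

*Composite efficacy indices* aggregate several indicators into one score
Y in [0, 1].  Each indicator is min-max normalized with an orientation
(higher-is-better or lower-is-better), and the normalized columns are
combined with entropy-weight-method (EWM) coefficients: indicators whose
distribution carries more information (lower Shannon entropy of the
normalized shares) receive larger weights.  With weights E_j and
normalized values z_sj, the composite is Y_s = sum_j E_j z_sj.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LesionRecord",
    "CompositeSpec",
    "ulcer_index",
    "lesion_score",
    "minmax_normalize",
    "entropy_weights",
    "composite_index",
    "zscore",
    "published_composites",
    "DegenerateColumnError",
]


class DegenerateColumnError(ValueError):
    """A column required to vary is constant (or otherwise uninformative)."""


@dataclass(frozen=True)
class LesionRecord:
    """One hemorrhagic lesion: length and erosion width in millimetres.

    ``punctate`` marks the small round lesions that score 1; when left None
    it defaults to ``length_mm < 1``.
    """

    length_mm: float
    width_mm: float
    punctate: bool | None = None

    def __post_init__(self) -> None:
        if self.length_mm < 0 or self.width_mm < 0:
            raise ValueError("lesion dimensions must be non-negative")

    @property
    def is_punctate(self) -> bool:
        if self.punctate is not None:
            return self.punctate
        return self.length_mm < 1.0


def lesion_score(lesion: LesionRecord) -> int:
    """Severity score of a single lesion (length band, width doubling)."""
    if lesion.is_punctate:
        base = 1
    elif lesion.length_mm < 2.0:
        base = 2
    elif lesion.length_mm <= 3.0:
        base = 3
    elif lesion.length_mm <= 4.0:
        base = 4
    else:
        base = 5
    return base * 2 if lesion.width_mm > 1.0 else base


def ulcer_index(lesions: list[LesionRecord]) -> int:
    """Ulcer index: sum of per-lesion severity scores (0 for no lesions)."""
    return sum(lesion_score(l) for l in lesions)


def minmax_normalize(values, orientation: str = "positive") -> np.ndarray:
    """Min-max normalize to [0, 1].

    ``positive`` (higher is better): (W - Wmin) / (Wmax - Wmin).
    ``negative`` (lower is better): (Wmax - W) / (Wmax - Wmin).
    """
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise DegenerateColumnError("constant column cannot be min-max normalized")
    if orientation == "positive":
        return (v - lo) / (hi - lo)
    if orientation == "negative":
        return (hi - v) / (hi - lo)
    raise ValueError(f"orientation must be 'positive' or 'negative', got {orientation!r}")


def entropy_weights(normalized: np.ndarray) -> np.ndarray:
    """Entropy-weight-method coefficients E_j for non-negative columns.

    p_ij = x_ij / sum_i x_ij; e_j = -(1/ln n) sum_i p_ij ln p_ij (0 ln 0 = 0);
    E_j = (1 - e_j) / sum_k (1 - e_k).  Columns with zero dispersion carry
    no information and get weight 0.
    """
    x = np.asarray(normalized, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if (x < 0).any():
        raise ValueError("entropy weights require non-negative entries")
    n = x.shape[0]
    colsums = x.sum(axis=0)
    d = np.zeros(x.shape[1])  # information content 1 - e_j per column
    for j in range(x.shape[1]):
        if colsums[j] == 0 or np.ptp(x[:, j]) == 0:
            continue  # constant column: zero information
        p = x[:, j] / colsums[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum() / np.log(n)
        d[j] = 1.0 - e
    total = d.sum()
    if total <= 0:
        raise DegenerateColumnError("all columns constant: entropy weights undefined")
    return d / total


@dataclass(frozen=True)
class CompositeSpec:
    """Specification of a composite index: components, orientations, weights.

    ``orientations`` maps each component to 'positive' or 'negative'.
    When ``weights`` is None the entropy-weight method supplies them.
    """

    name: str
    components: tuple[str, ...]
    orientations: dict[str, str] = field(default_factory=dict)
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for c in self.components:
            if self.orientations.get(c) not in ("positive", "negative"):
                raise ValueError(f"orientation missing/invalid for component {c!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, float)
            if len(w) != len(self.components):
                raise ValueError("one weight per component required")
            if (w < 0).any() or abs(w.sum() - 1.0) > 1e-4:
                raise ValueError("weights must be non-negative and sum to 1")


def composite_index(
    table: pd.DataFrame, spec: CompositeSpec
) -> tuple[pd.Series, np.ndarray]:
    """Composite score Y per sample plus the weights used.

    Components are min-max normalized per their orientation; weights come
    from the spec when given, otherwise from the EWM on the normalized
    matrix.  Y lies in [0, 1] by construction.
    """
    missing = [c for c in spec.components if c not in table.columns]
    if missing:
        raise KeyError(f"composite {spec.name}: missing components {missing}")
    z = np.column_stack(
        [
            minmax_normalize(table[c].to_numpy(float), spec.orientations[c])
            for c in spec.components
        ]
    )
    if spec.weights is not None:
        w = np.asarray(spec.weights, float)
    else:
        w = entropy_weights(z)
    scores = pd.Series(z @ w, index=table.index, name=f"Y_{spec.name}")
    return scores, w


def zscore(values) -> np.ndarray:
    """Z-score standardization (sample SD, ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateColumnError("zero-variance vector cannot be z-scored")
    return (v - v.mean()) / sd


def published_composites() -> dict[str, CompositeSpec]:
    """The six published composite-index specifications with their EWM weights.

    MRS (mucosal repair, from ulcer index + histopathological score), RF
    (regenerative factors EGF/EGFR), GIC/SIC/HIC (gastric/serum/hepatic
    inflammatory cytokines), LF (liver function ALT/AST/TBIL).  Injury and
    inflammation markers are lower-is-better; regenerative factors
    higher-is-better.
    """
    neg, pos = "negative", "positive"

    def spec(name, comps, orients, weights):
        return CompositeSpec(
            name=name,
            components=tuple(comps),
            orientations=dict(zip(comps, orients)),
            weights=tuple(weights),
        )

    return {
        "MRS": spec("MRS", ["UI", "HS"], [neg, neg], [0.5269, 0.4731]),
        "RF": spec("RF", ["EGF", "EGFR"], [pos, pos], [0.6304, 0.3696]),
        "GIC": spec(
            "GIC", ["IL1b_G", "IL6_G", "TNFa_G"], [neg, neg, neg],
            [0.2373, 0.3023, 0.4604],
        ),
        "SIC": spec(
            "SIC", ["IL1b_S", "IL6_S", "TNFa_S"], [neg, neg, neg],
            [0.3627, 0.4121, 0.2252],
        ),
        "LF": spec(
            "LF", ["ALT", "AST", "TBIL"], [neg, neg, neg],
            [0.3444, 0.3246, 0.3310],
        ),
        "HIC": spec("HIC", ["IL6_L", "TNFa_L"], [neg, neg], [0.5424, 0.4576]),
    }
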