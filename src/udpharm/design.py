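"""Uniform-design construction and dose mapping.

A uniform design (UD) spreads a small number of experimental runs evenly
over the factor space.  The classical good-lattice-point (GLP) construction
builds a U_n(n^s) table from a set of generators coprime with the run
count: column j of the table is the modular sequence
``level(i, j) = ((i * g_j - 1) mod n) + 1``, which is a permutation of
1..n.  Table quality is ranked by the centered L2 discrepancy (CD^2),
Hickernell's closed-form measure of how far the scaled design points
deviate from the uniform distribution on the unit cube.

The module also maps design levels to herb doses (linear, equally spaced
within per-herb ranges) and performs body-surface-area (BSA) interspecies
dose conversion.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignTable",
    "DoseMatrix",
    "glp_design",
    "centered_l2_discrepancy",
    "scale_doses",
    "bsa_convert",
    "DEFAULT_HERBS",
    "MHWP_DOSES_G",
    "default_dose_ranges",
]

#: Herb labels of the six-component reference formulation, in formula order:
#: Zingiberis Rhizoma, Glycyrrhizae Radix, Largehead Atractylodes Rhizome,
#: Codonopsis Radix, Forsythia Fruit, Pinelliae Rhizoma Praeparatum.
DEFAULT_HERBS: tuple[str, ...] = ("ZR", "GCR", "LAR", "CR", "FF", "PR")

#: Reference formulation doses in grams of crude drug per daily human dose.
MHWP_DOSES_G: dict[str, float] = {
    "ZR": 4.0, "GCR": 6.0, "LAR": 9.0, "CR": 6.0, "FF": 4.0, "PR": 6.0,
}


def default_dose_ranges(spread: float = 0.5) -> dict[str, tuple[float, float]]:
    """Per-herb [low, high] dose ranges: reference dose +/- ``spread`` fraction."""
    return {
        h: (d * (1.0 - spread), d * (1.0 + spread)) for h, d in MHWP_DOSES_G.items()
    }


class DesignError(ValueError):
    """Invalid uniform-design request (capacity or generator validation)."""


@dataclass(frozen=True)
class DesignTable:
    """A good-lattice-point uniform-design allocation table.

    ``levels`` is an (n_runs x n_factors) integer matrix with every column a
    permutation of 1..n_runs; ``generators`` holds the GLP generator used for
    each column.
    """

    levels: np.ndarray
    generators: tuple[int, ...]

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=int)
        object.__setattr__(self, "levels", levels)
        if levels.ndim != 2 or levels.size == 0:
            raise DesignError("design table must be a non-empty 2-D matrix")
        n = levels.shape[0]
        for j in range(levels.shape[1]):
            if sorted(levels[:, j]) != list(range(1, n + 1)):
                raise DesignError(
                    f"column {j} is not a permutation of 1..{n}: {levels[:, j]}"
                )

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def to_frame(self, factor_names: list[str] | None = None) -> pd.DataFrame:
        names = factor_names or [f"f{j + 1}" for j in range(self.n_factors)]
        df = pd.DataFrame(self.levels, columns=names)
        df.insert(0, "run", [f"UD{i + 1}" for i in range(self.n_runs)])
        return df


@dataclass(frozen=True)
class DoseMatrix:
    """Herb doses (grams) for each design run.

    Rows correspond 1:1 to design runs; ``dose_ranges`` records the per-herb
    [low, high] interval used for the level-to-dose mapping.
    """

    doses: np.ndarray
    herb_names: tuple[str, ...]
    dose_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    run_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        object.__setattr__(self, "doses", doses)
        if not self.run_ids:
            object.__setattr__(
                self, "run_ids", tuple(f"UD{i + 1}" for i in range(doses.shape[0]))
            )
        for j, h in enumerate(self.herb_names):
            lo, hi = self.dose_ranges.get(h, (-np.inf, np.inf))
            col = doses[:, j]
            if (col < lo - 1e-12).any() or (col > hi + 1e-12).any():
                raise DesignError(f"dose for {h} outside range [{lo}, {hi}]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.doses, columns=list(self.herb_names))
        df.insert(0, "run", list(self.run_ids))
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseMatrix":
        herbs = tuple(c for c in df.columns if c != "run")
        runs = tuple(df["run"]) if "run" in df.columns else ()
        return cls(df[list(herbs)].to_numpy(float), herbs, {}, runs)


def _glp_column(n_runs: int, g: int) -> np.ndarray:
    i = np.arange(1, n_runs + 1)
    return (i * g - 1) % n_runs + 1


def glp_design(
    n_runs: int,
    n_factors: int,
    generators: list[int] | None = None,
) -> DesignTable:
    """Construct a U_n(n^s) uniform-design table by the good-lattice-point rule.

    When ``generators`` is omitted, the s-subset of candidate generators
    (integers in [1, n_runs) coprime with n_runs) minimizing the centered L2
    discrepancy is chosen; ties break to the lexicographically smallest set.
    """
    if n_runs < 2:
        raise DesignError("n_runs must be >= 2")
    candidates = [g for g in range(1, n_runs) if math.gcd(g, n_runs) == 1]
    if generators is not None:
        generators = [int(g) for g in generators]
        if n_factors != len(generators):
            raise DesignError("generator count must equal n_factors")
        for g in generators:
            if g < 1 or math.gcd(g, n_runs) != 1:
                raise DesignError(f"generator {g} is not coprime with {n_runs}")
        if len(set(generators)) != len(generators):
            raise DesignError("generators must be pairwise distinct")
        chosen = generators
    else:
        if n_factors > len(candidates):
            raise DesignError(
                f"n_factors={n_factors} exceeds capacity {len(candidates)} "
                f"for n_runs={n_runs}"
            )
        best: tuple[int, ...] | None = None
        best_cd2 = np.inf
        for subset in itertools.combinations(candidates, n_factors):
            cd2 = _cd2_levels(
                np.column_stack([_glp_column(n_runs, g) for g in subset]), n_runs
            )
            # strict < keeps the lexicographically first subset on ties
            if cd2 < best_cd2 - 1e-12:
                best, best_cd2 = subset, cd2
        assert best is not None
        chosen = list(best)
    levels = np.column_stack([_glp_column(n_runs, g) for g in chosen])
    return DesignTable(levels=levels, generators=tuple(chosen))


def _cd2_levels(levels: np.ndarray, n_runs: int) -> float:
    u = (levels - 0.5) / n_runs
    return _cd2_points(u)


def _cd2_points(u: np.ndarray) -> float:
    """Hickernell's centered L2 discrepancy (squared) of points in (0,1)^s."""
    n, s = u.shape
    a = np.abs(u - 0.5)
    term1 = (13.0 / 12.0) ** s
    term2 = (2.0 / n) * np.prod(1.0 + 0.5 * a - 0.5 * a**2, axis=1).sum()
    # pairwise product kernel
    diff = np.abs(u[:, None, :] - u[None, :, :])
    kern = 1.0 + 0.5 * a[:, None, :] + 0.5 * a[None, :, :] - 0.5 * diff
    term3 = np.prod(kern, axis=2).sum() / n**2
    return float(term1 - term2 + term3)


def centered_l2_discrepancy(table: DesignTable) -> float:
    """CD^2 of a design table, levels mapped to (level - 0.5) / n_runs."""
    return _cd2_levels(table.levels, table.n_runs)


def scale_doses(
    table: DesignTable,
    dose_ranges: dict[str, tuple[float, float]],
    herb_names: tuple[str, ...] | None = None,
) -> DoseMatrix:
    """Map design levels linearly onto per-herb dose ranges (grams).

    Level 1 maps to the low end, level n_runs to the high end, with doses
    equally spaced across levels.
    """
    herbs = tuple(herb_names) if herb_names else tuple(dose_ranges)
    if len(herbs) != table.n_factors:
        raise DesignError(
            f"{len(herbs)} dose ranges supplied for {table.n_factors} factors"
        )
    cols = []
    for j, h in enumerate(herbs):
        lo, hi = dose_ranges[h]
        if not lo < hi:
            raise DesignError(f"range for {h} must satisfy low < high")
        frac = (table.levels[:, j] - 1) / (table.n_runs - 1)
        cols.append(lo + frac * (hi - lo))
    return DoseMatrix(
        doses=np.column_stack(cols), herb_names=herbs,
        dose_ranges={h: dose_ranges[h] for h in herbs},
    )


def bsa_convert(
    human_daily_dose_g: float, human_mass_kg: float, factor: float = 6.3
) -> float:
    """Body-surface-area interspecies dose conversion.

    Returns the animal-equivalent dose in g/kg/day:
    ``human_daily_dose_g / human_mass_kg * factor``.
    """
    if human_daily_dose_g <= 0 or human_mass_kg <= 0 or factor <= 0:
        raise ValueError("all BSA conversion inputs must be positive")
    return human_daily_dose_g / human_mass_kg * factor
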