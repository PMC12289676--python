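"""Synthetic study generator.

Emulates the data structure of the rat gastric-mucosal-injury experiment:
10 groups (healthy control, injured model, reference formulation MHWP,
and seven uniform-design formulations UD1-UD7), n animals per group, with

* an animal-level indicator table (pharmacological endpoints and liver
  markers),
* a genus-level relative-abundance table (rows sum to 1, via a softmax of
  Gaussian latents), and
* an HPLC characteristic-peak area table (positive, log-normal).

Every endpoint follows a known sparse polynomial model in the herb doses
(linear / quadratic / interaction terms on the standardized dose scale),
mediators follow declared directed paths, and outcomes add their mediator
contributions — so each downstream analysis stage has a recorded ground
truth to recover.  Noise is independent Gaussian per variable, drawn from
a per-variable RNG stream keyed by (seed, variable name), which makes
every table deterministic under a fixed seed and leaves a variable's draw
unchanged when unrelated variables are added or removed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .design import (
    DEFAULT_HERBS,
    MHWP_DOSES_G,
    DoseMatrix,
    default_dose_ranges,
    glp_design,
    scale_doses,
)
from .herbfx import expand_poly_terms

__all__ = [
    "EndpointModel",
    "MediatorModel",
    "StudyConfig",
    "StudyDataset",
    "default_config",
    "simulate_endpoints",
    "simulate_mediators",
    "simulate_study",
]

GROUPS = ("control", "model", "MHWP") + tuple(f"UD{i}" for i in range(1, 8))


def _rng(seed: int, name: str) -> np.random.Generator:
    """Per-variable RNG stream, stable across runs and config edits."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class EndpointModel:
    """Ground-truth dose model for one endpoint.

    Treated animals (MHWP, UD runs) get ``intercept + sum(beta_t * term_t)``
    on the standardized-term scale; control and model animals get their
    configured group means (healthy baseline vs. injury offset).
    """

    intercept: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25
    control_mean: float = 0.0
    model_mean: float = 0.0


@dataclass(frozen=True)
class MediatorModel:
    """Ground-truth model for one mediator.

    ``parents`` maps upstream variables (herb-dose terms, endpoints or
    other mediators) to path coefficients.  ``kind`` decides which output
    table the mediator lands in: 'plain' columns join the animal table
    (liver markers), 'genus' latents go through the per-row softmax into
    the relative-abundance table, 'peak' latents are exponentiated into
    the peak-area table.
    """

    parents: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.25
    kind: str = "plain"

    def __post_init__(self) -> None:
        if self.kind not in ("plain", "genus", "peak"):
            raise ValueError(f"unknown mediator kind {self.kind!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass(frozen=True)
class StudyConfig:
    """Full specification of a synthetic study."""

    n_per_group: int = 5
    herbs: tuple[str, ...] = DEFAULT_HERBS
    dose_ranges: dict[str, tuple[float, float]] = field(
        default_factory=default_dose_ranges
    )
    n_runs: int = 7
    generators: tuple[int, ...] | None = None
    endpoints: dict[str, EndpointModel] = field(default_factory=dict)
    mediators: dict[str, MediatorModel] = field(default_factory=dict)
    outcome_paths: dict[str, dict[str, float]] = field(default_factory=dict)
    n_genera: int = 10
    n_peaks: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        declared = set(self.endpoints) | set(self.mediators)
        for m, spec in self.mediators.items():
            for p in spec.parents:
                if p not in declared and not _is_term(p, self.herbs):
                    raise ValueError(f"mediator {m}: undeclared parent {p!r}")
        for e, paths in self.outcome_paths.items():
            if e not in self.endpoints:
                raise ValueError(f"outcome path target {e!r} has no endpoint model")
            for m in paths:
                if m not in self.mediators:
                    raise ValueError(f"outcome {e}: undeclared mediator {m!r}")


def _is_term(name: str, herbs: tuple[str, ...]) -> bool:
    from .herbfx import poly_term_names

    return name in poly_term_names(herbs)


@dataclass
class StudyDataset:
    """Generated study bundle: doses, animal indicators, genera, peaks."""

    doses: pd.DataFrame  # run x herb grams (UD runs + MHWP reference row)
    animals: pd.DataFrame  # animal_id, group, run, endpoint + liver columns
    genera: pd.DataFrame  # animal_id index, relative abundances summing to 1
    peaks: pd.DataFrame  # animal_id index, positive peak areas
    ground_truth: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.doses.to_csv(out / "doses.csv", index=False)
        self.animals.to_csv(out / "animals.csv", index=False)
        self.genera.to_csv(out / "genera.csv")
        self.peaks.to_csv(out / "peaks.csv")
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, outdir: str | Path) -> "StudyDataset":
        out = Path(outdir)
        return cls(
            doses=pd.read_csv(out / "doses.csv"),
            animals=pd.read_csv(
                out / "animals.csv", keep_default_na=False, na_values=["NA"]
            ),
            genera=pd.read_csv(out / "genera.csv", index_col=0),
            peaks=pd.read_csv(out / "peaks.csv", index_col=0),
            ground_truth=json.loads((out / "ground_truth.json").read_text()),
        )


def _dose_tables(config: StudyConfig) -> tuple[DoseMatrix, pd.DataFrame]:
    table = glp_design(
        config.n_runs,
        len(config.herbs),
        list(config.generators) if config.generators else None,
    )
    dm = scale_doses(table, config.dose_ranges, config.herbs)
    doses = dm.to_frame()
    mhwp = {"run": "MHWP", **{h: MHWP_DOSES_G.get(h, np.nan) for h in config.herbs}}
    doses = pd.concat([doses, pd.DataFrame([mhwp])], ignore_index=True)
    return dm, doses


def _animal_frame(config: StudyConfig) -> pd.DataFrame:
    rows = []
    for g in GROUPS[: 3 + config.n_runs]:
        for k in range(config.n_per_group):
            rows.append(
                {
                    "animal_id": f"{g}_{k + 1}",
                    "group": g,
                    "run": g if g == "MHWP" or g.startswith("UD") else "",
                }
            )
    return pd.DataFrame(rows)


def _term_values(config: StudyConfig, animals: pd.DataFrame, dm: DoseMatrix):
    """Standardized term value per animal; 0 (the mean) for undosed animals."""
    terms = expand_poly_terms(dm, standardize_doses=True)
    # standardize term columns across the UD runs (the regression scale)
    std = {}
    for c in terms.columns:
        col = terms[c].to_numpy(float)
        sd = col.std(ddof=1)
        std[c] = (col - col.mean()) / sd if sd > 0 else col * 0.0
    tstd = pd.DataFrame(std, index=terms.index)
    # MHWP reference row mapped through the same (UD-derived) standardization
    mh_doses = np.array([MHWP_DOSES_G.get(h, np.nan) for h in config.herbs])
    mu, sd = dm.doses.mean(axis=0), dm.doses.std(axis=0, ddof=1)
    zmh = (mh_doses - mu) / sd
    mh_row = {}
    import itertools as _it

    herbs = config.herbs
    vals = dict(zip(herbs, zmh))
    raw = {h: vals[h] for h in herbs}
    raw.update({f"{h}^2": vals[h] ** 2 for h in herbs})
    raw.update(
        {f"{a}*{b}": vals[a] * vals[b] for a, b in _it.combinations(herbs, 2)}
    )
    for c in terms.columns:
        col = terms[c].to_numpy(float)
        sdv = col.std(ddof=1)
        mh_row[c] = (raw[c] - col.mean()) / sdv if sdv > 0 else 0.0
    per_animal = {}
    for c in tstd.columns:
        vmap = dict(zip(tstd.index, tstd[c]))
        vmap["MHWP"] = mh_row[c]
        per_animal[c] = animals["run"].map(lambda r: vmap.get(r, 0.0)).to_numpy()
    return pd.DataFrame(per_animal, index=animals.index)


def simulate_endpoints(config: StudyConfig) -> pd.DataFrame:
    """Animal-level endpoint table (without mediator contributions)."""
    dm, _ = _dose_tables(config)
    animals = _animal_frame(config)
    tv = _term_values(config, animals, dm)
    for name, em in config.endpoints.items():
        systematic = _endpoint_systematic(animals, tv, em)
        noise = _rng(config.seed, f"endpoint:{name}").normal(
            0.0, em.noise_sd, len(animals)
        )
        animals[name] = systematic + noise
    return animals


def _endpoint_systematic(
    animals: pd.DataFrame, tv: pd.DataFrame, em: EndpointModel
) -> np.ndarray:
    dosed = animals["run"] != ""
    out = np.where(
        animals["group"] == "control",
        em.control_mean,
        np.where(animals["group"] == "model", em.model_mean, em.intercept),
    ).astype(float)
    contrib = np.zeros(len(animals))
    for t, beta in em.terms.items():
        contrib += beta * tv[t].to_numpy()
    out = out + np.where(dosed, contrib, 0.0)
    return out


def _mediator_order(config: StudyConfig) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(config.mediators)
    for m, spec in config.mediators.items():
        for p in spec.parents:
            if p in config.mediators:
                g.add_edge(p, m)
    if not nx.is_directed_acyclic_graph(g):
        raise nx.NetworkXUnfeasible("cyclic mediation specification")
    return list(nx.lexicographical_topological_sort(g))


def simulate_mediators(
    config: StudyConfig, endpoints: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate mediator latents, compose output tables, add outcome paths.

    Returns (genera, peaks, animals-with-liver-columns-and-final-outcomes).
    Mediators are evaluated in topological order; genus latents pass
    through a per-row softmax (rows sum to 1), peak latents are
    exponentiated (positive areas).  Endpoints that receive mediator paths
    gain those contributions on top of their simulated values.
    """
    animals = endpoints.copy()
    dm, _ = _dose_tables(config)
    tv = _term_values(config, animals, dm)
    latents: dict[str, np.ndarray] = {}

    def upstream(name: str) -> np.ndarray:
        if name in latents:
            return latents[name]
        if name in tv.columns:
            return tv[name].to_numpy()
        if name in animals.columns:
            return animals[name].to_numpy(float)
        raise KeyError(f"unknown mediator parent {name!r}")

    for m in _mediator_order(config):
        spec = config.mediators[m]
        val = np.zeros(len(animals))
        for p, beta in spec.parents.items():
            val = val + beta * upstream(p)
        val = val + _rng(config.seed, f"mediator:{m}").normal(
            0.0, spec.noise_sd, len(animals)
        )
        latents[m] = val
        if spec.kind == "plain":
            animals[m] = val

    # outcome contributions
    for e, paths in config.outcome_paths.items():
        contrib = np.zeros(len(animals))
        for m, beta in paths.items():
            contrib += beta * latents[m]
        animals[e] = animals[e].to_numpy(float) + contrib

    idx = animals["animal_id"]
    genera = _compose_genera(config, latents, len(animals), idx)
    peaks = _compose_peaks(config, latents, len(animals), idx)
    return genera, peaks, animals


def _compose_genera(config, latents, n, idx) -> pd.DataFrame:
    driven = [m for m, s in config.mediators.items() if s.kind == "genus"]
    cols = {}
    for m in driven:
        cols[m] = latents[m]
    k = 0
    while len(cols) < config.n_genera:
        k += 1
        name = f"g{k:02d}"
        if name in cols:
            continue
        cols[name] = _rng(config.seed, f"genus:{name}").normal(0.0, 1.0, n)
    lat = np.column_stack(list(cols.values()))
    expv = np.exp(lat - lat.max(axis=1, keepdims=True))
    rel = expv / expv.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, columns=list(cols.keys()), index=idx)


def _compose_peaks(config, latents, n, idx) -> pd.DataFrame:
    driven = [m for m, s in config.mediators.items() if s.kind == "peak"]
    cols = {}
    for m in driven:
        cols[m] = latents[m]
    k = 0
    while len(cols) < config.n_peaks:
        k += 1
        name = f"P{k}"
        if name in cols:
            continue
        cols[name] = _rng(config.seed, f"peak:{name}").normal(0.0, 1.0, n)
    lat = np.column_stack(list(cols.values()))
    return pd.DataFrame(np.exp(lat), columns=list(cols.keys()), index=idx)


def simulate_study(config: StudyConfig) -> StudyDataset:
    """Full synthetic study: design -> doses -> endpoints -> mediators."""
    _, doses = _dose_tables(config)
    endpoints = simulate_endpoints(config)
    genera, peaks, animals = simulate_mediators(config, endpoints)
    truth = {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "herbs": list(config.herbs),
        "endpoints": {
            k: {
                "intercept": v.intercept,
                "terms": v.terms,
                "noise_sd": v.noise_sd,
                "control_mean": v.control_mean,
                "model_mean": v.model_mean,
            }
            for k, v in config.endpoints.items()
        },
        "mediators": {
            k: {"parents": v.parents, "noise_sd": v.noise_sd, "kind": v.kind}
            for k, v in config.mediators.items()
        },
        "outcome_paths": config.outcome_paths,
    }
    return StudyDataset(
        doses=doses, animals=animals, genera=genera, peaks=peaks, ground_truth=truth
    )


def default_config(seed: int = 0, noise_sd: float = 0.25) -> StudyConfig:
    """Study conditions mirroring the rat experiment's structure.

    Ten groups of five animals; endpoint ground truths follow the study's
    qualitative narrative (ZR-centered effects with GCR/LAR/PR support on
    repair and inflammation endpoints); one liver-marker, one genus and
    one peak mediator carry mediation paths into gastric outcomes.
    Endpoints are on a standardized scale: healthy baseline vs. injury
    offset at -/+2 SD-equivalents, treated intercept in between.
    """
    inj = dict(control_mean=-2.0, model_mean=2.0, intercept=0.5, noise_sd=noise_sd)
    reg = dict(control_mean=0.0, model_mean=-2.0, intercept=-0.5, noise_sd=noise_sd)
    endpoints = {
        # mucosal repair block (lower is better)
        "UI": EndpointModel(terms={"ZR^2": -0.9, "ZR*PR": -0.8, "ZR*GCR": -0.4}, **inj),
        "HS": EndpointModel(terms={"ZR^2": -0.8, "ZR*PR": -0.7}, **inj),
        # regenerative factors (higher is better)
        "EGF": EndpointModel(terms={"ZR": 1.0, "ZR*GCR": 0.3}, **reg),
        "EGFR": EndpointModel(terms={"ZR": 0.8, "ZR*LAR": 0.3}, **reg),
        # gastric cytokines
        "IL1b_G": EndpointModel(terms={"ZR*LAR": -0.8, "ZR*CR": -0.5}, **inj),
        "IL6_G": EndpointModel(terms={"ZR*LAR": -0.7, "LAR*CR": -0.5}, **inj),
        "TNFa_G": EndpointModel(terms={"ZR*CR": -0.8, "ZR*LAR": -0.4}, **inj),
        # serum cytokines
        "IL1b_S": EndpointModel(terms={"ZR": -0.9, "ZR*PR": -0.3}, **inj),
        "IL6_S": EndpointModel(terms={"ZR": -0.8, "ZR*FF": -0.3}, **inj),
        "TNFa_S": EndpointModel(terms={"ZR": -0.7, "PR^2": 0.2}, **inj),
        # liver function markers
        "ALT": EndpointModel(terms={"ZR": -0.8, "ZR*PR": -0.3}, **inj),
        "AST": EndpointModel(terms={"ZR": -0.7, "ZR*FF": -0.3}, **inj),
        "TBIL": EndpointModel(terms={"ZR": -0.6, "GCR^2": -0.2}, **inj),
        # hepatic cytokines
        "IL6_L": EndpointModel(terms={"ZR": -0.9, "ZR*CR": -0.4}, **inj),
        "TNFa_L": EndpointModel(terms={"ZR": -0.8, "ZR*LAR": -0.4}, **inj),
        # gastroprotective mediator-fed endpoints
        "NO": EndpointModel(terms={"ZR": 0.4}, **reg),
        "PGE2": EndpointModel(terms={"ZR": 0.4}, **reg),
    }
    mediators = {
        "NFkB_L": MediatorModel(parents={"ZR^2": -0.8}, noise_sd=noise_sd),
        "Lactobacillus": MediatorModel(
            parents={"ZR": 0.8}, noise_sd=noise_sd, kind="genus"
        ),
        "P3": MediatorModel(parents={"ZR*PR": 0.8}, noise_sd=noise_sd, kind="peak"),
    }
    outcome_paths = {
        "UI": {"NFkB_L": 0.7},
        "NO": {"Lactobacillus": 0.7},
        "PGE2": {"P3": 0.7},
    }
    return StudyConfig(
        endpoints=endpoints,
        mediators=mediators,
        outcome_paths=outcome_paths,
        seed=seed,
    )
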