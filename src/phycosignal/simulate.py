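"""Synthetic data with known ground truth for every stage of the pipeline.

Three generators:

* Yule (pure-birth) trees with exponential waiting times, optionally
  branch-jittered so the tree is non-ultrametric like a real phylogram;
* trait vectors evolved on a tree under any of the five models (BM by a
  recursive walk, OU by its exact Gaussian transition, δ/λ as a single
  multivariate-normal draw from the transformed covariance, WN ignoring
  the tree) — the simulator behind traitgram figures and the parametric
  bootstrap;
* plate-reader fluorescence experiments: 14-day RFU series per well from
  Monod or light-optimum growth truths over the experimental resource
  grids, with an optional logistic density cap and multiplicative
  lognormal noise, retaining the true r and R* so downstream estimates
  can be scored as recovery error.

Everything is seed-deterministic.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .growth import FluorescenceSeries, MonodParams, solve_rstar
from .trees import PhyloTree, transform_covariance

__all__ = [
    "NITRATE_GRID",
    "PHOSPHATE_GRID",
    "LIGHT_GRID",
    "SimulationSpec",
    "PlateSpec",
    "generate_tree",
    "simulate_traits",
    "generate_plate_experiment",
    "plate_to_frame",
]

# experimental treatment grids (resource levels applied to each species):
# nitrate and phosphate in μmol L⁻¹, light in μEinstein m⁻² s⁻¹
NITRATE_GRID = (0.0, 0.2, 2.0, 20.0, 100.0, 200.0)
PHOSPHATE_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0)
LIGHT_GRID = (0.0, 1.0, 7.5, 10.0, 32.5, 48.0, 113.5, 133.0, 162.5,
              198.5, 210.5, 237.0, 248.5, 311.5)

_GRIDS = {"nitrate": NITRATE_GRID, "phosphate": PHOSPHATE_GRID, "light": LIGHT_GRID}


# ---------------------------------------------------------------------------
# trees


def generate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: Optional[int] = None,
    jitter_sd: float = 0.0,
) -> PhyloTree:
    """Yule pure-birth tree with ``n_tips`` extant tips.

    The simulation stops at the n-th birth, which would leave the two
    newest tip branches with zero length, so every tip edge is extended by
    the waiting time to the next speciation event (Exponential with rate
    n·birth_rate), keeping the tree ultrametric with strictly positive
    branches.  ``jitter_sd`` > 0 multiplies every branch by an independent
    lognormal factor, mimicking the rate heterogeneity of a phylogram.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng_py = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng_py
    )
    dtree.seed_node.edge.length = None
    rng = np.random.default_rng(seed)
    extra = float(rng.exponential(1.0 / (n_tips * birth_rate)))
    for lf in dtree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    # readable deterministic labels s01, s02, ...
    width = len(str(n_tips))
    for i, lf in enumerate(dtree.leaf_node_iter(), start=1):
        lf.taxon.label = f"s{i:0{width}d}"
    if jitter_sd > 0:
        for nd in dtree.preorder_node_iter():
            if nd is dtree.seed_node or nd.edge.length is None:
                continue
            nd.edge.length *= float(rng.lognormal(0.0, jitter_sd))
    return PhyloTree(dtree)


# ---------------------------------------------------------------------------
# trait evolution


@dataclass(frozen=True)
class SimulationSpec:
    """Trait-evolution scenario: which model generated the data and with
    what parameters.  ``sigma2`` is the BM rate, ``root`` the ancestral
    state; ``theta``/``alpha_ou`` apply to OU, ``delta``/``lam`` to the
    tree transforms."""

    model: str
    sigma2: float = 1.0
    root: float = 0.0
    theta: float = 0.0
    alpha_ou: float = 0.0
    delta: float = 1.0
    lam: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.model not in ("BM", "OU", "WN", "delta", "lambda"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.model == "OU" and not (0.0 <= self.alpha_ou <= 1000.0):
            raise ValueError("alpha_ou outside [0, 1000]")
        if self.model == "delta" and not (0.0 < self.delta <= 10.0):
            raise ValueError("delta outside (0, 10]")
        if self.model == "lambda" and not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda outside [0, 1]")


def simulate_traits(tree: PhyloTree, spec: SimulationSpec | None = None, **kwargs) -> pd.Series:
    """One trait vector evolved on the tree under ``spec``.

    Accepts either a :class:`SimulationSpec` or its fields as keyword
    arguments (``model=, sigma2=, root=, theta=, alpha_ou=, delta=, lam=,
    seed=``).  Returns a Series indexed by tip label.
    """
    if spec is None:
        spec = SimulationSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SimulationSpec or keyword fields, not both")
    rng = np.random.default_rng(spec.seed)
    labels = tree.tip_labels
    n = len(labels)

    if spec.model == "WN":
        vals = spec.root + np.sqrt(spec.sigma2) * rng.standard_normal(n)
        return pd.Series(vals, index=labels)

    if spec.model in ("delta", "lambda"):
        c = tree.covariance()
        param = spec.delta if spec.model == "delta" else spec.lam
        if spec.model == "lambda" and param == 1.0 or spec.model == "delta" and param == 1.0:
            ct = c.to_numpy()
        else:
            ct = transform_covariance(c, spec.model, param).to_numpy()
        cov = spec.sigma2 * ct
        # eigen factorisation tolerates the PSD boundary (λ = 0 off-tree noise)
        w, v = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        z = rng.standard_normal(n)
        vals = spec.root + v @ (np.sqrt(w) * z)
        return pd.Series(vals, index=labels)

    # BM and OU: recursive walk along branches with exact transitions
    dtree = tree._tree
    states = {dtree.seed_node: spec.root}
    sig = np.sqrt(spec.sigma2)
    a = spec.alpha_ou
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        parent = states[nd.parent_node]
        b = nd.edge.length
        if spec.model == "BM" or a <= 1e-12:
            mean, var = parent, spec.sigma2 * b
        else:
            decay = np.exp(-a * b)
            mean = spec.theta + (parent - spec.theta) * decay
            var = spec.sigma2 * (1.0 - np.exp(-2.0 * a * b)) / (2.0 * a)
        states[nd] = mean + np.sqrt(var) * rng.standard_normal()
    vals = {lf.taxon.label: states[lf] for lf in dtree.leaf_node_iter()}
    return pd.Series([vals[l] for l in labels], index=labels)


# ---------------------------------------------------------------------------
# plate-reader experiments


@dataclass(frozen=True)
class PlateSpec:
    """One synthetic resource-limitation experiment for one species.

    ``truth`` holds the generating growth-response parameters; readings
    run daily from day 0 through ``days``; ``f0`` is the fluorescence
    equivalent of the inoculation density (600 cells mL⁻¹); a finite
    ``carrying_capacity`` caps trajectories logistically, producing the
    density-dependent plateau that the suffix-trimming rule must handle;
    ``noise_sd`` is the sd of multiplicative lognormal noise on RFU.
    """

    truth: MonodParams
    resource_kind: str = "nitrate"
    grid: Sequence[float] = ()
    days: int = 14
    replicates: int = 2
    f0: float = 600.0
    carrying_capacity: Optional[float] = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.days < 2:
            raise ValueError("days must be >= 2")
        if any(g < 0 for g in self.grid):
            raise ValueError("resource grid must be non-negative")

    def resolved_grid(self) -> tuple:
        return tuple(self.grid) if self.grid else _GRIDS[self.resource_kind]


def _trajectory(f0: float, r: float, t: np.ndarray, cap: Optional[float]) -> np.ndarray:
    if cap is None or r <= 0:
        return f0 * np.exp(r * t)
    # logistic solution with intrinsic rate r and carrying capacity cap
    e = np.exp(r * t)
    return cap * f0 * e / (cap + f0 * (e - 1.0))


def generate_plate_experiment(
    spec: PlateSpec, seed: Optional[int] = None, species_id: str = "sp"
) -> tuple[list[FluorescenceSeries], dict]:
    """Simulate all wells of one species' resource-limitation experiment.

    Returns the list of per-well fluorescence series plus a ground-truth
    record: the generating net growth rate at each treatment and the true
    R* implied by the generating parameters.
    """
    rng = np.random.default_rng(seed)
    grid = spec.resolved_grid()
    t = np.arange(spec.days + 1, dtype=float)
    series: list[FluorescenceSeries] = []
    true_r = {}
    for level in grid:
        r = float(spec.truth.mu(level))
        true_r[level] = r
        for rep in range(1, spec.replicates + 1):
            f = _trajectory(spec.f0, r, t, spec.carrying_capacity)
            if spec.noise_sd > 0:
                f = f * rng.lognormal(0.0, spec.noise_sd, size=f.size)
            series.append(
                FluorescenceSeries(
                    species_id=species_id,
                    treatment_value=float(level),
                    replicate=rep,
                    readings=tuple(zip((int(d) for d in t), f.tolist())),
                    resource_kind=spec.resource_kind,
                )
            )
    rstar = solve_rstar(spec.truth, species_id, spec.resource_kind)
    truth = {
        "species_id": species_id,
        "resource_kind": spec.resource_kind,
        "true_r": true_r,
        "true_rstar": rstar.value,
        "attainable": rstar.attainable,
        "params": spec.truth,
    }
    return series, truth


def plate_to_frame(series: Sequence[FluorescenceSeries]) -> pd.DataFrame:
    """Long-format plate table: species_id, resource_kind, treatment_value,
    replicate, day, rfu — the CSV layout the growth pipeline reads."""
    rows = []
    for s in series:
        for day, rfu in s.readings:
            rows.append((s.species_id, s.resource_kind, s.treatment_value,
                         s.replicate, day, rfu))
    return pd.DataFrame(
        rows,
        columns=["species_id", "resource_kind", "treatment_value",
                 "replicate", "day", "rfu"],
    )
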