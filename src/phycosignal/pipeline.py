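"""End-to-end orchestration: traits table + tree → signal, Mantel and
model-selection tables with bootstrap significance flags.

`run_analysis` reproduces the structure of a comparative study of
competitive traits: for every trait it prunes the tree to species with
data, applies the configured transform (log10 for size-like traits),
computes the three signal statistics with their tests, a Mantel test of
patristic versus trait distance, the five trait-evolution model fits with
Akaike weights, and flags δ̂/λ̂/α̂ estimates that fall outside a shared
parametric-bootstrap BM null computed once on the full tree.  All
randomness flows from one master seed, so a rerun with the same
configuration is bit-identical.

`fit_growth_traits` is the upstream half: a long-format plate-reader
table in, a species × resource trait table (α, μ_max, R*) out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import growth as gk
from .models import (BootstrapNull, akaike_weights, bootstrap_bm_null,
                     fit_all_models)
from .signal import euclidean_trait_distance, mantel_test, phylo_signal
from .trees import PhyloTree

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "prune_to_shared",
    "run_analysis",
    "fit_growth_traits",
    "write_report",
]


@dataclass(frozen=True)
class AnalysisConfig:
    tree: PhyloTree
    traits: pd.DataFrame  # species in the index, one column per trait
    transforms: dict = field(default_factory=dict)  # trait -> "none" | "log10"
    n_rand: int = 999
    n_perm: int = 999
    n_sim: int = 1000
    seed: Optional[int] = None
    weight_threshold: float = 0.5
    min_species: int = 4

    def __post_init__(self):
        for nm, val in (("n_rand", self.n_rand), ("n_perm", self.n_perm),
                        ("n_sim", self.n_sim)):
            if val < 1:
                raise ValueError(f"{nm} must be >= 1")
        if not (0.0 < self.weight_threshold <= 1.0):
            raise ValueError("weight_threshold must be in (0, 1]")


@dataclass(frozen=True)
class AnalysisReport:
    signal_table: pd.DataFrame
    mantel_table: pd.DataFrame
    model_table: pd.DataFrame
    null: BootstrapNull
    metadata: dict


def prune_to_shared(
    tree: PhyloTree, table: pd.DataFrame, trait: str, min_species: int = 4
) -> tuple[PhyloTree, pd.Series]:
    """Subtree and trait vector for the species with data on ``trait``.

    Degree-2 nodes created by pruning are suppressed with branch lengths
    summed, so patristic distances among the retained species are exactly
    those of the full tree.
    """
    col = table[trait]
    shared = [t for t in tree.tip_labels if t in col.index and pd.notna(col.get(t))]
    if len(shared) < min_species:
        raise ValueError(
            f"trait {trait!r}: only {len(shared)} species shared with the tree "
            f"(need {min_species})"
        )
    sub = tree.prune_to(shared)
    return sub, col.reindex(sub.tip_labels).astype(float)


def _apply_transform(x: pd.Series, how: str, trait: str) -> pd.Series:
    if how in (None, "none", ""):
        return x
    if how == "log10":
        if (x <= 0).any():
            raise ValueError(f"trait {trait!r}: log10 transform needs positive values")
        return np.log10(x)
    raise ValueError(f"unknown transform {how!r} for trait {trait!r}")


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Full comparative analysis; see the module docstring for the stages."""
    tree, table = config.tree, config.traits
    overlap = set(tree.tip_labels) & set(table.index)
    if not overlap:
        raise ValueError(
            "no overlap between tree tips and trait table species; tips="
            f"{tree.tip_labels[:5]}..., table={list(table.index[:5])}..."
        )

    master = np.random.default_rng(config.seed)
    boot_seed = int(master.integers(0, 2**31 - 1))
    null = bootstrap_bm_null(tree, n_sim=config.n_sim, seed=boot_seed)

    pd_full = tree.cophenetic_distances()
    signal_rows, mantel_rows, model_rows = [], [], []
    skipped = {}
    for trait in table.columns:
        trait_seed = int(master.integers(0, 2**31 - 1))
        try:
            sub, x = prune_to_shared(tree, table, trait, config.min_species)
            x = _apply_transform(x, config.transforms.get(trait, "none"), trait)
            if np.allclose(x, x.iloc[0]):
                raise ValueError(f"trait {trait!r} has zero variance")
        except ValueError as exc:
            skipped[trait] = str(exc)
            continue

        sig = phylo_signal(sub, x, trait_name=trait, n_rand=config.n_rand,
                           seed=trait_seed)
        signal_rows.append({
            "trait": trait, "K": sig.k_stat, "p_K": sig.p_k,
            "lambda": sig.lambda_hat, "p_lambda": sig.p_lambda,
            "moran_I": sig.moran_i, "p_I": sig.p_i, "N": sig.n,
        })

        pd_sub = pd_full.loc[sub.tip_labels, sub.tip_labels]
        td = euclidean_trait_distance(x)
        man = mantel_test(pd_sub, td, n_perm=config.n_perm,
                          seed=trait_seed, trait_name=trait)
        mantel_rows.append({"trait": trait, "z": man.z_stat, "p": man.p})

        fits = fit_all_models(sub, x)
        sel = akaike_weights(fits, threshold=config.weight_threshold)
        by_model = {f.model: f for f in fits}
        d_hat = by_model["delta"].params["delta"]
        l_hat = by_model["lambda"].params["lambda"]
        a_hat = by_model["OU"].params["alpha_ou"]
        model_rows.append({
            "trait": trait, "best_model": sel.best,
            **{f"w_{m}": sel.weights[m] for m in ("WN", "BM", "OU", "delta", "lambda")},
            "alpha_ou": a_hat, "delta": d_hat, "lambda": l_hat,
            "alpha_at_bound": by_model["OU"].at_bound.get("alpha_ou", False),
            "delta_outside_bm_ci": null.is_outside("delta", d_hat),
            "lambda_outside_bm_ci": null.is_outside("lambda", l_hat),
            "alpha_outside_bm_ci": null.is_outside("alpha_ou", a_hat),
            "N": by_model["BM"].n,
        })

    metadata = {
        "seed": config.seed,
        "n_rand": config.n_rand,
        "n_perm": config.n_perm,
        "n_sim": config.n_sim,
        "weight_threshold": config.weight_threshold,
        "transforms": dict(config.transforms),
        "bm_null_ci": {k: list(v) for k, v in null.ci.items()},
        "skipped": skipped,
        "moran_weights": "inverse patristic distance",
        "delta_parameterization": "height-normalised power transform of shared paths",
        "ou_parameterization": "fixed-root (non-ultrametric-safe) covariance",
    }
    return AnalysisReport(
        signal_table=pd.DataFrame(signal_rows),
        mantel_table=pd.DataFrame(mantel_rows),
        model_table=pd.DataFrame(model_rows),
        null=null,
        metadata=metadata,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the three tables as TSV plus a JSON metadata sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.signal_table.to_csv(out / "signal_table.tsv", sep="\t", index=False)
    report.mantel_table.to_csv(out / "mantel_table.tsv", sep="\t", index=False)
    report.model_table.to_csv(out / "model_table.tsv", sep="\t", index=False)
    (out / "metadata.json").write_text(json.dumps(report.metadata, indent=2) + "\n")


# ---------------------------------------------------------------------------
# growth-side pipeline: plate table -> trait table


def fit_growth_traits(
    plate: pd.DataFrame, dilution: float = 0.05, min_points: int = 4
) -> pd.DataFrame:
    """Species × resource trait estimates from a long-format plate table.

    Expects columns species_id, resource_kind, treatment_value, replicate,
    day, rfu.  Per well, the exponential growth rate is estimated with
    suffix trimming; wells with zero or negative growth are excluded.  The
    remaining (treatment, rate) points are fit with the Monod model — plus
    the light-optimum model for light, AIC choosing between them — and the
    selected fit is solved for R*.  One output row per species × resource.
    """
    required = {"species_id", "resource_kind", "treatment_value",
                "replicate", "day", "rfu"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")

    rows = []
    for (sp, kind), grp in plate.groupby(["species_id", "resource_kind"], sort=True):
        points = []
        for (level, rep), well in grp.groupby(["treatment_value", "replicate"]):
            well = well.sort_values("day")
            series = gk.FluorescenceSeries(
                species_id=sp, treatment_value=float(level), replicate=int(rep),
                readings=tuple(zip(well["day"].astype(int), well["rfu"])),
                resource_kind=kind,
            )
            est = gk.estimate_growth_rate(series, min_points=min_points)
            if not est.excluded:
                points.append((float(level), est.r))
        if len(points) < 4:
            rows.append({"species_id": sp, "resource_kind": kind, "form": "none",
                         "alpha_slope": np.nan, "mu_max": np.nan, "r_opt": np.nan,
                         "rstar": np.nan, "attainable": False,
                         "note": f"only {len(points)} usable wells"})
            continue
        resp = gk.ResourceResponse(species_id=sp, points=tuple(points),
                                   resource_kind=kind)
        try:
            fit = gk.fit_monod(resp, dilution=dilution)
            if kind == "light":
                try:
                    fit = gk.select_growth_model(
                        fit, gk.fit_light_optimum(resp, dilution=dilution))
                except gk.GrowthFitError:
                    pass  # keep the Monod fit if the optimum form fails
            rstar = gk.solve_rstar(fit, sp, kind)
        except gk.GrowthFitError as exc:
            rows.append({"species_id": sp, "resource_kind": kind, "form": "none",
                         "alpha_slope": np.nan, "mu_max": np.nan, "r_opt": np.nan,
                         "rstar": np.nan, "attainable": False, "note": str(exc)})
            continue
        rows.append({
            "species_id": sp, "resource_kind": kind, "form": fit.form,
            "alpha_slope": fit.alpha_slope, "mu_max": fit.mu_max,
            "r_opt": fit.r_opt if fit.r_opt is not None else np.nan,
            "rstar": rstar.value, "attainable": rstar.attainable, "note": "",
        })
    return pd.DataFrame(rows)
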