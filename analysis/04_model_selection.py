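#!/usr/bin/env python
"""Fit the five trait-evolution models (BM, OU, WN, delta, lambda) to each
synthetic trait, compute Akaike weights and apply the 0.5 selection rule.

Reads results/synthetic/{tree.nwk,traits.tsv}; writes
results/model_table.tsv.
"""

from pathlib import Path

import pandas as pd

import phycosignal as ps
from phycosignal.models import akaike_weights, fit_all_models

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tree = ps.parse_newick((ROOT / "synthetic" / "tree.nwk").read_text())
    traits = pd.read_csv(ROOT / "synthetic" / "traits.tsv", sep="\t",
                         index_col="species_id")
    rows = []
    for trait in traits.columns:
        x = traits[trait].reindex(tree.tip_labels)
        fits = fit_all_models(tree, x)
        sel = akaike_weights(fits)
        by = {f.model: f for f in fits}
        rows.append({
            "trait": trait, "best_model": sel.best,
            **{f"w_{m}": round(sel.weights[m], 3)
               for m in ("WN", "BM", "OU", "delta", "lambda")},
            "alpha_ou": by["OU"].params["alpha_ou"],
            "delta": by["delta"].params["delta"],
            "lambda": by["lambda"].params["lambda"],
        })
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "model_table.tsv", sep="\t", index=False)
    print(table.round(3).to_string(index=False))
    print("\nExpectation: each trait's generating model (encoded in its name)"
          " should dominate the weights, with WN traits occasionally drawn to"
          " stem-erasing delta/lambda fits.")


if __name__ == "__main__":
    main()
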