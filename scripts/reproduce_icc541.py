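"""Reproduce the published bacteroid-model numbers from the deposited
iCC541 reconstruction (optional; requires a local copy of the model).

Download the reconstruction once (it is published at
https://github.com/cacontad/SfrediiScripts) and point this script at the
SBML or COBRA-JSON file:

    python scripts/reproduce_icc541.py --model iCC541.xml --out results/icc541.json

The script reports, computed entirely by this package:

* parsed model statistics (reaction and metabolite counts);
* the standard-condition symbiosis yields on carbon and nitrogen and
  their ratio (Table-3-style values; note that the deposited model must
  already carry its symbiosis reaction and condition bounds, or supply a
  condition YAML with --condition);
* the single-gene knockout screen: number of symbiotic genes (any
  detectable reduction), essential genes (rate ratio < 0.05) and
  partial-effect genes.
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from symbflux import (
    classify_symbiotic_genes,
    compute_symbiosis_yields,
    read_model,
    shadow_prices,
    single_gene_deletion,
    solve_fba,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", type=Path, required=True)
    parser.add_argument("--format", choices=["sbml", "json"], default=None)
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    model = read_model(args.model, args.format)
    results = {
        "total_reactions": len(model.reactions),
        "total_metabolites": len(model.metabolites),
        "total_genes": len(model.genes),
    }

    solution = solve_fba(model)
    results["fba_status"] = solution.status
    if solution.optimal and solution.objective_value > 1e-9:
        try:
            yields = compute_symbiosis_yields(model, solution)
            results["carbon_yield_g_per_mmol"] = yields.carbon_yield
            results["nitrogen_yield_g_per_mmol"] = yields.nitrogen_yield
            results["c_to_n"] = yields.c_to_n
        except Exception as exc:  # yields need formulas on all uptakes
            results["yield_error"] = str(exc)
        prices = shadow_prices(model)
        results["rate_limiting_metabolites"] = prices.rate_limiting
        knockouts = single_gene_deletion(model)
        _, counts = classify_symbiotic_genes(knockouts)
        results["symbiotic_genes"] = counts["symbiotic"]
        results["essential_genes"] = counts["essential"]
        results["partial_effect_genes"] = counts["partial"]

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(results, indent=1) + "\n")
    print(json.dumps(results, indent=1))


if __name__ == "__main__":
    main()
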