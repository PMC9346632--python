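#!/usr/bin/env python
"""Eligibility filtering, propensity fit, stabilized IPTW and balance check.

Reads the cohort from 01, applies the cohort-definition exclusions, fits the
logistic propensity model, derives stabilized IPTW weights, and writes the
balance table (absolute standardized differences before/after weighting),
mirroring a baseline-characteristics table.

Writes results/balance_iptw.csv and results/exclusions.json.
"""

import json
from pathlib import Path

from rwcea.cohort import apply_eligibility, read_cohort
from rwcea.propensity import balance_table, fit_propensity, stabilized_weights

ROOT = Path(__file__).resolve().parents[1] / "results"
COVS = ["age", "female", "ecog1", "metastatic", "prior_cancer"]


def main() -> None:
    cohort = read_cohort(ROOT / "data")
    cohort, exclusions = apply_eligibility(cohort)
    print(f"retained {cohort.n} patients; exclusions: "
          f"{ {k: v for k, v in exclusions.items() if v} or 'none'}")
    with open(ROOT / "exclusions.json", "w") as fh:
        json.dump(exclusions, fh, indent=2)

    ps = fit_propensity(cohort, COVS)
    wc = stabilized_weights(ps)
    eff = wc.effective_sizes
    print(f"effective sizes: focal {eff['focal']:.2f}, "
          f"comparator {eff['comparator']:.2f} (raw n = {cohort.n})")

    bt = balance_table(cohort, COVS, wc)
    bt.to_csv(ROOT / "balance_iptw.csv", index=False)
    print(bt.round(3).to_string(index=False))
    worst = bt["d_weighted"].max()
    verdict = "balanced" if worst <= 0.1 else "NOT balanced"
    print(f"max post-weighting |d| = {worst:.3f} -> {verdict} (threshold 0.1)")


if __name__ == "__main__":
    main()
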