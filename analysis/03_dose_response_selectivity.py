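#!/usr/bin/env python
"""4PL GI50 recovery and the sensitive/resistant selectivity arithmetic.

Part 1 regenerates 200 noisy fivefold-dilution curves from known 4PL
truth and measures how well the absolute GI50 (50%-of-control crossing,
censored above the top dose) is recovered. Part 2 feeds the published
confirmed-compound counts through summarize_selectivity to reproduce
the selectivity percentages. Writes results/gi50_recovery.tsv and
results/selectivity_summary.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from mbscreen.acceptance import gi50_recovery_experiment, selectivity_worked_example
from mbscreen.doseresponse import fit_4pl
from mbscreen.simulate import draw_drc_truth, simulate_drc, true_gi50

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(200):
        params = draw_drc_truth(rng)
        tab = simulate_drc(params, sigma=5.0, seed=int(rng.integers(2**31)))
        fit = fit_4pl(tab["dose"], tab["viability"])
        rows.append(
            {"true_gi50": true_gi50(params), "fitted_gi50": fit.gi50,
             "censored": fit.censored, "hill": fit.hill}
        )
    rec = pd.DataFrame(rows)
    rec.to_csv(OUT / "gi50_recovery.tsv", sep="\t", index=False)
    res = gi50_recovery_experiment(seed=SEED)
    print(f"GI50 recovery over {res['n_fitted']} noisy triplicate curves: "
          f"median relative error {res['median_rel_err']:.1%} "
          f"(noise-free: {res['noise_free_rel_err']:.2%})")
    print(f"censoring rule consistent with the fitted 50% crossing: "
          f"{res['censor_rule_consistent']}")

    sel = selectivity_worked_example()
    summary = pd.DataFrame(
        [
            {"set": "confirmed_hits", **sel["confirmed"]},
            {"set": "antimetabolites", **sel["antimetabolites"]},
        ]
    )
    summary.to_csv(OUT / "selectivity_summary.tsv", sep="\t", index=False)
    c, a = sel["confirmed"], sel["antimetabolites"]
    print(f"confirmed hits: {c['n_selective_R']}/{c['n_total']} R-selective "
          f"({c['pct_selective_R']}%), {c['n_selective_S']}/{c['n_total']} "
          f"S-selective ({c['pct_selective_S']}%)")
    print(f"antimetabolites: {a['n_selective_R']}/{a['n_total']} R-selective "
          f"({a['pct_selective_R']}%)")


if __name__ == "__main__":
    main()
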