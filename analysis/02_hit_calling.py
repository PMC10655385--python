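#!/usr/bin/env python
"""Score the simulated screen and call hits at the top 5th percentile.

Normalizes each plate to its DMSO median, robust-Z scores the test
wells, ranks compounds per model, and takes the cross-model union of
the per-model top-5% cuts — then grades the result against the known
spike-in truth. Writes results/hits.tsv and results/hit_union.tsv.
"""

import pathlib

from mbscreen.acceptance import hitcalling_experiment
from mbscreen.hitcall import score_screen
from mbscreen.simulate import SimConfig, simulate_screen

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SimConfig(seed=SEED, effect_range=(60.0, 95.0))
    plate_sets, truth = simulate_screen(cfg)
    hits, union = score_screen(plate_sets, percentile=0.05)
    hits.to_csv(OUT / "hits.tsv", sep="\t", index=False)
    union.to_csv(OUT / "hit_union.tsv", sep="\t", index=False)

    res = hitcalling_experiment(seed=SEED)
    print(f"per-model cut: {hits[hits.selected].groupby('model').size().iloc[0]} "
          f"compounds (= ceil(0.05 x {cfg.n_compounds}))")
    print(f"cross-model union: {res['n_union']} compounds "
          f"(the real campaign funnelled ~303 into confirmation)")
    print(f"recall of the {res['n_active']} spiked actives: {res['recall']:.2%}")
    print(f"mean per-model false-positive rate among inert compounds: "
          f"{res['fpr']:.2%}")


if __name__ == "__main__":
    main()
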