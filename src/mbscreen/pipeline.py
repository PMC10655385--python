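"""End-to-end run configuration and report assembly.

`run_pipeline` wires the simulators and analysis stages together:
simulate a screen → normalize/score/call hits → confirmation
dose–response on the hit union → S/R selectivity classification →
checkerboard synergy on the most R-selective compounds. Every stage
writes a TSV, a machine-readable JSON summary collects the headline
numbers, and the exact configuration (including the single seed that
feeds every random draw) is stored alongside the outputs so a rerun
reproduces them bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseresponse import (
    FIVEFOLD6,
    classify_selectivity,
    fit_4pl,
    summarize_selectivity,
)
from .hitcall import score_screen
from .simulate import SimConfig, simulate_drc, simulate_screen, simulate_synergy
from .synergy import build_checkerboard, score_matrix

log = logging.getLogger("mbscreen")


@dataclass
class RunConfig:
    """Defaults reproduce the screen's stated settings: 5 µM primary
    dose, top-5th-percentile hit cut, selectivity ratio > 2, HSA call
    thresholds at ±10, alpha 0.05."""

    seed: int = 0
    percentile: float = 0.05
    selectivity_threshold: float = 2.0
    hsa_threshold: float = 10.0
    alpha: float = 0.05
    drc_design: tuple[float, ...] = FIVEFOLD6
    drc_sigma: float = 5.0
    n_confirm: int = 24  # hits taken into confirmation dose-response
    n_synergy: int = 4  # top R-selective compounds taken to checkerboards
    sim: SimConfig = field(default_factory=SimConfig)
    version: str = __version__

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drc_design"] = list(self.drc_design)
        return d


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute simulate → score → drc → selectivity → synergy.

    Returns the summary dict; writes hits.tsv, union.tsv, fits.tsv,
    selectivity.tsv, synergy.tsv, summary.json and run_config.json
    under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.replace(config, sim=dataclasses.replace(config.sim, seed=config.seed))
    rng = np.random.default_rng(cfg.seed)

    log.info("stage simulate: %d compounds x %d models", cfg.sim.n_compounds, cfg.sim.n_models)
    plates, truth = simulate_screen(cfg.sim)

    log.info("stage score")
    hits, union = score_screen(plates, percentile=cfg.percentile)
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    union.to_csv(outdir / "union.tsv", sep="\t", index=False)

    log.info("stage drc: confirming %d compounds", min(cfg.n_confirm, len(union)))
    confirm = union.head(cfg.n_confirm)["compound_id"].tolist()
    truth_map = truth.compounds.set_index("compound_id")["true_inhibition"]
    pairs, fit_rows = [], []
    for cid in confirm:
        # resistant arm reflects the compound's screened potency; the
        # sensitive arm of a truly R-selective compound is right-shifted
        inh = float(truth_map[cid])
        potency_shift = 4.0 if inh >= 50 else 1.0
        gi50_R = float(10 ** rng.uniform(-1.5, 0.3))
        hill = float(rng.uniform(1.0, 2.5))
        params_R = (5.0, 100.0, gi50_R, hill)
        params_S = (5.0, 100.0, gi50_R * potency_shift, hill)
        fit_S = fit_4pl(
            *_drc_xy(simulate_drc(params_S, cfg.drc_design, cfg.drc_sigma,
                                  seed=int(rng.integers(2**31))))
        )
        fit_R = fit_4pl(
            *_drc_xy(simulate_drc(params_R, cfg.drc_design, cfg.drc_sigma,
                                  seed=int(rng.integers(2**31))))
        )
        pairs.append((cid, fit_S, fit_R))
        fit_rows.append(
            {"compound_id": cid, "gi50_S": fit_S.gi50_label, "gi50_R": fit_R.gi50_label}
        )
    pd.DataFrame(fit_rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    log.info("stage selectivity")
    records = classify_selectivity(pairs, threshold=cfg.selectivity_threshold)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        outdir / "selectivity.tsv", sep="\t", index=False
    )
    summary_sel = summarize_selectivity(records)

    log.info("stage synergy")
    selective = [r.compound_id for r in records if r.selective_R][: cfg.n_synergy]
    da, db = build_checkerboard(4.0, 0.2, 4)
    syn_rows = []
    for cid in selective:
        mat = simulate_synergy(
            (0.0, 100.0, 1.0, 1.5), (0.0, 100.0, 0.05, 1.2),
            delta=float(rng.uniform(10, 20)), doses_a=da, doses_b=db,
            sigma=3.0, seed=int(rng.integers(2**31)), drug_a=cid, drug_b="VECC",
        )
        res = score_matrix(mat)
        syn_rows.append({"compound_id": cid, "hsa_score": res.score, "call": res.call})
    pd.DataFrame(syn_rows).to_csv(outdir / "synergy.tsv", sep="\t", index=False)

    summary = {
        "version": cfg.version,
        "seed": cfg.seed,
        "n_compounds": cfg.sim.n_compounds,
        "n_models": cfg.sim.n_models,
        "n_hits_union": int(len(union)),
        "selectivity": summary_sel,
        "synergy_calls": {r["compound_id"]: r["call"] for r in syn_rows},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "run_config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True)
    )
    log.info("pipeline complete: %d hits, %d confirmed selective",
             len(union), summary_sel["n_selective_R"])
    return summary


def _drc_xy(tab: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return tab["dose"].to_numpy(), tab["viability"].to_numpy()
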