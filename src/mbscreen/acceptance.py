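"""Headline validation experiments, shared by the test suite and the
reporting script.

Each function re-runs one stage of the pipeline on synthetic data with
known ground truth (or on the published worked-example counts) and
returns the measured quantities. All randomness flows from the single
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import adjusted_rand_score

from .doseresponse import SelectivityRecord, fit_4pl, four_pl, summarize_selectivity
from .hitcall import score_screen
from .lda import compare_frequencies, fit_frequency
from .plates import CONTROL_COLUMNS, WellRole, default_layout, layout_counts
from .simulate import (
    SimConfig,
    draw_drc_truth,
    simulate_cohort,
    simulate_drc,
    simulate_lda,
    simulate_screen,
    simulate_synergy,
    true_gi50,
)
from .stratify import correlate_to_references, elbow_kmeans, survival_compare
from .synergy import build_checkerboard, hsa_score


def _rec(cid: str, sel_R: bool = False, sel_S: bool = False) -> SelectivityRecord:
    return SelectivityRecord(cid, 3.0 if sel_R else 1.0, 3.0 if sel_S else 1.0,
                             sel_R, sel_S, False)


def selectivity_worked_example() -> dict:
    """The screen's confirmed-compound arithmetic: 56 R-selective and 23
    S-selective of 303 confirmed hits; 16 of 41 antimetabolites."""
    confirmed = (
        [_rec(f"r{i}", sel_R=True) for i in range(56)]
        + [_rec(f"s{i}", sel_S=True) for i in range(23)]
        + [_rec(f"n{i}") for i in range(303 - 56 - 23)]
    )
    anti = [_rec(f"a{i}", sel_R=True) for i in range(16)] + [
        _rec(f"an{i}") for i in range(41 - 16)
    ]
    return {
        "confirmed": summarize_selectivity(confirmed),
        "antimetabolites": summarize_selectivity(anti),
    }


def plate_geometry() -> dict:
    layout = default_layout()
    counts = layout_counts(layout)
    control_cols = {
        w.column for w, r in layout.items()
        if r in (WellRole.NEG_CONTROL, WellRole.POS_CONTROL)
    }
    return {
        "n_test": counts["test"],
        "n_control": counts["neg_control"] + counts["pos_control"],
        "controls_confined": control_cols == set(CONTROL_COLUMNS),
    }


def hitcalling_experiment(seed: int, percentile: float = 0.05) -> dict:
    """Full-scale simulated screen: recall of spiked actives in the
    cross-model hit union and per-model false-positive rate."""
    cfg = SimConfig(seed=seed, effect_range=(60.0, 95.0))
    plates, truth = simulate_screen(cfg)
    hits, union = score_screen(plates, percentile=percentile)
    active = set(truth.active_ids)
    selected = set(union["compound_id"])
    n_inert = cfg.n_compounds - len(active)
    per_model_fp = (
        hits[hits["selected"]]
        .groupby("model")["compound_id"]
        .apply(lambda ids: len(set(ids) - active))
    )
    return {
        "n_compounds": cfg.n_compounds,
        "n_active": len(active),
        "recall": len(active & selected) / len(active),
        "fpr": float(per_model_fp.mean()) / n_inert,
        "n_union": len(selected),
    }


def gi50_recovery_experiment(seed: int, n_curves: int = 200, sigma: float = 5.0) -> dict:
    """Parameter recovery over simulated fivefold 6-point curves."""
    rng = np.random.default_rng(seed)
    rel_err, signed = [], []
    censor_consistent = True
    for i in range(n_curves):
        params = draw_drc_truth(rng)
        tab = simulate_drc(params, sigma=sigma, seed=int(rng.integers(2**31)))
        fit = fit_4pl(tab["dose"], tab["viability"])
        v_top = float(fit.predict(np.array([fit.top_dose]))[0])
        censor_consistent &= fit.censored == (v_top > 50.0)
        if fit.censored:
            continue
        g = true_gi50(params)
        rel_err.append(abs(fit.gi50 - g) / g)
        signed.append(fit.gi50 - g)
    # noise-free identifiability on one reference curve
    clean = simulate_drc((0.0, 100.0, 1.0, 1.0), sigma=0.0, n_rep=1)
    fit0 = fit_4pl(clean["dose"], clean["viability"])
    pos = int(np.sum(np.asarray(signed) > 0))
    return {
        "n_fitted": len(rel_err),
        "median_rel_err": float(np.median(rel_err)),
        "noise_free_rel_err": abs(fit0.gi50 - 1.0),
        "censor_rule_consistent": censor_consistent,
        "sign_test_p": float(binomtest(pos, len(signed)).pvalue),
    }


def hsa_recovery_experiment(seed: int, n_seeds: int = 100, sigma: float = 3.0) -> dict:
    """Planted HSA excess recovered from noisy checkerboards."""
    curves = ((0.0, 100.0, 1.0, 1.5), (0.0, 100.0, 0.05, 1.2))
    da, db = build_checkerboard(4.0, 0.2, 4)
    rng = np.random.default_rng(seed)
    out = {}
    for delta in (-15.0, 0.0, 15.0):
        scores = [
            hsa_score(
                simulate_synergy(*curves, delta, da, db, sigma=sigma,
                                 seed=int(rng.integers(2**31)))
            )
            for _ in range(n_seeds)
        ]
        out[delta] = float(np.mean(scores))
    # exact null surface: monotone margins, combo = max single agent
    inh = np.maximum(
        np.linspace(0, 80, 5)[:, None], np.linspace(0, 60, 5)[None, :]
    )
    from .synergy import SynergyMatrix

    null = SynergyMatrix(
        np.r_[0.0, np.logspace(-1, 1, 4)], np.r_[0.0, np.logspace(-1, 1, 4)],
        100.0 - inh,
    )
    out["exact_null"] = hsa_score(null)
    return out


def lda_experiment(seed: int, n_seeds: int = 200) -> dict:
    """Noise-free inversion, null comparison and two-group power."""
    doses = np.array([10.0, 100.0, 1000.0])
    n_wells = 10_000
    exact_neg = np.round(n_wells * np.exp(-0.01 * doses)).astype(int)
    from .lda import LdaExperiment

    exact = LdaExperiment(doses, np.full(3, n_wells), exact_neg)
    f_exact = fit_frequency(exact).F

    null_exp = simulate_lda(0.02, seed=seed, group="a")
    null_cmp = compare_frequencies(null_exp, null_exp)

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_seeds):
        a = simulate_lda(0.01, n_wells=24, seed=int(rng.integers(2**31)), group="S")
        b = simulate_lda(0.05, n_wells=24, seed=int(rng.integers(2**31)), group="R")
        if compare_frequencies(a, b).p_value < 0.05:
            rejections += 1
    return {
        "exact_F": f_exact,
        "null_f_statistic": null_cmp.f_statistic,
        "null_p": null_cmp.p_value,
        "power": rejections / n_seeds,
        "n_seeds": n_seeds,
    }


def stratification_experiment(seed: int, n_permutations: int = 10_000) -> dict:
    """Cohort recovery: elbow k, ARI vs truth, log-rank vs permutation."""
    sim = simulate_cohort(seed=seed)
    corr = correlate_to_references(sim.cohort, sim.refs, sim.genes)
    elbow = elbow_kmeans(corr, seed=seed)
    ari = adjusted_rand_score(sim.true_labels.to_numpy(), elbow.labels)

    surv = sim.surv.copy()
    surv["cluster"] = elbow.labels
    res = survival_compare(surv)

    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()
    labels = surv["cluster"].to_numpy()
    chi2_obs = _logrank_chi2(time, event, labels)
    rng = np.random.default_rng(seed)
    perm = np.array(
        [
            _logrank_chi2(time, event, rng.permutation(labels))
            for _ in range(n_permutations)
        ]
    )
    p_perm = float((np.sum(perm >= chi2_obs) + 1) / (n_permutations + 1))
    return {
        "k": elbow.k,
        "ari": float(ari),
        "logrank_chi2": res.statistic,
        "logrank_chi2_numpy": float(chi2_obs),
        "logrank_p": res.p_value,
        "logrank_p_permutation": p_perm,
        "n_patients": len(surv),
    }


def _logrank_chi2(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Multi-group log-rank chi-square (O−E with full covariance),
    vectorised for permutation use; matches lifelines' statistic."""
    groups = np.unique(group)
    k = len(groups)
    gi = np.searchsorted(groups, group)
    order = np.argsort(time, kind="mergesort")
    t_s = time[order]
    e_s = event[order].astype(float)
    g_s = gi[order]
    n = len(t_s)
    _, start = np.unique(t_s, return_index=True)  # distinct-time segments

    Y = np.zeros((n, k))
    Y[np.arange(n), g_s] = 1.0
    totals = Y.sum(axis=0)
    cum = np.cumsum(Y, axis=0)
    # at risk (per group and overall) just before each segment
    n_g = np.where(start[:, None] > 0, totals - cum[start - 1], totals)
    at_risk = (n - start).astype(float)
    d_g = np.add.reduceat(Y * e_s[:, None], start, axis=0)
    d = d_g.sum(axis=1)

    keep = d > 0
    n_g, at_risk, d_g, d = n_g[keep], at_risk[keep], d_g[keep], d[keep]
    frac = n_g / at_risk[:, None]
    O = d_g.sum(axis=0)
    E = (d[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(at_risk > 1, d * (at_risk - d) / (at_risk - 1), 0.0)
    V = np.diag((scale[:, None] * frac).sum(axis=0)) - np.einsum(
        "s,si,sj->ij", scale, frac, frac
    )
    z = (O - E)[:-1]
    return float(z @ np.linalg.solve(V[:-1, :-1], z))
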