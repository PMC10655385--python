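"""Ground-truth synthetic data for every pipeline stage.

Each generator is a pure function of its configuration and seed and
emits exactly the containers the analysis modules consume, so every
stage of the pipeline can be exercised against known truth:

* a primary viability screen (384-well plates, 320 test compounds each,
  spiked actives among a mildly toxic background library);
* 4PL dose–response tables with additive viability noise;
* HSA-null combination checkerboards with a planted excess;
* single-hit limiting dilution outcomes;
* a patient cohort with latent similarity clusters, matched reference
  samples, and cluster-dependent exponential survival.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .doseresponse import FIVEFOLD6, four_pl
from .lda import LdaExperiment
from .plates import (
    Measurement,
    PlateSet,
    WellRole,
    default_layout,
    wells_by_role,
)
from .stratify import ExpressionMatrix
from .synergy import SynergyMatrix

BASE_SIGNAL = 10_000.0  # fluorescence of an untreated well, a.u.


@dataclass
class SimConfig:
    """Primary-screen simulation settings.

    Defaults emulate the screening campaign's scale: a 3533-compound
    library screened at 5 µM on 4 cell models in duplicate, with 40
    confirmed-grade actives spiked in. Inactive library members carry a
    small half-normal nonspecific toxicity that, like any compound
    property, is shared across cell models; its scale (15 viability
    points) is calibrated so the cross-model union of per-model top-5%
    hits lands near the ~300 compounds a 4-model screen of this library
    size reports.
    """

    seed: int = 0
    n_compounds: int = 3533
    n_models: int = 4
    n_replicates: int = 2
    hit_fraction: float = 40 / 3533
    effect_range: tuple[float, float] = (50.0, 95.0)  # % inhibition of actives
    inert_scale: float = 15.0  # half-normal scale of background toxicity
    noise_cv: float = 0.10  # multiplicative fluorescence noise
    plate_gain_sigma: float = 0.05  # lognormal sigma of per-plate gain
    pos_control_inhibition: float = 95.0  # bortezomib kill control
    dose: float = 5.0  # µM, single-dose primary screen

    def __post_init__(self) -> None:
        if not 0 <= self.hit_fraction <= 1:
            raise ParameterError("hit_fraction must lie in [0, 1]")
        if self.noise_cv < 0 or self.inert_scale < 0:
            raise ParameterError("noise parameters must be >= 0")


@dataclass
class ScreenTruth:
    """Per-compound ground truth of a simulated screen."""

    compounds: pd.DataFrame  # compound_id, true_inhibition, is_active
    plate_gains: dict[str, float] = field(default_factory=dict)

    @property
    def active_ids(self) -> list[str]:
        return list(self.compounds.loc[self.compounds["is_active"], "compound_id"])


def simulate_screen(cfg: SimConfig) -> tuple[list[PlateSet], ScreenTruth]:
    """Simulate the whole primary screen: one PlateSet per cell model.

    Raw signal = plate_gain · BASE_SIGNAL · viability/100 · (1 + ε) with
    ε ~ N(0, noise_cv). DMSO wells sit at 0% inhibition, bortezomib
    wells at the configured kill level. Compounds fill plates of 320
    test wells; the last plate may be partially filled.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds
    n_active = round(cfg.hit_fraction * n)
    ids = np.array([f"C{i:05d}" for i in range(n)])
    active_idx = rng.choice(n, size=n_active, replace=False)
    inhibition = np.abs(rng.normal(0.0, cfg.inert_scale, size=n))
    inhibition[active_idx] = rng.uniform(*cfg.effect_range, size=n_active)
    inhibition = np.clip(inhibition, 0.0, 100.0)
    is_active = np.zeros(n, bool)
    is_active[active_idx] = True
    truth = ScreenTruth(
        pd.DataFrame(
            {"compound_id": ids, "true_inhibition": inhibition, "is_active": is_active}
        )
    )

    layout = default_layout()
    test_wells = wells_by_role(layout, WellRole.TEST)
    neg_wells = wells_by_role(layout, WellRole.NEG_CONTROL)
    pos_wells = wells_by_role(layout, WellRole.POS_CONTROL)
    per_plate = len(test_wells)  # 320
    n_plates = math.ceil(n / per_plate)

    def well_signal(inh: float, gain: float) -> float:
        v = max(0.0, (100.0 - inh) / 100.0)
        return max(0.0, gain * BASE_SIGNAL * v * (1.0 + rng.normal(0.0, cfg.noise_cv)))

    plate_sets = []
    for m in range(cfg.n_models):
        model = f"model{m + 1}"
        measurements: list[Measurement] = []
        for rep in range(1, cfg.n_replicates + 1):
            for p in range(n_plates):
                pid = f"{model}-p{p + 1:02d}-r{rep}"
                gain = float(rng.lognormal(0.0, cfg.plate_gain_sigma))
                truth.plate_gains[pid] = gain
                lo, hi = p * per_plate, min((p + 1) * per_plate, n)
                for w, ci in zip(test_wells, range(lo, hi)):
                    measurements.append(
                        Measurement(
                            pid, w, str(ids[ci]), cfg.dose, rep,
                            well_signal(inhibition[ci], gain),
                        )
                    )
                for w in neg_wells:
                    measurements.append(
                        Measurement(pid, w, "DMSO", None, rep, well_signal(0.0, gain))
                    )
                for w in pos_wells:
                    measurements.append(
                        Measurement(
                            pid, w, "bortezomib", None, rep,
                            well_signal(cfg.pos_control_inhibition, gain),
                        )
                    )
        plate_sets.append(
            PlateSet(measurements, layout=layout, cell_model=model, condition="resistant")
        )
    return plate_sets, truth


def simulate_drc(
    params: tuple[float, float, float, float],
    design: tuple[float, ...] = FIVEFOLD6,
    sigma: float = 5.0,
    n_rep: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Dose–response table from a true 4PL curve.

    ``params`` is (bottom, top, midpoint µM, hill); viability is drawn
    Gaussian around the curve with sd ``sigma`` viability points and
    clipped to [−5, 130] (plate-reader overshoot bounds). Dose–response
    confirmation runs in triplicate by default, the standard design for
    resazurin viability curves.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if n_rep < 1:
        raise ParameterError("n_rep must be >= 1")
    bottom, top, midpoint, hill = params
    rng = np.random.default_rng(seed)
    doses = np.asarray(sorted(design), float)
    rows = []
    for rep in range(1, n_rep + 1):
        v = four_pl(doses, bottom, top, midpoint, hill)
        if sigma > 0:
            v = v + rng.normal(0.0, sigma, size=len(doses))
        v = np.clip(v, -5.0, 130.0)
        rows.append(pd.DataFrame({"dose": doses, "replicate": rep, "viability": v}))
    return pd.concat(rows, ignore_index=True)


def draw_drc_truth(
    rng: np.random.Generator,
    design: tuple[float, ...] = FIVEFOLD6,
    gi50_range: tuple[float, float] | None = None,
    hill_range: tuple[float, float] = (1.0, 2.5),
    bottom_range: tuple[float, float] = (0.0, 15.0),
    top_range: tuple[float, float] = (95.0, 105.0),
) -> tuple[float, float, float, float]:
    """Draw true 4PL parameters for a confirmation-grade active.

    GI50 is log-uniform over the central portion of the dose design
    (second-lowest to second-highest dose by default) — the population
    a confirmation dose range is chosen to straddle — with hill slopes
    typical of cytotoxic agents. The curve midpoint is derived from the
    drawn absolute GI50. Returns (bottom, top, midpoint, hill).
    """
    doses = sorted(design)
    if gi50_range is None:
        gi50_range = (doses[1], doses[-2])
    gi50 = 10 ** rng.uniform(*np.log10(gi50_range))
    hill = rng.uniform(*hill_range)
    bottom = rng.uniform(*bottom_range)
    top = rng.uniform(*top_range)
    midpoint = gi50 * ((50.0 - bottom) / (top - 50.0)) ** (1.0 / hill)
    return bottom, top, midpoint, hill


def true_gi50(params: tuple[float, float, float, float]) -> float:
    """Absolute 50%-crossing of a 4PL parameter tuple."""
    bottom, top, midpoint, hill = params
    return midpoint * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill)


def simulate_synergy(
    curve_a: tuple[float, float, float, float],
    curve_b: tuple[float, float, float, float],
    delta: float,
    doses_a: np.ndarray,
    doses_b: np.ndarray,
    sigma: float = 3.0,
    seed: int = 0,
    drug_a: str = "A",
    drug_b: str = "B",
) -> SynergyMatrix:
    """Checkerboard built as HSA-null plus a planted excess ``delta``.

    Single-agent inhibitions come from the two 4PL curves (zero dose →
    zero inhibition); each combination cell is
    min(100, max(single_a, single_b) + delta); Gaussian viability noise
    (sd ``sigma``) is added to every measured cell.
    """
    doses_a = np.asarray(doses_a, float)
    doses_b = np.asarray(doses_b, float)
    if doses_a[0] != 0 or doses_b[0] != 0:
        raise ParameterError("dose grids must include the zero dose first")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    rng = np.random.default_rng(seed)

    def inh(curve, d):
        out = np.where(d > 0, 100.0 - four_pl(np.maximum(d, 1e-300), *curve), 0.0)
        return np.clip(out, 0.0, 100.0)

    ia = inh(curve_a, doses_a)[:, None]
    ib = inh(curve_b, doses_b)[None, :]
    combo = np.clip(np.maximum(ia, ib) + delta, 0.0, 100.0)
    combo[0, :] = ib[0, :]  # margins stay single-agent
    combo[:, 0] = ia[:, 0]
    combo[0, 0] = 0.0
    viability = 100.0 - combo
    if sigma > 0:
        viability = viability + rng.normal(0.0, sigma, size=viability.shape)
    return SynergyMatrix(doses_a, doses_b, viability, drug_a, drug_b)


def simulate_lda(
    F_true: float,
    doses: np.ndarray = (10, 50, 100, 500, 1000),
    n_wells: int = 24,
    seed: int = 0,
    group: str = "",
) -> LdaExperiment:
    """Single-hit limiting dilution outcomes.

    Negative wells per dose are Binomial(n_wells, exp(−F·d)); F = 0
    therefore leaves every well negative.
    """
    if F_true < 0:
        raise ParameterError("F_true must be >= 0")
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses, float)
    p_neg = np.exp(-F_true * doses)
    n_negative = rng.binomial(n_wells, p_neg)
    return LdaExperiment(doses, np.full(len(doses), n_wells), n_negative, group=group)


@dataclass
class CohortSim:
    cohort: ExpressionMatrix  # patients, with true_cluster annotation
    refs: ExpressionMatrix  # reference (resistant-model) samples
    surv: pd.DataFrame  # patient -> time (years), event
    genes: list[str]
    true_labels: pd.Series


def simulate_cohort(
    n_patients: int = 763,
    n_refs: int = 12,
    n_ref_models: int = 3,
    n_genes: int = 962,
    k_true: int = 3,
    sep: float = 1.0,
    hazard_by_cluster: tuple[float, ...] = (0.03, 0.06, 0.15),
    censor_rate: float = 0.3,
    cluster_probs: tuple[float, ...] | None = None,
    seed: int = 0,
) -> CohortSim:
    """Patient cohort with latent similarity clusters and survival.

    Expression is built from a shared resistant-signature core plus one
    latent profile per reference model; each patient cluster loads on
    the core and on one model profile, with loading scaled by ``sep``
    (sep = 0 collapses all clusters into one blob). Reference samples
    (``n_refs`` split over ``n_ref_models`` models) carry the core and
    their model's profile, so patient-to-reference Spearman correlation
    recovers the cluster structure. Survival times are exponential with
    cluster-specific hazards (per year) under independent exponential
    censoring with overall censoring probability ``censor_rate``;
    censor_rate = 1 censors everybody at a fixed horizon.
    """
    if k_true < 1 or len(hazard_by_cluster) < k_true:
        raise ParameterError("need one hazard per true cluster")
    if not 0 <= censor_rate <= 1:
        raise ParameterError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]

    core = rng.normal(0.0, 1.0, n_genes)
    profiles = rng.normal(0.0, 1.0, (n_ref_models, n_genes))

    if cluster_probs is None:
        # default three-cluster split mirrors the reported low/intermediate/
        # high-similarity subgroup sizes of the 763-patient cohort
        cluster_probs = (0.35, 0.42, 0.23) if k_true == 3 else tuple([1.0 / k_true] * k_true)
    probs = np.asarray(cluster_probs, float)
    probs = probs / probs.sum()
    labels = rng.choice(k_true, size=n_patients, p=probs)

    a = 0.35  # loading on the shared core
    b = 0.35 * sep  # cluster-specific model-profile loading
    resid = math.sqrt(max(0.0, 1.0 - a * a - b * b))
    X = np.empty((n_patients, n_genes))
    for i, c in enumerate(labels):
        X[i] = (
            a * core
            + b * profiles[c % n_ref_models]
            + resid * rng.normal(0.0, 1.0, n_genes)
        )
    cohort = ExpressionMatrix(
        pd.DataFrame(
            X.T + 8.0,  # shift to a log2-intensity-like scale
            index=genes,
            columns=[f"P{i:04d}" for i in range(n_patients)],
        ),
        sample_info=pd.DataFrame(
            {"true_cluster": labels}, index=[f"P{i:04d}" for i in range(n_patients)]
        ),
    )

    ref_ids, ref_models, R = [], [], []
    for j in range(n_refs):
        m = j % n_ref_models
        r = 0.6 * core + 0.6 * profiles[m] + 0.52 * rng.normal(0.0, 1.0, n_genes)
        R.append(r)
        ref_ids.append(f"R{m + 1}-{j // n_ref_models + 1}")
        ref_models.append(f"refmodel{m + 1}")
    refs = ExpressionMatrix(
        pd.DataFrame(np.array(R).T + 8.0, index=genes, columns=ref_ids),
        sample_info=pd.DataFrame({"model": ref_models}, index=ref_ids),
    )

    hazards = np.asarray(hazard_by_cluster, float)[labels]
    event_t = rng.exponential(1.0 / hazards)
    if censor_rate >= 1.0:
        time, event = np.full(n_patients, 10.0), np.zeros(n_patients, int)
    elif censor_rate == 0.0:
        time, event = event_t, np.ones(n_patients, int)
    else:
        cens_rate = hazards * censor_rate / (1.0 - censor_rate)
        cens_t = rng.exponential(1.0 / cens_rate)
        time = np.minimum(event_t, cens_t)
        event = (event_t <= cens_t).astype(int)
    surv = pd.DataFrame(
        {"time": time, "event": event}, index=cohort.data.columns
    )
    return CohortSim(
        cohort=cohort,
        refs=refs,
        surv=surv,
        genes=genes,
        true_labels=pd.Series(labels, index=cohort.data.columns, name="true_cluster"),
    )
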