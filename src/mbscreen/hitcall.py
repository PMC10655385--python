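"""Plate normalization, QC and robust-Z hit calling for the primary screen.

Raw fluorescence is converted to percent-of-negative-control viability
plate by plate (median of the DMSO wells defines 100%). Test wells are
then standardized within each plate with the robust Z score

    z = (viability − median_test) / (1.4826 · MAD_test),

computed over the plate's test wells, so more negative z means stronger
growth inhibition. Compounds are ranked per cell model by their mean z
across replicate plates and the top percentile (default 5%) selected;
the union of per-model hit sets is the screen's output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DegeneratePlateError, ParameterError, QCError
from .plates import PlateSet, WellRole

MAD_SCALE = 1.4826  # makes MAD consistent with sigma for a Gaussian


@dataclass
class PlateQC:
    z_prime: float
    neg_cv: float  # % coefficient of variation of negative controls
    pos_signal_ratio: float  # mean pos / mean neg viability
    passed: bool


@dataclass
class NormalizedPlate:
    """Per-well viability (% of negative control) plus per-plate QC."""

    data: pd.DataFrame  # plate_id, well, role, compound_id, replicate, viability_pct
    qc: dict[str, PlateQC] = field(default_factory=dict)
    cell_model: str = "unknown"
    condition: str = "sensitive"


def normalize_plate(plates: PlateSet) -> NormalizedPlate:
    """Percent-of-negative-control normalization, one plate at a time.

    viability_pct(w) = 100 · raw(w) / median(raw over DMSO wells of the
    same plate). Control wells are retained with their normalized values.
    """
    df = plates.to_frame()
    out = []
    for pid, sub in df.groupby("plate_id", sort=True):
        neg = sub.loc[sub["role"] == WellRole.NEG_CONTROL.value, "signal"]
        if len(neg) < 2:
            raise QCError(f"plate {pid}: fewer than 2 negative-control wells")
        neg_median = float(neg.median())
        if neg_median == 0:
            raise DegeneratePlateError(f"plate {pid}: negative-control median is 0")
        sub = sub.copy()
        sub["viability_pct"] = 100.0 * sub["signal"] / neg_median
        out.append(sub)
    data = pd.concat(out, ignore_index=True).drop(columns=["signal", "dose"])
    norm = NormalizedPlate(
        data=data, cell_model=plates.cell_model, condition=plates.condition
    )
    norm.qc = {pid: plate_qc(norm, pid) for pid in data["plate_id"].unique()}
    return norm


def plate_qc(
    plate: NormalizedPlate, plate_id: str, z_prime_threshold: float = 0.5
) -> PlateQC:
    """Z′-factor and control CVs for one plate.

    Z′ = 1 − 3(σ_pos + σ_neg)/|µ_pos − µ_neg|; ≥ 0.5 is an excellent
    assay window. Identical control means give Z′ = −inf and a fail flag.
    """
    sub = plate.data[plate.data["plate_id"] == plate_id]
    neg = sub.loc[sub["role"] == WellRole.NEG_CONTROL.value, "viability_pct"].to_numpy()
    pos = sub.loc[sub["role"] == WellRole.POS_CONTROL.value, "viability_pct"].to_numpy()
    if len(neg) < 2 or len(pos) < 2:
        raise QCError(f"plate {plate_id}: need >= 2 wells per control role")
    sep = abs(float(np.mean(pos)) - float(np.mean(neg)))
    if sep == 0:
        z_prime = -math.inf
    else:
        z_prime = 1.0 - 3.0 * (float(np.std(pos, ddof=1)) + float(np.std(neg, ddof=1))) / sep
    neg_cv = 100.0 * float(np.std(neg, ddof=1)) / float(np.mean(neg))
    return PlateQC(
        z_prime=z_prime,
        neg_cv=neg_cv,
        pos_signal_ratio=float(np.mean(pos)) / float(np.mean(neg)),
        passed=z_prime >= z_prime_threshold,
    )


def robust_z(plate: NormalizedPlate, min_test_wells: int = 8) -> pd.DataFrame:
    """Per-test-well robust Z scores, computed within each plate.

    Center and scale are the median and 1.4826·MAD of the plate's own
    test wells; controls do not enter the score.
    """
    test = plate.data[plate.data["role"] == WellRole.TEST.value]
    out = []
    for pid, sub in test.groupby("plate_id", sort=True):
        if len(sub) < min_test_wells:
            raise DegeneratePlateError(
                f"plate {pid}: fewer than {min_test_wells} test wells"
            )
        v = sub["viability_pct"].to_numpy(float)
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        if mad == 0:
            raise DegeneratePlateError(
                f"plate {pid}: MAD of test-well viability is 0"
            )
        sub = sub.copy()
        sub["z"] = (v - med) / (MAD_SCALE * mad)
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["model"] = plate.cell_model
    res["condition"] = plate.condition
    return res[["plate_id", "well", "compound_id", "replicate", "viability_pct", "z", "model", "condition"]]


def call_hits(zscores: pd.DataFrame, percentile: float = 0.05) -> pd.DataFrame:
    """Rank compounds per model by mean robust Z and select the top cut.

    ``zscores`` needs columns compound_id, model, z; replicate rows are
    averaged per compound before ranking. Ranks ascend with z (rank 1 =
    strongest inhibition); selected ⇔ rank ≤ ceil(percentile·n). Ties
    break deterministically by (z, compound_id).
    """
    if not 0 < percentile <= 1:
        raise ParameterError(f"percentile {percentile} outside (0, 1]")
    mean_z = (
        zscores.groupby(["model", "compound_id"], sort=True)["z"]
        .mean()
        .reset_index()
        .rename(columns={"z": "mean_z"})
    )
    out = []
    for model, sub in mean_z.groupby("model", sort=True):
        sub = sub.sort_values(["mean_z", "compound_id"], kind="mergesort").reset_index(
            drop=True
        )
        sub["rank"] = np.arange(1, len(sub) + 1)
        n_sel = math.ceil(percentile * len(sub))
        sub["selected"] = sub["rank"] <= n_sel
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def hit_union(hits: pd.DataFrame) -> pd.DataFrame:
    """Cross-model union of selected compounds with per-model provenance.

    One row per compound in any model's top cut; ``models`` lists the
    models that selected it and ``best_z`` its most extreme mean z.
    """
    sel = hits[hits["selected"]]
    grouped = sel.groupby("compound_id", sort=True)
    return pd.DataFrame(
        {
            "compound_id": list(grouped.groups),
            "models": [",".join(sorted(g["model"])) for _, g in grouped],
            "n_models": grouped.size().to_numpy(),
            "best_z": grouped["mean_z"].min().to_numpy(),
        }
    ).sort_values("best_z", kind="mergesort", ignore_index=True)


def score_screen(
    plate_sets: list[PlateSet], percentile: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize, score and rank a whole screen (one PlateSet per model).

    Returns (per-model hit table, cross-model union).
    """
    z_frames = [robust_z(normalize_plate(ps)) for ps in plate_sets]
    hits = call_hits(pd.concat(z_frames, ignore_index=True), percentile=percentile)
    return hits, hit_union(hits)
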