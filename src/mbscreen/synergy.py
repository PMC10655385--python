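"""HSA (highest-single-agent) synergy scoring of combination checkerboards.

A checkerboard crosses a dilution series of drug A (rows, including a
zero dose) with a series of drug B (columns, including zero); each cell
holds measured viability (% of control). Under the HSA reference model
the expected combination effect equals the stronger of the two single
agents, so the per-cell excess is

    delta(i, j) = inhibition(a_i, b_j) − max(inhibition(a_i, 0),
                                             inhibition(0, b_j)),

in percentage points, defined only where both doses are > 0. The HSA
score is the mean excess over those combination cells; scores >= +10
are called synergistic, <= −10 antagonistic, and anything between
non-interactive. When one axis is the VECC cocktail, its "dose" is the
unit multiplier U and the per-drug concentrations follow from
:func:`mbscreen.doseresponse.vecc_cocktail`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import FormatError, ParameterError

SYNERGY_THRESHOLD = 10.0  # percentage points of mean excess over HSA


@dataclass
class SynergyMatrix:
    """A checkerboard viability surface with zero-dose margins."""

    doses_a: np.ndarray  # µM (or VECC units), ascending, doses_a[0] == 0
    doses_b: np.ndarray
    viability_pct: np.ndarray  # shape (|a|, |b|)
    drug_a: str = "A"
    drug_b: str = "B"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, float)
        self.doses_b = np.asarray(self.doses_b, float)
        self.viability_pct = np.asarray(self.viability_pct, float)
        if self.viability_pct.shape != (len(self.doses_a), len(self.doses_b)):
            raise ParameterError("viability matrix shape does not match dose grids")
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ParameterError(
                "single-agent margins missing: dose grids must start at 0"
            )

    @property
    def inhibition_pct(self) -> np.ndarray:
        return np.clip(100.0 - self.viability_pct, 0.0, 100.0)


def hsa_delta(matrix: SynergyMatrix) -> np.ndarray:
    """Per-cell excess inhibition over the HSA reference.

    Returned with the same shape as the viability matrix; margin cells
    (either dose zero) are NaN since they define the reference.
    """
    inh = matrix.inhibition_pct
    single_a = inh[:, 0][:, None]  # column of drug-A-alone inhibitions
    single_b = inh[0, :][None, :]
    delta = inh - np.maximum(single_a, single_b)
    delta = delta.astype(float)
    delta[0, :] = np.nan
    delta[:, 0] = np.nan
    return delta


def hsa_score(matrix: SynergyMatrix) -> float:
    """Mean HSA excess over combination cells (both doses > 0)."""
    delta = hsa_delta(matrix)
    return float(np.nanmean(delta[1:, 1:]))


def classify_synergy(score: float, threshold: float = SYNERGY_THRESHOLD) -> str:
    """"synergistic" (score >= +threshold), "antagonistic" (<= −threshold)
    or "non_interactive"; thresholds are inclusive."""
    if not np.isfinite(score):
        raise ParameterError(f"hsa score {score!r} not finite")
    if score >= threshold:
        return "synergistic"
    if score <= -threshold:
        return "antagonistic"
    return "non_interactive"


@dataclass
class SynergyResult:
    matrix: SynergyMatrix
    delta: np.ndarray = field(init=False)
    score: float = field(init=False)
    call: str = field(init=False)

    def __post_init__(self) -> None:
        self.delta = hsa_delta(self.matrix)
        self.score = hsa_score(self.matrix)
        self.call = classify_synergy(self.score)


def score_matrix(matrix: SynergyMatrix) -> SynergyResult:
    return SynergyResult(matrix)


def build_checkerboard(
    top_a: float, top_b: float, n_steps: int, dilution: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Dose grids for a serial-dilution checkerboard.

    Each axis is {0} ∪ {top/dilution^i}, i = 0..n_steps−1, ascending
    (n_steps two-fold dilutions from the top dose by default).
    """
    if top_a <= 0 or top_b <= 0:
        raise ParameterError("top doses must be > 0")
    if n_steps < 2:
        raise ParameterError("n_steps must be >= 2")
    if dilution <= 1:
        raise ParameterError("dilution factor must be > 1")

    def axis(top: float) -> np.ndarray:
        series = top / dilution ** np.arange(n_steps)[::-1]
        return np.concatenate([[0.0], series])

    return axis(top_a), axis(top_b)


def average_replicates(matrices: list[SynergyMatrix]) -> SynergyMatrix:
    """Cell-wise mean of replicate checkerboards on identical grids."""
    if not matrices:
        raise ParameterError("no matrices to average")
    ref = matrices[0]
    for m in matrices[1:]:
        if not (
            np.allclose(m.doses_a, ref.doses_a) and np.allclose(m.doses_b, ref.doses_b)
        ):
            raise ParameterError("replicate matrices have differing dose grids")
    stacked = np.stack([m.viability_pct for m in matrices])
    return SynergyMatrix(
        ref.doses_a, ref.doses_b, stacked.mean(axis=0), ref.drug_a, ref.drug_b
    )


def read_checkerboard(path: str | Path, drug_a: str = "A", drug_b: str = "B") -> SynergyMatrix:
    """Read a wide CSV: dose_a as row index, dose_b as column header,
    viability % in the cells."""
    df = pd.read_csv(path, index_col=0)
    try:
        doses_a = df.index.to_numpy(float)
        doses_b = np.asarray([float(c) for c in df.columns])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: dose axes must be numeric") from exc
    order_a, order_b = np.argsort(doses_a), np.argsort(doses_b)
    return SynergyMatrix(
        doses_a[order_a],
        doses_b[order_b],
        df.to_numpy(float)[np.ix_(order_a, order_b)],
        drug_a,
        drug_b,
    )


def write_checkerboard(matrix: SynergyMatrix, path: str | Path) -> None:
    pd.DataFrame(
        matrix.viability_pct,
        index=pd.Index(matrix.doses_a, name=f"dose_{matrix.drug_a}"),
        columns=matrix.doses_b,
    ).to_csv(path)
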