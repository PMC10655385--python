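"""Four-parameter logistic dose–response fitting, GI50 and selectivity.

The viability model is the 4PL sigmoid on log dose,

    v(d) = bottom + (top − bottom) / (1 + (d / midpoint)^hill),

with viability in percent of control and dose in µM. GI50 is the
*absolute* 50%-of-control crossing, not the curve midpoint: it is
censored at the top tested dose whenever the fitted curve stays above
50% viability across the tested range (the "no GI50 when < 50%
inhibition at the highest dose" rule). Matched sensitive/resistant
(S/R) fits yield two directional ratios:

* resistance fold-shift = GI50_R / GI50_S (how much resistance the
  selected model acquired to a chemotherapeutic);
* compound selectivity ratio = GI50_S / GI50_R (> 1 means the compound
  is more potent on the resistant model; > 2 is the selectivity call).

The VECC composite unit (Vincristine + Etoposide + Cisplatin +
Cyclophosphamide) is also defined here: 1 U doses each drug at its own
GI50, and x U scales all four linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import least_squares

from ._errors import InsufficientDesignError, PairingError, ParameterError

#: Default confirmation design: 6-point fivefold dilution from 5 µM.
FIVEFOLD6 = tuple(5.0 / 5.0**i for i in range(6))

# box constraints keeping small-n fits biophysically sane
BOTTOM_BOUNDS = (0.0, 100.0)
TOP_BOUNDS = (50.0, 120.0)
HILL_BOUNDS = (1e-3, 10.0)


def four_pl(d: np.ndarray, bottom: float, top: float, midpoint: float, hill: float) -> np.ndarray:
    d = np.asarray(d, float)
    return bottom + (top - bottom) / (1.0 + (d / midpoint) ** hill)


@dataclass
class DoseResponseFit:
    """4PL parameters plus the derived (possibly censored) GI50."""

    bottom: float
    top: float
    hill: float
    midpoint: float  # µM
    gi50: float  # µM; if censored, the top tested dose (a lower bound)
    censored: bool  # True ⇔ curve stays above 50% viability in range
    rss: float
    n_points: int
    top_dose: float
    converged: bool = True

    def predict(self, d: np.ndarray) -> np.ndarray:
        return four_pl(d, self.bottom, self.top, self.midpoint, self.hill)

    @property
    def gi50_label(self) -> str:
        return f">{self.top_dose:g}" if self.censored else f"{self.gi50:g}"


def _gi50_from_params(bottom: float, top: float, midpoint: float, hill: float) -> float:
    """Dose at the absolute 50% viability crossing (inf if unreachable)."""
    if not (bottom < 50.0 < top):
        return math.inf
    return midpoint * ((top - 50.0) / (50.0 - bottom)) ** (1.0 / hill)


def fit_4pl(doses, viability, n_starts: int = 7) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start on the midpoint.

    Requires >= 4 distinct positive doses. The midpoint is optimized on
    log10 scale with starts spread over the tested dose range extended
    one log either side; the best RSS wins. GI50 is censored at the top
    dose when the fitted viability at the top dose exceeds 50%.
    """
    d = np.asarray(doses, float)
    v = np.asarray(viability, float)
    if d.shape != v.shape:
        raise ParameterError("doses and viability must have equal length")
    if np.any(d <= 0):
        raise ParameterError("doses must be > 0")
    if not np.all(np.isfinite(v)):
        raise ParameterError("viabilities must be finite")
    if len(np.unique(d)) < 4:
        raise InsufficientDesignError(
            f"need >= 4 distinct doses, got {len(np.unique(d))}"
        )

    log_d = np.log10(d)
    lo, hi = log_d.min() - 1.0, log_d.max() + 1.0

    def residuals(p):
        bottom, top, logmid, hill = p
        return four_pl(d, bottom, top, 10.0**logmid, hill) - v

    bounds = (
        [BOTTOM_BOUNDS[0], TOP_BOUNDS[0], lo, HILL_BOUNDS[0]],
        [BOTTOM_BOUNDS[1], TOP_BOUNDS[1], hi, HILL_BOUNDS[1]],
    )
    v_hi = float(np.clip(v.max(), *TOP_BOUNDS))
    v_lo = float(np.clip(v.min(), *BOTTOM_BOUNDS))
    best = None
    for logmid0 in np.linspace(log_d.min() - 0.5, log_d.max() + 0.5, n_starts):
        for hill0 in (0.7, 1.5):
            p0 = [v_lo, v_hi, logmid0, hill0]
            try:
                sol = least_squares(residuals, p0, bounds=bounds, method="trf")
            except Exception:  # pragma: no cover - solver hiccup on one start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        return DoseResponseFit(
            math.nan, math.nan, math.nan, math.nan, math.nan,
            censored=False, rss=math.nan, n_points=len(d),
            top_dose=float(d.max()), converged=False,
        )
    bottom, top, logmid, hill = best.x
    midpoint = 10.0**logmid
    top_dose = float(d.max())
    v_at_top_dose = float(four_pl(np.array([top_dose]), bottom, top, midpoint, hill)[0])
    censored = v_at_top_dose > 50.0
    gi50 = top_dose if censored else _gi50_from_params(bottom, top, midpoint, hill)
    return DoseResponseFit(
        bottom=float(bottom), top=float(top), hill=float(hill),
        midpoint=float(midpoint), gi50=float(gi50), censored=censored,
        rss=float(2 * best.cost), n_points=len(d), top_dose=top_dose,
    )


@dataclass
class CensoredRatio:
    """A ratio bound when one GI50 is censored, e.g. "> 5"."""

    bound: float
    direction: str  # ">" or "<"

    def __str__(self) -> str:
        return f"{self.direction} {self.bound:g}"


def resistance_ratio(fit_R: DoseResponseFit, fit_S: DoseResponseFit):
    """Resistance fold-shift GI50_R / GI50_S (R over S, as plotted for
    the VECC shift). Censored inputs return a bound, not a number."""
    if fit_R.censored and fit_S.censored:
        raise ParameterError("both GI50s censored: ratio undefined")
    if fit_R.censored:
        return CensoredRatio(fit_R.top_dose / fit_S.gi50, ">")
    if fit_S.censored:
        return CensoredRatio(fit_R.gi50 / fit_S.top_dose, "<")
    return fit_R.gi50 / fit_S.gi50


@dataclass
class SelectivityRecord:
    """Per-compound call across one or more matched S/R model pairs."""

    compound_id: str
    best_ratio_R: float  # max over models of GI50_S / GI50_R (or its bound)
    best_ratio_S: float  # max over models of GI50_R / GI50_S (or its bound)
    selective_R: bool
    selective_S: bool
    inactive: bool  # censored on both arms in every model


def _fold_pair(fit_S: DoseResponseFit, fit_R: DoseResponseFit) -> tuple[float, float]:
    """(selectivity-for-R fold, selectivity-for-S fold) for one model pair.

    Censoring yields the conservative lower bound on the fold in the
    direction that remains estimable, and 0 in the other direction.
    """
    if fit_S.censored and fit_R.censored:
        return 0.0, 0.0
    if fit_S.censored:  # inactive on S, active on R -> R-selective bound
        return fit_S.top_dose / fit_R.gi50, 0.0
    if fit_R.censored:
        return 0.0, fit_R.top_dose / fit_S.gi50
    r = fit_S.gi50 / fit_R.gi50
    return r, 1.0 / r


def classify_selectivity(
    pairs: list[tuple[str, DoseResponseFit, DoseResponseFit]],
    threshold: float = 2.0,
) -> list[SelectivityRecord]:
    """Call compounds selective for resistant (or sensitive) models.

    ``pairs`` holds (compound_id, fit_S, fit_R) tuples, one per compound
    per model; a compound is R-selective when GI50_S/GI50_R > threshold
    on at least one model (and symmetrically for S). Should a compound
    cross the threshold in both directions on different models, the
    larger fold wins (the calls are mutually exclusive).
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    by_compound: dict[str, list[tuple[DoseResponseFit, DoseResponseFit]]] = {}
    for item in pairs:
        if len(item) != 3:
            raise PairingError(f"malformed pair {item!r}")
        cid, fit_S, fit_R = item
        if fit_S is None or fit_R is None:
            raise PairingError(f"compound {cid}: unmatched S/R fits")
        by_compound.setdefault(cid, []).append((fit_S, fit_R))
    records = []
    for cid in sorted(by_compound):
        folds = [_fold_pair(s, r) for s, r in by_compound[cid]]
        best_R = max(f[0] for f in folds)
        best_S = max(f[1] for f in folds)
        inactive = all(f == (0.0, 0.0) for f in folds)
        sel_R = best_R > threshold and best_R >= best_S
        sel_S = best_S > threshold and not sel_R
        records.append(
            SelectivityRecord(cid, best_R, best_S, sel_R, sel_S, inactive)
        )
    return records


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to 2 decimals (as printed in reports)."""
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_selectivity(
    records: list[SelectivityRecord], n_total: int | None = None
) -> dict[str, float | int]:
    """Counts and percentages of R-selective / S-selective / neither."""
    if n_total is None:
        n_total = len(records)
    if n_total < 1:
        raise ParameterError("n_total must be >= 1")
    n_R = sum(r.selective_R for r in records)
    n_S = sum(r.selective_S for r in records)
    if n_R + n_S > n_total:
        raise ParameterError("selective counts exceed n_total")
    return {
        "n_total": n_total,
        "n_selective_R": n_R,
        "n_selective_S": n_S,
        "n_neither": n_total - n_R - n_S,
        "pct_selective_R": _pct(n_R, n_total),
        "pct_selective_S": _pct(n_S, n_total),
        "pct_neither": _pct(n_total - n_R - n_S, n_total),
    }


@dataclass
class VeccUnit:
    """The VECC composite: 1 U = each drug at its GI50 (µM)."""

    gi50_vincristine: float
    gi50_etoposide: float
    gi50_cisplatin: float
    gi50_cyclophosphamide: float

    def __post_init__(self) -> None:
        for name, g in self.as_dict().items():
            if not (math.isfinite(g) and g > 0):
                raise ParameterError(f"{name}: GI50 must be finite and > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "vincristine": self.gi50_vincristine,
            "etoposide": self.gi50_etoposide,
            "cisplatin": self.gi50_cisplatin,
            "cyclophosphamide": self.gi50_cyclophosphamide,
        }


def vecc_cocktail(unit: VeccUnit, x: float) -> dict[str, float]:
    """Per-drug concentrations (µM) of the cocktail dosed at x U."""
    if x < 0:
        raise ParameterError(f"multiplier x={x} must be >= 0")
    return {drug: x * gi50 for drug, gi50 in unit.as_dict().items()}
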