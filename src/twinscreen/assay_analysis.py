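"""In-vitro analytics: dilution ladders, 4PL fits, AUC/z/TWS, Bliss, morphometry.

These are the bench-side counterparts of the in silico screen: dose-response
viability plates are fit with a four-parameter logistic to report IC50 and a
log-dose-normalized AUC; compound sensitivities are compared across cell
models by AUC z-scores and a therapeutic window score (mean healthy AUC over
mean tumor AUC); two-drug 4x4 matrices are scored against the Bliss
independence reference; and the morphometric/growth formulas (wound closure,
nuclear circularity, xenograft tumor volume, positive-cell fractions) are
provided as plain functions over measured quantities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegeneratePanelError, ValidationError, ZeroTumorAucError

__all__ = [
    "PlateAssay",
    "FitResult",
    "SynergyMatrix",
    "build_dilution_ladder",
    "four_pl",
    "fit_4pl",
    "compute_auc",
    "zscore_auc",
    "therapeutic_window",
    "bliss_synergy",
    "wound_closure",
    "circularity_index",
    "tumor_volume",
    "positive_fraction",
]


@dataclass(frozen=True)
class PlateAssay:
    """Replicate viability fractions over an ascending dose series."""

    doses: np.ndarray
    viability: np.ndarray           # replicates x doses
    compound: str = ""
    model_id: str = ""
    tissue_class: str = "tumor"     # "tumor" | "healthy"
    dose_unit: str = "nM"

    def __post_init__(self):
        d = np.asarray(self.doses, float)
        v = np.atleast_2d(np.asarray(self.viability, float))
        if np.any(np.diff(d) <= 0):
            raise ValidationError("doses must be strictly ascending")
        if v.shape[1] != d.size or not np.all(np.isfinite(v)):
            raise ValidationError("viability must be finite, replicates x doses")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "viability", v)

    def mean_viability(self) -> np.ndarray:
        return self.viability.mean(axis=0)


@dataclass(frozen=True)
class FitResult:
    ic50: float
    hill: float
    top: float
    bottom: float
    auc: float
    rss: float
    converged: bool
    warning: str | None = None


@dataclass(frozen=True)
class SynergyMatrix:
    """4x4 inhibition grid with row/column 0 the single-agent responses."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    bliss_excess: np.ndarray | None = None
    score: float | None = None


def build_dilution_ladder(top: float, ratio: float, floor: float) -> np.ndarray:
    """Serial dilution doses from ``top`` down to ``floor``, returned ascending.

    The bench default (top 100 uM = 1e5 nM, 1:3 ratio, 5 nM floor) yields the
    10-point ladder used for plate assays.
    """
    if top < floor:
        raise ValidationError("top dose below floor")
    if ratio <= 1:
        raise ValidationError("dilution ratio must exceed 1")
    doses = []
    dose = float(top)
    while dose >= floor * (1.0 - 1e-12):
        doses.append(dose)
        dose /= ratio
    return np.array(doses[::-1])


def four_pl(c, top, bottom, ic50, hill):
    """V(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill)."""
    c = np.asarray(c, float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_4pl(plate: PlateAssay) -> FitResult:
    """Least-squares 4PL fit; reported IC50 is the curve midpoint (relative).

    A plate whose mean viability never decreases is flagged ``no_inhibition``
    and gets the upper IC50 bound; optimizer failure returns best-effort
    parameters with ``converged=False``.
    """
    doses = plate.doses
    if len(doses) < 4:
        raise ValidationError("4PL fit needs >= 4 distinct doses")
    mean = plate.mean_viability()
    c = np.tile(doses, plate.viability.shape[0])
    v = plate.viability.ravel()

    ic50_lo, ic50_hi = doses.min() / 10.0, doses.max() * 10.0
    warning = None
    if np.all(np.diff(mean) >= 0):
        warning = "no_inhibition"
        warnings.warn(f"{plate.compound or 'plate'}: viability never decreases",
                      stacklevel=2)
        flat = FitResult(ic50=ic50_hi, hill=1.0, top=float(mean.max()),
                         bottom=float(mean.min()), auc=compute_auc(plate),
                         rss=float(np.sum((v - mean.mean()) ** 2)),
                         converged=False, warning=warning)
        return flat

    p0 = [float(np.clip(mean.max(), 0.5, 1.5)),
          float(np.clip(mean.min(), 0.0, 1.0)),
          float(doses[np.argmin(np.abs(mean - (mean.max() + mean.min()) / 2))]),
          1.0]
    bounds = ([0.5, 0.0, ic50_lo, 0.1], [1.5, 1.0, ic50_hi, 10.0])
    try:
        popt, _ = curve_fit(four_pl, c, v, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    top, bottom, ic50, hill = (float(x) for x in popt)
    rss = float(np.sum((v - four_pl(c, *popt)) ** 2))
    return FitResult(ic50=ic50, hill=hill, top=top, bottom=bottom,
                     auc=compute_auc(plate), rss=rss, converged=converged,
                     warning=warning)


def compute_auc(plate: PlateAssay) -> float:
    """Trapezoidal mean-viability area over log10 dose, span-normalized.

    A flat plate at viability v gives AUC = v, so values are comparable
    across compounds with different dose ranges.
    """
    if len(plate.doses) < 2:
        raise ValidationError("AUC needs >= 2 doses")
    x = np.log10(plate.doses)
    y = plate.mean_viability()
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def zscore_auc(aucs: dict[str, float]) -> dict[str, float]:
    """z_i = (AUC_i - mean) / SD with sample (n-1) standard deviation."""
    if len(aucs) < 2:
        raise ValidationError("z-scores need >= 2 models")
    values = np.array(list(aucs.values()), float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegeneratePanelError("all AUC values identical")
    mean = values.mean()
    return {k: float((v - mean) / sd) for k, v in aucs.items()}


def therapeutic_window(aucs_healthy, aucs_tumor) -> float:
    """TWS = mean(healthy AUC) / mean(tumor AUC); > 1 means tumor-selective."""
    healthy = np.asarray(list(aucs_healthy), float)
    tumor = np.asarray(list(aucs_tumor), float)
    if healthy.size == 0 or tumor.size == 0:
        raise ValidationError("both AUC lists must be non-empty")
    if tumor.mean() == 0:
        raise ZeroTumorAucError("tumor mean AUC is zero")
    return float(healthy.mean() / tumor.mean())


def bliss_synergy(doses_a, doses_b, inhibition) -> SynergyMatrix:
    """Score a 4x4 combination grid against Bliss independence.

    expected(a, b) = y_a + y_b - y_a*y_b from the single-agent margins; the
    summary score is 100 x the mean excess over the 3x3 combination block.
    Single-agent cells have zero excess by definition.
    """
    da = np.asarray(doses_a, float)
    db = np.asarray(doses_b, float)
    y = np.asarray(inhibition, float)
    if y.shape != (da.size, db.size):
        raise ValidationError("inhibition grid must be len(doses_a) x len(doses_b)")
    if da[0] != 0 or db[0] != 0:
        raise ValidationError("first dose of each agent must be 0 (single-agent margin)")
    if np.any(y < -0.05) or np.any(y > 1.05):
        warnings.warn("inhibition outside [-0.05, 1.05] before clipping",
                      stacklevel=2)
    y = np.clip(y, 0.0, 1.0)
    ya = y[:, 0][:, None]       # margin of agent A down the rows
    yb = y[0, :][None, :]       # margin of agent B across the columns
    expected = ya + yb - ya * yb
    excess = y - expected
    excess[0, :] = 0.0
    excess[:, 0] = 0.0
    score = float(100.0 * excess[1:, 1:].mean())
    return SynergyMatrix(doses_a=da, doses_b=db, inhibition=y,
                         bliss_excess=excess, score=score)


def wound_closure(gap0: float, gap1: float) -> float:
    """Percent closure 100 * (gap0 - gap1) / gap0 of a scratch-assay gap."""
    if gap0 <= 0:
        raise ValidationError("initial gap must be > 0")
    if gap1 < 0:
        raise ValidationError("gap cannot be negative")
    return float(100.0 * (gap0 - gap1) / gap0)


def circularity_index(area: float, perimeter: float) -> float:
    """CI = 4*pi*area / perimeter^2; 1 for a circle, < 1 for irregular shapes."""
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be positive")
    return float(4.0 * math.pi * area / perimeter ** 2)


def tumor_volume(length: float, width: float) -> float:
    """Caliper xenograft volume TV = length * width^2 / 2 (mm^3).

    Length is the longer axis by convention; swapped inputs are corrected
    with a warning.
    """
    if length <= 0 or width <= 0:
        raise ValidationError("length and width must be positive")
    if width > length:
        warnings.warn("width exceeded length; axes swapped", stacklevel=2)
        length, width = width, length
    return float(length * width ** 2 / 2.0)


def positive_fraction(n_positive: int, n_total: int) -> float:
    """Fraction of positively stained cells among all counted nuclei."""
    if n_total <= 0 or not (0 <= n_positive <= n_total):
        raise ValidationError("need 0 <= n_positive <= n_total and n_total > 0")
    return float(n_positive / n_total)
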