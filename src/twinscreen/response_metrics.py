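"""Dose-response summaries: viability, Emax/EC50 and GR50/GRmax.

The simulated phenotype combines a pro-viability readout (nuclear MYC:MAX)
and a pro-death readout (active Caspase-3) into a relative viability

    rho(C) = max(0, (pos_C/pos_0 - lambda * neg_C/neg_0) / (1 - lambda))

which equals 1 in the control by construction.  Potency/efficacy are then
summarized both classically (Emax as maximal percent inhibition with an
inclusive 50% effectiveness cutoff, EC50 as the half-maximal-inhibition
concentration) and on the per-division growth-rate-inhibition (GR) scale,
where rho is interpreted as the treated/control cell-count ratio of an assay
window with ``n_div`` control divisions:

    GR(rho) = 2 * rho**(1/n_div) - 1

GR = 1 means unperturbed growth, 0 perfect cytostasis, -1 complete killing;
for the default n_div = 1 this reduces to the affine map GR = 2*rho - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, NoContrastError, ValidationError

__all__ = [
    "DoseResponseCurve",
    "DrugResponseSummary",
    "viability_score",
    "compute_emax",
    "compute_ec50",
    "gr_value",
    "gr_metrics",
    "summarize_curve",
    "rank_drugs",
    "gr50_matrix",
    "DEFAULT_LAMBDA",
    "DEFAULT_N_DIV",
    "EFFECTIVE_EMAX_CUTOFF",
]

DEFAULT_LAMBDA = 0.5
DEFAULT_N_DIV = 1.0
#: Emax at or above this percentage flags a drug as potentially effective
EFFECTIVE_EMAX_CUTOFF = 50.0


@dataclass(frozen=True)
class DoseResponseCurve:
    concentrations: np.ndarray
    viability: np.ndarray
    readouts_raw: np.ndarray | None = None
    control_readouts: tuple[float, float] | None = None
    dropped_runs: np.ndarray | None = None

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        v = np.asarray(self.viability, float)
        if c.ndim != 1 or v.shape != c.shape:
            raise ValidationError("concentrations and viability must align")
        if np.any(c <= 0):
            raise ValidationError("concentrations must be positive (control is implicit)")
        order = np.argsort(c)
        object.__setattr__(self, "concentrations", c[order])
        object.__setattr__(self, "viability", np.maximum(v[order], 0.0))
        if self.readouts_raw is not None:
            object.__setattr__(self, "readouts_raw",
                               np.asarray(self.readouts_raw, float)[order])


@dataclass(frozen=True)
class DrugResponseSummary:
    emax: float
    ec50: float | None
    gr50: float | None
    grmax: float
    effective: bool


def viability_score(pos_C, neg_C, pos_0, neg_0, lam: float = DEFAULT_LAMBDA):
    """Control-normalized signed combination of the two readouts, clipped at 0."""
    if not (0 <= lam < 1):
        raise ConfigError("lambda must lie in [0, 1)")
    if not (pos_0 > 0 and neg_0 > 0):
        raise ValidationError("control readouts must be positive")
    s = np.asarray(pos_C, float) / pos_0 - lam * np.asarray(neg_C, float) / neg_0
    rho = np.maximum(0.0, s / (1.0 - lam))
    return float(rho) if np.ndim(rho) == 0 else rho


def compute_emax(curve: DoseResponseCurve) -> float:
    """Maximal percent inhibition over the dose range (0 for a flat curve)."""
    if len(curve.viability) < 1:
        raise ValidationError("curve needs at least one dose")
    return float(100.0 * (1.0 - np.min(curve.viability)))


def _log_interp_crossing(conc: np.ndarray, y: np.ndarray, target: float):
    """Smallest concentration where y rises through target (linear in log10 C)."""
    if y[0] >= target:
        return float(conc[0])
    idx = np.nonzero(y >= target)[0]
    if idx.size == 0:
        return None
    j = int(idx[0])
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(conc[j])
    f = (target - y0) / (y1 - y0)
    logc = np.log10(conc[j - 1]) + f * (np.log10(conc[j]) - np.log10(conc[j - 1]))
    return float(10.0 ** logc)


def compute_ec50(curve: DoseResponseCurve, emax: float) -> float | None:
    """Concentration of half-maximal inhibition; undefined when Emax = 0."""
    if emax <= 0:
        return None
    inhibition = 1.0 - curve.viability
    return _log_interp_crossing(curve.concentrations, inhibition, emax / 200.0)


def gr_value(rho, n_div: float = DEFAULT_N_DIV):
    """Per-division growth-rate-inhibition value of a viability ratio."""
    if n_div <= 0:
        raise ConfigError("n_div must be > 0")
    r = np.maximum(np.asarray(rho, float), 0.0)
    gr = 2.0 * np.power(r, 1.0 / n_div) - 1.0
    return float(gr) if np.ndim(gr) == 0 else gr


def gr_metrics(curve: DoseResponseCurve,
               n_div: float = DEFAULT_N_DIV) -> tuple[float | None, float]:
    """(GR50, GRmax): first crossing of GR = 0.5 and the minimum GR."""
    gr = gr_value(curve.viability, n_div)
    grmax = float(np.min(gr))
    gr50 = _log_interp_crossing(curve.concentrations, 0.5 - gr, 0.0)
    return gr50, grmax


def summarize_curve(curve: DoseResponseCurve,
                    n_div: float = DEFAULT_N_DIV) -> DrugResponseSummary:
    emax = compute_emax(curve)
    ec50 = compute_ec50(curve, emax)
    gr50, grmax = gr_metrics(curve, n_div)
    return DrugResponseSummary(
        emax=emax, ec50=ec50, gr50=gr50, grmax=grmax,
        effective=bool(emax >= EFFECTIVE_EMAX_CUTOFF))


def _screen_table(screen) -> pd.DataFrame:
    return screen.table if hasattr(screen, "table") else screen


def rank_drugs(screen) -> pd.DataFrame:
    """Rank panel drugs by tumor-vs-normal selectivity of mean Emax.

    Ties break by mean tumor Emax (descending), then drug name.  The result
    is independent of the row order of the input.
    """
    table = _screen_table(screen)
    tissues = set(table["tissue"])
    if not {"tumor", "normal"} <= tissues:
        raise NoContrastError("screen must contain both tumor and normal twins")
    means = (table.pivot_table(index="drug", columns="tissue",
                               values="emax_pct", aggfunc="mean")
             .rename(columns={"tumor": "mean_tumor_emax",
                              "normal": "mean_normal_emax"}))
    means["selectivity"] = means["mean_tumor_emax"] - means["mean_normal_emax"]
    ranking = (means.reset_index()
               .sort_values(["selectivity", "mean_tumor_emax", "drug"],
                            ascending=[False, False, True],
                            kind="mergesort")
               .reset_index(drop=True))
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking[["rank", "drug", "selectivity",
                    "mean_tumor_emax", "mean_normal_emax"]]


def gr50_matrix(screen) -> pd.DataFrame:
    """Drugs x samples GR50 heatmap table (NaN where GR never reaches 0.5)."""
    table = _screen_table(screen)
    return table.pivot_table(index="drug", columns="sample_id",
                             values="gr50_nM", aggfunc="first", dropna=False)
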