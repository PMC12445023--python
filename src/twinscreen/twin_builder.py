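"""Individualize the network model into per-patient digital twins.

A twin is the reference network plus (a) per-gene synthesis multipliers
derived from one sample's expression relative to the normal-tissue baseline
and (b) activation levels for the clamped input species (the CTNNB1/Wnt
input being the cohort's dominant driver).  Individualization is bounded and
multiplicative: a gene at the baseline keeps its nominal synthesis rate, and
ratios are clipped to [0.1, 10] so no single transcript can produce a
degenerate model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyLibraryError, NoExpressionError, UnknownInputError
from .model_core import NetworkModel

logger = logging.getLogger(__name__)

__all__ = [
    "PatientProfile",
    "DigitalTwin",
    "ActivationPolicy",
    "normalize_expression",
    "reference_baseline",
    "individualize",
    "apply_activation",
    "default_activation",
    "profiles_from_tables",
    "build_cohort_twins",
]

#: pseudocount (CPM units) guarding the expression ratio
EPSILON_CPM = 0.5
SCALE_BOUNDS = (0.1, 10.0)

MUTATION_COLUMNS = ("CTNNB1", "NFE2L2", "TERT")


@dataclass(frozen=True)
class PatientProfile:
    sample_id: str
    tissue: str                      # "tumor" | "normal"
    histology: str                   # "HB" | "HCC" | "TLCT" | "normal"
    expression: dict[str, float]     # gene -> log2(CPM+1)
    mutations: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class DigitalTwin:
    model: NetworkModel
    synthesis_scale: dict[str, float]   # gene-representative species id -> multiplier
    activation: dict[str, float]        # input species id -> level in [0, 1]
    provenance: dict[str, str]


@dataclass(frozen=True)
class ActivationPolicy:
    """Input activation encoding for the cohort.

    CTNNB1-mutant tumors get full Wnt input; wild-type tumors an intermediate
    level (their expression still carries the Wnt program); normal tissue a
    low baseline tone.  The Hedgehog input idles at a common low tone.
    """

    ctnnb1_mutant: float = 1.0
    tumor_wildtype: float = 0.6
    normal: float = 0.05
    hedgehog_tone: float = 0.2


def normalize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million then log2(x+1), per sample (genes x samples)."""
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise EmptyLibraryError("negative counts", code="negative_counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise EmptyLibraryError(f"all-zero library: {list(zero.index)}")
    cpm = counts.div(totals, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def reference_baseline(normalized: pd.DataFrame, normal_samples) -> pd.Series:
    """Per-gene median of the normal samples on the log2(CPM+1) scale."""
    cols = [c for c in normalized.columns if c in set(normal_samples)]
    if not cols:
        raise NoExpressionError("no normal samples for the reference baseline")
    return normalized[cols].median(axis=1)


def _back_transform(log2_value: float) -> float:
    return float(2.0 ** log2_value - 1.0)


def individualize(model: NetworkModel, profile: PatientProfile,
                  reference: pd.Series | dict) -> DigitalTwin:
    """Derive a twin's synthesis multipliers from one expression profile.

    scale_g = clip((CPM_g + eps) / (CPM_ref,g + eps), 0.1, 10); genes missing
    from the profile keep scale 1 with a logged warning.
    """
    if not profile.expression:
        raise NoExpressionError(f"profile {profile.sample_id} has no expression")
    ref = dict(reference)
    lo, hi = SCALE_BOUNDS
    scales: dict[str, float] = {}
    for sp in model.gene_representatives():
        gene = sp.gene
        if gene is None or gene not in profile.expression or gene not in ref:
            logger.warning("sample %s: gene %s missing; synthesis scale set to 1",
                           profile.sample_id, gene)
            scales[sp.id] = 1.0
            continue
        expr = _back_transform(profile.expression[gene])
        base = _back_transform(float(ref[gene]))
        ratio = (expr + EPSILON_CPM) / (base + EPSILON_CPM)
        scales[sp.id] = float(min(max(ratio, lo), hi))
    return DigitalTwin(
        model=model,
        synthesis_scale=scales,
        activation={},
        provenance={"sample_id": profile.sample_id,
                    "tissue": profile.tissue,
                    "normalization": "log2(CPM+1), normal-median baseline"},
    )


def apply_activation(twin: DigitalTwin, driver: str, level: float) -> DigitalTwin:
    """Set one input's activation level in [0, 1] (idempotent, pure)."""
    if not (0 <= level <= 1):
        raise UnknownInputError(f"activation level {level} outside [0, 1]",
                                code="bad_level")
    sid = _resolve_input(twin.model, driver)
    activation = dict(twin.activation)
    activation[sid] = float(level)
    return replace(twin, activation=activation)


def _resolve_input(model: NetworkModel, driver: str) -> str:
    if driver in model.input_species:
        return driver
    candidate = f"{driver}_in"
    if candidate in model.input_species:
        return candidate
    raise UnknownInputError(f"{driver!r} is not an input of the model")


def default_activation(twin: DigitalTwin, profile: PatientProfile,
                       policy: ActivationPolicy = ActivationPolicy()) -> DigitalTwin:
    """Apply the cohort activation policy for the Wnt and Hedgehog inputs."""
    if profile.tissue == "normal":
        wnt = policy.normal
    elif profile.mutations.get("CTNNB1", False):
        wnt = policy.ctnnb1_mutant
    else:
        wnt = policy.tumor_wildtype
    twin = apply_activation(twin, "CTNNB1", wnt)
    if "SHH_in" in twin.model.input_species:
        twin = apply_activation(twin, "SHH_in", policy.hedgehog_tone)
    return twin


def profiles_from_tables(normalized: pd.DataFrame,
                         metadata: pd.DataFrame) -> list[PatientProfile]:
    """Build profiles from a genes-x-samples matrix and a metadata table.

    Metadata columns: sample_id, tissue, histology and boolean mutation flags
    (CTNNB1, NFE2L2, TERT).
    """
    profiles = []
    meta = metadata.set_index("sample_id")
    for sample in normalized.columns:
        if sample not in meta.index:
            continue
        row = meta.loc[sample]
        mutations = {m: bool(row[m]) for m in MUTATION_COLUMNS if m in row.index}
        profiles.append(PatientProfile(
            sample_id=str(sample),
            tissue=str(row["tissue"]),
            histology=str(row.get("histology", "")),
            expression=normalized[sample].to_dict(),
            mutations=mutations,
        ))
    return profiles


def build_cohort_twins(model: NetworkModel, counts: pd.DataFrame,
                       metadata: pd.DataFrame,
                       policy: ActivationPolicy = ActivationPolicy()
                       ) -> list[DigitalTwin]:
    """Normalize, individualize and activate a twin per cohort sample."""
    normalized = normalize_expression(counts)
    normals = metadata.loc[metadata["tissue"] == "normal", "sample_id"]
    reference = reference_baseline(normalized, normals)
    twins = []
    for profile in profiles_from_tables(normalized, metadata):
        twin = individualize(model, profile, reference)
        twins.append(default_activation(twin, profile, policy))
    return twins
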