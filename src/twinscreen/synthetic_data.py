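"""Synthetic cohort, drug panel, viability plate and synergy-grid generators.

The cohort generator emulates the study conditions the pipeline is built
for: 13 pediatric liver tumor and 8 normal liver expression profiles in
which Wnt-target and MYC-target genes are strongly upregulated in tumors
(mean log2 fold change 3), with CTNNB1 mutation flags set for 11 of the 13
tumors.  The default drug panel has 20 compounds: one multi-kinase
"ceritinib-like" inhibitor hitting the FAK/MTOR/AKT/ERK nodes at low-nM kD,
a deliberately inert compound whose target (ALK) is absent from the network,
and single-target comparators across the modeled kinases.  Every generator
returns its ground truth alongside the data so downstream recovery tests are
self-verifying.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay_analysis import PlateAssay, SynergyMatrix, four_pl
from .errors import ValidationError
from .model_core import NetworkModel
from .sim_engine import DrugSpec

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "generate_cohort",
    "generate_panel",
    "generate_plate",
    "generate_synergy_grid",
    "DEFAULT_SIGNATURE_GENES",
]

#: tumor-upregulated signature: Wnt targets and MYC targets
DEFAULT_SIGNATURE_GENES = ("LGR5", "DKK1", "NKD1", "MYCN", "CAD", "NPM1")

_FILLER_GENES = 100


@dataclass(frozen=True)
class CohortSpec:
    n_tumor: int = 13
    n_normal: int = 8
    n_ctnnb1: int = 11
    signature_genes_up: tuple[str, ...] = DEFAULT_SIGNATURE_GENES
    effect_log2fc: float = 3.0
    noise_sd_log2: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_ctnnb1 > self.n_tumor:
            raise ValidationError("n_ctnnb1 cannot exceed n_tumor")
        if self.effect_log2fc < 0:
            raise ValidationError("effect_log2fc must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    n_drugs: int = 20
    ceritinib_like_kd_nM: float = 50.0
    kd_range_nM: tuple[float, float] = (1.0, 1000.0)
    seed: int = 0


def generate_cohort(spec: CohortSpec = CohortSpec(),
                    model: NetworkModel | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression counts (genes x samples) and sample metadata.

    Baseline per-gene log2 means are drawn once (log-normal abundances);
    tumor samples add the signature effect; every value gets per-sample
    Gaussian log2 noise before back-transforming to integer counts.
    """
    rng = np.random.default_rng(spec.seed)
    model_genes = ([s.gene for s in model.gene_representatives() if s.gene]
                   if model is not None else [])
    genes = list(dict.fromkeys([*model_genes, *spec.signature_genes_up]))
    genes += [f"FILLER{i:03d}" for i in range(_FILLER_GENES)]
    base_log2 = rng.normal(6.0, 1.5, size=len(genes))

    tumor_ids = [f"T{i + 1:02d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i + 1:02d}" for i in range(spec.n_normal)]
    samples = tumor_ids + normal_ids
    sig = np.isin(genes, spec.signature_genes_up)

    values = np.empty((len(genes), len(samples)))
    for j, sample in enumerate(samples):
        is_tumor = sample.startswith("T")
        log2 = base_log2.copy()
        if is_tumor:
            log2 = log2 + spec.effect_log2fc * sig
        log2 = log2 + rng.normal(0.0, spec.noise_sd_log2, size=len(genes))
        values[:, j] = np.maximum(np.rint(2.0 ** log2), 0.0)
    expression = pd.DataFrame(values.astype(int), index=genes, columns=samples)

    histology = (["HB"] * max(spec.n_tumor - 2, 0) +
                 ["HCC", "TLCT"][: min(2, spec.n_tumor)])
    meta = pd.DataFrame({
        "sample_id": samples,
        "tissue": ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
        "histology": histology + ["normal"] * spec.n_normal,
        "CTNNB1": [i < spec.n_ctnnb1 for i in range(spec.n_tumor)]
        + [False] * spec.n_normal,
        "NFE2L2": [i in (spec.n_tumor - 2,) for i in range(spec.n_tumor)]
        + [False] * spec.n_normal,
        "TERT": [i in (spec.n_tumor - 1,) for i in range(spec.n_tumor)]
        + [False] * spec.n_normal,
    })
    return expression, meta


_COMPARATOR_TARGETS = (
    ("MEK_a", "MEK inhibitor"),
    ("ERK_a", "ERK inhibitor"),
    ("AKT_a", "AKT inhibitor"),
    ("MTOR_a", "MTOR inhibitor"),
    ("FAK_a", "FAK inhibitor"),
    ("PI3K_a", "PI3K inhibitor"),
    ("RAS_a", "RAS inhibitor"),
    ("GLI1_a", "Hedgehog/GLI inhibitor"),
)


def generate_panel(spec: PanelSpec = PanelSpec(),
                   model: NetworkModel | None = None
                   ) -> tuple[list[DrugSpec], pd.DataFrame]:
    """Drug panel plus a ground-truth table of intended effect classes.

    Exactly one compound is the multi-target ceritinib-like inhibitor
    (FAK/MTOR/AKT/ERK nodes, low-nM kD); one targets a species absent from
    the network (ALK surrogate, expected inert); the rest are single-target
    comparators with log-uniform kD draws.
    """
    if spec.n_drugs < 2:
        raise ValidationError("panel needs at least the multi-target and inert drugs")
    known = {s.id for s in model.species} if model is not None else None
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.kd_range_nM

    drugs: list[DrugSpec] = []
    truth_rows = []
    kd = spec.ceritinib_like_kd_nM
    drugs.append(DrugSpec(
        name="ceritinib_like",
        targets=tuple((t, kd) for t in ("FAK_a", "MTOR_a", "AKT_a", "ERK_a")),
        class_label="multi-kinase inhibitor"))
    truth_rows.append(("ceritinib_like", "multi_target", "selective", True))

    drugs.append(DrugSpec(name="alk_surrogate", targets=(("ALK", 30.0),),
                          class_label="ALK inhibitor"))
    truth_rows.append(("alk_surrogate", "absent_target", "inert", False))

    i = 0
    while len(drugs) < spec.n_drugs:
        target, label = _COMPARATOR_TARGETS[i % len(_COMPARATOR_TARGETS)]
        if known is not None and target not in known:
            raise ValidationError(f"panel target {target} not in model")
        kd_draw = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        name = f"{target.split('_')[0].lower()}_inhib_{i // len(_COMPARATOR_TARGETS) + 1}"
        drugs.append(DrugSpec(name=name, targets=((target, kd_draw),),
                              class_label=label))
        truth_rows.append((name, "single_target", "partial", False))
        i += 1

    truth = pd.DataFrame(truth_rows, columns=["drug", "target_class",
                                              "intended_effect",
                                              "ceritinib_like"])
    return drugs, truth


def generate_plate(true_ic50: float, hill: float = 1.5, top: float = 1.0,
                   bottom: float = 0.0, doses=None, n_replicates: int = 3,
                   noise_sd: float = 0.05, seed: int = 0,
                   compound: str = "synthetic", model_id: str = "model",
                   tissue_class: str = "tumor") -> tuple[PlateAssay, dict]:
    """Noisy 4PL viability plate with retained ground truth."""
    from .assay_analysis import build_dilution_ladder

    if doses is None:
        doses = build_dilution_ladder(1e5, 3.0, 5.0)
    doses = np.asarray(doses, float)
    rng = np.random.default_rng(seed)
    clean = four_pl(doses, top, bottom, true_ic50, hill)
    viability = np.maximum(
        clean[None, :] + rng.normal(0.0, noise_sd, (n_replicates, doses.size)),
        0.0)
    plate = PlateAssay(doses=doses, viability=viability, compound=compound,
                       model_id=model_id, tissue_class=tissue_class)
    truth = {"ic50": float(true_ic50), "hill": float(hill),
             "top": float(top), "bottom": float(bottom),
             "noise_sd": float(noise_sd), "seed": int(seed)}
    return plate, truth


def generate_synergy_grid(mode: str = "independent",
                          margins_a=(0.2, 0.4, 0.6),
                          margins_b=(0.15, 0.35, 0.55),
                          delta: float = 0.15, noise_sd: float = 0.0,
                          seed: int = 0,
                          doses_a=(0.0, 10.0, 100.0, 1000.0),
                          doses_b=(0.0, 10.0, 100.0, 1000.0)) -> SynergyMatrix:
    """4x4 inhibition grid at, above or below the Bliss expectation.

    ``independent`` places every combination cell exactly on the Bliss
    surface; ``synergistic``/``antagonistic`` shift the combination block by
    +/- delta before optional Gaussian noise.
    """
    if mode not in ("independent", "synergistic", "antagonistic"):
        raise ValidationError(f"unknown mode {mode!r}")
    ya = np.concatenate([[0.0], np.asarray(margins_a, float)])
    yb = np.concatenate([[0.0], np.asarray(margins_b, float)])
    if np.any(ya < 0) or np.any(ya > 1) or np.any(yb < 0) or np.any(yb > 1):
        raise ValidationError("margins must lie in [0, 1]")
    grid = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    shift = {"independent": 0.0, "synergistic": delta,
             "antagonistic": -delta}[mode]
    grid[1:, 1:] += shift
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        grid[1:, 1:] += rng.normal(0.0, noise_sd, grid[1:, 1:].shape)
    grid = np.clip(grid, 0.0, 1.0)
    return SynergyMatrix(doses_a=np.asarray(doses_a, float),
                         doses_b=np.asarray(doses_b, float),
                         inhibition=grid)
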