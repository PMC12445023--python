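"""Shared fixtures: reference model, synthetic cohort, toy networks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import twinscreen as ts
from twinscreen.model_core import NetworkModel, Reaction, Species

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_model():
    return ts.build_reference_network()


@pytest.fixture(scope="session")
def default_cohort(ref_model):
    expr, meta = ts.generate_cohort(ts.CohortSpec(), model=ref_model)
    return expr, meta


@pytest.fixture(scope="session")
def cohort_twins(ref_model, default_cohort):
    expr, meta = default_cohort
    return ts.build_cohort_twins(ref_model, expr, meta)


@pytest.fixture(scope="session")
def default_panel(ref_model):
    panel, truth = ts.generate_panel(ts.PanelSpec(), model=ref_model)
    return panel, truth


def _rxn(id, kind, reactants=(), products=(), modifiers=(), **params):
    return Reaction(id, kind,
                    tuple((s, 1.0) for s in reactants),
                    tuple((s, 1.0) for s in products),
                    tuple(modifiers), dict(params))


def make_sk_model(k_syn: float = 2.0, k_deg: float = 1.0) -> NetworkModel:
    """One species with constant synthesis and first-order decay (x* = s/k)."""
    return NetworkModel(
        species=(Species("IN", compartment="cytoplasm"),
                 Species("X"),
                 Species("Y")),
        reactions=(
            _rxn("syn_X", "synthesis", [], ["X"], k_syn=k_syn),
            _rxn("deg_X", "degradation", ["X"], [], k_deg=k_deg),
            _rxn("syn_Y", "synthesis", [], ["Y"], k_syn=1.0),
            _rxn("deg_Y", "degradation", ["Y"], [], k_deg=1.0),
            _rxn("mk_X", "mass_action_activation", ["Y"], ["X"], ["IN"],
                 k_cat=0.0),
        ),
        pathway_tags={"IN": "Core", "X": "Core", "Y": "Core"},
        input_species=("IN",),
        readout_positive="X",
        readout_negative="Y",
    )


def make_binding_model(a0: float = 1.0, b0: float = 0.8,
                       k_on: float = 1.0, k_off: float = 0.5) -> NetworkModel:
    """Closed A + B <-> C pair: A+C and B+C are conserved moieties."""
    return NetworkModel(
        species=(Species("IN"),
                 Species("A", initial_concentration=a0),
                 Species("B", initial_concentration=b0),
                 Species("C", initial_concentration=0.0)),
        reactions=(
            _rxn("on", "complex_formation", ["A", "B"], ["C"], k_on=k_on),
            _rxn("off", "complex_dissociation", ["C"], ["A", "B"], k_off=k_off),
        ),
        pathway_tags={},
        input_species=("IN",),
        readout_positive="C",
        readout_negative="A",
    )


def make_chain_model(n_steps: int = 2, k_act: float = 0.05) -> NetworkModel:
    """Linear activation chain IN -> K1 -> ... -> Kn -> OUT, weak coupling.

    Each tier is an inactive pool (synthesis 1, degradation 1) converted by
    the previous tier's active form.  With k_act << 1 the chain is nearly
    linear in the input, so scaling any one tier's catalysis by phi scales
    the output by phi.  NEG is an untouched constant readout.
    """
    species = [Species("IN", initial_concentration=1.0)]
    reactions = []
    prev = "IN"
    for i in range(1, n_steps + 1):
        inact, act = f"K{i}_i", f"K{i}_a"
        species += [Species(inact), Species(act)]
        reactions += [
            _rxn(f"syn_K{i}", "synthesis", [], [inact], k_syn=1.0),
            _rxn(f"deg_K{i}i", "degradation", [inact], [], k_deg=1.0),
            _rxn(f"act_K{i}", "mass_action_activation", [inact], [act], [prev],
                 k_cat=k_act),
            _rxn(f"deg_K{i}a", "degradation", [act], [], k_deg=1.0),
        ]
        prev = act
    species += [Species("OUT_pre"), Species("OUT"), Species("NEG")]
    reactions += [
        _rxn("syn_OUT_pre", "synthesis", [], ["OUT_pre"], k_syn=1.0),
        _rxn("deg_OUT_pre", "degradation", ["OUT_pre"], [], k_deg=1.0),
        _rxn("act_OUT", "mass_action_activation", ["OUT_pre"], ["OUT"], [prev],
             k_cat=k_act),
        _rxn("deg_OUT", "degradation", ["OUT"], [], k_deg=1.0),
        _rxn("syn_NEG", "synthesis", [], ["NEG"], k_syn=1.0),
        _rxn("deg_NEG", "degradation", ["NEG"], [], k_deg=1.0),
    ]
    return NetworkModel(
        species=tuple(species),
        reactions=tuple(reactions),
        pathway_tags={s.id: "Core" for s in species},
        input_species=("IN",),
        readout_positive="OUT",
        readout_negative="NEG",
    )


def make_twin(model: NetworkModel, sample_id: str = "S1", tissue: str = "tumor",
              scales: dict | None = None, activation: dict | None = None):
    from twinscreen.twin_builder import DigitalTwin

    sc = {s.id: 1.0 for s in model.gene_representatives()}
    sc.update(scales or {})
    return DigitalTwin(model, sc, dict(activation or {}),
                       {"sample_id": sample_id, "tissue": tissue,
                        "normalization": "synthetic"})


@pytest.fixture
def sk_model():
    return make_sk_model()


@pytest.fixture
def binding_model():
    return make_binding_model()
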