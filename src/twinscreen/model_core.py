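"""Reduced mechanistic ODE signaling network with MYC:MAX and Caspase-3 readouts.

The network is a curated surrogate spanning the Wnt, RAS/MAPK, PI3K/AKT/MTOR,
Hedgehog and apoptosis arms that converge on two phenotypic readouts: the
nuclear MYC:MAX complex (pro-viability) and active Caspase-3 (pro-death).
Rate laws are restricted to a small vocabulary — synthesis, first-order
degradation, modifier-catalyzed mass-action activation, Michaelis–Menten
conversion, and bimolecular complex formation/dissociation — which is
sufficient to express every interaction in the topology while keeping drug
action well-defined (inhibitors scale the catalytic constant of reactions
their target species catalyzes).

Units are arbitrary concentration (a.u.) and arbitrary time; only drug
concentrations carry nM units elsewhere in the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "Species",
    "Reaction",
    "NetworkModel",
    "ParameterSet",
    "ValidationIssue",
    "REACTION_KINDS",
    "KIND_PARAMETERS",
    "build_reference_network",
    "validate_network",
    "evaluate_rates",
    "nominal_parameters",
]

REACTION_KINDS = (
    "synthesis",
    "degradation",
    "mass_action_activation",
    "michaelis_menten",
    "complex_formation",
    "complex_dissociation",
)

#: exact parameter names each reaction kind must define
KIND_PARAMETERS = {
    "synthesis": ("k_syn",),
    "degradation": ("k_deg",),
    "mass_action_activation": ("k_cat",),
    "michaelis_menten": ("k_cat", "Km"),
    "complex_formation": ("k_on",),
    "complex_dissociation": ("k_off",),
}

PATHWAY_LABELS = ("Wnt", "MAPK", "PI3K_AKT_MTOR", "Hedgehog", "Apoptosis", "Core")

#: activation inputs are clamped at level x this reference maximum (a.u.)
INPUT_REFERENCE_MAX = 1.0


@dataclass(frozen=True)
class Species:
    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    initial_concentration: float = 0.0
    is_gene_representative: bool = False
    gene: str | None = None
    degradation_rate: float = 0.0


@dataclass(frozen=True)
class Reaction:
    id: str
    kind: str
    reactants: tuple[tuple[str, float], ...] = ()
    products: tuple[tuple[str, float], ...] = ()
    modifiers: tuple[str, ...] = ()
    parameters: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class NetworkModel:
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    pathway_tags: dict[str, str]
    input_species: tuple[str, ...]
    readout_positive: str
    readout_negative: str

    def species_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.species)}

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def gene_representatives(self) -> tuple[Species, ...]:
        return tuple(s for s in self.species if s.is_gene_representative)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species], float)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    subject: str
    message: str


class ParameterSet:
    """Kinetic parameters of a model, keyed by ``(reaction id, parameter name)``.

    A plain value container; drug perturbation and Monte Carlo sampling produce
    new ``ParameterSet`` objects rather than mutating in place.
    """

    def __init__(self, model: NetworkModel, values: dict[tuple[str, str], float]):
        self.model = model
        self.values = dict(values)

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.values == other.values

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.model, self.values)

    def scaled(self, factors: dict[tuple[str, str], float]) -> "ParameterSet":
        out = dict(self.values)
        for key, f in factors.items():
            out[key] = out[key] * f
        return ParameterSet(self.model, out)


def nominal_parameters(model: NetworkModel) -> ParameterSet:
    """Collect the rate constants stored on the model's reactions."""
    values = {}
    for r in model.reactions:
        for name in KIND_PARAMETERS[r.kind]:
            values[(r.id, name)] = float(r.parameters[name])
    return ParameterSet(model, values)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_network(model: NetworkModel) -> list[ValidationIssue]:
    """Structural validation; an empty report means the model is well-formed."""
    issues: list[ValidationIssue] = []
    ids = [s.id for s in model.species]
    known = set(ids)
    seen: set[str] = set()
    for sid in ids:
        if sid in seen:
            issues.append(ValidationIssue("duplicate_id", sid, "species id repeated"))
        seen.add(sid)

    for s in model.species:
        if s.initial_concentration < 0:
            issues.append(ValidationIssue(
                "negative_value", s.id, "initial_concentration < 0"))
        if s.degradation_rate < 0:
            issues.append(ValidationIssue("negative_value", s.id, "degradation_rate < 0"))

    for r in model.reactions:
        if r.kind not in REACTION_KINDS:
            issues.append(ValidationIssue("unknown_kind", r.id, f"kind {r.kind!r}"))
            continue
        for sid, _ in (*r.reactants, *r.products):
            if sid not in known:
                issues.append(ValidationIssue(
                    "dangling_reference", r.id, f"unknown species {sid!r}"))
        for sid in r.modifiers:
            if sid not in known:
                issues.append(ValidationIssue(
                    "dangling_reference", r.id, f"unknown modifier {sid!r}"))
        required = set(KIND_PARAMETERS[r.kind])
        got = set(r.parameters)
        for name in sorted(required - got):
            issues.append(ValidationIssue(
                "missing_parameter", r.id, f"{r.kind} requires {name!r}"))
        for name in sorted(got - required):
            issues.append(ValidationIssue(
                "unexpected_parameter", r.id, f"{name!r} not used by {r.kind}"))
        for name, value in r.parameters.items():
            if value < 0:
                issues.append(ValidationIssue(
                    "negative_parameter", r.id, f"{name} = {value}"))

    for role, sid in (("readout_positive", model.readout_positive),
                      ("readout_negative", model.readout_negative)):
        if sid not in known:
            issues.append(ValidationIssue("missing_readout", sid, f"{role} absent"))
    for sid in model.input_species:
        if sid not in known:
            issues.append(ValidationIssue("dangling_reference", sid, "input absent"))

    reachable = _reachable_from(model, set(model.input_species) & known)
    for role, sid in (("readout_positive", model.readout_positive),
                      ("readout_negative", model.readout_negative)):
        if sid in known and sid not in reachable:
            issues.append(ValidationIssue(
                "unreachable_readout", sid, f"{role} unreachable from inputs"))

    synth_products = {sid for r in model.reactions if r.kind == "synthesis"
                      for sid, _ in r.products}
    for s in model.species:
        if s.is_gene_representative and s.id not in synth_products:
            issues.append(ValidationIssue(
                "missing_synthesis", s.id,
                "gene representative without a synthesis reaction"))
    return issues


def _reachable_from(model: NetworkModel, sources: set[str]) -> set[str]:
    # edge: any reactant or modifier -> any product
    edges: dict[str, set[str]] = {}
    for r in model.reactions:
        heads = {sid for sid, _ in r.reactants} | set(r.modifiers)
        tails = {sid for sid, _ in r.products}
        for h in heads:
            edges.setdefault(h, set()).update(tails)
    seen = set(sources)
    frontier = list(sources)
    while frontier:
        node = frontier.pop()
        for nxt in edges.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


# ---------------------------------------------------------------------------
# rate evaluation (compiled array form, shared with the simulation engine)
# ---------------------------------------------------------------------------

class CompiledNetwork:
    """Index-array form of a model for vectorized rate/Jacobian evaluation.

    Every reaction rate is ``theta_main * f1 * f2`` where ``f1`` is the
    modifier (or first complex partner) concentration and ``f2`` is the
    substrate term — linear for mass action, ``S/(Km+S)`` for
    Michaelis–Menten. Evaluation broadcasts over arbitrary leading batch axes
    of both state and parameter arrays, which is what makes the Monte Carlo
    screens cheap.
    """

    def __init__(self, model: NetworkModel):
        self.model = model
        self.index = model.species_index()
        self.n_species = len(model.species)
        self.n_reactions = len(model.reactions)

        theta_keys: list[tuple[str, str]] = []
        for r in model.reactions:
            for name in KIND_PARAMETERS[r.kind]:
                theta_keys.append((r.id, name))
        self.theta_keys = theta_keys
        self.theta_index = {k: i for i, k in enumerate(theta_keys)}
        self.n_theta = len(theta_keys)

        n_r = self.n_reactions
        self.S = np.zeros((self.n_species, n_r))
        main = np.zeros(n_r, int)
        km = np.zeros(n_r, int)
        d1 = np.full(n_r, -1, int)
        d2 = np.full(n_r, -1, int)
        mm = np.zeros(n_r, bool)
        for j, r in enumerate(model.reactions):
            for sid, st in r.reactants:
                self.S[self.index[sid], j] -= st
            for sid, st in r.products:
                self.S[self.index[sid], j] += st
            main[j] = self.theta_index[(r.id, KIND_PARAMETERS[r.kind][0])]
            if r.kind == "synthesis":
                pass
            elif r.kind == "degradation":
                d2[j] = self.index[r.reactants[0][0]]
            elif r.kind == "mass_action_activation":
                d1[j] = self.index[r.modifiers[0]]
                d2[j] = self.index[r.reactants[0][0]]
            elif r.kind == "michaelis_menten":
                d1[j] = self.index[r.modifiers[0]]
                d2[j] = self.index[r.reactants[0][0]]
                mm[j] = True
                km[j] = self.theta_index[(r.id, "Km")]
            elif r.kind == "complex_formation":
                d1[j] = self.index[r.reactants[0][0]]
                d2[j] = self.index[r.reactants[1][0]]
            elif r.kind == "complex_dissociation":
                d2[j] = self.index[r.reactants[0][0]]
        self._main, self._km, self._d1, self._d2, self._mm = main, km, d1, d2, mm
        self._m1 = d1 >= 0
        self._m2 = d2 >= 0
        self._d1c = np.where(self._m1, d1, 0)
        self._d2c = np.where(self._m2, d2, 0)
        self.S_T = np.ascontiguousarray(self.S.T)
        # reactions catalyzed by each modifier species (drug action surface)
        self.modifier_reactions: dict[str, list[int]] = {}
        for j, r in enumerate(model.reactions):
            for sid in r.modifiers:
                self.modifier_reactions.setdefault(sid, []).append(j)

    def theta_from(self, params: ParameterSet) -> np.ndarray:
        return np.array([params.values[k] for k in self.theta_keys], float)

    def reaction_rates(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        k = theta[..., self._main]
        f1 = np.where(self._m1, x[..., self._d1c], 1.0)
        s = x[..., self._d2c]
        kmv = theta[..., self._km]
        denom = kmv + s
        with np.errstate(divide="ignore", invalid="ignore"):
            sat = np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), 0.0)
        f2 = np.where(self._mm, sat, np.where(self._m2, s, 1.0))
        return k * f1 * f2

    def rates(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return self.reaction_rates(x, theta) @ self.S_T

    def jacobian(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """d(dx/dt)/dx with shape (..., n_species, n_species)."""
        batch = np.broadcast_shapes(x.shape[:-1], theta.shape[:-1])
        xb = np.broadcast_to(x, batch + (self.n_species,))
        tb = np.broadcast_to(theta, batch + (self.n_theta,))
        k = tb[..., self._main]
        f1 = np.where(self._m1, xb[..., self._d1c], 1.0)
        s = xb[..., self._d2c]
        kmv = tb[..., self._km]
        denom = kmv + s
        safe = np.where(denom > 0, denom, 1.0)
        sat = np.where(denom > 0, s / safe, 0.0)
        f2 = np.where(self._mm, sat, np.where(self._m2, s, 1.0))
        # partials of the rate wrt its (at most two) state dependencies
        g1 = k * f2                                   # d rate / d x[d1]
        df2 = np.where(self._mm, np.where(denom > 0, kmv / safe**2, 0.0),
                       np.where(self._m2, 1.0, 0.0))
        g2 = k * f1 * df2                             # d rate / d x[d2]
        DR = np.zeros(batch + (self.n_reactions, self.n_species))
        j_all = np.arange(self.n_reactions)
        j1 = j_all[self._m1]
        j2 = j_all[self._m2]
        DR[..., j1, self._d1[self._m1]] += g1[..., self._m1]
        DR[..., j2, self._d2[self._m2]] += g2[..., self._m2]
        return np.matmul(self.S, DR)


def evaluate_rates(model: NetworkModel, state, params: ParameterSet) -> np.ndarray:
    """d[x]/dt for one state vector under one parameter set."""
    x = np.asarray(state, float)
    if x.shape != (len(model.species),):
        raise ValidationError(
            f"state has length {x.size}, model has {len(model.species)} species",
            code="dimension_mismatch")
    if np.any(x < 0):
        raise ValidationError("state must be non-negative", code="negative_state")
    for key, value in params.values.items():
        if value < 0:
            raise ValidationError(f"parameter {key} is negative", code="negative_parameter")
    compiled = CompiledNetwork(model)
    return compiled.rates(x, compiled.theta_from(params))


# ---------------------------------------------------------------------------
# reference network
# ---------------------------------------------------------------------------

def _sp(id, name, tag, *, comp="cytoplasm", init=0.0, gene=None, deg=1.0):
    return (Species(id, name, comp, init, gene is not None, gene, deg), tag)


def _rxn(id, kind, reactants=(), products=(), modifiers=(), **params):
    return Reaction(id, kind,
                    tuple((s, 1.0) for s in reactants),
                    tuple((s, 1.0) for s in products),
                    tuple(modifiers), dict(params))


def build_reference_network() -> NetworkModel:
    """Curated reduced signaling network used for all digital twins.

    Topology (32 species): a Wnt arm (clamped CTNNB1 input activates TCF/LEF,
    which drives MYC synthesis and an autocrine growth-factor relay), a MAPK
    arm (relay -> RAS -> MEK -> ERK), a PI3K/AKT/MTOR arm (relay -> PI3K ->
    AKT -> MTOR, suppressing the apoptotic signal), a FAK node co-activated by
    the relay, a Hedgehog arm (SHH input -> GLI1, weak MYC crosstalk), and an
    apoptosis arm (Wnt-stress-primed signal converting pro-Caspase-3 to active
    Caspase-3).  MYC maturation is gated serially by ERK and FAK with a small
    kinase-independent bypass; MYC:MAX forms by bimolecular association in the
    nucleus.  Tumor-like states (high Wnt input, high LGR5/MYCN synthesis)
    therefore route MYC output and apoptosis suppression through the drug-able
    kinases, while low-Wnt states run mostly on the bypass — the structural
    origin of tumor-selective drug response.

    Nominal constants: every degradation rate is 1/time; synthesis rates are
    calibrated at build time so each gene representative sits at 1 a.u. in the
    unactivated (inputs clamped to 0) steady state; remaining constants are
    order-one values fixed by design (documented in the methods note).
    """
    defs = [
        _sp("BASAL", "constitutive tone", "Core", init=1.0),
        _sp("CTNNB1_in", "CTNNB1/Wnt activation input", "Wnt", comp="nucleus", deg=0.0),
        _sp("SHH_in", "Hedgehog ligand input", "Hedgehog", comp="membrane", deg=0.0),
        _sp("TCF_LEF_i", "TCF/LEF (inactive)", "Wnt", comp="nucleus", gene="LGR5"),
        _sp("TCF_LEF_a", "TCF/LEF transcriptional activity", "Wnt", comp="nucleus"),
        _sp("GLI1_i", "GLI1 (inactive)", "Hedgehog", gene="GLI1"),
        _sp("GLI1_a", "GLI1 (active)", "Hedgehog", comp="nucleus"),
        _sp("RTK_pre", "growth-factor receptor reserve", "Core", comp="membrane"),
        _sp("RTK_act", "autocrine growth-factor signal", "Core", comp="membrane"),
        _sp("RAS_i", "RAS (GDP)", "MAPK", gene="KRAS"),
        _sp("RAS_a", "RAS (GTP)", "MAPK"),
        _sp("MEK_i", "MEK", "MAPK", gene="MAP2K1"),
        _sp("MEK_a", "phospho-MEK", "MAPK"),
        _sp("ERK_i", "ERK", "MAPK", gene="MAPK1"),
        _sp("ERK_a", "phospho-ERK", "MAPK"),
        _sp("PI3K_i", "PI3K", "PI3K_AKT_MTOR", gene="PIK3CA"),
        _sp("PI3K_a", "PI3K (active)", "PI3K_AKT_MTOR"),
        _sp("AKT_i", "AKT", "PI3K_AKT_MTOR", gene="AKT1"),
        _sp("AKT_a", "phospho-AKT", "PI3K_AKT_MTOR"),
        _sp("MTOR_i", "MTOR", "PI3K_AKT_MTOR", gene="MTOR"),
        _sp("MTOR_a", "MTOR (active)", "PI3K_AKT_MTOR"),
        _sp("FAK_i", "FAK", "Core", gene="PTK2"),
        _sp("FAK_a", "phospho-FAK", "Core"),
        _sp("MYC_pre", "nascent MYC pool", "Core", gene="MYCN"),
        _sp("MYC_cyt", "MYC (translated)", "Core"),
        _sp("MYC_p", "MYC (ERK-primed)", "Core"),
        _sp("MYC_a", "MYC (stabilized)", "Core", comp="nucleus"),
        _sp("MAX", "MAX", "Core", comp="nucleus", gene="MAX"),
        _sp("MYC_MAX_nuc", "nuclear MYC:MAX complex", "Core", comp="nucleus"),
        _sp("APOPT_pre", "apoptotic effector reserve", "Apoptosis", gene="BAX"),
        _sp("APOPT_sig", "apoptotic signal", "Apoptosis"),
        _sp("APOPT_off", "neutralized apoptotic signal", "Apoptosis"),
        _sp("CASP3_pro", "pro-Caspase-3", "Apoptosis", gene="CASP3"),
        _sp("CASP3_act", "active Caspase-3", "Apoptosis"),
    ]
    species = tuple(s for s, _ in defs)
    tags = {s.id: tag for s, tag in defs}
    inputs = ("CTNNB1_in", "SHH_in")

    reactions = [
        # activation / conversion steps
        _rxn("act_tcf", "mass_action_activation", ["TCF_LEF_i"], ["TCF_LEF_a"],
             ["CTNNB1_in"], k_cat=1.0),
        _rxn("act_gli1", "mass_action_activation", ["GLI1_i"], ["GLI1_a"],
             ["SHH_in"], k_cat=1.0),
        _rxn("relay_wnt", "mass_action_activation", ["RTK_pre"], ["RTK_act"],
             ["TCF_LEF_a"], k_cat=1.0),
        _rxn("relay_basal", "mass_action_activation", ["RTK_pre"], ["RTK_act"],
             ["BASAL"], k_cat=0.02),
        # zero-order deactivation of the relay: a saturable phosphatase-like
        # sink whose capacity sits between the normal and tumor Wnt drive,
        # giving the switch-like kinase dependence of the high-Wnt state
        _rxn("relay_off", "michaelis_menten", ["RTK_act"], ["RTK_pre"],
             ["BASAL"], k_cat=0.4, Km=0.005),
        _rxn("act_ras", "mass_action_activation", ["RAS_i"], ["RAS_a"],
             ["RTK_act"], k_cat=1.5),
        _rxn("act_ras_fak", "mass_action_activation", ["RAS_i"], ["RAS_a"],
             ["FAK_a"], k_cat=0.5),
        _rxn("act_mek", "michaelis_menten", ["MEK_i"], ["MEK_a"],
             ["RAS_a"], k_cat=2.0, Km=1.0),
        _rxn("act_erk", "michaelis_menten", ["ERK_i"], ["ERK_a"],
             ["MEK_a"], k_cat=2.0, Km=1.0),
        _rxn("act_pi3k", "mass_action_activation", ["PI3K_i"], ["PI3K_a"],
             ["RTK_act"], k_cat=1.5),
        _rxn("act_akt", "michaelis_menten", ["AKT_i"], ["AKT_a"],
             ["PI3K_a"], k_cat=2.0, Km=1.0),
        _rxn("act_mtor", "mass_action_activation", ["MTOR_i"], ["MTOR_a"],
             ["AKT_a"], k_cat=2.0),
        _rxn("act_fak", "mass_action_activation", ["FAK_i"], ["FAK_a"],
             ["RTK_act"], k_cat=1.5),
        # MYC synthesis, maturation and complex formation
        _rxn("myc_txn_wnt", "mass_action_activation", ["MYC_pre"], ["MYC_cyt"],
             ["TCF_LEF_a"], k_cat=2.0),
        _rxn("myc_txn_gli", "mass_action_activation", ["MYC_pre"], ["MYC_cyt"],
             ["GLI1_a"], k_cat=0.1),
        _rxn("myc_txn_basal", "mass_action_activation", ["MYC_pre"], ["MYC_cyt"],
             ["BASAL"], k_cat=0.1),
        _rxn("myc_prime_erk", "mass_action_activation", ["MYC_cyt"], ["MYC_p"],
             ["ERK_a"], k_cat=4.0),
        _rxn("myc_mature_fak", "mass_action_activation", ["MYC_p"], ["MYC_a"],
             ["FAK_a"], k_cat=4.0),
        _rxn("myc_bypass", "mass_action_activation", ["MYC_cyt"], ["MYC_a"],
             ["BASAL"], k_cat=0.35),
        _rxn("myc_bypass_p", "mass_action_activation", ["MYC_p"], ["MYC_a"],
             ["BASAL"], k_cat=0.35),
        _rxn("mycmax_on", "complex_formation", ["MYC_a", "MAX"], ["MYC_MAX_nuc"],
             k_on=1.0),
        _rxn("mycmax_off", "complex_dissociation", ["MYC_MAX_nuc"], ["MYC_a", "MAX"],
             k_off=0.1),
        # apoptosis arm: Wnt-stress priming, AKT/MTOR survival suppression
        _rxn("apopt_prime", "mass_action_activation", ["APOPT_pre"], ["APOPT_sig"],
             ["TCF_LEF_a"], k_cat=0.5),
        _rxn("apopt_prime_basal", "mass_action_activation", ["APOPT_pre"], ["APOPT_sig"],
             ["BASAL"], k_cat=0.05),
        _rxn("apopt_supp_akt", "michaelis_menten", ["APOPT_sig"], ["APOPT_off"],
             ["AKT_a"], k_cat=3.0, Km=1.0),
        _rxn("apopt_supp_mtor", "michaelis_menten", ["APOPT_sig"], ["APOPT_off"],
             ["MTOR_a"], k_cat=3.0, Km=1.0),
        _rxn("act_casp3", "mass_action_activation", ["CASP3_pro"], ["CASP3_act"],
             ["APOPT_sig"], k_cat=2.0),
        _rxn("act_casp3_basal", "mass_action_activation", ["CASP3_pro"], ["CASP3_act"],
             ["BASAL"], k_cat=0.1),
    ]
    # synthesis and degradation for every non-input species
    synth_species = ["BASAL", "TCF_LEF_i", "GLI1_i", "RTK_pre", "RAS_i", "MEK_i",
                     "ERK_i", "PI3K_i", "AKT_i", "MTOR_i", "FAK_i", "MYC_pre",
                     "MAX", "APOPT_pre", "CASP3_pro"]
    for sid in synth_species:
        reactions.append(_rxn(f"syn_{sid}", "synthesis", [], [sid], k_syn=1.0))
    for s in species:
        if s.id in inputs:
            continue
        reactions.append(_rxn(f"deg_{s.id}", "degradation", [s.id], [],
                              k_deg=s.degradation_rate))

    model = NetworkModel(
        species=species,
        reactions=tuple(reactions),
        pathway_tags=tags,
        input_species=inputs,
        readout_positive="MYC_MAX_nuc",
        readout_negative="CASP3_act",
    )
    model = _calibrate_synthesis(model)
    issues = validate_network(model)
    if issues:  # pragma: no cover - construction contract
        raise ValidationError(f"reference network invalid: {issues}")
    return model


def _calibrate_synthesis(model: NetworkModel, n_iter: int = 40) -> NetworkModel:
    """Set synthesis rates so gene representatives rest at 1 a.u. unactivated.

    With every degradation rate at 1, the unactivated (all inputs clamped at
    zero) steady state of each synthesis-bearing pool is k_syn divided by its
    total outflow coefficient; a short fixed-point loop absorbs the weak
    basal-tone drains so the baseline is exactly self-normalizing.
    """
    from .sim_engine import steady_state_model  # local import: avoid cycle

    model_cur = model
    targets = [s.id for s in model.species
               if any(r.kind == "synthesis" and r.products[0][0] == s.id
                      for r in model.reactions)]
    clamps = {sid: 0.0 for sid in model.input_species}
    for _ in range(n_iter):
        params = nominal_parameters(model_cur)
        ss = steady_state_model(model_cur, params, clamps)
        idx = model_cur.species_index()
        worst = 0.0
        new_reactions = []
        for r in model_cur.reactions:
            if r.kind == "synthesis" and r.products[0][0] in targets:
                x = ss.concentrations[idx[r.products[0][0]]]
                if x > 0:
                    factor = 1.0 / x
                    worst = max(worst, abs(math.log(factor)))
                    p = dict(r.parameters)
                    p["k_syn"] = p["k_syn"] * factor
                    r = replace(r, parameters=p)
            new_reactions.append(r)
        model_cur = replace(model_cur, reactions=tuple(new_reactions))
        if worst < 1e-12:
            break
    # record calibrated baseline as the initial state (inputs start at 0)
    params = nominal_parameters(model_cur)
    ss = steady_state_model(model_cur, params, clamps)
    new_species = tuple(
        replace(s, initial_concentration=float(max(ss.concentrations[i], 0.0)))
        if s.id not in model.input_species else s
        for i, s in enumerate(model_cur.species))
    return replace(model_cur, species=new_species)
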