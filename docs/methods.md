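# Methods

## Scope and intent

`twinscreen` reproduces a digital-twin drug-screening *procedure* at desk
scale: individualize a mechanistic signaling model per patient from
expression data, simulate targeted drugs to steady state under parameter
uncertainty, and rank compounds by tumor-vs-normal selectivity.  The
production-scale models this emulates span hundreds of genes and thousands
of reactions with proprietary parameterizations; no attempt is made to
reproduce any such parameter set.  Instead the package ships a reduced,
fully documented surrogate network whose behavior under the same procedure
is constructed — and verified by tests against generator ground truth — to
express the qualitative biology: high-Wnt tumor states become dependent on
a drug-able kinase program, low-Wnt normal states do not.

## The reference network

34 species, 75 reactions, six rate-law kinds only:

| kind | rate | parameters |
|---|---|---|
| synthesis | k_syn | k_syn (a.u./time) |
| degradation | k_deg·X | k_deg (1/time) |
| mass_action_activation | k_cat·M·S | k_cat (1/(a.u.·time)) |
| michaelis_menten | k_cat·M·S/(Km+S) | k_cat (1/time per a.u. modifier), Km (a.u.) |
| complex_formation | k_on·A·B | k_on (1/(a.u.·time)) |
| complex_dissociation | k_off·C | k_off (1/time) |

All "activation" is modifier-catalyzed conversion between inactive and
active species forms; every non-input species has first-order degradation.
Units are arbitrary (concentrations in a.u., time in a.u.); only drug
concentrations carry nM.

Topology.  A clamped CTNNB1/Wnt input activates TCF/LEF; TCF/LEF drives
(i) MYC transcription, (ii) apoptotic priming (oncogenic stress), and
(iii) an autocrine growth-factor relay.  The relay feeds the RAS→MEK→ERK,
PI3K→AKT→MTOR and FAK arms.  MYC maturation is gated serially by ERK and
FAK with a small constitutive bypass; mature MYC associates with MAX into
the nuclear MYC:MAX complex (positive readout).  AKT and MTOR suppress the
primed apoptotic signal, which otherwise converts pro-Caspase-3 to active
Caspase-3 (negative readout).  A Hedgehog arm (SHH input → GLI1) is present
with weak MYC crosstalk but is not a default readout.

Two deliberate nonlinearities carry the biology:

1. **Relay switch.**  The growth-factor relay is deactivated by a
   saturable, phosphatase-like sink (Michaelis–Menten, capacity 0.4,
   Km 0.005 a.u.).  Tumor-level Wnt drive exceeds the sink's capacity and
   switches the kinase program on; normal-level drive stays pinned near
   zero (zero-order ultrasensitivity).  This is the structural origin of
   oncogene addiction in the model: the kinase arms carry most of the MYC
   flux *only* in high-Wnt states, so multi-kinase inhibition collapses
   tumor viability while normals, running on the bypass, are barely
   touched.
2. **Priming/suppression asymmetry.**  Apoptotic priming follows TCF/LEF
   (drug-insensitive), while its suppression follows AKT/MTOR
   (drug-sensitive).  Inhibiting the survival kinases therefore raises
   active Caspase-3 roughly in proportion to the Wnt drive — a second,
   tumor-selective kill channel.

Nominal constants.  Every degradation rate is 1/time.  Synthesis rates are
calibrated at build time by a deterministic fixed-point loop so that each
synthesis-bearing pool rests at exactly 1 a.u. in the unactivated state
(inputs clamped to 0); individualization multipliers then act on a
self-normalized baseline.  The remaining order-one constants (activation
k_cat 1–4, bypass 0.35, priming 0.5, suppression 3, relay sink 0.4/0.005)
were fixed at design time so that the deterministic tumor/normal archetypes
(Wnt 1.0 with 8x Wnt-target synthesis, vs Wnt 0.05 at baseline synthesis)
fall on the intended sides of the 50% effectiveness cutoff with wide
margins.  They are ordinary model constants, editable in the shipped
SBML/YAML model files.

The normal-tissue Wnt tone (0.05) is chosen so the unactivated operating
point sits more than 3 sigma of the combined noise sources (expression
log2 noise 0.5 plus Monte Carlo parameter spread) below the relay switch;
with a tone closer to the switch, noise-only twins sporadically flip and
the null cohort (no expression effect, equal activation) would show
spurious selectivity.

## Individualization

Counts are normalized to CPM and log2(x+1)-transformed.  The reference
baseline is the per-gene median over the cohort's normal samples — the
screen is explicitly relative to the cohort's own normal tissue, not an
external atlas.  The synthesis multiplier is the back-transformed ratio
with a 0.5-CPM pseudocount, clipped to [0.1, 10]; genes absent from a
profile keep scale 1 with a logged warning.  The mapping is pure,
monotone in expression, and bounded for any finite input.

Mutation flags set only the Wnt input level (1.0 mutant / 0.6 wild-type
tumor); no mechanistic edits are made per mutation.  In practice wild-type
tumor twins respond almost identically to mutant ones because the
expression program dominates — the screen's predictions are insensitive to
the mutation encoding.

## Simulation

Steady states solve dx/dt = 0 subject to input clamps, from the model's
calibrated initial state (or, in dose ladders, from the previous dose's
solution — a continuation that both accelerates and stabilizes the solve).
The solver is pseudo-transient continuation: damped implicit-Euler steps
whose pseudo-time step grows geometrically (x3 on success, /4 on rejection,
from 1 up to 1e9), so the iteration starts as a stiff integrator and ends
as a full Newton polish.  Steps that would leave the non-negative orthant
are projected to 0.  Small-dt steps are accepted even if the residual
transiently rises (they track the convergent trajectory); large-dt steps
must reduce it.  Convergence requires max_i |dx_i/dt| / (|x_i| + 1e-9)
< 1e-8; runs that fail anywhere along a dose ladder are dropped from that
ladder's statistics (with a logged count), keeping control and treated
samples strictly paired.  Everything is vectorized across Monte Carlo runs
(batched rates, batched analytic Jacobians, batched linear solves), which
is what makes 1,000-run screens tractable on one CPU.

Monte Carlo.  Every kinetic parameter θ_j is perturbed to θ_j·10^z with
z ~ N(0, sigma_log10), sigma_log10 = 0.1 by default.  The per-run streams
are seeded by (master seed, sample, drug, run) — *not* by concentration —
so the same parameter sets are used across a drug's whole dose ladder.
This paired design is what makes a drug with no target in the network
exactly inert (its treated and control solves are identical per run).

Readout combination.  Each run's readouts are first normalized to that
run's own control; the median across runs of these per-run relative
abundances enters the viability score.  The alternative — ratio of medians
of raw concentrations — is confounded when baseline levels spread widely
across parameter draws (the identity of the median run reorders with dose),
and in null-cohort experiments it manufactured apparent responses of ~17%
Emax for twins whose per-run median response was 0.3%.  Raw median
concentrations are still reported (`DoseResponseCurve.readouts_raw`).

The positive/negative readout weight lambda = 0.5 treats a doubling of
relative Caspase-3 as canceling the entire MYC:MAX signal; it is exposed
everywhere (`lam=`).  The GR mapping uses n_div = 1 control division per
assay window (GR = 2·rho − 1) because the steady-state simulation produces
no time-resolved growth; n_div is likewise exposed.

## Synthetic data

The cohort generator emulates the study conditions: 13 tumor + 8 normal
profiles; CTNNB1 flags on the first 11 tumors; a tumor-up signature
(LGR5, DKK1, NKD1 — Wnt targets; MYCN, CAD, NPM1 — MYC targets) at mean
log2 fold change 3 with per-sample log2 noise 0.5; per-gene log-normal
baselines (log2 mean 6, sd 1.5) over the 13 model genes plus the signature
and 100 filler genes; counts are rounded back-transformed values.  Of the
signature genes, LGR5 and MYCN are also model genes (TCF/LEF and MYC pools)
and carry the mechanism; the others are markers only.

The default panel has 20 drugs: the ceritinib-like multi-kinase compound
(FAK_a, MTOR_a, AKT_a, ERK_a at 50 nM each), the ALK surrogate whose target
is deliberately absent (the network contains no ALK, mirroring an
ALK-independent mechanism), and 18 single-target comparators cycling over
the modeled kinases with log-uniform kD in [1, 1000] nM.

What the generator does *not* emulate: RNA-seq count dispersion beyond
log-normal noise, library-size artifacts, batch effects, histology-specific
expression programs, or any relation between mutation flags and expression
beyond the shared signature.  Passing tests therefore demonstrate that the
*pipeline* recovers its own construction under realistic noise — not that
the surrogate network predicts real drug response.

## Numerical choices

- Dose grid: 9 log-spaced points, one per decade, 1e-4–1e4 nM; EC50 and
  GR50 are located by linear interpolation in log10-concentration, so both
  are accurate to well within one grid interval.
- Emax cutoff is inclusive at 50%.
- 4PL fits use least squares with bounds (top ∈ [0.5, 1.5], bottom ∈
  [0, 1], hill ∈ [0.1, 10], IC50 within a decade of the dose range) and
  report the relative (curve-midpoint) IC50; monotone non-decreasing plates
  short-circuit with a `no_inhibition` warning.
- AUC is the trapezoidal mean-viability integral over log10 dose divided by
  the log10 span, so a flat plate at viability v has AUC = v and values are
  comparable across dose ranges.
- z-scores use the sample (n−1) standard deviation.
- The Bliss score is 100x the mean observed-minus-expected inhibition over
  the 3x3 combination block of a 4x4 grid; no surface smoothing is applied.
- The wound-closure formula is read as percent closure
  100·(gap0 − gap1)/gap0, the only reading that yields a percentage.
- Ties in drug ranking break by mean tumor Emax, then drug name, making the
  ranking independent of input row order.

## Problem sizes

The test suite and the acceptance script use a scaled screen — 100 Monte
Carlo runs, 5 drugs, 6 twins, 20 master seeds — alongside one deterministic
full screen (21 twins x 20 drugs at the nominal parameter point).  These
sizes exercise every code path of the full-depth screen; the shipped
defaults (1,000 runs, 20 drugs, full cohort) remain the standard
configuration for actual use.

## Known limitations

- The surrogate network is a construction, not a fitted model; its rate
  constants encode the intended qualitative biology rather than measured
  kinetics, and no equivalence with any production-scale model's outputs
  can be asserted — only procedural fidelity.
- Steady-state viability is an equilibrium surrogate; there is no
  pharmacokinetics, no explicit growth dynamics behind the GR mapping, no
  drug–drug interaction inside the ODE system, and no resistance.
- Inhibition is single-site occupancy on catalytic activity; allosteric,
  covalent or degradation-based mechanisms are out of scope.
- The per-twin effective/ineffective classification of weak responders
  depends on the realized cohort draws; class-level statistics (mean Emax,
  selectivity ranking) are the robust outputs.
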