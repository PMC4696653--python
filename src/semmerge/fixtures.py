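"""Synthetic annotated model suite for exercising overlap detection and merging.

The suite miniaturises a classic integrative-modeling motif from cardiac
electrophysiology: an excitation model ``E`` (stimulus-driven membrane
potential, a background calcium current in nanoamps, a vestigial
sarcoplasmic-reticulum branch, cell volume in microlitres), a calcium-
dynamics model ``C`` (SR uptake/release, troponin buffering with a CUSTOM
"calcium-bound troponin" entity, background calcium *flux* in millimolar
per second, cell volume in cubic micrometres), and a tension model ``T``
driven by cytosolic calcium.  ``C_prime`` is ``C`` plus a glue variable
that converts the background concentration flow into an electrical current,
which is what lets overlap detection recognise the two models' background
calcium pathways as the same process.

By construction the suite encodes, pair by pair, exactly which concepts are
shared (the *manifest*): cytosolic calcium concentration, myoplasmic volume
(with a microlitre vs cubic-micrometre mismatch, factor 1e9), the Faraday
constant as a singular term, the background calcium current (only after
glue insertion), and the always-paired temporal solution domains.  Custom-
term annotations (troponin buffering, the L-type channel mediator, the
E-side SR compartment) are deliberately unmatched and require manual
mappings, as are the two voltage variables (C's clamp voltage is
unannotated).

All numeric parameters are inventions chosen for a stable 1 Hz-forced limit
cycle at desk scale; none are claimed to reproduce any published cell model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .annotation import (
    EntityComposite,
    Singular,
    TermRef,
    build_entity_annotation,
    build_process_annotation,
    entity,
)
from .errors import SemMergeError
from .merge import MergeResult, Resolution, merge
from .model import Model, Variable, add_variable
from .overlap import OverlapReport, add_manual_mapping, find_overlaps
from .units import UnitDef

# ---------------------------------------------------------------------------
# term vocabulary (ids are opaque handles into the respective ontologies)

OPB_CONCENTRATION = TermRef("OPB", "OPB_00340", "Chemical concentration")
OPB_FLUID_VOLUME = TermRef("OPB", "OPB_00154", "Fluid volume")
OPB_CHARGE_FLOW = TermRef("OPB", "OPB_00318", "Charge flow rate")
OPB_CHEM_FLOW = TermRef("OPB", "OPB_00592", "Chemical concentration flow rate")
OPB_MEMBRANE_POTENTIAL = TermRef("OPB", "OPB_00506", "Membrane potential")
OPB_FARADAY = TermRef("OPB", "OPB_01226", "Faraday's constant")
OPB_GAS_CONSTANT = TermRef("OPB", "OPB_01301", "Universal gas constant")
OPB_STRESS = TermRef("OPB", "OPB_00562", "Mechanical stress")

CHEBI_CALCIUM = TermRef("CHEBI", "CHEBI:29108", "calcium(2+)")
CHEBI_SODIUM = TermRef("CHEBI", "CHEBI:29101", "sodium(1+)")
FMA_CYTOSOL = TermRef("FMA", "FMA:66836", "Cytosol")
FMA_CARDIOMYOCYTE = TermRef("FMA", "FMA:67839", "Cardiac myocyte")
FMA_EXTRACELLULAR = TermRef("FMA", "FMA:9673", "Extracellular space")
FMA_PLASMA_MEMBRANE = TermRef("FMA", "FMA:63841", "Plasma membrane")
FMA_SR = TermRef("FMA", "FMA:83619", "Sarcoplasmic reticulum")
FMA_SARCOMERE = TermRef("FMA", "FMA:67895", "Sarcomere")

CUSTOM_CA_TRPN = TermRef("CUSTOM", "", "calcium-bound troponin")
CUSTOM_JSR = TermRef("CUSTOM", "", "junctional SR")
CUSTOM_LCC = TermRef("CUSTOM", "", "L-type calcium channel")
CUSTOM_DIADIC = TermRef("CUSTOM", "", "diadic space")

CA_CYTO = entity(CHEBI_CALCIUM, FMA_CYTOSOL, FMA_CARDIOMYOCYTE)
CA_EXT = entity(CHEBI_CALCIUM, FMA_EXTRACELLULAR)
CA_SR = entity(CHEBI_CALCIUM, FMA_SR, FMA_CARDIOMYOCYTE)
CA_JSR_CUSTOM = entity(CHEBI_CALCIUM, CUSTOM_JSR, FMA_CARDIOMYOCYTE)
CA_TRPN_CYTO = entity(CUSTOM_CA_TRPN, FMA_CYTOSOL, FMA_CARDIOMYOCYTE)
MEMBRANE = entity(FMA_PLASMA_MEMBRANE, FMA_CARDIOMYOCYTE)
SARCOMERE = entity(FMA_SARCOMERE, FMA_CARDIOMYOCYTE)

ANN_CA_CYTO = build_entity_annotation(OPB_CONCENTRATION, CA_CYTO.chain)
ANN_VOLUME = build_entity_annotation(OPB_FLUID_VOLUME, (FMA_CYTOSOL, FMA_CARDIOMYOCYTE))
ANN_VOLTAGE = build_entity_annotation(OPB_MEMBRANE_POTENTIAL, MEMBRANE.chain)
ANN_FARADAY = Singular(OPB_FARADAY)
ANN_CA_TRPN = build_entity_annotation(OPB_CONCENTRATION, CA_TRPN_CYTO.chain)
ANN_CA_JSR = build_entity_annotation(OPB_CONCENTRATION, CA_JSR_CUSTOM.chain)
ANN_CA_SR = build_entity_annotation(OPB_CONCENTRATION, CA_SR.chain)
ANN_TENSION = build_entity_annotation(OPB_STRESS, SARCOMERE.chain)


def _bg_current_annotation(process_name: str):
    """Background calcium transport expressed as an electrical current."""
    return build_process_annotation(
        OPB_CHARGE_FLOW, process_name,
        sources=[(CA_EXT, 1.0)], sinks=[(CA_CYTO, 1.0)], mediators=[MEMBRANE],
    )


def _bg_flux_annotation(process_name: str):
    """The same transport expressed as a chemical concentration flow rate."""
    return build_process_annotation(
        OPB_CHEM_FLOW, process_name,
        sources=[(CA_EXT, 1.0)], sinks=[(CA_CYTO, 1.0)], mediators=[MEMBRANE],
    )


# ---------------------------------------------------------------------------
# default parameter sets (one flat mapping per model, overridable by
# "<model>.<param>" keys in generate_suite)

E_PARAMS: dict[str, float] = {
    "F_E": 96485.0,
    "R_gas": 8.314,
    "Temp": 310.0,
    "Ca_o_E": 1.8,
    "C_m": 1.0,
    "stim_amp": 50000.0,
    "stim_period": 1.0,
    "stim_onset": 0.05,
    "stim_duration": 0.002,
    "g_bCa": 2e-06,
    "g_leak": 25.0,
    "E_leak": -80.0,
    "Ca_rest": 0.0001,
    "Vol_myo_E": 1.6e-05,
    "k_relax_E": 1.0,
    "k_up_E": 0.8,
    "k_srl_E": 0.5,
}

E_EPI_PARAMS: dict[str, float] = dict(
    E_PARAMS, g_leak=30.0, stim_amp=55000.0, k_relax_E=1.2, g_bCa=2.4e-06,
)

# chosen so the resting balance k_b*(Ca_o - Ca) = k_pump*(Ca - Ca_rest)
# sits at Ca ~= 1.2e-4 mM, the states' initial conditions
C_PARAMS: dict[str, float] = {
    "F_C": 96485.0,
    "Vol_C": 16000.0,
    "Ca_rest": 2e-05,
    "Ca_o_C": 1.8,
    "V_C": -80.0,
    "k_b_C": 0.0139,
    "g_LCC_C": 0.3,
    "k_up_C": 30.0,
    "k_rel_C": 1.0,
    "k_pump_C": 250.0,
    "vol_ratio_C": 10.0,
    "Trpn_tot_C": 0.07,
    "k_on_C": 5000.0,
    "k_off_C": 2.5,
}

T_PARAMS: dict[str, float] = {
    "Ca_i_T": 0.00012,
    "Trpn_tot_T": 0.07,
    "k_on_T": 5000.0,
    "k_off_T": 2.5,
    "k_ten_T": 100.0,
    "tau_ten_T": 0.08,
}

_PARAM_UNITS = {
    # only where a parameter is not dimensionless
    "F_E": "coulomb_per_mole", "Temp": "kelvin", "Ca_o_E": "millimolar",
    "stim_amp": "nanoamp", "stim_period": "second", "stim_onset": "second",
    "stim_duration": "second", "E_leak": "millivolt", "Ca_rest": "millimolar",
    "Vol_myo_E": "microlitre",
    "F_C": "coulomb_per_mole", "Vol_C": "cubic_micrometre",
    "Ca_o_C": "millimolar", "V_C": "millivolt", "Trpn_tot_C": "millimolar",
    "Ca_i_T": "millimolar", "Trpn_tot_T": "millimolar", "tau_ten_T": "second",
}

_PARAM_ANNOTATIONS = {
    "F_E": ANN_FARADAY, "F_C": ANN_FARADAY,
    "Vol_myo_E": ANN_VOLUME, "Vol_C": ANN_VOLUME,
    "Ca_i_T": ANN_CA_CYTO,
}


def _constants(params: Mapping[str, float]) -> list[Variable]:
    return [
        Variable.constant(
            name, _PARAM_UNITS.get(name, "dimensionless"), value,
            annotation=_PARAM_ANNOTATIONS.get(name),
        )
        for name, value in params.items()
    ]


def _build_excitation(name: str, params: Mapping[str, float], annotated: bool) -> Model:
    """Stimulus-driven membrane model with a terminal SR branch."""
    ann = (lambda a: a) if annotated else (lambda a: None)
    variables = [Variable.domain("t", "second")]
    variables += _constants(params) if annotated else [
        Variable.constant(n, _PARAM_UNITS.get(n, "dimensionless"), v) for n, v in params.items()
    ]
    variables += [
        Variable.algebraic(
            "E_Ca", "millivolt",
            "((R_gas * Temp) / (2 * F_E)) * 1000 * ln(Ca_o_E / Ca_i_E)",
        ),
        Variable.algebraic("i_stim", "nanoamp",
                           "stim_amp * pulse(t, stim_period, stim_onset, stim_duration)"),
        Variable.algebraic("i_b_Ca", "nanoamp", "g_bCa * (V_m - E_Ca)",
                           annotation=ann(_bg_current_annotation("background calcium current"))),
        Variable.algebraic("i_leak", "nanoamp", "g_leak * (V_m - E_leak)"),
        Variable.state("V_m", "millivolt", "(i_stim - i_b_Ca - i_leak) / C_m", -80.0,
                       annotation=ann(ANN_VOLTAGE)),
        Variable.state(
            "Ca_i_E", "millimolar",
            "-(i_b_Ca / (2 * F_E * Vol_myo_E)) + k_relax_E * (Ca_rest - Ca_i_E)",
            0.0001, annotation=ann(ANN_CA_CYTO),
        ),
        # vestigial SR branch: reads cytosolic calcium, feeds nothing else
        Variable.algebraic(
            "J_up_E", "millimolar_per_second", "k_up_E * Ca_i_E",
            annotation=ann(build_process_annotation(
                OPB_CHEM_FLOW, "SR uptake",
                sources=[(CA_CYTO, 1.0)], sinks=[(CA_JSR_CUSTOM, 1.0)],
            )),
            group="sr_branch",
        ),
        Variable.state("Ca_SR_E", "millimolar", "J_up_E - k_srl_E * Ca_SR_E", 0.00016,
                       annotation=ann(ANN_CA_JSR), group="sr_branch"),
    ]
    return Model(name=name, solution_domain="t", variables=tuple(variables))


def _build_calcium(params: Mapping[str, float]) -> Model:
    """Calcium-handling model: SR cycling, troponin buffering, clamped voltage."""
    variables = [Variable.domain("time", "second")]
    variables += _constants(params)
    variables += [
        Variable.algebraic("act_C", "dimensionless", "1 / (1 + exp(-(V_C + 20) / 6))"),
        Variable.algebraic("J_b_Ca", "millimolar_per_second", "k_b_C * (Ca_o_C - Ca_i_C)",
                           annotation=_bg_flux_annotation("background calcium influx")),
        Variable.algebraic(
            "J_LCC", "millimolar_per_second", "g_LCC_C * act_C * (Ca_o_C - Ca_i_C)",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "L-type calcium influx",
                sources=[(CA_EXT, 1.0)], sinks=[(CA_CYTO, 1.0)],
                mediators=[entity(CUSTOM_LCC, FMA_PLASMA_MEMBRANE)],
            ),
        ),
        Variable.algebraic(
            "J_up_C", "millimolar_per_second", "k_up_C * Ca_i_C",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "SERCA uptake",
                sources=[(CA_CYTO, 1.0)], sinks=[(CA_SR, 1.0)],
            ),
        ),
        Variable.algebraic(
            "J_rel_C", "millimolar_per_second", "k_rel_C * Ca_SR_C",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "SR release",
                sources=[(CA_SR, 1.0)], sinks=[(CA_CYTO, 1.0)],
            ),
        ),
        Variable.algebraic(
            "J_pump_C", "millimolar_per_second", "k_pump_C * (Ca_i_C - Ca_rest)",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "sarcolemmal extrusion",
                sources=[(CA_CYTO, 1.0)], sinks=[(CA_EXT, 1.0)], mediators=[MEMBRANE],
            ),
        ),
        Variable.algebraic(
            "J_trpn", "millimolar_per_second",
            "k_on_C * Ca_i_C * (Trpn_tot_C - CaTrpn_C) - k_off_C * CaTrpn_C",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "troponin-calcium buffering",
                sources=[(CA_CYTO, 1.0)], sinks=[(CA_TRPN_CYTO, 1.0)],
            ),
        ),
        Variable.state(
            "Ca_i_C", "millimolar",
            "J_b_Ca + J_LCC + J_rel_C - J_up_C - J_pump_C - J_trpn",
            0.00012, annotation=ANN_CA_CYTO,
        ),
        Variable.state("Ca_SR_C", "millimolar", "vol_ratio_C * (J_up_C - J_rel_C)", 0.0036,
                       annotation=ANN_CA_SR),
        Variable.state(
            "CaTrpn_C", "millimolar",
            "k_on_C * Ca_i_C * (Trpn_tot_C - CaTrpn_C) - k_off_C * CaTrpn_C",
            0.01354838709677419, annotation=ANN_CA_TRPN,
        ),
    ]
    return Model(name="C", solution_domain="time", variables=tuple(variables))


def glue_current_variable() -> Variable:
    """The glue: background concentration flow re-expressed as a current.

    i = -z * F * Vol * J, with the volume in cubic micrometres scaled to
    coherent units and the result scaled to nanoamps (net factor 1e-9); the
    sign follows the inward-current convention of the excitation model.  Its
    process annotation carries the *charge flow rate* property with the same
    participants as the excitation model's background current, which is what
    makes the shared process automatically detectable after insertion.
    """
    return Variable.algebraic(
        "i_b_Ca_C", "nanoamp", "-(2 * F_C * Vol_C * J_b_Ca) * 1e-9",
        annotation=_bg_current_annotation("background calcium current (from flux)"),
    )


def _build_tension(params: Mapping[str, float]) -> Model:
    """Calcium-driven tension model (troponin buffering + first-order stress)."""
    units = {"kilopascal": UnitDef.make(
        "kilopascal", {"kilogram": 1, "metre": -1, "second": -2}, "1e3")}
    variables = [Variable.domain("time_T", "second")]
    variables += _constants(params)
    variables += [
        Variable.algebraic(
            "d_trpn", "millimolar_per_second",
            "k_on_T * Ca_i_T * (Trpn_tot_T - CaTrpn_T) - k_off_T * CaTrpn_T",
            annotation=build_process_annotation(
                OPB_CHEM_FLOW, "troponin-calcium buffering",
                sources=[(CA_CYTO, 1.0)], sinks=[(CA_TRPN_CYTO, 1.0)],
            ),
        ),
        Variable.state("CaTrpn_T", "millimolar", "d_trpn", 0.01354838709677419,
                       annotation=ANN_CA_TRPN),
        Variable.state("tension", "kilopascal",
                       "(k_ten_T * CaTrpn_T - tension) / tau_ten_T",
                       1.354838709677419, annotation=ANN_TENSION),
    ]
    return Model(name="T", solution_domain="time_T", variables=tuple(variables), units=units)


# ---------------------------------------------------------------------------
# suite assembly

@dataclass
class FixtureSuite:
    E: Model
    E_epi: Model
    C: Model
    C_prime: Model
    T: Model
    #: designed overlap manifest: pair label -> set of (kind, left_var, right_var)
    #: for every *automatic* item find_overlaps must return
    manifest: dict[str, set] = field(default_factory=dict)

    def models(self) -> dict[str, Model]:
        return {m.name: m for m in (self.E, self.E_epi, self.C, self.C_prime, self.T)}


def generate_suite(overrides: Optional[Mapping[str, float]] = None) -> FixtureSuite:
    """Build the fixture suite, optionally overriding parameters.

    Override keys are ``"<model>.<parameter>"`` (e.g. ``"C.k_b_C"``); the
    parameter must exist in that model's default set.  ``C_prime`` inherits
    ``C`` overrides.  With no overrides the suite is fully deterministic.
    """
    param_sets = {
        "E": dict(E_PARAMS),
        "E_epi": dict(E_EPI_PARAMS),
        "C": dict(C_PARAMS),
        "T": dict(T_PARAMS),
    }
    for key, value in (overrides or {}).items():
        model_name, _, param = key.partition(".")
        if model_name not in param_sets or param not in param_sets[model_name]:
            raise SemMergeError(f"unknown fixture parameter override {key!r}")
        param_sets[model_name][param] = float(value)

    E = _build_excitation("E", param_sets["E"], annotated=True)
    E_epi = _build_excitation("E_epi", param_sets["E_epi"], annotated=False)
    C = _build_calcium(param_sets["C"])
    from dataclasses import replace as _replace
    C_prime = _replace(add_variable(C, glue_current_variable()), name="C_prime")
    T = _build_tension(param_sets["T"])

    manifest = {
        "E:C": {
            ("solution_domain", "t", "time"),
            ("singular", "F_E", "F_C"),
            ("entity_property", "Vol_myo_E", "Vol_C"),
            ("entity_property", "Ca_i_E", "Ca_i_C"),
        },
        "E:C_prime": {
            ("solution_domain", "t", "time"),
            ("singular", "F_E", "F_C"),
            ("entity_property", "Vol_myo_E", "Vol_C"),
            ("entity_property", "Ca_i_E", "Ca_i_C"),
            ("process_property", "i_b_Ca", "i_b_Ca_C"),
        },
        "EC:T": {
            ("solution_domain", "t", "time_T"),
            ("entity_property", "Ca_i_C", "Ca_i_T"),
        },
    }
    return FixtureSuite(E=E, E_epi=E_epi, C=C, C_prime=C_prime, T=T, manifest=manifest)


# ---------------------------------------------------------------------------
# the canonical resolved merges (the suite's re-enactment of the use case)

def excitation_calcium_report(suite: FixtureSuite) -> OverlapReport:
    """Overlaps of E and C_prime plus the manual voltage mapping.

    The calcium model's clamp voltage is unannotated, so the pairing
    V_m <-> V_C must be asserted manually for the merged system to couple
    membrane excitation into calcium influx.
    """
    report = find_overlaps(suite.E, suite.C_prime)
    return add_manual_mapping(report, "V_m", "V_C")


def _resolve(report: OverlapReport, choices: Mapping[tuple[str, str], str]) -> list[Resolution]:
    resolutions = []
    for item in report.items:
        choice = choices.get(item.pair())
        if choice is None:
            choice = "keep_left" if item.kind == "solution_domain" else "ignore"
        resolutions.append(Resolution(item, choice))
    return resolutions


EXCITATION_CALCIUM_CHOICES: dict[tuple[str, str], str] = {
    ("t", "time"): "keep_left",
    ("Ca_i_E", "Ca_i_C"): "keep_right",
    ("Vol_myo_E", "Vol_C"): "keep_left",
    ("F_E", "F_C"): "keep_right",
    ("i_b_Ca", "i_b_Ca_C"): "keep_right",
    ("V_m", "V_C"): "keep_left",
}


def merge_excitation_calcium(suite: FixtureSuite,
                             choices: Optional[Mapping[tuple[str, str], str]] = None) -> MergeResult:
    """The resolved E + C_prime merge (current, calcium, volume, Faraday, voltage)."""
    report = excitation_calcium_report(suite)
    return merge(suite.E, suite.C_prime,
                 _resolve(report, choices if choices is not None else EXCITATION_CALCIUM_CHOICES))


def merge_with_tension(suite: FixtureSuite, ec_merged: Optional[Model] = None) -> MergeResult:
    """Merge the coupled excitation-calcium model with the tension model.

    Calcium and the solution domain pair automatically; the troponin
    buffering rate carries CUSTOM terms on both sides and needs a manual
    mapping (J_trpn <-> d_trpn, resolved to the calcium model's side).
    """
    if ec_merged is None:
        ec_merged = merge_excitation_calcium(suite).merged
    report = find_overlaps(ec_merged, suite.T)
    report = add_manual_mapping(report, "J_trpn", "d_trpn")
    choices = {
        (ec_merged.solution_domain, suite.T.solution_domain): "keep_left",
        ("Ca_i_C", "Ca_i_T"): "keep_left",
        ("J_trpn", "d_trpn"): "keep_left",
    }
    return merge(ec_merged, suite.T, _resolve(report, choices))


def c_prime_volume_in_microlitre(suite: FixtureSuite) -> Model:
    """Control variant of C_prime with the cell volume pre-harmonised to microlitres.

    The volume constant is re-declared in microlitres (value / 1e9) and the
    glue expression carries the explicit 1e9 back-conversion, so the model's
    numerics are unchanged while its coupling-point units match E's.
    """
    variables = []
    for v in suite.C_prime.variables:
        if v.name == "Vol_C":
            v = Variable.constant("Vol_C", "microlitre", v.value / 1e9, annotation=v.annotation)
        elif v.name == "i_b_Ca_C":
            v = Variable.algebraic(
                "i_b_Ca_C", "nanoamp", "-(2 * F_C * (Vol_C * 1e9) * J_b_Ca) * 1e-9",
                annotation=v.annotation,
            )
        variables.append(v)
    from dataclasses import replace as _replace
    return _replace(suite.C_prime, variables=tuple(variables))


# ---------------------------------------------------------------------------
# random annotated models for property-based oracle testing

_RANDOM_UNIT_POOL = (
    "dimensionless", "millivolt", "millimolar", "microlitre",
    "cubic_micrometre", "nanoamp", "second", "millimolar_per_second",
)

_RANDOM_PROPERTY_POOL = (OPB_CONCENTRATION, OPB_FLUID_VOLUME, OPB_MEMBRANE_POTENTIAL)
_RANDOM_RATE_POOL = (OPB_CHARGE_FLOW, OPB_CHEM_FLOW)
_RANDOM_SINGULAR_POOL = (OPB_FARADAY, OPB_GAS_CONSTANT,
                         TermRef("CUSTOM", "", "lab-specific constant"))
_RANDOM_CHAIN_POOL = (
    CA_CYTO, CA_EXT, CA_SR, CA_JSR_CUSTOM, CA_TRPN_CYTO, MEMBRANE, SARCOMERE,
    entity(CHEBI_SODIUM, FMA_CYTOSOL, FMA_CARDIOMYOCYTE),
    entity(CHEBI_CALCIUM, CUSTOM_DIADIC, FMA_CARDIOMYOCYTE),
    entity(CHEBI_CALCIUM, FMA_CYTOSOL),  # shorter-granularity chain: must not match CA_CYTO
)


def _random_annotation(rng: random.Random):
    kind = rng.random()
    if kind < 0.4:
        chain = rng.choice(_RANDOM_CHAIN_POOL)
        return build_entity_annotation(rng.choice(_RANDOM_PROPERTY_POOL), chain.chain)
    if kind < 0.7:
        chains = rng.sample(_RANDOM_CHAIN_POOL, 3)
        mult = rng.choice((1.0, 1.0, 2.0))
        mediators = [chains[2]] if rng.random() < 0.5 else []
        return build_process_annotation(
            rng.choice(_RANDOM_RATE_POOL), f"process_{rng.randrange(3)}",
            sources=[(chains[0], mult)], sinks=[(chains[1], 1.0)], mediators=mediators,
        )
    return Singular(rng.choice(_RANDOM_SINGULAR_POOL))


def random_annotated_model(n_vars: int, seed: int) -> Model:
    """A deterministic, valid (not necessarily simulatable) annotated model.

    Annotations are drawn from a small fixed term pool with high duplication
    probability, so random model pairs share concepts often — the input
    distribution for the indexed-versus-brute-force overlap equivalence
    property.
    """
    if n_vars < 2:
        raise SemMergeError("random_annotated_model needs n_vars >= 2")
    rng = random.Random(seed)
    variables = [Variable.domain("t", "second")]
    names: list[str] = []
    for i in range(n_vars - 1):
        name = f"v{i}"
        units = rng.choice(_RANDOM_UNIT_POOL)
        annotation = _random_annotation(rng) if rng.random() < 0.75 else None
        if names and rng.random() < 0.3:
            deps = rng.sample(names, min(len(names), rng.randrange(1, 3)))
            variables.append(Variable.algebraic(name, units, " + ".join(deps),
                                                annotation=annotation))
        else:
            variables.append(Variable.constant(name, units, round(rng.uniform(0.1, 10.0), 6),
                                               annotation=annotation))
        names.append(name)
    return Model(name=f"rnd_{seed}", solution_domain="t", variables=tuple(variables))
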