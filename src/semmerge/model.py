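"""Model and variable domain types, validation, editing, and the JSON dialect.

A model is a named, ordered set of variables over a single temporal solution
domain.  Each variable is a constant (numeric value), an algebraic quantity
(defining expression), an ODE state (right-hand side + initial condition),
or the solution domain itself, and may carry a composite annotation stating
its biological meaning.

Validation is report-based: :func:`validate_model` returns every violation
it finds (dangling symbols, duplicate names, missing units, algebraic
cycles) and never raises on invalid content.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import networkx as nx

from . import expr as ex
from .annotation import (
    CompositeAnnotation,
    annotation_from_json,
    annotation_to_json,
)
from .errors import ModelError
from .units import BUILTIN_UNITS, UnitDef

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

ROLES = ("constant", "algebraic", "state", "solution_domain")


@dataclass(frozen=True)
class Variable:
    """One model quantity.  Exactly one definition form must match the role:

    constant -> ``value``; algebraic -> ``expr``; state -> ``rhs`` +
    ``initial``; solution_domain -> no definition.
    """

    name: str
    units: str
    role: str
    value: Optional[float] = None
    expr: Optional[ex.Expr] = None
    rhs: Optional[ex.Expr] = None
    initial: Optional[float] = None
    annotation: Optional[CompositeAnnotation] = None
    group: Optional[str] = None

    # --- convenience constructors -----------------------------------------
    @classmethod
    def constant(cls, name, units, value, annotation=None, group=None):
        return cls(name, units, "constant", value=float(value), annotation=annotation, group=group)

    @classmethod
    def algebraic(cls, name, units, expression, annotation=None, group=None):
        return cls(name, units, "algebraic", expr=ex.as_expr(expression), annotation=annotation, group=group)

    @classmethod
    def state(cls, name, units, rhs, initial, annotation=None, group=None):
        return cls(name, units, "state", rhs=ex.as_expr(rhs), initial=float(initial), annotation=annotation, group=group)

    @classmethod
    def domain(cls, name, units, annotation=None):
        return cls(name, units, "solution_domain", annotation=annotation)

    def definition_symbols(self) -> set[str]:
        """Names referenced by this variable's defining expression(s)."""
        if self.role == "algebraic" and self.expr is not None:
            return ex.symbols(self.expr)
        if self.role == "state" and self.rhs is not None:
            return ex.symbols(self.rhs)
        return set()

    def map_expressions(self, fn) -> "Variable":
        """Return a copy with ``fn`` applied to every defining expression."""
        changes = {}
        if self.expr is not None:
            changes["expr"] = fn(self.expr)
        if self.rhs is not None:
            changes["rhs"] = fn(self.rhs)
        return replace(self, **changes) if changes else self


@dataclass(frozen=True)
class Model:
    """A named variable collection over one solution domain.

    ``units`` is the model-local unit table; lookups fall back to the
    built-in catalog, so models only declare units the catalog lacks (or
    deliberately redefine).
    """

    name: str
    solution_domain: str
    variables: tuple[Variable, ...] = ()
    units: Mapping[str, UnitDef] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "units", dict(self.units))

    # --- lookups ----------------------------------------------------------
    def var_map(self) -> dict[str, Variable]:
        out: dict[str, Variable] = {}
        for v in self.variables:
            out.setdefault(v.name, v)
        return out

    def get(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise ModelError(f"model {self.name!r} has no variable {name!r}")

    def has(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def unit(self, name: str) -> UnitDef:
        if name in self.units:
            return self.units[name]
        if name in BUILTIN_UNITS:
            return BUILTIN_UNITS[name]
        raise ModelError(f"model {self.name!r}: unknown unit {name!r}")

    def has_unit(self, name: str) -> bool:
        return name in self.units or name in BUILTIN_UNITS

    def unit_of(self, var_name: str) -> UnitDef:
        return self.unit(self.get(var_name).units)

    def domain_variable(self) -> Variable:
        return self.get(self.solution_domain)


@dataclass(frozen=True)
class Violation:
    code: str
    message: str

    def to_json(self) -> dict:
        return {"code": self.code, "message": self.message}


def _definition_violations(v: Variable) -> Iterable[Violation]:
    def bad(msg):
        return Violation("bad_definition", f"variable {v.name!r}: {msg}")

    forms = {
        "constant": (v.value is not None, v.expr is None and v.rhs is None and v.initial is None,
                     "a constant needs a numeric value and nothing else"),
        "algebraic": (v.expr is not None, v.value is None and v.rhs is None and v.initial is None,
                      "an algebraic variable needs a defining expression and nothing else"),
        "state": (v.rhs is not None and v.initial is not None, v.value is None and v.expr is None,
                  "a state needs a rhs expression and an initial condition"),
        "solution_domain": (True, v.value is None and v.expr is None and v.rhs is None and v.initial is None,
                            "the solution domain carries no definition"),
    }
    if v.role not in forms:
        yield Violation("bad_role", f"variable {v.name!r}: unknown role {v.role!r}")
        return
    required, exclusive, msg = forms[v.role]
    if not (required and exclusive):
        yield bad(msg)


def validate_model(model: Model) -> list[Violation]:
    """Collect every structural violation; an empty list means valid."""
    out: list[Violation] = []

    if not IDENTIFIER_RE.match(model.name or ""):
        out.append(Violation("bad_name", f"model name {model.name!r} is not an identifier"))

    seen: set[str] = set()
    for v in model.variables:
        if not IDENTIFIER_RE.match(v.name or ""):
            out.append(Violation("bad_name", f"variable name {v.name!r} is not an identifier"))
        if v.name in seen:
            out.append(Violation("duplicate_name", f"duplicate variable name {v.name!r}"))
        seen.add(v.name)
        if not model.has_unit(v.units):
            out.append(Violation("unknown_unit", f"variable {v.name!r}: unknown unit {v.units!r}"))
        out.extend(_definition_violations(v))

    domains = [v.name for v in model.variables if v.role == "solution_domain"]
    if len(domains) != 1:
        out.append(Violation(
            "solution_domain",
            f"model must declare exactly one solution_domain variable, found {domains!r}",
        ))
    elif model.solution_domain != domains[0]:
        out.append(Violation(
            "solution_domain",
            f"model.solution_domain = {model.solution_domain!r} but the domain variable is {domains[0]!r}",
        ))

    # dangling symbol references
    names = {v.name for v in model.variables}
    for v in model.variables:
        for sym in sorted(v.definition_symbols() - names):
            out.append(Violation("dangling_symbol", f"variable {v.name!r} references undeclared symbol {sym!r}"))

    # algebraic cycles: edges into non-state variables only; cycles may pass
    # only through the integrated value of a state
    g = nx.DiGraph()
    var_map = model.var_map()
    g.add_nodes_from(names)
    for v in model.variables:
        if v.role in ("state", "solution_domain"):
            continue
        for dep in v.definition_symbols() & names:
            g.add_edge(dep, v.name)
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1 or (len(scc) == 1 and g.has_edge(next(iter(scc)), next(iter(scc)))):
            cyc = sorted(scc)
            out.append(Violation("algebraic_cycle", f"algebraic cycle among {{{', '.join(cyc)}}}"))

    return out


def require_valid(model: Model) -> None:
    violations = validate_model(model)
    if violations:
        msgs = "; ".join(v.message for v in violations)
        raise ModelError(f"model {model.name!r} is invalid: {msgs}")


# ---------------------------------------------------------------------------
# editing primitives

def add_variable(model: Model, variable: Variable) -> Model:
    """Return the model extended with one variable; existing content untouched."""
    if model.has(variable.name):
        raise ModelError(f"cannot add variable: name {variable.name!r} already exists in model {model.name!r}")
    if not model.has_unit(variable.units):
        raise ModelError(f"cannot add variable {variable.name!r}: unknown unit {variable.units!r}")
    return replace(model, variables=model.variables + (variable,))


def rename_variable(model: Model, old: str, new: str) -> Model:
    """Alpha-rename: rename a variable and rewrite every reference to it."""
    if not model.has(old):
        raise ModelError(f"cannot rename: {old!r} not in model {model.name!r}")
    if old == new:
        return model
    if model.has(new):
        raise ModelError(f"cannot rename {old!r}: name {new!r} already taken in model {model.name!r}")
    if not IDENTIFIER_RE.match(new):
        raise ModelError(f"cannot rename {old!r}: {new!r} is not a legal identifier")
    renames = {old: new}
    new_vars = []
    for v in model.variables:
        v = v.map_expressions(lambda e: ex.rename_symbols(e, renames))
        if v.name == old:
            v = replace(v, name=new)
        new_vars.append(v)
    domain = new if model.solution_domain == old else model.solution_domain
    return replace(model, variables=tuple(new_vars), solution_domain=domain)


def dependency_graph(model: Model) -> nx.DiGraph:
    """Directed graph over variable names; edge u->v iff v's definition references u.

    State variables contribute their rhs references (including self-loops
    through the integrated value).  Rejects invalid models.
    """
    require_valid(model)
    g = nx.DiGraph()
    for v in model.variables:
        g.add_node(v.name)
    for v in model.variables:
        for dep in v.definition_symbols():
            g.add_edge(dep, v.name)
    return g


# ---------------------------------------------------------------------------
# JSON dialect

def model_to_json(model: Model) -> dict:
    variables = []
    for v in model.variables:
        obj: dict = {"name": v.name, "units": v.units, "role": v.role}
        if v.role == "constant":
            obj["value"] = v.value
        elif v.role == "algebraic":
            obj["expr"] = ex.to_string(v.expr)
        elif v.role == "state":
            obj["rhs"] = ex.to_string(v.rhs)
            obj["init"] = v.initial
        if v.annotation is not None:
            obj["annotation"] = annotation_to_json(v.annotation)
        if v.group is not None:
            obj["group"] = v.group
        variables.append(obj)
    return {
        "name": model.name,
        "solution_domain": model.solution_domain,
        "units": {name: u.to_json() for name, u in model.units.items()},
        "variables": variables,
    }


def _variable_from_json(obj: Mapping) -> Variable:
    if not isinstance(obj, Mapping) or "name" not in obj or "role" not in obj:
        raise ModelError(f"variable entry must be an object with 'name' and 'role': {obj!r}")
    role = obj["role"]
    if role not in ROLES:
        raise ModelError(f"variable {obj['name']!r}: unknown role {role!r}")
    common = dict(
        name=obj["name"],
        units=obj.get("units", "dimensionless"),
        role=role,
        annotation=annotation_from_json(obj["annotation"]) if "annotation" in obj else None,
        group=obj.get("group"),
    )
    try:
        if role == "constant":
            return Variable(value=float(obj["value"]), **common)
        if role == "algebraic":
            return Variable(expr=ex.parse(obj["expr"]), **common)
        if role == "state":
            return Variable(rhs=ex.parse(obj["rhs"]), initial=float(obj["init"]), **common)
        return Variable(**common)
    except KeyError as exc:
        raise ModelError(f"variable {obj['name']!r}: missing field {exc.args[0]!r} for role {role!r}") from None


def model_from_json(obj: Mapping) -> Model:
    if not isinstance(obj, Mapping):
        raise ModelError("model document must be a JSON object")
    for key in ("name", "solution_domain", "variables"):
        if key not in obj:
            raise ModelError(f"model document missing required field {key!r}")
    units = {
        name: UnitDef.from_json(name, spec)
        for name, spec in (obj.get("units") or {}).items()
    }
    variables = tuple(_variable_from_json(v) for v in obj["variables"])
    return Model(
        name=obj["name"],
        solution_domain=obj["solution_domain"],
        variables=variables,
        units=units,
    )


def dumps_model(model: Model, indent: int | None = 2) -> str:
    return json.dumps(model_to_json(model), indent=indent)


def loads_model(text: str) -> Model:
    return model_from_json(json.loads(text))


def load_model(path) -> Model:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_json(json.load(fh))


def save_model(model: Model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_model(model))
        fh.write("\n")
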