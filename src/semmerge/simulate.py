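"""Compilation of models to executable ODE systems and fixed-step integration.

A valid model compiles to one generated Python function: constants first,
algebraic variables in topological order, then the state derivatives.  The
integrator is classical fixed-step fourth-order Runge-Kutta with output at
every step — deliberately not adaptive and not stiff-aware, so results are
deterministic across runs and platforms; commensurate step sizes place
piecewise pulse edges on step boundaries.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx

from . import expr as ex
from .errors import SimulationError
from .model import Model, validate_model

_SAFE_ENV = {
    "exp": math.exp,
    "log": math.log,
    "log10": math.log10,
    "sqrt": math.sqrt,
    "abs": abs,
    "min": min,
    "max": max,
    "pulse": ex.pulse,
    "__builtins__": {},
}


def _mangle(name: str) -> str:
    return f"_v_{name}"


@dataclass
class CompiledSystem:
    """An executable model: ordered evaluation plan over (t, state)."""

    model: Model
    state_names: tuple[str, ...]
    variable_names: tuple[str, ...]  # declaration order, domain included
    initial_state: tuple[float, ...]
    #: (t, y) -> (derivatives tuple, all-variable values tuple)
    step_fn: Callable[[float, Sequence[float]], tuple[tuple, tuple]]
    source: str = field(repr=False, default="")


def compile_model(model: Model) -> CompiledSystem:
    """Build the evaluation plan; rejects invalid models listing violations."""
    violations = validate_model(model)
    if violations:
        msgs = "; ".join(v.message for v in violations)
        raise SimulationError(f"cannot compile invalid model {model.name!r}: {msgs}")

    domain = model.solution_domain
    constants = [v for v in model.variables if v.role == "constant"]
    algebraic = [v for v in model.variables if v.role == "algebraic"]
    states = [v for v in model.variables if v.role == "state"]

    # topological order among algebraic variables (constants, states and the
    # domain are available before any algebraic evaluation)
    g = nx.DiGraph()
    alg_names = {v.name for v in algebraic}
    g.add_nodes_from(alg_names)
    for v in algebraic:
        for dep in v.definition_symbols() & alg_names:
            g.add_edge(dep, v.name)
    order = list(nx.lexicographical_topological_sort(g))
    alg_by_name = {v.name: v for v in algebraic}

    lines = ["def _evaluate(t, y):"]
    lines.append(f"    {_mangle(domain)} = t")
    for i, v in enumerate(states):
        lines.append(f"    {_mangle(v.name)} = y[{i}]")
    for v in constants:
        lines.append(f"    {_mangle(v.name)} = {v.value!r}")
    for name in order:
        v = alg_by_name[name]
        lines.append(f"    {_mangle(name)} = {ex.render_python(v.expr, _mangle)}")
    derivs = ", ".join(ex.render_python(v.rhs, _mangle) for v in states)
    values = ", ".join(_mangle(v.name) for v in model.variables)
    lines.append(f"    return ({derivs}{',' if len(states) == 1 else ''}), ({values}{',' if len(model.variables) == 1 else ''})")
    source = "\n".join(lines)

    namespace: dict = {}
    exec(compile(source, f"<compiled model {model.name}>", "exec"), dict(_SAFE_ENV), namespace)

    return CompiledSystem(
        model=model,
        state_names=tuple(v.name for v in states),
        variable_names=tuple(v.name for v in model.variables),
        initial_state=tuple(v.initial for v in states),
        step_fn=namespace["_evaluate"],
        source=source,
    )


@dataclass
class Trajectory:
    """Sampled solution: strictly increasing domain values plus aligned columns."""

    domain_name: str
    domain: list[float]
    columns: dict[str, list[float]]

    def column(self, name: str) -> list[float]:
        if name == self.domain_name:
            return self.domain
        try:
            return self.columns[name]
        except KeyError:
            raise SimulationError(f"trajectory has no column {name!r}") from None


def integrate(system: CompiledSystem, t0: float, t1: float, dt: float) -> Trajectory:
    """Classical RK4 from t0 to t1 with step (and sampling interval) dt.

    Raises :class:`SimulationError` naming the first variable and time at
    which a non-finite value appears.
    """
    t0, t1, dt = float(t0), float(t1), float(dt)
    if not dt > 0:
        raise SimulationError("dt must be positive")
    if not t1 > t0:
        raise SimulationError("t1 must exceed t0")
    f = system.step_fn
    names = system.variable_names
    n_steps = round((t1 - t0) / dt)
    if n_steps < 1:
        raise SimulationError("integration span shorter than one step")

    domain: list[float] = []
    columns: dict[str, list[float]] = {name: [] for name in names if name != system.model.solution_domain}

    def record(t: float, values: tuple) -> None:
        domain.append(t)
        for name, val in zip(names, values):
            if name == system.model.solution_domain:
                continue
            if not math.isfinite(val):
                raise SimulationError(f"non-finite value in variable {name!r} at {system.model.solution_domain}={t!r}")
            columns[name].append(val)

    y = system.initial_state
    k1, values = f(t0, y)
    record(t0, values)
    t = t0
    h = dt
    for step in range(n_steps):
        t = t0 + step * h
        k1, _ = f(t, y)
        y2 = tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k1))
        k2, _ = f(t + 0.5 * h, y2)
        y3 = tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k2))
        k3, _ = f(t + 0.5 * h, y3)
        y4 = tuple(yi + h * ki for yi, ki in zip(y, k3))
        k4, _ = f(t + h, y4)
        y = tuple(
            yi + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
            for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
        )
        t_next = t0 + (step + 1) * h
        _, values = f(t_next, y)
        record(t_next, values)
    return Trajectory(domain_name=system.model.solution_domain, domain=domain, columns=columns)


def simulate(model: Model, t0: float, t1: float, dt: float) -> Trajectory:
    """Compile and integrate in one call."""
    return integrate(compile_model(model), t0, t1, dt)


def write_trajectory(traj: Trajectory, selection: Sequence[str] | None = None) -> str:
    """Render selected columns as CSV text (domain column first).

    ``repr`` formatting keeps the output bit-stable across runs and
    round-trippable through any standard CSV reader.
    """
    if selection is None:
        selection = list(traj.columns.keys())
    for name in selection:
        if name != traj.domain_name and name not in traj.columns:
            raise SimulationError(f"unknown trajectory column {name!r}")
    selection = [s for s in selection if s != traj.domain_name]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([traj.domain_name] + list(selection))
    cols = [traj.columns[name] for name in selection]
    for i, t in enumerate(traj.domain):
        writer.writerow([repr(t)] + [repr(col[i]) for col in cols])
    return buf.getvalue()


def count_transients(values: Sequence[float], threshold: float) -> int:
    """Number of upward crossings of ``threshold`` — one per stimulus-evoked transient."""
    count = 0
    prev = values[0]
    for v in values[1:]:
        if prev < threshold <= v:
            count += 1
        prev = v
    return count
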