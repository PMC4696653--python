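"""Resolution-driven model merging and dependency pruning.

For every shared concept the user chooses which model's mathematical
implementation survives (``keep_left`` / ``keep_right``) or keeps both
(``ignore``).  A keep removes the losing variable's entire definition —
including any initial condition — and rewires every surviving reference to
it onto the kept variable, multiplied by the unit conversion factor into
the discarded variable's declared units, so surviving equations keep their
original numeric meaning.  Keeps across incommensurable units are rejected:
that is the current-versus-concentration-flow situation, which must be
bridged by inserting an explicit glue variable before merging.

Name collisions among surviving variables are resolved deterministically by
suffixing the right-model variable with ``__<right model name>``.  Pruning
is a separate, explicit operation that drops every variable with no
computational path to a chosen output set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx

from . import expr as ex
from .errors import MergeError
from .model import Model, Variable, dependency_graph, require_valid, validate_model
from .overlap import OverlapItem, OverlapReport
from .units import commensurable, conversion_factor, identical

CHOICES = ("keep_left", "keep_right", "ignore")


@dataclass(frozen=True)
class Resolution:
    item: OverlapItem
    choice: str

    def __post_init__(self):
        if self.choice not in CHOICES:
            raise MergeError(f"unknown resolution choice {self.choice!r} (expected one of {CHOICES})")


@dataclass
class MergeResult:
    merged: Model
    log: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _substitution(kept_name: str, factor: float) -> ex.Expr:
    if factor == 1.0:
        return ex.Sym(kept_name)
    return ex.BinOp("*", ex.Num(factor), ex.Sym(kept_name))


def _check_resolutions(a: Model, b: Model, resolutions: Sequence[Resolution]) -> None:
    seen: set[tuple[str, str]] = set()
    for res in resolutions:
        it = res.item
        if not a.has(it.left_var):
            raise MergeError(f"resolution references unknown left variable {it.left_var!r}")
        if not b.has(it.right_var):
            raise MergeError(f"resolution references unknown right variable {it.right_var!r}")
        if it.pair() in seen:
            raise MergeError(f"duplicate resolution for pair {it.pair()!r}")
        seen.add(it.pair())


def merge(a: Model, b: Model, resolutions: Sequence[Resolution]) -> MergeResult:
    """Couple two models under the given resolution decisions.

    The solution-domain pairing must be resolved ``keep_left`` or
    ``keep_right``; the discarded domain variable is removed and its symbol
    rewritten like any other discarded variable.  The result satisfies
    ``|merged| = |a| + |b| - #keep`` (the domain keep included) and passes
    validation.
    """
    require_valid(a)
    require_valid(b)
    _check_resolutions(a, b, resolutions)
    result = MergeResult(merged=None)  # type: ignore[arg-type]

    domain_res = [r for r in resolutions if r.item.kind == "solution_domain"]
    if len(domain_res) != 1 or domain_res[0].choice == "ignore":
        raise MergeError(
            "the solution-domain pairing must be resolved keep_left or keep_right "
            "(a merged model has a single independent variable)"
        )

    # kept/discarded bookkeeping per keep resolution
    discard_a: dict[str, tuple[str, float]] = {}  # discarded A name -> (kept B name, factor)
    discard_b: dict[str, tuple[str, float]] = {}
    for res in resolutions:
        it = res.item
        if res.choice == "ignore":
            result.log.append({"action": "ignore", "concept": it.concept,
                               "left_var": it.left_var, "right_var": it.right_var})
            continue
        if res.choice == "keep_left":
            kept_model, kept, disc_model, disc = a, it.left_var, b, it.right_var
        else:
            kept_model, kept, disc_model, disc = b, it.right_var, a, it.left_var
        ku, du = kept_model.unit_of(kept), disc_model.unit_of(disc)
        if not commensurable(ku, du):
            raise MergeError(
                f"cannot resolve {it.concept!r} by keeping {kept!r}: units {ku.name!r} and "
                f"{du.name!r} of pair ({it.left_var!r}, {it.right_var!r}) are incommensurable; "
                f"insert a glue conversion variable instead"
            )
        factor = 1.0 if identical(ku, du) else conversion_factor(ku, du)
        target = discard_b if disc_model is b else discard_a
        if disc in target:
            raise MergeError(f"variable {disc!r} discarded by more than one resolution")
        target[disc] = (kept, factor)
        result.log.append({
            "action": "resolve", "concept": it.concept, "choice": res.choice,
            "kept": kept, "discarded": disc, "conversion_factor": factor,
        })

    # a kept variable must itself survive; the kept side is always the
    # opposite model of the discarded one
    for disc, (kept, _) in discard_a.items():
        if kept in discard_b:
            raise MergeError(f"kept variable {kept!r} is itself discarded by another resolution")
    for disc, (kept, _) in discard_b.items():
        if kept in discard_a:
            raise MergeError(f"kept variable {kept!r} is itself discarded by another resolution")

    surviving_a = [v for v in a.variables if v.name not in discard_a]
    surviving_b = [v for v in b.variables if v.name not in discard_b]

    # unit-table union; conflicting same-name definitions rename the B unit
    merged_units = dict(a.units)
    unit_renames: dict[str, str] = {}
    for name, u in b.units.items():
        if name not in merged_units:
            merged_units[name] = u
        elif not identical(merged_units[name], u):
            new_name = f"{name}__{b.name}"
            n = 2
            while new_name in merged_units:
                new_name = f"{name}__{b.name}_{n}"
                n += 1
            merged_units[new_name] = replace(u, name=new_name)
            unit_renames[name] = new_name
            result.warnings.append(f"unit {name!r} redefined by {b.name!r}; renamed to {new_name!r}")
    if unit_renames:
        surviving_b = [
            replace(v, units=unit_renames.get(v.units, v.units)) for v in surviving_b
        ]

    # disambiguate surviving right-model names that collide with left names
    a_names = {v.name for v in surviving_a}
    taken = a_names | {v.name for v in surviving_b}
    renames: dict[str, str] = {}
    for v in surviving_b:
        if v.name in a_names:
            candidate = f"{v.name}__{b.name}"
            n = 2
            while candidate in taken:
                candidate = f"{v.name}__{b.name}_{n}"
                n += 1
            renames[v.name] = candidate
            taken.add(candidate)
            result.log.append({"action": "rename", "old": v.name, "new": candidate})

    if renames:
        surviving_b = [
            replace(v.map_expressions(lambda e: ex.rename_symbols(e, renames)),
                    name=renames.get(v.name, v.name))
            for v in surviving_b
        ]

    # rewire references to discarded variables
    # kept name for A-side substitutions lives in B and may have been renamed
    subs_a = {disc: _substitution(renames.get(kept, kept), f) for disc, (kept, f) in discard_a.items()}
    subs_b = {disc: _substitution(kept, f) for disc, (kept, f) in discard_b.items()}

    if subs_a:
        surviving_a = [v.map_expressions(lambda e: ex.substitute(e, subs_a)) for v in surviving_a]
    if subs_b:
        surviving_b = [v.map_expressions(lambda e: ex.substitute(e, subs_b)) for v in surviving_b]

    # merged solution domain: the kept side's domain variable (post-rename)
    if domain_res[0].choice == "keep_left":
        domain_name = a.solution_domain
    else:
        domain_name = renames.get(b.solution_domain, b.solution_domain)

    merged = Model(
        name=f"{a.name}__{b.name}",
        solution_domain=domain_name,
        variables=tuple(surviving_a) + tuple(surviving_b),
        units=merged_units,
    )
    violations = validate_model(merged)
    if violations:
        msgs = "; ".join(v.message for v in violations)
        raise MergeError(f"merged model failed validation: {msgs}")
    result.merged = merged
    return result


def prune(model: Model, outputs: Sequence[str] | set[str]) -> Model:
    """Drop every variable with no computational path to any output.

    Retains exactly the outputs, their ancestors in the dependency graph,
    and the solution domain; trajectories of retained variables are
    unchanged because removed variables are, by construction, never read by
    retained ones.
    """
    outputs = list(outputs)
    if not outputs:
        raise MergeError("prune requires a non-empty output set")
    for name in outputs:
        if not model.has(name):
            raise MergeError(f"prune: unknown output variable {name!r}")
    g = dependency_graph(model)
    keep: set[str] = set(outputs) | {model.solution_domain}
    for name in outputs:
        keep |= nx.ancestors(g, name)
    new_vars = tuple(v for v in model.variables if v.name in keep)
    return replace(model, variables=new_vars)


def resolution_from_file(report: OverlapReport, decisions) -> list[Resolution]:
    """Build the full resolution list from a batch decisions document.

    ``decisions`` is a parsed JSON array (or a path/str handled by the CLI):
    each entry carries ``choice`` plus either ``concept`` (matched against
    item labels) or ``left_var``/``right_var``.  Items not referenced
    default to ``ignore`` — except the solution-domain item, which defaults
    to ``keep_left``.  Ambiguous or unknown references and duplicate
    decisions are rejected.
    """
    if isinstance(decisions, Mapping):
        decisions = decisions.get("resolutions", [])
    if not isinstance(decisions, Sequence) or isinstance(decisions, (str, bytes)):
        raise MergeError("decisions document must be a JSON array of resolution entries")

    chosen: dict[tuple[str, str], str] = {}
    for entry in decisions:
        if not isinstance(entry, Mapping) or "choice" not in entry:
            raise MergeError(f"bad decision entry {entry!r}: needs a 'choice'")
        choice = entry["choice"]
        if choice not in CHOICES:
            raise MergeError(f"bad decision entry {entry!r}: unknown choice {choice!r}")
        if "left_var" in entry or "right_var" in entry:
            pair = (entry.get("left_var"), entry.get("right_var"))
            matches = [it for it in report.items if it.pair() == pair]
            if not matches:
                raise MergeError(f"decision references unknown item pair {pair!r}")
        elif "concept" in entry:
            matches = [it for it in report.items if it.concept == entry["concept"]]
            if not matches:
                raise MergeError(f"decision references unknown concept {entry['concept']!r}")
            if len(matches) > 1:
                raise MergeError(
                    f"concept {entry['concept']!r} is ambiguous "
                    f"({len(matches)} items); reference it by variable pair"
                )
        else:
            raise MergeError(f"bad decision entry {entry!r}: needs 'concept' or 'left_var'/'right_var'")
        key = matches[0].pair()
        if key in chosen:
            raise MergeError(f"duplicate decision for item {matches[0].concept!r}")
        chosen[key] = choice

    out = []
    for it in report.items:
        if it.pair() in chosen:
            choice = chosen[it.pair()]
        elif it.kind == "solution_domain":
            choice = "keep_left"
        else:
            choice = "ignore"
        out.append(Resolution(it, choice))
    return out


def load_decisions(path) -> list:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
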