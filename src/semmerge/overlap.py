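"""Detection of the biophysical concepts two annotated models share.

Two variables overlap when their composite annotations are semantically
equivalent: same OPB property and identical entity partonomy chains (entity
properties), same property and role-wise identical participant sets with
equal stoichiometry (process properties), or the same reference term
(singular annotations).  CUSTOM terms never match across models, and
exchanging a process's sources and sinks — the opposite-directionality
formulation of the same process — breaks equivalence.

The temporal solution domains of the two models are always paired: every
model has exactly one, and merging is meaningless without a shared
independent variable.  Manual mappings let the user assert equivalencies
the annotations cannot express (custom terms, granularity mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .annotation import (
    CompositeAnnotation,
    EntityProperty,
    ProcessProperty,
    Singular,
    canonical_key,
    concept_label,
    contains_custom,
)
from .errors import OverlapError
from .model import Model, require_valid
from .units import commensurable, conversion_factor, identical

KINDS = ("entity_property", "process_property", "singular", "solution_domain")


def annotations_equivalent(
    a: Optional[CompositeAnnotation],
    b: Optional[CompositeAnnotation],
    same_model: bool = False,
) -> bool:
    """Semantic equivalence of two composite annotations.

    Cross-variant comparisons are false.  With ``same_model=False`` (the
    inter-model case) any CUSTOM term on either side blocks equivalence;
    within one model (``same_model=True``) custom terms are compared by
    label.  Process names are ignored: processes match on property and
    participants only.
    """
    if a is None or b is None:
        return False
    if type(a) is not type(b):
        return False
    if not same_model and (contains_custom(a) or contains_custom(b)):
        return False
    if isinstance(a, EntityProperty):
        return a.property.key() == b.property.key() and a.entity.key() == b.entity.key()
    if isinstance(a, ProcessProperty):
        return a.property.key() == b.property.key() and a.participants.key() == b.participants.key()
    if isinstance(a, Singular):
        return a.term.key() == b.term.key()
    return False


def _annotation_kind(a: CompositeAnnotation) -> str:
    if isinstance(a, EntityProperty):
        return "entity_property"
    if isinstance(a, ProcessProperty):
        return "process_property"
    return "singular"


@dataclass(frozen=True)
class OverlapItem:
    """One shared biophysical concept: a variable in each model, plus unit status.

    ``conversion_factor`` converts left-variable values into the right
    variable's units (None when the units are incommensurable).
    """

    concept: str
    kind: str
    left_var: str
    right_var: str
    unit_mismatch: bool
    conversion_factor: Optional[float]
    origin: str  # "auto" | "manual"
    sort_key: str = ""

    def pair(self) -> tuple[str, str]:
        return (self.left_var, self.right_var)

    def to_json(self) -> dict:
        return {
            "concept": self.concept,
            "kind": self.kind,
            "left_var": self.left_var,
            "right_var": self.right_var,
            "unit_mismatch": self.unit_mismatch,
            "conversion_factor": self.conversion_factor,
            "origin": self.origin,
        }


@dataclass
class OverlapReport:
    """The resolution worklist for one (left, right) model pair."""

    left: Model
    right: Model
    items: list[OverlapItem] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "left_model": self.left.name,
            "right_model": self.right.name,
            "items": [it.to_json() for it in self.items],
            "warnings": list(self.warnings),
        }

    def auto_items(self) -> list[OverlapItem]:
        return [it for it in self.items if it.origin == "auto"]

    def find(self, left_var: str, right_var: str) -> Optional[OverlapItem]:
        for it in self.items:
            if it.pair() == (left_var, right_var):
                return it
        return None


def _unit_status(left: Model, lv: str, right: Model, rv: str):
    lu, ru = left.unit_of(lv), right.unit_of(rv)
    if identical(lu, ru):
        return False, 1.0
    if commensurable(lu, ru):
        return True, conversion_factor(lu, ru)
    return True, None


def _annotation_index(model: Model) -> tuple[dict[str, list[str]], dict[str, CompositeAnnotation]]:
    by_key: dict[str, list[str]] = {}
    anns: dict[str, CompositeAnnotation] = {}
    for v in model.variables:
        if v.annotation is None or v.role == "solution_domain":
            continue
        key = canonical_key(v.annotation, scope=model.name)
        by_key.setdefault(key, []).append(v.name)
        anns[v.name] = v.annotation
    return by_key, anns


def find_overlaps(a: Model, b: Model) -> OverlapReport:
    """List every biophysical concept shared by two valid annotated models.

    One auto item per pair of variables with equivalent annotations, plus
    exactly one solution-domain item.  Within-model duplicate annotations
    (two variables with the same canonical key) are reported as warnings and
    excluded from automatic pairing.
    """
    require_valid(a)
    require_valid(b)
    report = OverlapReport(left=a, right=b)
    same_model = a.name == b.name

    left_index, left_anns = _annotation_index(a)
    right_index, _ = _annotation_index(b)

    ambiguous: set[str] = set()
    for side, index, model in (("left", left_index, a), ("right", right_index, b)):
        for key, names in index.items():
            if len(names) > 1:
                ambiguous.add(key)
                report.warnings.append(
                    f"duplicate annotation in {side} model {model.name!r}: "
                    f"variables {sorted(names)} share one annotation; excluded from automatic pairing"
                )

    items: list[OverlapItem] = []
    for key, left_names in left_index.items():
        if key in ambiguous or key not in right_index:
            continue
        (lv,), (rv,) = left_names, right_index[key]
        ann = left_anns[lv]
        mismatch, factor = _unit_status(a, lv, b, rv)
        items.append(OverlapItem(
            concept=concept_label(ann),
            kind=_annotation_kind(ann),
            left_var=lv,
            right_var=rv,
            unit_mismatch=mismatch,
            conversion_factor=factor,
            origin="auto",
            sort_key=key,
        ))
    del same_model  # cross-model custom scoping is handled by canonical_key scope

    items.sort(key=lambda it: (it.sort_key, it.left_var, it.right_var))

    # the two temporal solution domains are always paired
    mismatch, factor = _unit_status(a, a.solution_domain, b, b.solution_domain)
    domain_item = OverlapItem(
        concept="Temporal solution domain",
        kind="solution_domain",
        left_var=a.solution_domain,
        right_var=b.solution_domain,
        unit_mismatch=mismatch,
        conversion_factor=factor,
        origin="auto",
        sort_key="",
    )
    report.items = [domain_item] + items
    return report


def add_manual_mapping(report: OverlapReport, left_var: str, right_var: str) -> OverlapReport:
    """Assert an equivalency the annotations could not establish.

    The pair's unit compatibility is computed like any auto item; the
    annotations need not match (custom terms, granularity differences).
    Rejects unknown variables and pairs already present in the report.
    """
    if not report.left.has(left_var):
        raise OverlapError(f"left model {report.left.name!r} has no variable {left_var!r}")
    if not report.right.has(right_var):
        raise OverlapError(f"right model {report.right.name!r} has no variable {right_var!r}")
    existing = report.find(left_var, right_var)
    if existing is not None:
        raise OverlapError(
            f"pair ({left_var!r}, {right_var!r}) is already an {existing.origin} item of this report"
        )
    ann = report.left.get(left_var).annotation
    kind = _annotation_kind(ann) if ann is not None else "entity_property"
    label = concept_label(ann) if ann is not None else f"{left_var} <-> {right_var}"
    mismatch, factor = _unit_status(report.left, left_var, report.right, right_var)
    item = OverlapItem(
        concept=label,
        kind=kind,
        left_var=left_var,
        right_var=right_var,
        unit_mismatch=mismatch,
        conversion_factor=factor,
        origin="manual",
        sort_key=f"manual|{left_var}|{right_var}",
    )
    return replace(report, items=report.items + [item])


def brute_force_overlap_pairs(a: Model, b: Model) -> set[tuple[str, str]]:
    """Independent O(n*m) oracle: all variable pairs with equivalent annotations.

    Pairs involved in within-model duplicate annotations are excluded, as in
    :func:`find_overlaps`.  Used by the test suite to cross-check the indexed
    implementation; not part of the production path.
    """
    require_valid(a)
    require_valid(b)
    same_model = a.name == b.name

    def annotated(m: Model):
        return [v for v in m.variables if v.annotation is not None and v.role != "solution_domain"]

    def dup_names(m: Model) -> set[str]:
        out = set()
        vs = annotated(m)
        for i, v in enumerate(vs):
            for w in vs[i + 1:]:
                if annotations_equivalent(v.annotation, w.annotation, same_model=True):
                    out.update((v.name, w.name))
        return out

    skip_a, skip_b = dup_names(a), dup_names(b)
    pairs = set()
    for va in annotated(a):
        if va.name in skip_a:
            continue
        for vb in annotated(b):
            if vb.name in skip_b:
                continue
            if annotations_equivalent(va.annotation, vb.annotation, same_model=same_model):
                pairs.add((va.name, vb.name))
    return pairs
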