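"""Composite semantic annotations.

A composite annotation is a machine-readable statement of what a model
variable *means* biologically, assembled from reference-ontology terms:

* ``EntityProperty`` — a physical property (an OPB term such as chemical
  concentration) borne by a physical entity described as a partonomy chain,
  e.g. concentration of calcium(2+), part of the cytosol, part of a cardiac
  myocyte.  Position 0 of the chain bears the property.
* ``ProcessProperty`` — a rate property (current, molar flow, ...) of a
  named physical process, with the participating entities designated as
  thermodynamic sources (consumed), sinks (produced) or mediators
  (influencing without consumption), each source/sink with a stoichiometric
  multiplier.
* ``Singular`` — a single reference term for widely used constitutive
  constants (Faraday's constant, the universal gas constant).

Terms from reference ontologies are compared by (ontology, id).  ``CUSTOM``
terms — coined by an annotator when no reference term exists — carry meaning
only inside their own model: they are compared by label within a model and
never match across models, which is exactly why custom-term annotations
block automatic overlap detection and must be bridged by manual mappings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

from .errors import AnnotationError

ONTOLOGIES = ("OPB", "FMA", "MA", "CL", "GO", "PR", "CHEBI", "OBI", "CUSTOM")


@dataclass(frozen=True)
class TermRef:
    """A reference into a knowledge resource (or a model-local CUSTOM term)."""

    ontology: str
    id: str
    label: str

    def __post_init__(self) -> None:
        if self.ontology not in ONTOLOGIES:
            raise AnnotationError(f"unknown ontology {self.ontology!r} (expected one of {ONTOLOGIES})")
        if self.ontology == "CUSTOM":
            if not self.label:
                raise AnnotationError("CUSTOM terms must carry a non-empty label")
        elif not self.id:
            raise AnnotationError(f"reference term from {self.ontology} must carry a non-empty id")

    @property
    def is_custom(self) -> bool:
        return self.ontology == "CUSTOM"

    def key(self) -> tuple[str, str]:
        """Identity used for matching: (ontology, id), or the label for CUSTOM."""
        return ("CUSTOM", self.label) if self.is_custom else (self.ontology, self.id)

    def to_json(self) -> dict:
        return {"ontology": self.ontology, "id": self.id, "label": self.label}

    @classmethod
    def from_json(cls, obj: Mapping) -> "TermRef":
        return cls(obj.get("ontology", ""), obj.get("id", ""), obj.get("label", ""))


@dataclass(frozen=True)
class EntityComposite:
    """A partonomy chain; chain[i] is part of chain[i+1], chain[0] bears the property."""

    chain: tuple[TermRef, ...]

    def __post_init__(self) -> None:
        if not self.chain:
            raise AnnotationError("entity partonomy chain must be non-empty")

    @property
    def contains_custom(self) -> bool:
        return any(t.is_custom for t in self.chain)

    def key(self) -> tuple:
        return tuple(t.key() for t in self.chain)

    def to_json(self) -> list:
        return [t.to_json() for t in self.chain]

    @classmethod
    def from_json(cls, obj: Sequence) -> "EntityComposite":
        return cls(tuple(TermRef.from_json(t) for t in obj))


def entity(*terms: TermRef) -> EntityComposite:
    """Convenience constructor for a partonomy chain."""
    return EntityComposite(tuple(terms))


@dataclass(frozen=True)
class ProcessParticipants:
    """Source/sink/mediator entity sets of a physical process.

    Sources and sinks carry stoichiometric multipliers; the three role sets
    must be pairwise disjoint under entity identity.
    """

    sources: tuple[tuple[EntityComposite, float], ...] = ()
    sinks: tuple[tuple[EntityComposite, float], ...] = ()
    mediators: tuple[EntityComposite, ...] = ()

    def __post_init__(self) -> None:
        for role in (self.sources, self.sinks):
            for _, mult in role:
                if not mult > 0:
                    raise AnnotationError("participant multipliers must be positive")
        src = {e.key() for e, _ in self.sources}
        snk = {e.key() for e, _ in self.sinks}
        med = {e.key() for e in self.mediators}
        if len(src) != len(self.sources) or len(snk) != len(self.sinks) or len(med) != len(self.mediators):
            raise AnnotationError("duplicate participant within a role set")
        overlap = (src & snk) | (src & med) | (snk & med)
        if overlap:
            raise AnnotationError(f"participant roles must be disjoint; shared entities: {sorted(overlap)}")

    @property
    def contains_custom(self) -> bool:
        return (
            any(e.contains_custom for e, _ in self.sources)
            or any(e.contains_custom for e, _ in self.sinks)
            or any(e.contains_custom for e in self.mediators)
        )

    def key(self) -> tuple:
        srcs = tuple(sorted((e.key(), repr(m)) for e, m in self.sources))
        snks = tuple(sorted((e.key(), repr(m)) for e, m in self.sinks))
        meds = tuple(sorted(e.key() for e in self.mediators))
        return (srcs, snks, meds)

    def swapped(self) -> "ProcessParticipants":
        """Sources and sinks exchanged (the opposite-directionality process)."""
        return ProcessParticipants(self.sinks, self.sources, self.mediators)

    def to_json(self) -> dict:
        return {
            "sources": [{"entity": e.to_json(), "multiplier": m} for e, m in self.sources],
            "sinks": [{"entity": e.to_json(), "multiplier": m} for e, m in self.sinks],
            "mediators": [{"entity": e.to_json()} for e in self.mediators],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "ProcessParticipants":
        def pairs(items: Iterable) -> tuple:
            return tuple(
                (EntityComposite.from_json(it["entity"]), float(it.get("multiplier", 1)))
                for it in items
            )

        return cls(
            sources=pairs(obj.get("sources", ())),
            sinks=pairs(obj.get("sinks", ())),
            mediators=tuple(EntityComposite.from_json(it["entity"]) for it in obj.get("mediators", ())),
        )


def _require_opb(property: TermRef, what: str) -> None:
    if property.ontology != "OPB":
        raise AnnotationError(f"{what} property term must come from OPB, got {property.ontology}")


@dataclass(frozen=True)
class EntityProperty:
    property: TermRef
    entity: EntityComposite

    def __post_init__(self) -> None:
        _require_opb(self.property, "entity")

    @property
    def contains_custom(self) -> bool:
        return self.entity.contains_custom


@dataclass(frozen=True)
class ProcessProperty:
    property: TermRef
    process_name: str
    participants: ProcessParticipants = field(default_factory=ProcessParticipants)

    def __post_init__(self) -> None:
        _require_opb(self.property, "process")

    @property
    def contains_custom(self) -> bool:
        return self.participants.contains_custom


@dataclass(frozen=True)
class Singular:
    term: TermRef

    @property
    def contains_custom(self) -> bool:
        return self.term.is_custom


CompositeAnnotation = Union[EntityProperty, ProcessProperty, Singular]


def build_entity_annotation(property: TermRef, chain: Sequence[TermRef]) -> EntityProperty:
    """Attach an OPB property term to a partonomy chain of physical entities."""
    if not chain:
        raise AnnotationError("entity partonomy chain must be non-empty")
    return EntityProperty(property=property, entity=EntityComposite(tuple(chain)))


def build_process_annotation(
    property: TermRef,
    process_name: str,
    sources: Sequence[tuple[EntityComposite, float]] = (),
    sinks: Sequence[tuple[EntityComposite, float]] = (),
    mediators: Sequence[EntityComposite] = (),
) -> ProcessProperty:
    return ProcessProperty(
        property=property,
        process_name=process_name,
        participants=ProcessParticipants(tuple(sources), tuple(sinks), tuple(mediators)),
    )


def contains_custom(a: CompositeAnnotation) -> bool:
    return a.contains_custom


# ---------------------------------------------------------------------------
# canonical keys

def canonical_key(a: CompositeAnnotation, scope: str | None = None) -> str:
    """Deterministic text encoding of an annotation's matchable content.

    For annotations free of CUSTOM terms, two annotations receive the same
    key iff they are semantically equivalent: the process name is excluded
    (processes match on property + participants), term labels of reference
    terms are excluded (matching is by ontology id), and participant role
    sets are order-insensitive but role-sensitive, so swapping sources and
    sinks changes the key.

    Annotations containing CUSTOM terms are scoped: the key embeds ``scope``
    (conventionally the model name), so such annotations can never match
    across models.  Within one model, equal-label custom content yields equal
    keys, feeding the within-model duplicate warning path.
    """
    if isinstance(a, EntityProperty):
        body = ["entity_property", a.property.key(), a.entity.key()]
    elif isinstance(a, ProcessProperty):
        body = ["process_property", a.property.key(), a.participants.key()]
    elif isinstance(a, Singular):
        body = ["singular", a.term.key()]
    else:
        raise AnnotationError(f"not a composite annotation: {a!r}")
    encoded = json.dumps(body, separators=(",", ":"), default=list)
    if contains_custom(a):
        return f"custom|{scope}|{encoded}"
    return encoded


def concept_label(a: CompositeAnnotation | None) -> str:
    """Human-readable rendering used in overlap reports and merge logs."""
    if a is None:
        return "(unannotated)"
    if isinstance(a, EntityProperty):
        chain = " in ".join(t.label or t.id for t in a.entity.chain)
        return f"{a.property.label} of {chain}"
    if isinstance(a, ProcessProperty):
        return f"{a.property.label} ({a.process_name})"
    return a.term.label or a.term.id


# ---------------------------------------------------------------------------
# serialization

def annotation_to_json(a: CompositeAnnotation) -> dict:
    if isinstance(a, EntityProperty):
        return {
            "type": "entity_property",
            "property": a.property.to_json(),
            "entity": a.entity.to_json(),
        }
    if isinstance(a, ProcessProperty):
        out = {
            "type": "process_property",
            "property": a.property.to_json(),
            "process": a.process_name,
        }
        out.update(a.participants.to_json())
        return out
    if isinstance(a, Singular):
        return {"type": "singular", "term": a.term.to_json()}
    raise AnnotationError(f"not a composite annotation: {a!r}")


def annotation_from_json(obj: Mapping) -> CompositeAnnotation:
    kind = obj.get("type")
    if kind == "entity_property":
        return EntityProperty(
            property=TermRef.from_json(obj["property"]),
            entity=EntityComposite.from_json(obj["entity"]),
        )
    if kind == "process_property":
        return ProcessProperty(
            property=TermRef.from_json(obj["property"]),
            process_name=obj.get("process", ""),
            participants=ProcessParticipants.from_json(obj),
        )
    if kind == "singular":
        return Singular(term=TermRef.from_json(obj["term"]))
    raise AnnotationError(f"unknown annotation type {kind!r}")


# ---------------------------------------------------------------------------
# annotation transfer between models with shared variable names

@dataclass
class TransferReport:
    transferred: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "transferred": list(self.transferred),
            "skipped": list(self.skipped),
            "unmatched": list(self.unmatched),
        }


def transfer_annotations(source, target):
    """Copy annotations from ``source`` onto same-named variables of ``target``.

    Unannotated target variables whose name matches an annotated source
    variable receive a copy of that annotation; target variables that already
    carry an annotation are skipped.  Returns ``(new_target, TransferReport)``;
    idempotent by construction.  This is the mechanism for propagating a
    curated annotation set onto a parameter variant of the same model (e.g.
    an epicardial re-parameterisation of an endocardial cell model).
    """
    from .model import Model  # local import to avoid a cycle

    if not isinstance(target, Model) or not isinstance(source, Model):
        raise AnnotationError("transfer_annotations expects two models")
    report = TransferReport()
    target_map = {v.name: v for v in target.variables}
    new_vars = list(target.variables)
    index = {v.name: i for i, v in enumerate(new_vars)}
    for sv in source.variables:
        if sv.annotation is None:
            continue
        tv = target_map.get(sv.name)
        if tv is None:
            report.unmatched.append(sv.name)
        elif tv.annotation is not None:
            report.skipped.append(sv.name)
        else:
            new_vars[index[sv.name]] = replace(tv, annotation=sv.annotation)
            report.transferred.append(sv.name)
    return replace(target, variables=tuple(new_vars)), report
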