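"""Minimal multiplicative unit system.

A unit is a vector of integer exponents over the seven SI base dimensions
plus a positive rational scale to coherent base units.  Two units are
commensurable when their dimension vectors agree; conversion between
commensurable units is a pure ratio of scales (no affine offsets, so
substituting ``factor * x`` for a variable is always linear).

Scales are held internally as exact :class:`fractions.Fraction` values parsed
from decimal text, so conversions between decimal-scaled units (microlitre to
cubic micrometre, nanoamp to amp, ...) are exact in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction
from typing import Mapping, Union

from .errors import UnitError

#: Canonical ordering of the SI base dimensions.
BASE_DIMENSIONS = ("metre", "kilogram", "second", "ampere", "kelvin", "mole", "candela")

ScaleLike = Union[int, float, str, Fraction, Decimal]


def _as_fraction(scale: ScaleLike) -> Fraction:
    """Convert a scale to an exact Fraction via its decimal text form."""
    if isinstance(scale, Fraction):
        return scale
    if isinstance(scale, (int, Decimal)):
        return Fraction(scale)
    if isinstance(scale, float):
        # repr() gives the shortest decimal that round-trips; Decimal of that
        # text keeps 1e-9 meaning exactly 10^-9 rather than the nearest double.
        return Fraction(Decimal(repr(scale)))
    if isinstance(scale, str):
        return Fraction(Decimal(scale))
    raise UnitError(f"cannot interpret unit scale {scale!r}")


@dataclass(frozen=True)
class UnitDef:
    """A named unit: dimension exponents plus a multiplicative scale.

    ``dims`` is stored as a 7-tuple of integer exponents ordered as
    :data:`BASE_DIMENSIONS`; construct with :meth:`make` to pass a sparse
    mapping instead.
    """

    name: str
    dims: tuple[int, ...]
    scale: Fraction

    def __post_init__(self) -> None:
        if len(self.dims) != len(BASE_DIMENSIONS):
            raise UnitError(f"unit {self.name!r}: expected {len(BASE_DIMENSIONS)} dimension exponents")
        if not all(isinstance(d, int) for d in self.dims):
            raise UnitError(f"unit {self.name!r}: dimension exponents must be integers")
        if self.scale <= 0:
            raise UnitError(f"unit {self.name!r}: scale must be positive")

    @classmethod
    def make(cls, name: str, dims: Mapping[str, int] | None = None, scale: ScaleLike = 1) -> "UnitDef":
        dims = dict(dims or {})
        unknown = set(dims) - set(BASE_DIMENSIONS)
        if unknown:
            raise UnitError(f"unit {name!r}: unknown base dimensions {sorted(unknown)}")
        vec = tuple(int(dims.get(d, 0)) for d in BASE_DIMENSIONS)
        return cls(name=name, dims=vec, scale=_as_fraction(scale))

    def dim_map(self) -> dict[str, int]:
        """Sparse {dimension: exponent} mapping (zeros omitted)."""
        return {d: e for d, e in zip(BASE_DIMENSIONS, self.dims) if e != 0}

    def to_json(self) -> dict:
        return {"dims": self.dim_map(), "scale": float(self.scale)}

    @classmethod
    def from_json(cls, name: str, obj: Mapping) -> "UnitDef":
        if not isinstance(obj, Mapping) or "scale" not in obj:
            raise UnitError(f"unit {name!r}: expected an object with 'dims' and 'scale'")
        return cls.make(name, obj.get("dims", {}), obj["scale"])


def commensurable(a: UnitDef, b: UnitDef) -> bool:
    """True iff the two units share a dimension vector."""
    return a.dims == b.dims


def conversion_factor(from_unit: UnitDef, to_unit: UnitDef) -> float:
    """Factor ``c`` with ``value_in_to = c * value_in_from``.

    Raises :class:`UnitError` on incommensurable units, naming both
    dimension vectors.
    """
    if not commensurable(from_unit, to_unit):
        raise UnitError(
            f"units {from_unit.name!r} {from_unit.dim_map()} and "
            f"{to_unit.name!r} {to_unit.dim_map()} are not commensurable"
        )
    return float(from_unit.scale / to_unit.scale)


def identical(a: UnitDef, b: UnitDef) -> bool:
    """Same dimensions and same scale (names may differ)."""
    return a.dims == b.dims and a.scale == b.scale


def _catalog() -> dict[str, UnitDef]:
    u = UnitDef.make
    entries = [
        u("dimensionless"),
        u("second", {"second": 1}),
        u("millisecond", {"second": 1}, "1e-3"),
        u("ampere", {"ampere": 1}),
        u("nanoamp", {"ampere": 1}, "1e-9"),
        u("volt", {"kilogram": 1, "metre": 2, "second": -3, "ampere": -1}),
        u("millivolt", {"kilogram": 1, "metre": 2, "second": -3, "ampere": -1}, "1e-3"),
        u("litre", {"metre": 3}, "1e-3"),
        u("microlitre", {"metre": 3}, "1e-9"),
        u("cubic_micrometre", {"metre": 3}, "1e-18"),
        u("mole", {"mole": 1}),
        u("molar", {"mole": 1, "metre": -3}, "1e3"),
        u("millimolar", {"mole": 1, "metre": -3}),
        u("millimolar_per_second", {"mole": 1, "metre": -3, "second": -1}),
        u("kelvin", {"kelvin": 1}),
        u("coulomb_per_mole", {"ampere": 1, "second": 1, "mole": -1}),
    ]
    return {e.name: e for e in entries}


#: Built-in unit catalog available to every model; models may extend it with
#: their own ``units`` table (model-local names shadow the catalog).
BUILTIN_UNITS: dict[str, UnitDef] = _catalog()
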