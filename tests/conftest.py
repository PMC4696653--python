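import pytest

from semmerge import Model, Variable
from semmerge import fixtures as fx


@pytest.fixture(scope="session")
def suite():
    """The deterministic fixture suite (built once per test session)."""
    return fx.generate_suite()


@pytest.fixture()
def decay_model():
    """dx/dt = -k x, x(0) = 1 — the closed-form integration benchmark."""
    return Model(
        name="decay",
        solution_domain="t",
        variables=(
            Variable.domain("t", "second"),
            Variable.constant("k", "dimensionless", 0.5),
            Variable.state("x", "dimensionless", "-(k * x)", 1.0),
        ),
    )


def trajectories_close(left, right, names, rel=None, abs_tol=None, rename=None):
    """Max deviation between two trajectories on the given columns."""
    rename = rename or {}
    worst = 0.0
    for name in names:
        a = left.column(name)
        b = right.column(rename.get(name, name))
        for x, y in zip(a, b):
            if rel is not None:
                worst = max(worst, abs(x - y) / max(1e-300, abs(x), abs(y)))
            else:
                worst = max(worst, abs(x - y))
    if rel is not None:
        assert worst <= rel, f"relative deviation {worst} exceeds {rel}"
    if abs_tol is not None:
        assert worst <= abs_tol, f"absolute deviation {worst} exceeds {abs_tol}"
    return worst
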