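import pytest
from hypothesis import HealthCheck, settings

from dfmscreen.fuzzy import (
    LinguisticTerm,
    LinguisticVariable,
    MembershipFunction,
    SymbolTable,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def low_high_terms(universe=(0.0, 1.0)):
    lo, hi = universe
    mid = (lo + hi) / 2.0
    return (
        LinguisticTerm("low", MembershipFunction("triangular", (lo, lo, mid), universe), lo),
        LinguisticTerm("high", MembershipFunction("triangular", (mid, hi, hi), universe), hi),
    )


def make_variable(name, role="inner", initial=0.0, **kwargs):
    return LinguisticVariable(name, role, low_high_terms(), initial=initial, **kwargs)


@pytest.fixture
def abc_symbols():
    """Three inner variables A, B, C with standard low/high terms."""
    return SymbolTable([make_variable(n) for n in "ABC"])
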