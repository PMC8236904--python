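import logging

import numpy as np
import pytest

from invivokin import EnzymeParams, TwoEnzymeChain

logging.getLogger("invivokin").setLevel(logging.ERROR)


@pytest.fixture
def mm_chain():
    """Irreversible MM chain with A=20, B=20, C=1."""
    return TwoEnzymeChain(
        upstream=EnzymeParams(e_total=1.0, k_cat=1.0, k_m=10.0),
        downstream=EnzymeParams(e_total=1.0, k_cat=2.0, k_m=20.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def flux_balance_bisect(chain: TwoEnzymeChain, s1: float, tol: float = 1e-13) -> float:
    """Independent steady-state oracle: bisection on v1(s1) = v2(s2).

    Uses nothing from the closed-form path: rates are evaluated from the
    raw MM expression and S2 is bracketed and bisected directly.
    """
    up, down = chain.upstream, chain.downstream
    v1 = up.vmax * s1 / (up.k_m + s1)
    if v1 >= down.vmax:
        raise RuntimeError("no steady state: upstream flux >= downstream capacity")
    lo, hi = 0.0, down.k_m
    while down.vmax * hi / (down.k_m + hi) < v1:
        hi *= 2.0
    while hi - lo > tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if down.vmax * mid / (down.k_m + mid) < v1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
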