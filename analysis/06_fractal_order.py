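"""Fractal kinetics: diffusion limitation raises the effective order.

Simulates the decay of a dimerisation whose rate "constant" decays as
k0*t**(-h), then re-estimates the effective reaction order alpha from the
late-time trace by regressing ln(rate) on ln(concentration).  The
recovered orders match alpha = 2 + h/(1-h): already at h = 0.5 a
bimolecular step behaves as third order.  This is the formal basis for
reading the in vivo Hill exponent of ~2.5 as diffusion limitation of the
substrate (e.g. inside a metabolon) rather than allostery.

Writes results/fractal_orders.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from invivokin import FractalParams, effective_order_from_trace, fractal_decay_numeric

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for h in (0.0, 0.2, 0.5, 0.7):
        params = FractalParams(k0=1.0, h=h)
        trace = fractal_decay_numeric(1e4, params, np.geomspace(1e-6, 1e6, 4000))
        alpha_hat = effective_order_from_trace(trace)
        rows.append(
            {
                "h": h,
                "alpha_theory": params.alpha,
                "alpha_estimated": alpha_hat,
                "k_star": params.k_star,
            }
        )
        print(
            f"h = {h}: alpha = {params.alpha:.3f}, "
            f"estimated from trace = {alpha_hat:.3f}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "fractal_orders.csv", index=False)


if __name__ == "__main__":
    main()
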