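"""Brute-force filter/sort oracle and toy-grid builder shared by tests.

Kept independent of the optimizer implementation: plain python loops and
``min`` with explicit sort keys.
"""

import numpy as np
import pandas as pd

NUMERIC_TOL = 1e-9


def toy_table(seed):
    """Randomised toy grid table with hand-scale factorial structure."""
    rng = np.random.default_rng(seed)
    rows = [
        {
            "usage": "joint",
            "c1": c1,
            "c2": c2,
            "lifespan": l,
            "price": float(np.round(rng.uniform(1, 5), 2)),
            "coverage": float(rng.choice([0.3, 0.7, 1.0])),
            "avg_control": float(np.round(rng.random(), 3)),
            "start_bioefficacy": float(np.round(rng.random(), 3)),
            "end_bioefficacy": 0.5,
            "relative_change": 0.5,
            "mean_steps1_end": 1.0,
            "mean_steps2_end": 1.0,
        }
        for c1 in (0.0, 0.5, 1.0)
        for c2 in (0.0, 0.5, 1.0)
        for l in (1.0, 2.0, 3.0)
    ]
    return pd.DataFrame(rows)


def brute_force(table, code, who=0.8):
    """Exhaustive filter-and-sort selection for one optimality criterion."""
    rows = [r for _, r in table.iterrows()]
    if code in ("CW", "MW"):
        rows = [
            r
            for r in rows
            if np.isclose(r.lifespan, 3.0) and r.start_bioefficacy > who - NUMERIC_TOL
        ]
    if code == "UC":
        rows = [r for r in rows if r.coverage >= 1.0 - NUMERIC_TOL]
    if not rows:
        return None
    keys = {
        "CW": lambda r: (r.price, -r.avg_control, r.c1, r.c2),
        "MC": lambda r: (-r.avg_control, r.price, r.c1, r.c2, r.lifespan),
        "MW": lambda r: (-r.avg_control, r.price, r.c1, r.c2),
        "UC": lambda r: (-r.avg_control, r.price, r.c1, r.c2, r.lifespan),
    }
    return min(rows, key=keys[code])
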