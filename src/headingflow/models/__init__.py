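"""Four heading-estimation models sharing one call convention.

``get_model(name, resolution)`` returns a callable ``model(field, rng=None)
-> HeadingEstimate``.  The resolution parameter (deg) sets the candidate
grid / template grid / column width for hj92, p92 and wc99; lhp80 has no
resolution parameter and ignores it.
"""

from __future__ import annotations

from functools import partial

import numpy as np

from .hj92 import (CandidateGrid, build_candidate_grid, constraint_basis,
                   estimate_heading_hj92, residual_hj92)
from .lhp80 import (DifferenceLine, ProximalPair, difference_lines,
                    estimate_foe_lhp80, estimate_heading_lhp80,
                    select_proximal_pairs)
from .p92 import (TemplateBank, build_template_bank, estimate_heading_p92,
                  template_activation)
from .wc99 import (ConvergenceParams, HeadingColumns, build_columns,
                   classify_pair, estimate_heading_wc99, update_posterior)

MODEL_NAMES = ("lhp80", "p92", "hj92", "wc99")


def get_model(name: str, resolution: float = 1.0, **kwargs):
    """Build a ``model(field, rng=None) -> HeadingEstimate`` callable."""
    name = name.lower()
    if name == "lhp80":
        def run(field, rng=None, _kw=kwargs):
            return estimate_heading_lhp80(field, **_kw)
    elif name == "p92":
        bank = build_template_bank(resolution=resolution, **kwargs)

        def run(field, rng=None, _bank=bank):
            return estimate_heading_p92(_bank, field)
    elif name == "hj92":
        grid = build_candidate_grid(resolution=resolution)

        def run(field, rng=None, _grid=grid):
            return estimate_heading_hj92(field, _grid)
    elif name == "wc99":
        cols = build_columns(width=resolution)

        def run(field, rng=None, _cols=cols, _kw=kwargs):
            return estimate_heading_wc99(field, _cols, rng=rng, **_kw)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    run.__name__ = f"model_{name}"
    return run


__all__ = [
    "MODEL_NAMES", "get_model",
    "CandidateGrid", "build_candidate_grid", "constraint_basis",
    "estimate_heading_hj92", "residual_hj92",
    "DifferenceLine", "ProximalPair", "difference_lines",
    "estimate_foe_lhp80", "estimate_heading_lhp80", "select_proximal_pairs",
    "TemplateBank", "build_template_bank", "estimate_heading_p92",
    "template_activation",
    "ConvergenceParams", "HeadingColumns", "build_columns", "classify_pair",
    "estimate_heading_wc99", "update_posterior",
]
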