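"""Built-in expert impact matrices for the worked example.

Two consensus expert-judgement matrices on the 0-3 impact scale, one for
the five economic indicator variables and one for the five social-climate
variables.  Cell (i, j) is the judged strength of the direct impact of
variable i on variable j (0 none .. 3 huge); they are the standard inputs
for the DEMATEL worked examples and acceptance checks in this package.
"""

from __future__ import annotations

import numpy as np

from .dematel import ImpactMatrix

__all__ = [
    "ECONOMIC_LABELS",
    "SOCIAL_LABELS",
    "economic_impact_matrix",
    "social_impact_matrix",
]

# the labour-market variable is measured as the registered unemployment rate
ECONOMIC_LABELS = ("gdp", "remuneration", "inflation", "unemployment", "budget_deficit")

SOCIAL_LABELS = (
    "system_assessment",
    "monetary_availability",
    "social_capital",
    "sense_of_threat",
    "sense_of_wealth",
)

_ECONOMIC_CELLS = np.array(
    [
        [0, 2, 1, 3, 2],
        [2, 0, 3, 2, 1],
        [2, 2, 0, 2, 1],
        [3, 3, 1, 0, 1],
        [1, 0, 2, 1, 0],
    ]
)

_SOCIAL_CELLS = np.array(
    [
        [0, 1, 2, 3, 2],
        [0, 0, 2, 3, 3],
        [3, 2, 0, 3, 2],
        [3, 2, 2, 0, 2],
        [1, 3, 1, 3, 0],
    ]
)


def economic_impact_matrix() -> ImpactMatrix:
    """Expert impact matrix for the five economic KPI variables."""
    return ImpactMatrix(labels=ECONOMIC_LABELS, cells=_ECONOMIC_CELLS.copy())


def social_impact_matrix() -> ImpactMatrix:
    """Expert impact matrix for the five social KPI variables."""
    return ImpactMatrix(labels=SOCIAL_LABELS, cells=_SOCIAL_CELLS.copy())
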