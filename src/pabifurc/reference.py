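"""Published reference fixtures: worked score examples and enrolment flow.

These are the printed inputs of the source study, packaged so the score
formula and the exclusion accounting can be exercised without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from pabifurc.risk_model import PUBLISHED_FORMULA

__all__ = [
    "published_worked_examples",
    "EnrollmentFlow",
    "apply_exclusions",
    "PUBLISHED_ENROLLMENT_TOTAL",
    "PUBLISHED_EXCLUSION_COUNTS",
]

# per worked case: (bifurcation area, outlet hydraulic diameter, outlet CSA)
# in scaled units, with the printed two-decimal score
_WORKED_CASES = [
    ("B", 0.84, 2.94, 7.68, 3.01),
    ("C", 5.78, 3.40, 13.04, 8.32),
    ("D", 0.79, 2.88, 6.74, 2.84),
    ("E", 4.07, 4.15, 15.04, 7.32),
    ("F", 0.88, 2.76, 9.34, 3.12),
    ("G", 5.57, 3.45, 11.72, 8.02),
]


def published_worked_examples() -> pd.DataFrame:
    """Six printed worked measurement cases with their expected scores."""
    rows = []
    for case, area, dh, csa_, expected in _WORKED_CASES:
        rows.append(
            {
                "case": case,
                "MPA bifurcation area (100 mm2)": area,
                "MPA outlet hydraulic diameter (10 mm)": dh,
                "MPA outlet CSA (100 mm2)": csa_,
                "expected_score": expected,
            }
        )
    return pd.DataFrame(rows)


PUBLISHED_ENROLLMENT_TOTAL = 391
PUBLISHED_EXCLUSION_COUNTS = (17, 5, 10, 2, 13, 2, 46)


@dataclass
class EnrollmentFlow:
    """Sequential exclusion accounting from an initial record count."""

    initial: int
    steps: List[Tuple[str, int, int]]  # (label, excluded, remaining)

    @property
    def enrolled(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    @property
    def total_excluded(self) -> int:
        return self.initial - self.enrolled


def apply_exclusions(initial: int, exclusions) -> EnrollmentFlow:
    """Apply labelled (or plain-count) exclusions in sequence.

    ``exclusions`` is an iterable of ``(label, count)`` pairs or bare
    counts.  Raises if any step would leave a negative remainder.
    """
    steps = []
    remaining = int(initial)
    for i, item in enumerate(exclusions, start=1):
        if isinstance(item, (tuple, list)):
            label, count = item
        else:
            label, count = f"exclusion_{i}", item
        count = int(count)
        if count < 0:
            raise ValueError(f"negative exclusion count at step {label!r}")
        remaining -= count
        if remaining < 0:
            raise ValueError(f"exclusions exceed available records at {label!r}")
        steps.append((str(label), count, remaining))
    return EnrollmentFlow(initial=int(initial), steps=steps)


def published_enrollment_flow() -> EnrollmentFlow:
    return apply_exclusions(PUBLISHED_ENROLLMENT_TOTAL, PUBLISHED_EXCLUSION_COUNTS)


def published_formula():
    return PUBLISHED_FORMULA
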