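"""Threshold estimation from control runs.

FNT (fluorescence negative threshold) is set from no-template controls as
mean + k*sd of their end-point fluorescence (k = 3 by default, the usual
blank-plus-three-sigma limit-of-blank construction).

RPT (positive ratio threshold) is set per target from the signal ratios of
wild-type-only (0% mutant) runs and 5%-mutant / 95%-wild-type mixture runs:
the threshold is placed at the geometric mean of the largest negative SR and
the smallest 5%-mutant SR.  The geometric midpoint is used because SR is a
ratio; an arithmetic midpoint is available as an option.  Calibration fails
loudly when the two SR distributions overlap — a threshold placed inside
overlapping classes would be meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay_model import MutationTarget


class CalibrationError(ValueError):
    """Insufficient or non-separable calibration data."""


@dataclass
class CalibrationSet:
    """Calibration inputs for one target (one well-channel).

    sr_negative:     SR values from 0%-mutant (wild-type-only) replicates.
    sr_low_mutant:   SR values from 5%-mutant mixture replicates.
    fep_no_template: F(EP) values from no-template controls.
    """

    target: MutationTarget | None = None
    sr_negative: list[float] = field(default_factory=list)
    sr_low_mutant: list[float] = field(default_factory=list)
    fep_no_template: list[float] = field(default_factory=list)


def estimate_fnt(fep_no_template: Sequence[float], k: float = 3.0) -> float:
    """FNT = mean + k*sd (sample sd, ddof=1) of no-template end-point signals."""
    if len(fep_no_template) < 3:
        raise CalibrationError(
            f"need >= 3 no-template controls for FNT, got {len(fep_no_template)}"
        )
    arr = np.asarray(fep_no_template, dtype=float)
    return float(arr.mean() + k * arr.std(ddof=1))


def estimate_rpt(
    cal: CalibrationSet, method: str = "geometric", min_replicates: int = 1
) -> float:
    """Place RPT between the negative and 5%-mutant SR distributions.

    Requires max(sr_negative) < min(sr_low_mutant); otherwise the classes
    overlap and no threshold separates them, which is reported with both
    boundary values.  The returned threshold always lies strictly between the
    two class boundaries.
    """
    if method not in ("geometric", "arithmetic"):
        raise CalibrationError(f"unknown RPT method {method!r}")
    for name, vals in (("sr_negative", cal.sr_negative), ("sr_low_mutant", cal.sr_low_mutant)):
        if len(vals) < max(min_replicates, 1):
            raise CalibrationError(
                f"{name} has {len(vals)} replicates; need >= {max(min_replicates, 1)}"
            )
    hi_neg = max(cal.sr_negative)
    lo_pos = min(cal.sr_low_mutant)
    if hi_neg >= lo_pos:
        raise CalibrationError(
            f"SR distributions overlap: max negative SR {hi_neg:.4g} >= "
            f"min 5%-mutant SR {lo_pos:.4g}; cannot place RPT"
        )
    if method == "geometric":
        if hi_neg <= 0:
            raise CalibrationError("geometric RPT needs positive SR values")
        return math.sqrt(hi_neg * lo_pos)
    return 0.5 * (hi_neg + lo_pos)
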