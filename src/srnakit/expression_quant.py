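"""Stem-loop qPCR arithmetic: relative expression, differential
expression, and primer efficiency."""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target_id: str
    ct_values: tuple[float, ...]
    reference_id: str = "U6"

    def __post_init__(self):
        if not self.ct_values:
            raise ValueError("at least one CT replicate is required")
        if any(ct <= 0 for ct in self.ct_values):
            raise ValueError("CT values must be positive")

    @property
    def mean_ct(self) -> float:
        return statistics.fmean(self.ct_values)

    @property
    def sd_ct(self) -> float:
        return statistics.stdev(self.ct_values) if len(self.ct_values) > 1 else 0.0


def relative_expression(ct_target: float, ct_ref: float) -> float:
    """Expression relative to the internal reference: 2^-(CT_t - CT_ref)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_ref)):
        raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_target - ct_ref)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ddct: float
    sd_fold: float | None = None  # from per-replicate folds
    sd_fold_propagated: float | None = None  # from propagated CT SDs


def fold_change(ct_target_a, ct_ref_a, ct_target_b, ct_ref_b) -> FoldChange:
    """Condition A vs B fold change by 2^-ddCT.

    ddCT = (CT_targetA - CT_refA) - (CT_targetB - CT_refB).  Scalars or
    replicate sequences are accepted; replicate means are taken before
    exponentiation (Livak convention).  The replicate spread is emitted
    two ways, since published +/- ranges do not state their convention:
    the SD of per-replicate folds and the fold SD propagated from CT
    standard deviations.
    """
    groups = [_as_tuple(x) for x in
              (ct_target_a, ct_ref_a, ct_target_b, ct_ref_b)]
    means = [statistics.fmean(g) for g in groups]
    ddct = (means[0] - means[1]) - (means[2] - means[3])
    fold = 2.0 ** -ddct
    sd_fold = sd_prop = None
    if all(len(g) > 1 for g in groups):
        n = min(len(g) for g in groups)
        per_rep = [2.0 ** -((groups[0][i] - groups[1][i])
                            - (groups[2][i] - groups[3][i]))
                   for i in range(n)]
        sd_fold = statistics.stdev(per_rep)
        var_ddct = sum(statistics.variance(g) / len(g) for g in groups)
        sd_prop = fold * math.log(2.0) * math.sqrt(var_ddct)
    return FoldChange(fold=fold, ddct=ddct, sd_fold=sd_fold,
                      sd_fold_propagated=sd_prop)


def _as_tuple(x) -> tuple[float, ...]:
    if isinstance(x, (int, float)):
        return (float(x),)
    t = tuple(float(v) for v in x)
    if not t:
        raise ValueError("empty replicate group")
    return t


def pcr_efficiency(slope: float) -> tuple[float, float]:
    """Amplification factor and percent efficiency from a standard-curve
    slope (cycles per log10 dilution).

    Returns (E, percent) with E = 10^(-1/slope); percent = (E - 1) x 100,
    so a slope of -3.3219 (perfect doubling) gives exactly 100%.
    """
    if not math.isfinite(slope) or slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    e = 10.0 ** (-1.0 / slope)
    return e, (e - 1.0) * 100.0


def efficiency_from_standard_curve(log10_dilutions: Sequence[float],
                                   cts: Sequence[float]) -> tuple[float, float]:
    """Fit CT vs log10(dilution) by least squares and report efficiency."""
    if len(log10_dilutions) != len(cts) or len(cts) < 2:
        raise ValueError("need >= 2 matched (dilution, CT) points")
    xbar = statistics.fmean(log10_dilutions)
    ybar = statistics.fmean(cts)
    num = sum((x - xbar) * (y - ybar)
              for x, y in zip(log10_dilutions, cts))
    den = sum((x - xbar) ** 2 for x in log10_dilutions)
    return pcr_efficiency(num / den)
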