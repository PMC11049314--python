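"""Agreement statistics between two segmentation/volumetry methods.

Mirrors the comparison machinery used to validate automatic lesion volumes
against manual reference segmentations: Pearson correlation, paired t-test,
Bland-Altman limits of agreement, and the Dice overlap coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ParameterError

__all__ = ["ComparisonReport", "dice", "compare_volumes"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks.

    Two empty masks overlap perfectly by convention (returns 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("masks must share a shape")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass(frozen=True)
class ComparisonReport:
    """Paired agreement between method A and method B volume lists (mL)."""

    volumes_a: np.ndarray
    volumes_b: np.ndarray
    pearson_r: float
    pearson_p: float
    paired_t: float
    paired_t_p: float
    mean_difference: float
    loa_low: float
    loa_high: float

    def summary(self) -> str:
        return "\n".join(
            [
                f"paired volumes (n={len(self.volumes_a)})",
                f"  Pearson r = {self.pearson_r:.3f} (p = {self.pearson_p:.3g})",
                f"  paired t = {self.paired_t:.3f} (p = {self.paired_t_p:.3g})",
                f"  Bland-Altman: bias {self.mean_difference:.3f} mL, "
                f"limits [{self.loa_low:.3f}, {self.loa_high:.3f}] mL",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n": int(len(self.volumes_a)),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "paired_t": self.paired_t,
            "paired_t_p": self.paired_t_p,
            "mean_difference": self.mean_difference,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def compare_volumes(a, b) -> ComparisonReport:
    """Pearson r, two-sided paired t-test and Bland-Altman agreement.

    ``a`` and ``b`` are paired volume measurements (same regions, two
    methods).  Limits of agreement are mean difference +/- 1.96 SD of the
    differences (sample SD).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("inputs must be paired 1-D volume lists")
    if len(a) < 3:
        raise ParameterError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ParameterError("correlation undefined for zero-variance input")
    r, rp = stats.pearsonr(a, b)
    t, tp = stats.ttest_rel(a, b)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return ComparisonReport(
        a, b, float(r), float(rp), float(t), float(tp),
        bias, bias - 1.96 * sd, bias + 1.96 * sd,
    )
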