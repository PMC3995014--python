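"""Agreement metrics between segmentations and volume series.

Dice overlap (with resampling of one mask onto the other's grid when
needed), summary statistics over cohorts, Pearson correlation between volume
series, Bland-Altman bias and limits of agreement, OLS regression of Dice on
volume, and interrater/intrarater reliability tables.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .image_io import LabelVolume, matching_grids, resample


@dataclass
class DiceResult:
    dice: float
    intersection: int
    size_a: int
    size_b: int

    def __float__(self):
        return self.dice


def dice(a: LabelVolume, b: LabelVolume, label: int | None = None) -> DiceResult:
    """Dice coefficient 2|A.B| / (|A|+|B|) between two masks.

    If the grids differ, ``b`` is resampled onto ``a``'s grid with
    nearest-neighbour interpolation first.  Two empty masks count as perfect
    agreement (Dice 1); empty versus nonempty is 0.
    """
    if not matching_grids(a, b):
        b = resample(b, a.grid, mode="nearest")
    ma = a.binary(label)
    mb = b.binary(label)
    size_a, size_b = int(ma.sum()), int(mb.sum())
    inter = int((ma & mb).sum())
    if size_a + size_b == 0:
        return DiceResult(1.0, 0, 0, 0)
    return DiceResult(2.0 * inter / (size_a + size_b), inter, size_a, size_b)


@dataclass
class AgreementSummary:
    n: int
    mean_dice: float | None
    sd_dice: float | None
    pearson_r: float | None
    p_one_tailed: float | None           # descriptive only
    bias: float | None                   # mean(a - b)
    loa_low: float | None                # bias - 1.96 SD(diff)
    loa_high: float | None
    dice_slope: float | None             # OLS of Dice on volume a
    dice_intercept: float | None


def agreement_summary(
    dice_values=None,
    volumes_a=None,
    volumes_b=None,
) -> AgreementSummary:
    """Summarize agreement: Dice mean/SD, Pearson r between the two volume
    series, Bland-Altman bias and limits, and the OLS trend of Dice on
    volume.  A constant series makes r undefined and it is reported as
    missing (None), not 0.
    """
    mean_d = sd_d = None
    slope = intercept = None
    if dice_values is not None and len(dice_values):
        dv = np.asarray([float(d) for d in dice_values], dtype=float)
        mean_d = float(dv.mean())
        sd_d = float(dv.std(ddof=1)) if len(dv) > 1 else None
    r = p = bias = lo = hi = None
    n = 0
    if volumes_a is not None and volumes_b is not None:
        va = np.asarray(volumes_a, dtype=float)
        vb = np.asarray(volumes_b, dtype=float)
        if va.shape != vb.shape:
            raise DomainError("volume series must have equal length")
        n = len(va)
        if n >= 2:
            if np.std(va) > 0 and np.std(vb) > 0:
                r_res = stats.pearsonr(va, vb)
                r = float(r_res.statistic)
                two = float(r_res.pvalue)
                p = two / 2.0 if r >= 0 else 1.0 - two / 2.0
            diff = va - vb
            bias = float(diff.mean())
            sd_diff = float(diff.std(ddof=1))
            lo, hi = bias - 1.96 * sd_diff, bias + 1.96 * sd_diff
        if dice_values is not None and len(dice_values) == n and n >= 2 \
                and np.std(va) > 0:
            fit = stats.linregress(va, [float(d) for d in dice_values])
            slope, intercept = float(fit.slope), float(fit.intercept)
    if dice_values is not None:
        n = max(n, len(dice_values))
    return AgreementSummary(n, mean_d, sd_d, r, p, bias, lo, hi, slope, intercept)


def rater_reliability(segmentations: dict) -> pd.DataFrame:
    """Inter- and intrarater Dice from repeated segmentations.

    ``segmentations`` maps ``(rater, repeat, subject)`` to a mask.
    Intrarater Dice compares a rater's repeats of the same subject;
    interrater Dice compares different raters across all repeat pairings.
    Returns one row per subject with pairwise-complete means and counts.
    """
    keys = list(segmentations)
    raters = sorted({k[0] for k in keys})
    repeats = sorted({k[1] for k in keys})
    subjects = sorted({k[2] for k in keys})
    if len(raters) < 2 or len(repeats) < 2:
        raise DomainError("reliability needs >= 2 raters and >= 2 repeats")
    rows = []
    for s in subjects:
        intra, inter = [], []
        for rt in raters:
            for rep1, rep2 in combinations(repeats, 2):
                a = segmentations.get((rt, rep1, s))
                b = segmentations.get((rt, rep2, s))
                if a is not None and b is not None:
                    intra.append(dice(a, b).dice)
        for r1, r2 in combinations(raters, 2):
            for rep1, rep2 in product(repeats, repeats):
                a = segmentations.get((r1, rep1, s))
                b = segmentations.get((r2, rep2, s))
                if a is not None and b is not None:
                    inter.append(dice(a, b).dice)
        rows.append(
            {
                "subject": s,
                "intrarater_dice": float(np.mean(intra)) if intra else np.nan,
                "n_intra": len(intra),
                "interrater_dice": float(np.mean(inter)) if inter else np.nan,
                "n_inter": len(inter),
            }
        )
    return pd.DataFrame(rows)
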