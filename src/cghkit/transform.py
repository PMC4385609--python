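"""MAD-scaled soft-threshold rescaling and ternary gain/loss calling.

Segmented log-ratios from different arrays are made comparable by dividing
out each array's noise scale ``m`` (the "mad1dr": the median absolute
deviation of lag-1 differences of the log-ratios, a standard per-array QC
metric) and suppressing values inside a dead zone of ``tl``/``tg`` MAD
units:

    f(x) = 0                 for -tl*m <= x <= tg*m
    f(x) = (x - tg*m) / m    for x >  tg*m   (gains, positive)
    f(x) = (x + tl*m) / m    for x < -tl*m   (losses, negative)

The transform is continuous, monotone non-decreasing, odd-symmetric when
``tl == tg``, and affine with slope ``1/m`` outside the dead zone.  Its
sign is the ternary gain/loss call: +1 gain, 0 no variation, -1 loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import SegmentMatrix

__all__ = [
    "TransformParams",
    "mad1dr_estimate",
    "soft_threshold",
    "transform_matrix",
    "ternary_call",
]

# MAD -> Gaussian-sigma consistency constant, and 1/sqrt(2) because a lag-1
# difference of iid noise has variance 2*sigma^2.
_MAD_CONSTANT = 1.4826
_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class TransformParams:
    """Per-array rescaling parameters.

    m : noise scale in log-ratio units (mad1dr), > 0
    tl : loss threshold in MAD units, > 0
    tg : gain threshold in MAD units, > 0
    """

    m: float
    tl: float = 2.0
    tg: float = 2.0

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError(f"m must be > 0, got {self.m}")
        if not (self.tl > 0 and self.tg > 0):
            raise ValueError(f"thresholds must be > 0, got tl={self.tl}, tg={self.tg}")


def mad1dr_estimate(
    values: Sequence[float] | np.ndarray,
    chroms: Sequence[str] | None = None,
) -> float:
    """Estimate the per-array noise scale from lag-1 differences.

    ``m = 1.4826 * median(|d - median(d)|) / sqrt(2)`` where ``d`` are the
    lag-1 differences of ``values`` taken within each chromosome (so that
    real breakpoints between chromosomes do not inflate the estimate).
    Vendors report this quantity directly; pass it to
    :class:`TransformParams` instead when available.

    Parameters
    ----------
    values : array-like
        Probe- or segment-level log-ratios in genomic order.
    chroms : sequence of str, optional
        Chromosome of each value; differences are only taken between
        consecutive values on the same chromosome.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 3:
        raise ValueError("need at least 3 values in genomic order")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if chroms is None:
        diffs = np.diff(values)
    else:
        if len(chroms) != values.size:
            raise ValueError("chroms length must match values")
        same = np.array([chroms[i] == chroms[i + 1] for i in range(len(chroms) - 1)])
        diffs = np.diff(values)[same]
    if diffs.size < 2:
        raise ValueError("need at least 2 within-chromosome lag-1 differences")
    m = _MAD_CONSTANT * float(np.median(np.abs(diffs - np.median(diffs)))) / _SQRT2
    if m == 0.0:
        raise ValueError(
            "degenerate input (all lag-1 differences equal): scale is 0; "
            "supply m directly via TransformParams"
        )
    return m


def soft_threshold(x, p: TransformParams):
    """Apply the dead-zone rescaling to a scalar or array of log-ratios.

    Returns 0 inside ``[-tl*m, tg*m]``; ``(x - tg*m)/m`` above; and
    ``(x + tl*m)/m`` below.  NaN propagates.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = -p.tl * p.m, p.tg * p.m
    out = np.where(x > hi, (x - hi) / p.m, np.where(x < lo, (x - lo) / p.m, 0.0))
    out = np.where(np.isnan(x), np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def transform_matrix(
    mat: SegmentMatrix, params: Mapping[str, TransformParams] | TransformParams
) -> SegmentMatrix:
    """Soft-threshold every cell of a segment matrix, per-sample parameters.

    ``params`` maps each sample_id to its TransformParams (arrays have
    different noise scales); a single TransformParams applies to all
    samples.  Missing cells stay missing.
    """
    if isinstance(params, TransformParams):
        params = {s: params for s in mat.samples}
    absent = [s for s in mat.samples if s not in params]
    if absent:
        raise ValueError(f"no transform parameters for samples: {absent}")
    out = np.full(mat.shape, np.nan)
    for j, sample in enumerate(mat.samples):
        col = mat.values[:, j]
        out[:, j] = soft_threshold(col, params[sample])
    out[mat.missing] = np.nan
    return SegmentMatrix(mat.segments, mat.samples, out, mat.missing.copy())


def ternary_call(mat: SegmentMatrix) -> SegmentMatrix:
    """Sign of each transformed value: +1 gain, -1 loss, 0 no variation.

    Input should already be soft-thresholded; missing propagates.
    """
    calls = np.sign(mat.values)
    calls[mat.missing] = np.nan
    return SegmentMatrix(mat.segments, mat.samples, calls, mat.missing.copy())
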