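"""Most-likely-ratio (MLR) normalization of protein area matrices.

Loading and spray variation scale every area of an injection by a common
unknown factor.  Because most proteins do not change between conditions,
the distribution of per-protein log2 ratios between an injection and a
reference column piles up at the (log of the) loading factor, with
genuinely regulated proteins contributing off-mode tails.  The "most
likely ratio" is the mode of that distribution.

The mode is estimated with a Gaussian kernel density (Silverman
bandwidth) evaluated on a 512-point grid spanning [min - 1, max + 1] of
the observed log2 ratios; below ``min_shared`` shared proteins the mode
estimate is unreliable and the estimator falls back to the median,
flagging the fallback.  The default reference is a per-protein median
pseudo-sample, robust and symmetric across injections; a named injection
may be pinned instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .quantio import QuantMatrix

__all__ = ["MlrEstimate", "NormalizationResult", "log_ratios",
           "estimate_mlr_factor", "normalize_dataset", "GRID_SIZE"]

GRID_SIZE = 512
GRID_PAD = 1.0


class NormalizationError(ValueError):
    """A sample pair cannot be normalized (no shared proteins)."""


@dataclass(frozen=True)
class MlrEstimate:
    factor: float            # multiplicative scale, linear
    log2_factor: float
    n_shared: int            # proteins used for the estimate
    used_fallback: bool      # True when the median stood in for the mode
    grid_step: float         # resolution of the KDE grid (0 if degenerate)


def log_ratios(sample, reference) -> np.ndarray:
    """log2(sample / reference) over entries finite and positive in both.

    Zero areas cannot enter a log ratio; they are excluded (callers can
    compare ``len`` against the overlap to count exclusions).  Returns an
    empty array when nothing is shared.
    """
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != r.shape:
        raise ValueError("sample and reference must have equal length")
    ok = np.isfinite(s) & np.isfinite(r) & (s > 0) & (r > 0)
    return np.log2(s[ok] / r[ok])


def estimate_mlr_factor(sample, reference, min_shared: int = 50) -> MlrEstimate:
    """Estimate the multiplicative loading factor of ``sample`` relative
    to ``reference`` as 2**mode of the log2-ratio distribution."""
    ratios = log_ratios(sample, reference)
    n = len(ratios)
    if n == 0:
        raise NormalizationError(
            "no shared quantified proteins between sample and reference")
    if n < min_shared:
        m = float(np.median(ratios))
        return MlrEstimate(float(2.0 ** m), m, n, True, 0.0)
    lo, hi = ratios.min() - GRID_PAD, ratios.max() + GRID_PAD
    grid = np.linspace(lo, hi, GRID_SIZE)
    step = float(grid[1] - grid[0])
    # a (numerically) degenerate ratio distribution has an exact mode; the
    # KDE bandwidth would underflow and zero out the whole grid
    if np.ptp(ratios) < 1e-9:
        m = float(np.median(ratios))
        return MlrEstimate(float(2.0 ** m), m, n, False, step)
    kde = gaussian_kde(ratios, bw_method="silverman")
    density = kde(grid)
    if not np.isfinite(density).all() or density.max() <= 0:
        m = float(np.median(ratios))
        return MlrEstimate(float(2.0 ** m), m, n, True, step)
    m = float(grid[int(np.argmax(density))])
    return MlrEstimate(float(2.0 ** m), m, n, False, step)


@dataclass
class NormalizationResult:
    factors: pd.Series              # per sample_id, linear scale
    normalized: QuantMatrix         # input areas divided by the factors
    n_shared: pd.Series             # proteins shared with the reference
    used_fallback: pd.Series        # per sample, median fallback flag
    method_detail: dict


def normalize_dataset(matrix: QuantMatrix,
                      reference: str = "median_pseudo",
                      min_shared: int = 50) -> NormalizationResult:
    """Estimate one MLR factor per injection and divide it out.

    ``reference`` is either ``"median_pseudo"`` (per-protein median
    across all injections, ignoring missing values) or the sample_id of
    an injection to pin as reference; a pinned reference gets factor
    exactly 1.
    """
    if matrix.data.shape[1] < 2:
        raise NormalizationError("normalization needs at least 2 samples")
    if reference == "median_pseudo":
        ref_column = matrix.data.median(axis=1, skipna=True).to_numpy()
        pinned = None
    else:
        if reference not in matrix.data.columns:
            raise NormalizationError(
                f"reference sample {reference!r} not in matrix")
        ref_column = matrix.data[reference].to_numpy()
        pinned = reference

    factors, shared, fallback, steps = {}, {}, {}, {}
    for sample_id in matrix.data.columns:
        if pinned is not None and sample_id == pinned:
            est = MlrEstimate(1.0, 0.0, int(np.isfinite(ref_column).sum()),
                              False, 0.0)
        else:
            est = estimate_mlr_factor(matrix.data[sample_id].to_numpy(),
                                      ref_column, min_shared=min_shared)
        factors[sample_id] = est.factor
        shared[sample_id] = est.n_shared
        fallback[sample_id] = est.used_fallback
        steps[sample_id] = est.grid_step

    factor_series = pd.Series(factors, name="factor")
    normalized = matrix.copy()
    normalized.data = matrix.data.div(factor_series, axis=1)
    return NormalizationResult(
        factors=factor_series,
        normalized=normalized,
        n_shared=pd.Series(shared, name="n_shared"),
        used_fallback=pd.Series(fallback, name="used_fallback"),
        method_detail={"reference": reference, "grid_size": GRID_SIZE,
                       "grid_pad": GRID_PAD, "bandwidth": "silverman",
                       "min_shared": min_shared, "grid_step": steps},
    )
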