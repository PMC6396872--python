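"""Mono- versus biexponential model selection per voxel and per ROI.

Two complementary criteria decide whether the extra two parameters of the
biexponential model are warranted:

* the small-sample (second-order bias corrected) Akaike information
  criterion,

      AICc = 2k + n ln(SSE/n) + 2k(k+1)/(n-k-1),

  with n data points, k parameters, and SSE the residual sum of squares;
  the lower value wins, ties resolving to the monoexponential model
  (parsimony);

* the nested F-test,

      F = ((SSE_mono - SSE_bi)/SSE_bi) * (v_bi/(v_mono - v_bi)),  v = n - k,

  whose p-value comes from the F(2, n-5) distribution; the biexponential
  model is preferred when p < alpha (alpha = 0.05 by default).

The natural logarithm is used in AICc; both models share n, so the ranking
is independent of that convention and of any overall signal rescaling.
Voxels where either fit failed to converge are excluded from all
percentages rather than counted as monoexponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitResult, ParameterMaps

__all__ = [
    "aicc",
    "f_test",
    "SelectionResult",
    "select_fit_pair",
    "SelectionMaps",
    "select_voxels",
    "biexp_percentage",
    "slice_summary",
]

# RMS residual below 1e-12 of the signal scale counts as a perfect fit. On
# noise-free data both SSEs are rounding artifacts with arbitrary ratios;
# without the floor those ratios would decide the model, which is noise.
_PERFECT_FIT_RTOL = 1e-12


def _sse_floor(n: int, scale: float) -> float:
    return n * (_PERFECT_FIT_RTOL * scale) ** 2


def aicc(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion.

    A perfect fit (sse = 0) returns ``-inf`` as a sentinel: the model is
    preferred over any imperfect competitor.
    """
    n = int(n)
    k = int(k)
    if n - k - 1 < 1:
        raise ValueError(f"AICc needs n - k - 1 >= 1 (n={n}, k={k})")
    if sse < 0:
        raise ValueError("sse must be >= 0")
    if sse == 0:
        return float("-inf")
    return 2.0 * k + n * np.log(sse / n) + 2.0 * k * (k + 1) / (n - k - 1)


def f_test(sse_mono: float, sse_bi: float, n: int):
    """Nested F-test of the biexponential against the monoexponential fit.

    Numerator df is v_mono - v_bi = 2, denominator df is v_bi = n - 5. A
    biexponential SSE above the monoexponential one (a local-minimum
    artifact) clamps F to 0. Returns ``(f_stat, p_value)``.
    """
    n = int(n)
    if n < 7:
        raise ValueError("F-test needs n >= 7 so that v_bi = n - 5 >= 2")
    if sse_mono < 0 or sse_bi < 0:
        raise ValueError("sums of squares must be >= 0")
    df_num = 2
    df_den = n - 5
    if sse_bi == 0:
        if sse_mono == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = max(0.0, (sse_mono - sse_bi) / sse_bi * (df_den / df_num))
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return float(f_stat), p_value


@dataclass(frozen=True)
class SelectionResult:
    """Model-selection verdict for one decay curve."""

    aicc_mono: float
    aicc_bi: float
    f_stat: float
    p_value: float
    prefer_bi_aicc: bool
    prefer_bi_ftest: bool
    alpha: float


def select_fit_pair(mono: FitResult, bi: FitResult, alpha: float = 0.05) -> SelectionResult:
    """Apply both criteria to a fitted mono/bi pair on the same data."""
    if mono.n_points != bi.n_points:
        raise ValueError("mono and bi fits must share the data points")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = mono.n_points
    floor = _sse_floor(n, max(mono.scale, bi.scale))
    sse_mono = 0.0 if mono.sse <= floor else mono.sse
    sse_bi = 0.0 if bi.sse <= floor else bi.sse
    a_mono = aicc(sse_mono, n, mono.k_params)
    a_bi = aicc(sse_bi, n, bi.k_params)
    f_stat, p_value = f_test(sse_mono, sse_bi, n)
    return SelectionResult(
        aicc_mono=a_mono,
        aicc_bi=a_bi,
        f_stat=f_stat,
        p_value=p_value,
        prefer_bi_aicc=bool(a_bi < a_mono),
        prefer_bi_ftest=bool(p_value < alpha),
        alpha=alpha,
    )


@dataclass
class SelectionMaps:
    """Voxel-wise selection volumes.

    ``valid`` marks voxels where both fits converged; all other volumes are
    NaN (or False) outside it. ``prefer_bi_*`` are the binary decay-type
    maps (0 = mono, 1 = bi); ``fs_percent``/``fl_percent`` are the short/long
    component amplitude fractions from the biexponential fit.
    """

    aicc_mono: np.ndarray
    aicc_bi: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    prefer_bi_aicc: np.ndarray
    prefer_bi_ftest: np.ndarray
    fs_percent: np.ndarray
    fl_percent: np.ndarray
    valid: np.ndarray
    alpha: float


def select_voxels(
    maps_mono: ParameterMaps, maps_bi: ParameterMaps, alpha: float = 0.05
) -> SelectionMaps:
    """Run AICc and the F-test on aligned mono/bi parameter maps."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if maps_mono.mask.shape != maps_bi.mask.shape:
        raise ValueError("parameter maps are not aligned")
    if maps_mono.n_points != maps_bi.n_points:
        raise ValueError("mono and bi maps come from different echo counts")
    n = maps_mono.n_points
    valid = maps_mono.mask & maps_bi.mask & maps_mono.converged & maps_bi.converged
    shape = valid.shape
    out = {
        name: np.full(shape, np.nan)
        for name in ("aicc_mono", "aicc_bi", "f_stat", "p_value", "fs_percent", "fl_percent")
    }
    prefer_aicc = np.zeros(shape, dtype=bool)
    prefer_f = np.zeros(shape, dtype=bool)

    sse_m = maps_mono.maps["sse"][valid]
    sse_b = maps_bi.maps["sse"][valid]
    scale = np.maximum(maps_mono.maps["scale"][valid], maps_bi.maps["scale"][valid])
    floor = _sse_floor(n, scale)
    sse_m = np.where(sse_m <= floor, 0.0, sse_m)
    sse_b = np.where(sse_b <= floor, 0.0, sse_b)
    with np.errstate(divide="ignore"):
        pen_m = 2 * 3 + 2 * 3 * 4 / (n - 3 - 1)
        pen_b = 2 * 5 + 2 * 5 * 6 / (n - 5 - 1)
        a_m = np.where(sse_m > 0, n * np.log(np.maximum(sse_m, 1e-300) / n) + pen_m, -np.inf)
        a_b = np.where(sse_b > 0, n * np.log(np.maximum(sse_b, 1e-300) / n) + pen_b, -np.inf)
    df_den = n - 5
    with np.errstate(divide="ignore", invalid="ignore"):
        f_raw = (sse_m - sse_b) / sse_b * (df_den / 2.0)
    f_stat = np.where(sse_b > 0, np.maximum(f_raw, 0.0), np.where(sse_m > 0, np.inf, 0.0))
    p_val = stats.f.sf(f_stat, 2, df_den)

    out["aicc_mono"][valid] = a_m
    out["aicc_bi"][valid] = a_b
    out["f_stat"][valid] = f_stat
    out["p_value"][valid] = p_val
    prefer_aicc[valid] = a_b < a_m  # ties -> mono
    prefer_f[valid] = p_val < alpha

    b1 = maps_bi.maps["b1"][valid]
    b2 = maps_bi.maps["b2"][valid]
    total = b1 + b2
    with np.errstate(invalid="ignore", divide="ignore"):
        fs = np.where(total > 0, 100.0 * b1 / total, np.nan)
    out["fs_percent"][valid] = fs
    out["fl_percent"][valid] = 100.0 - fs

    return SelectionMaps(
        aicc_mono=out["aicc_mono"],
        aicc_bi=out["aicc_bi"],
        f_stat=out["f_stat"],
        p_value=out["p_value"],
        prefer_bi_aicc=prefer_aicc,
        prefer_bi_ftest=prefer_f,
        fs_percent=out["fs_percent"],
        fl_percent=out["fl_percent"],
        valid=valid,
        alpha=alpha,
    )


def biexp_percentage(flags: np.ndarray, valid: np.ndarray) -> float:
    """Percentage of valid voxels flagged biexponential."""
    valid = np.asarray(valid, dtype=bool)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid voxels to take a percentage over")
    return 100.0 * int(np.count_nonzero(np.asarray(flags, bool) & valid)) / n


def slice_summary(selection: SelectionMaps, slice_axis: int = 2) -> pd.DataFrame:
    """Per-slice table: n valid voxels and % biexponential by each criterion."""
    valid = np.moveaxis(selection.valid, slice_axis, 0)
    aicc_flags = np.moveaxis(selection.prefer_bi_aicc, slice_axis, 0)
    f_flags = np.moveaxis(selection.prefer_bi_ftest, slice_axis, 0)
    rows = []
    for idx in range(valid.shape[0]):
        n = int(valid[idx].sum())
        if n == 0:
            continue
        rows.append(
            {
                "slice": idx,
                "n_voxels": n,
                "pct_bi_aicc": biexp_percentage(aicc_flags[idx], valid[idx]),
                "pct_bi_ftest": biexp_percentage(f_flags[idx], valid[idx]),
            }
        )
    return pd.DataFrame(rows, columns=["slice", "n_voxels", "pct_bi_aicc", "pct_bi_ftest"])
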