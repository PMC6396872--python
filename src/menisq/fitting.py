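"""Constrained nonlinear least-squares fitting of the decay models.

Per voxel (or per ROI-averaged decay) both models are fitted by bounded
trust-region least squares with analytic Jacobians. Each fit runs from a
small set of starting points and keeps the lowest-SSE solution:

* monoexponential — a data-driven start (A1 from the first echo, T2* = 10 ms)
  plus a flat start (A1 = 0, offset = mean signal) that handles constant
  signals exactly;
* biexponential — the data-driven start (amplitudes split 50/50,
  T2*s/T2*l = 2/15 ms), a mono-seeded start (B1 = B2 = A1/2,
  T2*s = 0.2 T2*m), and an exact embedding of the mono solution
  (B1 = 0, B2 = A1, T2*l = T2*m). The embedding start makes the nesting
  guarantee sse_bi <= sse_mono hold by construction, since the solver never
  worsens its starting point.

Parameter standard errors are estimated from the Jacobian at the solution
and stored, but no filtering decision is taken from them. Non-converged
voxels (iteration-limit exits) are flagged and excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .decay_models import (
    BiParams,
    EchoSchedule,
    MonoParams,
    parameter_bounds,
)
from .nifti_io import EchoSeries

__all__ = [
    "FitResult",
    "ParameterMaps",
    "fit_mono",
    "fit_bi",
    "fit_volume",
    "mask_foreground",
    "MONO_MAP_NAMES",
    "BI_MAP_NAMES",
]

# positive floor for time constants inside the solver; reported bounds stay [0, ...]
_T2_FLOOR = 1e-6
_FTOL = 1e-10
_MAX_NFEV = 200
# solver amplitude cap as a multiple of the largest observed signal; guards the
# degenerate ridge where a sub-TE time constant drives an amplitude to infinity
_AMP_CAP_FACTOR = 10.0

MONO_MAP_NAMES = ("a1", "t2m_ms", "epsilon", "sse", "scale")
BI_MAP_NAMES = ("b1", "b2", "t2s_ms", "t2l_ms", "epsilon", "sse", "scale")


@dataclass
class FitResult:
    """One model fitted to one decay curve.

    ``scale`` is the largest absolute signal value of the fitted curve; model
    selection uses it to recognize numerically perfect fits (SSE at rounding
    level) and treat them as SSE = 0.
    """

    params: object
    sse: float
    n_points: int
    k_params: int
    converged: bool
    scale: float = 1.0
    param_se: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return self.n_points - self.k_params


@dataclass
class ParameterMaps:
    """Per-voxel parameter volumes for one model; NaN outside the mask."""

    model: str
    maps: dict
    mask: np.ndarray
    converged: np.ndarray
    n_points: int

    @property
    def k_params(self) -> int:
        return 3 if self.model == "mono" else 5


def _mono_resid(x, te, y):
    a1, t2, eps = x
    return a1 * np.exp(-te / t2) + eps - y


def _mono_jac(x, te, y):
    a1, t2, _ = x
    e = np.exp(-te / t2)
    jac = np.empty((te.size, 3))
    jac[:, 0] = e
    jac[:, 1] = a1 * te / t2**2 * e
    jac[:, 2] = 1.0
    return jac


def _bi_resid(x, te, y):
    b1, b2, t2s, t2l, eps = x
    return b1 * np.exp(-te / t2s) + b2 * np.exp(-te / t2l) + eps - y


def _bi_jac(x, te, y):
    b1, b2, t2s, t2l, _ = x
    es = np.exp(-te / t2s)
    el = np.exp(-te / t2l)
    jac = np.empty((te.size, 5))
    jac[:, 0] = es
    jac[:, 1] = el
    jac[:, 2] = b1 * te / t2s**2 * es
    jac[:, 3] = b2 * te / t2l**2 * el
    jac[:, 4] = 1.0
    return jac


def _solver_bounds(model: str, y=None):
    lower, upper = parameter_bounds(model)
    lower = lower.copy()
    upper = upper.copy()
    amp_cap = np.inf
    if y is not None:
        ymax = float(np.max(y))
        amp_cap = _AMP_CAP_FACTOR * ymax if ymax > 0 else 1.0
    if model == "mono":
        lower[1] = _T2_FLOOR
        upper[0] = amp_cap
    else:
        lower[2] = lower[3] = _T2_FLOOR
        upper[0] = upper[1] = amp_cap
    return lower, upper


def _param_se(jac: np.ndarray, sse: float, dof: int) -> np.ndarray:
    if dof <= 0:
        return np.full(jac.shape[1], np.nan)
    jtj = jac.T @ jac
    try:
        cov = np.linalg.inv(jtj) * (sse / dof)
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)
    diag = np.diag(cov)
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.where(diag >= 0, diag, np.nan))


def _run_starts(resid, jac, starts, bounds, te, y):
    lower, upper = bounds
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lower, upper)
        res = least_squares(
            resid,
            x0,
            jac=jac,
            bounds=(lower, upper),
            args=(te, y),
            method="trf",
            ftol=_FTOL,
            xtol=_FTOL,
            gtol=_FTOL,
            max_nfev=_MAX_NFEV,
        )
        sse = 2.0 * res.cost
        if best is None or sse < best[0]:
            best = (sse, res)
    return best


def _prepare(signal, schedule: EchoSchedule, min_points: int):
    y = np.asarray(signal, dtype=float).ravel()
    te = schedule.array
    if y.size != te.size:
        raise ValueError(
            f"signal has {y.size} points but schedule lists {te.size} echoes"
        )
    if y.size < min_points:
        raise ValueError(
            f"need at least {min_points} echoes for this model, got {y.size}"
        )
    return y, te


def fit_mono(signal, schedule: EchoSchedule, inits: MonoParams | None = None) -> FitResult:
    """Fit the 3-parameter monoexponential model to one decay curve."""
    y, te = _prepare(signal, schedule, 4)
    bounds = _solver_bounds("mono", y)
    if inits is not None:
        starts = [inits.as_array()]
    else:
        s0 = max(float(y[0]), 0.0)
        starts = [
            np.array([s0, 10.0, 0.0]),
            np.array([0.0, 10.0, float(np.mean(y))]),
        ]
    sse, res = _run_starts(_mono_resid, _mono_jac, starts, bounds, te, y)
    params = MonoParams(a1=res.x[0], t2star_ms=max(res.x[1], _T2_FLOOR), epsilon=res.x[2])
    return FitResult(
        params=params,
        sse=float(sse),
        n_points=y.size,
        k_params=3,
        converged=res.status > 0,
        scale=float(np.max(np.abs(y))),
        param_se=_param_se(res.jac, float(sse), y.size - 3),
    )


def fit_bi(
    signal,
    schedule: EchoSchedule,
    mono: FitResult | None = None,
    inits: BiParams | None = None,
) -> FitResult:
    """Fit the 5-parameter biexponential model to one decay curve.

    Restarts from the mono solution (computed here if not supplied) so that
    the returned SSE never exceeds the monoexponential one. The stored
    parameters are canonically ordered (short component first).
    """
    y, te = _prepare(signal, schedule, 6)
    if mono is None:
        mono = fit_mono(signal, schedule)
    a1m, t2m, epsm = mono.params.a1, mono.params.t2star_ms, mono.params.epsilon
    bounds = _solver_bounds("bi", y)
    s0 = max(float(y[0]), 0.0)
    starts = [
        np.array([s0 / 2, s0 / 2, 2.0, 15.0, 0.0]),
        np.array([a1m / 2, a1m / 2, 0.2 * t2m, t2m, epsm]),
        np.array([0.0, a1m, 2.0, t2m, epsm]),  # exact mono embedding
    ]
    if inits is not None:
        starts.insert(0, inits.as_array())
    sse, res = _run_starts(_bi_resid, _bi_jac, starts, bounds, te, y)
    b1, b2, t2s, t2l, eps = res.x
    params = BiParams(
        b1=b1,
        b2=b2,
        t2s_ms=max(t2s, _T2_FLOOR),
        t2l_ms=max(t2l, _T2_FLOOR),
        epsilon=eps,
    ).canonical()
    return FitResult(
        params=params,
        sse=float(sse),
        n_points=y.size,
        k_params=5,
        converged=res.status > 0,
        scale=float(np.max(np.abs(y))),
        param_se=_param_se(res.jac, float(sse), y.size - 5),
    )


def mask_foreground(
    series: EchoSeries, threshold_factor: float = 5.0, noise_sd: float | None = None
) -> np.ndarray:
    """Threshold the first echo against the background noise level.

    A voxel enters the mask iff its first-echo signal exceeds
    ``threshold_factor`` times the background noise SD. When ``noise_sd`` is
    not given it is estimated as the smallest SD over the eight corner
    patches of the first echo — at least one corner of a phantom or ex vivo
    FOV holds no tissue. A noise-free volume (SD 0) degenerates to a simple
    positivity mask.
    """
    first = series.first_echo
    if noise_sd is None:
        c = [max(1, min(8, n // 4)) if n > 1 else 1 for n in first.shape]
        sds = []
        for sx in (slice(None, c[0]), slice(-c[0], None)):
            for sy in (slice(None, c[1]), slice(-c[1], None)):
                for sz in (slice(None, c[2]), slice(-c[2], None)):
                    sds.append(float(first[sx, sy, sz].std()))
        noise_sd = min(sds)
    mask = first > threshold_factor * noise_sd
    if not mask.any():
        warnings.warn("foreground mask is empty", stacklevel=2)
    return mask


def fit_volume(series, schedule: EchoSchedule, mask: np.ndarray, model: str = "both"):
    """Fit one or both models to every masked voxel.

    Returns :class:`ParameterMaps` for ``model`` in {"mono", "bi"}, or a
    ``(mono_maps, bi_maps)`` tuple for ``"both"`` (the bi fit reuses each
    voxel's mono solution as a restart, which is also cheaper). Unmasked
    voxels carry NaN; the result is deterministic given its inputs.
    """
    data = series.data if isinstance(series, EchoSeries) else np.asarray(series, float)
    if data.ndim != 4:
        raise ValueError("series must be 4D")
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"series has {data.shape[3]} echoes but schedule lists {len(schedule)}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape does not match the series")
    if model not in {"mono", "bi", "both"}:
        raise ValueError(f"unknown model {model!r}")
    shape = data.shape[:3]

    def _empty(names):
        return {name: np.full(shape, np.nan) for name in names}

    mono_maps = _empty(MONO_MAP_NAMES)
    bi_maps = _empty(BI_MAP_NAMES)
    conv_mono = np.zeros(shape, dtype=bool)
    conv_bi = np.zeros(shape, dtype=bool)

    want_mono = model in {"mono", "both"}
    want_bi = model in {"bi", "both"}
    for i, j, k in np.argwhere(mask):
        y = data[i, j, k, :]
        m = fit_mono(y, schedule)
        if want_mono:
            p = m.params
            for name, value in zip(
                MONO_MAP_NAMES, (p.a1, p.t2star_ms, p.epsilon, m.sse, m.scale)
            ):
                mono_maps[name][i, j, k] = value
            conv_mono[i, j, k] = m.converged
        if want_bi:
            b = fit_bi(y, schedule, mono=m)
            p = b.params
            for name, value in zip(
                BI_MAP_NAMES, (p.b1, p.b2, p.t2s_ms, p.t2l_ms, p.epsilon, b.sse, b.scale)
            ):
                bi_maps[name][i, j, k] = value
            conv_bi[i, j, k] = b.converged

    mono_result = ParameterMaps("mono", mono_maps, mask, conv_mono, data.shape[3])
    bi_result = ParameterMaps("bi", bi_maps, mask, conv_bi, data.shape[3])
    if model == "mono":
        return mono_result
    if model == "bi":
        return bi_result
    return mono_result, bi_result
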