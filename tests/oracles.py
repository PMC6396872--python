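"""Brute-force fitting oracles, independent of the package's solver path.

Both oracles profile out the linear parameters (amplitudes and offset) on a
coarse grid over the time constants, then polish the best grid point with a
derivative-free Nelder-Mead search (bounds enforced by an infinite penalty).
They share no code with menisq.fitting.
"""

import numpy as np
from scipy.optimize import lsq_linear, minimize


def _linear_fit(design, y):
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _clip_mono(x):
    a1, t2, eps = x
    return max(a1, 0.0), min(max(t2, 1e-6), 200.0), eps


def _mono_sse(x, te, y):
    # projected objective: evaluate at the nearest feasible point, so the
    # polish can settle onto a bound exactly
    a1, t2, eps = _clip_mono(x)
    r = a1 * np.exp(-te / t2) + eps - y
    return float(r @ r)


def grid_polish_mono(y, te):
    """Coarse T2* grid + amplitude/offset linear solve + Nelder-Mead polish."""
    y = np.asarray(y, float)
    best = (np.inf, None)
    for t2 in np.geomspace(0.1, 200.0, 160):
        e = np.exp(-te / t2)
        design = np.column_stack([e, np.ones_like(te)])
        a1, eps = _linear_fit(design, y)
        if a1 < 0:
            a1, eps = 0.0, float(np.mean(y))
        sse = _mono_sse((a1, t2, eps), te, y)
        if sse < best[0]:
            best = (sse, np.array([a1, t2, eps]))
    res = minimize(
        _mono_sse, best[1], args=(te, y), method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14},
    )
    if res.fun <= best[0]:
        return res.fun, np.array(_clip_mono(res.x))
    return best[0], best[1]


def _bi_profile(t2s, t2l, te, y):
    """Exact bounded linear solve for (b1, b2, eps) at fixed time constants."""
    design = np.column_stack(
        [np.exp(-te / t2s), np.exp(-te / t2l), np.ones_like(te)]
    )
    res = lsq_linear(
        design, y, bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf])
    )
    r = design @ res.x - y
    return float(r @ r), res.x


def grid_polish_bi(y, te):
    """Profile-surface brute force for the biexponential model.

    The amplitudes and offset are linear, so they are profiled out exactly
    (bounded linear least squares) at every node of a fine (T2*s, T2*l)
    grid; the resulting smooth 2D profile surface is then polished by
    Nelder-Mead in log time-constant space from the best grid points. This
    sidesteps the knife-edge basins that defeat a direct 5-parameter search
    (e.g. a small long component at the 200 ms bound, nearly collinear with
    the offset).
    """
    y = np.asarray(y, float)

    def profile_obj(logx):
        t2s = float(np.clip(np.exp(logx[0]), 1e-6, 20.0))
        t2l = float(np.clip(np.exp(logx[1]), 1e-6, 200.0))
        return _bi_profile(t2s, t2l, te, y)[0]

    candidates = []
    for t2s in np.geomspace(0.08, 20.0, 45):
        for t2l in np.geomspace(0.2, 200.0, 45):
            if t2l <= t2s:
                continue
            sse, _ = _bi_profile(t2s, t2l, te, y)
            candidates.append((sse, t2s, t2l))
    candidates.sort(key=lambda c: c[0])
    # polish a diverse set: global top plus the best per t2l decade
    starts = candidates[:4]
    seen = set()
    for sse, t2s, t2l in candidates:
        key = int(np.floor(np.log10(t2l) * 3))
        if key not in seen:
            seen.add(key)
            starts.append((sse, t2s, t2l))
    best_sse, best_t2s, best_t2l = candidates[0]
    for _, t2s, t2l in starts:
        res = minimize(
            profile_obj,
            np.log([t2s, t2l]),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-14},
        )
        if res.fun < best_sse:
            best_sse = res.fun
            best_t2s = float(np.clip(np.exp(res.x[0]), 1e-6, 20.0))
            best_t2l = float(np.clip(np.exp(res.x[1]), 1e-6, 200.0))
    sse, coef = _bi_profile(best_t2s, best_t2l, te, y)
    x = np.array([coef[0], coef[1], best_t2s, best_t2l, coef[2]])
    return sse, x
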