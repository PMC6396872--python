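"""Nested signal-decay models for multi-echo gradient-echo relaxometry.

Two models describe the magnitude signal of a voxel as a function of echo
time TE (milliseconds):

* monoexponential (3 parameters)::

      S(TE) = A1 * exp(-TE / T2*) + eps

* biexponential (5 parameters)::

      S(TE) = B1 * exp(-TE / T2*s) + B2 * exp(-TE / T2*l) + eps

``A1`` is the extrapolated signal at TE = 0, ``eps`` a constant baseline
offset that absorbs the noise floor, and in the biexponential case the short
(``T2*s``) and long (``T2*l``) time constants are conventionally read as
bound- and free-water pools of fibrocartilage. The monoexponential model is
nested inside the biexponential one (set ``B2 = 0``), which is what makes
AICc ranking and the nested F-test meaningful downstream.

All time quantities are in milliseconds; signal amplitudes are in arbitrary
scanner units.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "EchoSchedule",
    "MonoParams",
    "BiParams",
    "eval_mono",
    "eval_bi",
    "default_inits",
    "parameter_bounds",
    "decode_params",
    "T2_SHORT_MAX_MS",
    "T2_LONG_MAX_MS",
    "MONO_PARAM_NAMES",
    "BI_PARAM_NAMES",
]

#: Upper fit bound for short-component time constants (ms).
T2_SHORT_MAX_MS = 20.0
#: Upper fit bound for long-component (and monoexponential) time constants (ms).
T2_LONG_MAX_MS = 200.0

MONO_PARAM_NAMES = ("a1", "t2star_ms", "epsilon")
BI_PARAM_NAMES = ("b1", "b2", "t2s_ms", "t2l_ms", "epsilon")


@dataclass(frozen=True)
class EchoSchedule:
    """Strictly increasing echo times in milliseconds.

    Any fit using a schedule needs more echoes than model parameters; that
    check lives in the fitting routines because it depends on the model.
    """

    te_ms: tuple

    def __post_init__(self):
        te = tuple(float(t) for t in self.te_ms)
        if len(te) == 0:
            raise ValueError("echo schedule is empty")
        if any(t <= 0 for t in te):
            raise ValueError("all echo times must be > 0 ms")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "te_ms", te)

    def __len__(self) -> int:
        return len(self.te_ms)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.te_ms, dtype=float)

    @classmethod
    def from_file(cls, path) -> "EchoSchedule":
        """Read a schedule from a JSON or YAML sidecar.

        Accepts either a bare list of echo times or a mapping with a
        ``te_ms`` key.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        if isinstance(payload, dict):
            payload = payload["te_ms"]
        return cls(tuple(payload))

    def to_file(self, path) -> None:
        path = Path(path)
        payload = {"te_ms": list(self.te_ms)}
        if path.suffix.lower() in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(payload))
        else:
            path.write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class MonoParams:
    """Parameters of the 3-parameter monoexponential model."""

    a1: float
    t2star_ms: float
    epsilon: float = 0.0

    def __post_init__(self):
        if self.t2star_ms <= 0:
            raise ValueError("t2star_ms must be > 0")
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.t2star_ms, self.epsilon], dtype=float)

    def to_dict(self) -> dict:
        return {"model": "mono", **asdict(self)}


@dataclass(frozen=True)
class BiParams:
    """Parameters of the 5-parameter biexponential model.

    The two components are exchangeable in the model expression; the
    canonical representation orders them so that ``t2s_ms <= t2l_ms``
    (apply :meth:`canonical` after fitting). The constructor deliberately
    does not enforce the ordering so that the swap-invariance of
    :func:`eval_bi` stays expressible.
    """

    b1: float
    b2: float
    t2s_ms: float
    t2l_ms: float
    epsilon: float = 0.0

    def __post_init__(self):
        if self.t2s_ms <= 0 or self.t2l_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("amplitudes must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.b1, self.b2, self.t2s_ms, self.t2l_ms, self.epsilon], dtype=float
        )

    @property
    def is_canonical(self) -> bool:
        return self.t2s_ms <= self.t2l_ms

    def canonical(self) -> "BiParams":
        """Return the representation with the short component first."""
        if self.is_canonical:
            return self
        return BiParams(self.b2, self.b1, self.t2l_ms, self.t2s_ms, self.epsilon)

    @property
    def short_fraction_percent(self) -> float:
        """Short-component amplitude fraction Fs = 100*B1/(B1+B2); NaN if both zero."""
        p = self.canonical()
        total = p.b1 + p.b2
        if total == 0:
            return float("nan")
        return 100.0 * p.b1 / total

    def to_dict(self) -> dict:
        return {"model": "bi", **asdict(self)}


def decode_params(payload: dict):
    """Rebuild a parameter set from its ``to_dict`` form (or JSON thereof)."""
    if isinstance(payload, str):
        payload = json.loads(payload)
    payload = dict(payload)
    model = payload.pop("model")
    if model == "mono":
        return MonoParams(**payload)
    if model == "bi":
        return BiParams(**payload)
    raise ValueError(f"unknown model {model!r}")


def _check_te(te):
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise ValueError("echo times must be >= 0")
    return te


def eval_mono(params: MonoParams, te):
    """Evaluate the monoexponential signal at echo time(s) ``te`` (ms)."""
    te = _check_te(te)
    return params.a1 * np.exp(-te / params.t2star_ms) + params.epsilon


def eval_bi(params: BiParams, te):
    """Evaluate the biexponential signal at echo time(s) ``te`` (ms)."""
    te = _check_te(te)
    return (
        params.b1 * np.exp(-te / params.t2s_ms)
        + params.b2 * np.exp(-te / params.t2l_ms)
        + params.epsilon
    )


def default_inits(model: str, first_echo_signal: float = 1.0):
    """Default starting values for the nonlinear fit.

    Time-constant starts are the literature values used throughout:
    T2* = 10 ms for the monoexponential model, (T2*s, T2*l) = (2, 15) ms for
    the biexponential one. Amplitudes start from the first-echo signal
    (split 50/50 between the two components); the offset starts at zero.
    """
    a = float(max(first_echo_signal, 0.0))
    if model == "mono":
        return MonoParams(a1=a, t2star_ms=10.0, epsilon=0.0)
    if model == "bi":
        return BiParams(b1=a / 2, b2=a / 2, t2s_ms=2.0, t2l_ms=15.0, epsilon=0.0)
    raise ValueError(f"unknown model {model!r}")


def parameter_bounds(model: str):
    """Box bounds (lower, upper) arrays in the model's parameter order.

    Time constants: short component capped at 20 ms, long component (and the
    monoexponential T2*) at 200 ms. Amplitudes are nonnegative and unbounded
    above; the offset is unbounded.
    """
    inf = np.inf
    if model == "mono":
        lower = np.array([0.0, 0.0, -inf])
        upper = np.array([inf, T2_LONG_MAX_MS, inf])
    elif model == "bi":
        lower = np.array([0.0, 0.0, 0.0, 0.0, -inf])
        upper = np.array([inf, inf, T2_SHORT_MAX_MS, T2_LONG_MAX_MS, inf])
    else:
        raise ValueError(f"unknown model {model!r}")
    return lower, upper
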