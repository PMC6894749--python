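"""Behavioural parameter vector for the feeding model.

One individual is described by eight parameters:

==========  ==========  =====================================================
name        units       role
==========  ==========  =====================================================
lambda_F    1/s         feeding-bout termination rate (mean bout = 1/lambda_F)
mu_F        g/s         mean within-bout feeding rate
sigma_F     g/s         spread of the per-bout feeding rate
lambda_S    1/s         short within-meal pause termination rate
T1          1/g         sharpness of the meal-termination sigmoid
T2          g           fullness at which meal termination reaches 50%
L1          s           fullness-independent intermeal-interval scale
L2          s/g         fullness-dependent intermeal-interval scale
==========  ==========  =====================================================

Group-level inference operates on a transformed scale: log10 for the six
strictly positive scale parameters, raw for T1 and T2 (which may take any
real value; a negative T1 inverts the fullness dependence of termination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

PARAM_NAMES: tuple[str, ...] = (
    "lambda_F", "mu_F", "sigma_F", "lambda_S", "T1", "T2", "L1", "L2",
)

#: True where the group-level model works on a log10 scale.
LOG10_MASK = np.array([True, True, True, True, False, False, True, True])

N_PARAMS = len(PARAM_NAMES)

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ModelParams:
    """One individual's behavioural parameter vector."""

    lambda_F: float
    mu_F: float
    sigma_F: float
    lambda_S: float
    T1: float
    T2: float
    L1: float
    L2: float

    def __post_init__(self) -> None:
        for name in ("lambda_F", "mu_F", "sigma_F", "lambda_S", "L1"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (np.isfinite(self.L2) and self.L2 >= 0):
            raise ValueError(f"L2 must be finite and >= 0, got {self.L2!r}")
        for name in ("T1", "T2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def tau_F(self) -> float:
        """Characteristic (mean) bout duration 1/lambda_F in seconds."""
        return 1.0 / self.lambda_F

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAMS,):
            raise ValueError(f"expected shape ({N_PARAMS},), got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr.tolist())))

    def to_transformed(self) -> np.ndarray:
        """Natural -> inference scale (log10 on the positive parameters)."""
        return transform(self.as_array())

    @classmethod
    def from_transformed(cls, arr: np.ndarray) -> "ModelParams":
        return cls.from_array(back_transform(np.asarray(arr, dtype=float)))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise ValueError(f"missing parameter fields: {missing}")
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})


def transform(theta: np.ndarray) -> np.ndarray:
    """Map a natural-scale parameter array to the inference scale."""
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    out[..., LOG10_MASK] = np.log10(theta[..., LOG10_MASK])
    return out


def back_transform(theta_t: np.ndarray) -> np.ndarray:
    """Inverse of :func:`transform` (exact round-trip)."""
    theta_t = np.asarray(theta_t, dtype=float)
    out = theta_t.copy()
    out[..., LOG10_MASK] = 10.0 ** theta_t[..., LOG10_MASK]
    return out


# A realistic "dark-period, ad-libitum" rat parametrisation used as the
# package-wide default study condition for simulations and tests: ~2 min
# bouts at ~0.3 g/min, 3-4 bouts per meal (~2 g meals), intermeal intervals
# of tens of minutes modulated by fullness.
DEFAULT_PARAMS = ModelParams(
    lambda_F=1.0 / 120.0,
    mu_F=0.005,
    sigma_F=0.0015,
    lambda_S=1.0 / 60.0,
    T1=4.0,
    T2=1.75,
    L1=600.0,
    L2=1100.0,
)
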