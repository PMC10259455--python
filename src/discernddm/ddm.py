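"""Four-parameter Wiener diffusion model.

The model runs on the log-transformed response-time axis (log-milliseconds):
``rt = t0 + decision_time`` where the decision time is the first-passage
time of a unit-diffusion Wiener process with drift ``v`` between absorbing
bounds ``0`` and ``a``, started at ``z * a``.  The upper bound codes the
veracity-promoting response, the lower bound the veracity-obstructing one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels

__all__ = [
    "DDMParams",
    "BoundaryOutcome",
    "wfpt_density",
    "trial_loglik",
    "choice_probability",
    "simulate_trial",
    "simulate_trials",
]

#: Euler step used by the simulator, on the decision-time axis.
SIM_DT = 5e-3


@dataclass(frozen=True)
class DDMParams:
    """Diffusion parameters: drift ``v``, bound separation ``a``,
    relative start ``z`` in (0, 1), non-decision time ``t0`` (>= 0)."""

    v: float
    a: float
    z: float
    t0: float

    def __post_init__(self) -> None:
        vals = (self.v, self.a, self.z, self.t0)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite DDM parameters: {self}")
        if self.a <= 0:
            raise ValueError(f"bound separation must be positive, got {self.a}")
        if not 0 < self.z < 1:
            raise ValueError(f"relative start must lie in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t0}")


@dataclass(frozen=True)
class BoundaryOutcome:
    """A single simulated decision: which bound absorbed and when."""

    upper: bool
    decision_time: float
    rt: float


def wfpt_density(t_dec: float, params: DDMParams, boundary: str = "upper") -> float:
    """Defective first-passage density at ``t_dec`` for the named boundary.

    The upper and lower defective densities jointly integrate to one.
    """
    if not np.isfinite(t_dec) or t_dec <= 0:
        raise ValueError(f"decision time must be positive and finite, got {t_dec}")
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return float(
        _kernels.wfpt_pdf(float(t_dec), params.v, params.a, params.z, boundary == "upper")
    )


def trial_loglik(choice: str, rt: float, params: DDMParams) -> float:
    """Log density of one (choice, rt) pair; ``-inf`` when ``rt <= t0``."""
    if not np.isfinite(rt):
        raise ValueError(f"rt must be finite, got {rt}")
    if choice not in ("upper", "lower"):
        raise ValueError(f"choice must be 'upper' or 'lower', got {choice!r}")
    return float(
        _kernels.wfpt_logpdf(float(rt) - params.t0, params.v, params.a, params.z, choice == "upper")
    )


def choice_probability(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary.

    ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``; equals ``z`` at ``v = 0``.
    """
    x = 2.0 * params.v * params.a
    z = params.z
    if abs(x) < 1e-8:  # series expansion avoids 0/0 at v = 0
        return float(z + x * z * (1.0 - z) / 2.0)
    return float(math.expm1(-x * z) / math.expm1(-x))


def simulate_trial(params: DDMParams, rng: np.random.Generator) -> BoundaryOutcome:
    """Draw one (boundary, rt) outcome from the diffusion process."""
    rt, up = simulate_trials(params, 1, rng)
    return BoundaryOutcome(upper=bool(up[0]), decision_time=float(rt[0]) - params.t0, rt=float(rt[0]))


def simulate_trials(params: DDMParams, n: int, rng: np.random.Generator):
    """Draw ``n`` outcomes; returns ``(rt, upper)`` arrays."""
    if n < 0:
        raise ValueError("n must be >= 0")
    seed = int(rng.integers(0, 2**31 - 1))
    return _kernels.simulate_trials(params.v, params.a, params.z, params.t0, int(n), SIM_DT, seed)
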