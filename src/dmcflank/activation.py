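"""Expected distractor activation and its drift-rate contribution.

The automatic (distractor-based) process contributes a time-varying mean
activation shaped as a rescaled gamma density,

    E[X_d](t) = A * exp(-t / tau) * (t * e / ((a - 1) * tau)) ** (a - 1),

which rises to a single maximum ``A`` at ``t_peak = (a - 1) * tau`` and then
decays toward zero.  Its time derivative is the drift-rate contribution of the
distractor; on congruent trials it pushes toward the correct boundary, on
incongruent trials its sign is flipped.
"""

from __future__ import annotations

import numpy as np

from .params import DMCParams

__all__ = [
    "automatic_activation_mean",
    "automatic_drift",
    "peak_time",
    "drift_grid",
    "CONGRUENT",
    "INCONGRUENT",
]

CONGRUENT = 1
INCONGRUENT = -1


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("automatic activation is defined for t > 0 only")
    return t


def automatic_activation_mean(t, params: DMCParams):
    """Expected distractor activation E[X_d](t) at time ``t`` (ms).

    Scalar in, scalar out; array in, array out.  Attains exactly ``A`` at
    ``t = (a_shape - 1) * tau``.
    """
    t = _check_t(t)
    a, tau, A = params.a_shape, params.tau, params.A
    out = A * np.exp(-t / tau) * (t * np.e / ((a - 1.0) * tau)) ** (a - 1.0)
    return out if out.ndim else float(out)


def automatic_drift(t, params: DMCParams, congruency: int = CONGRUENT):
    """Drift-rate contribution of the distractor at time ``t``.

    This is ``sign * d/dt E[X_d](t) = sign * E[X_d](t) * ((a-1)/t - 1/tau)``
    with ``sign = +1`` on congruent and ``-1`` on incongruent trials.  It is
    positive (toward the correct boundary) before the activation peak on
    congruent trials and vanishes exactly at the peak.
    """
    if congruency not in (CONGRUENT, INCONGRUENT):
        raise ValueError(f"congruency sign must be +1 or -1, got {congruency}")
    t = _check_t(t)
    a, tau = params.a_shape, params.tau
    e_xd = automatic_activation_mean(t, params)
    out = congruency * np.asarray(e_xd) * ((a - 1.0) / t - 1.0 / tau)
    return out if out.ndim else float(out)


def peak_time(params: DMCParams) -> float:
    """Time (ms) at which the distractor activation attains its maximum ``A``."""
    return (params.a_shape - 1.0) * params.tau


def drift_grid(params: DMCParams, congruency: int, dt: float, max_steps: int) -> np.ndarray:
    """Distractor drift evaluated at step midpoints ``(k + 0.5) * dt``.

    The Euler-Maruyama walk uses this per-step drift contribution; midpoints
    keep the first step inside the activation's domain (t > 0).
    """
    t = (np.arange(max_steps) + 0.5) * dt
    return np.asarray(automatic_drift(t, params, congruency), dtype=np.float64)
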