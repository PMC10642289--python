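"""Trial-level simulation of the conflict diffusion process.

Decision evidence follows an Euler-Maruyama discretization

    X(t + dt) = X(t) + [mu_t + sign * dE[X_d]/dt] * dt + sigma * sqrt(dt) * eps,

started from a symmetric-beta starting point in ``(-b, b)`` and absorbed at
``+b`` (correct) or ``-b`` (error).  RT = first-passage time + a nonnegative
normal residual.  Trials are flagged ``too_slow`` (RT above the deadline),
``too_fast`` (below the floor), or ``nonresponse`` (no absorption within the
decision-time horizon), mirroring the behavioral response window.

The per-trial walk is compiled with numba; the per-step normal increments are
drawn in blocks, which roughly doubles throughput over scalar draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .activation import CONGRUENT, INCONGRUENT, drift_grid
from .params import DMCParams, SimOptions

__all__ = [
    "simulate_trial",
    "simulate_condition",
    "sample_starting_point",
    "sample_residual",
    "simulate_decisions",
    "STATUS_OK",
    "STATUS_TOO_SLOW",
    "STATUS_TOO_FAST",
    "STATUS_NONRESPONSE",
    "CONGRUENCY_SIGN",
    "TRIAL_COLUMNS",
]

STATUS_OK = "ok"
STATUS_TOO_SLOW = "too_slow"
STATUS_TOO_FAST = "too_fast"
STATUS_NONRESPONSE = "nonresponse"

CONGRUENCY_SIGN = {"congruent": CONGRUENT, "incongruent": INCONGRUENT}

TRIAL_COLUMNS = ["participant", "proximity", "object", "congruency", "rt_ms", "accuracy", "status"]

_MAX_SEED = 2**31 - 1


@njit(cache=True, fastmath=True)
def _walk_batch(n, mu_t, auto_drift, b, sigma, alpha_s, dt, max_steps, seed):  # pragma: no cover
    np.random.seed(seed)
    dec_t = np.empty(n)
    correct = np.empty(n, np.int8)
    absorbed = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    chunk = 128
    buf = np.empty(chunk)
    for i in range(n):
        x = (2.0 * np.random.beta(alpha_s, alpha_s) - 1.0) * b
        done = False
        k = 0
        while k < max_steps and not done:
            m = min(chunk, max_steps - k)
            buf[:m] = np.random.standard_normal(m)
            for j in range(m):
                x += (mu_t + auto_drift[k]) * dt + sq * buf[j]
                k += 1
                if x >= b:
                    dec_t[i] = k * dt
                    correct[i] = 1
                    done = True
                    break
                elif x <= -b:
                    dec_t[i] = k * dt
                    correct[i] = 0
                    done = True
                    break
        absorbed[i] = done
        if not done:
            dec_t[i] = max_steps * dt
            correct[i] = 0
    return dec_t, correct, absorbed


@njit(cache=True, fastmath=True)
def _walk_batch_pool(n, mu_t, auto_drift, b, sigma, dt, max_steps, noise, z0, seed):  # pragma: no cover
    """Walk driven by a pre-generated noise pool indexed by (trial, step).

    Because draw consumption is path-independent, re-running with the same
    pool but different parameters yields a smooth objective (true common
    random numbers).  Trials outliving the pool's horizon continue with fresh
    per-trial draws (a vanishing fraction at these drifts).
    """
    np.random.seed(seed)
    dec_t = np.empty(n)
    correct = np.empty(n, np.int8)
    absorbed = np.empty(n, np.bool_)
    sq = sigma * np.sqrt(dt)
    pool_len = noise.shape[1]
    for i in range(n):
        x = z0[i] * b
        done = False
        for k in range(max_steps):
            eps = noise[i, k] if k < pool_len else np.random.standard_normal()
            x += (mu_t + auto_drift[k]) * dt + sq * eps
            if x >= b:
                dec_t[i] = (k + 1) * dt
                correct[i] = 1
                done = True
                break
            elif x <= -b:
                dec_t[i] = (k + 1) * dt
                correct[i] = 0
                done = True
                break
        absorbed[i] = done
        if not done:
            dec_t[i] = max_steps * dt
            correct[i] = 0
    return dec_t, correct, absorbed


def sample_starting_point(params: DMCParams, rng: np.random.Generator, size=None):
    """Draw starting point(s) from beta(alpha_s, alpha_s) rescaled to (-b, b)."""
    z = rng.beta(params.alpha_s, params.alpha_s, size=size)
    return (2.0 * z - 1.0) * params.b


def sample_residual(params: DMCParams, rng: np.random.Generator, size: int) -> np.ndarray:
    """Nonnegative residual times: Normal(mu_r, sigma_r) with negatives redrawn."""
    r = rng.normal(params.mu_r, params.sigma_r, size=size)
    bad = r < 0
    while bad.any():
        r[bad] = rng.normal(params.mu_r, params.sigma_r, size=int(bad.sum()))
        bad = r < 0
    return r


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_decisions(
    params: DMCParams,
    congruency_sign: int,
    n: int,
    options: SimOptions,
    rng,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` decision-stage walks.

    Returns ``(decision_time_ms, correct, absorbed)``; unabsorbed walks carry
    the horizon time and ``correct = 0`` but must be treated via ``absorbed``.
    """
    rng = _as_rng(rng)
    auto = drift_grid(params, congruency_sign, options.dt, options.max_steps)
    seed = int(rng.integers(_MAX_SEED))
    return _walk_batch(
        int(n),
        float(params.mu_t),
        auto,
        float(params.b),
        float(params.sigma),
        float(params.alpha_s),
        float(options.dt),
        int(options.max_steps),
        seed,
    )


def _status_from(rt: np.ndarray, absorbed: np.ndarray, options: SimOptions) -> np.ndarray:
    status = np.full(rt.shape, STATUS_OK, dtype=object)
    status[rt > options.deadline] = STATUS_TOO_SLOW
    status[rt < options.rt_floor] = STATUS_TOO_FAST
    status[~absorbed] = STATUS_NONRESPONSE
    return status


def simulate_trial(
    params: DMCParams,
    congruency: str,
    options: SimOptions = SimOptions(),
    rng=None,
) -> tuple[float, int, str]:
    """Simulate one trial; returns ``(rt_ms, accuracy, status)``.

    ``rt_ms`` is NaN for nonresponse trials (no boundary crossing within the
    decision horizon).
    """
    table = simulate_condition(params, congruency, 1, options, rng)
    row = table.iloc[0]
    return float(row["rt_ms"]), int(row["accuracy"]), str(row["status"])


def simulate_condition(
    params: DMCParams,
    congruency: str,
    n: int,
    options: SimOptions = SimOptions(),
    rng=None,
    participant=0,
    proximity: str = "near",
    object_membership: str = "same",
) -> pd.DataFrame:
    """Simulate ``n`` independent trials of one condition as a trial table.

    Deterministic for a fixed ``rng`` seed.  ``congruency`` is the string
    label ("congruent"/"incongruent"); the distractor drift sign follows it.
    """
    if congruency not in CONGRUENCY_SIGN:
        raise ValueError(f"unknown congruency {congruency!r}")
    rng = _as_rng(rng)
    n = int(n)
    if n == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    dec_t, correct, absorbed = simulate_decisions(
        params, CONGRUENCY_SIGN[congruency], n, options, rng
    )
    resid = sample_residual(params, rng, n)
    rt = dec_t + resid
    rt[~absorbed] = np.nan
    status = _status_from(rt, absorbed, options)
    return pd.DataFrame(
        {
            "participant": participant,
            "proximity": proximity,
            "object": object_membership,
            "congruency": congruency,
            "rt_ms": rt,
            "accuracy": correct.astype(np.int64),
            "status": status,
        }
    )
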