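"""Parameter containers for the Diffusion Model for Conflict tasks (DMC).

The DMC describes a single Wiener diffusion process whose drift is the
superposition of a constant target ("controlled") input ``mu_t`` and a
pulse-shaped distractor ("automatic") input that rises to a peak amplitude
``A`` at ``t_peak = (a_shape - 1) * tau`` and then decays to zero.  The
process starts from a beta-distributed point between the two decision
boundaries ``-b`` (error) and ``+b`` (correct); normally distributed residual
(nondecision) time with mean ``mu_r`` and SD ``sigma_r`` is added to the
first-passage time to form the response time.  All times are in ms, evidence
in arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["DMCParams", "SimOptions", "FIXED_SIGMA", "FIXED_ALPHA_S", "FIXED_A_SHAPE"]

# Conventional fixed constants for this model family.
FIXED_SIGMA = 4.0
FIXED_ALPHA_S = 3.0
FIXED_A_SHAPE = 2.0


@dataclass(frozen=True)
class DMCParams:
    """DMC parameters for a single experimental condition.

    Parameters
    ----------
    mu_t : float
        Target drift rate (evidence/ms).
    A : float
        Peak amplitude of distractor activation (evidence units).
    tau : float
        Scale of the gamma-shaped distractor activation (ms).
    b : float
        Correct decision boundary (evidence units); error boundary at ``-b``.
    mu_r, sigma_r : float
        Mean and SD of the normal residual (nondecision) time (ms).
    sigma : float
        Diffusion constant (evidence per sqrt(ms)); conventionally fixed to 4.
    alpha_s : float
        Shape of the symmetric beta starting-point distribution; fixed to 3.
    a_shape : float
        Shape of the gamma-shaped distractor activation; fixed to 2, for which
        ``t_peak = tau``.
    """

    mu_t: float
    A: float
    tau: float
    b: float
    mu_r: float
    sigma_r: float
    sigma: float = FIXED_SIGMA
    alpha_s: float = FIXED_ALPHA_S
    a_shape: float = FIXED_A_SHAPE

    def __post_init__(self) -> None:
        if not self.tau >= 1.0:
            raise ValueError(f"tau must be >= 1 ms, got {self.tau}")
        if not self.A >= 0.0:
            raise ValueError(f"A must be >= 0, got {self.A}")
        if not self.b > 0.0:
            raise ValueError(f"b must be > 0, got {self.b}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.mu_r >= 0.0:
            raise ValueError(f"mu_r must be >= 0 ms, got {self.mu_r}")
        if not self.sigma_r >= 0.0:
            raise ValueError(f"sigma_r must be >= 0 ms, got {self.sigma_r}")
        if not self.a_shape > 1.0:
            raise ValueError(f"a_shape must be > 1, got {self.a_shape}")
        if not self.alpha_s > 0.0:
            raise ValueError(f"alpha_s must be > 0, got {self.alpha_s}")

    def with_(self, **kwargs) -> "DMCParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimOptions:
    """Integration and response-window options for trial simulation.

    ``dt`` is the Euler-Maruyama step (ms); the decision stage is simulated up
    to ``t_max_decision``; total RTs above ``deadline`` are flagged too_slow
    and below ``rt_floor`` too_fast, mirroring the behavioral task's response
    window (2 s deadline, 150 ms floor).
    """

    dt: float = 1.0
    t_max_decision: float = 5000.0
    deadline: float = 2000.0
    rt_floor: float = 150.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.t_max_decision >= self.deadline:
            raise ValueError(
                f"t_max_decision ({self.t_max_decision}) must be >= deadline ({self.deadline})"
            )

    @property
    def max_steps(self) -> int:
        return int(round(self.t_max_decision / self.dt))
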