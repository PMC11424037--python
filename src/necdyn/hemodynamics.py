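"""Balloon-Windkessel hemodynamics and the FIR prior derived from it.

The nonlinear hemodynamic model maps neural activity to BOLD through four
states: vasodilatory signal s, blood inflow f, venous volume v and
deoxyhemoglobin content q.  Driven by a unit impulse it yields the canonical
hemodynamic response (rise peaking around 4-6 s, then undershoot), which,
sampled at the scan repetition time, gives a finite impulse response (FIR).

The observation model used for inference treats each region's hemodynamics as
an unknown FIR with a Gaussian prior N(mu_h, Sigma_h); that prior is
calibrated here by Monte-Carlo sampling of Balloon-Windkessel responses under
jittered physiological parameters.  The nominal parameter values and the 10%
independent Gaussian jitter of the sampling prior are implementation
constants, collected in :class:`BalloonParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BalloonParams",
    "HrfPrior",
    "balloon_windkessel_response",
    "sample_hrf_prior",
]


@dataclass(frozen=True)
class BalloonParams:
    """Balloon-Windkessel parameters (nominal values, standard parameterization).

    kappa : signal decay rate, 1/s
    gamma : autoregulatory feedback rate, 1/s
    tau   : mean transit time of the venous balloon, s
    alpha : vessel stiffness exponent (Grubb)
    rho   : resting oxygen extraction fraction
    V0    : resting venous blood volume fraction
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    rho: float = 0.32
    V0: float = 0.02

    def validate(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"non-physical Balloon-Windkessel parameter: "
                                 f"{name} = {getattr(self, name)}")


@dataclass
class HrfPrior:
    """Gaussian FIR prior: mean mu_h (length L) and covariance Sigma_h (L x L)."""

    mu_h: np.ndarray
    Sigma_h: np.ndarray
    TR: float

    def __post_init__(self) -> None:
        self.mu_h = np.asarray(self.mu_h, dtype=float)
        self.Sigma_h = np.asarray(self.Sigma_h, dtype=float)
        L = self.mu_h.size
        if L < 2:
            raise ValueError("FIR length must be >= 2")
        if self.Sigma_h.shape != (L, L):
            raise ValueError("Sigma_h shape inconsistent with mu_h")
        self.Sigma_h = (self.Sigma_h + self.Sigma_h.T) / 2.0

    @property
    def L(self) -> int:
        return self.mu_h.size


def _bw_rhs_batch(t, y, kappa, gamma, tau, alpha, rho):
    """Vectorized Balloon-Windkessel RHS for a batch of parameter draws."""
    m = kappa.size
    s, f, v, q = y.reshape(4, m)
    f = np.maximum(f, 1e-6)
    v = np.maximum(v, 1e-6)
    ds = -kappa * s - gamma * (f - 1.0)
    df = s
    vexp = v ** (1.0 / alpha)
    dv = (f - vexp) / tau
    E = 1.0 - (1.0 - rho) ** (1.0 / f)
    dq = (f * E / rho - vexp * q / v) / tau
    return np.concatenate([ds, df, dv, dq])


def _bold_signal(v, q, rho, V0):
    k1 = 7.0 * rho
    k2 = 2.0
    k3 = 2.0 * rho - 0.2
    return V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


def _batch_response(
    impulse_amplitude: float,
    kappa: np.ndarray,
    gamma: np.ndarray,
    tau: np.ndarray,
    alpha: np.ndarray,
    rho: np.ndarray,
    V0: np.ndarray,
    TR: float,
    L: int,
) -> np.ndarray:
    """Integrate a batch of impulse responses; returns (batch, L) FIRs."""
    m = kappa.size
    y0 = np.concatenate(
        [np.full(m, float(impulse_amplitude)), np.ones(m), np.ones(m), np.ones(m)]
    )
    t_eval = np.arange(L) * TR
    sol = solve_ivp(
        _bw_rhs_batch,
        (0.0, float(t_eval[-1])),
        y0,
        t_eval=t_eval,
        args=(kappa, gamma, tau, alpha, rho),
        method="RK45",
        rtol=1e-6,
        atol=1e-8,
        max_step=0.2,
    )
    if not sol.success:
        raise RuntimeError(f"hemodynamic ODE integration failed: {sol.message}")
    y = sol.y.reshape(4, m, L)
    v, q = y[2], y[3]
    return _bold_signal(v, q, rho[:, None], V0[:, None])


def balloon_windkessel_response(
    impulse_amplitude: float = 1.0,
    params: BalloonParams | None = None,
    TR: float = 1.0,
    L: int = 18,
) -> np.ndarray:
    """FIR of the Balloon-Windkessel model driven by a neural impulse.

    Integrates the 4-state hemodynamic ODE from rest with the vasodilatory
    signal kicked by ``impulse_amplitude`` and samples the BOLD output at TR
    for L samples.  A zero impulse returns an exactly zero FIR.
    """
    if L < 2:
        raise ValueError("FIR length must be >= 2")
    if params is None:
        params = BalloonParams()
    params.validate()
    if impulse_amplitude == 0.0:
        return np.zeros(L)
    one = np.ones(1)
    return _batch_response(
        impulse_amplitude,
        one * params.kappa,
        one * params.gamma,
        one * params.tau,
        one * params.alpha,
        one * params.rho,
        one * params.V0,
        TR,
        L,
    )[0]


def sample_hrf_prior(
    n_samples: int = 10_000,
    TR: float = 1.0,
    L: int = 18,
    seed: int | np.random.Generator | None = None,
    params: BalloonParams | None = None,
    jitter: float = 0.10,
) -> HrfPrior:
    """Monte-Carlo FIR prior: jitter the hemodynamic parameters, collect responses.

    Draws ``n_samples`` parameter sets with independent Gaussian jitter of
    ``jitter`` (fractional s.d.) around nominal values, integrates all impulse
    responses in one batched ODE solve, and returns the empirical mean and
    covariance of the sampled FIRs.
    """
    if n_samples < 100:
        raise ValueError("need at least 100 samples for a usable covariance")
    if params is None:
        params = BalloonParams()
    params.validate()
    rng = np.random.default_rng(seed)

    def draw(nominal: float) -> np.ndarray:
        vals = nominal * (1.0 + jitter * rng.standard_normal(n_samples))
        return np.clip(vals, 0.05 * nominal, None)  # keep parameters physical

    kappa = draw(params.kappa)
    gamma = draw(params.gamma)
    tau = draw(params.tau)
    alpha = draw(params.alpha)
    rho = draw(params.rho)
    V0 = np.full(n_samples, params.V0)
    firs = _batch_response(1.0, kappa, gamma, tau, alpha, rho, V0, TR, L)
    mu_h = firs.mean(axis=0)
    Sigma_h = np.cov(firs, rowvar=False)
    if float(np.trace(Sigma_h)) < 1e-30:
        warnings.warn("degenerate FIR prior: all sampled responses identical")
    return HrfPrior(mu_h=mu_h, Sigma_h=Sigma_h, TR=TR)
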