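"""Ground-truth generators and surrogate BOLD recordings.

Builds stable (possibly asymmetric) effective-connectivity matrices, simulates
the Ornstein-Uhlenbeck neural state exactly, convolves it with per-region
hemodynamic FIRs and adds diagonal observation noise -- i.e. the full forward
model the inference module inverts.  Because the generator's analytic
stationary statistics (Sigma, S) are known in closed form, it doubles as the
oracle in every recovery test.

The default study conditions emulate resting-state parcel data: a handful of
regions to a few dozen, TR of 1 s, fluctuations concentrated in the
0.01-0.1 Hz band, FIR length 18, observation noise around 10% of signal
variance, and a solenoidal coupling strength comparable to half the
dissipative diagonal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import linalg, signal

from .exceptions import DataError
from .hemodynamics import HrfPrior, sample_hrf_prior
from .model import (
    LinearModel,
    SteadyState,
    reconstruct_ec,
    solve_stationary_covariance,
    steady_state,
)

__all__ = [
    "BoldRecording",
    "GroundTruth",
    "random_stable_ec",
    "random_sparse_stable_ec",
    "simulate_ou",
    "generate_bold",
    "time_reverse",
    "synthesize_recording",
]


@dataclass
class BoldRecording:
    """Labeled multivariate time series sampled at period TR (seconds).

    Carrier for both empirical and synthetic data: ``data`` is time x node.
    """

    data: np.ndarray
    TR: float
    labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(f"data must be 2-D (time x node), got {self.data.ndim}-D")
        if self.data.shape[1] < 2:
            raise DataError("need at least 2 nodes")
        if not np.all(np.isfinite(self.data)):
            raise DataError("data contain non-finite values")
        self.TR = float(self.TR)
        if self.TR <= 0:
            raise DataError("TR must be positive")
        if self.labels is None:
            self.labels = [f"r{i:03d}" for i in range(self.n_nodes)]
        elif len(self.labels) != self.data.shape[1]:
            raise DataError(
                f"{len(self.labels)} labels for {self.data.shape[1]} columns"
            )

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    """Everything the generator knows: model, stationary stats, HRFs, noise, seed."""

    model: LinearModel
    steady_state: SteadyState
    hrfs: np.ndarray  # node x L
    obs_noise: np.ndarray  # per-node variance lambda_i
    seed: int | None


def random_stable_ec(
    n: int,
    asymmetry: float = 0.5,
    sparsity: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sigma2: float = 1.0,
    Sigma: np.ndarray | None = None,
) -> LinearModel:
    """Random stable EC with controlled solenoidal strength.

    Constructs a random correlation-like SPD covariance Sigma (unless one is
    supplied), a random skew-symmetric S scaled so ``max|S| = asymmetry`` with
    a ``sparsity`` fraction of off-diagonal pairs zeroed symmetrically, and
    returns the drift ``A = (-(sigma2/2) I + S) Sigma^{-1}``.  Stability is
    guaranteed by construction: this A satisfies the Lyapunov equation with
    the SPD Sigma, hence is Hurwitz.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    rng = np.random.default_rng(seed)
    if Sigma is None:
        W = rng.standard_normal((n, 2 * n))
        G = W @ W.T / (2 * n)
        d = np.sqrt(np.diag(G))
        Sigma = G / np.outer(d, d)  # correlation-like, unit diagonal
        Sigma += 0.05 * np.eye(n)  # keep it comfortably conditioned
    else:
        Sigma = np.asarray(Sigma, dtype=float)
    K = rng.standard_normal((n, n))
    S = (K - K.T) / 2.0
    if sparsity > 0:
        iu, ju = np.triu_indices(n, k=1)
        n_pairs = iu.size
        kill = rng.choice(n_pairs, size=int(round(sparsity * n_pairs)), replace=False)
        S[iu[kill], ju[kill]] = 0.0
        S[ju[kill], iu[kill]] = 0.0
    smax = np.max(np.abs(S))
    if asymmetry == 0.0 or smax == 0.0:
        S = np.zeros((n, n))
    else:
        S *= asymmetry / smax
    A = reconstruct_ec(Sigma, S, sigma2)
    return LinearModel(A=A, sigma2=sigma2)


def random_sparse_stable_ec(
    n: int,
    zero_fraction: float = 0.5,
    coupling_scale: float = 0.3,
    seed: int | np.random.Generator | None = None,
    sigma2: float = 1.0,
) -> LinearModel:
    """Stable EC with structurally zero off-diagonal couplings in A itself.

    Off-diagonal entries are zero with probability ``zero_fraction`` and
    otherwise drawn Gaussian with s.d. ``coupling_scale``; the diagonal is set
    below minus the row absolute sum (diagonal dominance), which guarantees
    stability.  Used as ground truth for sparsity-recovery tests, where the
    zeros must live in A (not in S).
    """
    if not 0.0 <= zero_fraction < 1.0:
        raise ValueError("zero_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    A = coupling_scale * rng.standard_normal((n, n))
    mask = rng.random((n, n)) < zero_fraction
    np.fill_diagonal(mask, False)
    A[mask] = 0.0
    np.fill_diagonal(A, 0.0)
    row_abs = np.abs(A).sum(axis=1)
    A[np.diag_indices(n)] = -(row_abs + 0.25 + 0.25 * rng.random(n))
    return LinearModel(A=A, sigma2=sigma2)


def simulate_ou(
    model: LinearModel,
    dt: float,
    n_steps: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Exact stationary simulation of the OU state, (n_steps, n) array.

    Uses the exact discretization ``x_{k+1} = e^{A dt} x_k + w_k`` with
    ``Cov(w_k) = Sigma - e^{A dt} Sigma e^{A dt}^T`` and the initial state
    drawn from the stationary law, so every sample path is stationary and the
    only approximation anywhere is Monte-Carlo error.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    n = model.n
    Sigma = solve_stationary_covariance(model)
    Ad = linalg.expm(model.A * dt)
    Qd = Sigma - Ad @ Sigma @ Ad.T
    Qd = (Qd + Qd.T) / 2.0
    try:
        Lq = np.linalg.cholesky(Qd)
    except np.linalg.LinAlgError:
        warnings.warn("process-noise covariance not PD; adding jitter")
        jit = 1e-12 * max(1.0, float(np.trace(Qd)) / n)
        Lq = np.linalg.cholesky(Qd + jit * np.eye(n))
    Ls = np.linalg.cholesky(Sigma)
    x = Ls @ rng.standard_normal(n)
    noise = rng.standard_normal((n_steps, n)) @ Lq.T
    out = np.empty((n_steps, n))
    AdT = Ad.T
    for k in range(n_steps):
        x = x @ AdT + noise[k]
        out[k] = x
    return out


def generate_bold(
    states: np.ndarray,
    hrfs: np.ndarray,
    obs_noise: np.ndarray | float,
    TR: float,
    labels: list[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> BoldRecording:
    """Region-wise FIR convolution of the neural state plus observation noise.

    ``y[k, i] = sum_l h_i[l] x[k - l, i] + e[k, i]`` with ``e ~ N(0, lambda_i)``;
    each region's BOLD depends only on its own state history.  The first L - 1
    samples (incomplete convolution support) are dropped.
    """
    states = np.asarray(states, dtype=float)
    hrfs = np.atleast_2d(np.asarray(hrfs, dtype=float))
    T, n = states.shape
    if hrfs.shape[0] == 1 and n > 1:
        hrfs = np.repeat(hrfs, n, axis=0)
    if hrfs.shape[0] != n:
        raise DataError(f"{hrfs.shape[0]} FIRs for {n} regions")
    L = hrfs.shape[1]
    if T < L:
        raise DataError(f"series length {T} shorter than FIR length {L}")
    lam = np.broadcast_to(np.asarray(obs_noise, dtype=float), (n,)).copy()
    if np.any(lam < 0):
        raise DataError("observation-noise variances must be >= 0")
    rng = np.random.default_rng(seed)
    y = np.empty((T, n))
    for i in range(n):
        y[:, i] = signal.lfilter(hrfs[i], [1.0], states[:, i])
    y = y[L - 1:]
    y = y + np.sqrt(lam) * rng.standard_normal(y.shape)
    return BoldRecording(data=y, TR=TR, labels=labels)


def time_reverse(recording: BoldRecording) -> BoldRecording:
    """Flip the recording in time (rows reversed); involutive."""
    return BoldRecording(
        data=recording.data[::-1].copy(), TR=recording.TR, labels=list(recording.labels)
    )


def synthesize_recording(
    n: int = 5,
    n_time: int = 4000,
    TR: float = 1.0,
    asymmetry: float = 0.5,
    sparsity: float = 0.0,
    sigma2: float = 1.0,
    L: int = 18,
    obs_noise_frac: float = 0.10,
    seed: int | None = None,
    hrf_prior: HrfPrior | None = None,
    model: LinearModel | None = None,
) -> tuple[BoldRecording, GroundTruth]:
    """End-to-end surrogate: ground-truth system -> OU states -> HRF -> noisy BOLD.

    Per-region FIRs are drawn from the Balloon-Windkessel prior; observation
    noise variance is ``obs_noise_frac`` of each region's noiseless BOLD
    variance.  Returns the recording together with the full ground truth.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = random_stable_ec(
            n, asymmetry=asymmetry, sparsity=sparsity, seed=rng, sigma2=sigma2
        )
    ss = steady_state(model)
    if hrf_prior is None:
        hrf_prior = sample_hrf_prior(n_samples=1000, TR=TR, L=L, seed=rng)
    Lh = np.linalg.cholesky(
        hrf_prior.Sigma_h + 1e-12 * np.eye(hrf_prior.L)
    )
    hrfs = hrf_prior.mu_h + rng.standard_normal((model.n, hrf_prior.L)) @ Lh.T
    states = simulate_ou(model, dt=TR, n_steps=n_time + hrf_prior.L - 1, seed=rng)
    clean = generate_bold(states, hrfs, 0.0, TR, seed=rng)
    lam = obs_noise_frac * clean.data.var(axis=0)
    noisy = clean.data + np.sqrt(lam) * rng.standard_normal(clean.data.shape)
    rec = BoldRecording(data=noisy, TR=TR, labels=list(model.labels))
    truth = GroundTruth(
        model=model,
        steady_state=ss,
        hrfs=hrfs,
        obs_noise=lam,
        seed=seed if isinstance(seed, int) else None,
    )
    return rec, truth
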