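"""Model inversion: closed-form OU baseline and sparse-DCM EM with FIR hemodynamics.

Two estimators, both scikit-learn style:

:class:`BaselineOU`
    Assumption-free closed-form estimator for *directly observed* states:
    lag-1 regression gives the discrete propagator, a principal matrix
    logarithm recovers the continuous drift.  Serves as the oracle against
    which the full inversion is validated.

:class:`SparseDCM`
    EM inversion of the discretized, linearized hemodynamic state-space
    model.  The latent neural state follows ``x_{k+1} = A_d x_k + w_k`` with
    ``A_d = I + TR * A`` (first-order discretization; an exact-exponential
    readout of the continuous drift is available as an option), each region's
    BOLD is its own state history filtered by an FIR with a Gaussian prior
    calibrated on Balloon-Windkessel responses, and observation noise is
    diagonal.  The E-step is a Kalman smoother on the lag-augmented state;
    M-steps are closed-form updates of A (per-entry zero-mean Gaussian prior
    with automatic-relevance-determination variances ``gamma``), the FIRs,
    the noise variances and the state-noise level.  Entries whose gamma
    collapses below a floor are pruned to exactly zero and frozen -- the
    sparse MAP estimate.

    The fit runs in two phases: a relevance-determination phase in which the
    gamma hyperparameters adapt and entries prune (objective logged in
    ``ard_trace_``), then an EM refinement phase with gamma and support
    frozen, whose penalized log-likelihood (``evidence_trace_``, normalized
    per observation) is non-decreasing by EM theory.  An optional symmetry
    constraint on A imposes time-reversible dynamics; the constrained M-step
    is solved exactly on the half-vectorized parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator

from .dynamics import bandpass
from .exceptions import DataError, InferenceError
from .hemodynamics import HrfPrior
from .kalman import filter_loglik, smooth_lagged_dcm, stationary_augmented_cov
from .model import LinearModel, SteadyState, compute_dccov, steady_state
from .synthetic import BoldRecording

__all__ = [
    "BaselineOU",
    "SparseDCM",
    "DcmFit",
    "fit_baseline_ou",
    "fit_sparse_dcm",
    "fit_sparse_dcm_symmetric",
    "postfit_steady_state",
    "one_step_prediction_error",
]


# ---------------------------------------------------------------------------
# closed-form baseline
# ---------------------------------------------------------------------------


class BaselineOU(BaseEstimator):
    """Closed-form OU estimator from directly observed states.

    ``Sigma0`` = sample covariance, ``Sigma1`` = lag-1 cross-covariance,
    ``A_d = Sigma1 Sigma0^{-1}``, ``A = logm(A_d)/dt``, and the differential
    cross-covariance follows as ``S = (A Sigma0 - Sigma0 A^T)/2``.

    Parameters
    ----------
    dt : float
        Sampling period of the state series, seconds.
    """

    def __init__(self, dt: float = 1.0):
        self.dt = dt

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < X.shape[1] + 2:
            raise DataError("states must be time x node with T > n + 1")
        T, n = X.shape
        X = X - X.mean(axis=0)
        Sigma0 = (X.T @ X) / (T - 1)
        Sigma1 = (X[1:].T @ X[:-1]) / (T - 1)
        Ad = linalg.solve(Sigma0, Sigma1.T, assume_a="pos").T
        eigs = np.linalg.eigvals(Ad)
        bad = (eigs.real <= 1e-12) & (np.abs(eigs.imag) <= 1e-9 * np.abs(eigs.real + 1e-30))
        near_zero = np.abs(eigs) <= 1e-12
        if np.any(bad | near_zero):
            raise InferenceError(
                "principal matrix logarithm undefined: the lag-1 propagator has "
                f"eigenvalues on the closed negative real axis ({eigs}); "
                "re-estimate with a shorter sampling period dt"
            )
        logAd = linalg.logm(Ad)
        if np.max(np.abs(np.imag(logAd))) > 1e-8 * max(1.0, np.max(np.abs(logAd))):
            raise InferenceError(
                "matrix logarithm has a significant imaginary part; "
                "the lag-1 propagator is outside the principal branch "
                "(consider a shorter sampling period dt)"
            )
        A = np.real(logAd) / self.dt
        Sigma0 = (Sigma0 + Sigma0.T) / 2.0
        S = (A @ Sigma0 - Sigma0 @ A.T) / 2.0
        S = (S - S.T) / 2.0
        np.fill_diagonal(S, 0.0)
        Sw = -(A @ Sigma0 + Sigma0 @ A.T)
        sigma2 = float(np.mean(np.diag(Sw)))
        self.A_ = A
        self.Sigma_ = Sigma0
        self.Precision_ = linalg.inv(Sigma0)
        self.S_ = S
        self.sigma2_ = max(sigma2, 1e-12)
        return self

    def to_model(self) -> LinearModel:
        return LinearModel(A=self.A_, sigma2=self.sigma2_)

    def to_steady_state(self) -> SteadyState:
        return SteadyState(Sigma=self.Sigma_, Precision=self.Precision_, S=self.S_)


def fit_baseline_ou(states: np.ndarray, dt: float) -> tuple[LinearModel, SteadyState]:
    """Functional wrapper around :class:`BaselineOU`."""
    est = BaselineOU(dt=dt).fit(states)
    return est.to_model(), est.to_steady_state()


# ---------------------------------------------------------------------------
# sparse DCM
# ---------------------------------------------------------------------------


@dataclass
class DcmFit:
    """Result bundle of a sparse-DCM inversion."""

    A_cont: np.ndarray
    sigma2: float
    hrfs: np.ndarray
    obs_noise: np.ndarray
    gamma: np.ndarray  # n x n ARD prior variances (0 = pruned entry)
    evidence_trace: np.ndarray
    converged: bool
    config_echo: dict[str, Any]
    Ad: np.ndarray
    q: float
    TR: float
    labels: list[str] = field(default_factory=list)
    stable: bool = True
    ard_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0


def _duplication_basis(n: int, active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Basis D (n^2 x p) and fixed part f for symmetric matrices on active pairs.

    Row-major vec convention.  Inactive (pruned) pairs are fixed at the
    identity values (A entry exactly zero).
    """
    cols = []
    f = np.eye(n).flatten()
    for i in range(n):
        for j in range(i, n):
            if not (active[i, j] or active[j, i]):
                continue
            col = np.zeros(n * n)
            col[i * n + j] = 1.0
            if i != j:
                col[j * n + i] = 1.0
            cols.append(col)
            f[i * n + j] = 0.0
            f[j * n + i] = 0.0
    D = np.array(cols).T if cols else np.zeros((n * n, 0))
    return D, f


class SparseDCM(BaseEstimator):
    """Sparse-DCM EM inversion of BOLD recordings (see module docstring).

    Parameters
    ----------
    tr : float
        Sampling period (TR), seconds; overridden by a BoldRecording input.
    hrf_prior : HrfPrior
        Gaussian FIR prior (mean, covariance, TR).  Required at fit time.
    symmetric : bool
        Constrain A to be symmetric (time-reversible dynamics).
    max_iter, tol : int, float
        EM stopping rule: relative change of the normalized evidence below
        ``tol``, or ``max_iter`` total iterations, whichever first.
    n_ard : int
        Iterations of the relevance-determination phase (gamma adaptation and
        pruning) before gamma is frozen; set 0 to disable the sparsity prior.
    ard_update : {"mackay", "em"}
        gamma fixed point: MacKay (``m^2 / (1 - v/gamma)``, fast pruning,
        default) or plain posterior second moment (``m^2 + v``).
    prune_tol : float
        Entries with gamma below this are pruned to exactly zero and frozen.
    gamma0 : float
        Initial ARD prior variance for every coupling.
    discretization : {"linear", "exact"}
        Map from the discrete propagator back to continuous time:
        ``(A_d - I)/TR`` or ``logm(A_d)/TR``.
    estimate_sigma2 : bool
        Update the state-noise level during EM (otherwise keep sigma2 = 1).
    hrf_prior_reg : float
        Ridge (fraction of mean prior variance) added to the FIR prior
        covariance, which is low-rank by construction.
    freeze_tol : float
        Riccati gain-freezing tolerance in the smoother; 0 = dense reference.
    band : tuple or None
        Band (Hz) for the band-passed lag-1 initialization regression.
    """

    def __init__(
        self,
        tr: float = 1.0,
        hrf_prior: HrfPrior | None = None,
        symmetric: bool = False,
        max_iter: int = 500,
        tol: float = 1e-6,
        n_ard: int = 30,
        ard_update: str = "mackay",
        prune_tol: float = 1e-12,
        gamma0: float = 1.0,
        discretization: str = "linear",
        estimate_sigma2: bool = True,
        hrf_prior_reg: float = 1e-4,
        freeze_tol: float = 1e-12,
        band: tuple[float, float] | None = (0.01, 0.1),
        ridge_init: float = 0.1,
    ):
        self.tr = tr
        self.hrf_prior = hrf_prior
        self.symmetric = symmetric
        self.max_iter = max_iter
        self.tol = tol
        self.n_ard = n_ard
        self.ard_update = ard_update
        self.prune_tol = prune_tol
        self.gamma0 = gamma0
        self.discretization = discretization
        self.estimate_sigma2 = estimate_sigma2
        self.hrf_prior_reg = hrf_prior_reg
        self.freeze_tol = freeze_tol
        self.band = band
        self.ridge_init = ridge_init

    # -- initialization -------------------------------------------------

    def _initialize(self, y: np.ndarray, TR: float, L: int):
        T, n = y.shape
        rec = BoldRecording(data=y, TR=TR)
        yb = y
        if self.band is not None:
            low, high = self.band
            if 0 < low < high < 0.5 / TR:
                yb = bandpass(rec, low, high).data
        Y0, Y1 = yb[:-1], yb[1:]
        G = Y0.T @ Y0
        alpha = self.ridge_init * np.trace(G) / n
        Ad0 = linalg.solve(G + alpha * np.eye(n), Y0.T @ Y1).T
        rho = float(np.max(np.abs(np.linalg.eigvals(Ad0))))
        if rho >= 0.98:
            Ad0 *= 0.95 / rho
        lam0 = 0.10 * y.var(axis=0)
        q0 = 1.0 * TR
        return Ad0, lam0, q0

    # -- M-step pieces ---------------------------------------------------

    def _update_A_rows(self, Sxx, Cx, q, gamma, active, TR):
        """Per-row MAP update of A_d with entrywise prior; returns means and vars of a."""
        n = Cx.shape[0]
        Ad = np.eye(n)  # pruned entries keep identity (A entry exactly 0)
        a_mean = np.zeros((n, n))
        a_var = np.zeros((n, n))
        eyen = np.eye(n)
        for i in range(n):
            J = np.flatnonzero(active[i])
            if J.size == 0:
                continue
            g = 1.0 / (gamma[i, J] * TR * TR)
            Prec = Sxx[np.ix_(J, J)] / q + np.diag(g)
            rhs = Cx[i, J] / q + g * eyen[i, J]
            cho = linalg.cho_factor(Prec, lower=True)
            mean = linalg.cho_solve(cho, rhs)
            cov_diag = np.diag(linalg.cho_solve(cho, np.eye(J.size)))
            Ad[i, J] = mean
            a_mean[i, J] = (mean - eyen[i, J]) / TR
            a_var[i, J] = cov_diag / (TR * TR)
        return Ad, a_mean, a_var

    def _update_A_symmetric(self, Sxx, Cx, q, gamma, active, TR):
        """Symmetric-constrained MAP update via half-vectorized normal equations."""
        n = Cx.shape[0]
        D, f = _duplication_basis(n, active)
        p = D.shape[1]
        if p == 0:
            eye = np.eye(n)
            return eye, np.zeros((n, n)), np.zeros((n, n))
        g = np.zeros_like(gamma)
        np.divide(1.0, gamma * TR * TR, out=g, where=active)
        g = g.flatten()
        # quadratic form in row-major vec(A_d)
        M = np.kron(np.eye(n), Sxx) / q + np.diag(g)
        r = Cx.flatten() / q + g * np.eye(n).flatten()
        Mn = D.T @ M @ D
        rn = D.T @ (r - M @ f)
        cho = linalg.cho_factor(Mn, lower=True)
        u = linalg.cho_solve(cho, rn)
        cov = linalg.cho_solve(cho, np.eye(p))
        vec = D @ u + f
        Ad = vec.reshape(n, n)
        Ad = (Ad + Ad.T) / 2.0
        a_mean = (Ad - np.eye(n)) / TR
        a_var = np.zeros((n, n))
        # scatter posterior variances back to entries (tied across the pair)
        idx = 0
        for i in range(n):
            for j in range(i, n):
                if not (active[i, j] or active[j, i]):
                    continue
                v = cov[idx, idx] / (TR * TR)
                a_var[i, j] = v
                a_var[j, i] = v
                idx += 1
        return Ad, a_mean, a_var

    # -- main loop -------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, BoldRecording):
            data = X.data
            TR = X.TR
            self.labels_ = list(X.labels)
        else:
            data = np.asarray(X, dtype=float)
            TR = float(self.tr)
            self.labels_ = [f"r{i:03d}" for i in range(data.shape[1])]
        if data.ndim != 2:
            raise DataError("BOLD data must be time x node")
        if not np.all(np.isfinite(data)):
            raise DataError("BOLD data contain non-finite values")
        prior = self.hrf_prior
        if prior is None:
            raise ValueError("an HrfPrior is required (see sample_hrf_prior)")
        L = prior.L
        T, n = data.shape
        if T < 10 * L:
            raise DataError(f"recording length {T} < 10 * FIR length {L}")
        yobs = data - data.mean(axis=0)

        mu_h = prior.mu_h
        Sig_h = prior.Sigma_h + self.hrf_prior_reg * (
            np.trace(prior.Sigma_h) / L
        ) * np.eye(L)
        cho_h = linalg.cho_factor(Sig_h, lower=True)
        logdet_h = 2.0 * float(np.sum(np.log(np.diag(cho_h[0]))))

        Ad, lam, q = self._initialize(yobs, TR, L)
        hrfs = np.tile(mu_h, (n, 1))
        gamma = np.full((n, n), float(self.gamma0))
        active = np.ones((n, n), dtype=bool)
        a_mean = (Ad - np.eye(n)) / TR
        a_var = np.zeros((n, n))

        P0 = stationary_augmented_cov(Ad, q, L)

        use_ard = self.n_ard > 0
        ard_trace: list[float] = []
        ev_trace: list[float] = []
        converged = False
        n_iter = 0
        lam_floor = 1e-10 * yobs.var(axis=0)

        def _log_priors():
            lp = 0.0
            if np.any(active):
                g = gamma[active]
                a = a_mean[active]
                lp += float(
                    np.sum(-0.5 * (np.log(2 * np.pi * g) + a * a / g))
                )
            resid = hrfs - mu_h
            sol = linalg.cho_solve(cho_h, resid.T)
            lp += -0.5 * (
                n * (L * np.log(2 * np.pi) + logdet_h)
                + float(np.sum(resid.T * sol))
            )
            return lp

        for it in range(self.max_iter):
            n_iter = it + 1
            stats = smooth_lagged_dcm(
                yobs, Ad, hrfs, lam, q, P0, freeze_tol=self.freeze_tol
            )
            obj = (stats.loglik + _log_priors()) / (T * n)
            in_ard = use_ard and it < self.n_ard
            if in_ard:
                ard_trace.append(obj)
            else:
                ev_trace.append(obj)
                if (
                    len(ev_trace) >= 2
                    and abs(ev_trace[-1] - ev_trace[-2])
                    < self.tol * max(1.0, abs(ev_trace[-1]))
                ):
                    converged = True
                    break

            # ---- M-step ----
            if self.symmetric:
                Ad, a_mean, a_var = self._update_A_symmetric(
                    stats.Sxx, stats.Cx, q, gamma, active, TR
                )
            else:
                Ad, a_mean, a_var = self._update_A_rows(
                    stats.Sxx, stats.Cx, q, gamma, active, TR
                )
            if self.estimate_sigma2:
                qn = (
                    float(np.trace(stats.Exx2))
                    - 2.0 * float(np.sum(Ad * stats.Cx))
                    + float(np.sum((Ad @ stats.Sxx) * Ad))
                ) / (n * (stats.T - 1))
                q = max(qn, 1e-12)
            for i in range(n):
                Prec = linalg.inv(Sig_h) + stats.Suu[i] / lam[i]
                rhs = linalg.cho_solve(cho_h, mu_h) + stats.suy[i] / lam[i]
                hrfs[i] = linalg.solve(Prec, rhs, assume_a="pos")
            lam_new = (
                stats.syy
                - 2.0 * np.einsum("il,il->i", hrfs, stats.suy)
                + np.einsum("il,ilm,im->i", hrfs, stats.Suu, hrfs)
            ) / stats.T
            lam = np.maximum(lam_new, lam_floor)

            if in_ard:
                m2 = a_mean**2
                if self.ard_update == "em":
                    gamma_new = m2 + a_var
                else:  # MacKay fixed point
                    denom = np.maximum(1.0 - a_var / np.maximum(gamma, 1e-300), 1e-12)
                    gamma_new = m2 / denom
                gamma = np.where(active, gamma_new, 0.0)
                pruned = active & (gamma < self.prune_tol)
                if self.symmetric:
                    pruned = pruned | pruned.T
                if np.any(pruned):
                    active[pruned] = False
                    gamma[pruned] = 0.0
                    Ad[pruned & ~np.eye(n, dtype=bool)] = 0.0
                    diag_pruned = pruned & np.eye(n, dtype=bool)
                    Ad[diag_pruned] = 1.0
                    a_mean[pruned] = 0.0

        # ---- continuous-time readout ----
        if self.discretization == "exact":
            eigs = np.linalg.eigvals(Ad)
            if np.any((eigs.real <= 0) & (np.abs(eigs.imag) < 1e-12)):
                raise InferenceError(
                    "exact discretization readout impossible: propagator has "
                    "eigenvalues on the closed negative real axis"
                )
            A_cont = np.real(linalg.logm(Ad)) / TR
            Sd = linalg.solve_discrete_lyapunov(Ad, q * np.eye(n))
            Sw = -(A_cont @ Sd + Sd @ A_cont.T)
            sigma2 = max(float(np.mean(np.diag(Sw))), 1e-12)
        else:
            A_cont = (Ad - np.eye(n)) / TR
            sigma2 = q / TR
        stable = bool(np.max(np.linalg.eigvals(A_cont).real) < 0)
        if not stable:
            warnings.warn("fitted A is not stable; downstream stationary "
                          "analyses will reject it")

        self.Ad_ = Ad
        self.A_ = A_cont
        self.sigma2_ = sigma2
        self.q_ = q
        self.hrfs_ = hrfs
        self.obs_noise_ = lam
        self.gamma_ = gamma
        self.active_ = active
        self.evidence_trace_ = np.array(ev_trace)
        self.ard_trace_ = np.array(ard_trace)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.stable_ = stable
        self.TR_ = TR
        self.P0_ = P0
        return self

    def to_fit(self) -> DcmFit:
        return DcmFit(
            A_cont=self.A_,
            sigma2=self.sigma2_,
            hrfs=self.hrfs_,
            obs_noise=self.obs_noise_,
            gamma=self.gamma_,
            evidence_trace=self.evidence_trace_,
            converged=self.converged_,
            config_echo=self.get_params(deep=False) | {"hrf_prior": "<HrfPrior>"},
            Ad=self.Ad_,
            q=self.q_,
            TR=self.TR_,
            labels=self.labels_,
            stable=self.stable_,
            ard_trace=self.ard_trace_,
            n_iter=self.n_iter_,
        )


def fit_sparse_dcm(
    recording: BoldRecording, prior: HrfPrior, config: dict | None = None
) -> DcmFit:
    """Fit the sparse DCM to a recording; ``config`` overrides estimator params."""
    est = SparseDCM(tr=recording.TR, hrf_prior=prior, **(config or {}))
    est.fit(recording)
    return est.to_fit()


def fit_sparse_dcm_symmetric(
    recording: BoldRecording, prior: HrfPrior, config: dict | None = None
) -> DcmFit:
    """Time-reversible variant: identical algorithm with A constrained symmetric."""
    cfg = dict(config or {})
    cfg["symmetric"] = True
    return fit_sparse_dcm(recording, prior, cfg)


def postfit_steady_state(fit: DcmFit) -> SteadyState:
    """Stationary covariance, precision and dC-Cov implied by a fitted model.

    Raises a stability error (no silent projection) when the fitted drift is
    not Hurwitz.
    """
    model = LinearModel(A=fit.A_cont, sigma2=fit.sigma2, labels=list(fit.labels) or None)
    return steady_state(model)


def dccov_of_fit(fit: DcmFit) -> np.ndarray:
    """Shorthand: the S matrix of a fit's stationary regime."""
    model = LinearModel(A=fit.A_cont, sigma2=fit.sigma2)
    from .model import solve_stationary_covariance

    return compute_dccov(model, solve_stationary_covariance(model))


def one_step_prediction_error(fit: DcmFit, recording: BoldRecording) -> float:
    """Mean squared one-step-ahead innovation of the fitted model on a recording."""
    yobs = recording.data - recording.data.mean(axis=0)
    L = fit.hrfs.shape[1]
    P0 = stationary_augmented_cov(fit.Ad, fit.q, L)
    _, innov = filter_loglik(
        yobs, fit.Ad, fit.hrfs, fit.obs_noise, fit.q, P0, return_innovations=True
    )
    return float(np.mean(innov**2))
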